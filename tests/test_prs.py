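"""PRS construction: parsing, allele alignment, clumping, scoring."""

import numpy as np
import pandas as pd
import pytest

from endopls import prs as prsmod
from endopls.prs import (SummaryStatsFormatError, align_alleles, clump,
                         compute_prs, read_summary_stats)

from conftest import make_geno, make_stats


class TestReadSummaryStats:
    def test_odds_ratio_one_becomes_beta_zero(self, tmp_path):
        f = tmp_path / "stats.txt"
        f.write_text("SNP A1 A2 OR P\nrs1 A G 1.0 0.5\nrs2 T C 2.0 0.01\n")
        st = read_summary_stats(f)
        assert st.table.loc[0, "beta"] == 0.0
        assert np.isclose(st.table.loc[1, "beta"], np.log(2.0))

    def test_rows_with_missing_p_dropped(self, tmp_path):
        f = tmp_path / "stats.txt"
        f.write_text("SNP A1 A2 BETA P\nrs1 A G 0.1 0.5\nrs2 T C 0.2 NA\nrs3 A C 0.3 0.9\n")
        st = read_summary_stats(f)
        assert len(st) == 2
        assert list(st.table["snp_id"]) == ["rs1", "rs3"]

    def test_column_map_equivalent_to_canonical_header(self, tmp_path):
        canonical = tmp_path / "canon.txt"
        canonical.write_text("SNP A1 A2 BETA P\nrs1 A G 0.4 0.01\nrs2 T C -0.2 0.2\n")
        odd = tmp_path / "odd.txt"
        odd.write_text("marker Allele1 Allele2 effect Pvalue\nrs1 A G 0.4 0.01\nrs2 T C -0.2 0.2\n")
        st1 = read_summary_stats(canonical)
        st2 = read_summary_stats(odd, column_map={
            "snp_id": "marker", "effect_allele": "Allele1",
            "other_allele": "Allele2", "beta": "effect", "p": "Pvalue"})
        pd.testing.assert_frame_equal(st1.table, st2.table)

    def test_missing_mandatory_column_named(self, tmp_path):
        f = tmp_path / "stats.txt"
        f.write_text("SNP A1 A2 BETA\nrs1 A G 0.1\n")
        with pytest.raises(SummaryStatsFormatError, match="p"):
            read_summary_stats(f)


class TestAlignAlleles:
    def test_flip_negates_beta(self):
        geno = make_geno([[0, 1]], alleles=[("A", "G"), ("T", "C")])
        stats = make_stats([0.4, 0.3], [0.01, 0.01],
                           alleles=[("G", "A"), ("T", "C")])
        out = align_alleles(stats, geno)
        assert np.isclose(out.table.loc[0, "beta"], -0.4)   # flipped
        assert np.isclose(out.table.loc[1, "beta"], 0.3)    # already aligned
        assert out.table.loc[0, "effect_allele"] == "A"

    def test_ambiguous_snps_removed(self):
        geno = make_geno([[1, 1]], alleles=[("A", "T"), ("C", "G")])
        stats = make_stats([0.4, 0.5], [0.01, 0.01],
                           alleles=[("A", "T"), ("C", "G")])
        out = align_alleles(stats, geno)
        assert len(out) == 0

    def test_irreconcilable_removed(self):
        geno = make_geno([[1]], alleles=[("A", "G")])
        stats = make_stats([0.4], [0.01], alleles=[("T", "C")])
        out = align_alleles(stats, geno)
        assert len(out) == 0

    def test_zero_overlap_raises(self):
        geno = make_geno([[1]])
        stats = make_stats([0.4], [0.01], snp_ids=["rsX"])
        with pytest.raises(ValueError, match="overlap"):
            align_alleles(stats, geno)


class TestComputePRS:
    def test_hand_worked_example(self):
        """3 SNPs, betas (0.5, -0.2, 0.1), p (0.01, 0.2, 0.04), thr 0.05:
        only SNPs 1 and 3 enter; dosages (2,1,0) -> 1.0, (0,1,2) -> 0.2."""
        geno = make_geno([[2, 1, 0], [0, 1, 2]])
        stats = make_stats([0.5, -0.2, 0.1], [0.01, 0.2, 0.04])
        vec = compute_prs(stats, geno, p_threshold=0.05)
        assert vec.n_snps_used == 2
        np.testing.assert_allclose(vec.score, [1.0, 0.2])

    def test_no_snp_passes_threshold(self):
        geno = make_geno([[2, 1], [0, 1]])
        stats = make_stats([0.5, -0.2], [0.5, 0.9])
        vec = compute_prs(stats, geno, p_threshold=0.05)
        assert vec.n_snps_used == 0
        np.testing.assert_array_equal(vec.score, 0.0)

    def test_linearity_in_beta(self, rng):
        dos = rng.integers(0, 3, size=(20, 8)).astype(float)
        geno = make_geno(dos)
        betas = rng.normal(size=8)
        ps = rng.uniform(0.001, 0.04, 8)
        v1 = compute_prs(make_stats(betas, ps), geno)
        v2 = compute_prs(make_stats(2 * betas, ps), geno)
        np.testing.assert_allclose(v2.score, 2 * v1.score, atol=1e-12)

    def test_additivity_over_disjoint_snp_sets(self, rng):
        dos = rng.integers(0, 3, size=(15, 6)).astype(float)
        geno = make_geno(dos)
        betas = rng.normal(size=6)
        ps = np.full(6, 0.01)
        full = compute_prs(make_stats(betas, ps), geno)
        a = compute_prs(make_stats(np.where(np.arange(6) < 3, betas, 0.0), ps), geno)
        b = compute_prs(make_stats(np.where(np.arange(6) >= 3, betas, 0.0), ps), geno)
        np.testing.assert_allclose(full.score, a.score + b.score, atol=1e-12)

    def test_invalid_threshold_raises(self):
        geno = make_geno([[1]])
        stats = make_stats([0.4], [0.01])
        with pytest.raises(ValueError):
            compute_prs(stats, geno, p_threshold=1.5)

    def test_allele_coding_invariance_after_centring(self, rng):
        """Flipping the counted allele (dosage -> 2 - dosage, metadata swapped)
        changes centred scores by < 1e-10."""
        dos = rng.integers(0, 3, size=(30, 10)).astype(float)
        geno = make_geno(dos)
        betas = rng.normal(size=10)
        ps = rng.uniform(0.001, 0.04, 10)
        stats = make_stats(betas, ps)

        flipped_geno = make_geno(2 - dos, alleles=[("G", "A")] * 10)
        s1 = compute_prs(align_alleles(stats, geno), geno).score
        s2 = compute_prs(align_alleles(stats, flipped_geno), flipped_geno).score
        np.testing.assert_allclose(s1 - s1.mean(), s2 - s2.mean(), atol=1e-10)


def _brute_force_clump(table, r2, window_bp, r2_max):
    """Independent re-statement of the greedy rule for the oracle."""
    order = table.sort_values(["p", "chrom", "pos", "snp_id"], kind="mergesort").index
    kept = []
    for idx in order:
        ok = True
        for k in kept:
            same_chrom = table.loc[k, "chrom"] == table.loc[idx, "chrom"]
            close = abs(table.loc[k, "pos"] - table.loc[idx, "pos"]) <= window_bp
            if same_chrom and close and r2[idx, k] > r2_max:
                ok = False
        if ok:
            kept.append(idx)
    return set(table.loc[kept, "snp_id"])


class TestClump:
    def test_uncorrelated_snps_all_kept(self, rng):
        dos = rng.integers(0, 3, size=(500, 5)).astype(float)
        geno = make_geno(dos)
        stats = make_stats(rng.normal(size=5), rng.uniform(0.001, 0.9, 5))
        out = clump(stats, geno, r2_max=0.5)
        assert len(out) == 5

    def test_perfect_ld_keeps_smaller_p(self):
        x = np.array([0, 1, 2, 0, 1, 2, 1, 1], dtype=float)
        geno = make_geno(np.column_stack([x, x]), positions=[1000, 2000])
        stats = make_stats([0.3, 0.2], [0.01, 0.02], positions=[1000, 2000])
        out = clump(stats, geno, r2_max=0.1)
        assert list(out.table["snp_id"]) == ["rs0"]

    def test_block_fixture_matches_brute_force_oracle(self, rng):
        # 20 SNPs in 4 LD blocks of 5 (shared latent causes high within-block r2)
        n = 400
        blocks = []
        for _ in range(4):
            base = rng.binomial(2, 0.4, n).astype(float)
            for _ in range(5):
                noise = rng.binomial(2, 0.4, n).astype(float)
                mix = np.where(rng.random(n) < 0.85, base, noise)
                blocks.append(mix)
        dos = np.column_stack(blocks)
        positions = list(range(1000, 21000, 1000))
        geno = make_geno(dos, positions=positions)
        stats = make_stats(rng.normal(size=20), rng.uniform(1e-4, 0.5, 20),
                           positions=positions)
        out = clump(stats, geno, r2_max=0.1, window_kb=250)

        r = np.corrcoef(dos, rowvar=False)
        expected = _brute_force_clump(stats.table, r * r, 250_000, 0.1)
        assert set(out.table["snp_id"]) == expected

    def test_invariant_to_input_row_order(self, rng):
        dos = rng.integers(0, 3, size=(200, 12)).astype(float)
        geno = make_geno(dos)
        stats = make_stats(rng.normal(size=12), rng.uniform(1e-4, 0.5, 12))
        shuffled = prsmod.SummaryStats(
            stats.table.sample(frac=1, random_state=1).reset_index(drop=True))
        out1 = clump(stats, geno, r2_max=0.2)
        out2 = clump(shuffled, geno, r2_max=0.2)
        assert set(out1.table["snp_id"]) == set(out2.table["snp_id"])

    def test_empty_input_empty_output(self):
        geno = make_geno(np.zeros((3, 0)))
        stats = make_stats([], [])
        assert len(clump(stats, geno)) == 0
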