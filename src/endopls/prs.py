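"""Polygenic risk scores from GWAS summary statistics and allele dosages.

A polygenic risk score (PRS) for subject *i* is the weighted allele count

    score_i = sum_j  beta_j * dosage_ij        over SNPs with p_j < threshold,

where ``beta_j`` is the per-effect-allele estimate from an external discovery
GWAS and ``dosage_ij`` in [0, 2] counts the effect allele.  The module covers
the standard bookkeeping around that sum: reading summary statistics, aligning
the reported effect allele with the allele counted in the dosage file
(negating beta where they disagree, dropping strand-ambiguous A/T and C/G
sites), optional greedy LD clumping, and scoring at a fixed p-value inclusion
threshold.

A single nominal threshold (default p = 0.05) is used rather than a threshold
scan: scanning thresholds against the target phenotype overfits and leaks the
phenotype into the genetic score, which is fatal when the score is then
correlated with brain measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STATS_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p"]

#: strand-ambiguous allele pairs — indistinguishable from their reverse complement
AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

DEFAULT_COLUMN_MAP = {
    "snp_id": ("SNP", "snp", "rsid", "ID"),
    "chrom": ("CHR", "chrom", "chromosome"),
    "pos": ("BP", "pos", "position"),
    "effect_allele": ("A1", "effect_allele", "EA"),
    "other_allele": ("A2", "other_allele", "OA", "NEA"),
    "beta": ("BETA", "beta", "b"),
    "odds_ratio": ("OR", "or"),
    "se": ("SE", "se"),
    "p": ("P", "p", "pval", "P_VALUE"),
}


class SummaryStatsFormatError(ValueError):
    """Raised when a summary-statistics file cannot be interpreted."""


@dataclass
class SummaryStats:
    """Per-SNP GWAS effects used to weight a PRS.

    ``table`` columns: snp_id, chrom, pos, effect_allele, other_allele,
    beta, se, p.  beta is on the per-effect-allele scale (log-odds for
    case/control traits).
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in STATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise SummaryStatsFormatError(f"summary stats missing columns: {missing}")
        if self.table["snp_id"].duplicated().any():
            raise SummaryStatsFormatError("duplicate snp_id in summary stats")
        p = self.table["p"].to_numpy(dtype=float)
        if len(p) and (np.any(p <= 0) or np.any(p > 1)):
            raise SummaryStatsFormatError("p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """Subject x SNP effect-allele dosages in [0, 2] with allele metadata.

    ``snps`` columns: snp_id, chrom, pos, counted_allele, other_allele.
    """

    subject_ids: np.ndarray
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.subject_ids), len(self.snps)):
            raise ValueError("dosage matrix shape does not match subject/SNP metadata")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in genotype matrix")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class PRSVector:
    """Per-subject polygenic score at a given inclusion threshold."""

    subject_ids: np.ndarray
    score: np.ndarray
    n_snps_used: int
    threshold: float
    trait: str = field(default="")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_ids, "score": self.score,
             "n_snps_used": self.n_snps_used}
        )

    def standardized(self) -> "PRSVector":
        """Mean-centred, unit-variance copy (population SD).

        Centring makes the score exactly invariant to which allele the
        dosage file counts (a flip shifts every subject by the constant
        2*beta), and standardization is harmless for correlation-based
        downstream analyses.
        """
        s = np.asarray(self.score, dtype=float)
        sd = s.std()
        if sd == 0:
            centred = s - s.mean()
        else:
            centred = (s - s.mean()) / sd
        return PRSVector(self.subject_ids, centred, self.n_snps_used, self.threshold, self.trait)


def read_summary_stats(path, column_map: dict | None = None) -> SummaryStats:
    """Read whitespace/tab-delimited GWAS summary statistics.

    ``column_map`` maps canonical names (``snp_id``, ``effect_allele``, ...,
    ``beta`` or ``odds_ratio``, ``p``) to the actual header names; unmapped
    fields fall back to common aliases (SNP/A1/A2/BETA/OR/P...).  OR columns
    are converted to beta = ln(OR).  Rows with missing beta or p are dropped
    and the count logged.
    """
    df = pd.read_csv(path, sep=r"\s+")
    column_map = dict(column_map or {})

    def resolve(canon, required=True):
        if canon in column_map:
            name = column_map[canon]
            if name not in df.columns:
                raise SummaryStatsFormatError(f"mapped column '{name}' for '{canon}' not in file")
            return name
        for alias in DEFAULT_COLUMN_MAP.get(canon, ()):
            if alias in df.columns:
                return alias
        if required:
            raise SummaryStatsFormatError(f"missing mandatory column for '{canon}'")
        return None

    out = pd.DataFrame()
    out["snp_id"] = df[resolve("snp_id")].astype(str)
    chrom = resolve("chrom", required=False)
    out["chrom"] = df[chrom].astype(str) if chrom else "0"
    pos = resolve("pos", required=False)
    out["pos"] = pd.to_numeric(df[pos], errors="coerce").astype("Int64") if pos else 0
    out["effect_allele"] = df[resolve("effect_allele")].astype(str).str.upper()
    out["other_allele"] = df[resolve("other_allele")].astype(str).str.upper()

    beta_col = resolve("beta", required=False)
    if beta_col is not None:
        out["beta"] = pd.to_numeric(df[beta_col], errors="coerce")
    else:
        or_col = resolve("odds_ratio", required=False)
        if or_col is None:
            raise SummaryStatsFormatError("missing mandatory column for 'beta' (or 'odds_ratio')")
        out["beta"] = np.log(pd.to_numeric(df[or_col], errors="coerce"))

    se_col = resolve("se", required=False)
    out["se"] = pd.to_numeric(df[se_col], errors="coerce") if se_col else np.nan

    p_raw = df[resolve("p")]
    p_num = pd.to_numeric(p_raw, errors="coerce")
    bad_p = p_num.isna() & p_raw.notna()
    for line in bad_p[bad_p].index:
        log.warning("non-numeric p-value at data line %d: %r", line + 2, p_raw[line])
    out["p"] = p_num

    keep = out["beta"].notna() & out["p"].notna()
    if (~keep).any():
        log.info("dropped %d/%d rows with missing beta or p", int((~keep).sum()), len(out))
    out = out[keep].reset_index(drop=True)
    return SummaryStats(out)


def align_alleles(stats: SummaryStats, geno: GenotypeMatrix) -> SummaryStats:
    """Align summary-statistic effect alleles with the counted dosage allele.

    Where the stats effect allele equals the genotype's *other* allele the
    beta is negated and the allele labels swapped; strand-ambiguous SNPs
    (A/T, C/G) and SNPs whose allele pairs cannot be reconciled are removed.
    Removal counts are logged.
    """
    merged = stats.table.merge(
        geno.snps[["snp_id", "counted_allele", "other_allele"]].rename(
            columns={"other_allele": "geno_other"}
        ),
        on="snp_id",
        how="inner",
    )
    if merged.empty:
        raise ValueError("no overlapping SNPs between summary stats and genotypes")

    pair = [frozenset((a, b)) for a, b in zip(merged["effect_allele"], merged["other_allele"])]
    ambiguous = np.array([p in AMBIGUOUS_PAIRS for p in pair])

    # ".raw"-style dosage tables only name the counted allele; an unknown
    # other allele ("N") is reconciled through the counted allele alone
    unknown = merged["geno_other"] == "N"
    same = (merged["effect_allele"] == merged["counted_allele"]) & (
        (merged["other_allele"] == merged["geno_other"]) | unknown
    )
    flipped = ~same & (
        ((merged["effect_allele"] == merged["geno_other"])
         & (merged["other_allele"] == merged["counted_allele"]))
        | (unknown & (merged["other_allele"] == merged["counted_allele"]))
    )
    irreconcilable = ~(same | flipped)

    log.info(
        "allele alignment: %d overlapping, %d ambiguous removed, %d flipped, %d irreconcilable removed",
        len(merged), int(ambiguous.sum()), int((flipped & ~ambiguous).sum()),
        int((irreconcilable & ~ambiguous).sum()),
    )

    keep = ~ambiguous & ~irreconcilable
    out = merged[keep].copy()
    flip = flipped[keep].to_numpy()
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out["effect_allele"] = out["counted_allele"]
    out["other_allele"] = out["geno_other"]
    out = out.drop(columns=["counted_allele", "geno_other"]).reset_index(drop=True)
    return SummaryStats(out)


def clump(stats: SummaryStats, geno: GenotypeMatrix,
          r2_max: float = 0.1, window_kb: float = 250.0) -> SummaryStats:
    """Greedy LD clumping: keep index SNPs by ascending p, drop neighbours.

    A SNP within ``window_kb`` of an already-kept SNP on the same chromosome
    is removed when its sample dosage r^2 with that SNP exceeds ``r2_max``.
    Ties are broken deterministically by (p, chrom, pos, snp_id).
    """
    tbl = stats.table
    if tbl.empty:
        return SummaryStats(tbl.copy())

    order = tbl.sort_values(
        ["p", "chrom", "pos", "snp_id"], kind="mergesort"
    ).index.to_numpy()
    col_of = {sid: j for j, sid in enumerate(geno.snps["snp_id"])}
    window_bp = window_kb * 1000.0

    kept: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for idx in order:
        row = tbl.loc[idx]
        sid = row["snp_id"]
        if sid not in col_of:
            continue
        pos, chrom = float(row["pos"]), row["chrom"]
        x = geno.dosages[:, col_of[sid]]
        ok = True
        for kidx in kept_by_chrom.get(chrom, ()):  # only same-chromosome LD
            krow = tbl.loc[kidx]
            if abs(float(krow["pos"]) - pos) > window_bp:
                continue
            y = geno.dosages[:, col_of[krow["snp_id"]]]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(idx)
            kept_by_chrom.setdefault(chrom, []).append(idx)

    out = tbl.loc[sorted(kept)].reset_index(drop=True)
    log.info("clumping kept %d/%d SNPs (r2 > %.3g within %.0f kb removed)",
             len(out), len(tbl), r2_max, window_kb)
    return SummaryStats(out)


def compute_prs(stats: SummaryStats, geno: GenotypeMatrix,
                p_threshold: float = 0.05, trait: str = "",
                standardize: bool = False) -> PRSVector:
    """Score subjects: sum of beta * dosage over SNPs with p < p_threshold.

    ``stats`` must already be allele-aligned to ``geno``.  Missing dosages
    contribute 0 to the sum; the missingness rate is logged.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError(f"p_threshold must lie in (0, 1], got {p_threshold}")
    tbl = stats.table[stats.table["p"] < p_threshold]
    col_of = {sid: j for j, sid in enumerate(geno.snps["snp_id"])}
    cols = [col_of[s] for s in tbl["snp_id"] if s in col_of]
    betas = tbl["beta"].to_numpy(dtype=float)[[s in col_of for s in tbl["snp_id"]]]

    if len(cols) == 0:
        score = np.zeros(geno.n_subjects)
    else:
        D = geno.dosages[:, cols]
        n_missing = int(np.isnan(D).sum())
        if n_missing:
            log.info("PRS: %d missing dosages (%.3g%%) contribute 0",
                     n_missing, 100.0 * n_missing / D.size)
            D = np.nan_to_num(D, nan=0.0)
        score = D @ betas

    out = PRSVector(geno.subject_ids, score, len(cols), p_threshold, trait)
    return out.standardized() if standardize else out
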