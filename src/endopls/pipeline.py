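"""End-to-end orchestration of the three-step analysis.

Step 1 — polygenic scores at the fixed p < 0.05 inclusion threshold,
pairwise correlations among (ADHD PRS, BMI PRS, impulsivity, BMI) with
one-sided permutation p-values and Holm correction, and Steiger's test that
the PRS-PRS correlation exceeds the phenotype-phenotype correlation.

Step 2 — sparse PLS of the 4-variable explanatory block against the
concatenated (VBM + MID) imaging block: stability-selected brain weights,
the per-subject neural endophenotype score, cross-validated association
strengths with permutation/Holm inference, and a cluster table.

Step 3 — bias-corrected bootstrapped mediation of the four
PRS -> endophenotype -> phenotype pathways.

All blocks are residualized on sex, site, age, TIV and eight genetic PCs
before Steps 1-2; Step 3 adjusts for the same covariates inside the path
regressions.  A run directory receives one TSV/JSON artifact per stage plus
a manifest with the seed and config hash, making every table reproducible
and each stage resumable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import config_hash, stream_rng
from . import cohort_prep as prep
from . import inference, mediation, prs as prsmod, spls as splsmod, synthdata

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Configuration for one pipeline run (synthetic or real-data mode)."""

    seed: int = 0
    out_dir: str = "run"
    generator: synthdata.GeneratorConfig | None = None
    data_paths: dict | None = None            # real-data mode: files per block
    spls: splsmod.SPLSConfig = field(default_factory=splsmod.SPLSConfig)
    p_threshold: float = 0.05
    clump: bool = False
    n_permutations_step1: int = 10_000
    n_boot: int = 10_000
    residualize_prs: bool = True
    apply_bmi_exclusion: bool = True

    def __post_init__(self):
        if (self.generator is None) == (self.data_paths is None):
            raise ValueError("exactly one of generator / data_paths must be set")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.to_jsonable()
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        sp = raw.pop("spls", None)
        kwargs = dict(raw)
        if gen is not None:
            if "target_corr" in gen:
                gen["target_corr"] = np.asarray(gen["target_corr"], float)
            for key in ("maf_range", "discovery_n", "grid_shape", "loading_signs",
                        "path_a", "path_b", "noise_sd"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            kwargs["generator"] = synthdata.GeneratorConfig(**gen)
        if sp is not None:
            kwargs["spls"] = splsmod.SPLSConfig(**sp)
        return cls(**kwargs)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _stage(manifest: dict, out: Path, name: str, fn):
    """Run one stage with a completion marker; errors abort naming the stage.

    The pipeline is deterministic under a fixed seed, so re-entry after a
    failure recomputes earlier stages bit-identically and resumes from the
    failed one with identical downstream outputs.
    """
    try:
        result = fn()
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise PipelineStageError(name, exc) from exc
    (out / f".done_{name}").write_text("ok\n")
    manifest["stages"].append(name)
    return result


def _load_inputs(cfg: RunConfig, out: Path):
    """Genotypes, stats, cohort (synthetic study or real files); imaging is
    loaded lazily by the sPLS stage."""
    if cfg.generator is not None:
        study = synthdata.simulate_study(cfg.generator)
        synthdata.write_cohort(study.cohort, out / "cohort.tsv")
        synthdata.write_truth(study.truth, out / "truth.json")
        return study.genotypes, study.summary_stats, study.cohort, study
    paths = cfg.data_paths
    geno = synthdata.read_genotypes_raw(paths["genotypes"])
    stats = {
        "adhd": prsmod.read_summary_stats(paths["stats_adhd"]),
        "bmi": prsmod.read_summary_stats(paths["stats_bmi"]),
    }
    cohort = prep.CohortTable(pd.read_csv(paths["cohort"], sep="\t"))
    return geno, stats, cohort, None


def _load_views(cfg: RunConfig, study) -> list[prep.ImagingView]:
    if study is not None:
        return [study.views["VBM"], study.views["MID"]]
    paths = cfg.data_paths
    return [
        synthdata.read_view(paths["vbm"], paths["vbm_coords"], "VBM"),
        synthdata.read_view(paths["mid"], paths["mid_coords"], "MID",
                            contrast="highwin-vs-nowin"),
    ]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the three analysis steps; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "config_hash": config_hash(cfg.to_jsonable()),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "stages": [],
    }

    state: dict = {}

    def stage_inputs():
        state["geno"], state["stats"], state["cohort"], state["study"] = _load_inputs(cfg, out)

    def stage_prs():
        geno, stats = state["geno"], state["stats"]
        scores = {}
        for trait in ("adhd", "bmi"):
            aligned = prsmod.align_alleles(stats[trait], geno)
            if cfg.clump:
                aligned = prsmod.clump(aligned, geno)
            scores[trait] = prsmod.compute_prs(
                aligned, geno, cfg.p_threshold, trait=trait, standardize=True)
        state["prs"] = scores
        both = scores["adhd"].to_frame().rename(columns={
            "score": "prs_adhd", "n_snps_used": "n_snps_adhd"})
        both["prs_bmi"] = scores["bmi"].score
        both["n_snps_bmi"] = scores["bmi"].n_snps_used
        _write_tsv(both, out / "prs.tsv")

    def _explanatory_block(cohort, prs_list, design):
        blocks = {
            "prs_adhd": prs_list[0].score,
            "prs_bmi": prs_list[1].score,
            "impulsivity": cohort.df["impulsivity"].to_numpy(float),
            "bmi": cohort.df["bmi"].to_numpy(float),
        }
        cols = []
        for name, col in blocks.items():
            if name.startswith("prs") and not cfg.residualize_prs:
                res = col - col.mean()
            else:
                res = prep.residualize(col, design)
            cols.append(prep.standardize(res)[0])
        return np.column_stack(cols)

    def stage_prep():
        # Step-1 sample: subjects with complete genetic + phenotype data
        cohort = state["cohort"]
        if cfg.apply_bmi_exclusion:
            cohort, report = prep.apply_bmi_exclusion(cohort)
        else:
            report = {}
        prs_list = [state["prs"]["adhd"], state["prs"]["bmi"]]
        cohort, prs_list, _, attrition = prep.intersect_complete(
            cohort, prs_list, [])
        design = prep.build_design(cohort)
        state.update(cohort1=cohort, prs_aligned=prs_list,
                     X1=_explanatory_block(cohort, prs_list, design),
                     exclusion_report=report)
        with open(out / "prep_report.json", "w") as fh:
            json.dump({"bmi_exclusion": report, "attrition_step1": attrition,
                       "n_step1": len(cohort)}, fh, indent=2)

    def stage_step1():
        X = state["X1"]
        data = pd.DataFrame(X, columns=list(splsmod.X_VARIABLES))
        cm = inference.correlation_matrix(
            data, n_permutations=cfg.n_permutations_step1, seed=cfg.seed)
        state["corr"] = cm
        r = cm.r
        R4 = r.copy()
        z, p_st = inference.steiger_test(r[0, 1], r[2, 3], R4, cm.n)
        cm.to_frame().to_csv(out / "step1_matrix.tsv", sep="\t",
                             float_format=FLOAT_FMT)
        rows = []
        for (a, b) in inference.DEFAULT_STEP1_FAMILY:
            i, j = cm.variables.index(a), cm.variables.index(b)
            rows.append({"var_a": a, "var_b": b, "r": r[i, j],
                         "p_perm": cm.p[i, j], "p_fwe": cm.p_fwe[i, j]})
        _write_tsv(pd.DataFrame(rows), out / "step1_correlations.tsv")
        with open(out / "step1_steiger.json", "w") as fh:
            json.dump({"z": z, "p_one_sided": p_st,
                       "r_prs": float(r[0, 1]), "r_phen": float(r[2, 3]),
                       "n": cm.n}, fh, indent=2)

    def stage_step2():
        # Step-2 sample: the subset of the Step-1 sample with imaging data
        views = _load_views(cfg, state["study"])
        cohort, prs_list, views, attrition = prep.intersect_complete(
            state["cohort1"], state["prs_aligned"], views)
        design = prep.build_design(cohort)
        X = _explanatory_block(cohort, prs_list, design)

        Y_parts, mods, coords = [], [], []
        for v in views:
            res = prep.residualize(v.features, design)
            z, keep = prep.standardize(res)
            # equal total variance per view before concatenation
            z = z / np.sqrt(z.shape[1])
            Y_parts.append(z)
            mods.append(np.repeat(v.modality, int(keep.sum())))
            coords.append(v.coords[keep])
        Y = np.hstack(Y_parts)
        state.update(cohort=cohort, design=design, X=X, Y=Y,
                     modality=np.concatenate(mods), coords=np.vstack(coords),
                     attrition_imaging=attrition)
        with open(out / "prep_report.json", "w") as fh:
            json.dump({"bmi_exclusion": state["exclusion_report"],
                       "attrition_imaging": attrition,
                       "n_analyzed": len(cohort),
                       "n_step1": len(state["cohort1"])}, fh, indent=2)

        rng = stream_rng(cfg.seed, "spls")
        fit = splsmod.stability_select(X, Y, cfg.spls, rng=rng)
        assoc, pooled = splsmod.cv_association(X, Y, cfg.spls, rng=rng)
        clusters = splsmod.report_clusters(fit.brain_weights, state["coords"],
                                           state["modality"])
        state["fit"], state["assoc"] = fit, assoc
        score = fit.scores
        sd = score.std()
        state["endo_score"] = (score - score.mean()) / sd if sd > 0 else score * 0.0

        weights = pd.DataFrame({
            "modality": state["modality"],
            "i": state["coords"][:, 0], "j": state["coords"][:, 1],
            "k": state["coords"][:, 2],
            "weight": fit.brain_weights,
            "selection_freq": fit.selection_freq,
        })
        _write_tsv(weights, out / "step2_weights.tsv")
        _write_tsv(assoc, out / "step2_associations.tsv")
        _write_tsv(clusters, out / "step2_clusters.tsv")
        scores_df = pd.DataFrame({
            "subject_id": state["cohort"].subject_ids,
            "endophenotype": state["endo_score"],
            "endophenotype_oos": pooled,
        })
        _write_tsv(scores_df, out / "step2_scores.tsv")

    def stage_step3():
        cohort = state["cohort"]
        design = state["design"]
        cov_cols = [c for c in design.columns if c != "intercept"]
        data = pd.DataFrame({
            "prs_adhd": state["X"][:, 0],
            "prs_bmi": state["X"][:, 1],
            "impulsivity": cohort.df["impulsivity"].to_numpy(float),
            "bmi": cohort.df["bmi"].to_numpy(float),
            "endophenotype": state["endo_score"],
        })
        for c in cov_cols:
            data[c] = design[c].to_numpy(float)
        table = mediation.run_all_pathways(
            data, covariate_cols=tuple(cov_cols),
            n_boot=cfg.n_boot, seed=cfg.seed)
        _write_tsv(table, out / "step3_mediation.tsv")
        state["mediation"] = table

    for name, fn in (("inputs", stage_inputs), ("prs", stage_prs),
                     ("prep", stage_prep), ("step1", stage_step1),
                     ("spls", stage_step2), ("mediation", stage_step3)):
        _stage(manifest, out, name, fn)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


REPORT_ARTIFACTS = ("correlation_matrix.png", "step1_correlations.tsv",
                    "step2_associations.tsv", "step2_clusters.tsv",
                    "step3_mediation.tsv")


def make_report(run_dir) -> list[Path]:
    """Figures + tables for a completed run: the correlation/significance
    matrix (r below the diagonal, FWE p above), association, cluster and
    mediation tables, and a weight-map montage."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    needed = ["step1_matrix.tsv", "step2_associations.tsv",
              "step2_clusters.tsv", "step3_mediation.tsv", "step2_weights.tsv"]
    missing = [f for f in needed if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing {missing}")

    mat = pd.read_csv(run_dir / "step1_matrix.tsv", sep="\t", index_col=0)
    rvals = mat.to_numpy(float)
    # validation: r entries below the diagonal must be mirror-consistent
    corr = pd.read_csv(run_dir / "step1_correlations.tsv", sep="\t")
    for row in corr.itertuples():
        i = list(mat.index).index(row.var_a)
        j = list(mat.index).index(row.var_b)
        lo = rvals[max(i, j), min(i, j)]
        if not np.isclose(lo, row.r, atol=1e-6):
            raise ValueError("correlation matrix inconsistent with pair table")

    k = len(mat)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    ax.imshow(np.isnan(rvals), cmap="Greys", vmin=0, vmax=4)
    for i in range(k):
        for j in range(k):
            if not np.isnan(rvals[i, j]):
                txt = f"r={rvals[i, j]:.2f}" if i > j else f"p={rvals[i, j]:.3g}"
                ax.text(j, i, txt, ha="center", va="center", fontsize=8)
    ax.set_xticks(range(k), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(k), mat.index)
    ax.set_title("correlations (lower) / FWE p (upper)")
    fig.tight_layout()
    fig.savefig(run_dir / "correlation_matrix.png", dpi=120)
    plt.close(fig)

    weights = pd.read_csv(run_dir / "step2_weights.tsv", sep="\t")
    mods = weights["modality"].unique()
    fig, axes = plt.subplots(1, max(len(mods), 1), figsize=(4 * len(mods), 3.5))
    axes = np.atleast_1d(axes)
    for ax, mod in zip(axes, mods):
        sub = weights[weights["modality"] == mod]
        shape = tuple(sub[["i", "j", "k"]].max() + 1)
        vol = np.zeros(shape)
        vol[sub["i"], sub["j"], sub["k"]] = sub["weight"]
        ax.imshow(vol[:, :, shape[2] // 2], cmap="coolwarm",
                  vmin=-np.abs(vol).max() or -1, vmax=np.abs(vol).max() or 1)
        ax.set_title(f"{mod} weights (mid-slice)")
    fig.tight_layout()
    fig.savefig(run_dir / "weight_maps.png", dpi=120)
    plt.close(fig)

    return [run_dir / a for a in REPORT_ARTIFACTS] + [run_dir / "weight_maps.png"]
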