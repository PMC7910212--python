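"""Cohort assembly: inclusion filters, block alignment, covariate residualization.

Every downstream model (correlations, sparse PLS, mediation) operates on
blocks that have been adjusted for the same nuisance covariates: sex, imaging
site, age, total intracranial volume and the first eight genetic principal
components.  Adjustment is ordinary least-squares residualization against a
full-rank design built from those covariates (categoricals expanded to
indicator contrasts, intercept always included), so the Pearson correlation
between two residualized variables is their partial correlation given the
covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import as_2d

log = logging.getLogger(__name__)

COHORT_COLUMNS = ["subject_id", "impulsivity", "bmi", "sex", "site", "age", "tiv"] + [
    f"pc{i}" for i in range(1, 9)
]

#: inclusion bounds for BMI (kg/m^2); strict inequalities, boundary retained
BMI_UNDERWEIGHT = 18.5
BMI_EXTREME = 50.0

DEFAULT_COVARIATES = ("sex", "site", "age", "tiv") + tuple(f"pc{i}" for i in range(1, 9))


class SchemaError(ValueError):
    pass


@dataclass
class CohortTable:
    """Phenotypes (impulsivity, BMI) plus covariates, one row per subject."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COHORT_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"cohort table missing columns: {missing}")
        if self.df["subject_id"].duplicated().any():
            raise SchemaError("duplicate subject_id in cohort table")
        bmi = self.df["bmi"].to_numpy(dtype=float)
        if len(bmi) and np.nanmin(bmi) <= 0:
            raise SchemaError("bmi must be positive")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["subject_id"].to_numpy()


@dataclass
class ImagingView:
    """Subject x feature matrix on a voxel lattice (one modality)."""

    subject_ids: np.ndarray
    features: np.ndarray          # (n_subjects, n_features)
    coords: np.ndarray            # (n_features, 3) integer voxel indices
    modality: str                 # "VBM" or "MID"
    contrast: str = field(default="")

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        self.features = np.asarray(self.features, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.features.shape[0] != len(self.subject_ids):
            raise ValueError("feature rows do not align with subject_ids")
        if self.features.shape[1] != len(self.coords):
            raise ValueError("feature columns do not align with coordinates")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("duplicate voxel coordinates")

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def apply_bmi_exclusion(cohort: CohortTable) -> tuple[CohortTable, dict]:
    """Remove underweight (BMI < 18.5) and extremely overweight (BMI > 50) rows.

    Boundary values are retained (strict inequalities).  Returns the filtered
    table and a report with per-rule counts.
    """
    if "bmi" not in cohort.df.columns:
        raise SchemaError("cohort table has no 'bmi' column")
    bmi = cohort.df["bmi"].to_numpy(dtype=float)
    under = bmi < BMI_UNDERWEIGHT
    extreme = bmi > BMI_EXTREME
    report = {
        "underweight": int(under.sum()),
        "extreme": int(extreme.sum()),
        "excluded": int((under | extreme).sum()),
        "retained": int((~(under | extreme)).sum()),
    }
    log.info("BMI exclusion: %s", report)
    kept = cohort.df[~(under | extreme)].reset_index(drop=True)
    return CohortTable(kept), report


def intersect_complete(
    cohort: CohortTable,
    prs_list: list,
    views: list[ImagingView],
) -> tuple[CohortTable, list, list[ImagingView], dict]:
    """Align all blocks on the common subjects, in one canonical (sorted) order.

    Returns re-indexed copies of every block plus an attrition log counting
    subjects each block lacked relative to the union.
    """
    id_sets = {"cohort": set(cohort.subject_ids)}
    for prs in prs_list:
        id_sets[f"prs_{prs.trait or id(prs)}"] = set(np.asarray(prs.subject_ids))
    for v in views:
        id_sets[f"imaging_{v.modality}"] = set(np.asarray(v.subject_ids))

    common = set.intersection(*id_sets.values())
    if not common:
        raise ValueError("empty subject intersection across blocks")
    union = set.union(*id_sets.values())
    attrition = {name: len(union - ids) for name, ids in id_sets.items() if union - ids}
    if attrition:
        log.info("block attrition vs union of %d ids: %s", len(union), attrition)

    order = sorted(common)

    def reindex(ids, matrix):
        lookup = {s: i for i, s in enumerate(np.asarray(ids))}
        rows = [lookup[s] for s in order]
        return np.asarray(matrix)[rows]

    cohort_out = CohortTable(
        cohort.df.set_index("subject_id").loc[order].reset_index()
    )
    prs_out = []
    for prs in prs_list:
        new = type(prs)(
            np.asarray(order), reindex(prs.subject_ids, prs.score),
            prs.n_snps_used, prs.threshold, prs.trait,
        )
        prs_out.append(new)
    views_out = [
        ImagingView(np.asarray(order), reindex(v.subject_ids, v.features),
                    v.coords, v.modality, v.contrast)
        for v in views
    ]
    return cohort_out, prs_out, views_out, attrition


def build_design(cohort: CohortTable,
                 covariates: tuple[str, ...] = DEFAULT_COVARIATES) -> pd.DataFrame:
    """Covariate design matrix: intercept + indicator contrasts + numerics.

    Categorical covariates (sex, site) are expanded to drop-first indicator
    columns; numeric covariates enter as-is.  Raises on rank deficiency,
    naming the collinear columns.
    """
    pieces = [pd.Series(1.0, index=cohort.df.index, name="intercept")]
    for cov in covariates:
        col = cohort.df[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            pieces.append(dummies)
        else:
            pieces.append(col.astype(float))
    design = pd.concat(pieces, axis=1)
    check_full_rank(design)
    return design


def check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    # scale columns for a meaningful rank tolerance
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    rank = np.linalg.matrix_rank(X / norms)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X / norms)
        suspect = [design.columns[j] for j in range(X.shape[1])
                   if abs(R[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {suspect}")


def residualize(block: np.ndarray, design: pd.DataFrame | np.ndarray) -> np.ndarray:
    """OLS residuals of every block column on the covariate design.

    Output columns are orthogonal to every (unit-scaled) design column to
    1e-8; with an intercept present they are mean-zero.  Design columns are
    rescaled internally for conditioning, which leaves the projection — and
    hence the residuals — unchanged.
    """
    B = as_2d(block)
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    if isinstance(design, pd.DataFrame):
        check_full_rank(design)
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    Xs = X / norms
    coef, *_ = np.linalg.lstsq(Xs, B, rcond=None)
    resid = B - Xs @ coef
    out = resid if np.asarray(block).ndim > 1 else resid[:, 0]
    return out


def standardize(block: np.ndarray, ddof: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize (mean 0, population SD 1); drop constant columns.

    Returns ``(standardized, keep_mask)``.  Raises if every column is
    constant.
    """
    B = as_2d(block)
    sd = B.std(axis=0, ddof=ddof)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns are constant; nothing to standardize")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant column(s)", stacklevel=2)
    Z = (B[:, keep] - B[:, keep].mean(axis=0)) / sd[keep]
    if np.asarray(block).ndim == 1:
        return Z[:, 0], keep
    return Z, keep


# ---------------------------------------------------------------------------
# NIfTI interchange: flatten in-mask voxels to a feature matrix and back.

def view_from_nifti(paths, mask_path, subject_ids, modality: str,
                    contrast: str = "") -> ImagingView:
    """Load per-subject NIfTI volumes, flattening voxels inside a binary mask."""
    import nibabel as nib

    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    coords = np.argwhere(mask)
    rows = []
    for p in paths:
        vol = np.asarray(nib.load(str(p)).dataobj, dtype=float)
        if vol.shape != mask.shape:
            raise ValueError(f"volume {p} shape {vol.shape} != mask shape {mask.shape}")
        rows.append(vol[mask])
    return ImagingView(np.asarray(subject_ids), np.vstack(rows), coords, modality, contrast)


def view_to_nifti(view: ImagingView, out_dir, grid_shape=None) -> list:
    """Write one NIfTI volume per subject (values outside the mask are 0)."""
    import nibabel as nib
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shape = tuple(grid_shape) if grid_shape is not None else tuple(view.coords.max(axis=0) + 1)
    idx = tuple(view.coords.T)
    paths = []
    for i, sid in enumerate(view.subject_ids):
        vol = np.zeros(shape)
        vol[idx] = view.features[i]
        p = out_dir / f"{sid}_{view.modality.lower()}.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(p))
        paths.append(p)
    return paths
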