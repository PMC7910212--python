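"""Sparse partial least squares with stability selection and permutation tests.

The model links a small explanatory block ``X`` (two polygenic scores and two
phenotypes, residualized and standardized) to a wide imaging block ``Y``
(concatenated voxel features).  One latent component is sought:

    maximize  u' X' Y v   subject to  ||u||2 <= 1, ||v||2 <= 1, ||v||1 <= c,

i.e. a rank-one penalized matrix decomposition of the cross-covariance
``M = X'Y / n`` in which only the brain side is sparsified.  ``c`` is
parameterized by ``l1_frac`` in [0, 1] interpolating between a single feature
(c = 1) and no constraint (c = sqrt(p)).  The alternating updates are

    u <- M v / ||M v||,    v <- S(M'u, lam) / ||S(M'u, lam)||,

with the soft threshold ``lam`` found by bisection so the L1 constraint
binds.  The per-subject *neural endophenotype score* is ``Y v``.

Robust feature selection uses stability selection: the fit is repeated on
random subsamples and only features whose nonzero-selection frequency
reaches ``freq_threshold`` are retained; the final weights are an
unpenalized rank-one refit on the retained features.  Association strength
between each explanatory variable and the endophenotype is quantified
out-of-sample by k-fold cross-validation, with one-sided permutation
p-values and Holm step-down family-wise correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._utils import stream_rng
from .inference import holm_bonferroni

log = logging.getLogger(__name__)

X_VARIABLES = ("prs_adhd", "prs_bmi", "impulsivity", "bmi")


@dataclass
class SPLSConfig:
    l1_frac: float = 0.18
    n_resamples: int = 100
    subsample_frac: float = 0.8
    freq_threshold: float = 0.8
    n_components: int = 1
    max_iter: int = 500
    tol: float = 1e-6
    cv_folds: int = 5
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.l1_frac <= 1):
            raise ValueError("l1_frac must lie in [0, 1]")
        if not (0 <= self.freq_threshold <= 1):
            raise ValueError("freq_threshold must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_components != 1:
            raise ValueError("only a single latent component is supported")


@dataclass
class SPLSFit:
    """One fitted sparse PLS component."""

    x_weights: np.ndarray           # unit-norm over the explanatory block
    brain_weights: np.ndarray       # sparse, unit-norm over imaging features
    scores: np.ndarray              # per-subject endophenotype score Y @ v
    objective: float                # u' M v at convergence
    n_iter: int
    converged: bool
    selection_freq: np.ndarray | None = None
    objective_trace: np.ndarray | None = None


@dataclass
class AssociationResult:
    variable: str
    r: float
    p_perm: float
    p_fwe: float = np.nan


def l1_bound(l1_frac: float, p: int) -> float:
    """Map the sparsity fraction to the L1 bound c in [1, sqrt(p)]."""
    return 1.0 + l1_frac * (np.sqrt(p) - 1.0)


def _soft(w: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)


def _l1_project(w: np.ndarray, c: float) -> np.ndarray:
    """Soft-threshold ``w`` and L2-normalize so that ||v||1 <= c binds.

    The L1 norm of the normalized soft-thresholded vector decreases
    monotonically in the threshold; lam is resolved by bisection to 1e-10
    relative precision.
    """
    nrm = np.linalg.norm(w)
    if nrm == 0:
        return np.zeros_like(w)
    v = w / nrm
    if np.abs(v).sum() <= c:
        return v
    lo, hi = 0.0, np.abs(w).max()
    for _ in range(200):
        lam = 0.5 * (lo + hi)
        s = _soft(w, lam)
        ns = np.linalg.norm(s)
        l1 = np.abs(s).sum() / ns if ns > 0 else 0.0
        if l1 > c:
            lo = lam
        else:
            hi = lam
        if hi - lo <= 1e-10 * max(hi, 1e-300):
            break
    s = _soft(w, hi)
    ns = np.linalg.norm(s)
    if ns == 0:                     # keep at least the largest element
        j = int(np.argmax(np.abs(w)))
        s = np.zeros_like(w)
        s[j] = np.sign(w[j])
        return s
    return s / ns


def fit_component(X: np.ndarray, Y: np.ndarray, cfg: SPLSConfig,
                  sign_index: int = 3) -> SPLSFit:
    """Alternating rank-one sparse PLS fit of standardized blocks.

    The global sign of (u, v) is arbitrary; the convention here makes the
    explanatory weight at ``sign_index`` (default: the BMI phenotype slot)
    non-negative.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n, p = Y.shape
    M = X.T @ Y / n
    c = l1_bound(cfg.l1_frac, p)

    # initialize from the dense leading pair of the small k x p matrix
    U0, _, Vt0 = np.linalg.svd(M, full_matrices=False)
    u, v = U0[:, 0], Vt0[0]

    trace = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        Mv = M @ v
        u_new = Mv / np.linalg.norm(Mv) if np.linalg.norm(Mv) > 0 else u
        v_new = _l1_project(M.T @ u_new, c)
        trace.append(float(u_new @ M @ v_new))
        delta = max(np.abs(u_new - u).max(), np.abs(v_new - v).max())
        u, v = u_new, v_new
        if delta < cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"sPLS did not converge in {cfg.max_iter} iterations "
            f"(last objective {trace[-1]:.6g})", stacklevel=2)

    if u[sign_index] < 0 or (u[sign_index] == 0 and (u < 0).any() and u[u != 0][0] < 0):
        u, v = -u, -v
    return SPLSFit(u, v, Y @ v, float(u @ M @ v), it, converged,
                   objective_trace=np.asarray(trace))


def _rank_one_refit(X: np.ndarray, Y: np.ndarray, mask: np.ndarray,
                    sign_index: int = 3) -> SPLSFit:
    """Unpenalized leading singular pair restricted to the masked features."""
    n, p = Y.shape
    v_full = np.zeros(p)
    if not mask.any():
        u = np.zeros(X.shape[1])
        return SPLSFit(u, v_full, np.zeros(n), 0.0, 0, True)
    M = X.T @ Y[:, mask] / n
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    u, v = U[:, 0], Vt[0]
    if u[sign_index] < 0:
        u, v = -u, -v
    v_full[mask] = v
    return SPLSFit(u, v_full, Y @ v_full, float(s[0]), 1, True)


def stability_select(X: np.ndarray, Y: np.ndarray, cfg: SPLSConfig,
                     rng: np.random.Generator | None = None) -> SPLSFit:
    """Stability selection + unpenalized refit on the stable support.

    Fits the penalized component on ``n_resamples`` random subsamples
    (fraction ``subsample_frac`` of rows, without replacement); a feature's
    selection frequency is the fraction of fits in which its weight was
    nonzero.  Features at or above ``freq_threshold`` form the stable set,
    on which the final unpenalized rank-one model is refit.
    """
    if cfg.n_resamples < 10:
        raise ValueError("n_resamples must be >= 10 for stability selection")
    rng = rng if rng is not None else stream_rng(cfg.seed, "spls")
    n, p = Y.shape
    m = max(int(round(cfg.subsample_frac * n)), 2)
    counts = np.zeros(p)
    for _ in range(cfg.n_resamples):
        rows = rng.choice(n, size=m, replace=False)
        fit = fit_component(X[rows], Y[rows], cfg)
        counts += fit.brain_weights != 0
    freq = counts / cfg.n_resamples
    mask = freq >= cfg.freq_threshold
    refit = _rank_one_refit(X, Y, mask)
    refit.selection_freq = freq
    if not mask.any():
        log.info("stability selection retained no features")
    return refit


def permutation_test(x: np.ndarray, scores: np.ndarray, n_permutations: int = 10_000,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> tuple[float, float]:
    """One-sided permutation p-value for the Pearson correlation.

    Returns ``(r_obs, p)`` with the add-one rule
    ``p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations)``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    x = np.asarray(x, float)
    s = np.asarray(scores, float)
    if len(x) != len(s):
        raise ValueError("length mismatch")
    if x.std() == 0 or s.std() == 0:
        raise ValueError("correlation undefined for constant input")
    rng = rng if rng is not None else stream_rng(0 if seed is None else seed, "permutation")

    n = len(x)
    xz = (x - x.mean()) / x.std()
    sz = (s - s.mean()) / s.std()
    r_obs = float(xz @ sz / n)

    count = 0
    chunk = max(1, min(n_permutations, int(2e6 // n)))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        perms = np.argsort(rng.random((b, n)), axis=1)
        r_perm = xz[perms] @ sz / n
        count += int((r_perm >= r_obs).sum())
        done += b
    p = (1 + count) / (1 + n_permutations)
    return r_obs, p


def cv_association(X: np.ndarray, Y: np.ndarray, cfg: SPLSConfig,
                   x_names: tuple[str, ...] = X_VARIABLES,
                   rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Out-of-sample association of each explanatory variable with the score.

    The stability-selected model is trained within each of ``cv_folds``
    folds and held-out subjects are scored with the trained brain weights;
    every subject is scored exactly once.  Pearson correlations of each X
    column with the pooled out-of-sample score get one-sided permutation
    p-values and Holm family-wise adjustment over the ``x_names`` family.
    """
    rng = rng if rng is not None else stream_rng(cfg.seed, "spls")
    n = X.shape[0]
    order = rng.permutation(n)
    folds = np.array_split(order, cfg.cv_folds)
    if min(len(f) for f in folds) < 10:
        raise ValueError("each CV fold must contain at least 10 rows")

    pooled = np.zeros(n)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(n), test_idx)
        fit = stability_select(X[train], Y[train], cfg, rng=rng)
        pooled[test_idx] = Y[test_idx] @ fit.brain_weights

    rows = []
    for j, name in enumerate(x_names):
        if pooled.std() == 0:
            rows.append(AssociationResult(name, 0.0, 1.0))
            continue
        r, p = permutation_test(X[:, j], pooled, cfg.n_permutations, rng=rng)
        rows.append(AssociationResult(name, r, p))
    p_fwe = holm_bonferroni(np.array([a.p_perm for a in rows]))
    out = pd.DataFrame({
        "variable": [a.variable for a in rows],
        "r": [a.r for a in rows],
        "p_perm": [a.p_perm for a in rows],
        "p_fwe": p_fwe,
    })
    return out, pooled


def report_clusters(brain_weights: np.ndarray, coords: np.ndarray,
                    modality: np.ndarray) -> pd.DataFrame:
    """Connected components (26-connectivity) of nonzero weights, per modality.

    Clusters are split by sign before labelling so that each reported
    cluster has a uniform weight sign.  Columns: modality, cluster_id, sign,
    n_voxels, peak coordinates (max |weight|), centroid, mean and peak
    weight.
    """
    coords = np.asarray(coords, int)
    modality = np.asarray(modality)
    w = np.asarray(brain_weights, float)
    rows = []
    structure = np.ones((3, 3, 3), dtype=int)
    for mod in pd.unique(modality):
        sel = modality == mod
        c = coords[sel]
        wv = w[sel]
        if not len(c):
            continue
        shape = tuple(c.max(axis=0) + 1)
        for sign in (+1, -1):
            vol = np.zeros(shape)
            mask = (np.sign(wv) == sign)
            if not mask.any():
                continue
            vol[tuple(c[mask].T)] = wv[mask]
            labels, n_lab = ndimage.label(vol != 0, structure=structure)
            for lab in range(1, n_lab + 1):
                vox = np.argwhere(labels == lab)
                weights = vol[tuple(vox.T)]
                peak = vox[np.argmax(np.abs(weights))]
                rows.append({
                    "modality": mod, "cluster_id": lab, "sign": sign,
                    "n_voxels": len(vox),
                    "peak_i": int(peak[0]), "peak_j": int(peak[1]), "peak_k": int(peak[2]),
                    "centroid_i": float(vox[:, 0].mean()),
                    "centroid_j": float(vox[:, 1].mean()),
                    "centroid_k": float(vox[:, 2].mean()),
                    "mean_weight": float(weights.mean()),
                    "peak_weight": float(weights[np.argmax(np.abs(weights))]),
                })
    return pd.DataFrame(rows, columns=[
        "modality", "cluster_id", "sign", "n_voxels",
        "peak_i", "peak_j", "peak_k",
        "centroid_i", "centroid_j", "centroid_k",
        "mean_weight", "peak_weight"])
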