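"""Indirect-effect estimation with bias-corrected bootstrap intervals.

For each pathway (PRS exposure x, neural endophenotype mediator m, phenotype
outcome y) two covariate-adjusted OLS regressions are fit:

    m ~ 1 + x + C          ->  a  (exposure -> mediator)
    y ~ 1 + x + m + C      ->  b  (mediator -> outcome), c' (direct effect)

The indirect effect is the product ab = a*b of unstandardized coefficients,
which in linear OLS equals the total minus direct effect (c - c').  Because
the sampling distribution of a product is skewed, inference uses the
nonparametric subject-level bootstrap with bias-corrected (BC) percentile
intervals: with z0 = Phi^{-1}(fraction of bootstrap ab* below the point
estimate, ties counted half), the interval endpoints are the bootstrap
quantiles at Phi(2*z0 + z_{alpha/2}) and Phi(2*z0 + z_{1-alpha/2}).  Both
90% and 95% intervals are always computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._utils import as_2d, stream_rng

#: the four pathways: (exposure, outcome); the mediator is always the score
DEFAULT_PATHWAYS = (
    ("prs_adhd", "impulsivity"),
    ("prs_adhd", "bmi"),
    ("prs_bmi", "bmi"),
    ("prs_bmi", "impulsivity"),
)


@dataclass
class MediationSpec:
    exposure: str
    mediator: str
    outcome: str
    covariates: tuple[str, ...] = ()
    n_boot: int = 10_000
    ci_levels: tuple[float, ...] = (0.90, 0.95)
    seed: int = 0

    def __post_init__(self):
        if self.exposure == self.outcome:
            raise ValueError("exposure and outcome must differ")
        if not all(0 < lv < 1 for lv in self.ci_levels):
            raise ValueError("ci_levels must lie in (0, 1)")


@dataclass
class MediationResult:
    pathway: str
    a: float
    b: float
    c_prime: float
    ab: float
    cis: dict                      # level -> (lower, upper)
    n: int
    n_boot: int
    z0: float
    boot_mean: float
    boot_sd: float
    flags: list = field(default_factory=list)

    def to_row(self) -> dict:
        row = {"pathway": self.pathway, "a": self.a, "b": self.b, "ab": self.ab,
               "c_prime": self.c_prime}
        for lv, (lo, hi) in sorted(self.cis.items()):
            pct = int(round(100 * lv))
            row[f"ci{pct}_lo"], row[f"ci{pct}_hi"] = lo, hi
        row["n"] = self.n
        row["flags"] = ";".join(self.flags)
        return row


def _design(x, C):
    n = len(x)
    cols = [np.ones(n), np.asarray(x, float)]
    if C is not None and np.size(C):
        cols.append(as_2d(C))
    return np.column_stack(cols)


def fit_paths(x, m, y, covariates=None) -> tuple[float, float, float]:
    """Unstandardized path coefficients (a, b, c') from the two OLS fits."""
    X1 = _design(x, covariates)
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("rank-deficient design in mediation regression")
    a = np.linalg.lstsq(X1, np.asarray(m, float), rcond=None)[0][1]
    X2 = np.column_stack([X1[:, :2], np.asarray(m, float), X1[:, 2:]])
    coef2 = np.linalg.lstsq(X2, np.asarray(y, float), rcond=None)[0]
    c_prime, b = coef2[1], coef2[2]
    return float(a), float(b), float(c_prime)


def total_effect(x, y, covariates=None) -> float:
    """Coefficient of x in y ~ 1 + x + C (the total effect c)."""
    X = _design(x, covariates)
    return float(np.linalg.lstsq(X, np.asarray(y, float), rcond=None)[0][1])


def _batched_ab(x, m, y, C, idx_chunk):
    """Bootstrap a*b for one chunk of resample index rows (vectorized).

    Builds per-resample Gram matrices of the y-regression design
    [1, x, C, m]; the m-regression uses the same design minus the last
    row/column, so both normal-equation systems come from one einsum.
    """
    D = np.column_stack([_design(x, C), np.asarray(m, float)])   # (n, p); m last
    yv = np.asarray(y, float)
    mv = np.asarray(m, float)
    Db = D[idx_chunk]                                            # (B, n, p)
    G = np.einsum("bni,bnj->bij", Db, Db)
    rhs_y = np.einsum("bni,bn->bi", Db, yv[idx_chunk])
    coef_y = np.linalg.solve(G, rhs_y[..., None])[..., 0]
    b = coef_y[:, -1]
    G1 = G[:, :-1, :-1]
    rhs_m = G[:, :-1, -1]                                        # = X1' m per resample
    coef_m = np.linalg.solve(G1, rhs_m[..., None])[..., 0]
    a = coef_m[:, 1]
    return a * b


def bc_interval(boot: np.ndarray, estimate: float, level: float
                ) -> tuple[float, float, float, list]:
    """Bias-corrected percentile interval from a bootstrap sample.

    Returns ``(lower, upper, z0, flags)``.  With a bootstrap distribution
    symmetric about the estimate, z0 = 0 and the interval equals the plain
    percentile interval.
    """
    flags = []
    frac = (np.sum(boot < estimate) + 0.5 * np.sum(boot == estimate)) / len(boot)
    if frac <= 0 or frac >= 1:
        frac = float(np.clip(frac, 0.5 / len(boot), 1 - 0.5 / len(boot)))
        flags.append("z0_clipped")
    z0 = float(sps.norm.ppf(frac))
    alpha = 1 - level
    lo_q = sps.norm.cdf(2 * z0 + sps.norm.ppf(alpha / 2))
    hi_q = sps.norm.cdf(2 * z0 + sps.norm.ppf(1 - alpha / 2))
    lo, hi = np.quantile(boot, [lo_q, hi_q])
    return float(lo), float(hi), z0, flags


def bootstrap_indirect(x, m, y, spec: MediationSpec, covariates=None,
                       rng: np.random.Generator | None = None) -> MediationResult:
    """Bias-corrected bootstrap of the indirect effect ab.

    Subjects are resampled with replacement ``n_boot`` times and both path
    regressions refit per resample.  BC intervals can in pathological cases
    fail to cover the point estimate; this is flagged, not forced.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 50:
        raise ValueError("mediation bootstrap requires n >= 50")
    if spec.n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    rng = rng if rng is not None else stream_rng(spec.seed, "bootstrap")

    a, b, c_prime = fit_paths(x, m, y, covariates)
    ab = a * b

    B = spec.n_boot
    ab_star = np.empty(B)
    chunk = max(1, int(4e6 // (n * (3 + (as_2d(covariates).shape[1] if covariates is not None and np.size(covariates) else 0)))))
    done = 0
    while done < B:
        nb = min(chunk, B - done)
        idx = rng.integers(0, n, size=(nb, n))
        ab_star[done:done + nb] = _batched_ab(x, m, y, covariates, idx)
        done += nb

    flags = []
    if np.ptp(ab_star) == 0:
        val = float(ab_star[0])
        cis = {lv: (val, val) for lv in spec.ci_levels}
        return MediationResult(f"{spec.exposure}->{spec.mediator}->{spec.outcome}",
                               a, b, c_prime, ab, cis, n, B, 0.0, val, 0.0,
                               ["degenerate_bootstrap"])

    cis = {}
    z0 = 0.0
    for lv in spec.ci_levels:
        lo, hi, z0, fl = bc_interval(ab_star, ab, lv)
        for f in fl:
            if f not in flags:
                flags.append(f)
        cis[lv] = (lo, hi)
        if not (lo <= ab <= hi):
            flags.append(f"estimate_outside_ci{int(round(100 * lv))}")
    return MediationResult(f"{spec.exposure}->{spec.mediator}->{spec.outcome}",
                           a, b, c_prime, ab, cis, n, B, z0,
                           float(ab_star.mean()), float(ab_star.std()), flags)


def run_all_pathways(data: pd.DataFrame, mediator_col: str = "endophenotype",
                     covariate_cols: tuple[str, ...] = (),
                     pathways=DEFAULT_PATHWAYS, n_boot: int = 10_000,
                     ci_levels=(0.90, 0.95), seed: int = 0) -> pd.DataFrame:
    """Evaluate the four PRS -> endophenotype -> phenotype pathways.

    ``data`` must contain the exposure and outcome columns named in
    ``pathways``, the mediator column and any covariate columns.  Returns a
    4-row table with both CI levels.
    """
    rng = stream_rng(seed, "bootstrap")
    C = data[list(covariate_cols)].to_numpy(dtype=float) if covariate_cols else None
    rows = []
    for exposure, outcome in pathways:
        spec = MediationSpec(exposure, mediator_col, outcome,
                             covariates=tuple(covariate_cols),
                             n_boot=n_boot, ci_levels=tuple(ci_levels), seed=seed)
        res = bootstrap_indirect(
            data[exposure].to_numpy(float),
            data[mediator_col].to_numpy(float),
            data[outcome].to_numpy(float),
            spec, covariates=C, rng=rng)
        rows.append(res.to_row())
    return pd.DataFrame(rows)
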