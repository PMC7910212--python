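"""Association statistics: Pearson correlations with permutation p-values,
Holm-Bonferroni family-wise correction, and Steiger's test for comparing two
dependent (non-overlapping) correlations.

Steiger's comparison of r_ab and r_cd measured on the same subjects uses the
Fisher transforms z_ab, z_cd and the Pearson-Filon expression for their
asymptotic covariance, evaluated at the pooled (back-transformed mean)
correlation — Steiger's Z2*-bar statistic:

    z = (z_ab - z_cd) * sqrt((n - 3) / (2 - 2*s)),

where ``s`` is the estimated correlation between the two Fisher z's.  When
all four cross-correlations vanish the statistic reduces to the independent
two-sample Fisher-z comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: the four Step-1 association tests reported in the correlation analysis
DEFAULT_STEP1_FAMILY = (
    ("prs_adhd", "prs_bmi"),
    ("prs_adhd", "impulsivity"),
    ("prs_bmi", "bmi"),
    ("impulsivity", "bmi"),
)


def correlate(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("inputs must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


def analytic_p_one_sided(r: float, n: int) -> float:
    """Upper-tail p from the exact t distribution of r under bivariate normality."""
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(sps.t.sf(t, n - 2))


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    Sort ascending; the i-th ordered adjusted value is the running maximum
    of (m - k + 1) * p_(k) for k <= i, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


@dataclass
class CorrelationMatrixResult:
    """Pairwise correlations with permutation and Holm-adjusted p-values.

    ``p`` and ``p_fwe`` are populated (upper triangle mirrored to lower) for
    the pairs in the declared family; other entries are NaN.
    """

    variables: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray
    p_fwe: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        """Compact display: r in the lower triangle, FWE p above the diagonal."""
        k = len(self.variables)
        out = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(k):
                if i > j:
                    out[i, j] = self.r[i, j]
                elif i < j:
                    out[i, j] = self.p_fwe[i, j]
        return pd.DataFrame(out, index=self.variables, columns=self.variables)


def correlation_matrix(data: pd.DataFrame, n_permutations: int = 10_000,
                       seed: int = 0, family=DEFAULT_STEP1_FAMILY
                       ) -> CorrelationMatrixResult:
    """Correlations among the data columns with one-sided permutation tests.

    ``family`` lists the (var, var) pairs making up the multiplicity family;
    Holm correction is applied over exactly those tests.
    """
    from .spls import permutation_test  # shared permutation engine

    names = tuple(data.columns)
    X = data.to_numpy(dtype=float)
    k = len(names)
    r = np.corrcoef(X, rowvar=False)
    p = np.full((k, k), np.nan)
    rng = np.random.default_rng([11, seed])
    fam_idx = []
    for a, b in family:
        i, j = names.index(a), names.index(b)
        _, pv = permutation_test(X[:, i], X[:, j], n_permutations, rng=rng)
        p[i, j] = p[j, i] = pv
        fam_idx.append((i, j))
    adj = holm_bonferroni([p[i, j] for i, j in fam_idx])
    p_fwe = np.full((k, k), np.nan)
    for (i, j), a in zip(fam_idx, adj):
        p_fwe[i, j] = p_fwe[j, i] = a
    return CorrelationMatrixResult(names, r, p, p_fwe, n=X.shape[0])


def _fisher_z(r):
    return np.arctanh(r)


def _pearson_filon(rb, R, j=0, k=1, h=2, m=3):
    """Pearson-Filon covariance term for (r_jk, r_hm), with both compared
    correlations replaced by the pooled value ``rb``."""
    return (0.5 * rb * rb * (R[..., j, h] ** 2 + R[..., j, m] ** 2
                             + R[..., k, h] ** 2 + R[..., k, m] ** 2)
            + R[..., j, h] * R[..., k, m] + R[..., j, m] * R[..., k, h]
            - rb * (R[..., j, h] * R[..., j, m] + R[..., k, h] * R[..., k, m])
            - rb * (R[..., j, h] * R[..., k, h] + R[..., j, m] * R[..., k, m]))


def steiger_z(r_ab, r_cd, corr4, n):
    """Vectorized Steiger Z2*-bar statistic (no shared variable).

    ``corr4`` has shape (..., 4, 4) with variables ordered (a, b, c, d);
    r_ab and r_cd occupy slots (0,1) and (2,3).
    """
    r_ab = np.asarray(r_ab, float)
    r_cd = np.asarray(r_cd, float)
    R = np.asarray(corr4, float)
    z1, z2 = _fisher_z(r_ab), _fisher_z(r_cd)
    rb = np.tanh(0.5 * (z1 + z2))                 # back-transformed pooled r
    psi = _pearson_filon(rb, R)
    s = psi / (1 - rb * rb) ** 2                  # corr between the two z's
    return (z1 - z2) * np.sqrt((n - 3) / (2 - 2 * s))


def steiger_test(r_ab: float, r_cd: float, corr4: np.ndarray, n: int
                 ) -> tuple[float, float]:
    """One-sided Steiger test that the population r_ab exceeds r_cd.

    Returns ``(z, p_one_sided)`` with p the upper normal tail.  ``corr4``
    must be the positive-definite 4x4 correlation matrix of (a, b, c, d)
    containing r_ab and r_cd in their slots.
    """
    R = np.asarray(corr4, float)
    if R.shape != (4, 4):
        raise ValueError("corr4 must be 4x4")
    if n <= 4:
        raise ValueError("n must exceed the number of variables")
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise ValueError("corr4 is not positive definite") from None
    if not (np.isclose(R[0, 1], r_ab) and np.isclose(R[2, 3], r_cd)):
        raise ValueError("corr4 must contain r_ab at (0,1) and r_cd at (2,3)")
    z = float(steiger_z(r_ab, r_cd, R, n))
    return z, float(sps.norm.sf(z))


def steiger_test_overlapping(*args, **kwargs):
    """Shared-variable (overlapping) comparison — not implemented."""
    raise NotImplementedError(
        "only the non-overlapping dependent-correlations case is supported")
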