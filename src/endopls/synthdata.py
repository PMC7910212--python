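"""Synthetic imaging-genetics cohorts with a planted shared neural substrate.

The generator emulates the statistical structure that the three-step
analysis (PRS correlations -> sparse PLS endophenotype -> mediation)
assumes, with full ground truth:

* genotype dosages are independent binomial(2, maf) draws; two traits
  ("adhd", "bmi") get true per-SNP effects that overlap on a shared causal
  set, which induces the PRS-PRS correlation;
* a latent neural substrate ``L = a1*PRS_adhd + a2*PRS_bmi + noise`` loads
  onto two imaging views through sparse, spatially clustered, signed maps
  (grey-matter loadings all negative, reward-task loadings all positive);
* impulsivity and BMI phenotypes receive direct genetic paths, the mediated
  path through L, covariate effects and a shared non-genetic confounder.

All free coefficients are solved analytically so that the population
correlation matrix of (PRS_adhd, PRS_bmi, impulsivity, BMI) equals the
configured ``target_corr`` exactly; the default targets are the observed
cohort values r = 0.17 (PRS-PRS), 0.23 (BMI PRS-BMI), 0.10 (ADHD
PRS-impulsivity), 0.10 (impulsivity-BMI), with the two cross terms not
pinned down by those observations set to 0.05.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from ._utils import stream_rng
from .cohort_prep import CohortTable, ImagingView
from .prs import GenotypeMatrix, SummaryStats

VARIABLES = ("prs_adhd", "prs_bmi", "impulsivity", "bmi")

#: the four mediation pathways: (exposure PRS, outcome phenotype)
PATHWAYS = (
    ("prs_adhd", "impulsivity"),
    ("prs_adhd", "bmi"),
    ("prs_bmi", "bmi"),
    ("prs_bmi", "impulsivity"),
)

#: non-strand-ambiguous allele pairs to draw SNP alleles from
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


def default_target_corr() -> np.ndarray:
    """4x4 population correlations over (PRS_adhd, PRS_bmi, impulsivity, BMI)."""
    r = np.eye(4)
    r[0, 1] = r[1, 0] = 0.17   # PRS-PRS
    r[0, 2] = r[2, 0] = 0.10   # ADHD PRS - impulsivity
    r[0, 3] = r[3, 0] = 0.05   # ADHD PRS - BMI (not pinned by observation)
    r[1, 2] = r[2, 1] = 0.05   # BMI PRS - impulsivity (not pinned)
    r[1, 3] = r[3, 1] = 0.23   # BMI PRS - BMI
    r[2, 3] = r[3, 2] = 0.10   # impulsivity - BMI
    return r


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    ``discovery_n`` are the effective discovery-GWAS sample sizes for the
    ADHD and BMI traits (defaults: 55,374 = cases+controls of a large ADHD
    GWAS; 339,224 for BMI), controlling summary-statistic estimation noise.
    ``path_a`` are the latent-substrate loadings on the two standardized
    PRS, ``path_b`` the substrate effects on (impulsivity, BMI); their
    products are the generative indirect effects (standardized units).
    """

    n_subjects: int = 874
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_shared: int = 30
    n_causal_specific: int = 30
    causal_beta_scale: float = 0.08
    discovery_n: tuple[int, int] = (55_374, 339_224)
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_clusters_vbm: int = 2
    n_clusters_mid: int = 2
    cluster_radius: float = 2.0
    loading_signs: tuple[float, float] = (-1.0, +1.0)   # (VBM, MID)
    loading_scale: float = 1.0
    target_corr: np.ndarray = field(default_factory=default_target_corr)
    path_a: tuple[float, float] = (0.15, 0.15)
    path_b: tuple[float, float] = (0.15, 0.20)
    noise_sd: tuple[float, float] = (1.0, 1.0)          # per view
    smooth_fwhm: float = 2.0                            # voxels
    covariate_effect_scale: float = 1.0
    n_sites: int = 8
    phen_scale: dict = field(default_factory=lambda: {
        "impulsivity": (62.0, 9.0), "bmi": (24.0, 3.0)})
    seed: int = 0

    def __post_init__(self):
        self.target_corr = np.asarray(self.target_corr, dtype=float)
        if self.n_subjects <= 0 or self.n_snps <= 0:
            raise ConfigurationError("n_subjects and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"invalid maf_range {self.maf_range}")
        if any(n <= 0 for n in self.discovery_n):
            raise ConfigurationError("discovery_n must be positive")
        if self.n_causal_shared + 2 * self.n_causal_specific > self.n_snps:
            raise ConfigurationError("causal SNP counts exceed n_snps")
        R = self.target_corr
        if R.shape != (4, 4) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1):
            raise ConfigurationError("target_corr must be symmetric with unit diagonal")
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            raise ConfigurationError("target_corr is not positive definite") from None
        if 2 * self.cluster_radius + 1 > min(self.grid_shape):
            raise ConfigurationError("cluster volumes do not fit inside grid_shape")

    @property
    def indirect_effects(self) -> dict[tuple[str, str], float]:
        """Generative a*b products for the four pathways (standardized units)."""
        a = {"prs_adhd": self.path_a[0], "prs_bmi": self.path_a[1]}
        b = {"impulsivity": self.path_b[0], "bmi": self.path_b[1]}
        return {(x, y): a[x] * b[y] for x, y in PATHWAYS}

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["target_corr"] = self.target_corr.tolist()
        return d


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator, for recovery tests."""

    mafs: np.ndarray
    snp_effects: dict[str, np.ndarray]
    loading_maps: dict[str, np.ndarray]       # generative loadings incl. scale & sign
    cluster_centers: dict[str, np.ndarray]
    latent: np.ndarray                        # substrate L per subject
    path_a: tuple[float, float]
    path_b: tuple[float, float]
    c_direct: np.ndarray                      # 2x2 direct paths PRS -> phenotypes
    confounder_loadings: tuple[float, float]
    pop_corr: np.ndarray                      # realized 4x4 over VARIABLES
    pop_cov5: np.ndarray                      # (zA, zB, L, imp_std, bmi_std)
    phen_scale: dict

    @property
    def indirect_effects(self) -> dict[tuple[str, str], float]:
        a = {"prs_adhd": self.path_a[0], "prs_bmi": self.path_a[1]}
        b = {"impulsivity": self.path_b[0], "bmi": self.path_b[1]}
        return {(x, y): a[x] * b[y] for x, y in PATHWAYS}

    def implied_mediation(self, exposure: str, outcome: str,
                          raw_scale: bool = True) -> dict:
        """Population single-exposure mediation coefficients for a pathway.

        The mediation model regresses the substrate on one PRS at a time
        (m ~ x) and the phenotype on both (y ~ x + m); because the second
        PRS is omitted, the population coefficients differ slightly from
        the generative paths.  They are derived here from the population
        covariance matrix, on the raw phenotype scale by default.
        """
        names = ["prs_adhd", "prs_bmi", "latent", "impulsivity", "bmi"]
        S = self.pop_cov5
        ix, im, iy = names.index(exposure), 2, names.index(outcome)
        a = S[ix, im] / S[ix, ix]
        XtX = S[np.ix_([ix, im], [ix, im])]
        Xty = S[np.ix_([ix, im], [iy])][:, 0]
        c_prime, b = np.linalg.solve(XtX, Xty)
        scale = self.phen_scale[outcome][1] if raw_scale else 1.0
        return {"a": a, "b": b * scale, "ab": a * b * scale, "c_prime": c_prime * scale}

    def summary_jsonable(self) -> dict:
        return {
            "path_a": list(self.path_a),
            "path_b": list(self.path_b),
            "c_direct": self.c_direct.tolist(),
            "confounder_loadings": list(self.confounder_loadings),
            "pop_corr": self.pop_corr.tolist(),
            "cluster_centers": {k: v.tolist() for k, v in self.cluster_centers.items()},
            "indirect_effects": {f"{x}->{y}": v for (x, y), v in self.indirect_effects.items()},
            "phen_scale": self.phen_scale,
        }


@dataclass
class SyntheticStudy:
    """Everything one synthetic cohort provides to the pipeline."""

    genotypes: GenotypeMatrix
    summary_stats: dict[str, SummaryStats]
    cohort: CohortTable
    views: dict[str, ImagingView]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# genotypes and summary statistics

def _draw_mafs(cfg: GeneratorConfig) -> np.ndarray:
    rng = stream_rng(cfg.seed, "genotypes")
    lo, hi = cfg.maf_range
    return rng.uniform(lo, hi, cfg.n_snps)


def simulate_genotypes(cfg: GeneratorConfig, mafs: np.ndarray | None = None) -> GenotypeMatrix:
    """Independent binomial(2, maf) dosages with allele metadata."""
    rng = stream_rng(cfg.seed, "genotypes")
    lo, hi = cfg.maf_range
    if mafs is None:
        mafs = rng.uniform(lo, hi, cfg.n_snps)
    else:
        rng.uniform(lo, hi, cfg.n_snps)   # keep downstream draws aligned
    dosages = rng.binomial(2, mafs, size=(cfg.n_subjects, cfg.n_snps)).astype(float)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), cfg.n_snps)
    counted = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    other = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    snps = pd.DataFrame({
        "snp_id": [f"rs{100000 + j}" for j in range(cfg.n_snps)],
        "chrom": (np.arange(cfg.n_snps) % 22 + 1).astype(str),
        "pos": 10_000 + 5_000 * np.arange(cfg.n_snps),
        "counted_allele": counted,
        "other_allele": other,
    })
    subject_ids = np.array([f"S{i:05d}" for i in range(cfg.n_subjects)])
    return GenotypeMatrix(subject_ids, snps, dosages)


def _calibrated_weights(cfg: GeneratorConfig, mafs: np.ndarray):
    """True per-SNP effects for both traits, scaled so the population
    correlation between the two genetic scores equals target_corr[0, 1]."""
    rng = stream_rng(cfg.seed, "cohort")
    h = 2 * mafs * (1 - mafs)                     # per-SNP dosage variance
    ns, nsp = cfg.n_causal_shared, cfg.n_causal_specific
    idx = rng.permutation(cfg.n_snps)
    shared, spec_a, spec_b = idx[:ns], idx[ns:ns + nsp], idx[ns + nsp:ns + 2 * nsp]

    w0 = cfg.causal_beta_scale
    mag = lambda k: w0 * (0.5 + np.abs(rng.standard_normal(k)))
    w_shared = mag(ns)                            # same sign, same value in both traits
    w_a = np.zeros(cfg.n_snps)
    w_b = np.zeros(cfg.n_snps)
    w_a[spec_a] = mag(nsp) * rng.choice([-1.0, 1.0], nsp)
    w_b[spec_b] = mag(nsp) * rng.choice([-1.0, 1.0], nsp)

    rho = cfg.target_corr[0, 1]
    H_s = float(np.sum(w_shared**2 * h[shared]))
    H_a = float(np.sum(w_a**2 * h))
    H_b = float(np.sum(w_b**2 * h))
    if rho == 0:
        tau = 0.0
        w_shared_a = w_shared_b = np.zeros(ns)
    else:
        # solve rho^2 (g+H_a)(g+H_b) = g^2 for g = tau^2 * H_s
        A = 1 - rho**2
        Bq = rho**2 * (H_a + H_b)
        Cq = rho**2 * H_a * H_b
        g = (Bq + np.sqrt(Bq**2 + 4 * A * Cq)) / (2 * A)
        tau = np.sqrt(g / H_s)
        w_shared_a = w_shared_b = tau * w_shared
    w_a[shared] = w_shared_a
    w_b[shared] = w_shared_b

    var_a = float(np.sum(w_a**2 * h))
    var_b = float(np.sum(w_b**2 * h))
    return w_a, w_b, var_a, var_b, rng


def simulate_summary_stats(truth: SyntheticTruth, cfg: GeneratorConfig,
                           geno: GenotypeMatrix) -> dict[str, SummaryStats]:
    """Discovery-GWAS estimates: true beta + noise, Wald p-values.

    Estimation noise has SD = 1/sqrt(discovery_n * 2*maf*(1-maf)), the
    leading-order standard error of a per-allele regression coefficient for
    a standardized trait.  Roughly 30% of SNPs are reported on the opposite
    allele (beta negated) to exercise allele alignment downstream.
    """
    rng = stream_rng(cfg.seed, "summary_stats")
    h = 2 * truth.mafs * (1 - truth.mafs)
    out = {}
    for trait, n_disc in zip(("adhd", "bmi"), cfg.discovery_n):
        if n_disc <= 0:
            raise ConfigurationError("discovery_n must be positive")
        w = truth.snp_effects[trait]
        se = 1.0 / np.sqrt(n_disc * h)
        beta_hat = w + rng.standard_normal(cfg.n_snps) * se
        z = beta_hat / se
        p = np.clip(2 * sps.norm.sf(np.abs(z)), 1e-300, 1.0)

        flip = rng.random(cfg.n_snps) < 0.3
        eff = np.where(flip, geno.snps["other_allele"], geno.snps["counted_allele"])
        oth = np.where(flip, geno.snps["counted_allele"], geno.snps["other_allele"])
        beta_rep = np.where(flip, -beta_hat, beta_hat)
        out[trait] = SummaryStats(pd.DataFrame({
            "snp_id": geno.snps["snp_id"],
            "chrom": geno.snps["chrom"],
            "pos": geno.snps["pos"],
            "effect_allele": eff,
            "other_allele": oth,
            "beta": beta_rep,
            "se": se,
            "p": p,
        }))
    return out


# ---------------------------------------------------------------------------
# spatial maps

def _plant_loadings(grid_shape, n_clusters, radius, sign, scale, rng):
    """Sparse signed loading map: ``n_clusters`` well-separated spherical
    clusters with a mild Gaussian radial taper (unique peak at the center)."""
    shape = np.asarray(grid_shape)
    margin = int(np.ceil(radius))
    # separation > 2r + 2 keeps clusters disjoint under 26-connectivity
    centers: list = []
    for _ in range(200):
        centers = []
        for _ in range(500):
            c = np.array([rng.integers(margin, s - margin) for s in shape])
            if all(np.linalg.norm(c - other) > 2 * radius + 2 for other in centers):
                centers.append(c)
            if len(centers) == n_clusters:
                break
        if len(centers) == n_clusters:
            break
    else:
        raise ConfigurationError("could not place non-overlapping clusters in grid")

    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    vol = np.zeros(tuple(shape))
    for c in centers:
        d2 = np.sum((grid - c) ** 2, axis=-1)
        bump = np.exp(-d2 / (2 * radius**2))
        bump[d2 > radius**2 + 1e-9] = 0.0
        vol = np.maximum(vol, bump)
    return sign * scale * vol.ravel(), np.array(centers)


def _smooth_noise(rng, n, grid_shape, fwhm):
    """Unit-variance spatially smooth noise (white noise, Gaussian kernel)."""
    sigma = fwhm / 2.3548
    raw = rng.standard_normal((n, *grid_shape))
    sm = ndimage.gaussian_filter(raw, sigma=(0, sigma, sigma, sigma))
    sm /= sm.std()
    return sm.reshape(n, -1)


# ---------------------------------------------------------------------------
# the cohort

def simulate_study(cfg: GeneratorConfig) -> SyntheticStudy:
    """Generate genotypes, summary statistics, cohort, imaging and truth."""
    mafs = _draw_mafs(cfg)
    geno = simulate_genotypes(cfg, mafs=mafs)
    w_a, w_b, var_a, var_b, rng = _calibrated_weights(cfg, mafs)
    n = cfg.n_subjects
    R = cfg.target_corr
    rho = R[0, 1]

    # population-standardized planted genetic scores
    mu_a = float(np.sum(w_a * 2 * mafs))
    mu_b = float(np.sum(w_b * 2 * mafs))
    zA = (geno.dosages @ w_a - mu_a) / np.sqrt(var_a) if var_a > 0 else np.zeros(n)
    zB = (geno.dosages @ w_b - mu_b) / np.sqrt(var_b) if var_b > 0 else np.zeros(n)

    a1, a2 = cfg.path_a
    b1, b2 = cfg.path_b
    var_sys_L = a1**2 + a2**2 + 2 * a1 * a2 * rho
    if var_sys_L > 1:
        raise ConfigurationError("path_a too large: latent variance exceeds 1")
    sL = np.sqrt(1 - var_sys_L)
    L = a1 * zA + a2 * zB + sL * rng.standard_normal(n)
    rAL = a1 + a2 * rho
    rBL = a2 + a1 * rho

    # covariates ---------------------------------------------------------
    sex_c = rng.choice([-1.0, 1.0], n)
    site = rng.integers(0, cfg.n_sites, n)
    site_delta = np.arange(cfg.n_sites, dtype=float)
    site_delta = (site_delta - site_delta.mean()) / site_delta.std()
    site_f = site_delta[site]
    age_z = rng.standard_normal(n)
    tiv_z = rng.standard_normal(n)
    pcs = rng.standard_normal((n, 8))
    F = np.column_stack([sex_c, site_f, age_z, tiv_z, pcs[:, 0]])  # unit-variance effects

    ces = cfg.covariate_effect_scale
    gamma_imp = ces * np.array([0.10, 0.12, 0.05, 0.04, 0.03])
    gamma_bmi = ces * np.array([0.12, 0.10, 0.06, 0.05, 0.03])

    # phenotypes: solve direct paths so marginal PRS correlations hit targets
    Sz = np.array([[1.0, rho], [rho, 1.0]])
    c_imp = np.linalg.solve(Sz, np.array([R[0, 2] - b1 * rAL, R[1, 2] - b1 * rBL]))
    c_bmi = np.linalg.solve(Sz, np.array([R[0, 3] - b2 * rAL, R[1, 3] - b2 * rBL]))

    cov_L_cimp = c_imp[0] * rAL + c_imp[1] * rBL
    cov_L_cbmi = c_bmi[0] * rAL + c_bmi[1] * rBL
    base_cov = (c_imp @ Sz @ c_bmi + b1 * b2
                + b1 * cov_L_cbmi + b2 * cov_L_cimp + gamma_imp @ gamma_bmi)
    s_prod = R[2, 3] - base_cov
    s1 = np.sqrt(abs(s_prod))
    s2 = np.sign(s_prod) * s1

    var_sys_imp = (c_imp @ Sz @ c_imp + b1**2 + 2 * b1 * cov_L_cimp
                   + gamma_imp @ gamma_imp + s1**2)
    var_sys_bmi = (c_bmi @ Sz @ c_bmi + b2**2 + 2 * b2 * cov_L_cbmi
                   + gamma_bmi @ gamma_bmi + s2**2)
    if var_sys_imp > 1 or var_sys_bmi > 1:
        raise ConfigurationError(
            "systematic phenotype variance exceeds 1; reduce paths/targets")
    sig1, sig2 = np.sqrt(1 - var_sys_imp), np.sqrt(1 - var_sys_bmi)

    U = rng.standard_normal(n)
    imp_std = (c_imp[0] * zA + c_imp[1] * zB + b1 * L + F @ gamma_imp
               + s1 * U + sig1 * rng.standard_normal(n))
    bmi_std = (c_bmi[0] * zA + c_bmi[1] * zB + b2 * L + F @ gamma_bmi
               + s2 * U + sig2 * rng.standard_normal(n))

    mu_i, sd_i = cfg.phen_scale["impulsivity"]
    mu_m, sd_m = cfg.phen_scale["bmi"]
    impulsivity = mu_i + sd_i * imp_std
    bmi = np.maximum(mu_m + sd_m * bmi_std, 10.0)   # guard: BMI must be positive

    # population covariance of (zA, zB, L, imp_std, bmi_std) via the
    # coefficient representation over independent unit-variance components
    K = 2 + 2 + 5 + 2                               # g1 g2, eL U, f1..f5, e1 e2
    def vec(**kw):
        v = np.zeros(K)
        for key, val in kw.items():
            v[{"g1": 0, "g2": 1, "eL": 2, "U": 3, "e1": 9, "e2": 10}[key]
              if key != "f" else slice(4, 9)] = val
        return v
    vzA = vec(g1=1.0)
    vzB = vec(g1=rho, g2=np.sqrt(1 - rho**2))
    vL = a1 * vzA + a2 * vzB + vec(eL=sL)
    vimp = c_imp[0] * vzA + c_imp[1] * vzB + b1 * vL + vec(f=gamma_imp, U=s1, e1=sig1)
    vbmi = c_bmi[0] * vzA + c_bmi[1] * vzB + b2 * vL + vec(f=gamma_bmi, U=s2, e2=sig2)
    C5 = np.vstack([vzA, vzB, vL, vimp, vbmi])
    pop_cov5 = C5 @ C5.T
    pop_corr = pop_cov5[np.ix_([0, 1, 3, 4], [0, 1, 3, 4])]

    # imaging views ------------------------------------------------------
    img_rng = stream_rng(cfg.seed, "imaging")
    views = {}
    maps, centers = {}, {}
    p = int(np.prod(cfg.grid_shape))
    coords = np.argwhere(np.ones(cfg.grid_shape, dtype=bool))
    for name, n_clusters, sign, noise_sd in (
        ("VBM", cfg.n_clusters_vbm, cfg.loading_signs[0], cfg.noise_sd[0]),
        ("MID", cfg.n_clusters_mid, cfg.loading_signs[1], cfg.noise_sd[1]),
    ):
        m, ctr = _plant_loadings(cfg.grid_shape, n_clusters, cfg.cluster_radius,
                                 sign, cfg.loading_scale, img_rng)
        cov_maps = _smooth_noise(img_rng, F.shape[1], cfg.grid_shape, cfg.smooth_fwhm)
        Gamma = 0.25 * ces * cov_maps                  # covariate leakage into voxels
        noise = noise_sd * _smooth_noise(img_rng, n, cfg.grid_shape, cfg.smooth_fwhm)
        Y = np.outer(L, m) + F @ Gamma + noise
        views[name] = ImagingView(geno.subject_ids, Y, coords, name,
                                  contrast="highwin-vs-nowin" if name == "MID" else "")
        maps[name], centers[name] = m, ctr

    cohort = CohortTable(pd.DataFrame({
        "subject_id": geno.subject_ids,
        "impulsivity": impulsivity,
        "bmi": bmi,
        "sex": np.where(sex_c > 0, "M", "F"),
        "site": np.array([f"site{s + 1:02d}" for s in site]),
        "age": 19.0 + 0.6 * age_z,
        "tiv": 1.45e6 + 1.0e5 * tiv_z + 6.0e4 * sex_c,
        **{f"pc{i + 1}": pcs[:, i] for i in range(8)},
        "prs_adhd": zA,
        "prs_bmi": zB,
    }))

    truth = SyntheticTruth(
        mafs=mafs,
        snp_effects={"adhd": w_a, "bmi": w_b},
        loading_maps=maps,
        cluster_centers=centers,
        latent=L,
        path_a=cfg.path_a,
        path_b=cfg.path_b,
        c_direct=np.vstack([c_imp, c_bmi]),
        confounder_loadings=(float(s1), float(s2)),
        pop_corr=pop_corr,
        pop_cov5=pop_cov5,
        phen_scale=dict(cfg.phen_scale),
    )
    stats = simulate_summary_stats(truth, cfg, geno)
    return SyntheticStudy(geno, stats, cohort, views, truth)


def simulate_cohort(cfg: GeneratorConfig):
    """Cohort table, the two imaging views and the planted ground truth."""
    study = simulate_study(cfg)
    return study.cohort, study.views["VBM"], study.views["MID"], study.truth


# ---------------------------------------------------------------------------
# plain-text writers

def write_genotypes_raw(geno: GenotypeMatrix, path) -> None:
    """PLINK ``.raw``-dialect dosage table (FID IID PAT MAT SEX PHENOTYPE, then
    one SNP_countedallele column per SNP)."""
    cols = [f"{r.snp_id}_{r.counted_allele}" for r in geno.snps.itertuples()]
    df = pd.DataFrame(geno.dosages, columns=cols)
    head = pd.DataFrame({
        "FID": geno.subject_ids, "IID": geno.subject_ids,
        "PAT": 0, "MAT": 0, "SEX": 0, "PHENOTYPE": -9,
    })
    pd.concat([head, df], axis=1).to_csv(path, sep="\t", index=False)


def read_genotypes_raw(path, snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a PLINK ``.raw``-dialect dosage table written by this package."""
    df = pd.read_csv(path, sep="\t")
    snp_cols = [c for c in df.columns if c not in
                ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")]
    ids = [c.rsplit("_", 1) for c in snp_cols]
    if snp_meta is None:
        snp_meta = pd.DataFrame({
            "snp_id": [i[0] for i in ids],
            "chrom": "0", "pos": 0,
            "counted_allele": [i[1] for i in ids],
            "other_allele": "N",
        })
    return GenotypeMatrix(df["IID"].to_numpy(), snp_meta,
                          df[snp_cols].to_numpy(dtype=float))


def write_summary_stats(stats: SummaryStats, path) -> None:
    out = stats.table.rename(columns={
        "snp_id": "SNP", "chrom": "CHR", "pos": "BP",
        "effect_allele": "A1", "other_allele": "A2",
        "beta": "BETA", "se": "SE", "p": "P"})
    out.to_csv(path, sep="\t", index=False)


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_view(view: ImagingView, features_path, coords_path) -> None:
    pd.DataFrame(view.features, index=pd.Index(view.subject_ids, name="subject_id")
                 ).to_csv(features_path, sep="\t", float_format="%.8g")
    pd.DataFrame(view.coords, columns=["i", "j", "k"]).to_csv(coords_path, sep="\t", index=False)


def read_view(features_path, coords_path, modality: str, contrast: str = "") -> ImagingView:
    feats = pd.read_csv(features_path, sep="\t", index_col="subject_id")
    coords = pd.read_csv(coords_path, sep="\t")[["i", "j", "k"]].to_numpy()
    return ImagingView(feats.index.to_numpy(), feats.to_numpy(dtype=float),
                       coords, modality, contrast)


def write_truth(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.summary_jsonable(), fh, indent=2)
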