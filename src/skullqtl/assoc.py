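"""Kinship-aware linear-mixed-model association scan with scan-level QC.

The scan fits, for each marker x, the univariate mixed model

    y = W a + x b + u + e,   u ~ N(0, s2_g K),   e ~ N(0, s2_e I)

where ``K`` is the centred genomic relationship matrix and ``W`` the fixed
covariates (intercept, sex, genotype PCs).  ``K`` is eigendecomposed once;
in the rotated basis the covariance is diagonal and the variance ratio
``lambda = s2_g / s2_e`` is profiled per marker by 1-D REML optimisation
(Brent on a log grid), after which ``b`` is tested by a Wald test — the
EMMA/GEMMA strategy with exact per-marker optimisation rather than
null-model reuse.

Scan-level QC mirrors standard GWAS practice: the genomic inflation factor
(median chi-square ratio), the Bonferroni significance threshold, and
r^2-based pruning of index markers and their LD partners for re-scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "AssocScan",
    "qc_filter",
    "kinship",
    "genotype_pcs",
    "lmm_scan",
    "genomic_inflation",
    "bonferroni_threshold",
    "ld_r2",
    "ld_prune_rescan",
]

#: median of the 1-df chi-square distribution (null median for lambda).
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with a genomic map.

    ``dosages`` holds alt-allele counts in {0, 1, 2} with ``nan`` for
    missing.  ``gmap`` is a DataFrame with columns ``chrom``, ``pos``
    (1-based), ``id``, ``ref``, ``alt``; positions must be non-decreasing
    within a chromosome.
    """

    sample_ids: list[str]
    dosages: np.ndarray
    gmap: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be samples x markers")
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if len(self.gmap) != self.dosages.shape[1]:
            raise ValueError("map length must equal marker count")
        for _, grp in self.gmap.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must be non-decreasing within chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def imputed(self) -> np.ndarray:
        """Dosages with residual missing values mean-imputed per marker."""
        x = self.dosages.copy()
        mean = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x[idx] = mean[idx[1]]
        return x


@dataclass
class KinshipMatrix:
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = self.values
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(k, k.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")


@dataclass
class AssocScan:
    """Per-marker effects and scan QC."""

    results: pd.DataFrame  # chrom, pos, id, beta, se, p
    lam: float
    threshold_p: float
    n_tests: int
    extra: dict = field(default_factory=dict)


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    sample_missing_max: float = 0.1,
) -> tuple[GenotypeMatrix, dict]:
    """Drop high-missingness samples, then low-MAF markers.

    Samples with missing fraction strictly greater than
    ``sample_missing_max`` are removed first; minor-allele frequencies are
    then computed on the retained samples and markers with MAF strictly
    below ``maf_min`` are removed.
    """
    miss_frac = np.isnan(g.dosages).mean(axis=1)
    keep_s = miss_frac <= sample_missing_max
    if not keep_s.any():
        raise ValueError("all samples dropped by missingness filter")
    d = g.dosages[keep_s]
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep_m = ~np.isnan(maf) & (maf >= maf_min)
    out = GenotypeMatrix(
        [s for s, k in zip(g.sample_ids, keep_s) if k],
        d[:, keep_m],
        g.gmap.loc[keep_m].reset_index(drop=True),
    )
    report = {
        "samples_dropped_missingness": int((~keep_s).sum()),
        "markers_dropped_maf": int((~keep_m).sum()),
        "samples_retained": int(keep_s.sum()),
        "markers_retained": int(keep_m.sum()),
    }
    return out, report


def kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """Centred genomic relationship matrix K = Z Z' / m.

    Z is the column-centred (mean-imputed) dosage matrix and m the marker
    count — the "centered relatedness" kinship of mixed-model GWAS tools.
    """
    if g.n_markers == 0:
        raise ValueError("no markers for kinship")
    z = g.imputed()
    z = z - z.mean(axis=0)
    return KinshipMatrix(z @ z.T / g.n_markers)


def genotype_pcs(g: GenotypeMatrix, n_components: int) -> np.ndarray:
    """Genotype principal-component covariates (population structure).

    Top eigenvectors of the kinship matrix scaled by the root eigenvalue,
    i.e. classical PC scores of the centred dosage matrix.
    """
    if n_components <= 0:
        raise ValueError("n_components must be positive")
    if n_components >= g.n_samples:
        raise ValueError("n_components must be < sample count")
    k = kinship(g).values
    w, v = np.linalg.eigh(k)
    order = np.argsort(w)[::-1][:n_components]
    w = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(w)


def _reml_neg2ll(log_lam: float, s: np.ndarray, xr: np.ndarray, yr: np.ndarray):
    """-2 x (restricted log-likelihood up to a constant) at lambda=exp(log_lam).

    Rotated model: Var(y_i) = s2_e * (lambda * s_i + 1).  Returns the
    criterion plus the GLS pieces needed for the Wald test.
    """
    lam = np.exp(log_lam)
    v = lam * s + 1.0
    w = 1.0 / v
    xtw = xr.T * w
    a = xtw @ xr
    b = xtw @ yr
    coef = np.linalg.solve(a, b)
    rss = float(w @ (yr - xr @ coef) ** 2)
    n, c = xr.shape
    sign, logdet_a = np.linalg.slogdet(a)
    crit = float(np.log(v).sum() + logdet_a + (n - c) * np.log(rss))
    return crit, coef, rss, a


def lmm_scan(
    y: np.ndarray,
    g: GenotypeMatrix,
    k: KinshipMatrix,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
) -> AssocScan:
    """Per-marker exact-REML mixed-model association scan.

    Parameters
    ----------
    y
        Phenotype, one value per sample.
    g
        Genotypes after QC; residual missing dosages are mean-imputed.
    k
        Kinship (random-effect covariance up to the genetic variance).
    covariates
        Optional samples x q fixed covariates; an intercept is always
        included and must not be supplied.
    alpha
        Family-wise error rate for the Bonferroni threshold in the QC block.

    Notes
    -----
    The variance ratio is profiled per marker by Brent search over
    log(lambda) on [1e-5, 1e5] (relative tolerance 1e-6).  The Wald
    statistic beta/se is referred to a t distribution with n - c degrees of
    freedom (c = number of fixed effects including the marker); with
    ``K = I`` this reduces exactly to the ordinary least-squares t test.
    Monomorphic markers are recorded with missing p.
    """
    y = np.asarray(y, dtype=float)
    n = g.n_samples
    if y.shape != (n,):
        raise ValueError("phenotype length must equal sample count")
    w_cols = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        w_cols.extend(cov.T)
    w_mat = np.column_stack(w_cols)
    if np.linalg.matrix_rank(w_mat) < w_mat.shape[1]:
        raise ValueError("singular covariate matrix")

    s, u = np.linalg.eigh(k.values)
    s = np.clip(s, 0.0, None)
    yr = u.T @ y
    wr = u.T @ w_mat
    x_all = g.imputed()

    log_lo, log_hi = np.log(1e-5), np.log(1e5)
    beta = np.full(g.n_markers, np.nan)
    se = np.full(g.n_markers, np.nan)
    pval = np.full(g.n_markers, np.nan)
    for j in range(g.n_markers):
        xj = x_all[:, j]
        if np.ptp(xj) == 0:
            continue
        xr = np.column_stack([wr, u.T @ xj])
        c = xr.shape[1]

        def crit(ll, xr=xr):
            return _reml_neg2ll(ll, s, xr, yr)[0]

        res = optimize.minimize_scalar(
            crit, bounds=(log_lo, log_hi), method="bounded", options={"xatol": 1e-6}
        )
        _, coef, rss, a = _reml_neg2ll(res.x, s, xr, yr)
        sigma2_e = rss / (n - c)
        cov_b = sigma2_e * np.linalg.inv(a)
        b_j = coef[-1]
        se_j = float(np.sqrt(cov_b[-1, -1]))
        t = b_j / se_j
        beta[j] = b_j
        se[j] = se_j
        pval[j] = 2.0 * stats.t.sf(abs(t), df=n - c)

    n_tests = int(np.isfinite(pval).sum())
    lam = genomic_inflation(pval[np.isfinite(pval)]) if n_tests else float("nan")
    thr, _ = bonferroni_threshold(max(n_tests, 1), alpha)
    results = g.gmap[["chrom", "pos", "id"]].copy()
    results["beta"] = beta
    results["se"] = se
    results["p"] = pval
    return AssocScan(results, lam, thr, n_tests)


def genomic_inflation(pvals: np.ndarray) -> float:
    """Genomic inflation factor lambda.

    Median of the 1-df chi-square quantile transform of the p-values,
    divided by the chi-square null median (0.4549364); ~1 for a
    well-calibrated scan.
    """
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """Bonferroni family-wise threshold: (p_threshold, -log10 threshold)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    p = alpha / n_tests
    return p, float(-np.log10(p))


def ld_r2(g: GenotypeMatrix, marker_i: int, marker_j: int) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples."""
    a = g.dosages[:, marker_i]
    b = g.dosages[:, marker_j]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("monomorphic marker in r^2 computation")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune_rescan(
    scan: AssocScan, g: GenotypeMatrix, r2_threshold: float = 0.2
) -> tuple[list[str], dict]:
    """Prune index markers and their LD partners for a re-scan.

    Per chromosome the lowest-p marker at or below the scan's significance
    threshold is the index; the index and every marker with r^2 strictly
    greater than ``r2_threshold`` to it are removed.  Returns surviving
    marker ids and a note describing what was pruned.
    """
    res = scan.results
    sig = res["p"] <= scan.threshold_p
    if not sig.any():
        return list(res["id"]), {"note": "no significant markers; nothing pruned"}
    drop: set[int] = set()
    indices: dict[str, str] = {}
    for chrom, grp in res[sig].groupby("chrom", sort=False):
        idx = int(grp["p"].idxmin())
        indices[str(chrom)] = str(res.loc[idx, "id"])
        drop.add(idx)
        for j in range(g.n_markers):
            if j == idx:
                continue
            try:
                if ld_r2(g, idx, j) > r2_threshold:
                    drop.add(j)
            except ValueError:
                continue
    keep = [str(res.loc[j, "id"]) for j in range(len(res)) if j not in drop]
    return keep, {"index_markers": indices, "n_pruned": len(drop)}
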