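"""Downstream effect modelling for a nominated causal variant.

Covers the post-mapping analyses: size-normalized linear measurements and
genotype-class tests (additive-effect checks across homozygous ancestral /
heterozygous / homozygous derived animals), stepwise proportion-of-variance
modelling across candidate loci, efficiency-corrected qPCR expression
ratios, allelic-imbalance ratios from read counts, cryptic splice-acceptor
scanning, and a transparent naive fold-change on count matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PVEResult",
    "SpliceScan",
    "normalize_by_centroid",
    "genotype_class_tests",
    "stepwise_pve",
    "pfaffl_ratio",
    "allele_ratio",
    "scan_acceptor_sites",
    "naive_fold_change",
]


@dataclass
class PVEResult:
    """Stepwise variance-explained summary.

    ``single_pve`` holds each locus's standalone R^2 (percent) — the
    maximum potential contribution of that genotype, not an additive
    share.  ``joint_pve`` is the R^2 of the selected multi-locus model.
    """

    single_pve: dict
    selected: list[str]
    joint_pve: float
    path: list[tuple[str, float]]  # (term added, criterion value after adding)
    criterion: str = "aic"


@dataclass
class SpliceScan:
    sequence: str
    junctions: list[int]
    junction_dinucleotides: list[str | None]
    junction_is_ag: list[bool | None]
    candidate_positions: list[int] = field(default_factory=list)


def normalize_by_centroid(measurements, centroid_sizes) -> np.ndarray:
    """Size-normalize linear measurements by centroid size (elementwise)."""
    m = np.asarray(measurements, dtype=float)
    c = np.asarray(centroid_sizes, dtype=float)
    if m.shape != c.shape:
        raise ValueError("measurements and centroid sizes must align")
    if np.any(c <= 0):
        raise ValueError("centroid sizes must be positive")
    return m / c


def _mww(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact null for combined n <= 20 without
    ties, tie-corrected normal approximation otherwise."""
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def genotype_class_tests(values, classes) -> dict:
    """Pairwise distribution tests plus an additive-trend regression.

    For every pair of genotype classes (dosage 0 = homozygous ancestral,
    1 = heterozygous, 2 = homozygous derived) a two-sided
    Mann-Whitney-Wilcoxon and a Kolmogorov-Smirnov test are run; classes
    with fewer than two observations are skipped with a note.  The
    additive trend is the least-squares slope of the value on dosage with
    its two-sided p.
    """
    y = np.asarray(values, dtype=float)
    d = np.asarray(classes, dtype=int)
    if y.shape != d.shape:
        raise ValueError("values and classes must align")
    present = sorted(np.unique(d))
    if len(present) < 2:
        raise ValueError("need at least two genotype classes")
    pairs = {}
    notes = []
    for i, ci in enumerate(present):
        for cj in present[i + 1 :]:
            a, b = y[d == ci], y[d == cj]
            if len(a) < 2 or len(b) < 2:
                notes.append(f"pair {ci}-{cj} skipped: class with n < 2")
                continue
            pairs[(ci, cj)] = {
                "mww_p": _mww(a, b),
                "ks_p": float(stats.ks_2samp(a, b).pvalue),
            }
    lr = stats.linregress(d.astype(float), y)
    return {
        "pairs": pairs,
        "trend_slope": float(lr.slope),
        "trend_p": float(lr.pvalue),
        "notes": notes,
    }


def _fit_r2_aic(y: np.ndarray, x: np.ndarray, criterion: str):
    model = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
    if criterion == "aic":
        crit = model.aic
    elif criterion == "bic":
        crit = model.bic
    elif criterion == "adjr2":
        crit = -model.rsquared_adj
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return float(model.rsquared), float(crit)


def stepwise_pve(
    phenotype,
    dosage_matrix,
    names: list[str] | None = None,
    criterion: str = "aic",
    min_improve: float = 0.0,
) -> PVEResult:
    """Single-locus and forward-stepwise proportion of variance explained.

    Each locus's PVE is 100 x R^2 of its single-predictor linear model.
    Forward selection then grows a joint model, at each step adding the
    predictor that most improves the criterion (AIC by default; BIC and
    adjusted R^2 available) and stopping when no addition improves it by
    more than ``min_improve``.  Samples with any missing dosage are
    dropped listwise.
    """
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(dosage_matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if names is None:
        names = [f"locus{i}" for i in range(x.shape[1])]
    keep = np.isfinite(y) & np.isfinite(x).all(axis=1)
    y, x = y[keep], x[keep]
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")

    single = {}
    for j, name in enumerate(names):
        r2, _ = _fit_r2_aic(y, x[:, [j]], "aic")
        single[name] = 100.0 * r2

    selected: list[int] = []
    path: list[tuple[str, float]] = []
    null_model = sm.OLS(y, np.ones((len(y), 1))).fit()
    best_crit = {
        "aic": float(null_model.aic),
        "bic": float(null_model.bic),
        "adjr2": 0.0,
    }[criterion]
    joint_r2 = 0.0
    while len(selected) < x.shape[1]:
        cand = [(j, *_fit_r2_aic(y, x[:, selected + [j]], criterion))
                for j in range(x.shape[1]) if j not in selected]
        j, r2, crit = min(cand, key=lambda t: t[2])
        if best_crit - crit <= min_improve:
            break
        selected.append(j)
        best_crit = crit
        joint_r2 = r2
        path.append((names[j], crit))
    return PVEResult(
        single, [names[j] for j in selected], 100.0 * joint_r2, path, criterion
    )


def pfaffl_ratio(
    ct_target_sample: float,
    ct_target_calibrator: float,
    ct_ref_sample: float,
    ct_ref_calibrator: float,
    eff_target: float = 2.0,
    eff_ref: float = 2.0,
) -> float:
    """Efficiency-corrected relative expression ratio.

    ratio = E_target^(Ct_cal - Ct_sample) / E_ref^(Ct_cal - Ct_sample),
    with per-assay amplification efficiencies E in (1, 2] (fold per cycle).
    """
    for e in (eff_target, eff_ref):
        if not 1.0 < e <= 2.0:
            raise ValueError("efficiency must be in (1, 2]")
    num = eff_target ** (ct_target_calibrator - ct_target_sample)
    den = eff_ref ** (ct_ref_calibrator - ct_ref_sample)
    return float(num / den)


def allele_ratio(count_a: int, count_b: int) -> tuple[int, int]:
    """Integer percentage pair summing to exactly 100 (largest remainder)."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    total = count_a + count_b
    if total == 0:
        raise ValueError("both counts zero")
    exact = (100.0 * count_a / total, 100.0 * count_b / total)
    floors = [int(np.floor(v)) for v in exact]
    short = 100 - sum(floors)
    remainders = [v - f for v, f in zip(exact, floors)]
    order = sorted(range(2), key=lambda i: remainders[i], reverse=True)
    for i in order[:short]:
        floors[i] += 1
    return floors[0], floors[1]


def scan_acceptor_sites(sequence: str, junctions: list[int]) -> SpliceScan:
    """Check splice junctions for the canonical AG acceptor dinucleotide.

    For each junction offset (0-based position of the first exonic base)
    the two bases immediately preceding it are reported with an is-AG
    flag; junctions with offset < 2 are not assessable (None).  All
    positions in the sequence that could act as acceptors (preceded by
    "AG") are also enumerated.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over A/C/G/T/N")
    dints: list[str | None] = []
    flags: list[bool | None] = []
    for j in junctions:
        if not 0 <= j <= len(seq):
            raise ValueError(f"junction {j} outside sequence")
        if j < 2:
            dints.append(None)
            flags.append(None)
        else:
            d = seq[j - 2 : j]
            dints.append(d)
            flags.append(d == "AG")
    candidates = [i for i in range(2, len(seq) + 1) if seq[i - 2 : i] == "AG"]
    return SpliceScan(seq, list(junctions), dints, flags, candidates)


def naive_fold_change(
    counts_group1: np.ndarray, counts_group2: np.ndarray
) -> np.ndarray:
    """Median-of-ratios normalized per-gene fold change (group2 / group1).

    A transparent descriptive statistic, not a differential-expression
    inference: library size factors are the median across genes of each
    sample's ratio to the per-gene geometric mean (genes with any zero
    excluded from factor estimation), and the fold change is the ratio of
    mean normalized counts.  Orientation: group2 over group1 (e.g.
    non-carriers over carriers to express a reduction as > 1).
    """
    c1 = np.atleast_2d(np.asarray(counts_group1, dtype=float))
    c2 = np.atleast_2d(np.asarray(counts_group2, dtype=float))
    if c1.shape[0] != c2.shape[0]:
        raise ValueError("groups must share the gene axis")
    all_counts = np.hstack([c1, c2])
    if np.any(all_counts.sum(axis=0) == 0):
        raise ValueError("zero library size")
    with np.errstate(divide="ignore"):
        log_gm = np.log(all_counts).mean(axis=1)
    usable = np.isfinite(log_gm)
    if not usable.any():
        raise ValueError("no gene with all-positive counts for normalization")
    sf = np.exp(
        np.median(np.log(all_counts[usable]) - log_gm[usable, None], axis=0)
    )
    norm = all_counts / sf
    n1 = c1.shape[1]
    mean1 = norm[:, :n1].mean(axis=1)
    mean2 = norm[:, n1:].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mean2 / mean1
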