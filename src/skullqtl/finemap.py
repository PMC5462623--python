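"""Haplotype fine-mapping: sliding-window tests, consensus haplotype, and
recombination-count critical intervals.

Given a phased panel and a shape phenotype (facial PC1, oriented so
brachycephalic animals are negative), the locus is narrowed in four steps:

1. :func:`window_haplotype_assoc` — omnibus ANOVA of the phenotype across
   the distinct haplotypes of each sliding marker window.
2. :func:`select_cases` — restrict to the phenotype tail (e.g. PC1 <= -0.2)
   whose chromosomes are expected to be fixed for the causal variant.
3. :func:`consensus_haplotype` — per-marker majority allele over case
   chromosome copies.
4. :func:`critical_interval` — walk outward from the index marker and stop
   once at least ``min_recomb`` distinct case copies have recombined away
   from the consensus on each side; the markers strictly inside those two
   boundary gaps form the critical interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HaplotypePanel",
    "ConsensusHaplotype",
    "CriticalInterval",
    "CarrierStats",
    "window_haplotype_assoc",
    "select_cases",
    "consensus_haplotype",
    "critical_interval",
    "interval_length",
    "carrier_stats",
    "select_core_markers",
]


@dataclass
class HaplotypePanel:
    """Phased allele matrix: chromosome copies x markers, values in {0,1}.

    Copies are stored sample-major: rows ``2i`` and ``2i+1`` are copies A
    and B of ``sample_ids[i]``.  ``gmap`` carries chrom / 1-based pos /
    id / ref / alt per marker.
    """

    sample_ids: list[str]
    alleles: np.ndarray
    gmap: pd.DataFrame

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be copies x markers")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("need exactly two copies per sample")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be binary")
        if len(self.gmap) != self.alleles.shape[1]:
            raise ValueError("map length must equal marker count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    @property
    def copy_ids(self) -> list[str]:
        return [f"{s}_{c}" for s in self.sample_ids for c in ("A", "B")]

    def copy_sample_index(self) -> np.ndarray:
        """Sample index of each chromosome copy row."""
        return np.repeat(np.arange(self.n_samples), 2)

    def dosages(self) -> np.ndarray:
        """Per-sample alt-dosage matrix (sum of the two copies)."""
        return self.alleles[0::2].astype(float) + self.alleles[1::2]


@dataclass
class ConsensusHaplotype:
    marker_indices: np.ndarray  # indices into the panel's map
    alleles: np.ndarray
    support: np.ndarray  # per-marker fraction of case copies matching

    def __post_init__(self) -> None:
        self.marker_indices = np.asarray(self.marker_indices, dtype=int)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.support = np.asarray(self.support, dtype=float)

    def restrict(self, marker_indices: np.ndarray) -> "ConsensusHaplotype":
        pos = {m: i for i, m in enumerate(self.marker_indices)}
        sel = np.array([pos[m] for m in np.asarray(marker_indices, int)])
        return ConsensusHaplotype(
            self.marker_indices[sel], self.alleles[sel], self.support[sel]
        )


@dataclass
class CriticalInterval:
    chrom: str
    start_pos: int  # 1-based position of the leftmost included marker
    end_pos: int  # 1-based position of the rightmost included marker
    start_marker: int  # marker index (into the panel) of the left boundary
    end_marker: int
    left_breakpoints: int  # case copies recombining at/beyond the left gap
    right_breakpoints: int
    core_haplotype: ConsensusHaplotype
    hit_edge: bool = False  # breakpoint quota not reached; clipped to panel
    excluded_copies: list[int] = field(default_factory=list)  # index mismatch

    def marker_indices(self) -> np.ndarray:
        return np.arange(self.start_marker, self.end_marker + 1)


@dataclass
class CarrierStats:
    """Carrier counts per phenotype group plus a carrier t test."""

    counts: dict  # group -> (carrier copies, total copies)
    frequencies_pct: dict  # group -> exact percentage
    t_stat: float
    t_p: float
    note: str = ""

    def frequency_str(self, group: str) -> str:
        return f"{self.frequencies_pct[group]:.1f}"


def window_haplotype_assoc(
    panel: HaplotypePanel,
    phenotype: np.ndarray,
    window: int = 10,
    step: int = 1,
    min_copies: int = 5,
) -> pd.DataFrame:
    """Sliding-window haplotype ANOVA.

    Within each window of ``window`` consecutive markers the distinct
    haplotypes are enumerated; classes carried by fewer than ``min_copies``
    chromosome copies are pooled into a single rare class; a one-way ANOVA
    of the per-copy phenotype (each sample contributes its phenotype once
    per copy) across classes yields the window p-value.  Windows with fewer
    than two classes after pooling get a missing p.

    Returns a DataFrame with ``start`` (marker index), ``pos`` (first-marker
    coordinate) and ``p``.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape != (panel.n_samples,):
        raise ValueError("phenotype length must equal sample count")
    if window > panel.n_markers:
        raise ValueError("window exceeds marker count")
    y_copy = np.repeat(y, 2)
    rows = []
    for s0 in range(0, panel.n_markers - window + 1, step):
        block = panel.alleles[:, s0 : s0 + window]
        _, inverse, counts = np.unique(
            block, axis=0, return_inverse=True, return_counts=True
        )
        rare = counts[inverse] < min_copies
        classes = inverse.astype(int).copy()
        classes[rare] = -1
        uniq = np.unique(classes)
        groups = [y_copy[classes == c] for c in uniq]
        groups = [grp for grp in groups if len(grp) > 0]
        if len(groups) < 2 or np.ptp(y_copy) == 0:
            p = np.nan
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = stats.f_oneway(*groups)
            p = float(p) if np.isfinite(p) else np.nan
        rows.append((s0, int(panel.gmap["pos"].iloc[s0]), p))
    return pd.DataFrame(rows, columns=["start", "pos", "p"])


def select_cases(
    phenotype: np.ndarray, threshold: float = -0.2, rule: str = "le"
) -> np.ndarray:
    """Boolean case mask: phenotype <= threshold ("le") or < ("lt")."""
    y = np.asarray(phenotype, dtype=float)
    if rule == "le":
        mask = y <= threshold
    elif rule == "lt":
        mask = y < threshold
    elif rule in ("ge", "gt"):
        mask = y >= threshold if rule == "ge" else y > threshold
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if not mask.any():
        raise ValueError("empty case set")
    return mask


def consensus_haplotype(
    case_alleles: np.ndarray, copy_phenotype: np.ndarray | None = None
) -> ConsensusHaplotype:
    """Per-marker majority allele over case chromosome copies.

    Exact 50:50 ties are broken toward the allele carried by the copy with
    the most negative phenotype (the most extreme case); without a
    phenotype, toward the first copy's allele.
    """
    h = np.asarray(case_alleles, dtype=np.int8)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValueError("need >= 1 case copy")
    n = h.shape[0]
    ones = h.sum(axis=0)
    cons = (ones * 2 > n).astype(np.int8)
    tie = ones * 2 == n
    if tie.any():
        ref = 0 if copy_phenotype is None else int(np.argmin(copy_phenotype))
        cons[tie] = h[ref, tie]
    match_frac = (h == cons).mean(axis=0)
    return ConsensusHaplotype(np.arange(h.shape[1]), cons, match_frac)


def _matching_run(match_row: np.ndarray, index: int) -> tuple[int, int]:
    """Maximal run of consecutive True containing ``index`` (inclusive ends)."""
    lo = index
    while lo > 0 and match_row[lo - 1]:
        lo -= 1
    hi = index
    m = len(match_row)
    while hi < m - 1 and match_row[hi + 1]:
        hi += 1
    return lo, hi


def critical_interval(
    case_alleles: np.ndarray,
    consensus: ConsensusHaplotype,
    index_marker: int,
    gmap: pd.DataFrame,
    min_recomb: int = 3,
) -> CriticalInterval:
    """Recombination-count critical interval around an index marker.

    For every case copy matching the consensus at the index marker, the
    maximal consensus-matching run containing the index defines one left
    and one right breakpoint (the gaps immediately outside the run; a run
    reaching the panel edge contributes none on that side).  Walking
    outward from the index, each boundary is placed at the first inter-
    marker gap where the cumulative number of distinct recombining copies
    reaches ``min_recomb``; the interval spans the markers strictly inside
    the two boundary gaps.  Copies mismatching the consensus AT the index
    are non-carriers: they are excluded from breakpoint counting and
    reported in ``excluded_copies``.

    If a side never accumulates ``min_recomb`` breakpoints the interval is
    clipped to the panel edge and flagged via ``hit_edge``.
    """
    h = np.asarray(case_alleles, dtype=np.int8)
    m = h.shape[1]
    if not 0 <= index_marker < m:
        raise ValueError("index marker outside the map")
    if len(consensus.alleles) != m:
        raise ValueError("consensus must cover all markers")
    match = h == consensus.alleles[None, :]

    excluded = [i for i in range(h.shape[0]) if not match[i, index_marker]]
    carriers = [i for i in range(h.shape[0]) if match[i, index_marker]]

    left_gaps: list[int] = []  # gap g sits between markers g and g+1
    right_gaps: list[int] = []
    for i in carriers:
        lo, hi = _matching_run(match[i], index_marker)
        if lo > 0:
            left_gaps.append(lo - 1)
        if hi < m - 1:
            right_gaps.append(hi)

    hit_edge = False
    # left boundary: walk gaps index-1, index-2, ... accumulating breakpoints
    lg = np.sort(np.asarray(left_gaps, dtype=int))[::-1]
    if len(lg) >= min_recomb:
        g_left = int(lg[min_recomb - 1])
        start_marker = g_left + 1
        left_count = int((np.asarray(left_gaps) >= g_left).sum())
    else:
        start_marker = 0
        left_count = len(left_gaps)
        hit_edge = True
    rg = np.sort(np.asarray(right_gaps, dtype=int))
    if len(rg) >= min_recomb:
        g_right = int(rg[min_recomb - 1])
        end_marker = g_right
        right_count = int((np.asarray(right_gaps) <= g_right).sum())
    else:
        end_marker = m - 1
        right_count = len(right_gaps)
        hit_edge = True

    core = consensus.restrict(np.arange(start_marker, end_marker + 1))
    return CriticalInterval(
        chrom=str(gmap["chrom"].iloc[index_marker]),
        start_pos=int(gmap["pos"].iloc[start_marker]),
        end_pos=int(gmap["pos"].iloc[end_marker]),
        start_marker=start_marker,
        end_marker=end_marker,
        left_breakpoints=left_count,
        right_breakpoints=right_count,
        core_haplotype=core,
        hit_edge=hit_edge,
        excluded_copies=excluded,
    )


def interval_length(interval: CriticalInterval) -> int:
    """Interval length in bp under the end - start convention."""
    return int(interval.end_pos - interval.start_pos)


def carrier_stats(
    panel: HaplotypePanel,
    core_haplotype: ConsensusHaplotype,
    phenotype: np.ndarray,
    threshold: float = -0.2,
    rule: str = "le",
) -> CarrierStats:
    """Carrier frequencies of a core haplotype and a carrier phenotype test.

    A chromosome copy carries the haplotype iff it matches the core allele
    at every defining marker.  Copies are split into the case group
    (phenotype passes the threshold rule) and the rest; frequencies are the
    exact percentage of carrier copies per group.  A two-sided pooled t
    test compares the phenotype of carrier samples (>= 1 carrier copy)
    against non-carrier samples.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape != (panel.n_samples,):
        raise ValueError("phenotype length must equal sample count")
    idx = core_haplotype.marker_indices
    if idx.max() >= panel.n_markers:
        raise ValueError("core haplotype markers outside panel")
    carrier_copy = (panel.alleles[:, idx] == core_haplotype.alleles[None, :]).all(axis=1)
    case_mask = select_cases(y, threshold, rule)
    copy_case = np.repeat(case_mask, 2)
    counts = {
        "case": (int(carrier_copy[copy_case].sum()), int(copy_case.sum())),
        "control": (int(carrier_copy[~copy_case].sum()), int((~copy_case).sum())),
    }
    freqs = {
        grp: (100.0 * c / t if t else float("nan")) for grp, (c, t) in counts.items()
    }
    carrier_sample = carrier_copy.reshape(-1, 2).any(axis=1)
    note = ""
    if carrier_sample.all() or not carrier_sample.any():
        t_stat, t_p = float("nan"), float("nan")
        note = "carrier t test skipped: only one carrier class present"
    else:
        t_stat, t_p = stats.ttest_ind(y[carrier_sample], y[~carrier_sample])
        t_stat, t_p = float(t_stat), float(t_p)
    return CarrierStats(counts, freqs, t_stat, t_p, note)


def select_core_markers(
    interval: CriticalInterval,
    scan_p: np.ndarray,
    p_threshold: float,
    r2_to_index: np.ndarray | None = None,
    r2_threshold: float = 0.2,
) -> ConsensusHaplotype:
    """Defining-marker subset of the interval's consensus.

    Markers inside the interval whose single-marker association p passes
    the genome-wide threshold, or whose r^2 with the index marker exceeds
    the pruning threshold, define the reported core haplotype (the
    "12-SNP" style signature).
    """
    idx = interval.marker_indices()
    keep = np.asarray(scan_p, dtype=float)[idx] <= p_threshold
    if r2_to_index is not None:
        keep |= np.asarray(r2_to_index, dtype=float)[idx] > r2_threshold
    if not keep.any():
        raise ValueError("no markers pass the core-haplotype selection rule")
    return interval.core_haplotype.restrict(idx[keep])
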