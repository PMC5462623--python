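"""Identity-by-descent variant filtering over multi-sample variant tables.

Candidate causal variants inside a critical interval are nominated by five
logical assumptions about a haplotype shared identical-by-descent:

1. case samples homozygous for the associated haplotype carry the causal
   variant;
2. haplotype sharing implies identity-by-descent, so all such cases carry
   the SAME causal allele — they must be uniformly homozygous for it;
3. the causal allele may be the REFERENCE allele (the dog assembly derives
   from a breed fixed for the haplotype), so REF and ALT are candidate
   alleles on equal footing;
4. the causal allele is derived and therefore absent from wild canids;
5. haplotype-free (dolichocephalic) controls cannot carry it.

Assumptions 1-3 collapse into candidate-allele assignment
(:func:`assign_candidate_allele`); 4 and 5 are carrier screens against the
wild and control panels.  Missing genotypes are non-informative by default:
an absent call never eliminates a record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VariantRecord",
    "VariantTable",
    "SampleGroups",
    "FilterReport",
    "assign_candidate_allele",
    "filter_variants",
    "complete_ld_check",
]

MISSING = (-1, -1)


@dataclass
class VariantRecord:
    """One variant with per-sample genotypes as allele-index pairs.

    ``genotypes[sample] = (i, j)`` with 0 = REF, 1.. = ALT index + 1 and
    ``(-1, -1)`` for missing.  ``vtype`` is "SNV", "INDEL" or "SV".
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    vtype: str
    genotypes: dict[str, tuple[int, int]]

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    def allele_name(self, index: int) -> str:
        return self.ref if index == 0 else self.alts[index - 1]


@dataclass
class VariantTable:
    records: list[VariantRecord]
    sample_ids: list[str]
    region: tuple[str, int, int] | None = None  # chrom, start, end (1-based)

    def __post_init__(self) -> None:
        if self.region is not None:
            chrom, start, end = self.region
            for r in self.records:
                if r.chrom != chrom or not start <= r.pos <= end:
                    raise ValueError(
                        f"record {r.chrom}:{r.pos} outside region {chrom}:{start}-{end}"
                    )

    def counts_by_class(self) -> dict[str, int]:
        """Record counts pooled as SNV/INDEL vs SV (the two report rows)."""
        out = {"snv_indel": 0, "sv": 0}
        for r in self.records:
            out["sv" if r.vtype == "SV" else "snv_indel"] += 1
        return out


@dataclass
class SampleGroups:
    """Disjoint, non-empty sample groups for the filter."""

    case_hom: list[str]
    control: list[str]
    wild: list[str]

    def __post_init__(self) -> None:
        for name in ("case_hom", "control", "wild"):
            if not getattr(self, name):
                raise ValueError(f"group {name!r} is empty")
        sets = [set(self.case_hom), set(self.control), set(self.wild)]
        if len(sets[0] | sets[1] | sets[2]) != sum(len(s) for s in sets):
            raise ValueError("sample groups must be disjoint")


@dataclass
class FilterReport:
    pre_counts: dict[str, int]
    post_counts: dict[str, int]
    eliminations: dict[str, int]  # first-failing rule -> count
    survivors: list[tuple[int, int]]  # (record index, candidate allele index)
    no_data: int = 0
    extra: dict = field(default_factory=dict)

    def survivor_indices(self) -> list[int]:
        return [i for i, _ in self.survivors]


def _carries(gt: tuple[int, int], allele: int) -> bool:
    return gt != MISSING and allele in gt


def assign_candidate_allele(record: VariantRecord, groups: SampleGroups):
    """Candidate allele under the fixation/IBD assumptions, or a rejection.

    Returns ``(allele_index, None)`` when every non-missing haplotype-
    homozygous case is homozygous for the same single allele (which may be
    the reference allele), else ``(None, reason)`` with reason
    ``"no_data"`` (all case genotypes missing) or ``"not_fixed"``.
    """
    seen: set[int] = set()
    any_call = False
    for s in groups.case_hom:
        gt = record.genotypes.get(s, MISSING)
        if gt == MISSING:
            continue
        any_call = True
        if gt[0] != gt[1]:
            return None, "not_fixed"
        seen.add(gt[0])
        if len(seen) > 1:
            return None, "not_fixed"
    if not any_call:
        return None, "no_data"
    return seen.pop(), None


def filter_variants(
    table: VariantTable, groups: SampleGroups, strict: bool = False
) -> FilterReport:
    """Apply the five identity-by-descent assumptions to every record.

    A record survives iff (i) a candidate allele can be assigned, (ii) no
    non-missing wild canid carries the candidate, (iii) no non-missing
    control carries it.  Eliminations are tallied by the first failing
    rule (``not_fixed`` / ``wild_carrier`` / ``control_carrier``);
    records with no case data are tallied separately as ``no_data``.

    ``strict=True`` additionally requires at least one non-missing wild and
    control call, excluding records that cannot be screened (reason
    ``insufficient_screen_data``).
    """
    elim = {"not_fixed": 0, "wild_carrier": 0, "control_carrier": 0}
    if strict:
        elim["insufficient_screen_data"] = 0
    survivors: list[tuple[int, int]] = []
    no_data = 0
    for i, rec in enumerate(table.records):
        cand, reason = assign_candidate_allele(rec, groups)
        if cand is None:
            if reason == "no_data":
                no_data += 1
            else:
                elim[reason] += 1
            continue
        wild_gts = [rec.genotypes.get(s, MISSING) for s in groups.wild]
        ctrl_gts = [rec.genotypes.get(s, MISSING) for s in groups.control]
        if strict and (
            all(g == MISSING for g in wild_gts) or all(g == MISSING for g in ctrl_gts)
        ):
            elim["insufficient_screen_data"] += 1
            continue
        if any(_carries(g, cand) for g in wild_gts):
            elim["wild_carrier"] += 1
            continue
        if any(_carries(g, cand) for g in ctrl_gts):
            elim["control_carrier"] += 1
            continue
        survivors.append((i, cand))

    pre = table.counts_by_class()
    post = {"snv_indel": 0, "sv": 0}
    for i, _ in survivors:
        post["sv" if table.records[i].vtype == "SV" else "snv_indel"] += 1
    return FilterReport(pre, post, elim, survivors, no_data)


def complete_ld_check(
    carrier_status: np.ndarray, labels: list[str] | None = None, tol: float = 1e-9
):
    """Pairwise r^2 of survivor carrier vectors over an extended cohort.

    ``carrier_status`` is records x samples (1 = sample carries that
    record's candidate allele).  Returns ``(r2_matrix, complete)`` where
    ``complete`` is True iff every assessable pair has r^2 = 1 within
    ``tol``; monomorphic records yield NaN rows/columns (not assessable).
    """
    c = np.asarray(carrier_status, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need >= 2 survivors")
    k = c.shape[0]
    r2 = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            if np.ptp(c[i]) == 0 or np.ptp(c[j]) == 0:
                continue
            r = np.corrcoef(c[i], c[j])[0, 1]
            r2[i, j] = r2[j, i] = r * r
    off = r2[~np.eye(k, dtype=bool)]
    assessable = off[np.isfinite(off)]
    complete = bool(assessable.size) and bool((np.abs(assessable - 1.0) <= tol).all())
    return r2, complete
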