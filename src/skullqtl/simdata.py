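"""Synthetic studies with known ground truth.

Generates desk-scale cohorts that reproduce the statistical structure the
downstream stages assume:

* breed-structured diploid genotypes — Balding-Nichols breed allele
  frequencies over LD blocks built by copying founder haplotypes, with a
  contiguous multi-marker causal haplotype planted at high frequency in
  designated "case" breeds;
* landmark configurations built from a mean shape plus isometric size,
  allometric shape change, an additive QTL displacement confined to the
  facial (viscerocranium) landmarks, and Gaussian noise, wrapped in random
  similarity transforms so Procrustes alignment is genuinely exercised;
* multi-group variant tables (haplotype-homozygous cases, haplotype-free
  controls, wild canids) in which a known subset of records satisfies all
  five identity-by-descent filtering assumptions and every other record
  violates at least one;
* binomial allele-specific read counts.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import GenotypeMatrix
from .finemap import HaplotypePanel
from .morpho import LandmarkSet
from .varfilter import MISSING, SampleGroups, VariantRecord, VariantTable

__all__ = [
    "SimConfig",
    "SyntheticStudy",
    "simulate_genotypes",
    "simulate_landmarks",
    "simulate_variant_table",
    "simulate_ase_counts",
    "simulate_study",
]

#: landmark split mirroring the real study's substructure sizes
_MASK_WEIGHTS = {"neurocranium": 18, "viscerocranium": 25, "mandible": 30}


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults emulate the real study's design: 374 dogs across many breeds,
    a 12-SNP causal haplotype near-fixed in brachycephalic (case) breeds
    (observed case-chromosome frequency ~85%) and rare elsewhere (~4%),
    73 landmarks split 18/25/30 across neurocranium / viscerocranium /
    mandible, and 3-D coordinates.
    """

    n_dogs: int = 374
    n_breeds: int = 12
    fst: float = 0.15
    n_snps: int = 1000
    ld_block_len: int = 25
    causal_markers: int = 12
    causal_freq_case_breeds: float = 0.9
    causal_freq_other: float = 0.04
    n_landmarks: int = 73
    dims: int = 3
    allometry_slope: float = 0.15
    qtl_effect: float = 0.06
    noise_sd: float = 0.01
    seed: int = 0
    n_case_breeds: int = 3
    n_founders: int | None = None  # per-breed founder pool; default ~1/fst
    mutation_rate: float = 0.01
    log_size_sd: float = 0.3
    base_size: float = 100.0  # mean centroid size, length units (~mm)

    def __post_init__(self) -> None:
        for f_ in (self.causal_freq_case_breeds, self.causal_freq_other):
            if not 0.0 <= f_ <= 1.0:
                raise ValueError("haplotype frequencies must be in [0,1]")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0,1)")
        if self.causal_markers > self.n_snps:
            raise ValueError("causal_markers must be <= n_snps")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if not 1 <= self.n_case_breeds <= self.n_breeds:
            raise ValueError("n_case_breeds must be in 1..n_breeds")


@dataclass
class SyntheticStudy:
    haplotypes: HaplotypePanel
    genotypes: GenotypeMatrix
    breed_labels: np.ndarray
    truth: dict
    landmarks: LandmarkSet
    variant_table: VariantTable
    groups: SampleGroups


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


def simulate_genotypes(config: SimConfig):
    """Breed-structured phased genotypes with a planted causal haplotype.

    Balding-Nichols structure: each LD block draws an ancestral frequency
    p0 ~ U(0.1, 0.9) shared by its markers; each breed's block frequency is
    Beta-distributed around p0 with variance fst * p0 * (1 - p0).  Within a
    block each chromosome copy inherits one of a small set of breed founder
    haplotypes (alleles Bernoulli(breed frequency)) with a ~1% per-site
    copying-error rate, producing realistic within-block r^2 without a
    coalescent simulation.  A contiguous run of ``causal_markers`` markers
    is then overwritten with the all-alt planted haplotype on each copy
    with probability ``causal_freq_case_breeds`` in the first
    ``n_case_breeds`` breeds and ``causal_freq_other`` elsewhere.

    Returns ``(panel, genotypes, breed_labels, truth)``; genotype dosages
    are the sums of the two copies by construction.
    """
    rng = _rng(config.seed, 0)
    n, m = config.n_dogs, config.n_snps
    breed = np.arange(n) % config.n_breeds
    copies = np.zeros((2 * n, m), dtype=np.int8)
    copy_breed = np.repeat(breed, 2)

    block_edges = list(range(0, m, config.ld_block_len)) + [m]
    f = config.fst
    # breed founder bottleneck: drift and frequency divergence share one
    # cause, so the pool size scales inversely with fst (fst -> 0 recovers
    # a panmictic population with vanishing breed differentiation)
    n_founders = config.n_founders or int(np.clip(round(1 / f), 2, 500))
    c0 = (m - config.causal_markers) // 2
    causal_idx = np.arange(c0, c0 + config.causal_markers)
    for b0, b1 in zip(block_edges[:-1], block_edges[1:]):
        blen = b1 - b0
        if b0 <= causal_idx[-1] and b1 > causal_idx[0]:
            # the planted haplotype is a derived sweep: its alt alleles are
            # rare on non-carrier backgrounds
            p0 = rng.uniform(0.02, 0.1)
        else:
            p0 = rng.uniform(0.1, 0.9)
        for br in range(config.n_breeds):
            if f < 1e-9:
                pb = p0
            else:
                a = p0 * (1 - f) / f
                bb = (1 - p0) * (1 - f) / f
                pb = rng.beta(a, bb)
            founders = (rng.random((n_founders, blen)) < pb).astype(np.int8)
            rows = np.where(copy_breed == br)[0]
            pick = rng.integers(0, n_founders, size=rows.size)
            block = founders[pick]
            flips = rng.random(block.shape) < config.mutation_rate
            copies[rows, b0:b1] = block ^ flips

    planted = np.ones(config.causal_markers, dtype=np.int8)
    case_breeds = np.arange(config.n_case_breeds)
    freq = np.where(
        np.isin(copy_breed, case_breeds),
        config.causal_freq_case_breeds,
        config.causal_freq_other,
    )
    carrier = rng.random(2 * n) < freq
    copies[np.where(carrier)[0][:, None], causal_idx[None, :]] = planted

    spacing = rng.integers(200, 2000, size=m)
    pos = 55_000_000 + np.cumsum(spacing)
    gmap = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos.astype(int),
            "id": [f"snp{i}" for i in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    sample_ids = [f"dog{i:03d}" for i in range(n)]
    panel = HaplotypePanel(sample_ids, copies, gmap)
    dosage = panel.dosages()
    genotypes = GenotypeMatrix(sample_ids, dosage, gmap.copy())
    truth = {
        "causal_indices": causal_idx,
        "planted_alleles": planted,
        "causal_dosage": carrier.reshape(-1, 2).sum(axis=1).astype(int),
        "carrier_copy": carrier,
        "case_breeds": case_breeds,
    }
    return panel, genotypes, breed, truth


def simulate_landmarks(dosage: np.ndarray, config: SimConfig):
    """Landmark configurations with size, allometry and a planted QTL effect.

    Specimen i is ``s_i * R_i (M + log(s_i) A + d_i q V + E_i) + t_i``:
    a unit-centroid-size mean shape M, allometric direction A (scaled by
    ``allometry_slope`` per log-size unit), a unit-norm QTL displacement V
    confined to the viscerocranium landmarks dosed by ``d_i * qtl_effect``,
    iid Gaussian landmark noise, and a random similarity transform
    (uniform proper rotation, log-normal size, Gaussian translation).

    Returns ``(landmarks, truth)`` with the generative directions recorded.
    """
    d_vec = np.asarray(dosage, dtype=float)
    n = d_vec.shape[0]
    if n != config.n_dogs:
        raise ValueError("dosage length must equal n_dogs")
    rng = _rng(config.seed, 1)
    k, dm = config.n_landmarks, config.dims

    total_w = sum(_MASK_WEIGHTS.values())
    counts = {nm: max(2, round(k * w / total_w)) for nm, w in _MASK_WEIGHTS.items()}
    counts["mandible"] = k - counts["neurocranium"] - counts["viscerocranium"]
    if counts["mandible"] < 2:
        raise ValueError("n_landmarks too small to split into substructures")
    edges = np.cumsum([0, counts["neurocranium"], counts["viscerocranium"], counts["mandible"]])
    masks = {
        "neurocranium": np.arange(edges[0], edges[1]),
        "viscerocranium": np.arange(edges[1], edges[2]),
        "mandible": np.arange(edges[2], edges[3]),
    }

    mean_shape = rng.standard_normal((k, dm))
    mean_shape -= mean_shape.mean(axis=0)
    mean_shape /= np.sqrt((mean_shape**2).sum())

    allo = rng.standard_normal((k, dm))
    allo /= np.sqrt((allo**2).sum())
    allo *= config.allometry_slope

    qtl = np.zeros((k, dm))
    qtl[masks["viscerocranium"]] = rng.standard_normal(
        (len(masks["viscerocranium"]), dm)
    )
    qtl /= np.sqrt((qtl**2).sum())

    log_rel = rng.normal(0.0, config.log_size_sd, size=n)
    sizes = config.base_size * np.exp(log_rel)
    coords = np.empty((n, k, dm))
    for i in range(n):
        shape = (
            mean_shape
            + np.log(sizes[i]) * allo
            + d_vec[i] * config.qtl_effect * qtl
            + rng.normal(0.0, config.noise_sd, size=(k, dm))
        )
        rot = _random_rotation(rng, dm)
        trans = rng.normal(0.0, 50.0, size=dm)
        coords[i] = sizes[i] * (shape @ rot) + trans

    ids = [f"dog{i:03d}" for i in range(n)]
    truth = {
        "mean_shape": mean_shape,
        "allometry_direction": allo,
        "qtl_direction": qtl,
        "sizes": sizes,
        "dosage": d_vec,
        "masks": masks,
    }
    return LandmarkSet(ids, coords, masks), truth


def _random_rotation(rng: np.random.Generator, d: int) -> np.ndarray:
    """Uniform proper rotation (det = +1, no reflection)."""
    if d == 2:
        th = rng.uniform(0, 2 * np.pi)
        return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    q, r = np.linalg.qr(rng.standard_normal((d, d)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


# ordered so violations are spread across the five filtering assumptions
_VIOLATIONS = (
    "not_fixed_het",  # assumption 1: a haplotype-homozygous case is het
    "not_fixed_split",  # assumption 2: cases fixed for different alleles
    "ref_candidate_control_carrier",  # assumption 3 path, killed by rule 5
    "wild_carrier",  # assumption 4: a wild canid carries the candidate
    "control_carrier",  # assumption 5: a haplotype-free control carries it
)


def simulate_variant_table(
    groups_spec: dict | SampleGroups,
    n_snvs: int,
    n_svs: int,
    n_true_snvs: int,
    n_true_svs: int,
    seed: int,
    region: tuple[str, int, int] = ("chr1", 55_850_299, 56_037_676),
):
    """Variant table in which exactly the planted records pass the filter.

    Planted-true records satisfy all five assumptions (the first planted
    SNV, when present, has the REFERENCE allele as its candidate — the
    derived-allele-in-the-assembly scenario); every other record violates
    at least one assumption, with first-violated rules cycled across the
    five assumptions, and a sprinkling of records with no case data.

    ``groups_spec`` is either a ``SampleGroups`` or a mapping
    ``{"case_hom": n, "control": n, "wild": n}``.

    Returns ``(table, groups, truth_indices)``.
    """
    if isinstance(groups_spec, SampleGroups):
        groups = groups_spec
    else:
        for name in ("case_hom", "control", "wild"):
            if groups_spec.get(name, 0) in (0, None, []):
                raise ValueError(f"group {name!r} is empty")
        mk = lambda p, c: [f"{p}{i:02d}" for i in range(c)]
        spec = {
            nm: (v if isinstance(v, list) else mk(nm, v))
            for nm, v in groups_spec.items()
        }
        groups = SampleGroups(spec["case_hom"], spec["control"], spec["wild"])
    if n_true_snvs > n_snvs or n_true_svs > n_svs:
        raise ValueError("planted-true counts exceed record counts")

    rng = np.random.default_rng(seed)
    chrom, start, end = region
    n_rec = n_snvs + n_svs
    pos = np.sort(rng.choice(np.arange(start, end + 1), size=n_rec, replace=False))
    vtypes = ["INDEL" if rng.random() < 0.05 else "SNV" for _ in range(n_snvs)]
    vtypes += ["SV"] * n_svs
    order = rng.permutation(n_rec)
    vtypes = [vtypes[i] for i in order]
    snv_positions = [i for i, v in enumerate(vtypes) if v != "SV"]
    sv_positions = [i for i, v in enumerate(vtypes) if v == "SV"]
    true_idx = sorted(
        list(rng.choice(snv_positions, size=n_true_snvs, replace=False))
        + list(rng.choice(sv_positions, size=n_true_svs, replace=False))
    )
    true_set = set(int(i) for i in true_idx)
    ref_candidate_idx = min(true_set) if true_set else None

    samples = groups.case_hom + groups.control + groups.wild
    records: list[VariantRecord] = []
    viol_cycle = 0
    bases = "ACGT"
    for i in range(n_rec):
        vt = vtypes[i]
        if vt == "SV":
            ref, alts = "N", ("<INS>",)
        elif vt == "INDEL":
            ref, alts = "AT", ("A",)
        else:
            r = bases[rng.integers(4)]
            a = bases[(bases.index(r) + 1 + rng.integers(3)) % 4]
            ref, alts = r, (a,)
        gts: dict[str, tuple[int, int]] = {}

        def fill(names, gt):
            for s in names:
                gts[s] = gt

        if i in true_set:
            cand = 0 if i == ref_candidate_idx else 1
            other = 1 - cand
            fill(groups.case_hom, (cand, cand))
            fill(groups.control, (other, other))
            fill(groups.wild, (other, other))
            # missing calls are non-informative; drop a few (never all cases)
            for s in groups.control + groups.wild:
                if rng.random() < 0.1:
                    gts[s] = MISSING
            for s in groups.case_hom[1:]:
                if rng.random() < 0.1:
                    gts[s] = MISSING
        elif rng.random() < 0.01:
            # no case data at all: excluded (not eliminated) by the filter
            fill(groups.case_hom, MISSING)
            fill(groups.control, (0, 0))
            fill(groups.wild, (0, 0))
        else:
            kind = _VIOLATIONS[viol_cycle % len(_VIOLATIONS)]
            viol_cycle += 1
            if kind == "not_fixed_het":
                fill(groups.case_hom, (1, 1))
                gts[groups.case_hom[0]] = (0, 1)
                fill(groups.control, (0, 0))
                fill(groups.wild, (0, 0))
            elif kind == "not_fixed_split":
                half = len(groups.case_hom) // 2 or 1
                fill(groups.case_hom[:half], (0, 0))
                fill(groups.case_hom[half:], (1, 1))
                if len(groups.case_hom) == 1:
                    gts[groups.case_hom[0]] = (0, 1)
                fill(groups.control, (0, 0))
                fill(groups.wild, (0, 0))
            elif kind == "ref_candidate_control_carrier":
                fill(groups.case_hom, (0, 0))
                fill(groups.control, (1, 1))
                gts[groups.control[0]] = (0, 1)  # carries the REF candidate
                fill(groups.wild, (1, 1))
            elif kind == "wild_carrier":
                fill(groups.case_hom, (1, 1))
                fill(groups.control, (0, 0))
                fill(groups.wild, (0, 0))
                gts[groups.wild[rng.integers(len(groups.wild))]] = (
                    (0, 1) if rng.random() < 0.5 else (1, 1)
                )
            else:  # control_carrier
                fill(groups.case_hom, (1, 1))
                fill(groups.wild, (0, 0))
                fill(groups.control, (0, 0))
                gts[groups.control[rng.integers(len(groups.control))]] = (0, 1)
        records.append(
            VariantRecord(chrom, int(pos[i]), ref, alts, vt, dict(gts))
        )
    table = VariantTable(records, samples, region)
    return table, groups, [int(i) for i in true_idx]


def simulate_ase_counts(
    total_reads: int, allele_fraction: float, seed: int
) -> tuple[int, int]:
    """Binomial allele-specific read counts ``(allele_a, allele_b)``."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not 0.0 <= allele_fraction <= 1.0:
        raise ValueError("allele_fraction must be in [0,1]")
    a = int(np.random.default_rng(seed).binomial(total_reads, allele_fraction))
    return a, total_reads - a


def simulate_study(
    config: SimConfig,
    n_variant_records: tuple[int, int] = (200, 20),
    n_true_variants: tuple[int, int] = (4, 1),
    n_wild: int = 10,
) -> SyntheticStudy:
    """Full synthetic study: genotypes, landmarks, variant table, groups.

    Variant-table case samples are the study's planted-dosage-2 dogs and
    controls its dosage-0 dogs (capped at 12 each); wild canids are extra
    synthetic samples, haplotype-free by construction.
    """
    panel, genotypes, breed, truth = simulate_genotypes(config)
    landmarks, lm_truth = simulate_landmarks(truth["causal_dosage"], config)
    truth = {**truth, "landmarks": lm_truth}

    dosage = truth["causal_dosage"]
    case_ids = [panel.sample_ids[i] for i in np.where(dosage == 2)[0][:12]]
    ctrl_ids = [panel.sample_ids[i] for i in np.where(dosage == 0)[0][:12]]
    if not case_ids or not ctrl_ids:
        raise ValueError("study lacks haplotype-homozygous cases or free controls")
    wild_ids = [f"wolf{i:02d}" for i in range(n_wild)]
    table, groups, true_idx = simulate_variant_table(
        {"case_hom": case_ids, "control": ctrl_ids, "wild": wild_ids},
        n_variant_records[0],
        n_variant_records[1],
        n_true_variants[0],
        n_true_variants[1],
        seed=int(np.random.SeedSequence([config.seed, 2]).generate_state(1)[0] % 2**31),
    )
    truth["true_variant_indices"] = true_idx
    return SyntheticStudy(panel, genotypes, breed, truth, landmarks, table, groups)
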