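"""Readers/writers for the pipeline's file formats.

Landmark CSV (one row per specimen: id, x1, y1[, z1], ...), TPS landmark
blocks, phased/unphased VCF (via cyvcf2 for reading), sample-map TSV,
phenotype/scan TSV, QC JSON and interval BED.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .assoc import AssocScan, GenotypeMatrix
from .finemap import CriticalInterval, HaplotypePanel
from .morpho import LandmarkSet
from .varfilter import MISSING, VariantRecord, VariantTable

__all__ = [
    "write_landmarks_csv",
    "read_landmarks_csv",
    "read_landmarks_tps",
    "write_landmarks_tps",
    "write_phased_vcf",
    "read_phased_vcf",
    "read_genotype_vcf",
    "read_variant_vcf",
    "write_sample_map",
    "read_sample_map",
    "write_scan_tsv",
    "write_qc_json",
    "write_interval_bed",
    "write_haplotypes_tsv",
    "write_phenotypes_tsv",
    "write_truth_json",
]

_AXES = "xyz"


def write_landmarks_csv(landmarks: LandmarkSet, path) -> None:
    n, k, d = landmarks.coords.shape
    header = ["id"] + [f"{_AXES[a]}{i + 1}" for i in range(k) for a in range(d)]
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for sid, cfg in zip(landmarks.specimen_ids, landmarks.coords):
            # repr round-trips doubles bit-exactly
            fh.write(sid + "," + ",".join(repr(float(v)) for v in cfg.ravel()) + "\n")


def read_landmarks_csv(path, masks: dict | None = None) -> LandmarkSet:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        d = sum(1 for c in header[1:] if c.startswith(("x", "y", "z")) and c[1:] == "1")
        ids, rows = [], []
        k = (len(header) - 1) // d
        for line in fh:
            parts = line.strip().split(",")
            if len(parts) != 1 + k * d:
                raise ValueError(
                    f"specimen {parts[0]!r}: expected {k} landmarks x {d} dims"
                )
            ids.append(parts[0])
            rows.append(np.array([float(v) for v in parts[1:]]).reshape(k, d))
    return LandmarkSet(ids, np.array(rows), masks or {})


def read_landmarks_tps(path, masks: dict | None = None) -> LandmarkSet:
    """TPS dialect: LM=/LM3= blocks of coordinate lines plus ID= lines."""
    ids, rows, dims = [], [], set()
    cur: list | None = None
    expect = 0
    cur_id = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            up = line.upper()
            if up.startswith("LM3=") or up.startswith("LM="):
                if cur is not None:
                    _close_tps_block(cur, expect, cur_id, ids, rows)
                d = 3 if up.startswith("LM3=") else 2
                dims.add(d)
                expect = int(line.split("=", 1)[1])
                cur = []
                cur_id = None
            elif up.startswith("ID="):
                cur_id = line.split("=", 1)[1].strip()
            elif "=" in line and not line[0].isdigit() and not line[0] in "-+.":
                continue  # SCALE=, IMAGE=, ... ignored
            else:
                if cur is None:
                    raise ValueError("coordinate line before any LM= header")
                cur.append([float(v) for v in line.split()])
    if cur is not None:
        _close_tps_block(cur, expect, cur_id, ids, rows)
    if len(dims) > 1:
        raise ValueError("mixed 2D and 3D blocks in TPS file")
    ks = {len(r) for r in rows}
    if len(ks) > 1:
        raise ValueError("inconsistent landmark counts across specimens")
    return LandmarkSet(ids, np.array(rows, dtype=float), masks or {})


def _close_tps_block(cur, expect, cur_id, ids, rows):
    if len(cur) != expect:
        raise ValueError(
            f"specimen {cur_id or len(ids)}: {len(cur)} coordinate lines, LM={expect}"
        )
    ids.append(cur_id if cur_id is not None else f"specimen{len(ids)}")
    rows.append(cur)


def write_landmarks_tps(landmarks: LandmarkSet, path) -> None:
    n, k, d = landmarks.coords.shape
    tag = "LM3" if d == 3 else "LM"
    with open(path, "w") as fh:
        for sid, cfg in zip(landmarks.specimen_ids, landmarks.coords):
            fh.write(f"{tag}={k}\n")
            for row in cfg:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")
            fh.write(f"ID={sid}\n")


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    gmap = panel.gmap
    contigs = list(dict.fromkeys(gmap["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        a = panel.alleles
        for j in range(panel.n_markers):
            row = gmap.iloc[j]
            gts = "\t".join(
                f"{a[2 * i, j]}|{a[2 * i + 1, j]}" for i in range(panel.n_samples)
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def _vcf_reader(path):
    from cyvcf2 import VCF

    return VCF(str(path))


def read_phased_vcf(path) -> HaplotypePanel:
    """Phased VCF -> haplotype panel; every GT must use the '|' separator."""
    vcf = _vcf_reader(path)
    samples = list(vcf.samples)
    alleles, rows = [], []
    for var in vcf:
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a, b, phased = g[0], g[1], g[2]
            if not phased:
                raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
            if a < 0 or b < 0:
                raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
            col[2 * i], col[2 * i + 1] = a, b
        alleles.append(col)
        rows.append(
            (var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}", var.REF,
             var.ALT[0] if var.ALT else ".")
        )
    gmap = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return HaplotypePanel(samples, np.array(alleles).T, gmap)


def read_genotype_vcf(path) -> GenotypeMatrix:
    """VCF -> dosage matrix; accepts both '/' and '|' GT dialects."""
    vcf = _vcf_reader(path)
    samples = list(vcf.samples)
    cols, rows = [], []
    for var in vcf:
        dos = np.full(len(samples), np.nan)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                dos[i] = (a > 0) + (b > 0)
        cols.append(dos)
        rows.append(
            (var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}", var.REF,
             var.ALT[0] if var.ALT else ".")
        )
    gmap = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeMatrix(samples, np.array(cols).T, gmap)


def read_variant_vcf(path, region: tuple[str, int, int] | None = None) -> VariantTable:
    """Multi-sample VCF (SNV/INDEL/SV) -> VariantTable.

    SV records are recognised by a symbolic ALT or an SVTYPE INFO key; the
    record position is the (leftmost) POS.
    """
    vcf = _vcf_reader(path)
    samples = list(vcf.samples)
    records = []
    for var in vcf:
        alts = tuple(var.ALT)
        if var.INFO.get("SVTYPE") or any(a.startswith("<") for a in alts):
            vtype = "SV"
        elif len(var.REF) == 1 and all(len(a) == 1 for a in alts):
            vtype = "SNV"
        else:
            vtype = "INDEL"
        gts = {}
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            gts[samples[i]] = MISSING if (a < 0 or b < 0) else (int(a), int(b))
        records.append(VariantRecord(var.CHROM, var.POS, var.REF, alts, vtype, gts))
    return VariantTable(records, samples, region)


def write_sample_map(path, sample_ids, group, breed=None, sex=None) -> None:
    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group,
            "breed": breed if breed is not None else ["."] * len(sample_ids),
            "sex": sex if sex is not None else ["."] * len(sample_ids),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_sample_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_scan_tsv(scan: AssocScan, path) -> None:
    scan.results.to_csv(path, sep="\t", index=False)


def write_qc_json(scan: AssocScan, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "lambda": scan.lam,
                "threshold_p": scan.threshold_p,
                "neglog10_threshold": float(-np.log10(scan.threshold_p)),
                "n_tests": scan.n_tests,
            },
            fh,
            indent=2,
        )


def write_interval_bed(interval: CriticalInterval, path) -> None:
    """Critical interval as BED: 0-based half-open [start_pos-1, end_pos)."""
    with open(path, "w") as fh:
        fh.write(f"{interval.chrom}\t{interval.start_pos - 1}\t{interval.end_pos}\n")


def write_haplotypes_tsv(panel: HaplotypePanel, path) -> None:
    df = pd.DataFrame(panel.alleles, index=panel.copy_ids, columns=panel.gmap["id"])
    df.to_csv(path, sep="\t", index_label="copy_id")


def write_phenotypes_tsv(path, specimen_ids, centroid_sizes, scores) -> None:
    scores = np.atleast_2d(np.asarray(scores))
    if scores.shape[0] != len(specimen_ids):
        scores = scores.T
    df = pd.DataFrame({"specimen_id": specimen_ids, "centroid_size": centroid_sizes})
    for j in range(scores.shape[1]):
        df[f"PC{j + 1}"] = scores[:, j]
    df.to_csv(path, sep="\t", index=False)


def write_truth_json(truth: dict, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, dict):
            return {str(k): v for k, v in o.items()}
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(truth, fh, default=default)
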