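"""Readers, writers and validation for the pipeline's tabular formats.

Canonical interchange is TSV with a header: variant tables
(sample, chrom, pos, ref, alt, alt_count, depth), BED-like segment tables
(chrom, start, end, major_cn, minor_cn; 0-based half-open), plasma tables
(variant_id, cluster_id, timepoint, alt_count, depth) and clone tables
(cdr3b, count).  Region annotations and configs travel as JSON.  Malformed
rows are dropped with enumerated reason codes and accounted for in a
ValidationReport; structural problems (missing columns, overlapping
segments) are fatal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .timing import CopyNumberSegment, RegionProfile

COUNT_EXCEEDS_DEPTH = "COUNT_EXCEEDS_DEPTH"
NON_POSITIVE_DEPTH = "NON_POSITIVE_DEPTH"
BAD_POSITION = "BAD_POSITION"
NEGATIVE_COUNT = "NEGATIVE_COUNT"

VARIANT_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "alt_count", "depth"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "major_cn", "minor_cn"]


@dataclass
class ValidationReport:
    """Accounting for one parsed file: every input row is either used or
    dropped for an enumerated reason."""

    path: str
    records_in: int = 0
    records_used: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    def check(self) -> None:
        assert self.records_in == self.records_used + sum(self.dropped.values())

    def to_dict(self) -> dict:
        return {"path": self.path, "records_in": self.records_in,
                "records_used": self.records_used, "dropped": self.dropped,
                "warnings": self.warnings}


class InputError(ValueError):
    """Fatal, structural problem with an input file."""


def read_variant_table(path: str | Path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a variant TSV, dropping malformed rows with reason codes.

    A ``variant_id`` column is synthesised as chrom:pos:ref>alt when absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    report = ValidationReport(str(path), records_in=len(df))

    keep = pd.Series(True, index=df.index)
    for idx, row in df.iterrows():
        if row["depth"] <= 0:
            report.drop(NON_POSITIVE_DEPTH)
            keep[idx] = False
        elif row["alt_count"] < 0:
            report.drop(NEGATIVE_COUNT)
            keep[idx] = False
        elif row["alt_count"] > row["depth"]:
            report.drop(COUNT_EXCEEDS_DEPTH)
            keep[idx] = False
        elif row["pos"] < 1:
            report.drop(BAD_POSITION)
            keep[idx] = False
    out = df[keep].reset_index(drop=True)
    if "variant_id" not in out.columns:
        out = out.assign(variant_id=[
            f"{r.chrom}:{r.pos}:{r.ref}>{r.alt}" for r in out.itertuples(index=False)])
    report.records_used = len(out)
    report.check()
    return out, report


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = VARIANT_COLUMNS + [c for c in df.columns if c not in VARIANT_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> list[CopyNumberSegment]:
    """Read a BED-like segment TSV; sorted, non-overlapping per chromosome.

    Overlaps, inverted intervals and major < minor are fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.end <= row.start:
            raise InputError(f"{path} line {i}: end <= start")
        if row.minor_cn < 0 or row.major_cn < row.minor_cn:
            raise InputError(f"{path} line {i}: need major_cn >= minor_cn >= 0")
        segments.append(CopyNumberSegment(str(row.chrom), int(row.start), int(row.end),
                                          int(row.major_cn), int(row.minor_cn)))
    segments.sort(key=lambda s: (s.chrom, s.start))
    for a, b in zip(segments, segments[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise InputError(
                f"{path}: overlapping segments {a.chrom}:{a.start}-{a.end} "
                f"and {b.chrom}:{b.start}-{b.end}")
    return segments


def write_segments(segments: list[CopyNumberSegment], path: str | Path) -> None:
    pd.DataFrame(
        [(s.chrom, s.start, s.end, s.major_cn, s.minor_cn) for s in segments],
        columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_region_profiles(path: str | Path) -> dict[str, RegionProfile]:
    """Region annotations from JSON: {region_id: {purity, n_wgd}, ...}."""
    with open(path) as fh:
        raw = json.load(fh)
    out = {}
    for rid, rec in raw.items():
        extra = set(rec) - {"purity", "n_wgd"}
        if extra:
            raise InputError(f"{path}: unknown keys {sorted(extra)} for region {rid}")
        out[rid] = RegionProfile(rid, float(rec["purity"]), int(rec["n_wgd"]))
    return out


def write_region_profiles(profiles: dict[str, RegionProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({rid: {"purity": p.purity, "n_wgd": p.n_wgd}
                   for rid, p in profiles.items()}, fh, indent=1, sort_keys=True)


def read_clone_table(path: str | Path) -> dict[str, int]:
    """TCR clone table TSV with columns (cdr3b, count)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("cdr3b", "count") if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    if df["cdr3b"].duplicated().any():
        raise InputError(f"{path}: duplicate CDR3B sequences")
    return dict(zip(df["cdr3b"].astype(str), df["count"].astype(int)))


def read_plasma_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["variant_id", "cluster_id", "timepoint", "alt_count", "depth"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return df


def read_variants_vcf(path: str | Path, sample: str | None = None) -> pd.DataFrame:
    """Optional VCF ingestion: map the AD FORMAT field to alt_count/depth.

    Requires pysam (pre-installed in the analysis environments this package
    targets); only the first ALT allele of each record is used.
    """
    import pysam  # deferred: optional reader

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if not sample_names:
            raise InputError(f"{path}: VCF has no sample columns")
        sname = sample or sample_names[0]
        for rec in vcf:
            ad = rec.samples[sname].get("AD")
            if ad is None or len(ad) < 2 or ad[0] is None:
                continue
            depth = int(sum(x for x in ad if x is not None))
            rows.append((sname, rec.chrom, rec.pos, rec.ref,
                         rec.alts[0] if rec.alts else ".", int(ad[1]), depth))
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return df.assign(variant_id=[
        f"{r.chrom}:{r.pos}:{r.ref}>{r.alt}" for r in df.itertuples(index=False)])
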