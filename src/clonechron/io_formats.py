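"""Input/output tables and dialect conventions.

Every external table the pipeline touches is defined here, together with
the coordinate conventions used throughout the package:

* genomic **segments** are 0-based, half-open ``[start, end)``;
* **variant positions** are 1-based (VCF convention);
* TSV files are tab-separated, ``#``-prefixed comment lines are skipped,
  and the headers documented on each reader are required.

The domain records are plain dataclasses; heavier numeric work elsewhere
operates on arrays extracted from them.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "GenomicSegment",
    "SomaticMutation",
    "GermlineHetSite",
    "SegmentCNRecord",
    "read_mutations",
    "read_het_sites",
    "read_segments",
    "write_mutations",
    "write_het_sites",
    "write_segments",
    "write_report",
    "read_report",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicSegment:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end} has non-positive length"
            )

    @property
    def length_mb(self) -> float:
        return (self.end - self.start) / 1e6

    def contains(self, chrom: str, pos: int) -> bool:
        """1-based position containment."""
        return chrom == self.chrom and self.start < pos <= self.end


@dataclass
class SomaticMutation:
    """One somatic SNV with tumor read counts (1-based position)."""

    id: str
    chrom: str
    pos: int
    ref_count: int
    alt_count: int
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(f"mutation {self.id}: negative read count")
        if self.ref_count + self.alt_count == 0:
            raise ValidationError(f"mutation {self.id}: zero total depth")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf_obs(self) -> float:
        return self.alt_count / self.depth


@dataclass
class GermlineHetSite:
    """Tumor read counts at a site heterozygous in the matched normal."""

    chrom: str
    pos: int
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count + self.alt_count <= 0:
            raise ValidationError(
                f"het site {self.chrom}:{self.pos}: zero total depth"
            )

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclass
class SegmentCNRecord:
    """Observed (normal-scaled) total copy number and LAF of one segment.

    ``laf_obs`` is the lesser allele fraction in [0, 0.5]; it may be NaN
    when no heterozygous sites informed the segment.
    """

    segment: GenomicSegment
    cn_obs: float
    laf_obs: float = math.nan

    def __post_init__(self) -> None:
        if self.cn_obs < 0:
            raise ValidationError(
                f"segment {self.segment.chrom}: negative copy number {self.cn_obs}"
            )
        if not math.isnan(self.laf_obs) and not 0.0 <= self.laf_obs <= 0.5:
            raise ValidationError(
                f"segment {self.segment.chrom}: LAF {self.laf_obs} outside [0, 0.5]"
            )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    except pd.errors.EmptyDataError as exc:  # header missing entirely
        raise FormatError(f"{path}: empty file without header") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_mutations(path: str | Path, dialect: str = "tsv") -> list[SomaticMutation]:
    """Read somatic SNVs with tumor ref/alt read counts.

    TSV dialect requires header ``chrom, pos, ref_count, alt_count`` with
    optional ``id`` and ``gene`` columns.  VCF dialect reads the per-sample
    allelic depth (``AD``) of the first sample.  Records with zero total
    depth are dropped with a warning, not errors.
    """
    if dialect == "tsv":
        df = _read_tsv(path, ["chrom", "pos", "ref_count", "alt_count"])
        out: list[SomaticMutation] = []
        dropped = 0
        for i, row in enumerate(df.itertuples(index=False)):
            ref, alt = int(row.ref_count), int(row.alt_count)
            if ref + alt == 0:
                dropped += 1
                continue
            mid = str(getattr(row, "id", f"m{i}")) if hasattr(row, "id") else f"m{i}"
            gene = getattr(row, "gene", None)
            if gene is not None and (gene != gene or gene == ""):  # NaN
                gene = None
            out.append(
                SomaticMutation(
                    id=mid, chrom=str(row.chrom), pos=int(row.pos),
                    ref_count=ref, alt_count=alt,
                    gene=None if gene is None else str(gene),
                )
            )
        if dropped:
            warnings.warn(f"{path}: dropped {dropped} zero-depth record(s)")
        return out
    if dialect == "vcf":
        return _read_mutations_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_mutations_vcf(path: str | Path) -> list[SomaticMutation]:
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    out: list[SomaticMutation] = []
    dropped = 0
    for i, var in enumerate(VCF(str(path))):
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise FormatError(
                f"{path}: record {var.CHROM}:{var.POS} has no AD (allelic depth) field"
            )
        ref, alt = int(ad[0][0]), int(ad[0][1])
        if ref < 0 or alt < 0 or ref + alt == 0:
            dropped += 1
            continue
        out.append(
            SomaticMutation(
                id=var.ID or f"m{i}", chrom=var.CHROM, pos=var.POS,
                ref_count=ref, alt_count=alt,
            )
        )
    if dropped:
        warnings.warn(f"{path}: dropped {dropped} zero-depth record(s)")
    return out


def read_het_sites(path: str | Path) -> list[GermlineHetSite]:
    """Read germline heterozygous sites (TSV: chrom, pos, ref_count, alt_count)."""
    df = _read_tsv(path, ["chrom", "pos", "ref_count", "alt_count"])
    out: list[GermlineHetSite] = []
    dropped = 0
    for row in df.itertuples(index=False):
        ref, alt = int(row.ref_count), int(row.alt_count)
        if ref + alt == 0:
            dropped += 1
            continue
        out.append(GermlineHetSite(str(row.chrom), int(row.pos), ref, alt))
    if dropped:
        warnings.warn(f"{path}: dropped {dropped} zero-depth site(s)")
    return out


def read_segments(path: str | Path) -> list[SegmentCNRecord]:
    """Read copy-number segments (TSV: chrom, start, end, cn_obs[, laf_obs]).

    Segments on one chromosome must be non-overlapping; a LAF above 0.5 is
    mirrored to ``1 - laf`` with a warning.
    """
    df = _read_tsv(path, ["chrom", "start", "end", "cn_obs"])
    out: list[SegmentCNRecord] = []
    for row in df.itertuples(index=False):
        laf = float(getattr(row, "laf_obs", math.nan))
        if not math.isnan(laf) and laf > 0.5:
            warnings.warn(
                f"{path}: LAF {laf} at {row.chrom}:{row.start} mirrored to {1 - laf:.6g}"
            )
            laf = 1.0 - laf
        seg = GenomicSegment(str(row.chrom), int(row.start), int(row.end))
        out.append(SegmentCNRecord(seg, float(row.cn_obs), laf))
    _check_non_overlapping(out)
    return out


def _check_non_overlapping(records: Iterable[SegmentCNRecord]) -> None:
    by_chrom: dict[str, list[GenomicSegment]] = {}
    for rec in records:
        by_chrom.setdefault(rec.segment.chrom, []).append(rec.segment)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_mutations(mutations: Iterable[SomaticMutation], path: str | Path) -> None:
    rows = [
        {"chrom": m.chrom, "pos": m.pos, "ref_count": m.ref_count,
         "alt_count": m.alt_count, "id": m.id, "gene": m.gene or ""}
        for m in mutations
    ]
    cols = ["chrom", "pos", "ref_count", "alt_count", "id", "gene"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_het_sites(sites: Iterable[GermlineHetSite], path: str | Path) -> None:
    rows = [
        {"chrom": s.chrom, "pos": s.pos, "ref_count": s.ref_count,
         "alt_count": s.alt_count}
        for s in sites
    ]
    cols = ["chrom", "pos", "ref_count", "alt_count"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_segments(records: Iterable[SegmentCNRecord], path: str | Path) -> None:
    rows = [
        {"chrom": r.segment.chrom, "start": r.segment.start,
         "end": r.segment.end, "cn_obs": r.cn_obs, "laf_obs": r.laf_obs}
        for r in records
    ]
    cols = ["chrom", "start", "end", "cn_obs", "laf_obs"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_report(results, path: str | Path, format: str = "json") -> None:
    """Write analysis results; reading the file back reproduces all numeric
    fields to at least 6 decimals.

    ``json`` accepts any JSON-serializable object; ``tsv`` accepts a list of
    flat dicts or a DataFrame.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(results, fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "json"):
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    if format == "tsv":
        try:
            return pd.read_csv(path, sep="\t", comment="#")
        except pd.errors.EmptyDataError:
            return pd.DataFrame()
    raise ValueError(f"unknown report format {format!r}")
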