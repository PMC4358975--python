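"""Allelic copy-number states, LAF estimation and subclonal CNA detection.

A segment's allelic state is the pair of integer parental-allele copy
numbers (major, minor), written with letters: AB is balanced diploid, AA
is uniparental disomy (copy-neutral LOH followed by duplication), AAB is
trisomy, AABB is the tetraploid state left by a whole-genome duplication.

The lesser allele fraction (LAF) of a state is minor/(major+minor) and is
estimated from read counts at germline heterozygous sites.  After purity
correction a clonal segment sits on an integer state; a segment whose
corrected (copy number, LAF) falls off the integer grid is explained as a
two-population mixture of a major-clone state and a subclone state, which
yields the subclone's cell fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GermlineHetSite, SegmentCNRecord

__all__ = [
    "AllelicState",
    "SubcloneCNACall",
    "SegmentCNAVerdict",
    "InsufficientSitesError",
    "estimate_laf",
    "estimate_laf_counts",
    "nearest_integer_state",
    "detect_subclonal_cna",
    "MAX_STATE_TOTAL",
    "INTEGER_STATE_TOLERANCE",
]

#: Largest total copy number considered when snapping to integer states.
MAX_STATE_TOTAL = 8

#: Per-coordinate tolerance (copy-number units / LAF units) within which a
#: corrected segment is accepted as clonal.  Roughly two binomial standard
#: deviations of a segment LAF estimate at ~100x depth.
INTEGER_STATE_TOLERANCE = 0.05

#: Minimum heterozygous sites for a usable segment LAF.
MIN_HET_SITES = 10


class InsufficientSitesError(ValueError):
    """Too few heterozygous sites to estimate a segment LAF."""


@dataclass(frozen=True, order=True)
class AllelicState:
    """Integer parental-allele copy numbers of a segment (major >= minor)."""

    n_major: int
    n_minor: int

    def __post_init__(self) -> None:
        if self.n_minor < 0 or self.n_major < self.n_minor:
            raise ValueError(f"invalid allelic state ({self.n_major},{self.n_minor})")

    @property
    def total(self) -> int:
        return self.n_major + self.n_minor

    @property
    def laf(self) -> float:
        return self.n_minor / self.total if self.total else 0.0

    @property
    def label(self) -> str:
        if self.total == 0:
            return "-"
        return "A" * self.n_major + "B" * self.n_minor

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class SubcloneCNACall:
    """A segment explained as a two-state mixture.

    ``phi`` is the fraction of tumor cells in the minority lineage carrying
    ``state_minor``; the remaining ``1 - phi`` carry ``state_major``.
    """

    segment: SegmentCNRecord
    state_major: AllelicState
    state_minor: AllelicState
    phi: float
    residual: float


@dataclass
class SegmentCNAVerdict:
    """Outcome of subclonal-CNA detection on one purity-corrected segment."""

    record: SegmentCNRecord
    verdict: str  # "clonal" | "subclonal" | "unresolved"
    state: AllelicState
    distance: float
    subclone: SubcloneCNACall | None = None


# ---------------------------------------------------------------------------
# LAF estimation
# ---------------------------------------------------------------------------

def estimate_laf_counts(
    ref_counts: np.ndarray, alt_counts: np.ndarray, min_sites: int = MIN_HET_SITES
) -> float:
    """Segment LAF from arrays of per-site tumor read counts.

    Each site contributes its folded allele fraction ``min(v, 1 - v)`` with
    ``v = alt/(ref+alt)``; the segment LAF is the read-count-weighted mean.
    """
    ref = np.asarray(ref_counts, dtype=float)
    alt = np.asarray(alt_counts, dtype=float)
    total = ref + alt
    keep = total > 0
    ref, alt, total = ref[keep], alt[keep], total[keep]
    if ref.size < min_sites:
        raise InsufficientSitesError(
            f"{ref.size} informative het sites < required {min_sites}"
        )
    v = alt / total
    lesser = np.minimum(v, 1.0 - v)
    return float(np.average(lesser, weights=total))


def estimate_laf(
    sites: Iterable[GermlineHetSite] | pd.DataFrame,
    min_sites: int = MIN_HET_SITES,
) -> float:
    """Segment LAF from germline heterozygous sites (records or DataFrame)."""
    if isinstance(sites, pd.DataFrame):
        ref = sites["ref_count"].to_numpy()
        alt = sites["alt_count"].to_numpy()
    else:
        sites = list(sites)
        ref = np.array([s.ref_count for s in sites], dtype=float)
        alt = np.array([s.alt_count for s in sites], dtype=float)
    return estimate_laf_counts(ref, alt, min_sites=min_sites)


# ---------------------------------------------------------------------------
# Integer-state assignment
# ---------------------------------------------------------------------------

def enumerate_states(max_total: int = MAX_STATE_TOTAL) -> list[AllelicState]:
    """All allelic states with total copy number <= ``max_total``."""
    out = []
    for total in range(max_total + 1):
        for minor in range(total // 2 + 1):
            out.append(AllelicState(total - minor, minor))
    return out


_STATES = enumerate_states()


def nearest_integer_state(
    cn_t: float, laf_t: float, max_total: int = MAX_STATE_TOTAL
) -> tuple[AllelicState, float]:
    """Closest integer allelic state in (copy number, LAF) space.

    Distance is Euclidean over the two coordinates; ties break toward the
    smaller total copy number, then the larger minor-allele count.
    """
    if cn_t < 0:
        raise ValueError(f"negative copy number {cn_t}")
    states = _STATES if max_total == MAX_STATE_TOTAL else enumerate_states(max_total)
    best: tuple[float, int, int, AllelicState] | None = None
    for s in states:
        d = math.hypot(cn_t - s.total, laf_t - s.laf)
        key = (d, s.total, -s.n_minor)
        if best is None or key < best[:3]:
            best = (*key, s)
    assert best is not None
    return best[3], best[0]


# ---------------------------------------------------------------------------
# Subclonal CNA detection
# ---------------------------------------------------------------------------

def _candidate_states(major: AllelicState) -> list[AllelicState]:
    """States within one copy per allele of the major-clone state."""
    out = set()
    for da in (-1, 0, 1):
        for db in (-1, 0, 1):
            a, b = major.n_major + da, major.n_minor + db
            if a < 0 or b < 0:
                continue
            s = AllelicState(max(a, b), min(a, b))
            if s != major:
                out.add(s)
    return sorted(out)


def detect_subclonal_cna(
    record: SegmentCNRecord,
    epsilon: float = INTEGER_STATE_TOLERANCE,
    phi_bounds: tuple[float, float] = (0.05, 0.95),
    max_total: int = MAX_STATE_TOTAL,
) -> SegmentCNAVerdict:
    """Classify one purity-corrected segment as clonal or subclonal.

    The record must carry contamination-corrected ``cn_obs``/``laf_obs``
    (pure-tumor values).  If the segment lies within ``epsilon`` of an
    integer state in both coordinates it is clonal.  Otherwise a mixture
    ``(1 - phi) * state_major + phi * state_minor`` is fitted over candidate
    minority states within one copy per allele of the major state, solving
    the linear mixing equations for total copies and minor-allele copies.
    """
    cn_t, laf_t = record.cn_obs, record.laf_obs
    if math.isnan(laf_t):
        raise ValueError("segment LAF required for subclonal CNA detection")
    state, dist = nearest_integer_state(cn_t, laf_t, max_total=max_total)
    if abs(cn_t - state.total) <= epsilon and abs(laf_t - state.laf) <= epsilon:
        return SegmentCNAVerdict(record, "clonal", state, dist)

    # point to explain, in (total copies, minor-allele copies) space
    target = np.array([cn_t, cn_t * laf_t])
    x1 = np.array([state.total, state.n_minor], dtype=float)
    best: SubcloneCNACall | None = None
    for cand in _candidate_states(state):
        x2 = np.array([cand.total, cand.n_minor], dtype=float)
        direction = x2 - x1
        denom = float(direction @ direction)
        if denom == 0.0:
            continue
        phi = float((target - x1) @ direction) / denom
        if not phi_bounds[0] < phi < phi_bounds[1]:
            continue
        residual = float(np.linalg.norm(target - x1 - phi * direction))
        if best is None or residual < best.residual:
            best = SubcloneCNACall(record, state, cand, phi, residual)
    if best is None:
        return SegmentCNAVerdict(record, "unresolved", state, dist)
    return SegmentCNAVerdict(record, "subclonal", state, dist, subclone=best)
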