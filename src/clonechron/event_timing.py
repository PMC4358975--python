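"""Mutation multiplicity, molecular timing of copy-number events, WGD.

Molecular time runs from 0 (tumor origin) to 1 (biopsy) and is measured
in mutation accumulation: under a constant per-copy rate, the number of
mutations a chromosome copy gains over an interval is proportional to the
interval's length.  A duplication at time t copies every mutation already
on the duplicated allele, so pre-event mutations appear at multiplicity 2
and post-event ones at multiplicity 1.  With per-copy rate lambda and
segment length L the expected multiplicity-class counts are:

* copy-neutral LOH + duplication (AB -> AA):
  ``N2 = lambda*L*t``, ``N1 = 2*lambda*L*(1-t)``  ->  ``t = 2*N2/(2*N2 + N1)``
* whole-genome / whole-chromosome duplication (AB -> AABB):
  ``N2 = 2*lambda*L*t``, ``N1 = 4*lambda*L*(1-t)``  ->  ``t = 2*N2/(2*N2 + N1)``
* single-chromatid gain (AB -> AAB):
  ``N2 = lambda*L*t``, ``N1 = lambda*L*t + 3*lambda*L*(1-t)``
  ->  ``t = 3*r/(1 + 2*r)`` with ``r = N2/N1``

Each estimator is the exact inverse of its expected counts, so applied to
noise-free expectations it returns the true t identically.  Pure losses
leave no multiplicity signal and are untimeable; segments whose state
implies two or more sequential duplications are reported complex and left
untimed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .allelic_cn import AllelicState, nearest_integer_state
from .io_formats import SegmentCNRecord, SomaticMutation
from .purity import expected_obs_vaf

__all__ = [
    "CNEvent",
    "MutationTiming",
    "WGDCall",
    "RateFit",
    "UntimeableEventError",
    "ComplexHistoryError",
    "assign_multiplicity",
    "multiplicity_counts",
    "time_segment",
    "time_event",
    "bootstrap_ci",
    "mutation_interval",
    "detect_wgd",
    "fusion_duplication_test",
    "rate_consistency",
    "TIMEABLE_CLASSES",
]

#: Event classes with a single-duplication timing estimator.
TIMEABLE_CLASSES = {"cn_loh_dup", "wgd", "tetrasomy", "trisomy_gain", "gain"}

#: Per-coordinate tolerances for calling a segment tetraploid (AABB).
_WGD_CN_TOL = 0.4
_WGD_LAF_TOL = 0.05

#: Minimum mutations on a chromosome for a usable per-chromosome WGD time.
_WGD_MIN_MUTATIONS = 10


class UntimeableEventError(ValueError):
    """No multiplicity signal from which to time the event."""


@dataclass
class CNEvent:
    """A timed copy-number event on one segment."""

    segment: SegmentCNRecord | None
    state_pre: AllelicState
    state_post: AllelicState
    event_class: str  # cn_loh_dup | trisomy_gain | wgd | gain | loss
    t: float
    ci: tuple[float, float] | None = None
    n_by_multiplicity: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise ValueError(f"event time {self.t} outside [0, 1]")


@dataclass
class MutationTiming:
    """Molecular-time interval of one mutation."""

    mutation_id: str
    multiplicity: int
    interval: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"invalid timing interval {self.interval}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.interval[0] + self.interval[1])


@dataclass
class WGDCall:
    is_wgd: bool
    t_by_chrom: dict[str, float]
    t_mean: float
    concordance: float  # SD of per-chromosome times; small = one event
    tetraploid_fraction: float


@dataclass
class RateFit:
    rates_per_mb: np.ndarray
    slope: float
    r_squared: float


# ---------------------------------------------------------------------------
# Multiplicity
# ---------------------------------------------------------------------------

def assign_multiplicity(
    mutation: SomaticMutation, state: AllelicState, alpha: float = 0.0
) -> int:
    """Maximum-likelihood mutation multiplicity on a segment of known state.

    Candidates run 1..n_major (a mutation can occupy at most every copy of
    one parental allele); the binomial likelihood of the alt count is
    evaluated at the expected observed VAF of each candidate.  Ties break
    toward the smaller multiplicity.
    """
    n_t = state.total
    if n_t < 1:
        raise ValueError("cannot assign multiplicity on a zero-copy segment")
    best_m, best_ll = 1, -math.inf
    for m in range(1, max(state.n_major, 1) + 1):
        v = expected_obs_vaf(alpha, n_t, m, 1.0)
        ll = binom.logpmf(mutation.alt_count, mutation.depth, v)
        if ll > best_ll + 1e-12:
            best_m, best_ll = m, ll
    return best_m


def multiplicity_counts(
    mutations: Iterable[SomaticMutation], state: AllelicState, alpha: float = 0.0
) -> dict[int, int]:
    """Histogram of assigned multiplicities for mutations on one segment."""
    counts: dict[int, int] = {}
    for m in mutations:
        mult = assign_multiplicity(m, state, alpha)
        counts[mult] = counts.get(mult, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Event timing
# ---------------------------------------------------------------------------

def time_event(event_class: str, n_by_multiplicity: Mapping[int, int]) -> float:
    """Molecular time of a duplication-bearing event from multiplicity counts."""
    n1 = n_by_multiplicity.get(1, 0)
    n2 = sum(c for m, c in n_by_multiplicity.items() if m >= 2)
    if n1 + n2 == 0:
        raise UntimeableEventError("no mutations in multiplicity classes 1/2")
    if event_class in ("cn_loh_dup", "wgd", "tetrasomy"):
        t = 2.0 * n2 / (2.0 * n2 + n1)
    elif event_class in ("trisomy_gain", "gain"):
        if n1 == 0:
            t = 1.0
        else:
            r = n2 / n1
            t = 3.0 * r / (1.0 + 2.0 * r)
    elif event_class == "loss":
        raise UntimeableEventError("pure losses leave no multiplicity signal")
    else:
        raise ValueError(f"unknown event class {event_class!r}")
    return min(max(t, 0.0), 1.0)


def bootstrap_ci(
    event_class: str,
    n_by_multiplicity: Mapping[int, int],
    resamples: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% interval for the event time from multinomial
    resampling of the multiplicity counts; widened, if needed, to contain
    the point estimate."""
    t_hat = time_event(event_class, n_by_multiplicity)
    mults = sorted(n_by_multiplicity)
    counts = np.array([n_by_multiplicity[m] for m in mults], dtype=float)
    n = int(counts.sum())
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, counts / n, size=resamples)
    ts = np.array(
        [time_event(event_class, dict(zip(mults, d))) for d in draws]
    )
    lo, hi = np.percentile(ts, [2.5, 97.5])
    return (min(float(lo), t_hat), max(float(hi), t_hat))


def mutation_interval(
    mutation_id: str, multiplicity: int, event: CNEvent | None
) -> MutationTiming:
    """Molecular-time interval implied by a mutation's multiplicity.

    On a duplicated segment, multiplicity >= 2 means the mutation predates
    the duplication ([0, t]); multiplicity 1 postdates it ([t, 1]) except
    on a trisomy, where pre-event mutations on the unduplicated allele are
    also multiplicity 1, leaving [0, 1].  Without a timed event the whole
    lifetime [0, 1] remains.
    """
    if event is None or event.event_class not in TIMEABLE_CLASSES:
        interval = (0.0, 1.0)
    elif event.event_class in ("cn_loh_dup", "wgd", "tetrasomy"):
        interval = (0.0, event.t) if multiplicity >= 2 else (event.t, 1.0)
    else:  # trisomy_gain / gain
        interval = (0.0, event.t) if multiplicity >= 2 else (0.0, 1.0)
    return MutationTiming(mutation_id, multiplicity, interval)


#: Single-event histories from a heterozygous diploid ancestor: the final
#: state determines the event class that produced it.
_STATE_TO_EVENT = {
    (2, 0): "cn_loh_dup",
    (2, 1): "trisomy_gain",
    (2, 2): "wgd",
    (1, 0): "loss",
}


def time_segment(
    record: SegmentCNRecord,
    mutations: Iterable[SomaticMutation],
    alpha: float = 0.0,
    resamples: int = 200,
    seed: int = 0,
) -> CNEvent | None:
    """Time the copy-number event behind one purity-corrected segment.

    The segment's nearest integer state is interpreted as the outcome of a
    single event on a heterozygous diploid ancestor; multiplicities of the
    segment's mutations are assigned and fed to the timing estimator.
    Returns None for balanced diploid segments; pure losses are returned
    untimed (t NaN is not allowed, so they raise ``UntimeableEventError``);
    states requiring two or more sequential events are reported complex by
    raising ``ComplexHistoryError``.
    """
    state, _ = nearest_integer_state(record.cn_obs, record.laf_obs)
    key = (state.n_major, state.n_minor)
    if key == (1, 1):
        return None
    if key not in _STATE_TO_EVENT:
        raise ComplexHistoryError(
            f"{record.segment.chrom}: state {state.label} implies a multi-event "
            "history; left untimed"
        )
    event_class = _STATE_TO_EVENT[key]
    counts = multiplicity_counts(mutations, state, alpha)
    t = time_event(event_class, counts)  # raises for losses / empty counts
    ci = bootstrap_ci(event_class, counts, resamples=resamples, seed=seed)
    return CNEvent(
        segment=record,
        state_pre=AllelicState(1, 1),
        state_post=state,
        event_class=event_class,
        t=t,
        ci=ci,
        n_by_multiplicity=counts,
    )


class ComplexHistoryError(ValueError):
    """The segment state cannot arise from a single timed event."""


# ---------------------------------------------------------------------------
# Whole-genome duplication
# ---------------------------------------------------------------------------

_AABB = AllelicState(2, 2)


def detect_wgd(
    records: Sequence[SegmentCNRecord],
    mutations: Sequence[SomaticMutation],
    alpha: float = 0.0,
    genome_fraction: float = 0.5,
    cn_tol: float = _WGD_CN_TOL,
    laf_tol: float = _WGD_LAF_TOL,
    min_mutations: int = _WGD_MIN_MUTATIONS,
) -> WGDCall:
    """Call whole-genome duplication and time it per chromosome.

    ``records`` must carry purity-corrected (cn, laf).  WGD is called when
    at least ``genome_fraction`` of the autosomal genome (by length) is
    consistent with the tetraploid AABB state (cn near 4, LAF near 0.5).
    Each tetraploid chromosome is timed from its mutation multiplicity
    counts with the duplication estimator; the standard deviation of the
    per-chromosome times measures single-event concordance (a genuinely
    single WGD gives near-identical times genome-wide).
    """
    from .purity import SEX_CHROMS

    autosomal = [r for r in records if r.segment.chrom not in SEX_CHROMS]
    if not autosomal:
        raise ValueError("no autosomal segments")
    total_len = sum(r.segment.length_mb for r in autosomal)
    tetra = [
        r
        for r in autosomal
        if not math.isnan(r.laf_obs)
        and abs(r.cn_obs - 4.0) <= cn_tol
        and abs(r.laf_obs - 0.5) <= laf_tol
    ]
    tetra_len = sum(r.segment.length_mb for r in tetra)
    tetra_fraction = tetra_len / total_len
    is_wgd = tetra_fraction >= genome_fraction

    t_by_chrom: dict[str, float] = {}
    tetra_chroms = {r.segment.chrom for r in tetra}
    for chrom in sorted(tetra_chroms):
        segs = [r.segment for r in tetra if r.segment.chrom == chrom]
        muts = [
            m for m in mutations if any(s.contains(m.chrom, m.pos) for s in segs)
        ]
        if len(muts) < min_mutations:
            continue
        counts = multiplicity_counts(muts, _AABB, alpha)
        try:
            t_by_chrom[chrom] = time_event("wgd", counts)
        except UntimeableEventError:
            continue
    if t_by_chrom:
        ts = np.array(list(t_by_chrom.values()))
        t_mean, concordance = float(ts.mean()), float(ts.std())
    else:
        t_mean, concordance = math.nan, math.nan
    return WGDCall(is_wgd, t_by_chrom, t_mean, concordance, tetra_fraction)


def fusion_duplication_test(
    junction_reads: int,
    local_depth: float,
    wgd: bool,
    lr_threshold: float = 3.0,
) -> str:
    """Did a fusion junction predate a WGD?

    In a tetraploid genome a junction formed before the duplication is
    itself duplicated (2 of 4 copies, expecting half the local coverage);
    one formed after sits on a single copy (a quarter of the coverage).
    The junction read count is scored under binomial models at those two
    fractions; the higher-likelihood class wins when the likelihood ratio
    reaches ``lr_threshold``.  Returns ``before_wgd``/``after_wgd``/
    ``indeterminate``.
    """
    if not wgd or local_depth <= 0:
        return "indeterminate"
    n = max(int(round(local_depth)), junction_reads)
    ll_before = binom.logpmf(junction_reads, n, 2.0 / 4.0)
    ll_after = binom.logpmf(junction_reads, n, 1.0 / 4.0)
    if abs(ll_before - ll_after) < math.log(lr_threshold):
        return "indeterminate"
    return "before_wgd" if ll_before > ll_after else "after_wgd"


# ---------------------------------------------------------------------------
# Rate consistency
# ---------------------------------------------------------------------------

def rate_consistency(
    counts: Sequence[int], lengths_mb: Sequence[float]
) -> RateFit:
    """Check that mutation counts scale with chromosome length.

    Fits counts ~ length by least squares through the origin (the natural
    model for a homogeneous genome-wide rate) and reports the regression
    r-squared; a uniform accumulation rate gives r-squared near 1.
    """
    import statsmodels.api as sm

    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths_mb, dtype=float)
    if counts.size < 5:
        raise ValueError(f"need >= 5 chromosomes, got {counts.size}")
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths differ in shape")
    fit = sm.OLS(counts, lengths).fit()
    return RateFit(
        rates_per_mb=counts / lengths,
        slope=float(fit.params[0]),
        r_squared=float(fit.rsquared),
    )
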