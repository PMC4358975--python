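"""Normal-cell contamination estimation and correction.

A sequenced tumor sample is modeled as a linear mixture of tumor cells
(fraction ``1 - alpha``) and diploid normal cells (fraction ``alpha``).
For a mutation of multiplicity ``m`` carried by a fraction ``f`` of tumor
cells on a segment of tumor total copy number ``n_t``, the observed VAF is

    v = (1 - alpha) * f * m / ((1 - alpha) * n_t + 2 * alpha)

and the observed lesser allele fraction of a segment with ``n_minor``
minor-allele copies is

    l = ((1 - alpha) * n_minor + alpha) / ((1 - alpha) * n_t + 2 * alpha)

(the normal contributes one copy of each parental allele).  The observed,
normal-scaled total copy number is ``(1 - alpha) * n_t + 2 * alpha``.

``estimate_purity`` recovers ``alpha`` by grid search: at the true value
the corrected allelic copy numbers of clonal imbalanced segments snap onto
integer states and the dominant corrected VAF mode of mutations on
balanced diploid segments lands on a lattice value m/n_t (0.5 for
heterozygous clonal mutations).  The inverse maps ``correct_vaf`` and
``correct_allelic_cn`` then re-express all observations on the pure-tumor
scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .allelic_cn import nearest_integer_state
from .io_formats import SegmentCNRecord, SomaticMutation

__all__ = [
    "DomainError",
    "UninformativeSampleError",
    "PurityEstimate",
    "expected_obs_vaf",
    "expected_obs_laf",
    "estimate_purity",
    "correct_vaf",
    "correct_allelic_cn",
    "ALPHA_GRID_STEP",
    "ALPHA_MAX",
]

#: Default contamination grid: step and upper bound.
ALPHA_GRID_STEP = 0.005
ALPHA_MAX = 0.5

#: Segment classification thresholds for the purity objective.
_BALANCED_LAF_MIN = 0.42
_DIPLOID_CN_TOL = 0.2

#: Minimum number of balanced-segment mutations to use the VAF-mode term.
_MIN_MUTATIONS = 50

#: Sex chromosomes are excluded from purity fitting (single-copy ambiguity).
SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


class DomainError(ValueError):
    """An argument is outside the model's domain."""


class UninformativeSampleError(ValueError):
    """Neither imbalanced segments nor enough mutations to estimate purity."""


@dataclass
class PurityEstimate:
    """Estimated normal-cell fraction with its grid-search diagnostics."""

    alpha: float
    objective: float
    grid: list[tuple[float, float]] = field(repr=False, default_factory=list)

    @property
    def purity(self) -> float:
        return 1.0 - self.alpha


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def expected_obs_vaf(alpha: float, n_t: int, m: int, f: float = 1.0) -> float:
    """Observed VAF of a multiplicity-``m`` mutation under contamination.

    ``f`` is the cancer-cell fraction carrying the mutation (1 for clonal).
    Reduces to ``m / n_t`` at ``alpha = 0, f = 1``.
    """
    if not 0.0 <= alpha < 1.0:
        raise DomainError(f"alpha {alpha} outside [0, 1)")
    if n_t < 1:
        raise DomainError(f"tumor copy number {n_t} < 1")
    if not 1 <= m <= n_t:
        raise DomainError(f"multiplicity {m} outside 1..{n_t}")
    if not 0.0 < f <= 1.0:
        raise DomainError(f"cancer-cell fraction {f} outside (0, 1]")
    return (1.0 - alpha) * f * m / ((1.0 - alpha) * n_t + 2.0 * alpha)


def expected_obs_laf(alpha: float, n_t: int, n_minor: int) -> float:
    """Observed lesser allele fraction of a clonal segment under contamination."""
    if not 0.0 <= alpha < 1.0:
        raise DomainError(f"alpha {alpha} outside [0, 1)")
    if n_t < 1 or n_minor < 0:
        raise DomainError(f"invalid state ({n_t}, {n_minor})")
    if n_minor > n_t - n_minor:
        raise DomainError(f"minor copies {n_minor} exceed major copies")
    return ((1.0 - alpha) * n_minor + alpha) / ((1.0 - alpha) * n_t + 2.0 * alpha)


# ---------------------------------------------------------------------------
# Inverse maps (contamination correction)
# ---------------------------------------------------------------------------

def correct_vaf(vaf_obs: float, alpha: float, n_t: int) -> float:
    """Pure-tumor VAF from an observed VAF.

    Exact inverse of :func:`expected_obs_vaf`:
    ``correct_vaf(expected_obs_vaf(a, n, m, f), a, n) == f * m / n``.
    Values pushed above 1 by sampling noise are clipped with a warning.
    """
    if not 0.0 <= vaf_obs <= 1.0:
        raise DomainError(f"observed VAF {vaf_obs} outside [0, 1]")
    if not 0.0 <= alpha < 1.0:
        raise DomainError(f"alpha {alpha} outside [0, 1)")
    tumor_reads = (1.0 - alpha) * n_t
    v = vaf_obs * (tumor_reads + 2.0 * alpha) / tumor_reads
    if v > 1.0:
        warnings.warn(f"corrected VAF {v:.4f} > 1 clipped to 1")
        return 1.0
    return v


def correct_allelic_cn(
    cn_obs: float, laf_obs: float, alpha: float
) -> tuple[float, float]:
    """Pure-tumor (total copy number, LAF) from observed segment values."""
    if not 0.0 <= alpha < 1.0:
        raise DomainError(f"alpha {alpha} outside [0, 1)")
    cn_t = (cn_obs - 2.0 * alpha) / (1.0 - alpha)
    if cn_t < 0.0:
        warnings.warn(f"corrected copy number {cn_t:.4f} < 0 clipped to 0")
        cn_t = 0.0
    if math.isnan(laf_obs):
        return cn_t, math.nan
    minor_t = (cn_obs * laf_obs - alpha) / (1.0 - alpha)
    minor_t = max(minor_t, 0.0)
    laf_t = minor_t / cn_t if cn_t > 0 else 0.0
    return cn_t, min(laf_t, 0.5)


# ---------------------------------------------------------------------------
# Purity estimation
# ---------------------------------------------------------------------------

def _is_balanced_diploid(rec: SegmentCNRecord) -> bool:
    return (
        not math.isnan(rec.laf_obs)
        and rec.laf_obs >= _BALANCED_LAF_MIN
        and abs(rec.cn_obs - 2.0) <= _DIPLOID_CN_TOL
    )


def _is_imbalanced(rec: SegmentCNRecord) -> bool:
    if math.isnan(rec.laf_obs):
        return abs(rec.cn_obs - 2.0) > _DIPLOID_CN_TOL
    return rec.laf_obs < _BALANCED_LAF_MIN or abs(rec.cn_obs - 2.0) > _DIPLOID_CN_TOL


def _vaf_mode(vafs: np.ndarray) -> float:
    """Dominant mode of the observed VAF distribution (Silverman-bandwidth KDE)."""
    if np.ptp(vafs) < 1e-9:
        return float(vafs[0])
    kde = gaussian_kde(vafs, bw_method="silverman")
    grid = np.linspace(max(vafs.min() - 0.05, 0.01), min(vafs.max() + 0.05, 1.0), 256)
    return float(grid[np.argmax(kde(grid))])


def estimate_purity(
    segments: list[SegmentCNRecord],
    mutations: list[SomaticMutation],
    grid_step: float = ALPHA_GRID_STEP,
    alpha_max: float = ALPHA_MAX,
) -> PurityEstimate:
    """Estimate the normal-cell fraction by genome-wide grid search.

    The objective at each candidate ``alpha`` sums (a) the length-weighted
    mean squared distance of contamination-corrected allelic copy numbers
    of imbalanced segments to their nearest integer state, and (b) the
    squared distance of the dominant corrected VAF mode (mutations on
    balanced diploid segments) to its nearest lattice value m/n_t.
    Ties break toward the smaller ``alpha``.
    """
    autosomal = [s for s in segments if s.segment.chrom not in SEX_CHROMS]
    imbalanced = [s for s in autosomal if _is_imbalanced(s) and not math.isnan(s.laf_obs)]
    balanced = [s for s in autosomal if _is_balanced_diploid(s)]

    balanced_vafs = np.array(
        [
            m.vaf_obs
            for m in mutations
            if m.chrom not in SEX_CHROMS
            and any(seg.segment.contains(m.chrom, m.pos) for seg in balanced)
        ]
    )
    use_vaf_term = balanced_vafs.size >= _MIN_MUTATIONS
    if not imbalanced and not use_vaf_term:
        raise UninformativeSampleError(
            "no imbalanced segments and fewer than "
            f"{_MIN_MUTATIONS} mutations on balanced diploid segments"
        )

    mode_obs = _vaf_mode(balanced_vafs) if use_vaf_term else math.nan
    weights = np.array([s.segment.length_mb for s in imbalanced])

    grid: list[tuple[float, float]] = []
    best_alpha, best_obj = 0.0, math.inf
    n_steps = int(round(alpha_max / grid_step))
    for i in range(n_steps + 1):
        alpha = i * grid_step
        obj = 0.0
        if imbalanced:
            d2 = np.empty(len(imbalanced))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # clip warnings off-grid
                for j, rec in enumerate(imbalanced):
                    cn_t, laf_t = correct_allelic_cn(rec.cn_obs, rec.laf_obs, alpha)
                    _, d = nearest_integer_state(cn_t, laf_t)
                    d2[j] = d * d
            obj += float(np.average(d2, weights=weights))
        if use_vaf_term:
            # balanced diploid: observed total CN is 2 at any alpha, so the
            # corrected mode is just the observed mode rescaled by 1/(1-alpha)
            mode_corr = mode_obs / (1.0 - alpha)
            lattice = np.array([0.5, 1.0])
            obj += float(np.min((lattice - mode_corr) ** 2))
        grid.append((alpha, obj))
        if obj < best_obj - 1e-12:
            best_alpha, best_obj = alpha, obj
    return PurityEstimate(alpha=best_alpha, objective=best_obj, grid=grid)
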