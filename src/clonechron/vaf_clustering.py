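"""Binomial-mixture clustering of somatic VAFs and subclonal-mutation flags.

Mutations sharing a copy-number context are clustered on their raw read
counts with a binomial mixture fitted by EM: each component j has a
success probability p_j (its VAF on the observed scale) and a weight, and
``alt_i ~ Binomial(depth_i, p_j)``.  The binomial likelihood uses the
per-site depth directly, so deep and shallow sites are weighted properly.
The number of components k is selected by the Bayesian information
criterion over k = 1..5.  Component means are reported on the
contamination-corrected (pure-tumor) scale.

A mutation is flagged subclonal when its corrected VAF falls more than a
threshold (default 0.10) *below* the expected full-clonal VAF of its
segment; ``detection_limit`` measures, by seeded simulation, the smallest
subclonal VAF the clustering reliably resolves at a given mean coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .io_formats import SomaticMutation
from .purity import correct_vaf

__all__ = [
    "VAFCluster",
    "VAFClusterSet",
    "cluster_vafs",
    "flag_subclonal",
    "detection_limit",
    "SUBCLONAL_VAF_THRESHOLD",
]

#: Deviation below the expected clonal VAF that marks a mutation subclonal.
SUBCLONAL_VAF_THRESHOLD = 0.10

_EM_MAX_ITER = 500
_EM_TOL = 1e-6
_P_FLOOR = 1e-6


@dataclass
class VAFCluster:
    mean: float       # corrected (pure-tumor) scale
    weight: float
    count: int
    mean_obs: float   # observed scale (binomial success probability)


@dataclass
class VAFClusterSet:
    """Fitted binomial mixture with model-selection diagnostics."""

    clusters: list[VAFCluster]
    k: int
    score_by_k: dict[int, float]
    assignments: dict[str, tuple[int, float]] = field(repr=False, default_factory=dict)
    log_likelihood: float = 0.0
    converged: bool = True

    @property
    def means(self) -> list[float]:
        return [c.mean for c in self.clusters]


# ---------------------------------------------------------------------------
# EM core (arrays only)
# ---------------------------------------------------------------------------

def _log_binom_matrix(alt, depth, log_coeff, p):
    p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    return (
        log_coeff[:, None]
        + alt[:, None] * np.log(p)[None, :]
        + (depth - alt)[:, None] * np.log1p(-p)[None, :]
    )


def _em(alt, depth, log_coeff, p0, max_iter, tol):
    """EM for a k-component binomial mixture; returns (w, p, ll, gamma, conv)."""
    k = len(p0)
    p = np.asarray(p0, dtype=float)
    w = np.full(k, 1.0 / k)
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        logpmf = _log_binom_matrix(alt, depth, log_coeff, p)
        weighted = logpmf + np.log(np.maximum(w, 1e-300))[None, :]
        norm = logsumexp(weighted, axis=1)
        ll = float(norm.sum())
        gamma = np.exp(weighted - norm[:, None])
        w = gamma.mean(axis=0)
        denom = gamma.T @ depth
        p = np.where(denom > 0, (gamma.T @ alt) / np.maximum(denom, 1e-300), p)
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    return w, p, ll_prev, gamma, converged


def _fit_k(alt, depth, log_coeff, k, rng, restarts, max_iter):
    n = alt.size
    vaf = alt / depth
    if k == 1:
        p = np.array([alt.sum() / depth.sum()])
        logpmf = _log_binom_matrix(alt, depth, log_coeff, p)
        ll = float(logpmf.sum())
        return np.array([1.0]), p, ll, np.ones((n, 1)), True
    # quantile-spread initialization plus jittered restarts
    base = np.quantile(vaf, (np.arange(k) + 0.5) / k)
    inits = [base]
    for _ in range(restarts - 1):
        inits.append(np.clip(base + rng.normal(0, 0.05, size=k), 0.01, 0.99))
    best = None
    for p0 in inits:
        fit = _em(alt, depth, log_coeff, p0, max_iter=25, tol=_EM_TOL)
        if best is None or fit[2] > best[2]:
            best = fit
    # polish the best restart to convergence
    w, p, ll, gamma, conv = _em(alt, depth, log_coeff, best[1], max_iter, _EM_TOL)
    return w, p, ll, gamma, conv


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def cluster_vafs(
    mutations: list[SomaticMutation],
    alpha: float = 0.0,
    n_t: int = 2,
    k_max: int = 5,
    restarts: int = 10,
    seed: int = 0,
    max_iter: int = _EM_MAX_ITER,
) -> VAFClusterSet:
    """Cluster somatic mutations of one copy-number context.

    Fits binomial mixtures for k = 1..``k_max`` and selects k by BIC
    (``-2 log L + (2k - 1) log n``).  Cluster means are reported on the
    contamination-corrected scale for the given ``alpha``/``n_t`` context;
    clusters are ordered by descending mean.
    """
    if len(mutations) < 20:
        raise ValueError(f"need >= 20 mutations to cluster, got {len(mutations)}")
    alt = np.array([m.alt_count for m in mutations], dtype=float)
    depth = np.array([m.depth for m in mutations], dtype=float)
    ids = [m.id for m in mutations]
    log_coeff = gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
    rng = np.random.default_rng(seed)
    n = alt.size

    degenerate = np.ptp(alt / depth) < 1e-12
    fits: dict[int, tuple] = {}
    score_by_k: dict[int, float] = {}
    for k in range(1, k_max + 1):
        if degenerate and k > 1:
            break
        w, p, ll, gamma, conv = _fit_k(alt, depth, log_coeff, k, rng, restarts, max_iter)
        fits[k] = (w, p, ll, gamma, conv)
        score_by_k[k] = -2.0 * ll + (2 * k - 1) * np.log(n)
    k_best = min(score_by_k, key=lambda k: (score_by_k[k], k))
    w, p, ll, gamma, conv = fits[k_best]
    if not conv:
        warnings.warn(
            f"EM for the selected k={k_best} stopped at {max_iter} iterations; "
            "reporting the best fit so far"
        )

    order = np.argsort(-p)
    w, p, gamma = w[order], p[order], gamma[:, order]
    hard = np.argmax(gamma, axis=1)
    counts = np.bincount(hard, minlength=k_best)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clipping of near-1 means
        clusters = [
            VAFCluster(
                mean=correct_vaf(min(float(pj), 1.0), alpha, n_t),
                weight=float(wj),
                count=int(cj),
                mean_obs=float(pj),
            )
            for pj, wj, cj in zip(p, w, counts)
        ]
    assignments = {
        mid: (int(hard[i]), float(gamma[i, hard[i]])) for i, mid in enumerate(ids)
    }
    return VAFClusterSet(
        clusters=clusters,
        k=k_best,
        score_by_k=score_by_k,
        assignments=assignments,
        log_likelihood=float(ll),
        converged=bool(conv),
    )


def flag_subclonal(
    vaf_corrected: float,
    expected_clonal_vaf: float,
    threshold: float = SUBCLONAL_VAF_THRESHOLD,
) -> bool:
    """True iff the corrected VAF sits strictly more than ``threshold``
    below the expected full-clonal VAF (subclonal mutations are depleted,
    never enriched, relative to the clonal expectation)."""
    return expected_clonal_vaf - vaf_corrected > threshold


def detection_limit(
    depth: float,
    n_clonal: int = 1000,
    n_sub: int = 100,
    replicates: int = 20,
    seed: int = 0,
    grid: tuple[float, ...] = (0.30, 0.25, 0.20, 0.15, 0.10, 0.05),
    clonal_vaf: float = 0.5,
    min_success: float = 0.9,
    mean_tol: float = 0.05,
) -> float | None:
    """Smallest reliably detectable subclonal VAF at a given mean coverage.

    Walks the descending VAF ``grid``; at each candidate v it simulates
    ``replicates`` cohorts of ``n_clonal`` clonal mutations (VAF
    ``clonal_vaf``) plus ``n_sub`` subclonal mutations (VAF v) with
    Poisson depths, clusters them, and counts a success when a non-clonal
    cluster mean falls within ``mean_tol`` of v.  Returns the smallest v
    recovered in at least ``min_success`` of replicates before the first
    failure, or None if even the largest candidate fails.
    """
    last_pass: float | None = None
    for gi, v in enumerate(grid):
        successes = 0
        for rep in range(replicates):
            rng = np.random.default_rng([seed, gi, rep])
            depths = np.maximum(rng.poisson(depth, n_clonal + n_sub), 1)
            probs = np.concatenate(
                [np.full(n_clonal, clonal_vaf), np.full(n_sub, v)]
            )
            alts = rng.binomial(depths, probs)
            muts = [
                SomaticMutation(f"m{i}", "chr1", i + 1, int(d - a), int(a))
                for i, (d, a) in enumerate(zip(depths, alts))
                if a + (d - a) > 0
            ]
            cs = cluster_vafs(muts, alpha=0.0, n_t=2, seed=rep)
            if cs.k >= 2 and any(abs(c.mean - v) <= mean_tol for c in cs.clusters):
                successes += 1
        if successes / replicates >= min_success:
            last_pass = v
        else:
            break
    return last_pass
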