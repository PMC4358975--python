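"""Synthetic tumor genomes with known purity, event history and subclones.

The generator follows the same molecular-clock model the inference
assumes: every chromosome copy accumulates mutations at a constant rate
``lambda_rate`` per megabase per unit molecular time, and a duplication
at time t copies each mutation already on the duplicated allele, so the
mutant copy count (multiplicity) of pre-event mutations doubles.  Copy
genealogies are simulated explicitly per segment: copies are duplicated
or lost by events; a subclone forks the whole cell lineage at its branch
time and then evolves privately while the major lineage continues.

Observed read counts mirror deep WGS of an impure sample: per-site depth
is Poisson around the configured mean coverage (default 105x), alt
counts are binomial at the contamination-mixed expected VAF, and
germline heterozygous sites are sampled the same way per parental
allele.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .allelic_cn import estimate_laf_counts, InsufficientSitesError
from .io_formats import (
    GenomicSegment,
    SegmentCNRecord,
    SomaticMutation,
    write_het_sites,
    write_mutations,
    write_report,
    write_segments,
)

__all__ = [
    "SimEvent",
    "SubcloneConfig",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "ConfigError",
    "default_genome",
    "simulate_tumor",
    "make_fixture",
    "FIXTURE_NAMES",
]


class ConfigError(ValueError):
    """The requested event history is internally inconsistent."""


#: hg19-scale autosome lengths in Mb.
_AUTOSOME_MB = {
    "chr1": 249, "chr2": 243, "chr3": 198, "chr4": 191, "chr5": 181,
    "chr6": 171, "chr7": 159, "chr8": 146, "chr9": 141, "chr10": 136,
    "chr11": 135, "chr12": 134, "chr13": 115, "chr14": 107, "chr15": 103,
    "chr16": 90, "chr17": 81, "chr18": 78, "chr19": 59, "chr20": 63,
    "chr21": 48, "chr22": 51,
}


def default_genome(scale: float = 1.0, chroms: list[str] | None = None) -> list[GenomicSegment]:
    """One segment per autosome, optionally length-scaled for small runs."""
    names = chroms if chroms is not None else list(_AUTOSOME_MB)
    return [
        GenomicSegment(c, 0, int(_AUTOSOME_MB[c] * 1e6 * scale)) for c in names
    ]


@dataclass(frozen=True)
class SimEvent:
    chrom: str
    event_class: str  # cn_loh_dup | trisomy_gain | gain | loss | wgd | tetrasomy
    t: float

    def __post_init__(self) -> None:
        if not 0.0 < self.t < 1.0:
            raise ConfigError(f"event time {self.t} outside (0, 1)")


@dataclass(frozen=True)
class SubcloneConfig:
    """A lineage branching off the dominant clone at ``t_branch`` and
    occupying fraction ``phi`` of tumor cells at biopsy."""

    phi: float
    t_branch: float
    private_events: tuple[SimEvent, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ConfigError(f"subclone fraction {self.phi} outside (0, 1)")
        if not 0.0 < self.t_branch < 1.0:
            raise ConfigError(f"branch time {self.t_branch} outside (0, 1)")
        for ev in self.private_events:
            if ev.t <= self.t_branch:
                raise ConfigError("private event predates the subclone branch")


@dataclass
class SimConfig:
    """Study conditions for one synthetic tumor.

    ``lambda_rate`` is mutations per Mb per chromosome copy per unit
    molecular time; ``het_density`` is germline heterozygous sites per Mb
    (default 500/Mb, i.e. 0.5 sites per kb, typical human heterozygosity).
    """

    seed: int = 0
    alpha: float = 0.0
    lambda_rate: float = 0.7
    depth_mean: float = 105.0
    segments: list[GenomicSegment] = field(default_factory=default_genome)
    events: list[SimEvent] = field(default_factory=list)
    subclones: list[SubcloneConfig] = field(default_factory=list)
    het_density: float = 500.0
    cn_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ConfigError(f"alpha {self.alpha} outside [0, 1)")
        if self.lambda_rate <= 0:
            raise ConfigError("lambda_rate must be positive")
        if sum(s.phi for s in self.subclones) >= 1.0:
            raise ConfigError("subclone fractions sum to >= 1")


@dataclass
class SimTruth:
    """Generative record used by recovery tests."""

    alpha: float
    events: list[dict]
    subclones: list[dict]
    mutations: pd.DataFrame  # id, chrom, pos, time, lineage, multiplicity, ccf
    segment_states: list[dict]  # chrom, lineage copy numbers, aggregate cn/laf

    def to_jsonable(self) -> dict:
        return {
            "alpha": self.alpha,
            "events": self.events,
            "subclones": self.subclones,
            "segment_states": self.segment_states,
            "n_mutations": int(len(self.mutations)),
        }


@dataclass
class SimResult:
    mutations: list[SomaticMutation]
    het_sites: pd.DataFrame  # chrom, pos, ref_count, alt_count
    segments: list[SegmentCNRecord]
    truth: SimTruth

    def het_sites_for(self, chrom: str) -> pd.DataFrame:
        return self.het_sites[self.het_sites["chrom"] == chrom]


# ---------------------------------------------------------------------------
# Copy genealogy
# ---------------------------------------------------------------------------

class _Copy:
    __slots__ = ("allele", "muts")

    def __init__(self, allele: str, muts: list[int] | None = None):
        self.allele = allele
        self.muts: list[int] = muts if muts is not None else []

    def clone(self) -> "_Copy":
        return _Copy(self.allele, list(self.muts))


def _apply_event(copies: list[_Copy], ev: SimEvent) -> None:
    alleles = [c.allele for c in copies]
    n_a, n_b = alleles.count("A"), alleles.count("B")
    if ev.event_class == "cn_loh_dup":
        if n_a < 1 or n_b < 1:
            raise ConfigError(
                f"{ev.chrom}: cn_loh_dup at t={ev.t} requires both alleles present"
            )
        # lose every B copy, duplicate the remaining A copies back to the
        # original total (AB -> AA)
        survivors = [c for c in copies if c.allele == "A"]
        copies[:] = survivors + [c.clone() for c in survivors[: n_b]]
    elif ev.event_class in ("trisomy_gain", "gain"):
        major = "A" if n_a >= n_b else "B"
        if alleles.count(major) == 0:
            raise ConfigError(f"{ev.chrom}: gain of an absent allele")
        idx = alleles.index(major)
        copies.append(copies[idx].clone())
    elif ev.event_class == "loss":
        minor = "B" if 0 < n_b <= n_a else "A"
        if alleles.count(minor) == 0:
            raise ConfigError(f"{ev.chrom}: loss of an absent allele")
        copies.pop(alleles.index(minor))
    elif ev.event_class in ("wgd", "tetrasomy"):
        if not copies:
            raise ConfigError(f"{ev.chrom}: duplication of an empty segment")
        copies.extend(c.clone() for c in list(copies))
    else:
        raise ConfigError(f"unknown event class {ev.event_class!r}")


def _evolve(
    rng: np.random.Generator,
    copies: list[_Copy],
    events: list[SimEvent],
    t_start: float,
    t_end: float,
    rate: float,  # lambda * L_mb: mutations per copy per unit time
    register,  # callable(time) -> mutation index
    snapshots: dict[float, list[_Copy]] | None = None,
) -> None:
    """Advance one lineage from t_start to t_end, mutating along the way.

    ``snapshots`` maps fork times to lists that receive a deep copy of the
    copy state at that time (for subclone branching).
    """
    breaks: list[tuple[float, str, object]] = [(ev.t, "event", ev) for ev in events]
    if snapshots:
        breaks += [(t, "fork", t) for t in snapshots]
    breaks.sort(key=lambda b: (b[0], b[1]))  # events before forks at equal t
    t_prev = t_start
    for t_b, kind, payload in breaks + [(t_end, "end", None)]:
        dt = t_b - t_prev
        if dt > 0:
            for c in copies:
                for _ in range(rng.poisson(rate * dt)):
                    c.muts.append(register(float(rng.uniform(t_prev, t_b))))
            t_prev = t_b
        if kind == "event":
            _apply_event(copies, payload)  # type: ignore[arg-type]
        elif kind == "fork":
            snapshots[payload][:] = [c.clone() for c in copies]  # type: ignore[index]


# ---------------------------------------------------------------------------
# Tumor simulation
# ---------------------------------------------------------------------------

def simulate_tumor(config: SimConfig) -> SimResult:
    """Generate one tumor's mutation, het-site and segment tables plus truth."""
    rng = np.random.default_rng(config.seed)
    alpha = config.alpha
    w_major = 1.0 - sum(s.phi for s in config.subclones)

    mutations: list[SomaticMutation] = []
    truth_rows: list[dict] = []
    segment_records: list[SegmentCNRecord] = []
    segment_states: list[dict] = []
    het_frames: list[pd.DataFrame] = []
    mut_counter = 0

    for seg in config.segments:
        L = seg.length_mb
        rate = config.lambda_rate * L
        trunk_events = sorted(
            (e for e in config.events if e.chrom == seg.chrom), key=lambda e: e.t
        )
        registry: list[float] = []

        def register(time: float) -> int:
            registry.append(time)
            return len(registry) - 1

        copies = [_Copy("A"), _Copy("B")]
        snapshots: dict[float, list[_Copy]] = {
            s.t_branch: [] for s in config.subclones
        }
        _evolve(rng, copies, trunk_events, 0.0, 1.0, rate, register, snapshots)

        sub_copies: list[list[_Copy]] = []
        for s in config.subclones:
            branch_copies = snapshots[s.t_branch]
            priv = sorted(
                (e for e in s.private_events if e.chrom == seg.chrom),
                key=lambda e: e.t,
            )
            _evolve(rng, branch_copies, priv, s.t_branch, 1.0, rate, register)
            sub_copies.append(branch_copies)

        # lineage-aggregate copy numbers
        lineages = [(w_major, copies)] + [
            (s.phi, sc) for s, sc in zip(config.subclones, sub_copies)
        ]
        n_bar = sum(w * len(cs) for w, cs in lineages)
        ca_bar = sum(w * sum(1 for c in cs if c.allele == "A") for w, cs in lineages)
        cb_bar = n_bar - ca_bar
        denom = (1.0 - alpha) * n_bar + 2.0 * alpha

        # multiplicity of every registered mutation per lineage
        n_reg = len(registry)
        mult = np.zeros((len(lineages), n_reg), dtype=int)
        for li, (_, cs) in enumerate(lineages):
            for c in cs:
                for mi in c.muts:
                    mult[li, mi] += 1
        weights = np.array([w for w, _ in lineages])
        c_mut_bar = weights @ mult
        ccf = weights @ (mult > 0)

        # emit observed mutation read counts
        for mi in range(n_reg):
            if c_mut_bar[mi] <= 0:
                continue  # lost before biopsy
            v = (1.0 - alpha) * c_mut_bar[mi] / denom
            depth = max(int(rng.poisson(config.depth_mean)), 1)
            alt = int(rng.binomial(depth, min(v, 1.0)))
            pos = int(rng.integers(seg.start + 1, seg.end + 1))
            mid = f"m{mut_counter:06d}"
            mut_counter += 1
            mutations.append(
                SomaticMutation(mid, seg.chrom, pos, depth - alt, alt)
            )
            if mult[0, mi] > 0 and all(
                registry[mi] < s.t_branch for s in config.subclones
            ):
                lineage = "trunk"
            elif mult[0, mi] > 0:
                lineage = "major"
            else:
                lineage = "subclone"
            truth_rows.append(
                {
                    "id": mid,
                    "chrom": seg.chrom,
                    "pos": pos,
                    "time": registry[mi],
                    "lineage": lineage,
                    "multiplicity": int(mult[:, mi].max()),
                    "ccf": float(ccf[mi]),
                }
            )

        # germline heterozygous sites
        n_sites = int(round(config.het_density * L))
        laf_obs = math.nan
        if n_sites > 0:
            pos_h = np.sort(rng.integers(seg.start + 1, seg.end + 1, n_sites))
            alt_on_a = rng.random(n_sites) < 0.5
            c_alt = np.where(alt_on_a, ca_bar, cb_bar)
            p = ((1.0 - alpha) * c_alt + alpha) / denom
            depths = np.maximum(rng.poisson(config.depth_mean, n_sites), 1)
            alts = rng.binomial(depths, np.clip(p, 0.0, 1.0))
            het_frames.append(
                pd.DataFrame(
                    {
                        "chrom": seg.chrom,
                        "pos": pos_h,
                        "ref_count": depths - alts,
                        "alt_count": alts,
                    }
                )
            )
            try:
                laf_obs = estimate_laf_counts(depths - alts, alts)
            except InsufficientSitesError:
                laf_obs = math.nan

        cn_obs = (1.0 - alpha) * n_bar + 2.0 * alpha
        if config.cn_noise_sd > 0:
            cn_obs = max(cn_obs + rng.normal(0.0, config.cn_noise_sd), 0.0)
        segment_records.append(SegmentCNRecord(seg, float(cn_obs), float(laf_obs)))
        segment_states.append(
            {
                "chrom": seg.chrom,
                "n_major_lineage": len(copies),
                "n_subclones": [len(cs) for cs in sub_copies],
                "cn_tumor": float(n_bar),
                "laf_tumor": float(min(ca_bar, cb_bar) / n_bar) if n_bar else 0.0,
            }
        )

    het = (
        pd.concat(het_frames, ignore_index=True)
        if het_frames
        else pd.DataFrame(columns=["chrom", "pos", "ref_count", "alt_count"])
    )
    truth = SimTruth(
        alpha=alpha,
        events=[
            {"chrom": e.chrom, "event_class": e.event_class, "t": e.t}
            for e in config.events
        ],
        subclones=[
            {"phi": s.phi, "t_branch": s.t_branch} for s in config.subclones
        ],
        mutations=pd.DataFrame(
            truth_rows,
            columns=["id", "chrom", "pos", "time", "lineage", "multiplicity", "ccf"],
        ),
        segment_states=segment_states,
    )
    return SimResult(mutations, het, segment_records, truth)


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("pfn_like", "pfp_like", "null_diploid")

#: Fixtures run on a 25%-length genome with the per-Mb rate raised to keep
#: per-chromosome mutation counts realistic for a hypermutated-free tumor.
_FIXTURE_SCALE = 0.25


def _fixture_config(name: str) -> SimConfig:
    genome = default_genome(scale=_FIXTURE_SCALE)
    if name == "null_diploid":
        return SimConfig(seed=20110, alpha=0.16, lambda_rate=4.0, segments=genome)
    if name == "pfn_like":
        # fusion-negative profile: early UPD of chr11/chr9, UPD chr5/7/17
        # later, late trisomies, and a minority subclone
        events = [
            SimEvent("chr11", "cn_loh_dup", 0.14),
            SimEvent("chr9", "cn_loh_dup", 0.14),
            SimEvent("chr5", "cn_loh_dup", 0.26),
            SimEvent("chr7", "cn_loh_dup", 0.26),
            SimEvent("chr17", "cn_loh_dup", 0.26),
            SimEvent("chr13", "trisomy_gain", 0.77),
            SimEvent("chr20", "trisomy_gain", 0.97),
        ]
        sub = SubcloneConfig(phi=0.4, t_branch=0.98)
        return SimConfig(
            seed=2110, alpha=0.12, lambda_rate=5.0, segments=genome,
            events=events, subclones=[sub],
        )
    if name == "pfp_like":
        # fusion-positive profile: quiet diploid genome duplicated wholesale
        # around the molecular mid-life
        events = [
            SimEvent(seg.chrom, "tetrasomy", 0.62) for seg in genome
        ]
        return SimConfig(
            seed=1907, alpha=0.16, lambda_rate=3.0, segments=genome, events=events
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def make_fixture(name: str, out_dir: str | Path) -> dict[str, Path]:
    """Write a named synthetic tumor to ``out_dir`` as the TSV dialects the
    readers consume, plus a JSON truth record.  Deterministic per name."""
    config = _fixture_config(name)
    result = simulate_tumor(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": out / "mutations.tsv",
        "het_sites": out / "het_sites.tsv",
        "segments": out / "segments.tsv",
        "truth": out / "truth.json",
    }
    write_mutations(result.mutations, paths["mutations"])
    result.het_sites.to_csv(paths["het_sites"], sep="\t", index=False)
    write_segments(result.segments, paths["segments"])
    write_report(result.truth.to_jsonable(), paths["truth"], format="json")
    return paths
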