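"""Per-tumor evolutionary timelines (clone trees) and cohort summaries.

The trunk of a clone tree is the ordered sequence of clonal copy-number
events and timed mutations, sorted by point time (interval midpoint for
mutations).  Subclonal calls hang off the trunk as branches, each with
the fraction of tumor cells it contains.  Serialization is canonical
JSON (byte-identical for identical inputs) with an optional Newick
export whose branch lengths are molecular-time spans.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .allelic_cn import SubcloneCNACall
from .event_timing import CNEvent, MutationTiming

__all__ = [
    "TimelineItem",
    "Branch",
    "CloneTree",
    "build_timeline",
    "to_json",
    "to_newick",
    "cohort_summary",
    "CohortSummary",
]

#: Subclone calls whose fractions spread more than this are split into
#: separate branches.
BRANCH_PHI_SPREAD = 0.1


@dataclass
class TimelineItem:
    kind: str  # "cn_event" | "mutation"
    label: str
    time: float
    detail: dict = field(default_factory=dict)


@dataclass
class Branch:
    phi: float
    items: list[str]


@dataclass
class CloneTree:
    trunk: list[TimelineItem]
    branches: list[Branch]
    molecular_length: int  # total mutation count at biopsy


def _event_label(event: CNEvent) -> str:
    chrom = event.segment.segment.chrom if event.segment is not None else "genome"
    return f"{event.event_class}:{chrom}"


def _subclone_entry(call) -> tuple[float, str]:
    if isinstance(call, SubcloneCNACall):
        chrom = call.segment.segment.chrom
        return call.phi, f"{call.state_major.label}->{call.state_minor.label}:{chrom}"
    phi, label = call  # (phi, label) pair
    return float(phi), str(label)


def build_timeline(
    events: Sequence[CNEvent],
    mutation_timings: Sequence[MutationTiming] = (),
    subclone_calls: Sequence = (),
    molecular_length: int | None = None,
) -> CloneTree:
    """Assemble one tumor's events and timed mutations into a clone tree.

    Trunk items are sorted by (time, segment label, id) so identical
    inputs always serialize identically.  Subclone calls are grouped into
    branches by cell fraction; fractions spreading more than
    ``BRANCH_PHI_SPREAD`` are emitted as separate branches with a warning.
    """
    trunk: list[TimelineItem] = []
    for e in events:
        trunk.append(
            TimelineItem(
                "cn_event",
                _event_label(e),
                float(e.t),
                {
                    "event_class": e.event_class,
                    "state_pre": e.state_pre.label,
                    "state_post": e.state_post.label,
                    "ci": list(e.ci) if e.ci else None,
                },
            )
        )
    for mt in mutation_timings:
        trunk.append(
            TimelineItem(
                "mutation",
                mt.mutation_id,
                mt.midpoint,
                {
                    "interval": list(mt.interval),
                    "multiplicity": mt.multiplicity,
                },
            )
        )
    trunk.sort(key=lambda it: (it.time, it.label.split(":")[-1], it.label))

    entries = sorted(_subclone_entry(c) for c in subclone_calls)
    branches: list[Branch] = []
    if entries:
        groups: list[list[tuple[float, str]]] = [[entries[0]]]
        for entry in entries[1:]:
            if entry[0] - groups[-1][0][0] > BRANCH_PHI_SPREAD:
                groups.append([entry])
            else:
                groups[-1].append(entry)
        if len(groups) > 1:
            warnings.warn(
                f"subclone fractions spread > {BRANCH_PHI_SPREAD}; "
                f"emitting {len(groups)} branches"
            )
        for grp in groups:
            branches.append(
                Branch(
                    phi=float(np.mean([p for p, _ in grp])),
                    items=[lbl for _, lbl in grp],
                )
            )
    if molecular_length is None:
        molecular_length = len(mutation_timings)
    return CloneTree(trunk, branches, molecular_length)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def to_json(tree: CloneTree) -> str:
    """Canonical JSON: sorted keys, fixed separators, deterministic floats."""
    payload = {
        "molecular_length": tree.molecular_length,
        "trunk": [
            {"kind": it.kind, "label": it.label, "time": round(it.time, 10),
             "detail": it.detail}
            for it in tree.trunk
        ],
        "branches": [
            {"phi": round(b.phi, 10), "items": b.items} for b in tree.branches
        ],
    }
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def to_newick(tree: CloneTree) -> str:
    """Newick export: the trunk is a chain of internal nodes with edge
    lengths equal to molecular-time spans between consecutive events;
    subclone branches attach at the biopsy end."""
    import dendropy

    t = dendropy.Tree()
    node = t.seed_node
    prev_time = 0.0
    for it in tree.trunk:
        if it.kind != "cn_event":
            continue
        child = dendropy.Node()
        child.label = it.label
        child.edge.length = max(it.time - prev_time, 0.0)
        node.add_child(child)
        prev_time = it.time
        node = child
    leaf = dendropy.Node()
    leaf.taxon = dendropy.Taxon("dominant_clone")
    leaf.edge.length = max(1.0 - prev_time, 0.0)
    node.add_child(leaf)
    for i, b in enumerate(tree.branches):
        bn = dendropy.Node()
        bn.taxon = dendropy.Taxon(f"subclone_{i}_phi{b.phi:.2f}")
        bn.edge.length = max(1.0 - prev_time, 0.0)
        node.add_child(bn)
    t.taxon_namespace = dendropy.TaxonNamespace(
        [n.taxon for n in t.leaf_node_iter() if n.taxon is not None]
    )
    return t.as_string(schema="newick").strip()


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    presence: pd.DataFrame  # lesion x tumor, bool
    time: pd.DataFrame      # lesion x tumor, float (NaN when untimed/absent)


def cohort_summary(
    trees: Sequence[CloneTree], labels: Sequence[str] | None = None
) -> CohortSummary:
    """Occurrence/time matrix of recurrent lesions across tumors.

    CN events are keyed by chromosome and class; mutation times are the
    median (midpoint) of their inferred interval.  Subclonal branch items
    are present but untimed.
    """
    if labels is None:
        labels = [f"tumor{i}" for i in range(len(trees))]
    if len(labels) != len(trees):
        raise ValueError("labels and trees differ in length")
    lesions: list[str] = []
    presence: dict[str, dict[str, bool]] = {}
    times: dict[str, dict[str, float]] = {}
    for lab, tree in zip(labels, trees):
        for it in tree.trunk:
            key = it.label if it.kind == "cn_event" else f"mut:{it.label}"
            if key not in presence:
                lesions.append(key)
                presence[key] = {}
                times[key] = {}
            presence[key][lab] = True
            times[key][lab] = it.time
        for b in tree.branches:
            for item in b.items:
                key = f"subclonal:{item}"
                if key not in presence:
                    lesions.append(key)
                    presence[key] = {}
                    times[key] = {}
                presence[key][lab] = True
                times[key][lab] = math.nan
    pres = pd.DataFrame(
        [[presence[k].get(lab, False) for lab in labels] for k in lesions],
        index=lesions, columns=list(labels), dtype=bool,
    )
    tm = pd.DataFrame(
        [[times[k].get(lab, math.nan) for lab in labels] for k in lesions],
        index=lesions, columns=list(labels), dtype=float,
    )
    return CohortSummary(presence=pres, time=tm)
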