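"""Clone-tree reconstruction and event timing.

The tree is built over SNV clusters under two classical constraints:

- pigeonhole / sum rule: in every sample a parent clone's CCF must be at
  least the sum of its children's CCFs (minus a noise tolerance epsilon);
- presence-subset rule: a child clone can only be present in samples
  where its parent is present.

Copy-number events inform the tree in two ways, reflecting their
precedence over SNVs: the sharing pattern of CNAs breaks ties between
otherwise equivalent attachment points, and events decorate the branches
whose sample footprint they match (truncal events decorate the root).

Event timing assumes persistence: an event, once acquired, is never lost,
so its origin is bracketed by the last dated sample lacking it and the
first dated sample carrying it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import ClonevoError, GenomicEvent, SamplePanel

log = logging.getLogger(__name__)

ORIGIN = "origin"


@dataclass
class CloneNode:
    cluster_id: str
    parent: str | None
    centers: dict[str, float]
    n_snvs: int
    presence: frozenset[str]
    events: list[GenomicEvent] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


@dataclass
class CloneTree:
    root: str
    nodes: dict[str, CloneNode]

    def children(self, cluster_id: str) -> list[str]:
        return sorted(
            c for c, n in self.nodes.items() if n.parent == cluster_id
        )

    def depth(self, cluster_id: str) -> int:
        d = 0
        node = self.nodes[cluster_id]
        while node.parent is not None:
            node = self.nodes[node.parent]
            d += 1
        return d

    def validate(self, samples: list[str], epsilon: float = 0.15) -> None:
        """Assert the sum rule and subset rule hold for every edge."""
        roots = [c for c, n in self.nodes.items() if n.parent is None]
        if roots != [self.root]:
            raise ClonevoError(f"tree must have the single root {self.root}")
        for cid, node in self.nodes.items():
            kids = self.children(cid)
            for s in samples:
                total = sum(self.nodes[k].centers[s] for k in kids
                            if "unplaced-constraint-violation" not in self.nodes[k].flags)
                if node.centers[s] < total - epsilon:
                    raise ClonevoError(
                        f"sum rule violated at {cid} in {s}: "
                        f"{node.centers[s]:.3f} < {total:.3f} - {epsilon}"
                    )

    def to_newick(self) -> str:
        """Newick with branch lengths = SNV count of the child cluster."""

        def render(cid: str) -> str:
            kids = self.children(cid)
            label = f"{cid}:{self.nodes[cid].n_snvs}"
            if not kids:
                return label
            inner = ",".join(render(k) for k in kids)
            return f"({inner}){label}"

        return render(self.root) + ";"

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "nodes": [
                {
                    "cluster": cid,
                    "parent": n.parent,
                    "n_snvs": n.n_snvs,
                    "centers": {s: round(v, 4) for s, v in n.centers.items()},
                    "presence": sorted(n.presence),
                    "events": [
                        {"kind": e.kind, "scope": e.scope, "target": e.target}
                        for e in n.events
                    ],
                    "flags": list(n.flags),
                }
                for cid, n in sorted(self.nodes.items())
            ],
        }


@dataclass(frozen=True)
class TimedEvent:
    """Origin interval (last_absent, first_present] for one event."""

    label: str
    scope: str
    kind: str
    last_absent: float | None  # None = tumor origin (truncal event)
    first_present: float | None
    non_persistent: bool = False

    def interval_str(self) -> str:
        if self.non_persistent:
            return "non-persistent"
        left = ORIGIN if self.last_absent is None else f"{self.last_absent:g}"
        return f"({left}, {self.first_present:g}]"


def identify_mrca(
    centers: dict[str, dict[str, float]],
    sizes: dict[str, int],
    samples: list[str],
    mrca_threshold: float = 0.9,
) -> tuple[str, dict[str, dict[str, float]], dict[str, int]]:
    """Find (or synthesize) the most recent common ancestor cluster.

    The MRCA is the cluster whose CCF center is >= ``mrca_threshold`` in
    every sample. Several qualifying clusters are merged into one root
    clone (size-weighted mean center) with a warning; if none qualifies,
    the cluster maximizing the minimum per-sample center is returned with
    a prominent warning. Returns (mrca_id, centers, sizes) where the maps
    reflect any merge.
    """
    if not centers:
        raise ClonevoError("identify_mrca: no clusters")
    qualifying = [
        c
        for c in sorted(centers)
        if all(centers[c][s] >= mrca_threshold for s in samples)
    ]
    if len(qualifying) == 1:
        return qualifying[0], centers, sizes
    if len(qualifying) > 1:
        log.warning(
            "identify_mrca: %d clusters (%s) are clonal in all samples; "
            "merging into one root clone",
            len(qualifying), ",".join(qualifying),
        )
        total = sum(sizes[c] for c in qualifying)
        merged_center = {
            s: sum(centers[c][s] * sizes[c] for c in qualifying) / total
            for s in samples
        }
        root_id = qualifying[0]
        new_centers = {
            c: v for c, v in centers.items() if c not in qualifying
        }
        new_sizes = {c: v for c, v in sizes.items() if c not in qualifying}
        new_centers[root_id] = merged_center
        new_sizes[root_id] = total
        return root_id, new_centers, new_sizes
    best = max(
        sorted(centers),
        key=lambda c: min(centers[c][s] for s in samples),
    )
    log.warning(
        "identify_mrca: NO cluster is clonal (>= %.2f) in all samples; "
        "falling back to %s which maximizes the minimum per-sample CCF. "
        "Interpret the tree root with caution.",
        mrca_threshold, best,
    )
    return best, centers, sizes


def _presence(center: dict[str, float], samples: list[str],
              threshold: float) -> frozenset[str]:
    return frozenset(s for s in samples if center[s] > threshold)


def build_tree(
    centers: dict[str, dict[str, float]],
    sizes: dict[str, int],
    panel: SamplePanel,
    event_partition: dict[str, list[GenomicEvent]] | None = None,
    mrca_threshold: float = 0.9,
    presence_threshold: float = 0.10,
    epsilon: float = 0.15,
) -> CloneTree:
    """Greedy constrained clone-tree construction with CNA precedence.

    Clusters are attached in order of descending total CCF, each to the
    deepest existing node satisfying the presence-subset rule and the sum
    rule in every sample. When several nodes at the maximal depth qualify,
    preference goes to the one whose sample footprint shares a CNA
    sharing-set with the cluster being placed; remaining ties break on
    cluster id. A cluster satisfying the constraints nowhere is attached
    to the root and flagged ``unplaced-constraint-violation``.

    CNA decoration: truncal events (present in all samples) decorate the
    root; any other event decorates every maximal node whose footprint is
    contained in the event's sample set.
    """
    samples = panel.samples
    root_id, centers, sizes = identify_mrca(centers, sizes, samples,
                                            mrca_threshold)
    nodes: dict[str, CloneNode] = {
        root_id: CloneNode(
            cluster_id=root_id,
            parent=None,
            centers=dict(centers[root_id]),
            n_snvs=sizes[root_id],
            presence=_presence(centers[root_id], samples, presence_threshold),
        )
    }
    cna_sets: list[frozenset[str]] = []
    all_events: list[GenomicEvent] = []
    if event_partition:
        for group in event_partition.values():
            for ev in group:
                all_events.append(ev)
                pres = ev.present_in()
                if pres and pres not in cna_sets:
                    cna_sets.append(pres)

    order = sorted(
        (c for c in centers if c != root_id),
        key=lambda c: (-sum(centers[c][s] for s in samples), c),
    )
    for cid in order:
        center = centers[cid]
        pres = _presence(center, samples, presence_threshold)
        candidates = []
        for pid, pnode in nodes.items():
            # subset rule, with slack for barely-present samples
            ok = all(
                (s in pnode.presence) or (center[s] <= presence_threshold + epsilon)
                for s in pres
            )
            if not ok:
                continue
            # sum rule including already-attached children
            sib_sum = {
                s: sum(
                    nodes[k].centers[s]
                    for k in nodes
                    if nodes[k].parent == pid
                    and "unplaced-constraint-violation" not in nodes[k].flags
                )
                for s in samples
            }
            if any(
                pnode.centers[s] < sib_sum[s] + center[s] - epsilon
                for s in samples
            ):
                continue
            depth = _depth_of(nodes, pid)
            cna_bonus = int(
                any(pres <= cs and pnode.presence <= cs for cs in cna_sets)
            )
            candidates.append((depth, cna_bonus, pid))
        if candidates:
            # deepest first, CNA-consistent preferred, then id order
            candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
            parent = candidates[0][2]
            flags: list[str] = []
        else:
            parent = root_id
            flags = ["unplaced-constraint-violation"]
            log.warning(
                "cluster %s violates tree constraints everywhere; "
                "attached to root and flagged", cid,
            )
        nodes[cid] = CloneNode(
            cluster_id=cid,
            parent=parent,
            centers=dict(center),
            n_snvs=sizes[cid],
            presence=pres,
            flags=flags,
        )

    tree = CloneTree(root=root_id, nodes=nodes)
    _decorate(tree, all_events, samples)
    tree.validate(samples, epsilon=epsilon)
    return tree


def _depth_of(nodes: dict[str, CloneNode], cid: str) -> int:
    d = 0
    while nodes[cid].parent is not None:
        cid = nodes[cid].parent
        d += 1
    return d


def _decorate(tree: CloneTree, events: list[GenomicEvent],
              samples: list[str]) -> None:
    all_samples = frozenset(samples)
    for ev in events:
        pres = ev.present_in()
        if not pres:
            continue
        if pres == all_samples:
            tree.nodes[tree.root].events.append(ev)
            continue
        # highest nodes whose sample footprint sits inside the event's set
        fitting = {
            cid for cid, n in tree.nodes.items()
            if n.presence and n.presence <= pres
        }
        maximal = [
            cid for cid in fitting
            if not any(_is_ancestor(tree, other, cid) for other in fitting)
        ]
        if not maximal:
            tree.nodes[tree.root].events.append(ev)
            log.warning(
                "event %s (%s) matches no clone footprint; placed at root",
                ev.target, ev.kind,
            )
            continue
        for cid in sorted(maximal):
            tree.nodes[cid].events.append(ev)


def _is_ancestor(tree: CloneTree, anc: str, cid: str) -> bool:
    node = tree.nodes[cid]
    while node.parent is not None:
        if node.parent == anc:
            return True
        node = tree.nodes[node.parent]
    return False


def time_events(
    events: list[GenomicEvent],
    panel: SamplePanel,
) -> list[TimedEvent]:
    """Bracket each event's origin between dated samples.

    Samples sharing a collection date form one time point; an event counts
    as present at a date if any sample collected then carries it. Under
    the persistence assumption the event arose in
    (last absent date, first present date]; truncal events get
    (origin, earliest date]. A presence pattern that turns absent after
    being present (possible for branch-private events when lineages are
    sampled at different times) is flagged non-persistent and left
    un-timed.
    """
    dates = sorted({panel.dates[s] for s in panel.samples})
    by_date = {
        d: [s for s in panel.samples if panel.dates[s] == d] for d in dates
    }
    out: list[TimedEvent] = []
    for ev in events:
        present = [
            any(ev.sample_presence.get(s, False) for s in by_date[d])
            for d in dates
        ]
        if not any(present):
            continue
        first_idx = present.index(True)
        if any(not p for p in present[first_idx:]):
            out.append(
                TimedEvent(
                    label=ev.target, scope=ev.scope, kind=ev.kind,
                    last_absent=None, first_present=None, non_persistent=True,
                )
            )
            continue
        last_absent = dates[first_idx - 1] if first_idx > 0 else None
        out.append(
            TimedEvent(
                label=ev.target, scope=ev.scope, kind=ev.kind,
                last_absent=last_absent, first_present=dates[first_idx],
            )
        )
    return out
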