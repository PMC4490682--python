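"""Recurrence detection by reciprocal overlap and CNVR construction.

Two calls overlap reciprocally at fraction f when the shared length is at
least f of BOTH call lengths (the bedtools ``-f x -r`` semantic).  Calls
are nodes of an undirected graph with an edge for every pair at >= 40 %
reciprocal overlap; connected components of size two or more are candidate
copy-number-variable regions (CNVRs).  A call is "recurrent" when it has at
least one edge anywhere in the panel — uniqueness is never re-evaluated
within subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .core_io import CnvCall, interval_length

DEFAULT_RECIPROCAL_FRACTION = 0.40
COMPLEX_CONCORDANCE_THRESHOLD = 0.75


def reciprocal_overlap(
    a: tuple[str, int, int] | CnvCall, b: tuple[str, int, int] | CnvCall
) -> float:
    """min(ov/len(a), ov/len(b)) for 1-based inclusive intervals; 0 if disjoint."""
    ca, sa, ea = a.interval if isinstance(a, CnvCall) else a
    cb, sb, eb = b.interval if isinstance(b, CnvCall) else b
    if ea < sa or eb < sb:
        raise ValueError("invalid interval")
    if ca != cb:
        return 0.0
    ov = min(ea, eb) - max(sa, sb) + 1
    if ov <= 0:
        return 0.0
    return min(ov / interval_length(sa, ea), ov / interval_length(sb, eb))


def _sorted_calls(calls: Sequence[CnvCall]) -> list[CnvCall]:
    return sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.sample_id))


def build_recurrence_graph(
    calls: Sequence[CnvCall], f: float = DEFAULT_RECIPROCAL_FRACTION
) -> nx.Graph:
    """Graph over call indices with edges at reciprocal overlap >= f.

    Nodes are indices into the (chrom, start, end, sample_id)-sorted call
    list; each node carries its call as attribute ``call``.  Built with a
    sorted sweep: a pair can only satisfy f > 0 if the intervals intersect,
    so for each call only the subsequent calls starting before its end are
    examined.
    """
    if not 0 < f <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ordered = _sorted_calls(calls)
    g = nx.Graph()
    for i, c in enumerate(ordered):
        g.add_node(i, call=c)
    for i, a in enumerate(ordered):
        for j in range(i + 1, len(ordered)):
            b = ordered[j]
            if b.chrom != a.chrom or b.start > a.end:
                break
            if reciprocal_overlap(a, b) >= f:
                g.add_edge(i, j)
    return g


def classify_uniqueness(graph: nx.Graph) -> dict[int, str]:
    """Per-node label: 'recurrent' iff the node has any edge, else 'unique'.

    The graph must span the entire analysis; subgroup tables re-use these
    labels rather than re-evaluating within the subgroup.
    """
    return {
        n: "recurrent" if graph.degree[n] >= 1 else "unique" for n in graph.nodes
    }


@dataclass(frozen=True)
class CnvRegion:
    """A connected component of >= 2 recurrently overlapping calls."""

    member_ids: tuple[int, ...]
    members: tuple[CnvCall, ...]
    chrom: str
    start: int  # min member start
    end: int    # max member end
    n_samples: int
    state_mix: str  # all_deletion / all_amplification / mixed
    boundary_concordance: float
    complex: bool


def boundary_concordance(members: Sequence[CnvCall]) -> float:
    """Mean pairwise reciprocal overlap over all member pairs.

    Regions whose members all share identical boundaries score exactly 1.0;
    scores below 0.75 mark the region as complex.
    """
    if len(members) < 2:
        raise ValueError("boundary concordance needs >= 2 members")
    pairs = list(combinations(members, 2))
    return sum(reciprocal_overlap(a, b) for a, b in pairs) / len(pairs)


def extract_regions(
    graph: nx.Graph,
    concordance_threshold: float = COMPLEX_CONCORDANCE_THRESHOLD,
) -> list[CnvRegion]:
    """Connected components of size >= 2 as CnvRegions, sorted by span."""
    regions = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        ids = tuple(sorted(comp))
        members = tuple(graph.nodes[i]["call"] for i in ids)
        states = {
            "deletion" if m.copy_state < 2 else "amplification" for m in members
        }
        mix = "mixed" if len(states) > 1 else f"all_{states.pop()}"
        conc = boundary_concordance(members)
        regions.append(
            CnvRegion(
                member_ids=ids,
                members=members,
                chrom=members[0].chrom,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                n_samples=len({m.sample_id for m in members}),
                state_mix=mix,
                boundary_concordance=conc,
                complex=conc < concordance_threshold,
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def most_common_cnvs(calls: Sequence[CnvCall]) -> pd.DataFrame:
    """Tally calls sharing the exact same (chrom, start, end).

    Counts distinct samples (a sample carrying the event twice counts
    once) and reports the copy-state composition.  Sorted by descending
    sample count.
    """
    groups: dict[tuple[str, int, int], list[CnvCall]] = {}
    for c in calls:
        groups.setdefault(c.interval, []).append(c)
    rows = []
    for (chrom, start, end), members in groups.items():
        states = sorted({m.copy_state for m in members})
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_mice": len({m.sample_id for m in members}),
                "states": ",".join(str(s) for s in states),
            }
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_mice", "states"]
    )
    return df.sort_values(
        ["n_mice", "chrom", "start"], ascending=[False, True, True]
    ).reset_index(drop=True)


def concordance_with_study(
    calls: Sequence[CnvCall],
    reference_intervals: Iterable[tuple[str, int, int]],
    mode: str = "reciprocal_20",
) -> tuple[list[bool], float]:
    """Match calls against a previously reported interval set.

    ``reciprocal_20``: matched iff >= 20 % reciprocal overlap with any
    reference interval; ``onebp``: matched iff they share >= 1 bp.  Copy
    state is ignored — the presence of any reported variant in the region
    counts as concordance.  Returns per-call booleans (in input order) and
    the matched fraction.
    """
    if mode not in ("reciprocal_20", "onebp"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in reference_intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    matched = []
    for c in calls:
        hit = False
        for start, end in by_chrom.get(c.chrom, ()):
            if mode == "onebp":
                if start <= c.end and end >= c.start:
                    hit = True
                    break
            elif reciprocal_overlap(c.interval, (c.chrom, start, end)) >= 0.20:
                hit = True
                break
        matched.append(hit)
    frac = sum(matched) / len(matched) if matched else 0.0
    return matched, frac


def graph_to_table(graph: nx.Graph) -> pd.DataFrame:
    """Edge list with per-node degree, for external renderers."""
    rows = [
        {
            "node_i": i,
            "node_j": j,
            "sample_i": graph.nodes[i]["call"].sample_id,
            "sample_j": graph.nodes[j]["call"].sample_id,
        }
        for i, j in sorted(graph.edges)
    ]
    return pd.DataFrame(rows, columns=["node_i", "node_j", "sample_i", "sample_j"])
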