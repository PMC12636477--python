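"""Graph-based ordering of per-fiber CRE-accessibility combinations.

Each spanning read is a binary vector over tracked elements; observed
combinations become nodes (rare ones filtered), edges connect combinations
differing in exactly one element, and candidate trajectories are simple
paths from a designated initial combination through the peak (all-open)
combination to a terminal combination, ranked by summed read support.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product

import numpy as np

Combo = tuple[int, ...]


@dataclass
class ComboNode:
    vector: Combo
    count: int


@dataclass
class Route:
    nodes: list[Combo]
    support: int
    stages: list[str] = field(default_factory=list)

    def __len__(self):
        return len(self.nodes)


def combination_space(n_elements: int) -> list[Combo]:
    """All binary accessibility combinations over `n_elements` elements."""
    if n_elements < 0:
        raise ValueError("element count must be non-negative")
    return [tuple(bits) for bits in product((0, 1), repeat=n_elements)]


def tabulate_combos(
    vectors: list[Combo] | np.ndarray,
    min_support_fraction: float = 0.01,
    min_support_absolute: int = 0,
) -> list[ComboNode]:
    """Count distinct accessibility vectors and drop rare combinations.

    A combination is kept iff its count >= max(`min_support_fraction` x
    total reads, `min_support_absolute`). Nodes are returned in descending
    count order (ties: lexicographic vector).
    """
    vecs = [tuple(int(b) for b in v) for v in vectors]
    if not vecs:
        raise ValueError("no reads supplied")
    widths = {len(v) for v in vecs}
    if len(widths) > 1:
        raise ValueError(f"inconsistent vector lengths {sorted(widths)}")
    counts = Counter(vecs)
    floor = max(min_support_fraction * len(vecs), min_support_absolute)
    nodes = [
        ComboNode(v, c) for v, c in counts.items() if c >= floor
    ]
    nodes.sort(key=lambda n: (-n.count, n.vector))
    return nodes


def hamming(a: Combo, b: Combo) -> int:
    return sum(x != y for x, y in zip(a, b))


def enumerate_routes(
    nodes: list[ComboNode],
    initial: Combo,
    peak: Combo,
    terminals: list[Combo],
    require_peak: bool = True,
    support_mode: str = "sum",
) -> list[Route]:
    """Enumerate and rank simple paths initial -> (peak) -> terminal.

    Edges connect observed combinations at Hamming distance 1; no node may
    repeat within a route. Routes are ranked by support (`support_mode`
    "sum" of node read counts, or "min"), ties broken by shorter route then
    lexicographic node sequence. Missing anchor combinations raise.
    """
    initial = tuple(initial)
    peak = tuple(peak)
    terminals = [tuple(t) for t in terminals]
    by_vec = {n.vector: n.count for n in nodes}
    for name, anchor in (("initial", initial), ("peak", peak)):
        if anchor not in by_vec:
            raise ValueError(f"{name} combination {anchor} not among nodes")
    present_terminals = {t for t in terminals if t in by_vec}
    if not present_terminals:
        raise ValueError(f"no terminal combination among nodes: {terminals}")

    adjacency: dict[Combo, list[Combo]] = {v: [] for v in by_vec}
    vecs = sorted(by_vec)
    for i, a in enumerate(vecs):
        for b in vecs[i + 1 :]:
            if hamming(a, b) == 1:
                adjacency[a].append(b)
                adjacency[b].append(a)

    routes: list[Route] = []

    def dfs(node: Combo, path: list[Combo], visited: set[Combo]):
        if node in present_terminals and node != initial:
            if not require_peak or peak in path:
                support = (
                    sum(by_vec[v] for v in path)
                    if support_mode == "sum"
                    else min(by_vec[v] for v in path)
                )
                routes.append(Route(list(path), support))
        for nxt in adjacency[node]:
            if nxt in visited:
                continue
            visited.add(nxt)
            path.append(nxt)
            dfs(nxt, path, visited)
            path.pop()
            visited.remove(nxt)

    dfs(initial, [initial], {initial})
    routes.sort(key=lambda r: (-r.support, len(r.nodes), r.nodes))
    return routes


def annotate_stages(
    route: Route,
    read_vectors: dict[str, Combo],
    stage_names: list[str] | None = None,
) -> dict[str, list[str]]:
    """Assign each read to its route stage (or "off-route").

    Returns a mapping stage -> read ids; stages default to "stage_1"...;
    reads whose combination is not on the route land in "off-route".
    """
    names = stage_names or [f"stage_{i + 1}" for i in range(len(route.nodes))]
    if len(names) != len(route.nodes):
        raise ValueError("one stage name per route node required")
    by_vec = {v: names[i] for i, v in enumerate(route.nodes)}
    out: dict[str, list[str]] = {name: [] for name in names}
    out["off-route"] = []
    for read_id, vec in read_vectors.items():
        out[by_vec.get(tuple(vec), "off-route")].append(read_id)
    return out
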