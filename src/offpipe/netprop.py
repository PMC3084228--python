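"""Signed off-target interaction network and qualitative sign propagation.

Nodes are typed (off_target, intermediate, pathway, effect) and edges carry
a regulatory sign: activation preserves a perturbation's direction,
inhibition flips it, and a dual edge can do either. Inhibiting a set of
off-targets seeds them "down"; directions then propagate to every reachable
node. A node reached only by paths that agree gets that direction; any
disagreement — or any dual edge en route — makes it "mixed". The
implementation runs a monotone fixpoint over the lattice
unknown < {up, down} < mixed, which terminates on cyclic graphs and, on
DAGs, coincides with brute-force enumeration of simple paths. The analysis
is deliberately qualitative: no edge weights, no kinetics.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import KindError, SchemaError

NODE_KINDS = {"off_target", "intermediate", "pathway", "effect"}
EDGE_SIGNS = {"activation", "inhibition", "dual"}

#: lattice order used by the fixpoint: frozensets of base directions;
#: "mixed" is the top element {up, down}
_UP = frozenset({"up"})
_DOWN = frozenset({"down"})
_MIXED = frozenset({"up", "down"})


@dataclass
class SignedNetwork:
    graph: nx.DiGraph

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == kind)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class PerturbationResult:
    directions: dict[str, str]  # up | down | mixed | unchanged
    path_counts: dict[str, dict[str, int]]  # node -> {"up": n, "down": m}
    inhibited: tuple[str, ...]


def build_network(nodes, edges) -> SignedNetwork:
    """Assemble and validate a network from (id, kind) and
    (source, target, sign) iterables; duplicate edges with conflicting signs
    collapse to dual with a warning."""
    g = nx.DiGraph()
    for nid, kind in nodes:
        if kind not in NODE_KINDS:
            raise SchemaError(f"unknown node kind {kind!r} for {nid!r}")
        g.add_node(nid, kind=kind)
    for src, dst, sign in edges:
        if sign not in EDGE_SIGNS:
            raise SchemaError(f"unknown edge sign {sign!r} on {src}->{dst}")
        if src == dst:
            raise SchemaError(f"self-loop on {src!r} not allowed")
        for n in (src, dst):
            if n not in g:
                raise SchemaError(f"edge endpoint {n!r} is not a declared node")
        if g.has_edge(src, dst):
            old = g[src][dst]["sign"]
            if old != sign:
                warnings.warn(
                    f"conflicting duplicate edge {src}->{dst} "
                    f"({old} vs {sign}): collapsed to dual",
                    stacklevel=2,
                )
                g[src][dst]["sign"] = "dual"
        else:
            g.add_edge(src, dst, sign=sign)
    return SignedNetwork(g)


def load_network(source) -> SignedNetwork:
    """Read a TSV edge list with columns source, target, sign, source_kind,
    target_kind."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"source", "target", "sign", "source_kind", "target_kind"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"edge table missing column(s): {sorted(missing)}")
    nodes: dict[str, str] = {}
    for _, row in df.iterrows():
        for node, kind in ((row["source"], row["source_kind"]), (row["target"], row["target_kind"])):
            if node in nodes and nodes[node] != kind:
                raise SchemaError(f"node {node!r} declared with two kinds")
            nodes[node] = kind
    edges = list(df[["source", "target", "sign"]].itertuples(index=False, name=None))
    return build_network(sorted(nodes.items()), edges)


def _apply_sign(direction: frozenset, sign: str) -> frozenset:
    if not direction:
        return direction
    if sign == "activation":
        return direction
    if sign == "inhibition":
        flipped = set()
        if "up" in direction:
            flipped.add("down")
        if "down" in direction:
            flipped.add("up")
        return frozenset(flipped)
    return _MIXED  # dual


def propagate(net: SignedNetwork, inhibited) -> PerturbationResult:
    """Qualitative consequence of inhibiting a set of off-target nodes.

    Runs the lattice fixpoint; afterwards, supporting simple-path counts per
    pure direction are tallied for reporting (capped enumeration on large
    graphs is unnecessary at this network's scale).
    """
    inhibited = tuple(sorted(set(inhibited)))
    g = net.graph
    for n in inhibited:
        if n not in g:
            raise KindError(f"unknown node {n!r}")
        if g.nodes[n]["kind"] != "off_target":
            raise KindError(
                f"node {n!r} has kind {g.nodes[n]['kind']!r}; only off_target "
                "nodes can be inhibited"
            )
    state: dict[str, frozenset] = {n: frozenset() for n in g.nodes}
    for n in inhibited:
        state[n] = _DOWN
    changed = True
    while changed:
        changed = False
        for src, dst, data in g.edges(data=True):
            new = state[dst] | _apply_sign(state[src], data["sign"])
            if new != state[dst]:
                state[dst] = new
                changed = True

    def label(s: frozenset) -> str:
        if not s:
            return "unchanged"
        if s == _MIXED:
            return "mixed"
        return next(iter(s))

    counts = {n: {"up": 0, "down": 0} for n in g.nodes}
    for seed in inhibited:
        counts[seed]["down"] += 1
        for target in g.nodes:
            if target == seed:
                continue
            for path in nx.all_simple_paths(g, seed, target):
                d = _DOWN
                for a, b in zip(path, path[1:]):
                    d = _apply_sign(d, g[a][b]["sign"])
                if d == _UP:
                    counts[target]["up"] += 1
                elif d == _DOWN:
                    counts[target]["down"] += 1
                else:
                    counts[target]["up"] += 1
                    counts[target]["down"] += 1
    return PerturbationResult(
        directions={n: label(s) for n, s in state.items()},
        path_counts=counts,
        inhibited=inhibited,
    )


def propagate_bruteforce(net: SignedNetwork, inhibited) -> dict[str, str]:
    """Simple-path enumeration oracle (exponential; sound on DAGs only).

    Retained as an independent cross-check of the fixpoint on small graphs.
    """
    g = net.graph
    out: dict[str, str] = {}
    for target in g.nodes:
        dirs = set()
        for seed in inhibited:
            if target == seed:
                dirs.add(_DOWN)
                continue
            for path in nx.all_simple_paths(g, seed, target):
                d = _DOWN
                for a, b in zip(path, path[1:]):
                    d = _apply_sign(d, g[a][b]["sign"])
                dirs.add(d)
        merged = frozenset().union(*dirs) if dirs else frozenset()
        if not merged:
            out[target] = "unchanged"
        elif merged == _MIXED:
            out[target] = "mixed"
        else:
            out[target] = next(iter(merged))
    return out


def report(net: SignedNetwork, result: PerturbationResult) -> tuple[str, pd.DataFrame]:
    """Per-node direction summary, text plus TSV-ready frame (stable order:
    pathways, then effects, then the rest)."""
    rows = []
    order = {"pathway": 0, "effect": 1, "off_target": 2, "intermediate": 3}
    for node in sorted(net.graph.nodes, key=lambda n: (order[net.graph.nodes[n]["kind"]], n)):
        kind = net.graph.nodes[node]["kind"]
        rows.append(
            {
                "node": node,
                "kind": kind,
                "direction": result.directions[node],
                "paths_up": result.path_counts[node]["up"],
                "paths_down": result.path_counts[node]["down"],
            }
        )
    df = pd.DataFrame(rows)
    lines = [f"inhibited off-targets: {', '.join(result.inhibited) or '(none)'}"]
    for _, r in df.iterrows():
        lines.append(
            f"{r['kind']:<12} {r['node']:<20} {r['direction']:<9} "
            f"(up paths: {r['paths_up']}, down paths: {r['paths_down']})"
        )
    return "\n".join(lines), df


def result_to_tsv(net: SignedNetwork, result: PerturbationResult) -> str:
    buf = io.StringIO()
    report(net, result)[1].to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


def result_from_tsv(text: str) -> dict[str, str]:
    df = pd.read_csv(io.StringIO(text), sep="\t")
    return dict(zip(df["node"], df["direction"]))
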