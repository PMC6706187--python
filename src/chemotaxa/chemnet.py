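"""Chemotype ("chemical haplotype") networks from CHC compositions.

The core idea: treat a colony's clr-transformed CHC profile like a DNA
sequence. A PCA of the clr data defines a handful of informative axes; each
axis is cut into a small number of ordered categories in proportion to the
variance it explains; every colony then carries a short integer "category
sequence". Colonies with identical sequences collapse into one chemical
type, inter-type distances are summed per-axis category differences, and a
minimum spanning network over the types plays the role of a haplotype
network, making the separation between chemotypes countable in discrete
steps.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._pca import PcaResult, principal_components
from .preprocess import CompositionMatrix

__all__ = [
    "clr_transform",
    "pca_clr",
    "axis_categories",
    "discretize_scores",
    "collapse_chemical_types",
    "type_distance",
    "build_msn",
    "ChemicalType",
    "ChemotypeNetwork",
    "network_from_composition",
    "cut_longest_mst_edge",
]


def clr_transform(
    cm: CompositionMatrix | pd.DataFrame,
    zero_strategy: str = "multiplicative_replacement",
    delta: float = 1e-5,
) -> pd.DataFrame:
    """Centered log-ratio transform of closed compositions.

    Zeros are handled by multiplicative replacement (zeros set to ``delta``,
    non-zero parts shrunk proportionally so rows stay closed) or rejected
    outright with ``zero_strategy="error_on_zero"``. Output rows sum to 0.
    """
    X = cm.proportions if isinstance(cm, CompositionMatrix) else cm
    vals = X.values.astype(float).copy()
    zeros = vals == 0
    if zeros.any():
        if zero_strategy == "error_on_zero":
            i, j = np.argwhere(zeros)[0]
            raise ValueError(
                f"zero proportion at sample {X.index[i]!r}, part {X.columns[j]!r}"
            )
        if zero_strategy != "multiplicative_replacement":
            raise ValueError(f"unknown zero strategy {zero_strategy!r}")
        nz = zeros.sum(axis=1)
        shrink = 1.0 - nz * delta
        if (shrink <= 0).any():
            raise ValueError("delta too large for the number of zeros")
        vals = vals * shrink[:, None]
        vals[zeros] = delta
    logs = np.log(vals)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=X.index, columns=X.columns)


def pca_clr(clr: pd.DataFrame) -> PcaResult:
    """Covariance-matrix PCA of clr coordinates (column-centered, unscaled)."""
    return principal_components(clr, standardize=False)


def axis_categories(
    eigen_pct: Sequence[float],
    min_pct: float = 5.0,
    divisor: float = 5.0,
) -> tuple[list[int], list[int]]:
    """Number of ordered categories per retained PC axis.

    Axes explaining less than ``min_pct`` percent of the variance are
    dropped; axes between ``min_pct`` and ``2*min_pct`` get two categories;
    otherwise k = round(eigen_pct / divisor) (round half to even). Returns
    ``(retained_axis_indices, k_per_axis)``.
    """
    retained: list[int] = []
    ks: list[int] = []
    for j, e in enumerate(eigen_pct):
        if e < min_pct:
            continue
        k = 2 if e <= 2 * min_pct else int(np.rint(e / divisor))
        retained.append(j)
        ks.append(max(k, 2))
    if not retained:
        raise ValueError(
            f"no PC axis explains >= {min_pct}% of the variance; nothing to discretize"
        )
    return retained, ks


def discretize_scores(
    scores: pd.DataFrame,
    k_per_axis: Sequence[int],
    axes: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Map PC scores to integer categories 0..k-1 per retained axis.

    c = rint((s - min) / (max - min) * (k - 1)); the sample at the axis
    minimum gets 0 and at the maximum k-1. Rounding is half-to-even.
    """
    if axes is None:
        axes = list(range(len(k_per_axis)))
    cols = {}
    for ax, k in zip(axes, k_per_axis):
        s = scores.iloc[:, ax].values
        lo, hi = s.min(), s.max()
        if hi == lo:
            raise ValueError(f"axis {scores.columns[ax]} is constant; cannot discretize")
        cols[scores.columns[ax]] = np.rint((s - lo) / (hi - lo) * (k - 1)).astype(int)
    return pd.DataFrame(cols, index=scores.index)


@dataclass
class ChemicalType:
    """A unique category sequence and the samples carrying it."""

    label: str
    categories: tuple[int, ...]
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


def collapse_chemical_types(sequences: pd.DataFrame) -> list[ChemicalType]:
    """Group samples with identical category sequences into chemical types.

    Types are labelled CT1, CT2, ... by decreasing membership, ties broken
    by lexicographic category vector.
    """
    lengths = {len(row) for row in sequences.itertuples(index=False)}
    if len(lengths) > 1:  # pragma: no cover - DataFrame guarantees rectangularity
        raise ValueError("category sequences differ in length")
    groups: dict[tuple[int, ...], list[str]] = {}
    for sid, row in sequences.iterrows():
        groups.setdefault(tuple(int(v) for v in row), []).append(sid)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        ChemicalType(label=f"CT{i + 1}", categories=cats, members=members)
        for i, (cats, members) in enumerate(ordered)
    ]


def type_distance(a: Sequence[int], b: Sequence[int]) -> int:
    """Summed per-axis scalar distances (L1 over category vectors)."""
    if len(a) != len(b):
        raise ValueError("category sequences differ in length")
    return int(sum(abs(int(x) - int(y)) for x, y in zip(a, b)))


@dataclass
class ChemotypeNetwork:
    """Chemical types joined by integer-weight edges; MST edges flagged."""

    types: list[ChemicalType]
    graph: nx.Graph  # all recorded edges, attrs: weight, is_mst_edge

    @property
    def mst_edges(self) -> list[tuple[str, str, int]]:
        return [
            (u, v, d["weight"])
            for u, v, d in self.graph.edges(data=True)
            if d["is_mst_edge"]
        ]

    def membership(self) -> pd.Series:
        """Sample id -> chemical type label."""
        return pd.Series(
            {sid: t.label for t in self.types for sid in t.members}, name="type"
        )

    # ---- exports -----------------------------------------------------
    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [t.label for t in self.types],
                "size": [t.size for t in self.types],
                "categories": [";".join(map(str, t.categories)) for t in self.types],
                "members": [";".join(t.members) for t in self.types],
            }
        )

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"a": u, "b": v, "weight": d["weight"], "is_mst_edge": d["is_mst_edge"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["a", "b", "weight", "is_mst_edge"])

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for t in self.types:
            g.nodes[t.label]["size"] = t.size
            g.nodes[t.label]["members"] = ";".join(t.members)
        nx.write_graphml(g, path)

    def write_dot(self, path: str | Path) -> None:
        lines = ["graph chemotypes {"]
        for t in self.types:
            lines.append(f'  "{t.label}" [width={t.size}];')
        for u, v, d in sorted(self.graph.edges(data=True)):
            style = "solid" if d["is_mst_edge"] else "dashed"
            lines.append(f'  "{u}" -- "{v}" [label={d["weight"]}, style={style}];')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")


def build_msn(
    types: list[ChemicalType],
    distances: pd.DataFrame | None = None,
    include_alternatives: bool = False,
) -> ChemotypeNetwork:
    """Minimum spanning network over chemical types.

    Kruskal MST with deterministic tie-break (edges considered in ascending
    weight, then lexicographic label order). With ``include_alternatives``,
    each non-tree edge whose weight equals the maximum edge weight on the
    tree path between its endpoints is added as an alternative link.
    """
    labels = [t.label for t in types]
    if distances is None:
        n = len(types)
        d = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = type_distance(
                    types[i].categories, types[j].categories
                )
        distances = pd.DataFrame(d, index=labels, columns=labels)
    full = nx.Graph()
    full.add_nodes_from(labels)
    for a, b in sorted(
        (tuple(sorted((a, b))) for i, a in enumerate(labels) for b in labels[i + 1:])
    ):
        full.add_edge(a, b, weight=float(distances.loc[a, b]))
    mst = nx.minimum_spanning_tree(full, algorithm="kruskal")

    g = nx.Graph()
    g.add_nodes_from(labels)
    for u, v, d in mst.edges(data=True):
        g.add_edge(u, v, weight=int(round(d["weight"])), is_mst_edge=True)
    if include_alternatives and len(labels) > 1:
        for u, v, d in full.edges(data=True):
            if g.has_edge(u, v):
                continue
            path = nx.shortest_path(mst, u, v)
            path_max = max(
                mst[a][b]["weight"] for a, b in zip(path, path[1:])
            )
            if d["weight"] == path_max:
                g.add_edge(u, v, weight=int(round(d["weight"])), is_mst_edge=False)
    return ChemotypeNetwork(types=types, graph=g)


def network_from_composition(
    cm: CompositionMatrix | pd.DataFrame,
    zero_strategy: str = "multiplicative_replacement",
    delta: float = 1e-5,
    min_pct: float = 5.0,
    include_alternatives: bool = False,
) -> tuple[ChemotypeNetwork, PcaResult, pd.DataFrame]:
    """Full clr -> PCA -> discretize -> collapse -> MSN pipeline.

    Returns the network, the PCA result, and the per-sample category
    sequences.
    """
    clr = clr_transform(cm, zero_strategy=zero_strategy, delta=delta)
    pca = pca_clr(clr)
    axes, ks = axis_categories(pca.eigen_pct, min_pct=min_pct)
    seqs = discretize_scores(pca.scores, ks, axes)
    types = collapse_chemical_types(seqs)
    net = build_msn(types, include_alternatives=include_alternatives)
    return net, pca, seqs


def cut_longest_mst_edge(net: ChemotypeNetwork) -> pd.Series:
    """Split the network at its single longest MST edge.

    Removes the heaviest MST edge (deterministic tie-break by label pair) and
    returns a sample id -> component label ("G1"/"G2"/...) partition; the
    natural two-chemotype readout of a chemical network.
    """
    edges = sorted(net.mst_edges, key=lambda e: (-e[2], e[0], e[1]))
    if not edges:
        return pd.Series(
            {sid: "G1" for t in net.types for sid in t.members}, name="component"
        )
    u, v, _ = edges[0]
    tree = nx.Graph()
    tree.add_nodes_from(t.label for t in net.types)
    tree.add_edges_from((a, b) for a, b, _ in net.mst_edges)
    tree.remove_edge(u, v)
    comps = sorted(nx.connected_components(tree), key=lambda c: sorted(c)[0])
    by_label = {t.label: t for t in net.types}
    out: dict[str, str] = {}
    for i, comp in enumerate(comps):
        for lbl in comp:
            for sid in by_label[lbl].members:
                out[sid] = f"G{i + 1}"
    return pd.Series(out, name="component")
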