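"""Bipartite gene-lipid association networks.

Significant lipid species are mapped to candidate lipid-metabolism genes
through a packaged selector table (exact species, headgroup class, or
LIPID MAPS subclass selectors; each row documents its enzymatic basis).
Generic metabolite aliases (e.g. trade names such as "Carnicor") are
filtered before graph construction. The resulting graph is strictly
bipartite (edges run gene-lipid only); node prominence is summarised by
degree centrality (degree / (n - 1)) and a node-size score min-max scaled
to [1, 10]. Stress-minimising (Kamada-Kawai) coordinates are exported for
plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .nomenclature import LipidStructure, parse_lipid_name

__all__ = [
    "GeneLipidRule",
    "GeneLipidTable",
    "TableValidationError",
    "BipartiteViolationError",
    "default_blocklist",
    "map_lipids_to_genes",
    "filter_generic_nodes",
    "build_graph",
    "layout_coordinates",
    "node_table",
]

_SELECTOR_TYPES = frozenset({"species", "class", "subclass"})


class TableValidationError(ValueError):
    """Raised when a gene-lipid association table is malformed."""


class BipartiteViolationError(ValueError):
    """Raised when an edge would connect nodes of the same partition."""


@dataclass(frozen=True)
class GeneLipidRule:
    gene: str
    selector_type: str  # species | class | subclass
    selector_value: str
    provenance: str = ""

    def matches(self, lipid: LipidStructure) -> bool:
        if self.selector_type == "species":
            return self.selector_value in (lipid.canonical_name, lipid.raw_name)
        if self.selector_type == "class":
            return lipid.lipid_class == self.selector_value
        return lipid.subclass_code == self.selector_value


@dataclass
class GeneLipidTable:
    rules: list[GeneLipidRule]

    def __post_init__(self) -> None:
        problems = []
        for i, rule in enumerate(self.rules):
            if rule.selector_type not in _SELECTOR_TYPES:
                problems.append(
                    f"row {i}: selector_type {rule.selector_type!r} not in "
                    f"{sorted(_SELECTOR_TYPES)}"
                )
            if not rule.gene or rule.gene != rule.gene.upper():
                problems.append(f"row {i}: gene symbol {rule.gene!r} must be uppercase")
            if not rule.selector_value:
                problems.append(f"row {i}: empty selector value")
        if problems:
            raise TableValidationError("; ".join(problems))

    @property
    def genes(self) -> list[str]:
        return sorted({r.gene for r in self.rules})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneLipidTable":
        rules = [
            GeneLipidRule(
                gene=str(row["gene"]),
                selector_type=str(row["selector_type"]),
                selector_value=str(row["selector_value"]),
                provenance=str(row.get("provenance", "")),
            )
            for _, row in frame.iterrows()
        ]
        return cls(rules=rules)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneLipidTable":
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return cls.from_frame(frame)

    @classmethod
    def default(cls) -> "GeneLipidTable":
        path = resources.files("lipidlens.data").joinpath("gene_lipid_map.tsv")
        with resources.as_file(path) as p:
            return cls.from_tsv(p)


def default_blocklist() -> list[str]:
    path = resources.files("lipidlens.data").joinpath("generic_nodes.txt")
    with resources.as_file(path) as p:
        lines = Path(p).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def map_lipids_to_genes(
    lipids: Sequence[LipidStructure | str], table: GeneLipidTable | None = None
) -> list[tuple[str, str]]:
    """Resolve the selector table against a lipid list into gene-species edges.

    Accepts parsed structures or shorthand names. Edges use the species'
    raw name; duplicate matches collapse. Output is sorted for determinism.
    """
    if table is None:
        table = GeneLipidTable.default()
    parsed = [
        lipid if isinstance(lipid, LipidStructure) else parse_lipid_name(lipid)
        for lipid in lipids
    ]
    edges = {
        (rule.gene, lipid.raw_name)
        for rule in table.rules
        for lipid in parsed
        if rule.matches(lipid)
    }
    return sorted(edges)


def filter_generic_nodes(
    edges: Iterable[tuple[str, str]], blocklist: Iterable[str] | None = None
) -> list[tuple[str, str]]:
    """Drop every edge incident to a blocked (uninformative generic) label."""
    blocked = set(default_blocklist() if blocklist is None else blocklist)
    return [e for e in edges if e[0] not in blocked and e[1] not in blocked]


def build_graph(edges: Iterable[tuple[str, str]]) -> nx.Graph:
    """Bipartite graph from gene-lipid edges with centrality-based node sizes.

    Node attributes: ``partition`` ("gene"/"lipid"), ``degree``,
    ``centrality`` (degree / (n - 1)) and ``size`` (centrality min-max
    scaled to [1, 10]; all nodes get the midpoint 5.5 when degrees are
    uniform). Isolated nodes cannot arise: every node comes in on an edge.
    """
    edges = list(edges)
    genes = {g for g, _ in edges}
    lipids = {l for _, l in edges}
    overlap = genes & lipids
    if overlap:
        raise BipartiteViolationError(
            f"labels appear in both partitions (self-loop or same-partition "
            f"edge): {sorted(overlap)}"
        )
    g = nx.Graph()
    g.add_nodes_from(sorted(genes), partition="gene")
    g.add_nodes_from(sorted(lipids), partition="lipid")
    g.add_edges_from(edges)
    centrality = nx.degree_centrality(g) if g.number_of_nodes() > 1 else {
        n: 0.0 for n in g.nodes
    }
    values = list(centrality.values())
    lo, hi = (min(values), max(values)) if values else (0.0, 0.0)
    for node in g.nodes:
        c = centrality[node]
        size = 5.5 if hi == lo else 1.0 + 9.0 * (c - lo) / (hi - lo)
        g.nodes[node]["degree"] = g.degree[node]
        g.nodes[node]["centrality"] = c
        g.nodes[node]["size"] = size
    return g


def layout_coordinates(
    g: nx.Graph, seed: int = 0, min_separation: float = 1e-6
) -> dict[str, tuple[float, float]]:
    """Deterministic 2D stress-minimising coordinates per node.

    Kamada-Kawai is deterministic for a given graph; ``seed`` only drives
    the tiny jitter used to resolve coincident points (enforcing
    ``min_separation`` between distinct nodes).
    """
    if g.number_of_nodes() == 0:
        return {}
    if g.number_of_nodes() == 1:
        return {next(iter(g.nodes)): (0.0, 0.0)}
    pos = nx.kamada_kawai_layout(g)
    import numpy as np

    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    coords = {n: np.asarray(pos[n], dtype=float) for n in nodes}
    for _ in range(100):
        moved = False
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                if np.linalg.norm(coords[a] - coords[b]) < min_separation:
                    coords[b] = coords[b] + rng.uniform(
                        min_separation, 2 * min_separation, size=2
                    )
                    moved = True
        if not moved:
            break
    return {n: (float(c[0]), float(c[1])) for n, c in coords.items()}


def node_table(g: nx.Graph, coords: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Node attribute table (partition, degree, centrality, size, x, y)."""
    rows = []
    for node in sorted(g.nodes):
        row = {
            "node": node,
            "partition": g.nodes[node]["partition"],
            "degree": g.nodes[node]["degree"],
            "centrality": g.nodes[node]["centrality"],
            "size": g.nodes[node]["size"],
        }
        if coords is not None:
            row["x"], row["y"] = coords[node]
        rows.append(row)
    return pd.DataFrame.from_records(rows)
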