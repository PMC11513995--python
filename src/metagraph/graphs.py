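"""Per-sample taxon-function graphs.

Each metagenome sample becomes one undirected weighted graph: species nodes
link to KEGG-orthologue (K-number) nodes with the number of read pairs
supporting both annotations as the edge weight, and the sample's habitat node
links to each long-term environment feature node with the feature's value as
the weight.  Node features are two bits: ``is_function`` (K-number vs
anything else) and ``central_carbon`` (K-number in the central carbon
metabolism pathway).  The graph label is the sample's SOC in g kg^-1.

Three scales are supported: *large* (all species), *mid* (species sharing a
genus with an allow-listed species) and *small* (allow-listed species only).
Graphs serialise to one ``source,target,weight`` CSV edge list per sample.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import is_k_number

__all__ = [
    "EdgeRecord",
    "GraphScale",
    "SampleGraph",
    "build_edge_list",
    "assemble_graph",
    "build_sample_graphs",
    "write_edge_list",
    "read_edge_list",
    "genus_of",
    "read_central_carbon_set",
]


class EdgeRecord(NamedTuple):
    source: str  # species name, or habitat label for environment edges
    target: str  # K-number, or environment feature name
    weight: float


@dataclass(frozen=True)
class GraphScale:
    """Species filter applied before graph construction.

    ``large``: no filter.  ``mid``: keep species whose genus appears in the
    allow list (genus expansion).  ``small``: keep exactly the allow-listed
    species.  Functions with no surviving incident species edge drop out with
    their species.
    """

    name: str
    species_allow_list: frozenset[str] | None = None
    genus_mode: bool = False

    def __post_init__(self) -> None:
        if self.name not in ("large", "mid", "small"):
            raise ValueError(f"scale name must be large/mid/small, got {self.name!r}")
        if self.name == "large" and (self.species_allow_list or self.genus_mode):
            raise ValueError("large scale takes no species filter")
        if self.name == "small" and (not self.species_allow_list or self.genus_mode):
            raise ValueError("small scale requires an allow list and genus_mode=False")
        if self.name == "mid" and (not self.species_allow_list or not self.genus_mode):
            raise ValueError("mid scale requires an allow list and genus_mode=True")

    @classmethod
    def large(cls) -> "GraphScale":
        return cls("large")

    @classmethod
    def mid(cls, allow_list: Iterable[str]) -> "GraphScale":
        return cls("mid", frozenset(allow_list), genus_mode=True)

    @classmethod
    def small(cls, allow_list: Iterable[str]) -> "GraphScale":
        return cls("small", frozenset(allow_list), genus_mode=False)

    def keeps(self, species: str) -> bool:
        if self.name == "large":
            return True
        if self.name == "small":
            return species in self.species_allow_list
        allowed_genera = {genus_of(s) for s in self.species_allow_list}
        return genus_of(species) in allowed_genera


def genus_of(species: str) -> str:
    """First whitespace token of a binomial name, skipping 'Candidatus'."""
    tokens = species.split()
    if not tokens:
        return species
    if tokens[0] == "Candidatus" and len(tokens) > 1:
        return tokens[1]
    return tokens[0]


@dataclass
class SampleGraph:
    """One sample's undirected weighted graph with 2-bit node features."""

    sample_id: str
    node_names: list[str]
    node_features: np.ndarray  # (n, 2) ints: [is_function, central_carbon]
    edges: np.ndarray  # (E, 2) int node indices, undirected, each pair once
    weights: np.ndarray  # (E,) float
    label: float  # SOC, g kg^-1

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=np.int64)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        n = len(self.node_names)
        if self.node_features.shape != (n, 2):
            raise ValueError("node feature matrix must be (n_nodes, 2)")
        if len(self.edges) != len(self.weights):
            raise ValueError("edges and weights length mismatch")
        if len(self.edges) and (self.edges.min() < 0 or self.edges.max() >= n):
            raise ValueError("edge endpoint refers to an undeclared node")
        if len(self.edges) and (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValueError("self-loops are not allowed")
        keys = {tuple(sorted(e)) for e in self.edges.tolist()}
        if len(keys) != len(self.edges):
            raise ValueError("duplicate undirected edges")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_weight(self, source: str, target: str) -> float | None:
        idx = self.find_edge(source, target)
        return None if idx is None else float(self.weights[idx])

    def find_edge(self, source: str, target: str) -> int | None:
        try:
            i = self.node_names.index(source)
            j = self.node_names.index(target)
        except ValueError:
            return None
        for k, (a, b) in enumerate(self.edges.tolist()):
            if (a, b) == (i, j) or (a, b) == (j, i):
                return k
        return None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(sample_id=self.sample_id, soc=self.label)
        for name, (isf, cc) in zip(self.node_names, self.node_features.tolist()):
            g.add_node(name, is_function=isf, central_carbon=cc)
        for (i, j), w in zip(self.edges.tolist(), self.weights.tolist()):
            g.add_edge(self.node_names[i], self.node_names[j], weight=w)
        return g


def build_edge_list(
    pair_counts: pd.DataFrame,
    metadata_row: pd.Series,
    env_features: Iterable[str],
    scale: GraphScale,
) -> list[EdgeRecord]:
    """Edge records for one sample.

    ``pair_counts`` holds this sample's rows of the (species, function, count)
    table; zero-count pairs emit no edge.  One extra record per environment
    feature links the sample's habitat label to the feature name with the
    feature's value as weight.
    """
    records: list[EdgeRecord] = []
    for row in pair_counts.itertuples(index=False):
        if row.count <= 0:
            continue
        if not scale.keeps(row.species):
            continue
        records.append(EdgeRecord(str(row.species), str(row.function), float(row.count)))
    habitat = str(metadata_row["habitat"])
    for feat in env_features:
        if feat not in metadata_row or pd.isna(metadata_row[feat]):
            sid = metadata_row.name if metadata_row.name is not None else "<unknown>"
            raise ValueError(f"sample {sid}: missing environment feature {feat!r}")
        records.append(EdgeRecord(habitat, str(feat), float(metadata_row[feat])))
    return records


def assemble_graph(
    records: Iterable[EdgeRecord],
    central_carbon_set: set[str],
    soc: float,
    sample_id: str = "",
) -> SampleGraph:
    """Union the edge records into a :class:`SampleGraph`.

    Node features: K-numbers get ``is_function=1`` and ``central_carbon=1``
    iff listed in *central_carbon_set*; species, habitat and environment
    nodes get ``(0, 0)``.  A duplicate undirected edge with conflicting
    weights signals an upstream bug and raises.
    """
    records = list(records)
    names = sorted({r.source for r in records} | {r.target for r in records})
    index = {n: i for i, n in enumerate(names)}
    feats = np.zeros((len(names), 2), dtype=np.int64)
    for n, i in index.items():
        if is_k_number(n):
            feats[i, 0] = 1
            if n in central_carbon_set:
                feats[i, 1] = 1
    seen: dict[tuple[int, int], float] = {}
    for r in records:
        if r.source == r.target:
            raise ValueError(f"self-loop on node {r.source!r}")
        key = tuple(sorted((index[r.source], index[r.target])))
        if key in seen:
            if seen[key] != r.weight:
                raise ValueError(
                    f"conflicting weights for undirected edge {r.source!r}-{r.target!r}: "
                    f"{seen[key]} vs {r.weight}"
                )
            continue
        seen[key] = r.weight
    edges = np.array(sorted(seen), dtype=np.int64).reshape(-1, 2)
    weights = np.array([seen[tuple(e)] for e in edges.tolist()], dtype=np.float64)
    return SampleGraph(
        sample_id=sample_id,
        node_names=names,
        node_features=feats,
        edges=edges,
        weights=weights,
        label=float(soc),
    )


def build_sample_graphs(
    pair_counts: pd.DataFrame,
    metadata: pd.DataFrame,
    scale: GraphScale,
    central_carbon_set: set[str] | None = None,
    env_features: Iterable[str] = ("temp_long", "soilwater_0_7_long"),
    soc_column: str = "soc",
) -> list[SampleGraph]:
    """One graph per metadata row, in metadata order."""
    central = central_carbon_set or set()
    env_features = list(env_features)
    grouped = dict(tuple(pair_counts.groupby("sample_id", sort=False)))
    empty = pair_counts.iloc[0:0]
    graphs = []
    for sid, row in metadata.iterrows():
        sub = grouped.get(sid, empty)
        recs = build_edge_list(sub, row, env_features, scale)
        graphs.append(assemble_graph(recs, central, float(row[soc_column]), sample_id=str(sid)))
    return graphs


def write_edge_list(records: Iterable[EdgeRecord], path: str | Path) -> None:
    """Serialise to headerless ``source,target,weight`` CSV lines."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for r in records:
            w = r.weight
            writer.writerow([r.source, r.target, int(w) if float(w).is_integer() else w])


def read_edge_list(path: str | Path) -> list[EdgeRecord]:
    """Parse a ``source,target,weight`` CSV file; malformed lines raise."""
    records = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            try:
                weight = float(row[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: weight {row[2]!r} is not a number") from exc
            records.append(EdgeRecord(row[0], row[1], weight))
    return records


def read_central_carbon_set(path: str | Path) -> set[str]:
    """One K-number per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not is_k_number(line):
            raise ValueError(f"not a K-number: {line!r}")
        out.add(line)
    return out
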