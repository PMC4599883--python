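"""Reading, validating, writing and slicing anatomical networks.

An anatomical network is an undirected, simple, unweighted graph whose nodes
are anatomical parts (bones/cartilages or muscles) and whose edges are
physical contacts (articulations, muscle fusions, bone–muscle attachments).
On disk it is a square CSV adjacency matrix with a header row and first-column
labels, plus an optional YAML sidecar carrying per-node class/region tags and
network-level metadata.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

BONE = "bone_cartilage"
MUSCLE = "muscle"
NODE_CLASSES = (BONE, MUSCLE)
SYSTEMS = ("skeletal", "muscular", "musculoskeletal")
REGIONS = ("proximal", "distal")


class NetworkValidationError(ValueError):
    """Base class for all adjacency/metadata validation failures."""


class NonSquareMatrixError(NetworkValidationError):
    pass


class AsymmetricMatrixError(NetworkValidationError):
    pass


class NonBinaryEntryError(NetworkValidationError):
    pass


class NonzeroDiagonalError(NetworkValidationError):
    pass


class DuplicateLabelError(NetworkValidationError):
    pass


class LabelMismatchError(NetworkValidationError):
    """Row and column labels disagree, or a mapped label is unknown."""


class UnknownSystemError(NetworkValidationError):
    pass


class UncoveredNodeError(NetworkValidationError):
    """A region map or node-class table does not cover every node."""


@dataclasses.dataclass
class AnatomicalNetwork:
    """A labelled, validated anatomical contact network.

    Parameters
    ----------
    labels
        Ordered unique node identifiers.
    adjacency
        Symmetric binary N x N matrix with zero diagonal.
    node_class
        label -> ``bone_cartilage`` or ``muscle`` for every node.
    region
        Optional label -> ``proximal``/``distal`` tags (may be partial or
        empty; region-aware operations require full coverage).
    meta
        Free-form network-level metadata (limb, side, condition, system...).
    """

    labels: list[str]
    adjacency: np.ndarray
    node_class: dict[str, str]
    region: dict[str, str] = dataclasses.field(default_factory=dict)
    meta: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = [str(l).strip() for l in self.labels]
        self.adjacency = np.asarray(self.adjacency)
        self.node_class = {str(k).strip(): v for k, v in self.node_class.items()}
        self.region = {str(k).strip(): v for k, v in self.region.items()}
        validate_adjacency(self.adjacency, self.labels)
        self.adjacency = self.adjacency.astype(np.int8)
        missing = [l for l in self.labels if l not in self.node_class]
        if missing:
            raise UncoveredNodeError(
                f"node_class missing for {len(missing)} node(s), e.g. {missing[0]!r}"
            )
        bad = {v for v in self.node_class.values()} - set(NODE_CLASSES)
        if bad:
            raise NetworkValidationError(f"unknown node class(es): {sorted(bad)}")
        bad_r = set(self.region.values()) - set(REGIONS)
        if bad_r:
            raise NetworkValidationError(f"unknown region tag(s): {sorted(bad_r)}")

    # -- basic quantities -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for l in self.labels:
            g.add_node(l, node_class=self.node_class[l])
            if l in self.region:
                g.nodes[l]["region"] = self.region[l]
        rows, cols = np.nonzero(np.triu(self.adjacency))
        g.add_edges_from((self.labels[i], self.labels[j]) for i, j in zip(rows, cols))
        return g

    def induced_subgraph(self, keep: Iterable[str]) -> "AnatomicalNetwork":
        keep = [str(l).strip() for l in keep]
        unknown = [l for l in keep if l not in self.labels]
        if unknown:
            raise LabelMismatchError(f"unknown label(s): {unknown[:3]}")
        idx = [self.index_of(l) for l in keep]
        sub = self.adjacency[np.ix_(idx, idx)]
        return AnatomicalNetwork(
            labels=keep,
            adjacency=sub,
            node_class={l: self.node_class[l] for l in keep},
            region={l: self.region[l] for l in keep if l in self.region},
            meta=dict(self.meta),
        )


def validate_adjacency(adj: np.ndarray, labels: list[str]) -> None:
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise NonSquareMatrixError(f"adjacency has shape {adj.shape}, expected square")
    if len(labels) != adj.shape[0]:
        raise LabelMismatchError(
            f"{len(labels)} labels for a {adj.shape[0]}x{adj.shape[1]} matrix"
        )
    if len(set(labels)) != len(labels):
        seen, dups = set(), []
        for l in labels:
            if l in seen:
                dups.append(l)
            seen.add(l)
        raise DuplicateLabelError(f"duplicate label(s): {sorted(set(dups))}")
    vals = np.unique(adj)
    if not np.isin(vals, (0, 1)).all():
        raise NonBinaryEntryError(f"entries outside {{0,1}}: {vals[~np.isin(vals, (0, 1))][:5]}")
    if np.any(np.diag(adj) != 0):
        bad = [labels[i] for i in np.nonzero(np.diag(adj))[0][:3]]
        raise NonzeroDiagonalError(f"self-contact on diagonal at {bad}")
    if not np.array_equal(adj, adj.T):
        i, j = map(int, np.argwhere(adj != adj.T)[0])
        raise AsymmetricMatrixError(
            f"A[{labels[i]!r},{labels[j]!r}]={adj[i, j]} but A[{labels[j]!r},{labels[i]!r}]={adj[j, i]}"
        )


# -- CSV + sidecar dialect --------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def read_adjacency_csv(
    path: str | Path,
    metadata: str | Path | None = None,
    node_class: Mapping[str, str] | None = None,
) -> AnatomicalNetwork:
    """Read a square 0/1 adjacency CSV (header row, first-column labels).

    Node classes come from, in order of precedence: the ``node_class``
    mapping argument, the explicit ``metadata`` sidecar, or the default
    sidecar ``<path>.meta.yaml``. Asymmetry is an error, never silently
    symmetrized.
    """
    path = Path(path)
    # pandas mangles duplicate column names, so take the header verbatim
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    col_labels = [str(l).strip() for l in header[1:]]
    if len(set(col_labels)) != len(col_labels):
        dups = sorted({l for l in col_labels if col_labels.count(l) > 1})
        raise DuplicateLabelError(f"duplicate label(s): {dups}")
    df = pd.read_csv(path, index_col=0)
    row_labels = [str(l).strip() for l in df.index]
    if row_labels != col_labels:
        if sorted(row_labels) != sorted(col_labels):
            raise LabelMismatchError("row and column label sets differ")
        raise LabelMismatchError("row and column labels are ordered differently")
    adj = df.to_numpy()
    if not np.issubdtype(adj.dtype, np.number):
        raise NonBinaryEntryError("non-numeric entry in adjacency table")

    meta: dict = {}
    classes: dict[str, str] = {}
    regions: dict[str, str] = {}
    sidecar = Path(metadata) if metadata is not None else _sidecar_path(path)
    if sidecar.exists():
        payload = yaml.safe_load(sidecar.read_text()) or {}
        meta = dict(payload.get("meta", {}))
        classes = {str(k).strip(): v for k, v in (payload.get("node_class") or {}).items()}
        regions = {str(k).strip(): v for k, v in (payload.get("region") or {}).items()}
    if node_class is not None:
        classes = {str(k).strip(): v for k, v in node_class.items()}
    if not classes:
        raise UncoveredNodeError(
            f"no node classes: provide a sidecar ({sidecar.name}) or node_class mapping"
        )
    return AnatomicalNetwork(row_labels, adj, classes, regions, meta)


def write_adjacency_csv(net: AnatomicalNetwork, path: str | Path) -> Path:
    """Write the adjacency CSV plus its ``.meta.yaml`` sidecar.

    ``read_adjacency_csv(write_adjacency_csv(net))`` reproduces labels,
    adjacency, node classes and regions exactly; repeated writes are
    byte-identical.
    """
    path = Path(path)
    df = pd.DataFrame(net.adjacency.astype(int), index=net.labels, columns=net.labels)
    df.to_csv(path)
    payload = {
        "meta": {k: net.meta[k] for k in sorted(net.meta)},
        "node_class": {l: net.node_class[l] for l in net.labels},
        "region": {l: net.region[l] for l in net.labels if l in net.region},
    }
    _sidecar_path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def extract_subsystem(net: AnatomicalNetwork, system: str) -> AnatomicalNetwork:
    """Induced subgraph on bones (skeletal), muscles (muscular), or all nodes."""
    if system not in SYSTEMS:
        raise UnknownSystemError(f"unknown system {system!r}, expected one of {SYSTEMS}")
    if system == "musculoskeletal":
        out = net.induced_subgraph(net.labels)
    else:
        want = BONE if system == "skeletal" else MUSCLE
        out = net.induced_subgraph([l for l in net.labels if net.node_class[l] == want])
    out.meta["system"] = system
    return out


def split_by_region(
    net: AnatomicalNetwork, regions: Mapping[str, str] | None = None
) -> tuple[AnatomicalNetwork, AnatomicalNetwork]:
    """Split into (proximal, distal) induced subgraphs.

    ``regions`` defaults to the network's own region tags; it must cover
    every node.
    """
    rmap = dict(net.region) if regions is None else {str(k).strip(): v for k, v in regions.items()}
    missing = [l for l in net.labels if l not in rmap]
    if missing:
        raise UncoveredNodeError(f"region map misses {len(missing)} node(s), e.g. {missing[0]!r}")
    unknown = set(rmap.values()) - set(REGIONS)
    if unknown:
        raise NetworkValidationError(f"unknown region tag(s): {sorted(unknown)}")
    prox = net.induced_subgraph([l for l in net.labels if rmap[l] == "proximal"])
    dist = net.induced_subgraph([l for l in net.labels if rmap[l] == "distal"])
    return prox, dist


def write_graphml(net: AnatomicalNetwork, path: str | Path) -> Path:
    """Export to GraphML with node_class/region as node attributes."""
    path = Path(path)
    nx.write_graphml(net.to_networkx(), path)
    return path
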