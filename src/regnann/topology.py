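"""Ground-truth network topologies as symmetric binary adjacency matrices.

Regulatory networks are modelled here as undirected, unweighted graphs: a
link between two genes records that their expression levels interact, with
no direction or strength attached.  Two random-graph families are provided
— preferential attachment (Barabási–Albert, scale-free degree distribution)
and Erdős–Rényi G(n, p) parameterised by its mean degree — together with
structural statistics and a plain-text TSV interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class AdjacencyFormatError(ValueError):
    """Raised when an adjacency file violates the format contract."""


@dataclass
class AdjacencyMatrix:
    """Symmetric binary adjacency matrix with a zero diagonal.

    Parameters
    ----------
    entries
        Square ``(n, n)`` array of 0/1 values.  Must be symmetric with a
        zero diagonal: graphs are undirected and self-regulation is
        excluded by construction.
    node_labels
        Optional node identifiers, length ``n``.  Generated on demand
        (``G0``, ``G1``, ...) when written to disk.
    """

    entries: np.ndarray
    node_labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        a = np.asarray(self.entries)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency matrix must be square, got shape {a.shape}")
        if a.shape[0] < 1:
            raise ValueError("adjacency matrix must have at least one node")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8)
        if (np.diag(a) != 0).any():
            raise ValueError("adjacency diagonal must be zero (no self-loops)")
        if (a != a.T).any():
            raise ValueError("adjacency matrix must be symmetric")
        self.entries = a
        if self.node_labels is not None:
            self.node_labels = [str(x) for x in self.node_labels]
            if len(self.node_labels) != a.shape[0]:
                raise ValueError("node_labels length must equal n_nodes")

    @property
    def n_nodes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_links(self) -> int:
        """Number of undirected links (symmetric pairs counted once)."""
        return int(self.entries.sum()) // 2

    def labels(self) -> list[str]:
        if self.node_labels is not None:
            return list(self.node_labels)
        return [f"G{i}" for i in range(self.n_nodes)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AdjacencyMatrix):
            return NotImplemented
        return (
            self.entries.shape == other.entries.shape
            and (self.entries == other.entries).all()
            and self.labels() == other.labels()
        )


def generate_barabasi(
    n_nodes: int,
    power: float = 1.0,
    edges_per_step: int = 1,
    seed: int = 0,
) -> AdjacencyMatrix:
    """Sample a preferential-attachment (Barabási–Albert) graph.

    The graph grows one node at a time.  Each new node attaches to
    ``edges_per_step`` distinct existing nodes, chosen with probability
    proportional to ``(degree + 1) ** power``.  The +1 smoothing keeps
    degree-zero nodes reachable and makes ``power`` act like the
    power-law exponent knob of igraph's generator: ``power = 0`` is
    uniform attachment, larger values concentrate links on hubs.

    With ``edges_per_step = 1`` the result is a random tree with exactly
    ``n_nodes - 1`` links.

    Parameters
    ----------
    n_nodes
        Number of nodes, at least 2.
    power
        Preferential-attachment exponent, >= 0.
    edges_per_step
        Links added by each arriving node (capped by the number of nodes
        already present), >= 1.
    seed
        Seed for the random number generator.
    """
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    if power < 0:
        raise ValueError(f"power must be >= 0, got {power}")
    if edges_per_step < 1:
        raise ValueError(f"edges_per_step must be >= 1, got {edges_per_step}")

    rng = np.random.default_rng(seed)
    a = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    degree = np.zeros(n_nodes, dtype=np.int64)
    for new in range(1, n_nodes):
        weights = (degree[:new] + 1.0) ** power
        k = min(edges_per_step, new)
        targets = rng.choice(new, size=k, replace=False, p=weights / weights.sum())
        for t in targets:
            a[new, t] = a[t, new] = 1
        degree[targets] += 1
        degree[new] += k
    return AdjacencyMatrix(a)


def generate_erdos_renyi(n_nodes: int, mean_degree: float, seed: int = 0) -> AdjacencyMatrix:
    """Sample an Erdős–Rényi G(n, p) graph with a requested mean degree.

    The link probability is ``p = mean_degree / (n_nodes - 1)`` so the
    expected degree of every node equals ``mean_degree``.  Disconnected
    samples are kept as drawn.

    Parameters
    ----------
    n_nodes
        Number of nodes, at least 2.
    mean_degree
        Requested expected degree, in ``(0, n_nodes - 1]``.
    seed
        Seed for the random number generator.
    """
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    if not 0 < mean_degree <= n_nodes - 1:
        raise ValueError(
            f"mean_degree must be in (0, n_nodes - 1], got {mean_degree} for n={n_nodes}"
        )
    p = mean_degree / (n_nodes - 1)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_nodes, k=1)
    links = rng.random(iu[0].size) < p
    a = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    a[iu] = links
    a += a.T
    return AdjacencyMatrix(a)


def density(adj: AdjacencyMatrix) -> float:
    """Link density L / N**2, links counted once per unordered pair."""
    return adj.n_links / adj.n_nodes**2


def write_adjacency(adj: AdjacencyMatrix, path: str | Path) -> None:
    """Write a labelled square adjacency TSV (first row/column = labels)."""
    labels = adj.labels()
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, adj.entries):
            fh.write(lab + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_adjacency(path: str | Path) -> AdjacencyMatrix:
    """Read a labelled square adjacency TSV written by :func:`write_adjacency`.

    Raises :class:`AdjacencyFormatError` naming the offending cell when the
    file is non-square, non-binary or asymmetric.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise AdjacencyFormatError(f"{path}: empty adjacency file")
    header = lines[0].split("\t")
    labels = header[1:] if header[0] == "" else header
    n = len(labels)
    if len(lines) - 1 != n:
        raise AdjacencyFormatError(
            f"{path}: {n} columns but {len(lines) - 1} data rows (matrix must be square)"
        )
    a = np.zeros((n, n), dtype=np.int8)
    for i, ln in enumerate(lines[1:]):
        cells = ln.split("\t")
        if len(cells) != n + 1:
            raise AdjacencyFormatError(
                f"{path}: row {i} ({cells[0]!r}) has {len(cells) - 1} cells, expected {n}"
            )
        for j, cell in enumerate(cells[1:]):
            if cell not in ("0", "1"):
                raise AdjacencyFormatError(
                    f"{path}: cell ({labels[i]}, {labels[j]}) is {cell!r}, must be 0 or 1"
                )
            a[i, j] = int(cell)
    bad = np.argwhere(a != a.T)
    if bad.size:
        i, j = bad[0]
        raise AdjacencyFormatError(
            f"{path}: asymmetric entries at ({labels[i]}, {labels[j]})"
        )
    bad_diag = np.flatnonzero(np.diag(a))
    if bad_diag.size:
        i = bad_diag[0]
        raise AdjacencyFormatError(f"{path}: non-zero diagonal at ({labels[i]}, {labels[i]})")
    return AdjacencyMatrix(a, node_labels=labels)


def write_edge_list(adj: AdjacencyMatrix, path: str | Path) -> None:
    """Write an undirected edge list TSV (`source`/`target`), one row per pair."""
    labels = adj.labels()
    iu = np.triu_indices(adj.n_nodes, k=1)
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for i, j in zip(*iu):
            if adj.entries[i, j]:
                fh.write(f"{labels[i]}\t{labels[j]}\n")


def read_edge_list(
    path: str | Path, node_labels: Sequence[str] | None = None
) -> AdjacencyMatrix:
    """Read a `source`/`target` edge list TSV into an adjacency matrix.

    ``node_labels`` fixes the node set and ordering; when omitted, nodes are
    the labels seen in the file, in order of first appearance.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or lines[0].split("\t") != ["source", "target"]:
        raise AdjacencyFormatError(f"{path}: expected header 'source\\ttarget'")
    pairs = []
    seen: dict[str, int] = {}
    if node_labels is not None:
        seen = {str(lab): i for i, lab in enumerate(node_labels)}
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != 2:
            raise AdjacencyFormatError(f"{path}: malformed edge row {ln!r}")
        for c in cells:
            if c not in seen:
                if node_labels is not None:
                    raise AdjacencyFormatError(f"{path}: unknown node label {c!r}")
                seen[c] = len(seen)
        if cells[0] == cells[1]:
            raise AdjacencyFormatError(f"{path}: self-loop on node {cells[0]!r}")
        pairs.append((seen[cells[0]], seen[cells[1]]))
    n = len(seen)
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in pairs:
        a[i, j] = a[j, i] = 1
    labels = [lab for lab, _ in sorted(seen.items(), key=lambda kv: kv[1])]
    return AdjacencyMatrix(a, node_labels=labels)
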