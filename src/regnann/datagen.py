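"""Synthetic expression data: SLC synthesis, toy motifs and normalisation.

The SLC (Simple Linear Correlation) scheme turns a network topology into
steady-state expression profiles: a seed matrix ``S`` of independent
uniform values is propagated one step through the adjacency matrix,

    E = S + S @ adjM,

so the expression of a gene is its own seed plus the seeds of its
neighbours, which makes linked columns linearly correlated and leaves
unlinked columns independent.

Four 4-gene toy motifs (single, cooperative, multiple, indirect
regulation) provide hand-checkable inference exercises, and the two
normalisation schemes used for microarray-style data (linear rescaling to
[-1, 1], z-scoring) plus a sign-of-differences discretisation complete
the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

from .topology import AdjacencyMatrix

logger = logging.getLogger(__name__)

Normalization = Literal["raw", "linear_rescaled", "statistical", "discretized"]

TOY_GENES = ["A", "B", "C", "D"]


@dataclass
class ExpressionMatrix:
    """M x N expression profiles (rows = samples, columns = genes)."""

    values: np.ndarray
    normalization: Normalization = "raw"
    gene_labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"expression matrix must be 2-D, got shape {v.shape}")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("expression matrix must be non-empty")
        self.values = v
        if self.gene_labels is not None:
            self.gene_labels = [str(x) for x in self.gene_labels]
            if len(self.gene_labels) != v.shape[1]:
                raise ValueError("gene_labels length must equal n_genes")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def labels(self) -> list[str]:
        if self.gene_labels is not None:
            return list(self.gene_labels)
        return [f"G{i}" for i in range(self.n_genes)]


@dataclass(frozen=True)
class ToySpec:
    """Configuration of a 4-gene toy regulation motif.

    The numeric settings are deliberately configurable: they control the
    qualitative sharpness of the motif, not a fact about any real system.

    Parameters
    ----------
    motif
        One of ``single``, ``cooperative``, ``multiple``, ``indirect``.
    n_samples
        Number of expression profiles to draw.
    activation_threshold
        Gate level theta: a regulator acts on its target only when the
        magnitude of its (summed) signal exceeds theta.
    noise_amplitude
        Half-width of the uniform additive noise on regulated genes.
    activation_probability
        Probability that the regulator A is active (single motif only).
    seed
        Seed for the random number generator.
    """

    motif: Literal["single", "cooperative", "multiple", "indirect"]
    n_samples: int = 100
    activation_threshold: float = 0.5
    noise_amplitude: float = 0.1
    activation_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        if not 0 <= self.activation_probability <= 1:
            raise ValueError("activation_probability must be in [0, 1]")


def generate_slc(adj: AdjacencyMatrix, n_samples: int, seed: int = 0) -> ExpressionMatrix:
    """Synthesise SLC expression profiles for a given topology.

    Draws an ``(n_samples, n_genes)`` seed matrix ``S`` uniform in
    ``[-1, 1]`` and returns ``E = S + S @ adjM``; the result is ``raw``
    (the caller chooses the normalisation, which is studied as an
    independent experimental factor).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    s = rng.uniform(-1.0, 1.0, size=(n_samples, adj.n_nodes))
    e = s + s @ adj.entries.astype(float)
    return ExpressionMatrix(e, normalization="raw", gene_labels=adj.node_labels)


def _toy_truth(motif: str) -> AdjacencyMatrix:
    links = {
        "single": [(0, 1)],
        "cooperative": [(0, 2), (1, 2)],
        "multiple": [(0, 1), (0, 2)],
        "indirect": [(0, 1), (1, 2)],
    }[motif]
    a = np.zeros((4, 4), dtype=np.int8)
    for i, j in links:
        a[i, j] = a[j, i] = 1
    return AdjacencyMatrix(a, node_labels=list(TOY_GENES))


def generate_toy(spec: ToySpec) -> tuple[ExpressionMatrix, AdjacencyMatrix]:
    """Generate expression profiles and ground truth for a toy motif.

    Motifs over genes A, B, C, D (gate = signal passes only when its
    magnitude exceeds ``activation_threshold``, otherwise the target is
    uniform noise):

    - ``single``: A is inactive (0) with probability ``1 - p`` else
      uniform in (0, 1]; when active, B = A + noise; C and D are pure
      noise.  Truth: A-B.
    - ``cooperative``: A and B carry their seeds; C = s_A + s_B through
      the gate; D isolated.  Truth: A-C, B-C.
    - ``multiple``: B and C are each driven by s_A through the gate; D
      isolated.  Truth: A-B, A-C.
    - ``indirect``: B is driven by s_A through the gate, C by the
      realised B through the gate (chain A -> B -> C); D isolated.
      Truth: A-B, B-C.

    All columns are linearly rescaled to ``[-1, 1]`` before return, which
    is the input convention of the inference engine.
    """
    if spec.motif not in ("single", "cooperative", "multiple", "indirect"):
        raise ValueError(f"unknown motif {spec.motif!r}")
    rng = np.random.default_rng(spec.seed)
    m = spec.n_samples
    theta = spec.activation_threshold
    amp = spec.noise_amplitude

    def gate(signal: np.ndarray) -> np.ndarray:
        """Pass signal where |signal| > theta, else uniform noise."""
        out = rng.uniform(-amp, amp, size=signal.shape)
        on = np.abs(signal) > theta
        out[on] = signal[on]
        return out

    if spec.motif == "single":
        active = rng.random(m) < spec.activation_probability
        a_col = np.where(active, rng.uniform(0.0, 1.0, m), 0.0)
        # active A drives B linearly; inactive leaves B as pure noise
        b_col = np.where(
            active,
            a_col + rng.uniform(-amp, amp, m),
            rng.uniform(0.0, 1.0, m),
        )
        c_col = rng.uniform(0.0, 1.0, m)
        d_col = rng.uniform(0.0, 1.0, m)
        cols = [a_col, b_col, c_col, d_col]
    else:
        seeds = rng.uniform(-1.0, 1.0, size=(m, 4))
        if spec.motif == "cooperative":
            cols = [seeds[:, 0], seeds[:, 1], gate(seeds[:, 0] + seeds[:, 1]), seeds[:, 3]]
        elif spec.motif == "multiple":
            b_col = gate(seeds[:, 0])
            c_col = gate(seeds[:, 0])  # independent gate-noise draw
            cols = [seeds[:, 0], b_col, c_col, seeds[:, 3]]
        else:  # indirect: chain through the realised value of B
            b_col = gate(seeds[:, 0])
            c_col = gate(b_col)
            cols = [seeds[:, 0], b_col, c_col, seeds[:, 3]]

    expr = ExpressionMatrix(
        np.column_stack(cols), normalization="raw", gene_labels=list(TOY_GENES)
    )
    return rescale_linear(expr), _toy_truth(spec.motif)


def rescale_linear(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Affinely map each gene column onto [-1, 1].

    Non-constant columns attain both endpoints exactly; constant columns
    map to zero (the mid-point, read as "no signal" by the tanh probe).
    Idempotent.
    """
    v = expr.values
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    span = hi - lo
    out = np.zeros_like(v)
    nc = span > 0
    out[:, nc] = 2.0 * (v[:, nc] - lo[nc]) / span[nc] - 1.0
    return replace(expr, values=out, normalization="linear_rescaled")


def normalize_statistical(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene column (mean 0, population SD 1).

    Constant columns cannot be scaled and become all zeros, with a
    logged warning.
    """
    v = expr.values
    mu = v.mean(axis=0)
    sd = v.std(axis=0)  # population (1/M) convention
    out = np.zeros_like(v)
    nc = sd > 0
    if (~nc).any():
        logger.warning(
            "statistical normalization: %d constant column(s) set to zero",
            int((~nc).sum()),
        )
    out[:, nc] = (v[:, nc] - mu[nc]) / sd[nc]
    return replace(expr, values=out, normalization="statistical")


def discretize_signs(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Discretise to the sign of successive differences.

    Output row ``t`` is ``sign(E[t+1] - E[t])`` elementwise with values in
    {-1, 0, +1}; the result has one row fewer than the input.
    """
    if expr.n_samples < 2:
        raise ValueError("discretization needs at least 2 samples")
    d = np.sign(np.diff(expr.values, axis=0))
    return replace(expr, values=d, normalization="discretized")


NORMALIZERS = {
    "raw": lambda e: e,
    "linear_rescaled": rescale_linear,
    "statistical": normalize_statistical,
    "discretized": discretize_signs,
}


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression TSV: comment line with the normalization state,
    a header of gene labels, one row per sample."""
    with open(path, "w") as fh:
        fh.write(f"# normalization={expr.normalization}\n")
        fh.write("\t".join(expr.labels()) + "\n")
        for row in expr.values:
            fh.write("\t".join(format(x, ".17g") for x in row) + "\n")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV written by :func:`write_expression`.

    A missing normalization comment is accepted and read as ``raw``.
    """
    normalization: Normalization = "raw"
    rows: list[list[float]] = []
    labels: list[str] | None = None
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            if ln.startswith("#"):
                key, _, val = ln.lstrip("# ").partition("=")
                if key.strip() == "normalization":
                    val = val.strip()
                    if val not in NORMALIZERS:
                        raise ValueError(f"{path}: unknown normalization {val!r}")
                    normalization = val  # type: ignore[assignment]
                continue
            if labels is None:
                labels = ln.split("\t")
            else:
                rows.append([float(x) for x in ln.split("\t")])
    if labels is None or not rows:
        raise ValueError(f"{path}: no expression data found")
    return ExpressionMatrix(
        np.array(rows, dtype=float), normalization=normalization, gene_labels=labels
    )
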