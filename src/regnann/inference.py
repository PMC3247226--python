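"""Per-gene MLP ensemble inference of gene regulatory networks.

One multilayer perceptron is trained per gene: a single input neuron
(the expression of that gene), one tanh hidden layer of
``ceil(sqrt(N - 1))`` units, and ``N - 1`` tanh output neurons (the
expression of every other gene).  Cycling through the rows of the
expression matrix, each network learns to regress the whole neighbourhood
of its gene from that gene alone.  With input ``x``, hidden weights
``w_in`` and output weights ``w_out`` the output for gene ``j`` is

    y_j = tanh( sum_h w_out[h, j] * tanh(w_in[h] * x) ).

Training is classical online back-propagation with momentum on half the
sum of squared output errors:

    dW(t) = -eta * grad_E + alpha * dW(t-1),

patterns presented in a freshly shuffled order each epoch.  After
training, each network is *probed* with the maximal normalised input
(1.0, "the gene maximally expressed"); its outputs are read as inferred
correlations in [-1, 1] between the probed gene and every other gene
(+1 perfect correlation, -1 perfect anti-correlation, 0 none).  Joining
the N probe vectors, with zeros on the diagonal, gives the correlation
matrix, which is thresholded into a predicted adjacency matrix.

Each gene's network trains independently: seeds are derived per gene, so
the result never depends on the order in which the ensemble is trained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .datagen import ExpressionMatrix
from .topology import AdjacencyMatrix

logger = logging.getLogger(__name__)


class TrainingDivergedError(FloatingPointError):
    """Raised when back-propagation produces non-finite weights."""


@dataclass(frozen=True)
class LearningParams:
    """Back-propagation hyper-parameters.

    Defaults sit on the plateau of the learning-parameter sweep harness
    (see :mod:`regnann.experiments`): small learning rate, substantial
    momentum, enough epochs for the small networks involved.

    Parameters
    ----------
    learning_rate
        Gradient step size eta, > 0.
    momentum
        Fraction alpha of the previous update carried over, in [0, 1).
    epochs
        Full passes over the training patterns, >= 1.
    hidden_override
        Fix the hidden-layer size instead of the default
        ``ceil(sqrt(n_outputs))`` rule of thumb.
    init_scale
        Weights initialised uniform in ``[-init_scale, init_scale]``.
    seed
        Base seed; each gene trains from seed ``seed + gene_index``.
    """

    learning_rate: float = 0.01
    momentum: float = 0.8
    epochs: int = 200
    hidden_override: int | None = None
    init_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.hidden_override is not None and self.hidden_override < 1:
            raise ValueError("hidden_override must be >= 1")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be > 0")


def hidden_size(n_outputs: int, override: int | None = None) -> int:
    """Hidden-layer size: ceil(sqrt(1 * n_outputs)) unless overridden."""
    if override is not None:
        return override
    return math.ceil(math.sqrt(n_outputs))


@dataclass
class GeneRegressor:
    """One trained per-gene MLP: 1 input, H hidden, N-1 tanh outputs."""

    target_gene: int
    w_in: np.ndarray  # (H,) input -> hidden weights
    w_out: np.ndarray  # (H, N-1) hidden -> output weights
    prev_in: np.ndarray = field(default=None)  # type: ignore[assignment]
    prev_out: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        if self.w_in.ndim != 1 or self.w_out.ndim != 2:
            raise ValueError("w_in must be 1-D and w_out 2-D")
        if self.w_out.shape[0] != self.w_in.shape[0]:
            raise ValueError("w_out rows must match hidden size")
        if self.prev_in is None:
            self.prev_in = np.zeros_like(self.w_in)
        if self.prev_out is None:
            self.prev_out = np.zeros_like(self.w_out)

    @property
    def n_hidden(self) -> int:
        return self.w_in.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.w_out.shape[1]


@dataclass
class CorrelationMatrix:
    """N x N inferred pairwise interaction scores in [-1, 1], zero diagonal."""

    entries: np.ndarray
    gene_labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError(f"correlation matrix must be square, got {e.shape}")
        if (np.abs(e) > 1).any():
            raise ValueError("correlation entries must lie in [-1, 1]")
        if (np.diag(e) != 0).any():
            raise ValueError("correlation diagonal must be zero")
        self.entries = e
        if self.gene_labels is not None:
            self.gene_labels = [str(x) for x in self.gene_labels]
            if len(self.gene_labels) != e.shape[0]:
                raise ValueError("gene_labels length must equal n_genes")

    @property
    def n_genes(self) -> int:
        return self.entries.shape[0]

    def labels(self) -> list[str]:
        if self.gene_labels is not None:
            return list(self.gene_labels)
        return [f"G{i}" for i in range(self.n_genes)]


StrengthMode = Literal["max", "mean", "signed-max"]


def interaction_strength(
    corr: CorrelationMatrix, mode: StrengthMode = "max", absolute: bool = True
) -> np.ndarray:
    """Symmetrise directed probe scores into one strength per pair.

    The probe is directional (gene i driven, gene j read out), but the
    evaluated networks are undirected.  ``max`` keeps the larger of the
    two directed magnitudes — the direction with the stronger response is
    the one that identifies the regulation.  ``absolute`` counts
    anti-correlation as interaction.
    """
    c = corr.entries
    a = np.abs(c) if absolute else c
    if mode == "max":
        s = np.maximum(a, a.T)
    elif mode == "mean":
        s = (a + a.T) / 2.0
    elif mode == "signed-max":
        # keep the signed entry of larger magnitude
        pick = np.abs(c) >= np.abs(c.T)
        s = np.where(pick, c, c.T)
        s = np.abs(s) if absolute else s
    else:
        raise ValueError(f"unknown strength mode {mode!r}")
    np.fill_diagonal(s, 0.0)
    return s


def build_patterns(
    expr: ExpressionMatrix, target_gene: int
) -> tuple[np.ndarray, np.ndarray]:
    """Build the training patterns for one gene.

    Each expression row yields one pattern: the input is the target
    gene's value, the output target is the row with the target gene's
    column removed (gene order preserved).

    Returns ``(inputs, targets)`` with shapes ``(M,)`` and ``(M, N-1)``.
    Raises if the matrix is still raw: tanh outputs live in (-1, 1), so
    targets must be normalised (linear rescaling to [-1, 1] is the
    intended convention).
    """
    if expr.normalization == "raw":
        raise ValueError(
            "expression matrix must be normalized before training "
            "(apply rescale_linear to map each gene onto [-1, 1]); "
            "tanh outputs cannot match unbounded targets"
        )
    n = expr.n_genes
    if n < 2:
        raise ValueError("need at least 2 genes")
    if not 0 <= target_gene < n:
        raise ValueError(f"target_gene {target_gene} out of range for {n} genes")
    x = expr.values[:, target_gene].copy()
    t = np.delete(expr.values, target_gene, axis=1)
    return x, t


def forward(reg: GeneRegressor, x: float) -> np.ndarray:
    """Forward pass: y = tanh(w_out.T @ tanh(w_in * x))."""
    hidden = np.tanh(reg.w_in * x)
    return np.tanh(reg.w_out.T @ hidden)


def _pattern_gradient(
    reg: GeneRegressor, x: float, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of E = 0.5 * sum((y - t)^2) w.r.t. (w_in, w_out)."""
    hidden = np.tanh(reg.w_in * x)
    y = np.tanh(reg.w_out.T @ hidden)
    delta_out = (y - target) * (1.0 - y * y)  # (N-1,)
    g_out = np.outer(hidden, delta_out)  # (H, N-1)
    delta_hid = (1.0 - hidden * hidden) * (reg.w_out @ delta_out)  # (H,)
    g_in = delta_hid * x
    return g_in, g_out


def train_gene(
    expr: ExpressionMatrix, target_gene: int, params: LearningParams
) -> GeneRegressor:
    """Train one per-gene regressor by online back-propagation.

    Weights start uniform in ``[-init_scale, init_scale]`` from a seed
    offset by the gene index; every epoch presents the patterns in a
    freshly shuffled seeded order, updating after each pattern with
    momentum.  Raises :class:`TrainingDivergedError` if weights become
    non-finite (the learning rate is then the usual culprit).
    """
    x_all, t_all = build_patterns(expr, target_gene)
    m, n_out = t_all.shape
    h = hidden_size(n_out, params.hidden_override)
    rng = np.random.default_rng(params.seed + target_gene)
    w_in = rng.uniform(-params.init_scale, params.init_scale, size=h)
    w_out = rng.uniform(-params.init_scale, params.init_scale, size=(h, n_out))
    d_in = np.zeros(h)
    d_out = np.zeros((h, n_out))
    eta = params.learning_rate
    alpha = params.momentum

    for epoch in range(params.epochs):
        order = rng.permutation(m)
        for i in order:
            x = x_all[i]
            hid = np.tanh(w_in * x)
            y = np.tanh(w_out.T @ hid)
            delta_out = (y - t_all[i]) * (1.0 - y * y)
            delta_hid = (1.0 - hid * hid) * (w_out @ delta_out)
            d_out *= alpha
            d_out -= eta * np.outer(hid, delta_out)
            d_in *= alpha
            d_in -= eta * x * delta_hid
            w_out += d_out
            w_in += d_in
        if not (np.isfinite(w_in).all() and np.isfinite(w_out).all()):
            raise TrainingDivergedError(
                f"training diverged for gene {target_gene} at epoch {epoch}: "
                f"non-finite weights (learning_rate={eta} is the likely cause)"
            )
    return GeneRegressor(target_gene=target_gene, w_in=w_in, w_out=w_out,
                         prev_in=d_in, prev_out=d_out)


def training_mse(reg: GeneRegressor, expr: ExpressionMatrix) -> float:
    """Mean squared output error of a regressor over the training set."""
    x_all, t_all = build_patterns(expr, reg.target_gene)
    hid = np.tanh(np.outer(x_all, reg.w_in))  # (M, H)
    y = np.tanh(hid @ reg.w_out)  # (M, N-1)
    return float(np.mean((y - t_all) ** 2))


def probe(reg: GeneRegressor) -> np.ndarray:
    """Probe a trained regressor with the maximal normalised input (1.0).

    The outputs are the expected normalised expression of every other
    gene when the probed gene is maximally expressed, read as inferred
    correlations.  Pure function of the weights.
    """
    return forward(reg, 1.0)


def infer_network(expr: ExpressionMatrix, params: LearningParams) -> CorrelationMatrix:
    """Train the full per-gene ensemble and join the probe vectors.

    Row ``g`` of the result is the probe of gene ``g``'s regressor with a
    zero reinserted at position ``g`` (no self-regulation by
    construction).  Genes are independent: the matrix does not depend on
    the order in which they are trained.
    """
    n = expr.n_genes
    out = np.zeros((n, n))
    for g in range(n):
        reg = train_gene(expr, g, params)
        v = probe(reg)
        out[g, :g] = v[:g]
        out[g, g + 1:] = v[g:]
        logger.debug("gene %d/%d trained (H=%d)", g + 1, n, reg.n_hidden)
    return CorrelationMatrix(out, gene_labels=expr.gene_labels)


def binarize(
    corr: CorrelationMatrix,
    threshold: float,
    mode: StrengthMode = "max",
    absolute: bool = True,
) -> AdjacencyMatrix:
    """Threshold a correlation matrix into a predicted adjacency matrix.

    A link i-j is present iff the symmetrised strength strictly exceeds
    the threshold.  ``threshold`` must lie in [0, 1].
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    s = interaction_strength(corr, mode=mode, absolute=absolute)
    a = (s > threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    return AdjacencyMatrix(a, node_labels=corr.gene_labels)


def majority_vote(
    expr: ExpressionMatrix,
    params: LearningParams,
    n_runs: int,
    threshold: float,
    vote_fraction: float,
    mode: StrengthMode = "max",
) -> AdjacencyMatrix:
    """Smooth out weight-initialisation noise by majority voting.

    Repeats inference ``n_runs`` times with distinct derived seeds
    (``seed + run * N``), binarizes each run, and keeps the links whose
    appearance frequency strictly exceeds ``vote_fraction``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 0 <= vote_fraction <= 1:
        raise ValueError("vote_fraction must be in [0, 1]")
    n = expr.n_genes
    votes = np.zeros((n, n))
    from dataclasses import replace as _replace

    for run in range(n_runs):
        run_params = _replace(params, seed=params.seed + run * n)
        adj = binarize(infer_network(expr, run_params), threshold, mode=mode)
        votes += adj.entries
    keep = (votes / n_runs > vote_fraction).astype(np.int8)
    np.fill_diagonal(keep, 0)
    return AdjacencyMatrix(keep, node_labels=expr.gene_labels)


def write_correlation(corr: CorrelationMatrix, path: str | Path) -> None:
    """Write a labelled correlation-matrix TSV (same dialect as adjacency)."""
    labels = corr.labels()
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, corr.entries):
            fh.write(lab + "\t" + "\t".join(format(x, ".17g") for x in row) + "\n")


def read_correlation(path: str | Path) -> CorrelationMatrix:
    """Read a labelled correlation-matrix TSV."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty correlation file")
    labels = lines[0].split("\t")[1:]
    n = len(labels)
    if len(lines) - 1 != n:
        raise ValueError(f"{path}: expected square matrix of size {n}")
    rows = [[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]]
    return CorrelationMatrix(np.array(rows), gene_labels=labels)
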