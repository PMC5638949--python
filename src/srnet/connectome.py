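"""Weighted connectome container, delimited-text I/O and a Gaussian random-network generator.

The networks handled here are undirected, weighted graphs whose nodes stand
for gray-matter regions and whose edge weights measure the strength of the
white-matter connection between two regions.  The generator reproduces the
degree/weight statistics of such a network without any of its topology:
node degrees are drawn from a Gaussian, the graph is wired by
configuration-model stub pairing, and each realized edge receives an
independent Gaussian weight truncated to be positive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Connectome",
    "GeneratorConfig",
    "generate_random_connectome",
    "load_connectome",
    "save_connectome",
    "node_strengths",
]

#: absolute tolerance used when validating symmetry of loaded matrices
SYMMETRY_TOL = 1e-9


class ConnectomeError(ValueError):
    """Raised when a matrix violates the connectome contract."""


@dataclass
class Connectome:
    """A weighted, symmetric, non-negative adjacency matrix with node labels.

    Parameters
    ----------
    weights:
        N x N array of non-negative connection strengths.  Symmetric with a
        zero diagonal (no self-connections).
    labels:
        Node identifiers; defaults to ``n0 .. n{N-1}``.
    hemisphere:
        Optional per-node tag (e.g. ``"L"``/``"R"``) carried as metadata.
    """

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)
    hemisphere: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(f"weights must be a square matrix, got shape {w.shape}")
        n = w.shape[0]
        if n < 2:
            raise ConnectomeError("a connectome needs at least 2 nodes")
        bad = np.argwhere(np.abs(w - w.T) > SYMMETRY_TOL)
        if bad.size:
            i, j = bad[0]
            raise ConnectomeError(
                f"matrix not symmetric at cell ({i},{j}): {w[i, j]!r} vs {w[j, i]!r}"
            )
        neg = np.argwhere(w < 0)
        if neg.size:
            i, j = neg[0]
            raise ConnectomeError(f"negative weight at cell ({i},{j}): {w[i, j]!r}")
        diag = np.flatnonzero(np.diag(w))
        if diag.size:
            i = diag[0]
            raise ConnectomeError(f"nonzero diagonal at cell ({i},{i}): {w[i, i]!r}")
        self.weights = w
        if not self.labels:
            self.labels = [f"n{i}" for i in range(n)]
        elif len(self.labels) != n:
            raise ConnectomeError(
                f"{len(self.labels)} labels for a {n}-node matrix"
            )
        if self.hemisphere is not None and len(self.hemisphere) != n:
            raise ConnectomeError("hemisphere tags must match the number of nodes")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Number of nonzero connections per node."""
        return np.count_nonzero(self.weights, axis=1)

    @property
    def strengths(self) -> np.ndarray:
        """Total connection weight per node (row sums)."""
        return self.weights.sum(axis=1)

    def n_components(self) -> int:
        """Number of connected components (isolated nodes count as components)."""
        from scipy.sparse.csgraph import connected_components

        n, _ = connected_components(self.weights > 0, directed=False)
        return int(n)


@dataclass
class GeneratorConfig:
    """Parameters of the Gaussian random-network generator.

    Defaults match the degree and weight statistics of a 114-region cortical
    connectome: degrees ~ Normal(20.92, 7.01), weights ~ Normal(0.5, 0.12).
    """

    n_nodes: int = 114
    degree_mean: float = 20.92
    degree_sd: float = 7.01
    weight_mean: float = 0.5
    weight_sd: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.degree_sd <= 0 or self.weight_sd <= 0:
            raise ValueError("degree_sd and weight_sd must be positive")


def _sample_degree_sequence(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Gaussian degrees, rounded, clipped to [1, N-1], parity-adjusted."""
    n = cfg.n_nodes
    deg = np.rint(rng.normal(cfg.degree_mean, cfg.degree_sd, size=n)).astype(int)
    deg = np.clip(deg, 1, n - 1)
    if deg.sum() % 2:
        # stub count must be even for pairing; bump one node by the minimal amount
        candidates = np.flatnonzero(deg < n - 1)
        if candidates.size:
            deg[rng.choice(candidates)] += 1
        else:
            deg[rng.integers(n)] -= 1
    return deg


def _pair_stubs(deg: np.ndarray, rng: np.random.Generator, max_rounds: int = 200) -> set[tuple[int, int]]:
    """Configuration-model stub pairing, repairing self-loops and multi-edges.

    All stubs are shuffled and paired; offending pairs are then repeatedly
    re-matched against randomly chosen legal pairs (a degree-preserving swap)
    until the edge set is simple.  Raises if the sequence cannot be realized
    within the retry budget.
    """
    stubs = np.repeat(np.arange(deg.size), deg)
    rng.shuffle(stubs)
    pairs = stubs.reshape(-1, 2)
    for _ in range(max_rounds):
        edges: dict[tuple[int, int], int] = {}
        bad: list[int] = []
        for idx, (a, b) in enumerate(pairs):
            key = (min(a, b), max(a, b))
            if a == b or key in edges:
                bad.append(idx)
            else:
                edges[key] = idx
        if not bad:
            return set(edges)
        # swap one endpoint of each bad pair with a random other pair
        for idx in bad:
            j = rng.integers(len(pairs))
            side = rng.integers(2)
            pairs[idx, 1], pairs[j, side] = pairs[j, side], pairs[idx, 1]
    raise ConnectomeError(
        "could not realize the degree sequence as a simple graph "
        f"after {max_rounds} repair rounds"
    )


def generate_random_connectome(cfg: GeneratorConfig) -> Connectome:
    """Generate a random network with Gaussian degrees and Gaussian edge weights.

    Degrees are drawn from Normal(degree_mean, degree_sd), rounded and clipped
    to ``[1, N-1]`` (parity-adjusted so the stub count is even), and the graph
    is wired by configuration-model pairing with rejection of self-loops and
    multi-edges.  Each realized edge gets a weight drawn from
    Normal(weight_mean, weight_sd), redrawn until positive, assigned
    symmetrically.

    Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    deg = _sample_degree_sequence(cfg, rng)
    edges = _pair_stubs(deg, rng)
    w = np.zeros((cfg.n_nodes, cfg.n_nodes))
    for (i, j) in sorted(edges):
        weight = rng.normal(cfg.weight_mean, cfg.weight_sd)
        while weight <= 0:
            weight = rng.normal(cfg.weight_mean, cfg.weight_sd)
        w[i, j] = w[j, i] = weight
    return Connectome(w)


def node_strengths(c: Connectome) -> np.ndarray:
    """Node strength: the total weight of all connections of each node."""
    return c.strengths


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def load_connectome(path: str | Path) -> Connectome:
    """Read a square delimited (CSV/TSV) weight matrix, with an optional label header.

    The delimiter is auto-detected from the first line.  A first line whose
    fields are not all numeric is taken as the label row.  Symmetry,
    non-negativity and a zero diagonal are validated on load.
    """
    path = Path(path)
    text = path.read_text()
    first, _, rest = text.partition("\n")
    delim = _detect_delimiter(first)
    fields = [f.strip() for f in first.split(delim)]
    labels: list[str] = []
    try:
        [float(f) for f in fields if f]
    except ValueError:
        labels = [f for f in fields if f]
        text = rest
    try:
        w = np.loadtxt(io.StringIO(text), delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise ConnectomeError(f"could not parse {path} as a numeric matrix: {exc}") from exc
    return Connectome(w, labels=labels)


def save_connectome(c: Connectome, path: str | Path, delimiter: str = ",") -> None:
    """Write the weight matrix as delimited text with a label header row.

    Weights are written with ``repr`` precision so a save/load round trip is
    exact.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delimiter.join(c.labels) + "\n")
        for row in c.weights:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")
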