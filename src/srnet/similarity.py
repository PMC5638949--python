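"""Fourier-spectrum similarity between an input signal and node activities.

Two signals are considered similar when their power spectra share the same
principal frequencies, even if amplitudes differ by an overall rescaling.
For an input (seeder) spectrum ``phi_i`` and an output (receiver) spectrum
``phi_j``, a factor ``lambda_ij`` minimizing the input-amplitude-weighted
squared difference is found in closed form::

    lambda_ij = sum_m (phi_i_m)^2 phi_j_m / sum_m (phi_j_m)^2 phi_i_m

and the similarity is the negative log of the normalized weighted residual::

    sim(i, j) = -log( sum_n (phi_i_n - lambda_ij phi_j_n)^2 phi_i_n
                      / sum_m (phi_i_m)^3 )

with both sums restricted to the input's M principal frequencies (the bins
whose amplitude exceeds a small threshold).  sim is scale-invariant in the
output, zero for an output carrying none of the input's principal
frequencies, and capped when the residual underflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from srnet.connectome import Connectome
from srnet.dynamics import ModelParams, SignalProtocol, simulate_ensemble

__all__ = [
    "Spectrum",
    "SimilarityMatrix",
    "SRCurveResult",
    "power_spectrum",
    "lambda_factor",
    "similarity",
    "similarity_matrix",
    "summarize",
    "sr_curve",
    "deaf_nodes",
    "AMPLITUDE_THRESHOLD",
    "RESIDUAL_FLOOR",
]

#: amplitude (|DFT|/L of the mean-removed series) above which a frequency
#: bin counts as principal
AMPLITUDE_THRESHOLD = 1e-4

#: floor applied to the residual before the log; caps sim at ~27.6 when the
#: rescaled output matches the input exactly
RESIDUAL_FLOOR = 1e-12


@dataclass
class Spectrum:
    """One-sided amplitude spectrum of a time series with its principal bins.

    ``amps[k]`` is ``|DFT|/L`` of the mean-removed series at frequency
    ``freqs[k]`` (cycles/step); the zero-frequency bin is excluded.
    ``principal`` marks the bins with amplitude above the threshold.
    """

    freqs: np.ndarray
    amps: np.ndarray
    principal: np.ndarray

    @property
    def n_principal(self) -> int:
        """M, the number of principal frequencies."""
        return int(self.principal.sum())


def power_spectrum(series: np.ndarray, threshold: float = AMPLITUDE_THRESHOLD) -> Spectrum:
    """Amplitude spectrum of a (typically binary) activity series.

    The series mean is removed before the DFT so the constant offset of a
    binary signal does not enter the amplitude ranking, and the
    zero-frequency bin is dropped.  Amplitudes are normalized by the series
    length, making the principal-frequency threshold length-independent.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        raise ValueError(f"series too short for a spectrum: length {x.size}")
    L = x.size
    amps = np.abs(np.fft.rfft(x - x.mean())) / L
    freqs = np.fft.rfftfreq(L)
    return Spectrum(freqs[1:], amps[1:], amps[1:] > threshold)


def lambda_factor(input_spec: Spectrum, output_spec: Spectrum) -> float:
    """Closed-form rescaling factor minimizing the weighted spectral residual.

    Sums run over the input's principal frequencies.  When the output
    spectrum vanishes on every principal bin the factor is undefined; zero
    is returned, which yields the minimal similarity for that input.
    """
    m = input_spec.principal
    if not m.any():
        raise ValueError("input spectrum has no principal frequencies")
    if input_spec.amps.shape != output_spec.amps.shape:
        raise ValueError("spectra must share one frequency grid")
    pi = input_spec.amps[m]
    pj = output_spec.amps[m]
    den = float(pj**2 @ pi)
    if den == 0.0:
        return 0.0
    return float(pi**2 @ pj) / den


def similarity(input_spec: Spectrum, output_spec: Spectrum) -> float:
    """Spectral similarity sim(i, j) between an input and an output spectrum.

    Returns NaN when the input has no principal frequencies (undefined).
    The residual is floored, capping the value for a perfect rescaled match.
    """
    m = input_spec.principal
    if not m.any():
        return float("nan")
    lam = lambda_factor(input_spec, output_spec)
    pi = input_spec.amps[m]
    pj = output_spec.amps[m]
    residual = float(((pi - lam * pj) ** 2 @ pi) / (pi**3).sum())
    return -float(np.log(max(residual, RESIDUAL_FLOOR)))


@dataclass
class SimilarityMatrix:
    """Seeder (rows) x receiver (columns) similarity values.

    The diagonal and any row that was not run as a seeder are NaN-masked.
    """

    values: np.ndarray
    params: ModelParams
    period: int = 50
    n_realizations: int = 1
    seeders: list[int] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def _seeder_row_similarities(states: np.ndarray, seeder: int,
                             threshold: float = AMPLITUDE_THRESHOLD) -> np.ndarray:
    """Similarity of every node's activity to the clamped signal at ``seeder``.

    ``states`` is the (steps x nodes) record of one run in which ``seeder``
    was clamped; its own column is the input signal, so input and output
    spectra share the frequency grid by construction.
    """
    x = states.astype(float)
    L = x.shape[0]
    amps = np.abs(np.fft.rfft(x - x.mean(axis=0), axis=0))[1:] / L
    inp = amps[:, seeder]
    m = inp > threshold
    if not m.any():
        return np.full(x.shape[1], np.nan)
    pi = inp[m]
    pj = amps[m]
    den = pi @ pj**2
    lam = np.divide(pi**2 @ pj, den, out=np.zeros_like(den), where=den > 0)
    residual = ((pi[:, None] - lam[None, :] * pj) ** 2 * pi[:, None]).sum(axis=0)
    residual /= (pi**3).sum()
    sims = -np.log(np.maximum(residual, RESIDUAL_FLOOR))
    sims[seeder] = np.nan
    return sims


def similarity_matrix(
    c: Connectome,
    params: ModelParams,
    protocol: SignalProtocol | None = None,
    rng: np.random.Generator | int | None = None,
    seeders: Sequence[int] | None = None,
    n_realizations: int = 5,
) -> SimilarityMatrix:
    """Run the clamped-signal experiment for every seeder and fill sim(i, j).

    The same square-wave input (``protocol`` gives period/phase; its seeder
    field is ignored) is injected at each node in ``seeders`` (default: all
    nodes) in independent runs; each run's receivers are scored against the
    input and similarities are averaged over ``n_realizations`` runs per
    seeder.  Rows not in ``seeders`` and the diagonal stay NaN.
    """
    rng = np.random.default_rng(rng)
    n = c.n_nodes
    if seeders is None:
        seeders = list(range(n))
    seeders = list(seeders)
    template = protocol or SignalProtocol(seeder=0)
    acc = np.zeros((n, n))
    for _ in range(n_realizations):
        states, _ = simulate_ensemble(
            c, params, seeders=seeders, protocol_template=template, rng=rng,
        )
        for k, i in enumerate(seeders):
            acc[i] += np.nan_to_num(_seeder_row_similarities(states[:, k, :], i))
    values = np.full((n, n), np.nan)
    values[seeders] = acc[seeders] / n_realizations
    np.fill_diagonal(values, np.nan)
    return SimilarityMatrix(values, params, template.period, n_realizations, seeders)


def summarize(mat: SimilarityMatrix) -> dict:
    """Grand mean/median and per-seeder (row) / per-receiver (column) means."""
    import warnings

    v = mat.values
    if np.all(np.isnan(v)):
        raise ValueError("similarity matrix is fully masked")
    with warnings.catch_warnings():
        # rows that were not run as seeders are all-NaN and average to NaN
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        return {
            "mean": float(np.nanmean(v)),
            "median": float(np.nanmedian(v)),
            "row_means": np.nanmean(v, axis=1),
            "col_means": np.nanmean(v[mat.seeders], axis=0),
        }


@dataclass
class SRCurveResult:
    """Mean/median similarity as a function of the noise level p_qe."""

    table: pd.DataFrame
    peak_mean: float
    peak_median: float
    matrices: list[SimilarityMatrix] = field(default_factory=list)


def sr_curve(
    c: Connectome,
    p_ee: float,
    threshold: float,
    pqe_grid: Sequence[float],
    rng: np.random.Generator | int | None = None,
    seeders: Sequence[int] | None = None,
    n_realizations: int = 5,
    period: int = 50,
    steps: int = 5000,
    transient: int = 1000,
    keep_matrices: bool = False,
) -> SRCurveResult:
    """Stochastic-resonance scan: summarized similarity at each noise level.

    For every ``p_qe`` on the grid, a full similarity matrix is computed and
    summarized; the returned table has columns ``p_qe``, ``mean_sim``,
    ``median_sim`` and the result records the grid argmax of each summary.
    """
    rng = np.random.default_rng(rng)
    rows = []
    result_mats = []
    for p_qe in pqe_grid:
        params = ModelParams(p_qe, p_ee, threshold, transient=transient, steps=steps)
        mat = similarity_matrix(
            c, params, SignalProtocol(0, period), rng,
            seeders=seeders, n_realizations=n_realizations,
        )
        s = summarize(mat)
        rows.append({"p_qe": p_qe, "mean_sim": s["mean"], "median_sim": s["median"]})
        if keep_matrices:
            result_mats.append(mat)
    table = pd.DataFrame(rows)
    if len(table) == 0:
        raise ValueError("empty p_qe grid")
    return SRCurveResult(
        table,
        peak_mean=float(table.p_qe[table.mean_sim.idxmax()]),
        peak_median=float(table.p_qe[table.median_sim.idxmax()]),
        matrices=result_mats,
    )


def deaf_nodes(mat: SimilarityMatrix, c: Connectome | None = None,
               quantile: float = 0.15) -> pd.DataFrame:
    """Receivers whose column-mean similarity is in the lowest ``quantile``.

    A node is flagged when its column mean is strictly below the quantile
    value of all column means, so a perfectly uniform matrix flags nothing.
    Returns a table with the column mean and, when a connectome is given,
    the node strength.
    """
    s = summarize(mat)
    col = s["col_means"]
    cut = np.nanquantile(col, quantile)
    idx = np.flatnonzero(col < cut)
    out = pd.DataFrame({"node": idx, "col_mean_sim": col[idx]})
    if c is not None:
        out["label"] = [c.labels[i] for i in idx]
        out["strength"] = c.strengths[idx]
    return out
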