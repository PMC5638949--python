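"""Phase-space characterization: activity PDFs, coexistence curves, critical points.

Without any input signal the model shows, at fixed persistence ``p_ee`` and
threshold ``T``, a discontinuous transition of the active-node density S(t)
from a low- to a high-activity phase as the noise ``p_qe`` grows.  Inside a
region of parameter space both phases coexist: a long run jumps between two
activity levels and the distribution of S(t) is bimodal.  The *coexistence
curve* collects, for each T, the noise level at which the two modes are
equally likely (equal peak heights); as T increases the modes approach and
finally merge at the *critical point*, identified by the distribution with
skewness closest to zero, negative excess kurtosis, the largest integrated
autocorrelation time, and maximal standard deviation of S(t).

Distributions of the active-node count are fitted with one- and
two-component Gaussian mixtures; a fit is declared bimodal when the
component means are separated by more than the sum of the component
standard deviations and neither component weight is negligible (< 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from srnet.connectome import Connectome
from srnet.dynamics import ModelParams, simulate_ensemble

__all__ = [
    "MixtureFit",
    "PhasePoint",
    "CoexistencePoint",
    "CriticalPoint",
    "fit_activity_modes",
    "activity_statistics",
    "autocorr_time",
    "criticality_scan",
    "select_critical",
    "find_coexistence_point",
    "coexistence_curve",
    "find_critical_point",
    "is_bimodal_at",
]

#: minimum mixture weight for a mode to count as a real phase
MIN_COMPONENT_WEIGHT = 0.1

#: relative peak-height tolerance of the equal-occupancy search
EQUAL_HEIGHT_TOL = 0.05


@dataclass
class MixtureFit:
    """Gaussian mixture fitted to an activity distribution (1 or 2 components).

    Components are ordered by increasing mean.  ``bimodal`` applies the
    separation rule |mu2 - mu1| > sigma1 + sigma2 with both weights >= 0.1.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    bimodal: bool
    degenerate: bool = False

    def peak_heights(self) -> np.ndarray:
        """Probability-density height of each component at its own mean."""
        return self.weights / (self.sds * np.sqrt(2 * np.pi))


def fit_activity_modes(samples: np.ndarray, random_state: int = 0,
                       min_separation: float = 3.0) -> MixtureFit:
    """Fit one- and two-component Gaussian mixtures and decide modality.

    Operates on raw samples (activity counts, by convention).  A constant
    series is flagged degenerate.  The two-component fit is kept only when
    the separation rule declares it bimodal: component means further apart
    than the sum of the component SDs and than ``min_separation`` sample
    units (the floor keeps the near-silent phase's discrete spike at zero
    counts from masquerading as a second macroscopic mode), with neither
    weight below 0.1.  Otherwise the single-Gaussian fit is reported.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(samples, dtype=float).reshape(-1, 1)
    if x.size < 10:
        raise ValueError("need at least 10 samples to fit activity modes")
    if np.ptp(x) == 0:
        v = float(x[0, 0])
        return MixtureFit(np.array([1.0]), np.array([v]), np.array([0.0]),
                          bimodal=False, degenerate=True)
    gm2 = GaussianMixture(2, n_init=3, random_state=random_state).fit(x)
    order = np.argsort(gm2.means_[:, 0])
    w = gm2.weights_[order]
    mu = gm2.means_[order, 0]
    sd = np.sqrt(gm2.covariances_[order, 0, 0])
    separated = abs(mu[1] - mu[0]) > max(sd[0] + sd[1], min_separation)
    if separated and w.min() >= MIN_COMPONENT_WEIGHT:
        return MixtureFit(w, mu, sd, bimodal=True)
    return MixtureFit(np.array([1.0]), np.array([float(x.mean())]),
                      np.array([float(x.std())]), bimodal=False)


def autocorr_time(series: np.ndarray) -> float:
    """Integrated autocorrelation time 1 + 2*sum_k rho(k).

    The sum runs to the first non-positive autocorrelation (initial-positive
    -sequence cutoff), a standard estimator that is robust at moderate run
    lengths.  A series with no non-positive lag (e.g. perfectly periodic) is
    summed in full and reported with a warning as non-mixing.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("series too short for an autocorrelation time")
    x = x - x.mean()
    var = x @ x
    if var == 0:
        raise ValueError("zero-variance series has no autocorrelation time")
    n = x.size
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n]
    rho = acov / acov[0]
    nonpos = np.flatnonzero(rho[1:] <= 0)
    if nonpos.size == 0:
        warnings.warn("no autocorrelation cutoff found; series looks non-mixing")
        cut = n
    else:
        cut = int(nonpos[0]) + 1
    tail = np.abs(rho[n // 4: n // 2])
    if tail.size and tail.max() > 0.5:
        # e.g. a perfectly periodic series: the ACF never decays
        warnings.warn("autocorrelation persists at long lags; series looks non-mixing")
    return float(1.0 + 2.0 * rho[1:cut].sum())


@dataclass
class PhasePoint:
    """Statistics of the activity density S(t) at one parameter setting.

    ``mean_activity``/``sd_activity`` are sample statistics of S(t);
    skewness and excess kurtosis are the sample moments used by the
    critical-point criteria; ``fit`` holds the Gaussian mixture (component
    means and SDs in density units).
    """

    params: ModelParams
    mean_activity: float
    sd_activity: float
    skewness: float
    excess_kurtosis: float
    autocorr_time: float
    bimodal: bool
    fit: MixtureFit
    degenerate: bool = False
    n_samples: int = 0

    @property
    def component_means(self) -> np.ndarray:
        return self.fit.means


def _phase_point(params: ModelParams, density: np.ndarray, n_nodes: int,
                 tau: float, random_state: int = 0) -> PhasePoint:
    counts = density * n_nodes
    fit_counts = fit_activity_modes(counts, random_state=random_state)
    fit = MixtureFit(fit_counts.weights, fit_counts.means / n_nodes,
                     fit_counts.sds / n_nodes, fit_counts.bimodal,
                     fit_counts.degenerate)
    if fit.degenerate:
        sk = ku = 0.0
    else:
        sk = float(stats.skew(density))
        ku = float(stats.kurtosis(density))
    return PhasePoint(
        params=params,
        mean_activity=float(density.mean()),
        sd_activity=float(density.std()),
        skewness=sk,
        excess_kurtosis=ku,
        autocorr_time=tau,
        bimodal=fit.bimodal,
        fit=fit,
        degenerate=fit.degenerate,
        n_samples=int(density.size),
    )


def activity_statistics(traj) -> PhasePoint:
    """Moments, autocorrelation time and mixture fit of one trajectory's S(t)."""
    density = traj.density
    if density.size < 1000:
        raise ValueError("need at least 1000 recorded steps for phase statistics")
    try:
        tau = autocorr_time(density)
    except ValueError:
        tau = 0.0
    return _phase_point(traj.params, density, traj.n_nodes, tau)


def _scan_points(
    c: Connectome,
    p_ee: float,
    threshold: float,
    pqe_values: np.ndarray,
    rng: np.random.Generator,
    n_realizations: int,
    steps: int,
    transient: int,
) -> list[PhasePoint]:
    """Simulate all (p_qe, realization) replicas in one batch and summarize.

    Samples of the ``n_realizations`` independent runs at each noise level
    are pooled for the distribution statistics; the autocorrelation time is
    averaged over runs.
    """
    pqe_values = np.asarray(pqe_values, dtype=float)
    reps = np.repeat(pqe_values, n_realizations)
    params0 = ModelParams(0.0, p_ee, threshold, transient=transient, steps=steps)
    _, dens = simulate_ensemble(c, params0, p_qe_values=reps, rng=rng,
                                record_states=False)
    points = []
    for k, p_qe in enumerate(pqe_values):
        block = dens[:, k * n_realizations:(k + 1) * n_realizations]
        taus = []
        for col in block.T:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    taus.append(autocorr_time(col))
            except ValueError:
                taus.append(0.0)
        params = ModelParams(p_qe, p_ee, threshold, transient=transient, steps=steps)
        points.append(_phase_point(params, block.T.reshape(-1), c.n_nodes,
                                   float(np.mean(taus))))
    return points


def criticality_scan(
    c: Connectome,
    p_ee: float,
    threshold: float,
    pqe_values: Sequence[float],
    rng: np.random.Generator | int | None = None,
    n_realizations: int = 3,
    steps: int = 10_000,
    transient: int = 1000,
) -> list[PhasePoint]:
    """PhasePoint diagnostics over a grid of noise levels (signal-free runs)."""
    rng = np.random.default_rng(rng)
    return _scan_points(c, p_ee, threshold, np.asarray(pqe_values), rng,
                        n_realizations, steps, transient)


def select_critical(points: Sequence[PhasePoint], kurtosis_se_factor: float = 3.0) -> int:
    """Index of the scan point satisfying the critical-point criteria.

    Among points whose excess kurtosis is negative beyond sampling noise
    (below ``-kurtosis_se_factor`` standard errors of the kurtosis
    estimator, SE = sqrt(24/n); a platykurtic distribution, not a zero
    estimate), picks the skewness closest to zero; warns when the
    autocorrelation time or the SD of S(t) is not maximal there (criteria
    conflict), still returning the best-skewness point.
    """
    if not points:
        raise ValueError("empty scan")
    ku = np.array([p.excess_kurtosis for p in points])
    sk = np.abs([p.skewness for p in points])
    ns = np.array([max(p.n_samples, 1) for p in points])
    cutoff = -kurtosis_se_factor * np.sqrt(24.0 / ns)
    eligible = np.flatnonzero(ku < cutoff)
    if eligible.size == 0:
        warnings.warn("no scan point has clearly negative excess kurtosis; "
                      "falling back to the skewness criterion alone")
        eligible = np.arange(len(points))
    best = int(eligible[np.argmin(sk[eligible])])
    taus = np.array([p.autocorr_time for p in points])
    sds = np.array([p.sd_activity for p in points])
    if taus.argmax() != best:
        warnings.warn(
            f"criteria conflict: autocorrelation time peaks at "
            f"p_qe={points[taus.argmax()].params.p_qe:.3f}, "
            f"skewness criterion selects p_qe={points[best].params.p_qe:.3f}"
        )
    if sds.argmax() != best:
        warnings.warn(
            f"criteria conflict: SD of S(t) peaks at "
            f"p_qe={points[sds.argmax()].params.p_qe:.3f}, "
            f"skewness criterion selects p_qe={points[best].params.p_qe:.3f}"
        )
    return best


@dataclass
class CoexistencePoint:
    """Equal-occupancy point of the two activity phases at fixed (p_ee, T)."""

    p_ee: float
    threshold: float
    p_qe: float
    low_mean: float
    high_mean: float

    def __post_init__(self) -> None:
        if not self.low_mean < self.high_mean:
            raise ValueError("low_mean must be below high_mean")


@dataclass
class CriticalPoint:
    """End of a coexistence curve: the merged-mode, maximal-fluctuation point."""

    p_ee: float
    threshold: float
    p_qe: float
    diagnostics: PhasePoint
    scan: list[PhasePoint] = field(default_factory=list)


def _height_diff(fit: MixtureFit) -> float:
    """Signed relative peak-height difference, high mode minus low mode."""
    h = fit.peak_heights()
    return float((h[1] - h[0]) / h.max())


def _equal_height_search(
    sampler: Callable[[float], np.ndarray],
    grid: np.ndarray,
    tol: float = EQUAL_HEIGHT_TOL,
    max_iter: int = 20,
) -> tuple[float, MixtureFit] | None:
    """Find the noise level where the two activity modes have equal heights.

    ``sampler(p_qe)`` returns pooled activity samples.  A scan of ``grid``
    locates bimodal points and a sign change of the peak-height difference;
    bisection then refines until the relative height difference is within
    ``tol`` (or returns the closest-to-equal bimodal point found).  Returns
    None when no grid point is bimodal.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = float(grid[0]), float(grid[-1])
    fits: dict[float, MixtureFit] = {}
    diffs: dict[float, float] = {}
    for p in grid:
        f = fit_activity_modes(sampler(p))
        if f.bimodal:
            fits[p] = f
            diffs[p] = _height_diff(f)
    if not fits:
        return None
    best_p = min(diffs, key=lambda p: abs(diffs[p]))
    best = (best_p, fits[best_p], abs(diffs[best_p]))
    if best[2] <= tol:
        return best[0], best[1]
    # bracket a sign change for bisection; the low mode dominates at low
    # noise, so the signed height difference increases with p_qe
    neg = [p for p in diffs if diffs[p] < 0]
    pos = [p for p in diffs if diffs[p] > 0]
    if neg and pos:
        a, b = max(neg), min(pos)
    else:
        step = (hi - lo) / max(grid.size - 1, 1)
        a, b = best_p - step, best_p + step
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        f = fit_activity_modes(sampler(mid))
        if f.bimodal:
            d = _height_diff(f)
            if abs(d) < best[2]:
                best = (mid, f, abs(d))
            if abs(d) <= tol:
                return mid, f
            if d < 0:
                a = mid
            else:
                b = mid
        elif mid < best[0]:
            # stepped off the bimodal region; shrink toward the best point
            a = mid
        else:
            b = mid
        if b - a < 1e-4:
            break
    return best[0], best[1]


def _transition_window(
    c: Connectome,
    p_ee: float,
    threshold: float,
    pqe_bracket: tuple[float, float],
    rng: np.random.Generator,
    steps: int,
    transient: int,
    n_coarse: int = 25,
    step: float = 0.005,
    half: float = 0.05,
) -> np.ndarray:
    """Dense noise grid centred on the low-to-high activity transition.

    A cheap single-run order-parameter sweep over the bracket locates the
    largest jump of the average activity; the returned grid covers
    ``centre +/- half`` at resolution ``step``, clipped to the bracket.
    """
    coarse = np.linspace(pqe_bracket[0], pqe_bracket[1], n_coarse)
    params0 = ModelParams(0.0, p_ee, threshold, transient=transient, steps=steps)
    _, dens = simulate_ensemble(c, params0, p_qe_values=coarse, rng=rng,
                                record_states=False)
    means = dens.mean(axis=0)
    jump = int(np.argmax(np.diff(means))) if means.size > 1 else 0
    centre = 0.5 * (coarse[jump] + coarse[min(jump + 1, coarse.size - 1)])
    lo = max(pqe_bracket[0], centre - half)
    hi = min(pqe_bracket[1], centre + half)
    return np.arange(lo, hi + step / 2, step)


def _make_sampler(
    c: Connectome,
    p_ee: float,
    threshold: float,
    rng: np.random.Generator,
    n_realizations: int,
    steps: int,
    transient: int,
) -> Callable[[float], np.ndarray]:
    def sampler(p_qe: float) -> np.ndarray:
        params = ModelParams(p_qe, p_ee, threshold, transient=transient, steps=steps)
        _, dens = simulate_ensemble(
            c, params, p_qe_values=[p_qe] * n_realizations, rng=rng,
            record_states=False,
        )
        return dens.T.reshape(-1) * c.n_nodes

    return sampler


def find_coexistence_point(
    c: Connectome,
    p_ee: float,
    threshold: float,
    pqe_bracket: tuple[float, float] = (0.0, 1.0),
    rng: np.random.Generator | int | None = None,
    n_realizations: int = 3,
    steps: int = 10_000,
    transient: int = 1000,
) -> CoexistencePoint | None:
    """Equal-occupancy point of the low and high activity phases, or None.

    Scans/bisects the noise level inside ``pqe_bracket`` until the two modes
    of the activity PDF have equal peak heights (within the 5% tolerance).
    Returns None when the distribution is never bimodal in the bracket,
    which is the expected outcome outside the coexistence region.

    The bimodal window in the noise level is narrow, so the search first
    locates the low-to-high transition with a cheap order-parameter sweep
    and then scans densely around the jump.
    """
    rng = np.random.default_rng(rng)
    sampler = _make_sampler(c, p_ee, threshold, rng, n_realizations, steps, transient)
    grid = _transition_window(c, p_ee, threshold, pqe_bracket, rng,
                              steps=max(steps // 4, 1000), transient=transient)
    hit = _equal_height_search(sampler, grid)
    if hit is None:
        return None
    p_qe, fit = hit
    return CoexistencePoint(p_ee, threshold, float(p_qe),
                            float(fit.means[0] / c.n_nodes),
                            float(fit.means[1] / c.n_nodes))


def coexistence_curve(
    c: Connectome,
    p_ee: float,
    T_grid: Sequence[float],
    rng: np.random.Generator | int | None = None,
    pqe_bracket: tuple[float, float] = (0.0, 1.0),
    **kwargs,
) -> list[CoexistencePoint]:
    """One equal-occupancy point per threshold value; misses are dropped.

    The curve ends where the two modes merge: thresholds past the critical
    value simply return no point.
    """
    rng = np.random.default_rng(rng)
    points = []
    for T in T_grid:
        pt = find_coexistence_point(c, p_ee, T, pqe_bracket, rng, **kwargs)
        if pt is not None:
            points.append(pt)
    return points


def is_bimodal_at(
    c: Connectome,
    params: ModelParams,
    rng: np.random.Generator | int | None = None,
    n_realizations: int = 3,
) -> bool:
    """Whether the activity PDF at this parameter setting is bimodal."""
    rng = np.random.default_rng(rng)
    sampler = _make_sampler(c, params.p_ee, params.threshold, rng,
                            n_realizations, params.steps, params.transient)
    return fit_activity_modes(sampler(params.p_qe)).bimodal


def find_critical_point(
    c: Connectome,
    p_ee: float,
    threshold: float | None = None,
    T_bracket: tuple[float, float] | None = None,
    pqe_bracket: tuple[float, float] = (0.0, 0.6),
    pqe_resolution: float = 0.005,
    refine_resolution: float = 0.001,
    rng: np.random.Generator | int | None = None,
    n_realizations: int = 3,
    steps: int = 10_000,
    transient: int = 1000,
    T_tol: float = 0.05,
) -> CriticalPoint:
    """Locate the critical point for a fixed persistence probability.

    When ``threshold`` is None, first bisects ``T_bracket`` for the largest
    threshold at which the activity PDF is still bimodal somewhere in
    ``pqe_bracket`` (the end of the coexistence curve).  Then scans the
    noise level around the transition at ``pqe_resolution``, selects the
    point with skewness nearest zero, negative excess kurtosis and maximal
    autocorrelation time, refines the scan at ``refine_resolution`` around
    it, and reports the refined point with its diagnostics and the coarse
    scan attached.
    """
    rng = np.random.default_rng(rng)
    if threshold is None:
        if T_bracket is None:
            raise ValueError("give either a threshold or a T_bracket")
        lo, hi = T_bracket

        def has_coexistence(T: float) -> bool:
            return find_coexistence_point(
                c, p_ee, T, pqe_bracket, rng,
                n_realizations=n_realizations, steps=steps, transient=transient,
            ) is not None

        if not has_coexistence(lo):
            raise ValueError(f"no coexistence at the lower threshold bracket {lo}")
        while hi - lo > T_tol:
            mid = 0.5 * (lo + hi)
            if has_coexistence(mid):
                lo = mid
            else:
                hi = mid
        threshold = lo

    # centre the noise scan on the transition found by a cheap sweep
    grid = _transition_window(
        c, p_ee, threshold, pqe_bracket, rng,
        steps=max(steps // 4, 1000), transient=transient,
        step=pqe_resolution, half=max(10 * pqe_resolution, 0.05),
    )
    scan = _scan_points(c, p_ee, threshold, grid, rng, n_realizations, steps,
                        transient)
    best = select_critical(scan)
    p_best = scan[best].params.p_qe
    if refine_resolution < pqe_resolution:
        flo = max(pqe_bracket[0], p_best - pqe_resolution)
        fhi = min(pqe_bracket[1], p_best + pqe_resolution)
        fine_grid = np.arange(flo, fhi + refine_resolution / 2, refine_resolution)
        fine = _scan_points(c, p_ee, threshold, fine_grid, rng, n_realizations,
                            steps, transient)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fbest = select_critical(fine)
        diag = fine[fbest]
        p_best = diag.params.p_qe
    else:
        diag = scan[best]
    return CriticalPoint(p_ee, float(threshold), float(p_best), diag, scan)
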