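import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from srnet import Connectome
from srnet.dynamics import ModelParams, SignalProtocol
from srnet.similarity import (
    RESIDUAL_FLOOR,
    Spectrum,
    deaf_nodes,
    lambda_factor,
    power_spectrum,
    similarity,
    similarity_matrix,
    sr_curve,
    summarize,
    SimilarityMatrix,
)

CAP = -np.log(RESIDUAL_FLOOR)


def spec_from(amps):
    """Spectrum with the given amplitudes, all bins principal."""
    amps = np.asarray(amps, dtype=float)
    freqs = np.arange(1, amps.size + 1) / (2.0 * amps.size)
    return Spectrum(freqs, amps, amps > 0)


class TestPowerSpectrum:
    def test_constant_series_has_no_principal_frequencies(self):
        s = power_spectrum(np.ones(500))
        assert np.allclose(s.amps, 0)
        assert s.n_principal == 0

    def test_square_wave_odd_harmonics(self):
        """A period-50 square wave has principal bins at 1/50 and odd
        harmonics, the third harmonic at exactly 1/3 of the fundamental."""
        t = np.arange(1000)
        s = power_spectrum(((t % 50) < 25).astype(float))
        fund = np.argmin(np.abs(s.freqs - 1 / 50))
        third = np.argmin(np.abs(s.freqs - 3 / 50))
        second = np.argmin(np.abs(s.freqs - 2 / 50))
        assert s.principal[fund] and s.principal[third]
        assert not s.principal[second]
        # exact discrete amplitudes: amp(m) = 1 / (P sin(pi m / P)) for odd
        # harmonics of a half-duty square wave of period P; the third/first
        # ratio approaches 1/3 in the continuum limit
        assert s.amps[fund] == pytest.approx(1 / (50 * np.sin(np.pi / 50)))
        assert s.amps[third] == pytest.approx(1 / (50 * np.sin(3 * np.pi / 50)))
        assert s.amps[third] / s.amps[fund] == pytest.approx(1 / 3, rel=0.01)

    def test_two_sinusoids_two_principal_bins(self):
        t = np.arange(1000)
        x = 0.3 * np.sin(2 * np.pi * t / 100) + 0.2 * np.sin(2 * np.pi * t / 20)
        s = power_spectrum(x)
        assert s.n_principal == 2
        assert np.allclose(sorted(s.freqs[s.principal]), [1 / 100, 1 / 20])

    def test_series_too_short(self):
        with pytest.raises(ValueError, match="short"):
            power_spectrum(np.ones(2))


class TestSimilarityAlgebra:
    def test_worked_example(self):
        """phi_i = (2,1), phi_j = (1,2): lambda = 1 and sim = log 3."""
        i, j = spec_from([2, 1]), spec_from([1, 2])
        assert lambda_factor(i, j) == pytest.approx(1.0)
        assert similarity(i, j) == pytest.approx(np.log(3.0))

    def test_identical_spectra_reach_cap(self):
        i = spec_from([2, 1])
        assert lambda_factor(i, i) == pytest.approx(1.0)
        assert similarity(i, i) == pytest.approx(CAP)

    @pytest.mark.parametrize("c", [0.5, 2.0, 8.0])
    def test_rescaled_output_lambda_absorbs_scale(self, c):
        i = spec_from([2, 1, 0.5])
        j = spec_from(np.array([2, 1, 0.5]) * c)
        assert lambda_factor(i, j) == pytest.approx(1 / c)
        assert similarity(i, j) == pytest.approx(CAP)

    @pytest.mark.parametrize("c", [2.0, 0.25])
    def test_scale_invariance_binary_exact(self, c):
        rng = np.random.default_rng(0)
        i = spec_from(rng.random(8) + 0.1)
        j_amps = rng.random(8) + 0.1
        assert similarity(i, spec_from(j_amps)) == similarity(i, spec_from(c * j_amps))

    def test_scale_invariance_general(self):
        rng = np.random.default_rng(1)
        i = spec_from(rng.random(8) + 0.1)
        j_amps = rng.random(8) + 0.1
        base = similarity(i, spec_from(j_amps))
        for c in [0.37, 3.7, 123.4]:
            assert similarity(i, spec_from(c * j_amps)) == pytest.approx(base, rel=1e-9)

    def test_lambda_matches_numerical_argmin(self):
        """The closed form coincides with the numerical minimizer of the
        weighted squared spectral difference, over 100 random spectra."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            pi = rng.random(6) + 0.05
            pj = rng.random(6) + 0.05
            i, j = spec_from(pi), spec_from(pj)
            objective = lambda lam: float(((pi - lam * pj) ** 2 @ pi))
            res = minimize_scalar(objective, bounds=(0, 50), method="bounded",
                                  options={"xatol": 1e-10})
            assert lambda_factor(i, j) == pytest.approx(res.x, abs=1e-5)

    def test_zero_output_gives_minimal_similarity(self):
        i = spec_from([2, 1])
        j = Spectrum(i.freqs, np.zeros(2), np.zeros(2, dtype=bool))
        assert lambda_factor(i, j) == 0.0
        assert similarity(i, j) == pytest.approx(0.0)

    def test_no_principal_frequencies_undefined(self):
        i = Spectrum(np.array([0.1, 0.2]), np.zeros(2), np.zeros(2, dtype=bool))
        assert np.isnan(similarity(i, i))
        with pytest.raises(ValueError):
            lambda_factor(i, i)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            lambda_factor(spec_from([1, 2]), spec_from([1, 2, 3]))


class TestSimilarityMatrix:
    @pytest.fixture(scope="class")
    def net_with_isolate(self):
        # triangle 0-1-2 plus isolated node 3
        w = np.zeros((4, 4))
        for a, b in [(0, 1), (1, 2), (0, 2)]:
            w[a, b] = w[b, a] = 1.0
        return Connectome(w)

    def test_isolated_receiver_has_minimal_column(self, net_with_isolate):
        """With no path and no noise, an isolated node stays silent and its
        column similarity is the minimum (zero)."""
        params = ModelParams(0.0, 0.5, 0.8, transient=100, steps=400)
        mat = similarity_matrix(net_with_isolate, params, rng=3,
                                seeders=[0, 1, 2], n_realizations=2)
        col = np.nanmean(mat.values[[0, 1, 2], :], axis=0)
        assert col[3] == pytest.approx(0.0, abs=1e-9)
        assert col[3] <= np.nanmin(col[:3]) + 1e-12

    def test_determinism(self, net_with_isolate):
        params = ModelParams(0.2, 0.5, 0.8, transient=100, steps=400)
        a = similarity_matrix(net_with_isolate, params, rng=9, n_realizations=2)
        b = similarity_matrix(net_with_isolate, params, rng=9, n_realizations=2)
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_diagonal_and_unrun_rows_masked(self, net_with_isolate):
        params = ModelParams(0.2, 0.5, 0.8, transient=100, steps=400)
        mat = similarity_matrix(net_with_isolate, params, rng=9, seeders=[1])
        assert np.isnan(mat.values[1, 1])
        assert np.isnan(mat.values[0]).all()
        assert np.isfinite(mat.values[1, [0, 2, 3]]).all()

    def test_saturated_noise_rows_exchangeable(self, small_net):
        """At p_qe = 1 receivers ignore the seeder, so rows differ only by
        sampling noise."""
        params = ModelParams(1.0, 0.1, 2.0, transient=200, steps=2000)
        mat = similarity_matrix(small_net, params, rng=21, seeders=[0, 5, 10],
                                n_realizations=2)
        row_means = np.nanmean(mat.values[[0, 5, 10]], axis=1)
        assert np.ptp(row_means) < 0.1


class TestSummaries:
    def make_matrix(self, values, seeders):
        params = ModelParams(0.1, 0.1, 1.0, transient=0, steps=10)
        return SimilarityMatrix(np.asarray(values, dtype=float), params,
                                seeders=seeders)

    def test_hand_filled_three_by_three(self):
        nan = np.nan
        v = [[nan, 1.0, 2.0], [3.0, nan, 4.0], [5.0, 6.0, nan]]
        s = summarize(self.make_matrix(v, [0, 1, 2]))
        assert s["mean"] == pytest.approx(3.5)
        assert s["median"] == pytest.approx(3.5)
        assert np.allclose(s["row_means"], [1.5, 3.5, 5.5])
        assert np.allclose(s["col_means"], [4.0, 3.5, 3.0])

    def test_constant_matrix(self):
        v = np.full((3, 3), 2.0)
        np.fill_diagonal(v, np.nan)
        s = summarize(self.make_matrix(v, [0, 1, 2]))
        assert s["mean"] == 2.0 == s["median"]

    def test_all_masked_rejected(self):
        v = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            summarize(self.make_matrix(v, []))

    def test_distinct_row_detected(self):
        v = np.array([[np.nan, 5.0, 5.0], [1.0, np.nan, 1.0], [1.0, 1.0, np.nan]])
        s = summarize(self.make_matrix(v, [0, 1, 2]))
        assert s["row_means"][0] > s["row_means"][1]


class TestDeafNodes:
    def test_near_zero_column_flagged(self, line3):
        v = np.array([[np.nan, 1.0, 0.01], [1.0, np.nan, 0.01], [1.0, 1.0, np.nan]])
        mat = SimilarityMatrix(v, ModelParams(0.1, 0.1, 1.0), seeders=[0, 1, 2])
        deaf = deaf_nodes(mat, line3, quantile=0.4)
        assert deaf.node.tolist() == [2]
        assert deaf.strength.tolist() == [2.0]

    def test_deaf_nodes_at_criticality_are_weak(self, default_net):
        """At a near-critical setting the receivers that suppress the
        signal's principal frequencies are the low-strength nodes: every
        flagged deaf node sits below the median node strength."""
        params = ModelParams(0.33, 0.1, 5.2, transient=1000, steps=5000)
        mat = similarity_matrix(default_net, params, rng=55,
                                seeders=list(range(0, 114, 4)), n_realizations=2)
        deaf = deaf_nodes(mat, default_net)
        assert len(deaf) > 0
        assert (deaf.strength < np.median(default_net.strengths)).mean() > 0.8

    def test_uniform_matrix_flags_nothing(self, line3):
        v = np.full((3, 3), 1.0)
        np.fill_diagonal(v, np.nan)
        mat = SimilarityMatrix(v, ModelParams(0.1, 0.1, 1.0), seeders=[0, 1, 2])
        assert len(deaf_nodes(mat, line3)) == 0


class TestSRCurve:
    def test_single_point_grid(self, small_net):
        res = sr_curve(small_net, 0.1, 2.0, [0.2], rng=5, seeders=[0, 1],
                       n_realizations=1, steps=1000, transient=200)
        assert len(res.table) == 1
        assert res.peak_mean == 0.2

    def test_interior_noise_beats_extremes_near_criticality(self, default_net):
        """Stochastic resonance: at a near-critical threshold an intermediate
        noise level transmits the signal better than both the quiet and the
        saturated regimes."""
        res = sr_curve(default_net, 0.1, 5.2, [0.05, 0.33, 0.9], rng=17,
                       seeders=[3, 30, 60, 90], n_realizations=1,
                       steps=2500, transient=500)
        sims = res.table.mean_sim.to_numpy()
        assert sims[1] > sims[0]
        assert sims[1] > sims[2]
        assert res.peak_mean == 0.33
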