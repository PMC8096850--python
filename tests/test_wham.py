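"""WHAM estimator: unit behavior, oracle equivalence, invariances."""

import numpy as np
import pytest
from scipy.special import erf

from cptk.structio import TimeSeries
from cptk.synth import double_well_pmf, flat_pmf, sample_windows
from cptk.wham import (
    AVOGADRO,
    BOLTZMANN_SI,
    DisconnectedSamplingError,
    KCAL_PER_MOL_JOULE,
    PMFResult,
    ThermoState,
    UmbrellaSampling,
    UmbrellaWindow,
    barrier_report,
    bias_potential,
    build_histograms,
    convergence_profile,
    make_windows,
    smooth_pmf,
    wham_solve,
)


def brute_force_wham(counts, n_i, edges, windows, beta, tol=1e-10,
                     max_iter=2_000_000):
    """Independent fixed-point WHAM oracle (scalar loops, own weights).

    Uses the same binned-likelihood weight definition (bin-averaged
    harmonic Boltzmann factor via erf) but a completely separate direct
    iteration in plain probability space.
    """
    counts = np.asarray(counts, float)
    n_bins = counts.size
    width = edges[1] - edges[0]
    W = np.zeros((len(windows), n_bins))
    for i, w in enumerate(windows):
        for k in range(n_bins):
            if w.force_const <= 0:
                W[i, k] = 1.0
            else:
                s = np.sqrt(0.5 * beta * w.force_const)
                lo = s * (edges[k] - w.anchor)
                hi = s * (edges[k + 1] - w.anchor)
                W[i, k] = np.sqrt(np.pi) / (2 * s * width) * (erf(hi) - erf(lo))
    f = np.ones(len(windows))
    for _ in range(max_iter):
        denom = np.zeros(n_bins)
        for i in range(len(windows)):
            denom += n_i[i] * W[i] / f[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(denom > 0, counts / denom, 0.0)
        f_new = W @ P
        f_new /= f_new[0]
        if np.max(np.abs(np.log(f_new / f))) / beta < tol:
            f = f_new
            break
        f = f_new
    denom = np.zeros(n_bins)
    for i in range(len(windows)):
        denom += n_i[i] * W[i] / f[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(denom > 0, counts / denom, 0.0)
    P /= P.sum() * width
    with np.errstate(divide="ignore"):
        A = np.where(P > 0, -np.log(np.where(P > 0, P, 1.0)) / beta, np.inf)
    A -= A[np.isfinite(A)].min()
    return A


def tiny_problem(seed=0, n_windows=3):
    """A small overlapping umbrella problem (<= 12 populated 0.5 A bins)."""
    pmf = flat_pmf(domain=(-2.0, 2.0))
    anchors = np.linspace(-0.6, 0.6, n_windows)
    windows = [UmbrellaWindow(a, 20.0) for a in anchors]
    return sample_windows(pmf, windows, n_steps=2000, method="exact",
                          seed=seed)


class TestBiasPotential:
    def test_zero_at_anchor(self):
        w = UmbrellaWindow(3.0, 20.0)
        assert bias_potential(3.0, w) == 0.0

    @pytest.mark.parametrize("dq,expected", [(1.0, 10.0), (0.5, 2.5)])
    def test_harmonic_values(self, dq, expected):
        w = UmbrellaWindow(0.0, 20.0)
        assert bias_potential(dq, w) == pytest.approx(expected)


class TestThermo:
    def test_kT_at_310K(self):
        th = ThermoState(310.0)
        expected = BOLTZMANN_SI * AVOGADRO * 310.0 / KCAL_PER_MOL_JOULE
        assert th.kT == pytest.approx(expected)
        assert th.kT == pytest.approx(0.616, abs=1e-3)
        assert th.beta * th.kT == pytest.approx(1.0)

    def test_bad_temperature(self):
        with pytest.raises(ValueError):
            ThermoState(0.0)


class TestWindows:
    def test_standard_protocol_grid(self):
        ws = make_windows(55.0, -55.0, 1.0, replicas=5)
        anchors = sorted({w.anchor for w in ws})
        assert len(anchors) == 111  # both ends inclusive
        assert len(ws) == 111 * 5
        assert anchors[0] == -55.0 and anchors[-1] == 55.0

    def test_degenerate_spans(self):
        assert len(make_windows(3.0, 3.0, 1.0, replicas=1)) == 1
        ws = make_windows(0.0, 1.0, 5.0, replicas=1)
        assert sorted(w.anchor for w in ws) == [0.0, 1.0]

    def test_bad_interval(self):
        with pytest.raises(ValueError):
            make_windows(1.0, -1.0, 0.0)


class TestHistograms:
    def test_conservation(self):
        rng = np.random.default_rng(1)
        windows = [
            UmbrellaWindow(0.0, 1.0, TimeSeries(np.arange(1, 51) * 0.1,
                                                rng.normal(size=50))),
            UmbrellaWindow(1.0, 1.0, TimeSeries(np.arange(1, 31) * 0.1,
                                                rng.normal(1, 1, size=30))),
        ]
        counts, n_i, edges = build_histograms(windows, 0.5)
        assert counts.sum() == n_i.sum() == 80

    def test_edge_sample_counted_right(self):
        w = UmbrellaWindow(0.0, 1.0, TimeSeries([0.1, 0.2], [0.5, 0.2]))
        counts, _, edges = build_histograms([w], 0.5)
        k = int(np.floor((0.5 - edges[0]) / 0.5))
        assert counts[k] == 1  # the 0.5 sample sits in the right-hand bin

    def test_empty_window_warns(self):
        w1 = UmbrellaWindow(0.0, 1.0, TimeSeries([0.1], [0.0]))
        w2 = UmbrellaWindow(1.0, 1.0, None)
        with pytest.warns(UserWarning, match="no samples"):
            counts, n_i, _ = build_histograms([w1, w2], 0.5)
        assert n_i[1] == 0


class TestSolver:
    def test_oracle_equivalence_on_tiny_problems(self):
        """Iterative solver vs independent brute-force fixed point."""
        th = ThermoState()
        for seed in range(3):
            sampled = tiny_problem(seed)
            hist = build_histograms(sampled, 0.5)
            res = wham_solve(hist, sampled, thermo=th, tol=1e-12,
                             n_refine=0, max_iter=2_000_000)
            assert hist[0].size <= 12
            oracle = brute_force_wham(hist[0], hist[1], hist[2], sampled,
                                      th.beta)
            pop = np.isfinite(res.pmf)
            assert np.max(np.abs(res.pmf[pop] - oracle[pop])) < 1e-6

    def test_single_unbiased_window_flat(self):
        rng = np.random.default_rng(0)
        q = rng.uniform(0, 4, size=4000)
        w = UmbrellaWindow(0.0, 0.0, TimeSeries(np.arange(1, 4001) * 0.1, q))
        res = UmbrellaSampling([w], bin_width=1.0).fit()
        pop = np.isfinite(res.pmf)
        # uniform unbiased sampling: A constant (0 after anchoring) up to noise
        assert np.max(np.abs(res.pmf[pop])) < 0.05

    def test_flat_pmf_null(self):
        """Exact biased-Gaussian samples recover a flat PMF."""
        pmf = flat_pmf(domain=(-10.0, 10.0))
        wins = make_windows(10.0, -10.0, 0.5, replicas=5, force_const=20.0)
        sampled = sample_windows(pmf, wins, n_steps=10_000, method="exact",
                                 seed=1)
        res = UmbrellaSampling(sampled, bin_width=0.5).fit()
        pop = np.isfinite(res.pmf)
        inside = pop & (np.abs(res.bin_centers) <= 10.0)
        assert np.max(np.abs(res.pmf[inside])) < 0.2

    def test_duplication_invariance(self):
        sampled = tiny_problem(2)
        res1 = UmbrellaSampling(sampled, bin_width=0.5).fit()
        doubled = sampled + [
            UmbrellaWindow(w.anchor, w.force_const, w.series, w.replica + 10)
            for w in sampled
        ]
        res2 = UmbrellaSampling(doubled, bin_width=0.5).fit()
        pop = np.isfinite(res1.pmf)
        assert np.allclose(res1.pmf[pop], res2.pmf[pop], atol=1e-6)

    def test_disconnected_sampling_error(self):
        rng = np.random.default_rng(0)
        left = UmbrellaWindow(
            -20.0, 20.0,
            TimeSeries(np.arange(1, 501) * 0.1,
                       -20 + 0.2 * rng.standard_normal(500)))
        right = UmbrellaWindow(
            20.0, 20.0,
            TimeSeries(np.arange(1, 501) * 0.1,
                       20 + 0.2 * rng.standard_normal(500)))
        with pytest.raises(DisconnectedSamplingError):
            UmbrellaSampling([left, right], bin_width=0.5).fit()

    def test_probability_normalization_and_anchor(self):
        sampled = tiny_problem(3)
        res = UmbrellaSampling(sampled, bin_width=0.5).fit()
        pop = np.isfinite(res.pmf)
        assert np.sum(res.prob[pop]) * res.bin_width == pytest.approx(1.0)
        assert res.pmf[pop].min() == pytest.approx(0.0, abs=1e-12)
        assert res.converged

    def test_summary_mentions_key_quantities(self):
        res = UmbrellaSampling(tiny_problem(0), bin_width=0.5).fit()
        s = res.summary()
        assert "kT = 0.616" in s
        assert "barrier" in s


class TestSmoothing:
    def _result_from_profile(self, q, a):
        p = np.exp(-a / 0.616)
        p /= p.sum() * (q[1] - q[0])
        return PMFResult(q, a - a.min(), p, np.zeros(1), 1, True,
                         ThermoState(), float(q[1] - q[0]))

    def test_quadratic_is_fixed_point(self):
        q = np.linspace(-5, 5, 21)
        res = self._result_from_profile(q, q**2)
        sm = smooth_pmf(res, 5)
        assert np.allclose(sm, res.pmf, atol=1e-9)

    def test_constant_preserved(self):
        q = np.linspace(-5, 5, 11)
        res = self._result_from_profile(q, np.full(11, 2.0))
        assert np.allclose(smooth_pmf(res, 5), 0.0, atol=1e-9)

    def test_wide_window_is_global_fit(self):
        q = np.linspace(-3, 3, 7)
        a = 0.5 * q**2 + 0.1 * np.sin(q)
        res = self._result_from_profile(q, a)
        sm = smooth_pmf(res, 99)
        coef = np.polyfit(q, res.pmf, 2)
        assert np.allclose(sm, np.polyval(coef, q), atol=1e-9)

    def test_noise_reduction_on_double_well(self):
        pmf = double_well_pmf()
        q = np.arange(-10.75, 11.0, 0.5)
        truth = pmf(q)
        truth = truth - truth.min()
        rng = np.random.default_rng(5)
        noisy = truth + 0.15 * rng.standard_normal(q.size)
        res = self._result_from_profile(q, noisy - noisy.min())
        sm = smooth_pmf(res, 7)
        raw_err = np.sum((res.pmf - truth) ** 2)
        sm_err = np.sum((sm - truth) ** 2)
        assert sm_err < raw_err


class TestConvergenceProfile:
    def test_full_block_zero_deviation(self):
        sampled = tiny_problem(1)
        t_end = float(sampled[0].series.times[-1])
        _, devs = convergence_profile(sampled, [t_end])
        assert devs[0] == pytest.approx(0.0, abs=1e-9)

    def test_deviation_nonincreasing_with_block_length(self):
        pmf = double_well_pmf()
        wins = make_windows(11.0, -11.0, 1.0, replicas=1, force_const=20.0)
        sampled = sample_windows(pmf, wins, n_steps=4000, seed=7)
        t_end = float(sampled[0].series.times[-1])
        _, devs = convergence_profile(
            sampled, [0.25 * t_end, 0.5 * t_end, t_end])
        assert devs[-1] <= devs[0] + 1e-9
        assert devs[-1] == pytest.approx(0.0, abs=1e-9)


class TestBarrierReport:
    def _result(self, q, a):
        p = np.exp(-(a - a.min()) / 0.616)
        p /= p.sum() * (q[1] - q[0])
        return PMFResult(q, a - a.min(), p, np.zeros(1), 1, True,
                         ThermoState(), float(q[1] - q[0]))

    def test_flat_profile_no_peaks(self):
        q = np.arange(-5, 5.1, 0.5)
        assert barrier_report(self._result(q, np.zeros(q.size))) == []

    def test_two_known_peaks_in_z_order(self):
        q = np.arange(-20, 20.1, 0.5)
        a = 5.0 * np.exp(-((q + 10) ** 2) / 8) + 3.0 * np.exp(-((q - 8) ** 2) / 8)
        peaks = barrier_report(self._result(q, a), prominence=0.5)
        assert len(peaks) == 2
        assert peaks[0].z < peaks[1].z
        assert peaks[0].height == pytest.approx(5.0, abs=0.2)
        assert peaks[1].height == pytest.approx(3.0, abs=0.2)

    def test_peak_mapped_to_waist_residues(self, two_waist):
        from cptk.pore import channel_axis

        q = np.arange(-18, 18.1, 0.5)
        a = 5.0 * np.exp(-((q + 12) ** 2) / 8)
        axis = channel_axis(two_waist)
        peaks = barrier_report(self._result(q, a), two_waist, axis,
                               prominence=0.5, slab_half_width=1.0)
        assert len(peaks) == 1
        resids = {r[1] for r in peaks[0].residues}
        # ring residue indices at construction z ~ -12 (rings start at z=-20)
        assert 9 in resids
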