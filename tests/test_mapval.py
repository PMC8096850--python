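"""Model-map synthesis, FSC, cross-validation, local fit, local scaling."""

import numpy as np
import pytest

from cptk.mapval import (
    BETTER_THAN_NYQUIST,
    FSCCurve,
    crossval_fsc,
    fsc,
    local_fit_z,
    local_scale,
    model_to_map,
    perturb_model,
    resolution_at,
)
from cptk.structio import Atom, AtomicModel, DensityMap
from cptk.synth import helix_model, synth_map


def direct_fsc_oracle(a, b):
    """Brute-force discrete-Fourier FSC for tiny grids."""
    n = a.shape[0]
    idx = np.arange(n)
    x, y, z = np.meshgrid(idx, idx, idx, indexing="ij")

    def dft(v):
        out = np.zeros((n, n, n), complex)
        for kx in range(n):
            for ky in range(n):
                for kz in range(n):
                    ph = np.exp(-2j * np.pi * (kx * x + ky * y + kz * z) / n)
                    out[kx, ky, kz] = np.sum(v * ph)
        return out

    fa, fb = dft(a), dft(b)
    freqs = np.fft.fftfreq(n, 1.0)
    fx, fy, fz = np.meshgrid(freqs, freqs, freqs, indexing="ij")
    shell = np.round(np.sqrt(fx**2 + fy**2 + fz**2) * n).astype(int)
    corr = []
    for s in range(shell.max() + 1):
        m = shell == s
        cross = np.sum((fa[m] * np.conj(fb[m])).real)
        denom = np.sqrt(np.sum(np.abs(fa[m]) ** 2) * np.sum(np.abs(fb[m]) ** 2))
        corr.append(cross / denom)
    return np.array(corr)


class TestModelToMap:
    def test_single_atom_max_at_voxel(self):
        m = AtomicModel([Atom("A", 1, "GLY", "CA", "C", [5.0, 5.0, 5.0])])
        dmap = model_to_map(m, (11, 11, 11), 1.0, np.zeros(3), blur_width=1.5)
        assert np.unravel_index(np.argmax(dmap.values), dmap.shape) == (5, 5, 5)

    def test_mirror_symmetry(self):
        m = AtomicModel([
            Atom("A", 1, "GLY", "CA", "C", [3.0, 5.0, 5.0]),
            Atom("A", 2, "GLY", "CA", "C", [7.0, 5.0, 5.0]),
        ])
        dmap = model_to_map(m, (11, 11, 11), 1.0, np.zeros(3), blur_width=1.5)
        assert np.allclose(dmap.values, dmap.values[::-1, :, :], atol=1e-12)

    def test_total_mass_equals_atom_count(self):
        rng = np.random.default_rng(3)
        atoms = [Atom("A", i + 1, "GLY", "CA", "C",
                      20 + rng.uniform(-5, 5, 3)) for i in range(100)]
        dmap = model_to_map(AtomicModel(atoms), (40, 40, 40), 1.0,
                            np.zeros(3), blur_width=2.0)
        assert dmap.values.sum() == pytest.approx(100.0, rel=1e-3)

    def test_out_of_grid_atom_warns(self):
        m = AtomicModel([Atom("A", 1, "GLY", "CA", "C", [100.0, 5.0, 5.0])])
        with pytest.warns(UserWarning, match="beyond the grid"):
            dmap = model_to_map(m, (11, 11, 11), 1.0, np.zeros(3), 2.0)
        assert dmap.values.sum() < 1.0


class TestFSC:
    def test_self_correlation_is_one(self, helix_map):
        c = fsc(helix_map, helix_map)
        populated = np.asarray(c.n_voxels) > 0
        assert np.allclose(c.correlation[populated], 1.0, atol=1e-12)

    def test_sign_flip_is_minus_one(self, helix_map):
        neg = DensityMap(-helix_map.values, helix_map.voxel_size,
                         helix_map.origin)
        c = fsc(helix_map, neg)
        populated = np.asarray(c.n_voxels) > 0
        assert np.allclose(c.correlation[populated], -1.0, atol=1e-12)

    def test_against_direct_dft_oracle(self):
        rng = np.random.default_rng(0)
        a = DensityMap(rng.standard_normal((8, 8, 8)), 1.0)
        b = DensityMap(rng.standard_normal((8, 8, 8)), 1.0)
        curve = fsc(a, b)
        oracle = direct_fsc_oracle(a.values, b.values)
        assert np.max(np.abs(curve.correlation - oracle)) <= 1e-10

    def test_symmetric_and_scale_invariant(self):
        rng = np.random.default_rng(1)
        a = DensityMap(rng.standard_normal((10, 10, 10)), 1.0)
        b = DensityMap(rng.standard_normal((10, 10, 10)), 1.0)
        c_ab = fsc(a, b).correlation
        c_ba = fsc(b, a).correlation
        scaled = DensityMap(7.5 * b.values, b.voxel_size, b.origin)
        c_scaled = fsc(a, scaled).correlation
        assert np.allclose(c_ab, c_ba, atol=1e-12)
        assert np.allclose(c_ab, c_scaled, atol=1e-10)

    def test_mask_applied(self, helix_map):
        rng = np.random.default_rng(2)
        noisy = DensityMap(
            helix_map.values + 0.3 * helix_map.values.std()
            * rng.standard_normal(helix_map.shape),
            helix_map.voxel_size, helix_map.origin)
        mask = DensityMap((helix_map.values > 0.05 * helix_map.values.max())
                          .astype(float), helix_map.voxel_size,
                          helix_map.origin)
        unmasked = fsc(helix_map, noisy)
        masked = fsc(helix_map, noisy, mask)
        # masking away empty solvent raises mid-frequency correlation
        assert masked.correlation[2:8].mean() >= unmasked.correlation[2:8].mean()

    def test_grid_mismatch_rejected(self):
        a = DensityMap(np.zeros((4, 4, 4)), 1.0)
        b = DensityMap(np.zeros((5, 5, 5)), 1.0)
        with pytest.raises(ValueError):
            fsc(a, b)


class TestResolutionAt:
    def test_never_crossing_gives_sentinel(self):
        c = FSCCurve(np.arange(5) * 0.05, np.ones(5), np.ones(5, int),
                     [""] * 5)
        assert resolution_at(c, 0.143) == BETTER_THAN_NYQUIST

    def test_known_crossing_interpolated(self):
        freq = np.array([0.0, 0.1, 0.2, 0.3])
        corr = np.array([1.0, 1.0, 0.5, 0.0])
        c = FSCCurve(freq, corr, np.ones(4, int), [""] * 4)
        # crosses 0.25 halfway between 0.2 and 0.3 -> 1/0.25 = 4 A
        assert resolution_at(c, 0.25) == pytest.approx(4.0)

    def test_threshold_above_all_gives_coarsest_shell(self):
        freq = np.array([0.0, 0.1, 0.2])
        corr = np.array([1.0, 0.4, 0.3])
        c = FSCCurve(freq, corr, np.ones(3, int), [""] * 3)
        assert resolution_at(c, 0.9) == pytest.approx(10.0)


class TestPerturbModel:
    def test_zero_displacement_identity(self, helix):
        p = perturb_model(helix, 0.0, seed=3)
        assert np.allclose(p.coords, helix.coords)

    def test_norm_bound_and_reproducibility(self, helix):
        p1 = perturb_model(helix, 0.5, seed=7)
        p2 = perturb_model(helix, 0.5, seed=7)
        p3 = perturb_model(helix, 0.5, seed=8)
        d = np.linalg.norm(p1.coords - helix.coords, axis=1)
        assert np.all(d <= 0.5 + 1e-12)
        assert d.max() > 0.2  # not degenerate
        assert np.array_equal(p1.coords, p2.coords)
        assert not np.array_equal(p1.coords, p3.coords)


class TestCrossval:
    def test_identical_halves_zero_gap(self, helix):
        full = synth_map(helix, voxel_size=1.5, blur_width=2.0, pad=8)
        c1, c2, cf, gap = crossval_fsc(helix, full, full, full,
                                       blur_width=2.0)
        assert gap == 0.0
        pop = np.asarray(cf.n_voxels) > 0
        assert np.all(cf.correlation[pop] > 0.99)

    def test_signal_free_half_opens_gap(self, helix):
        h1 = synth_map(helix, voxel_size=1.5, blur_width=2.0, noise_sd=0.002,
                       seed=1, pad=8)
        rng = np.random.default_rng(2)
        h2 = DensityMap(0.002 * rng.standard_normal(h1.shape),
                        h1.voxel_size, h1.origin)
        full = synth_map(helix, voxel_size=1.5, blur_width=2.0, pad=8)
        _, _, _, gap = crossval_fsc(helix, h1, h2, full, blur_width=2.0)
        assert gap > 0.5

    def test_perturbation_degrades_resolution_monotonically(self, helix):
        full = synth_map(helix, voxel_size=1.5, blur_width=2.0, pad=8)
        res = []
        for disp in (0.0, 1.0, 2.0):
            vals = []
            for seed in (0, 1, 2):
                test = perturb_model(helix, disp, seed=seed)
                tmap = model_to_map(test, full.shape, full.voxel_size,
                                    full.origin, 2.0)
                curve = fsc(tmap, full)
                r = resolution_at(curve, 0.5)
                if np.isinf(r):  # agrees out to the finest shell
                    r = 1.0 / curve.freq[-1]
                vals.append(r)
            res.append(np.mean(vals))
        assert res[0] <= res[1] + 1e-9 <= res[2] + 2e-9


class TestLocalFitZ:
    def test_self_map_degenerate_pooling(self, helix):
        m = synth_map(helix, voxel_size=1.5, blur_width=2.0, pad=10)
        with pytest.warns(UserWarning, match="degenerate"):
            z = local_fit_z(helix, m, blur_width=2.0)
        assert all(v == 0.0 for v in z.values())

    def test_displaced_residue_ranks_last_and_moments(self, helix):
        m = synth_map(helix, voxel_size=1.5, blur_width=2.0, pad=10)
        shifted = AtomicModel([
            Atom(a.chain, a.resid, a.resname, a.name, a.element,
                 a.xyz + (np.array([5.0, 0.0, 0.0]) if a.resid == 15 else 0.0),
                 vdw=a.vdw)
            for a in helix.atoms
        ])
        z = local_fit_z(shifted, m, blur_width=2.0)
        vals = np.array(list(z.values()))
        keys = list(z.keys())
        assert keys[int(np.argmin(vals))] == ("A", 15)
        assert vals.mean() == pytest.approx(0.0, abs=1e-9)
        assert vals.std() == pytest.approx(1.0, abs=1e-9)

    def test_sliding_window_scores(self, helix):
        m = synth_map(helix, voxel_size=1.5, blur_width=2.0, pad=10)
        shifted = AtomicModel([
            Atom(a.chain, a.resid, a.resname, a.name, a.element,
                 a.xyz + (np.array([5.0, 0.0, 0.0]) if a.resid == 15 else 0.0),
                 vdw=a.vdw)
            for a in helix.atoms
        ])
        z = local_fit_z(shifted, m, blur_width=2.0, window=3)
        vals = np.array(list(z.values()))
        assert vals.mean() == pytest.approx(0.0, abs=1e-9)
        # misfit spreads over the window but residue 15 stays at the minimum
        keys = list(z.keys())
        assert keys[int(np.argmin(vals))][1] in (14, 15, 16)


class TestLocalScale:
    def test_identity(self, helix_map):
        out = local_scale(helix_map, helix_map, window=20.0)
        denom = np.abs(helix_map.values).max()
        assert np.abs(out.values - helix_map.values).max() / denom < 1e-6

    def test_uniform_scale_recovery(self, helix_map):
        exp = DensityMap(0.5 * helix_map.values, helix_map.voxel_size,
                         helix_map.origin)
        out = local_scale(exp, helix_map, window=20.0)
        ref_amp = np.abs(np.fft.fftn(helix_map.values))
        out_amp = np.abs(np.fft.fftn(out.values))
        strong = ref_amp > 0.01 * ref_amp.max()
        assert np.allclose(out_amp[strong], ref_amp[strong], rtol=0.05)
        corr = np.corrcoef(out.values.ravel(), exp.values.ravel())[0, 1]
        assert corr > 0.99

    def test_grid_mismatch_rejected(self, helix_map):
        other = DensityMap(np.zeros((4, 4, 4)), 1.0)
        with pytest.raises(ValueError):
            local_scale(helix_map, other)
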