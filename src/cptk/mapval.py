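"""Model/map validation: model-derived density synthesis, Fourier shell
correlation (FSC), perturbation cross-validation against half maps,
per-residue Z-scored local fit, and simplified windowed local amplitude
scaling.

Model-derived maps place a unit-mass isotropic Gaussian of width sigma
(default 3.15 A, interpreted as the standard deviation) on every atom,
truncated at 4 sigma.  FSC is the per-shell normalized cross-power of the
two maps' discrete Fourier transforms; resolution is read off where the
curve first crosses a threshold (0.143 for half maps, 0.5 for map-model,
by convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from cptk.structio import AtomicModel, Atom, DensityMap

__all__ = [
    "FSCCurve",
    "model_to_map",
    "fsc",
    "resolution_at",
    "perturb_model",
    "crossval_fsc",
    "local_fit_z",
    "local_scale",
    "BETTER_THAN_NYQUIST",
]

#: Sentinel returned by :func:`resolution_at` when the curve never drops
#: below the threshold: the map pair agrees out to the grid's Nyquist limit.
BETTER_THAN_NYQUIST = float("inf")

#: Gaussian truncation radius for atom splatting, in sigmas.
SPLAT_TRUNCATION = 4.0


@dataclass
class FSCCurve:
    """Per-shell correlation between two maps.

    ``freq`` shell-center spatial frequencies in 1/A (increasing),
    ``correlation`` in [-1, 1], ``n_voxels`` voxel count per shell, and
    ``flags`` marking zero-power shells (correlation recorded as 0).
    """

    freq: np.ndarray
    correlation: np.ndarray
    n_voxels: np.ndarray
    flags: list[str]

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, float)
        self.correlation = np.asarray(self.correlation, float)
        self.n_voxels = np.asarray(self.n_voxels, int)
        if np.any(np.diff(self.freq) <= 0):
            raise ValueError("frequencies must be increasing")
        if np.any(np.abs(self.correlation) > 1 + 1e-9):
            raise ValueError("|correlation| must be <= 1")


def model_to_map(
    model: AtomicModel,
    shape: tuple[int, int, int],
    voxel_size: float | np.ndarray,
    origin: np.ndarray | None = None,
    blur_width: float = 3.15,
) -> DensityMap:
    """Gaussian-blurred model density on the given grid.

    Each atom contributes a unit-mass isotropic Gaussian of standard
    deviation ``blur_width``, truncated at 4 sigma, so the total grid mass
    approximates the atom count.  Atoms whose truncation sphere leaves the
    grid contribute only their in-grid mass (with a warning).
    """
    if blur_width <= 0:
        raise ValueError("blur_width must be positive")
    voxel = np.broadcast_to(np.asarray(voxel_size, float), (3,)).copy()
    if origin is None:
        origin = np.zeros(3)
    origin = np.asarray(origin, float)
    values = np.zeros(shape, dtype=np.float64)
    r = SPLAT_TRUNCATION * blur_width
    norm = voxel.prod() / ((2 * np.pi) ** 1.5 * blur_width**3)
    axes = [origin[a] + np.arange(shape[a]) * voxel[a] for a in range(3)]
    clipped = 0
    for pos in model.coords:
        sl = []
        oob = False
        for a in range(3):
            lo = int(np.ceil((pos[a] - r - origin[a]) / voxel[a]))
            hi = int(np.floor((pos[a] + r - origin[a]) / voxel[a]))
            if lo < 0 or hi > shape[a] - 1:
                clipped += 1 if not oob else 0
                oob = True
            lo, hi = max(lo, 0), min(hi, shape[a] - 1)
            if hi < lo:
                sl = None
                break
            sl.append(slice(lo, hi + 1))
        if sl is None:
            continue
        dx = axes[0][sl[0]] - pos[0]
        dy = axes[1][sl[1]] - pos[1]
        dz = axes[2][sl[2]] - pos[2]
        g = (
            np.exp(-dx[:, None, None] ** 2 / (2 * blur_width**2))
            * np.exp(-dy[None, :, None] ** 2 / (2 * blur_width**2))
            * np.exp(-dz[None, None, :] ** 2 / (2 * blur_width**2))
        )
        values[tuple(sl)] += norm * g
    if clipped:
        warnings.warn(
            f"{clipped} atoms extend beyond the grid; partial mass deposited",
            stacklevel=2,
        )
    return DensityMap(values, voxel, origin)


def _shell_index(shape: tuple[int, int, int], voxel: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Integer shell index per FFT voxel and the shell-center frequencies.

    Shells are one reciprocal voxel wide (of the largest axis extent).
    """
    freqs = [np.fft.fftfreq(n, d=v) for n, v in zip(shape, voxel)]
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij")
    fmag = np.sqrt(fx**2 + fy**2 + fz**2)
    dstar = min(1.0 / (n * v) for n, v in zip(shape, voxel))
    shell = np.round(fmag / dstar).astype(int)
    n_shells = shell.max() + 1
    centers = dstar * np.arange(n_shells)
    return shell, centers


def fsc(
    map_a: DensityMap,
    map_b: DensityMap,
    mask: DensityMap | None = None,
) -> FSCCurve:
    """Fourier shell correlation between two maps on identical grids.

    The optional real-space mask (values clamped to [0, 1]) multiplies both
    maps before the transform.  Shells with zero power in either map are
    recorded with correlation 0 and flagged.
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share a grid")
    a, b = map_a.values, map_b.values
    if mask is not None:
        if mask.shape != map_a.shape:
            raise ValueError("mask grid mismatch")
        m = np.clip(mask.values, 0.0, 1.0)
        a, b = a * m, b * m
    fa, fb = np.fft.fftn(a), np.fft.fftn(b)
    shell, centers = _shell_index(map_a.shape, map_a.voxel_size)
    n_shells = centers.size
    flat = shell.ravel()
    cross = np.bincount(flat, weights=(fa * np.conj(fb)).real.ravel(),
                        minlength=n_shells)
    pa = np.bincount(flat, weights=(np.abs(fa) ** 2).ravel(), minlength=n_shells)
    pb = np.bincount(flat, weights=(np.abs(fb) ** 2).ravel(), minlength=n_shells)
    counts = np.bincount(flat, minlength=n_shells)
    corr = np.zeros(n_shells)
    flags = [""] * n_shells
    nz = (pa > 0) & (pb > 0)
    corr[nz] = cross[nz] / np.sqrt(pa[nz] * pb[nz])
    for k in np.flatnonzero(~nz):
        flags[k] = "zero-power"
    corr = np.clip(corr, -1.0, 1.0)
    return FSCCurve(centers, corr, counts, flags)


def resolution_at(curve: FSCCurve, threshold: float) -> float:
    """Resolution (angstrom) where the FSC first crosses below ``threshold``.

    Linear interpolation between the bracketing shells; the zero-frequency
    shell is ignored.  Returns :data:`BETTER_THAN_NYQUIST` (``inf`` — i.e.
    the curve stays above threshold out to the grid limit) when there is no
    crossing, and the coarsest shell's resolution when the curve starts
    below threshold.
    """
    if curve.freq.size == 0:
        raise ValueError("empty curve")
    f = curve.freq[1:]
    c = curve.correlation[1:]
    if f.size == 0:
        raise ValueError("curve has only the DC shell")
    if c[0] < threshold:
        return float(1.0 / f[0])
    below = np.flatnonzero(c < threshold)
    if below.size == 0:
        return BETTER_THAN_NYQUIST
    j = below[0]
    f0, f1 = f[j - 1], f[j]
    c0, c1 = c[j - 1], c[j]
    fx = f0 + (c0 - threshold) / (c0 - c1) * (f1 - f0) if c0 != c1 else f1
    return float(1.0 / fx)


def perturb_model(model: AtomicModel, max_disp: float = 0.5,
                  seed: int = 0) -> AtomicModel:
    """Displace every atom by an independent uniform random vector of norm
    at most ``max_disp`` angstrom (uniform in the ball); reproducible under
    ``seed``.  Used to build the "test" model for overfitting
    cross-validation.
    """
    if max_disp < 0:
        raise ValueError("max_disp must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(model)
    direction = rng.normal(size=(n, 3))
    norm = np.linalg.norm(direction, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    radius = max_disp * rng.random(n) ** (1.0 / 3.0)
    disp = direction / norm * radius[:, None]
    atoms = [
        Atom(a.chain, a.resid, a.resname, a.name, a.element, a.xyz + d,
             a.occupancy, a.b_factor, a.vdw)
        for a, d in zip(model.atoms, disp)
    ]
    return AtomicModel(atoms)


def crossval_fsc(
    model_test: AtomicModel,
    halfmap1: DensityMap,
    halfmap2: DensityMap,
    fullmap: DensityMap,
    blur_width: float = 3.15,
    model_final: AtomicModel | None = None,
) -> tuple[FSCCurve, FSCCurve, FSCCurve, float]:
    """Half-map cross-validation curves for overfitting detection.

    Returns ``(FSC(test, half1), FSC(test, half2), FSC(final, full), gap)``
    where the overfitting indicator ``gap`` is the maximum per-shell
    difference between the two half-map curves.  ``model_final`` defaults
    to ``model_test``.
    """
    for m in (halfmap2, fullmap):
        if m.shape != halfmap1.shape:
            raise ValueError("all maps must share one grid")
    test_map = model_to_map(model_test, halfmap1.shape, halfmap1.voxel_size,
                            halfmap1.origin, blur_width)
    final = model_final or model_test
    final_map = (
        test_map
        if final is model_test
        else model_to_map(final, fullmap.shape, fullmap.voxel_size,
                          fullmap.origin, blur_width)
    )
    c1 = fsc(test_map, halfmap1)
    c2 = fsc(test_map, halfmap2)
    cf = fsc(final_map, fullmap)
    gap = float(np.max(np.abs(c1.correlation - c2.correlation)))
    return c1, c2, cf, gap


def local_fit_z(
    model: AtomicModel,
    dmap: DensityMap,
    blur_width: float = 3.15,
    window: int = 1,
) -> dict[tuple[str, int], float]:
    """Per-residue Z-scored local map fit.

    For each residue the raw score is the Manders-style overlap
    ``sum(m_r * e) / sqrt(sum(m_r^2) * sum(e^2))`` between the residue's
    model-derived density ``m_r`` and the experimental density ``e`` over
    the residue's voxel footprint, optionally averaged over a sliding
    window of ``window`` consecutive residues per chain.  Z-scores are
    formed by pooling mean and standard deviation across all scored
    residues.  Residues with an empty footprint are excluded and flagged
    (NaN in the result).  A pooled sd of ~0 (all scores equal, e.g. a map
    generated from the model itself) yields Z = 0 with a warning.
    """
    by_res: dict[tuple[str, int], list[Atom]] = {}
    order: list[tuple[str, int]] = []
    for a in model.atoms:
        key = (a.chain, a.resid)
        if key not in by_res:
            by_res[key] = []
            order.append(key)
        by_res[key].append(a)
    full = model_to_map(model, dmap.shape, dmap.voxel_size, dmap.origin,
                        blur_width)
    axes = [dmap.origin[a] + np.arange(dmap.shape[a]) * dmap.voxel_size[a]
            for a in range(3)]
    reach = 2.0 * blur_width  # footprint radius around each residue atom
    raw: dict[tuple[str, int], float] = {}
    for key, atoms in by_res.items():
        foot = np.zeros(dmap.shape, dtype=bool)
        for a in atoms:
            sl = []
            ok = True
            for ax in range(3):
                lo = int(np.ceil((a.xyz[ax] - reach - dmap.origin[ax])
                                 / dmap.voxel_size[ax]))
                hi = int(np.floor((a.xyz[ax] + reach - dmap.origin[ax])
                                  / dmap.voxel_size[ax]))
                lo, hi = max(lo, 0), min(hi, dmap.shape[ax] - 1)
                if hi < lo:
                    ok = False
                    break
                sl.append(slice(lo, hi + 1))
            if not ok:
                continue
            dx = axes[0][sl[0]][:, None, None] - a.xyz[0]
            dy = axes[1][sl[1]][None, :, None] - a.xyz[1]
            dz = axes[2][sl[2]][None, None, :] - a.xyz[2]
            foot[tuple(sl)] |= dx**2 + dy**2 + dz**2 <= reach**2
        if not foot.any():
            raw[key] = np.nan
            continue
        mv = full.values[foot]
        ev = dmap.values[foot]
        denom = np.sqrt(np.sum(mv**2) * np.sum(ev**2))
        raw[key] = float(np.sum(mv * ev) / denom) if denom > 0 else np.nan
    if window > 1:
        smoothed: dict[tuple[str, int], float] = {}
        half = window // 2
        for chain in {k[0] for k in order}:
            keys = [k for k in order if k[0] == chain]
            vals = np.array([raw[k] for k in keys])
            for j, k in enumerate(keys):
                seg = vals[max(0, j - half): j + half + 1]
                seg = seg[np.isfinite(seg)]
                smoothed[k] = float(seg.mean()) if seg.size else np.nan
        raw = smoothed
    scores = np.array([v for v in raw.values() if np.isfinite(v)])
    if scores.size == 0:
        raise ValueError("no residue produced a defined local-fit score")
    mean, sd = scores.mean(), scores.std()
    if sd < 1e-12:
        warnings.warn("pooled score sd ~ 0 (degenerate pooling); Z set to 0",
                      stacklevel=2)
        return {k: (0.0 if np.isfinite(v) else np.nan) for k, v in raw.items()}
    return {k: ((v - mean) / sd if np.isfinite(v) else np.nan)
            for k, v in raw.items()}


def local_scale(
    map_exp: DensityMap,
    map_ref: DensityMap,
    window: float = 30.0,
) -> DensityMap:
    """Simplified windowed local amplitude scaling.

    The experimental map is partitioned into cubes of ``window`` angstrom
    with stride window/2; within each cube the radial Fourier amplitudes of
    the experimental subvolume are scaled to match the reference model
    map's, and the rescaled cubes are blended with linear (triangular)
    weights.  Windows whose reference shell amplitude is zero fall back to
    scale 1.  This is a single-pass variant of reference-based local
    sharpening; no per-voxel sliding or reference B-factor handling.
    """
    if map_exp.shape != map_ref.shape:
        raise ValueError("maps must share a grid")
    voxel = map_exp.voxel_size
    w_vox = np.maximum((np.round(window / voxel)).astype(int), 2)
    w_vox = np.minimum(w_vox, np.array(map_exp.shape))
    stride = np.maximum(w_vox // 2, 1)
    out = np.zeros(map_exp.shape)
    weight = np.zeros(map_exp.shape)
    tri = [_triangle(w_vox[a]) for a in range(3)]
    starts = [
        _window_starts(map_exp.shape[a], w_vox[a], stride[a]) for a in range(3)
    ]
    for i0 in starts[0]:
        for j0 in starts[1]:
            for k0 in starts[2]:
                sl = (
                    slice(i0, i0 + w_vox[0]),
                    slice(j0, j0 + w_vox[1]),
                    slice(k0, k0 + w_vox[2]),
                )
                sub_e = map_exp.values[sl]
                sub_r = map_ref.values[sl]
                scaled = _match_radial_amplitudes(sub_e, sub_r)
                wgt = (
                    tri[0][:, None, None]
                    * tri[1][None, :, None]
                    * tri[2][None, None, :]
                )
                out[sl] += scaled * wgt
                weight[sl] += wgt
    nz = weight > 0
    out[nz] /= weight[nz]
    return DensityMap(out, map_exp.voxel_size.copy(), map_exp.origin.copy(),
                      map_exp.symmetry_order)


def _window_starts(n: int, w: int, stride: int) -> list[int]:
    starts = list(range(0, max(n - w, 0) + 1, stride))
    if starts[-1] != n - w:
        starts.append(n - w)
    return starts


def _triangle(w: int) -> np.ndarray:
    x = np.arange(w, dtype=float)
    t = 1.0 - np.abs(x - (w - 1) / 2.0) / ((w - 1) / 2.0 + 1e-12)
    return np.maximum(t, 1e-3)


def _match_radial_amplitudes(sub_exp: np.ndarray, sub_ref: np.ndarray
                             ) -> np.ndarray:
    fe = np.fft.fftn(sub_exp)
    fr = np.fft.fftn(sub_ref)
    shell, _ = _shell_index(sub_exp.shape, np.ones(3))
    flat = shell.ravel()
    n_shells = int(flat.max()) + 1
    amp_e = np.sqrt(np.bincount(flat, weights=(np.abs(fe) ** 2).ravel(),
                                minlength=n_shells))
    amp_r = np.sqrt(np.bincount(flat, weights=(np.abs(fr) ** 2).ravel(),
                                minlength=n_shells))
    scale = np.ones(n_shells)
    nz = (amp_e > 0) & (amp_r > 0)
    scale[nz] = amp_r[nz] / amp_e[nz]
    return np.fft.ifftn(fe * scale[shell]).real
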