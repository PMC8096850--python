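"""Synthetic-data generators.

These stand in for the cluster-scale inputs of a channel study: analytic
free-energy profiles replace the unknown true PMF, a 1-D overdamped
Langevin sampler replaces all-atom biased MD, ring-stack pseudo-atom models
replace the deposited coordinates, and Gaussian-blurred (optionally noisy)
grids replace experimental reconstructions.  Everything is seeded and
deterministic.

Units: angstrom, nanosecond, kcal/mol; temperature defaults to 310 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from cptk.structio import Atom, AtomicModel, DensityMap, TimeSeries
from cptk.wham import ThermoState, UmbrellaWindow, bias_potential
from cptk.mapval import model_to_map

__all__ = [
    "AnalyticPMF",
    "flat_pmf",
    "harmonic_pmf",
    "double_well_pmf",
    "multi_barrier_pmf",
    "channel_like_pmf",
    "tabulated_pmf",
    "sample_window",
    "sample_windows",
    "steered_seed",
    "ToyChannelSpec",
    "build_toy_channel",
    "cylinder_channel",
    "cone_channel",
    "two_waist_channel",
    "synth_map",
    "rmsd",
    "rmsf",
    "StepSizeError",
]


class StepSizeError(RuntimeError):
    """Raised when a Langevin trajectory escapes its domain (dt too large)."""


@dataclass
class AnalyticPMF:
    """An analytic free-energy profile A*(q) with its gradient.

    ``form`` is one of flat | harmonic | double_well | multi_barrier |
    tabulated; construct via the factory functions below.  ``domain`` is
    the q interval (angstrom) on which the profile is meant to be sampled.
    """

    form: str
    fn: Callable[[np.ndarray], np.ndarray]
    grad: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float] = (-60.0, 60.0)
    params: dict = field(default_factory=dict)

    def __call__(self, q):
        return self.fn(np.asarray(q, float))

    def barrier_positions(self) -> list[tuple[float, float]]:
        """(position, height) of the designed barriers, where known."""
        if self.form == "double_well":
            return [(0.0, self.params["height"])]
        if self.form == "multi_barrier":
            return list(zip(self.params["positions"], self.params["heights"]))
        return []


def flat_pmf(domain=(-60.0, 60.0)) -> AnalyticPMF:
    """A*(q) = 0 — the null profile (biased sampling is exactly Gaussian)."""
    return AnalyticPMF("flat", lambda q: np.zeros_like(q),
                       lambda q: np.zeros_like(q), domain)


def harmonic_pmf(k: float = 0.5, q0: float = 0.0,
                 domain=(-60.0, 60.0)) -> AnalyticPMF:
    """A*(q) = k/2 (q - q0)^2."""
    return AnalyticPMF(
        "harmonic",
        lambda q: 0.5 * k * (q - q0) ** 2,
        lambda q: k * (q - q0),
        domain,
        {"k": k, "q0": q0},
    )


def double_well_pmf(height: float = 5.0, half_width: float = 10.0,
                    domain=(-11.0, 11.0)) -> AnalyticPMF:
    """A*(q) = h ((q/w)^2 - 1)^2 — minima at ±w, barrier h at q = 0."""
    h, w = height, half_width

    def fn(q):
        return h * ((q / w) ** 2 - 1.0) ** 2

    def grad(q):
        return h * 2.0 * ((q / w) ** 2 - 1.0) * (2.0 * q / w**2)

    return AnalyticPMF("double_well", fn, grad, domain,
                       {"height": h, "half_width": w})


def multi_barrier_pmf(
    heights: Sequence[float],
    positions: Sequence[float],
    widths: Sequence[float],
    domain=(-60.0, 60.0),
) -> AnalyticPMF:
    """Sum of Gaussian barriers  A*(q) = sum_i h_i exp(-(q-z_i)^2 / 2 w_i^2)."""
    h = np.asarray(heights, float)
    z = np.asarray(positions, float)
    w = np.asarray(widths, float)

    def fn(q):
        q = np.atleast_1d(np.asarray(q, float))
        out = np.sum(h * np.exp(-((q[..., None] - z) ** 2) / (2 * w**2)), axis=-1)
        return out if out.shape else float(out)

    def grad(q):
        q = np.atleast_1d(np.asarray(q, float))
        terms = h * np.exp(-((q[..., None] - z) ** 2) / (2 * w**2))
        return np.sum(terms * (-(q[..., None] - z) / w**2), axis=-1)

    return AnalyticPMF("multi_barrier", fn, grad, domain,
                       {"heights": list(h), "positions": list(z),
                        "widths": list(w)})


def channel_like_pmf(domain=(-20.0, 20.0)) -> AnalyticPMF:
    """The shipped channel-like profile: a 5 kcal/mol barrier at z = -12 A
    (intracellular-vestibule constriction) and a 4 kcal/mol barrier at
    z = +12 A (pore-funnel constriction), each 3 A wide — the barrier
    scale reported for divalent/monovalent cation permeation through the
    closed heptameric channel."""
    return multi_barrier_pmf([5.0, 4.0], [-12.0, 12.0], [3.0, 3.0], domain)


def tabulated_pmf(q: np.ndarray, a: np.ndarray) -> AnalyticPMF:
    """Cubic-spline interpolation of a tabulated profile."""
    spl = CubicSpline(np.asarray(q, float), np.asarray(a, float))
    der = spl.derivative()
    return AnalyticPMF("tabulated", spl, der,
                       (float(np.min(q)), float(np.max(q))))


# ---------------------------------------------------------------------------
# Biased sampling
# ---------------------------------------------------------------------------


def _escape_margin(domain: tuple[float, float]) -> float:
    return 0.25 * (domain[1] - domain[0]) + 10.0


def sample_windows(
    pmf: AnalyticPMF,
    windows: list[UmbrellaWindow],
    n_steps: int = 10_000,
    dt: float = 0.002,
    damping: float = 1.0,
    thermo: ThermoState | None = None,
    seed: int = 0,
    burn_in: float = 0.1,
    method: str = "langevin",
    thin: int = 1,
) -> list[UmbrellaWindow]:
    """Sample every window and return copies with ``series`` attached.

    ``thin`` records every thin-th Langevin step (the dynamics still take
    every step), keeping long runs in memory.

    ``method="langevin"``: all windows are propagated simultaneously with
    the overdamped update

        q  <-  q - (dt / gamma) dU/dq + sqrt(2 kT dt / gamma) xi

    where U = A*(q) + c/2 (q - q_i)^2, gamma is the ``damping`` in
    kcal mol^-1 ns A^-2 and xi is standard normal.  Stability requires
    ``(c + |A*''|) dt / gamma`` well below 1 (the defaults give 0.04 for
    the stiffest shipped case); a trajectory escaping far beyond the PMF
    domain raises :class:`StepSizeError` naming dt.  The first ``burn_in``
    fraction of steps is discarded.

    ``method="exact"``: independent draws from the stationary law
    exp(-beta U) by inverse-CDF sampling on a fine grid — no dynamics, no
    burn-in; the flat-profile case reduces to exact Gaussian draws of
    variance kT/c.
    """
    thermo = thermo or ThermoState()
    rng = np.random.default_rng(seed)
    if method == "exact":
        return [_exact_window(pmf, w, n_steps, dt, thermo,
                              rng.integers(2**31)) for w in windows]
    if method != "langevin":
        raise ValueError(f"unknown method {method!r}")

    kT = thermo.kT
    anchors = np.array([w.anchor for w in windows])
    consts = np.array([w.force_const for w in windows])
    # start at the biased minimum: anchor relaxed a few descent steps
    q = anchors.copy()
    for _ in range(200):
        g = pmf.grad(q) + consts * (q - anchors)
        q = q - np.clip(0.5 * g / np.maximum(consts, 1.0), -0.5, 0.5)
    if thin < 1:
        raise ValueError("thin must be >= 1")
    n_burn = int(burn_in * n_steps)
    total = n_steps + n_burn
    sigma = np.sqrt(2.0 * kT * dt / damping)
    lo, hi = pmf.domain
    margin = _escape_margin(pmf.domain)
    n_rec = n_steps // thin
    out = np.empty((n_rec, len(windows)))
    rec = 0
    for t in range(total):
        force = -(pmf.grad(q) + consts * (q - anchors))
        q = q + (dt / damping) * force + sigma * rng.standard_normal(len(windows))
        if np.any(q < lo - margin) or np.any(q > hi + margin):
            raise StepSizeError(
                f"trajectory escaped the PMF domain; dt={dt} ns is too large "
                f"for this stiffness (try reducing dt or raising damping)"
            )
        if t >= n_burn and (t - n_burn) % thin == thin - 1 and rec < n_rec:
            out[rec] = q
            rec += 1
    times = dt * thin * (1 + np.arange(n_rec))
    return [
        UmbrellaWindow(w.anchor, w.force_const,
                       TimeSeries(times, out[:, i]), w.replica)
        for i, w in enumerate(windows)
    ]


def sample_window(
    pmf: AnalyticPMF,
    window: UmbrellaWindow,
    n_steps: int = 10_000,
    dt: float = 0.002,
    damping: float = 1.0,
    thermo: ThermoState | None = None,
    seed: int = 0,
    burn_in: float = 0.1,
    method: str = "langevin",
    thin: int = 1,
) -> TimeSeries:
    """Single-window convenience wrapper around :func:`sample_windows`."""
    (w,) = sample_windows(pmf, [window], n_steps, dt, damping, thermo, seed,
                          burn_in, method, thin)
    assert w.series is not None
    return w.series


def _exact_window(pmf: AnalyticPMF, window: UmbrellaWindow, n: int, dt: float,
                  thermo: ThermoState, seed: int) -> UmbrellaWindow:
    beta = thermo.beta
    c = window.force_const
    if c > 0:
        s = np.sqrt(thermo.kT / c)
        lo = window.anchor - 8 * s
        hi = window.anchor + 8 * s
    else:
        lo, hi = pmf.domain
    lo = max(lo, pmf.domain[0] - 5.0)
    hi = min(hi, pmf.domain[1] + 5.0)
    grid = np.linspace(lo, hi, 4001)
    u = pmf(grid) + bias_potential(grid, window)
    w = np.exp(-beta * (u - u.min()))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]))])
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    q = np.interp(rng.random(n), cdf, grid)
    times = dt * (1 + np.arange(n))
    return UmbrellaWindow(window.anchor, window.force_const,
                          TimeSeries(times, q), window.replica)


def steered_seed(
    pmf: AnalyticPMF,
    q_a: float,
    q_b: float,
    anchors: Sequence[float],
    velocity: float = 10.0,
    force_const: float = 20.0,
    dt: float = 0.002,
    damping: float = 1.0,
    thermo: ThermoState | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Steered pull with a moving harmonic anchor; snapshot per window anchor.

    The anchor moves from ``q_a`` to ``q_b`` at ``velocity`` (A/ns) while
    the coordinate follows the biased Langevin dynamics; the instantaneous
    position is recorded as the anchor crosses each target in ``anchors``.
    In the stiff-spring limit the snapshots coincide with the anchors.
    """
    if q_a == q_b:
        raise ValueError("pull endpoints must differ")
    thermo = thermo or ThermoState()
    rng = np.random.default_rng(seed)
    kT = thermo.kT
    sign = 1.0 if q_b > q_a else -1.0
    sigma = np.sqrt(2.0 * kT * dt / damping)
    # keep the update stable for arbitrarily stiff pulls
    dt_eff = min(dt, 0.1 * damping / max(force_const, 1e-9))
    sigma = np.sqrt(2.0 * kT * dt_eff / damping)
    targets = sorted(anchors, key=lambda a: sign * a)
    q = float(q_a)
    anchor = float(q_a)
    snaps: list[float] = []
    ti = 0
    t = 0.0
    while targets and sign * (anchor - q_b) <= 1e-12:
        force = -(float(pmf.grad(np.array([q]))[0])
                  + force_const * (q - anchor))
        q = q + (dt_eff / damping) * force + sigma * rng.standard_normal()
        t += dt_eff
        anchor = q_a + sign * velocity * t
        while targets and sign * anchor >= sign * targets[0] - 1e-12:
            snaps.append(q)
            targets.pop(0)
        ti += 1
        if ti > 500_000_000:
            raise StepSizeError("steered pull did not terminate")
    return np.array(snaps)


# ---------------------------------------------------------------------------
# Toy channel models
# ---------------------------------------------------------------------------


@dataclass
class ToyChannelSpec:
    """A ring-stack channel with a known radius-vs-axis profile.

    ``radius_profile(z)`` gives the lumen construction radius (distance of
    the pseudo-atom centers from the axis) in angstrom; the accessible pore
    radius at z is then ``radius_profile(z) - vdw``.  ``atoms_per_ring``
    atoms are placed per ring, assigned to ``symmetry_order`` chains by
    angular sector; residue indices increase along z.
    """

    radius_profile: Callable[[float], float]
    z_range: tuple[float, float] = (-20.0, 20.0)
    ring_spacing: float = 1.0
    atoms_per_ring: int = 14
    vdw: float = 1.5
    symmetry_order: int = 7

    def __post_init__(self) -> None:
        if self.ring_spacing <= 0:
            raise ValueError("ring spacing must be positive")


def build_toy_channel(spec: ToyChannelSpec) -> AtomicModel:
    """Materialize a :class:`ToyChannelSpec` as pseudo-atom rings."""
    zs = np.arange(spec.z_range[0], spec.z_range[1] + 0.5 * spec.ring_spacing,
                   spec.ring_spacing)
    chains = [chr(ord("A") + i) for i in range(spec.symmetry_order)]
    atoms: list[Atom] = []
    for ri, z in enumerate(zs, start=1):
        r = float(spec.radius_profile(float(z)))
        for k in range(spec.atoms_per_ring):
            ang = 2.0 * np.pi * k / spec.atoms_per_ring
            chain = chains[int(k * spec.symmetry_order / spec.atoms_per_ring)
                           % spec.symmetry_order]
            atoms.append(
                Atom(
                    chain=chain,
                    resid=ri,
                    resname="RNG",
                    name=f"X{k}",
                    element="C",
                    xyz=np.array([r * np.cos(ang), r * np.sin(ang), z]),
                    vdw=spec.vdw,
                )
            )
    return AtomicModel(atoms)


def cylinder_channel(radius: float = 5.0, **kw) -> AtomicModel:
    """Constant-radius channel: accessible pore radius = radius - vdw."""
    return build_toy_channel(ToyChannelSpec(lambda z: radius, **kw))


def cone_channel(r0: float = 4.0, slope: float = 0.2, **kw) -> AtomicModel:
    """Linearly widening channel (monotone profile along z)."""
    spec = ToyChannelSpec(lambda z: r0 + slope * (z - kw.get("z_range",
                          (-20.0, 20.0))[0]), **kw)
    return build_toy_channel(spec)


def two_waist_channel(
    waist_radii: tuple[float, float] = (3.5, 4.1),
    waist_z: tuple[float, float] = (-12.0, 12.0),
    bulk_radius: float = 9.0,
    waist_width: float = 3.0,
    **kw,
) -> AtomicModel:
    """Channel with two Gaussian waists; with the default vdw of 1.5 A the
    accessible pore radii at the waists are 2.0 and 2.6 A, both narrower
    than the hydrated radius of any common permeant ion."""

    def profile(z: float) -> float:
        dips = sum(
            (bulk_radius - rw) * np.exp(-((z - zw) ** 2) / (2 * waist_width**2))
            for rw, zw in zip(waist_radii, waist_z)
        )
        return bulk_radius - dips

    return build_toy_channel(ToyChannelSpec(profile, **kw))


def helix_model(
    n_residues: int = 30,
    radius: float = 2.3,
    rise: float = 1.5,
    residues_per_turn: float = 3.6,
    offset: float = 20.0,
) -> AtomicModel:
    """A C-alpha alpha-helix trace (2.3 A radius, 1.5 A rise, 3.6 res/turn).

    Used as the main-chain-tracing fixture: blur it at a stated map
    resolution (FWHM) and check that mean-shift local dense points follow
    the backbone spiral.
    """
    pts = [
        np.array(
            [
                radius * np.cos(2 * np.pi * i / residues_per_turn),
                radius * np.sin(2 * np.pi * i / residues_per_turn),
                rise * i,
            ]
        )
        + offset
        for i in range(n_residues)
    ]
    return AtomicModel(
        [Atom("A", i + 1, "ALA", "CA", "C", p) for i, p in enumerate(pts)]
    )


#: FWHM-to-sigma conversion for Gaussian blurs: a map "at resolution R"
#: carries a point-spread of FWHM ~ R, i.e. sigma = R / 2.355.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Synthetic maps
# ---------------------------------------------------------------------------


def synth_map(
    model: AtomicModel,
    shape: tuple[int, int, int] | None = None,
    voxel_size: float = 1.08,
    blur_width: float = 3.15,
    noise_sd: float = 0.0,
    seed: int = 0,
    halves: bool = False,
    pad: float = 8.0,
):
    """Model-derived density with optional Gaussian voxel noise.

    The grid defaults to the model bounding box padded by ``pad`` angstrom
    at the stated voxel size.  With ``halves=True`` two maps sharing the
    same signal but carrying independent noise realizations are returned
    (the synthetic analogue of half maps from split particle sets).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if shape is None:
        lo = model.coords.min(axis=0) - pad
        hi = model.coords.max(axis=0) + pad
        shape = tuple(int(np.ceil((hi[a] - lo[a]) / voxel_size)) + 1
                      for a in range(3))
        origin = lo
    else:
        origin = model.coords.mean(axis=0) - 0.5 * voxel_size * (
            np.array(shape) - 1
        )
    signal = model_to_map(model, shape, voxel_size, origin, blur_width)
    rng = np.random.default_rng(seed)
    if halves:
        h1 = DensityMap(signal.values + noise_sd * rng.standard_normal(shape),
                        signal.voxel_size, signal.origin)
        h2 = DensityMap(signal.values + noise_sd * rng.standard_normal(shape),
                        signal.voxel_size, signal.origin)
        return h1, h2
    if noise_sd > 0:
        return DensityMap(signal.values + noise_sd * rng.standard_normal(shape),
                          signal.voxel_size, signal.origin)
    return signal


# ---------------------------------------------------------------------------
# r.m.s.d. / r.m.s.f.
# ---------------------------------------------------------------------------


def _superpose(ref: np.ndarray, mob: np.ndarray) -> np.ndarray:
    """Optimal rigid-body superposition of ``mob`` onto ``ref`` (Kabsch)."""
    rc = ref - ref.mean(axis=0)
    mc = mob - mob.mean(axis=0)
    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    R = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (R @ mc.T).T + ref.mean(axis=0)


def rmsd(ref: np.ndarray, coords: np.ndarray, superpose: bool = False) -> float:
    """Root-mean-square deviation between matched coordinate sets (A)."""
    ref = np.asarray(ref, float)
    coords = np.asarray(coords, float)
    if ref.shape != coords.shape:
        raise ValueError(
            f"atom mismatch: reference has {ref.shape[0]} atoms, "
            f"coordinates have {coords.shape[0]}"
        )
    if superpose:
        coords = _superpose(ref, coords)
    return float(np.sqrt(np.mean(np.sum((coords - ref) ** 2, axis=1))))


def rmsf(traj: np.ndarray, ref: np.ndarray | None = None,
         superpose: bool = True) -> np.ndarray:
    """Per-atom root-mean-square fluctuation over a trajectory.

    ``traj`` has shape (n_frames, n_atoms, 3).  Frames are optionally
    superposed onto ``ref`` (default: the trajectory mean) first; the
    fluctuation is measured about the per-atom time average.
    """
    traj = np.asarray(traj, float)
    if traj.ndim != 3 or traj.shape[2] != 3:
        raise ValueError("traj must have shape (n_frames, n_atoms, 3)")
    if ref is None:
        ref = traj.mean(axis=0)
    ref = np.asarray(ref, float)
    if ref.shape != traj.shape[1:]:
        raise ValueError(
            f"atom mismatch: reference has {ref.shape[0]} atoms, "
            f"trajectory frames have {traj.shape[1]}"
        )
    if superpose:
        traj = np.stack([_superpose(ref, f) for f in traj])
    mean = traj.mean(axis=0)
    return np.sqrt(np.mean(np.sum((traj - mean) ** 2, axis=2), axis=0))
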