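"""HOLE-style pore-pathway profiling.

At each position along the channel axis the largest sphere that fits in the
lumen without overlapping any atom's van der Waals surface is found:

    r(z) = max_{c in plane z}  min_atoms ( |c - x_a| - vdw_a )

clipped to ``[0, r_cap]``.  Local minima of r(z) are constrictions; the
channel is classified closed for an ion whenever min r(z) is below that
ion's hydrated radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.signal import find_peaks

from cptk.structio import AtomicModel, IndexMap, dual_label, model_to_native_index

__all__ = [
    "PoreProfile",
    "IonRadiusTable",
    "DEFAULT_IONS",
    "channel_axis",
    "max_inscribed_radius",
    "pore_profile",
    "find_constrictions",
    "classify_state",
    "Constriction",
    "DegenerateAxisError",
]

#: Cap on reported pore radii (angstrom); beyond this the plane is treated
#: as effectively unbounded (vestibule open to bulk).
R_CAP = 30.0


class DegenerateAxisError(ValueError):
    """Raised when the model has too few atoms to define an axis."""


@dataclass
class IonRadiusTable:
    """Hydrated (and where known, Stokes) radii per ion, in angstrom."""

    entries: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for name, radii in self.entries.items():
            for kind, r in radii.items():
                if r <= 0:
                    raise ValueError(f"{name} {kind} radius must be positive")

    def hydrated(self, ion: str) -> float:
        return self.entries[ion]["hydrated"]

    def ions(self) -> list[str]:
        return list(self.entries)


#: Hydrated radii of the physiologically relevant ions; chloride's bare
#: Stokes radius is listed alongside since the gap between the two scales
#: decides how small a conformational change could open a Cl- pathway.
DEFAULT_IONS = IonRadiusTable(
    {
        "Ca2+": {"hydrated": 4.12},
        "Cl-": {"hydrated": 3.32, "stokes": 1.21},
        "K+": {"hydrated": 3.31},
    }
)


@dataclass
class PoreProfile:
    """Per-axis-position maximal inscribed-sphere profile.

    ``z`` are axial positions (angstrom, strictly monotone), ``radius`` the
    maximal inscribed-sphere radius clipped to [0, r_cap], ``center_xy`` the
    in-plane sphere centers, ``lining`` the (chain, resid, atom name) of the
    contact atom, and ``flags`` marks unbounded planes (no atoms nearby).
    """

    z: np.ndarray
    radius: np.ndarray
    center_xy: np.ndarray
    lining: list[tuple[str, int, str] | None]
    flags: list[str]
    r_cap: float = R_CAP

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.center_xy = np.asarray(self.center_xy, dtype=float)
        n = self.z.size
        if not (self.radius.size == n and self.center_xy.shape == (n, 2)
                and len(self.lining) == n and len(self.flags) == n):
            raise ValueError("profile arrays must have equal length")
        if n > 1 and not (np.all(np.diff(self.z) > 0) or np.all(np.diff(self.z) < 0)):
            raise ValueError("z must be strictly monotone")
        if np.any(self.radius < -1e-9) or np.any(self.radius > self.r_cap + 1e-9):
            raise ValueError("radius must lie in [0, r_cap]")

    def min_radius(self) -> float:
        ok = [i for i, f in enumerate(self.flags) if f == ""]
        return float(np.min(self.radius[ok])) if ok else float(np.min(self.radius))


# ---------------------------------------------------------------------------
# Axis determination
# ---------------------------------------------------------------------------


def channel_axis(model: AtomicModel) -> tuple[np.ndarray, np.ndarray]:
    """Symmetry/principal axis of a channel model.

    Returns ``(point, direction)`` — a point on the axis (the center of mass)
    and a unit direction.  For a Cn assembly the per-chain centroids lie on a
    circle; the axis is the normal of the best-fit plane through them, which
    minimizes the centroid dispersion about the axis.  Single-chain models
    fall back to the principal axis of the coordinate covariance.
    """
    if len(model) < 3:
        raise DegenerateAxisError("need at least 3 atoms to define an axis")
    com = model.coords.mean(axis=0)
    chains = model.chains
    if len(chains) >= 3:
        cents = np.array(
            [model.coords[[a.chain == c for a in model.atoms]].mean(axis=0)
             for c in chains]
        )
        centered = cents - cents.mean(axis=0)
        # plane normal = least-variance direction of the centroid cloud
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[-1]
    else:
        centered = model.coords - com
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
    # deterministic sign: largest-magnitude component positive
    k = int(np.argmax(np.abs(direction)))
    if direction[k] < 0:
        direction = -direction
    return com, direction / np.linalg.norm(direction)


def _axis_frame(axis: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Orthonormal frame (e1, e2, n) with n the axis direction."""
    _, n = axis
    n = np.asarray(n, float)
    n = n / np.linalg.norm(n)
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(probe, n)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    e1 = probe - np.dot(probe, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return np.vstack([e1, e2, n])


def axial_coordinates(model: AtomicModel,
                      axis: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Signed axial coordinate of every atom relative to the axis point."""
    point, n = axis
    return (model.coords - point) @ (np.asarray(n) / np.linalg.norm(n))


# ---------------------------------------------------------------------------
# Maximal inscribed sphere
# ---------------------------------------------------------------------------


def _clearance(centers: np.ndarray, coords: np.ndarray, vdw: np.ndarray
               ) -> np.ndarray:
    """min over atoms of (distance - vdw) for each candidate 3-D center."""
    d = np.linalg.norm(coords[None, :, :] - centers[:, None, :], axis=2)
    return np.min(d - vdw[None, :], axis=1)


def max_inscribed_radius(
    model: AtomicModel,
    z: float,
    axis: tuple[np.ndarray, np.ndarray],
    start_xy: np.ndarray | None = None,
    r_cap: float = R_CAP,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[float, np.ndarray, tuple[str, int, str] | None, str]:
    """Largest sphere centered in the plane at axial position ``z``.

    Maximizes the clearance ``min_a(|c - x_a| - vdw_a)`` over in-plane
    centers ``c`` by multi-start Nelder-Mead ascent: the previous plane's
    optimum (``start_xy``), the axis point, and a fixed ring of perturbed
    starts.  Deterministic for a given ``seed``.

    Returns ``(radius, center_xy, lining (chain, resid, atom) or None,
    flag)`` with flag ``"unbounded"`` when no atom lies within reach of the
    plane.
    """
    frame = _axis_frame(axis)
    point = np.asarray(axis[0], float)
    local = (model.coords - point) @ frame.T  # columns: in-plane 1, 2, axial
    vdw = model.vdw_radii
    slab = r_cap + (vdw.max() if vdw.size else 0.0)
    near = np.abs(local[:, 2] - z) <= slab
    if not np.any(near):
        # no atoms anywhere near the plane: lumen open to bulk
        return r_cap, np.zeros(2), None, "unbounded"
    coords = local[near]
    vdw_near = vdw[near]
    idx_near = np.flatnonzero(near)

    def clearance_xy(c_xy: np.ndarray) -> float:
        c = np.array([c_xy[0], c_xy[1], z])
        return float(_clearance(c[None, :], coords, vdw_near)[0])

    rng = np.random.default_rng(seed)
    starts = [np.zeros(2)]
    if start_xy is not None:
        starts.insert(0, np.asarray(start_xy, float))
    base = starts[0]
    for ang in np.linspace(0, 2 * np.pi, n_starts, endpoint=False):
        starts.append(base + 1.5 * np.array([np.cos(ang), np.sin(ang)]))
    # coarse grid pass keeps the ascent out of off-axis side pockets
    g = np.linspace(-4.0, 4.0, 9)
    gx, gy = np.meshgrid(g + base[0], g + base[1])
    grid = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
    vals = _clearance(grid, coords, vdw_near)
    starts.append(grid[int(np.argmax(vals)), :2])

    best_val, best_xy = -np.inf, np.zeros(2)
    for s in starts:
        res = minimize(lambda c: -clearance_xy(c), s, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
        if -res.fun > best_val:
            best_val, best_xy = -res.fun, res.x
    # simulated-annealing style random restarts if the ascent looks stuck low
    if best_val < 0:
        for _ in range(n_starts):
            s = base + rng.normal(scale=3.0, size=2)
            res = minimize(lambda c: -clearance_xy(c), s, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
            if -res.fun > best_val:
                best_val, best_xy = -res.fun, res.x

    radius = float(np.clip(best_val, 0.0, r_cap))
    flag = "unbounded" if best_val >= r_cap else ""
    c3 = np.array([best_xy[0], best_xy[1], z])
    d = np.linalg.norm(coords - c3, axis=1) - vdw_near
    order = np.argsort(d, kind="stable")  # ties: smallest atom index wins
    contact = model.atoms[idx_near[order[0]]]
    lining = (contact.chain, contact.resid, contact.name)
    return radius, best_xy, lining, flag


def pore_profile(
    model: AtomicModel,
    axis: tuple[np.ndarray, np.ndarray] | None = None,
    z_min: float | None = None,
    z_max: float | None = None,
    step: float = 0.5,
    r_cap: float = R_CAP,
    seed: int = 0,
) -> PoreProfile:
    """Sweep the maximal-inscribed-sphere search along the channel axis.

    Planes are visited in order and each search is seeded from the previous
    plane's optimal center (path continuity).  ``z`` bounds default to the
    model's axial extent.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if axis is None:
        axis = channel_axis(model)
    ax_coords = axial_coordinates(model, axis)
    if z_min is None:
        z_min = float(ax_coords.min())
    if z_max is None:
        z_max = float(ax_coords.max())
    if not z_min < z_max:
        raise ValueError("z_min must be < z_max")
    zs = np.arange(z_min, z_max + 0.5 * step, step)
    radii, centers, lining, flags = [], [], [], []
    prev: np.ndarray | None = None
    for z in zs:
        r, cxy, lin, flag = max_inscribed_radius(
            model, float(z), axis, start_xy=prev, r_cap=r_cap, seed=seed
        )
        radii.append(r)
        centers.append(cxy)
        lining.append(lin)
        flags.append(flag)
        if flag == "":
            prev = cxy
    return PoreProfile(zs, np.array(radii), np.array(centers), lining, flags,
                       r_cap=r_cap)


# ---------------------------------------------------------------------------
# Constriction detection and state classification
# ---------------------------------------------------------------------------


@dataclass
class Constriction:
    """One local minimum of the pore-radius profile."""

    z: float
    radius: float
    lining: list[tuple[str, int, str]]
    excluded_ions: list[str] = field(default_factory=list)


def find_constrictions(
    profile: PoreProfile,
    model: AtomicModel | None = None,
    ions: IonRadiusTable | None = None,
    prominence: float = 0.5,
) -> list[Constriction]:
    """Interior local minima of the radius profile.

    A minimum qualifies when its prominence (depth relative to surrounding
    profile) is at least ``prominence`` angstrom.  Each constriction reports
    the lining residue(s) realizing the minimum and the ions whose hydrated
    radius exceeds the local radius (i.e. ions excluded there).
    """
    if profile.z.size == 0:
        raise ValueError("profile is empty")
    ions = ions or DEFAULT_IONS
    ok = np.array([f == "" for f in profile.flags])
    r = np.where(ok, profile.radius, profile.r_cap)
    idx, _ = find_peaks(-r, prominence=prominence)
    out: list[Constriction] = []
    for i in idx:
        lin = profile.lining[i]
        excluded = [name for name in ions.ions()
                    if ions.hydrated(name) > profile.radius[i]]
        out.append(
            Constriction(
                z=float(profile.z[i]),
                radius=float(profile.radius[i]),
                lining=[lin] if lin is not None else [],
                excluded_ions=excluded,
            )
        )
    return out


def classify_state(
    profile: PoreProfile, ions: IonRadiusTable | None = None
) -> dict[str, dict[str, float | bool]]:
    """Open/closed verdict per ion.

    Closed for an ion iff the profile's minimum radius is strictly below the
    ion's hydrated radius; a minimum radius exactly equal to the hydrated
    radius counts as open (strict-inequality convention).  The margin is
    ``hydrated_radius - min_radius`` (positive when closed).
    """
    if profile.z.size == 0:
        raise ValueError("profile is empty")
    ions = ions or DEFAULT_IONS
    rmin = profile.min_radius()
    verdict: dict[str, dict[str, float | bool]] = {}
    for name in ions.ions():
        rh = ions.hydrated(name)
        verdict[name] = {
            "closed": bool(rmin < rh),
            "margin": float(rh - rmin),
            "min_radius": rmin,
            "hydrated_radius": rh,
        }
    return verdict


def constriction_report(
    constrictions: list[Constriction],
    model: AtomicModel,
    index_map: IndexMap | None = None,
) -> str:
    """Human-readable constriction listing in dual native(model) numbering.

    Residue indices in the model are taken to be model (tagged-construct)
    numbering; tag residues are labelled as such.
    """
    resname_by_id = {(a.chain, a.resid): a.resname for a in model.atoms}
    lines = []
    for c in constrictions:
        labels = []
        for chain, resid, _atom in c.lining:
            rn = resname_by_id.get((chain, resid), "")
            code = _one_letter(rn)
            try:
                native = model_to_native_index(resid, index_map)
                labels.append(f"{chain}:{dual_label(native, code, index_map)}")
            except KeyError:
                labels.append(f"{chain}:{code}{resid}(tag)")
        ions = ", ".join(c.excluded_ions) if c.excluded_ions else "none"
        lines.append(
            f"constriction at z = {c.z:+.1f} A: radius {c.radius:.2f} A, "
            f"lined by {', '.join(labels) or 'n/a'}; excludes {ions}"
        )
    return "\n".join(lines)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _one_letter(resname: str) -> str:
    return _THREE_TO_ONE.get(resname.upper(), resname)
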