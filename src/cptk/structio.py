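"""Readers/writers for density maps, atomic models and trajectory tables,
plus residue-numbering bookkeeping between native and tagged constructs.

Maps use the MRC/CCP4 2014 container (via gemmi); models use PDB/mmCIF.
Trajectory tables are plain two-column text (time_ns, q_angstrom) with ``#``
comments, whitespace- or comma-delimited.

Conventions
-----------
Coordinates and map origins are absolute angstroms in a right-handed frame.
``DensityMap.values`` is indexed ``[ix, iy, iz]``; the position of voxel
``(i, j, k)`` is ``origin + (i, j, k) * voxel_size``.  Files whose axis
order differs are normalized at read time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "DensityMap",
    "Atom",
    "AtomicModel",
    "TimeSeries",
    "IndexMap",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "read_map",
    "write_map",
    "read_model",
    "write_model",
    "read_timeseries",
    "write_timeseries",
    "native_to_model_index",
    "model_to_native_index",
    "UnsupportedFormatError",
    "TagResidueError",
]

#: van der Waals radii in angstrom (Bondi 1964 for the common elements).
#: The table is deliberately small and configurable: pass ``vdw_table=`` to
#: :func:`read_model` to override entries.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 2.00,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 2.31,
    "K": 2.75,
    "NA": 2.27,
    "SE": 1.90,
    "X": 1.70,
}

#: Fallback radius for elements missing from the table (with a warning).
DEFAULT_VDW_RADIUS = 1.70


class UnsupportedFormatError(ValueError):
    """Raised for malformed or unsupported map/model files."""


class TagResidueError(KeyError):
    """Raised when a model index inside the inserted tag span is mapped back
    to native numbering (tag residues have no native equivalent)."""


# ---------------------------------------------------------------------------
# Density maps
# ---------------------------------------------------------------------------


@dataclass
class DensityMap:
    """A 3-D scalar grid with voxel size and origin in angstrom.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar density values (arbitrary units).
    voxel_size : array-like of 3 floats
        Angstrom per grid step along x, y, z.  Must be positive.
    origin : array-like of 3 floats
        Absolute position (angstrom) of voxel (0, 0, 0).
    symmetry_order : int, optional
        Rotational symmetry order of the content (e.g. 7 for C7), if known.
    """

    values: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    symmetry_order: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3).copy()
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3-D grid with dimensions >= 1")
        if not np.all(self.voxel_size > 0):
            raise ValueError("voxel_size must be positive on all axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates in angstrom."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.voxel_size[a]
            for a in range(3)
        )  # type: ignore[return-value]

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.origin.copy()
        hi = self.origin + (np.array(self.shape) - 1) * self.voxel_size
        return lo, hi

    def copy(self) -> "DensityMap":
        return DensityMap(
            self.values.copy(),
            self.voxel_size.copy(),
            self.origin.copy(),
            self.symmetry_order,
        )


def read_map(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 2014 map.

    Only orthogonal (P1, 90/90/90) cells are supported; axis order is
    normalized to x-fastest-in-memory ``[ix, iy, iz]`` indexing.
    """
    try:
        m = gemmi.read_ccp4_map(str(path), setup=True)
    except (RuntimeError, ValueError) as exc:
        raise UnsupportedFormatError(f"cannot read map {path}: {exc}") from exc
    cell = m.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3
        and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise UnsupportedFormatError(
            f"non-orthogonal map axes (angles {cell.alpha}, {cell.beta}, "
            f"{cell.gamma}) are not supported"
        )
    values = np.array(m.grid, copy=True, dtype=np.float64)  # indexed [ix, iy, iz]
    nx, ny, nz = values.shape
    voxel = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    # absolute origin: ORIGIN header words if set, else NXSTART-style offsets
    origin = np.array(
        [m.header_float(50), m.header_float(51), m.header_float(52)], dtype=float
    )
    if np.all(origin == 0.0):
        start = np.array(
            [m.header_i32(5), m.header_i32(6), m.header_i32(7)], dtype=float
        )
        origin = start * voxel
    return DensityMap(values, voxel, origin)


def write_map(dmap: DensityMap, path: str | Path) -> None:
    """Write ``dmap`` as an MRC/CCP4 2014 map (mode 2, float32)."""
    nx, ny, nz = dmap.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    grid.set_unit_cell(
        gemmi.UnitCell(
            nx * dmap.voxel_size[0],
            ny * dmap.voxel_size[1],
            nz * dmap.voxel_size[2],
            90.0,
            90.0,
            90.0,
        )
    )
    np.asarray(grid)[...] = dmap.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), dmap.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Atomic models
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    """One typed atom record."""

    chain: str
    resid: int
    resname: str
    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    vdw: float = DEFAULT_VDW_RADIUS

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("atom coordinates must be finite")
        if self.vdw <= 0:
            raise ValueError("vdW radius must be positive")


class AtomicModel:
    """An ordered collection of atom records with array views.

    The triple (chain, residue index, atom name) is unique within a model.
    """

    def __init__(self, atoms: list[Atom]):
        keys = {(a.chain, a.resid, a.name) for a in atoms}
        if len(keys) != len(atoms):
            raise ValueError("(chain, resid, atom name) must be unique")
        self.atoms = list(atoms)
        self._coords = (
            np.array([a.xyz for a in atoms], dtype=np.float64)
            if atoms
            else np.empty((0, 3))
        )
        self._vdw = np.array([a.vdw for a in atoms], dtype=np.float64)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in angstrom."""
        return self._coords

    @property
    def vdw_radii(self) -> np.ndarray:
        return self._vdw

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "AtomicModel":
        """Rigidly transformed copy (rotate about the origin, then translate)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        new = []
        for a in self.atoms:
            new.append(
                Atom(a.chain, a.resid, a.resname, a.name, a.element,
                     R @ a.xyz + t, a.occupancy, a.b_factor, a.vdw)
            )
        return AtomicModel(new)

    def with_vdw(self, delta: float = 0.0, table: dict[str, float] | None = None
                 ) -> "AtomicModel":
        """Copy with every vdW radius shifted by ``delta`` or reassigned from
        ``table`` (element lookup)."""
        new = []
        for a in self.atoms:
            r = table[a.element.upper()] if table is not None else a.vdw + delta
            new.append(Atom(a.chain, a.resid, a.resname, a.name, a.element,
                            a.xyz.copy(), a.occupancy, a.b_factor, r))
        return AtomicModel(new)


def _assign_vdw(element: str, table: dict[str, float], default: float) -> float:
    key = element.upper().strip()
    if key in table:
        return table[key]
    warnings.warn(
        f"unknown element {element!r}: assigning default vdW radius {default} A",
        stacklevel=3,
    )
    return default


def read_model(
    path: str | Path,
    vdw_table: dict[str, float] | None = None,
    default_vdw: float = DEFAULT_VDW_RADIUS,
) -> AtomicModel:
    """Read a PDB or mmCIF coordinate file into an :class:`AtomicModel`.

    vdW radii are assigned per element from ``vdw_table`` (default:
    :data:`VDW_RADII`); unknown elements get ``default_vdw`` with a warning.
    Only the first model of multi-model files is read.
    """
    table = dict(VDW_RADII if vdw_table is None else vdw_table)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise UnsupportedFormatError(f"cannot read model {path}: {exc}") from exc
    if len(st) == 0:
        raise UnsupportedFormatError(f"no models in {path}")
    atoms: list[Atom] = []
    for chain in st[0]:
        for res in chain:
            for at in res:
                elem = at.element.name if at.element else "X"
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resid=res.seqid.num,
                        resname=res.name,
                        name=at.name,
                        element=elem,
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        b_factor=at.b_iso,
                        vdw=_assign_vdw(elem, table, default_vdw),
                    )
                )
    return AtomicModel(atoms)


def write_model(model: AtomicModel, path: str | Path) -> None:
    """Write a model as PDB (``.pdb``) or mmCIF (``.cif``/``.mmcif``)."""
    st = gemmi.Structure()
    st.name = "cptk"
    md = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple[str, int], gemmi.Residue] = {}
    for a in model.atoms:
        if a.chain not in chain_map:
            chain_map[a.chain] = gemmi.Chain(a.chain)
        ch = chain_map[a.chain]
        key = (a.chain, a.resid)
        if key not in res_map:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resid, " ")
            ch.add_residue(res)
            res_map[key] = ch[-1]
        res = res_map[key]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.xyz)
        at.occ = a.occupancy
        at.b_iso = a.b_factor
        res.add_atom(at)
    for ch in chain_map.values():
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    p = str(path)
    if p.endswith((".cif", ".mmcif")):
        st.make_mmcif_document().write_file(p)
    else:
        st.write_pdb(p)


# ---------------------------------------------------------------------------
# Trajectory tables
# ---------------------------------------------------------------------------


@dataclass
class TimeSeries:
    """A 1-D reaction-coordinate trajectory.

    ``times`` in nanoseconds (strictly increasing), ``q`` in angstrom
    (signed displacement along the channel axis z).
    """

    times: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64).ravel()
        self.q = np.asarray(self.q, dtype=np.float64).ravel()
        if self.times.shape != self.q.shape:
            raise ValueError("times and q must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def truncated(self, t_max: float) -> "TimeSeries":
        """Samples with time <= t_max (cumulative block)."""
        mask = self.times <= t_max
        return TimeSeries(self.times[mask], self.q[mask])


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read a two-column (time_ns, q_angstrom) text table.

    Whitespace- or comma-delimited; lines starting with ``#`` are comments.
    """
    text = Path(path).read_text()
    body = "\n".join(ln for ln in text.splitlines()
                     if ln.strip() and not ln.lstrip().startswith("#"))
    delim = "," if "," in body else None
    data = np.loadtxt(str(path), comments="#", delimiter=delim, ndmin=2)
    if data.shape[1] < 2:
        raise UnsupportedFormatError(f"{path}: expected two columns (time, q)")
    return TimeSeries(data[:, 0], data[:, 1])


def write_timeseries(series: TimeSeries, path: str | Path) -> None:
    header = "time_ns q_angstrom"
    np.savetxt(str(path), np.column_stack([series.times, series.q]),
               header=header, fmt="%.8g")


# ---------------------------------------------------------------------------
# Dual residue numbering (native vs tagged construct)
# ---------------------------------------------------------------------------


@dataclass
class IndexMap:
    """Residue-numbering offset induced by an inserted affinity tag.

    The default describes an eight-residue Strep-tag (WSHPQFEK) inserted
    after native residue 172, so native index N maps to model index N for
    N <= 172 and N + 8 for N > 172 (the tag occupies model 173-180).
    Written N(model) in reports, e.g. E414(422).
    """

    insertion_site: int = 172
    tag_length: int = 8
    tag_sequence: str = "WSHPQFEK"

    def __post_init__(self) -> None:
        if self.tag_length != len(self.tag_sequence):
            raise ValueError("tag_length must equal len(tag_sequence)")

    @property
    def tag_span(self) -> range:
        """Model indices occupied by the tag."""
        return range(self.insertion_site + 1, self.insertion_site + 1 + self.tag_length)


def native_to_model_index(i: int, index_map: IndexMap | None = None) -> int:
    """Map a native residue index to the tagged-construct (model) index."""
    im = index_map or IndexMap()
    if i < 1:
        raise ValueError("residue index must be >= 1")
    return i if i <= im.insertion_site else i + im.tag_length


def model_to_native_index(i: int, index_map: IndexMap | None = None) -> int:
    """Inverse of :func:`native_to_model_index`.

    Raises :class:`TagResidueError` for model indices inside the tag span.
    """
    im = index_map or IndexMap()
    if i < 1:
        raise ValueError("residue index must be >= 1")
    if i in im.tag_span:
        raise TagResidueError(
            f"model residue {i} is part of the inserted tag "
            f"({im.tag_span.start}-{im.tag_span.stop - 1}); no native equivalent"
        )
    return i if i <= im.insertion_site else i - im.tag_length


def dual_label(native_index: int, resname: str = "",
               index_map: IndexMap | None = None) -> str:
    """Format a residue in dual native(model) numbering, e.g. ``E414(422)``."""
    model = native_to_model_index(native_index, index_map)
    return f"{resname}{native_index}({model})"
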