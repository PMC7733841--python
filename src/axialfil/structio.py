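"""Atomic-model container and structure I/O.

All coordinates are stored internally in nanometres; PDB/mmCIF files store
ångströms and are converted at the I/O boundary.  The Cartesian frame follows
the standard crystallographic orthogonalization: the *a*-axis lies along x,
*b* in the xy-plane, *c* completes a right-handed frame (so for a hexagonal
cell the *c*-axis is along z).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

NM_PER_ANGSTROM = 0.1
ANGSTROM_PER_NM = 10.0

#: elements the pipeline recognises (extend as needed; validation only)
KNOWN_ELEMENTS = frozenset(
    "H HE LI BE B C N O F NE NA MG AL SI P S CL AR K CA MN FE CO NI CU ZN SE BR I".split()
)


class FormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class GeometryError(ValueError):
    """Raised for degenerate cells or impossible geometric requests."""


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell; lengths in nm, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise GeometryError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise GeometryError(f"cell angles must lie in (0, 180): {self}")
        if self.volume <= 0 or not np.isfinite(self.volume):
            raise GeometryError(f"degenerate cell (zero volume): {self}")

    @property
    def frac_to_cart_matrix(self) -> np.ndarray:
        """3x3 matrix M with cart = M @ frac (nm)."""
        ca, cb, cg = (np.cos(np.deg2rad(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.deg2rad(self.gamma))
        v = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if v <= 0:
            raise GeometryError(f"degenerate cell: {self}")
        v = np.sqrt(v)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def cart_to_frac_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.frac_to_cart_matrix)

    @property
    def volume(self) -> float:
        """Cell volume in nm^3."""
        ca, cb, cg = (np.cos(np.deg2rad(x)) for x in (self.alpha, self.beta, self.gamma))
        v = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return float(self.a * self.b * self.c * np.sqrt(max(v, 0.0)))

    @property
    def is_hexagonal(self) -> bool:
        return (
            np.isclose(self.a, self.b, rtol=1e-6)
            and np.isclose(self.alpha, 90.0, atol=1e-6)
            and np.isclose(self.beta, 90.0, atol=1e-6)
            and np.isclose(self.gamma, 120.0, atol=1e-6)
        )

    @property
    def is_orthogonal(self) -> bool:
        return all(np.isclose(x, 90.0, atol=1e-6) for x in (self.alpha, self.beta, self.gamma))

    @property
    def heights(self) -> np.ndarray:
        """Perpendicular distances between opposite cell faces, in nm.

        height_i = V / area(face spanned by the other two axes); bounds the
        radius below which the wrapped fractional difference is the true
        periodic minimum image.
        """
        m = self.frac_to_cart_matrix
        av, bv, cv = m[:, 0], m[:, 1], m[:, 2]
        vol = abs(np.dot(av, np.cross(bv, cv)))
        return np.array(
            [
                vol / np.linalg.norm(np.cross(bv, cv)),
                vol / np.linalg.norm(np.cross(cv, av)),
                vol / np.linalg.norm(np.cross(av, bv)),
            ]
        )


def frac_to_cart(cell: UnitCell, frac: np.ndarray) -> np.ndarray:
    """Fractional -> Cartesian nm.  Accepts (3,) or (N, 3)."""
    return np.asarray(frac, dtype=float) @ cell.frac_to_cart_matrix.T


def cart_to_frac(cell: UnitCell, cart: np.ndarray) -> np.ndarray:
    """Cartesian nm -> fractional."""
    return np.asarray(cart, dtype=float) @ cell.cart_to_frac_matrix.T


@dataclass(frozen=True)
class Atom:
    """A single atom; convenience record for constructing small models."""

    element: str
    name: str
    res_name: str
    res_id: int
    chain_id: str
    position: tuple[float, float, float]  # Cartesian nm
    occupancy: float = 1.0
    b_factor: float = 0.0  # A^2
    hetero: bool = False

    def __post_init__(self) -> None:
        if self.element.upper() not in KNOWN_ELEMENTS:
            raise ValueError(f"unrecognized element symbol: {self.element!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must lie in [0, 1]: {self.occupancy}")


@dataclass
class AtomicModel:
    """Array-backed collection of atoms, the pipeline's universal currency.

    Coordinates (``xyz``) are Cartesian nm.  ``cell`` and ``space_group_name``
    may be absent for non-crystalline fragments.
    """

    element: np.ndarray  # (N,) str
    name: np.ndarray  # (N,) str
    res_name: np.ndarray  # (N,) str
    res_id: np.ndarray  # (N,) int
    chain_id: np.ndarray  # (N,) str
    xyz: np.ndarray  # (N, 3) float nm
    occupancy: np.ndarray  # (N,) float
    b_factor: np.ndarray  # (N,) float A^2
    hetero: np.ndarray = None  # (N,) bool
    cell: UnitCell | None = None
    space_group_name: str | None = None

    def __post_init__(self) -> None:
        n = len(self.xyz)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(n, 3)
        for attr in ("element", "name", "res_name", "chain_id"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype="U8"))
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        self.b_factor = np.asarray(self.b_factor, dtype=float)
        if self.hetero is None:
            self.hetero = np.zeros(n, dtype=bool)
        self.hetero = np.asarray(self.hetero, dtype=bool)
        for attr in ("element", "name", "res_name", "res_id", "chain_id", "occupancy", "b_factor", "hetero"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"field {attr!r} length mismatch ({len(getattr(self, attr))} != {n})")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_atoms(
        cls,
        atoms: Sequence[Atom],
        cell: UnitCell | None = None,
        space_group_name: str | None = None,
    ) -> "AtomicModel":
        return cls(
            element=np.array([a.element for a in atoms], dtype="U8"),
            name=np.array([a.name for a in atoms], dtype="U8"),
            res_name=np.array([a.res_name for a in atoms], dtype="U8"),
            res_id=np.array([a.res_id for a in atoms], dtype=int),
            chain_id=np.array([a.chain_id for a in atoms], dtype="U8"),
            xyz=np.array([a.position for a in atoms], dtype=float).reshape(len(atoms), 3),
            occupancy=np.array([a.occupancy for a in atoms], dtype=float),
            b_factor=np.array([a.b_factor for a in atoms], dtype=float),
            hetero=np.array([a.hetero for a in atoms], dtype=bool),
            cell=cell,
            space_group_name=space_group_name,
        )

    @classmethod
    def empty(cls, cell: UnitCell | None = None, space_group_name: str | None = None) -> "AtomicModel":
        z = np.zeros(0)
        return cls(
            element=np.zeros(0, dtype="U8"),
            name=np.zeros(0, dtype="U8"),
            res_name=np.zeros(0, dtype="U8"),
            res_id=np.zeros(0, dtype=int),
            chain_id=np.zeros(0, dtype="U8"),
            xyz=np.zeros((0, 3)),
            occupancy=z.copy(),
            b_factor=z.copy(),
            hetero=np.zeros(0, dtype=bool),
            cell=cell,
            space_group_name=space_group_name,
        )

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.xyz)

    def __iter__(self) -> Iterator[Atom]:
        for i in range(len(self)):
            yield Atom(
                element=str(self.element[i]),
                name=str(self.name[i]),
                res_name=str(self.res_name[i]),
                res_id=int(self.res_id[i]),
                chain_id=str(self.chain_id[i]),
                position=tuple(self.xyz[i]),
                occupancy=float(self.occupancy[i]),
                b_factor=float(self.b_factor[i]),
                hetero=bool(self.hetero[i]),
            )

    def select(self, mask: np.ndarray) -> "AtomicModel":
        return AtomicModel(
            element=self.element[mask],
            name=self.name[mask],
            res_name=self.res_name[mask],
            res_id=self.res_id[mask],
            chain_id=self.chain_id[mask],
            xyz=self.xyz[mask],
            occupancy=self.occupancy[mask],
            b_factor=self.b_factor[mask],
            hetero=self.hetero[mask],
            cell=self.cell,
            space_group_name=self.space_group_name,
        )

    def with_(self, **changes) -> "AtomicModel":
        return replace(self, **changes)

    @staticmethod
    def concatenate(models: Sequence["AtomicModel"]) -> "AtomicModel":
        if not models:
            raise ValueError("need at least one model to concatenate")
        first = models[0]
        return AtomicModel(
            element=np.concatenate([m.element for m in models]),
            name=np.concatenate([m.name for m in models]),
            res_name=np.concatenate([m.res_name for m in models]),
            res_id=np.concatenate([m.res_id for m in models]),
            chain_id=np.concatenate([m.chain_id for m in models]),
            xyz=np.concatenate([m.xyz for m in models]),
            occupancy=np.concatenate([m.occupancy for m in models]),
            b_factor=np.concatenate([m.b_factor for m in models]),
            hetero=np.concatenate([m.hetero for m in models]),
            cell=first.cell,
            space_group_name=first.space_group_name,
        )

    # -- crystallographic helpers ------------------------------------------

    def frac(self) -> np.ndarray:
        if self.cell is None:
            raise GeometryError("model has no unit cell; fractional coordinates undefined")
        return cart_to_frac(self.cell, self.xyz)

    def wrapped(self) -> "AtomicModel":
        """Return a copy with fractional coordinates wrapped into [0, 1)."""
        f = self.frac() % 1.0
        return self.with_(xyz=frac_to_cart(self.cell, f))


# ---------------------------------------------------------------------------
# gemmi-backed reading and writing


def _normalize_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        suffix = Path(path).suffix.lower()
        fmt = {".cif": "mmcif", ".mmcif": "mmcif", ".pdb": "pdb", ".ent": "pdb"}.get(suffix, "")
    if fmt not in ("mmcif", "pdb"):
        raise ValueError(f"unsupported structure format {format or Path(path).suffix!r}; use 'mmcif' or 'pdb'")
    return fmt


def read_structure(path: str | Path, format: str | None = None) -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel` (nm units).

    Alternate conformations: the blank or 'A' altloc is kept, others dropped
    (count logged).  Zero-occupancy atoms are retained; strip them explicitly
    with :func:`strip_zero_occupancy`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _normalize_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path.name} as {fmt}: {exc}") from exc

    if len(st) == 0:
        raise FormatError(f"{path.name}: no coordinate model found")

    cell = None
    if st.cell is not None and st.cell.a > 0 and st.cell.is_crystal():
        cell = UnitCell(
            st.cell.a * NM_PER_ANGSTROM,
            st.cell.b * NM_PER_ANGSTROM,
            st.cell.c * NM_PER_ANGSTROM,
            st.cell.alpha,
            st.cell.beta,
            st.cell.gamma,
        )
    else:
        warnings.warn(f"{path.name}: no unit cell recorded; model returned without cell")

    sg = st.spacegroup_hm if st.spacegroup_hm else None

    atoms: list[Atom] = []
    n_altloc_dropped = 0
    model = st[0]
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            for atom in residue:
                if atom.altloc not in ("", "A", "\x00"):
                    n_altloc_dropped += 1
                    continue
                el = atom.element.name.upper() if atom.element else atom.name[:1].upper()
                atoms.append(
                    Atom(
                        element=el,
                        name=atom.name,
                        res_name=residue.name,
                        res_id=residue.seqid.num,
                        chain_id=chain.name,
                        position=(
                            atom.pos.x * NM_PER_ANGSTROM,
                            atom.pos.y * NM_PER_ANGSTROM,
                            atom.pos.z * NM_PER_ANGSTROM,
                        ),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        b_factor=atom.b_iso,
                        hetero=het,
                    )
                )
    if n_altloc_dropped:
        logger.info("%s: dropped %d alternate-conformation atoms (kept altloc ''/'A')", path.name, n_altloc_dropped)
    if not atoms:
        raise FormatError(f"{path.name}: no atoms parsed")
    out = AtomicModel.from_atoms(atoms, cell=cell, space_group_name=sg)
    n_zero = int(np.sum(out.occupancy == 0.0))
    if n_zero:
        logger.info("%s: %d atoms have occupancy 0.0 (flagged removable)", path.name, n_zero)
    return out


def strip_zero_occupancy(model: AtomicModel) -> AtomicModel:
    """Return the model restricted to atoms with occupancy > 0 (order kept)."""
    mask = model.occupancy > 0.0
    if not mask.any():
        warnings.warn("all atoms have occupancy 0.0; returning an empty model")
    return model.select(mask)


def strip_hetero(model: AtomicModel) -> AtomicModel:
    """Drop non-polymer (HETATM) records: ligands, waters, ions."""
    return model.select(~model.hetero)


_PDB_MAX_ATOMS = 99999


def write_structure(model: AtomicModel, path: str | Path, format: str | None = None) -> None:
    """Write the model as mmCIF or PDB (coordinates converted nm -> A)."""
    if len(model) == 0:
        raise ValueError("refusing to write an empty model")
    path = Path(path)
    fmt = _normalize_format(path, format)
    if fmt == "pdb" and len(model) > _PDB_MAX_ATOMS:
        raise ValueError(
            f"{len(model)} atoms exceed the fixed-width PDB serial field ({_PDB_MAX_ATOMS}); write mmCIF instead"
        )

    st = gemmi.Structure()
    st.name = path.stem
    if model.cell is not None:
        st.cell = gemmi.UnitCell(
            model.cell.a * ANGSTROM_PER_NM,
            model.cell.b * ANGSTROM_PER_NM,
            model.cell.c * ANGSTROM_PER_NM,
            model.cell.alpha,
            model.cell.beta,
            model.cell.gamma,
        )
    if model.space_group_name:
        st.spacegroup_hm = model.space_group_name

    # group atoms into (chain, residue) runs; gemmi's add_* copy their
    # argument, so each object is fully built before insertion
    chain_order: list[str] = []
    residues: dict[str, list[tuple[tuple, list[int]]]] = {}
    for i in range(len(model)):
        cid = str(model.chain_id[i])
        key = (int(model.res_id[i]), str(model.res_name[i]), bool(model.hetero[i]))
        if cid not in residues:
            residues[cid] = []
            chain_order.append(cid)
        if not residues[cid] or residues[cid][-1][0] != key:
            residues[cid].append((key, []))
        residues[cid][-1][1].append(i)

    gm = gemmi.Model("1")
    for cid in chain_order:
        chain = gemmi.Chain(cid)
        for (res_id, res_name, het), idx in residues[cid]:
            residue = gemmi.Residue()
            residue.name = res_name
            residue.seqid = gemmi.SeqId(res_id, " ")
            residue.het_flag = "H" if het else "A"
            for i in idx:
                at = gemmi.Atom()
                at.name = str(model.name[i])
                at.element = gemmi.Element(str(model.element[i]).capitalize())
                at.pos = gemmi.Position(*(model.xyz[i] * ANGSTROM_PER_NM))
                at.occ = float(model.occupancy[i])
                at.b_iso = float(model.b_factor[i])
                residue.add_atom(at)
            chain.add_residue(residue)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()

    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))
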