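"""Space-group expansion of an asymmetric unit and supercell construction.

Only the two groups the axial-filament pipeline needs are supported: the
trigonal group P3(1)21 (IT #152, general-position multiplicity 6 — six
protein molecules per hexagonal cell) and trivial P1.  The operator table is
hard-coded from the International Tables general positions and is small
enough to audit by eye; tests verify closure and agreement with gemmi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .structio import AtomicModel, GeometryError, UnitCell, frac_to_cart


@dataclass(frozen=True)
class SymOp:
    """Symmetry operator in the fractional basis: x' = R @ x + t."""

    rotation: tuple  # 3x3 nested tuple of ints
    translation: tuple  # length-3 tuple of Fractions/floats

    @property
    def R(self) -> np.ndarray:
        return np.array(self.rotation, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return np.array([float(x) for x in self.translation])

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates (no wrapping); (3,) or (N, 3)."""
        return np.asarray(frac, dtype=float) @ self.R.T + self.t

    def compose(self, other: "SymOp") -> "SymOp":
        """self after other, translation reduced modulo lattice."""
        r = np.array(self.rotation, dtype=int) @ np.array(other.rotation, dtype=int)
        tr = np.array(self.rotation, dtype=int) @ np.array(
            [Fraction(x).limit_denominator(12) for x in other.translation], dtype=object
        ) + np.array([Fraction(x).limit_denominator(12) for x in self.translation], dtype=object)
        tr = tuple(x % 1 for x in tr)
        return SymOp(tuple(map(tuple, r.tolist())), tr)

    def triplet(self) -> str:
        """Human-readable x,y,z style triplet."""
        names = "xyz"
        parts = []
        for row, tr in zip(self.rotation, self.translation):
            s = ""
            for coef, nm in zip(row, names):
                if coef == 1:
                    s += ("+" if s else "") + nm
                elif coef == -1:
                    s += "-" + nm
            f = Fraction(tr).limit_denominator(12)
            if f:
                s += f"+{f}" if f > 0 else f"{f}"
            parts.append(s)
        return ",".join(parts)


IDENTITY = SymOp(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0, 0, 0))

_F13 = Fraction(1, 3)
_F23 = Fraction(2, 3)

#: International Tables general positions of P3(1)21:
#: x,y,z; -y,x-y,z+1/3; -x+y,-x,z+2/3; y,x,-z; x-y,-y,-z+2/3; -x,-x+y,-z+1/3
P3121_OPS: tuple[SymOp, ...] = (
    IDENTITY,
    SymOp(((0, -1, 0), (1, -1, 0), (0, 0, 1)), (0, 0, _F13)),
    SymOp(((-1, 1, 0), (-1, 0, 0), (0, 0, 1)), (0, 0, _F23)),
    SymOp(((0, 1, 0), (1, 0, 0), (0, 0, -1)), (0, 0, 0)),
    SymOp(((1, -1, 0), (0, -1, 0), (0, 0, -1)), (0, 0, _F23)),
    SymOp(((-1, 0, 0), (-1, 1, 0), (0, 0, -1)), (0, 0, _F13)),
)


@dataclass(frozen=True)
class SpaceGroup:
    name: str
    number: int
    ops: tuple[SymOp, ...]

    @property
    def multiplicity(self) -> int:
        return len(self.ops)


P1 = SpaceGroup("P1", 1, (IDENTITY,))
P3121 = SpaceGroup("P3121", 152, P3121_OPS)

_ALIASES = {
    "P1": P1,
    "P 1": P1,
    "P3121": P3121,
    "P 31 2 1": P3121,
    "P31 21": P3121,
    "P 3121": P3121,
}


def get_space_group(name: str) -> SpaceGroup:
    """Look up a supported space group by (forgivingly normalized) name."""
    key = name.strip().upper().replace("(", "").replace(")", "")
    sg = _ALIASES.get(key) or _ALIASES.get(key.replace(" ", ""))
    if sg is None:
        supported = sorted({g.name for g in _ALIASES.values()})
        raise ValueError(f"unsupported space group {name!r}; supported: {supported}")
    return sg


def apply_symop(op: SymOp, frac: np.ndarray) -> np.ndarray:
    """Apply an operator to fractional coordinates and wrap into [0, 1)."""
    return op.apply(frac) % 1.0


def expand_to_p1(model: AtomicModel, sg: SpaceGroup) -> AtomicModel:
    """Expand an asymmetric unit to the full P1 cell.

    Each operator produces one symmetry copy; chain identifiers get a
    per-operator suffix so the copies stay distinguishable.  Molecules
    (grouped by chain) are kept whole: each copy is wrapped into the cell by
    its centroid, never atom-by-atom.  Overlapping copies (special
    positions) are not merged; a warning reports the overlap count.
    """
    if model.cell is None:
        raise GeometryError("expand_to_p1 requires a model with a unit cell")
    if len(model) == 0:
        return model.with_(space_group_name="P1")
    frac = model.frac()
    chains = model.chain_id
    copies: list[AtomicModel] = []
    for i, op in enumerate(sg.ops):
        f = op.apply(frac)
        # wrap per molecule (chain) by centroid
        for cid in np.unique(chains):
            m = chains == cid
            f[m] -= np.floor(f[m].mean(axis=0))
        suffix = "" if i == 0 else str(i)
        copies.append(
            model.with_(
                xyz=frac_to_cart(model.cell, f),
                chain_id=np.array([c + suffix for c in chains], dtype="U8"),
            )
        )
    out = AtomicModel.concatenate(copies)
    out.cell = model.cell
    out.space_group_name = "P1"

    if sg.multiplicity > 1:
        n_overlap = _count_coincident(out, model.cell)
        if n_overlap:
            warnings.warn(f"{n_overlap} atom pairs coincide between symmetry copies (special position?)")
    return out


def _count_coincident(model: AtomicModel, cell: UnitCell, tol: float = 1e-4) -> int:
    """Count atom pairs closer than `tol` fractional (cheap grid check)."""
    f = model.frac() % 1.0
    key = np.round(f / tol).astype(np.int64)
    _, counts = np.unique(key, axis=0, return_counts=True)
    return int(np.sum(counts * (counts - 1) // 2))


def build_supercell(model: AtomicModel, na: int, nb: int, nc: int) -> AtomicModel:
    """Replicate a P1 cell na x nb x nc; cell lengths scale accordingly."""
    if min(na, nb, nc) < 1:
        raise ValueError(f"replication counts must be positive: {(na, nb, nc)}")
    if model.cell is None:
        raise GeometryError("build_supercell requires a model with a unit cell")
    if model.space_group_name not in (None, "P1"):
        raise ValueError("build_supercell expects a P1 model; call expand_to_p1 first")
    cell = model.cell
    new_cell = UnitCell(cell.a * na, cell.b * nb, cell.c * nc, cell.alpha, cell.beta, cell.gamma)
    if (na, nb, nc) == (1, 1, 1):
        return model.with_(cell=new_cell)
    copies = []
    shift_idx = 0
    for i in range(na):
        for j in range(nb):
            for k in range(nc):
                shift = frac_to_cart(cell, np.array([i, j, k], dtype=float))
                suffix = "" if shift_idx == 0 else f"s{shift_idx}"
                copies.append(
                    model.with_(
                        xyz=model.xyz + shift,
                        chain_id=np.array([c + suffix for c in model.chain_id], dtype="U8"),
                    )
                )
                shift_idx += 1
    out = AtomicModel.concatenate(copies)
    out.cell = new_cell
    out.space_group_name = "P1"
    return out


def min_interchain_distance(model: AtomicModel) -> float:
    """Minimum periodic distance between atoms of different chains, in nm.

    Brute force with the wrapped-fractional minimum image; valid while
    distances of interest stay below half the smallest cell height.
    """
    if model.cell is None:
        raise GeometryError("needs a cell")
    f = model.frac() % 1.0
    chains = model.chain_id
    m = model.cell.frac_to_cart_matrix
    best = np.inf
    uniq = np.unique(chains)
    for i, ca in enumerate(uniq):
        fa = f[chains == ca]
        for cb in uniq[i + 1 :]:
            fb = f[chains == cb]
            d = fa[:, None, :] - fb[None, :, :]
            d -= np.round(d)
            cart = d @ m.T
            best = min(best, float(np.sqrt((cart**2).sum(axis=2).min())))
    return best
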