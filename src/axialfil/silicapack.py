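"""Amorphous-silica void filling of the expanded protein crystal.

The hybrid model is built by random sequential insertion of independent Si
and O atoms at 1:2 stoichiometry into the periodic cell, subject to hard
minimum-distance constraints: every filler atom stays at least
``protein_exclusion`` (default 0.4 nm, i.e. 4 A) from every protein atom,
and filler-filler pairs respect species-dependent minima.  This realizes the
"silica randomly dispersed in the void" picture without any packing physics:
downstream projections and multislice contrast depend only on species and
positions at the resolution of interest.

Placement uses a periodic cell-list grid in fractional space; the
independent check is :func:`verify_packing`, an all-pairs brute-force
verifier.  Packing is bit-for-bit reproducible from (model, config).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structio import AtomicModel, UnitCell

AVOGADRO = 6.02214076e23
SIO2_MOLAR_MASS = 60.0843  # g/mol

# g/cm^3 contributed by one SiO2 unit per nm^3
_DENSITY_PER_UNIT = SIO2_MOLAR_MASS / AVOGADRO / 1e-21


@dataclass(frozen=True)
class FillConfig:
    """Parameters of the amorphous-silica fill.

    Distances in nm.  The filler-filler minima default to values that a
    random sequential insertion can satisfy at amorphous-silica density
    (2.2 g/cm^3); a bonded-network model could support larger nonbonded
    minima, but hard-sphere insertion jams well below that density if they
    are imposed on all pairs.
    """

    protein_exclusion: float = 0.4
    si_si_min: float = 0.26
    si_o_min: float = 0.15
    o_o_min: float = 0.22
    target_density: float = 2.2  # g/cm^3 of SiO2 over the whole cell
    max_attempts_per_atom: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for nm_ in ("protein_exclusion", "si_si_min", "si_o_min", "o_o_min"):
            if getattr(self, nm_) <= 0:
                raise ValueError(f"{nm_} must be > 0")
        if not 0.0 < self.target_density <= 3.0:
            raise ValueError("target_density must lie in (0, 3.0] g/cm^3")
        if self.max_attempts_per_atom < 1:
            raise ValueError("max_attempts_per_atom must be >= 1")


@dataclass
class PackingReport:
    n_si: int
    n_o: int
    achieved_density: float  # g/cm^3
    void_fraction: float
    attempts: int
    seed: int
    n_violations: int = 0
    violations: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_si": self.n_si,
            "n_o": self.n_o,
            "achieved_density_g_cm3": self.achieved_density,
            "void_fraction": self.void_fraction,
            "attempts": self.attempts,
            "seed": self.seed,
            "n_violations": self.n_violations,
        }


FILLER_RES_NAME = "SIL"


def target_unit_count(cell: UnitCell, target_density: float) -> int:
    """Number of SiO2 units corresponding to `target_density` over the cell."""
    return int(round(target_density * cell.volume / _DENSITY_PER_UNIT))


def _pair_limit_matrix(config: FillConfig) -> np.ndarray:
    """Squared distance limits indexed by species codes (0=protein, 1=Si, 2=O)."""
    lim = np.zeros((3, 3))
    lim[0, 1] = lim[1, 0] = config.protein_exclusion
    lim[0, 2] = lim[2, 0] = config.protein_exclusion
    lim[1, 1] = config.si_si_min
    lim[1, 2] = lim[2, 1] = config.si_o_min
    lim[2, 2] = config.o_o_min
    return lim**2


class _CellList:
    """Periodic cell-list over fractional coordinates of a triclinic cell."""

    def __init__(self, cell: UnitCell, cutoff: float, capacity: int):
        h = cell.heights
        self.nbins = np.maximum(1, np.floor(h / cutoff).astype(int))
        self.M = cell.frac_to_cart_matrix
        self.bins: dict[tuple, list[int]] = {}
        self.frac = np.zeros((capacity, 3))
        self.species = np.zeros(capacity, dtype=np.int8)
        self.n = 0
        # neighbor offsets, deduplicated for small bin counts
        offs = np.array(np.meshgrid(*[[-1, 0, 1]] * 3, indexing="ij")).reshape(3, -1).T
        self._offs = offs

    def _bin(self, f: np.ndarray) -> tuple:
        return tuple(((f % 1.0) * self.nbins).astype(int) % self.nbins)

    def add(self, f: np.ndarray, species: int) -> None:
        i = self.n
        self.frac[i] = f % 1.0
        self.species[i] = species
        self.bins.setdefault(self._bin(f), []).append(i)
        self.n += 1

    def neighbor_indices(self, f: np.ndarray) -> np.ndarray:
        b = np.array(self._bin(f))
        cells = {tuple((b + o) % self.nbins) for o in self._offs}
        idx: list[int] = []
        for c in cells:
            idx.extend(self.bins.get(c, ()))
        return np.array(idx, dtype=int)

    def admissible(self, f: np.ndarray, species: int, lim2: np.ndarray) -> bool:
        idx = self.neighbor_indices(f)
        if idx.size == 0:
            return True
        d = (f % 1.0) - self.frac[idx]
        d -= np.round(d)
        cart = d @ self.M.T
        dd = np.einsum("ij,ij->i", cart, cart)
        return bool(np.all(dd >= lim2[species, self.species[idx]]))


def pack_silica(model: AtomicModel, config: FillConfig) -> tuple[AtomicModel, PackingReport]:
    """Fill the void of a P1 cell with Si/O atoms under distance constraints.

    Returns the combined model (protein + filler, filler residues named
    ``SIL``) and a :class:`PackingReport`.  Deterministic given
    ``config.seed``.  If the configuration admits no insertions the filler
    is empty and a warning is raised.
    """
    if model.cell is None:
        raise ValueError("pack_silica requires a model with a unit cell")
    cell = model.cell
    rng = np.random.default_rng(config.seed)
    lim2 = _pair_limit_matrix(config)
    n_units = target_unit_count(cell, config.target_density)
    cutoff = max(config.protein_exclusion, config.si_si_min, config.si_o_min, config.o_o_min)
    clist = _CellList(cell, cutoff, capacity=len(model) + 3 * n_units)

    prot_frac = (model.frac() % 1.0) if len(model) else np.zeros((0, 3))
    for f in prot_frac:
        clist.add(f, 0)

    placed_frac: list[np.ndarray] = []
    placed_species: list[int] = []
    attempts = 0
    consecutive_failures = 0
    max_consecutive_failures = 50
    M = cell.frac_to_cart_matrix
    for _unit in range(n_units):
        # transactional: the whole SiO2 unit is committed or discarded, so
        # the 1:2 stoichiometry is exact by construction
        pending_f: list[np.ndarray] = []
        pending_sp: list[int] = []
        unit_ok = True
        for sp in (1, 2, 2):  # Si, O, O
            ok = False
            for _ in range(config.max_attempts_per_atom):
                attempts += 1
                f = rng.random(3)
                if not clist.admissible(f, sp, lim2):
                    continue
                if pending_f:
                    d = (f % 1.0) - np.array(pending_f)
                    d -= np.round(d)
                    dd = np.einsum("ij,ij->i", d @ M.T, d @ M.T)
                    if np.any(dd < lim2[sp, np.array(pending_sp)]):
                        continue
                pending_f.append(f % 1.0)
                pending_sp.append(sp)
                ok = True
                break
            if not ok:
                unit_ok = False
                break
        if unit_ok:
            for f, sp in zip(pending_f, pending_sp):
                clist.add(f, sp)
                placed_frac.append(f)
                placed_species.append(sp)
            consecutive_failures = 0
        else:
            consecutive_failures += 1
            if consecutive_failures >= max_consecutive_failures:
                break

    n_si = placed_species.count(1)
    n_o = placed_species.count(2)
    if n_si + n_o == 0:
        warnings.warn("packing placed no filler atoms (unsatisfiable exclusions or zero void)")

    # Monte-Carlo estimate of the void fraction (volume beyond the protein
    # exclusion), with its own deterministic stream.
    vf_rng = np.random.default_rng(config.seed + 1)
    n_probe = 2000
    probes = vf_rng.random((n_probe, 3))
    if len(model):
        free = np.fromiter(
            (clistp_admissible(probes[i], prot_frac, cell, config.protein_exclusion) for i in range(n_probe)),
            dtype=bool,
            count=n_probe,
        )
        void_fraction = float(free.mean())
    else:
        void_fraction = 1.0

    achieved = (n_si * _DENSITY_PER_UNIT) / cell.volume if n_si else 0.0
    report = PackingReport(
        n_si=n_si,
        n_o=n_o,
        achieved_density=achieved,
        void_fraction=void_fraction,
        attempts=attempts,
        seed=config.seed,
    )

    if n_si + n_o == 0:
        return model.with_(space_group_name="P1"), report

    frac = np.array(placed_frac)
    species = np.array(placed_species)
    xyz = frac @ cell.frac_to_cart_matrix.T
    n_fill = len(frac)
    filler = AtomicModel(
        element=np.where(species == 1, "SI", "O").astype("U8"),
        name=np.where(species == 1, "SI", "O").astype("U8"),
        res_name=np.full(n_fill, FILLER_RES_NAME, dtype="U8"),
        res_id=np.arange(n_fill) // 3 + 1,
        chain_id=np.full(n_fill, "Z", dtype="U8"),
        xyz=xyz,
        occupancy=np.ones(n_fill),
        b_factor=np.zeros(n_fill),
        hetero=np.ones(n_fill, dtype=bool),
        cell=cell,
        space_group_name="P1",
    )
    combined = AtomicModel.concatenate([model, filler]) if len(model) else filler
    combined.cell = cell
    combined.space_group_name = "P1"
    return combined, report


def clistp_admissible(f: np.ndarray, prot_frac: np.ndarray, cell: UnitCell, cutoff: float) -> bool:
    """Brute-force: is fractional point `f` at least `cutoff` from all protein atoms?"""
    if len(prot_frac) == 0:
        return True
    d = f - prot_frac
    d -= np.round(d)
    cart = d @ cell.frac_to_cart_matrix.T
    return bool(np.min(np.einsum("ij,ij->i", cart, cart)) >= cutoff**2)


def verify_packing(model: AtomicModel, config: FillConfig) -> PackingReport:
    """Independently re-check all packing constraints by brute force.

    All filler-filler and filler-protein pairs are measured with the
    periodic minimum image (wrapped fractional difference; exact while the
    constraint distances stay below half the smallest cell height, which is
    asserted).  Returns a report whose ``n_violations`` must be zero for any
    :func:`pack_silica` output.
    """
    if model.cell is None:
        raise ValueError("verify_packing requires a model with a unit cell")
    cell = model.cell
    if max(config.protein_exclusion, config.si_si_min, config.si_o_min, config.o_o_min) >= min(cell.heights) / 2:
        raise ValueError("constraint distances too large for minimum-image verification in this cell")
    is_filler = model.res_name == FILLER_RES_NAME
    if len(model) and not is_filler.any() and not (~is_filler).any():
        raise ValueError("model atoms do not distinguish protein from filler")
    elem = np.char.upper(model.element.astype(str))
    species = np.where(is_filler & (elem == "SI"), 1, np.where(is_filler, 2, 0))
    if np.any(is_filler & ~np.isin(elem, ("SI", "O"))):
        raise ValueError("filler residues contain elements other than Si/O")

    f = model.frac() % 1.0
    m = cell.frac_to_cart_matrix
    lim2 = _pair_limit_matrix(config)
    fill_idx = np.flatnonzero(is_filler)
    other_idx = np.arange(len(model))
    violations: list[tuple[int, int, float]] = []
    chunk = 256
    for s in range(0, len(fill_idx), chunk):
        ii = fill_idx[s : s + chunk]
        d = f[ii][:, None, :] - f[None, :, :]
        d -= np.round(d)
        cart = d @ m.T
        dd = (cart**2).sum(axis=2)
        lim = lim2[species[ii]][:, species[other_idx]]
        bad = (dd < lim) & (ii[:, None] != other_idx[None, :])
        for a, b in zip(*np.nonzero(bad)):
            i, j = int(ii[a]), int(other_idx[b])
            if i < j or not is_filler[j]:  # count each pair once
                violations.append((i, j, float(np.sqrt(dd[a, b]))))

    n_si = int(np.sum(species == 1))
    n_o = int(np.sum(species == 2))
    achieved = (n_si * _DENSITY_PER_UNIT) / cell.volume if n_si else 0.0
    vf_rng = np.random.default_rng(config.seed + 1)
    probes = vf_rng.random((2000, 3))
    prot_frac = f[~is_filler]
    if len(prot_frac):
        free = np.array([clistp_admissible(p, prot_frac, cell, config.protein_exclusion) for p in probes])
        void_fraction = float(free.mean())
    else:
        void_fraction = 1.0
    return PackingReport(
        n_si=n_si,
        n_o=n_o,
        achieved_density=achieved,
        void_fraction=void_fraction,
        attempts=0,
        seed=config.seed,
        n_violations=len(violations),
        violations=violations,
    )
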