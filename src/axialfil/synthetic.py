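"""Desk-scale synthetic fixtures.

Everything the pipeline consumes can be generated here without downloads:

* a toy P3(1)21 crystal -- a self-avoiding pseudo-protein polymer placed at
  a general position of a small hexagonal cell, optionally with a planted
  Ser/His/Asn triad whose OG -> imidazole-ring distances are hand-set (both
  the as-built distance and the minimum reachable by a chi1 rotation);
* noisy reference images standing in for experimental micrographs;
* synthetic C-alpha model pairs and sequence pairs with planted
  ground-truth deviations, for exercising superposition and identity
  analysis when no deposited comparator structure is at hand.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .structio import ANGSTROM_PER_NM, Atom, AtomicModel, UnitCell, frac_to_cart
from .symmetry import expand_to_p1, get_space_group, min_interchain_distance
from .emsim import ImageGrid

#: general position maximizing the minimum inter-copy distance in the
#: default toy cell (found by grid search over the P3(1)21 orbit)
_DEFAULT_CENTER_FRAC = np.array([0.34, 0.68, 0.08])


@dataclass(frozen=True)
class ToyCrystalSpec:
    cell: UnitCell = field(default_factory=lambda: UnitCell(2.0, 2.0, 4.0, 90.0, 90.0, 120.0))
    n_residues: int = 20
    sg_name: str = "P3121"
    include_triad: bool = False
    seed: int = 0
    #: as-built Ser OG -> His ring minimum distance, A
    triad_distance: float = 3.6
    #: minimum OG -> ring distance reachable by rotating chi1, A
    triad_scan_minimum: float = 2.9

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if not self.cell.is_hexagonal:
            raise ValueError("toy crystal requires a hexagonal cell")


def toy_triad_ids(spec: ToyCrystalSpec) -> dict[str, int]:
    """Residue ids of the planted triad (silicatein-style numbering when free)."""
    n = spec.n_residues
    if n < 26:
        return {"SER": 26, "HIS": 165, "ASN": 185}
    return {"SER": n + 26, "HIS": n + 165, "ASN": n + 185}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    p = _unit(np.cross(ref, u))
    return p, np.cross(u, p)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _build_chain(rng: np.random.Generator, n_residues: int, radius: float) -> list[tuple[str, np.ndarray]]:
    """Self-avoiding pseudo-residue walk inside a sphere at the origin.

    Each residue contributes N, CA, C, O, CB at fixed local geometry
    (chemically naive; sufficient for symmetry, packing and contrast
    tests).  Returns (atom_name, position) pairs.
    """
    step = 0.20
    clash = 0.07
    placed: list[np.ndarray] = []
    atoms: list[tuple[str, np.ndarray]] = []
    ca = rng.normal(size=3)
    ca = ca / np.linalg.norm(ca) * radius * 0.3
    prev_dir = _unit(rng.normal(size=3))
    for _res in range(n_residues):
        for attempt in range(400):
            # persistent walk at first; fully random direction when stuck
            bias = prev_dir if attempt < 100 else np.zeros(3)
            d = _unit(bias + 0.8 * rng.normal(size=3))
            new_ca = ca + step * d if _res else ca
            if np.linalg.norm(new_ca) > radius:
                continue
            e1 = d
            e2, e3 = _perp_basis(e1)
            local = {
                "N": new_ca - 0.10 * e1 + 0.05 * e2,
                "CA": new_ca,
                "C": new_ca + 0.10 * e1 + 0.05 * e2,
                "O": new_ca + 0.10 * e1 + 0.14 * e2,
                "CB": new_ca + 0.10 * e3,
            }
            cand = list(local.values())
            ok = True
            check = placed[:-5]  # exclude the bonded previous residue
            if check:
                arr = np.array(check)
                for c in cand:
                    if np.min(np.linalg.norm(arr - c, axis=1)) < clash:
                        ok = False
                        break
            if ok:
                for nm in ("N", "CA", "C", "O", "CB"):
                    atoms.append((nm, local[nm]))
                    placed.append(local[nm])
                ca, prev_dir = new_ca, d
                break
        else:
            raise RuntimeError(
                "could not grow the toy chain without clashes; use a larger cell or fewer residues"
            )
    return atoms


def _build_triad(distance_nm: float, scan_min_nm: float) -> list[tuple[str, str, np.ndarray]]:
    """Plant Ser/His/Asn with hand-set OG -> ring distances, local frame.

    Geometry: OG sits on the chi1 circle about the CA->CB axis (bond
    0.143 nm, tetrahedral angle).  NE2 is placed so that the closest
    approach of that circle is `scan_min_nm` while the as-built chi1 gives
    `distance_nm`; the remaining ring atoms lie in the plane perpendicular
    to the chi1 axis through NE2, strictly farther from the circle.
    """
    out: list[tuple[str, str, np.ndarray]] = []
    # --- serine
    ca = np.array([0.30, 0.0, 0.0])
    u = _unit(np.array([-0.94, 0.0, 0.342]))  # CA -> CB direction
    cb = ca + 0.153 * u
    out += [
        ("SER", "N", ca + np.array([0.10, 0.10, 0.0])),
        ("SER", "CA", ca),
        ("SER", "CB", cb),
    ]
    half_angle = np.deg2rad(180.0 - 109.47)
    oc = cb + 0.143 * np.cos(half_angle) * u  # chi1 circle center
    r_c = 0.143 * np.sin(half_angle)
    p, q = _perp_basis(u)

    # --- NE2 placement from the two hand-set distances
    h = 0.5 * scan_min_nm * 1.15  # axial offset, leaves room for rho
    if scan_min_nm**2 <= h**2:
        h = 0.6 * scan_min_nm
    rho = r_c + np.sqrt(scan_min_nm**2 - h**2)
    cos_delta = (h**2 + rho**2 + r_c**2 - distance_nm**2) / (2 * rho * r_c)
    if not -1.0 <= cos_delta <= 1.0:
        raise ValueError("requested triad distances are geometrically inconsistent")
    delta = np.arccos(cos_delta)
    ne2 = oc - h * u + rho * p
    og = oc + r_c * (np.cos(delta) * p + np.sin(delta) * q)
    out.append(("SER", "OG", og))

    # --- imidazole ring in the plane perpendicular to u through NE2
    r5 = 0.137 / (2 * np.sin(np.pi / 5))
    center = ne2 + r5 * p
    ring = {}
    for name, k in zip(("NE2", "CD2", "CG", "ND1", "CE1"), range(5)):
        ang = np.pi + 2 * np.pi * k / 5  # NE2 at the vertex nearest the axis
        ring[name] = center + r5 * (np.cos(ang) * p + np.sin(ang) * q)
    for name in ("CG", "ND1", "CD2", "CE1", "NE2"):
        out.append(("HIS", name, ring[name]))
    his_ca = center + 0.30 * p + 0.10 * q
    out += [
        ("HIS", "N", his_ca + np.array([0.0, 0.0, 0.12])),
        ("HIS", "CA", his_ca),
        ("HIS", "CB", his_ca - 0.12 * q),
    ]

    # --- asparagine, a compact side cluster (no planted distances)
    base = oc - 0.42 * q - 0.1 * u
    offs = {
        "N": (0.0, 0.0, 0.12),
        "CA": (0.0, 0.0, 0.0),
        "CB": (0.12, 0.0, 0.0),
        "CG": (0.20, 0.09, 0.0),
        "OD1": (0.20, 0.21, 0.0),
        "ND2": (0.31, 0.04, 0.05),
    }
    for name, off in offs.items():
        out.append(("ASN", name, base + np.array(off)))
    return out


_ELEMENT_FROM_NAME = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "OG": "O",
                      "CG": "C", "ND1": "N", "CD2": "C", "CE1": "C", "NE2": "N",
                      "OD1": "O", "ND2": "N"}


def make_toy_crystal(spec: ToyCrystalSpec) -> AtomicModel:
    """Generate the asymmetric unit of the toy crystal.

    Returns a single-chain model (chain 'A') carrying the hexagonal cell
    and the P3(1)21 space-group name.  Post-generation the full P1
    expansion is verified to be free of symmetry clashes; a handful of
    rigid re-orientations are tried before giving up.
    """
    rng = np.random.default_rng(spec.seed)
    sg = get_space_group(spec.sg_name)
    scale = spec.cell.a / 2.0
    chain_radius = 0.32 * scale
    center_cart = frac_to_cart(spec.cell, _DEFAULT_CENTER_FRAC)

    ids = toy_triad_ids(spec)
    last_err = None
    for _attempt in range(24):
        rot = _random_rotation(rng) if _attempt else np.eye(3)
        try:
            chain = _build_chain(rng, spec.n_residues, chain_radius)
        except RuntimeError as exc:
            last_err = exc
            continue
        atoms: list[Atom] = []
        chain_shift = -0.38 * scale * np.array([0.0, 0.0, 1.0])
        for i, (nm, pos) in enumerate(chain):
            atoms.append(
                Atom(
                    element=_ELEMENT_FROM_NAME[nm],
                    name=nm,
                    res_name="ALA",
                    res_id=i // 5 + 1,
                    chain_id="A",
                    position=tuple(center_cart + rot @ (pos + chain_shift)),
                )
            )
        if spec.include_triad:
            for res, nm, pos in _build_triad(spec.triad_distance / ANGSTROM_PER_NM,
                                             spec.triad_scan_minimum / ANGSTROM_PER_NM):
                atoms.append(
                    Atom(
                        element=_ELEMENT_FROM_NAME[nm],
                        name=nm,
                        res_name=res,
                        res_id=ids[res],
                        chain_id="A",
                        position=tuple(center_cart + rot @ (pos + 0.20 * scale * np.array([0.0, 0.0, 1.0]))),
                    )
                )
        model = AtomicModel.from_atoms(atoms, cell=spec.cell, space_group_name="P3121")
        try:
            expanded = expand_to_p1(model, sg)
        except Exception as exc:  # pragma: no cover - defensive
            last_err = exc
            continue
        if min_interchain_distance(expanded) >= 0.10:
            return model
        last_err = RuntimeError("symmetry copies clash")
    raise RuntimeError(
        f"could not place the toy molecule without symmetry clashes ({last_err}); try a larger cell"
    )


# ---------------------------------------------------------------------------
# reference images


@dataclass(frozen=True)
class ReferenceImageSpec:
    source: ImageGrid
    noise_sigma: float = 0.3  # fraction of the source std
    blur_fwhm: float = 0.0  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def make_reference_image(spec: ReferenceImageSpec) -> ImageGrid:
    """Blur + noise model of an experimental reference micrograph."""
    src = spec.source
    pix = src.pixels.astype(float)
    if spec.blur_fwhm > 0:
        sigma_nm = spec.blur_fwhm / 2.3548200450309493  # FWHM -> sigma
        gaussian_filter_sigma = (sigma_nm / src.pixel_size[0], sigma_nm / src.pixel_size[1])
        pix = gaussian_filter(pix, gaussian_filter_sigma, mode="wrap")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        pix = pix + rng.normal(scale=spec.noise_sigma * pix.std(), size=pix.shape)
    return ImageGrid(pix, src.pixel_size, origin=src.origin, axis_labels=src.axis_labels)


# ---------------------------------------------------------------------------
# synthetic comparator stand-ins


def make_calpha_pair(
    n_residues: int = 218,
    rms_noise: float = 0.67,
    n_outliers: int = 19,
    outlier_shift: float = 4.0,
    seed: int = 0,
) -> tuple[AtomicModel, AtomicModel, np.ndarray]:
    """A C-alpha trace and a rigidly moved, noise-perturbed copy.

    Stands in for a pair of homologous folds: model B equals model A under
    a random rigid transform plus isotropic Gaussian noise of root mean
    square `rms_noise` (A) per matched position, with `n_outliers`
    residues additionally displaced by about `outlier_shift` (A) to mimic
    diverging loops.  Returns (model_a, model_b, applied_rotation).
    """
    rng = np.random.default_rng(seed)
    step = 0.38
    xyz = np.zeros((n_residues, 3))
    d = _unit(rng.normal(size=3))
    for i in range(1, n_residues):
        d = _unit(d + 0.6 * rng.normal(size=3))
        xyz[i] = xyz[i - 1] + step * d

    R = _random_rotation(rng)
    t = rng.normal(scale=1.0, size=3)
    noise = rng.normal(scale=rms_noise / np.sqrt(3.0) / ANGSTROM_PER_NM, size=xyz.shape)
    xyz_b = xyz @ R.T + t + noise
    out_idx = rng.choice(n_residues, size=n_outliers, replace=False)
    shift_dirs = rng.normal(size=(n_outliers, 3))
    shift_dirs /= np.linalg.norm(shift_dirs, axis=1, keepdims=True)
    xyz_b[out_idx] += (
        shift_dirs * (outlier_shift / ANGSTROM_PER_NM) * (1.0 + 0.3 * rng.random(n_outliers))[:, None]
    )

    def _trace(coords: np.ndarray) -> AtomicModel:
        n = len(coords)
        return AtomicModel(
            element=np.full(n, "C", dtype="U8"),
            name=np.full(n, "CA", dtype="U8"),
            res_name=np.full(n, "ALA", dtype="U8"),
            res_id=np.arange(1, n + 1),
            chain_id=np.full(n, "A", dtype="U8"),
            xyz=coords,
            occupancy=np.ones(n),
            b_factor=np.zeros(n),
        )

    return _trace(xyz), _trace(xyz_b), R


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def make_sequence_pair(length: int = 218, identity_pct: float = 52.0, seed: int = 0) -> tuple[str, str]:
    """A random protein sequence and a mutated copy at the given identity."""
    rng = np.random.default_rng(seed)
    seq_a = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    n_mut = int(round(length * (1.0 - identity_pct / 100.0)))
    idx = rng.choice(length, size=n_mut, replace=False)
    b = list(seq_a)
    for i in idx:
        choices = [a for a in AMINO_ACIDS if a != b[i]]
        b[i] = choices[rng.integers(len(choices))]
    return seq_a, "".join(b)
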