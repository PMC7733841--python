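"""Quantitative structure analysis.

Covers the catalytic-triad geometry of silicatein (Ser-His-Asn; the Ser
hydroxyl to His imidazole distance separates the inactive from the
hypothesized active conformation), a chi1 rotamer scan of the Ser side
chain, least-squares C-alpha superposition (Kabsch) with optional iterative
trimming, and pairwise sequence identity from a global alignment.

Distances are reported in angstroms, matching crystallographic convention;
coordinates stay in nm internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

from .structio import ANGSTROM_PER_NM, AtomicModel

#: atoms of the His imidazole ring
HIS_RING_ATOMS = ("CG", "ND1", "CD2", "CE1", "NE2")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class SelectorError(KeyError):
    """An atom/residue selector did not resolve as required."""


@dataclass(frozen=True)
class TriadGeometry:
    """Distances characterizing the Ser...His arrangement, in angstroms."""

    ser_og_to_his_ring: float  # minimum over the five imidazole ring atoms
    ser_og_to_his_ne2: float
    residues: tuple  # ((chain, resid, resname), ...) of the triad


@dataclass
class SuperpositionResult:
    rmsd: float  # angstrom
    n_matched: int
    rotation: np.ndarray  # 3x3 proper orthogonal
    translation: np.ndarray  # nm triple
    per_pair_deviations: np.ndarray  # angstrom


@dataclass(frozen=True)
class Chi1ScanResult:
    best_angle: float  # degrees rotated from the input conformation
    best_distance: float  # angstrom
    angles: np.ndarray
    distances: np.ndarray


def _atom_xyz(model: AtomicModel, chain: str, res_id: int, atom_name: str) -> np.ndarray:
    mask = (model.chain_id == chain) & (model.res_id == res_id) & (model.name == atom_name)
    n = int(mask.sum())
    if n != 1:
        raise SelectorError(f"selector {chain}/{res_id}/{atom_name} matched {n} atoms (need exactly 1)")
    return model.xyz[mask][0]


def min_ring_distance(
    model: AtomicModel,
    donor: tuple[str, int, str],
    ring_residue: tuple[str, int],
) -> float:
    """Minimum distance (A) from a donor atom to the His imidazole ring.

    `donor` is (chain, res_id, atom_name); `ring_residue` is (chain, res_id)
    of a histidine.  Plain Euclidean distance; no periodicity is applied
    within a molecule.
    """
    d_xyz = _atom_xyz(model, *donor)
    chain, res_id = ring_residue
    ring_mask = (
        (model.chain_id == chain)
        & (model.res_id == res_id)
        & np.isin(model.name, HIS_RING_ATOMS)
    )
    if not ring_mask.any():
        raise SelectorError(f"no imidazole ring atoms found for residue {chain}/{res_id}")
    dists = np.linalg.norm(model.xyz[ring_mask] - d_xyz, axis=1)
    return float(dists.min() * ANGSTROM_PER_NM)


def triad_geometry(
    model: AtomicModel,
    ser: tuple[str, int],
    his: tuple[str, int],
    asn: tuple[str, int] | None = None,
) -> TriadGeometry:
    """Measure the Ser-OG...His-ring distances of a catalytic triad."""
    chain_s, id_s = ser
    ring = min_ring_distance(model, (chain_s, id_s, "OG"), his)
    og = _atom_xyz(model, chain_s, id_s, "OG")
    ne2 = _atom_xyz(model, his[0], his[1], "NE2")
    residues = [(*ser, "SER"), (*his, "HIS")]
    if asn is not None:
        residues.append((*asn, "ASN"))
    return TriadGeometry(
        ser_og_to_his_ring=ring,
        ser_og_to_his_ne2=float(np.linalg.norm(og - ne2) * ANGSTROM_PER_NM),
        residues=tuple(residues),
    )


def _rodrigues(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a unit axis."""
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def scan_chi1(
    model: AtomicModel,
    ser: tuple[str, int],
    his: tuple[str, int],
    step: float = 1.0,
) -> Chi1ScanResult:
    """Rigidly rotate Ser OG about the CA-CB axis and scan a full turn.

    The CB-OG bond length and CA-CB-OG angle are preserved exactly (rigid
    rotation about the CA->CB axis).  Returns the rotation (degrees from
    the input conformation) minimizing the OG -> His-ring distance.
    """
    chain, res_id = ser
    try:
        ca = _atom_xyz(model, chain, res_id, "CA")
        cb = _atom_xyz(model, chain, res_id, "CB")
        og = _atom_xyz(model, chain, res_id, "OG")
        _atom_xyz(model, chain, res_id, "N")
    except SelectorError as exc:
        raise SelectorError(f"chi1 scan needs Ser N, CA, CB, OG atoms: {exc}") from exc

    ring_mask = (
        (model.chain_id == his[0]) & (model.res_id == his[1]) & np.isin(model.name, HIS_RING_ATOMS)
    )
    if not ring_mask.any():
        raise SelectorError(f"no imidazole ring atoms for residue {his[0]}/{his[1]}")
    ring_xyz = model.xyz[ring_mask]

    axis = cb - ca
    angles = np.arange(0.0, 360.0, step)
    dists = np.empty_like(angles)
    for i, ang in enumerate(angles):
        R = _rodrigues(axis, np.deg2rad(ang))
        og_rot = cb + R @ (og - cb)
        dists[i] = np.linalg.norm(ring_xyz - og_rot, axis=1).min()
    dists *= ANGSTROM_PER_NM
    best = int(np.argmin(dists))
    return Chi1ScanResult(
        best_angle=float(angles[best]),
        best_distance=float(dists[best]),
        angles=angles,
        distances=dists,
    )


# ---------------------------------------------------------------------------
# Kabsch superposition


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform: R @ p + t best maps P onto Q.

    Returns (R, t) with R proper orthogonal (det +1).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cq - R @ cp


def _calpha_table(model: AtomicModel) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(res_ids, coords, one-letter sequence) of CA atoms, model order."""
    mask = model.name == "CA"
    if not mask.any():
        raise ValueError("model contains no C-alpha atoms")
    res_ids = model.res_id[mask]
    seq = [THREE_TO_ONE.get(rn, "X") for rn in model.res_name[mask]]
    return res_ids, model.xyz[mask], seq


def superpose_calpha(
    model_a: AtomicModel,
    model_b: AtomicModel,
    matching: str = "sequence",
    trim_threshold: float | None = None,
) -> SuperpositionResult:
    """Kabsch superposition of model_a onto model_b over matched CA pairs.

    matching='resnum' pairs identical residue numbers; matching='sequence'
    pairs residues through a global sequence alignment of the one-letter
    sequences.  With `trim_threshold` (A) set, the worst pair is dropped and
    the fit repeated while any deviation exceeds the threshold (at least 3
    pairs are kept).
    """
    ids_a, xyz_a, seq_a = _calpha_table(model_a)
    ids_b, xyz_b, seq_b = _calpha_table(model_b)

    if matching == "resnum":
        common, ia, ib = np.intersect1d(ids_a, ids_b, return_indices=True)
        P, Q = xyz_a[ia], xyz_b[ib]
    elif matching == "sequence":
        sa = bseq.ProteinSequence("".join(seq_a).replace("X", "A"))
        sb = bseq.ProteinSequence("".join(seq_b).replace("X", "A"))
        matrix = balign.SubstitutionMatrix.std_protein_matrix()
        aln = balign.align_optimal(sa, sb, matrix, gap_penalty=(-10, -1), terminal_penalty=False)[0]
        tr = aln.trace
        pairs = tr[(tr[:, 0] >= 0) & (tr[:, 1] >= 0)]
        P, Q = xyz_a[pairs[:, 0]], xyz_b[pairs[:, 1]]
    else:
        raise ValueError("matching must be 'sequence' or 'resnum'")

    if len(P) < 3:
        raise ValueError(f"only {len(P)} matched C-alpha pairs; need at least 3")

    keep = np.arange(len(P))
    while True:
        R, t = kabsch(P[keep], Q[keep])
        dev = np.linalg.norm((P[keep] @ R.T + t) - Q[keep], axis=1) * ANGSTROM_PER_NM
        if trim_threshold is None or dev.max() <= trim_threshold or len(keep) <= 3:
            break
        keep = np.delete(keep, int(np.argmax(dev)))
    rmsd = float(np.sqrt(np.mean(dev**2)))
    return SuperpositionResult(
        rmsd=rmsd,
        n_matched=len(keep),
        rotation=R,
        translation=t,
        per_pair_deviations=dev,
    )


# ---------------------------------------------------------------------------
# Sequence identity


def _validate_sequence(seq: str, label: str) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - set("ACDEFGHIKLMNPQRSTVWY")
    if bad:
        raise ValueError(f"{label}: invalid amino-acid characters {sorted(bad)}")
    return seq


def sequence_identity(seq_a: str, seq_b: str, convention: str = "core_columns") -> float:
    """Percent identity from a global alignment (BLOSUM62, affine gaps).

    Conventions for the denominator:
      - 'core_columns': aligned columns excluding terminal gaps (default)
      - 'all_columns':  every alignment column
      - 'shorter':      length of the shorter sequence
    """
    sa = bseq.ProteinSequence(_validate_sequence(seq_a, "seq_a"))
    sb = bseq.ProteinSequence(_validate_sequence(seq_b, "seq_b"))
    matrix = balign.SubstitutionMatrix.std_protein_matrix()
    aln = balign.align_optimal(sa, sb, matrix, gap_penalty=(-10, -1), terminal_penalty=False)[0]
    tr = aln.trace
    both = (tr[:, 0] >= 0) & (tr[:, 1] >= 0)
    matches = int(
        np.sum(
            [
                both[i] and str(sa)[tr[i, 0]] == str(sb)[tr[i, 1]]
                for i in range(len(tr))
            ]
        )
    )
    # core: strip leading/trailing columns where either side is a gap
    inner = np.flatnonzero(both)
    first, last = int(inner[0]), int(inner[-1])
    denominators = {
        "core_columns": last - first + 1,
        "all_columns": len(tr),
        "shorter": min(len(sa), len(sb)),
    }
    if convention not in denominators:
        raise ValueError(f"unknown convention {convention!r}; options: {sorted(denominators)}")
    return 100.0 * matches / denominators[convention]


def sequence_identity_all_conventions(seq_a: str, seq_b: str) -> dict[str, float]:
    return {c: sequence_identity(seq_a, seq_b, c) for c in ("core_columns", "all_columns", "shorter")}
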