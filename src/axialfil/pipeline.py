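"""End-to-end orchestration: read/generate -> strip -> expand -> pack ->
simulate both zone axes -> compare -> geometry report.

A run directory receives the hybrid model (mmCIF), the packing report, the
projections and simulated images (MRC + PNG), the geometry, comparison and
provenance JSON files.  Identical config + seed gives identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compare import detect_lattice, register_and_correlate
from .emsim import ImageGrid, MicroscopeParams, project_atoms, simulate_zone_axis
from .geometry import scan_chi1, triad_geometry
from .silicapack import FillConfig, pack_silica, verify_packing
from .structio import UnitCell, read_structure, strip_hetero, strip_zero_occupancy, write_structure
from .symmetry import expand_to_p1, get_space_group
from .synthetic import ToyCrystalSpec, make_toy_crystal, toy_triad_ids

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML/JSON mirror)."""

    input_path: str | None = None  # mmCIF/PDB input; None -> synthetic toy
    toy: dict = field(default_factory=dict)  # ToyCrystalSpec overrides
    fill: dict = field(default_factory=dict)  # FillConfig overrides
    microscope: dict = field(default_factory=dict)  # MicroscopeParams overrides
    zones: tuple = ("001", "100")
    pixel_size: float = 0.05  # nm
    reference_noise_sigma: float = 0.3
    strip_ligands: bool = True
    triad: dict | None = None  # {"ser": [chain, id], "his": [...], "asn": [...]}
    out_dir: str = "runs/axialfil"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _write_image(img: ImageGrid, stem: Path) -> None:
    """Write an image as MRC (pixel size in the cell header) and PNG."""
    import gemmi
    from PIL import Image

    ny, nx = img.pixels.shape
    grid = gemmi.FloatGrid(nx, ny, 1)
    grid.set_unit_cell(
        gemmi.UnitCell(nx * img.pixel_size[1] * 10.0, ny * img.pixel_size[0] * 10.0, 10.0, 90, 90, 90)
    )
    arr = np.array(grid, copy=False)
    arr[:, :, 0] = img.pixels.T.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(stem.with_suffix(".mrc")))

    lo, hi = img.pixels.min(), img.pixels.max()
    disp = np.zeros_like(img.pixels) if hi == lo else (img.pixels - lo) / (hi - lo)
    Image.fromarray((disp * 255).astype(np.uint8)).save(stem.with_suffix(".png"))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}
    t_all = time.perf_counter()

    def _stage(name: str):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                stage_times[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                return False

        return _T()

    triad_sel = config.triad
    with _stage("input"):
        if config.input_path:
            model = read_structure(config.input_path)
            model = strip_zero_occupancy(model)
            if config.strip_ligands:
                model = strip_hetero(model)
            sg = get_space_group(model.space_group_name or "P1")
        else:
            toy_kwargs = dict(config.toy)
            if "cell" in toy_kwargs:
                toy_kwargs["cell"] = UnitCell(*toy_kwargs["cell"])
            toy_kwargs.setdefault("include_triad", True)
            toy_kwargs.setdefault("seed", config.seed)
            spec = ToyCrystalSpec(**toy_kwargs)
            model = make_toy_crystal(spec)
            sg = get_space_group(spec.sg_name)
            if triad_sel is None and spec.include_triad:
                ids = toy_triad_ids(spec)
                triad_sel = {"ser": ["A", ids["SER"]], "his": ["A", ids["HIS"]], "asn": ["A", ids["ASN"]]}

    with _stage("expand"):
        cell_model = expand_to_p1(model, sg)

    with _stage("pack"):
        fill = FillConfig(**{"seed": config.seed + 1, **config.fill})
        hybrid, pack_report = pack_silica(cell_model, fill)
        check = verify_packing(hybrid, fill)
        pack_report.n_violations = check.n_violations
        write_structure(hybrid, out / "hybrid.cif", format="mmcif")
        (out / "packing_report.json").write_text(json.dumps(pack_report.to_dict(), indent=2))

    with _stage("geometry"):
        geo: dict = {}
        if triad_sel:
            ser = tuple(triad_sel["ser"])
            his = tuple(triad_sel["his"])
            tg = triad_geometry(model, ser, his, tuple(triad_sel.get("asn") or ()) or None)
            scan = scan_chi1(model, ser, his, step=1.0)
            geo = {
                "ser_og_to_his_ring_A": round(tg.ser_og_to_his_ring, 3),
                "ser_og_to_his_ne2_A": round(tg.ser_og_to_his_ne2, 3),
                "chi1_scan_min_distance_A": round(scan.best_distance, 3),
                "chi1_scan_best_angle_deg": round(scan.best_angle, 1),
                "units": "angstrom",
            }
        (out / "geometry_report.json").write_text(json.dumps(geo, indent=2))

    params = MicroscopeParams(**config.microscope)
    comparison: dict = {}
    for zone in config.zones:
        with _stage(f"simulate_{zone}"):
            proj = project_atoms(hybrid, zone, config.pixel_size, weighting="Z")
            _write_image(proj, out / f"projection_{zone}")
            sim = simulate_zone_axis(hybrid, zone, params, config.pixel_size)
            _write_image(sim, out / f"sim_{zone}")
        with _stage(f"compare_{zone}"):
            from .synthetic import ReferenceImageSpec, make_reference_image

            ref = make_reference_image(
                ReferenceImageSpec(source=sim, noise_sigma=config.reference_noise_sigma, seed=config.seed + 2)
            )
            _write_image(ref, out / f"reference_{zone}")
            reg = register_and_correlate(sim, ref)
            lat = detect_lattice(sim, expected_cell=hybrid.cell if zone == "001" else None)
            comparison[zone] = {
                "ncc_vs_reference": round(reg.ncc, 4),
                "best_shift_nm": list(reg.best_shift),
                "lattice_found": lat.lattice_found,
                "lattice_vectors_nm": [list(np.round(v, 4)) for v in lat.lattice_vectors_detected],
                "lattice_mismatch_percent": None if lat.lattice_mismatch is None else round(lat.lattice_mismatch, 3),
            }
    (out / "comparison_report.json").write_text(json.dumps(comparison, indent=2))

    with _stage("provenance"):
        prov = {
            "package": "axialfil",
            "version": __version__,
            "seed": config.seed,
            "config": {**asdict(config), "zones": list(config.zones)},
            "stage_seconds": stage_times,
            "total_seconds": round(time.perf_counter() - t_all, 3),
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
    return out
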