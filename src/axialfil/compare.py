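"""Quantitative comparison of simulated and reference images.

Operationalizes "the simulation agrees with the experiment": exhaustive
cyclic translational registration with normalized cross-correlation, and
detection of the projected lattice from power-spectrum peaks with sub-pixel
(parabolic) localization.  Declared agreement thresholds — lattice constants
within 3%, NCC >= 0.5 — are package policy, configurable by callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter, zoom

from .emsim import ImageGrid
from .structio import UnitCell


@dataclass
class ComparisonReport:
    ncc: float | None = None  # [-1, 1] at best registration
    best_shift: tuple[float, float] | None = None  # (dy, dx) nm
    lattice_vectors_detected: list = field(default_factory=list)  # [(y, x) nm, ...]
    lattice_mismatch: float | None = None  # percent vs expected
    lattice_found: bool = False

    def to_dict(self) -> dict:
        return {
            "ncc": self.ncc,
            "best_shift_nm": self.best_shift,
            "lattice_vectors_nm": [list(v) for v in self.lattice_vectors_detected],
            "lattice_mismatch_percent": self.lattice_mismatch,
            "lattice_found": self.lattice_found,
        }


def _resample_to(b: ImageGrid, a: ImageGrid) -> ImageGrid:
    factors = (b.pixel_size[0] / a.pixel_size[0], b.pixel_size[1] / a.pixel_size[1])
    if np.allclose(factors, 1.0, rtol=1e-6):
        return b
    res = zoom(b.pixels, factors, order=1, mode="grid-wrap")
    return ImageGrid(res, a.pixel_size, origin=b.origin, axis_labels=b.axis_labels)


def register_and_correlate(a: ImageGrid, b: ImageGrid) -> ComparisonReport:
    """Cyclic translational registration via FFT cross-correlation.

    Both images are reduced to zero mean and unit variance, so the peak of
    the cyclic cross-correlation is exactly the normalized cross-
    correlation at the best shift; NCC is invariant to affine intensity
    rescaling of either image.
    """
    b = _resample_to(b, a)
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(f"image shapes differ after resampling: {a.pixels.shape} vs {b.pixels.shape}")
    x = a.pixels - a.pixels.mean()
    y = b.pixels - b.pixels.mean()
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("cannot correlate a constant image")
    x /= sx
    y /= sy
    n = x.size
    cc = np.real(np.fft.ifft2(np.fft.fft2(x) * np.conj(np.fft.fft2(y)))) / n
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
    ncc = float(cc[iy, ix])
    ny, nx = cc.shape
    dy = iy if iy <= ny // 2 else iy - ny
    dx = ix if ix <= nx // 2 else ix - nx
    return ComparisonReport(
        ncc=float(np.clip(ncc, -1.0, 1.0)),
        best_shift=(dy * a.pixel_size[0], dx * a.pixel_size[1]),
    )


def _parabolic_refine(p: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Sub-pixel peak position by separable parabola fit."""
    ny, nx = p.shape
    out = [float(iy), float(ix)]
    for axis, i in ((0, iy), (1, ix)):
        m1 = p[(iy - 1) % ny, ix] if axis == 0 else p[iy, (ix - 1) % nx]
        p0 = p[iy, ix]
        p1 = p[(iy + 1) % ny, ix] if axis == 0 else p[iy, (ix + 1) % nx]
        denom = m1 - 2 * p0 + p1
        if denom != 0:
            out[axis] = i + 0.5 * (m1 - p1) / denom
    return out[0], out[1]


def detect_lattice(
    img: ImageGrid,
    expected_cell: UnitCell | None = None,
    peak_to_background: float = 3.0,
) -> ComparisonReport:
    """Find the projected lattice from the image power spectrum.

    Looks for the six lowest-order significant peaks (three Friedel pairs),
    converts the two shortest independent reciprocal vectors to real-space
    lattice vectors, and optionally reports the mismatch of their mean
    length against the expected hexagonal `a`.  A peak is significant when
    the (lightly smoothed) power exceeds `peak_to_background` times the
    median power in its frequency annulus; an image without such peaks
    yields ``lattice_found=False`` rather than an exception.
    """
    pix = img.pixels - img.pixels.mean()
    ny, nx = pix.shape
    wy = np.hanning(ny)[:, None]
    wx = np.hanning(nx)[None, :]
    power = np.abs(np.fft.fft2(pix * wy * wx)) ** 2
    power = gaussian_filter(np.fft.fftshift(power), 1.0, mode="wrap")

    ky = np.fft.fftshift(np.fft.fftfreq(ny, d=img.pixel_size[0]))
    kx = np.fft.fftshift(np.fft.fftfreq(nx, d=img.pixel_size[1]))
    KY, KX = np.meshgrid(ky, kx, indexing="ij")
    K = np.sqrt(KY**2 + KX**2)

    # radial median background
    kbin = np.minimum((K / (K.max() / 64.0)).astype(int), 63)
    background = np.zeros(64)
    for i in range(64):
        sel = kbin == i
        background[i] = np.median(power[sel]) if sel.any() else 0.0
    bg = background[kbin]

    local_max = power == maximum_filter(power, size=5, mode="wrap")
    # exclude the windowing-broadened DC region (3 frequency pixels)
    dc_radius = 3.5 * max(abs(ky[1] - ky[0]), abs(kx[1] - kx[0]))
    significant = local_max & (K > dc_radius) & (power > peak_to_background * np.maximum(bg, 1e-300))

    report = ComparisonReport()
    peaks = np.argwhere(significant)
    if len(peaks) < 2:
        return report
    # sort by |k|, keep the six lowest-order
    kvals = K[tuple(peaks.T)]
    order = np.argsort(kvals)
    peaks = peaks[order][:6]

    gvecs = []
    for iy, ix in peaks:
        py, px = _parabolic_refine(power, iy, ix)
        gy = np.interp(py, np.arange(ny), ky)
        gx = np.interp(px, np.arange(nx), kx)
        gvecs.append(np.array([gy, gx]))

    # two shortest independent (non-anti-parallel) reciprocal vectors
    g1 = gvecs[0]
    g2 = None
    for g in gvecs[1:]:
        cross = g1[0] * g[1] - g1[1] * g[0]
        if abs(cross) > 0.05 * np.linalg.norm(g1) * np.linalg.norm(g):
            g2 = g
            break
    if g2 is None:
        return report
    G = np.array([g1, g2])
    A = np.linalg.inv(G).T  # rows: real-space lattice vectors
    # lattice consistency: every low-order peak must sit on the lattice
    # generated by (g1, g2); random noise maxima pass the amplitude test
    # occasionally but essentially never index on a common lattice
    for g in gvecs:
        coords = A @ g
        if np.max(np.abs(coords - np.round(coords))) > 0.12:
            return report
    report.lattice_found = True
    report.lattice_vectors_detected = [tuple(A[0]), tuple(A[1])]
    if expected_cell is not None:
        lengths = np.linalg.norm(A, axis=1)
        report.lattice_mismatch = float(100.0 * np.mean(np.abs(lengths - expected_cell.a) / expected_cell.a))
    return report
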