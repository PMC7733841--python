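"""Parameterized electron atomic scattering factors.

Five-Gaussian fits of the elastic electron scattering factor,

    f_e(s) = sum_i a_i * exp(-b_i * s**2),    s = sin(theta)/lambda  [1/A]

with f_e in angstroms (Peng-style parameterization, International Tables
convention).  Only the elements present in the hybrid protein/silica model
are tabulated: H, C, N, O, S, Si.  The forward values f_e(0) reproduce the
published zero-angle factors (H 0.529, C 2.509, N 2.213, O 1.983,
Si 5.828, S 5.160 A).
"""

from __future__ import annotations

import numpy as np

# element -> (a[5], b[5]); s in 1/A, f in A
PENG_PARAMS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "H": (
        (0.0349, 0.1201, 0.1970, 0.0573, 0.1195),
        (0.5347, 3.5867, 12.3471, 18.9525, 38.6269),
    ),
    "C": (
        (0.0893, 0.2563, 0.7570, 1.0487, 0.3575),
        (0.2465, 1.7100, 6.4094, 18.6113, 50.2523),
    ),
    "N": (
        (0.1022, 0.3219, 0.7982, 0.8197, 0.1715),
        (0.2451, 1.7481, 6.1925, 17.3894, 48.1431),
    ),
    "O": (
        (0.0974, 0.2921, 0.6910, 0.6990, 0.2039),
        (0.2067, 1.3815, 4.6943, 12.7105, 32.4726),
    ),
    "SI": (
        (0.2519, 0.6372, 1.3795, 2.5082, 1.0500),
        (0.3075, 2.0174, 9.6746, 29.3799, 80.4732),
    ),
    "S": (
        (0.2497, 0.5628, 1.3899, 2.1865, 0.7715),
        (0.2681, 1.6711, 7.0267, 19.5377, 50.3888),
    ),
}

#: atomic numbers for Z-weighted projections
ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "SI": 14, "S": 16}


class ScatteringFactorError(KeyError):
    pass


def scattering_factor(element: str, g_inv_nm: np.ndarray) -> np.ndarray:
    """f_e in nm as a function of spatial frequency g = 1/d in 1/nm.

    The tabulated variable is s = g/2 in 1/A; conversions applied here so
    that callers can stay in the package's nm units throughout.
    """
    el = element.upper()
    if el not in PENG_PARAMS:
        raise ScatteringFactorError(
            f"no electron scattering parameterization for element {el!r}; available: {sorted(PENG_PARAMS)}"
        )
    a, b = PENG_PARAMS[el]
    s_inv_A = np.asarray(g_inv_nm, dtype=float) / 2.0 / 10.0  # 1/nm -> 1/A, g -> s
    f_A = np.zeros_like(s_inv_A)
    for ai, bi in zip(a, b):
        f_A = f_A + ai * np.exp(-bi * s_inv_A**2)
    return f_A * 0.1  # A -> nm


def forward_scattering(element: str) -> float:
    """f_e(0) in nm."""
    a, _ = PENG_PARAMS[element.upper()]
    return 0.1 * float(np.sum(a))
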