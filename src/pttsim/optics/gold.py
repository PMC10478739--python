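"""Complex refractive index of bulk gold in the visible / near-infrared.

A small table of (wavelength nm, n, k) values digitized from the standard
thin-film measurements of Johnson & Christy (Phys. Rev. B 6, 4370, 1972),
log-linearly interpolated in wavelength.  Gold is strongly dispersive through
the interband edge (~520 nm) and becomes an increasingly good Drude metal in
the NIR; at 1064 nm the index is ~0.27 + 7.1i.
"""

from __future__ import annotations

import numpy as np

# (wavelength nm, n, k)
_GOLD_NK = np.array(
    [
        (400.0, 1.658, 1.956),
        (450.0, 1.502, 1.879),
        (500.0, 0.971, 1.870),
        (520.0, 0.628, 2.037),
        (550.0, 0.430, 2.455),
        (600.0, 0.249, 2.990),
        (650.0, 0.166, 3.150),
        (700.0, 0.131, 3.842),
        (750.0, 0.138, 4.518),
        (800.0, 0.154, 4.908),
        (850.0, 0.163, 5.286),
        (900.0, 0.166, 5.717),
        (950.0, 0.174, 6.083),
        (1000.0, 0.208, 6.491),
        (1064.0, 0.272, 7.070),
        (1100.0, 0.307, 7.295),
        (1200.0, 0.433, 8.093),
        (1300.0, 0.561, 8.746),
    ]
)


def gold_refractive_index(wavelength_nm: float | np.ndarray) -> complex | np.ndarray:
    """Interpolated complex refractive index n + ik of gold.

    Parameters
    ----------
    wavelength_nm : scalar or array, in nanometres, within [400, 1300].
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl < _GOLD_NK[0, 0]) or np.any(wl > _GOLD_NK[-1, 0]):
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside tabulated range "
            f"[{_GOLD_NK[0, 0]:.0f}, {_GOLD_NK[-1, 0]:.0f}] nm"
        )
    n = np.interp(wl, _GOLD_NK[:, 0], _GOLD_NK[:, 1])
    k = np.interp(wl, _GOLD_NK[:, 0], _GOLD_NK[:, 2])
    out = n + 1j * k
    return complex(out) if np.isscalar(wavelength_nm) else out
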