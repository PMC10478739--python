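"""Lorenz–Mie efficiencies for a homogeneous sphere.

Classic Bohren–Huffman series: logarithmic derivative D_n by downward
recurrence, Riccati–Bessel functions psi/chi by upward recurrence.  Serves as
the closed-form oracle against which the coupled-dipole (DDA) solver is
validated.
"""

from __future__ import annotations

import numpy as np

from .dda import OpticalEfficiencies


def mie_oracle(
    radius: float,
    wavelength: float,
    material_index: complex,
    medium_index: float = 1.0,
) -> OpticalEfficiencies:
    """Mie Q_abs / Q_sca / Q_ext (and cross-sections) of a sphere.

    Parameters
    ----------
    radius, wavelength : same length unit (e.g. metres); wavelength in vacuum.
    material_index : complex refractive index of the sphere, n + ik.
    medium_index : real refractive index of the non-absorbing host.
    """
    if radius <= 0 or wavelength <= 0:
        raise ValueError("radius and wavelength must be positive")
    x = 2.0 * np.pi * medium_index * radius / wavelength
    m = complex(material_index) / medium_index

    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    # Logarithmic derivative by downward recurrence, started well above nmax.
    nstart = nmax + 16
    mx = m * x
    D = np.zeros(nstart + 1, dtype=complex)
    for n in range(nstart, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)

    qext = 0.0
    qsca = 0.0
    # Riccati-Bessel psi_n(x) = x j_n(x), chi_n(x) = -x y_n(x); upward recurrence.
    psi_m1, psi_0 = np.cos(x), np.sin(x)          # psi_{-1}, psi_0
    chi_m1, chi_0 = -np.sin(x), np.cos(x)         # chi_{-1}, chi_0
    for n in range(1, nmax + 1):
        psi_1 = (2 * n - 1) / x * psi_0 - psi_m1
        chi_1 = (2 * n - 1) / x * chi_0 - chi_m1
        xi_1 = psi_1 - 1j * chi_1
        xi_0 = psi_0 - 1j * chi_0
        da = D[n] / m + n / x
        db = D[n] * m + n / x
        a_n = (da * psi_1 - psi_0) / (da * xi_1 - xi_0)
        b_n = (db * psi_1 - psi_0) / (db * xi_1 - xi_0)
        qext += (2 * n + 1) * (a_n.real + b_n.real)
        qsca += (2 * n + 1) * (abs(a_n) ** 2 + abs(b_n) ** 2)
        psi_m1, psi_0 = psi_0, psi_1
        chi_m1, chi_0 = chi_0, chi_1

    qext *= 2.0 / x**2
    qsca *= 2.0 / x**2
    qabs = qext - qsca
    geom = np.pi * radius**2
    return OpticalEfficiencies(
        Q_abs=qabs, Q_sca=qsca, Q_ext=qext,
        C_abs=qabs * geom, C_sca=qsca * geom, C_ext=qext * geom,
    )
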