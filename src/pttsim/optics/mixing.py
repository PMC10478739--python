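"""Composite-medium optics: dilute nanoparticle suspensions in tissue.

For a volume fraction f_v of particles with efficiencies Q and equal-volume
radius r_eff, the added coefficients are

    mu_abs,np  = 0.75 f_v Q_abs / r_eff
    mu_sca,np  = 0.75 f_v Q_sca / r_eff,   mu'_sca,np = mu_sca,np (1 - g_np)

(the independent-scattering mixing rule of Dombrovsky), and the composite
medium adds them to the host coefficients:

    mu_abs  = mu_abs,np  + mu_abs,m
    mu'_sca = mu'_sca,np + mu'_sca,m

Both relations are exactly linear in f_v.  The composite is reported with the
host anisotropy g_m, with mu_sca chosen to preserve the summed reduced
scattering (similarity relation), since a single Henyey–Greenstein g must
represent the mixture in transport.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dda import NanoparticleSpec, OpticalEfficiencies

_MM_PER_M = 1e3


@dataclass(frozen=True)
class MediumOpticalProperties:
    """Absorption / scattering coefficients (1/mm) and HG anisotropy."""

    mu_abs: float
    mu_sca: float
    g: float

    def __post_init__(self):
        if self.mu_abs < 0 or self.mu_sca < 0:
            raise ValueError("optical coefficients must be non-negative")
        if not 0.0 <= self.g < 1.0:
            raise ValueError("anisotropy must satisfy 0 <= g < 1")

    @property
    def mu_sca_reduced(self) -> float:
        return self.mu_sca * (1.0 - self.g)

    @property
    def mu_ext(self) -> float:
        return self.mu_abs + self.mu_sca


def mix_properties(
    Q: OpticalEfficiencies,
    spec: NanoparticleSpec,
    f_v: float,
    medium: MediumOpticalProperties,
) -> MediumOpticalProperties:
    """Composite optical coefficients of medium + dispersed nanoparticles.

    ``spec.effective_radius`` is in metres and is converted to mm internally
    so the output coefficients are in 1/mm.  Exactly linear in ``f_v``.
    """
    if not 0.0 <= f_v <= 1.0:
        raise ValueError("volume fraction must lie in [0, 1]")
    r_eff_mm = spec.effective_radius * _MM_PER_M
    mu_abs_np = 0.75 * f_v * Q.Q_abs / r_eff_mm
    mu_sca_np_reduced = 0.75 * f_v * Q.Q_sca / r_eff_mm * (1.0 - spec.anisotropy)
    mu_sca_reduced = mu_sca_np_reduced + medium.mu_sca_reduced
    return MediumOpticalProperties(
        mu_abs=mu_abs_np + medium.mu_abs,
        mu_sca=mu_sca_reduced / (1.0 - medium.g),
        g=medium.g,
    )


def invert_qabs(
    mu_abs_composite: float,
    mu_abs_medium: float,
    f_v: float,
    r_eff_mm: float,
) -> float:
    """Back out Q_abs from a composite absorption coefficient (1/mm)."""
    if f_v <= 0:
        raise ValueError("volume fraction must be positive for inversion")
    return (mu_abs_composite - mu_abs_medium) * r_eff_mm / (0.75 * f_v)
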