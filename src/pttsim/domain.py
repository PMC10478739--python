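"""Voxelized simulation scenario: layered skin cylinder, tumor, AuNP sphere.

Geometry (all mm): a cylinder of normal tissue, radius 10 and depth 20,
with four skin layers stacked in depth (epidermis 0-0.08, papillary dermis
0.08-0.58, reticular dermis 0.58-1.18, subcutaneous fat below).  A squamous
cell carcinoma is modeled as a right cylinder of diameter 3 and depth 2,
flush with the surface on the axis, replacing the skin layers it overlaps.
Gold nanoparticles occupy a sphere of radius 1 centered at depth 1 on the
axis (entirely inside the tumor), carrying the AuNP-loaded composite optics
for the chosen volume fraction.

Coordinates: z is depth with 0 at the skin surface; the Cartesian box spans
x, y in [-10, 10), z in [0, 20) with half-open voxels and centers at
(i + 0.5) * dx.  The cylinder is embedded in the box; voxels outside it are
flagged inert (tissue id 0).  A 3-D Cartesian grid is used (not r-z) because
oblique beam incidence breaks axial symmetry.

When the voxel size does not resolve the 0.08 mm epidermis, the top voxel
layer carries volume-weighted blended epidermis/papillary-dermis properties
(both thermal and optical); deeper voxels take the layer at their center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import constants as C
from .optics.mixing import MediumOpticalProperties

__all__ = [
    "TissueLayer",
    "TissueDomain",
    "SyntheticTemperatureField",
    "build_domain",
    "hazard_shell",
    "make_synthetic_field",
]

# Tissue ids used in TissueDomain.tissue_id
EXTERIOR = 0
EPIDERMIS = 1
PAPILLARY = 2
RETICULAR = 3
FAT = 4
TUMOR = 5
AUNP = 6
SURFACE_BLEND = 7

_LAYER_NAMES = {
    EPIDERMIS: "epidermis",
    PAPILLARY: "papillary_dermis",
    RETICULAR: "reticular_dermis",
    FAT: "subcutaneous_fat",
    TUMOR: "tumor",
}


@dataclass(frozen=True)
class TissueLayer:
    """Thermal and optical properties of one tissue type."""

    name: str
    thickness: float          # mm
    k_m: float                # W/mK
    c_v: float                # J/kgK
    rho: float                # kg/m^3
    w_b: float                # blood perfusion rate, 1/s (0 = avascular)
    optics: MediumOpticalProperties

    def __post_init__(self):
        if min(self.thickness, self.k_m, self.c_v, self.rho) <= 0 or self.w_b < 0:
            raise ValueError(f"non-physical property in layer {self.name}")

    @classmethod
    def from_table(cls, name: str) -> "TissueLayer":
        t, k, c, rho, wb, mua, mus, g = C.TISSUE_TABLE[name]
        return cls(name, t, k, c, rho, wb, MediumOpticalProperties(mua, mus, g))


@dataclass
class TissueDomain:
    """Voxelized cylinder with per-voxel tissue identity and property lookup.

    Property lookup tables are indexed by tissue id; index 0 (exterior) holds
    placeholder zeros for optics and per-depth layer values for the thermal
    volumes (so the cylinder wall behaves as clamped surrounding tissue).
    """

    voxel_size: float                      # mm
    tissue_id: np.ndarray                  # (nx, ny, nz) uint8
    layers: dict[int, TissueLayer]         # id -> layer (blend included)
    f_v: float
    origin: tuple[float, float, float] = (-C.DOMAIN_RADIUS_MM, -C.DOMAIN_RADIUS_MM, 0.0)
    metadata: dict = field(default_factory=dict)

    # ---- lookup tables (filled by build_domain) ----
    mu_abs_by_id: np.ndarray = None
    mu_sca_by_id: np.ndarray = None
    mu_ext_by_id: np.ndarray = None
    g_by_id: np.ndarray = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tissue_id.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size**3

    @property
    def inside_mask(self) -> np.ndarray:
        return self.tissue_id != EXTERIOR

    @property
    def tumor_mask(self) -> np.ndarray:
        return (self.tissue_id == TUMOR) | (self.tissue_id == AUNP)

    @property
    def aunp_mask(self) -> np.ndarray:
        return self.tissue_id == AUNP

    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinate axes (mm)."""
        dx = self.voxel_size
        nx, ny, nz = self.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * dx
        y = self.origin[1] + (np.arange(ny) + 0.5) * dx
        z = self.origin[2] + (np.arange(nz) + 0.5) * dx
        return x, y, z

    def voxel_index(self, x: float, y: float, z: float) -> tuple[int, int, int]:
        dx = self.voxel_size
        return (
            int((x - self.origin[0]) / dx),
            int((y - self.origin[1]) / dx),
            int((z - self.origin[2]) / dx),
        )

    def layer_at(self, x: float, y: float, z: float) -> str:
        """Tissue name at a point (mm)."""
        tid = self.tissue_id[self.voxel_index(x, y, z)]
        if tid == EXTERIOR:
            return "exterior"
        if tid == AUNP:
            return "tumor_aunp"
        if tid == SURFACE_BLEND:
            return "surface_blend"
        return _LAYER_NAMES[tid]

    def thermal_volumes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-voxel k (W/mK), rho*c_v (J/m^3 K), and w_b (1/s) volumes.

        Exterior voxels take the skin-layer properties of their depth so
        conduction across the cylinder wall sees physical tissue (the wall is
        temperature-clamped by the heat solver).
        """
        nid = max(self.layers) + 1
        k_t = np.zeros(nid)
        rc_t = np.zeros(nid)
        wb_t = np.zeros(nid)
        for tid, layer in self.layers.items():
            k_t[tid] = layer.k_m
            rc_t[tid] = layer.rho * layer.c_v
            wb_t[tid] = layer.w_b
        k3 = k_t[self.tissue_id]
        rc3 = rc_t[self.tissue_id]
        wb3 = wb_t[self.tissue_id]
        ext = self.tissue_id == EXTERIOR
        if np.any(ext):
            lid = self._layer_id_by_depth()
            k3[ext] = k_t[lid][ext]
            rc3[ext] = rc_t[lid][ext]
            wb3[ext] = wb_t[lid][ext]
        return k3, rc3, wb3

    def _layer_id_by_depth(self) -> np.ndarray:
        """(nx, ny, nz) skin-layer id ignoring tumor and cylinder clipping."""
        _, _, z = self.centers()
        b = C.LAYER_BOUNDARIES_MM
        col = np.where(
            z < b[0], EPIDERMIS,
            np.where(z < b[1], PAPILLARY, np.where(z < b[2], RETICULAR, FAT)),
        )
        if SURFACE_BLEND in self.layers:
            col = np.where(z < self.metadata.get("blend_depth", 0.0), SURFACE_BLEND, col)
        return np.broadcast_to(col[None, None, :], self.shape)


def _blend_layers(a: TissueLayer, b: TissueLayer, fa: float, name: str) -> TissueLayer:
    """Volume-weighted property blend of two layers (fa = fraction of a)."""
    fb = 1.0 - fa
    mix = lambda x, y: fa * x + fb * y  # noqa: E731
    optics = MediumOpticalProperties(
        mu_abs=mix(a.optics.mu_abs, b.optics.mu_abs),
        mu_sca=mix(a.optics.mu_sca, b.optics.mu_sca),
        g=mix(a.optics.g, b.optics.g),
    )
    return TissueLayer(
        name, a.thickness + 0.0, mix(a.k_m, b.k_m), mix(a.c_v, b.c_v),
        mix(a.rho, b.rho), mix(a.w_b, b.w_b), optics,
    )


def aunp_region_optics(f_v: float, q_abs: float | None = None) -> MediumOpticalProperties:
    """Composite optics of the AuNP-loaded tumor core at 1064 nm.

    Tabulated values are used for the four study volume fractions; any other
    f_v requires ``q_abs`` so the absorption column can be extended through
    the (linear) mixing rule; reduced scattering is then log-interpolated
    from the table.
    """
    tumor = TissueLayer.from_table("tumor").optics
    if f_v == 0.0:
        return tumor
    if f_v in C.AUNP_TUMOR_OPTICS:
        mu_abs, mu_sca_red = C.AUNP_TUMOR_OPTICS[f_v]
    elif q_abs is not None:
        r_eff_mm = C.NP_EFFECTIVE_RADIUS_NM * 1e-6
        mu_abs = 0.75 * f_v * q_abs / r_eff_mm + tumor.mu_abs
        fv_tab = np.array(sorted(C.AUNP_TUMOR_OPTICS))
        red_tab = np.array([C.AUNP_TUMOR_OPTICS[v][1] for v in fv_tab])
        mu_sca_red = float(
            np.exp(np.interp(np.log(f_v), np.log(fv_tab), np.log(red_tab)))
        )
    else:
        raise ValueError(
            f"f_v = {f_v:g} is not tabulated and no Q_abs was provided"
        )
    return MediumOpticalProperties(mu_abs=mu_abs, mu_sca=mu_sca_red / (1.0 - tumor.g), g=tumor.g)


def build_domain(
    voxel_size: float = 0.2,
    f_v: float = 1e-6,
    q_abs: float | None = None,
) -> TissueDomain:
    """Construct the voxelized treatment scenario.

    Deterministic (no RNG).  ``f_v`` selects the AuNP-region optics from the
    tabulated composite coefficients; non-tabulated fractions need ``q_abs``.
    """
    dx = voxel_size
    R = C.DOMAIN_RADIUS_MM
    depth = C.DOMAIN_DEPTH_MM
    n_xy = int(round(2 * R / dx))
    n_z = int(round(depth / dx))

    x = -R + (np.arange(n_xy) + 0.5) * dx
    z = (np.arange(n_z) + 0.5) * dx
    X, Y = np.meshgrid(x, x, indexing="ij")
    r2 = X**2 + Y**2

    layers = {tid: TissueLayer.from_table(nm) for tid, nm in _LAYER_NAMES.items()}
    meta: dict = {"f_v": f_v}

    # Skin-layer id per depth (voxel centers).
    b = C.LAYER_BOUNDARIES_MM
    layer_of_z = np.where(
        z < b[0], EPIDERMIS,
        np.where(z < b[1], PAPILLARY, np.where(z < b[2], RETICULAR, FAT)),
    ).astype(np.uint8)
    blend_depth = 0.0
    if dx > C.TISSUE_TABLE["epidermis"][0]:
        # Epidermis thinner than a voxel: blend it into the top voxel layer.
        f_epi = C.TISSUE_TABLE["epidermis"][0] / dx
        layers[SURFACE_BLEND] = _blend_layers(
            layers[EPIDERMIS], layers[PAPILLARY], f_epi, "surface_blend"
        )
        layer_of_z[0] = SURFACE_BLEND
        blend_depth = dx
        meta["surface_blend_fraction_epidermis"] = f_epi
    meta["blend_depth"] = blend_depth

    tissue = np.broadcast_to(
        layer_of_z[None, None, :], (n_xy, n_xy, n_z)
    ).copy()

    # Tumor cylinder replaces the skin layers it overlaps.
    tumor_xy = r2 <= C.TUMOR_RADIUS_MM**2
    tumor_z = z < C.TUMOR_DEPTH_MM
    tumor3 = tumor_xy[:, :, None] & tumor_z[None, None, :]
    tissue[tumor3] = TUMOR

    # AuNP sphere inside the tumor.
    cx, cy, cz = C.AUNP_SPHERE_CENTER_MM
    d2 = (X - cx)[:, :, None] ** 2 + (Y - cy)[:, :, None] ** 2 + (
        (z - cz) ** 2
    )[None, None, :]
    # Clip to the tumor: the sphere touches the tumor's base plane, and
    # voxel-center sampling can otherwise round its bottom pole outside.
    aunp3 = (d2 <= C.AUNP_SPHERE_RADIUS_MM**2) & tumor3
    tissue[aunp3] = AUNP

    # Cylinder clipping.
    outside = r2 > R**2
    tissue[outside] = EXTERIOR

    aunp_optics = aunp_region_optics(f_v, q_abs)
    layers[AUNP] = TissueLayer(
        "tumor_aunp",
        layers[TUMOR].thickness,
        layers[TUMOR].k_m,
        layers[TUMOR].c_v,
        layers[TUMOR].rho,
        layers[TUMOR].w_b,
        aunp_optics,
    )

    dom = TissueDomain(
        voxel_size=dx, tissue_id=tissue, layers=layers, f_v=f_v, metadata=meta
    )
    _attach_optics_tables(dom)
    return dom


def _attach_optics_tables(dom: TissueDomain) -> None:
    nid = max(dom.layers) + 1
    mu_a = np.zeros(nid)
    mu_s = np.zeros(nid)
    g = np.zeros(nid)
    for tid, layer in dom.layers.items():
        mu_a[tid] = layer.optics.mu_abs
        mu_s[tid] = layer.optics.mu_sca
        g[tid] = layer.optics.g
    dom.mu_abs_by_id = mu_a
    dom.mu_sca_by_id = mu_s
    dom.mu_ext_by_id = mu_a + mu_s
    dom.g_by_id = g


def hazard_shell(domain: TissueDomain) -> np.ndarray:
    """Normal-tissue shell within 1 mm outward of the tumor boundary.

    The assessed region extends from the tumor surface outward by 50% of the
    tumor length (2 mm), i.e. 1 mm; tumor voxels are excluded, as are voxels
    outside the tissue cylinder.  Distances are voxel-center to nearest
    tumor-voxel-center (Euclidean distance transform).
    """
    tumor = domain.tumor_mask
    if not np.any(tumor):
        raise ValueError("tumor mask is empty")
    dist = ndimage.distance_transform_edt(~tumor, sampling=domain.voxel_size)
    shell_width = 0.5 * C.TUMOR_DEPTH_MM
    return (dist > 0) & (dist <= shell_width + 1e-9) & domain.inside_mask & ~tumor


@dataclass
class SyntheticTemperatureField:
    """Piecewise-constant temperature field with known band occupancy."""

    temperatures: np.ndarray          # (nx, ny, nz) deg C
    mask: np.ndarray                  # voxels the bands were assigned over
    expected_fractions: dict[float, float]  # band temperature -> fraction


def make_synthetic_field(
    domain: TissueDomain,
    band_spec: dict[float, float],
    mask: np.ndarray | None = None,
    background: float = 37.0,
) -> SyntheticTemperatureField:
    """Assign band temperatures over a mask at requested volume fractions.

    ``band_spec`` maps a representative temperature (deg C) to the fraction
    of mask voxels to hold at it; fractions must sum to 1.  Assignment is
    deterministic (flattened voxel order), so realized fractions match the
    request to within one voxel.
    """
    if mask is None:
        mask = domain.tumor_mask
    fracs = np.array(list(band_spec.values()), dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("band fractions must sum to 1")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask is empty")
    counts = np.floor(fracs * n).astype(int)
    # Distribute the rounding remainder to the largest bands, stably.
    for i in np.argsort(-fracs)[: n - counts.sum()]:
        counts[i] += 1
    if np.any((counts == 0) & (fracs > 0)):
        raise ValueError("mask too small to realize a requested band fraction")
    temps = np.full(domain.shape, background)
    values = np.repeat(np.fromiter(band_spec, dtype=float), counts)
    temps[mask] = values
    return SyntheticTemperatureField(temps, mask, dict(band_spec))
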