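"""YAML configuration loading for sweeps and thermal scenarios."""

from __future__ import annotations

from pathlib import Path

import yaml

from .bioheat import ThermalScenario
from .driver import SweepConfig
from .metrics import HazardWeighting

_SWEEP_KEYS = {
    "angles_deg", "volume_fractions", "powers_w", "n_photons", "voxel_size",
    "base_seed", "snapshot_interval", "cache_dir",
}
_SCENARIO_KEYS = {
    "initial_temperature", "boundary_temperature", "rho_b", "c_b", "T_b",
    "duration", "dt", "snapshot_interval", "perfusion_enabled", "scheme",
}


def load_config(path: str | Path) -> SweepConfig:
    """Build a SweepConfig from a YAML file.

    Top-level keys map onto SweepConfig fields; a nested ``scenario`` block
    maps onto ThermalScenario, and a ``weighting`` block (``edges``,
    ``weights``) onto HazardWeighting.  Unknown keys raise.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, val in raw.items():
        if key == "scenario":
            bad = set(val) - _SCENARIO_KEYS
            if bad:
                raise ValueError(f"unknown scenario keys: {sorted(bad)}")
            kwargs["scenario"] = ThermalScenario(**val)
        elif key == "weighting":
            kwargs["weighting"] = HazardWeighting(
                edges=tuple(val["edges"]), weights=tuple(val["weights"])
            )
        elif key in _SWEEP_KEYS:
            kwargs[key] = tuple(val) if isinstance(val, list) else val
        else:
            raise ValueError(f"unknown config key: {key}")
    return SweepConfig(**kwargs)
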