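"""Reference constants shipped as data files.

The optimised half-center parameters, the printed speed maps and the
curved-walk demonstration schedules live in JSON files here so that
neither library code nor tests embed the numbers directly.
"""

from __future__ import annotations

import json
from importlib import resources

from ..empirical import SpeedMaps
from ..model_core import HalfCenterParams, LimbCPGParams

__all__ = [
    "default_limb_params",
    "default_speed_maps",
    "steering_scenarios",
]


def _load(name: str) -> dict:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return json.load(fh)


def default_limb_params() -> LimbCPGParams:
    """Optimised cat-walking parameters for the single-limb CPG."""
    d = _load("default_params.json")
    return LimbCPGParams(
        hc1=HalfCenterParams(x0=d["x01"], g=d["g1"]),
        hc2=HalfCenterParams(x0=d["x02"], g=d["g2"]),
        r_leak=d["r_leak"],
    )


def default_speed_maps() -> SpeedMaps:
    """Printed speed-to-drive regression and duration power law."""
    d = _load("speed_maps.json")
    return SpeedMaps(
        u_offset=d["u_offset"],
        u_scale=d["u_scale"],
        emp_coeff=d["emp_coeff"],
        emp_exp=d["emp_exp"],
        swing_const=d["swing_const"],
    )


def steering_scenarios() -> dict:
    """Curved-walk demonstration schedule specification."""
    return _load("steering_scenarios.json")
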