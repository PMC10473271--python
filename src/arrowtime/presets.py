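"""Named analysis presets and the run configuration shared by CLI commands.

Two acquisition presets are bundled:

``hcp``   fast-TR acquisition (TR = 0.72 s), series truncated to 176
          samples; global/system window 20 TRs shifted by 3, node window
          150 TRs shifted by 2; lagged-FC delay fixed at tau = 3 TRs.
``ucla``  slow-TR acquisition (TR = 2 s), 152 samples; global window
          10 TRs shifted by 1, node window 20 TRs shifted by 1; tau chosen
          from the autocorrelation decay at run time.

Explicit fields always override the preset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class RunConfig:
    """Everything a pipeline run needs, resolvable from a preset + overrides."""

    preset: str = "custom"
    scale: str = "global"
    w: int = 20
    shift: int = 3
    tau: int | None = None
    tr_seconds: float = 1.0
    truncate_to: int | None = None
    eval_fraction: float = 0.1
    low_hz: float = 0.008
    high_hz: float = 0.08
    filter_order: int = 2
    normalization: str = "per_region_zscore"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


_PRESET_FIELDS = {
    "hcp": {
        "tr_seconds": 0.72, "truncate_to": 176, "tau": 3,
        "global": {"w": 20, "shift": 3},
        "system": {"w": 20, "shift": 3},
        "node": {"w": 150, "shift": 2},
    },
    "ucla": {
        "tr_seconds": 2.0, "truncate_to": 152, "tau": None,
        "global": {"w": 10, "shift": 1},
        "system": {"w": 10, "shift": 1},
        "node": {"w": 20, "shift": 1},
    },
}


def resolve_config(preset: str = "custom", scale: str = "global",
                   **overrides) -> RunConfig:
    """Build a RunConfig from a named preset, then apply explicit overrides."""
    if preset not in ("custom", *_PRESET_FIELDS):
        raise ValueError(f"unknown preset {preset!r}")
    fields: dict = {"preset": preset, "scale": scale}
    if preset in _PRESET_FIELDS:
        p = _PRESET_FIELDS[preset]
        fields.update(tr_seconds=p["tr_seconds"], truncate_to=p["truncate_to"],
                      tau=p["tau"], **p[scale])
    fields.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**fields)
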