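"""Run configuration: the pipeline's fixed constants, with strict parsing.

The defaults encode the analysis conventions used throughout: a 30%-of-max
functional threshold, V20's 20 Gy cut, 0.1 Gy DVH bins, inclusive (>=) dose
comparison, binary-mask functional metrics, and a 0.05 band for calling two
metric families equivalent in the dominance label. Config files (JSON or
YAML) are merged over these defaults; unknown keys and out-of-range values
are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .grid import ORIGIN_ATOL_MM, SPACING_ATOL_MM


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    threshold_fraction: float = 0.30
    vx_dose_gy: float = 20.0
    dvh_bin_width_gy: float = 0.1
    vx_inequality: str = "ge"            # "ge" or "gt"
    functional_mode: str = "binary_mask" # or "activity_weighted"
    dominance_epsilon: float = 0.05
    p_method: str = "t_approx"           # or "permutation"
    n_perm: int = 10000
    seed: int = 0
    spacing_atol_mm: float = SPACING_ATOL_MM
    origin_atol_mm: float = ORIGIN_ATOL_MM

    def __post_init__(self):
        checks = [
            (0.0 < self.threshold_fraction <= 1.0,
             f"threshold_fraction must be in (0, 1], got {self.threshold_fraction}"),
            (self.vx_dose_gy >= 0, f"vx_dose_gy must be >= 0, got {self.vx_dose_gy}"),
            (self.dvh_bin_width_gy > 0,
             f"dvh_bin_width_gy must be > 0, got {self.dvh_bin_width_gy}"),
            (self.vx_inequality in ("ge", "gt"),
             f"vx_inequality must be 'ge' or 'gt', got {self.vx_inequality!r}"),
            (self.functional_mode in ("binary_mask", "activity_weighted"),
             f"functional_mode must be 'binary_mask' or 'activity_weighted', "
             f"got {self.functional_mode!r}"),
            (self.dominance_epsilon > 0,
             f"dominance_epsilon must be > 0, got {self.dominance_epsilon}"),
            (self.p_method in ("t_approx", "permutation"),
             f"p_method must be 't_approx' or 'permutation', got {self.p_method!r}"),
            (self.n_perm >= 1, f"n_perm must be >= 1, got {self.n_perm}"),
            (self.spacing_atol_mm > 0, "spacing_atol_mm must be > 0"),
            (self.origin_atol_mm > 0, "origin_atol_mm must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @property
    def vx_inclusive(self) -> bool:
        return self.vx_inequality == "ge"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def _read_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping, got {type(data).__name__}")
    return data


def load_config(path) -> RunConfig:
    """Load a JSON/YAML config merged over the documented defaults.

    Unknown keys are an error, as are out-of-range values.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = _read_structured(path)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {unknown}")
    return RunConfig(**data)
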