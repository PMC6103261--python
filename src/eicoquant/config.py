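"""Pipeline configuration: one flat mapping of method constants and paths.

Defaults mirror the published method: 25 min gradient at 0.6 mL/min with a
10 µL injection, 0.05 Da fragment windows, 10 ms dwell, pH 5.8 retention
times. A YAML file can override any field; CLI flags override the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .validation import GateThresholds

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # paths (None -> bundled reference data)
    library_path: str | None = None
    rt_table_path: str | None = None
    ph_label: str = "5.8"
    output_dir: str = "eicoquant_out"
    # extraction
    window_da: float = 0.05
    precursor_tol_da: float = 0.7
    rt_tolerance_min: float = 0.5
    # calibration
    weighting: str = "1/x"
    response_mode: str = "area"
    # validation thresholds (percent)
    rsd_limit: float = 15.0
    rsd_limit_lloq: float = 20.0
    re_limit: float = 15.0
    re_limit_lloq: float = 20.0
    accuracy_low: float = 80.0
    accuracy_high: float = 120.0
    replicate_cv_limit: float = 15.0
    # run metadata (documentation of the chromatographic method)
    run_length_min: float = 25.0
    flow_ml_min: float = 0.6
    injection_ul: float = 10.0
    dwell_ms: float = 10.0
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in (
            "window_da",
            "precursor_tol_da",
            "rt_tolerance_min",
            "rsd_limit",
            "re_limit",
            "replicate_cv_limit",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def thresholds(self) -> GateThresholds:
        return GateThresholds(
            rsd_limit=self.rsd_limit,
            rsd_limit_lloq=self.rsd_limit_lloq,
            re_limit=self.re_limit,
            re_limit_lloq=self.re_limit_lloq,
            accuracy_low=self.accuracy_low,
            accuracy_high=self.accuracy_high,
            replicate_cv_limit=self.replicate_cv_limit,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file, and overrides."""
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)
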