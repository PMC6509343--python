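"""Pipeline configuration: nested sections, YAML round-trip, validation."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs.

    ``inputs`` holds TSV paths (expression, detection, metadata,
    annotation); when ``simulate`` is non-null the cohort is generated
    instead and ``inputs`` may be empty.  Section contents mirror the
    stage configs; unknown keys are rejected at stage construction.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    simulate: dict | None = None
    preprocess: dict = field(default_factory=lambda: {
        "already_log2": True,
        "quantile_normalize": True,
        "detection_alpha": 0.05,
        "min_detected_subjects": 841 / 849,
        "min_age": 25,
    })
    model: dict = field(default_factory=lambda: {
        "case": "schizophrenia",
        "reference": "control",
        "robust_tuning": 5.0,
    })
    subtyping: dict = field(default_factory=lambda: {
        "soft_power": 6.0,
        "network_sign": "signed",
        "n_clusters": 2,
        "de_alpha_bonf": 0.05,
    })
    stability: dict = field(default_factory=lambda: {
        "levels": [0.0, 0.05, 0.10, 0.25, 0.50],
        "n_runs": 100,
        "sd_scope": "per_probe",
    })
    graph: dict = field(default_factory=lambda: {
        "thresholds": [0.05, 0.08, 0.10, 0.12],
    })
    criterion: dict = field(default_factory=lambda: {
        "method": "bonferroni",
        "alpha": 0.05,
    })

    def validate(self) -> None:
        if self.simulate is None and not self.inputs:
            raise ConfigurationError(
                "either 'inputs' paths or a 'simulate' section is required")
        if self.simulate is None:
            for key in ("expression", "detection", "metadata", "annotation"):
                if key not in self.inputs:
                    raise ConfigurationError(f"inputs.{key} is required")
        levels = self.stability.get("levels", [])
        if sorted(levels) != list(levels):
            raise ConfigurationError(
                "stability.levels must be sorted ascending")
        method = self.criterion.get("method")
        if method not in ("bonferroni", "fdr"):
            raise ConfigurationError(
                f"criterion.method must be 'bonferroni' or 'fdr', got "
                f"{method!r}")
        if not 0 < float(self.criterion.get("alpha", 0.05)) < 1:
            raise ConfigurationError("criterion.alpha must be in (0, 1)")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown pipeline config sections: {sorted(unknown)}")
        base = cls()
        merged = {}
        for name in known:
            default = getattr(base, name)
            if name in d:
                val = d[name]
                if isinstance(default, dict) and isinstance(val, dict):
                    merged[name] = {**default, **val}
                else:
                    merged[name] = val
            else:
                merged[name] = default
        cfg = cls(**merged)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the configuration for the run manifest."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
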