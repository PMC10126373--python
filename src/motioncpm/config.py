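"""Run-level configuration shared by every pipeline stage."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

from .exceptions import ValidationError

_CENSOR_RULES = ("both", "either")
_VARIANTS = ("bilinear", "positive_only", "negative_only")
_DIALECTS = ("hcp", "mcflirt")
_SUMMARY_STYLES = ("pooled", "per_scan_mean")


@dataclass
class RunConfig:
    """Constants and switches of the head-motion analysis.

    Defaults follow the published protocol: frames are censored when the
    frame-to-frame RMS BOLD change exceeds 0.5 % *and* framewise
    displacement (on a 50 mm sphere) exceeds 0.5 mm; connectivity uses the
    first 150 surviving frames; signals are low-pass filtered at 0.10 Hz;
    CPM feature selection at p < 0.01; significance from 1,000 score
    permutations.

    Parameters
    ----------
    fd_threshold : float
        Framewise-displacement censoring threshold in mm (0.5, or 0.2 for
        strict scrubbing).
    bold_change_threshold : float
        Frame-to-frame RMS BOLD change threshold in percent.
    censor_rule : {"both", "either"}
        Whether a frame must exceed both thresholds or either one to be
        censored.
    sphere_radius : float
        Radius in mm used to convert rotation increments to arc length.
    frames_keep : int
        Number of surviving frames used for connectivity and summaries.
    lowpass_cutoff : float
        Low-pass filter cutoff in Hz.
    selection_p : float
        Two-sided parametric p threshold for edge selection.
    model_variant : {"bilinear", "positive_only", "negative_only"}
        Which network strengths enter the prediction model.
    overlap_fraction : float
        Fraction of edge-mask sets an edge must appear in to enter the
        motion-sensitive network.
    n_permutations : int
        Number of score permutations for the null distribution.
    rng_seed : int
        Seed for every random operation; no global random state is used.
    realignment_dialect : {"hcp", "mcflirt"}
        Column convention of realignment parameter files.
    summary_style : {"pooled", "per_scan_mean"}
        Whether RMS motion summaries pool frames across scans before one
        RMS, or average per-scan RMS values.
    """

    fd_threshold: float = 0.5
    bold_change_threshold: float = 0.5
    censor_rule: str = "both"
    sphere_radius: float = 50.0
    frames_keep: int = 150
    lowpass_cutoff: float = 0.10
    selection_p: float = 0.01
    model_variant: str = "bilinear"
    overlap_fraction: float = 0.5
    n_permutations: int = 1000
    rng_seed: int = 0
    realignment_dialect: str = "hcp"
    summary_style: str = "pooled"

    def __post_init__(self) -> None:
        for name in ("fd_threshold", "bold_change_threshold", "sphere_radius",
                     "lowpass_cutoff", "selection_p"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not (0.0 < self.overlap_fraction <= 1.0):
            raise ValidationError("overlap_fraction must lie in (0, 1]")
        if self.frames_keep < 2:
            raise ValidationError("frames_keep must be at least 2")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be positive")
        if self.censor_rule not in _CENSOR_RULES:
            raise ValidationError(f"censor_rule must be one of {_CENSOR_RULES}")
        if self.model_variant not in _VARIANTS:
            raise ValidationError(f"model_variant must be one of {_VARIANTS}")
        if self.realignment_dialect not in _DIALECTS:
            raise ValidationError(f"realignment_dialect must be one of {_DIALECTS}")
        if self.summary_style not in _SUMMARY_STYLES:
            raise ValidationError(f"summary_style must be one of {_SUMMARY_STYLES}")

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from a JSON or YAML file (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))
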