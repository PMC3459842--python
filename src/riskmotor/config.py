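"""Pipeline configuration: YAML schema, validation, defaults, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigError
from .fitting import DesignConstants, FitOptions
from .model import CostFunction, ModelParams
from .simulate import DesignSpec, SubjectSpec, default_costs

__all__ = [
    "AnalysisOptions",
    "PipelineConfig",
    "default_config",
    "load_config",
    "config_from_dict",
    "config_hash",
]


@dataclass(frozen=True)
class AnalysisOptions:
    axis_flip: bool = False
    gg_correction: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for the simulate -> analyze -> fit pipeline."""

    seed: int
    output_dir: str
    design: DesignSpec
    model: dict  # sigma_p, Q, halfwidth, sigma_o_full
    costs: dict[str, CostFunction]
    subjects: list[SubjectSpec]
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    fitting: FitOptions = field(default_factory=FitOptions)
    raw: dict = field(default_factory=dict, repr=False)

    def design_constants(self) -> DesignConstants:
        return DesignConstants(
            sigma_p=self.model["sigma_p"],
            Q=self.model["Q"],
            costs=self.costs,
            sigma_o_full=self.model["sigma_o_full"],
        )


def _expect_keys(d: dict, allowed: set[str], required: set[str], context: str) -> None:
    if not isinstance(d, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(d).__name__}")
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")
    missing = required - set(d)
    if missing:
        raise ConfigError(f"{context}: missing required key(s) {sorted(missing)}")


def config_from_dict(raw: dict) -> PipelineConfig:
    """Validate a raw config mapping; unknown keys are rejected."""
    _expect_keys(
        raw,
        {"seed", "output_dir", "design", "model", "costs", "subjects",
         "analysis", "fitting"},
        {"seed", "design", "model", "costs", "subjects"},
        "config",
    )
    try:
        d = raw["design"]
        _expect_keys(
            d,
            {"trials_per_block", "feedback_weights", "block_order", "burn_in"},
            {"trials_per_block"},
            "config.design",
        )
        design = DesignSpec(
            trials_per_block=int(d["trials_per_block"]),
            feedback_weights=tuple(d.get("feedback_weights", (2, 1, 1))),
            block_order=tuple(d.get("block_order", ("F0", "FL", "FR"))),
            burn_in=int(d.get("burn_in", 0)),
        )
        m = raw["model"]
        _expect_keys(m, {"sigma_p", "Q", "halfwidth", "sigma_o_full"},
                     {"sigma_p", "Q", "halfwidth"}, "config.model")
        model = {
            "sigma_p": float(m["sigma_p"]),
            "Q": float(m["Q"]),
            "halfwidth": float(m["halfwidth"]),
            "sigma_o_full": float(m.get("sigma_o_full", 0.0)),
        }
        c = raw["costs"]
        _expect_keys(c, {"c0", "c1"}, {"c1"}, "config.costs")
        costs = default_costs(c1=float(c["c1"]), c0=float(c.get("c0", 0.0)))
        subjects = []
        for i, s in enumerate(raw["subjects"]):
            _expect_keys(
                s,
                {"subject_id", "theta", "sigma_m", "sigma_blur", "blur_mode",
                 "cloud_size"},
                {"subject_id", "theta", "sigma_m", "sigma_blur"},
                f"config.subjects[{i}]",
            )
            subjects.append(
                SubjectSpec(
                    subject_id=str(s["subject_id"]),
                    params=ModelParams(
                        sigma_p=model["sigma_p"], Q=model["Q"],
                        theta=float(s["theta"]), sigma_m=float(s["sigma_m"]),
                        halfwidth=model["halfwidth"],
                    ),
                    sigma_blur=float(s["sigma_blur"]),
                    blur_mode=s.get("blur_mode", "scalar"),
                    cloud_size=int(s.get("cloud_size", 5)),
                )
            )
        a = raw.get("analysis", {})
        _expect_keys(a, {"axis_flip", "gg_correction"}, set(), "config.analysis")
        analysis = AnalysisOptions(
            axis_flip=bool(a.get("axis_flip", False)),
            gg_correction=bool(a.get("gg_correction", False)),
        )
        f = raw.get("fitting", {})
        _expect_keys(
            f,
            {"n_starts", "theta_bounds", "sigma_blur_bounds", "sigma_m_bounds",
             "k0_bounds", "breakdown_margin", "seed", "maxiter"},
            set(),
            "config.fitting",
        )
        fit_kwargs = {k: v for k, v in f.items()}
        for key in ("theta_bounds", "sigma_blur_bounds", "sigma_m_bounds", "k0_bounds"):
            if key in fit_kwargs:
                fit_kwargs[key] = tuple(float(v) for v in fit_kwargs[key])
        fitting = FitOptions(**fit_kwargs)
    except ConfigError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    return PipelineConfig(
        seed=int(raw["seed"]),
        output_dir=str(raw.get("output_dir", "riskmotor_out")),
        design=design,
        model=model,
        costs=costs,
        subjects=subjects,
        analysis=analysis,
        fitting=fitting,
        raw=raw,
    )


def load_config(path) -> PipelineConfig:
    with open(Path(path), encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def default_config(**overrides) -> PipelineConfig:
    """The packaged default study conditions, optionally with top-level
    overrides (e.g. ``default_config(seed=1)``)."""
    text = resources.files("riskmotor").joinpath("defaults.yaml").read_text()
    raw = yaml.safe_load(text)
    raw.update(overrides)
    return config_from_dict(raw)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the raw configuration mapping."""
    canonical = json.dumps(config.raw, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
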