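"""Cohort scenario configuration for the synthetic generator.

A Scenario describes one regeneration experiment: the experimental groups
with their per-timepoint BFP+/control area ratios and mCherry survival after
ablation, the acquisition geometry, and the nuisance model.  The default
scenario encodes the study conditions of the genetic-ablation experiment:
three groups (negative control / not ablated / ablated), three timepoints
(0, 1, 3 days post injury), n = 24 larvae per group, BFP+ area of the
ablated group at 45 / 65 / 85% of the negative control, and near-total
(97%) loss of the mCherry+ FHF compartment after ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .heart import HeartModel, NoiseParams

__all__ = ["GroupSpec", "ImagingParams", "Scenario", "default_scenario", "load_scenario", "save_scenario"]

TIMEPOINTS = ("TP1", "TP2", "TP3")


@dataclass(frozen=True)
class GroupSpec:
    """One experimental condition.

    ``bfp_ratio_by_timepoint`` maps timepoint label to the group-mean BFP+
    area as a fraction of the negative-control mean at that timepoint.
    ``effect_multiplier`` rescales the TP1->TP2 and TP2->TP3 regeneration
    increments (a drug or crispant modifier: <1 anti-, >1 pro-regenerative).
    """

    name: str
    n_larvae: int = 24
    recombined: bool = True
    ablation_survival_fraction: float = 1.0
    bfp_ratio_by_timepoint: Mapping[str, float] = field(default_factory=dict)
    effect_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.n_larvae < 1:
            raise ValueError(f"group {self.name!r}: n_larvae must be >= 1")
        if not 0.0 <= self.ablation_survival_fraction <= 1.5:
            raise ValueError(f"group {self.name!r}: ablation_survival_fraction outside [0, 1.5]")
        for tp, r in self.bfp_ratio_by_timepoint.items():
            if not 0.0 <= r <= 1.5:
                raise ValueError(f"group {self.name!r}, {tp}: bfp ratio {r} outside [0, 1.5]")
        if self.effect_multiplier < 0:
            raise ValueError(f"group {self.name!r}: effect_multiplier must be >= 0")

    def ratio_trajectory(self, timepoints: Sequence[str]) -> dict[str, float]:
        """Per-timepoint ratios with the effect multiplier applied to increments."""
        out: dict[str, float] = {}
        prev = None
        for tp in timepoints:
            r = float(self.bfp_ratio_by_timepoint.get(tp, 1.0))
            if prev is None:
                out[tp] = r
            else:
                out[tp] = out[timepoints[list(timepoints).index(tp) - 1]] + self.effect_multiplier * (r - prev)
            prev = r
        return out


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition geometry of the automated imaging platform."""

    frame_rate_fps: float = 96.8
    duration_s: float = 2.8
    pixel_size_um: float = 1.3
    frame_shape: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if self.frame_rate_fps <= 0 or self.duration_s <= 0 or self.pixel_size_um <= 0:
            raise ValueError("imaging parameters must be positive")
        if self.n_frames < 2:
            raise ValueError("duration_s x frame_rate_fps must span at least 2 frames")

    @property
    def n_frames(self) -> int:
        return int(self.duration_s * self.frame_rate_fps)


@dataclass(frozen=True)
class Scenario:
    groups: tuple[GroupSpec, ...]
    timepoints: tuple[str, ...] = TIMEPOINTS
    imaging: ImagingParams = field(default_factory=ImagingParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    heart: HeartModel = field(default_factory=HeartModel)
    size_cv: float = 0.10       # lognormal CV of per-larva diastolic area
    heart_rate_cv: float = 0.05  # mild per-larva heart-rate variability
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("scenario needs at least one group")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        if self.size_cv < 0 or self.heart_rate_cv < 0:
            raise ValueError("variability CVs must be >= 0")

    @property
    def total_larvae(self) -> int:
        return sum(g.n_larvae for g in self.groups)


def default_scenario(
    n_larvae: int = 24,
    fhf_area_fraction: float = 0.55,
    ablation_survival_fraction: float = 0.03,
    seed: int = 0,
    **overrides,
) -> Scenario:
    """The calibrated genetic-ablation scenario.

    The not-ablated group's BFP+ pool is the SHF crescent, i.e. a fixed
    1 - fhf_area_fraction of the control ventricle; the ablated group starts
    there and regenerates to 65% and 85% of control by 1 and 3 days post
    injury.
    """
    shf = 1.0 - fhf_area_fraction
    groups = (
        GroupSpec(
            name="negative_control",
            n_larvae=n_larvae,
            recombined=False,
            bfp_ratio_by_timepoint={"TP1": 1.0, "TP2": 1.0, "TP3": 1.0},
        ),
        GroupSpec(
            name="not_ablated",
            n_larvae=n_larvae,
            recombined=True,
            bfp_ratio_by_timepoint={"TP1": shf, "TP2": shf, "TP3": shf},
        ),
        GroupSpec(
            name="ablated",
            n_larvae=n_larvae,
            recombined=True,
            ablation_survival_fraction=ablation_survival_fraction,
            bfp_ratio_by_timepoint={"TP1": shf, "TP2": 0.65, "TP3": 0.85},
        ),
    )
    heart = overrides.pop("heart", None) or HeartModel(fhf_area_fraction=fhf_area_fraction)
    return Scenario(groups=groups, heart=heart, seed=seed, **overrides)


def _scenario_to_dict(s: Scenario) -> dict:
    d = asdict(s)
    d["heart"]["intensities"] = dict(s.heart.intensities)
    for g in d["groups"]:
        g["bfp_ratio_by_timepoint"] = dict(g["bfp_ratio_by_timepoint"])
    return d


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_scenario_to_dict(scenario), fh, sort_keys=False)


def load_scenario(path: str | Path) -> Scenario:
    """Load a Scenario from a YAML (or JSON, a YAML subset) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    groups = tuple(GroupSpec(**g) for g in raw.pop("groups"))
    imaging = raw.pop("imaging", None)
    noise = raw.pop("noise", None)
    heart = raw.pop("heart", None)
    kwargs = dict(raw)
    kwargs["groups"] = groups
    kwargs["timepoints"] = tuple(raw.get("timepoints", TIMEPOINTS))
    if imaging is not None:
        imaging["frame_shape"] = tuple(imaging["frame_shape"])
        kwargs["imaging"] = ImagingParams(**imaging)
    if noise is not None:
        kwargs["noise"] = NoiseParams(**noise)
    if heart is not None:
        for key in ("center_xy", "diastolic_semi_axes", "bulbus_offset_xy"):
            if key in heart:
                heart[key] = tuple(heart[key])
        kwargs["heart"] = HeartModel(**heart)
    return Scenario(**kwargs)
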