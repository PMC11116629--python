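"""Parametric beating-heart model and fluorescence frame renderer.

The larval ventricle is modelled as an ellipse whose semi-axes contract
sinusoidally at the heart rate.  The ventricular myocardium is split into two
developmental compartments by a chord perpendicular to the long axis: the
first-heart-field (FHF) sector, which expresses mCherry after Cre
recombination, and the second-heart-field (SHF) crescent, which retains BFP.
The chord is placed so that the FHF sector occupies a configurable fraction
of the ellipse area (~55% at 6 dpf).

Regeneration state is encoded geometrically: the BFP+ region is the part of
the ellipse on the SHF side of a moving chord whose area fraction equals the
larva's current BFP+/control ratio, and genetic ablation leaves a compact
patch of surviving mCherry+ cells whose area is a configurable fraction of
the FHF sector.  Both compartments keep full fluorophore intensity — ablation
removes cells (area), it does not dim the survivors.

This is a deliberately simple phantom: 2-D, single focal plane, no optics
model.  Its virtue is that every rendered area has a closed-form value, so
the downstream measurement chain can be validated against analytic geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "HeartModel",
    "NoiseParams",
    "heart_geometry_at",
    "chord_offset_for_area_fraction",
    "segment_area_fraction",
    "draw_distractor_positions",
    "render_frame",
    "render_video",
]

CHANNELS = ("BFP", "mCherry")

DEFAULT_INTENSITIES: Mapping[str, float] = {
    "bfp": 3000.0,      # compartment intensity, arbitrary units on a 16-bit range
    "mcherry": 3000.0,
    "bulbus": 1500.0,   # weak BFP signal occasionally seen in the bulbus arteriosus
}


def segment_area_fraction(d: float) -> float:
    """Fraction of a unit disc's area lying at x >= d (circular segment).

    Because the compartment boundary is a chord at constant normalized
    abscissa u = d, the same expression gives the area fraction of the
    corresponding elliptical segment for any semi-axes.
    """
    d = float(np.clip(d, -1.0, 1.0))
    return (math.acos(d) - d * math.sqrt(max(0.0, 1.0 - d * d))) / math.pi


def chord_offset_for_area_fraction(fraction: float) -> float:
    """Normalized chord abscissa d such that the region u >= d holds `fraction`
    of the ellipse area.  fraction=0 -> d=1 (empty), fraction=1 -> d=-1 (all)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"area fraction must be in [0, 1], got {fraction}")
    if fraction <= 0.0:
        return 1.0
    if fraction >= 1.0:
        return -1.0
    return float(brentq(lambda d: segment_area_fraction(d) - fraction, -1.0, 1.0, xtol=1e-12))


def _segment_centroid(d: float) -> float:
    """Centroid abscissa of the unit-disc segment x >= d."""
    area = segment_area_fraction(d) * math.pi
    if area <= 0.0:
        return 1.0
    return (2.0 / 3.0) * (1.0 - d * d) ** 1.5 / area


@dataclass(frozen=True)
class HeartModel:
    """Geometric and photometric description of one larva's heart.

    Parameters
    ----------
    center_xy : (x, y) ellipse centre in pixels.
    diastolic_semi_axes : (a0, b0) semi-axes at full relaxation, pixels.
    contraction_fraction : fractional reduction of both semi-axes at peak
        systole, in [0, 1).
    heart_rate_bpm : beats per minute.  The default (214.3) puts ten full
        beats into a 2.8 s acquisition.
    phase : phase offset of the contraction sinusoid, radians.
    fhf_area_fraction : share of ventricular area occupied by the FHF
        (mCherry after recombination) compartment.
    recombined : whether Cre recombination occurred (tamoxifen-treated
        groups).  Unrecombined hearts are BFP throughout and carry no mCherry.
    bfp_area_fraction : BFP+ share of the *control-sized* ellipse area.
        1.0 for unrecombined hearts; equals the regeneration ratio for
        recombined hearts (0.45 right after ablation, growing toward 1).
        Values > 1 scale the whole ellipse (regrowth beyond control size).
    mcherry_survival : fraction of the FHF sector area still mCherry+
        (1.0 = not ablated; ~0.03 after metronidazole ablation).
    bulbus_offset_xy, bulbus_radius : position (relative to centre) and size
        of the bulbus arteriosus disc, rendered with weak BFP.
    intensities : per-compartment fluorophore intensities, arbitrary units.
    """

    center_xy: tuple[float, float] = (64.0, 56.0)
    diastolic_semi_axes: tuple[float, float] = (40.0, 30.0)
    contraction_fraction: float = 0.2
    heart_rate_bpm: float = 214.3
    phase: float = 0.0
    fhf_area_fraction: float = 0.55
    recombined: bool = False
    bfp_area_fraction: float = 1.0
    mcherry_survival: float = 1.0
    bulbus_offset_xy: tuple[float, float] = (0.0, -43.0)
    bulbus_radius: float = 9.0
    intensities: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))

    def __post_init__(self) -> None:
        a0, b0 = self.diastolic_semi_axes
        if a0 <= 0 or b0 <= 0:
            raise ValueError("diastolic semi-axes must be strictly positive")
        if not 0.0 <= self.contraction_fraction < 1.0:
            raise ValueError("contraction_fraction must be in [0, 1)")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart_rate_bpm must be positive")
        if not 0.0 <= self.fhf_area_fraction <= 1.0:
            raise ValueError("fhf_area_fraction must be in [0, 1]")
        if self.bfp_area_fraction < 0:
            raise ValueError("bfp_area_fraction must be non-negative")
        if not 0.0 <= self.mcherry_survival <= 1.0:
            raise ValueError("mcherry_survival must be in [0, 1]")
        if self.bulbus_radius < 0:
            raise ValueError("bulbus_radius must be non-negative")

    @property
    def shf_area_fraction(self) -> float:
        return 1.0 - self.fhf_area_fraction

    @property
    def beat_frequency_hz(self) -> float:
        return self.heart_rate_bpm / 60.0

    def with_(self, **kwargs) -> "HeartModel":
        return replace(self, **kwargs)


def heart_geometry_at(model: HeartModel, t):
    """Ellipse semi-axes (a, b) in pixels at time ``t`` seconds.

    a(t) = a0 * (1 - c * (1 + sin(2*pi*f*t + phi)) / 2), likewise b(t);
    the minimum over one period is a0 * (1 - c).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    a0, b0 = model.diastolic_semi_axes
    c = model.contraction_fraction
    s = np.sin(2.0 * math.pi * model.beat_frequency_hz * t + model.phase)
    factor = 1.0 - c * (1.0 + s) / 2.0
    return a0 * factor, b0 * factor


@dataclass(frozen=True)
class NoiseParams:
    """Background and nuisance-structure parameters for rendering."""

    background_level: float = 200.0
    gaussian_sd: float = 150.0
    n_distractors: int = 6
    distractor_intensity: float = 1500.0
    distractor_sigma_px: float = 3.0

    def __post_init__(self) -> None:
        if self.background_level < 0 or self.gaussian_sd < 0:
            raise ValueError("background_level and gaussian_sd must be >= 0")
        if self.n_distractors < 0:
            raise ValueError("n_distractors must be >= 0")


def draw_distractor_positions(
    model: HeartModel,
    frame_shape: tuple[int, int],
    n: int,
    rng: np.random.Generator,
    margin: float = 5.0,
    min_separation: float = 12.0,
) -> np.ndarray:
    """Sample ``n`` static autofluorescent-blob centres outside the ventricle.

    Rejection-samples uniform positions until they clear the diastolic
    ellipse (with a 30% safety dilation), the bulbus disc, and each other
    (``min_separation`` keeps blobs resolvable as separate structures).
    """
    ny, nx = frame_shape
    cx, cy = model.center_xy
    a0, b0 = model.diastolic_semi_axes
    bx, by = cx + model.bulbus_offset_xy[0], cy + model.bulbus_offset_xy[1]
    out = np.empty((n, 2), dtype=float)
    k = 0
    attempts = 0
    while k < n:
        attempts += 1
        if attempts > 10000 * max(n, 1):
            raise RuntimeError("could not place distractors outside the heart; frame too small")
        x = rng.uniform(margin, nx - 1 - margin)
        y = rng.uniform(margin, ny - 1 - margin)
        u = (x - cx) / (1.3 * a0)
        v = (y - cy) / (1.3 * b0)
        if u * u + v * v <= 1.0:
            continue
        if (x - bx) ** 2 + (y - by) ** 2 <= (model.bulbus_radius + 4.0) ** 2:
            continue
        if k and np.min(np.hypot(out[:k, 0] - x, out[:k, 1] - y)) < min_separation:
            continue
        out[k] = (x, y)
        k += 1
    return out


def _compartment_field(model: HeartModel, t: float, channel: str, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    """Noise-free fluorophore signal for one channel at time t (float field)."""
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}")
    cx, cy = model.center_xy
    a, b = heart_geometry_at(model, float(t))
    frac = model.bfp_area_fraction
    # BFP fractions above 1 model regrowth past control size: dilate the ellipse.
    if frac > 1.0:
        scale = math.sqrt(frac)
        a, b = a * scale, b * scale
        frac = 1.0
    u = (xx - cx) / a
    v = (yy - cy) / b
    inside = u * u + v * v <= 1.0
    out = np.zeros(xx.shape, dtype=float)
    if channel == "BFP":
        if model.recombined:
            d = chord_offset_for_area_fraction(1.0 - frac)
            region = inside & (u < d)
        else:
            region = inside
        out[region] = model.intensities["bfp"]
        if model.bulbus_radius > 0 and model.intensities.get("bulbus", 0) > 0:
            bx = cx + model.bulbus_offset_xy[0]
            by = cy + model.bulbus_offset_xy[1]
            bulbus = (xx - bx) ** 2 + (yy - by) ** 2 <= model.bulbus_radius**2
            out[bulbus] = model.intensities["bulbus"]
    else:  # mCherry
        if model.recombined and model.fhf_area_fraction > 0:
            d = chord_offset_for_area_fraction(model.fhf_area_fraction)
            sector = inside & (u >= d)
            if model.mcherry_survival >= 1.0:
                region = sector
            elif model.mcherry_survival <= 0.0:
                region = np.zeros_like(sector)
            else:
                # Surviving cells: a compact disc centred at the sector
                # centroid, area = survival * sector area.
                r_patch = math.sqrt(model.mcherry_survival * model.fhf_area_fraction * a * b)
                px = cx + _segment_centroid(d) * a
                py = cy
                region = sector & ((xx - px) ** 2 + (yy - py) ** 2 <= r_patch**2)
            out[region] = model.intensities["mcherry"]
    return out


def _distractor_field(
    positions: np.ndarray | None,
    noise: NoiseParams,
    yy: np.ndarray,
    xx: np.ndarray,
) -> np.ndarray:
    out = np.zeros(xx.shape, dtype=float)
    if positions is None or len(positions) == 0:
        return out
    s2 = 2.0 * noise.distractor_sigma_px**2
    for x, y in positions:
        out += noise.distractor_intensity * np.exp(-(((xx - x) ** 2 + (yy - y) ** 2) / s2))
    return out


def render_frame(
    model: HeartModel,
    t: float,
    channel: str,
    frame_shape: tuple[int, int] = (128, 128),
    noise: NoiseParams | None = None,
    rng: np.random.Generator | None = None,
    distractor_positions: np.ndarray | None = None,
) -> np.ndarray:
    """Render one 16-bit fluorescence frame at time ``t`` seconds.

    Distractor positions may be supplied to keep nuisance structures static
    across frames (the realistic case); if omitted and ``noise.n_distractors``
    is positive, fresh positions are drawn from ``rng``.
    """
    ny, nx = frame_shape
    if ny <= 0 or nx <= 0:
        raise ValueError("frame dimensions must be positive")
    noise = noise or NoiseParams()
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    field_ = _compartment_field(model, t, channel, yy, xx)
    if distractor_positions is None and noise.n_distractors > 0:
        if rng is None:
            raise ValueError("rng required to draw distractor positions")
        distractor_positions = draw_distractor_positions(model, frame_shape, noise.n_distractors, rng)
    field_ += _distractor_field(distractor_positions, noise, yy, xx)
    field_ += noise.background_level
    if noise.gaussian_sd > 0:
        if rng is None:
            raise ValueError("rng required for Gaussian noise")
        field_ += noise.gaussian_sd * rng.standard_normal(field_.shape)
    return np.clip(field_, 0, np.iinfo(np.uint16).max).astype(np.uint16)


def render_video(
    model: HeartModel,
    times: Sequence[float],
    channel: str,
    frame_shape: tuple[int, int] = (128, 128),
    noise: NoiseParams | None = None,
    rng: np.random.Generator | None = None,
    distractor_positions: np.ndarray | None = None,
) -> np.ndarray:
    """Render a T x Y x X uint16 stack at the given frame times (seconds)."""
    ny, nx = frame_shape
    if ny <= 0 or nx <= 0:
        raise ValueError("frame dimensions must be positive")
    noise = noise or NoiseParams()
    if distractor_positions is None and noise.n_distractors > 0:
        if rng is None:
            raise ValueError("rng required to draw distractor positions")
        distractor_positions = draw_distractor_positions(model, frame_shape, noise.n_distractors, rng)
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    dfield = _distractor_field(distractor_positions, noise, yy, xx) + noise.background_level
    frames = np.empty((len(times), ny, nx), dtype=np.uint16)
    vmax = np.iinfo(np.uint16).max
    for i, t in enumerate(times):
        f = _compartment_field(model, t, channel, yy, xx) + dfield
        if noise.gaussian_sd > 0:
            if rng is None:
                raise ValueError("rng required for Gaussian noise")
            f = f + noise.gaussian_sd * rng.standard_normal(f.shape)
        frames[i] = np.clip(f, 0, vmax).astype(np.uint16)
    return frames
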