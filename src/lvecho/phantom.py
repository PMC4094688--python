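"""Synthetic apical two-chamber contrast-echocardiography phantoms.

The generator emulates the statistical structure of left-ventricular
opacification imaging after a microbubble contrast bolus:

* a bright blood pool (truncated-ellipse cavity) inside a darker myocardial
  wall, with an equally opacified atrium beyond the atrioventricular (AV)
  plane — so intensity alone cannot separate ventricle from atrium;
* a wash-in → plateau → exponential wash-out intensity time course whose
  plateau duration and peak level depend on the injected dose;
* dose-dependent inhomogeneity: a linear axial gain ramp (attenuation with
  depth) plus elliptical low-intensity dropouts on the cavity border
  (swirling/shadowing at low doses);
* fully-developed-speckle surrogate: i.i.d. multiplicative gamma noise with
  shape ``speckle_looks`` (variance 1/looks).

Alongside image sequences the module simulates the two tabular inputs of the
downstream statistics: observer segment-score tables and per-minute
physiological logs (SaO2, heart rate, mean arterial pressure).

All randomness flows through one seeded :class:`numpy.random.Generator`; the
same seed reproduces a sequence bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import ellipse_mask, half_plane_side, pixel_grid
from .scoring import REGION_OF_SEGMENT, SegmentScoreTable
from .stats import PHYSIO_VARIABLES, PhysioLog

#: dose label → (peak plateau intensity, inhomogeneity, plateau duration s).
#: The ordering emulates the in-vivo finding that the 5 ml polymer-shelled
#: dose behaves like the SonoVue reference while lower doses are dimmer,
#: less homogeneous and fade within the first 20-s interval.
DOSE_DEFAULTS = {
    "1.5": (0.45, 0.60, 15.0),
    "3": (0.60, 0.45, 16.0),
    "5": (0.75, 0.20, 30.0),
    "sonovue-1.5": (0.80, 0.15, 30.0),
}

#: Segment-score probabilities per dose and region (fractions of n=48 counts
#: from the in-vivo score distribution table); generator defaults.
IN_VIVO_SCORE_PROBS = {
    "sonovue-1.5": {
        "apical": (1 / 48, 33 / 48, 14 / 48),
        "mid": (0.0, 0.0, 1.0),
        "base": (0.0, 6 / 48, 42 / 48),
    },
    "1.5": {
        "apical": (1 / 48, 26 / 48, 21 / 48),
        "mid": (0.0, 3 / 48, 45 / 48),
        "base": (3 / 48, 20 / 48, 25 / 48),
    },
    "3": {
        "apical": (3 / 48, 27 / 48, 18 / 48),
        "mid": (3 / 48, 4 / 48, 41 / 48),
        "base": (6 / 48, 17 / 48, 25 / 48),
    },
    "5": {
        "apical": (2 / 48, 22 / 48, 24 / 48),
        "mid": (0.0, 4 / 48, 44 / 48),
        "base": (0.0, 21 / 48, 27 / 48),
    },
}

#: physiological baselines (mean, between-animal sd): SaO2 %, HR bpm, MAP mmHg
PHYSIO_BASELINES = {"sao2": (98.0, 1.5), "hr": (93.0, 14.0), "map": (78.0, 13.0)}
#: minute-to-minute within-animal noise sd
PHYSIO_WITHIN_SD = {"sao2": 0.3, "hr": 2.0, "map": 2.5}


class ConfigurationError(ValueError):
    """Phantom geometry does not fit the requested raster."""


@dataclass(frozen=True)
class CavityShape:
    """Truncated-ellipse cavity: apex at the top (transducer side), base below."""

    apex_row: float
    apex_col: float
    long_axis_px: float
    basal_width_px: float

    @property
    def av_row(self) -> float:
        return self.apex_row + self.long_axis_px

    def ellipse(self) -> tuple[tuple[float, float], float, float]:
        """(center, semi_row, semi_col) of the generating ellipse.

        The vertical semi-axis is 0.62 of the long axis so the AV plane
        truncates the ellipse below its equator, giving a rounded apex and a
        wide base.
        """
        b = 0.62 * self.long_axis_px
        frac = (self.long_axis_px - b) / b
        a = (self.basal_width_px / 2.0) / math.sqrt(1.0 - frac**2)
        return (self.apex_row + b, self.apex_col), b, a


def default_cavity(image_height: int, image_width: int) -> CavityShape:
    return CavityShape(
        apex_row=round(0.06 * image_height),
        apex_col=image_width / 2.0,
        long_axis_px=round(0.68 * image_height),
        basal_width_px=round(0.47 * image_width),
    )


@dataclass(frozen=True)
class PhantomConfig:
    image_height: int = 256
    image_width: int = 256
    cavity: CavityShape | None = None
    av_plane: tuple[tuple[float, float], tuple[float, float]] | None = None
    dose_label: str = "5"
    peak_intensity: float = 0.75
    inhomogeneity: float = 0.20
    speckle_looks: int | None = 36  # None → noiseless limit
    arrival_time: float = 5.0
    washin_time: float = 2.0
    plateau_duration: float = 30.0
    washout_tau: float = 4.0
    frame_interval: float = 1.0
    duration: float | None = None
    myocardium_level: float = 0.15
    background_level: float = 0.05
    wall_thickness_frac: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cavity is None:
            object.__setattr__(
                self, "cavity", default_cavity(self.image_height, self.image_width)
            )
        if self.av_plane is None:
            cav = self.cavity
            half = cav.basal_width_px / 2.0
            object.__setattr__(
                self,
                "av_plane",
                (
                    (cav.av_row, cav.apex_col - half),
                    (cav.av_row, cav.apex_col + half),
                ),
            )
        if not (0.0 < self.peak_intensity <= 1.0):
            raise ValueError("peak_intensity must be in (0, 1]")
        if self.inhomogeneity < 0:
            raise ValueError("inhomogeneity must be >= 0")
        if self.plateau_duration <= 0:
            raise ValueError("plateau_duration must be > 0")
        if self.speckle_looks is not None and not (
            math.isinf(self.speckle_looks) or self.speckle_looks >= 1
        ):
            raise ValueError("speckle_looks must be a positive integer (or None)")
        self._check_fits()

    def _check_fits(self) -> None:
        cav = self.cavity
        (center, b, a) = cav.ellipse()
        wall = self.wall_thickness_frac * self.image_height
        atrium_bottom = cav.av_row + 0.30 * cav.long_axis_px
        if (
            cav.apex_row - wall < 0
            or center[1] - a - wall < 0
            or center[1] + a + wall > self.image_width - 1
            or atrium_bottom + 1 > self.image_height - 1
        ):
            raise ConfigurationError("raster too small to contain the cavity phantom")

    @property
    def total_duration(self) -> float:
        if self.duration is not None:
            return self.duration
        return (
            self.arrival_time
            + self.washin_time
            + self.plateau_duration
            + 5.0 * self.washout_tau
        )

    @classmethod
    def for_dose(cls, dose_label: str, rng_seed: int = 0, **overrides) -> "PhantomConfig":
        """Configuration with the default parameter triple for one dose label."""
        if dose_label not in DOSE_DEFAULTS:
            raise ValueError(
                f"unknown dose {dose_label!r}; expected one of {sorted(DOSE_DEFAULTS)}"
            )
        peak, inhom, plateau = DOSE_DEFAULTS[dose_label]
        params = dict(
            dose_label=dose_label,
            peak_intensity=peak,
            inhomogeneity=inhom,
            plateau_duration=plateau,
            rng_seed=rng_seed,
        )
        params.update(overrides)
        return cls(**params)

    def with_(self, **overrides) -> "PhantomConfig":
        return replace(self, **overrides)


@dataclass
class FrameSequence:
    """Timestamped grayscale frames with ground truth.

    The truth mask is identical across frames: acquisition at a fixed cardiac
    phase (end-systole) is emulated as a fixed geometry.
    """

    timestamps: np.ndarray
    frames: list[np.ndarray]
    truth_masks: list[np.ndarray]
    av_plane: tuple[tuple[float, float], tuple[float, float]]
    meta: PhantomConfig

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.truth_masks):
            raise ValueError("frames and truth_masks must have equal length")
        if len(self.frames) != len(self.timestamps):
            raise ValueError("timestamps and frames must have equal length")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        shapes = {f.shape for f in self.frames} | {m.shape for m in self.truth_masks}
        if len(shapes) != 1:
            raise ValueError("all rasters must share one shape")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def truth_mask(self) -> np.ndarray:
        return self.truth_masks[0]


def intensity_timecourse(config: PhantomConfig, t: float) -> float:
    """Normalized cavity enhancement f(t) ∈ [0, 1]: ramp, plateau, decay."""
    t0 = config.arrival_time
    if t < t0:
        return 0.0
    if t < t0 + config.washin_time:
        return (t - t0) / config.washin_time
    t_end = t0 + config.washin_time + config.plateau_duration
    if t <= t_end:
        return 1.0
    return math.exp(-(t - t_end) / config.washout_tau)


def _region_masks(config: PhantomConfig):
    shape = (config.image_height, config.image_width)
    center, b, a = config.cavity.ellipse()
    ellipse = ellipse_mask(shape, center, b, a)
    ventric_ref = (config.cavity.apex_row + 1.0, config.cavity.apex_col)
    atrial_side = half_plane_side(shape, *config.av_plane, reference=ventric_ref)
    cavity = ellipse & ~atrial_side
    if not cavity.any():
        raise ConfigurationError("cavity mask is empty")
    cav = config.cavity
    atrium = (
        ellipse_mask(
            shape,
            (cav.av_row + 0.10 * cav.long_axis_px, cav.apex_col),
            0.20 * cav.long_axis_px,
            0.45 * cav.basal_width_px,
        )
        & atrial_side
    )
    pool = cavity | atrium
    wall_px = config.wall_thickness_frac * config.image_height
    dist = ndimage.distance_transform_edt(~pool)
    wall = (dist > 0) & (dist <= wall_px)
    return cavity, atrium, wall, atrial_side


def _inhomogeneity_profile(config: PhantomConfig, cavity: np.ndarray, rng) -> np.ndarray:
    """Axial gain ramp times border dropouts; ≡1 when inhomogeneity = 0.

    Three dropout candidates are always drawn (so random state consumption is
    independent of the inhomogeneity level) and the first
    ``min(3, floor(2.5·inhomogeneity + 0.5))`` are applied.
    """
    shape = cavity.shape
    rows, cols = pixel_grid(shape)
    cav = config.cavity
    inhom = config.inhomogeneity
    gain = np.clip(
        1.0 - 0.25 * inhom * (rows - cav.apex_row) / cav.long_axis_px, 0.2, None
    )
    profile = gain

    boundary = cavity & ~ndimage.binary_erosion(cavity)
    br, bc = np.nonzero(boundary)
    n_drop = min(3, int(math.floor(2.5 * inhom + 0.5)))
    amp = min(0.85, 0.8 * inhom)
    base_r = 0.12 * config.image_height
    for k in range(3):
        idx = rng.integers(len(br))
        semi = base_r * rng.uniform(0.7, 1.3, size=2)
        if k >= n_drop or amp <= 0:
            continue
        q = ((rows - br[idx]) / semi[0]) ** 2 + ((cols - bc[idx]) / semi[1]) ** 2
        profile = profile * (1.0 - amp * np.exp(-q))
    return profile


def generate_sequence(config: PhantomConfig) -> FrameSequence:
    """Render the frame sequence for one injection."""
    rng = np.random.default_rng(config.rng_seed)
    shape = (config.image_height, config.image_width)
    cavity, atrium, wall, _ = _region_masks(config)
    profile = _inhomogeneity_profile(config, cavity, rng)
    center, _, _ = config.cavity.ellipse()
    rows, _ = pixel_grid(shape)
    cav = config.cavity
    atrium_gain = np.clip(
        1.0 - 0.25 * config.inhomogeneity * (rows - cav.apex_row) / cav.long_axis_px,
        0.2,
        None,
    )

    timestamps = np.arange(0.0, config.total_duration + 1e-9, config.frame_interval)
    looks = config.speckle_looks
    noiseless = looks is None or math.isinf(looks)
    frames = []
    for t in timestamps:
        f = intensity_timecourse(config, float(t))
        img = np.full(shape, config.background_level)
        img[wall] = config.myocardium_level
        img[cavity] = np.maximum(f * config.peak_intensity * profile[cavity], 0.02)
        img[atrium] = np.maximum(f * config.peak_intensity * atrium_gain[atrium], 0.02)
        if not noiseless:
            img = img * rng.gamma(shape=looks, scale=1.0 / looks, size=shape)
        frames.append(img)

    return FrameSequence(
        timestamps=timestamps,
        frames=frames,
        truth_masks=[cavity] * len(frames),
        av_plane=config.av_plane,
        meta=config,
    )


# ---------------------------------------------------------------------------
# Observer score tables


def _normalize_dose_effects(dose_effects) -> dict:
    norm = {}
    for dose, probs in dose_effects.items():
        if isinstance(probs, dict):
            per_region = {r: tuple(map(float, p)) for r, p in probs.items()}
        else:
            p = tuple(map(float, probs))
            per_region = {r: p for r in ("apical", "mid", "base")}
        for region, p in per_region.items():
            if len(p) != 3 or any(x < 0 for x in p):
                raise ValueError(f"invalid probabilities for ({dose}, {region}): {p}")
            if abs(sum(p) - 1.0) > 1e-8:
                raise ValueError(
                    f"probabilities for ({dose}, {region}) sum to {sum(p)}, not 1"
                )
        norm[dose] = per_region
    return norm


def simulate_score_table(
    n_animals: int,
    n_observers: int,
    dose_effects: dict | None = None,
    rng=None,
) -> SegmentScoreTable:
    """Draw a full-design segment-score table from per-(dose, region)
    categorical score distributions.

    One record per (animal, observer, dose, segment); scores drawn
    independently. ``dose_effects`` maps dose → (p0, p1, p2) or
    dose → {region: (p0, p1, p2)}; defaults to :data:`IN_VIVO_SCORE_PROBS`.
    """
    if dose_effects is None:
        dose_effects = IN_VIVO_SCORE_PROBS
    probs = _normalize_dose_effects(dose_effects)
    rng = np.random.default_rng(rng)
    records = []
    for dose in probs:
        for animal in range(1, n_animals + 1):
            for observer in range(1, n_observers + 1):
                for segment, region in REGION_OF_SEGMENT.items():
                    score = int(rng.choice(3, p=probs[dose][region]))
                    records.append(
                        {
                            "animal": animal,
                            "observer": observer,
                            "dose": dose,
                            "segment": segment,
                            "region": region,
                            "score": score,
                        }
                    )
    return SegmentScoreTable(pd.DataFrame(records))


# ---------------------------------------------------------------------------
# Physiological logs


def simulate_physio_log(
    n_animals: int,
    injections,
    effects: dict | None = None,
    duration_min: int | None = None,
    baselines: dict | None = None,
    between_sd: dict | None = None,
    within_sd: dict | None = None,
    effect_duration_min: int = 3,
    rng=None,
) -> PhysioLog:
    """Per-minute SaO2/HR/MAP series for ``n_animals`` animals.

    ``injections`` is a list of (dose_label, t_min). ``effects`` maps dose →
    {variable: relative shift} (e.g. −0.04 for a 4% drop) applied for
    ``effect_duration_min`` minutes after each injection. Baseline means and
    between-/within-animal noise default to the porcine anesthesia values
    (SaO2 98%, HR 93 bpm, MAP 78 mmHg).
    """
    injections = [(d, int(t)) for d, t in injections]
    if duration_min is None:
        duration_min = (max(t for _, t in injections) if injections else 0) + 5
    for _, t in injections:
        if not (0 <= t <= duration_min):
            raise ValueError(f"injection at minute {t} outside log duration")
    effects = effects or {}
    if effects and all(isinstance(v, (int, float)) for v in effects.values()):
        # flat {variable: shift} → same effect for every injection
        effects = {dose: dict(effects) for dose, _ in injections}
    baselines = baselines or {v: PHYSIO_BASELINES[v][0] for v in PHYSIO_VARIABLES}
    between_sd = between_sd or {v: PHYSIO_BASELINES[v][1] for v in PHYSIO_VARIABLES}
    within_sd = within_sd or dict(PHYSIO_WITHIN_SD)
    rng = np.random.default_rng(rng)

    minutes = np.arange(0, duration_min + 1)
    rows = []
    for animal in range(1, n_animals + 1):
        level = {
            v: baselines[v] + between_sd[v] * rng.standard_normal()
            for v in PHYSIO_VARIABLES
        }
        for t in minutes:
            row = {"animal": animal, "t_min": int(t)}
            for v in PHYSIO_VARIABLES:
                shift = 0.0
                for dose, t_inj in injections:
                    if t_inj < t <= t_inj + effect_duration_min:
                        shift += effects.get(dose, {}).get(v, 0.0)
                value = level[v] * (1.0 + shift) + within_sd[v] * rng.standard_normal()
                if v == "sao2":
                    value = min(value, 100.0)
                row[v] = value
            rows.append(row)
    return PhysioLog(samples=pd.DataFrame(rows), injections=injections)
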