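"""Synthetic murine bone Raman study generator.

Emulates the acquisition design of the animal study: per mouse, one femur
measured at 7 sites x 5 replicates (35 spectra) and one vertebral column at
12 vertebrae x 5 replicates (60 spectra), at weeks {0, 2, 4, 5} after tumor
inoculation.  Each raw spectrum is

    measured = (sum of pseudo-Voigt bands + fluorescence polynomial
                + probe background) * white-light response + noise
               [+ cosmic-ray spikes], clipped at 0

The week- and region-dependent composition is injected through a class-effect
table of amplitude/width multipliers whose *directions* encode the osteolytic
progression: mineral-to-matrix rising through the weeks in femur metaphyses,
carbonate substitution up at week 2 then down, carbonate-to-matrix elevated
at all tumor weeks, crystallinity dipping at week 2 in femur (unchanged in
spine) then rising, diaphysis attenuated relative to metaphysis, and the
lumbar-sacral (L5-S2) vertebrae showing the largest spine deviations.
Effect magnitudes are free parameters of the generator, not measured values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    BONES,
    FEMUR_SITES,
    VERTEBRAE,
    WEEKS,
    InstrumentProfile,
    SpectrumMeta,
    SpectrumSet,
    ValidationError,
)

__all__ = [
    "PeakSpec",
    "ClassEffect",
    "SimulationConfig",
    "default_config",
    "default_class_effects",
    "pseudo_voigt",
    "make_instrument_profile",
    "simulate_spectrum",
    "simulate_study",
    "expected_metrics",
    "ground_truth_table",
]

METRIC_NAMES = ("mineral_to_matrix", "phos_to_carb", "carb_to_matrix", "crystallinity")


# ---------------------------------------------------------------------------
# Peak model
# ---------------------------------------------------------------------------


def pseudo_voigt(x: np.ndarray, height: float, center: float, fwhm: float,
                 gauss_fraction: float) -> np.ndarray:
    """Pseudo-Voigt profile: linear mix of a Gaussian and a Lorentzian that
    share the same FWHM, scaled to the given apex height.

    With this parametrization the profile's full width at half maximum equals
    ``fwhm`` exactly for any mixing fraction.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    d = x - center
    g = np.exp(-4.0 * np.log(2.0) * (d / fwhm) ** 2)
    hw = fwhm / 2.0
    lor = hw**2 / (hw**2 + d**2)
    return height * (gauss_fraction * g + (1.0 - gauss_fraction) * lor)


@dataclass(frozen=True)
class PeakSpec:
    """One simulated Raman band."""

    name: str
    center: float  # cm^-1
    amplitude_mean: float  # apex height, arbitrary detector units
    fwhm_mean: float  # cm^-1
    gauss_fraction: float = 0.98
    center_jitter_sd: float = 1.0  # cm^-1
    amplitude_cv: float = 0.02
    fwhm_sd: float = 0.5  # cm^-1

    def __post_init__(self) -> None:
        if self.fwhm_mean <= 0 or self.amplitude_mean < 0:
            raise ValidationError(f"band {self.name}: invalid amplitude/width")
        if not 0.0 <= self.gauss_fraction <= 1.0:
            raise ValidationError(f"band {self.name}: gauss_fraction outside [0,1]")


@dataclass(frozen=True)
class ClassEffect:
    """Multiplicative composition effect for one (week, bone, region) class.

    All multipliers are relative to the week-0 baseline (1.0 = no change);
    ``phosphate_fwhm`` scales the phosphate band width, i.e. the inverse
    of crystallinity.
    """

    week: int
    bone: str
    region: str
    phosphate: float = 1.0
    carbonate: float = 1.0
    amide_i: float = 1.0
    phosphate_fwhm: float = 1.0

    def __post_init__(self) -> None:
        for name in ("phosphate", "carbonate", "amide_i", "phosphate_fwhm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"class effect multiplier {name} must be > 0")
        if self.week == 0 and any(
            getattr(self, n) != 1.0
            for n in ("phosphate", "carbonate", "amide_i", "phosphate_fwhm")
        ):
            raise ValidationError("week-0 multipliers must all equal 1.0")

    def amplitude_multiplier(self, band: str) -> float:
        return {
            "phosphate_v1": self.phosphate,
            "carbonate": self.carbonate,
            "amide_I": self.amide_i,
        }.get(band, 1.0)


# Baseline deviation vectors; per-region multipliers are 1 + scale * (base - 1)
# so that attenuation ratios (e.g. diaphysis at 0.2x metaphysis) hold exactly.
_FEMUR_BASE = {
    2: dict(phosphate=1.05, carbonate=1.18, amide_i=0.98, phosphate_fwhm=1.08),
    4: dict(phosphate=1.12, carbonate=1.10, amide_i=0.90, phosphate_fwhm=0.95),
    5: dict(phosphate=1.20, carbonate=1.08, amide_i=0.85, phosphate_fwhm=0.92),
}
_SPINE_BASE = {
    2: dict(phosphate=1.03, carbonate=1.10, amide_i=0.99, phosphate_fwhm=1.00),
    4: dict(phosphate=1.08, carbonate=1.06, amide_i=0.93, phosphate_fwhm=0.96),
    5: dict(phosphate=1.14, carbonate=1.05, amide_i=0.90, phosphate_fwhm=0.94),
}
_FEMUR_REGION_SCALE = {"distal_metaphysis": 1.0, "diaphysis": 0.2, "proximal_metaphysis": 1.0}
_SPINE_REGION_SCALE = {"L1_L4": 0.6, "L5_S2": 1.0, "S3_C2": 0.6}


def default_class_effects() -> dict[tuple[int, str, str], ClassEffect]:
    """Default effect table keyed by (week, bone, region)."""
    table: dict[tuple[int, str, str], ClassEffect] = {}
    for bone, base_table, scales in (
        ("femur", _FEMUR_BASE, _FEMUR_REGION_SCALE),
        ("spine", _SPINE_BASE, _SPINE_REGION_SCALE),
    ):
        for region, scale in scales.items():
            table[(0, bone, region)] = ClassEffect(0, bone, region)
            for week, base in base_table.items():
                table[(week, bone, region)] = ClassEffect(
                    week,
                    bone,
                    region,
                    **{k: 1.0 + scale * (v - 1.0) for k, v in base.items()},
                )
    return table


def default_peaks() -> tuple[PeakSpec, ...]:
    """The six quantified bands of bone tissue in the fingerprint region."""
    return (
        PeakSpec("phosphate_v1", 958.0, 100.0, 15.0, fwhm_sd=0.4),
        PeakSpec("phenylalanine", 1004.0, 16.0, 10.0),
        PeakSpec("carbonate", 1070.0, 40.0, 16.0),
        PeakSpec("amide_III", 1250.0, 22.0, 30.0, fwhm_sd=1.0),
        PeakSpec("CH2", 1450.0, 38.0, 28.0, fwhm_sd=1.0),
        PeakSpec("amide_I", 1660.0, 42.0, 38.0, fwhm_sd=1.0),
    )


@dataclass
class SimulationConfig:
    """Full description of a simulated study.

    Fluorescence baseline coefficients are sampled uniformly per spectrum
    from ``baseline_coef_ranges`` (polynomial in the axis rescaled to [0, 1],
    lowest order first) and shifted up if needed so the baseline stays
    >= ``baseline_floor``.
    """

    axis_start: float = 600.0
    axis_stop: float = 1800.0
    axis_step: float = 2.0
    peaks: tuple[PeakSpec, ...] = field(default_factory=default_peaks)
    class_effects: dict = field(default_factory=default_class_effects)
    baseline_order: int = 5
    baseline_coef_ranges: tuple = (
        (35.0, 55.0), (-40.0, -15.0), (5.0, 20.0), (-10.0, 10.0), (-6.0, 6.0), (-4.0, 4.0),
    )
    baseline_floor: float = 3.0
    probe_background_scale: float = 8.0
    response_center: float = 1150.0
    response_width: float = 500.0
    noise_sd0: float = 0.15
    shot_scale: float = 0.06
    cosmic_ray_rate: float = 0.3  # expected spikes per spectrum
    cosmic_ray_amplitude: tuple[float, float] = (5.0, 50.0)  # x local intensity
    cosmic_ray_width: tuple[int, int] = (1, 2)
    subject_cv: float = 0.005  # per-subject, per-band log-normal amplitude CV
    subjects_per_week: int = 3
    seed: int = 0
    ideal_profile: bool = False  # response = 1, background = 0

    def __post_init__(self) -> None:
        for name in ("probe_background_scale", "noise_sd0", "shot_scale", "subject_cv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.cosmic_ray_rate:
            raise ValidationError("cosmic_ray_rate must be >= 0")
        if self.subjects_per_week < 1:
            raise ValidationError("subjects_per_week must be >= 1")
        if len(self.baseline_coef_ranges) != self.baseline_order + 1:
            raise ValidationError("need baseline_order + 1 coefficient ranges")
        self.peaks = tuple(
            p if isinstance(p, PeakSpec) else PeakSpec(**p) for p in self.peaks
        )
        if isinstance(self.class_effects, (list, tuple)):
            effs = [e if isinstance(e, ClassEffect) else ClassEffect(**e) for e in self.class_effects]
            self.class_effects = {(e.week, e.bone, e.region): e for e in effs}

    @property
    def axis(self) -> np.ndarray:
        return np.arange(self.axis_start, self.axis_stop + 1e-9, self.axis_step)

    def peak(self, name: str) -> PeakSpec:
        for p in self.peaks:
            if p.name == name:
                return p
        raise KeyError(name)

    def effect(self, week: int, bone: str, region: str) -> ClassEffect:
        try:
            return self.class_effects[(week, bone, region)]
        except KeyError as exc:
            raise ValidationError(f"no class effect for ({week}, {bone}, {region})") from exc

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["peaks"] = [dataclasses.asdict(p) for p in self.peaks]
        d["class_effects"] = [dataclasses.asdict(e) for e in self.class_effects.values()]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "baseline_coef_ranges" in d:
            d["baseline_coef_ranges"] = tuple(tuple(r) for r in d["baseline_coef_ranges"])
        for k in ("cosmic_ray_amplitude", "cosmic_ray_width"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


# ---------------------------------------------------------------------------
# Instrument profile
# ---------------------------------------------------------------------------


def make_instrument_profile(config: SimulationConfig) -> InstrumentProfile:
    """Instrument profile shared by every spectrum of a study.

    The white-light response is a broad bell in [0.5, 1.0] across the axis;
    the substrate background is stored *as measured*, i.e. a smooth low-order
    intrinsic curve multiplied by the response, which is what subtracting a
    recorded substrate spectrum removes.
    """
    axis = config.axis
    if config.ideal_profile:
        return InstrumentProfile(axis, np.zeros_like(axis), np.ones_like(axis))
    response = 0.5 + 0.5 * np.exp(-(((axis - config.response_center) / config.response_width) ** 2))
    intrinsic = _intrinsic_background(config)
    return InstrumentProfile(axis, intrinsic * response, response)


def _intrinsic_background(config: SimulationConfig) -> np.ndarray:
    axis = config.axis
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    if config.ideal_profile:
        return np.zeros_like(axis)
    return config.probe_background_scale * (0.5 + 0.5 * (1.0 - t) ** 2)


# ---------------------------------------------------------------------------
# Spectrum synthesis
# ---------------------------------------------------------------------------


def _check_axis_covers_bands(config: SimulationConfig) -> None:
    axis = config.axis
    for p in config.peaks:
        if not (axis[0] <= p.center <= axis[-1]):
            raise ValidationError(f"axis does not cover configured band {p.name} at {p.center}")


def _fluorescence_baseline(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    axis = config.axis
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    coefs = np.array([rng.uniform(lo, hi) for lo, hi in config.baseline_coef_ranges])
    base = np.polynomial.polynomial.polyval(t, coefs)
    lift = config.baseline_floor - base.min()
    if lift > 0:  # shift the constant term; still a polynomial of the same order
        base = base + lift
    return base


def _peak_signal(
    config: SimulationConfig,
    effect: ClassEffect,
    rng: np.random.Generator,
    subject_factors: dict[str, float] | None = None,
    *,
    jitter: bool = True,
) -> np.ndarray:
    axis = config.axis
    signal = np.zeros_like(axis)
    for p in config.peaks:
        amp = p.amplitude_mean * effect.amplitude_multiplier(p.name)
        if subject_factors is not None:
            amp *= subject_factors.get(p.name, 1.0)
        fwhm = p.fwhm_mean * (effect.phosphate_fwhm if p.name == "phosphate_v1" else 1.0)
        center = p.center
        if jitter:
            if p.amplitude_cv > 0:
                sigma = np.sqrt(np.log1p(p.amplitude_cv**2))
                amp *= rng.lognormal(-0.5 * sigma**2, sigma)
            center = center + rng.normal(0.0, p.center_jitter_sd)
            fwhm = max(1.0, fwhm + rng.normal(0.0, p.fwhm_sd))
        signal += pseudo_voigt(axis, amp, center, fwhm, p.gauss_fraction)
    return signal


def _subject_factors(config: SimulationConfig, rng: np.random.Generator) -> dict[str, float]:
    if config.subject_cv <= 0:
        return {p.name: 1.0 for p in config.peaks}
    sigma = np.sqrt(np.log1p(config.subject_cv**2))
    return {p.name: rng.lognormal(-0.5 * sigma**2, sigma) for p in config.peaks}


def simulate_spectrum(
    config: SimulationConfig,
    meta: SpectrumMeta,
    rng: np.random.Generator,
    subject_factors: dict[str, float] | None = None,
    *,
    return_clean: bool = False,
):
    """Simulate one raw spectrum for the given metadata.

    Returns the intensity vector (and, when ``return_clean`` is set, the
    noise-free peak-only signal produced by the same random draws, which the
    preprocessing chain should recover up to normalization).
    """
    _check_axis_covers_bands(config)
    effect = config.effect(meta.week, meta.bone, meta.region)
    peaks = _peak_signal(config, effect, rng, subject_factors)
    baseline = _fluorescence_baseline(config, rng)
    profile_bg = _intrinsic_background(config)
    if config.ideal_profile:
        response = np.ones_like(config.axis)
    else:
        axis = config.axis
        response = 0.5 + 0.5 * np.exp(
            -(((axis - config.response_center) / config.response_width) ** 2)
        )
    clean = (peaks + baseline + profile_bg) * response
    sd = config.noise_sd0 + config.shot_scale * np.sqrt(np.clip(clean, 0.0, None))
    noisy = clean + rng.normal(0.0, 1.0, clean.size) * sd
    n_rays = rng.poisson(config.cosmic_ray_rate)
    for _ in range(n_rays):
        pos = rng.integers(0, clean.size)
        width = rng.integers(config.cosmic_ray_width[0], config.cosmic_ray_width[1] + 1)
        amp = rng.uniform(*config.cosmic_ray_amplitude) * max(clean[pos], 1.0)
        noisy[pos : pos + width] += amp
    noisy = np.clip(noisy, 0.0, None)
    if return_clean:
        return noisy, peaks
    return noisy


def simulate_study(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    *,
    return_clean: bool = False,
):
    """Simulate a full study: every subject contributes one femur (7 sites x
    5 replicates = 35 spectra) and one spine (12 vertebrae x 5 replicates =
    60 spectra) at its harvest week.

    Returns ``(SpectrumSet, InstrumentProfile, ground_truth)`` where the
    ground truth is the per-(week, bone, region) table of noise-free metrics;
    with ``return_clean`` a fourth item holds the noise-free peak-only
    signal matrix aligned with the returned spectra.
    """
    config = config or default_config()
    if seed is None:
        seed = config.seed
    _check_axis_covers_bands(config)
    rng = np.random.default_rng(seed)
    profile = make_instrument_profile(config)

    rows, specs, cleans = [], [], []
    for week in WEEKS:
        for k in range(1, config.subjects_per_week + 1):
            subject = f"m{week:02d}{k:02d}"
            factors = _subject_factors(config, rng)
            for bone in BONES:
                sites = FEMUR_SITES if bone == "femur" else VERTEBRAE
                for site in sites:
                    for rep in range(1, 6):
                        sid = f"{'F' if bone == 'femur' else 'S'}_w{week}_{subject}_{site}_r{rep}"
                        meta = SpectrumMeta(
                            spectrum_id=sid,
                            subject_id=subject,
                            week=week,
                            bone=bone,
                            site=site,
                            replicate=rep,
                            stage="raw",
                        )
                        noisy, clean = simulate_spectrum(
                            config, meta, rng, factors, return_clean=True
                        )
                        rows.append(
                            dict(
                                spectrum_id=sid,
                                subject_id=subject,
                                week=week,
                                bone=bone,
                                site=site,
                                replicate=rep,
                                stage="raw",
                            )
                        )
                        specs.append(noisy)
                        cleans.append(clean)
    sset = SpectrumSet(
        axis=config.axis, intensities=np.array(specs), meta=pd.DataFrame(rows)
    )
    truth = ground_truth_table(config)
    if return_clean:
        return sset, profile, truth, np.array(cleans)
    return sset, profile, truth


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


def expected_metrics(config: SimulationConfig, week: int, bone: str, region: str) -> dict:
    """Closed-form noise-free composition metrics for one class.

    Ratios are ratios of the configured (multiplier-adjusted) apex
    amplitudes; crystallinity is exactly 1 / configured phosphate FWHM.
    """
    eff = config.effect(week, bone, region)
    a_p = config.peak("phosphate_v1").amplitude_mean * eff.phosphate
    a_c = config.peak("carbonate").amplitude_mean * eff.carbonate
    a_a = config.peak("amide_I").amplitude_mean * eff.amide_i
    fwhm = config.peak("phosphate_v1").fwhm_mean * eff.phosphate_fwhm
    return dict(
        mineral_to_matrix=a_p / a_a,
        phos_to_carb=a_p / a_c,
        carb_to_matrix=a_c / a_a,
        crystallinity=1.0 / fwhm,
    )


def ground_truth_table(config: SimulationConfig) -> pd.DataFrame:
    """Noise-free metrics for every simulated (week, bone, region) class."""
    rows = []
    for (week, bone, region), _ in sorted(config.class_effects.items()):
        rows.append(
            dict(week=week, bone=bone, region=region, **expected_metrics(config, week, bone, region))
        )
    return pd.DataFrame(rows)
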