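"""Spectral correction chain for fiber-probe bone Raman spectra.

Five steps, applied in acquisition-correction order:

1. cosmic-ray removal (running-median despike with a robust z threshold),
2. subtraction of the recorded aluminum-substrate background,
3. division by the white-light (BaSO4 / tungsten-halogen) response,
4. automated fluorescence-baseline removal by iterative constrained
   ("modified") polynomial fitting,
5. normalization to the phosphate nu1 apex (~958 cm^-1).

The chain is also exposed as a scikit-learn style transformer,
:class:`RamanPreprocessor`, operating on (n_spectra, n_channels) matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .data_model import InstrumentProfile, SpectrumSet, ValidationError
from .bands import BandCatalog, default_catalog

__all__ = [
    "PreprocessParams",
    "BaselineFit",
    "SpikeReport",
    "remove_cosmic_rays",
    "subtract_substrate",
    "correct_white_light",
    "remove_fluorescence",
    "normalize_phosphate",
    "preprocess_pipeline",
    "RamanPreprocessor",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable settings of the correction chain.

    despike_window : odd running-median window in channels.
    despike_z : robust z-score threshold above which a channel is treated as
        a cosmic-ray spike.
    baseline_order : order of the constrained fluorescence polynomial.
    baseline_tol : convergence tolerance as a fraction of the input maximum.
    baseline_max_iter : iteration cap for the constrained fit.
    normalization_band : catalog band whose window apex is scaled to 1.
    """

    despike_window: int = 5
    despike_z: float = 8.0
    baseline_order: int = 5
    baseline_tol: float = 1e-6
    baseline_max_iter: int = 100
    normalization_band: str = "phosphate_v1"

    def __post_init__(self) -> None:
        if self.despike_window < 3 or self.despike_window % 2 == 0:
            raise ValidationError("despike_window must be odd and >= 3")
        if self.baseline_order < 1:
            raise ValidationError("baseline_order must be >= 1")
        if self.baseline_tol <= 0:
            raise ValidationError("baseline_tol must be > 0")


@dataclass
class BaselineFit:
    """Result of the iterative constrained polynomial baseline fit."""

    coefficients: np.ndarray  # polynomial in axis rescaled to [0, 1], low order first
    baseline: np.ndarray
    iterations: int
    converged: bool


@dataclass
class SpikeReport:
    """Channels replaced by the despiker (indices into the axis)."""

    channels: np.ndarray

    def __len__(self) -> int:
        return self.channels.size


# ---------------------------------------------------------------------------
# Single-spectrum steps
# ---------------------------------------------------------------------------


def remove_cosmic_rays(
    intensities: np.ndarray, params: PreprocessParams = PreprocessParams()
) -> tuple[np.ndarray, SpikeReport]:
    """Detect cosmic-ray spikes against the running median and interpolate
    across them.

    A channel is a spike when its positive excess over the running median
    exceeds ``despike_z`` times the robust (MAD-based) noise SD of the
    median residual AND that excess is isolated: at least 5x larger than
    the excess two channels away on both sides.  Cosmic rays are 1-2
    channel positive transients, so they tower over their surroundings,
    whereas the apex of a genuine Raman band rises smoothly — its median
    residual is comparable to its neighbors' — and is left untouched even
    where shot noise makes the global robust SD an underestimate.
    """
    y = np.asarray(intensities, dtype=float)
    if y.size < params.despike_window:
        raise ValidationError("spectrum shorter than the despike window")
    # pad with the global median so a ray on the first/last channels cannot
    # dominate its own edge-replicated window
    half = params.despike_window // 2
    padded = np.concatenate([np.full(half, np.median(y)), y, np.full(half, np.median(y))])
    med = median_filter(padded, size=params.despike_window, mode="nearest")[half:-half]
    resid = y - med
    mad = np.median(np.abs(resid - np.median(resid)))
    robust_sd = 1.4826 * mad
    if robust_sd <= 0:
        robust_sd = np.finfo(float).tiny
    shifted = np.full((2, y.size), 0.0)
    shifted[0, 2:] = resid[:-2]
    shifted[1, :-2] = resid[2:]
    neighbor_excess = np.clip(shifted.max(axis=0), 0.0, None)
    # a ray also towers over the local signal itself (they are several-fold
    # the local intensity), which keeps smooth band apexes untouchable even
    # when their neighbors' residuals dip to zero by chance
    spikes = (
        (resid > params.despike_z * robust_sd)
        & (resid > 5.0 * neighbor_excess)
        & (resid > 0.5 * np.clip(med, 0.0, None))
    )
    out = y.copy()
    if spikes.any():
        # interpolate across each spike run from unflagged neighbors; the
        # running median itself overshoots badly on steep band flanks
        good = np.flatnonzero(~spikes)
        if good.size == 0:
            out[:] = med
        else:
            bad = np.flatnonzero(spikes)
            out[bad] = np.interp(bad, good, y[good])
    return out, SpikeReport(channels=np.flatnonzero(spikes))


def subtract_substrate(intensities: np.ndarray, profile: InstrumentProfile) -> np.ndarray:
    """Subtract the recorded aluminum-substrate background spectrum."""
    y = np.asarray(intensities, dtype=float)
    if y.shape != profile.axis.shape:
        raise ValidationError("spectrum and instrument profile are on different axes")
    return y - profile.substrate_background


def correct_white_light(intensities: np.ndarray, profile: InstrumentProfile) -> np.ndarray:
    """Divide by the white-light response to flatten the detection efficiency."""
    y = np.asarray(intensities, dtype=float)
    if y.shape != profile.axis.shape:
        raise ValidationError("spectrum and instrument profile are on different axes")
    if np.min(profile.white_light_response) <= 0:
        raise ValidationError("white-light response must be strictly positive")
    return y / profile.white_light_response


def remove_fluorescence(
    intensities: np.ndarray, params: PreprocessParams = PreprocessParams()
) -> tuple[np.ndarray, BaselineFit]:
    """Remove the broad fluorescence background by iterative constrained
    polynomial fitting.

    An order-k polynomial is fit by least squares; channels rising more than
    twice the robust residual spread above the fit are flagged as Raman
    peaks and excluded, and the fit is repeated on the remaining channels
    until the fit and the exclusion set stabilize (maximum change between
    successive fits below ``baseline_tol * max(input)``) or the iteration
    cap is reached.  Excluding peak channels instead of clipping them keeps
    the converged polynomial centered in the noise of the peak-free
    channels, so the estimate is unbiased rather than sagging below the
    true fluorescence.  Output channels may be slightly negative in noise;
    they are deliberately not clipped.
    """
    y = np.asarray(intensities, dtype=float)
    t = np.linspace(0.0, 1.0, y.size)
    scale = np.max(np.abs(y))
    if scale == 0:
        fit = BaselineFit(np.zeros(params.baseline_order + 1), np.zeros_like(y), 0, True)
        return y.copy(), fit
    V = np.polynomial.polynomial.polyvander(t, params.baseline_order)
    include = np.ones(y.size, dtype=bool)
    prev = None
    converged = False
    iterations = 0
    coefs = np.zeros(params.baseline_order + 1)
    base = np.zeros_like(y)
    for iterations in range(1, params.baseline_max_iter + 1):
        coefs, *_ = np.linalg.lstsq(V[include], y[include], rcond=None)
        base = V @ coefs
        resid = y - base
        dev = np.std(resid[include])
        new_include = resid <= 2.0 * dev + 1e-12 * scale
        if new_include.sum() < params.baseline_order + 2:
            break  # degenerate: nearly everything looks like peak
        if (
            prev is not None
            and np.max(np.abs(base - prev)) < params.baseline_tol * scale
            and bool(np.all(new_include == include))
        ):
            converged = True
            break
        prev = base
        include = new_include
    fit = BaselineFit(coefficients=coefs, baseline=base, iterations=iterations, converged=converged)
    return y - base, fit


def normalize_phosphate(
    intensities: np.ndarray,
    axis: np.ndarray,
    catalog: BandCatalog | None = None,
    band: str = "phosphate_v1",
) -> np.ndarray:
    """Scale the spectrum so the apex inside the phosphate nu1 window is 1.

    Idempotent and invariant to positive rescaling of the input.
    """
    catalog = catalog or default_catalog()
    lo, hi = catalog.window(band)
    mask = (axis >= lo) & (axis <= hi)
    if not mask.any():
        raise ValidationError("normalization window is outside the axis")
    peak = np.max(np.asarray(intensities, float)[mask])
    if peak <= 0:
        raise ValidationError(
            "non-positive maximum in the phosphate window; preprocessing failed"
        )
    return np.asarray(intensities, float) / peak


# ---------------------------------------------------------------------------
# Whole-set pipeline
# ---------------------------------------------------------------------------


class RamanPreprocessor:
    """Scikit-learn style transformer running the five-step correction chain.

    Parameters
    ----------
    axis : ndarray
        Shared wavenumber axis of the input rows.
    profile : InstrumentProfile
        Substrate background and white-light response recorded on that axis.
    params : PreprocessParams
    catalog : BandCatalog, optional
        Band windows; only the normalization band is used here.

    After :meth:`transform`, ``baseline_fits_`` and ``spike_reports_`` hold
    the per-spectrum processing log of the most recent call.
    """

    def __init__(
        self,
        axis: np.ndarray,
        profile: InstrumentProfile,
        params: PreprocessParams = PreprocessParams(),
        catalog: BandCatalog | None = None,
    ):
        self.axis = axis
        self.profile = profile
        self.params = params
        self.catalog = catalog or default_catalog()

    def get_params(self, deep: bool = True) -> dict:
        return dict(axis=self.axis, profile=self.profile, params=self.params, catalog=self.catalog)

    def set_params(self, **kw) -> "RamanPreprocessor":
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None) -> "RamanPreprocessor":
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != np.asarray(self.axis).size:
            raise ValidationError("X must be (n_spectra, n_channels) on the configured axis")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        out = np.empty_like(X)
        self.baseline_fits_: list[BaselineFit] = []
        self.spike_reports_: list[SpikeReport] = []
        for i, row in enumerate(X):
            y, spikes = remove_cosmic_rays(row, self.params)
            y = subtract_substrate(y, self.profile)
            y = correct_white_light(y, self.profile)
            y, bfit = remove_fluorescence(y, self.params)
            y = normalize_phosphate(y, self.axis, self.catalog, self.params.normalization_band)
            out[i] = y
            self.baseline_fits_.append(bfit)
            self.spike_reports_.append(spikes)
        return out

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def preprocess_pipeline(
    sset: SpectrumSet,
    profile: InstrumentProfile,
    params: PreprocessParams = PreprocessParams(),
    catalog: BandCatalog | None = None,
) -> tuple[SpectrumSet, dict]:
    """Apply the five-step chain to every spectrum of a set.

    Returns the normalized :class:`SpectrumSet` and a processing log mapping
    spectrum_id to its baseline fit and despike report.  Step failures are
    re-raised with the offending spectrum_id attached.
    """
    pre = RamanPreprocessor(sset.axis, profile, params, catalog)
    out = np.empty_like(sset.intensities)
    log: dict[str, dict] = {}
    for i, sid in enumerate(sset.spectrum_ids):
        try:
            row = pre.fit_transform(sset.intensities[i : i + 1])[0]
        except ValidationError as exc:
            raise ValidationError(f"spectrum {sid!r}: {exc}") from exc
        out[i] = row
        log[sid] = {
            "baseline": pre.baseline_fits_[0],
            "spikes": pre.spike_reports_[0],
        }
    return sset.with_intensities(out, stage="normalized"), log
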