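"""Band quantification and bone-composition metrics.

Four per-spectrum metrics summarize bone quality:

- mineral-to-matrix: phosphate nu1 height / amide I height (collagen
  mineralization),
- phosphate-to-carbonate: phosphate nu1 / carbonate height (inverse marker
  of carbonate substitution into the apatite lattice),
- carbonate-to-matrix: carbonate / amide I height (remodeling, associated
  with fracture risk),
- crystallinity: 1 / FWHM of the phosphate nu1 band (apatite crystal order).

Heights are local-baseline-corrected window maxima of normalized spectra;
the phosphate FWHM comes from a pseudo-Voigt + linear-baseline least-squares
fit with a half-maximum-crossing fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .data_model import SpectrumSet, ValidationError

__all__ = [
    "BandCatalog",
    "default_catalog",
    "PeakFit",
    "BoneMetrics",
    "peak_height",
    "window_max_height",
    "fit_band",
    "fit_phosphate_peak",
    "compute_metrics",
    "metrics_table",
]

BAND_NAMES = ("phosphate_v1", "phenylalanine", "carbonate", "amide_III", "CH2", "amide_I")


@dataclass(frozen=True)
class BandCatalog:
    """Named bands with nominal centers and quantification windows (cm^-1).

    Windows must not overlap and must each contain the band's nominal
    center (the amide I window spans the 1630-1656 region of its feature).
    """

    bands: dict = field(
        default_factory=lambda: {
            "phosphate_v1": (958.0, (938.0, 978.0)),
            "phenylalanine": (1004.0, (994.0, 1014.0)),
            "carbonate": (1070.0, (1050.0, 1090.0)),
            "amide_III": (1250.0, (1220.0, 1280.0)),
            "CH2": (1450.0, (1420.0, 1480.0)),
            "amide_I": (1645.0, (1608.0, 1704.0)),
        }
    )

    def __post_init__(self) -> None:
        wins = sorted(w for _, w in self.bands.values())
        for (_, hi), (lo, _) in zip(wins, wins[1:]):
            if lo < hi:
                raise ValidationError("band windows must not overlap")
        for name, (center, (lo, hi)) in self.bands.items():
            if not lo <= center <= hi:
                raise ValidationError(f"band {name}: center outside its window")

    def center(self, band: str) -> float:
        return self.bands[band][0]

    def window(self, band: str) -> tuple[float, float]:
        return self.bands[band][1]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def channel_mask(self, axis: np.ndarray) -> np.ndarray:
        """Boolean mask of axis channels inside any band window."""
        axis = np.asarray(axis, float)
        mask = np.zeros(axis.size, dtype=bool)
        for _, (lo, hi) in self.bands.values():
            mask |= (axis >= lo) & (axis <= hi)
        return mask

    def to_yaml(self, path) -> None:
        import yaml

        payload = {
            name: {"center": center, "window": list(window)}
            for name, (center, window) in self.bands.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BandCatalog":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            bands={
                name: (float(spec["center"]), tuple(float(v) for v in spec["window"]))
                for name, spec in payload.items()
            }
        )


def default_catalog() -> BandCatalog:
    return BandCatalog()


@dataclass
class PeakFit:
    """Fitted phosphate nu1 parameters."""

    center: float
    height: float
    fwhm: float
    gauss_fraction: float
    baseline_slope: float
    baseline_intercept: float
    residual_rms: float
    from_fallback: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.fwhm) or self.fwhm <= 0:
            raise ValidationError("fitted FWHM must be finite and > 0")


@dataclass(frozen=True)
class BoneMetrics:
    """The four per-spectrum composition metrics."""

    mineral_to_matrix: float
    phos_to_carb: float
    carb_to_matrix: float
    crystallinity: float

    def as_dict(self) -> dict:
        return {
            "mineral_to_matrix": self.mineral_to_matrix,
            "phos_to_carb": self.phos_to_carb,
            "carb_to_matrix": self.carb_to_matrix,
            "crystallinity": self.crystallinity,
        }


# ---------------------------------------------------------------------------
# Heights
# ---------------------------------------------------------------------------


def _window_slice(axis: np.ndarray, lo: float, hi: float) -> np.ndarray:
    idx = np.flatnonzero((axis >= lo) & (axis <= hi))
    if idx.size == 0:
        raise ValidationError(f"band window [{lo}, {hi}] cm^-1 outside the axis")
    return idx


def _edge_value(y: np.ndarray, idx: int, side: str) -> float:
    # median of 3 channels at the window edge damps single-channel noise
    if side == "left":
        return float(np.median(y[idx : idx + 3]))
    return float(np.median(y[max(idx - 2, 0) : idx + 1]))


def window_max_height(
    intensities: np.ndarray, axis: np.ndarray, band: str, catalog: BandCatalog | None = None
) -> float:
    """Window maximum minus a local linear baseline anchored at the edges.

    Edge anchor values are medians of the 3 channels at each window end,
    which makes the height robust to noise at the anchors and removes the
    smooth tails of neighboring bands.  Note the raw maximum of a *noisy*
    window overestimates broad bands (extreme-value bias over the many
    near-apex channels); :func:`peak_height` therefore fits the band by
    default and uses this estimator only as initial guess and fallback.
    """
    catalog = catalog or default_catalog()
    axis = np.asarray(axis, float)
    y = np.asarray(intensities, float)
    lo, hi = catalog.window(band)
    idx = _window_slice(axis, lo, hi)
    left = _edge_value(y, idx[0], "left")
    right = _edge_value(y, idx[-1], "right")
    x0, x1 = axis[idx[0]], axis[idx[-1]]
    base = left + (right - left) * (axis[idx] - x0) / (x1 - x0)
    corrected = y[idx] - base
    return float(np.max(corrected))


def peak_height(
    intensities: np.ndarray,
    axis: np.ndarray,
    band: str,
    catalog: BandCatalog | None = None,
    method: str = "fit",
) -> float:
    """Apex height of a band above its local linear baseline.

    ``method="fit"`` (default) takes the apex of a pseudo-Voigt + linear
    baseline least-squares fit over the band window, which is unbiased under
    noise; ``method="max"`` is the plain baseline-corrected window maximum.
    """
    if method == "max":
        return window_max_height(intensities, axis, band, catalog)
    if method != "fit":
        raise ValidationError(f"unknown height method {method!r}")
    return fit_band(intensities, axis, band, catalog).height


# ---------------------------------------------------------------------------
# Phosphate peak fit
# ---------------------------------------------------------------------------


def _halfmax_width(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Interpolated half-maximum crossing width (fallback estimator)."""
    i = int(np.argmax(y))
    top = y[i]
    half = top / 2.0
    left = x[0]
    for j in range(i, 0, -1):
        if y[j - 1] <= half:
            f = (y[j] - half) / (y[j] - y[j - 1])
            left = x[j] - f * (x[j] - x[j - 1])
            break
    right = x[-1]
    for j in range(i, y.size - 1):
        if y[j + 1] <= half:
            f = (y[j] - half) / (y[j] - y[j + 1])
            right = x[j] + f * (x[j + 1] - x[j])
            break
    return right - left, x[i], top


def fit_band(
    intensities: np.ndarray,
    axis: np.ndarray,
    band: str,
    catalog: BandCatalog | None = None,
    fwhm0: float | None = None,
) -> PeakFit:
    """Least-squares pseudo-Voigt + linear baseline fit over the band window.

    Initial values: center at the window argmax, height from
    :func:`window_max_height`, FWHM 15 cm^-1 (phosphate) or a third of the
    window span, Gaussian fraction 0.5.  If the fit fails to produce a
    usable width, the interpolated half-maximum crossing width of the
    baseline-corrected window is returned instead, flagged via
    ``from_fallback``.
    """
    catalog = catalog or default_catalog()
    axis = np.asarray(axis, float)
    y = np.asarray(intensities, float)
    lo, hi = catalog.window(band)
    idx = _window_slice(axis, lo, hi)
    x, yy = axis[idx], y[idx]
    h0 = window_max_height(intensities, axis, band, catalog)
    c0 = float(x[np.argmax(yy)])
    if fwhm0 is None:
        fwhm0 = 15.0 if band == "phosphate_v1" else (hi - lo) / 3.0
    slope0 = (yy[-1] - yy[0]) / (x[-1] - x[0])
    intercept0 = float(yy[0]) - x[0] * slope0

    def model(xv, h, c, w, f, slope, intercept):
        d = xv - c
        g = np.exp(-4.0 * np.log(2.0) * (d / w) ** 2)
        lor = (w / 2.0) ** 2 / ((w / 2.0) ** 2 + d**2)
        return h * (f * g + (1.0 - f) * lor) + slope * xv + intercept

    p0 = [max(h0, 1e-6), c0, fwhm0, 0.5, slope0, intercept0]
    bounds = (
        [0.0, lo, 0.5, 0.0, -np.inf, -np.inf],
        [np.inf, hi, hi - lo, 1.0, np.inf, np.inf],
    )
    try:
        popt, _ = curve_fit(model, x, yy, p0=p0, bounds=bounds, maxfev=2000)
        h, c, w, f, slope, intercept = popt
        ok = np.isfinite(w) and 0.5 < w < (hi - lo) and np.isfinite(h)
    except (RuntimeError, ValueError):
        ok = False
    if ok:
        resid = yy - model(x, *popt)
        return PeakFit(
            center=float(c),
            height=float(h),
            fwhm=float(w),
            gauss_fraction=float(f),
            baseline_slope=float(slope),
            baseline_intercept=float(intercept),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            from_fallback=False,
        )
    # fallback: half-maximum crossings of the edge-baseline-corrected window
    left = _edge_value(y, idx[0], "left")
    right = _edge_value(y, idx[-1], "right")
    base = left + (right - left) * (x - x[0]) / (x[-1] - x[0])
    corr = yy - base
    width, center, top = _halfmax_width(x, corr)
    return PeakFit(
        center=float(center),
        height=float(top),
        fwhm=float(width),
        gauss_fraction=np.nan,
        baseline_slope=(right - left) / (x[-1] - x[0]),
        baseline_intercept=left,
        residual_rms=np.nan,
        from_fallback=True,
    )


def fit_phosphate_peak(
    intensities: np.ndarray,
    axis: np.ndarray,
    catalog: BandCatalog | None = None,
) -> PeakFit:
    """Pseudo-Voigt fit of the phosphate nu1 band (crystallinity = 1/FWHM)."""
    return fit_band(intensities, axis, "phosphate_v1", catalog)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def compute_metrics(
    intensities: np.ndarray, axis: np.ndarray, catalog: BandCatalog | None = None
) -> BoneMetrics:
    """The four composition metrics of one normalized spectrum.

    The phosphate fit supplies both its apex height and the FWHM for
    crystallinity, so the band is fit once.
    """
    catalog = catalog or default_catalog()
    for band in ("phosphate_v1", "carbonate", "amide_I"):
        if window_max_height(intensities, axis, band, catalog) <= 0:
            raise ValidationError(f"non-positive height in band {band!r}")
    fits = {b: fit_band(intensities, axis, b, catalog) for b in ("phosphate_v1", "carbonate", "amide_I")}
    heights = {b: f.height for b, f in fits.items()}
    return BoneMetrics(
        mineral_to_matrix=heights["phosphate_v1"] / heights["amide_I"],
        phos_to_carb=heights["phosphate_v1"] / heights["carbonate"],
        carb_to_matrix=heights["carbonate"] / heights["amide_I"],
        crystallinity=1.0 / fits["phosphate_v1"].fwhm,
    )


def metrics_table(sset: SpectrumSet, catalog: BandCatalog | None = None) -> pd.DataFrame:
    """Per-spectrum metrics table: metadata columns plus the four metrics.

    Per-spectrum failures are collected into an ``error`` column rather than
    aborting the whole table.
    """
    catalog = catalog or default_catalog()
    rows = []
    for i, sid in enumerate(sset.spectrum_ids):
        meta = sset.meta.iloc[i].to_dict()
        try:
            m = compute_metrics(sset.intensities[i], sset.axis, catalog)
            rows.append({**meta, **m.as_dict(), "error": ""})
        except (ValidationError, ValueError) as exc:
            rows.append(
                {
                    **meta,
                    **{k: np.nan for k in (
                        "mineral_to_matrix", "phos_to_carb", "carb_to_matrix", "crystallinity"
                    )},
                    "error": str(exc),
                }
            )
    columns = list(sset.meta.columns) + [
        "mineral_to_matrix", "phos_to_carb", "carb_to_matrix", "crystallinity", "error",
    ]
    return pd.DataFrame(rows, columns=columns)
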