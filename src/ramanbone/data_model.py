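"""Domain types, tabular spectrum I/O, and the anatomical sampling map.

A study is a collection of Raman spectra of murine femurs and spines,
all sharing one wavenumber axis.  Spectra are stored *wide*: one CSV with
a ``wavenumber_cm1`` column plus one column per spectrum, and a companion
metadata table keyed by ``spectrum_id``.  The anatomy map links the numbered
femur measurement sites and the vertebra codes to the bone regions used for
region-stratified statistics and classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "WEEKS",
    "BONES",
    "STAGES",
    "FEMUR_SITES",
    "VERTEBRAE",
    "AnatomyMap",
    "DEFAULT_ANATOMY",
    "SpectrumMeta",
    "SpectrumSet",
    "InstrumentProfile",
    "ValidationError",
    "default_axis",
    "validate_axis",
    "region_of",
    "read_spectrum_table",
    "write_spectrum_table",
    "read_instrument_profile",
    "write_instrument_profile",
]

#: Time points (weeks after tumor-cell inoculation) used in the study design.
WEEKS = (0, 2, 4, 5)
BONES = ("femur", "spine")
STAGES = ("raw", "preprocessed", "normalized")

#: Femur measurement sites along the bone axis (distal -> proximal).
FEMUR_SITES = (1, 2, 3, 4, 5, 6, 7)

#: Vertebra codes, lumbar through caudal.
VERTEBRAE = ("L1", "L2", "L3", "L4", "L5", "L6", "S1", "S2", "S3", "S4", "C1", "C2")

#: Columns of the metadata CSV, in order.
META_COLUMNS = ["spectrum_id", "subject_id", "week", "bone", "site", "replicate", "stage"]

REPLICATES_PER_SITE = 5


class ValidationError(ValueError):
    """Raised when a spectrum table or metadata record violates the study design."""


# ---------------------------------------------------------------------------
# Anatomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnatomyMap:
    """Mapping of measurement sites to bone regions.

    Femur sites 1-7 partition into distal metaphysis, diaphysis and proximal
    metaphysis; the 12 vertebrae partition into three groups of four:
    lumbar (L1-L4), lumbar-sacral (L5-S2) and sacral-caudal (S3-C2).
    """

    femur_site_regions: Mapping[int, str]
    spine_vertebra_regions: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.femur_site_regions) != set(FEMUR_SITES):
            raise ValidationError("femur map must cover sites 1-7 exactly")
        if set(self.spine_vertebra_regions) != set(VERTEBRAE):
            raise ValidationError("spine map must cover the 12 vertebrae exactly")

    @property
    def femur_regions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for site in FEMUR_SITES:
            r = self.femur_site_regions[site]
            if r not in seen:
                seen.append(r)
        return tuple(seen)

    @property
    def spine_regions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for v in VERTEBRAE:
            r = self.spine_vertebra_regions[v]
            if r not in seen:
                seen.append(r)
        return tuple(seen)

    def regions_for(self, bone: str) -> tuple[str, ...]:
        if bone == "femur":
            return self.femur_regions
        if bone == "spine":
            return self.spine_regions
        raise ValidationError(f"unknown bone {bone!r}")

    def sites_for(self, bone: str) -> tuple:
        return FEMUR_SITES if bone == "femur" else VERTEBRAE


#: Default map. Femur: symmetric 2-3-2 split mirroring the
#: metaphysis-diaphysis-metaphysis anatomy of a long bone.
DEFAULT_ANATOMY = AnatomyMap(
    femur_site_regions={
        1: "distal_metaphysis",
        2: "distal_metaphysis",
        3: "diaphysis",
        4: "diaphysis",
        5: "diaphysis",
        6: "proximal_metaphysis",
        7: "proximal_metaphysis",
    },
    spine_vertebra_regions={
        "L1": "L1_L4",
        "L2": "L1_L4",
        "L3": "L1_L4",
        "L4": "L1_L4",
        "L5": "L5_S2",
        "L6": "L5_S2",
        "S1": "L5_S2",
        "S2": "L5_S2",
        "S3": "S3_C2",
        "S4": "S3_C2",
        "C1": "S3_C2",
        "C2": "S3_C2",
    },
)


def region_of(bone: str, site, anatomy: AnatomyMap = DEFAULT_ANATOMY) -> str:
    """Region label for a measurement site.

    Parameters
    ----------
    bone : {"femur", "spine"}
    site : int or str
        Femur site index 1-7, or vertebra code such as ``"L5"``.
    """
    if bone == "femur":
        try:
            return anatomy.femur_site_regions[int(site)]
        except (KeyError, ValueError, TypeError) as exc:
            raise ValidationError(f"unknown femur site {site!r}") from exc
    if bone == "spine":
        try:
            return anatomy.spine_vertebra_regions[str(site)]
        except KeyError as exc:
            raise ValidationError(f"unknown vertebra {site!r}") from exc
    raise ValidationError(f"unknown bone {bone!r}")


# ---------------------------------------------------------------------------
# Axis
# ---------------------------------------------------------------------------


def default_axis() -> np.ndarray:
    """Default Raman shift axis: 600-1800 cm^-1 at 2 cm^-1 (601 channels).

    Covers the fingerprint region containing all six quantified bands at a
    typical dispersive-spectrograph resolution.
    """
    return np.arange(600.0, 1800.0 + 1e-9, 2.0)


def validate_axis(axis: np.ndarray, *, require_metric_range: bool = False) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValidationError("axis must be 1-D with at least 2 wavenumbers")
    if not np.all(np.diff(axis) > 0):
        raise ValidationError("wavenumber axis must be strictly increasing")
    if require_metric_range and (axis[0] > 900.0 or axis[-1] < 1700.0):
        raise ValidationError("axis must cover at least [900, 1700] cm^-1 for metrics")
    return axis


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumMeta:
    """Anatomical/temporal metadata for one spectrum."""

    spectrum_id: str
    subject_id: str
    week: int
    bone: str
    site: object  # int (femur) or vertebra code (spine)
    replicate: int
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.week not in WEEKS:
            raise ValidationError(
                f"spectrum {self.spectrum_id!r}: week {self.week} not in {WEEKS}"
            )
        if self.bone not in BONES:
            raise ValidationError(f"spectrum {self.spectrum_id!r}: unknown bone {self.bone!r}")
        if not 1 <= int(self.replicate) <= REPLICATES_PER_SITE:
            raise ValidationError(
                f"spectrum {self.spectrum_id!r}: replicate {self.replicate} outside 1-5"
            )
        if self.stage not in STAGES:
            raise ValidationError(f"spectrum {self.spectrum_id!r}: unknown stage {self.stage!r}")
        # raises for inconsistent (bone, site)
        region_of(self.bone, self.site)

    @property
    def region(self) -> str:
        return region_of(self.bone, self.site)


@dataclass
class SpectrumSet:
    """A collection of spectra on one shared wavenumber axis.

    Attributes
    ----------
    axis : ndarray, shape (n_channels,)
        Raman shift in cm^-1, strictly increasing.
    intensities : ndarray, shape (n_spectra, n_channels)
        One row per spectrum, arbitrary detector units.
    meta : DataFrame
        One row per spectrum, columns ``spectrum_id, subject_id, week, bone,
        site, replicate, stage`` plus a derived ``region`` column, aligned to
        the rows of ``intensities``.
    """

    axis: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.axis = validate_axis(self.axis)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != self.axis.size:
            raise ValidationError("intensities must be (n_spectra, n_channels) on the axis")
        if len(self.meta) != self.intensities.shape[0]:
            raise ValidationError("metadata rows must match intensity rows")
        self.meta = self.meta.reset_index(drop=True)
        ids = self.meta["spectrum_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate spectrum_id(s): {dupes}")
        if "region" not in self.meta.columns:
            self.meta = self.meta.assign(
                region=[
                    region_of(b, s) for b, s in zip(self.meta["bone"], self.meta["site"])
                ]
            )
        self.validate()

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def spectrum_ids(self) -> list[str]:
        return list(self.meta["spectrum_id"])

    def select(self, mask) -> "SpectrumSet":
        """Subset by a boolean mask or an index array over spectra."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectrumSet(
            axis=self.axis,
            intensities=self.intensities[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    def record(self, spectrum_id: str) -> tuple[SpectrumMeta, np.ndarray]:
        i = self.spectrum_ids.index(spectrum_id)
        row = self.meta.iloc[i]
        meta = SpectrumMeta(
            spectrum_id=row["spectrum_id"],
            subject_id=row["subject_id"],
            week=int(row["week"]),
            bone=row["bone"],
            site=row["site"],
            replicate=int(row["replicate"]),
            stage=row["stage"],
        )
        return meta, self.intensities[i]

    def with_intensities(self, intensities: np.ndarray, stage: str | None = None) -> "SpectrumSet":
        meta = self.meta.copy()
        if stage is not None:
            meta["stage"] = stage
        return SpectrumSet(axis=self.axis, intensities=np.asarray(intensities, float), meta=meta)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        m = self.meta
        bad_week = ~m["week"].isin(WEEKS)
        if bad_week.any():
            offender = m.loc[bad_week, "spectrum_id"].iloc[0]
            raise ValidationError(
                f"spectrum {offender!r}: week {m.loc[bad_week, 'week'].iloc[0]} not in {WEEKS}"
            )
        bad_bone = ~m["bone"].isin(BONES)
        if bad_bone.any():
            offender = m.loc[bad_bone, "spectrum_id"].iloc[0]
            raise ValidationError(f"spectrum {offender!r}: unknown bone")
        bad_rep = ~m["replicate"].astype(int).between(1, REPLICATES_PER_SITE)
        if bad_rep.any():
            offender = m.loc[bad_rep, "spectrum_id"].iloc[0]
            raise ValidationError(f"spectrum {offender!r}: replicate outside 1-5")
        bad_stage = ~m["stage"].isin(STAGES)
        if bad_stage.any():
            offender = m.loc[bad_stage, "spectrum_id"].iloc[0]
            raise ValidationError(f"spectrum {offender!r}: unknown stage")
        for sid, bone, site, region in zip(m["spectrum_id"], m["bone"], m["site"], m["region"]):
            if region_of(bone, site) != region:
                raise ValidationError(
                    f"spectrum {sid!r}: region {region!r} inconsistent with site {site!r}"
                )
        if (m["stage"] == "raw").any():
            raw = self.intensities[(m["stage"] == "raw").to_numpy()]
            if np.any(raw < 0):
                raise ValidationError("raw-stage intensities must be >= 0")


@dataclass
class InstrumentProfile:
    """Per-instrument correction spectra on the shared axis.

    ``substrate_background`` is the signal measured from the bare aluminum
    substrate (as recorded, i.e. already shaped by the detection response);
    ``white_light_response`` is the relative wavelength-dependent detection
    efficiency measured with a broadband reference, strictly positive.
    """

    axis: np.ndarray
    substrate_background: np.ndarray
    white_light_response: np.ndarray

    def __post_init__(self) -> None:
        self.axis = validate_axis(self.axis)
        self.substrate_background = np.asarray(self.substrate_background, float)
        self.white_light_response = np.asarray(self.white_light_response, float)
        if self.substrate_background.shape != self.axis.shape:
            raise ValidationError("substrate_background must align with the axis")
        if self.white_light_response.shape != self.axis.shape:
            raise ValidationError("white_light_response must align with the axis")
        if np.min(self.white_light_response) <= 0:
            raise ValidationError("white_light_response must be strictly positive")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_spectrum_table(spectra_path, metadata_path) -> SpectrumSet:
    """Read the wide spectra CSV and its companion metadata CSV.

    The spectra file's first column must be ``wavenumber_cm1``; each remaining
    column is one spectrum named by its ``spectrum_id``.  Every spectrum
    column must have a metadata row and vice versa.
    """
    spectra = pd.read_csv(spectra_path, float_precision="round_trip")
    if spectra.columns[0] != "wavenumber_cm1":
        raise ValidationError("spectra CSV must start with a 'wavenumber_cm1' column")
    axis = validate_axis(spectra["wavenumber_cm1"].to_numpy(float))
    ids = [str(c) for c in spectra.columns[1:]]

    meta = pd.read_csv(metadata_path, dtype={"site": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata CSV missing columns: {missing}")
    meta["spectrum_id"] = meta["spectrum_id"].astype(str)

    unmatched_cols = sorted(set(ids) - set(meta["spectrum_id"]))
    unmatched_rows = sorted(set(meta["spectrum_id"]) - set(ids))
    if unmatched_cols or unmatched_rows:
        raise ValidationError(
            "spectra/metadata join failed: "
            f"columns without metadata {unmatched_cols}, rows without spectra {unmatched_rows}"
        )
    meta = meta.set_index("spectrum_id").loc[ids].reset_index()
    meta["week"] = meta["week"].astype(int)
    meta["replicate"] = meta["replicate"].astype(int)
    # femur sites are integers stored as text in CSV
    meta["site"] = [
        int(s) if b == "femur" else str(s) for b, s in zip(meta["bone"], meta["site"])
    ]
    intensities = spectra[ids].to_numpy(float).T
    return SpectrumSet(axis=axis, intensities=intensities, meta=meta)


def write_spectrum_table(sset: SpectrumSet, spectra_path, metadata_path) -> None:
    """Write a :class:`SpectrumSet` as the wide spectra CSV + metadata CSV.

    Floats are written with the shortest representation that parses back to
    the identical binary64 value, so a read/write cycle is value- and
    byte-stable.
    """
    wide = pd.DataFrame({"wavenumber_cm1": sset.axis})
    for sid, row in zip(sset.spectrum_ids, sset.intensities):
        wide[sid] = row
    wide.to_csv(spectra_path, index=False)
    sset.meta[META_COLUMNS].to_csv(metadata_path, index=False)


def read_instrument_profile(path) -> InstrumentProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["wavenumber_cm1", "substrate_background", "white_light_response"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"instrument profile CSV missing columns: {missing}")
    return InstrumentProfile(
        axis=df["wavenumber_cm1"].to_numpy(float),
        substrate_background=df["substrate_background"].to_numpy(float),
        white_light_response=df["white_light_response"].to_numpy(float),
    )


def write_instrument_profile(profile: InstrumentProfile, path) -> None:
    pd.DataFrame(
        {
            "wavenumber_cm1": profile.axis,
            "substrate_background": profile.substrate_background,
            "white_light_response": profile.white_light_response,
        }
    ).to_csv(path, index=False)
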