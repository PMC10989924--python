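"""Wet-lab-derived biomarker quantities.

Four independent assays feed the life-history analysis:

* PLFA (phospholipid fatty acid) profiles quantified against a 19:0
  (methyl nonadecanoate) internal standard, summarized as fungal, Gram-positive,
  Gram-negative and general-bacterial pools and their ratios (F:B, G+:G-, and
  the K:r index, defined as the G+:G- concentration ratio).
* Chloroform fumigation-extraction microbial biomass C/N/P with the standard
  extraction-efficiency constants kEC=0.45, kEN=0.54, kEP=0.40.
* Fluorometric extracellular enzyme activities calibrated against a
  4-methylumbelliferone (MUB) standard curve, reported in nmol g^-1 h^-1.
* GeoChip functional-gene microarray signals, filtered by background and
  signal-to-noise rules and normalized for cross-sample comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlfaProfile",
    "PlfaTraits",
    "EnzymePlate",
    "GeoChipMatrix",
    "DEFAULT_MARKER_MAP",
    "BIOMASS_K",
    "plfa_concentrations",
    "plfa_ratios",
    "microbial_biomass",
    "enzyme_activity",
    "filter_geochip",
    "normalize_geochip",
]

# Standard literature assignments of PLFA markers to microbial groups;
# fully overridable by the caller.
DEFAULT_MARKER_MAP: dict[str, str] = {
    "i15:0": "gram_positive",
    "a15:0": "gram_positive",
    "i16:0": "gram_positive",
    "i17:0": "gram_positive",
    "a17:0": "gram_positive",
    "16:1w7c": "gram_negative",
    "18:1w7c": "gram_negative",
    "cy17:0": "gram_negative",
    "cy19:0": "gram_negative",
    "18:2w6,9c": "fungal",
    "18:1w9c": "fungal",
    "15:0": "general_bacterial",
    "17:0": "general_bacterial",
}

# Fumigation-extraction efficiency constants per analyte.
BIOMASS_K = {"C": 0.45, "N": 0.54, "P": 0.40}

INTERNAL_STANDARD = "19:0"


class CalibrationError(ValueError):
    """Raised when an internal standard or standard curve is unusable."""


@dataclass
class PlfaProfile:
    """PLFA peak areas for one sample, with internal-standard calibration."""

    sample_id: str
    areas: dict[str, float]
    internal_standard_area: float
    internal_standard_amount_nmol: float
    dry_mass_g: float

    def __post_init__(self) -> None:
        if self.internal_standard_area <= 0:
            raise CalibrationError("internal standard (19:0) peak area must be positive")
        if self.dry_mass_g <= 0:
            raise ValueError("dry soil mass must be positive")
        if any(a < 0 for a in self.areas.values()):
            raise ValueError("peak areas must be nonnegative")


@dataclass
class PlfaTraits:
    """Per-sample PLFA pools (nmol g^-1) and life-history ratios."""

    sample_id: str
    class_nmol_g: dict[str, float]
    total_nmol_g: float
    fb_ratio: float | None
    gpgn_ratio: float | None
    kr_ratio: float | None


def plfa_concentrations(profile: PlfaProfile) -> dict[str, float]:
    """Marker concentrations (nmol per g dry soil) from peak areas.

    conc_m = (area_m / area_19:0) x internal standard amount / dry mass.
    The internal-standard marker itself is not reported.
    """
    scale = profile.internal_standard_amount_nmol / (
        profile.internal_standard_area * profile.dry_mass_g
    )
    return {
        m: a * scale
        for m, a in profile.areas.items()
        if m != INTERNAL_STANDARD
    }


def plfa_ratios(
    concentrations: dict[str, float],
    marker_map: dict[str, str] | None = None,
    sample_id: str = "",
) -> PlfaTraits:
    """Class sums and the F:B, G+:G- and K:r ratios.

    F:B divides fungal markers by all bacterial markers (Gram-positive +
    Gram-negative + general bacterial); K:r is the Gram-positive to
    Gram-negative concentration ratio, an oligotroph:copiotroph index.
    Zero denominators yield None rather than an exception.
    """
    marker_map = DEFAULT_MARKER_MAP if marker_map is None else marker_map
    sums = {
        "gram_positive": 0.0,
        "gram_negative": 0.0,
        "fungal": 0.0,
        "general_bacterial": 0.0,
        "other": 0.0,
    }
    for marker, conc in concentrations.items():
        sums[marker_map.get(marker, "other")] += conc
    bacterial = sums["gram_positive"] + sums["gram_negative"] + sums["general_bacterial"]
    gpgn = sums["gram_positive"] / sums["gram_negative"] if sums["gram_negative"] > 0 else None
    return PlfaTraits(
        sample_id=sample_id,
        class_nmol_g=sums,
        total_nmol_g=sum(sums.values()),
        fb_ratio=sums["fungal"] / bacterial if bacterial > 0 else None,
        gpgn_ratio=gpgn,
        kr_ratio=gpgn,
    )


def microbial_biomass(analyte: str, fumigated: float, nonfumigated: float) -> float:
    """Fumigation-extraction biomass: (fumigated - nonfumigated) / k_analyte.

    k is 0.45 for C, 0.54 for N, 0.40 for P.  A negative flush (fumigated
    below nonfumigated) is reported as-is with a warning rather than raised.
    """
    try:
        k = BIOMASS_K[analyte.upper()]
    except KeyError:
        raise ValueError(f"unknown analyte {analyte!r}; expected C, N or P") from None
    if fumigated < nonfumigated:
        warnings.warn(
            f"negative fumigation flush for {analyte}: {fumigated} < {nonfumigated}",
            stacklevel=2,
        )
    return (fumigated - nonfumigated) / k


@dataclass
class EnzymePlate:
    """One fluorometric enzyme assay plate.

    ``standards`` maps MUB concentration (µM) to fluorescence; ``wells`` has
    columns sample, enzyme, test, control.  Defaults follow the assay
    protocol: 100 µL homogenate + 150 µL buffer per well (250 µL), slurry of
    4 g soil in 40 mL so 0.01 g dry-soil equivalent per well, 3 h at 25 °C.
    """

    standards: dict[float, float]
    wells: pd.DataFrame
    incubation_h: float = 3.0
    soil_equivalent_g: float = 0.01
    well_volume_ml: float = 0.25
    quench_factor: float = 1.0
    min_r_squared: float = 0.98

    def __post_init__(self) -> None:
        if len(set(self.standards)) < 2:
            raise CalibrationError("need at least two distinct standard concentrations")
        if self.incubation_h <= 0:
            raise ValueError("incubation time must be positive")


def _standard_curve(standards: dict[float, float], min_r_squared: float) -> float:
    conc = np.array(sorted(standards))
    fluor = np.array([standards[c] for c in conc])
    fit = stats.linregress(conc, fluor)
    if fit.slope <= 0:
        raise CalibrationError(f"nonpositive standard-curve slope {fit.slope:.3g}")
    if fit.rvalue**2 < min_r_squared:
        raise CalibrationError(
            f"standard curve R²={fit.rvalue ** 2:.4f} below {min_r_squared}"
        )
    return float(fit.slope)


def enzyme_activity(plate: EnzymePlate) -> pd.DataFrame:
    """Enzyme activities in nmol MUB g^-1 dry soil h^-1.

    Net fluorescence = (test - control)/quench; the MUB µM equivalent is
    net/slope of the standard curve; µM x well volume (mL) gives nmol
    released, divided by soil equivalent and incubation time.
    """
    slope = _standard_curve(plate.standards, plate.min_r_squared)
    net = (plate.wells["test"] - plate.wells["control"]) / plate.quench_factor
    mub_um = net / slope
    nmol = mub_um * plate.well_volume_ml  # µM == nmol/mL
    activity = nmol / (plate.soil_equivalent_g * plate.incubation_h)
    out = plate.wells[["sample", "enzyme"]].copy()
    out["activity_nmol_g_h"] = activity
    return out


@dataclass
class GeoChipMatrix:
    """Probe x sample signal intensities with per-spot QC and replicate groups.

    ``signal``, ``background`` and ``snr`` share the same probe index and
    sample columns; ``groups`` maps each sample to its replicate group.
    A spot with signal 0 is "not detected".
    """

    signal: pd.DataFrame
    background: pd.DataFrame
    snr: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        for name, df in (("background", self.background), ("snr", self.snr)):
            if not df.index.equals(self.signal.index) or not df.columns.equals(
                self.signal.columns
            ):
                raise ValueError(f"{name} matrix shape/labels differ from signal")
        missing = [s for s in self.signal.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without replicate group: {missing[:5]}")
        if (self.signal.to_numpy() < 0).any():
            raise ValueError("signals must be nonnegative")


def filter_geochip(
    matrix: GeoChipMatrix,
    fold_background: float = 2.0,
    min_snr: float = 2.0,
    min_prevalence: float = 0.10,
) -> GeoChipMatrix:
    """Apply the spot- and probe-level quality rules; signals keep their scale.

    Rules, in order: zero spots whose signal is below ``fold_background`` x
    background; zero spots with signal-to-noise ratio below ``min_snr``; zero
    probe detections present in fewer than two replicates of a replicate
    group; finally drop probes detected in fewer than ``min_prevalence`` of
    all samples.  The filter is idempotent: zeroed spots stay zeroed and the
    surviving-probe set is stable under re-application.
    """
    sig = matrix.signal.copy()
    detected = sig > 0
    fail = detected & (
        (sig < fold_background * matrix.background) | (matrix.snr < min_snr)
    )
    sig[fail] = 0.0
    # replicate rule: a detection supported by a single replicate in its group
    # is treated as spurious
    for group in sorted(set(matrix.groups.values())):
        cols = [s for s in sig.columns if matrix.groups[s] == group]
        det = sig[cols] > 0
        singleton = det.sum(axis=1) < 2
        sig.loc[singleton, cols] = 0.0
    prevalence = (sig > 0).mean(axis=1)
    keep = prevalence >= min_prevalence
    if not keep.any():
        warnings.warn("all probes removed by GeoChip filtering", stacklevel=2)
    sig = sig.loc[keep]
    return GeoChipMatrix(
        signal=sig,
        background=matrix.background.loc[keep],
        snr=matrix.snr.loc[keep],
        groups=dict(matrix.groups),
    )


def normalize_geochip(matrix: GeoChipMatrix) -> pd.DataFrame:
    """Per-probe relative abundance across samples, then ln(x + 1).

    Destructive (changes scale), hence separate from the drop-rule filter.
    """
    sig = matrix.signal
    row_sums = sig.sum(axis=1).replace(0, np.nan)
    rel = sig.div(row_sums, axis=0).fillna(0.0)
    return np.log1p(rel)
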