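"""Western-blot densitometry: background subtraction, loading normalization
and fold-change activation profiles.

Band intensities are corrected by subtracting the local background (the
minimum intensity surrounding the band), normalized to a loading control
(GAPDH) quantified the same way, and expressed as fold change over the
unstimulated (timepoint 0) lane.  A signaling intermediate is called
*activated* when its peak fold change reaches the activation threshold
(default: at least 2-fold over basal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: fold-change threshold at which a signaling intermediate counts as activated
ACTIVATION_THRESHOLD = 2.0

CSV_COLUMNS = [
    "target",
    "timepoint_min",
    "raw",
    "background",
    "loading_raw",
    "loading_background",
]


@dataclass(frozen=True)
class BandMeasurement:
    """One quantified band: target intensity plus its loading-control lane."""

    target: str
    timepoint: float
    raw: float
    local_background: float
    loading_raw: float
    loading_background: float

    def __post_init__(self) -> None:
        if self.raw < 0 or self.local_background < 0:
            raise ValueError(
                f"band intensities must be non-negative "
                f"(target={self.target!r}, t={self.timepoint})"
            )
        if self.loading_raw < 0 or self.loading_background < 0:
            raise ValueError(
                f"loading-control intensities must be non-negative "
                f"(target={self.target!r}, t={self.timepoint})"
            )
        if self.timepoint < 0:
            raise ValueError(f"timepoint must be non-negative, got {self.timepoint}")


@dataclass
class ActivationProfile:
    """Fold-change time course of one signaling intermediate."""

    target: str
    fold_by_time: dict[float, float]
    peak_fold: float
    activated: bool
    threshold: float = field(default=ACTIVATION_THRESHOLD)


def corrected_intensity(raw: float, background: float) -> float:
    """Background-corrected intensity, floored at zero.

    Intensities are physical quantities; a background estimate exceeding the
    band reading yields zero, not a negative value.
    """
    if raw < 0 or background < 0:
        raise ValueError(
            f"intensities must be non-negative, got raw={raw}, background={background}"
        )
    return max(raw - background, 0.0)


def normalize_to_loading(band: BandMeasurement) -> float:
    """Corrected band intensity divided by the corrected loading-control
    intensity of the same lane."""
    loading = corrected_intensity(band.loading_raw, band.loading_background)
    if loading <= 0:
        raise ZeroDivisionError(
            f"corrected loading-control intensity is zero in lane "
            f"(target={band.target!r}, t={band.timepoint} min)"
        )
    return corrected_intensity(band.raw, band.local_background) / loading


def build_profile(
    measurements: list[BandMeasurement] | pd.DataFrame,
    target: str,
    threshold: float = ACTIVATION_THRESHOLD,
) -> ActivationProfile:
    """Fold-change profile of ``target`` relative to its timepoint-0 lane.

    The activation call is inclusive: a peak of exactly ``threshold`` counts
    as activated ("at least" the threshold).

    Raises
    ------
    ValueError
        If no timepoint-0 measurement exists for the target, or its
        normalized value is zero.
    """
    if isinstance(measurements, pd.DataFrame):
        measurements = measurements_from_frame(measurements)
    bands = sorted(
        (m for m in measurements if m.target == target), key=lambda m: m.timepoint
    )
    if not bands:
        raise ValueError(f"no measurements for target {target!r}")
    normalized = {m.timepoint: normalize_to_loading(m) for m in bands}
    if 0.0 not in normalized:
        raise ValueError(f"missing timepoint-0 baseline for target {target!r}")
    baseline = normalized[0.0]
    if baseline <= 0:
        raise ValueError(
            f"baseline (t=0) normalized intensity is zero for target {target!r}"
        )
    folds = {t: v / baseline for t, v in normalized.items()}
    peak = max(folds.values())
    return ActivationProfile(
        target=target,
        fold_by_time=folds,
        peak_fold=peak,
        activated=peak >= threshold,
        threshold=threshold,
    )


def build_profiles(
    measurements: list[BandMeasurement] | pd.DataFrame,
    threshold: float = ACTIVATION_THRESHOLD,
) -> list[ActivationProfile]:
    """Profiles for every target present in the measurement table."""
    if isinstance(measurements, pd.DataFrame):
        measurements = measurements_from_frame(measurements)
    targets = sorted({m.target for m in measurements})
    return [build_profile(measurements, t, threshold=threshold) for t in targets]


def measurements_from_frame(frame: pd.DataFrame) -> list[BandMeasurement]:
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    return [
        BandMeasurement(
            target=str(row.target),
            timepoint=float(row.timepoint_min),
            raw=float(row.raw),
            local_background=float(row.background),
            loading_raw=float(row.loading_raw),
            loading_background=float(row.loading_background),
        )
        for row in frame.itertuples(index=False)
    ]


def read_measurements(path) -> list[BandMeasurement]:
    """Read a band-measurement CSV (columns: target, timepoint_min, raw,
    background, loading_raw, loading_background)."""
    return measurements_from_frame(pd.read_csv(path))


def profiles_to_frame(profiles: list[ActivationProfile]) -> pd.DataFrame:
    """Tidy fold table: one row per (target, timepoint)."""
    rows = [
        {
            "target": p.target,
            "timepoint_min": t,
            "fold": f,
            "peak_fold": p.peak_fold,
            "activated": p.activated,
        }
        for p in profiles
        for t, f in sorted(p.fold_by_time.items())
    ]
    return pd.DataFrame(rows, columns=["target", "timepoint_min", "fold", "peak_fold", "activated"])
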