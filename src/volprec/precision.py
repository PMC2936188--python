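"""Test–retest precision statistics for longitudinal volume series.

A stable organ measured repeatedly yields a series whose spread is pure
measurement noise; the coefficient of variation (COV = SD / mean) of that
series is the standard precision figure in CT volumetry repeatability work.
This module computes per-series summaries, cohort aggregates of per-patient
COVs, the inter-observer mean percent difference, the squared Pearson
correlation of paired organ series (left vs right gland over time), and the
COV-vs-volume trend.

Conventions: the sample standard deviation (n−1 denominator) is used
throughout — the unbiased-variance convention for small repeatability
series; cohort COV aggregation averages per-patient COVs unweighted, not
pooled over scans.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError


class Measurement(NamedTuple):
    scan_id: str
    scan_date: str | None
    volume_cm3: float


@dataclasses.dataclass(eq=False)
class OrganSeries:
    """Longitudinal volume measurements of one organ in one patient."""

    patient_id: str
    organ_label: str
    measurements: list[Measurement]

    def __post_init__(self) -> None:
        vols = self.volumes
        if not np.all(np.isfinite(vols)) or np.any(vols <= 0):
            raise ValidationError(
                f"series({self.patient_id}, {self.organ_label}): "
                "volumes must be finite and > 0"
            )

    @property
    def volumes(self) -> np.ndarray:
        return np.array([m.volume_cm3 for m in self.measurements], dtype=float)

    def __len__(self) -> int:
        return len(self.measurements)


@dataclasses.dataclass(frozen=True)
class PrecisionSummary:
    """Mean, sample SD and COV of a measurement series."""

    n: int
    mean: float
    sd: float
    cov: float


class CohortCovSummary(NamedTuple):
    n: int
    mean: float
    sd: float  # NaN when only one patient


@dataclasses.dataclass(frozen=True)
class TrendFit:
    """OLS fit of COV on volume (or log volume)."""

    slope: float
    intercept: float
    r_squared: float
    form: str  # "linear" | "log-volume"


def _volumes(series) -> np.ndarray:
    if isinstance(series, OrganSeries):
        return series.volumes
    v = np.asarray(series, dtype=float)
    if v.ndim != 1:
        raise ValidationError("a series must be one-dimensional")
    return v


def series_summary(series) -> PrecisionSummary:
    """Mean, sample SD (ddof=1) and COV = SD/mean of one series.

    Accepts an :class:`OrganSeries` or a plain sequence of volumes (cm³).
    """
    v = _volumes(series)
    if len(v) < 2:
        raise InsufficientDataError(
            f"precision statistics need at least 2 measurements, got {len(v)}"
        )
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise ValidationError("volumes must be finite and > 0")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    return PrecisionSummary(n=len(v), mean=mean, sd=sd, cov=sd / mean)


def cohort_cov_summary(per_patient_covs: Sequence[float]) -> CohortCovSummary:
    """Unweighted mean and sample SD of per-patient COVs.

    Each patient contributes one COV regardless of how many scans it was
    computed from; pooling over scans would over-weight heavily scanned
    patients.  With a single patient the SD is undefined and reported NaN.
    """
    covs = np.asarray(per_patient_covs, dtype=float)
    if covs.size == 0:
        raise InsufficientDataError("cohort summary needs at least one COV")
    mean = float(np.mean(covs))
    sd = float(np.std(covs, ddof=1)) if covs.size > 1 else math.nan
    return CohortCovSummary(n=covs.size, mean=mean, sd=sd)


def interobserver_mean_percent_difference(
    volumes_obs1: Sequence[float],
    volumes_obs2: Sequence[float],
    signed: bool = False,
) -> float:
    """Mean pairwise percent difference between two observers' volumes.

    For each paired measurement the difference (observer 1 − observer 2) is
    scaled by the pair mean; the default reports the mean of absolute scaled
    differences (the conventional positive figure), ``signed=True`` keeps
    the sign and so exposes a systematic observer bias.
    """
    a = np.asarray(volumes_obs1, dtype=float)
    b = np.asarray(volumes_obs2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValidationError("observer series must be equal-length, non-empty 1-D")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValidationError("volumes must be > 0")
    diff = (a - b) / ((a + b) / 2.0)
    if not signed:
        diff = np.abs(diff)
    return float(np.mean(diff))


def paired_series_r2(series_a, series_b) -> float:
    """Squared Pearson correlation of two time-matched volume series.

    Pairing is by scan order (scan 1 with scan 1, ...).  A low r² between
    paired stable organs indicates the scan-to-scan fluctuation is
    measurement noise rather than a shared physiological signal.
    """
    a = _volumes(series_a)
    b = _volumes(series_b)
    if a.shape != b.shape:
        raise ValidationError("paired series must have equal length")
    if len(a) < 3:
        raise InsufficientDataError("correlation needs at least 3 paired scans")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("correlation undefined for a constant series")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


def cov_volume_trend(
    points: Sequence[tuple[float, float]], form: str = "linear"
) -> TrendFit:
    """OLS line of COV on volume across organs, with r².

    ``form="linear"`` regresses COV on volume in cm³; ``form="log-volume"``
    on its natural log.  The measured inverse precision–size relationship
    shows up as a negative slope.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("trend fit needs at least 3 (volume, cov) points")
    vol, cov = pts[:, 0], pts[:, 1]
    if np.ptp(vol) == 0:
        raise ValidationError("trend fit needs non-constant volumes")
    if form == "log-volume":
        if np.any(vol <= 0):
            raise ValidationError("log-volume trend needs positive volumes")
        x = np.log(vol)
    elif form == "linear":
        x = vol
    else:
        raise ValueError(f"unknown trend form {form!r}")
    fit = stats.linregress(x, cov)
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        form=form,
    )


def split_series(frame: pd.DataFrame) -> list[OrganSeries]:
    """Split a series DataFrame (series CSV layout) into per-organ series.

    Measurements within a series keep the file order of their scans, which
    is the pairing order used by :func:`paired_series_r2`.
    """
    out: list[OrganSeries] = []
    for (pid, organ), g in frame.groupby(["patient_id", "organ_label"], sort=True):
        ms = [
            Measurement(
                scan_id=str(r.scan_id),
                scan_date=None if pd.isna(r.scan_date) else str(r.scan_date),
                volume_cm3=float(r.volume_cm3),
            )
            for r in g.itertuples()
        ]
        out.append(OrganSeries(patient_id=pid, organ_label=organ, measurements=ms))
    return out
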