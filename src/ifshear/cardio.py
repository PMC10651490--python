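"""Blood-pressure and heart-rate variability analysis.

Covers the human-study computations: mean arterial pressure, cuff-log
aggregation into values of the day and of the week, artifact rejection of
beat-by-beat R-R interval (RRI) series, per-segment validity rules for
continuous recordings, and Hanning-windowed band power of systolic
blood-pressure (SBP) and RRI variability.

Frequency bands follow the cardiovascular-variability convention:
LF = 0.04–0.15 Hz (vascular sympathetic modulation, Mayer waves) and
HF = 0.15–0.4 Hz (respiratory modulation). LF power of SBP indexes
vascular sympathetic activity; the LF/HF ratio of RRI indexes
sympatho-vagal balance. The 0.15 Hz edge belongs to HF so no bin is
counted twice.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import interpolate

__all__ = [
    "LF_BAND",
    "HF_BAND",
    "BeatSeries",
    "CleaningReport",
    "SegmentValidity",
    "SpectralSummary",
    "compute_map",
    "value_of_day",
    "value_of_week",
    "weekly_values",
    "clean_rri",
    "validate_segment",
    "band_power",
    "spectral_summary",
    "normalize_to_baseline",
    "period_mean",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

# RRI cleaning rules
RRI_ABS_MIN = 0.5  # s
RRI_ABS_MAX = 1.5  # s
RRI_REL_LOW = 0.6  # x mean of 10 preceding retained values
RRI_REL_HIGH = 1.4
RRI_HISTORY = 10

SBP_FAILURE_MMHG = 50.0  # SBP below this is a measurement failure


# ---------------------------------------------------------------------------
# Types


@dataclasses.dataclass
class BeatSeries:
    """Beat-by-beat physiological samples.

    ``times`` are beat times in seconds (strictly increasing); ``sbp`` /
    ``dbp`` may contain NaN for beats whose pressure was not determined;
    ``rri`` is the interbeat interval ending at each beat; ``bp_valid``
    flags beats with a usable pressure reading.
    """

    times: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    rri: np.ndarray
    bp_valid: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        self.rri = np.asarray(self.rri, dtype=float)
        self.bp_valid = np.asarray(self.bp_valid, dtype=bool)
        n = self.times.size
        for name in ("sbp", "dbp", "rri", "bp_valid"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match times")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "beat_time_s": self.times,
                "sbp_mmhg": self.sbp,
                "dbp_mmhg": self.dbp,
                "rri_s": self.rri,
                "bp_valid": self.bp_valid.astype(int),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BeatSeries":
        df = pd.read_csv(path)
        return cls(
            times=df["beat_time_s"].to_numpy(),
            sbp=df["sbp_mmhg"].to_numpy(),
            dbp=df["dbp_mmhg"].to_numpy(),
            rri=df["rri_s"].to_numpy(),
            bp_valid=df["bp_valid"].to_numpy().astype(bool),
        )


@dataclasses.dataclass
class CleaningReport:
    """Itemised record of RRI artifact removal."""

    n_input: int
    n_removed_absolute: int
    n_removed_relative: int
    removed: list  # (index, reason, value)

    @property
    def n_removed(self) -> int:
        return self.n_removed_absolute + self.n_removed_relative

    @property
    def removal_fraction(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


@dataclasses.dataclass
class SegmentValidity:
    bp_valid: bool
    rri_valid: bool
    bp_failure_fraction: float
    rri_removal_fraction: float


@dataclasses.dataclass
class SpectralSummary:
    """Band-power summary of one validated recording segment."""

    sbp_lf_power: float  # (mm Hg)²
    rri_lf_power: float  # s²
    rri_hf_power: float  # s²
    segment_length: float  # s

    @property
    def rri_lf_hf_ratio(self) -> float:
        if self.rri_hf_power <= 0:
            raise ZeroDivisionError("LF/HF undefined: HF power is zero")
        return self.rri_lf_power / self.rri_hf_power


# ---------------------------------------------------------------------------
# Cuff measurements


def compute_map(sbp, dbp):
    """Mean arterial pressure: MAP = DBP + (SBP − DBP)/3. Vectorised."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.any(sbp < dbp):
        raise ValueError("SBP must be >= DBP")
    if np.any(dbp <= 0):
        raise ValueError("pressures must be positive")
    out = dbp + (sbp - dbp) / 3.0
    return float(out) if out.ndim == 0 else out


def value_of_day(measurements: Sequence[Sequence[float]]) -> dict:
    """Mean of the three same-morning cuff readings.

    ``measurements`` is exactly three (SBP, DBP, HR) triplets; returns a
    dict with the mean sbp, dbp, hr and the derived MAP of the means.
    """
    m = np.asarray(measurements, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"a value of the day needs exactly 3 (SBP, DBP, HR) rows, got {m.shape}")
    if np.any(~np.isfinite(m)):
        raise ValueError("malformed measurement row (non-finite value)")
    sbp, dbp, hr = m.mean(axis=0)
    return {"sbp": float(sbp), "dbp": float(dbp), "hr": float(hr),
            "map": compute_map(sbp, dbp)}


def value_of_week(day_values: Sequence[dict], min_days: int = 3) -> dict:
    """Mean of the daily values over one week.

    Defined only when values were recorded on at least ``min_days`` days;
    otherwise returns ``{"defined": False, ...}`` rather than raising.
    """
    if len(day_values) < min_days:
        return {"defined": False, "n_days": len(day_values)}
    keys = ("sbp", "dbp", "hr", "map")
    out = {k: float(np.mean([d[k] for d in day_values])) for k in keys}
    out.update(defined=True, n_days=len(day_values))
    return out


def weekly_values(cuff_log: pd.DataFrame, min_days: int = 3) -> pd.DataFrame:
    """Aggregate a cuff log (date, slot, sbp, dbp, hr) into weekly values.

    Each date must carry exactly three slots. Weeks are ISO weeks of the
    measurement date; weeks with fewer than ``min_days`` recorded days get
    ``defined = False`` and NaN summaries.
    """
    df = cuff_log.copy()
    df["date"] = pd.to_datetime(df["date"])
    days = []
    for date, grp in df.groupby("date"):
        if len(grp) != 3:
            raise ValueError(f"date {date.date()} has {len(grp)} measurements; expected 3")
        day = value_of_day(grp[["sbp", "dbp", "hr"]].to_numpy())
        iso = date.isocalendar()
        days.append({"date": date, "week": f"{iso.year}-W{iso.week:02d}", **day})
    day_df = pd.DataFrame(days)
    rows = []
    for week, grp in day_df.groupby("week"):
        wk = value_of_week(grp.to_dict("records"), min_days=min_days)
        rows.append({"week": week, "n_days": wk["n_days"], "defined": wk["defined"],
                     **{k: wk.get(k, np.nan) for k in ("sbp", "dbp", "hr", "map")}})
    return pd.DataFrame(rows).sort_values("week").reset_index(drop=True)


# ---------------------------------------------------------------------------
# RRI cleaning


def clean_rri(rri: Sequence[float]) -> tuple[np.ndarray, CleaningReport]:
    """Two-pass RRI artifact rejection.

    Pass 1 removes absolute outliers (< 0.5 s or > 1.5 s). Pass 2 scans
    the survivors in order and removes any value outside 0.6–1.4 × the
    mean of the 10 immediately preceding *retained* values; the first 10
    retained values have insufficient history and are exempt. The order
    (absolute rule first) matters and is fixed.
    """
    rri = np.asarray(rri, dtype=float)
    if rri.size == 0:
        raise ValueError("empty RRI series")
    removed: list[tuple[int, str, float]] = []

    pass1_idx = []
    for i, v in enumerate(rri):
        if v < RRI_ABS_MIN or v > RRI_ABS_MAX:
            removed.append((i, "absolute", float(v)))
        else:
            pass1_idx.append(i)
    n_abs = len(removed)

    retained: list[int] = []
    for i in pass1_idx:
        v = rri[i]
        if len(retained) >= RRI_HISTORY:
            ref = float(np.mean(rri[retained[-RRI_HISTORY:]]))
            if not (RRI_REL_LOW * ref <= v <= RRI_REL_HIGH * ref):
                removed.append((i, "relative", float(v)))
                continue
        retained.append(i)

    report = CleaningReport(
        n_input=int(rri.size),
        n_removed_absolute=n_abs,
        n_removed_relative=len(removed) - n_abs,
        removed=sorted(removed),
    )
    return rri[retained], report


def clean_beat_series(series: BeatSeries) -> tuple[BeatSeries, CleaningReport]:
    """Apply ``clean_rri`` to a beat series, keeping aligned beat times."""
    cleaned, report = clean_rri(series.rri)
    removed_idx = {i for i, _, _ in report.removed}
    keep = np.array([i not in removed_idx for i in range(len(series))])
    return (
        BeatSeries(
            times=series.times[keep],
            sbp=series.sbp[keep],
            dbp=series.dbp[keep],
            rri=series.rri[keep],
            bp_valid=series.bp_valid[keep],
        ),
        report,
    )


# ---------------------------------------------------------------------------
# Segment validity


def validate_segment(
    series: BeatSeries,
    window: float = 300.0,
    bp_fail_max: float = 0.04,
    rri_removed_max: float = 0.10,
) -> SegmentValidity:
    """Apply the per-segment validity rules to the last ``window`` seconds.

    A beat's pressure reading fails if it is flagged invalid, missing, or
    its SBP is below 50 mm Hg; the segment's BP channel fails when the
    summed duration of failed beats exceeds 4% of the window. The RRI
    channel fails when the cleaning removal fraction exceeds 10%. Both
    bounds are strict: exactly 4% / 10% still passes.
    """
    if series.duration < window:
        raise ValueError(f"series covers {series.duration:.1f} s < window {window} s")
    t_end = series.times[-1]
    # a beat belongs to the window when its interbeat interval lies inside it
    in_win = series.times > t_end - window

    failed = (~series.bp_valid) | ~np.isfinite(series.sbp) | (series.sbp < SBP_FAILURE_MMHG)
    fail_time = float(np.sum(series.rri[in_win & failed]))
    bp_fraction = fail_time / window

    _, report = clean_rri(series.rri[in_win])
    rri_fraction = report.removal_fraction

    return SegmentValidity(
        bp_valid=bp_fraction <= bp_fail_max,
        rri_valid=rri_fraction <= rri_removed_max,
        bp_failure_fraction=bp_fraction,
        rri_removal_fraction=rri_fraction,
    )


# ---------------------------------------------------------------------------
# Spectral analysis


def band_power(
    times: Sequence[float],
    values: Sequence[float],
    band: tuple[float, float],
    analysis_window: float = 256.0,
    resample_hz: float = 4.0,
    total_window: float = 300.0,
    right_closed: bool = False,
) -> float:
    """Band power of an unevenly sampled beat series.

    The central ``analysis_window`` seconds of the last ``total_window``
    seconds are resampled to a uniform ``resample_hz`` grid by cubic
    interpolation, mean-removed, Hanning-windowed (with 1/mean(w²) power
    compensation) and integrated over ``band`` on the one-sided
    periodogram. For a pure sinusoid of amplitude a whose frequency lies
    inside the band this returns a²/2 up to leakage. The lower band edge
    is inclusive; the upper edge is inclusive only if ``right_closed``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    times, values = times[ok], values[ok]
    if times.size < 4:
        raise ValueError("too few beats for spectral analysis")

    t_end = times[-1]
    t0 = t_end - total_window + (total_window - analysis_window) / 2.0
    t1 = t0 + analysis_window
    if times[0] > t0 or t_end < t1:
        raise ValueError("series does not span the analysis window")

    in_win = (times >= t0 - 5.0) & (times <= t1 + 5.0)
    if np.median(np.diff(times[in_win])) > 1.0 / (2.0 * band[1]):
        raise ValueError("beat rate too low to resolve the requested band")

    n = int(round(analysis_window * resample_hz))
    grid = t0 + np.arange(n) / resample_hz
    f = interpolate.interp1d(times, values, kind="cubic", assume_sorted=True)
    x = f(grid)
    x = x - x.mean()

    w = np.hanning(n)
    spec = np.fft.rfft(x * w)
    freqs = np.fft.rfftfreq(n, d=1.0 / resample_hz)
    lo, hi = band
    mask = (freqs >= lo) & ((freqs <= hi) if right_closed else (freqs < hi))
    mask &= freqs > 0
    # Parseval normalisation: sum over one-sided band of 2|X|²/(N Σw²)
    return float(2.0 * np.sum(np.abs(spec[mask]) ** 2) / (n * np.sum(w**2)))


def spectral_summary(
    series: BeatSeries,
    analysis_window: float = 256.0,
    resample_hz: float = 4.0,
    total_window: float = 300.0,
) -> SpectralSummary:
    """LF power of SBP and LF/HF band powers of RRI for one segment.

    The RRI tachogram is cleaned first and interpolated over time (not
    beat index) so SBP and RRI share a frequency axis; SBP uses only
    beats with a valid pressure reading.
    """
    cleaned, _ = clean_beat_series(series)
    kwargs = dict(
        analysis_window=analysis_window,
        resample_hz=resample_hz,
        total_window=total_window,
    )
    bp_ok = cleaned.bp_valid & np.isfinite(cleaned.sbp)
    sbp_lf = band_power(cleaned.times[bp_ok], cleaned.sbp[bp_ok], LF_BAND, **kwargs)
    rri_lf = band_power(cleaned.times, cleaned.rri, LF_BAND, **kwargs)
    rri_hf = band_power(cleaned.times, cleaned.rri, HF_BAND, right_closed=True, **kwargs)
    return SpectralSummary(
        sbp_lf_power=sbp_lf,
        rri_lf_power=rri_lf,
        rri_hf_power=rri_hf,
        segment_length=analysis_window,
    )


# ---------------------------------------------------------------------------
# Baseline normalisation and period aggregation


def normalize_to_baseline(
    begin_values: Sequence[float], end_values: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Scale begin/end values so the mean of the begin period is 1."""
    begin = np.asarray(begin_values, dtype=float)
    end = np.asarray(end_values, dtype=float)
    scale = begin.mean()
    if not np.isfinite(scale) or scale == 0:
        raise ValueError("begin-period mean is zero or non-finite")
    return begin / scale, end / scale


def period_mean(
    session_values: Sequence[float], min_sessions: int = 4
) -> tuple[float, bool]:
    """Per-participant mean over the (up to five) sessions of one period.

    Returns (mean, ok). ``ok`` is False when fewer than ``min_sessions``
    valid sessions are available, in which case the participant should be
    excluded from group statistics (the threshold is configurable for the
    documented single-case exception of three sessions).
    """
    vals = np.asarray(session_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), False
    return float(vals.mean()), vals.size >= min_sessions
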