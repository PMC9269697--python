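"""Windowed feature extraction from indoor and outdoor sample streams.

Raw streams are cut into fixed, non-overlapping windows (10 s indoors at
the 1.6 Hz tag rate, 40 min outdoors at the minutes-scale GPS rate) and
each window is summarised into one feature row:

* indoor — nine accelerometer statistics (mean, median, standard
  deviation, excess kurtosis, skewness, number of peaks, signal energy,
  signal magnitude area, average resultant acceleration), the distance
  travelled and the average speed derived from the tag positions, the
  modal zone (cluster) id and the modal mood state;
* outdoor — distance travelled and estimated speed from projected
  positions, mean speed over ground (knots converted to m/s), circular
  mean course, and the modal place-cluster id.

Per-axis statistics are averaged across the three axes into one value per
feature. Mean/median/SD/kurtosis/skewness use the per-axis samples; SMA,
energy and average resultant acceleration are defined on the per-sample
vector norm / absolute sums as usual in activity recognition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .geometry import knots_to_mps, path_distance, to_local_xy
from .io_formats import IndoorSample, OutdoorSample

INDOOR_WINDOW_S = 10.0
OUTDOOR_WINDOW_S = 2400.0  # 40 min

#: Fraction of the expected sample count a trailing partial window must
#: exceed (strictly) to be kept.
MIN_WINDOW_OCCUPANCY = 0.5

#: Peak prominence threshold, as a multiple of the within-window SD of the
#: resultant acceleration. Scale-free: louder signals need taller peaks.
PEAK_PROMINENCE_SD = 0.5

ACCEL_FEATURES = (
    "accel_mean", "accel_median", "accel_std", "accel_kurtosis",
    "accel_skewness", "accel_n_peaks", "accel_energy", "accel_sma",
    "accel_avg_resultant",
)

INDOOR_FEATURE_COLUMNS = (
    "user_id", "window_start", "window_end", *ACCEL_FEATURES,
    "avg_distance", "avg_speed", "cluster_id", "emotion",
)
OUTDOOR_FEATURE_COLUMNS = (
    "user_id", "window_start", "window_end", "avg_distance",
    "avg_estimated_speed", "speed_over_ground", "avg_course", "cluster_id",
)


@dataclass(frozen=True)
class Window:
    """One fixed-length window of samples for a single user."""

    user_id: int
    start: float
    end: float
    samples: tuple

    def __post_init__(self) -> None:
        for s in self.samples:
            t = _sample_time(s)
            if not (self.start <= t < self.end):
                raise ValueError(
                    f"sample at {t} outside window [{self.start}, {self.end})"
                )


def _sample_time(sample) -> float:
    if isinstance(sample, IndoorSample):
        return sample.timestamp
    if isinstance(sample, OutdoorSample):
        return sample.epoch
    return float(sample[0])  # (t, ...) tuples


def make_windows(
    samples: Sequence,
    length: float,
    user_id: int = 0,
    domain: Literal["indoor", "outdoor"] = "indoor",
) -> list[Window]:
    """Cut a time-sorted stream into contiguous, non-overlapping windows.

    Windows are anchored at the first sample's timestamp. The trailing
    partial window is kept only when it holds strictly more than half the
    samples a full window would (occupancy inferred from the median
    sampling interval), so a 35 s stream at a 10 s window yields exactly
    three windows.
    """
    if not samples:
        return []
    if length <= 0:
        raise ValueError("window length must be positive")
    times = np.array([_sample_time(s) for s in samples], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError(f"{domain} samples must be time-sorted")
    t0 = times[0]
    idx = np.floor((times - t0) / length).astype(int)
    n_windows = int(idx.max()) + 1
    if len(times) > 1:
        median_dt = float(np.median(np.diff(times)))
        expected = length / median_dt if median_dt > 0 else len(times)
    else:
        expected = 1.0
    # samples are sorted, so window membership is a run of consecutive indices
    bounds = np.searchsorted(idx, np.arange(n_windows + 1))
    windows: list[Window] = []
    for w in range(n_windows):
        members = tuple(samples[bounds[w]:bounds[w + 1]])
        if w == n_windows - 1 and n_windows > 1:
            # trailing partial window: keep only if strictly more than half full
            if len(members) / expected <= MIN_WINDOW_OCCUPANCY + 1e-12:
                break
        windows.append(
            Window(
                user_id=user_id,
                start=float(t0 + w * length),
                end=float(t0 + (w + 1) * length),
                samples=members,
            )
        )
    return windows


def accel_statistics(window: Window, average_axes: bool = True) -> dict[str, float]:
    """The nine per-window accelerometer statistics.

    Mean, median, population SD, Fisher (excess) kurtosis and adjusted
    skewness are computed per axis then averaged across the three axes
    (``average_axes=False`` keeps the per-axis values as ``*_x/_y/_z``
    keys instead). Zero-variance axes report skewness 0 and kurtosis 0
    rather than NaN. SMA = mean of |ax|+|ay|+|az|; energy = mean of
    ax²+ay²+az²; average resultant acceleration = mean of √(ax²+ay²+az²).
    Peaks are local maxima of the resultant magnitude with prominence
    ≥ 0.5 × its SD.
    """
    accel = np.array([s.accel for s in window.samples], dtype=float)
    if accel.shape[0] < 2:
        raise ValueError("accelerometer statistics need at least 2 samples")
    per_axis_sd = accel.std(axis=0)
    # scipy warns about precision on (near-)constant axes; those moments are
    # overwritten by the zero-variance convention below
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = stats.skew(accel, axis=0)
        kurt = stats.kurtosis(accel, axis=0)  # Fisher: normal → 0
    skew = np.where(per_axis_sd > 0, skew, 0.0)
    kurt = np.where(per_axis_sd > 0, kurt, 0.0)
    resultant = np.linalg.norm(accel, axis=1)
    res_sd = float(resultant.std())
    if res_sd > 0:
        peaks, _ = signal.find_peaks(resultant, prominence=PEAK_PROMINENCE_SD * res_sd)
        n_peaks = int(len(peaks))
    else:
        n_peaks = 0
    per_axis = {
        "accel_mean": accel.mean(axis=0),
        "accel_median": np.median(accel, axis=0),
        "accel_std": per_axis_sd,
        "accel_kurtosis": kurt,
        "accel_skewness": skew,
    }
    if average_axes:
        out = {k: float(v.mean()) for k, v in per_axis.items()}
    else:
        out = {
            f"{k}_{ax}": float(v[i])
            for k, v in per_axis.items()
            for i, ax in enumerate("xyz")
        }
    out.update(
        {
            "accel_n_peaks": n_peaks,
            "accel_energy": float((accel ** 2).sum(axis=1).mean()),
            "accel_sma": float(np.abs(accel).sum(axis=1).mean()),
            "accel_avg_resultant": float(resultant.mean()),
        }
    )
    return out


def window_mobility(
    window: Window, positions: np.ndarray | None = None
) -> tuple[float, float]:
    """(distance travelled, average speed) over one window.

    ``positions`` is an (n, 2) array of local-frame metres aligned with the
    window's samples. Average speed is the window-total distance divided by
    the window length, so speed × length ≡ distance by construction.
    """
    if positions is None or len(positions) == 0:
        raise ValueError("window has no positions")
    dist = path_distance(np.asarray(positions, dtype=float))
    length = window.end - window.start
    return dist, dist / length


def modal_category(values: Sequence) -> object:
    """Most frequent value; ties broken by earliest first occurrence."""
    values = list(values)
    if not values:
        raise ValueError("modal_category needs a non-empty sequence")
    counts: dict = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    for v in values:  # first occurrence order resolves ties
        if counts[v] == best:
            return v
    raise AssertionError("unreachable")


def _circular_mean_deg(degrees: np.ndarray) -> float:
    """Vector mean of unit headings, in [0, 360)."""
    rad = np.radians(np.asarray(degrees, dtype=float))
    ang = float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0)
    return 0.0 if ang >= 360.0 else ang  # guard the -0.0 % 360 == 360.0 edge


def indoor_feature_rows(
    samples: Sequence[IndoorSample],
    user_id: int,
    window_s: float = INDOOR_WINDOW_S,
    use_z: bool = False,
) -> pd.DataFrame:
    """Per-window indoor feature table: 9 accelerometer statistics, distance,
    speed, modal zone id and modal mood.

    Tag coordinates arrive in millimetres and are converted to metres;
    distance uses the planar x-y coordinates unless ``use_z`` is set.
    """
    windows = make_windows(samples, window_s, user_id=user_id, domain="indoor")
    rows = []
    for w in windows:
        if len(w.samples) < 2:
            continue  # flagged: too sparse for statistics
        dims = 3 if use_z else 2
        pos_m = np.array([s.coords[:dims] for s in w.samples], dtype=float) / 1000.0
        dist, speed = window_mobility(w, pos_m)
        row = {
            "user_id": user_id,
            "window_start": w.start,
            "window_end": w.end,
            **accel_statistics(w),
            "avg_distance": dist,
            "avg_speed": speed,
            "cluster_id": modal_category(
                [s.zones[0][0] if s.zones else -1 for s in w.samples]
            ),
            "emotion": modal_category([s.status for s in w.samples]),
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=list(INDOOR_FEATURE_COLUMNS))


def outdoor_feature_rows(
    samples: Sequence[OutdoorSample],
    user_id: int,
    ref: tuple[float, float] | None = None,
    window_s: float = OUTDOOR_WINDOW_S,
    cluster_ids: Sequence[int] | None = None,
    speed_method: Literal["window_total", "fix_to_fix"] = "window_total",
) -> pd.DataFrame:
    """Per-window outdoor feature table.

    Invalid ('V') fixes are excluded before windowing. Each window yields
    the projected path distance, the estimated speed, the mean GPS speed
    over ground converted from knots to m/s, the circular mean course and
    the modal place-cluster id (if cluster assignments are supplied;
    otherwise -1). Estimated speed defaults to window distance over window
    length; ``fix_to_fix`` instead averages the per-segment displacement
    speeds between consecutive fixes.
    """
    from .geometry import nmea_to_decimal  # local import avoids cycle at module load

    if cluster_ids is not None and len(cluster_ids) != len(samples):
        raise ValueError("cluster_ids must align with samples")
    pairs = [
        (s, (cluster_ids[i] if cluster_ids is not None else -1))
        for i, s in enumerate(samples)
        if s.valid
    ]
    if not pairs:
        return pd.DataFrame(columns=list(OUTDOOR_FEATURE_COLUMNS))
    valid = [s for s, _ in pairs]
    cids = [c for _, c in pairs]
    lats = [nmea_to_decimal(s.lat_raw, s.ns) for s in valid]
    lons = [nmea_to_decimal(s.lon_raw, s.ew) for s in valid]
    if ref is None:
        ref = (float(np.mean(lats)), float(np.mean(lons)))
    pts = [to_local_xy(la, lo, ref) for la, lo in zip(lats, lons)]
    xy = np.array([[p.x, p.y] for p in pts])

    windows = make_windows(valid, window_s, user_id=user_id, domain="outdoor")
    time_of = {id(s): i for i, s in enumerate(valid)}
    rows = []
    for w in windows:
        idx = [time_of[id(s)] for s in w.samples]
        if not idx:
            continue
        dist, speed = window_mobility(w, xy[idx])
        if speed_method == "fix_to_fix" and len(idx) > 1:
            ts = np.array([valid[i].epoch for i in idx])
            seg = np.linalg.norm(np.diff(xy[idx], axis=0), axis=1)
            dts = np.diff(ts)
            ok = dts > 0
            if ok.any():
                speed = float(np.mean(seg[ok] / dts[ok]))
        sog = float(np.mean([knots_to_mps(valid[i].speed_kn) for i in idx]))
        rows.append(
            {
                "user_id": user_id,
                "window_start": w.start,
                "window_end": w.end,
                "avg_distance": dist,
                "avg_estimated_speed": speed,
                "speed_over_ground": sog,
                "avg_course": _circular_mean_deg(
                    np.array([valid[i].course_deg for i in idx])
                ),
                "cluster_id": modal_category([cids[i] for i in idx]),
            }
        )
    return pd.DataFrame(rows, columns=list(OUTDOOR_FEATURE_COLUMNS))


def build_feature_table(
    indoor: dict[int, Sequence[IndoorSample]] | None = None,
    outdoor: dict[int, Sequence[OutdoorSample]] | None = None,
    outdoor_cluster_ids: dict[int, Sequence[int]] | None = None,
    indoor_window_s: float = INDOOR_WINDOW_S,
    outdoor_window_s: float = OUTDOOR_WINDOW_S,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-user window feature tables for both domains.

    Returns ``(indoor_table, outdoor_table)``; either may be empty when the
    corresponding streams are absent. Column order is part of the schema
    and stable across runs.
    """
    indoor_frames = [
        indoor_feature_rows(stream, uid, window_s=indoor_window_s)
        for uid, stream in sorted((indoor or {}).items())
    ]
    outdoor_frames = [
        outdoor_feature_rows(
            stream,
            uid,
            window_s=outdoor_window_s,
            cluster_ids=(outdoor_cluster_ids or {}).get(uid),
        )
        for uid, stream in sorted((outdoor or {}).items())
    ]
    indoor_table = (
        pd.concat(indoor_frames, ignore_index=True)
        if indoor_frames
        else pd.DataFrame(columns=list(INDOOR_FEATURE_COLUMNS))
    )
    outdoor_table = (
        pd.concat(outdoor_frames, ignore_index=True)
        if outdoor_frames
        else pd.DataFrame(columns=list(OUTDOOR_FEATURE_COLUMNS))
    )
    return indoor_table, outdoor_table
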