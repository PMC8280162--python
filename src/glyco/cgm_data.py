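"""Reading, cleaning, windowing, and labeling of CGM glucose series.

A continuous glucose monitor reports interstitial glucose every 5 minutes in
mg/dL. This module turns raw per-patient traces into model-ready segments:
a 30-minute input window (7 consecutive readings) paired with the reading one
prediction horizon after the window, labeled by glycemic class. Hypoglycemia
is defined as BG < 80 mg/dL (the threshold offsets a ~10 mg/dL real-time CGM
underestimation artifact near the low range), hyperglycemia as BG > 180 mg/dL,
and normoglycemia as the inclusive band between them.

Missing readings are never imputed: any candidate segment whose input window
or target touches a gap is discarded.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace
from datetime import datetime
from enum import IntEnum

import numpy as np
import pandas as pd

SAMPLE_MINUTES = 5
#: samples in a 30-min input window: 30/5 + 1 endpoints
DEFAULT_INPUT_MINUTES = 30
HYPO_THRESHOLD = 80.0
HYPER_THRESHOLD = 180.0
SENSOR_MIN = 40.0
SENSOR_MAX = 400.0
#: samples further than this from the 5-min grid are treated as missing
GRID_TOLERANCE_SECONDS = 90.0


class GlycemicLabel(IntEnum):
    HYPO = 0
    NORMO = 1
    HYPER = 2


class BinaryLabel(IntEnum):
    NO_HYPO = 0
    HYPO = 1


@dataclass
class GlucoseSeries:
    """One patient's CGM trace on a 5-minute grid.

    ``values`` holds glucose in mg/dL times ``scale`` (``scale`` is 1.0 for raw
    data, 0.01 after model rescaling), with NaN at missing grid points;
    ``gap_mask`` is True where a reading is absent.
    """

    patient_id: str
    values: np.ndarray
    gap_mask: np.ndarray
    start_time: datetime | None = None
    scale: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.values.shape != self.gap_mask.shape or self.values.ndim != 1:
            raise ValueError("values and gap_mask must be 1-D arrays of equal length")
        if np.isnan(self.values[~self.gap_mask]).any():
            raise ValueError("non-gap samples must not be NaN")
        present = self.values[~self.gap_mask] / self.scale
        if present.size and (present.min() < SENSOR_MIN or present.max() > SENSOR_MAX):
            raise ValueError(
                f"glucose outside sensor range [{SENSOR_MIN:g}, {SENSOR_MAX:g}] mg/dL"
            )

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def timestamps_minutes(self) -> np.ndarray:
        """Minutes since the first sample, on the nominal 5-min grid."""
        return np.arange(len(self)) * float(SAMPLE_MINUTES)

    @property
    def values_mgdl(self) -> np.ndarray:
        return self.values / self.scale


@dataclass
class SegmentSet:
    """A batch of (input window, horizon target) training/testing units.

    ``inputs`` is (n, window) and ``targets`` (n,), both in mg/dL times
    ``scale``. ``start_indices`` are grid indices of each window's first
    sample within its source series, used for leakage-free chronological
    splits. ``labels`` are GlycemicLabel / BinaryLabel integer codes (or None
    before :func:`assign_labels`).
    """

    inputs: np.ndarray
    targets: np.ndarray
    horizon_minutes: int
    patient_ids: np.ndarray
    start_indices: np.ndarray
    labels: np.ndarray | None = None
    scheme: str | None = None
    scale: float = 1.0

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=np.float64)
        self.targets = np.asarray(self.targets, dtype=np.float64)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.start_indices = np.asarray(self.start_indices, dtype=np.int64)
        if self.inputs.ndim != 2 or len(self.inputs) != len(self.targets):
            raise ValueError("inputs must be (n, window) aligned with targets")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @property
    def window(self) -> int:
        return self.inputs.shape[1]

    @property
    def targets_mgdl(self) -> np.ndarray:
        return self.targets / self.scale

    @property
    def target_indices(self) -> np.ndarray:
        return self.start_indices + (self.window - 1) + self.horizon_minutes // SAMPLE_MINUTES

    def subset(self, index) -> "SegmentSet":
        return SegmentSet(
            inputs=self.inputs[index],
            targets=self.targets[index],
            horizon_minutes=self.horizon_minutes,
            patient_ids=self.patient_ids[index],
            start_indices=self.start_indices[index],
            labels=None if self.labels is None else self.labels[index],
            scheme=self.scheme,
            scale=self.scale,
        )

    @staticmethod
    def concat(sets: list["SegmentSet"]) -> "SegmentSet":
        if not sets:
            raise ValueError("cannot concatenate an empty list of segment sets")
        first = sets[0]
        for s in sets[1:]:
            if s.horizon_minutes != first.horizon_minutes or s.scale != first.scale:
                raise ValueError("segment sets differ in horizon or units")
        has_labels = all(s.labels is not None for s in sets)
        return SegmentSet(
            inputs=np.concatenate([s.inputs for s in sets]),
            targets=np.concatenate([s.targets for s in sets]),
            horizon_minutes=first.horizon_minutes,
            patient_ids=np.concatenate([s.patient_ids for s in sets]),
            start_indices=np.concatenate([s.start_indices for s in sets]),
            labels=np.concatenate([s.labels for s in sets]) if has_labels else None,
            scheme=first.scheme if has_labels else None,
            scale=first.scale,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {f"bg_{i}": self.inputs[:, i] for i in range(self.window)}
        cols["target"] = self.targets
        cols["horizon_minutes"] = self.horizon_minutes
        cols["patient_id"] = self.patient_ids
        cols["start_index"] = self.start_indices
        if self.labels is not None:
            enum = GlycemicLabel if self.scheme == "three_class" else BinaryLabel
            cols["label"] = [enum(v).name for v in self.labels]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _series_from_samples(patient_id: str, minutes: np.ndarray,
                         values: np.ndarray, start_time=None) -> GlucoseSeries:
    """Snap irregular sample times onto the 5-min grid anchored at the first
    sample; samples deviating more than the grid tolerance become gaps."""
    minutes = np.asarray(minutes, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    rel = minutes - minutes[0]
    idx = np.rint(rel / SAMPLE_MINUTES).astype(np.int64)
    deviation_s = np.abs(rel - idx * SAMPLE_MINUTES) * 60.0
    keep = deviation_s <= GRID_TOLERANCE_SECONDS
    idx, values = idx[keep], values[keep]
    if idx.size == 0:
        raise ValueError(f"patient {patient_id!r}: no samples on the 5-min grid")
    n = int(idx[-1]) + 1
    grid = np.full(n, np.nan)
    grid[idx] = values
    gap = np.ones(n, dtype=bool)
    gap[idx] = False
    return GlucoseSeries(patient_id=str(patient_id), values=grid, gap_mask=gap,
                         start_time=start_time)


def _check_values(values: np.ndarray, where: str) -> None:
    bad = values[(values < 1.0) | (values > 1000.0)]
    if bad.size:
        raise ValueError(
            f"{where}: glucose value {bad[0]:g} outside [1, 1000] — wrong units?")
    bad = values[(values < SENSOR_MIN) | (values > SENSOR_MAX)]
    if bad.size:
        raise ValueError(
            f"{where}: glucose value {bad[0]:g} outside CGM sensor range "
            f"[{SENSOR_MIN:g}, {SENSOR_MAX:g}] mg/dL")


def read_cgm_csv(path) -> list[GlucoseSeries]:
    """Read a per-patient CGM CSV with columns patient_id, timestamp,
    glucose_mgdl (timestamp ISO-8601 or numeric minutes)."""
    df = pd.read_csv(path)
    required = {"patient_id", "timestamp", "glucose_mgdl"}
    if not required.issubset(df.columns):
        raise ValueError(f"CGM CSV must have columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError("CGM CSV is empty")

    values = pd.to_numeric(df["glucose_mgdl"], errors="coerce")
    if values.isna().any():
        row = int(values.index[values.isna()][0])
        raise ValueError(f"row {row}: malformed glucose value {df['glucose_mgdl'][row]!r}")
    _check_values(values.to_numpy(float), "CGM CSV")

    ts_numeric = pd.to_numeric(df["timestamp"], errors="coerce")
    if ts_numeric.notna().all():
        minutes = ts_numeric.to_numpy(float)
        starts = {pid: None for pid in df["patient_id"].unique()}
    else:
        parsed = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
        if parsed.isna().any():
            row = int(parsed.index[parsed.isna()][0])
            raise ValueError(f"row {row}: malformed timestamp {df['timestamp'][row]!r}")
        minutes = parsed.astype("int64").to_numpy() / 60e9
        starts = None

    series = []
    for pid in pd.unique(df["patient_id"]):
        sel = (df["patient_id"] == pid).to_numpy()
        m = minutes[sel]
        if np.any(np.diff(m) <= 0):
            rows = np.flatnonzero(sel)
            bad = int(rows[1:][np.diff(m) <= 0][0])
            raise ValueError(f"row {bad}: non-monotone timestamp for patient {pid!r}")
        start = None
        if starts is None:
            start = pd.to_datetime(df["timestamp"][np.flatnonzero(sel)[0]]).to_pydatetime()
        series.append(_series_from_samples(pid, m, values.to_numpy(float)[sel], start))
    return series


def write_cgm_csv(series_list: list[GlucoseSeries], path) -> None:
    """Write series (raw mg/dL) in the dialect :func:`read_cgm_csv` reads."""
    frames = []
    for s in series_list:
        present = ~s.gap_mask
        frames.append(pd.DataFrame({
            "patient_id": s.patient_id,
            "timestamp": s.timestamps_minutes[present],
            "glucose_mgdl": s.values_mgdl[present],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


_OHIO_TS_FORMATS = ("%d-%m-%Y %H:%M:%S", "%Y-%m-%d %H:%M:%S")


def read_ohio_xml(path) -> GlucoseSeries:
    """Extract the glucose channel from an OhioT1DM-dialect XML file.

    Only ``glucose_level/event`` elements are read; insulin, meal, exercise
    and other channels are ignored.
    """
    root = ET.parse(path).getroot()
    glucose = root.find(".//glucose_level")
    if glucose is None:
        raise ValueError(f"{path}: no glucose_level element")
    times, values = [], []
    for event in glucose.findall("event"):
        ts, val = event.get("ts"), event.get("value")
        if ts is None or val is None:
            raise ValueError(f"{path}: glucose event missing ts/value")
        for fmt in _OHIO_TS_FORMATS:
            try:
                t = datetime.strptime(ts, fmt)
                break
            except ValueError:
                t = None
        if t is None:
            raise ValueError(f"{path}: unparseable timestamp {ts!r}")
        times.append(t)
        values.append(float(val))
    if not times:
        raise ValueError(f"{path}: glucose_level element has no events")
    values = np.asarray(values, dtype=np.float64)
    _check_values(values, str(path))
    minutes = np.array([(t - times[0]).total_seconds() / 60.0 for t in times])
    if np.any(np.diff(minutes) <= 0):
        raise ValueError(f"{path}: non-monotone glucose timestamps")
    pid = root.get("id", "ohio")
    return _series_from_samples(pid, minutes, values, times[0])


# ---------------------------------------------------------------------------
# cleaning and rescaling
# ---------------------------------------------------------------------------

def smooth(series: GlucoseSeries, window_samples: int = 3) -> GlucoseSeries:
    """Centered moving-median filter removing isolated spikes (e.g. from
    patient movement) without lag.

    Missing samples are excluded from each window; positions whose centered
    window does not fit inside the series are left unchanged; output gaps
    equal input gaps.
    """
    if window_samples < 1 or window_samples % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window_samples == 1:
        return replace(series, values=series.values.copy(),
                       gap_mask=series.gap_mask.copy())
    half = window_samples // 2
    out = series.values.copy()
    v = series.values
    for i in range(half, len(series) - half):
        if series.gap_mask[i]:
            continue
        win = v[i - half:i + half + 1]
        win = win[~np.isnan(win)]
        out[i] = np.median(win)
    return replace(series, values=out, gap_mask=series.gap_mask.copy())


def rescale(obj, factor: float):
    """Multiply all glucose values by ``factor`` (e.g. 0.01 to put mg/dL into
    model units); exact inverse via ``rescale(x, 1/factor)``."""
    if factor <= 0:
        raise ValueError("rescale factor must be positive")
    if isinstance(obj, GlucoseSeries):
        return replace(obj, values=obj.values * factor, gap_mask=obj.gap_mask.copy(),
                       scale=obj.scale * factor)
    if isinstance(obj, SegmentSet):
        return replace(obj, inputs=obj.inputs * factor, targets=obj.targets * factor,
                       scale=obj.scale * factor)
    raise TypeError(f"cannot rescale object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# windowing, labeling, splitting
# ---------------------------------------------------------------------------

def make_segments(series: GlucoseSeries, input_minutes: int = DEFAULT_INPUT_MINUTES,
                  horizon_minutes: int = 30, stride_minutes: int = 5) -> SegmentSet:
    """Slide a window over the series and pair it with the reading one
    horizon later.

    The window covers ``input_minutes/5 + 1`` samples (both endpoints of the
    span), so 30 min yields 7 values. Candidates whose window or target
    touches a gap are discarded. A series too short for a single window
    yields an empty set.
    """
    for name, m in (("input_minutes", input_minutes),
                    ("horizon_minutes", horizon_minutes),
                    ("stride_minutes", stride_minutes)):
        if m <= 0 or m % SAMPLE_MINUTES != 0:
            raise ValueError(f"{name} must be a positive multiple of {SAMPLE_MINUTES}")
    n_in = input_minutes // SAMPLE_MINUTES + 1
    h = horizon_minutes // SAMPLE_MINUTES
    stride = stride_minutes // SAMPLE_MINUTES
    n = len(series)
    starts, inputs, targets = [], [], []
    ok = ~series.gap_mask
    for s in range(0, n - (n_in - 1) - h, stride):
        t = s + (n_in - 1) + h
        if ok[s:s + n_in].all() and ok[t]:
            starts.append(s)
            inputs.append(series.values[s:s + n_in])
            targets.append(series.values[t])
    if not starts:
        inputs = np.empty((0, n_in))
        targets = np.empty(0)
        starts = np.empty(0, dtype=np.int64)
    return SegmentSet(
        inputs=np.asarray(inputs), targets=np.asarray(targets),
        horizon_minutes=horizon_minutes,
        patient_ids=np.full(len(starts), series.patient_id, dtype=object),
        start_indices=np.asarray(starts, dtype=np.int64),
        scale=series.scale,
    )


def classify_bg(bg_mgdl, hypo_threshold: float = HYPO_THRESHOLD,
                hyper_threshold: float = HYPER_THRESHOLD,
                scheme: str = "three_class") -> np.ndarray:
    """Map glucose in mg/dL to glycemic class codes.

    Three-class: HYPO iff BG < hypo_threshold, HYPER iff BG > hyper_threshold,
    NORMO for the inclusive band in between. Binary: HYPO (positive) iff
    BG < hypo_threshold, else NO_HYPO.
    """
    bg = np.asarray(bg_mgdl, dtype=np.float64)
    if scheme == "three_class":
        out = np.full(bg.shape, int(GlycemicLabel.NORMO), dtype=np.int64)
        out[bg < hypo_threshold] = int(GlycemicLabel.HYPO)
        out[bg > hyper_threshold] = int(GlycemicLabel.HYPER)
    elif scheme == "binary":
        out = np.where(bg < hypo_threshold, int(BinaryLabel.HYPO),
                       int(BinaryLabel.NO_HYPO)).astype(np.int64)
    else:
        raise ValueError(f"unknown labeling scheme {scheme!r}")
    return out


def assign_labels(segments: SegmentSet, hypo_threshold: float = HYPO_THRESHOLD,
                  hyper_threshold: float = HYPER_THRESHOLD,
                  scheme: str = "three_class") -> SegmentSet:
    """Label each segment by the glycemic class of its (unscaled) target."""
    labels = classify_bg(segments.targets_mgdl, hypo_threshold, hyper_threshold, scheme)
    return replace(segments, labels=labels, scheme=scheme)


def split_target_patient(segments: SegmentSet, n_train: int) -> tuple[SegmentSet, SegmentSet]:
    """Chronological train/test split of one patient's segments.

    The first ``n_train`` segments (by window start) train; test keeps only
    segments whose input window starts after the last training target, so no
    sample is shared across the boundary.
    """
    if n_train < 0:
        raise ValueError("n_train must be non-negative")
    order = np.argsort(segments.start_indices, kind="stable")
    ordered = segments.subset(order)
    n_train = min(n_train, len(ordered))
    train = ordered.subset(np.arange(n_train))
    if n_train == 0:
        return train, ordered
    boundary = train.target_indices.max()
    keep = np.flatnonzero(ordered.start_indices > boundary)
    return train, ordered.subset(keep)


def segments_duration_hours(n_segments: int, stride_minutes: int = 5) -> int:
    """Whole hours of recording spanned by ``n_segments`` consecutive windows
    at the given stride (1000 segments at a 5-min stride -> 83 h)."""
    return int(n_segments * stride_minutes // 60)
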