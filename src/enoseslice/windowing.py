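"""Time-window slicing and feature extraction.

The sensing-phase signal ([20, 200] s) is divided into n equal-span
windows (the no-window case W0 instead uses the whole [0, 260] s trace).
Two feature families are supported per gas channel and window:

* ``slice_stats`` — one of the four order statistics (max, min, mean,
  median) of the hard-sliced segment.  The median follows the positional
  convention: values sorted ascending, even N averaging the two central
  elements, odd N taking the single middle one.
* ``bell_area`` — the discrete weighted area W_i = sum_k R(t_k) K_i(t_k) dt
  under a generalized bell window K_i(t) = 1 / (1 + ((t - c_i)/a_i)^(2 b_i))
  centred at c_i with half-width a_i and shape exponent b_i (K equals 1 at
  the centre and 0.5 at c_i +/- a_i; large b_i approaches a rectangular
  window).

Feature counts follow the study convention: 8 features at W0 (one per gas
channel), 8 n + 2 at W >= 1 (per-channel per-window features plus the mean
temperature and humidity over the sampling phase) — hence 8 / 10 / 42
features at W0 / W1 / W5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocessing
from .synthetic import (
    ENV_CHANNELS,
    GAS_CHANNELS,
    RECORD_DURATION_S,
    SENSING_REGION_S,
    Dataset,
)

STATISTICS: tuple[str, ...] = ("max", "min", "mean", "median")
FEATURE_MODES: tuple[str, ...] = ("slice_stats", "bell_area")
DEFAULT_BELL_SHAPE = 5.0
DEFAULT_MAX_WINDOWS = 10


@dataclass(frozen=True)
class WindowScheme:
    """Time-slicing specification.

    ``n_windows = 0`` covers the full record with no boundaries; n >= 1
    splits the sensing region into equal spans.  ``bell_params`` holds one
    (a_i, b_i, c_i) triple per window: centre c_i at the window midpoint,
    half-width a_i = half the window span, shape b_i steep by default.
    """

    n_windows: int
    region: tuple[float, float]
    boundaries: np.ndarray | None = None
    bell_params: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self):
        if self.boundaries is not None:
            b = np.asarray(self.boundaries, dtype=float)
            object.__setattr__(self, "boundaries", b)
            if b.ndim != 1 or b.shape[0] != self.n_windows + 1:
                raise ValueError("boundaries must hold n_windows + 1 edges")
            if np.any(np.diff(b) <= 0):
                raise ValueError("boundaries must be strictly increasing")


def make_window_scheme(
    n_windows: int, max_windows: int = DEFAULT_MAX_WINDOWS
) -> WindowScheme:
    """Equal-span window scheme over the sensing region.

    n = 0 yields the full-record scheme (region [0, 260] s, no boundaries);
    n >= 1 yields n equal spans over [20, 200] s with default bell
    parameters (centre = window midpoint, half-width = half span, shape
    exponent 5).
    """
    n_windows = int(n_windows)
    if n_windows < 0:
        raise ValueError(f"n_windows must be >= 0, got {n_windows}")
    if n_windows > max_windows:
        raise ValueError(f"n_windows={n_windows} exceeds max_windows={max_windows}")
    if n_windows == 0:
        return WindowScheme(n_windows=0, region=(0.0, RECORD_DURATION_S))
    start, end = SENSING_REGION_S
    boundaries = np.linspace(start, end, n_windows + 1)
    half_span = (end - start) / n_windows / 2.0
    bell = tuple(
        (half_span, DEFAULT_BELL_SHAPE, float(boundaries[i] + half_span))
        for i in range(n_windows)
    )
    return WindowScheme(
        n_windows=n_windows, region=(start, end), boundaries=boundaries, bell_params=bell
    )


def stat_feature(values, statistic: str) -> float:
    """One of the four per-segment order statistics.

    max/min are the extrema; mean = sum(Y_t) / N; median sorts ascending
    and averages the two central values (Y_{N/2} + Y_{N/2+1}) / 2 for even
    N, taking the middle element for odd N.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute a statistic of an empty segment")
    if statistic == "max":
        return float(values.max())
    if statistic == "min":
        return float(values.min())
    if statistic == "mean":
        return float(values.sum() / values.size)
    if statistic == "median":
        y = np.sort(values)
        n = y.size
        if n % 2 == 0:
            return float((y[n // 2 - 1] + y[n // 2]) / 2.0)
        return float(y[n // 2])
    raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")


def bell_window(t, a_i: float, b_i: float, c_i: float):
    """Generalized bell weight K_i(t) = 1 / (1 + ((t - c_i)/a_i)^(2 b_i)).

    Equals 1 at the centre, 0.5 at c_i +/- a_i, symmetric, and
    monotonically decreasing in |t - c_i|.
    """
    if not a_i > 0:
        raise ValueError(f"bell half-width a_i must be > 0, got {a_i}")
    if not b_i > 0:
        raise ValueError(f"bell shape b_i must be > 0, got {b_i}")
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.abs((t - c_i) / a_i) ** (2.0 * b_i))
    return out if out.ndim else float(out)


def weighted_area_feature(
    response_values, timestamps, window_index: int, scheme: WindowScheme
) -> float:
    """Discrete weighted area W_i = sum_k R(t_k) K_i(t_k) dt.

    Linear in the response values; requires a uniform timestamp grid.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    response_values = np.asarray(response_values, dtype=float)
    if timestamps.shape != response_values.shape:
        raise ValueError("response and timestamp arrays must align")
    steps = np.diff(timestamps)
    if steps.size == 0:
        raise ValueError("need at least two samples for an area")
    dt = steps[0]
    if not np.allclose(steps, dt, rtol=0, atol=1e-9):
        raise ValueError("timestamps must be uniformly spaced")
    if scheme.bell_params is None:
        raise ValueError("scheme has no bell parameters (n_windows = 0)")
    a_i, b_i, c_i = scheme.bell_params[window_index]
    weights = bell_window(timestamps, a_i, b_i, c_i)
    return float(np.sum(response_values * weights) * dt)


@dataclass
class FeatureMatrix:
    """Samples x named features, with per-row class labels."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.feature_names = tuple(self.feature_names)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels must match the number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def p(self) -> int:
        """Feature count."""
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, indices) -> "FeatureMatrix":
        indices = np.asarray(indices)
        return FeatureMatrix(
            values=self.values[indices],
            feature_names=self.feature_names,
            labels=self.labels[indices],
            sample_ids=None if self.sample_ids is None else self.sample_ids[indices],
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.feature_names))
        frame.insert(0, "label", self.labels)
        if self.sample_ids is not None:
            frame.insert(0, "sample_id", self.sample_ids)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        frame = pd.read_csv(path, float_precision="round_trip")
        sample_ids = None
        if "sample_id" in frame.columns:
            sample_ids = frame.pop("sample_id").to_numpy()
        labels = frame.pop("label").to_numpy()
        return cls(
            values=frame.to_numpy(dtype=float),
            feature_names=tuple(frame.columns),
            labels=labels,
            sample_ids=sample_ids,
        )


def feature_count(n_windows: int) -> int:
    """8 at W0; 8 n + 2 (environmental summaries included) at W >= 1."""
    return len(GAS_CHANNELS) if n_windows == 0 else len(GAS_CHANNELS) * n_windows + 2


def window_slices(timestamps: np.ndarray, scheme: WindowScheme) -> list[np.ndarray]:
    """Boolean masks of the hard-sliced windows on ``timestamps``.

    Windows are half-open [edge_i, edge_{i+1}) except the last, which is
    closed at the region end, so every sample belongs to exactly one
    window.
    """
    if scheme.n_windows == 0:
        return [np.ones(timestamps.shape[0], dtype=bool)]
    half = 0.5 * (timestamps[1] - timestamps[0])
    masks = []
    edges = scheme.boundaries
    for i in range(scheme.n_windows):
        lo, hi = edges[i], edges[i + 1]
        if i == scheme.n_windows - 1:
            m = (timestamps >= lo - half) & (timestamps <= hi + half)
        else:
            m = (timestamps >= lo - half) & (timestamps < hi - half)
        masks.append(m)
    return masks


def extract_features(
    dataset: Dataset,
    scheme: WindowScheme,
    statistic: str = "max",
    mode: str = "slice_stats",
) -> FeatureMatrix:
    """Assemble the samples x features matrix for one scheme and statistic.

    Records are expected baseline-corrected.  ``slice_stats`` takes the
    chosen statistic of each hard-sliced segment per gas channel;
    ``bell_area`` takes the bell-weighted area per window (at W0, the plain
    rectangular area of the full trace).  For n_windows >= 1 the mean
    temperature and humidity over the sampling phase are appended.  Row
    order preserves dataset order.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {FEATURE_MODES}")
    if mode == "slice_stats" and statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    lengths = {r.n_timestamps for r in dataset}
    if len(lengths) != 1:
        raise ValueError(f"mixed-length records: {sorted(lengths)}")

    names: list[str] = []
    if scheme.n_windows == 0:
        suffix = statistic if mode == "slice_stats" else "area"
        names = [f"{ch}_{suffix}" for ch in GAS_CHANNELS]
    else:
        for w in range(scheme.n_windows):
            suffix = statistic if mode == "slice_stats" else "area"
            names.extend(f"{ch}_W{w + 1}_{suffix}" for ch in GAS_CHANNELS)
        names.extend(f"{ch}_mean" for ch in ENV_CHANNELS)

    rows = np.empty((len(dataset), len(names)))
    for r, record in enumerate(dataset):
        region_t, region_vals = preprocessing.select_sensing_region(record, scheme)
        masks = window_slices(region_t, scheme)
        feats: list[float] = []
        for w, mask in enumerate(masks):
            for c in range(len(GAS_CHANNELS)):
                if mode == "slice_stats":
                    feats.append(stat_feature(region_vals[c, mask], statistic))
                elif scheme.n_windows == 0:
                    dt = region_t[1] - region_t[0]
                    feats.append(float(region_vals[c].sum() * dt))
                else:
                    feats.append(
                        weighted_area_feature(region_vals[c], region_t, w, scheme)
                    )
        if scheme.n_windows >= 1:
            sampling = preprocessing.segment_phases(record)["sampling"]
            for e in range(len(ENV_CHANNELS)):
                feats.append(float(record.env[e, sampling].mean()))
        rows[r] = feats

    return FeatureMatrix(
        values=rows,
        feature_names=tuple(names),
        labels=dataset.labels,
        sample_ids=dataset.sample_ids,
    )
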