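"""Synthetic electronic-nose measurement generation.

Emulates an 8-channel metal-oxide-semiconductor (MOS) gas-sensor array
sniffing three classes of meat floss (beef, chicken, pork).  Each simulated
measurement spans 260 s on a 100 ms grid and follows the instrument's
three-phase protocol: a 20 s delay phase (reference air, baseline), a 120 s
sampling phase (sample headspace flows over the array; the response rises
as a first-order saturation toward a class- and channel-dependent plateau),
and a 120 s purging phase (reference air flushes the chamber; the response
decays exponentially back toward baseline).  The resulting trace has the
trapezoidal shape typical of MOS chemoresistors.

The class/channel amplitude table encodes the qualitative volatile-compound
fingerprints of the three meats as seen by this sensor family:

* all three classes share a hydrocarbon response on S1, S2, S4, S5, S7, S8
  and an alcohol response on S3;
* pork carries unique aldehydes (raising S1, S2, S5, S7, S8) and a unique
  alcohol (raising S3), so it sits well apart from the other two classes;
* chicken carries unique hydrocarbon/ether traces that nudge S1, S3, S7, S8
  (and mildly the remaining hydrocarbon channels), so beef and chicken
  overlap strongly but not perfectly.

Two dials control separability: ``separation_margin`` (how far pork's
plateau amplitudes sit from the non-pork classes on the aldehyde/alcohol
channels) and ``overlap_margin`` (how little beef and chicken differ on the
chicken-specific channels).  A temperature and a humidity trace are carried
alongside the gas channels, simulated as slowly drifting constants around
typical lab ambient conditions.

All randomness flows from a single master seed through per-record
``numpy.random.SeedSequence`` children keyed by (class index, record
index), so datasets are bit-reproducible and independent of generation
order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# --- acquisition geometry -------------------------------------------------

GAS_CHANNELS: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8")
ENV_CHANNELS: tuple[str, ...] = ("temperature", "humidity")
ALL_CHANNELS: tuple[str, ...] = GAS_CHANNELS + ENV_CHANNELS
CLASS_LABELS: tuple[str, ...] = ("beef", "chicken", "pork")

SAMPLE_PERIOD_S = 0.1
RECORD_DURATION_S = 260.0
DELAY_END_S = 20.0
SAMPLING_END_S = 140.0
SENSING_REGION_S = (20.0, 200.0)
N_TIMESTAMPS = int(round(RECORD_DURATION_S / SAMPLE_PERIOD_S)) + 1  # 2601

# --- class/channel response table ----------------------------------------

#: Plateau response of the shared volatile background, per channel (volts).
BASE_AMPLITUDE_V: dict[str, float] = {
    "S1": 1.2, "S2": 1.0, "S3": 0.9, "S4": 1.1,
    "S5": 0.8, "S6": 0.7, "S7": 1.3, "S8": 1.0,
}

#: Channels responding to the hydrocarbons shared by all three meats.
HYDROCARBON_CHANNELS: tuple[str, ...] = ("S1", "S2", "S4", "S5", "S7", "S8")
#: Channels responding to ethers, including the chicken-specific ester/ether.
ETHER_CHANNELS: tuple[str, ...] = ("S1", "S3", "S7", "S8")
#: Channels responding to the pork-specific aldehydes.
ALDEHYDE_CHANNELS: tuple[str, ...] = ("S1", "S2", "S5", "S7", "S8")
#: Channel responding to alcohols (pork carries a unique alcohol).
ALCOHOL_CHANNEL = "S3"

#: Per-class response kinetics: (rise time constant s, decay time constant s).
CLASS_KINETICS_S: dict[str, tuple[float, float]] = {
    "beef": (12.0, 25.0),
    "chicken": (14.0, 28.0),
    "pork": (10.0, 20.0),
}

DEFAULT_SEPARATION_MARGIN_V = 0.5
DEFAULT_OVERLAP_MARGIN_V = 0.1

ENV_BASELINE = {"temperature": 25.0, "humidity": 55.0}
# Environmental variability relative to the gas-channel noise scales: a few
# tenths of a degree / a couple %RH offset, drifting slowly over a record.
_ENV_OFFSET_SCALE = {"temperature": 10.0, "humidity": 100.0}
_ENV_DRIFT_SCALE = {"temperature": 10.0, "humidity": 50.0}


class UnknownClassError(ValueError):
    """Raised for a meat-class label outside {beef, chicken, pork}."""


class DatasetParseError(ValueError):
    """Raised when a long-format dataset CSV cannot be parsed.

    Attributes
    ----------
    row : int or None
        1-based data-file row (header = row 1) of the first offending value,
        when the failure is attributable to a specific row.
    """

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"{message} (row {row})")
        self.row = row


# --- domain types ---------------------------------------------------------


@dataclass(frozen=True)
class ClassProfile:
    """Plateau amplitudes and response kinetics for one meat class.

    ``amplitude``, ``rise_tau`` and ``decay_tau`` are per-gas-channel arrays
    ordered as :data:`GAS_CHANNELS`.
    """

    class_label: str
    amplitude: np.ndarray
    rise_tau: np.ndarray
    decay_tau: np.ndarray

    def __post_init__(self):
        for name in ("amplitude", "rise_tau", "decay_tau"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (len(GAS_CHANNELS),):
                raise ValueError(f"{name} must have {len(GAS_CHANNELS)} entries")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name} values must be finite and strictly positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Within-class variability of the simulated instrument.

    Parameters
    ----------
    baseline_offset_sd : float
        Per-record, per-channel baseline offset spread (V).
    additive_noise_sd : float
        White measurement noise per sample (V).
    amplitude_cv : float
        Coefficient of variation of the plateau amplitude between records
        of the same class (dimensionless).
    drift_slope_sd : float
        Spread of a per-record linear baseline drift (V/s).
    """

    baseline_offset_sd: float = 0.02
    additive_noise_sd: float = 0.02
    amplitude_cv: float = 0.06
    drift_slope_sd: float = 1e-4

    def __post_init__(self):
        for name in ("baseline_offset_sd", "additive_noise_sd", "amplitude_cv", "drift_slope_sd"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass
class MeasurementRecord:
    """One 260 s multichannel acquisition.

    ``gas`` is an (8, T) array of sensor voltages ordered as
    :data:`GAS_CHANNELS`; ``env`` is a (2, T) array holding the temperature
    (deg C) and humidity (%RH) traces.
    """

    sample_id: str
    label: str
    timestamps: np.ndarray
    gas: np.ndarray
    env: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.gas = np.asarray(self.gas, dtype=float)
        self.env = np.asarray(self.env, dtype=float)
        T = self.timestamps.shape[0]
        if self.gas.shape != (len(GAS_CHANNELS), T):
            raise ValueError("gas array must be (8, T) matching the timestamps")
        if self.env.shape != (len(ENV_CHANNELS), T):
            raise ValueError("env array must be (2, T) matching the timestamps")
        if not (np.all(np.isfinite(self.gas)) and np.all(np.isfinite(self.env))):
            raise ValueError("all channel values must be finite")

    @property
    def n_timestamps(self) -> int:
        return self.timestamps.shape[0]


@dataclass
class Dataset:
    """An ordered collection of measurement records."""

    records: list[MeasurementRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    @property
    def sample_ids(self) -> np.ndarray:
        return np.array([r.sample_id for r in self.records])


# --- profile construction -------------------------------------------------


def make_class_profile(
    class_label: str,
    separation_margin: float = DEFAULT_SEPARATION_MARGIN_V,
    overlap_margin: float = DEFAULT_OVERLAP_MARGIN_V,
) -> ClassProfile:
    """Build the deterministic response profile of one meat class.

    ``separation_margin`` is the minimum plateau-amplitude gap (V) between
    pork and both non-pork classes on the aldehyde channel set
    {S1, S2, S5, S7, S8} and the alcohol channel S3.  ``overlap_margin``
    bounds how far beef and chicken may differ, and only on the
    chicken-specific channel subsets.  Pork is offset by
    ``separation_margin + overlap_margin`` so the gap to *both* other
    classes is at least ``separation_margin``.
    """
    if class_label not in CLASS_LABELS:
        raise UnknownClassError(
            f"unknown class label {class_label!r}; expected one of {CLASS_LABELS}"
        )
    separation_margin = float(separation_margin)
    overlap_margin = float(overlap_margin)
    if not (separation_margin > 0 and overlap_margin > 0):
        raise ValueError("margins must be strictly positive")
    if not separation_margin > overlap_margin:
        raise ValueError("separation_margin must exceed overlap_margin")

    amp = {ch: BASE_AMPLITUDE_V[ch] for ch in GAS_CHANNELS}
    if class_label == "chicken":
        # chicken-specific ether/ester compounds: full overlap offset
        for ch in ETHER_CHANNELS:
            amp[ch] += overlap_margin
        # chicken-specific hydrocarbon: mild offset on the remaining
        # hydrocarbon channels
        for ch in HYDROCARBON_CHANNELS:
            if ch not in ETHER_CHANNELS:
                amp[ch] += 0.5 * overlap_margin
    elif class_label == "pork":
        pork_offset = separation_margin + overlap_margin
        for ch in set(ALDEHYDE_CHANNELS) | {ALCOHOL_CHANNEL}:
            amp[ch] += pork_offset

    rise, decay = CLASS_KINETICS_S[class_label]
    n = len(GAS_CHANNELS)
    return ClassProfile(
        class_label=class_label,
        amplitude=np.array([amp[ch] for ch in GAS_CHANNELS]),
        rise_tau=np.full(n, rise),
        decay_tau=np.full(n, decay),
    )


def default_profiles(
    separation_margin: float = DEFAULT_SEPARATION_MARGIN_V,
    overlap_margin: float = DEFAULT_OVERLAP_MARGIN_V,
) -> dict[str, ClassProfile]:
    """Profiles for all three classes at the given margins."""
    return {
        label: make_class_profile(label, separation_margin, overlap_margin)
        for label in CLASS_LABELS
    }


# --- record simulation ----------------------------------------------------


def _trapezoid(t: np.ndarray, amplitude: np.ndarray, rise_tau: np.ndarray,
               decay_tau: np.ndarray) -> np.ndarray:
    """Noise-free trapezoidal response, channels x timestamps.

    Zero during the delay phase; first-order saturation toward the plateau
    during sampling; exponential decay toward zero during purging.  The
    trace is continuous at the phase boundaries.
    """
    amplitude = amplitude[:, None]
    rise_tau = rise_tau[:, None]
    decay_tau = decay_tau[:, None]
    resp = np.zeros((amplitude.shape[0], t.shape[0]))
    half = SAMPLE_PERIOD_S / 2.0
    sampling = (t >= DELAY_END_S - half) & (t < SAMPLING_END_S - half)
    purging = t >= SAMPLING_END_S - half
    resp[:, :] = 0.0
    rise = amplitude * (1.0 - np.exp(-(t[None, :] - DELAY_END_S) / rise_tau))
    peak = amplitude * (1.0 - np.exp(-(SAMPLING_END_S - DELAY_END_S) / rise_tau))
    fall = peak * np.exp(-(t[None, :] - SAMPLING_END_S) / decay_tau)
    resp = np.where(sampling[None, :], rise, resp)
    resp = np.where(purging[None, :], fall, resp)
    return resp


def simulate_record(
    profile: ClassProfile,
    noise: NoiseSpec,
    seed,
    sample_id: str | None = None,
) -> MeasurementRecord:
    """Simulate one acquisition of ``profile`` under ``noise``.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.  Identical
    (profile, noise, seed) triples yield bit-identical records.  With all
    noise terms zero the record is the pure trapezoid: zero during the delay
    phase, ``A*(1 - exp(-(t-20)/rise_tau))`` during sampling, exponential
    decay from the 140 s peak during purging.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(N_TIMESTAMPS) * SAMPLE_PERIOD_S
    n_ch = len(GAS_CHANNELS)

    # draw order is fixed so records with different noise settings stay
    # aligned to the same random stream
    amp_jitter = rng.standard_normal(n_ch)
    baseline = noise.baseline_offset_sd * rng.standard_normal(n_ch)
    drift = noise.drift_slope_sd * rng.standard_normal(n_ch)
    white = noise.additive_noise_sd * rng.standard_normal((n_ch, t.shape[0]))
    env_off = rng.standard_normal(len(ENV_CHANNELS))
    env_drift = rng.standard_normal(len(ENV_CHANNELS))

    amplitude = profile.amplitude * (1.0 + noise.amplitude_cv * amp_jitter)
    amplitude = np.maximum(amplitude, 1e-6)
    resp = _trapezoid(t, amplitude, profile.rise_tau, profile.decay_tau)
    gas = resp + baseline[:, None] + drift[:, None] * t[None, :] + white

    env = np.empty((len(ENV_CHANNELS), t.shape[0]))
    for i, ch in enumerate(ENV_CHANNELS):
        env[i] = (
            ENV_BASELINE[ch]
            + _ENV_OFFSET_SCALE[ch] * noise.baseline_offset_sd * env_off[i]
            + _ENV_DRIFT_SCALE[ch] * noise.drift_slope_sd * env_drift[i] * t
        )

    return MeasurementRecord(
        sample_id=sample_id or f"{profile.class_label}_x",
        label=profile.class_label,
        timestamps=t,
        gas=gas,
        env=env,
    )


def generate_dataset(
    n_per_class: int,
    seed: int = 0,
    profiles: dict[str, ClassProfile] | None = None,
    noise: NoiseSpec | None = None,
) -> Dataset:
    """Generate a class-balanced dataset of ``3 * n_per_class`` records.

    Per-record seeds are ``SeedSequence(seed, spawn_key=(class_idx,
    record_idx))`` children of the master seed, so any record is
    reproducible in isolation and the dataset is independent of generation
    order.
    """
    if int(n_per_class) < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    n_per_class = int(n_per_class)
    profiles = profiles if profiles is not None else default_profiles()
    noise = noise if noise is not None else NoiseSpec()

    records = []
    for class_idx, label in enumerate(CLASS_LABELS):
        profile = profiles[label]
        for rec_idx in range(n_per_class):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(class_idx, rec_idx))
            records.append(
                simulate_record(profile, noise, ss, sample_id=f"{label}_{rec_idx:03d}")
            )
    return Dataset(records)


# --- long-format CSV I/O --------------------------------------------------

_CSV_COLUMNS = ("sample_id", "label", "channel", "t_s", "value")


def dataset_to_frame(dataset: Dataset) -> pd.DataFrame:
    """Long-format view: one row per (record, channel, timestamp)."""
    chunks = []
    for rec in dataset:
        T = rec.n_timestamps
        values = np.concatenate([rec.gas.ravel(), rec.env.ravel()])
        chunks.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(rec.sample_id, len(ALL_CHANNELS) * T),
                    "label": np.repeat(rec.label, len(ALL_CHANNELS) * T),
                    "channel": np.repeat(np.array(ALL_CHANNELS), T),
                    "t_s": np.tile(rec.timestamps, len(ALL_CHANNELS)),
                    "value": values,
                }
            )
        )
    return pd.concat(chunks, ignore_index=True)


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as long-format CSV (lossless float round-trip)."""
    # 17 significant digits round-trip IEEE doubles exactly
    dataset_to_frame(dataset).to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> Dataset:
    """Read a long-format dataset CSV written by :func:`write_dataset`."""
    try:
        frame = pd.read_csv(
            path,
            dtype={"sample_id": str, "label": str, "channel": str},
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DatasetParseError(f"malformed CSV: {exc}") from exc

    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetParseError(f"missing column(s): {', '.join(missing)}")

    for col in ("t_s", "value"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise DatasetParseError(f"non-numeric {col!r} value", row=row)
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2
            raise DatasetParseError(f"missing {col!r} value", row=row)
        frame[col] = coerced

    records = []
    for sample_id in frame["sample_id"].unique():
        sub = frame[frame["sample_id"] == sample_id]
        labels = sub["label"].unique()
        if len(labels) != 1:
            raise DatasetParseError(f"sample {sample_id!r} has inconsistent labels")
        chan_traces = {}
        timestamps = None
        for ch in ALL_CHANNELS:
            trace = sub[sub["channel"] == ch].sort_values("t_s")
            if trace.empty:
                raise DatasetParseError(f"sample {sample_id!r} lacks channel {ch!r}")
            chan_traces[ch] = trace["value"].to_numpy()
            ts = trace["t_s"].to_numpy()
            if timestamps is None:
                timestamps = ts
            elif ts.shape != timestamps.shape or not np.array_equal(ts, timestamps):
                raise DatasetParseError(
                    f"sample {sample_id!r}: channel {ch!r} timestamp grid mismatch"
                )
        records.append(
            MeasurementRecord(
                sample_id=sample_id,
                label=str(labels[0]),
                timestamps=timestamps,
                gas=np.stack([chan_traces[ch] for ch in GAS_CHANNELS]),
                env=np.stack([chan_traces[ch] for ch in ENV_CHANNELS]),
            )
        )
    return Dataset(records)


def write_manifest(
    path,
    seed: int,
    n_per_class: int,
    separation_margin: float,
    overlap_margin: float,
    noise: NoiseSpec,
) -> None:
    """Record dataset provenance (seed, margins, noise spec) as YAML."""
    manifest = {
        "seed": int(seed),
        "n_per_class": int(n_per_class),
        "separation_margin": float(separation_margin),
        "overlap_margin": float(overlap_margin),
        "noise": {
            "baseline_offset_sd": noise.baseline_offset_sd,
            "additive_noise_sd": noise.additive_noise_sd,
            "amplitude_cv": noise.amplitude_cv,
            "drift_slope_sd": noise.drift_slope_sd,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
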