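"""Signal preprocessing: baseline correction and phase handling.

Baseline correction subtracts, per gas channel, the first reading of the
delay phase from the whole trace (V'_ij = V_ij - V_i0), so responses from
different runs share a common zero.  Environmental channels are never
corrected.  Phase segmentation maps the instrument protocol (delay
[0, 20) s, sampling [20, 140) s, purging [140, 260] s) onto the record's
sample grid, and sensing-region selection returns either the full trace
(the no-window case) or the [20, 200] s region used by window slicing.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING

import numpy as np

from .synthetic import (
    DELAY_END_S,
    RECORD_DURATION_S,
    SAMPLING_END_S,
    Dataset,
    MeasurementRecord,
)

if TYPE_CHECKING:  # pragma: no cover
    from .windowing import WindowScheme


def baseline_correct(record: MeasurementRecord) -> MeasurementRecord:
    """Shift each gas channel by its own first (t = 0) value.

    Idempotent: a corrected record has V'_i0 = 0, so a second application
    is the identity.  Environmental channels are returned untouched.
    """
    if record.n_timestamps == 0:
        raise ValueError("record has empty channel traces")
    corrected = record.gas - record.gas[:, :1]
    return dataclasses.replace(record, gas=corrected, env=record.env.copy())


def baseline_correct_dataset(dataset: Dataset) -> Dataset:
    return Dataset([baseline_correct(r) for r in dataset])


def segment_phases(record: MeasurementRecord) -> dict[str, np.ndarray]:
    """Partition the record's sample indices into the three phases.

    Returns index arrays for ``delay`` [0, 20) s, ``sampling`` [20, 140) s
    and ``purging`` [140, 260] s.  Thresholds are taken at half a sample
    step so floating-point grid jitter cannot move a sample across a phase
    boundary.  The three ranges partition the grid exactly.
    """
    t = record.timestamps
    if t[-1] < RECORD_DURATION_S - 1e-9:
        raise ValueError(
            f"record spans only {t[-1]:g} s; {RECORD_DURATION_S:g} s required"
        )
    half = 0.5 * (t[1] - t[0])
    idx = np.arange(t.shape[0])
    delay = idx[t < DELAY_END_S - half]
    sampling = idx[(t >= DELAY_END_S - half) & (t < SAMPLING_END_S - half)]
    purging = idx[t >= SAMPLING_END_S - half]
    return {"delay": delay, "sampling": sampling, "purging": purging}


def select_sensing_region(
    record: MeasurementRecord, scheme: "WindowScheme"
) -> tuple[np.ndarray, np.ndarray]:
    """Return (timestamps, gas values) of the scheme's sensing region.

    The no-window scheme uses the full [0, 260] s trace; windowed schemes
    use the closed [20, 200] s region.  Selection only — values are the
    record's values at the same timestamps.
    """
    t = record.timestamps
    start, end = scheme.region
    half = 0.5 * (t[1] - t[0])
    if t[0] > start + half or t[-1] < end - half:
        raise ValueError(
            f"record span [{t[0]:g}, {t[-1]:g}] s does not cover the "
            f"scheme region [{start:g}, {end:g}] s"
        )
    mask = (t >= start - half) & (t <= end + half)
    return t[mask], record.gas[:, mask]
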