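"""Trace containers, delimited-text I/O and acquisition-matched preprocessing.

A :class:`Trace` is a whole-cell voltage-clamp current record sampled at a
fixed rate (20 kHz in the recordings this package emulates).  Traces travel
as two-column delimited text (``time_s``, ``current_pA``) with a small YAML
sidecar carrying acquisition metadata, so nothing here depends on a
proprietary acquisition format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from scipy.signal import butter, sosfiltfilt

Polarity = Literal["inward", "outward"]

#: columns of an event table as written/read by this package
EVENT_COLUMNS = ["onset_s", "peak_s", "amplitude_pA", "decay_ms", "type"]


@dataclass
class Trace:
    """A sampled current record with acquisition metadata.

    Parameters
    ----------
    sampling_rate : float
        Samples per second; must be positive.
    current : ndarray
        Current samples in pA, all finite.
    holding_potential : float
        Command potential in mV (-70 for EPSC recordings, 0 for IPSC).
    polarity : {"inward", "outward"}
        Direction of synaptic deflections: inward currents are negative
        (EPSCs at -70 mV), outward positive (IPSCs at 0 mV).
    """

    sampling_rate: float
    current: np.ndarray
    holding_potential: float = -70.0
    polarity: Polarity = "inward"
    cell_id: str = ""
    region: str = ""
    genotype: str = ""
    age_group: str = ""
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.polarity not in ("inward", "outward"):
            raise ValueError(f"polarity must be 'inward' or 'outward', got {self.polarity!r}")
        self.current = np.asarray(self.current, dtype=float)
        if self.current.ndim != 1:
            raise ValueError("current must be one-dimensional")
        if not np.all(np.isfinite(self.current)):
            bad = int(np.flatnonzero(~np.isfinite(self.current))[0])
            raise ValueError(f"non-finite current sample at index {bad}")

    @property
    def n_samples(self) -> int:
        return self.current.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def with_current(self, current: np.ndarray) -> "Trace":
        return replace(self, current=np.asarray(current, dtype=float))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_trace(trace: Trace, path: str | Path, fmt: str = "%.6f") -> None:
    """Write a trace as two-column delimited text plus a metadata sidecar."""
    path = Path(path)
    header = "time_s\tcurrent_pA"
    data = np.column_stack([trace.time, trace.current])
    np.savetxt(path, data, fmt=["%.6f", fmt], delimiter="\t", header=header, comments="")
    meta = {
        "sampling_rate_hz": float(trace.sampling_rate),
        "holding_potential_mv": float(trace.holding_potential),
        "polarity": trace.polarity,
        "cell_id": trace.cell_id,
        "region": trace.region,
        "genotype": trace.genotype,
        "age_group": trace.age_group,
        "seed": trace.seed,
        **trace.meta,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_trace(path: str | Path) -> Trace:
    """Read a trace written by :func:`write_trace`.

    Raises
    ------
    ValueError
        With a line-numbered message for missing columns, non-monotone time
        or NaN samples; ``FileNotFoundError`` for a missing file or sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh) or {}

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["time_s", "current_pA"]:
            raise ValueError(f"{path}, line 1: expected columns time_s, current_pA, got {header}")
        times: list[float] = []
        currents: list[float] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}, line {lineno}: expected 2 columns, got {len(parts)}")
            t, c = float(parts[0]), float(parts[1])
            if math.isnan(c) or math.isinf(c):
                raise ValueError(f"{path}, line {lineno}: non-finite current value")
            if times and t <= times[-1]:
                raise ValueError(f"{path}, line {lineno}: non-monotone time")
            times.append(t)
            currents.append(c)
    if not currents:
        raise ValueError(f"{path}: no samples")

    rate = meta.pop("sampling_rate_hz", None)
    if rate is None:
        # infer from the time column as a fallback
        rate = 1.0 / float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    return Trace(
        sampling_rate=float(rate),
        current=np.asarray(currents),
        holding_potential=float(meta.pop("holding_potential_mv", -70.0)),
        polarity=meta.pop("polarity", "inward"),
        cell_id=str(meta.pop("cell_id", "") or ""),
        region=str(meta.pop("region", "") or ""),
        genotype=str(meta.pop("genotype", "") or ""),
        age_group=str(meta.pop("age_group", "") or ""),
        seed=meta.pop("seed", None),
        meta=meta,
    )


def lowpass_filter(trace: Trace, cutoff: float = 1000.0, order: int = 4) -> Trace:
    """Zero-phase low-pass Butterworth filter.

    The acquisition convention this package follows is to filter digitally
    at 1 kHz before event detection.  A forward-backward (zero-phase) filter
    is used so event onsets and decay kinetics are not skewed by phase lag;
    DC level and record length are preserved.
    """
    nyquist = trace.sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff}")
    sos = butter(order, cutoff, btype="low", fs=trace.sampling_rate, output="sos")
    filtered = sosfiltfilt(sos, trace.current)
    return trace.with_current(filtered)


def write_events(events, path: str | Path) -> None:
    """Write an event table (see :mod:`synquant.detect`) as TSV."""
    import pandas as pd

    rows = [
        {
            "onset_s": e.onset_time,
            "peak_s": e.peak_time,
            "amplitude_pA": e.amplitude,
            "decay_ms": e.decay_metric if e.decay_metric is not None else float("nan"),
            "type": e.type_label,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_events(path: str | Path):
    import pandas as pd

    from .detect import Event

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing event columns {missing}")
    events = []
    for row in df.itertuples(index=False):
        decay = None if math.isnan(row.decay_ms) else float(row.decay_ms)
        events.append(
            Event(
                onset_time=float(row.onset_s),
                peak_time=float(row.peak_s),
                amplitude=float(row.amplitude_pA),
                decay_metric=decay,
                type_label=str(row.type),
            )
        )
    return events
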