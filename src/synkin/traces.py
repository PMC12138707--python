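"""Raw NMR integral time-courses and normalized aggregation traces.

Aggregation is monitored by integrating probe methyl signals (3V, 8L,
15V) against an external reference; each probe ratio is self-normalized
to its t=0 value, so per-probe calibration constants and reference
rescaling cancel exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RawIntegralSeries",
    "AggregationTrace",
    "normalize_trace",
    "to_aggregate",
    "read_raw_csv",
    "read_trace_csv",
    "write_trace_csv",
]

DEFAULT_PROBES = ("3V", "8L", "15V")


@dataclass
class RawIntegralSeries:
    """Probe-signal integrals vs time with an external reference."""

    times: np.ndarray  # hours
    integrals: dict  # probe label -> integral array
    reference: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.integrals = {k: np.asarray(v, dtype=float) for k, v in self.integrals.items()}
        n = len(self.times)
        if not self.integrals:
            raise ValueError("at least one probe signal required")
        for label, arr in self.integrals.items():
            if len(arr) != n:
                raise ValueError(f"probe {label!r} length {len(arr)} != {n} times")
        if len(self.reference) != n:
            raise ValueError("reference length must match times")
        if np.any(self.reference <= 0):
            raise ValueError("reference integral must be > 0 everywhere")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class AggregationTrace:
    """Concentration time series for one peptide/salt/pH condition.

    ``species`` records whether ``values`` holds remaining monomer [A] or
    accumulated aggregate [B] = A0 - [A].
    """

    times: np.ndarray
    values: np.ndarray  # mM
    a0: float
    species: str = "monomer"
    metadata: dict = field(default_factory=dict)
    quality: np.ndarray | None = None  # per-time probe disagreement

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.species not in ("monomer", "aggregate"):
            raise ValueError(f"unknown species {self.species!r}")
        if self.a0 is not None and self.a0 <= 0:
            raise ValueError("a0 must be positive")

    def complement(self) -> "AggregationTrace":
        return to_aggregate(self)

    @property
    def monomer(self) -> np.ndarray:
        return self.values if self.species == "monomer" else self.a0 - self.values


def normalize_trace(
    raw: RawIntegralSeries, combine: str = "mean", slack: float = 0.05
) -> AggregationTrace:
    """Convert raw integrals to a monomer trace in mM.

    Per probe k, ratio_k(t) = integral_k(t)/reference(t); the monomer
    fraction is the mean (or median) over probes of ratio_k(t)/ratio_k(0)
    and the concentration fraction * A0.  Fractions up to 1+slack are
    clipped to A0 with a warning; larger excursions are rejected.  The
    max pairwise relative spread of the probe estimates is attached as a
    per-time quality metric.
    """
    if combine not in ("mean", "median"):
        raise ValueError("combine must be 'mean' or 'median'")
    if raw.times[0] != 0:
        raise ValueError("raw series must include t = 0 (self-normalization anchor)")
    a0 = float(raw.metadata.get("a0_mM", 2.0))
    ratios = []
    for label, arr in raw.integrals.items():
        ratio = arr / raw.reference
        if ratio[0] <= 0:
            raise ValueError(f"probe {label!r} has non-positive integral at t=0")
        ratios.append(ratio / ratio[0])
    mat = np.vstack(ratios)
    frac = np.mean(mat, axis=0) if combine == "mean" else np.median(mat, axis=0)
    spread = (np.max(mat, axis=0) - np.min(mat, axis=0)) / np.maximum(
        np.mean(mat, axis=0), 1e-12
    )
    if np.any(frac > 1.0 + slack) or np.any(frac < -slack):
        raise ValueError(f"normalized fraction outside [0, 1+{slack}]")
    clipped = int(np.sum((frac > 1.0) | (frac < 0.0)))
    if clipped:
        warnings.warn(f"{clipped} point(s) clipped into [0, A0]", UserWarning, stacklevel=2)
    frac = np.clip(frac, 0.0, 1.0)
    meta = dict(raw.metadata)
    meta["n_clipped"] = clipped
    return AggregationTrace(
        times=raw.times, values=frac * a0, a0=a0, species="monomer",
        metadata=meta, quality=spread,
    )


def to_aggregate(trace: AggregationTrace) -> AggregationTrace:
    """Complement trace: monomer <-> aggregate with [A] + [B] = A0."""
    if trace.a0 is None:
        raise ValueError("trace must carry A0 to form the complement")
    other = "aggregate" if trace.species == "monomer" else "monomer"
    return replace(trace, values=trace.a0 - trace.values, species=other)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------


def read_raw_csv(path, metadata: dict | None = None) -> RawIntegralSeries:
    """Read `time_h,int_<probe>...,int_ref` columns into a RawIntegralSeries."""
    df = pd.read_csv(path)
    if "time_h" not in df.columns or "int_ref" not in df.columns:
        raise ValueError("raw CSV requires 'time_h' and 'int_ref' columns")
    probes = {
        c[len("int_"):]: df[c].to_numpy()
        for c in df.columns
        if c.startswith("int_") and c != "int_ref"
    }
    return RawIntegralSeries(
        times=df["time_h"].to_numpy(),
        integrals=probes,
        reference=df["int_ref"].to_numpy(),
        metadata=metadata or {},
    )


def read_trace_csv(path, a0: float | None = None, metadata: dict | None = None) -> AggregationTrace:
    """Read `time_h,concentration_mM` (or `time_h,fraction` + a0)."""
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise ValueError("trace CSV requires a 'time_h' column")
    meta = dict(metadata or {})
    for col in ("peptide", "salt", "salt_mM", "pH"):
        if col in df.columns:
            meta.setdefault(col, df[col].iloc[0])
    if "concentration_mM" in df.columns:
        values = df["concentration_mM"].to_numpy()
        a0 = a0 if a0 is not None else float(meta.get("a0_mM", 2.0))
    elif "fraction" in df.columns:
        if a0 is None:
            raise ValueError("fraction traces require an explicit a0")
        values = df["fraction"].to_numpy() * a0
    else:
        raise ValueError("trace CSV requires 'concentration_mM' or 'fraction'")
    meta["a0_mM"] = a0
    return AggregationTrace(
        times=df["time_h"].to_numpy(), values=values, a0=a0, metadata=meta
    )


def write_trace_csv(trace: AggregationTrace, path) -> None:
    df = pd.DataFrame({"time_h": trace.times, "concentration_mM": trace.values})
    if trace.quality is not None:
        df["probe_spread"] = trace.quality
    df.to_csv(path, index=False)
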