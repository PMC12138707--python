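"""Synthetic-data generators for every input the analysis consumes.

Each generator draws from its own ``numpy`` Generator seeded through the
:class:`NoiseSpec`, so outputs are bit-reproducible and no global random
state is touched.  Out-of-range noisy values are clipped (never
rejected) and the clip count recorded in metadata.

Default noise scales mimicking experimental data quality:
0.02-0.05 mM for aggregation traces, 0.002 ppm for shifts, 0.1 Hz for J.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import TitrationSeries, isotherm_shift
from .fw import FWParams, fw_monomer
from .structure import DEFAULT_KARPLUS, JCouplingSet, KarplusParams, VTSeries, karplus_j
from .traces import AggregationTrace, RawIntegralSeries

__all__ = [
    "NoiseSpec",
    "gen_fw_trace",
    "gen_raw_integrals",
    "gen_titration",
    "gen_vt",
    "gen_jset",
]

SIGMA_TRACE_MM = 0.04
SIGMA_SHIFT_PPM = 0.002
SIGMA_J_HZ = 0.1


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise of width ``sigma`` (units of the target quantity)."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def perturb(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.sigma == 0:
            return values.copy()
        return values + self.rng().normal(0.0, self.sigma, size=values.shape)


def _clip_count(values: np.ndarray, lo: float, hi: float) -> tuple[np.ndarray, int]:
    clipped = int(np.sum((values < lo) | (values > hi)))
    return np.clip(values, lo, hi), clipped


def gen_fw_trace(
    params: FWParams, times, noise: NoiseSpec = NoiseSpec(), metadata: dict | None = None
) -> AggregationTrace:
    """Sigmoidal monomer-loss trace: closed-form curve + Gaussian noise,
    clipped to [0, A0]."""
    times = np.asarray(times, dtype=float)
    clean = fw_monomer(params, times)
    noisy, n_clip = _clip_count(noise.perturb(clean), 0.0, params.a0)
    meta = dict(metadata or {})
    meta.update({"a0_mM": params.a0, "n_clipped": n_clip, "sigma_mM": noise.sigma,
                 "seed": noise.seed})
    return AggregationTrace(
        times=times, values=noisy, a0=params.a0, species="monomer", metadata=meta
    )


def gen_raw_integrals(
    trace: AggregationTrace,
    probe_scales=(1.0, 0.8, 1.2),
    ref_level: float = 100.0,
    noise: NoiseSpec = NoiseSpec(),
    probe_labels=("3V", "8L", "15V"),
) -> RawIntegralSeries:
    """Inverse of :func:`synkin.traces.normalize_trace` (exact at sigma=0)."""
    if len(probe_scales) != len(probe_labels):
        raise ValueError("one scale per probe label required")
    if ref_level <= 0 or any(s <= 0 for s in probe_scales):
        raise ValueError("scales and reference level must be positive")
    frac = trace.monomer / trace.a0
    rng = noise.rng()
    integrals = {}
    for label, scale in zip(probe_labels, probe_scales):
        clean = scale * frac * ref_level
        integrals[label] = clean + (
            rng.normal(0.0, noise.sigma, size=clean.shape) if noise.sigma else 0.0
        )
    return RawIntegralSeries(
        times=trace.times,
        integrals=integrals,
        reference=np.full_like(trace.times, ref_level),
        metadata=dict(trace.metadata),
    )


def gen_titration(
    ka: float,
    delta_free: float,
    delta_max: float,
    concs,
    noise: NoiseSpec = NoiseSpec(),
    residue: str = "",
    peptide: str = "",
    salt: str = "",
) -> TitrationSeries:
    """Hyperbolic fast-exchange titration curve + Gaussian noise."""
    concs = np.asarray(concs, dtype=float)
    clean = isotherm_shift(ka, delta_free, delta_max, concs)
    return TitrationSeries(
        residue=residue, concentrations=concs, shifts=noise.perturb(clean),
        peptide=peptide, salt=salt,
    )


def gen_vt(
    slope_ppb_per_K: float,
    intercept_ppm: float,
    temps,
    noise: NoiseSpec = NoiseSpec(),
    residue: str = "",
    unit: str = "C",
) -> VTSeries:
    """Linear shift-vs-temperature series (slope given in ppb/K, signed)."""
    temps = np.asarray(temps, dtype=float)
    if len(temps) < 4:
        raise ValueError("need >= 4 temperatures")
    clean = intercept_ppm + (slope_ppb_per_K / 1000.0) * temps
    return VTSeries(
        residue=residue, temperatures=temps, shifts=noise.perturb(clean), unit=unit
    )


def gen_jset(
    phis: dict,
    params: KarplusParams = DEFAULT_KARPLUS,
    noise: NoiseSpec = NoiseSpec(),
    peptide: str = "",
) -> JCouplingSet:
    """J-coupling set from phi angles through the Karplus curve, noise
    clipped into the physically plausible [0, 12] Hz window."""
    clean = np.array([karplus_j(phi, params) for _, phi in sorted(phis.items())])
    noisy, n_clip = _clip_count(noise.perturb(clean), 0.0, 12.0)
    positions = sorted(phis)
    return JCouplingSet(
        peptide=peptide,
        values=dict(zip(positions, noisy)),
        condition={"n_clipped": n_clip, "seed": noise.seed},
    )
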