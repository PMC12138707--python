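"""Karplus 3J(HN-Ha) <-> phi analysis, J-set comparison and VT amide
temperature coefficients."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KarplusParams",
    "DEFAULT_KARPLUS",
    "PhiSolution",
    "JCouplingSet",
    "VTSeries",
    "TempCoeff",
    "karplus_j",
    "karplus_invert",
    "classify_residue",
    "j_rmsd",
    "temp_coeff",
    "COIL_MAX_HZ",
    "EXTENDED_MIN_HZ",
    "read_jset_csv",
    "read_vt_csv",
]

# Dataset-derived clustering boundaries for 3J(HN-Ha); configurable, not
# universal secondary-structure cutoffs.
COIL_MAX_HZ = 6.30
EXTENDED_MIN_HZ = 6.65

J_PLAUSIBLE_MAX = 12.0


@dataclass(frozen=True)
class KarplusParams:
    """Coefficients of J(phi) = A cos^2(theta) + B cos(theta) + C with
    theta = phi - phase_offset (degrees).  A literature provenance string
    is required so swapped coefficient sets stay traceable."""

    a: float
    b: float
    c: float
    phase_offset_deg: float = 60.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("Karplus A coefficient must be > 0")
        if not self.provenance:
            raise ValueError("a literature provenance string is required")

    def j_range(self) -> tuple[float, float]:
        """Attainable (min, max) of the quadratic in cos(theta) over [-1, 1]."""
        xs = [-1.0, 1.0]
        x_vertex = -self.b / (2.0 * self.a)
        if -1.0 <= x_vertex <= 1.0:
            xs.append(x_vertex)
        vals = [self.a * x * x + self.b * x + self.c for x in xs]
        return min(vals), max(vals)


#: 3J(HN-Ha) parameterization of Vuister & Bax, J. Am. Chem. Soc. 115,
#: 7772 (1993): A=6.51, B=-1.76, C=1.60 Hz, theta = phi - 60 deg.
DEFAULT_KARPLUS = KarplusParams(
    a=6.51, b=-1.76, c=1.60, phase_offset_deg=60.0,
    provenance="Vuister & Bax (1993) JACS 115:7772, 3J(HNHa)",
)


def _wrap_deg(phi: float) -> float:
    """Wrap an angle into (-180, 180]."""
    w = math.fmod(phi + 180.0, 360.0)
    if w <= 0:
        w += 360.0
    return w - 180.0


def karplus_j(phi: float, params: KarplusParams = DEFAULT_KARPLUS) -> float:
    """Forward Karplus curve at dihedral ``phi`` (degrees)."""
    theta = math.radians(_wrap_deg(phi) - params.phase_offset_deg)
    x = math.cos(theta)
    return params.a * x * x + params.b * x + params.c


def _phi_region(phi: float) -> str:
    # Coarse Ramachandran tag by sign convention; negative-phi basin split
    # at -100 deg between helical and extended sampling.
    if -100.0 < phi < 0.0:
        return "helical"
    if phi <= -100.0:
        return "extended"
    return "positive-phi"


@dataclass(frozen=True)
class PhiSolution:
    phi_deg: float
    region: str


def karplus_invert(j: float, params: KarplusParams = DEFAULT_KARPLUS) -> list[PhiSolution]:
    """All phi in (-180, 180] with karplus_j(phi) == j (0, 2 or 4 values).

    Solves the quadratic in cos(theta); roots within roundoff of +/-1 are
    clipped.  An unattainable ``j`` yields an empty list.
    """
    lo, hi = params.j_range()
    if j < lo - 1e-9 or j > hi + 1e-9:
        return []
    disc = params.b**2 - 4.0 * params.a * (params.c - j)
    if disc < 0:
        if disc > -1e-12:
            disc = 0.0
        else:
            return []
    sq = math.sqrt(disc)
    phis: list[float] = []
    for root in ((-params.b + sq) / (2 * params.a), (-params.b - sq) / (2 * params.a)):
        if abs(root) > 1.0:
            if abs(root) - 1.0 < 1e-9:
                root = math.copysign(1.0, root)
            else:
                continue
        theta = math.degrees(math.acos(root))
        for signed in {theta, -theta}:
            phis.append(_wrap_deg(signed + params.phase_offset_deg))
    uniq: list[float] = []
    for p in sorted(phis):
        if not uniq or abs(p - uniq[-1]) > 1e-9:
            uniq.append(p)
    return [PhiSolution(phi_deg=p, region=_phi_region(p)) for p in uniq]


def classify_residue(
    j: float, coil_max: float = COIL_MAX_HZ, extended_min: float = EXTENDED_MIN_HZ
) -> str:
    """Cluster-based label: "coil-like", "extended/helical-sampling" or
    "intermediate"."""
    if j < 0:
        raise ValueError("J must be >= 0")
    if coil_max >= extended_min:
        raise ValueError("coil_max must be below extended_min")
    if j <= coil_max:
        return "coil-like"
    if j >= extended_min:
        return "extended/helical-sampling"
    return "intermediate"


@dataclass
class JCouplingSet:
    """Per-residue 3J(HN-Ha) values (Hz) for one condition."""

    peptide: str
    values: dict  # position -> Hz
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = {int(k): float(v) for k, v in self.values.items()}
        bad = {p: v for p, v in self.values.items() if not 0.0 <= v <= J_PLAUSIBLE_MAX}
        if bad:
            raise ValueError(f"J values outside [0, {J_PLAUSIBLE_MAX}] Hz: {bad}")

    @property
    def positions(self) -> set:
        return set(self.values)


def j_rmsd(a: JCouplingSet, b: JCouplingSet) -> float:
    """RMSD between two J-sets over their shared residues (Hz)."""
    shared = sorted(a.positions & b.positions)
    if not shared:
        raise ValueError("J-coupling sets share no residues")
    diff = np.array([a.values[p] - b.values[p] for p in shared])
    return float(np.sqrt(np.mean(diff**2)))


# ---------------------------------------------------------------------------
# Variable-temperature coefficients
# ---------------------------------------------------------------------------


@dataclass
class VTSeries:
    """Amide shift vs temperature for one residue; ``unit`` is "K" or "C"."""

    residue: str
    temperatures: np.ndarray
    shifts: np.ndarray  # ppm
    unit: str = "C"

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.unit not in ("K", "C"):
            raise ValueError("unit must be 'K' or 'C'")
        if len(self.temperatures) != len(self.shifts):
            raise ValueError("temperatures and shifts must have equal length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    @property
    def kelvin(self) -> np.ndarray:
        return self.temperatures if self.unit == "K" else self.temperatures + 273.15


@dataclass
class TempCoeff:
    residue: str
    slope_ppb_per_K: float  # magnitude
    sign: int  # sign of the raw d(shift)/dT
    r_squared: float
    linear: bool

    def to_dict(self) -> dict:
        return {
            "residue": self.residue,
            "slope_ppb_per_K": self.slope_ppb_per_K,
            "sign": self.sign,
            "r_squared": self.r_squared,
            "linear": self.linear,
        }


def temp_coeff(series: VTSeries, r2_threshold: float = 0.99) -> TempCoeff:
    """OLS slope of shift vs temperature, reported as a magnitude in ppb/K.

    Temperature differences are identical in Celsius and Kelvin, so the
    slope is unit-independent; the sign convention (usually upfield with
    increasing temperature, i.e. negative raw slope) is kept separately.
    """
    if len(series.temperatures) < 4:
        raise ValueError("need >= 4 temperature points")
    if np.ptp(series.shifts) == 0:  # constant series: exact zero slope
        return TempCoeff(
            residue=series.residue, slope_ppb_per_K=0.0, sign=0,
            r_squared=1.0, linear=True,
        )
    res = stats.linregress(series.kelvin, series.shifts)
    slope_ppb = res.slope * 1000.0
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 1.0
    return TempCoeff(
        residue=series.residue,
        slope_ppb_per_K=abs(float(slope_ppb)),
        sign=int(np.sign(slope_ppb)),
        r_squared=r2,
        linear=r2 >= r2_threshold,
    )


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------


def read_jset_csv(path, peptide: str = "", condition: dict | None = None) -> JCouplingSet:
    """Read `position,residue,J_Hz` into a JCouplingSet."""
    df = pd.read_csv(path)
    for col in ("position", "J_Hz"):
        if col not in df.columns:
            raise ValueError(f"J-coupling CSV requires a {col!r} column")
    if "peptide" in df.columns and not peptide:
        peptide = str(df["peptide"].iloc[0])
    return JCouplingSet(
        peptide=peptide,
        values=dict(zip(df["position"].astype(int), df["J_Hz"].astype(float))),
        condition=condition or {},
    )


def read_vt_csv(path, residue: str = "") -> VTSeries:
    """Read `temperature_C,shift_ppm` (or `temperature_K,...`)."""
    df = pd.read_csv(path)
    if "temperature_C" in df.columns:
        temps, unit = df["temperature_C"], "C"
    elif "temperature_K" in df.columns:
        temps, unit = df["temperature_K"], "K"
    else:
        raise ValueError("VT CSV requires 'temperature_C' or 'temperature_K'")
    if "shift_ppm" not in df.columns:
        raise ValueError("VT CSV requires a 'shift_ppm' column")
    if "residue" in df.columns and not residue:
        residue = str(df["residue"].iloc[0])
    return VTSeries(
        residue=residue,
        temperatures=temps.to_numpy(),
        shifts=df["shift_ppm"].to_numpy(),
        unit=unit,
    )
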