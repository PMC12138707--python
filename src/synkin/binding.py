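"""Anion-binding isotherm fits and chemical-shift-perturbation mapping.

Fast-exchange 1:1 binding makes the observed amide shift the
population-weighted average of the free and bound shifts.  With the salt
in large excess over the per-site peptide concentration the bound
fraction is Ka*[L]/(1 + Ka*[L]), giving a hyperbolic titration curve;
the exact quadratic 1:1 solution is available behind a config flag.

Chemical-shift-perturbation (CSP) maps are signed per-residue shift
differences (bound - free).  Upfield (negative) changes are read as
anion association; downfield (positive) ones as non-specific
ionic-strength effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .peptides import PeptideSequence

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "BindingConfig",
    "ShiftTable",
    "CSPMap",
    "NeighborComparison",
    "NeighborAsymmetryReport",
    "isotherm_shift",
    "isotherm_shift_exact",
    "fit_ka",
    "csp",
    "neighbor_asymmetry",
    "bubble_map_export",
    "equivalents_to_molar",
    "read_titration_csv",
    "read_shift_table_csv",
]

DEFAULT_ERROR_PPM = 0.005


def equivalents_to_molar(equivalents: float, peptide_mM: float = 5.0) -> float:
    """Convert salt equivalents to molar total concentration (93 eq of a
    5 mM peptide -> 0.465 M)."""
    return equivalents * peptide_mM / 1000.0


@dataclass
class TitrationSeries:
    """Observed amide shift vs total salt concentration for one residue."""

    residue: str
    concentrations: np.ndarray  # M, ascending, starts at 0
    shifts: np.ndarray  # ppm
    peptide: str = ""
    salt: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if len(self.concentrations) != len(self.shifts):
            raise ValueError("concentrations and shifts must have equal length")
        if len(self.concentrations) and self.concentrations[0] != 0:
            raise ValueError("first concentration must be 0 (free peptide)")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class BindingFit:
    residue: str
    ka: float  # M^-1
    delta_free: float  # ppm
    delta_max: float  # signed ppm
    r_squared: float
    ka_stderr: float
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "residue": self.residue,
            "Ka_per_M": self.ka,
            "delta_free_ppm": self.delta_free,
            "delta_max_ppm": self.delta_max,
            "r_squared": self.r_squared,
            "Ka_stderr": self.ka_stderr,
            "warnings": list(self.warnings),
        }


@dataclass
class BindingConfig:
    """``model`` is "excess" (free salt ~ total salt) or "exact"
    (quadratic 1:1 solution using ``peptide_conc_M``)."""

    model: str = "excess"
    peptide_conc_M: float = 0.005
    weak_binding_threshold: float = 0.5  # max(Ka*c) below this -> warning
    n_starts: int = 6
    seed: int = 0


def isotherm_shift(ka: float, delta_free: float, delta_max: float, conc) -> float | np.ndarray:
    """Fast-exchange observed shift under the excess-ligand approximation.

    delta(c) = delta_free + delta_max * Ka*c / (1 + Ka*c); monotone in c
    and saturating at delta_free + delta_max.
    """
    if ka < 0:
        raise ValueError("Ka must be >= 0")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = delta_free + delta_max * (ka * c) / (1.0 + ka * c)
    return float(out) if out.ndim == 0 else out


def isotherm_shift_exact(
    ka: float, delta_free: float, delta_max: float, conc, peptide_conc: float
) -> float | np.ndarray:
    """Exact 1:1 observed shift (quadratic bound-fraction solution)."""
    if ka < 0:
        raise ValueError("Ka must be >= 0")
    if peptide_conc <= 0:
        raise ValueError("peptide concentration must be > 0")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    if ka == 0:
        out = np.full_like(c, delta_free)
        return float(out) if out.ndim == 0 else out
    p0 = peptide_conc
    b = p0 + c + 1.0 / ka
    bound = (b - np.sqrt(b * b - 4.0 * p0 * c)) / 2.0
    out = delta_free + delta_max * bound / p0
    return float(out) if out.ndim == 0 else out


def fit_ka(series: TitrationSeries, config: BindingConfig | None = None) -> BindingFit:
    """Nonlinear least-squares fit of (Ka, delta_free, delta_max).

    Ka is bounded below at 0.  Deterministic: a feature-based start plus a
    fixed logarithmic ladder of Ka restarts.  If saturation is not
    approached (max Ka*c below the weak-binding threshold) the fit is
    returned with a separability warning rather than rejected.
    """
    config = config or BindingConfig()
    c, y = series.concentrations, series.shifts
    if len(c) < 5:
        raise ValueError(f"need >= 5 titration points, got {len(c)}")

    def predict(x: np.ndarray) -> np.ndarray:
        ka, dfree, dmax = x
        if config.model == "exact":
            return isotherm_shift_exact(ka, dfree, dmax, c, config.peptide_conc_M)
        return isotherm_shift(ka, dfree, dmax, c)

    def residuals(x: np.ndarray) -> np.ndarray:
        return predict(x) - y

    total = y[-1] - y[0]
    half_idx = int(np.argmin(np.abs((y - y[0]) - 0.5 * total)))
    ka0 = 1.0 / c[half_idx] if c[half_idx] > 0 else 1.0
    starts = [np.array([ka0, y[0], 1.5 * total if total != 0 else 0.01])]
    for ka_s in np.geomspace(0.1, 100.0, config.n_starts):
        starts.append(np.array([ka_s, y[0], total if total != 0 else 0.01]))

    lb = np.array([0.0, -np.inf, -np.inf])
    ub = np.array([np.inf, np.inf, np.inf])
    best = None
    last_err: Exception | None = None
    for x0 in starts:
        try:
            res = least_squares(
                residuals, x0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=5000,
            )
        except Exception as err:  # noqa: BLE001
            last_err = err
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"isotherm fit failed to converge: {last_err}")

    ka, dfree, dmax = (float(v) for v in best.x)
    ss_res = float(np.sum(best.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    notes: list[str] = []
    if np.ptp(y) == 0:
        notes.append(
            "weak-binding: no titration response; Ka indistinguishable from 0"
        )
    elif ka * c[-1] < config.weak_binding_threshold:
        notes.append(
            "weak-binding: saturation not approached "
            f"(max Ka*c = {ka * c[-1]:.3g}); Ka and delta_max poorly separable"
        )
    ka_stderr = _param_stderr(best, index=0)
    if not best.success:
        notes.append(f"optimizer did not report convergence: {best.message}")
    return BindingFit(
        residue=series.residue, ka=ka, delta_free=dfree, delta_max=dmax,
        r_squared=r2, ka_stderr=ka_stderr, warnings=notes,
    )


def _param_stderr(res, index: int) -> float:
    n, p = res.fun.size, res.x.size
    if n <= p:
        return float("nan")
    s2 = 2.0 * res.cost / (n - p)
    try:
        cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
    except np.linalg.LinAlgError:
        return float("nan")
    v = cov[index, index]
    return float(math.sqrt(v)) if v >= 0 else float("nan")


# ---------------------------------------------------------------------------
# Chemical shift perturbation
# ---------------------------------------------------------------------------


@dataclass
class ShiftTable:
    """Per-residue amide 1H shifts (ppm) for one condition."""

    peptide: str
    shifts: dict  # position -> ppm
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shifts = {int(k): float(v) for k, v in self.shifts.items()}
        if any(p < 1 for p in self.shifts):
            raise ValueError("positions are 1-based")

    @property
    def positions(self) -> set:
        return set(self.shifts)


@dataclass
class CSPMap:
    """Signed per-residue shift differences (bound - free), ppm."""

    peptide: str
    salt: str
    delta: dict  # position -> ppm (upfield negative)
    error_threshold: float = DEFAULT_ERROR_PPM

    def __post_init__(self) -> None:
        self.delta = {int(k): float(v) for k, v in self.delta.items()}

    def significant(self, position: int) -> bool:
        return abs(self.delta[position]) > self.error_threshold

    def classify(self, position: int) -> str:
        """"association" (upfield), "non-specific" (downfield) or
        "insignificant"."""
        d = self.delta[position]
        if abs(d) <= self.error_threshold:
            return "insignificant"
        return "association" if d < 0 else "non-specific"

    def largest(self) -> tuple[int, float]:
        pos = max(self.delta, key=lambda p: abs(self.delta[p]))
        return pos, self.delta[pos]


def csp(free: ShiftTable, bound: ShiftTable, error_threshold: float = DEFAULT_ERROR_PPM) -> CSPMap:
    """Per-residue Delta-delta = bound - free, with a significance cut."""
    if free.peptide != bound.peptide:
        raise ValueError(f"peptide mismatch: {free.peptide!r} vs {bound.peptide!r}")
    missing = free.positions ^ bound.positions
    if missing:
        raise ValueError(f"residue coverage mismatch at positions {sorted(missing)}")
    delta = {p: bound.shifts[p] - free.shifts[p] for p in sorted(free.positions)}
    return CSPMap(
        peptide=free.peptide,
        salt=str(bound.condition.get("salt", "")),
        delta=delta,
        error_threshold=error_threshold,
    )


@dataclass
class NeighborComparison:
    position: int
    delta_i: float
    delta_ip1: float
    holds: bool  # |delta_i| > |delta_ip1| (strict; ties are exceptions)
    tie: bool = False


@dataclass
class NeighborAsymmetryReport:
    comparisons: list
    skipped: list  # (position, note)

    @property
    def holds_count(self) -> int:
        return sum(1 for c in self.comparisons if c.holds)

    @property
    def exception_count(self) -> int:
        return sum(1 for c in self.comparisons if not c.holds)

    def to_dict(self) -> dict:
        return {
            "comparisons": [
                {
                    "position": c.position,
                    "delta_i_ppm": c.delta_i,
                    "delta_ip1_ppm": c.delta_ip1,
                    "holds": c.holds,
                    "tie": c.tie,
                }
                for c in self.comparisons
            ],
            "holds": self.holds_count,
            "exceptions": self.exception_count,
            "skipped": [{"position": p, "note": n} for p, n in self.skipped],
        }


def neighbor_asymmetry(cmap: CSPMap, charged_positions) -> NeighborAsymmetryReport:
    """Test, at each charged position i, whether the N-terminal-side amide
    perturbation exceeds the C-terminal-side one: |Δδ_i| > |Δδ_{i+1}|.

    Ties fail the strict inequality and are counted as exceptions.
    Positions lacking either observable amide are skipped with a note.
    """
    comparisons, skipped = [], []
    for i in sorted(charged_positions):
        if i not in cmap.delta or (i + 1) not in cmap.delta:
            missing = [p for p in (i, i + 1) if p not in cmap.delta]
            skipped.append((i, f"amide(s) at position(s) {missing} not observable"))
            continue
        di, dip1 = cmap.delta[i], cmap.delta[i + 1]
        tie = abs(di) == abs(dip1)
        comparisons.append(
            NeighborComparison(
                position=i, delta_i=di, delta_ip1=dip1,
                holds=abs(di) > abs(dip1), tie=tie,
            )
        )
    return NeighborAsymmetryReport(comparisons=comparisons, skipped=skipped)


def bubble_map_export(cmap: CSPMap, peptide: PeptideSequence | None = None) -> pd.DataFrame:
    """Tidy plot-data table for a bubble map.

    Bubble *area* (not radius) is proportional to |Δδ|; radius therefore
    scales with sqrt(|Δδ|).  Color class follows the sign convention:
    upfield (negative) and downfield (positive).
    """
    rows = []
    for pos in sorted(cmap.delta):
        d = cmap.delta[pos]
        label = peptide.label(pos) if peptide is not None else str(pos)
        rows.append(
            {
                "position": pos,
                "residue": label,
                "delta_ppm": d,
                "area": abs(d),
                "radius": math.sqrt(abs(d)),
                "color_class": "upfield" if d < 0 else ("downfield" if d > 0 else "zero"),
                "significant": abs(d) > cmap.error_threshold,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------


def read_titration_csv(path) -> TitrationSeries:
    """Read `conc_M,shift_ppm` (+ optional residue/peptide/salt columns)."""
    df = pd.read_csv(path)
    for col in ("conc_M", "shift_ppm"):
        if col not in df.columns:
            raise ValueError(f"titration CSV requires a {col!r} column")
    get = lambda col: str(df[col].iloc[0]) if col in df.columns else ""
    return TitrationSeries(
        residue=get("residue"),
        concentrations=df["conc_M"].to_numpy(),
        shifts=df["shift_ppm"].to_numpy(),
        peptide=get("peptide"),
        salt=get("salt"),
    )


def read_shift_table_csv(path, peptide: str = "", condition: dict | None = None) -> ShiftTable:
    """Read `position,residue,shift_ppm` into a ShiftTable."""
    df = pd.read_csv(path)
    for col in ("position", "shift_ppm"):
        if col not in df.columns:
            raise ValueError(f"shift table CSV requires a {col!r} column")
    if "peptide" in df.columns and not peptide:
        peptide = str(df["peptide"].iloc[0])
    shifts = dict(zip(df["position"].astype(int), df["shift_ppm"].astype(float)))
    return ShiftTable(peptide=peptide, shifts=shifts, condition=condition or {})
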