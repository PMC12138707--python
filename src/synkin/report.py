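"""Consolidated study runner: configuration, hashing and the JSON report.

A study config is a plain dict (JSON or YAML on disk) naming input CSVs
and thresholds; `run_study` executes every configured stage, collects
per-stage results or diagnostics, and emits one deterministic report
(schema-versioned, config-hash stamped, no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .binding import (
    BindingConfig,
    csp,
    fit_ka,
    neighbor_asymmetry,
    bubble_map_export,
    read_shift_table_csv,
    read_titration_csv,
)
from .fw import FWFitConfig, fit_fw
from .structure import (
    COIL_MAX_HZ,
    DEFAULT_KARPLUS,
    EXTENDED_MIN_HZ,
    KarplusParams,
    classify_residue,
    j_rmsd,
    read_jset_csv,
    read_vt_csv,
    temp_coeff,
)
from .traces import normalize_trace, read_raw_csv, read_trace_csv, write_trace_csv

log = logging.getLogger("synkin")

SCHEMA_VERSION = "1"


@dataclass
class StudyConfig:
    """Wrapper around the raw config mapping; fully serializable, so a run
    is reproducible from config + inputs alone."""

    data: dict
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValueError("study config must be a mapping")
        return cls(data=data, base_dir=path.parent)

    def hash(self) -> str:
        canon = json.dumps(self.data, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()

    def resolve(self, p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p


def _stage(fn):
    """Run one stage item, capturing failures as diagnostics."""
    try:
        return {"status": "ok", **fn()}
    except Exception as err:  # noqa: BLE001 - stage isolation is the contract
        log.warning("stage failed: %s", err)
        return {"status": "failed", "error": f"{type(err).__name__}: {err}"}


def run_study(config: StudyConfig, out_dir=None) -> dict:
    """Execute every configured stage and return the consolidated report.

    Stages (each optional): ``raw_traces`` (normalize), ``fw_traces``
    (Finke-Watzky fits), ``titrations`` (Ka fits), ``csp`` (perturbation
    maps + neighbor asymmetry), ``jsets`` (classification + RMSD vs the
    reference set), ``vt`` (temperature coefficients).  Failures are
    recorded per item; partial results are preserved.
    """
    cfg = config.data
    thresholds = cfg.get("thresholds", {})
    seed = int(cfg.get("seed", 0))
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    karplus = DEFAULT_KARPLUS
    if "karplus" in cfg:
        k = cfg["karplus"]
        karplus = KarplusParams(
            a=k["A"], b=k["B"], c=k["C"],
            phase_offset_deg=k.get("phase_offset_deg", 60.0),
            provenance=k.get("provenance", "user-supplied"),
        )

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config.hash(),
        "seed": seed,
        "versions": {
            "synkin": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }

    if "raw_traces" in cfg:
        items = {}
        for item in cfg["raw_traces"]:
            label = item.get("label", Path(item["path"]).stem)

            def do(item=item, label=label):
                raw = read_raw_csv(
                    config.resolve(item["path"]),
                    metadata={"a0_mM": item.get("a0", cfg.get("a0_mM", 2.0))},
                )
                trace = normalize_trace(raw, combine=item.get("combine", "mean"))
                if out_dir is not None:
                    write_trace_csv(trace, out_dir / f"trace_{label}.csv")
                return {"n_points": len(trace.times), "n_clipped": trace.metadata["n_clipped"]}

            items[label] = _stage(do)
        report["stages"]["normalize"] = items

    if "fw_traces" in cfg:
        items = {}
        for item in cfg["fw_traces"]:
            label = item.get("label", Path(item["path"]).stem)

            def do(item=item):
                trace = read_trace_csv(
                    config.resolve(item["path"]),
                    a0=item.get("a0", cfg.get("a0_mM")),
                )
                fit_cfg = FWFitConfig(
                    a0=item.get("a0", cfg.get("a0_mM")),
                    r2_threshold=thresholds.get("r2_fw", 0.98),
                    fit_amplitude=bool(item.get("fit_amplitude", False)),
                    seed=seed,
                )
                return fit_fw(trace, fit_cfg).to_dict()

            items[label] = _stage(do)
        report["stages"]["fw"] = items

    if "titrations" in cfg:
        items = {}
        bind_cfg = BindingConfig(
            model=cfg.get("isotherm_model", "excess"),
            peptide_conc_M=cfg.get("peptide_conc_M", 0.005),
            seed=seed,
        )
        for item in cfg["titrations"]:
            label = item.get("label", Path(item["path"]).stem)

            def do(item=item):
                series = read_titration_csv(config.resolve(item["path"]))
                return fit_ka(series, bind_cfg).to_dict()

            items[label] = _stage(do)
        report["stages"]["binding"] = items

    if "csp" in cfg:
        items = {}
        err_ppm = thresholds.get("csp_error_ppm", 0.005)
        for item in cfg["csp"]:
            label = item.get("label", Path(item["bound"]).stem)

            def do(item=item, label=label):
                free = read_shift_table_csv(config.resolve(item["free"]))
                bound = read_shift_table_csv(config.resolve(item["bound"]))
                cmap = csp(free, bound, error_threshold=err_ppm)
                out = {
                    "delta_ppm": {str(p): d for p, d in sorted(cmap.delta.items())},
                    "largest": dict(zip(("position", "delta_ppm"), cmap.largest())),
                }
                if "charged_positions" in item:
                    out["neighbor_asymmetry"] = neighbor_asymmetry(
                        cmap, item["charged_positions"]
                    ).to_dict()
                if out_dir is not None:
                    bubble_map_export(cmap).to_csv(
                        out_dir / f"bubble_{label}.csv", index=False
                    )
                return out

            items[label] = _stage(do)
        report["stages"]["csp"] = items

    if "jsets" in cfg:

        def do_jsets():
            jcfg = cfg["jsets"]
            ref = read_jset_csv(config.resolve(jcfg["reference"]))
            coil_max = thresholds.get("coil_max_Hz", COIL_MAX_HZ)
            ext_min = thresholds.get("extended_min_Hz", EXTENDED_MIN_HZ)
            out = {
                "reference_classes": {
                    str(p): classify_residue(v, coil_max, ext_min)
                    for p, v in sorted(ref.values.items())
                },
                "rmsd_vs_reference_Hz": {},
            }
            for item in jcfg.get("others", []):
                other = read_jset_csv(config.resolve(item["path"]))
                label = item.get("label", Path(item["path"]).stem)
                out["rmsd_vs_reference_Hz"][label] = j_rmsd(ref, other)
            return out

        report["stages"]["jcoupling"] = _stage(do_jsets)

    if "vt" in cfg:
        items = {}
        r2_lin = thresholds.get("r2_linear", 0.99)
        for item in cfg["vt"]:
            label = item.get("label", Path(item["path"]).stem)

            def do(item=item):
                series = read_vt_csv(config.resolve(item["path"]))
                return temp_coeff(series, r2_threshold=r2_lin).to_dict()

            items[label] = _stage(do)
        report["stages"]["vt"] = items

    if out_dir is not None:
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
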