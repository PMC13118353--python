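"""Summary-table builders and CSV writers.

Three summary layouts mirror the study's reporting: steady-state exposure
with IVT-over-IV fold change per location; regimen summaries (route,
administrations, dose or rate, annual total, Red% per location); and the
device-failure sweep. ``write_summary_tables`` emits them as CSV together
with a JSON run log (config hash, package version) and a checksum
manifest.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .metrics import fold_change, red_percent, total_annual_dose
from .params import TNF_COMPARTMENTS, TargetParameters
from .simulate import SimulationResult, steady_state_average

_LOCATIONS = ("aqueous_humor", "icb_interstitial", "icb_plasma", "venous_plasma")

EXPOSURE_COLUMNS = ["drug", "location", "Cavg_ss_iv_pM", "Css_ivt_pM", "fold_change"]
REGIMEN_COLUMNS = [
    "drug", "roa", "regimen", "n_adm", "dose_ug", "release_rate_ug_per_week",
    "total_dose_ug",
    *[f"red_pct_{loc}" for loc in _LOCATIONS],
]


def exposure_table(
    drug_name: str,
    result_iv: SimulationResult,
    result_ivt: SimulationResult,
    window_iv: tuple[float, float],
    window_ivt: tuple[float, float],
) -> pd.DataFrame:
    """Steady-state drug exposure per location with IVT/IV fold change."""
    rows = []
    for loc in _LOCATIONS:
        c_iv = steady_state_average(result_iv, loc, "drug", window_iv)
        c_ivt = steady_state_average(result_ivt, loc, "drug", window_ivt)
        rows.append(
            {
                "drug": drug_name,
                "location": loc,
                "Cavg_ss_iv_pM": c_iv,
                "Css_ivt_pM": c_ivt,
                "fold_change": fold_change(c_ivt, c_iv),
            }
        )
    return pd.DataFrame(rows, columns=EXPOSURE_COLUMNS)


def regimen_row(
    drug_name: str,
    roa: str,
    regimen_label: str,
    schedule,
    result: SimulationResult,
    target: TargetParameters,
    window: tuple[float, float],
    dose_ug: float | None = None,
    release_rate: float | None = None,
) -> dict:
    """One regimen-summary row (Red% per location, annual total)."""
    n_adm = len(schedule)
    row = {
        "drug": drug_name,
        "roa": roa,
        "regimen": regimen_label,
        "n_adm": n_adm,
        "dose_ug": round(dose_ug, 1) if dose_ug is not None else None,
        "release_rate_ug_per_week": (
            round(release_rate, 3) if release_rate is not None else None
        ),
        "total_dose_ug": round(total_annual_dose(schedule), 1),
    }
    for loc in _LOCATIONS:
        c_avg = steady_state_average(result, loc, "tnf", window)
        row[f"red_pct_{loc}"] = round(
            red_percent(c_avg, target.SF, target.baseline_conc), 1
        )
    return row


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_summary_tables(
    out_dir: str | Path,
    *,
    exposure: pd.DataFrame | None = None,
    regimens: pd.DataFrame | Sequence[Mapping] | None = None,
    failure: pd.DataFrame | None = None,
    config: Mapping | None = None,
    extra_files: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Write summary CSVs plus a run log and a checksum manifest.

    Empty inputs produce header-only CSVs. Returns the manifest frame
    (one row per file with its SHA-256 checksum).
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame, columns=None) -> None:
        if columns is not None and frame.empty:
            frame = pd.DataFrame(columns=columns)
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)

    if exposure is not None:
        emit("exposure_summary.csv", pd.DataFrame(exposure), EXPOSURE_COLUMNS)
    if regimens is not None:
        emit("regimen_summary.csv", pd.DataFrame(regimens), REGIMEN_COLUMNS)
    if failure is not None:
        emit("failure_sweep.csv", pd.DataFrame(failure))
    for name, frame in (extra_files or {}).items():
        emit(name, frame)

    log = {
        "package": "ocusim",
        "version": __version__,
        "written_utc": datetime.now(timezone.utc).isoformat(),
        "config": dict(config) if config else None,
        "config_hash": (
            hashlib.sha256(
                json.dumps(dict(config), sort_keys=True, default=str).encode()
            ).hexdigest()[:16]
            if config
            else None
        ),
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, default=str))
    written.append(log_path)

    manifest = pd.DataFrame(
        [{"file": p.name, "sha256": _sha256(p)} for p in written]
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
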