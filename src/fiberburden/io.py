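"""Reading and writing the package's plain-text formats.

* Count sheet CSV — one row per logged fiber:
  ``field_index,length_um,width_um,mineral_class``.
* Session JSON — the companion record carrying ``n_fields_examined``
  and ``stop_reason`` (empty examined fields never appear in the CSV).
* Preparation JSON — ``dry_mass_ashed_mg, suspension_volume_ml,
  filtered_volume_ml, active_area_mm2, field_area_mm2, magnification``.
* Simulation config JSON — the fields of
  :class:`fiberburden.simulate.SimulationConfig` with the prep inline.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .burden import (
    CountingSession,
    FiberRecord,
    FilterPrep,
    MineralClass,
    StopReason,
)
from .simulate import SimulationConfig

__all__ = [
    "read_count_sheet",
    "write_count_sheet",
    "read_session",
    "write_session",
    "read_prep",
    "write_prep",
    "read_simulation_config",
    "write_simulation_config",
]

COUNT_SHEET_COLUMNS = ["field_index", "length_um", "width_um", "mineral_class"]

_PREP_KEYS = [
    "dry_mass_ashed_mg",
    "suspension_volume_ml",
    "filtered_volume_ml",
    "active_area_mm2",
    "field_area_mm2",
]


def read_count_sheet(path: str | Path) -> list[FiberRecord]:
    """Parse a count-sheet CSV into fiber records (empty file -> [])."""
    df = pd.read_csv(path)
    missing = [c for c in COUNT_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing count-sheet columns {missing}")
    return [
        FiberRecord(
            field_index=int(row.field_index),
            length_um=float(row.length_um),
            width_um=float(row.width_um),
            mineral_class=MineralClass(row.mineral_class),
        )
        for row in df.itertuples(index=False)
    ]


def write_count_sheet(fibers, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (f.field_index, f.length_um, f.width_um, f.mineral_class.value)
            for f in fibers
        ],
        columns=COUNT_SHEET_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_session(
    counts_path: str | Path, session_path: str | Path
) -> CountingSession:
    """Assemble a session from its count-sheet CSV and companion JSON."""
    fibers = read_count_sheet(counts_path)
    with open(session_path) as fh:
        doc = json.load(fh)
    return CountingSession(
        n_fields_examined=int(doc["n_fields_examined"]),
        fibers=tuple(fibers),
        stop_reason=StopReason(doc.get("stop_reason", "area_target_reached")),
    )


def write_session(
    session: CountingSession,
    counts_path: str | Path,
    session_path: str | Path,
) -> None:
    write_count_sheet(session.fibers, counts_path)
    with open(session_path, "w") as fh:
        json.dump(
            {
                "n_fields_examined": session.n_fields_examined,
                "stop_reason": session.stop_reason.value,
                "n_fibers_logged": len(session.fibers),
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def read_prep(path: str | Path) -> FilterPrep:
    with open(path) as fh:
        doc = json.load(fh)
    missing = [k for k in _PREP_KEYS if k not in doc]
    if missing:
        raise ValueError(f"{path}: missing preparation keys {missing}")
    return FilterPrep(
        dry_mass_ashed_mg=doc["dry_mass_ashed_mg"],
        suspension_volume_ml=doc["suspension_volume_ml"],
        filtered_volume_ml=doc["filtered_volume_ml"],
        active_area_mm2=doc["active_area_mm2"],
        field_area_mm2=doc["field_area_mm2"],
        magnification=int(doc.get("magnification", 12000)),
    )


def write_prep(prep: FilterPrep, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "dry_mass_ashed_mg": prep.dry_mass_ashed_mg,
                "suspension_volume_ml": prep.suspension_volume_ml,
                "filtered_volume_ml": prep.filtered_volume_ml,
                "active_area_mm2": prep.active_area_mm2,
                "field_area_mm2": prep.field_area_mm2,
                "magnification": prep.magnification,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def read_simulation_config(path: str | Path) -> SimulationConfig:
    """Simulation config JSON with the preparation inline under ``prep``."""
    with open(path) as fh:
        doc = json.load(fh)
    prep_doc = doc["prep"]
    prep = FilterPrep(
        dry_mass_ashed_mg=prep_doc["dry_mass_ashed_mg"],
        suspension_volume_ml=prep_doc["suspension_volume_ml"],
        filtered_volume_ml=prep_doc["filtered_volume_ml"],
        active_area_mm2=prep_doc["active_area_mm2"],
        field_area_mm2=prep_doc["field_area_mm2"],
        magnification=int(prep_doc.get("magnification", 12000)),
    )
    kwargs = dict(
        true_concentration=doc["true_concentration_ff_per_g"],
        prep=prep,
        dispersion=doc.get("dispersion", 0.0),
        fiber_cap=int(doc.get("fiber_cap", 50)),
        target_as=doc.get("target_as_ff_per_g", 1.0e5),
        sub_micron_fraction=doc.get("sub_micron_fraction", 0.0),
        seed=int(doc.get("seed", 0)),
    )
    if "length_log_mean" in doc:
        kwargs["length_log_mean"] = doc["length_log_mean"]
    if "length_log_sd" in doc:
        kwargs["length_log_sd"] = doc["length_log_sd"]
    if "mineral_class" in doc:
        kwargs["mineral_class"] = MineralClass(doc["mineral_class"])
    return SimulationConfig(**kwargs)


def write_simulation_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "true_concentration_ff_per_g": config.true_concentration,
                "dispersion": config.dispersion,
                "fiber_cap": config.fiber_cap,
                "target_as_ff_per_g": config.target_as,
                "length_log_mean": config.length_log_mean,
                "length_log_sd": config.length_log_sd,
                "sub_micron_fraction": config.sub_micron_fraction,
                "mineral_class": config.mineral_class.value,
                "seed": config.seed,
                "prep": {
                    "dry_mass_ashed_mg": config.prep.dry_mass_ashed_mg,
                    "suspension_volume_ml": config.prep.suspension_volume_ml,
                    "filtered_volume_ml": config.prep.filtered_volume_ml,
                    "active_area_mm2": config.prep.active_area_mm2,
                    "field_area_mm2": config.prep.field_area_mm2,
                    "magnification": config.prep.magnification,
                },
            },
            fh,
            indent=2,
        )
        fh.write("\n")
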