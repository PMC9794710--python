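"""CSV/JSON readers and writers shared across modules.

All tables are UTF-8 CSV with declared headers; decimal commas are rejected
explicitly rather than silently coerced to NaN.  Reports are JSON with the
settings and package version embedded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .kinetics import DoseResponsePoint, KineticObservation
from .mlr import DataTable, MLRModel
from .pampa import PampaWell

KINETICS_COLUMNS = ["substrate_mM", "inhibitor_uM", "velocity"]
DOSE_RESPONSE_COLUMNS = ["inhibitor_uM", "activity_pct"]
PAMPA_COLUMNS = ["compound", "c_donor", "c_acceptor", "v_donor_mL", "v_acceptor_mL", "area_cm2", "time_s"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in required if c not in frame.columns]
    extra = [c for c in frame.columns if c not in required and required != ["*"]]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}" + (f", unexpected {extra}" if extra else ""))
    if frame.empty:
        raise SchemaError(f"{path}: no data rows")
    return frame


def _float_column(frame: pd.DataFrame, column: str, path) -> np.ndarray:
    try:
        return frame[column].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise SchemaError(
            f"{path}: column {column!r} is not numeric "
            f"(decimal commas are not accepted): {exc}"
        ) from exc


def read_descriptor_table(path, response: str = "pIC50") -> DataTable:
    """descriptors.csv (+ response column) -> DataTable."""
    frame = _read_csv(path, ["id"])
    frame = frame.set_index("id")
    for column in frame.columns:
        frame[column] = _float_column(frame.reset_index(), column, path)
    return DataTable.from_frame(frame, response=response)


def read_kinetics_csv(path) -> list[KineticObservation]:
    frame = _read_csv(path, KINETICS_COLUMNS)
    return [
        KineticObservation(s, i, v)
        for s, i, v in zip(
            _float_column(frame, "substrate_mM", path),
            _float_column(frame, "inhibitor_uM", path),
            _float_column(frame, "velocity", path),
        )
    ]


def read_dose_response_csv(path) -> list[DoseResponsePoint]:
    frame = _read_csv(path, DOSE_RESPONSE_COLUMNS)
    return [
        DoseResponsePoint(c, a)
        for c, a in zip(
            _float_column(frame, "inhibitor_uM", path),
            _float_column(frame, "activity_pct", path),
        )
    ]


def read_pampa_csv(path) -> dict[str, list[PampaWell]]:
    frame = _read_csv(path, PAMPA_COLUMNS)
    wells: dict[str, list[PampaWell]] = {}
    for _, row in frame.iterrows():
        wells.setdefault(str(row["compound"]), []).append(
            PampaWell(
                c_donor=float(row["c_donor"]),
                c_acceptor=float(row["c_acceptor"]),
                v_donor=float(row["v_donor_mL"]),
                v_acceptor=float(row["v_acceptor_mL"]),
                area=float(row["area_cm2"]),
                time=float(row["time_s"]),
            )
        )
    return wells


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str)):
        return obj.value
    return obj


def write_report(path, payload: dict, settings: dict | None = None) -> None:
    """Write a JSON report with embedded settings and package version."""
    from . import __version__

    body = {"version": __version__, "settings": settings or {}}
    body.update(_jsonable(payload))
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True, allow_nan=False) + "\n")


def write_model_json(path, model: MLRModel, extra: dict | None = None) -> None:
    payload = {
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "train_ids": list(model.train_ids),
        "sigma": model.sigma,
    }
    payload.update(extra or {})
    write_report(path, payload)


def read_model_json(path) -> MLRModel:
    body = json.loads(Path(path).read_text())
    try:
        return MLRModel(
            intercept=float(body["intercept"]),
            coefficients={k: float(v) for k, v in body["coefficients"].items()},
            train_ids=tuple(body["train_ids"]),
            sigma=float(body["sigma"]),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: model JSON missing field {exc}") from exc
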