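"""End-to-end QSAR pipeline: registry -> descriptors -> split -> fit -> validate."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import descriptors as desc
from . import io as io_mod
from . import registry as reg
from . import validation as val
from .errors import ChalqsarError
from .mlr import DataTable, fit_mlr, split


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; the seed governs every stochastic step."""

    seed: int
    out_dir: str = "chalqsar_run"
    fixture_path: str | None = None  # packaged fixture when None
    subset: tuple[str, ...] = desc.MODEL_DESCRIPTORS
    split_fraction: float = 0.7
    split_strategy: str = "random"
    lmo_fraction: float = 0.3
    lmo_iterations: int = 1000
    yscr_iterations: int = 1000


def model_table(fixture_path: str | None = None) -> DataTable:
    """Descriptor/pIC50 table for the registry compounds (MAO-B response)."""
    records = reg.load_registry(fixture_path)
    smiles = {c.id: c.smiles for c, _ in records}
    frame = desc.descriptor_table(smiles)
    frame["pIC50"] = [reg.pic50(r.ic50_B) for _, r in records]
    return DataTable.from_frame(frame, response="pIC50")


def headline_ensemble(
    table: DataTable | None = None,
    subset: tuple[str, ...] = desc.MODEL_DESCRIPTORS,
    n_seeds: int = 50,
    fraction: float = 0.7,
    reference_r2: float | None = None,
    reference_q2: float | None = None,
) -> dict:
    """Training R² and Q²_loo distributions over seeded random splits.

    Because the exact train/test membership behind a published model is
    rarely recoverable, headline statistics are summarised over an ensemble
    of splits: per seed, fit the subset on the training rows and record
    R²_tr and Q²_loo.  When reference values are supplied the report flags
    whether each falls outside the 5–95% envelope (descriptor-dialect and
    split-membership sensitivity make that a documented possibility rather
    than an error).
    """
    import numpy as np

    if table is None:
        table = model_table()
    r2s, q2s = [], []
    for seed in range(n_seeds):
        plan = split(table, fraction, seed)
        train = table.take(plan.train_ids)
        model = fit_mlr(train, subset)
        r2s.append(val.fit_stats(model, train).r2_tr)
        q2s.append(val.q2_loo(train, subset).q2_loo)
    r2s, q2s = np.array(r2s), np.array(q2s)
    report = {
        "n_seeds": n_seeds,
        "r2_tr": {
            "median": float(np.median(r2s)),
            "p5": float(np.percentile(r2s, 5)),
            "p95": float(np.percentile(r2s, 95)),
        },
        "q2_loo": {
            "median": float(np.median(q2s)),
            "p5": float(np.percentile(q2s, 5)),
            "p95": float(np.percentile(q2s, 95)),
        },
    }
    for key, ref in (("r2_tr", reference_r2), ("q2_loo", reference_q2)):
        if ref is not None:
            block = report[key]
            block["reference"] = ref
            block["reference_outside_envelope"] = bool(ref < block["p5"] or ref > block["p95"])
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write model.json + validation.json.

    Returns the report dictionary; the Golbraikh–Tropsha overall outcome is
    under ``report["gt"]["all_pass"]``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = model_table(config.fixture_path)
    plan = split(table, config.split_fraction, config.seed, config.split_strategy)
    train, test = table.take(plan.train_ids), table.take(plan.test_ids)

    model = fit_mlr(train, config.subset)
    fit = val.fit_stats(model, train)
    cv = val.q2_loo(train, config.subset)
    lmo = val.q2_lmo(train, config.subset, config.lmo_fraction, config.lmo_iterations, config.seed)
    cv = val.CVStats(
        q2_loo=cv.q2_loo,
        rmse_cv=cv.rmse_cv,
        mae_cv=cv.mae_cv,
        press_cv=cv.press_cv,
        ccc_cv=cv.ccc_cv,
        q2_lmo=lmo,
        lmo_fraction=config.lmo_fraction,
        lmo_iterations=config.lmo_iterations,
        seed=config.seed,
    )
    scramble = val.y_scramble(train, config.subset, config.yscr_iterations, config.seed)
    ext = val.external_stats(model, test, train)
    gt = val.gt_check(fit, cv, ext)
    ad = val.applicability_domain(model, train, test)

    settings = {
        "seed": config.seed,
        "subset": list(config.subset),
        "split": {"fraction": config.split_fraction, "strategy": config.split_strategy},
        "lmo": {"fraction": config.lmo_fraction, "iterations": config.lmo_iterations},
        "yscrambling_iterations": config.yscr_iterations,
    }
    io_mod.write_model_json(out / "model.json", model, extra={"seed": config.seed})
    report = {
        "split": {"train_ids": list(plan.train_ids), "test_ids": list(plan.test_ids)},
        "fitting": fit,
        "internal_validation": {
            "q2_loo": cv.q2_loo,
            "rmse_cv": cv.rmse_cv,
            "mae_cv": cv.mae_cv,
            "press_cv": cv.press_cv,
            "ccc_cv": cv.ccc_cv,
            "q2_lmo": cv.q2_lmo,
        },
        "y_scrambling": {
            "r2_yscr_mean": scramble.r2_yscr_mean,
            "q2_yscr_mean": scramble.q2_yscr_mean,
            "iterations": scramble.iterations,
        },
        "external_validation": ext,
        "gt": gt,
        "applicability_domain": {
            "h_star": ad.h_star,
            "leverages": ad.leverages,
            "outliers": list(ad.outliers),
            "outside_domain": list(ad.outside_domain),
        },
    }
    io_mod.write_report(out / "validation.json", report, settings=settings)
    return report
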