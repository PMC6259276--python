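"""Pipeline orchestration and report generation.

Two entry points:

* :func:`run_pipeline` — the full structure-based chain: build the 26
  structures, embed/minimize/charge them, align to the template (compound
  10), evaluate CoMFA and CoMSIA fields on the common lattice, fit
  column-filtered PLS models with LOO component selection, validate on the
  5-compound test set, and export contour fields. Because the original
  force field and charge scheme are proprietary, this layer reproduces the
  published statistics approximately, not exactly.

* :func:`stats_only_report` — the exactly-verifiable statistics layer: all
  internal and external validation statistics recomputed purely from the
  published actual/predicted activity table, plus the rm^2/ratio arithmetic
  on the printed summary constants.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import compounds as cmpd
from . import prep
from .fields import (
    ALL_CHANNELS,
    COMFA_CHANNELS,
    COMSIA_CHANNELS,
    FieldMatrix,
    ProbeSpec,
    assemble_field_matrix,
    make_grid,
)
from .contours import stdev_coeff
from .pls import filter_columns, fit_pls, internal_stats, loo_q2, regression_stats
from .validation import external_validation, rm_squared

__all__ = ["RunConfig", "ModelResult", "PipelineResult", "run_pipeline", "stats_only_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; defaults are the study's stated conditions."""

    grid_spacing: float = 1.0       # A
    grid_margin: float = 4.0        # A
    probe_charge: float = 1.0       # e
    probe_radius: float = 1.0       # A (CoMSIA)
    attenuation: float = 0.3        # A^-2
    filter_threshold: float = 2.0   # minimum column sigma
    max_components: int = 10
    scaling: str = "comfa_std"
    seed: int = 2010
    out_dir: str | Path | None = None

    def probe(self) -> ProbeSpec:
        return ProbeSpec(charge=self.probe_charge, radius=self.probe_radius)


@dataclass
class ModelResult:
    """One fitted model (CoMFA or CoMSIA) with its statistics."""

    name: str
    channels: tuple[str, ...]
    q2: float
    onc: int
    internal: "object"              # InternalStats
    external: "object"              # ExternalValidationReport
    n_columns_kept: int
    model: "object"                 # PLSModel
    contours: dict[str, "object"]   # channel -> ContourField
    predictions: pd.DataFrame


@dataclass
class PipelineResult:
    comfa: ModelResult
    comsia: ModelResult
    field_matrix: FieldMatrix
    alignments: dict[int, "object"]
    log: dict = field(default_factory=dict)


def _fit_one_model(
    name: str,
    channels: tuple[str, ...],
    fm: FieldMatrix,
    table: pd.DataFrame,
    config: RunConfig,
) -> ModelResult:
    X = fm.channel_block(channels)
    labels = fm.channel_of_column(channels)
    is_train = (table["subset"] == "train").to_numpy()
    y = table["pec50_actual"].to_numpy(float)
    X_train, y_train = X[is_train], y[is_train]
    mask = filter_columns(X_train, config.filter_threshold)
    cv = loo_q2(
        X_train, y_train, config.max_components,
        column_mask=mask, scaling=config.scaling, channel_of_column=labels,
    )
    model = fit_pls(
        X_train, y_train, cv.onc,
        column_mask=mask, scaling=config.scaling, channel_of_column=labels,
    )
    stats = internal_stats(model, X_train, y_train)
    pred_all = model.predict(X)
    ext = external_validation(
        y[~is_train], pred_all[~is_train], float(y_train.mean()),
        q2=cv.q2, training_r2=stats.r2,
    )
    short = {c: c.split("_", 1)[1] for c in channels}
    contour = {short[c]: stdev_coeff(model, fm, c) for c in channels}
    predictions = pd.DataFrame(
        {
            "compound_id": table["compound_id"],
            "pec50_actual": y,
            "pec50_pred": pred_all,
            "residual": y - pred_all,
            "subset": table["subset"],
        }
    )
    logger.info(
        "%s: q2=%.3f onc=%d r2=%.3f see=%.3f f=%.1f r2pred=%.3f (%d columns kept)",
        name, cv.q2, cv.onc, stats.r2, stats.see, stats.f_value, ext.r2_pred,
        int(mask.sum()),
    )
    return ModelResult(
        name=name,
        channels=channels,
        q2=cv.q2,
        onc=cv.onc,
        internal=stats,
        external=ext,
        n_columns_kept=int(mask.sum()),
        model=model,
        contours=contour,
        predictions=predictions,
    )


def run_pipeline(config: RunConfig = RunConfig()) -> PipelineResult:
    """Run the full structure-to-statistics chain on the packaged 26 compounds."""
    t0 = time.time()
    log: dict = {"seed": config.seed, "stages": {}}
    records = cmpd.load_compound_table()
    table = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "pec50_actual": [r.pec50_actual for r in records],
            "subset": [r.subset for r in records],
        }
    )

    t = time.time()
    conformers = {}
    for r in records:
        mol = cmpd.build_structure(r)
        molh = prep.embed_and_minimize(mol, seed=config.seed + r.compound_id)
        conformers[r.compound_id] = prep.conformer_from_mol(molh, r.compound_id)
    log["stages"]["prepare"] = round(time.time() - t, 2)

    t = time.time()
    template = conformers[10]
    alignments, aligned = {}, []
    for r in records:
        res, conf = prep.align_to_template(conformers[r.compound_id], template)
        alignments[r.compound_id] = res
        aligned.append(conf)
    log["stages"]["align"] = round(time.time() - t, 2)

    t = time.time()
    grid = make_grid(aligned, config.grid_spacing, config.grid_margin)
    fm = assemble_field_matrix(aligned, grid, config.probe(), ALL_CHANNELS)
    log["stages"]["fields"] = round(time.time() - t, 2)
    log["grid"] = {"dims": list(grid.dims), "n_points": grid.n_points}

    t = time.time()
    comfa = _fit_one_model("CoMFA", COMFA_CHANNELS, fm, table, config)
    comsia = _fit_one_model("CoMSIA", COMSIA_CHANNELS, fm, table, config)
    log["stages"]["models"] = round(time.time() - t, 2)
    log["total_seconds"] = round(time.time() - t0, 2)

    result = PipelineResult(comfa=comfa, comsia=comsia, field_matrix=fm,
                            alignments=alignments, log=log)
    if config.out_dir is not None:
        _write_reports(result, Path(config.out_dir))
    return result


def _model_report(m: ModelResult) -> dict:
    return {
        "q2": m.q2,
        "onc": m.onc,
        "r2": m.internal.r2,
        "see": m.internal.see,
        "f_value": m.internal.f_value,
        "field_contributions": m.internal.field_contributions,
        "n_columns_kept": m.n_columns_kept,
    }


def _write_reports(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    t2 = result.comfa.predictions.rename(
        columns={"pec50_pred": "pec50_pred_comfa", "residual": "residual_comfa"}
    ).merge(
        result.comsia.predictions[["compound_id", "pec50_pred", "residual"]].rename(
            columns={"pec50_pred": "pec50_pred_comsia", "residual": "residual_comsia"}
        ),
        on="compound_id",
    )
    t2.to_csv(out_dir / "table2_like.csv", index=False, float_format="%.3f")
    t3 = {"comfa": _model_report(result.comfa), "comsia": _model_report(result.comsia)}
    (out_dir / "table3_like.json").write_text(json.dumps(t3, indent=1, sort_keys=True))
    t4 = {
        "comfa": result.comfa.external.to_dict(),
        "comsia": result.comsia.external.to_dict(),
    }
    (out_dir / "table4_like.json").write_text(json.dumps(t4, indent=1, sort_keys=True))
    (out_dir / "run_log.json").write_text(json.dumps(result.log, indent=1, sort_keys=True))


def stats_only_report(
    table: pd.DataFrame | None = None, reference: dict | None = None
) -> dict:
    """All Table-3/Table-4-style statistics from the printed activity table.

    Internal statistics (r2, SEE, F at the published ONC) come from the
    training rows; external statistics from the 5 test rows and the
    training-mean activity. ``from_printed_constants`` applies the rm^2 and
    gap-ratio arithmetic to the printed summary constants themselves, which
    is the arithmetic that reproduces the published rm^2 to print precision.
    """
    if table is None:
        table = cmpd.load_activity_table()
    if reference is None:
        reference = cmpd.load_reference_stats()
    out: dict = {"n_train": int((table["subset"] == "train").sum()),
                 "n_test": int((table["subset"] == "test").sum())}
    train = table[table["subset"] == "train"]
    test = table[table["subset"] == "test"]
    train_mean = float(train["pec50_actual"].mean())
    for model in ("comfa", "comsia"):
        ref = reference[model]
        onc = int(ref["onc"])
        r2, see, f = regression_stats(
            train["pec50_actual"], train[f"pec50_pred_{model}"], onc
        )
        ext = external_validation(
            test["pec50_actual"].to_numpy(),
            test[f"pec50_pred_{model}"].to_numpy(),
            train_mean,
            q2=ref["r2_cv"],
            training_r2=r2,
        )
        out[model] = {
            "recomputed_from_table2": {
                "r2": r2,
                "see": see,
                "f_value": f,
                "onc": onc,
                **ext.to_dict(),
            },
            "from_printed_constants": {
                "rm_sq": rm_squared(ref["r2"], ref["r0_sq"]),
                "ratio": (ref["r2"] - ref["r0_sq"]) / ref["r2"],
            },
        }
    return out
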