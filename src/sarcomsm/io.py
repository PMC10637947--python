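"""Readers, writers, configuration and the end-to-end analysis pipeline.

The staged-panel interchange format is a delimited text file with one row per
subject-visit: ``subject_id``, ``time`` (decimal years since the subject's
baseline), ``state`` (1 = no sarcopenia, 2 = possible sarcopenia,
3 = sarcopenia, 4 = death; 5 = dropout in the sensitivity structure), an
optional boolean ``death_exact`` and any covariate columns.  Raw-measurement
files carry one column per instrument reading with explicit unable-flag
columns rather than sentinel values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .msm import (DEFAULT_STRUCTURE, DROPOUT_STRUCTURE, PanelDataset,
                  TransitionStructure, crude_rates, fit_msm, goodness_of_fit,
                  hazard_ratios, observed_transition_table,
                  predict_probability_ci, sojourn_times)
from .staging import CutoffSet, MeasurementRecord, derive_mass_cutoffs, stage_panel

__all__ = ["RunConfig", "read_panel", "write_panel", "read_raw_measurements",
           "run_pipeline"]

logger = logging.getLogger("sarcomsm")

RAW_COLUMNS = {
    # column dictionary of the raw-measurement CSV
    "subject_id": "opaque subject identifier",
    "time": "years since baseline visit",
    "weight": "body weight, kg",
    "height": "standing height, cm",
    "sex": "1 = male, 2 = female",
    "age": "age in years",
    "grip1": "handgrip trial, kg", "grip2": "handgrip trial, kg",
    "grip3": "handgrip trial, kg", "grip4": "handgrip trial, kg",
    "grip_full_effort": "1 if trials performed with full effort",
    "walk1": "2.5 m walk time, s", "walk2": "2.5 m walk time, s",
    "walk_unable": "1 if unable to complete the walk",
    "chair_time": "time for 5 chair stands, s",
    "chair_unable": "1 if unable to perform chair stands",
    "bal_side": "side-by-side hold, s", "bal_semi": "semi-tandem hold, s",
    "bal_full": "full-tandem hold, s",
    "bal_unable": "1 if unable to perform the balance test",
}


def read_panel(path: str | Path,
               column_map: Optional[Mapping[str, str]] = None,
               covariates: Sequence[str] = (),
               structure: TransitionStructure = DEFAULT_STRUCTURE) -> PanelDataset:
    """Read a staged panel CSV into a validated :class:`PanelDataset`.

    ``column_map`` renames file columns to the canonical names.  Rows whose
    time or state fail to parse raise an error listing 1-based data line
    numbers; non-increasing times or post-absorbing observations raise with
    the offending subject named.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in ("time", "state"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:20])  # +2: header + 1-based
            raise ValueError(f"{path}: unparseable {col!r} on line(s) {lines}")
        df[col] = parsed
    n_na = int(df["state"].isna().sum())
    if n_na:
        logger.info("dropping %d rows without a staged state", n_na)
        df = df.dropna(subset=["state"])
    ds = PanelDataset.from_frame(df, covariates=covariates, structure=structure)
    if ds.n_dropped_singletons:
        logger.info("dropped %d single-observation subjects", ds.n_dropped_singletons)
    return ds


def write_panel(ds: PanelDataset, path: str | Path) -> None:
    """Write a panel dataset back to CSV (times with 2 decimals)."""
    df = ds.data.copy()
    df["time"] = df["time"].map(lambda t: f"{t:.2f}")
    df.to_csv(path, index=False)


def _opt_float(v) -> Optional[float]:
    return None if pd.isna(v) else float(v)


def read_raw_measurements(path: str | Path) -> list[MeasurementRecord]:
    """Read a raw-measurement CSV (see ``RAW_COLUMNS``) into records."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        grips = tuple(float(row[c]) for c in ("grip1", "grip2", "grip3", "grip4")
                      if c in df.columns and not pd.isna(row.get(c)))
        walks = tuple(float(row[c]) for c in ("walk1", "walk2")
                      if c in df.columns and not pd.isna(row.get(c)))
        records.append(MeasurementRecord(
            subject_id=str(row["subject_id"]),
            visit_time=float(row["time"]),
            weight=_opt_float(row.get("weight")),
            height=_opt_float(row.get("height")),
            sex_code=None if pd.isna(row.get("sex")) else int(row["sex"]),
            age=_opt_float(row.get("age")),
            grip_measurements=grips,
            grip_full_effort=bool(row.get("grip_full_effort", 1)),
            walk_times=walks,
            walk_unable=bool(row.get("walk_unable", 0)),
            chair_stand_time=_opt_float(row.get("chair_time")),
            chair_unable=bool(row.get("chair_unable", 0)),
            balance_side_by_side=_opt_float(row.get("bal_side")),
            balance_semi_tandem=_opt_float(row.get("bal_semi")),
            balance_full_tandem=_opt_float(row.get("bal_full")),
            balance_unable=bool(row.get("bal_unable", 0)),
        ))
    return records


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    input_path: str
    output_dir: str
    input_kind: str = "staged"            # "staged" | "raw"
    column_map: dict = field(default_factory=dict)
    structure: str = "default"            # "default" | "dropout-absorbing"
    covariates: list = field(default_factory=list)
    covariate_transitions: str = "transient"
    cutoffs: str = "default"              # "default" | "derive"
    exact_death: bool = True
    bootstrap_draws: int = 1000
    seed: int = 0
    optimizer_options: dict = field(default_factory=dict)
    prediction_time: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def transition_structure(self) -> TransitionStructure:
        if self.structure == "default":
            return DEFAULT_STRUCTURE
        if self.structure == "dropout-absorbing":
            return DROPOUT_STRUCTURE
        raise ValueError(f"unknown structure {self.structure!r}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run stage → fit → predict → summarize and write a report bundle.

    Steps: read (staging raw measurements first when configured), fit the
    no-covariate model, 1-year transition probabilities with bootstrap CIs,
    sojourn times, crude rates, the observed-transition table, an
    observed-vs-expected prevalence check, and — when covariates are
    configured — the proportional-intensity model with hazard ratios.
    Outputs (JSON report, CSV tables, plain-text log) are deterministic
    given the config seed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    structure = config.transition_structure()
    report: dict = {"config": config.__dict__.copy()}

    try:
        if config.input_kind == "raw":
            records = read_raw_measurements(config.input_path)
            if config.cutoffs == "derive":
                from .staging import estimate_asm
                male = [estimate_asm(r)[1] for r in records if r.sex_code == 1
                        and r.weight and r.height and r.age is not None]
                female = [estimate_asm(r)[1] for r in records if r.sex_code == 2
                          and r.weight and r.height and r.age is not None]
                cutoffs = derive_mass_cutoffs(male, female)
            else:
                cutoffs = CutoffSet()
            staged = stage_panel(records, cutoffs, compute_grip_qc=True)
            for _, row in staged[staged["exclusion_reason"].notna()].iterrows():
                logger.info("excluded %s t=%.2f: %s", row["subject_id"],
                            row["time"], row["exclusion_reason"])
            report["n_excluded_visits"] = int(staged["exclusion_reason"].notna().sum())
            staged_path = outdir / "staged.csv"
            staged.to_csv(staged_path, index=False)
            panel_df = staged.dropna(subset=["state"])[["subject_id", "time", "state"]]
            data = PanelDataset.from_frame(panel_df, structure=structure)
        else:
            data = read_panel(config.input_path, config.column_map,
                              covariates=tuple(config.covariates), structure=structure)
        report["n_subjects"] = data.n_subjects
        report["n_observations"] = len(data.data)

        model = fit_msm(data, structure=structure, exact_death=config.exact_death,
                        options=config.optimizer_options)
        logger.info("no-covariate fit: loglik=%.3f converged=%s iterations=%d",
                    model.log_likelihood, model.converged, model.n_iter)
        report["log_likelihood"] = model.log_likelihood
        report["converged"] = model.converged

        intens = model.intensities_with_ci()
        intens.to_csv(outdir / "intensities.csv", index=False)
        report["intensities"] = intens

        t = config.prediction_time
        point, lo, hi = predict_probability_ci(model, t, n_draws=config.bootstrap_draws,
                                               seed=config.seed)
        p_rows = []
        for r in range(structure.n_states):
            for s in range(structure.n_states):
                p_rows.append({"from": r + 1, "to": s + 1, "prob": point[r, s],
                               "lower": lo[r, s], "upper": hi[r, s]})
        p_df = pd.DataFrame(p_rows)
        p_df.to_csv(outdir / f"probabilities_t{t:g}.csv", index=False)
        report["transition_probabilities"] = {"t": t, "table": p_df}

        soj = model.sojourn_with_ci()
        soj.to_csv(outdir / "sojourn.csv", index=False)
        report["sojourn_times"] = soj

        panel_states = data.data[["subject_id", "time", "state"]]
        rates = crude_rates(panel_states)
        rates.to_csv(outdir / "crude_rates.csv", index=False)
        report["crude_rates"] = rates

        table = observed_transition_table(panel_states)
        table.counts.to_csv(outdir / "transition_counts.csv")
        table.percentages.round(1).to_csv(outdir / "transition_percentages.csv")
        report["transition_counts"] = table.counts
        report["transition_percentages"] = table.percentages.round(1)

        eval_times = sorted(data.data["time"].round().unique())[:4]
        gof = goodness_of_fit(model, data, eval_times)
        gof.to_csv(outdir / "goodness_of_fit.csv", index=False)
        report["goodness_of_fit"] = gof

        if config.covariates:
            cov_spec = {c: config.covariate_transitions for c in config.covariates}
            cmodel = fit_msm(data, structure=structure, covariates=cov_spec,
                             exact_death=config.exact_death,
                             options=config.optimizer_options)
            logger.info("covariate fit: loglik=%.3f converged=%s",
                        cmodel.log_likelihood, cmodel.converged)
            hr = hazard_ratios(cmodel)
            hr.to_csv(outdir / "hazard_ratios.csv", index=False)
            report["hazard_ratios"] = hr
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        with open(outdir / "error.json", "w") as fh:
            json.dump({"error": str(exc), "stage": "pipeline"}, fh, indent=2)
        logger.removeHandler(handler)
        handler.close()
        raise

    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    logger.removeHandler(handler)
    handler.close()
    return report
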