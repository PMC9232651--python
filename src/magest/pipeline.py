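"""End-to-end analysis pipeline.

From a study configuration (synthetic spec or existing trial tables) to
per-subject bias metrics, model fits, windowed-LOO model selection and
cross-condition predictions, written as CSV tables plus a JSON manifest.
Per-subject failures are logged and skipped so one bad series does not abort
a cohort run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from . import __version__
from .fitting import fit_model, loo_timeseries, predict_condition
from .io import read_study, read_trials, write_study
from .metrics import summarize_bias
from .sequences import TrialSequence
from .study import CONDITION_RANDOMIZED, CONDITION_WALK, SyntheticStudyConfig, make_synthetic_study

__all__ = ["StudyConfig", "run_pipeline"]

log = logging.getLogger("magest")


@dataclass
class StudyConfig:
    """Configuration of one pipeline run.

    Either ``trials_path`` (an existing CSV trial table or manifest JSON) or
    ``synthetic`` (a :class:`SyntheticStudyConfig` spec) must be given.
    ``fit_condition`` names the condition whose fits feed the
    cross-condition prediction of ``predict_condition_name``.
    """

    out_dir: str = "magest_out"
    trials_path: str | None = None
    synthetic: dict | None = None
    d0: float = 1.0
    model_kinds: tuple[str, ...] = ("static", "iterative", "two_state")
    window_k: int = 11
    max_lag: int = 3
    fit_condition: str = CONDITION_RANDOMIZED
    predict_condition_name: str = CONDITION_WALK
    run_loo: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, config: dict) -> "StudyConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(config) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(config)
        if "model_kinds" in cfg:
            cfg["model_kinds"] = tuple(cfg["model_kinds"])
        return cls(**cfg)

    def validate(self) -> None:
        if (self.trials_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of trials_path or synthetic must be set")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")


def _load_trials(config: StudyConfig) -> tuple[list[TrialSequence], dict]:
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        syn.setdefault("seed", config.seed)
        syn.setdefault("d0", config.d0)
        trials, manifest = make_synthetic_study(syn)
        return trials, manifest
    path = Path(config.trials_path)
    if path.suffix == ".json":
        return read_study(path)
    return read_trials(path), {"source": str(path)}


def run_pipeline(config: StudyConfig | dict) -> dict[str, Path]:
    """Run the full analysis and write report tables.

    Outputs (in ``config.out_dir``): ``metrics.csv`` (bias metrics per
    subject × condition), ``fits.csv`` (per-model parameter estimates, CIs
    and SSE for the fit condition), ``selection.csv`` (windowed-LOO errors
    and chosen model), ``prediction.csv`` (observed vs predicted metrics in
    the held-out condition), and ``run_manifest.json``.
    """
    if isinstance(config, dict):
        config = StudyConfig.from_dict(config)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials, data_manifest = _load_trials(config)
    if config.synthetic is not None:
        write_study(trials, data_manifest, out / "data")

    by_subject: dict[str, dict[str, TrialSequence]] = {}
    for seq in trials:
        by_subject.setdefault(seq.subject_id, {})[seq.condition] = seq

    metric_rows, fit_rows, selection_rows, prediction_rows = [], [], [], []
    for subject, conditions in sorted(by_subject.items()):
        try:
            for condition, seq in sorted(conditions.items()):
                summary = summarize_bias(seq, max_lag=config.max_lag)
                row = {"subject_id": subject, "condition": condition,
                       "c": summary.c, "s": summary.s,
                       "partial_r_prev": summary.partial_r_prev,
                       "partial_r_curr": summary.partial_r_curr}
                row.update({f"lag{g}_slope": v for g, v in summary.lag_slopes.items()})
                metric_rows.append(row)
                log.info("metrics subject=%s condition=%s c=%.3f s=%.3f",
                         subject, condition, summary.c, summary.s)

            fit_seq = conditions.get(config.fit_condition)
            if fit_seq is None:
                log.warning("subject=%s has no condition %r; skipping fits",
                            subject, config.fit_condition)
                continue
            fits = {}
            for kind in config.model_kinds:
                fit = fit_model(fit_seq, kind, d0=config.d0)
                fits[kind] = fit
                row = {"subject_id": subject, "model_kind": kind,
                       "sse": fit.sse, "n_trials": fit.n_trials,
                       "v_over_r": fit.params.v_over_r,
                       "q_over_r": fit.params.q_over_r,
                       "delta_x": fit.params.delta_x}
                for name, (lo, hi) in fit.ci.items():
                    row[f"{name}_ci_low"] = lo
                    row[f"{name}_ci_high"] = hi
                fit_rows.append(row)
                log.info("fit subject=%s model=%s sse=%.1f", subject, kind, fit.sse)

            if config.run_loo:
                sel = loo_timeseries(fit_seq, config.model_kinds,
                                     window_k=config.window_k, d0=config.d0)
                row = {"subject_id": subject, "window_k": sel.window_k,
                       "chosen": sel.chosen}
                row.update({f"cv_error_{k}": v for k, v in sel.per_model_cv_error.items()})
                selection_rows.append(row)
                log.info("loo subject=%s chosen=%s", subject, sel.chosen)
                best_kind = sel.chosen
            else:
                best_kind = min(fits, key=lambda k: fits[k].sse)

            pred_seq = conditions.get(config.predict_condition_name)
            if pred_seq is not None and config.predict_condition_name != config.fit_condition:
                _, pred_summary = predict_condition(fits[best_kind].params, pred_seq,
                                                    max_lag=config.max_lag)
                obs_summary = summarize_bias(pred_seq, max_lag=config.max_lag)
                prediction_rows.append({
                    "subject_id": subject, "model_kind": best_kind,
                    "condition": config.predict_condition_name,
                    "c_observed": obs_summary.c, "c_predicted": pred_summary.c,
                    "s_observed": obs_summary.s, "s_predicted": pred_summary.s,
                })
                log.info("predict subject=%s model=%s c_pred=%.3f s_pred=%.3f",
                         subject, best_kind, pred_summary.c, pred_summary.s)
        except Exception:
            log.exception("subject=%s failed; skipping", subject)
            continue

    outputs: dict[str, Path] = {}
    tables = {"metrics": metric_rows, "fits": fit_rows,
              "selection": selection_rows, "prediction": prediction_rows}
    for name, rows in tables.items():
        path = out / f"{name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        outputs[name] = path
    run_manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
        "n_subjects": len(by_subject),
    }
    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(run_manifest, indent=2, default=str))
    outputs["manifest"] = manifest_path
    return outputs
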