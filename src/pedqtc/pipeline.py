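"""Config-driven experiment orchestration.

A single :class:`ExperimentConfig` drives the whole chain:

    simulate -> predict (surrogate oracle | median-beat baseline | resnet)
             -> calibrate (per-fold, training folds only)
             -> evaluate -> report

Every stage is seeded from the global seed, artifacts are written as
CSV/JSON/HDF5 under the output directory, and a manifest records the
config hash, seed, stage timings and package version so a rerun with the
same config reproduces the same numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import (Mandate, OffsetTable, apply_calibration,
                        calibration_report, derive_offsets)
from .evalstats import (MetricWithCI, bland_altman, bootstrap_ci,
                        contingency_from_labels, diagnostic_metrics,
                        error_metrics, fairness_mae_by_group)
from .qtcore import bazett_qtc, median_beat, measure_qt_median_beat, \
    MeasurementFailure, InsufficientBeatsError
from .qtnet import (NetConfig, PredictionSet, cross_validate, desk_config,
                    patient_grouped_kfold)
from .synthcohort import (GeneratorParams, NoisyOracleParams, generate_cohort,
                          labels_frame, noisy_oracle_predict,
                          save_records_hdf5)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "evaluate_prediction_set", "EvaluationReport"]

log = logging.getLogger("pedqtc")

PREDICTORS = ("noisy_oracle", "median_beat_baseline", "resnet")


@dataclass(frozen=True)
class ExperimentConfig:
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    predictor: str = "noisy_oracle"
    oracle: NoisyOracleParams = field(default_factory=NoisyOracleParams)
    net: NetConfig = field(default_factory=desk_config)
    thresholds: tuple = (460.0, 470.0, 500.0)
    mandate: Mandate = field(default_factory=Mandate)
    k_folds: int = 10
    n_boot: int = 500
    alpha: float = 0.05
    bin_width_ms: float = 10.0
    seed: int = 0
    out_dir: str = "pedqtc_run"
    save_waveforms: bool = False

    def __post_init__(self) -> None:
        if self.predictor not in PREDICTORS:
            raise ValueError(f"predictor must be one of {PREDICTORS}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["sex_probs"] = dict(d["generator"]["sex_probs"])
        return d

    def to_yaml(self, path=None):
        text = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        if path is None:
            return text
        Path(path).write_text(text)

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        text = str(source)
        if "\n" not in text:
            try:
                if Path(text).exists():
                    text = Path(text).read_text()
            except OSError:
                pass
        raw = yaml.safe_load(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kw = dict(raw)
        try:
            if "generator" in kw:
                gen = dict(kw["generator"])
                gen.pop("n_samples", None)
                kw["generator"] = GeneratorParams(**gen)
            if "oracle" in kw:
                kw["oracle"] = NoisyOracleParams(**kw["oracle"])
            if "net" in kw:
                net = dict(kw["net"])
                if "input_leads" in net:
                    net["input_leads"] = tuple(net["input_leads"])
                kw["net"] = NetConfig(**net)
            if "mandate" in kw:
                kw["mandate"] = Mandate(**kw["mandate"])
            if "thresholds" in kw:
                kw["thresholds"] = tuple(float(t) for t in kw["thresholds"])
        except TypeError as exc:
            raise ValueError(f"malformed config: {exc}") from exc
        return cls(**kw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, MetricWithCI):
        return {"estimate": obj.estimate, "ci_low": obj.ci_low,
                "ci_high": obj.ci_high, "method": obj.method}
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


# ---------------------------------------------------------------------------
# evaluation report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Fold-pooled error, agreement, diagnostic and fairness metrics."""

    error: dict                 # mae/me/sde -> MetricWithCI (fold-pooled)
    bland_altman: dict
    diagnostics: dict           # threshold -> stage -> metric -> value
    fairness: dict
    n_records: int
    n_folds: int

    def to_json(self, path=None):
        payload = _jsonable(dataclasses.asdict(self))
        if path is None:
            return json.dumps(payload, indent=2)
        Path(path).write_text(json.dumps(payload, indent=2))

    def diagnostics_frame(self) -> pd.DataFrame:
        rows = []
        for thr, stages in self.diagnostics.items():
            for stage, metrics in stages.items():
                row = {"threshold_ms": thr, "stage": stage}
                for name, val in metrics.items():
                    if isinstance(val, MetricWithCI):
                        row[name] = val.estimate
                        row[f"{name}_ci_low"] = val.ci_low
                        row[f"{name}_ci_high"] = val.ci_high
                    else:
                        row[name] = val
                rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Evaluation over {self.n_records} records "
                 f"({self.n_folds} folds)"]
        for label, name in (("MAE", "mae_ms"), ("ME", "me_ms"),
                            ("SDE", "sde_ms")):
            m = self.error[name]
            lines.append(f"  {label}: {m.estimate:6.1f} "
                         f"({m.ci_low:.1f} to {m.ci_high:.1f}) ms")
        ba = self.bland_altman
        lines.append(f"  Bland-Altman slope {ba['slope']:+.4f} "
                     f"(p = {ba['wald_p']:.3g}), "
                     f"LoA [{ba['loa_low_ms']:.1f}, {ba['loa_high_ms']:.1f}] ms")
        for thr, stages in self.diagnostics.items():
            for stage, m in stages.items():
                lines.append(
                    f"  QTc >= {thr:g} ({stage:6s}): "
                    f"sens {m['sens'].estimate:.3f}  "
                    f"spec {m['spec'].estimate:.3f}  "
                    f"PLR {m['plr'].estimate:6.2f}  "
                    f"NLR {m['nlr'].estimate:.3f}")
        return "\n".join(lines)

    def plot_bland_altman(self, truth, preds, path):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        diff = np.asarray(truth) - np.asarray(preds)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(truth, diff, s=4, alpha=0.3)
        ba = self.bland_altman
        xs = np.linspace(np.min(truth), np.max(truth), 50)
        ax.plot(xs, ba["intercept"] + ba["slope"] * xs, "k-")
        for y in (ba["loa_low_ms"], ba["loa_high_ms"]):
            ax.axhline(y, color="k", lw=0.8)
        ax.axhline(0.0, color="gray", lw=0.8)
        ax.set_xlabel("gold-standard QTc (ms)")
        ax.set_ylabel("gold - predicted (ms)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _fold_pool(per_fold: list) -> MetricWithCI:
    """Mean-pool per-fold MetricWithCI values."""
    est = float(np.mean([m.estimate for m in per_fold]))
    lo = float(np.mean([m.ci_low for m in per_fold]))
    hi = float(np.mean([m.ci_high for m in per_fold]))
    return MetricWithCI(est, min(lo, est), max(hi, est), per_fold[0].method)


def _diag_with_ci(gold, flag, n_boot, seed):
    base = diagnostic_metrics(contingency_from_labels(flag, gold))
    out = {}
    for name in ("sens", "spec", "ppv", "npv", "plr", "nlr", "f1"):
        def stat(g, f, _name=name):
            val = diagnostic_metrics(contingency_from_labels(f, g))[_name]
            return val if np.isfinite(val) else np.nan
        if n_boot:
            rng_ci = bootstrap_ci(stat, (gold, flag), n_boot=n_boot, seed=seed)
            est = base[name] if np.isfinite(base[name]) else np.nan
            out[name] = MetricWithCI(est, min(rng_ci.ci_low, est),
                                     max(rng_ci.ci_high, est), "bootstrap")
        else:
            out[name] = MetricWithCI(base[name], base[name], base[name],
                                     "bootstrap")
    out["smoothed"] = base["smoothed"]
    return out


def evaluate_prediction_set(pset: PredictionSet, thresholds=(460., 470., 500.),
                            n_boot=500, seed=0, bin_width_ms=10.0,
                            fairness=True) -> EvaluationReport:
    """Fold-wise evaluation of a PredictionSet, pooled across folds.

    Error metrics and per-threshold diagnostics are computed per
    cross-validation fold with within-fold bootstrap CIs (the CI bounds are
    mean-pooled across folds); Bland-Altman agreement uses the pooled
    records.  Diagnostics are reported for the raw predictions and — when
    present — the calibrated ones.
    """
    frame = pset.frame
    folds = sorted(frame["fold"].unique())
    truth, raw = pset.truth, pset.raw
    cal = pset.calibrated

    err_by_fold = {"mae_ms": [], "me_ms": [], "sde_ms": []}
    diag = {float(t): {"raw": [], "calibrated": []} for t in thresholds}
    for i, f in enumerate(folds):
        m = (frame["fold"] == f).to_numpy()
        t_f, r_f = truth[m], raw[m]
        e = t_f - r_f
        err_by_fold["mae_ms"].append(bootstrap_ci(
            lambda a: np.mean(np.abs(a)), e, n_boot=n_boot, seed=seed + i))
        err_by_fold["me_ms"].append(bootstrap_ci(
            np.mean, e, n_boot=n_boot, seed=seed + i))
        err_by_fold["sde_ms"].append(bootstrap_ci(
            lambda a: np.std(a, ddof=1), e, n_boot=n_boot, seed=seed + i))
        for t in thresholds:
            gold = t_f >= t
            if gold.any() and (~gold).any():
                diag[float(t)]["raw"].append(
                    _diag_with_ci(gold, r_f >= t, n_boot, seed + i))
                if cal is not None:
                    diag[float(t)]["calibrated"].append(
                        _diag_with_ci(gold, cal[m] >= t, n_boot, seed + i))

    error = {k: _fold_pool(v) for k, v in err_by_fold.items()}
    diagnostics = {}
    for t, stages in diag.items():
        diagnostics[t] = {}
        for stage, per_fold in stages.items():
            if not per_fold:
                continue
            pooled = {}
            for name in ("sens", "spec", "ppv", "npv", "plr", "nlr", "f1"):
                vals = [pf[name] for pf in per_fold
                        if np.isfinite(pf[name].estimate)]
                pooled[name] = _fold_pool(vals) if vals else \
                    MetricWithCI(np.nan, np.nan, np.nan, "bootstrap")
            diagnostics[t][stage] = pooled

    ba = bland_altman(truth, cal if cal is not None else raw)
    fairness_out = {}
    if fairness:
        preds_eval = cal if cal is not None else raw
        for col in ("age_bin", "sex", "race"):
            if col in frame.columns:
                res = fairness_mae_by_group(truth, preds_eval, frame[col],
                                            n_boot=min(n_boot, 200), seed=seed)
                fairness_out[col] = {
                    "per_group": res["per_group"],
                    "low_n_groups": list(res["low_n_groups"]),
                    "p_values": {c.metric: c.p_value
                                 for c in res["comparisons"]},
                }
    return EvaluationReport(
        error=error, bland_altman=dataclasses.asdict(ba),
        diagnostics=diagnostics, fairness=fairness_out,
        n_records=len(pset), n_folds=len(folds),
    )


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------

def _predict_median_beat(records):
    """Median-beat baseline: measured QT, Bazett-corrected with the true
    mean RR.  Records where measurement fails yield NaN."""
    out = np.full(len(records), np.nan)
    for i, rec in enumerate(records):
        try:
            mb = median_beat(rec.waveform, fs=rec.fs)
            qt = measure_qt_median_beat(mb).qt_ms
            out[i] = bazett_qtc(qt, rec.true_mean_rr_ms)
        except (MeasurementFailure, InsufficientBeatsError):
            continue
    return out


# ---------------------------------------------------------------------------
# run_experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    config: ExperimentConfig
    predictions: PredictionSet
    offset_tables: dict         # fold -> OffsetTable
    report: EvaluationReport
    manifest: dict
    out_dir: Path


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": cfg.config_hash(), "seed": cfg.seed,
        "version": __version__, "stages": {}, "k_folds": cfg.k_folds,
        "status": "running",
    }
    _write_manifest(out, manifest)

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"status": "running",
                                    "started": time.time()}
        _write_manifest(out, manifest)
        return time.time()

    def done(name, t0):
        manifest["stages"][name] = {
            "status": "ok", "seconds": round(time.time() - t0, 3)}
        _write_manifest(out, manifest)

    try:
        # -- simulate ------------------------------------------------------
        t0 = stage("simulate")
        need_wave = cfg.predictor in ("median_beat_baseline", "resnet") \
            or cfg.save_waveforms
        gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
        cohort = generate_cohort(gen, waveforms=need_wave)
        labels = labels_frame(cohort)
        labels.to_csv(out / "labels.csv", index=False)
        if need_wave and cfg.save_waveforms:
            save_records_hdf5(out / "records.h5", cohort)
        done("simulate", t0)

        # -- folds + predict ----------------------------------------------
        t0 = stage("predict")
        patient_ids = labels["patient_id"].to_numpy()
        folds = patient_grouped_kfold(patient_ids, k=cfg.k_folds,
                                      seed=cfg.seed + 1)
        rec_fold = folds.record_folds(patient_ids)
        truth = labels["true_qtc_ms"].to_numpy()
        if cfg.predictor == "noisy_oracle":
            op = dataclasses.replace(cfg.oracle, seed=cfg.seed + 2)
            raw = noisy_oracle_predict(truth, op)
        elif cfg.predictor == "median_beat_baseline":
            raw = _predict_median_beat(cohort)
        else:
            wf = np.stack([r.waveform for r in cohort]).astype(np.float32)
            pset0 = cross_validate(wf, truth, patient_ids, cfg.net,
                                   k=cfg.k_folds, seed=cfg.seed + 3)
            raw = pset0.raw
        ok = np.isfinite(raw)
        frame = pd.DataFrame({
            "patient_id": patient_ids[ok], "fold": rec_fold[ok],
            "true_qtc_ms": truth[ok], "raw_pred_qtc_ms": raw[ok],
            "age_bin": labels["age_bin"].to_numpy()[ok],
            "sex": labels["sex"].to_numpy()[ok],
            "race": labels["race"].to_numpy()[ok],
        })
        pset = PredictionSet(frame)
        done("predict", t0)

        # -- calibrate (training folds only) --------------------------------
        t0 = stage("calibrate")
        calibrated = np.full(len(pset), np.nan)
        tables = {}
        fold_arr = frame["fold"].to_numpy()
        for f in sorted(np.unique(fold_arr)):
            test = fold_arr == f
            table = derive_offsets(pset.raw[~test], pset.truth[~test],
                                   cfg.thresholds, cfg.mandate)
            tables[int(f)] = table
            calibrated[test] = apply_calibration(pset.raw[test], table)
        pset = pset.with_calibrated(calibrated)
        pset.to_csv(out / "predictions.csv")
        with open(out / "offsets.json", "w") as fh:
            json.dump({str(f): json.loads(t.to_json())
                       for f, t in tables.items()}, fh, indent=2)
        done("calibrate", t0)

        # -- evaluate -------------------------------------------------------
        t0 = stage("evaluate")
        report = evaluate_prediction_set(
            pset, thresholds=cfg.thresholds, n_boot=cfg.n_boot,
            seed=cfg.seed + 4, bin_width_ms=cfg.bin_width_ms)
        report.to_json(out / "evaluation.json")
        report.diagnostics_frame().to_csv(out / "evaluation.csv", index=False)
        done("evaluate", t0)

        # -- report ---------------------------------------------------------
        t0 = stage("report")
        (out / "summary.txt").write_text(report.summary() + "\n")
        report.plot_bland_altman(pset.truth, pset.calibrated,
                                 out / "bland_altman.png")
        done("report", t0)
        manifest["status"] = "ok"
        _write_manifest(out, manifest)
    except Exception:
        failed = [k for k, v in manifest["stages"].items()
                  if v.get("status") == "running"]
        manifest["status"] = "failed"
        manifest["failed_stage"] = failed[0] if failed else None
        _write_manifest(out, manifest)
        raise
    return ExperimentResult(config=cfg, predictions=pset,
                            offset_tables=tables, report=report,
                            manifest=manifest, out_dir=out)


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest),
                                                  indent=2))
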