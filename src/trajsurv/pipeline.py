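"""End-to-end analysis workflow.

Ingest (or simulate) a cohort, filter to eligible subjects, fit the shared
random-effect model, enumerate latent-class models over a range of G with
BIC and the conditional-independence score test, select the class number,
classify subjects, compute class-specific survival curves, produce dynamic
predictions for both model families over a landmark grid, and compare
their time-dependent AUC.  Every stage writes machine-readable CSV/JSON
outputs; re-running with the same configuration and seeds reproduces the
tables exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._optim import FitResult
from .accuracy import compare_models
from .data import (
    JointDataset,
    filter_eligible,
    read_joint_data,
    summarize_cohort,
    write_joint_data,
)
from .jlcm import (
    class_survival_curves,
    classification_quality,
    conditional_independence_score_test,
    fit_jlcm,
    posterior_class_probs,
    select_num_classes,
)
from .predict import DEFAULT_WINDOW, batch_dynamic_predictions
from .srem import fit_srem
from .srem import _pack as _srem_pack
from .srem import _unpack as _srem_unpack
from .jlcm import _pack as _jlcm_pack
from .jlcm import _unpack as _jlcm_unpack
from .simulate import (
    SimulationConfig,
    default_jlcm_params,
    default_srem_params,
    separated_jlcm_params,
    simulate_cohort,
)
from .weibull import martingale_residuals

log = logging.getLogger("trajsurv")


@dataclass
class PipelineConfig:
    """Configuration of the full workflow (YAML-serializable)."""

    outdir: str = "trajsurv_output"
    measurements_path: str | None = None
    subjects_path: str | None = None
    simulate: dict | None = None  # e.g. {"generator": "JLCM", "n_subjects": 250, "truth": "separated"}
    transform: str = "fourth_root"
    min_measurements: int = 2
    g_range: tuple = (1, 2, 3, 4)
    landmarks: tuple = tuple(np.arange(1.0, 8.0 + 1e-9, 0.5))
    window: float = DEFAULT_WINDOW
    n_starts: int = 10
    seed: int = 0
    alpha: float = 0.05
    srem_nodes: int = 9

    def __post_init__(self) -> None:
        if not self.g_range:
            raise ValueError("g_range must be non-empty")
        lm = np.asarray(self.landmarks, dtype=float)
        if len(lm) and not np.all(np.diff(lm) > 0):
            raise ValueError("landmark grid must be strictly increasing")
        if not self.window > 0:
            raise ValueError("window must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "g_range" in raw:
            raw["g_range"] = tuple(raw["g_range"])
        if "landmarks" in raw:
            raw["landmarks"] = tuple(raw["landmarks"])
        return cls(**raw)


def save_fit(fit: FitResult, path) -> None:
    """Serialize a fit (parameters, SEs, convergence metadata) to JSON."""
    d = fit.to_dict()
    d["theta"] = [float(x) for x in fit.theta]
    if fit.model_tag == "JLCM":
        d["n_classes"] = int(fit.params.n_classes)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


def load_params(path):
    """Reload model parameters from a saved fit JSON."""
    with open(path) as fh:
        d = json.load(fh)
    theta = np.asarray(d["theta"], dtype=float)
    if d["model"] == "SREM":
        return _srem_unpack(theta)
    return _jlcm_unpack(theta, d["n_classes"])


def fit_table(fit: FitResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": list(fit.param_names),
            "estimate": fit.theta,
            "se": fit.standard_errors if fit.standard_errors is not None else np.nan,
        }
    )


def _obtain_dataset(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        sim = dict(config.simulate)
        truth_name = sim.pop("truth", "default")
        generator = sim.pop("generator", "JLCM")
        if generator == "SREM":
            params = default_srem_params()
        elif truth_name == "separated":
            params = separated_jlcm_params()
        else:
            params = default_jlcm_params()
        sim_cfg = SimulationConfig(generator=generator, params=params, **sim)
        cohort = simulate_cohort(sim_cfg, config.seed)
        cohort.truth.to_csv(outdir / "truth.csv", index=False)
        write_joint_data(cohort.dataset, outdir / "measurements.csv", outdir / "subjects.csv")
        return cohort.dataset
    if config.measurements_path is None or config.subjects_path is None:
        raise ValueError("either input paths or a simulate block must be configured")
    return read_joint_data(
        config.measurements_path, config.subjects_path, transform=config.transform
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns a bundle of key results and paths.

    Stage failures raise with the stage name; outputs written before the
    failure are preserved in ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outdir": str(outdir)}
    timings: dict = {}
    stage = "setup"

    def _run(name, fn):
        nonlocal stage
        stage = name
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        out = fn()
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.1fs", name, timings[name])
        return out

    try:
        dataset: JointDataset = _run("ingest", lambda: _obtain_dataset(config, outdir))

        def _filter():
            res = filter_eligible(dataset, config.min_measurements)
            res.excluded.to_csv(outdir / "exclusions.csv", index=False)
            return res.dataset

        data = _run("filter", _filter)

        def _summary():
            s = summarize_cohort(data)
            with open(outdir / "summary.json", "w") as fh:
                json.dump(s, fh, indent=2)
            return s

        bundle["summary"] = _run("summarize", _summary)

        def _srem():
            fit = fit_srem(data, n_nodes=config.srem_nodes)
            save_fit(fit, outdir / "srem_fit.json")
            fit_table(fit).to_csv(outdir / "srem_fit.csv", index=False)
            if not fit.converged:
                log.warning("SREM fit did not meet all convergence criteria")
            return fit

        srem_fit = _run("fit_srem", _srem)
        bundle["srem_fit"] = srem_fit

        def _enumerate():
            candidates = []
            for i, G in enumerate(config.g_range):
                fit = fit_jlcm(
                    data, G, n_starts=config.n_starts, seed=config.seed + 1000 * (i + 1)
                )
                if not fit.converged:
                    log.warning("JLCM G=%d: not all starts converged", G)
                test = conditional_independence_score_test(fit, data)
                post = posterior_class_probs(fit.params, data)
                quality = classification_quality(post)
                candidates.append((G, fit, test, quality))
            return candidates

        candidates = _run("fit_jlcm", _enumerate)

        def _select():
            sel = select_num_classes([(G, f, t) for G, f, t, _ in candidates], config.alpha)
            trace = sel.trace.copy()
            trace["class_proportions_pct"] = [
                "/".join(f"{p:.2f}" for p in q["proportion_pct"]) for _, _, _, q in candidates
            ]
            trace.to_csv(outdir / "class_enumeration.csv", index=False)
            return sel

        selection = _run("select", _select)
        bundle["selection"] = selection
        chosen = next(c for c in candidates if c[0] == selection.chosen_G)
        G, jlcm_fit, jlcm_test, quality = chosen
        bundle["jlcm_fit"] = jlcm_fit
        save_fit(jlcm_fit, outdir / "jlcm_fit.json")
        fit_table(jlcm_fit).to_csv(outdir / "jlcm_fit.csv", index=False)
        quality.to_csv(outdir / "classification_quality.csv", index=False)

        def _curves():
            profile = np.array([0.0, 0.0, float(data.subjects["age"].median())])
            tgrid = np.arange(0.0, 15.0 + 1e-9, 0.25)
            curves = class_survival_curves(jlcm_fit.params, profile, tgrid)
            df = pd.DataFrame({"time": tgrid})
            for g in range(curves.shape[0]):
                df[f"class{g + 1}_survival"] = curves[g]
            df.to_csv(outdir / "class_survival_curves.csv", index=False)
            return df

        _run("survival_curves", _curves)

        def _predict():
            preds = {}
            for tag, fit in (("SREM", srem_fit), ("JLCM", jlcm_fit)):
                preds[tag] = batch_dynamic_predictions(
                    fit, data, landmarks=config.landmarks, window=config.window
                )
            pd.concat(preds.values()).to_csv(outdir / "predictions.csv", index=False)
            return preds

        predictions = _run("predict", _predict)

        def _evaluate():
            comp = compare_models(data, predictions, config.landmarks, config.window)
            comp.table.to_csv(outdir / "auc_comparison.csv", index=False)
            with open(outdir / "auc_series.json", "w") as fh:
                json.dump({"average": comp.average, "series": comp.series}, fh, indent=2)
            return comp

        bundle["comparison"] = _run("evaluate", _evaluate)

        def _residuals():
            from .data import CohortArrays

            arrays = CohortArrays.from_dataset(data)
            hz = srem_fit.params.hazard
            res = martingale_residuals(hz, arrays.X, arrays.T, arrays.delta)
            pd.DataFrame({"subject_id": arrays.ids, "martingale_residual": res}).to_csv(
                outdir / "martingale_residuals.csv", index=False
            )

        _run("residuals", _residuals)

        def _log():
            import scipy

            payload = {
                "trajsurv_version": __version__,
                "numpy_version": np.__version__,
                "scipy_version": scipy.__version__,
                "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
                "seed": config.seed,
                "timings_s": timings,
                "selected_G": int(selection.chosen_G),
                "average_auc": bundle["comparison"].average,
            }
            with open(outdir / "run_log.json", "w") as fh:
                json.dump(payload, fh, indent=2)

        _run("run_log", _log)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return bundle
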