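"""End-to-end run: simulate/ingest -> features -> select -> train -> evaluate.

One master seed is expanded into independent per-stage seeds (cohort
generation, patient split, classifier randomness) through a
``numpy.random.SeedSequence`` counter scheme, so a run is reproducible from
its manifest alone.  Patients are split once; each requested window then gets
its own feature table, training-set-fitted normalisation, SU selection on the
training rows only, suite training and test evaluation — test labels are
never touched before evaluation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import evaluate
from .features import ALL_FEATURES, VALID_WINDOWS, assemble_feature_table, minmax_normalize
from .model import SplitSpec, default_classifier_suite, stratified_split, train_suite
from .selection import cfs_select
from .synthetic import CohortSpec, cohort_frames, generate_cohort


@dataclass
class RunConfig:
    cohort: CohortSpec | None = None          # simulate ...
    daily_csv: str | None = None              # ... or ingest these two files
    patients_csv: str | None = None
    windows: tuple = (5, 6, 7, 8)
    threshold: float = 0.9
    n_bins: int = 3
    selection_mode: str = "all_pairs"
    include_clinical: bool = True
    normalize_scope: str = "train"            # "train" | "all"
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [w for w in self.windows if w not in VALID_WINDOWS]
        if bad:
            raise ValueError(f"invalid window(s) {bad}; must be in {VALID_WINDOWS}")
        if self.normalize_scope not in ("train", "all"):
            raise ValueError("normalize_scope must be 'train' or 'all'")
        if self.cohort is None and not (self.daily_csv and self.patients_csv):
            raise ValueError("provide either a cohort spec or both input CSV paths")


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    cohort = CohortSpec(**raw["cohort"]) if "cohort" in raw else None
    kwargs = {k: v for k, v in raw.items() if k != "cohort"}
    if "windows" in kwargs:
        kwargs["windows"] = tuple(kwargs["windows"])
    return RunConfig(cohort=cohort, **kwargs)


def _stage_seeds(master: int) -> dict:
    ss = np.random.SeedSequence(master)
    names = ("cohort", "split", "model")
    states = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(len(names))]
    return dict(zip(names, states))


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(_to_jsonable(obj), indent=2, sort_keys=True) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_window(table: pd.DataFrame, train_ids, test_ids, config: RunConfig,
               model_seed: int) -> dict:
    """Select, train and evaluate one window; returns a JSON-ready report."""
    fit_rows = train_ids if config.normalize_scope == "train" else table.index
    norm, params = minmax_normalize(table, fit_rows=fit_rows)
    feat_cols = [c for c in norm.columns if c != "label"]

    train = norm.loc[train_ids]
    test = norm.loc[test_ids]
    sel = cfs_select(train[feat_cols], train["label"].to_numpy(),
                     threshold=config.threshold, n_bins=config.n_bins,
                     mode=config.selection_mode)
    used = sel.selected if sel.selected else feat_cols

    clf = train_suite(train[used].to_numpy(), train["label"].to_numpy(),
                      classifiers=default_classifier_suite(model_seed),
                      seed=model_seed)
    pred = clf.predict(test[used].to_numpy())
    report = evaluate(test["label"].to_numpy(), pred,
                      labels=sorted(table["label"].unique()))
    return {
        "selection": sel.to_dict(),
        "features_used": list(used),
        "dropped_constant": params.dropped,
        "cv_table": clf.cv_result_.scores,
        "winner": clf.best_name_,
        "winner_cv_accuracy": clf.cv_result_.winner_accuracy,
        "test_ids": list(map(str, test_ids)),
        "train_ids": list(map(str, train_ids)),
        "predictions": dict(zip(map(str, test_ids), map(str, pred))),
        "evaluation": report.to_dict(),
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> tuple[dict, dict]:
    """Execute the full workflow; returns (manifest, reports per window)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    log: list[dict] = []

    if config.cohort is not None:
        spec = CohortSpec(**{**asdict_cohort(config.cohort), "seed": seeds["cohort"]})
        patients_list = generate_cohort(spec)
        daily, patients = cohort_frames(patients_list)
        log.append({"stage": "simulate", "n_patients": len(patients_list)})
    else:
        daily = pd.read_csv(config.daily_csv)
        patients = pd.read_csv(config.patients_csv)
        log.append({"stage": "ingest", "n_patients": int(patients.shape[0])})
    daily.to_csv(out / "daily_intensity.csv", index=False)
    patients.to_csv(out / "patients.csv", index=False)

    # one patient split shared by all windows, stratified on the labels of the
    # patients usable at the widest requested window
    widest = max(config.windows)
    base_table, excluded = assemble_feature_table(daily, patients, widest,
                                                  config.include_clinical)
    log.append({"stage": "exclusions", "window": widest, "excluded": excluded})
    tr, te = stratified_split(base_table["label"].to_numpy(),
                              SplitSpec(config.train_fraction, seeds["split"]))
    train_ids = base_table.index[tr]
    test_ids = base_table.index[te]

    reports = {}
    for w in config.windows:
        table, excl_w = assemble_feature_table(daily, patients, w,
                                               config.include_clinical)
        table = table.loc[base_table.index]  # common patient set across windows
        table.to_csv(out / f"features_w{w}.csv")
        rep = run_window(table, train_ids, test_ids, config, seeds["model"])
        rep["window"] = w
        rep["excluded"] = excl_w
        write_json(rep, out / f"report_w{w}.json")
        reports[w] = rep
        log.append({"stage": "window", "window": w, "winner": rep["winner"],
                    "selected": rep["selection"]["selected"],
                    "fallback": rep["selection"]["fallback"],
                    "micro_f1": rep["evaluation"]["micro_f1"]})

    cfg_dict = _to_jsonable({**{k: v for k, v in vars(config).items() if k != "cohort"},
                             "cohort": asdict_cohort(config.cohort) if config.cohort else None})
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "seeds": seeds,
        "versions": {"actipat": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "artifacts": {},
    }
    with (out / "log.jsonl").open("w") as fh:
        for entry in log:
            fh.write(json.dumps(_to_jsonable(entry), sort_keys=True) + "\n")
    for p in sorted(out.glob("*")):
        if p.name != "manifest.json" and p.is_file():
            manifest["artifacts"][p.name] = _digest(p)
    write_json(manifest, out / "manifest.json")
    return manifest, reports


def asdict_cohort(spec: CohortSpec) -> dict:
    d = asdict(spec)
    return d
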