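"""End-to-end orchestration: data → reduction → split → GA → models → report.

``run`` executes the whole workflow from a single :class:`PipelineConfig`:
load (or synthesize) a descriptor table, remove constant/near-constant and
collinear columns, draw a cluster-based train/test split, select a descriptor
subset by GA, fit MLR and tuned RBF-SVR on the same subset, run the full
validation battery for both models, assess the applicability domain, and
emit one consolidated, JSON-serializable report. Every random draw is tied
to a seed recorded in the report, so a rerun with the same config reproduces
the report bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import preprocess, split as split_mod, synth
from .exceptions import ConfigurationError
from .gaselect import GaConfig, ga_select
from .models import DEFAULT_SVR_GRID, MLR, RBFSVR
from .domain import assess_domain
from .table import DescriptorTable
from .validate import validate_model


@dataclass
class PipelineConfig:
    """Everything one run needs; round-trips through ``to_dict``/``from_dict``."""

    input_csv: str | None = None
    synth: synth.SynthConfig | None = None
    near_constant_fraction: float = 0.95
    r_cut: float = 0.9
    test_fraction: float = 0.2
    linkage_method: str = "complete"
    split_seed: int = 0
    ga: GaConfig = field(default_factory=GaConfig)
    svr_grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_SVR_GRID.items()})
    n_boot: int = 5000
    n_yrand: int = 10
    validation_seed: int = 0

    def validate(self) -> None:
        if (self.input_csv is None) == (self.synth is None):
            raise ConfigurationError(
                "exactly one of input_csv or synth must be given")
        if self.synth is not None:
            self.synth.validate()

    def to_dict(self) -> dict:
        out = {
            "input_csv": self.input_csv,
            "synth": synth.config_to_dict(self.synth) if self.synth else None,
            "near_constant_fraction": self.near_constant_fraction,
            "r_cut": self.r_cut,
            "test_fraction": self.test_fraction,
            "linkage_method": self.linkage_method,
            "split_seed": self.split_seed,
            "ga": vars(self.ga).copy(),
            "svr_grid": {k: list(v) for k, v in self.svr_grid.items()},
            "n_boot": self.n_boot,
            "n_yrand": self.n_yrand,
            "validation_seed": self.validation_seed,
        }
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        synth_cfg = payload.pop("synth", None)
        ga_cfg = payload.pop("ga", None)
        cfg = cls(**payload)
        if synth_cfg:
            cfg.synth = synth.config_from_dict(synth_cfg)
        if ga_cfg:
            cfg.ga = GaConfig(**ga_cfg)
        cfg.validate()
        return cfg


def _stage(report: dict, name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {name!r} failed after stages "
            f"{list(report['stages'])}: {exc}") from exc


def run(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full workflow and return the consolidated report dict."""
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": []}

    # ------------------------------------------------------------------ data
    if config.synth is not None:
        dataset = _stage(report, "synth", synth.generate, config.synth)
        table = dataset.table
        report["truth"] = dataset.truth_dict()
    else:
        table = _stage(report, "load", DescriptorTable.from_csv, config.input_csv)
    report["stages"].append("data")
    report["n_compounds"] = table.n_compounds
    report["n_descriptors_raw"] = table.n_descriptors
    if out is not None:
        table.to_csv(out / "data.csv")

    # ------------------------------------------------------------- reduction
    reduced, rlog = _stage(report, "preprocess", preprocess.reduce_descriptors,
                           table, config.near_constant_fraction, config.r_cut)
    report["reduction"] = rlog.to_dict()
    report["stages"].append("preprocess")
    if out is not None:
        reduced.to_csv(out / "reduced.csv")

    # ----------------------------------------------------------------- split
    tree = _stage(report, "cluster", split_mod.cluster_dendrogram,
                  reduced, config.linkage_method)
    assignment = _stage(report, "split", split_mod.make_split,
                        tree, reduced, config.test_fraction, config.split_seed,
                        config.linkage_method)
    train, test = split_mod.split_table(reduced, assignment)
    report["split"] = assignment.to_dict()
    report["stages"].append("split")
    if out is not None:
        assignment.save(out / "split.json")

    # ------------------------------------------------------------------- GA
    ga_result = _stage(report, "gaselect", ga_select, train, config.ga)
    subset = ga_result.best_subset
    report["ga"] = ga_result.to_dict()
    report["alternative_models"] = _alternative_models(ga_result, train, test)
    report["stages"].append("gaselect")
    if out is not None:
        with open(out / "ga.json", "w") as fh:
            json.dump(ga_result.to_dict(), fh, indent=2)

    # --------------------------------------------------------------- models
    mlr = _stage(report, "fit_mlr",
                 lambda t, s: MLR.from_table(t, s).fit(), train, subset)
    svr = _stage(report, "fit_svr",
                 lambda t, s: RBFSVR.from_table(t, s).tune_and_fit(config.svr_grid),
                 train, subset)
    report["mlr"] = mlr.to_dict()
    report["mlr"]["equation"] = mlr.equation()
    report["svr"] = {k: v for k, v in svr.to_dict().items()}
    report["stages"].append("models")

    # ----------------------------------------------------------- validation
    val_mlr = _stage(report, "validate_mlr", validate_model, mlr, train, test,
                     None, config.n_boot, config.n_yrand, config.validation_seed)
    val_svr = _stage(report, "validate_svr", validate_model, svr, train, test,
                     None, config.n_boot, config.n_yrand, config.validation_seed)
    report["validation"] = {"mlr": val_mlr.to_dict(), "svr": val_svr.to_dict()}
    report["comparison"] = _comparison_table(val_mlr, val_svr)
    report["stages"].append("validate")

    # --------------------------------------------------------------- domain
    dom = _stage(report, "domain", assess_domain, mlr, train, test)
    report["domain"] = dom.to_dict()
    report["stages"].append("domain")

    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _alternative_models(ga_result, train, test) -> list[dict]:
    """Table of every GA run's winner refitted and scored (train/test)."""
    from .validate import f_statistic, q2_loo, rm2, squared_correlation

    rows = []
    for rank, run_ in enumerate(ga_result.ranked(), start=1):
        fitted = MLR.from_table(train, run_.subset).fit()
        q2, _ = q2_loo(train.select_descriptors(run_.subset))
        row = {
            "rank": rank,
            "subset": run_.subset,
            "equation": fitted.equation(),
            "r2_train": fitted.rsquared,
            "f_train": f_statistic(fitted.rsquared, fitted.nobs, len(run_.subset)),
            "q2_loo": q2,
        }
        if test is not None and test.n_compounds >= 3:
            pred = fitted.predict(test)
            row["r2_test"] = squared_correlation(test.y, pred)
            row["rm2_test"] = rm2(test.y, pred)
        rows.append(row)
    return rows


def _comparison_table(val_mlr, val_svr) -> dict:
    def block(v):
        out = {
            "train": {"r2": v.train.r2, "rmse": v.train.rmse,
                      "f": v.train.f_stat, "ccc": v.ccc_train,
                      "r2_adj": v.train.r2_adj},
            "q2_loo": v.q2_loo,
            "q2_boot": v.q2_boot,
        }
        if v.test is not None:
            out["test"] = {"r2": v.test_r2_pearson, "rmse": v.test.rmse,
                           "ccc": v.ccc_test, "rm2": v.rm2_test}
        return out

    return {"mlr": block(val_mlr), "svr": block(val_svr)}


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
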