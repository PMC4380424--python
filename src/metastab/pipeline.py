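"""End-to-end orchestration: simulate -> half-life -> QSPR -> annotation.

A single :class:`RunConfig` drives the whole workflow.  All randomness
flows from one root seed through named substreams (one per stage), so
toggling a stage never perturbs another stage's draws and re-running with
the same config reproduces byte-identical numeric outputs.  Every output
file is stamped with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import biotransform, kinetics, qspr_model, synthetic_data

__all__ = [
    "RunConfig",
    "RunReport",
    "validate_config",
    "run_pipeline",
    "substream_seed",
    "halflife_table",
    "annotate_tables",
]

logger = logging.getLogger(__name__)


def substream_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "metastab_run"
    stages: tuple[str, ...] = ("simulate", "halflife", "qspr", "annotate")
    depletion: synthetic_data.DepletionConfig = field(
        default_factory=synthetic_data.DepletionConfig
    )
    qspr_gen: synthetic_data.QsprConfig = field(
        default_factory=synthetic_data.QsprConfig
    )
    metabolite: synthetic_data.MetaboliteConfig = field(
        default_factory=synthetic_data.MetaboliteConfig
    )
    model: qspr_model.ModelConfig = field(default_factory=qspr_model.ModelConfig)
    r2_min: float = 0.95
    min_points: int = 3
    aggregate: str = "fit"
    tolerance: str = "10ppm"
    descriptor_file: str | None = None
    target_file: str | None = None

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return str(o)

        payload = asdict(self)
        payload.pop("outdir", None)  # output location is not part of the analysis
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StageStatus:
    status: str  # ok | failed | skipped
    warnings: list[str] = field(default_factory=list)
    seconds: float = 0.0
    error: str | None = None


@dataclass
class RunReport:
    stages: dict[str, StageStatus]
    config_hash: str
    seed: int
    version: str
    validation: dict | None = None

    @property
    def ok(self) -> bool:
        return all(s.status == "ok" for s in self.stages.values())


_KNOWN_STAGES = ("simulate", "halflife", "qspr", "annotate")


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations (empty means the config is valid)."""
    v: list[str] = []
    for stage in config.stages:
        if stage not in _KNOWN_STAGES:
            v.append(f"unknown stage {stage!r}")
    if config.model.n_train + config.model.n_test != config.qspr_gen.n and (
        "simulate" in config.stages and "qspr" in config.stages
    ):
        v.append(
            f"n_train + n_test = {config.model.n_train + config.model.n_test} "
            f"does not match the {config.qspr_gen.n}-compound dataset"
        )
    if config.r2_min <= 0 or config.r2_min > 1:
        v.append("r2_min must be in (0, 1]")
    try:
        biotransform.Tolerance.parse(config.tolerance)
    except biotransform.BiotransformError as exc:
        v.append(str(exc))
    if config.qspr_gen.sigma < 0:
        v.append("qspr noise sigma must be >= 0")
    for name in ("descriptor_file", "target_file"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            v.append(f"{name} {path!r} does not exist")
    if "simulate" not in config.stages:
        if "qspr" in config.stages and config.descriptor_file is None:
            v.append("qspr stage without simulate requires descriptor_file")
    if config.aggregate not in ("fit", "pool"):
        v.append(f"unknown aggregate mode {config.aggregate!r}")
    return v


def halflife_table(
    depletion: pd.DataFrame,
    min_points: int = 3,
    r2_min: float = 0.95,
    aggregate: str = "fit",
) -> pd.DataFrame:
    """Run the half-life estimator over a long-format depletion table."""
    results = []
    for cid, group in depletion.groupby("compound_id", sort=False):
        series = [
            kinetics.DepletionSeries(
                str(cid),
                int(rep),
                g["time_min"].to_numpy(),
                g["area_analyte"].to_numpy(),
                g["area_is"].to_numpy(),
            )
            for rep, g in group.groupby("replicate", sort=True)
        ]
        res = kinetics.estimate(series, min_points, r2_min, aggregate)
        results.append(
            {
                "compound_id": cid,
                "t_half_mean": res.t_half_mean,
                "t_half_sd": res.t_half_sd,
                "k_per_replicate": ";".join(f"{f.k:.6g}" for f in res.replicates),
                "r2": ";".join(f"{f.r2:.6g}" for f in res.replicates),
                "window": ";".join(
                    f"{f.window.start}-{f.window.end}" for f in res.replicates
                ),
                "warnings": ";".join(
                    w for f in res.replicates for w in f.warnings
                ),
            }
        )
    return pd.DataFrame(results)


def annotate_tables(
    parents: pd.DataFrame,
    features: pd.DataFrame,
    tolerance: str = "10ppm",
    keep_best_only: bool = True,
) -> pd.DataFrame:
    """Annotate a feature table against a parent table (long format)."""
    rows = []
    for prow in parents.itertuples(index=False):
        feats = features[features["compound_id"] == prow.compound_id]
        ions = [
            biotransform.FeatureIon(f.mz, f.rt, getattr(f, "intensity", 0.0))
            for f in feats.itertuples(index=False)
        ]
        annotations, unassigned = biotransform.annotate(
            str(prow.compound_id), prow.mh_mz, prow.rt, ions, tolerance
        )
        seen: set[float] = set()
        for a in annotations:
            if keep_best_only and a.feature.mz in seen:
                continue
            seen.add(a.feature.mz)
            rows.append(
                {
                    "compound_id": a.parent_id,
                    "feature_mz": a.feature.mz,
                    "delta_m": a.observed_shift,
                    "rules": a.rule_names,
                    "error_da": a.error_da,
                    "error_ppm": a.error_ppm,
                    "rt_earlier": a.rt_earlier_than_parent,
                }
            )
        for f in unassigned:
            rows.append(
                {
                    "compound_id": prow.compound_id,
                    "feature_mz": f.mz,
                    "delta_m": f.mz - prow.mh_mz,
                    "rules": "",
                    "error_da": np.nan,
                    "error_ppm": np.nan,
                    "rt_earlier": f.rt < prow.rt,
                }
            )
    return pd.DataFrame(rows)


def _stamp(path: Path, payload: dict, config: RunConfig) -> None:
    payload = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        **payload,
    }
    path.write_text(json.dumps(payload, indent=2, default=str))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in dependency order.

    Intermediate artifacts land in ``config.outdir``; each JSON artifact
    carries the config hash and root seed.  A stage failure is recorded in
    the report and downstream stages are skipped, but the report is always
    returned.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, StageStatus] = {}
    report = RunReport({}, config.config_hash(), config.seed, __version__)
    report.stages = stages
    failed = False

    artifacts: dict[str, object] = {}

    def run_stage(name, fn):
        nonlocal failed
        if name not in config.stages:
            return
        if failed:
            stages[name] = StageStatus("skipped")
            return
        t0 = time.perf_counter()
        try:
            warnings = fn() or []
            stages[name] = StageStatus("ok", warnings, time.perf_counter() - t0)
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed silently
            logger.exception("stage %s failed", name)
            stages[name] = StageStatus(
                "failed", [], time.perf_counter() - t0, f"{type(exc).__name__}: {exc}"
            )
            failed = True

    def stage_simulate():
        dep, truth = synthetic_data.gen_depletion(
            config.depletion, substream_seed(config.seed, "depletion")
        )
        dep.to_csv(outdir / "depletion.csv", index=False)
        pd.Series(truth, name="t_half_true").rename_axis("compound_id").to_csv(
            outdir / "depletion_truth.csv"
        )
        desc, t_half, meta = synthetic_data.gen_qspr(
            config.qspr_gen, substream_seed(config.seed, "qspr")
        )
        desc.to_csv(outdir / "descriptors.csv")
        t_half.to_frame().to_csv(outdir / "targets.csv")
        parents, features, truth_tab = synthetic_data.gen_metabolite_run(
            config.metabolite, substream_seed(config.seed, "metabolites")
        )
        parents.to_csv(outdir / "parents.csv", index=False)
        features.to_csv(outdir / "features.csv", index=False)
        truth_tab.to_csv(outdir / "features_truth.csv", index=False)
        artifacts["depletion"] = dep
        artifacts["descriptors"] = desc
        artifacts["targets"] = t_half
        artifacts["parents"] = parents
        artifacts["features"] = features

    def stage_halflife():
        dep = artifacts.get("depletion")
        if dep is None:
            dep = pd.read_csv(outdir / "depletion.csv")
        table = halflife_table(dep, config.min_points, config.r2_min, config.aggregate)
        table.to_csv(outdir / "halflife.csv", index=False)
        artifacts["halflife"] = table
        return [w for w in table["warnings"] if w]

    def stage_qspr():
        if config.descriptor_file is not None:
            desc = pd.read_csv(config.descriptor_file, index_col=0)
            targets = pd.read_csv(config.target_file, index_col=0).iloc[:, 0]
        else:
            desc = artifacts.get("descriptors")
            targets = artifacts.get("targets")
            if desc is None:
                desc = pd.read_csv(outdir / "descriptors.csv", index_col=0)
                targets = pd.read_csv(outdir / "targets.csv", index_col=0).iloc[:, 0]
        model, valrep, pred = qspr_model.fit_qspr(desc, targets, config.model)
        pred.to_csv(outdir / "predictions.csv")
        _stamp(
            outdir / "validation.json",
            {
                "selected_features": model.features,
                "svr_params": {
                    "C": model.config.svr_C,
                    "epsilon": model.config.svr_epsilon,
                    "gamma": model.config.svr_gamma,
                },
                "feature_selection": model.config.feature_selection,
                "report": valrep.as_dict(),
                "shapiro_wilk": pred.attrs.get("shapiro_wilk"),
            },
            config,
        )
        report.validation = valrep.as_dict()
        return model.warnings

    def stage_annotate():
        parents = artifacts.get("parents")
        features = artifacts.get("features")
        if parents is None:
            parents = pd.read_csv(outdir / "parents.csv")
            features = pd.read_csv(outdir / "features.csv")
        ann = annotate_tables(parents, features, config.tolerance)
        ann.to_csv(outdir / "annotations.csv", index=False)
        artifacts["annotations"] = ann

    run_stage("simulate", stage_simulate)
    run_stage("halflife", stage_halflife)
    run_stage("qspr", stage_qspr)
    run_stage("annotate", stage_annotate)

    _stamp(
        outdir / "run_report.json",
        {
            "stages": {k: asdict(v) for k, v in stages.items()},
            "validation": report.validation,
        },
        config,
    )
    return report
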