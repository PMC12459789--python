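"""Config-driven end-to-end pipeline with run manifests.

Stages: simulate (optional) -> build-cohort -> impute (or filter) -> split
-> train -> predict -> bioage -> survival validation -> interpretation ->
report.  Intermediate artifacts are files under the run directory, so each
stage is independently inspectable and re-runnable; a JSON manifest records
the config snapshot, per-stage seeds, artifact digests and timings.
Deterministic mode (the default) makes a replay byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from bioagekit import __version__
from bioagekit.cohort import CohortConfig, build_cohort, feature_columns
from bioagekit.impute import ChainedImputer, filter_complete
from bioagekit.interpret import (
    ReferenceMeans,
    attribute_table,
    cohort_intervention_summary,
    feature_gain_ranking,
    intervene_table,
    pcc_matrix,
)
from bioagekit.lifetable import load_life_expectancy, to_biological_age
from bioagekit.model import (
    ModelParams,
    ResidualLifeRegressor,
    SplitSpec,
    evaluate,
)
from bioagekit.simulate import config_from_dict, inject_missingness, simulate_cohort
from bioagekit.survival import (
    GroupingPolicy,
    assign_groups,
    km_estimate,
    logrank_test,
    validate_group_ordering,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: "RunManifest"):
        super().__init__(f"pipeline aborted at stage {stage!r}: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunManifest:
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)
    version: str = __version__

    def to_json(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "seeds": self.seeds,
            "digests": self.digests,
            "timings": self.timings,
            "stages_completed": self.stages_completed,
            "version": self.version,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def dump_config(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=True)


def fan_out_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, date_format="%Y-%m-%d")


def run_pipeline(config: dict, outdir: str | Path) -> RunManifest:
    """Execute every configured stage; return the run manifest.

    Raises :class:`StageError` (carrying the partial manifest) if a stage
    fails.  Stages whose input artifact paths are supplied in the config
    (``exams``/``mortality`` instead of a ``simulate`` block) are skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=json.loads(json.dumps(config, default=str)))
    global_seed = int(config.get("seed", 0))

    def finish_stage(stage: str, t0: float, *artifacts: Path) -> None:
        manifest.timings[stage] = round(time.perf_counter() - t0, 3)
        for a in artifacts:
            manifest.digests[a.name] = _digest(a)
        manifest.stages_completed.append(stage)
        manifest.to_json(outdir / "manifest.json")

    # ---- simulate -------------------------------------------------------
    stage = "simulate"
    t0 = time.perf_counter()
    try:
        if "simulate" in config:
            sim_cfg = config_from_dict({**config["simulate"], "seed": config["simulate"].get("seed", fan_out_seed(global_seed, stage))})
            manifest.seeds[stage] = sim_cfg.seed
            exam, mortality, gt = simulate_cohort(sim_cfg)
            exam = inject_missingness(exam, sim_cfg)
            exam_path, mort_path = outdir / "exam.csv", outdir / "mortality.csv"
            _write_csv(exam, exam_path)
            _write_csv(mortality, mort_path)
            gt.to_json(outdir / "ground_truth.json")
            finish_stage(stage, t0, exam_path, mort_path, outdir / "ground_truth.json")
        else:
            exam = pd.read_csv(config["exams"], parse_dates=["exam_date"])
            mortality = pd.read_csv(config["mortality"], parse_dates=["death_date"])
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc, manifest) from exc

    # ---- build-cohort ---------------------------------------------------
    stage = "build_cohort"
    t0 = time.perf_counter()
    try:
        ccfg = CohortConfig(**config.get("cohort", {}))
        cohort, report = build_cohort(exam, mortality, ccfg)
        logger.info("cohort: %d -> %d rows; removed %s", report.n_input, report.n_output, report.removed)
        cohort_path = outdir / "cohort.csv"
        _write_csv(cohort, cohort_path)
        (outdir / "exclusion_report.json").write_text(json.dumps(report.to_dict(), indent=1))
        finish_stage(stage, t0, cohort_path, outdir / "exclusion_report.json")
    except Exception as exc:
        raise StageError(stage, exc, manifest) from exc

    # ---- per-sex modeling ----------------------------------------------
    results: dict[str, dict] = {}
    icfg = config.get("impute", {})
    mcfg = config.get("model", {})
    scfg = config.get("split", {})
    bcfg = config.get("bioage", {})
    vcfg = config.get("survival", {})
    xcfg = config.get("interpret", {})

    for sex in sorted(cohort["sex"].unique()):
        sub = cohort[cohort["sex"] == sex].reset_index(drop=True)
        if len(sub) < 50:
            logger.warning("skipping sex %r: only %d records", sex, len(sub))
            continue
        sexdir = outdir / f"sex={sex}"
        sexdir.mkdir(exist_ok=True)
        try:
            results[sex] = _run_sex_stratum(
                sub, sexdir, manifest, global_seed, icfg, mcfg, scfg, bcfg, vcfg, xcfg
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"model[{sex}]", exc, manifest) from exc

    (outdir / "results.json").write_text(json.dumps(results, indent=1, default=float))
    manifest.digests["results.json"] = _digest(outdir / "results.json")
    manifest.stages_completed.append("collect")
    manifest.to_json(outdir / "manifest.json")

    if config.get("report", True):
        render_report(manifest, outdir)
        manifest.digests["report.md"] = _digest(outdir / "report.md")
        manifest.stages_completed.append("report")
        manifest.to_json(outdir / "manifest.json")
    return manifest


def _run_sex_stratum(
    sub: pd.DataFrame,
    sexdir: Path,
    manifest: RunManifest,
    global_seed: int,
    icfg: dict,
    mcfg: dict,
    scfg: dict,
    bcfg: dict,
    vcfg: dict,
    xcfg: dict,
) -> dict:
    sex = sub["sex"].iloc[0]
    out: dict = {"n_records": len(sub)}
    feats = feature_columns(sub) + ["chronological_age"]

    # split before imputation: the imputer must only see training rows
    split_seed = scfg.get("seed", fan_out_seed(global_seed, f"split:{sex}"))
    manifest.seeds[f"split:{sex}"] = split_seed
    spec = SplitSpec(seed=split_seed, ratios=tuple(scfg.get("ratios", (0.8, 0.1, 0.1))))
    from bioagekit.model import stratified_split

    train, val, test = stratified_split(sub, spec)

    method = icfg.get("method", "mice")
    t0 = time.perf_counter()
    if method == "mice":
        imputer = ChainedImputer(
            n_iterations=icfg.get("n_iterations", 5),
            model_family=icfg.get("model_family", "forest"),
            n_estimators=icfg.get("n_estimators", 12),
            max_depth=icfg.get("max_depth", 8),
            random_state=icfg.get("seed", fan_out_seed(global_seed, f"impute:{sex}")),
        )
        manifest.seeds[f"impute:{sex}"] = imputer.random_state
        train_f = imputer.fit_transform(train[feats])
        val_f = imputer.transform(val[feats])
        test_f = imputer.transform(test[feats])
        train, val, test = (
            pd.concat([f, t[["residual_life"]].reset_index(drop=True)], axis=1)
            for f, t in ((train_f, train), (val_f, val), (test_f, test))
        )
    elif method == "filter":
        cutoff = icfg.get("feature_cutoff", 0.02)
        full = pd.concat(
            [part.assign(_part=name) for part, name in ((train, "train"), (val, "val"), (test, "test"))]
        ).reset_index(drop=True)
        complete, rep = filter_complete(full[feats + ["_part", "residual_life"]], cutoff, feature_cols=feats)
        feats = [f for f in feats if f not in rep["dropped_features"]]
        train = complete[complete["_part"] == "train"].drop(columns="_part").reset_index(drop=True)
        val = complete[complete["_part"] == "val"].drop(columns="_part").reset_index(drop=True)
        test = complete[complete["_part"] == "test"].drop(columns="_part").reset_index(drop=True)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    manifest.timings[f"impute:{sex}"] = round(time.perf_counter() - t0, 3)
    train, val, test = (t.assign(sex=sex) for t in (train, val, test))

    for name, part in (("train", train), ("val", val), ("test", test)):
        _write_csv(part, sexdir / f"{name}.csv")

    feats = [f for f in feats if f in train.columns]
    for df in (train, val, test):
        for c in feats:
            if df[c].dtype == object:
                df[c] = df[c].astype("category")

    # train
    t0 = time.perf_counter()
    params = mcfg.get("preset", "synthetic-default")
    if isinstance(params, dict):
        params = ModelParams(**params)
    model_seed = mcfg.get("seed", fan_out_seed(global_seed, f"train:{sex}"))
    manifest.seeds[f"train:{sex}"] = model_seed
    model = ResidualLifeRegressor(params=params, seed=model_seed)
    model.fit(train[feats], train["residual_life"].to_numpy(), eval_set=(val[feats], val["residual_life"].to_numpy()))
    model.save(sexdir / "model.txt")
    manifest.timings[f"train:{sex}"] = round(time.perf_counter() - t0, 3)

    preds = model.predict(test[feats])
    metrics = evaluate(preds, test["residual_life"].to_numpy())
    out["metrics"] = metrics.to_dict()
    (sexdir / "metrics.json").write_text(json.dumps(metrics.to_dict(), indent=1))

    # bioage conversion
    if "avg_age" in bcfg:
        avg_age = np.full(len(test), float(bcfg["avg_age"]))
    else:
        table = load_life_expectancy(bcfg.get("table"))
        avg_age = np.full(len(test), table.latest_national.get(sex, table.latest_national["total"]))
    bio_age = to_biological_age(avg_age, preds)

    policy = GroupingPolicy(tolerance=vcfg.get("tolerance", 2.5))
    groups = assign_groups(bio_age, test["chronological_age"].to_numpy(), policy)
    pred_table = test[["chronological_age", "residual_life"]].copy()
    pred_table["predicted_residual_life"] = preds
    pred_table["bio_age"] = bio_age
    pred_table["group"] = groups
    _write_csv(pred_table, sexdir / "predictions.csv")

    # survival validation
    curves = {}
    curve_frames = []
    for g in ("Young", "Stable", "Aging"):
        times = pred_table.loc[pred_table["group"] == g, "residual_life"].to_numpy()
        if len(times) == 0:
            logger.warning("group %s empty for sex %s", g, sex)
            continue
        curves[g] = km_estimate(times)
        cf = curves[g].to_frame()
        cf.insert(0, "group", g)
        curve_frames.append(cf)
    if curve_frames:
        _write_csv(pd.concat(curve_frames), sexdir / "km_curves.csv")
    surv: dict = {"group_sizes": {g: int((pred_table["group"] == g).sum()) for g in ("Young", "Stable", "Aging")}}
    if len(curves) == 3:
        ordering = validate_group_ordering(curves)
        stat, df_, p = logrank_test(
            {g: (pred_table.loc[pred_table["group"] == g, "residual_life"].to_numpy(), None) for g in curves}
        )
        surv.update(
            ordering_fraction=ordering.ordering_fraction,
            small_groups=ordering.small_groups,
            logrank_stat=stat,
            logrank_df=df_,
            logrank_p=p,
        )
    out["survival"] = surv
    (sexdir / "survival.json").write_text(json.dumps(surv, indent=1, default=float))

    # interpretation
    t0 = time.perf_counter()
    gains = feature_gain_ranking(model, k=xcfg.get("top_gain", 10))
    _write_csv(gains, sexdir / "gains.csv")
    cont_feats = [f for f in feats if train[f].dtype.name != "category"]
    matrix = pcc_matrix(train, cont_feats)
    refs = ReferenceMeans(train, feats, granularity=xcfg.get("reference", "age-sex"))
    interventions = intervene_table(
        test,
        model,
        matrix,
        refs,
        threshold=xcfg.get("threshold", 0.5),
        top_k=xcfg.get("top_k", 3),
        partners_k=xcfg.get("partners_k", 3),
    )
    summary = cohort_intervention_summary(interventions)
    out["intervention"] = summary
    out["top_gain_features"] = gains["feature"].tolist()
    (sexdir / "intervention.json").write_text(json.dumps(summary, indent=1))
    manifest.timings[f"interpret:{sex}"] = round(time.perf_counter() - t0, 3)

    for name in ("model.txt", "metrics.json", "predictions.csv", "survival.json", "gains.csv", "intervention.json"):
        manifest.digests[f"sex={sex}/{name}"] = _digest(sexdir / name)
    return out


def render_report(manifest: RunManifest, outdir: str | Path) -> Path:
    """Collate a markdown report from the run artifacts.

    Sections: prediction scatter, metrics table, K-M validation, top-gain
    biomarkers, intervention breakdown.  Missing stage outputs leave a
    flagged gap instead of failing.
    """
    outdir = Path(outdir)
    results_path = outdir / "results.json"
    results = json.loads(results_path.read_text()) if results_path.exists() else {}
    lines = ["# Biological age pipeline report", ""]

    excl = outdir / "exclusion_report.json"
    if excl.exists():
        rep = json.loads(excl.read_text())
        lines += [
            "## Cohort construction",
            "",
            f"- input rows: {rep['n_input']}",
            *[f"- removed by {rule}: {n}" for rule, n in rep["removed"].items()],
            f"- sparse features dropped: {len(rep['dropped_features'])}",
            f"- modeling rows: {rep['n_output']}",
            "",
        ]
    else:
        lines += ["## Cohort construction", "", "_missing: cohort stage did not run_", ""]

    _plot_outputs(outdir, results)

    for section, key, render in (
        ("Residual-life prediction", "metrics", _metrics_md),
        ("Kaplan-Meier validation", "survival", _survival_md),
        ("Top biomarkers by average gain", "top_gain_features", _gains_md),
        ("Counterfactual intervention", "intervention", _intervention_md),
    ):
        lines += [f"## {section}", ""]
        any_present = False
        for sex, res in results.items():
            if key in res:
                any_present = True
                lines += [f"### {sex}", ""] + render(res[key]) + [""]
        if not any_present:
            lines += [f"_missing: no {key} output_", ""]

    for png in ("scatter.png", "km.png", "intervention.png"):
        if (outdir / png).exists():
            lines += [f"![{png}]({png})", ""]

    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path


def _metrics_md(m: dict) -> list[str]:
    return [
        "| metric | value |",
        "|---|---|",
        *[f"| {k} | {v:.4f} |" if isinstance(v, float) else f"| {k} | {v} |" for k, v in m.items()],
    ]


def _survival_md(s: dict) -> list[str]:
    rows = [f"- group sizes: {s.get('group_sizes')}"]
    if "ordering_fraction" in s:
        rows += [
            f"- ordering fraction (Young >= Stable >= Aging): {s['ordering_fraction']:.3f}",
            f"- log-rank: chi2 = {s['logrank_stat']:.2f}, df = {s['logrank_df']}, p = {s['logrank_p']:.3g}",
        ]
        if s.get("small_groups"):
            rows.append(f"- WARNING small groups (<80): {s['small_groups']}")
    return rows


def _gains_md(features: list) -> list[str]:
    return [f"{i + 1}. {f}" for i, f in enumerate(features)]


def _intervention_md(s: dict) -> list[str]:
    return [f"- {k}: {100 * v:.2f}%" for k, v in s.items()]


def _plot_outputs(outdir: Path, results: dict) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # pragma: no cover - plotting is best-effort
        return
    sexes = list(results)
    if not sexes:
        return
    fig, axes = plt.subplots(1, len(sexes), figsize=(5 * len(sexes), 4), squeeze=False)
    for ax, sex in zip(axes[0], sexes):
        pred_path = outdir / f"sex={sex}" / "predictions.csv"
        if not pred_path.exists():
            continue
        df = pd.read_csv(pred_path)
        ax.scatter(df["residual_life"], df["predicted_residual_life"], s=4, alpha=0.4)
        lim = [0, max(df["residual_life"].max(), df["predicted_residual_life"].max())]
        ax.plot(lim, lim, ls="--", c="orange")
        ax.set_xlabel("actual residual life (y)")
        ax.set_ylabel("predicted (y)")
        ax.set_title(sex)
    fig.tight_layout()
    fig.savefig(outdir / "scatter.png", dpi=110)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(sexes), figsize=(5 * len(sexes), 4), squeeze=False)
    for ax, sex in zip(axes[0], sexes):
        km_path = outdir / f"sex={sex}" / "km_curves.csv"
        if not km_path.exists():
            continue
        km = pd.read_csv(km_path)
        for g, gdf in km.groupby("group"):
            ax.step(gdf["time"], gdf["survival"], where="post", label=g)
        ax.set_xlabel("years since exam")
        ax.set_ylabel("survival")
        ax.set_title(sex)
        ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "km.png", dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    width = 0.8 / max(len(sexes), 1)
    cats = ["improved", "unchanged", "worsened"]
    for i, sex in enumerate(sexes):
        s = results[sex].get("intervention")
        if not s:
            continue
        ax.bar(np.arange(3) + i * width, [100 * s[c] for c in cats], width, label=sex)
    ax.set_xticks(np.arange(3) + width * (len(sexes) - 1) / 2, cats)
    ax.set_ylabel("% of records")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "intervention.png", dpi=110)
    plt.close(fig)
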