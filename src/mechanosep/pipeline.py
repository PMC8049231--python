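"""End-to-end pipeline orchestration.

Stages: simulate cohorts -> per-run bead QC -> trace synthesis -> event
metric extraction -> gating -> per-subject features -> model training on the
high-acuity cohort -> scoring of every subject -> evaluation report.  Each
stage writes a CSV/JSON artifact with a content hash recorded in
manifest.json; a rerun with the same config and seeds is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import event_sim, features, gating, imaging_metrics, model as mdl
from .config import PipelineConfig, config_to_dict
from .synth_cohort import generate_cohort

log = logging.getLogger("mechanosep")

ARTIFACTS = ("subjects.csv", "traces.csv", "events.csv", "gated_events.csv",
             "features.csv", "model.json", "scores.csv",
             "evaluation_report.json")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # %.17g round-trips float64 exactly, keeping staged CLI runs and
    # in-memory runs bit-identical
    df.to_csv(path, index=False, float_format="%.17g")


def simulate_stage(config: PipelineConfig, out: Path) -> dict[str, pd.DataFrame]:
    """Generate every cohort; writes subjects.csv and cells_truth.csv."""
    subjects, cells = [], {}
    for name, spec in config.cohorts.items():
        s, c = generate_cohort(spec)
        subjects.append(s)
        cells[name] = c
        log.info("simulated cohort %s: %d subjects, %d cells", name, len(s), len(c))
    subjects = pd.concat(subjects, ignore_index=True)
    _write_csv(subjects, out / "subjects.csv")
    _write_csv(pd.concat(cells.values(), ignore_index=True), out / "cells_truth.csv")
    return {"subjects": subjects, "cells": cells}


def qc_stage(config: PipelineConfig, subjects: pd.DataFrame, out: Path) -> dict:
    """Per-subject control-bead run and accept/reject decision."""
    seeds = np.random.SeedSequence(config.seed).spawn(len(subjects))
    reports = []
    excluded = []
    clogged = set(config.clogged_subjects)
    for (sid,), seed in zip(subjects[["subject_id"]].to_numpy(), seeds):
        rng = np.random.default_rng(seed)
        beads = event_sim.synthesize_bead_run(
            config.n_beads_per_run, config.acquisition,
            clogged=sid in clogged, rng=rng)
        rep = imaging_metrics.run_qc(beads, config.acquisition, config.qc,
                                     run_id=str(sid))
        reports.append(rep)
        if not rep.accepted:
            excluded.append(str(sid))
            log.warning("run %s rejected by QC: %s", sid, "; ".join(rep.reasons))
    (out / "qc_report.json").write_text(json.dumps(
        {"runs": [json.loads(r.to_json()) for r in reports],
         "excluded_subjects": excluded}, indent=2))
    return {"excluded": excluded}


def extract_stage(config: PipelineConfig, cells: dict[str, pd.DataFrame],
                  excluded: list[str], out: Path) -> pd.DataFrame:
    """Trace synthesis and per-event metric estimation; QC-excluded
    subjects never reach the event table."""
    events = []
    trace_frames = []
    for name in sorted(cells):  # seed per cohort name, not iteration order
        cohort_cells = cells[name]
        seed = np.random.SeedSequence(
            (config.seed, 1, sorted(cells).index(name)))
        keep = ~cohort_cells["subject_id"].isin(excluded)
        batch = event_sim.synthesize_traces(
            cohort_cells.loc[keep], config.acquisition,
            np.random.default_rng(seed))
        events.append(imaging_metrics.extract_events(batch))
        if config.write_traces:
            trace_frames.append(batch.to_frame())
        log.info("extracted %d events for cohort %s", int(keep.sum()), name)
    if config.write_traces:
        _write_csv(pd.concat(trace_frames, ignore_index=True), out / "traces.csv")
    else:  # keep the artifact list stable for downstream tooling
        (out / "traces.csv").write_text("cell_id,t,x,y,major,minor,orientation,is_bead\n")
    events = pd.concat(events, ignore_index=True)
    _write_csv(events, out / "events.csv")
    return events


def gate_stage(config: PipelineConfig, events: pd.DataFrame,
               subjects: pd.DataFrame, out: Path) -> pd.DataFrame:
    """Per-cohort gate fit and type assignment; writes gated_events.csv."""
    cohort_of = subjects.set_index("subject_id")["cohort_name"]
    events = events.assign(cohort_name=events["subject_id"].map(cohort_of))
    gates_json = {}
    typed = []
    for name, grp in events.groupby("cohort_name", sort=True):
        gm = gating.fit_gates(grp, config.gating)
        labels = gating.assign_types(gm, grp, config.gating.uncertain_posterior)
        typed.append(grp.assign(type=labels))
        gates_json[name] = gm.to_dict()
    gated = pd.concat(typed, ignore_index=True)
    (out / "gates.json").write_text(json.dumps(gates_json, indent=2))
    _write_csv(gated.drop(columns=["cohort_name"]), out / "gated_events.csv")
    return gated


def featurize_stage(config: PipelineConfig, gated: pd.DataFrame,
                    subjects: pd.DataFrame, out: Path) -> pd.DataFrame:
    table = features.compute_feature_table(gated, config.features)
    table = table.merge(
        subjects[["subject_id", "cohort_name", "disease_state"]],
        on="subject_id", how="left")
    _write_csv(table, out / "features.csv")
    (out / "registry.json").write_text(features.registry_json())
    n_flagged = int(table["insufficient"].sum())
    if n_flagged:
        log.warning("%d subjects flagged insufficient and excluded from training",
                    n_flagged)
    return table


def train_stage(config: PipelineConfig, feats: pd.DataFrame,
                out: Path) -> tuple[mdl.FittedScoreModel, dict]:
    """Sequester split + nested CV on the initial training set, then the
    final fit on the full high-acuity cohort."""
    ha = feats[(feats["cohort_name"] == "high_acuity")
               & (~feats["insufficient"].astype(bool))].reset_index(drop=True)
    if ha.empty:
        raise PipelineError("train", "no usable high-acuity subjects")
    y = (ha["disease_state"] == "septic").to_numpy().astype(int)
    names = list(features.FEATURE_REGISTRY)
    train_ids, seq_ids = mdl.sequester_split(
        ha["subject_id"].to_numpy(), y, config.validation)
    tr_mask = ha["subject_id"].isin(train_ids).to_numpy()
    X = ha[names].to_numpy(dtype=float)
    cv = mdl.nested_cv(X[tr_mask], y[tr_mask], config.validation)

    # validate on the sequestered set with a model fit on the initial set
    init = mdl.train_final_model(ha[tr_mask], y[tr_mask], names,
                                 config.validation, config.anchors, config.bands)
    seq_auc = ev.roc_auc(init.logodds(ha[~tr_mask]), y[~tr_mask])

    final = mdl.train_final_model(ha, y, names, config.validation,
                                  config.anchors, config.bands)
    final.save(out / "model.json")
    summary = {"nested_cv": cv, "sequester_auc": seq_auc,
               "n_training": int(tr_mask.sum()),
               "n_sequestered": int((~tr_mask).sum())}
    log.info("nested-CV mean AUC %.3f; sequestered-set AUC %.3f",
             cv["mean_auc"], seq_auc)
    return final, summary


def score_stage(config: PipelineConfig, final: mdl.FittedScoreModel,
                feats: pd.DataFrame, out: Path) -> pd.DataFrame:
    usable = feats[~feats["insufficient"].astype(bool)].reset_index(drop=True)
    isi = final.compute_isi(usable)
    scores = pd.DataFrame({
        "subject_id": usable["subject_id"],
        "cohort_name": usable["cohort_name"],
        "isi": isi,
        "band": mdl.assign_band(isi, config.bands),
    })
    _write_csv(scores, out / "scores.csv")
    return scores


def evaluate_stage(config: PipelineConfig, scores: pd.DataFrame,
                   subjects: pd.DataFrame, train_summary: dict,
                   out: Path, make_plots: bool = True) -> dict:
    df = scores.merge(subjects, on=["subject_id", "cohort_name"], how="left")
    ha = df[df["cohort_name"] == "high_acuity"]
    y = (ha["disease_state"] == "septic").to_numpy().astype(int)
    s = ha["isi"].to_numpy()
    auc = ev.roc_auc(s, y)
    auc_ci = ev.bootstrap_auc_ci(s, y, rng=np.random.default_rng(config.seed))

    report: dict = {"training": train_summary,
                    "high_acuity_auc": auc, "high_acuity_auc_ci95": auc_ci}
    report["band_distribution"] = {
        name: {b: int((grp["band"] == b).sum()) for b in ("Green", "Yellow", "Red")}
        for name, grp in df.groupby("cohort_name")}
    g = ha[ha["band"] == "Green"]
    r = ha[ha["band"] == "Red"]
    if len(g) and len(r):
        ct = ev.BandContingency(
            n_green=len(g), septic_green=int((g["disease_state"] == "septic").sum()),
            n_red=len(r), septic_red=int((r["disease_state"] == "septic").sum()))
        report["band_diagnostics"] = ev.band_diagnostics(ct)
    acute = df[df["cohort_name"].isin(["high_acuity", "low_acuity"])]
    try:
        report["band_trends"] = ev.band_trend_report(acute)
    except ValueError as exc:
        report["band_trends"] = {"note": str(exc)}
    km = ev.km_logrank(ha["survival_time"].to_numpy(),
                       (~ha["censored"].astype(bool)).to_numpy().astype(int),
                       ha["band"].to_numpy())
    report["km_logrank"] = {"statistic": km["statistic"], "p_value": km["p_value"]}

    (out / "evaluation_report.json").write_text(
        json.dumps(report, indent=2, default=float))
    if make_plots:
        _plots(ha, s, y, km, out)
    return report


def _plots(ha: pd.DataFrame, scores: np.ndarray, y: np.ndarray,
           km: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y, scores)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    fig.savefig(out / "roc.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    data = [ha.loc[ha["band"] == b, "sofa_3day_max"].dropna() for b in
            ("Green", "Yellow", "Red")]
    ax.boxplot(data, tick_labels=["Green", "Yellow", "Red"])
    ax.set_ylabel("SOFA (3-day max)")
    fig.savefig(out / "bands_box.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    for name, curve in km["curves"].items():
        ax.step(curve["time"], curve["survival"], where="post", label=name)
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.legend()
    fig.savefig(out / "km.png", dpi=120, bbox_inches="tight")
    plt.close(fig)


def run_pipeline(config: PipelineConfig,
                 output_dir: str | Path | None = None,
                 make_plots: bool = True) -> dict:
    """Run every stage; returns artifact paths, hashes and the evaluation
    report."""
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = simulate_stage(config, out)
    qc = qc_stage(config, sim["subjects"], out)
    all_ids = set(sim["subjects"]["subject_id"])
    if set(qc["excluded"]) >= all_ids:
        raise PipelineError("qc", "every run was rejected by QC")
    events = extract_stage(config, sim["cells"], qc["excluded"], out)
    gated = gate_stage(config, events, sim["subjects"], out)
    feats = featurize_stage(config, gated, sim["subjects"], out)
    final, train_summary = train_stage(config, feats, out)
    scores = score_stage(config, final, feats, out)
    report = evaluate_stage(config, scores, sim["subjects"], train_summary,
                            out, make_plots=make_plots)

    manifest = {
        "config": config_to_dict(config),
        "excluded_subjects": qc["excluded"],
        "artifacts": {name: _sha256(out / name) for name in ARTIFACTS
                      if (out / name).exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"output_dir": str(out), "report": report,
            "artifacts": manifest["artifacts"],
            "excluded_subjects": qc["excluded"]}
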