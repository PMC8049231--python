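"""End-to-end reproduction of the study's headline quantities.

Runs the default synthetic cohorts through the full measurement pipeline
(trace synthesis -> metric estimation -> gating -> aggregation), trains the
score model under the sequester/nested-CV architecture, and computes the
evaluation statistics the study reports: recovered biophysical group means,
the monocyte VEIR effect size, cross-validated AUC, and the interpretation-
band distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import event_sim, features, gating, imaging_metrics, model as mdl
from .config import (
    AcquisitionParams,
    CohortSpec,
    GatingConfig,
    ScoreAnchors,
    ValidationPlan,
    healthy_spec,
    high_acuity_spec,
    low_acuity_spec,
)
from .synth_cohort import generate_cohort


def cohort_features(spec: CohortSpec, acq: AcquisitionParams,
                    trace_seed: int,
                    gate_cfg: GatingConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort and push it through measurement, gating and
    aggregation.  Returns (subjects, per-subject feature table)."""
    subjects, cells = generate_cohort(spec)
    batch = event_sim.synthesize_traces(cells, acq,
                                        np.random.default_rng(trace_seed))
    events = imaging_metrics.extract_events(batch)
    gm = gating.fit_gates(events, gate_cfg)
    events = events.assign(type=gating.assign_types(gm, events))
    table = features.compute_feature_table(events)
    table = table.merge(subjects[["subject_id", "disease_state"]],
                        on="subject_id", how="left")
    return subjects, table


@dataclass
class StudyData:
    subjects: dict[str, pd.DataFrame]
    feats: dict[str, pd.DataFrame]


def run_study(seed: int, n_cells: int = 2000,
              acq: AcquisitionParams | None = None) -> StudyData:
    """Simulate and measure the three default cohorts (seeded)."""
    acq = acq or AcquisitionParams()
    specs = {
        "high_acuity": high_acuity_spec(n_cells_per_subject=n_cells, seed=seed),
        "low_acuity": low_acuity_spec(n_cells_per_subject=n_cells, seed=seed + 1),
        "healthy": healthy_spec(n_cells_per_subject=n_cells, seed=seed + 2),
    }
    subjects, feats = {}, {}
    for i, (name, spec) in enumerate(specs.items()):
        subjects[name], feats[name] = cohort_features(
            spec, acq, trace_seed=seed + 1000 + i)
    return StudyData(subjects=subjects, feats=feats)


def septic_features(data: StudyData) -> pd.DataFrame:
    """The 78 septic subjects of the combined acute cohorts (72 + 6)."""
    acute = pd.concat([data.feats["high_acuity"], data.feats["low_acuity"]],
                      ignore_index=True)
    return acute[acute["disease_state"] == "septic"]


def recovered_group_means(data: StudyData) -> dict[str, float]:
    """Per-subject-mean biophysical metrics averaged over disease groups,
    as recovered through the full pipeline (um for VEIR)."""
    septic = septic_features(data)
    healthy = data.feats["healthy"]
    return {
        "septic_neutrophil_ar_mean": float(septic["neutrophil_ar_mean"].mean()),
        "healthy_neutrophil_veir_mean": float(healthy["neutrophil_veir_mean"].mean()),
        "septic_monocyte_veir_mean": float(septic["monocyte_veir_mean"].mean()),
        "n_septic": int(len(septic)),
        "n_healthy": int(len(healthy)),
    }


def monocyte_veir_cohens_d(seed: int, n_healthy: int = 72, n_septic: int = 78,
                           n_replicates: int = 20) -> float:
    """Effect size of the published monocyte VEIR group statistics.

    Draws subject-level means at the printed healthy (8.26 +/- 0.79 um) and
    septic (10.41 +/- 0.90 um) moments and averages pooled-SD Cohen's d over
    seeded replicates.
    """
    from .config import default_population_params
    pp = default_population_params()
    h = pp[("healthy", "monocyte")]
    s = pp[("septic", "monocyte")]
    ds = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        x = rng.normal(h.mean_veir, h.sd_veir_between, n_healthy)
        y = rng.normal(s.mean_veir, s.sd_veir_between, n_septic)
        ds.append(ev.cohens_d(x, y))
    return float(np.mean(ds))


def train_and_band(data: StudyData, plan: ValidationPlan,
                   anchors: ScoreAnchors | None = None) -> dict:
    """Final model on the full high-acuity cohort; band distribution of its
    training scores plus the cross-validation summaries."""
    ha = data.feats["high_acuity"]
    ha = ha[~ha["insufficient"].astype(bool)].reset_index(drop=True)
    y = (ha["disease_state"] == "septic").to_numpy().astype(int)
    names = list(features.FEATURE_REGISTRY)
    X = ha[names].to_numpy(dtype=float)

    cv = mdl.nested_cv(X, y, plan)

    train_ids, _ = mdl.sequester_split(ha["subject_id"].to_numpy(), y, plan)
    tr = ha["subject_id"].isin(train_ids).to_numpy()
    init = mdl.train_final_model(ha[tr], y[tr], names, plan, anchors)
    sequester_auc = ev.roc_auc(init.logodds(ha[~tr]), y[~tr])

    final = mdl.train_final_model(ha, y, names, plan, anchors)
    isi = final.compute_isi(ha)
    bands = mdl.assign_band(isi)
    stability = mdl.repeated_kfold_auc(X, y, plan, k=10, n_repeats=10,
                                       lam=final.lam)
    return {
        "model": final,
        "nested_cv_mean_auc": cv["mean_auc"],
        "nested_cv_outer_aucs": cv["outer_aucs"],
        "sequester_auc": sequester_auc,
        "repeated_kfold_mean_auc": stability["mean_auc"],
        "green_fraction": float(np.mean(bands == "Green")),
        "band_counts": {b: int((bands == b).sum())
                        for b in ("Green", "Yellow", "Red")},
        "isi": isi,
        "labels": y,
        "n_subjects": int(len(ha)),
    }
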