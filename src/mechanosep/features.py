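"""Per-subject aggregation of gated per-cell metrics.

The feature registry spans {lymphocyte, neutrophil, monocyte} x
{size, AR, VEIR} x {mean, median, sd, p25, p75} (45 features) plus the three
type fractions, 48 in all.  The registry is a reconstruction of the
instrument's population-level descriptors: summary statistics of each
biophysical metric per gated subpopulation.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .config import CELL_TYPES, FeatureConfig

_METRICS = ("size", "ar", "veir")
_STATS = ("mean", "median", "sd", "p25", "p75")

FEATURE_REGISTRY: tuple[str, ...] = tuple(
    [f"{ct}_{m}_{s}" for ct in CELL_TYPES for m in _METRICS for s in _STATS]
    + [f"frac_{ct}" for ct in CELL_TYPES]
)

META_COLUMNS = ("subject_id", "n_cells_typed", "insufficient")


def registry_json() -> str:
    return json.dumps({"features": list(FEATURE_REGISTRY)}, indent=2)


def _stat(values: np.ndarray, stat: str) -> float:
    if stat == "mean":
        return float(values.mean())
    if stat == "median":
        return float(np.median(values))
    if stat == "sd":
        return float(values.std(ddof=1))
    if stat == "p25":
        return float(np.percentile(values, 25))  # linear interpolation
    if stat == "p75":
        return float(np.percentile(values, 75))
    raise ValueError(stat)


def compute_features(gated: pd.DataFrame,
                     config: FeatureConfig | None = None) -> pd.Series:
    """One subject's feature vector from its gated events.

    Subjects with fewer typed cells than ``min_events``, or with any
    subpopulation below ``min_events_per_type`` (whose statistics would be
    undefined or meaningless), are flagged ``insufficient`` and carry NaN
    features; they are excluded from model training.
    """
    config = config or FeatureConfig()
    typed = gated[gated["type"].isin(CELL_TYPES)]
    n_typed = len(typed)
    out: dict[str, float] = {}
    insufficient = n_typed < config.min_events
    counts = {ct: int((typed["type"] == ct).sum()) for ct in CELL_TYPES}
    if min(counts.values()) < config.min_events_per_type:
        insufficient = True
    for ct in CELL_TYPES:
        sub = typed[typed["type"] == ct]
        for m in _METRICS:
            vals = sub[m].to_numpy(dtype=float)
            for s in _STATS:
                name = f"{ct}_{m}_{s}"
                out[name] = (_stat(vals, s)
                             if len(vals) >= config.min_events_per_type
                             else np.nan)
    for ct in CELL_TYPES:
        out[f"frac_{ct}"] = counts[ct] / n_typed if n_typed else np.nan
    if insufficient:
        out = {k: np.nan for k in out}
    out["n_cells_typed"] = n_typed
    out["insufficient"] = insufficient
    return pd.Series(out)


def compute_feature_table(gated_events: pd.DataFrame,
                          config: FeatureConfig | None = None) -> pd.DataFrame:
    """Feature vectors for every subject present in ``gated_events``.

    The ``uncertain`` gate label is excluded from all per-type statistics and
    fractions (but those events still count toward the raw concentration,
    which is metadata, not a model feature).
    """
    config = config or FeatureConfig()
    rows = []
    for sid, grp in gated_events.groupby("subject_id", sort=True):
        fv = compute_features(grp, config)
        fv["subject_id"] = sid
        rows.append(fv)
    table = pd.DataFrame(rows).reset_index(drop=True)
    cols = ["subject_id"] + list(FEATURE_REGISTRY) + ["n_cells_typed", "insufficient"]
    return table[cols]
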