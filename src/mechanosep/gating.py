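"""Leukocyte subpopulation gating from cell size and optical intensity.

A 3-component Gaussian mixture is fitted in (log size, log intensity) space
— both are positive and right-skewed, and a global intensity rescale is a
pure shift in log space, leaving the gating invariant.  Components are
mapped to types by ordering rules (small+dim = lymphocyte, largest = monocyte,
remainder = neutrophil) rather than a learned reference, which keeps labels
deterministic and stable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .config import BEAD_DIAMETER_UM, CELL_TYPES, GatingConfig

UNCERTAIN = "uncertain"


class PopulationMissingError(ValueError):
    """The event cloud does not support three distinct leukocyte populations."""


def exclude_beads(events: pd.DataFrame,
                  tolerance_um: float = 0.30) -> pd.DataFrame:
    """Drop control-bead events before gating.

    Uses the is_bead flag when the acquisition provides it, plus the bead
    signature (diameter within ``tolerance_um`` of 8.86 um, no deformation,
    no recoil) so that stray control objects in the cell stream are caught
    without sacrificing neutrophils of similar size.
    """
    keep = np.ones(len(events), dtype=bool)
    if "is_bead" in events:
        keep &= ~events["is_bead"].to_numpy().astype(bool)
    sig = ((np.abs(events["size"].to_numpy() - BEAD_DIAMETER_UM) <= tolerance_um)
           & (events["ar"].to_numpy() < 1.15)
           & (events["veir"].to_numpy() < 1.0))
    keep &= ~sig
    return events.loc[keep]


@dataclass
class GateModel:
    """Fitted 3-component mixture plus the component-to-type bijection."""

    gmm: GaussianMixture
    assignment: dict[int, str]  # component index -> cell type

    @property
    def component_means(self) -> np.ndarray:
        return self.gmm.means_

    def to_dict(self) -> dict:
        return {
            "assignment": {str(k): v for k, v in self.assignment.items()},
            "weights": self.gmm.weights_.tolist(),
            "means_log_size_log_intensity": self.gmm.means_.tolist(),
            "covariances": self.gmm.covariances_.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _design(events: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.log(events["size"].to_numpy(dtype=float)),
                            np.log(events["intensity"].to_numpy(dtype=float))])


def fit_gates(events: pd.DataFrame,
              config: GatingConfig | None = None) -> GateModel:
    """EM-fit the 3-component gate model on non-bead events.

    Raises :class:`PopulationMissingError` when a component collapses (weight
    below 1%) or when one Gaussian explains the cloud at least as well as
    three (BIC), i.e. the three populations are not actually present.
    """
    config = config or GatingConfig()
    events = exclude_beads(events, config.bead_size_tolerance_um)
    if len(events) < config.min_events:
        raise ValueError(f"need >= {config.min_events} non-bead events, "
                         f"got {len(events)}")
    X = _design(events)
    gmm = GaussianMixture(n_components=3, covariance_type="full",
                          n_init=3, random_state=config.seed,
                          reg_covar=1e-6).fit(X)
    if gmm.weights_.min() < config.min_component_weight:
        raise PopulationMissingError(
            f"population missing: component weight {gmm.weights_.min():.3%} "
            f"below {config.min_component_weight:.0%}")
    single = GaussianMixture(n_components=1, covariance_type="full",
                             random_state=config.seed).fit(X)
    if single.bic(X) <= gmm.bic(X):
        raise PopulationMissingError(
            "population missing: one component explains the events at least "
            "as well as three (BIC)")

    means = gmm.means_
    scale = X.std(axis=0)
    z = means / np.maximum(scale, 1e-12)
    lymph = int(np.argmin(z.sum(axis=1)))        # dimmest and smallest
    rest = [i for i in range(3) if i != lymph]
    mono = int(rest[np.argmax(means[rest, 0])])  # largest size
    neut = next(i for i in rest if i != mono)
    assignment = {lymph: "lymphocyte", neut: "neutrophil", mono: "monocyte"}
    return GateModel(gmm=gmm, assignment=assignment)


def assign_types(model: GateModel, events: pd.DataFrame,
                 uncertain_posterior: float = 0.5) -> np.ndarray:
    """Maximum-posterior type per event; low-confidence events are labeled
    ``uncertain`` and excluded from per-type features downstream."""
    post = model.gmm.predict_proba(_design(events))
    comp = post.argmax(axis=1)
    best = post[np.arange(len(events)), comp]
    labels = np.array([model.assignment[c] for c in comp], dtype=object)
    labels[best < uncertain_posterior] = UNCERTAIN
    return labels


def validate_gates(labels: np.ndarray,
                   truth: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Confusion matrix (truth x assigned) and overall accuracy.

    Stands in for a fluorescence cross-check: truth here is the generator's
    type label.  ``uncertain`` assignments are tabulated but excluded from
    the accuracy denominator.
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ValueError("labels and truth must have equal length")
    cols = list(CELL_TYPES) + [UNCERTAIN]
    cm = pd.DataFrame(0, index=list(CELL_TYPES), columns=cols, dtype=int)
    for t in CELL_TYPES:
        sel = truth == t
        for c in cols:
            cm.loc[t, c] = int(np.sum(labels[sel] == c))
    typed = labels != UNCERTAIN
    accuracy = float(np.mean(labels[typed] == truth[typed])) if typed.any() else 0.0
    return cm, accuracy
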