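"""Synthetic cohort generator.

Subjects carry an adjudicated disease state (healthy / non-septic SIRS /
septic), a latent immune-activation severity factor, clinical outcomes, and a
bag of per-cell ground-truth biophysical parameters.

The generative model is hierarchical with a single latent factor:

* Each subject draws a severity factor ``a ~ N(m_state, 1)`` where
  ``m_state`` is 0 / 1.0 / 2.9 for healthy / SIRS / septic.
* Subject-level metric means (size, AR, VEIR per cell type) are
  ``state_mean + loading * (a - m_state) + idio * e``; the loadings are fixed
  by the healthy-to-septic group-mean margins, and the idiosyncratic SD tops
  the total between-subject SD up to the configured value.  Because every
  between-state shift acts through the one factor, the best achievable
  classifier AUC for septic vs SIRS is capped at Phi(1.9/sqrt 2) ~ 0.91 no
  matter how many features are measured — matching the redundancy of the real
  biomarkers.
* Cell-level size and AR scatter around the subject means with
  equicorrelated within-subject noise.  Cell-level VEIR is composed as the
  cell's stretch amplitude d(sqrt(AR)-1) plus a non-negative recoil margin
  centered so the subject's mean VEIR hits its drawn target — every cell is
  realizable by the recoil waveform of :mod:`mechanosep.event_sim` without
  clamping bias.
* Clinical outcomes (SOFA, APACHE-II, LOS, ICU admission, death, survival
  time) are monotone-in-expectation functions of the factor.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import (
    CELL_TYPES,
    DISEASE_STATES,
    FACTOR_MEANS,
    ClinicalLinks,
    CohortSpec,
    ConfigError,
    PopulationParams,
)

_SUBJECT_COLUMNS = [
    "subject_id", "cohort_name", "disease_state", "latent_severity",
    "age", "sex", "race", "sofa_3day_max", "apache2", "piro",
    "hospital_los", "icu_admit", "in_hospital_death",
    "survival_time", "censored", "wbc_count",
]

_CELL_COLUMNS = ["cell_id", "subject_id", "true_type", "size", "intensity",
                 "true_ar", "true_veir"]

_CORR_METRICS = ("size", "ar", "veir")  # cell-level equicorrelated triple

SIZE_BOUNDS_UM = (4.05, 19.95)  # leukocyte rest diameters must stay in (4, 20)
AR_FLOOR = 1.05


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def metric_loadings(
    params: Mapping[tuple[str, str], PopulationParams]
) -> dict[tuple[str, str], float]:
    """Factor loading per (cell type, metric), from the healthy/septic
    group-mean margins divided by the factor gap."""
    gap = FACTOR_MEANS["septic"] - FACTOR_MEANS["healthy"]
    out: dict[tuple[str, str], float] = {}
    for ct in CELL_TYPES:
        h, s = params[("healthy", ct)], params[("septic", ct)]
        for metric in ("size", "ar", "veir", "log_intensity"):
            out[(ct, metric)] = (s.mean(metric) - h.mean(metric)) / gap
    return out


def _idio_sd(pp: PopulationParams, metric: str, loading: float) -> float:
    sd = pp.sd_between(metric)
    if sd < abs(loading):
        raise ConfigError(
            f"between-subject SD {sd} for {metric} smaller than its factor "
            f"loading {loading}: total SD cannot be achieved")
    return float(np.sqrt(sd**2 - loading**2))


def veir_feasible_bounds(size: np.ndarray, ar: np.ndarray):
    """Physically realizable VEIR interval for the recoil waveform.

    The axial excursion can never be smaller than the stretch amplitude
    d(sqrt(AR)-1) itself, and the recoil trough must keep a positive axial
    extent, which caps the undershoot below the rest diameter (with a 5%
    margin so noisy descriptors stay well away from degeneracy).
    """
    stretch = size * (np.sqrt(ar) - 1.0)
    return stretch, stretch + 0.95 * size


def sample_clinical_outcomes(latent_severity: float, disease_state: str,
                             rng: np.random.Generator,
                             links: ClinicalLinks | None = None,
                             clinical_offset: float = 0.0) -> dict:
    """Clinical outcome fields for one subject (monotone links in severity).

    Healthy donors have no clinical course and get missing outcomes.
    """
    if not np.isfinite(latent_severity):
        raise ValueError("latent severity must be finite")
    links = links or ClinicalLinks()
    out = _sample_clinical_batch(
        np.array([latent_severity]), np.array([disease_state == "healthy"]),
        rng, links, clinical_offset)
    return {k: v[0] for k, v in out.items()}


def _sample_clinical_batch(severity: np.ndarray, is_healthy: np.ndarray,
                           rng: np.random.Generator, links: ClinicalLinks,
                           clinical_offset: float) -> dict[str, np.ndarray]:
    n = severity.size
    s = severity + clinical_offset
    sofa = np.round(_softplus(links.sofa_intercept + links.sofa_slope * s
                              + links.sofa_noise_sd * rng.standard_normal(n)))
    sofa = np.clip(sofa, 0, 24)
    apache = np.round(links.apache_intercept + links.apache_slope * s
                      + links.apache_noise_sd * rng.standard_normal(n))
    apache = np.clip(apache, 0, 71)
    piro = np.round(np.clip(2.0 + 1.8 * s + 2.0 * rng.standard_normal(n), 0, 20))
    los = np.round(np.exp(links.los_log_intercept + links.los_log_slope * s
                          + links.los_log_noise_sd * rng.standard_normal(n)))
    los = np.clip(los, 0, 60)
    icu = (rng.random(n) < _sigmoid(links.icu_intercept + links.icu_slope * s))
    death = (rng.random(n) < _sigmoid(links.death_intercept + links.death_slope * s))
    t_death = np.minimum(0.5 + rng.exponential(links.death_time_scale, n),
                         links.followup_days - 0.1)
    survival_time = np.where(death, t_death, links.followup_days)
    censored = ~death

    def _mask(a, fill=np.nan):
        a = a.astype(float)
        a[is_healthy] = fill
        return a

    return {
        "sofa_3day_max": _mask(sofa),
        "apache2": _mask(apache),
        "piro": _mask(piro),
        "hospital_los": _mask(los),
        "icu_admit": _mask(icu),
        "in_hospital_death": _mask(death),
        "survival_time": _mask(survival_time),
        "censored": _mask(censored),
    }


def _sample_demographics(spec: CohortSpec, n: int, rng: np.random.Generator):
    d = spec.demographics
    sd = (d.age_q3 - d.age_q1) / 1.349
    age = np.clip(np.round(rng.normal(d.age_median, sd, n), 1), 18.0, 100.0)
    sex = np.where(rng.random(n) < d.female_fraction, "F", "M")
    races = list(d.race_fractions)
    race = rng.choice(races, size=n, p=[d.race_fractions[r] for r in races])
    return age, sex, race


def _type_logit_loadings(spec: CohortSpec) -> dict[str, float]:
    gap = FACTOR_MEANS["septic"] - FACTOR_MEANS["healthy"]
    fh = spec.type_fractions["healthy"]
    fs = spec.type_fractions["septic"]
    return {ct: float(np.log(fs[ct] / fh[ct]) / gap) for ct in CELL_TYPES}


def _subject_type_fractions(spec: CohortSpec, states: np.ndarray,
                            factor: np.ndarray, rng: np.random.Generator):
    """Per-subject leukocyte differential: softmax of state logits shifted
    along the factor plus idiosyncratic noise."""
    n = states.size
    lam = _type_logit_loadings(spec)
    logits = np.empty((n, len(CELL_TYPES)))
    for j, ct in enumerate(CELL_TYPES):
        base = np.array([np.log(spec.type_fractions[s][ct]) for s in states])
        centred = factor - np.array([FACTOR_MEANS[s] for s in states])
        logits[:, j] = (base + lam[ct] * centred
                        + spec.type_fraction_logit_sd * rng.standard_normal(n))
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    return w / w.sum(axis=1, keepdims=True)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort: subject records and per-cell ground truth.

    Returns ``(subjects, cells)`` data frames.  Counts are fixed by the spec
    (exactly ``n_septic`` septic subjects), and the whole draw is a pure
    function of ``spec`` including its seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    if spec.cohort_name == "healthy":
        if spec.n_septic != 0:
            raise ConfigError("healthy cohort cannot contain septic subjects")
        states = np.array(["healthy"] * n)
    else:
        states = np.array(["septic"] * spec.n_septic
                          + ["sirs_nonseptic"] * (n - spec.n_septic))
        rng.shuffle(states)

    factor = np.array([FACTOR_MEANS[s] for s in states]) + rng.standard_normal(n)
    age, sex, race = _sample_demographics(spec, n, rng)
    wbc = rng.lognormal(spec.wbc_dist.mu, spec.wbc_dist.sigma, n)
    clinical = _sample_clinical_batch(factor, states == "healthy", rng,
                                      spec.clinical_links, spec.clinical_offset)

    subject_ids = np.array([f"{spec.cohort_name}_{i:04d}" for i in range(n)])
    subjects = pd.DataFrame({
        "subject_id": subject_ids,
        "cohort_name": spec.cohort_name,
        "disease_state": states,
        "latent_severity": factor,
        "age": age, "sex": sex, "race": race,
        **clinical,
        "wbc_count": wbc,
    })[_SUBJECT_COLUMNS]

    cells = _generate_cells(spec, subjects, rng)
    return subjects, cells


def _generate_cells(spec: CohortSpec, subjects: pd.DataFrame,
                    rng: np.random.Generator) -> pd.DataFrame:
    n = len(subjects)
    n_cells = spec.n_cells_per_subject
    states = subjects["disease_state"].to_numpy()
    factor = subjects["latent_severity"].to_numpy()
    loadings = metric_loadings(spec.population_params)

    # subject-level metric means, per cell type
    subj_means: dict[str, np.ndarray] = {}
    within_sd: dict[str, np.ndarray] = {}
    rho = np.empty(n)
    gap = FACTOR_MEANS["septic"] - FACTOR_MEANS["healthy"]
    for ct in CELL_TYPES:
        means = np.empty((n, 4))
        wsd = np.empty((n, 4))
        pp_h = spec.population_params[("healthy", ct)]
        pp_s = spec.population_params[("septic", ct)]
        for si, state in enumerate(DISEASE_STATES):
            mask = states == state
            if not mask.any():
                continue
            pp = spec.population_params[(state, ct)]
            centred = factor[mask] - FACTOR_MEANS[state]
            k = int(mask.sum())
            # subject-level idiosyncratic deviations of (size, AR, VEIR) are
            # equicorrelated with rho: stiff, strongly deformed cells also
            # recoil further, which keeps mean VEIR above mean stretch
            rho_s = np.clip(pp.between_feature_corr, 0.0, 1.0)
            shared_s = rng.standard_normal((k, 1))
            e_s = (np.sqrt(rho_s) * shared_s
                   + np.sqrt(1.0 - rho_s) * rng.standard_normal((k, 3)))
            e_int = rng.standard_normal(k)
            for mj, metric in enumerate(("size", "ar", "veir", "log_intensity")):
                lam = loadings[(ct, metric)]
                idio = _idio_sd(pp, metric, lam)
                dev = e_s[:, mj] if mj < 3 else e_int
                means[mask, mj] = pp.mean(metric) + lam * centred + idio * dev
                # cell-level spread grows smoothly with severity (a
                # deterministic function of the factor, so it adds no class
                # information beyond the factor itself)
                sd_h = pp_h.sd_between(metric)
                sd_slope = (pp_s.sd_between(metric) - sd_h) / gap
                sd_at_a = np.maximum(sd_h + sd_slope * factor[mask], 0.15 * sd_h)
                wsd[mask, mj] = pp.within_sd_factor * sd_at_a
            rho[mask] = pp.between_feature_corr
        subj_means[ct] = means
        within_sd[ct] = wsd

    fractions = _subject_type_fractions(spec, states, factor, rng)
    counts = np.stack([rng.multinomial(n_cells, fractions[i]) for i in range(n)])

    frames = []
    for j, ct in enumerate(CELL_TYPES):
        cnt = counts[:, j]
        total = int(cnt.sum())
        if total == 0:
            continue
        idx = np.repeat(np.arange(n), cnt)  # subject index per cell
        means = subj_means[ct][idx]         # (total, 4)
        wsd = within_sd[ct][idx]
        # equicorrelated (size, AR, VEIR) triple via shared-factor construction
        r = np.clip(rho[idx], 0.0, 1.0)[:, None]
        shared = rng.standard_normal((total, 1))
        eps = (np.sqrt(r) * shared
               + np.sqrt(1.0 - r) * rng.standard_normal((total, 3)))
        size = np.clip(means[:, 0] + wsd[:, 0] * eps[:, 0], *SIZE_BOUNDS_UM)
        ar = np.maximum(means[:, 1] + wsd[:, 1] * eps[:, 1], AR_FLOOR)
        log_int = means[:, 3] + wsd[:, 3] * rng.standard_normal(total)

        # VEIR decomposes as stretch amplitude + non-negative recoil margin.
        # Centering the margin on the subject's realized mean stretch keeps
        # the subject's mean VEIR on its drawn target without clamping bias.
        stretch = size * (np.sqrt(ar) - 1.0)
        sums = np.bincount(idx, weights=stretch, minlength=n)
        cnts = np.bincount(idx, minlength=n)
        stretch_bar = (sums / np.maximum(cnts, 1))[idx]
        resid_sd = wsd[:, 2] * np.sqrt(1.0 - r[:, 0])
        margin = means[:, 2] - stretch_bar + resid_sd * eps[:, 2]
        veir = stretch + np.clip(margin, 0.02, 0.94 * size)

        frames.append(pd.DataFrame({
            "subject_id": subjects["subject_id"].to_numpy()[idx],
            "true_type": ct,
            "size": size,
            "intensity": np.exp(log_int),
            "true_ar": ar,
            "true_veir": veir,
        }))

    if not frames:
        return pd.DataFrame(columns=_CELL_COLUMNS)
    cells = pd.concat(frames, ignore_index=True)
    cells = cells.sort_values("subject_id", kind="stable").reset_index(drop=True)
    cells.insert(0, "cell_id", [f"c{k:07d}" for k in range(len(cells))])
    return cells[_CELL_COLUMNS]
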