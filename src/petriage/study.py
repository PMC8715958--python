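"""End-to-end synthetic study: triage -> train -> diagnose -> validate.

This module wires the pipeline together at desk scale: generate a
cohort and its phantom volumes, cross-validate the classifier on the
certain cases, train a final model on all certain cases, diagnose the
uncertain ones, and validate the diagnoses with longitudinal decline and
predicted-probability ordering.  It is the programmatic equivalent of
the study flowchart and the basis of the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import dlnet, longitudinal, perfmetrics
from .synthetic import (
    GeneratorConfig,
    build_atlas,
    generate_cohort,
    generate_longitudinal,
    volumes_for_cohort,
)
from .triage import CERTAIN_HEALTHY, CERTAIN_IMPAIRED, UNCERTAIN


@dataclass
class StudyResult:
    """Everything the synthetic end-to-end study measures."""

    cv_results: list = field(default_factory=list)
    cv_pooled_accuracies: list = field(default_factory=list)
    mean_cv_accuracy: float = float("nan")
    cv_pooled_auc: float = float("nan")
    uncertain: pd.DataFrame | None = None
    slope_by_diagnosis: dict = field(default_factory=dict)
    slope_t: float = float("nan")
    slope_p: float = float("nan")
    mean_prob: dict = field(default_factory=dict)
    diagnosis_agreement: float = float("nan")
    n_certain: int = 0
    n_uncertain: int = 0


def run_study(
    seed: int = 0,
    n_cv_seeds: int = 3,
    n_certain_per_class: int = 100,
    n_uncertain: int = 300,
    cohort_size: int = 1000,
    grid_edge: int = 32,
    max_epochs: int = 40,
    fwhm_mm: float = 8.0,
) -> StudyResult:
    """Run the whole synthetic study once.

    The classifier is five-fold cross-validated on
    ``2 * n_certain_per_class`` certain phantoms (one CV per training
    seed), then refitted on all certain cases and applied to
    ``n_uncertain`` uncertain phantoms; their simulated CDR-Memory
    trajectories validate the diagnoses.  ``max_epochs`` is capped at 40
    — training converges within a handful of epochs at these effect
    sizes.
    """
    cfg = GeneratorConfig(n_samples=cohort_size, seed=seed)
    cfg.volume_params.grid_edge = grid_edge
    cohort = generate_cohort(cfg)

    ci = cohort[cohort.triage_label == CERTAIN_IMPAIRED].head(n_certain_per_class)
    ch = cohort[cohort.triage_label == CERTAIN_HEALTHY].head(n_certain_per_class)
    if len(ci) < n_certain_per_class or len(ch) < n_certain_per_class:
        raise ValueError(
            "cohort too small for the requested number of certain cases"
        )
    unc = cohort[cohort.triage_label == UNCERTAIN].head(n_uncertain)

    atlas = build_atlas(grid_edge, cfg.volume_params.voxel_mm)
    certain = pd.concat([ci, ch], ignore_index=True)
    vols_certain = volumes_for_cohort(certain, atlas, cfg, seed=seed, fwhm_mm=fwhm_mm)
    vols_unc = volumes_for_cohort(unc, atlas, cfg, seed=seed + 1, fwhm_mm=fwhm_mm)
    labels = certain["true_state"].eq("impaired").to_numpy().astype(int)

    spec = dlnet.NetworkSpec(input_edge=grid_edge)
    result = StudyResult(n_certain=len(certain), n_uncertain=len(unc))

    # -- fivefold cross-validation on certain cases, per training seed
    for s in range(n_cv_seeds):
        train_cfg = dlnet.TrainConfig(seed=seed + 101 * (s + 1), max_epochs=max_epochs)
        cv = perfmetrics.crossvalidate(
            vols_certain, labels, certain["id"].to_numpy(), spec, train_cfg,
            k=5, seed=seed + s,
        )
        result.cv_results.append(cv)
        result.cv_pooled_accuracies.append(cv.pooled_metrics["accuracy"] / 100.0)
    result.mean_cv_accuracy = float(np.mean(result.cv_pooled_accuracies))
    result.cv_pooled_auc = float(result.cv_results[0].pooled_auc)

    # -- final model on all certain cases; diagnose the uncertain ones
    model = dlnet.build_network(spec)
    final_cfg = dlnet.TrainConfig(seed=seed + 17, max_epochs=max_epochs)
    dlnet.train(model, vols_certain, labels, final_cfg)
    diag = dlnet.diagnose_uncertain(model, vols_unc, final_cfg.decision_threshold)
    unc = unc.reset_index(drop=True)
    unc["diagnosis"] = diag["diagnosis"]
    unc["diagnosis_prob"] = diag["diagnosis_prob"]
    result.uncertain = unc
    result.diagnosis_agreement = float(
        (unc["diagnosis"] == unc["true_state"]).mean()
    )

    # -- longitudinal validation: fitted CDR slopes by diagnosis
    visits = generate_longitudinal(unc, config=cfg)
    slopes = longitudinal.per_sample_slopes(visits, "cdr_memory")
    diagnosis_of = unc.set_index("id")["diagnosis"]
    imp = slopes[diagnosis_of.reindex(slopes.index) == "impaired"]
    hea = slopes[diagnosis_of.reindex(slopes.index) == "healthy"]
    result.slope_by_diagnosis = {
        "impaired_mean": float(imp.mean()), "healthy_mean": float(hea.mean()),
        "impaired_n": int(len(imp)), "healthy_n": int(len(hea)),
    }
    t, p = stats.ttest_ind(imp, hea, equal_var=False)
    result.slope_t, result.slope_p = float(t), float(p)

    # -- predicted-probability continuum over the four groups
    probs_certain = dlnet.predict(model, vols_certain)
    probs_unc = unc["diagnosis_prob"].to_numpy()
    unc_state = unc["true_state"].to_numpy()
    result.mean_prob = {
        "certain_impaired": float(probs_certain[: len(ci)].mean()),
        "uncertain_impaired": float(probs_unc[unc_state == "impaired"].mean()),
        "uncertain_healthy": float(probs_unc[unc_state == "healthy"].mean()),
        "certain_healthy": float(probs_certain[len(ci):].mean()),
    }
    return result
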