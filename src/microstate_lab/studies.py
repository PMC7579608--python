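"""Canned validation studies for the analysis chain.

Each study simulates data with known ground truth, runs the relevant part
of the pipeline, and returns scalar quality measures:

* :func:`noise_free_identifiability` -- in the noise-free limit the
  clustering, sorting and backfitting must reproduce the generating
  templates and state sequence essentially exactly.
* :func:`parameter_recovery` -- at a realistic SNR the full chain
  (per-participant T-AAHC → group maps → normative sorting → backfit →
  parameters) must recover programmed per-class durations and coverages.
* :func:`interaction_power` / :func:`interaction_null_rate` -- detection
  rate of a programmed group x condition duration effect, and the false-
  positive rate without one, over seeded replicates of the generator's
  ground-truth state sequences.
* :func:`cohort_statistics` -- the full pipeline on the study-like default
  cohort, summarising total GEV and the headline class-C contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .microstates import (
    Segmentation,
    backfit,
    extract_peak_maps,
    group_templates,
    sort_to_normative,
    taahc,
)
from .params import coverage, gev, mean_duration
from .preprocess import average_reference
from .stats import MixedAnova
from .synth import (
    StateDynamics,
    effect_design,
    recovery_design,
    simulate_cohort,
    simulate_recording,
)
from .templates import make_canonical_templates
from .montage import make_montage

__all__ = [
    "noise_free_identifiability",
    "parameter_recovery",
    "interaction_power",
    "interaction_null_rate",
    "cohort_statistics",
]


def noise_free_identifiability(
    seed: int = 0, n_epochs: int = 10, n_channels: int = 32
) -> dict:
    """Clustering/backfit identifiability in the noise-free limit.

    One participant, ``n_epochs`` x 2 s epochs from the canonical
    templates at SNR -> infinity. Returns the weakest template recovery
    correlation, the backfit label accuracy against ground truth, and the
    total GEV of the segmentation.
    """
    montage = make_montage(n_channels)
    canon = make_canonical_templates(montage)
    dyn = StateDynamics((74.0, 69.0, 67.0, 64.0), snr=np.inf, gfp_uv=10.0)
    ep, gt = simulate_recording(canon, dyn, n_epochs=n_epochs, seed=seed)
    ep = average_reference(ep)
    peaks = extract_peak_maps(ep)
    templates, _ = taahc(peaks.maps, peaks.gfp, 4, montage=montage)
    templates = sort_to_normative(templates, canon)
    r = [
        abs(float(np.corrcoef(templates.maps[i], canon.maps[i])[0, 1]))
        for i in range(4)
    ]
    seg = backfit(ep, templates)
    accuracy = float((seg.labels == gt.labels).mean())
    total_gev, _ = gev(ep, seg, templates)
    return {
        "min_template_r": min(r),
        "backfit_accuracy": accuracy,
        "total_gev": float(total_gev),
    }


def parameter_recovery(
    seed: int = 1,
    n_per_group: int = 13,
    n_epochs: int = 10,
    snr: float = 2.0,
) -> dict:
    """Full-chain recovery of programmed durations and coverages at SNR 2.

    Simulates the two-group recovery cohort (distinct per-class durations
    spanning 60--100 ms), runs per-participant clustering, group-map
    building, normative sorting and backfitting, and compares group-mean
    per-class durations and coverages with their programmed values.
    """
    design = recovery_design(n_per_group=n_per_group, n_epochs=n_epochs, snr=snr)
    cohort = simulate_cohort(design, seed=seed)
    canon = cohort.canonical
    programmed = np.asarray(design.dynamics[("TD", "EC")].mean_durations_ms)

    epochs = {}
    individual = {}
    for p in cohort.participants:
        for cond in design.conditions:
            ep = average_reference(p.epochs[cond])
            epochs[(p.participant_id, p.group, cond)] = ep
            peaks = extract_peak_maps(ep)
            individual[(p.participant_id, p.group, cond)] = taahc(
                peaks.maps, peaks.gfp, 4, montage=cohort.montage
            )[0]
    group_maps = {}
    for g, _ in design.groups:
        for cond in design.conditions:
            pool = [
                t for (pid, gg, cc), t in individual.items()
                if gg == g and cc == cond
            ]
            group_maps[(g, cond)] = sort_to_normative(
                group_templates(pool, 4), canon
            )
    durations, coverages = [], []
    for p in cohort.participants:
        for cond in design.conditions:
            seg = backfit(
                epochs[(p.participant_id, p.group, cond)],
                group_maps[(p.group, cond)],
            )
            durations.append(mean_duration(seg))
            coverages.append(coverage(seg))
    recovered = np.nanmean(durations, axis=0)
    rel_err = (recovered - programmed) / programmed
    cov_programmed = programmed / programmed.sum()
    cov_err = np.abs(np.mean(coverages, axis=0) - cov_programmed)
    return {
        "programmed_ms": programmed.tolist(),
        "recovered_ms": recovered.tolist(),
        "max_abs_duration_rel_err": float(np.abs(rel_err).max()),
        "rank_order_preserved": bool(
            np.array_equal(np.argsort(-recovered), np.argsort(-programmed))
        ),
        "max_abs_coverage_err": float(cov_err.max()),
    }


def _class_c_duration_table(cohort) -> pd.DataFrame:
    rows = []
    for p in cohort.participants:
        for cond, gt in p.truth.items():
            seg = Segmentation.from_labels(gt.labels, gt.fs, 4)
            rows.append(
                {
                    "participant": p.participant_id,
                    "group": p.group,
                    "condition": cond,
                    "value": mean_duration(seg)[2],
                }
            )
    return pd.DataFrame(rows)


def _interaction_p(seed: int, effect: float, n_epochs: int) -> float:
    design = effect_design(n_epochs=n_epochs, effect=effect)
    cohort = simulate_cohort(design, seed=seed, signals=False)
    table = _class_c_duration_table(cohort)
    return MixedAnova(table).fit().effects["interaction"]["p"]


def interaction_power(
    seed: int = 0, n_rep: int = 200, effect: float = 0.20,
    n_epochs: int = 5, alpha: float = 0.05,
) -> float:
    """Detection rate of a programmed +20% class-C duration effect.

    The effect lives in one group's EC condition only (n=13/group), so the
    group x condition interaction of the class-C duration carries it;
    replicates use the generator's ground-truth state sequences at a
    reduced epoch count.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=n_rep)
    hits = sum(_interaction_p(int(s), effect, n_epochs) < alpha for s in seeds)
    return hits / n_rep


def interaction_null_rate(
    seed: int = 0, n_rep: int = 1000, n_epochs: int = 5, alpha: float = 0.05
) -> float:
    """False-positive rate of the interaction test with no programmed effect."""
    return interaction_power(
        seed=seed, n_rep=n_rep, effect=0.0, n_epochs=n_epochs, alpha=alpha
    )


def cohort_statistics(seed: int = 0, n_per_group: int = 13, n_epochs: int = 10) -> dict:
    """Full pipeline on the study-like default cohort; headline summaries."""
    from .config import PipelineConfig
    from .pipeline import run_pipeline

    cfg = PipelineConfig.from_dict(
        {"simulate": {"n_per_group": n_per_group}, "n_epochs": n_epochs}
    )
    res = run_pipeline(cfg, seed=seed)
    params = res.params
    total_gev = params[params.parameter == "total_gev"]["value"].mean()
    c_dur = params[
        (params.parameter == "duration")
        & (params["class"] == "C")
        & (params.condition == "EC")
    ]
    by_group = c_dur.groupby("group")["value"].mean()
    anova_c = res.anova[
        (res.anova.parameter == "duration")
        & (res.anova["class"] == "C")
        & (res.anova.effect == "interaction")
    ].iloc[0]
    return {
        "mean_total_gev_pct": float(total_gev),
        "class_c_duration_ec_asd_over_td": float(by_group["ASD"] / by_group["TD"]),
        "class_c_duration_interaction_p": float(anova_c["p"]),
    }
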