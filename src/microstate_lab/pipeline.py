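"""End-to-end pipeline driver.

From a cohort (simulated, or real EDF recordings listed in a manifest) to
microstate parameters and group statistics:

preprocess → per-participant T-AAHC → group template maps per
group x condition → normative A--D sorting → backfitting → parameter
table → mixed ANOVAs, post hocs and covariate correlations.

Group maps are built and applied per group x condition cell (a
``shared_maps`` flag pools everything into one template set for
sensitivity analyses). Participants lacking either condition are dropped
with a logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .microstates import (
    MicrostateModel,
    backfit,
    extract_peak_maps,
    group_templates,
    sort_to_normative,
    taahc,
)
from .montage import Montage
from .params import compute_parameters, parameters_to_tidy
from .preprocess import (
    EpochSet,
    average_reference,
    preprocess_recording,
    select_artifact_free,
)
from .stats import MixedAnova, correlate_covariates, posthoc_bonferroni
from .synth import Cohort, default_design, simulate_cohort
from .templates import TemplateSet, make_canonical_templates, save_templates

logger = logging.getLogger("microstate_lab")

__all__ = ["run_pipeline", "PipelineResult", "write_cohort", "load_manifest"]

PARAMETERS = ("gev", "duration", "frequency", "coverage", "gfp")
#: covariate family for the a-priori correlation analysis
CORRELATION_FAMILY = ("age", "iq", "srs_total", "rbsr_total")


@dataclass(frozen=True)
class PipelineResult:
    """Bundle of every pipeline output table."""

    params: pd.DataFrame = field(repr=False)
    anova: pd.DataFrame = field(repr=False)
    posthoc: pd.DataFrame = field(repr=False)
    correlations: pd.DataFrame | None = field(repr=False)
    group_maps: dict = field(repr=False)
    canonical: TemplateSet = field(repr=False)
    config_hash: str = ""
    seed: int | None = None
    log: tuple = ()
    dropped: tuple = ()


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Serialize a simulated cohort: EDF files, truth sidecars, manifest CSV."""
    from .edf import write_edf
    from .preprocess import EEGRecording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.participants:
        for cond, ep in p.epochs.items():
            if ep is None:
                continue
            fname = f"sub-{p.participant_id}_{cond}.edf"
            flat = ep.data.transpose(1, 0, 2).reshape(ep.n_channels, -1)
            write_edf(EEGRecording(flat, ep.fs, ep.montage), out / fname)
            gt = p.truth[cond]
            (out / f"sub-{p.participant_id}_{cond}_truth.json").write_text(
                json.dumps(
                    {
                        "labels": gt.labels.tolist(),
                        "mean_duration_ms": gt.mean_duration_ms.tolist(),
                        "frequency_hz": gt.frequency_hz.tolist(),
                        "coverage": gt.coverage.tolist(),
                    }
                )
            )
            rows.append(
                {
                    "participant": p.participant_id,
                    "group": p.group,
                    "condition": cond,
                    "file": fname,
                }
            )
    manifest = pd.DataFrame(rows).merge(cohort.covariates, on="participant", how="left")
    manifest = manifest.rename(columns={"group_x": "group"}).drop(
        columns=[c for c in ("group_y",) if c in manifest.columns], errors="ignore"
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv"


def load_manifest(
    manifest_path: str | Path, config: PipelineConfig
) -> tuple[dict, pd.DataFrame, Montage]:
    """Read and preprocess every recording listed in a manifest CSV.

    Returns ``(epochs[(participant, condition)], participant_table, montage)``
    where each entry holds the first ``config.n_epochs`` artifact-free,
    interpolated, average-referenced epochs.
    """
    from .edf import read_edf

    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    required = {"participant", "group", "condition", "file"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    epochs: dict = {}
    montage = None
    for _, row in table.iterrows():
        rec = read_edf(manifest_path.parent / row["file"])
        montage = rec.montage
        ep = preprocess_recording(
            rec,
            target_fs=config.resample.fs,
            lo=config.filter.lo,
            hi=config.filter.hi,
            notch=config.filter.notch,
            epoch_s=config.epoch.s,
            amp_uv=config.artifact.amp_uv,
            flat_uv=config.artifact.flat_uv,
            max_bad_frac=config.artifact.max_bad_frac,
        )
        ep = select_artifact_free(ep, config.n_epochs)
        epochs[(row["participant"], row["condition"])] = ep
    participants = table[
        ["participant", "group"]
        + [c for c in table.columns if c not in ("participant", "group", "condition", "file")]
    ].drop_duplicates("participant")
    return epochs, participants, montage


def _cohort_epochs(cohort: Cohort) -> tuple[dict, pd.DataFrame]:
    """Average-referenced analysis epochs for every simulated participant."""
    epochs = {}
    for p in cohort.participants:
        for cond, ep in p.epochs.items():
            if ep is not None:
                epochs[(p.participant_id, cond)] = average_reference(ep)
    table = cohort.covariates.copy()
    return epochs, table


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    manifest: str | Path | None = None,
) -> PipelineResult:
    """Execute the full analysis; deterministic given config and seed.

    Without a ``manifest``, a cohort is simulated from the study-like
    default design (sample sizes and SNR from ``config.simulate``).
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    stages: list[dict] = []

    def stage(name: str, **info):
        logger.info("stage %s: %s", name, info)
        stages.append({"stage": name, **info})

    if manifest is None:
        design = default_design(
            n_per_group=config.simulate.n_per_group,
            n_epochs=config.n_epochs,
            n_channels=config.simulate.n_channels,
            snr=config.simulate.snr,
        )
        cohort = simulate_cohort(design, seed=seed)
        epochs, participant_table, montage = (
            *_cohort_epochs(cohort),
            cohort.montage,
        )
        stage("simulate", participants=len(cohort.participants), seed=seed)
    else:
        epochs, participant_table, montage = load_manifest(manifest, config)
        stage("load", recordings=len(epochs))
    conditions = sorted({c for _, c in epochs})

    # drop participants missing a condition
    dropped = []
    complete = []
    for _, prow in participant_table.iterrows():
        pid = prow["participant"]
        if all((pid, c) in epochs for c in conditions):
            complete.append(prow)
        else:
            dropped.append(pid)
            logger.warning("participant %s dropped: missing condition", pid)
    participant_table = pd.DataFrame(complete)
    stage("screen", kept=len(participant_table), dropped=dropped)

    canonical = make_canonical_templates(montage)
    k = config.microstates.n_states
    groups_of = dict(zip(participant_table["participant"], participant_table["group"]))

    # per-participant clustering
    individual: dict = {}
    for (pid, cond), ep in epochs.items():
        if pid not in groups_of:
            continue
        peaks = extract_peak_maps(ep, min_sep=config.microstates.min_peak_sep)
        templates, _ = taahc(peaks.maps, peaks.gfp, k, montage=montage)
        individual[(pid, cond)] = templates
    stage("cluster", datasets=len(individual), n_states=k)

    # group template maps per group x condition (or one shared set)
    group_maps: dict = {}
    cells = sorted({(groups_of[pid], cond) for (pid, cond) in individual})
    if config.microstates.shared_maps:
        pooled = group_templates(list(individual.values()), k)
        pooled = sort_to_normative(pooled, canonical)
        for cell in cells:
            group_maps[cell] = pooled
    else:
        for g, cond in cells:
            pool = [
                t
                for (pid, c), t in individual.items()
                if c == cond and groups_of[pid] == g
            ]
            maps = group_templates(pool, k)
            group_maps[(g, cond)] = sort_to_normative(maps, canonical)
    stage("group_templates", cells=[f"{g}/{c}" for g, c in cells])

    # backfit and parameters
    tidy = []
    for (pid, cond), ep in epochs.items():
        if pid not in groups_of:
            continue
        templates = group_maps[(groups_of[pid], cond)]
        seg = backfit(ep, templates)
        pars = compute_parameters(
            ep, seg, templates, include_truncated=config.params.include_truncated
        )
        tidy.append(parameters_to_tidy(pars, pid, groups_of[pid], cond))
    params_df = pd.concat(tidy, ignore_index=True)
    stage("parameters", rows=len(params_df))

    # mixed ANOVAs per parameter x class
    anova_rows = []
    posthoc_frames = []
    class_labels = list(canonical.labels)
    targets = [(p, lab) for p in PARAMETERS for lab in class_labels]
    targets.append(("total_gev", "all"))
    for pname, lab in targets:
        sub = params_df[
            (params_df["parameter"] == pname) & (params_df["class"] == lab)
        ].dropna(subset=["value"])
        try:
            res = MixedAnova(sub).fit(alpha=config.stats.alpha)
        except ValueError as exc:
            logger.warning("ANOVA skipped for %s/%s: %s", pname, lab, exc)
            continue
        for effect, e in res.effects.items():
            anova_rows.append({"parameter": pname, "class": lab, "effect": effect, **e})
        if res.effects["interaction"]["p"] < config.stats.alpha:
            try:
                ph = posthoc_bonferroni(
                    sub,
                    alpha=config.stats.posthoc_alpha,
                    equal_var=config.stats.equal_var,
                )
            except ValueError as exc:
                logger.warning("post hoc skipped for %s/%s: %s", pname, lab, exc)
                continue
            ph.insert(0, "class", lab)
            ph.insert(0, "parameter", pname)
            posthoc_frames.append(ph)
    anova_df = pd.DataFrame(anova_rows)
    posthoc_df = (
        pd.concat(posthoc_frames, ignore_index=True)
        if posthoc_frames
        else pd.DataFrame()
    )
    stage("anova", tests=len(anova_df) // 3, posthoc=len(posthoc_df))

    # a-priori covariate correlations: class-C frequency, EC, ASD-like group
    correlations = None
    cov_names = [c for c in CORRELATION_FAMILY if c in participant_table.columns]
    if cov_names and "ASD" in set(participant_table["group"]) and "EC" in conditions:
        asd = participant_table[participant_table["group"] == "ASD"].set_index(
            "participant"
        )
        y = (
            params_df[
                (params_df["group"] == "ASD")
                & (params_df["condition"] == "EC")
                & (params_df["parameter"] == "frequency")
                & (params_df["class"] == "C")
            ]
            .set_index("participant")["value"]
            .reindex(asd.index)
        )
        if len(asd) >= 3:
            correlations = correlate_covariates(asd, y, cov_names)
            stage("correlations", family=cov_names)
        else:
            logger.warning("correlation family skipped: fewer than 3 ASD participants")

    result = PipelineResult(
        params=params_df,
        anova=anova_df,
        posthoc=posthoc_df,
        correlations=correlations,
        group_maps=group_maps,
        canonical=canonical,
        config_hash=config.hash(),
        seed=seed,
        log=tuple(stages),
        dropped=tuple(dropped),
    )
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir))
    return result


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, seed) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def _write_outputs(
    result: PipelineResult, config: PipelineConfig, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(result.params, out / "params.csv", result.config_hash, result.seed)
    _write_csv(result.anova, out / "anova.csv", result.config_hash, result.seed)
    _write_csv(result.posthoc, out / "posthoc.csv", result.config_hash, result.seed)
    if result.correlations is not None:
        _write_csv(
            result.correlations, out / "correlations.csv",
            result.config_hash, result.seed,
        )
    for (g, c), templates in result.group_maps.items():
        save_templates(templates, out / f"templates_{g}_{c}.csv")
    (out / "run.json").write_text(
        json.dumps(
            {
                "config_hash": result.config_hash,
                "seed": result.seed,
                "config": config.to_dict(),
                "stages": list(result.log),
                "dropped": list(result.dropped),
            },
            indent=2,
        )
    )
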