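"""Microstate parameters computed from a segmentation.

Per class *k*: global explained variance (GEV), mean duration (ms),
frequency (run onsets per second, Hz), coverage (time share) and mean GFP
(µV), plus the class-to-class transition matrix.

Run statistics (duration, frequency) by default exclude runs touching an
epoch boundary, whose true length is unobserved; coverage is a pure time
share and always uses every labeled sample. Both conventions are exposed
via ``include_truncated``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .microstates import Segmentation, _centered_unit
from .preprocess import EpochSet
from .templates import TemplateSet

__all__ = [
    "MicrostateParameters",
    "gev",
    "mean_duration",
    "frequency",
    "coverage",
    "gfp_per_state",
    "transitions",
    "compute_parameters",
    "parameters_to_tidy",
]


@dataclass(frozen=True)
class MicrostateParameters:
    """Per-class microstate statistics for one dataset."""

    labels: tuple[str, ...]
    gev: np.ndarray = field(repr=False)  # fraction per class
    total_gev: float = 0.0
    duration_ms: np.ndarray = field(default=None, repr=False)
    frequency_hz: np.ndarray = field(default=None, repr=False)
    coverage: np.ndarray = field(default=None, repr=False)
    gfp_uv: np.ndarray = field(default=None, repr=False)
    transition: np.ndarray = field(default=None, repr=False)  # (K, K), zero diag
    transition_counts: np.ndarray = field(default=None, repr=False)
    transition_chi2: float = np.nan
    transition_chi2_df: int = 0
    transition_chi2_p: float = np.nan
    n_segments: np.ndarray = field(default=None, repr=False)
    analyzed_s: float = 0.0


def _runs(labels: np.ndarray):
    """Yield (class, length, truncated) for every within-epoch run."""
    for row in np.atleast_2d(labels):
        change = np.flatnonzero(np.diff(row)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(row)]])
        for i, (s, e) in enumerate(zip(starts, ends)):
            truncated = s == 0 or e == len(row)
            yield int(row[s]), int(e - s), truncated


def mean_duration(seg: Segmentation, include_truncated: bool = False) -> np.ndarray:
    """Per-class mean stable-run duration in ms (NaN when no run qualifies)."""
    sums = np.zeros(seg.n_states)
    counts = np.zeros(seg.n_states)
    for c, length, trunc in _runs(seg.labels):
        if trunc and not include_truncated:
            continue
        sums[c] += length
        counts[c] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out * 1000.0 / seg.fs


def frequency(seg: Segmentation, include_truncated: bool = False) -> np.ndarray:
    """Per-class run onsets per analyzed second (Hz)."""
    counts = np.zeros(seg.n_states)
    for c, _, trunc in _runs(seg.labels):
        if trunc and not include_truncated:
            continue
        counts[c] += 1
    return counts / seg.analyzed_seconds


def coverage(seg: Segmentation) -> np.ndarray:
    """Per-class fraction of labeled time; sums to 1 exactly."""
    counts = np.bincount(seg.labels.ravel(), minlength=seg.n_states)
    return counts / seg.n_points


def gfp_per_state(seg: Segmentation) -> np.ndarray:
    """Mean GFP over the samples assigned to each class (NaN if absent)."""
    out = np.full(seg.n_states, np.nan)
    flat_labels = seg.labels.ravel()
    flat_gfp = seg.gfp.ravel()
    for k in range(seg.n_states):
        mask = flat_labels == k
        if mask.any():
            out[k] = flat_gfp[mask].mean()
    return out


def transitions(seg: Segmentation):
    """Within-epoch transition matrix and its independence chi-square.

    Returns ``(P, counts, chi2, df, p)``. ``P[i, j]`` is the probability of
    switching to *j* given a switch out of *i* (zero diagonal; all-zero row
    for a class that never transitions). The chi-square compares observed
    transition counts with the coverage-implied independent null
    ``p_ij = c_j / (1 - c_i)``.
    """
    k = seg.n_states
    counts = np.zeros((k, k))
    for row in np.atleast_2d(seg.labels):
        a, b = row[:-1], row[1:]
        mask = a != b
        np.add.at(counts, (a[mask], b[mask]), 1.0)
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(row_sums[:, None] > 0, counts / row_sums[:, None], 0.0)
    total = counts.sum()
    if total == 0:
        return p, counts, np.nan, 0, np.nan
    cov = coverage(seg)
    chi2 = 0.0
    df = 0
    for i in range(k):
        if row_sums[i] == 0 or cov[i] >= 1.0:
            continue
        null = cov / (1.0 - cov[i])
        for j in range(k):
            if i == j:
                continue
            expected = row_sums[i] * null[j]
            if expected > 0:
                chi2 += (counts[i, j] - expected) ** 2 / expected
                df += 1
    df = max(df - k, 1)  # row totals are fixed
    return p, counts, float(chi2), df, float(sstats.chi2.sf(chi2, df))


def gev(
    ep: EpochSet, seg: Segmentation, templates: TemplateSet
) -> tuple[float, np.ndarray]:
    """Global explained variance of a labeling, total and per class.

    ``GEV = sum_t (GFP_t * r(v_t, T_L(t)))**2 / sum_t GFP_t**2`` over all
    labeled samples; per-class terms restrict the numerator to the samples
    of that class, so they sum to the total.
    """
    t_unit, _ = _centered_unit(templates.maps)
    n_ep, n_ch, n_s = ep.data.shape
    frames = ep.data.transpose(0, 2, 1).reshape(-1, n_ch)
    z = frames - frames.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    labels = seg.labels.ravel()
    r = np.zeros(len(labels))
    ok = norms > 0
    r[ok] = np.einsum(
        "ij,ij->i", z[ok] / norms[ok, None], t_unit[labels[ok]]
    )
    g = seg.gfp.ravel()
    denom = float(np.sum(g**2))
    if denom == 0:
        raise ValueError("GEV undefined: all-zero GFP")
    terms = (g * r) ** 2
    per_class = np.array(
        [terms[labels == k].sum() for k in range(templates.n_states)]
    ) / denom
    return float(per_class.sum()), per_class


def compute_parameters(
    ep: EpochSet | None,
    seg: Segmentation,
    templates: TemplateSet | None = None,
    include_truncated: bool = False,
) -> MicrostateParameters:
    """All per-class microstate parameters of a segmented dataset.

    ``ep`` and ``templates`` are needed only for GEV; pass ``None`` to
    parameterize a bare label sequence (e.g. simulation ground truth).
    """
    if templates is not None and ep is not None:
        total_gev, per_gev = gev(ep, seg, templates)
        labels = templates.labels
    else:
        total_gev, per_gev = np.nan, np.full(seg.n_states, np.nan)
        labels = tuple(f"C{i + 1}" for i in range(seg.n_states))
    p, counts, chi2, df, chi2_p = transitions(seg)
    n_seg = np.zeros(seg.n_states)
    for c, _, trunc in _runs(seg.labels):
        if trunc and not include_truncated:
            continue
        n_seg[c] += 1
    return MicrostateParameters(
        labels=labels,
        gev=per_gev,
        total_gev=total_gev,
        duration_ms=mean_duration(seg, include_truncated),
        frequency_hz=frequency(seg, include_truncated),
        coverage=coverage(seg),
        gfp_uv=gfp_per_state(seg),
        transition=p,
        transition_counts=counts,
        transition_chi2=chi2,
        transition_chi2_df=df,
        transition_chi2_p=chi2_p,
        n_segments=n_seg,
        analyzed_s=seg.analyzed_seconds,
    )


def parameters_to_tidy(
    pars: MicrostateParameters, participant: str, group: str, condition: str
) -> pd.DataFrame:
    """Tidy long-format rows: participant, group, condition, class, parameter, value.

    Units follow the reporting convention: duration ms, frequency Hz,
    coverage %, GFP µV, GEV %.
    """
    rows = []
    for i, lab in enumerate(pars.labels):
        for pname, value in (
            ("gev", 100.0 * pars.gev[i]),
            ("duration", pars.duration_ms[i]),
            ("frequency", pars.frequency_hz[i]),
            ("coverage", 100.0 * pars.coverage[i]),
            ("gfp", pars.gfp_uv[i]),
        ):
            rows.append(
                {
                    "participant": participant,
                    "group": group,
                    "condition": condition,
                    "class": lab,
                    "parameter": pname,
                    "value": value,
                }
            )
    rows.append(
        {
            "participant": participant,
            "group": group,
            "condition": condition,
            "class": "all",
            "parameter": "total_gev",
            "value": 100.0 * pars.total_gev,
        }
    )
    return pd.DataFrame(rows)
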