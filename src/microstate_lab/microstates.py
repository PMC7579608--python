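"""Polarity-invariant microstate extraction.

Pipeline: global field power (GFP) → topographic maps at GFP peaks →
Topographic Atomize & Agglomerate Hierarchical Clustering (T-AAHC) →
sorting of the cluster maps against a normative A--D reference →
backfitting of every time point to its best-correlated template.

All topographic similarity is the absolute Pearson correlation across
channels: for spontaneous EEG a map and its polarity reversal express the
same microstate.

The :class:`MicrostateModel` / :class:`MicrostateResults` pair wraps the
functional layer in a fit/results interface: construct the model from an
epoch set, call ``fit()``, and read templates, segmentation and per-class
parameters off the results object.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochSet
from .templates import TemplateSet

__all__ = [
    "gfp",
    "find_gfp_peaks",
    "spatial_correlation",
    "extract_peak_maps",
    "taahc",
    "group_templates",
    "sort_to_normative",
    "backfit",
    "PeakMaps",
    "Segmentation",
    "MicrostateModel",
    "MicrostateResults",
]


def gfp(x) -> np.ndarray:
    """Global field power: population SD of the potential across channels.

    Accepts an :class:`EpochSet` (returns per-epoch curves, shape
    ``(n_epochs, n_samples)``), a channels x samples array (returns one
    curve) or a single frame (returns a scalar). GFP is invariant to adding
    a constant to all channels and scales linearly with the data.
    """
    if isinstance(x, EpochSet):
        if x.n_channels < 2:
            raise ValueError("GFP needs at least 2 channels")
        return x.data.std(axis=1)
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        if arr.size < 2:
            raise ValueError("GFP needs at least 2 channels")
        return arr.std()
    if arr.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return arr.std(axis=0)


def find_gfp_peaks(values: np.ndarray, min_sep: int = 1) -> np.ndarray:
    """Indices of strict local maxima of a GFP curve.

    Edges are excluded; a flat plateau higher than both sides counts once,
    at its first sample. With ``min_sep > 1``, peaks closer than ``min_sep``
    samples are thinned keeping the larger (ties: the earlier).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        return np.empty(0, dtype=int)
    peaks = []
    i = 1
    n = v.size
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j + 1 < n and v[j + 1] < v[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    peaks = np.asarray(peaks, dtype=int)
    if min_sep > 1 and peaks.size > 1:
        order = np.argsort(-v[peaks], kind="stable")  # by height, earlier wins ties
        kept: list[int] = []
        for p in peaks[order]:
            if all(abs(p - q) >= min_sep for q in kept):
                kept.append(int(p))
        peaks = np.asarray(sorted(kept), dtype=int)
    return peaks


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two maps across channels (signed).

    Clustering and backfitting use ``abs()`` of this value; the sign is kept
    here so polarity alignment remains possible.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.size < 2:
        raise ValueError("maps must have equal length >= 2")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise ValueError("correlation undefined for a constant map")
    return float(np.clip(uc @ vc / (nu * nv), -1.0, 1.0))


@dataclass(frozen=True)
class PeakMaps:
    """Average-referenced maps at GFP peaks, with their GFP values."""

    maps: np.ndarray = field(repr=False)  # (n_maps, n_channels)
    gfp: np.ndarray = field(repr=False)  # (n_maps,)
    peak_indices: tuple[tuple[int, ...], ...] = None  # per epoch
    epoch_ids: np.ndarray = field(default=None, repr=False)

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]


def extract_peak_maps(ep: EpochSet, min_sep: int = 1) -> PeakMaps:
    """Collect the topographies at the GFP peaks of every epoch."""
    curves = gfp(ep)
    maps, gfps, idx, eids = [], [], [], []
    for e in range(ep.n_epochs):
        p = find_gfp_peaks(curves[e], min_sep=min_sep)
        idx.append(tuple(int(i) for i in p))
        for i in p:
            frame = ep.data[e, :, i]
            maps.append(frame - frame.mean())
            gfps.append(curves[e, i])
            eids.append(e)
    if not maps:
        return PeakMaps(
            np.empty((0, ep.n_channels)), np.empty(0), tuple(idx), np.empty(0, int)
        )
    return PeakMaps(
        np.asarray(maps), np.asarray(gfps), tuple(idx), np.asarray(eids, dtype=int)
    )


# ---------------------------------------------------------------------------
# T-AAHC


def _centered_unit(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms == 0):
        raise ValueError("constant map cannot be clustered")
    return z / norms[:, None], norms


def _principal_map(z_unit: np.ndarray) -> np.ndarray:
    """Polarity-invariant centroid: first right singular vector of the maps.

    Input rows are centered unit maps, so the result is centered too; it is
    re-normalized and its sign fixed deterministically (largest-magnitude
    channel positive).
    """
    if z_unit.shape[0] == 1:
        c = z_unit[0].copy()
    else:
        _, _, vt = np.linalg.svd(z_unit, full_matrices=False)
        c = vt[0]
    c = c - c.mean()
    c /= np.linalg.norm(c)
    if c[np.argmax(np.abs(c))] < 0:
        c = -c
    return c


def taahc(
    maps: np.ndarray,
    gfp_values: np.ndarray,
    n_states: int,
    montage=None,
    labels: tuple[str, ...] | None = None,
) -> tuple[TemplateSet | np.ndarray, np.ndarray]:
    """Topographic atomize-and-agglomerate hierarchical clustering.

    Starts from singleton clusters and repeatedly *atomizes* the cluster
    contributing least global explained variance
    (``sum((GFP_t * r(map_t, centroid))**2)`` over its members), reassigning
    each freed map to the surviving cluster whose centroid it correlates
    with most strongly in absolute value, until ``n_states`` clusters
    remain. Centroids are first principal eigenvectors of their member
    maps (polarity-invariant), zero-mean and unit-norm.

    Returns ``(templates, assignment)``: a :class:`TemplateSet` when a
    montage is given (else the raw centroid array) and the per-map cluster
    index (0..K-1, ordered by descending GEV contribution).
    """
    maps = np.asarray(maps, dtype=float)
    gfp_values = np.asarray(gfp_values, dtype=float)
    n_maps = maps.shape[0]
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if n_maps < n_states:
        raise ValueError(f"need at least {n_states} maps, got {n_maps}")
    z_unit, _ = _centered_unit(maps)

    members: dict[int, list[int]] = {i: [i] for i in range(n_maps)}
    centroids: dict[int, np.ndarray] = {i: z_unit[i].copy() for i in range(n_maps)}

    def contribution(cid: int) -> float:
        m = members[cid]
        r = z_unit[m] @ centroids[cid]
        return float(np.sum((gfp_values[m] * r) ** 2))

    contrib = {cid: contribution(cid) for cid in members}

    while len(members) > n_states:
        # atomize the lowest-contribution cluster; ties: fewer members, lower id
        worst = min(
            members, key=lambda c: (contrib[c], len(members[c]), c)
        )
        freed = members.pop(worst)
        centroids.pop(worst)
        contrib.pop(worst)
        cids = sorted(members)
        cmat = np.stack([centroids[c] for c in cids])  # (n_clusters, n_ch)
        sims = np.abs(z_unit[freed] @ cmat.T)  # (n_freed, n_clusters)
        touched = set()
        for row, m in zip(sims, freed):
            target = cids[int(np.argmax(row))]
            members[target].append(m)
            touched.add(target)
        for cid in touched:
            members[cid].sort()
            centroids[cid] = _principal_map(z_unit[members[cid]])
            contrib[cid] = contribution(cid)

    order = sorted(members, key=lambda c: -contrib[c])
    assignment = np.empty(n_maps, dtype=int)
    out = np.stack([centroids[c] for c in order])
    for slot, cid in enumerate(order):
        assignment[members[cid]] = slot
    if labels is None:
        labels = tuple(f"C{i + 1}" for i in range(n_states))
    if montage is not None:
        return TemplateSet(labels, out, montage), assignment
    return out, assignment


def group_templates(
    individual: list[TemplateSet], n_states: int | None = None
) -> TemplateSet:
    """Second-level T-AAHC over pooled individual template maps.

    Each individual map enters unit-normalized with equal weight, so every
    participant contributes equally regardless of amplitude.
    """
    if not individual:
        raise ValueError("empty template pool")
    n_states = n_states or individual[0].n_states
    montage = individual[0].montage
    pool = np.vstack([t.normalized().maps for t in individual])
    templates, _ = taahc(pool, np.ones(pool.shape[0]), n_states, montage=montage)
    return templates


def sort_to_normative(
    templates: TemplateSet, normative: TemplateSet
) -> TemplateSet:
    """Relabel templates against a normative set by exhaustive matching.

    Evaluates all K! label permutations, keeps the one maximizing the total
    absolute spatial correlation, and flips each map's polarity so its
    correlation with the matched normative map is non-negative.
    """
    if templates.montage.channel_ids != normative.montage.channel_ids:
        raise ValueError("montage mismatch between templates and normative set")
    if templates.n_states != normative.n_states:
        raise ValueError("template sets must have equal K")
    k = templates.n_states
    r = np.array(
        [
            [spatial_correlation(t, n) for n in normative.maps]
            for t in templates.maps
        ]
    )
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(abs(r[perm[j], j]) for j in range(k))
        if score > best_score + 1e-12:
            best_score, best_perm = score, perm
    maps = templates.maps[list(best_perm)].copy()
    for j in range(k):
        if r[best_perm[j], j] < 0:
            maps[j] = -maps[j]
    return TemplateSet(normative.labels, maps, templates.montage)


# ---------------------------------------------------------------------------
# backfitting


@dataclass(frozen=True)
class Segmentation:
    """Per-time-point microstate labels with correlation and GFP traces."""

    labels: np.ndarray = field(repr=False)  # (n_epochs, n_samples) int
    best_corr: np.ndarray = field(repr=False)
    gfp: np.ndarray = field(repr=False)
    fs: float
    n_states: int
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        if not (self.labels.shape == self.best_corr.shape == self.gfp.shape):
            raise ValueError("labels, best_corr and gfp must be congruent")
        if self.labels.min() < 0 or self.labels.max() >= self.n_states:
            raise ValueError("labels out of range")

    @classmethod
    def from_labels(
        cls, labels: np.ndarray, fs: float, n_states: int | None = None
    ) -> "Segmentation":
        """Wrap a known (e.g. ground-truth) label array as a Segmentation."""
        labels = np.asarray(labels, dtype=int)
        if n_states is None:
            n_states = int(labels.max()) + 1
        ones = np.ones_like(labels, dtype=float)
        return cls(labels, ones, ones, fs, n_states)

    @property
    def n_points(self) -> int:
        return self.labels.size

    @property
    def analyzed_seconds(self) -> float:
        return self.labels.size / self.fs


def backfit(ep: EpochSet, templates: TemplateSet) -> Segmentation:
    """Label every time point with its best-|r| template (no smoothing).

    All samples are labeled, not only GFP peaks; ties break to the lowest
    class index. Constant (zero-variance) frames inherit the previous
    sample's label (class 0 at an epoch start) and are counted in
    ``n_degenerate``.
    """
    if templates.n_states < 2:
        raise ValueError("need at least 2 templates")
    t_unit, _ = _centered_unit(templates.maps)
    n_ep, n_ch, n_s = ep.data.shape
    frames = ep.data.transpose(0, 2, 1).reshape(-1, n_ch)
    z = frames - frames.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    degenerate = norms == 0
    safe = np.where(degenerate, 1.0, norms)
    corr = np.abs((z / safe[:, None]) @ t_unit.T)
    labels = corr.argmax(axis=1)
    best = corr[np.arange(corr.shape[0]), labels]
    labels = labels.reshape(n_ep, n_s)
    best = best.reshape(n_ep, n_s)
    deg = degenerate.reshape(n_ep, n_s)
    if degenerate.any():
        for e, s in zip(*np.nonzero(deg)):
            labels[e, s] = labels[e, s - 1] if s > 0 else 0
            best[e, s] = 0.0
    return Segmentation(
        labels, best, gfp(ep), ep.fs, templates.n_states,
        n_degenerate=int(degenerate.sum()),
    )


# ---------------------------------------------------------------------------
# model / results interface


class MicrostateModel:
    """Microstate analysis of one epoched dataset.

    Parameters
    ----------
    epochs
        Average-referenced epoched EEG.
    n_states
        Number of microstate classes (4 canonical classes by default).
    normative
        Optional reference :class:`TemplateSet`; when given, the fitted
        templates are sorted and polarity-aligned against it so class
        labels are comparable across datasets.
    min_peak_sep
        Minimum GFP-peak separation in samples.
    """

    def __init__(
        self,
        epochs: EpochSet,
        n_states: int = 4,
        normative: TemplateSet | None = None,
        min_peak_sep: int = 1,
    ) -> None:
        self.epochs = epochs
        self.n_states = n_states
        self.normative = normative
        self.min_peak_sep = min_peak_sep

    def fit(self, templates: TemplateSet | None = None) -> "MicrostateResults":
        """Cluster (unless ``templates`` is given), backfit and parameterize."""
        from . import params as _params

        peaks = extract_peak_maps(self.epochs, min_sep=self.min_peak_sep)
        if templates is None:
            templates, _ = taahc(
                peaks.maps, peaks.gfp, self.n_states, montage=self.epochs.montage
            )
            if self.normative is not None:
                templates = sort_to_normative(templates, self.normative)
        seg = backfit(self.epochs, templates)
        pars = _params.compute_parameters(self.epochs, seg, templates)
        return MicrostateResults(self, templates, seg, pars, peaks)


@dataclass(frozen=True)
class MicrostateResults:
    """Fitted templates, segmentation and microstate parameters."""

    model: MicrostateModel = field(repr=False)
    templates: TemplateSet = field(repr=False)
    segmentation: Segmentation = field(repr=False)
    parameters: "object" = field(repr=False)  # params.MicrostateParameters
    peak_maps: PeakMaps = field(repr=False)

    def summary(self) -> str:
        """Plain-text per-class parameter table."""
        p = self.parameters
        lines = [
            "Microstate analysis"
            f"  (K={self.templates.n_states}, "
            f"{self.segmentation.analyzed_seconds:.1f} s analyzed, "
            f"{self.peak_maps.n_maps} GFP peaks)",
            f"Total GEV: {100 * p.total_gev:.2f} %",
            "",
            f"{'class':>5} {'GEV %':>8} {'duration ms':>12} "
            f"{'frequency Hz':>13} {'coverage %':>11} {'GFP µV':>8}",
        ]
        for i, lab in enumerate(self.templates.labels):
            lines.append(
                f"{lab:>5} {100 * p.gev[i]:>8.2f} {p.duration_ms[i]:>12.1f} "
                f"{p.frequency_hz[i]:>13.2f} {100 * p.coverage[i]:>11.2f} "
                f"{p.gfp_uv[i]:>8.2f}"
            )
        return "\n".join(lines)

    def plot_templates(self, ax=None):
        """Quick-look topographic scatter of the fitted template maps."""
        import matplotlib.pyplot as plt

        k = self.templates.n_states
        if ax is None:
            _, ax = plt.subplots(1, k, figsize=(2.2 * k, 2.4))
        pos = self.templates.montage.positions
        for i, a in enumerate(np.atleast_1d(ax)):
            m = self.templates.maps[i]
            a.scatter(pos[:, 0], pos[:, 1], c=m, cmap="RdBu_r", s=40)
            a.set_title(self.templates.labels[i])
            a.set_aspect("equal")
            a.axis("off")
        return ax
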