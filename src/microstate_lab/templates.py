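"""Microstate template sets and the canonical A--D map archetypes.

A template map is an average-referenced scalp topography (one value per
montage channel). The four canonical resting-state classes are modelled
analytically from their textbook orientations:

* **A** -- right-frontal / left-occipital diagonal axis
* **B** -- left-frontal / right-occipital diagonal axis
* **C** -- anterior--posterior axis
* **D** -- fronto-central maximum

These serve both as generators for synthetic EEG and as the normative
reference set for sorting cluster output into the A--D order. They are a
synthetic analytic stand-in for published normative maps, which are not
redistributable data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage

CANONICAL_LABELS = ("A", "B", "C", "D")

#: polar angle (rad) of the fronto-central bump centre of map D
_D_CENTER_POLAR = 0.35
#: angular width (rad) of the map-D Gaussian bump
_D_SIGMA = 0.5
#: z-level at which map C's anterior-posterior gradient reverses
_C_RIM_Z = 0.3


@dataclass(frozen=True)
class TemplateSet:
    """K labeled average-referenced topographic maps over a montage.

    Invariants: every map has (numerically) zero channel mean and nonzero
    norm; ``len(labels) == maps.shape[0]``.
    """

    labels: tuple[str, ...]
    maps: np.ndarray = field(repr=False)  # (K, n_channels)
    montage: Montage = field(repr=False)

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        object.__setattr__(self, "maps", maps)
        object.__setattr__(self, "labels", tuple(self.labels))
        if maps.ndim != 2:
            raise ValueError("maps must be 2-D (K, n_channels)")
        if maps.shape[0] != len(self.labels):
            raise ValueError("label count must equal map count")
        if maps.shape[1] != self.montage.n_channels:
            raise ValueError("map length must equal montage channel count")
        if np.max(np.abs(maps.mean(axis=1))) > 1e-9:
            raise ValueError("template maps must be average-referenced")
        norms = np.linalg.norm(maps, axis=1)
        if np.any(norms <= 0):
            raise ValueError("template maps must have nonzero norm")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def normalized(self) -> "TemplateSet":
        """Return a copy with every map scaled to unit norm."""
        norms = np.linalg.norm(self.maps, axis=1, keepdims=True)
        return TemplateSet(self.labels, self.maps / norms, self.montage)


def _center_normalize(m: np.ndarray) -> np.ndarray:
    m = m - m.mean()
    n = np.linalg.norm(m)
    if n == 0:
        raise ValueError("degenerate (constant) template map")
    return m / n


def save_templates(ts: TemplateSet, path) -> None:
    """Write maps as channels x K CSV plus a JSON metadata sidecar."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    pd.DataFrame(
        ts.maps.T, index=list(ts.montage.channel_ids), columns=list(ts.labels)
    ).to_csv(path, index_label="channel")
    meta = {
        "labels": list(ts.labels),
        "channel_ids": list(ts.montage.channel_ids),
        "positions": ts.montage.positions.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_templates(path) -> TemplateSet:
    """Read a template set written by :func:`save_templates`."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, index_col="channel")
    meta = json.loads(path.with_suffix(".json").read_text())
    montage = Montage(tuple(meta["channel_ids"]), np.asarray(meta["positions"]))
    return TemplateSet(tuple(df.columns), df.to_numpy().T, montage)


def make_canonical_templates(montage: Montage) -> TemplateSet:
    """Analytic canonical A--D template maps on the given montage.

    The maps realise the canonical orientations as smooth functions of the
    electrode coordinates (x right, y anterior): A is the ``x + y`` diagonal,
    B the ``-x + y`` diagonal, C an anterior--posterior gradient over the
    superior scalp that reverses polarity at the inferior rim
    (``y * (z - 0.3)``), and D a radially symmetric Gaussian bump centred
    slightly anterior of the vertex. C is built as a second-order pattern
    rather than a pure ``y`` dipole: a pure dipole would lie exactly in the
    span of A and B (A + B is proportional to y), leaving the four classes
    linearly degenerate; the rim reversal also matches the broad,
    non-dipolar structure of empirical class-C maps. The set is mutually
    quasi-orthogonal (all pairwise |r| < 0.35 on the default montage). Each
    map is centred to zero mean and scaled to unit norm.
    """
    x, y, z = montage.positions.T
    center = np.array(
        [0.0, np.sin(_D_CENTER_POLAR), np.cos(_D_CENTER_POLAR)]
    )
    ang = np.arccos(np.clip(montage.positions @ center, -1.0, 1.0))
    maps = np.stack(
        [
            _center_normalize(x + y),
            _center_normalize(-x + y),
            _center_normalize(y * (z - _C_RIM_Z)),
            _center_normalize(np.exp(-(ang**2) / (2.0 * _D_SIGMA**2))),
        ]
    )
    return TemplateSet(CANONICAL_LABELS, maps, montage)
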