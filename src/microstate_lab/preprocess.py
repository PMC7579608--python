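"""Signal-processing pipeline for resting-state EEG.

Stages, in the order they are applied to a continuous recording:

1. down-sample to the analysis rate (anti-aliased),
2. zero-phase band-pass (2--20 Hz default) plus 60 Hz notch,
3. segmentation into fixed-length epochs with per-channel baseline removal,
4. artifact flagging by an explicit amplitude / flatness rule,
5. spherical-spline interpolation of bad channels (Perrin),
6. average re-referencing.

The artifact rule replaces proprietary detection software with a
deterministic, documented criterion: an epoch is rejected when too many of
its channels exceed a peak-to-peak amplitude threshold; individual channels
are marked bad (and interpolated) when they exceed it alone or are flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.special import eval_legendre

from .montage import Montage

__all__ = [
    "EEGRecording",
    "EpochSet",
    "resample",
    "bandpass_notch",
    "epoch",
    "flag_artifacts",
    "interpolate_channels",
    "average_reference",
    "preprocess_recording",
    "select_artifact_free",
]


@dataclass(frozen=True)
class EEGRecording:
    """Continuous multichannel EEG: ``data`` is (n_channels, n_samples) in µV."""

    data: np.ndarray = field(repr=False)
    fs: float
    montage: Montage = field(repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (channels, samples)")
        if data.shape[0] != self.montage.n_channels:
            raise ValueError("channel count must match montage")
        if not np.all(np.isfinite(data)):
            raise ValueError("data must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class EpochSet:
    """Epoched EEG: ``data`` is (n_epochs, n_channels, n_samples) in µV.

    ``artifact_flags[i]`` marks epoch *i* as rejected; ``bad_channels[i]``
    lists channel indices to interpolate within epoch *i*.
    """

    data: np.ndarray = field(repr=False)
    fs: float
    epoch_s: float
    montage: Montage = field(repr=False)
    artifact_flags: np.ndarray = field(default=None, repr=False)
    bad_channels: tuple[tuple[int, ...], ...] = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError("data must be 3-D (epochs, channels, samples)")
        if data.shape[1] != self.montage.n_channels:
            raise ValueError("channel count must match montage")
        if data.shape[2] != round(self.fs * self.epoch_s):
            raise ValueError("samples per epoch must equal round(fs * epoch_s)")
        flags = self.artifact_flags
        if flags is None:
            flags = np.zeros(data.shape[0], dtype=bool)
        flags = np.asarray(flags, dtype=bool)
        if flags.shape != (data.shape[0],):
            raise ValueError("artifact_flags length must equal epoch count")
        object.__setattr__(self, "artifact_flags", flags)
        bad = self.bad_channels
        if bad is None:
            bad = tuple(() for _ in range(data.shape[0]))
        bad = tuple(tuple(int(c) for c in b) for b in bad)
        if len(bad) != data.shape[0]:
            raise ValueError("bad_channels length must equal epoch count")
        object.__setattr__(self, "bad_channels", bad)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# stage 1: resampling


def resample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Down-sample to ``target_fs`` with an explicit anti-alias low-pass.

    A zero-phase FIR (Kaiser window) low-pass at 0.4 * target_fs precedes
    polyphase resampling, guaranteeing the stop band above the new Nyquist
    regardless of the rational up/down factorisation. Upsampling is refused.
    """
    if target_fs > rec.fs:
        raise ValueError("target_fs must not exceed the current rate")
    if target_fs == rec.fs:
        frac = Fraction(1, 1)
    else:
        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    cutoff = 0.4 * target_fs
    data = rec.data
    if cutoff < rec.fs / 2:
        numtaps = int(32 * rec.fs / target_fs) | 1
        taps = signal.firwin(numtaps, cutoff, fs=rec.fs, window=("kaiser", 8.0))
        data = signal.filtfilt(taps, [1.0], data, axis=1)
    if frac != 1:
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    return EEGRecording(np.ascontiguousarray(data), target_fs, rec.montage)


# ---------------------------------------------------------------------------
# stage 2: filtering


def bandpass_notch(
    rec: EEGRecording,
    lo: float = 2.0,
    hi: float = 20.0,
    notch: float | None = 60.0,
    notch_q: float = 30.0,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass plus optional mains notch.

    Both filters run forward and backward (``filtfilt``), so pass-band
    components keep zero group delay.
    """
    nyq = rec.fs / 2.0
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError("hi must be below the Nyquist frequency")
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    if notch is not None and notch < nyq:
        b, a = signal.iirnotch(notch, notch_q, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    return EEGRecording(np.ascontiguousarray(data), rec.fs, rec.montage)


# ---------------------------------------------------------------------------
# stage 3: epoching


def epoch(rec: EEGRecording, epoch_s: float = 2.0) -> EpochSet:
    """Cut into consecutive non-overlapping epochs and baseline-correct.

    The trailing partial window is dropped. Baseline correction subtracts
    each channel's within-epoch mean.
    """
    n_per = round(rec.fs * epoch_s)
    n_ep = rec.n_samples // n_per
    if n_ep < 1:
        raise ValueError("recording shorter than one epoch")
    cut = rec.data[:, : n_ep * n_per]
    data = cut.reshape(rec.n_channels, n_ep, n_per).transpose(1, 0, 2).copy()
    data -= data.mean(axis=2, keepdims=True)
    return EpochSet(data, rec.fs, epoch_s, rec.montage)


# ---------------------------------------------------------------------------
# stage 4: artifact flagging


def flag_artifacts(
    ep: EpochSet,
    amp_uv: float = 200.0,
    flat_uv: float = 0.5,
    max_bad_frac: float = 0.1,
) -> EpochSet:
    """Flag artifact epochs and bad channels by peak-to-peak amplitude.

    An epoch is rejected when more than ``max_bad_frac`` of its channels
    exceed ``amp_uv`` peak-to-peak. Within surviving epochs, a channel is
    marked bad (for interpolation) if its own peak-to-peak exceeds
    ``amp_uv`` or falls below ``flat_uv`` (dead/flat channel).
    """
    if amp_uv <= 0 or flat_uv <= 0:
        raise ValueError("thresholds must be positive")
    p2p = ep.data.max(axis=2) - ep.data.min(axis=2)  # (n_epochs, n_channels)
    over = p2p > amp_uv
    flags = over.mean(axis=1) > max_bad_frac
    bad = tuple(
        tuple(np.flatnonzero(over[i] | (p2p[i] < flat_uv)))
        for i in range(ep.n_epochs)
    )
    return replace(ep, artifact_flags=flags, bad_channels=bad)


# ---------------------------------------------------------------------------
# stage 5: spherical-spline interpolation

#: Perrin spline flexibility order
SPLINE_M = 4
#: Legendre series truncation
SPLINE_TERMS = 50
#: Tikhonov regularisation added to the spline Gram matrix
SPLINE_LAMBDA = 1e-8

MAX_BAD_FRACTION = 0.25


def _spline_g(cosang: np.ndarray, m: int = SPLINE_M, n_terms: int = SPLINE_TERMS) -> np.ndarray:
    """Perrin spherical-spline kernel g(cos θ)."""
    x = np.clip(np.asarray(cosang, dtype=float), -1.0, 1.0)
    out = np.zeros_like(x)
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / (n * (n + 1)) ** m * eval_legendre(n, x)
    return out / (4.0 * np.pi)


def spline_interpolation_matrix(
    montage: Montage, good: np.ndarray, bad: np.ndarray
) -> np.ndarray:
    """Matrix mapping values on good channels to estimates at bad positions.

    Solves the constrained Perrin system on the good electrodes (spline
    coefficients summing to zero, plus a constant term) and evaluates the
    spline at the bad positions; exact for constants by construction.
    """
    cos_all = montage.cosines()
    g_gg = _spline_g(cos_all[np.ix_(good, good)])
    n_good = len(good)
    if np.linalg.matrix_rank(g_gg) < n_good:
        raise np.linalg.LinAlgError("singular spline system (duplicate positions?)")
    a = np.zeros((n_good + 1, n_good + 1))
    a[:n_good, :n_good] = g_gg + SPLINE_LAMBDA * np.eye(n_good)
    a[:n_good, n_good] = 1.0
    a[n_good, :n_good] = 1.0
    g_bg = _spline_g(cos_all[np.ix_(bad, good)])
    # rows of the solve: [c; c0] = A^-1 [v; 0]; estimate = G_bg c + c0
    inv = np.linalg.inv(a)
    proj = np.hstack([g_bg, np.ones((len(bad), 1))]) @ inv[:, :n_good]
    return proj


def interpolate_channels(ep: EpochSet, montage: Montage | None = None) -> EpochSet:
    """Replace each epoch's bad channels by spherical-spline estimates.

    Good channels are passed through bit-for-bit. Refuses epochs with more
    than 25% bad channels (the spline becomes unreliable).
    """
    montage = montage or ep.montage
    data = ep.data.copy()
    for i, bad in enumerate(ep.bad_channels):
        if not bad:
            continue
        if len(bad) > MAX_BAD_FRACTION * montage.n_channels:
            raise ValueError(
                f"epoch {i}: {len(bad)} bad channels exceeds "
                f"{MAX_BAD_FRACTION:.0%} of the montage"
            )
        bad_idx = np.asarray(bad, dtype=int)
        good_idx = np.setdiff1d(np.arange(montage.n_channels), bad_idx)
        proj = spline_interpolation_matrix(montage, good_idx, bad_idx)
        data[i, bad_idx, :] = proj @ data[i, good_idx, :]
    return replace(ep, data=data, bad_channels=tuple(() for _ in range(ep.n_epochs)))


# ---------------------------------------------------------------------------
# stage 6: referencing


def average_reference(ep: EpochSet) -> EpochSet:
    """Subtract the instantaneous channel mean from every time point (idempotent)."""
    data = ep.data - ep.data.mean(axis=1, keepdims=True)
    return replace(ep, data=data)


# ---------------------------------------------------------------------------
# composed pipeline


def preprocess_recording(
    rec: EEGRecording,
    target_fs: float = 125.0,
    lo: float = 2.0,
    hi: float = 20.0,
    notch: float | None = 60.0,
    epoch_s: float = 2.0,
    amp_uv: float = 200.0,
    flat_uv: float = 0.5,
    max_bad_frac: float = 0.1,
) -> EpochSet:
    """Run stages 1--6 in order on a continuous recording."""
    rec = resample(rec, target_fs)
    rec = bandpass_notch(rec, lo, hi, notch)
    ep = epoch(rec, epoch_s)
    ep = flag_artifacts(ep, amp_uv, flat_uv, max_bad_frac)
    ep = interpolate_channels(ep)
    return average_reference(ep)


def select_artifact_free(ep: EpochSet, n_epochs: int = 10) -> EpochSet:
    """Keep the first ``n_epochs`` unflagged epochs, in temporal order.

    Flagged epochs are skipped (not counted); raises if fewer than
    ``n_epochs`` clean epochs exist.
    """
    keep = np.flatnonzero(~ep.artifact_flags)[:n_epochs]
    if len(keep) < n_epochs:
        raise ValueError(
            f"only {len(keep)} artifact-free epochs available, need {n_epochs}"
        )
    return replace(
        ep,
        data=ep.data[keep],
        artifact_flags=ep.artifact_flags[keep],
        bad_channels=tuple(ep.bad_channels[i] for i in keep),
    )
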