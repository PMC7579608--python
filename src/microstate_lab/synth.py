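"""Synthetic resting-state EEG cohorts with known microstate structure.

The generator emulates a two-group (ASD-like vs typically-developing-like),
two-condition (eyes-closed vs eyes-open) resting-state study. Scalp EEG is
produced by a hidden semi-Markov state sequence over K template
topographies: each state persists for a gamma-distributed run (quasi-stable
~80--120 ms), the next state is drawn from a zero-diagonal transition
matrix, and the emitted frame is the state's template scaled by a slowly
fluctuating positive amplitude, plus spatially smoothed temporally pink
noise at a programmed signal-to-noise ratio.

Default cell parameters (per-class mean durations and per-state GFP for
each group x condition) follow published descriptive statistics for
children's resting EEG microstates, so the default cohort reproduces the
study conditions: 13 + 13 participants, 10 artifact-free 2 s epochs per
condition at the 125 Hz analysis rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import Montage, make_montage
from .preprocess import EpochSet
from .templates import TemplateSet, make_canonical_templates

__all__ = [
    "StateDynamics",
    "CohortDesign",
    "GroundTruth",
    "Cohort",
    "ParticipantRecord",
    "simulate_recording",
    "simulate_cohort",
    "default_design",
    "effect_design",
]

#: spatial smoothing kernel width for background noise (rad); wide enough
#: to correlate neighbouring electrodes, narrow enough that the noise is
#: not itself concentrated in the template subspace
NOISE_KERNEL_RAD = 0.4
#: per-sample amplitude fluctuation SD around 1
AMPLITUDE_SD = 0.2


@dataclass(frozen=True)
class StateDynamics:
    """Generative law for one group x condition cell.

    Parameters
    ----------
    mean_durations_ms
        Per-class mean run duration (ms); runs are gamma distributed.
    gamma_shape
        Shape of the gamma run-length law (4 gives a right-skewed,
        positive law without heavy tails).
    transition
        Zero-diagonal row-stochastic K x K matrix; ``None`` means uniform
        over the other classes.
    snr
        Template RMS over noise RMS; ``np.inf`` disables noise.
    gfp_uv
        Mean global field power of the emitted signal (µV).
    """

    mean_durations_ms: tuple[float, ...]
    gamma_shape: float = 4.0
    transition: np.ndarray | None = field(default=None, repr=False)
    snr: float = 2.0
    gfp_uv: float = 8.0

    def __post_init__(self) -> None:
        durs = tuple(float(d) for d in self.mean_durations_ms)
        object.__setattr__(self, "mean_durations_ms", durs)
        if any(d <= 0 for d in durs):
            raise ValueError("durations must be positive")
        if self.gamma_shape <= 0 or self.gfp_uv <= 0:
            raise ValueError("gamma_shape and gfp_uv must be positive")
        if not self.snr > 0:
            raise ValueError("snr must be positive (np.inf for noise-free)")
        k = len(durs)
        t = self.transition
        if t is None:
            t = (np.ones((k, k)) - np.eye(k)) / (k - 1)
        t = np.asarray(t, dtype=float)
        if t.shape != (k, k):
            raise ValueError("transition matrix shape must be (K, K)")
        if np.any(np.diag(t) != 0):
            raise ValueError("transition matrix must have zero diagonal")
        if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must be stochastic")
        object.__setattr__(self, "transition", t)

    @property
    def n_states(self) -> int:
        return len(self.mean_durations_ms)

    def scaled(self, duration_mult: float = 1.0, gfp_mult: float = 1.0) -> "StateDynamics":
        return replace(
            self,
            mean_durations_ms=tuple(d * duration_mult for d in self.mean_durations_ms),
            gfp_uv=self.gfp_uv * gfp_mult,
        )


@dataclass(frozen=True)
class GroundTruth:
    """True state sequence and derived per-class statistics for one dataset."""

    labels: np.ndarray = field(repr=False)  # (n_epochs, n_samples) int
    templates: TemplateSet = field(repr=False)
    fs: float
    mean_duration_ms: np.ndarray = field(repr=False)
    frequency_hz: np.ndarray = field(repr=False)
    coverage: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class CohortDesign:
    """Full cohort specification: who is simulated, and how."""

    groups: tuple[tuple[str, int], ...]
    conditions: tuple[str, ...] = ("EC", "EO")
    n_epochs: int = 10
    epoch_s: float = 2.0
    fs: float = 125.0
    n_channels: int = 32
    dynamics: dict[tuple[str, str], StateDynamics] = None
    covariates: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    #: relative norm of per-participant template perturbation (|r|>0.9 to canon)
    template_jitter: float = 0.25
    #: SD of the lognormal per-participant duration multiplier
    subject_sigma: float = 0.10
    #: SD of the lognormal per-participant GFP multiplier
    gfp_sigma: float = 0.15
    #: optional (covariate_name, rho): correlate a covariate with the
    #: participant duration factor within each group
    covariate_link: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if self.dynamics is None:
            raise ValueError("dynamics must map every (group, condition) cell")
        for (g, _), c in [(gr, cond) for gr in self.groups for cond in self.conditions]:
            if (g, c) not in self.dynamics:
                raise ValueError(f"missing dynamics for cell ({g!r}, {c!r})")
        if self.n_epochs < 1 or self.epoch_s <= 0 or self.fs <= 0:
            raise ValueError("epoch settings must be positive")


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    group: str
    templates: TemplateSet = field(repr=False)
    epochs: dict = field(repr=False)  # condition -> EpochSet | None
    truth: dict = field(repr=False)  # condition -> GroundTruth


@dataclass(frozen=True)
class Cohort:
    design: CohortDesign
    montage: Montage = field(repr=False)
    canonical: TemplateSet = field(repr=False)
    participants: tuple[ParticipantRecord, ...]
    covariates: pd.DataFrame = field(repr=False)


# ---------------------------------------------------------------------------
# state-sequence and signal generation


def _simulate_runs(
    dyn: StateDynamics, n_samples: int, fs: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Continuous label sequence of length n_samples plus its (class, length) runs."""
    k = dyn.n_states
    runs: list[tuple[int, int]] = []
    total = 0
    state = int(rng.integers(k))
    scale_samp = np.asarray(dyn.mean_durations_ms) * fs / 1000.0 / dyn.gamma_shape
    while total < n_samples:
        length = max(1, int(round(rng.gamma(dyn.gamma_shape, scale_samp[state]))))
        runs.append((state, length))
        total += length
        state = int(rng.choice(k, p=dyn.transition[state]))
    labels = np.repeat(
        [s for s, _ in runs], [length for _, length in runs]
    )[:n_samples]
    return labels.astype(np.int64), runs


def _truth_stats(
    runs: list[tuple[int, int]], labels: np.ndarray, k: int, fs: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """True per-class mean duration / frequency / coverage of the sequence.

    The final run is truncated by the simulation window and excluded from
    the duration mean; coverage is exact over the emitted samples.
    """
    dur = np.full(k, np.nan)
    complete = runs[:-1] if len(runs) > 1 else runs
    for c in range(k):
        lens = [length for s, length in complete if s == c]
        if lens:
            dur[c] = np.mean(lens) * 1000.0 / fs
    onsets = np.bincount([s for s, _ in runs], minlength=k).astype(float)
    seconds = len(labels) / fs
    freq = onsets / seconds
    cov = np.bincount(labels, minlength=k) / len(labels)
    return dur, freq, cov


def _pink_noise(
    n_channels: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Temporally pink (1/f amplitude) noise, unit RMS per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    noise = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(noise**2, axis=1, keepdims=True))
    return noise / rms


def _spatial_smooth(noise: np.ndarray, montage: Montage) -> np.ndarray:
    """Mix channels with a Gaussian great-circle-distance kernel (unit-RMS rows)."""
    w = np.exp(-(montage.angles() ** 2) / (2.0 * NOISE_KERNEL_RAD**2))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    return w @ noise


def simulate_recording(
    templates: TemplateSet,
    dynamics: StateDynamics,
    n_epochs: int = 10,
    epoch_s: float = 2.0,
    fs: float = 125.0,
    seed: int | np.random.Generator = 0,
) -> tuple[EpochSet, GroundTruth]:
    """Simulate one dataset: epoched EEG plus its generating state sequence.

    The state sequence is generated continuously and then cut into epochs,
    so boundary-truncated runs occur exactly as in real epoched data.
    """
    if fs <= 0 or epoch_s <= 0:
        raise ValueError("fs and epoch_s must be positive")
    if dynamics.n_states != templates.n_states:
        raise ValueError("dynamics and templates must agree on K")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    montage = templates.montage
    n_per = round(fs * epoch_s)
    n_total = n_epochs * n_per
    labels, runs = _simulate_runs(dynamics, n_total, fs, rng)

    unit_maps = templates.normalized().maps  # (K, n_ch), zero-mean unit-norm
    amp = np.abs(rng.normal(1.0, AMPLITUDE_SD, size=n_total))
    # unit-norm zero-mean map has GFP 1/sqrt(n_ch); rescale so frame GFP = amp*gfp_uv
    gain = dynamics.gfp_uv * np.sqrt(montage.n_channels)
    signal = (unit_maps[labels] * (amp * gain)[:, None]).T  # (n_ch, n_total)

    if np.isfinite(dynamics.snr):
        noise = _spatial_smooth(_pink_noise(montage.n_channels, n_total, rng), montage)
        sig_rms = np.sqrt(np.mean(signal**2))
        noise_rms = np.sqrt(np.mean(noise**2))
        signal = signal + noise * (sig_rms / (dynamics.snr * noise_rms))

    data = signal.reshape(montage.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    ep = EpochSet(np.ascontiguousarray(data), fs, epoch_s, montage)
    dur, freq, cov = _truth_stats(runs, labels, dynamics.n_states, fs)
    truth = GroundTruth(
        labels.reshape(n_epochs, n_per), templates, fs, dur, freq, cov
    )
    return ep, truth


# ---------------------------------------------------------------------------
# cohort generation


def _jitter_templates(
    canon: TemplateSet, jitter: float, rng: np.random.Generator
) -> TemplateSet:
    """Per-participant template perturbation, spatial |r| to canon > ~0.9."""
    n_ch = canon.montage.n_channels
    g = rng.standard_normal(canon.maps.shape) / np.sqrt(n_ch)
    maps = canon.normalized().maps + jitter * g
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return TemplateSet(canon.labels, maps, canon.montage)


def simulate_cohort(
    design: CohortDesign, seed: int = 0, signals: bool = True
) -> Cohort:
    """Simulate every participant of a cohort design, reproducibly.

    With ``signals=False`` only ground-truth state sequences and covariates
    are generated (fast path for statistical calibration studies).
    """
    rng = np.random.default_rng(seed)
    montage = make_montage(design.n_channels)
    canon = make_canonical_templates(montage)
    participants: list[ParticipantRecord] = []
    cov_rows: list[dict] = []
    for group, n in design.groups:
        for i in range(n):
            pid = f"{group}{i + 1:02d}"
            prng = np.random.default_rng(rng.integers(2**31))
            templates = _jitter_templates(canon, design.template_jitter, prng)
            z_dur = prng.standard_normal()
            dur_mult = float(np.exp(design.subject_sigma * z_dur))
            gfp_mult = float(np.exp(design.gfp_sigma * prng.standard_normal()))
            epochs: dict = {}
            truth: dict = {}
            for cond in design.conditions:
                dyn = design.dynamics[(group, cond)].scaled(dur_mult, gfp_mult)
                if signals:
                    ep, gt = simulate_recording(
                        templates, dyn, design.n_epochs, design.epoch_s,
                        design.fs, prng,
                    )
                else:
                    n_per = round(design.fs * design.epoch_s)
                    n_total = design.n_epochs * n_per
                    labels, runs = _simulate_runs(dyn, n_total, design.fs, prng)
                    dur, freq, cov = _truth_stats(runs, labels, dyn.n_states, design.fs)
                    ep = None
                    gt = GroundTruth(
                        labels.reshape(design.n_epochs, n_per),
                        templates, design.fs, dur, freq, cov,
                    )
                epochs[cond] = ep
                truth[cond] = gt
            row = {"participant": pid, "group": group}
            for name, by_group in design.covariates.items():
                if group not in by_group:
                    row[name] = np.nan
                    continue
                mean, sd = by_group[group]
                if design.covariate_link and design.covariate_link[0] == name:
                    rho = design.covariate_link[1]
                    z = rho * z_dur + np.sqrt(1 - rho**2) * prng.standard_normal()
                else:
                    z = prng.standard_normal()
                row[name] = max(0.0, mean + sd * z)
            cov_rows.append(row)
            participants.append(
                ParticipantRecord(pid, group, templates, epochs, truth)
            )
    return Cohort(
        design, montage, canon, tuple(participants), pd.DataFrame(cov_rows)
    )


# ---------------------------------------------------------------------------
# stock designs

# Per-class mean durations (ms) and per-state GFP (µV) for each cell of the
# two-group, two-condition design; values follow published descriptive
# statistics for children's resting-state microstates.
_CELL_DURATIONS = {
    ("TD", "EC"): (73.58, 69.32, 67.32, 63.99),
    ("ASD", "EC"): (81.32, 83.87, 81.56, 80.67),
    ("TD", "EO"): (73.20, 70.01, 66.99, 63.35),
    ("ASD", "EO"): (75.75, 73.63, 69.28, 68.56),
}
_CELL_GFP = {
    ("TD", "EC"): 11.5,
    ("ASD", "EC"): 7.3,
    ("TD", "EO"): 8.8,
    ("ASD", "EO"): 5.5,
}
_COVARIATES = {
    "age": {"ASD": (9.7, 1.5), "TD": (10.4, 1.4)},
    "iq": {"ASD": (101.3, 19.8), "TD": (102.1, 9.9)},
    "srs_total": {"ASD": (73.0, 10.0), "TD": (22.0, 8.0)},
    "rbsr_total": {"ASD": (34.9, 21.1), "TD": (1.8, 2.0)},
}


def default_design(
    n_per_group: int = 13,
    n_epochs: int = 10,
    n_channels: int = 32,
    snr: float = 2.0,
) -> CohortDesign:
    """Study-like cohort: 13+13 ASD/TD, EC+EO, 10 x 2 s epochs at 125 Hz."""
    dynamics = {
        cell: StateDynamics(_CELL_DURATIONS[cell], snr=snr, gfp_uv=_CELL_GFP[cell])
        for cell in _CELL_DURATIONS
    }
    return CohortDesign(
        groups=(("TD", n_per_group), ("ASD", n_per_group)),
        n_epochs=n_epochs,
        n_channels=n_channels,
        dynamics=dynamics,
        covariates=_COVARIATES,
    )


def recovery_design(
    n_per_group: int = 13,
    n_epochs: int = 10,
    durations: tuple[float, ...] = (85.0, 60.0, 100.0, 70.0),
    snr: float = 2.0,
    n_channels: int = 32,
) -> CohortDesign:
    """Parameter-recovery study: one dynamics law for every cell.

    Per-class mean durations span 60--100 ms with distinct values so both
    relative error and rank order of the recovered durations are testable;
    the longest dwell time goes to class C, as empirical resting-state
    reports typically find.
    """
    dyn = StateDynamics(durations, snr=snr)
    return CohortDesign(
        groups=(("TD", n_per_group), ("ASD", n_per_group)),
        n_epochs=n_epochs,
        n_channels=n_channels,
        dynamics={
            (g, c): dyn for g in ("TD", "ASD") for c in ("EC", "EO")
        },
    )


def effect_design(
    n_per_group: int = 13,
    n_epochs: int = 10,
    effect: float = 0.20,
    base_ms: tuple[float, ...] = (74.0, 69.0, 67.0, 64.0),
    target_class: int = 2,
    n_channels: int = 32,
    snr: float = 2.0,
) -> CohortDesign:
    """Two-group design with a programmed duration effect in one cell only.

    Class ``target_class`` (default C) gets a ``(1 + effect)`` duration
    multiplier in the ASD-like group's EC condition; every other cell uses
    the common baseline, so only the group x condition interaction carries
    the programmed effect. ``effect=0`` yields an exact null design.
    """
    base = StateDynamics(base_ms, snr=snr)
    bumped = list(base_ms)
    bumped[target_class] *= 1.0 + effect
    dynamics = {
        ("TD", "EC"): base,
        ("TD", "EO"): base,
        ("ASD", "EO"): base,
        ("ASD", "EC"): StateDynamics(tuple(bumped), snr=snr),
    }
    return CohortDesign(
        groups=(("TD", n_per_group), ("ASD", n_per_group)),
        n_epochs=n_epochs,
        n_channels=n_channels,
        dynamics=dynamics,
    )
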