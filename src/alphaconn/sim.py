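"""Synthetic EEG recordings and cohorts with known ground truth.

Nothing here imitates a head model: the generator produces just enough
structure to exercise every downstream stage with a known answer.

A recording is 1/f^alpha background noise (optionally mixed instantaneously
across channels through a ``mixing`` matrix, emulating volume conduction)
plus, per configured coupling pair, a shared narrow-band oscillator injected
into both channels with a fixed phase lag.  Coupling strength ``s`` in [0, 1]
mixes the shared analytic signal ``z0`` with an independent narrow-band
signal per endpoint::

    z_i = sqrt(s) * z0              + sqrt(1-s) * z_ind_i
    z_j = sqrt(s) * z0 * e^{-i*lag} + sqrt(1-s) * z_ind_j

so the analytic cross-correlation between endpoints equals ``s``: s = 0 is
independence (dbWPLI -> 0), s = 1 a perfectly consistent lag (dbWPLI -> 1 for
lags away from multiples of pi).  The empirical strength -> dbWPLI mapping is
monotone but not linear; it is documented in the methods note, not assumed
anywhere.

A cohort draws one true coupling strength per subject from its group's
normal distribution (clipped to [0, 1]), simulates one recording per subject
from a shared template, and generates each trait score as
``a + b * strength + N(0, sd)`` — a noisy monotone function of the planted
coupling, so rank-correlation recovery has a known target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import Recording

__all__ = [
    "CouplingPair",
    "SimConfig",
    "TraitModel",
    "CohortConfig",
    "GroundTruth",
    "simulate_recording",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CouplingPair:
    """A phase-lagged coupling between two channels.

    ``lag`` is the phase (radians) by which channel ``j`` trails channel
    ``i`` at ``freq`` Hz; ``strength`` in [0, 1] sets the shared-signal
    fraction of each endpoint's oscillatory component.
    """

    i: int
    j: int
    freq: float
    lag: float
    strength: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("coupling strength must lie in [0, 1]")
        if self.i == self.j:
            raise ValueError("coupling pair must join two distinct channels")
        if self.freq <= 0:
            raise ValueError("coupling frequency must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Recording-level generator settings.

    ``snr`` is the amplitude (RMS) ratio of each oscillatory component to the
    background noise; ``np.inf`` suppresses noise on channels that carry a
    coupling.  ``mixing`` (channels x sources) mixes independent noise
    sources instantaneously across channels; None means one independent
    noise source per channel.  ``bandwidth`` is the oscillator's spectral
    width (Hz, Gaussian profile) and controls how fast its phase decorrelates
    across epochs.
    """

    n_channels: int
    duration: float
    fs: float = 500.0
    coupling_pairs: tuple[CouplingPair, ...] = ()
    mixing: np.ndarray | None = None
    noise_exponent: float = 1.0
    snr: float = 1.0
    bandwidth: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.mixing is not None:
            m = np.asarray(self.mixing, dtype=float)
            if m.ndim != 2 or min(m.shape) < 1:
                raise ValueError("mixing must be a 2-D channels x sources matrix")
            if m.shape[0] != self.n_channels:
                raise ValueError("mixing row count must equal n_channels")
        for p in self.coupling_pairs:
            if not (0 <= p.i < self.n_channels and 0 <= p.j < self.n_channels):
                raise ValueError(f"coupling pair ({p.i}, {p.j}) outside channel range")


def _one_over_f_noise(rng: np.random.Generator, n_series: int, n: int, exponent: float) -> np.ndarray:
    """Gaussian noise with power spectral density 1/f^exponent, unit RMS rows."""
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (
        rng.standard_normal((n_series, len(freqs)))
        + 1j * rng.standard_normal((n_series, len(freqs)))
    )
    x = np.fft.irfft(spec, n=n, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _narrowband_analytic(
    rng: np.random.Generator, n: int, fs: float, f0: float, bandwidth: float
) -> np.ndarray:
    """Unit-RMS complex analytic signal with a Gaussian spectrum around f0."""
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    amp = np.exp(-0.5 * ((freqs - f0) / max(bandwidth, 1e-6)) ** 2)
    amp[freqs <= 0] = 0.0  # analytic: positive frequencies only
    spec = amp * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    z = np.fft.ifft(spec)
    rms = np.sqrt(np.mean(np.abs(z) ** 2))
    return z / (rms if rms > 0 else 1.0)


def simulate_recording(cfg: SimConfig) -> Recording:
    """Generate one synthetic recording; bit-identical under the same config."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.fs * cfg.duration))
    if cfg.mixing is None:
        noise = _one_over_f_noise(rng, cfg.n_channels, n, cfg.noise_exponent)
    else:
        m = np.asarray(cfg.mixing, dtype=float)
        sources = _one_over_f_noise(rng, m.shape[1], n, cfg.noise_exponent)
        noise = m @ sources

    samples = noise.copy()
    coupled_channels: set[int] = set()
    for pair in cfg.coupling_pairs:
        z0 = _narrowband_analytic(rng, n, cfg.fs, pair.freq, cfg.bandwidth)
        zi_ind = _narrowband_analytic(rng, n, cfg.fs, pair.freq, cfg.bandwidth)
        zj_ind = _narrowband_analytic(rng, n, cfg.fs, pair.freq, cfg.bandwidth)
        c = np.sqrt(pair.strength)
        d = np.sqrt(1.0 - pair.strength)
        zi = c * z0 + d * zi_ind
        zj = c * z0 * np.exp(-1j * pair.lag) + d * zj_ind
        amp = 1.0 if np.isinf(cfg.snr) else cfg.snr
        # analytic real part has RMS 1/sqrt(2); rescale to unit-RMS oscillation
        samples[pair.i] += amp * np.sqrt(2.0) * zi.real
        samples[pair.j] += amp * np.sqrt(2.0) * zj.real
        coupled_channels.update((pair.i, pair.j))
    if np.isinf(cfg.snr):
        for ch in coupled_channels:
            samples[ch] -= noise[ch]
    labels = [f"ch{idx:03d}" for idx in range(cfg.n_channels)]
    return Recording(samples=samples, fs=cfg.fs, channel_labels=labels, annotations=[])


@dataclass(frozen=True)
class TraitModel:
    """Linear-plus-noise link from planted coupling strength to a trait scale.

    score = intercept + slope * strength + N(0, noise_sd); ``integer=True``
    rounds and clips at 0 to mimic interview total scores.
    """

    intercept: float
    slope: float
    noise_sd: float
    integer: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("trait noise sd must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings.

    ``group_sizes`` maps group label -> subject count; ``coupling_by_group``
    maps group -> (mean, sd) of the true coupling strength (clipped to
    [0, 1]); ``traits`` maps trait column name -> TraitModel; ``template`` is
    the per-subject SimConfig whose coupling strengths are scaled by the
    subject's true strength.
    """

    group_sizes: Mapping[str, int]
    coupling_by_group: Mapping[str, tuple[float, float]]
    traits: Mapping[str, TraitModel]
    template: SimConfig
    male_fraction: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes must not be empty")
        for g, k in self.group_sizes.items():
            if k < 0:
                raise ValueError(f"negative subject count for group '{g}'")
            if g not in self.coupling_by_group:
                raise ValueError(f"no coupling distribution for group '{g}'")


@dataclass
class GroundTruth:
    """What the generator planted, retrievable for any simulated cohort."""

    strengths: pd.Series  # subject id -> true coupling strength
    coupled_edges: list[tuple[int, int]]
    trait_models: dict[str, TraitModel]


def simulate_cohort(cfg: CohortConfig) -> tuple[list[Recording], pd.DataFrame, GroundTruth]:
    """Simulate one recording and one cohort-table row per subject.

    Deterministic under ``cfg.seed`` (per-subject child seeds are spawned
    from it).  Trait scores are a noisy monotone function of each subject's
    planted coupling strength.
    """
    rng = np.random.default_rng(cfg.seed)
    recordings: list[Recording] = []
    rows: list[dict] = []
    strengths: dict[str, float] = {}
    sid = 0
    for group, count in cfg.group_sizes.items():
        mean, sd = cfg.coupling_by_group[group]
        for _ in range(count):
            subject = f"s{sid:03d}"
            strength = float(np.clip(rng.normal(mean, sd), 0.0, 1.0))
            pairs = tuple(
                replace(p, strength=float(np.clip(p.strength * strength, 0.0, 1.0)))
                for p in cfg.template.coupling_pairs
            )
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sub_cfg = replace(cfg.template, coupling_pairs=pairs, seed=sub_seed)
            recordings.append(simulate_recording(sub_cfg))
            row = {
                "subject": subject,
                "group": group,
                "sex": "M" if rng.random() < cfg.male_fraction else "F",
                "age_days": float(np.round(rng.normal(465.0, 45.0))),
            }
            for name, tm in cfg.traits.items():
                score = tm.intercept + tm.slope * strength + rng.normal(0.0, tm.noise_sd)
                row[name] = float(max(0.0, round(score))) if tm.integer else float(score)
            rows.append(row)
            strengths[subject] = strength
            sid += 1
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        strengths=pd.Series(strengths, name="true_strength"),
        coupled_edges=[(p.i, p.j) for p in cfg.template.coupling_pairs],
        trait_models=dict(cfg.traits),
    )
    return recordings, table, truth
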