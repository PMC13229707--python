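"""Seeded synthetic cohorts emulating the motor-cortical ECoG regime.

No raw rodent ECoG is distributed, so the pipeline is exercised on a
generator that reproduces the statistical structure the analysis
assumes: a parkinsonian group whose cortical-like signals are more
complex (rougher, higher fractal dimension) than controls, and a
treatment condition (DBS-like / dopamine-agonist-like) that shifts
complexity back toward control levels.

Complexity is controlled through the Hurst exponent H of a fractional
Brownian motion (fBm) background, because the graph of fBm has fractal
dimension 2 - H: lower H means a rougher, higher-FD signal.  HFD is
scale invariant, so the groups differ in H, never in amplitude.  On top
of the background each recording carries beta-band (12-30 Hz) burst
packets -- the spectral phenomenology of parkinsonian cortex -- and a
small white measurement noise floor.  fBm paths are sampled exactly via
circulant embedding (Davies-Harte) of the fractional Gaussian noise
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sfft

from .errors import ParameterError
from .signal_io import Recording

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "gen_fbm",
    "gen_subject_signal",
    "simulate_cohort",
    "simulate_acute_cohort",
    "subject_seed",
]


@dataclass
class CohortConfig:
    """Generating parameters of a synthetic cohort.

    Defaults mirror the emulated study: 8 parkinsonian and 7 control
    subjects, 8 channels each, 300 s sessions acquired at 1000 Hz and
    analyzed at 256 Hz.  ``hurst_pd < hurst_control`` encodes the
    higher complexity (FD ~ 2 - H) of the parkinsonian group;
    ``treatment_effect`` is the fraction of the Hurst gap the treatment
    closes.
    """

    n_pd: int = 8
    n_control: int = 7
    n_channels: int = 8
    duration_s: float = 300.0
    fs_acquire: float = 1000.0
    fs_analysis: float = 256.0
    hurst_control: float = 0.65
    hurst_pd: float = 0.45
    beta_burst_rate_pd: float = 0.5  # bursts / s
    beta_burst_rate_control: float = 0.1
    beta_band: tuple[float, float] = (12.0, 30.0)
    burst_duration_s: float = 0.5
    #: Burst peak amplitude relative to the unit-SD background path.  At
    #: HFD scales (milliseconds) the fBm's local increments are orders of
    #: magnitude below the path SD, so bursts are kept vestigial: they
    #: mark the spectral phenomenology without overriding the
    #: H-controlled fractal scaling the cohort is built to carry.
    burst_amplitude: float = 0.002
    treatment_effect: float = 0.8  # fraction of the PD-control gap closed
    channel_noise_sd: float = 0.05  # relative per-channel amplitude jitter
    hurst_channel_jitter_sd: float = 0.02
    hurst_subject_jitter_sd: float = 0.02
    common_signal_weight: float = 0.4  # shared background across channels
    #: White measurement noise relative to the unit-SD background; same
    #: caveat as burst_amplitude -- a large noise floor swamps the
    #: smoother group's fine-scale increments first and would invert the
    #: group ordering the cohort encodes.
    noise_sd: float = 0.0005
    amplitude_uv: float = 50.0  # nominal channel SD, microvolt-like
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.hurst_pd < 1 and 0 < self.hurst_control < 1):
            raise ParameterError("Hurst exponents must lie in (0, 1)")
        if self.hurst_pd >= self.hurst_control:
            raise ParameterError(
                "hurst_pd must be below hurst_control (PD complexity higher)"
            )
        if min(self.n_pd, self.n_control, self.n_channels) < 1:
            raise ParameterError("subject and channel counts must be positive")
        if self.duration_s <= 0 or self.fs_acquire <= 0:
            raise ParameterError("duration and sampling rate must be positive")
        if not self.fs_analysis < self.fs_acquire:
            raise ParameterError("fs_analysis must be below fs_acquire")
        if not 0 <= self.treatment_effect <= 1:
            raise ParameterError("treatment_effect must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """Generated recordings plus the per-recording generating truth."""

    recordings: list[Recording]
    truth: pd.DataFrame  # subject_id, group, condition, hurst, burst_rate
    config: CohortConfig

    def __post_init__(self) -> None:
        if len(self.recordings) != len(self.truth):
            raise ParameterError("truth must have one row per recording")


def _fgn(m: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise of length m via circulant embedding."""
    h2 = 2.0 * hurst
    lags = np.arange(m + 1, dtype=float)
    gamma = 0.5 * (
        np.abs(lags + 1) ** h2 - 2 * np.abs(lags) ** h2 + np.abs(lags - 1) ** h2
    )
    # Embed in a circulant of fast-FFT size >= 2m.
    big = sfft.next_fast_len(2 * m, real=True)
    g = big // 2
    if g > m:
        extra = np.arange(m + 1, g + 1, dtype=float)
        gamma = np.concatenate(
            [
                gamma,
                0.5
                * (
                    np.abs(extra + 1) ** h2
                    - 2 * np.abs(extra) ** h2
                    + np.abs(extra - 1) ** h2
                ),
            ]
        )
    row = np.concatenate([gamma[: g + 1], gamma[g - 1 : 0 : -1]])
    lam = sfft.fft(row).real
    # fGn embeddings are non-negative definite up to round-off.
    if lam.min() < -1e-8 * lam.max():
        raise ParameterError(
            f"circulant embedding not non-negative definite (H={hurst})"
        )
    lam = np.clip(lam, 0.0, None)
    n_big = lam.size
    w = np.zeros(n_big, dtype=complex)
    w[0] = np.sqrt(lam[0]) * rng.standard_normal()
    w[g] = np.sqrt(lam[g]) * rng.standard_normal()
    a = rng.standard_normal(g - 1)
    b = rng.standard_normal(g - 1)
    w[1:g] = np.sqrt(lam[1:g] / 2.0) * (a + 1j * b)
    w[g + 1 :] = np.conj(w[1:g][::-1])
    out = sfft.fft(w) / np.sqrt(n_big)
    return out[:m].real


def gen_fbm(n: int, hurst: float, seed) -> np.ndarray:
    """Fractional Brownian motion path of length ``n`` starting at 0.

    Exact-covariance sampling (circulant embedding of the increment
    process); the same ``(n, hurst, seed)`` always yields the identical
    path.  ``seed`` may be an int, SeedSequence, or Generator.
    """
    if not 0 < hurst < 1:
        raise ParameterError(f"hurst must be in (0, 1), got {hurst}")
    if n < 2:
        raise ParameterError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    incr = _fgn(n - 1, hurst, rng)
    path = np.empty(n)
    path[0] = 0.0
    np.cumsum(incr, out=path[1:])
    return path


def subject_seed(seed: int, group: str, index: int, condition: str) -> np.random.SeedSequence:
    """Stable per-subject/-condition seed stream.

    Derived from the cohort seed through a SeedSequence spawn key built
    from (group, subject index, condition), so adding subjects or
    conditions never perturbs existing ones.
    """
    group_code = {"pd": 1, "control": 2}[group]
    cond_code = {"control": 0, "pd": 1, "pd_treated": 2, "control_treated": 3}[condition]
    return np.random.SeedSequence(entropy=seed, spawn_key=(group_code, index, cond_code))


def _burst_component(
    n: int, fs: float, rate: float, band: tuple[float, float],
    dur_s: float, rng: np.random.Generator,
) -> np.ndarray:
    """Amplitude-modulated sinusoid packets at Poisson times, unit amplitude."""
    out = np.zeros(n)
    n_burst = rng.poisson(rate * n / fs)
    width = max(int(round(dur_s * fs)), 8)
    if n_burst == 0:
        return out
    env = np.hanning(width)
    t = np.arange(width) / fs
    for _ in range(n_burst):
        start = rng.integers(0, max(n - width, 1))
        f = rng.uniform(*band)
        phase = rng.uniform(0, 2 * np.pi)
        seg = env * np.sin(2 * np.pi * f * t + phase)
        stop = min(start + width, n)
        out[start:stop] += seg[: stop - start]
    return out


def _condition_params(config: CohortConfig, group: str, condition: str):
    """Generating (hurst, burst_rate) for a group x condition cell."""
    gap_h = config.hurst_control - config.hurst_pd
    gap_r = config.beta_burst_rate_control - config.beta_burst_rate_pd
    if condition in ("control", "control_treated"):
        # DBS on sham-like controls leaves complexity unchanged.
        return config.hurst_control, config.beta_burst_rate_control
    if condition == "pd":
        return config.hurst_pd, config.beta_burst_rate_pd
    if condition == "pd_treated":
        return (
            config.hurst_pd + config.treatment_effect * gap_h,
            config.beta_burst_rate_pd + config.treatment_effect * gap_r,
        )
    raise ParameterError(f"unknown condition {condition!r}")


def gen_subject_signal(
    config: CohortConfig,
    group: str,
    subject_seed,
    subject_id: str = "s00",
    condition: str | None = None,
) -> Recording:
    """One subject's multichannel session at the acquisition rate.

    Channels share a common fBm background (weight
    ``common_signal_weight``) plus an own fBm with per-channel Hurst
    jitter, group-rate beta bursts shared across channels, and a white
    measurement-noise floor.
    """
    if group not in ("pd", "control"):
        raise ParameterError(f"group must be 'pd' or 'control', got {group!r}")
    if condition is None:
        condition = "pd" if group == "pd" else "control"
    rng = np.random.default_rng(subject_seed)
    n = int(round(config.duration_s * config.fs_acquire))
    hurst, burst_rate = _condition_params(config, group, condition)
    h_subj = float(
        np.clip(rng.normal(hurst, config.hurst_subject_jitter_sd), 0.05, 0.95)
    )

    common = gen_fbm(n, h_subj, rng)
    common /= common.std() or 1.0
    bursts = _burst_component(
        n, config.fs_acquire, burst_rate, config.beta_band, config.burst_duration_s, rng
    )

    w = config.common_signal_weight
    samples = np.empty((n, config.n_channels))
    for j in range(config.n_channels):
        h_ch = float(
            np.clip(rng.normal(h_subj, config.hurst_channel_jitter_sd), 0.05, 0.95)
        )
        own = gen_fbm(n, h_ch, rng)
        own /= own.std() or 1.0
        background = np.sqrt(w) * common + np.sqrt(1 - w) * own
        gain = config.amplitude_uv * (1.0 + rng.normal(0.0, config.channel_noise_sd))
        burst_gain = config.burst_amplitude * (1.0 + 0.2 * rng.normal())
        chan = background + burst_gain * bursts
        chan = chan + config.noise_sd * rng.standard_normal(n)
        samples[:, j] = gain * chan
    return Recording(
        samples=samples,
        fs=config.fs_acquire,
        channel_ids=[f"ch{j}" for j in range(config.n_channels)],
        subject_id=subject_id,
        condition=condition,
    )


def _truth_row(config, subject_id, group, condition):
    hurst, rate = _condition_params(config, group, condition)
    return {
        "subject_id": subject_id,
        "group": group,
        "condition": condition,
        "hurst": hurst,
        "burst_rate": rate,
    }


def simulate_cohort(
    config: CohortConfig, include_treatment: bool = True
) -> SyntheticCohort:
    """Chronic-design cohort: PD and control groups, baseline
    (and optionally treatment/DBS-like) sessions per subject."""
    recordings: list[Recording] = []
    rows = []
    for group, n_subj, base_cond, treat_cond in (
        ("pd", config.n_pd, "pd", "pd_treated"),
        ("control", config.n_control, "control", "control_treated"),
    ):
        conditions = [base_cond] + ([treat_cond] if include_treatment else [])
        for i in range(n_subj):
            sid = f"{group}_{i:02d}"
            for cond in conditions:
                ss = subject_seed(config.seed, group, i, cond)
                recordings.append(
                    gen_subject_signal(config, group, ss, subject_id=sid, condition=cond)
                )
                rows.append(_truth_row(config, sid, group, cond))
    return SyntheticCohort(
        recordings=recordings, truth=pd.DataFrame(rows), config=config
    )


def simulate_acute_cohort(config: CohortConfig, n_subjects: int = 6) -> SyntheticCohort:
    """Acute-design cohort: each subject recorded in three sessions --
    drug-free baseline (control), induced parkinsonian state (pd), and
    after the rescue agonist (pd_treated).  The subject is its own
    control, matching a one-way repeated-measures design."""
    recordings: list[Recording] = []
    rows = []
    for i in range(n_subjects):
        sid = f"acute_{i:02d}"
        for cond, group in (("control", "control"), ("pd", "pd"), ("pd_treated", "pd")):
            ss = subject_seed(config.seed, "pd", i + 1000, cond)
            recordings.append(
                gen_subject_signal(config, group, ss, subject_id=sid, condition=cond)
            )
            rows.append(_truth_row(config, sid, group, cond))
    return SyntheticCohort(
        recordings=recordings, truth=pd.DataFrame(rows), config=config
    )
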