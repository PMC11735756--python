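"""Synthetic multichannel EEG epochs and clinically structured cohorts.

This module is the test bed for the whole decoding pipeline: it generates
epoched EEG with controllable local/global deviance effects on known
topographies, embedded in spatially correlated, temporally smoothed Gaussian
noise, plus synthetic patient cohorts whose covariates (FOUR score, CPC
outcome, sedative infusion rates, body temperature) can be linked to the
simulated effect amplitude through explicit, configurable rules.

The generator emulates the geometry of the real recordings (63 channels at
1200 Hz, epochs from -100 to 500 ms around the fifth-tone onset, 100 global
standards vs 20 global deviants per block over 8 blocks) but none of the
biophysics: no volume conduction model, no 1/f spectrum, no blink/ECG
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from ._utils import child_seed
from .epochs import DEVIANT, EpochSet
from .paradigm import StimulusSchedule, build_session

DEFAULT_SFREQ = 1200.0
DEFAULT_N_CHANNELS = 63
DEFAULT_EPOCH_WINDOW_MS = (-100.0, 500.0)
#: default effect windows (ms after fifth-tone onset): the local mismatch
#: response is early, the global effect is late (>= 300 ms, P3b-like)
DEFAULT_LOCAL_WINDOW_MS = (100.0, 250.0)
DEFAULT_GLOBAL_WINDOW_MS = (300.0, 500.0)


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the upper hemisphere
    (a stand-in electrode montage)."""
    i = np.arange(n)
    z = (i + 0.5) / n                       # upper hemisphere only
    phi = np.pi * (1 + 5**0.5) * i
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class HeadModel:
    """Channel geometry plus one fixed topography per simulated ERP component.

    Topographies are smooth linear-gradient maps over the electrode
    positions, average-referenced (zero channel mean) and unit L2 norm.
    """

    positions: np.ndarray       # (n_channels, 3) unit sphere
    topographies: np.ndarray    # (n_components, n_channels)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.topographies = np.atleast_2d(np.asarray(self.topographies, dtype=float))
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.topographies.shape[1] != self.n_channels:
            raise ValueError("topography length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def random(cls, n_channels: int = DEFAULT_N_CHANNELS, n_components: int = 2,
               seed: int = 0) -> "HeadModel":
        """Random head: Fibonacci electrode layout and smooth dipolar-looking
        component maps (projection of positions on random directions)."""
        rng = np.random.default_rng(seed)
        pos = fibonacci_hemisphere(n_channels)
        topos = []
        for _ in range(n_components):
            d = rng.normal(size=3)
            t = pos @ (d / np.linalg.norm(d))
            t = t - t.mean()
            topos.append(t / np.linalg.norm(t))
        return cls(positions=pos, topographies=np.array(topos))


@dataclass(frozen=True)
class EffectSpec:
    """An additive condition effect: which label dimension it keys on, when
    it occurs, how strong it is, and which head-model topography it uses."""

    component: str                                # "local" or "global"
    window_ms: tuple[float, float]
    amplitude_uv: float
    topography_index: int = 0

    def __post_init__(self) -> None:
        if self.component not in ("local", "global"):
            raise ValueError("component must be 'local' or 'global'")
        if self.amplitude_uv < 0:
            raise ValueError("amplitude must be >= 0")


def default_effects(global_amplitude_uv: float = 2.0,
                    local_amplitude_uv: float = 2.0) -> list[EffectSpec]:
    """Late global effect (>=300 ms) on topography 0, earlier local effect
    on topography 1."""
    return [
        EffectSpec("global", DEFAULT_GLOBAL_WINDOW_MS, global_amplitude_uv, 0),
        EffectSpec("local", DEFAULT_LOCAL_WINDOW_MS, local_amplitude_uv, 1),
    ]


@dataclass
class RecordingSimParams:
    """Everything needed to simulate one recording's epochs."""

    schedule: StimulusSchedule
    head: HeadModel
    effects: Sequence[EffectSpec]
    noise_sd: float = 5.0                       # microvolts per channel
    spatial_mixing: np.ndarray | None = None    # channels x channels; None -> random
    ar_coef: float = 0.3                        # AR(1) temporal smoothing in [0, 1)
    sfreq: float = DEFAULT_SFREQ
    epoch_window_ms: tuple[float, float] = DEFAULT_EPOCH_WINDOW_MS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0 <= self.ar_coef < 1):
            raise ValueError("AR(1) coefficient must be in [0, 1)")


def _half_cosine_envelope(times_s: np.ndarray, window_ms: tuple[float, float]
                          ) -> np.ndarray:
    """Smooth raised-cosine (Hann) bump supported on the effect window,
    avoiding the spectral splatter of a rectangular effect."""
    t0, t1 = (w / 1000.0 for w in window_ms)
    env = np.zeros_like(times_s)
    inside = (times_s >= t0) & (times_s < t1)
    phase = (times_s[inside] - t0) / (t1 - t0)
    env[inside] = np.sin(np.pi * phase) ** 2
    return env


def _random_mixing(n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Random full-rank spatial mixing with rows normalised so that each
    output channel keeps unit marginal variance for white unit-variance
    inputs (channels become correlated, not rescaled)."""
    m = rng.normal(size=(n_channels, n_channels)) + 2.0 * np.eye(n_channels)
    return m / np.linalg.norm(m, axis=1, keepdims=True)


def simulate_recording(params: RecordingSimParams) -> EpochSet:
    """Simulate one epoch per scheduled series.

    Noise is iid Gaussian, AR(1)-smoothed along time (variance-preserving),
    then spatially mixed. Each effect adds ``amplitude * envelope(t) *
    topography(ch)`` to trials that are deviant on the effect's label
    dimension. Deterministic given ``params.seed``.
    """
    w0, w1 = params.epoch_window_ms
    n_samples_f = (w1 - w0) / 1000.0 * params.sfreq
    n_samples = int(round(n_samples_f))
    if abs(n_samples_f - n_samples) > 1e-6:
        raise ValueError(
            f"epoch window {params.epoch_window_ms} ms is not an integer number "
            f"of samples at sfreq={params.sfreq}")
    times = w0 / 1000.0 + np.arange(n_samples) / params.sfreq
    n_ch = params.head.n_channels
    sched = params.schedule.series
    n_trials = len(sched)

    rng = np.random.default_rng(params.seed)
    eps = rng.normal(size=(n_trials, n_ch, n_samples))
    a = params.ar_coef
    if a > 0:
        # variance-preserving AR(1) along the time axis
        eps = signal.lfilter([np.sqrt(1 - a**2)], [1.0, -a], eps, axis=-1)
    mixing = params.spatial_mixing
    if mixing is None:
        mixing = _random_mixing(n_ch, np.random.default_rng(child_seed(params.seed, "mixing")))
    data = params.noise_sd * np.einsum("ij,tjs->tis", mixing, eps)

    glabels = sched["global_label"].to_numpy(dtype="U16")
    llabels = sched["local_label"].to_numpy(dtype="U16")
    for eff in params.effects:
        env = _half_cosine_envelope(times, eff.window_ms)
        topo = params.head.topographies[eff.topography_index]
        labels = glabels if eff.component == "global" else llabels
        mask = labels == DEVIANT
        data[mask] += eff.amplitude_uv * topo[:, None] * env[None, :]

    return EpochSet(
        data=data, times=times, sfreq=params.sfreq,
        labels_global=glabels, labels_local=llabels,
        block=sched["block"].to_numpy(), chan_pos=params.head.positions,
        log=[f"simulate_recording(seed={params.seed}, noise_sd={params.noise_sd}, "
             f"ar={params.ar_coef})"],
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def default_outcome_rule(amplitude_uv: np.ndarray, rng: np.random.Generator
                         ) -> np.ndarray:
    """Default mapping from global-effect amplitude to CPC outcome: the
    probability of a favourable outcome (CPC 1-2) increases logistically
    with amplitude; within each arm the CPC value is drawn uniformly."""
    p_fav = 1.0 / (1.0 + np.exp(-(amplitude_uv - 4.0) / 1.5))
    fav = rng.uniform(size=len(amplitude_uv)) < p_fav
    cpc = np.where(fav, rng.integers(1, 3, size=len(amplitude_uv)),
                   rng.integers(3, 6, size=len(amplitude_uv)))
    return cpc


@dataclass
class CohortSimParams:
    """Generative links between the cohort covariates and the per-recording
    global effect amplitude.

    amplitude_i = base + effect_vs_four_slope * FOUR_i
                  + sum_a sedation_effects[a] * rate_ai + N(0, amplitude_noise_sd),
    truncated at 0. None of these links is prescribed by the study protocol
    (they are the thing the cohort statistics are meant to recover); all are
    explicit configuration, linear by default.
    """

    n_patients: int = 30
    base_amplitude_uv: float = 1.0
    effect_vs_four_slope: float = 0.5           # microvolts per FOUR point
    four_range: tuple[int, int] = (0, 16)
    sedation_effects: Mapping[str, float] = field(
        default_factory=lambda: {"propofol": 0.0, "fentanyl": 0.0, "midazolam": 0.0})
    amplitude_noise_sd: float = 0.5
    outcome_rule: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None
    day: int = 1
    seed: int = 0
    # recording geometry (scaled down by default so a 30-recording cohort is
    # cheap to decode end to end)
    n_channels: int = 16
    sfreq: float = 120.0
    n_standard: int = 120
    n_deviant: int = 24
    noise_sd: float = 5.0
    ar_coef: float = 0.3

    def __post_init__(self) -> None:
        lo, hi = self.four_range
        if not (0 <= lo <= hi <= 16):
            raise ValueError("four_range must lie within [0, 16]")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if any(not np.isfinite(v) for v in self.sedation_effects.values()):
            raise ValueError("sedation effects must be finite")


#: typical infusion-rate scales per agent (gamma-distributed draws):
#: propofol mg/kg/h, fentanyl ug/kg/h, midazolam mg/kg/h
_SEDATION_SCALES = {"propofol": 1.0, "fentanyl": 0.5, "midazolam": 0.05}


def simulate_cohort(params: CohortSimParams,
                    make_recordings: bool = True
                    ) -> tuple[pd.DataFrame, list[EpochSet]]:
    """Draw a synthetic cohort table and (optionally) one simulated recording
    per patient, mutually consistent and deterministic given ``params.seed``.

    The returned table has one row per recording with the true simulated
    amplitude in ``amplitude_uv``; the ``auc``/``significant`` columns are
    left NaN/empty for the decoding stage to fill.
    """
    rng = np.random.default_rng(child_seed(params.seed, "cohort"))
    n = params.n_patients
    lo, hi = params.four_range
    four = rng.integers(lo, hi + 1, size=n)
    rates = {agent: rng.gamma(2.0, _SEDATION_SCALES.get(agent, 1.0), size=n)
             for agent in params.sedation_effects}
    amp = (params.base_amplitude_uv
           + params.effect_vs_four_slope * four.astype(float)
           + sum(coef * rates[a] for a, coef in params.sedation_effects.items())
           + rng.normal(0, params.amplitude_noise_sd, size=n))
    amp = np.clip(amp, 0.0, None)
    rule = params.outcome_rule or default_outcome_rule
    cpc = np.asarray(rule(amp, rng), dtype=int)
    if np.any((cpc < 1) | (cpc > 5)):
        raise ValueError("outcome rule produced CPC values outside 1..5")
    table = pd.DataFrame({
        "id": [f"rec{i:03d}" for i in range(n)],
        "day": params.day,
        "auc": np.nan,
        "significant": pd.array([None] * n, dtype="boolean"),
        "four": four,
        "cpc": cpc,
        "outcome": np.where(cpc <= 2, "favourable", "unfavourable"),
        **{agent: rates[agent] for agent in sorted(rates)},
        "temperature": np.clip(rng.normal(36.0, 0.5, size=n), 33.0, 37.5),
        "age": rng.integers(50, 63, size=n),
        "sex": rng.choice(["F", "M"], size=n),
        "amplitude_uv": amp,
    })

    recordings: list[EpochSet] = []
    if make_recordings:
        head = HeadModel.random(params.n_channels, n_components=2,
                                seed=child_seed(params.seed, "head"))
        for i in range(n):
            sched = single_block_schedule(child_seed(params.seed, "sched", i),
                                          params.n_standard, params.n_deviant)
            rec = simulate_recording(RecordingSimParams(
                schedule=sched, head=head,
                effects=[EffectSpec("global", DEFAULT_GLOBAL_WINDOW_MS, float(amp[i]), 0),
                         EffectSpec("local", DEFAULT_LOCAL_WINDOW_MS, 1.0, 1)],
                noise_sd=params.noise_sd, ar_coef=params.ar_coef,
                sfreq=params.sfreq, seed=child_seed(params.seed, "rec", i)))
            recordings.append(rec)
    return table, recordings


def single_block_schedule(seed: int, n_standard: int, n_deviant: int) -> StimulusSchedule:
    """Reduced one-repetition schedule used for scaled-down simulations."""
    sched = build_session(seed, n_standard=n_standard, n_deviant=n_deviant, n_reps=1)
    first = sched.series[sched.series["block"] == 1].reset_index(drop=True)
    return StimulusSchedule(series=first, soa_ms=sched.soa_ms,
                            iti_range_ms=sched.iti_range_ms, seed=seed,
                            blocks=sched.blocks[:1])
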