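"""Presynaptic input generation for the LSO model.

Excitatory fibers (spherical bushy cells) and inhibitory fibers (MNTB
neurons) are modeled as mutually independent Poisson processes.  For
unmodulated tones the process is homogeneous with a sigmoidal
level-dependent intensity λ(SPL); for amplitude-modulated (AM) tones it is
inhomogeneous, with a von Mises density (concentration κ set by the target
vector strength) as the per-cycle intensity profile.

All times are in milliseconds, rates in spikes/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.special import i0e, i1e

__all__ = [
    "RateModel",
    "PhaseLockedSpec",
    "ToneStimulus",
    "AMStimulus",
    "StimulusSpec",
    "SpikeTrainSet",
    "rate_from_spl",
    "am_rate_and_vs",
    "kappa_from_vs",
    "homogeneous_poisson",
    "phase_locked_poisson",
    "make_spike_trains",
    "vector_strength",
    "IPSI_SPL_DEFAULT",
]

#: Ipsilateral sound pressure level used in all level-tuning simulations.
IPSI_SPL_DEFAULT = 35.0


@dataclass(frozen=True)
class RateModel:
    """Input-rate and phase-locking functions of the afferent fibers.

    ``rate_from_spl`` is the sigmoidal level-dependent intensity of a fiber
    driven by an unmodulated tone; ``am_rate_and_vs`` gives the mean
    intensity and vector strength of a fiber driven by an AM tone with
    modulation frequency ``f_m``.
    """

    spl_offset: float = 20.0      # dB, sigmoid midpoint
    spl_slope: float = 6.0        # dB, sigmoid slope constant
    spl_floor: float = 30.0       # spikes/s, spontaneous floor
    spl_span: float = 240.0       # spikes/s, dynamic range
    am_base: float = 180.0        # spikes/s at f_m -> 0
    am_slope: float = 0.03        # spikes/s per Hz
    vs_max: float = 0.65          # asymptotic vector strength
    vs_knee: float = 2000.0       # Hz, VS vanishes here
    vs_scale: float = 500.0       # Hz

    def rate_from_spl(self, spl: float) -> float:
        if not np.isfinite(spl):
            raise ValueError(f"SPL must be finite, got {spl!r}")
        # logistic written via expit for overflow safety at extreme levels
        return self.spl_floor + self.spl_span * float(
            expit((spl - self.spl_offset) / self.spl_slope)
        )

    def am_rate_and_vs(self, f_m: float) -> tuple[float, float]:
        if not 0.0 <= f_m < self.vs_knee:
            raise ValueError(
                f"modulation frequency must be in [0, {self.vs_knee}) Hz, got {f_m}"
            )
        rate = self.am_base - self.am_slope * f_m
        x = (f_m - self.vs_knee) / self.vs_scale
        # (1 - e^x)/(1 + e^x) == tanh(-x/2), stable for all x
        vs = self.vs_max * math.tanh(-x / 2.0)
        return rate, vs


_DEFAULT_RATE_MODEL = RateModel()


def rate_from_spl(spl: float, model: RateModel = _DEFAULT_RATE_MODEL) -> float:
    """Fiber firing rate (spikes/s) for an unmodulated tone at ``spl`` dB."""
    return model.rate_from_spl(spl)


def am_rate_and_vs(
    f_m: float, model: RateModel = _DEFAULT_RATE_MODEL
) -> tuple[float, float]:
    """Mean rate (spikes/s) and vector strength of a fiber for an AM tone."""
    return model.am_rate_and_vs(f_m)


@lru_cache(maxsize=256)
def kappa_from_vs(vs: float) -> float:
    """Von Mises concentration κ whose mean resultant equals ``vs``.

    Inverts VS = I1(κ)/I0(κ) (ratio of modified Bessel functions) by
    bracketed root finding, to 1e-10 relative tolerance.
    """
    if not 0.0 <= vs < 1.0:
        raise ValueError(f"vector strength must be in [0, 1), got {vs}")
    if vs == 0.0:
        return 0.0

    def f(k: float) -> float:
        return i1e(k) / i0e(k) - vs

    hi = 2.0
    while f(hi) < 0.0:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - vs < 1 guarantees a bracket
            raise RuntimeError("failed to bracket kappa")
    return brentq(f, 0.0, hi, rtol=1e-12, xtol=1e-12)


@dataclass(frozen=True)
class PhaseLockedSpec:
    """One phase-locked fiber: mean rate, vector strength, f_m, locking phase."""

    mean_rate: float            # spikes/s, cycle-averaged
    vector_strength: float      # in [0, 1)
    mod_freq: float             # Hz
    locking_phase: float        # degrees in [-180, 180)

    def __post_init__(self) -> None:
        if self.mean_rate < 0:
            raise ValueError("mean_rate must be >= 0")
        if not 0.0 <= self.vector_strength < 1.0:
            raise ValueError("vector_strength must be in [0, 1)")
        if self.mod_freq <= 0:
            raise ValueError("mod_freq must be > 0")


@dataclass(frozen=True)
class ToneStimulus:
    """Binaural unmodulated tone; ipsilateral level fixed, contralateral = ipsi + ILD."""

    ild: float                  # dB, contralateral minus ipsilateral level
    ipsi_spl: float = IPSI_SPL_DEFAULT
    duration_ms: float = 500.0

    @property
    def contra_spl(self) -> float:
        return self.ipsi_spl + self.ild


@dataclass(frozen=True)
class AMStimulus:
    """Binaural AM tone with an interaural envelope phase difference.

    Positive ``phase_diff_deg`` means the inhibitory (contralateral) inputs
    arrive earlier than the excitatory (ipsilateral) inputs.
    """

    phase_diff_deg: float
    mod_freq: float = 300.0     # Hz
    duration_ms: float = 500.0


StimulusSpec = Union[ToneStimulus, AMStimulus]


@dataclass
class SpikeTrainSet:
    """Per-fiber presynaptic spike times for one trial."""

    excitatory: List[np.ndarray]
    inhibitory: List[np.ndarray]
    duration: float             # ms
    stimulus: StimulusSpec | None = field(default=None, compare=False)

    def to_text(self) -> str:
        """Two-column dump (fiber_id, time_ms); inhibitory fibers are offset
        by 1000 in fiber_id.  Debugging aid, not a pipeline format."""
        lines = []
        for m, t in enumerate(self.excitatory):
            lines.extend(f"{m}\t{x:.6f}" for x in t)
        for m, t in enumerate(self.inhibitory):
            lines.extend(f"{1000 + m}\t{x:.6f}" for x in t)
        return "\n".join(lines)


def homogeneous_poisson(
    rate: float, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson spike train on [0, duration) via exponential
    inter-event sampling."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if rate == 0:
        return np.empty(0)
    scale = 1000.0 / rate  # mean inter-event interval in ms
    expected = duration / scale
    block = max(16, int(expected + 4.0 * math.sqrt(expected) + 8))
    times = np.cumsum(rng.exponential(scale, size=block))
    while times[-1] < duration:
        more = np.cumsum(rng.exponential(scale, size=block)) + times[-1]
        times = np.concatenate([times, more])
    return times[times < duration]


def phase_locked_poisson(
    spec: PhaseLockedSpec, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous Poisson train with von Mises intensity profile.

    The intensity is λ(t) = mean_rate · 2π · vM(2π f t/1000 − φ; κ), i.e. the
    von Mises density scaled so the cycle-averaged rate equals ``mean_rate``.
    Sampling is by thinning a homogeneous envelope at the intensity peak,
    which is exact for bounded intensity functions.
    """
    kappa = kappa_from_vs(spec.vector_strength)
    if kappa == 0.0:
        return homogeneous_poisson(spec.mean_rate, duration, rng)
    # peak-to-mean intensity ratio of a von Mises profile: e^kappa / I0(kappa)
    peak_factor = 1.0 / i0e(kappa)
    lam_max = spec.mean_rate * peak_factor
    cand = homogeneous_poisson(lam_max, duration, rng)
    if cand.size == 0:
        return cand
    phi = math.radians(spec.locking_phase)
    theta = 2.0 * math.pi * spec.mod_freq * cand / 1000.0 - phi
    accept_p = np.exp(kappa * (np.cos(theta) - 1.0))
    keep = rng.random(cand.size) < accept_p
    return cand[keep]


def make_spike_trains(
    stim: StimulusSpec,
    m_ex: int,
    m_inh: int,
    rng: np.random.Generator,
    rate_model: RateModel = _DEFAULT_RATE_MODEL,
) -> SpikeTrainSet:
    """Generate the full presynaptic ensemble for one trial.

    Unmodulated tones: excitatory fibers fire at λ(ipsi SPL) and inhibitory
    fibers at λ(ipsi SPL + ILD), both homogeneous.  AM tones: both pathways
    share λ(f_m) and VS(f_m); the excitatory ensemble locks to phase 0 and
    the inhibitory ensemble to −Δφ, so positive Δφ makes inhibition lead.

    Each fiber draws from its own child stream spawned from ``rng``
    (excitatory fibers first), so fibers are mutually independent.
    """
    if not isinstance(stim, (ToneStimulus, AMStimulus)):
        raise TypeError(f"unknown stimulus kind: {type(stim).__name__}")
    streams = rng.spawn(m_ex + m_inh)
    T = stim.duration_ms
    if isinstance(stim, ToneStimulus):
        lam_ex = rate_model.rate_from_spl(stim.ipsi_spl)
        lam_inh = rate_model.rate_from_spl(stim.contra_spl)
        ex = [homogeneous_poisson(lam_ex, T, streams[m]) for m in range(m_ex)]
        inh = [
            homogeneous_poisson(lam_inh, T, streams[m_ex + m])
            for m in range(m_inh)
        ]
    elif isinstance(stim, AMStimulus):
        rate, vs = rate_model.am_rate_and_vs(stim.mod_freq)
        phi_inh = -stim.phase_diff_deg
        phi_inh = (phi_inh + 180.0) % 360.0 - 180.0
        ex_spec = PhaseLockedSpec(rate, vs, stim.mod_freq, 0.0)
        inh_spec = PhaseLockedSpec(rate, vs, stim.mod_freq, phi_inh)
        ex = [phase_locked_poisson(ex_spec, T, streams[m]) for m in range(m_ex)]
        inh = [
            phase_locked_poisson(inh_spec, T, streams[m_ex + m])
            for m in range(m_inh)
        ]
    else:
        raise TypeError(f"unknown stimulus kind: {type(stim).__name__}")
    return SpikeTrainSet(excitatory=ex, inhibitory=inh, duration=T, stimulus=stim)


def vector_strength(
    spike_times: np.ndarray, freq_hz: float
) -> tuple[float, float]:
    """Measured vector strength and circular-mean phase (degrees) of spikes
    relative to a ``freq_hz`` cycle.  Standard resultant-length estimator."""
    if spike_times.size == 0:
        return 0.0, 0.0
    theta = 2.0 * np.pi * freq_hz * np.asarray(spike_times) / 1000.0
    z = np.exp(1j * theta).mean()
    return float(abs(z)), float(math.degrees(math.atan2(z.imag, z.real)))
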