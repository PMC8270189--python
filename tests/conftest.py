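"""Shared fixtures: cached trial ensembles reused across the suite.

The heavy Monte-Carlo ensembles (ILD and phase tuning at several
inhibitory-input counts) are computed once per session and shared by the
property tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lsosim as L

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEED = 4242
DURATION = 500.0

#: trials per grid point for the scaled-down stochastic suites; the
#: midpoint checks use 500, the level/phase discriminability sweeps
#: 250/200 (see docs/methods.md).
N_TRIALS_MIDPOINT = 500
N_TRIALS_SWEEP = 250
N_TRIALS_PHASE = 200


def _scenario_seed(tag: int) -> int:
    ss = np.random.SeedSequence(entropy=(SEED, 97, tag))
    return int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)


@pytest.fixture(scope="session")
def ild_curves() -> dict[int, L.TuningCurve]:
    """Uncompensated ILD-tuning ensembles, active model, 31-point grid."""
    out: dict[int, L.TuningCurve] = {}
    for m in (4, 8):
        out[m] = L.run_tuning(
            L.ild_grid(), L.ScenarioSpec(m_inh=m),
            n_trials=N_TRIALS_MIDPOINT, seed=_scenario_seed(m),
        )
    for m in (6, 12, 16):
        out[m] = L.run_tuning(
            L.ild_grid(), L.ScenarioSpec(m_inh=m),
            n_trials=N_TRIALS_SWEEP, seed=_scenario_seed(m),
        )
    return out


@pytest.fixture(scope="session")
def phase_curves() -> dict[int, L.TuningCurve]:
    """Phase-tuning ensembles at 300 Hz: default plus compensated loss."""
    out: dict[int, L.TuningCurve] = {}
    for m, mode in ((8, "uncompensated"), (6, "compensated"), (4, "compensated")):
        out[m] = L.run_tuning(
            L.phase_grid(300.0), L.ScenarioSpec(m_inh=m, mode=mode),
            n_trials=N_TRIALS_PHASE, seed=_scenario_seed(50 + m),
        )
    return out


@pytest.fixture(scope="session")
def flat_curve_no_inhibition() -> L.TuningCurve:
    """ILD curve with every inhibitory fiber removed (m_inh = 0)."""
    grid = L.ild_grid(start=-40.0, stop=0.0, step=10.0)
    return L.run_tuning(
        grid, L.ScenarioSpec(m_inh=0), n_trials=200, seed=_scenario_seed(70)
    )


def _ratio_with_se(
    curve: L.TuningCurve,
    ref: L.TuningCurve,
    rng: tuple[float, float],
    n_blocks: int = 10,
) -> tuple[float, float]:
    num = L.summarize_discriminability(L.discriminability(curve), rng)
    den = L.summarize_discriminability(L.discriminability(ref), rng)
    bn = L.block_discriminability_summaries(curve, rng, n_blocks)
    bd = L.block_discriminability_summaries(ref, rng, n_blocks)
    se_n = bn.std(ddof=1) / np.sqrt(n_blocks)
    se_d = bd.std(ddof=1) / np.sqrt(n_blocks)
    r = num / den
    se = r * np.sqrt((se_n / num) ** 2 + (se_d / den) ** 2)
    return r, se


@pytest.fixture(scope="session")
def ratio_with_se():
    """Normalized averaged |D| of one ensemble against a reference, with a
    standard error combining block-wise SEs of numerator and denominator in
    quadrature (the two ensembles come from independent streams)."""
    return _ratio_with_se
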