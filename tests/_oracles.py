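"""Independent oracles used by the test suite.

The microsimulation here deliberately does NOT use the cohort engine: it
draws individual trajectories directly from the toy chain's hand-set
probabilities and accrues rewards per individual, so agreement with the
matrix-based engine is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np

WELL, CANCER, DEAD = 0, 1, 2


def microsimulate_toy(toy, n_paths: int, seed: int):
    """Simulate ``n_paths`` individuals through the toy well/cancer/dead
    chain, returning per-individual discounted costs, QALYs and an
    ever-had-cancer indicator (means + standard errors are up to the
    caller).  End-of-cycle accrual at discount factor (1+r)^-(t+1),
    matching the engine's convention."""
    rng = np.random.default_rng(seed)
    states = np.full(n_paths, WELL, dtype=np.int8)
    cost = np.zeros(n_paths)
    qaly = np.zeros(n_paths)
    had_cancer = np.zeros(n_paths, dtype=bool)

    u_state = np.array([toy.utility_well, toy.utility_cancer, 0.0])
    c_state = np.array([toy.cost_well, toy.cost_cancer, 0.0])

    for t in range(toy.horizon):
        df = (1.0 + toy.discount_rate) ** -(t + 1)
        cost += df * c_state[states]
        qaly += df * u_state[states]

        u = rng.random(n_paths)
        new = states.copy()
        well = states == WELL
        onset = well & (u < toy.p_well_cancer)
        die_well = well & (u >= toy.p_well_cancer) & (
            u < toy.p_well_cancer + toy.p_well_dead)
        new[onset] = CANCER
        new[die_well] = DEAD
        cancer = states == CANCER
        die_cancer = cancer & (u < toy.p_cancer_dead)
        new[die_cancer] = DEAD

        cost += df * toy.cost_onset * onset
        cost += df * toy.cost_palliative * die_cancer
        had_cancer |= onset
        states = new

    return cost, qaly, had_cancer
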