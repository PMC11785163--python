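"""Individual-level stochastic micro-simulation.

An independent oracle for the expected-value cohort engine: each person is
simulated through the same event order (status-specific death first, then
behaviour transitions among survivors) with Bernoulli draws.  State shares
should agree with the deterministic engine to Monte-Carlo error.
"""

import numpy as np

NEVER, CURRENT, FORMER, DEAD = 0, 1, 2, 3


def microsim_shares(
    ps,
    cal,
    gender,
    n_persons: int,
    n_cycles: int,
    seed: int,
    start_multiplier: float = 1.0,
):
    """Simulate ``n_persons`` 15-year-old never smokers for ``n_cycles``
    half-year cycles; returns (n_cycles + 1, 4) array of state shares."""
    rng = np.random.default_rng(seed)
    a0 = ps.start_age
    start = ps.transitions.start[gender].array(a0, ps.max_age) * start_multiplier
    quit_ = ps.transitions.quit[gender].array(a0, ps.max_age)
    relapse = ps.transitions.relapse[gender].array(a0, ps.max_age)
    death = cal.death[gender]  # (3, n_ages)

    state = np.zeros(n_persons, dtype=np.int8)
    shares = np.zeros((n_cycles + 1, 4))
    shares[0] = np.bincount(state, minlength=4) / n_persons
    for k in range(n_cycles):
        a = k // 2
        alive = state != DEAD
        u = rng.random(n_persons)
        p_death = np.zeros(n_persons)
        for s in (NEVER, CURRENT, FORMER):
            p_death[state == s] = death[s, a]
        dies = alive & (u < p_death)
        state[dies] = DEAD
        u2 = rng.random(n_persons)
        surv = state != DEAD
        starts = surv & (state == NEVER) & (u2 < start[a])
        quits = surv & (state == CURRENT) & (u2 < quit_[a])
        relapses = surv & (state == FORMER) & (u2 < relapse[a])
        state[starts] = CURRENT
        state[quits] = FORMER
        state[relapses] = CURRENT
        shares[k + 1] = np.bincount(state, minlength=4) / n_persons
    return shares
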