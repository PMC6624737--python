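"""Independent stochastic oracle: single-molecule carbon tracking.

Simulates the fate of individual labeled carbon atoms through the pathway
routing rules by drawing each branching event per molecule, without any of
the deterministic recursion used by the package.  Used to cross-check the
carbon-fate model's release fractions to binomial precision.
"""

from __future__ import annotations

import numpy as np

GLYC_MAP = {1: 3, 2: 2, 3: 1, 4: 1, 5: 2, 6: 3}


def mc_tca_release(entry: str, a_tca: float, n: int,
                   rng: np.random.Generator, max_turns: int = 400) -> float:
    """Fraction of n molecules entering the cycle (as acetyl 'carboxyl' or
    'methyl' carbon) that are released as CO2.

    Per turn: every molecule still cycling (including the one entering this
    turn) is diverted with probability a_tca; surviving molecules sitting at
    a carboxyl position are released; survivors then move on — entering
    carboxyl carbon to a carboxyl position, entering methyl carbon to an
    inner position, and inner carbon to a carboxyl position with probability
    1/2 (succinate-stage scrambling).
    """
    ENT_C, ENT_M, CARB, INNER = 0, 1, 2, 3
    state = np.full(n, ENT_C if entry == "carboxyl" else ENT_M, dtype=np.int8)
    released = 0
    for _ in range(max_turns):
        if state.size == 0:
            break
        keep = rng.random(state.size) >= a_tca
        state = state[keep]
        at_carb = state == CARB
        released += int(at_carb.sum())
        state = state[~at_carb]
        promote = np.where(
            state == INNER,
            np.where(rng.random(state.size) < 0.5, CARB, INNER),
            np.where(state == ENT_C, CARB, INNER),
        ).astype(np.int8)
        state = promote
    return released / n


def mc_position_release(substrate: str, position: int, params, n: int,
                        rng: np.random.Generator) -> float:
    """Monte-Carlo released fraction for one labeled position of glucose,
    pyruvate, or acetate under the given partition parameters."""
    alive = np.ones(n, dtype=bool)
    released = np.zeros(n, dtype=bool)

    if substrate == "glucose":
        via_ppp = rng.random(n) < params.phi_ppp
        if position == 1:
            released |= via_ppp  # oxidative-PPP decarboxylation
            alive &= ~via_ppp
        else:
            pent_kept = via_ppp & (rng.random(n) < params.a_pent)
            alive &= ~pent_kept
        pyr_pos = GLYC_MAP[position]
    elif substrate == "pyruvate":
        pyr_pos = position
    elif substrate == "acetate":
        pyr_pos = None
    else:
        raise ValueError(substrate)

    if pyr_pos is not None:
        kept = alive & (rng.random(n) < params.a_pyr)
        alive &= ~kept
        if pyr_pos == 1:
            released |= alive
            return released.mean()
        acetyl_entry = "carboxyl" if pyr_pos == 2 else "methyl"
    else:
        acetyl_entry = "carboxyl" if position == 1 else "methyl"

    kept = alive & (rng.random(n) < params.a_ac)
    alive &= ~kept
    n_cycle = int(alive.sum())
    if n_cycle:
        frac = mc_tca_release(acetyl_entry, params.a_tca, n_cycle, rng)
        # assign release uniformly among cycling molecules
        idx = np.flatnonzero(alive)[: int(round(frac * n_cycle))]
        released[idx] = True
    return released.mean()
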