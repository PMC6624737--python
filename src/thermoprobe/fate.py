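"""Positional carbon-fate model for central carbon metabolism.

Predicts, for each labeled carbon position of glucose, pyruvate, or acetate,
the fraction of label ultimately released as ¹³CO₂ versus retained in biomass
or fermentation products, under a small set of pathway-partitioning
parameters:

* glucose either enters the oxidative pentose phosphate branch (``phi_ppp``),
  where C1 is decarboxylated immediately and a fraction ``a_pent`` of the
  remaining pentose carbon is retained for biosynthesis, or proceeds through
  glycolysis, splitting into two pyruvates (glucose C1–C3 and C6–C4 map to
  pyruvate C3–C1 of the two halves);
* a fraction ``a_pyr`` of pyruvate is diverted whole (anabolism) before the
  pyruvate dehydrogenase / pyruvate-ferredoxin oxidoreductase step releases
  pyruvate C1 and hands C2/C3 to the acetyl pool as carboxyl/methyl carbon;
* a fraction ``a_ac`` of acetyl carbon is diverted (anabolism or accumulated
  fermentation product — deliberately conflated, since unconsumed
  fermentation products are indistinguishable from biomass retention in CO₂
  data);
* the remainder enters the TCA cycle, where each turn diverts a fraction
  ``a_tca`` of cycle carbon, releases the two carboxyl positions of the
  four-carbon acceptor pool as CO₂, and scrambles the surviving inner carbon
  symmetrically over the next turn's positions (succinate-stage symmetry).

With every parameter at zero the model reduces to complete catabolic
oxidation: all label from every position is eventually released, acetyl
carboxyl carbon first appears as CO₂ on the second cycle, and acetyl methyl
carbon (and glycolytic glucose C1) first appears on the third cycle, losing
half of what remains on each subsequent cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from functools import lru_cache
from itertools import product

import numpy as np
from scipy import optimize

_PARAM_NAMES = ("phi_ppp", "a_pent", "a_pyr", "a_ac", "a_tca")

#: glucose position -> pyruvate position under the glycolytic split
GLYCOLYTIC_MAP = {1: 3, 2: 2, 3: 1, 4: 1, 5: 2, 6: 3}

#: fixed pair orientations: (numerator isotopomer, denominator isotopomer)
PAIR_NAMES = ("glucose", "pyruvate", "acetate")

CATABOLIC_RATIOS = {"glucose": 6.0, "pyruvate": 0.5, "acetate": 1.0}


class UnsupportedSubstrateError(ValueError):
    pass


class UndefinedRatioError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class SubstrateIsotopomer:
    """A substrate labeled with ¹³C at specific carbon positions."""

    substrate: str
    labeled_positions: frozenset
    n_carbons: int
    label_purity: float = 0.99

    def __post_init__(self):
        object.__setattr__(self, "labeled_positions", frozenset(self.labeled_positions))
        if not self.labeled_positions <= set(range(1, self.n_carbons + 1)):
            raise ValueError("labeled positions outside the carbon skeleton")
        if not 0 < self.label_purity <= 1:
            raise ValueError("label purity must lie in (0, 1]")


def glucose(positions) -> SubstrateIsotopomer:
    return SubstrateIsotopomer("glucose", frozenset(positions), 6)


def pyruvate(positions) -> SubstrateIsotopomer:
    return SubstrateIsotopomer("pyruvate", frozenset(positions), 3)


def acetate(positions) -> SubstrateIsotopomer:
    return SubstrateIsotopomer("acetate", frozenset(positions), 2)


PAIRS = {
    "glucose": (glucose(range(1, 7)), glucose([1])),  # U : 1
    "pyruvate": (pyruvate([1]), pyruvate([2, 3])),  # 1 : 2,3
    "acetate": (acetate([1]), acetate([2])),  # 1 : 2
}


@dataclass(frozen=True)
class FluxParameters:
    """Diversion/partition fractions of the carbon-fate forward model.

    All fields are fractions in [0, 1]; zeros everywhere mean complete
    catabolic oxidation.
    """

    phi_ppp: float = 0.0
    a_pent: float = 0.0
    a_pyr: float = 0.0
    a_ac: float = 0.0
    a_tca: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _PARAM_NAMES])


@dataclass
class OaaLabelState:
    """Label amounts on the four-carbon acceptor pool.

    ``c1``/``c4`` are the two carboxyl positions (released as CO₂ each turn),
    ``i2``/``i3`` the two inner positions (scrambled symmetrically at the
    succinate stage).
    """

    c1: float = 0.0
    i2: float = 0.0
    i3: float = 0.0
    c4: float = 0.0

    @property
    def total(self) -> float:
        return self.c1 + self.i2 + self.i3 + self.c4


def tca_turn(state: OaaLabelState, acetyl_carboxyl: float, acetyl_methyl: float,
             a_tca: float):
    """Advance the acceptor-pool label state by one TCA turn.

    Within a turn, in order: (1) a fraction ``a_tca`` of all cycle carbon —
    the resident pool and the acetyl unit entering this turn — is diverted to
    anabolism; (2) the surviving carboxyl positions are released as CO₂;
    (3) surviving inner carbon and the incoming acetyl unit are redistributed
    symmetrically, acetyl carboxyl feeding the new carboxyl positions and
    acetyl methyl the new inner positions, with half of the old inner carbon
    promoted to carboxyl positions (succinate scrambling).

    Returns ``(new_state, co2_released, diverted)``.  Label is conserved:
    ``co2_released + diverted + new_state.total == state.total + inputs``.
    """
    if min(state.c1, state.i2, state.i3, state.c4, acetyl_carboxyl,
           acetyl_methyl) < 0:
        raise ValueError("label amounts must be nonnegative")
    if not 0.0 <= a_tca <= 1.0:
        raise ValueError("a_tca outside [0, 1]")
    keep = 1.0 - a_tca
    diverted = a_tca * (state.total + acetyl_carboxyl + acetyl_methyl)
    c1, i2, i3, c4 = keep * state.c1, keep * state.i2, keep * state.i3, keep * state.c4
    ac_c, ac_m = keep * acetyl_carboxyl, keep * acetyl_methyl
    co2_released = c1 + c4
    inner_half = (i2 + i3) / 2.0
    new_c = 0.5 * (ac_c + inner_half)
    new_i = 0.5 * (ac_m + inner_half)
    return OaaLabelState(c1=new_c, i2=new_i, i3=new_i, c4=new_c), co2_released, diverted


@dataclass
class ReleaseSchedule:
    """Cumulative fate of a unit label pulse entering the TCA cycle."""

    released: float
    retained: float
    residual: float
    per_turn: list = field(repr=False, default_factory=list)
    truncated: bool = False

    @property
    def first_release_turn(self):
        """1-based index of the first turn with nonzero CO₂ release."""
        for i, r in enumerate(self.per_turn, start=1):
            if r > 0:
                return i
        return None


def tca_release_schedule(acetyl_carboxyl: float = 0.0, acetyl_methyl: float = 0.0,
                         a_tca: float = 0.0, tol: float = 1e-9,
                         max_turns: int = 10_000) -> ReleaseSchedule:
    """Iterate :func:`tca_turn` on a single acetyl pulse until the residual
    cycling label falls below ``tol`` or ``max_turns`` is reached.

    With ``a_tca = 0`` the full pulse is eventually released (carboxyl on
    turn 2, methyl starting on turn 3 at half the remainder per turn).
    """
    state = OaaLabelState()
    released = retained = 0.0
    per_turn = []
    truncated = True
    for turn in range(1, max_turns + 1):
        ac_c = acetyl_carboxyl if turn == 1 else 0.0
        ac_m = acetyl_methyl if turn == 1 else 0.0
        state, co2, div = tca_turn(state, ac_c, ac_m, a_tca)
        released += co2
        retained += div
        per_turn.append(co2)
        if state.total < tol:
            truncated = False
            break
    return ReleaseSchedule(released=released, retained=retained,
                           residual=state.total, per_turn=per_turn,
                           truncated=truncated)


# -- per-position release fractions ----------------------------------------

@lru_cache(maxsize=8192)
def _schedule_cached(acetyl_carboxyl: float, acetyl_methyl: float,
                     a_tca: float, tol: float, max_turns: int):
    s = tca_release_schedule(acetyl_carboxyl, acetyl_methyl, a_tca, tol,
                             max_turns)
    return s.released, s.residual


def _acetyl_fates(a_ac: float, a_tca: float, tol=1e-9, max_turns=10_000):
    """(released, residual) for acetyl carboxyl and methyl label after the
    acetyl-pool diversion ``a_ac`` and the cycle schedule."""
    keep = 1.0 - a_ac
    carb = _schedule_cached(1.0, 0.0, a_tca, tol, max_turns)
    meth = _schedule_cached(0.0, 1.0, a_tca, tol, max_turns)
    return ((keep * carb[0], keep * carb[1]),
            (keep * meth[0], keep * meth[1]))


def _pyruvate_releases(params: FluxParameters, tol=1e-9, max_turns=10_000):
    """(released, residual) per pyruvate position {1, 2, 3}."""
    keep = 1.0 - params.a_pyr
    (carb_rel, carb_res), (meth_rel, meth_res) = _acetyl_fates(
        params.a_ac, params.a_tca, tol, max_turns)
    return {
        1: (keep * 1.0, 0.0),  # PDH / PFOR decarboxylation
        2: (keep * carb_rel, keep * carb_res),
        3: (keep * meth_rel, keep * meth_res),
    }


@dataclass
class PositionFate:
    released: float
    retained: float
    residual: float


@dataclass
class FatePrediction:
    """Per-position label fate and the implied ¹³CO₂ production rate
    (released label per mole substrate per unit uptake)."""

    isotopomer: SubstrateIsotopomer
    positions: dict
    co2_rate: float

    @property
    def released(self) -> dict:
        return {p: f.released for p, f in self.positions.items()}


def predict_fates(isotopomer: SubstrateIsotopomer, params: FluxParameters,
                  tol: float = 1e-9, max_turns: int = 10_000) -> FatePrediction:
    """Forward-run the carbon-fate model for one substrate isotopomer.

    Returns released/retained/residual fractions for every labeled position
    (summing to 1) and the total CO₂ production rate per mole of substrate,
    weighted by label purity.
    """
    pyr = _pyruvate_releases(params, tol, max_turns)
    sub = isotopomer.substrate
    positions = {}
    if sub == "pyruvate":
        for pos in sorted(isotopomer.labeled_positions):
            rel, res = pyr[pos]
            positions[pos] = PositionFate(rel, 1.0 - rel - res, res)
    elif sub == "acetate":
        (carb_rel, carb_res), (meth_rel, meth_res) = _acetyl_fates(
            params.a_ac, params.a_tca, tol, max_turns)
        table = {1: (carb_rel, carb_res), 2: (meth_rel, meth_res)}
        for pos in sorted(isotopomer.labeled_positions):
            rel, res = table[pos]
            positions[pos] = PositionFate(rel, 1.0 - rel - res, res)
    elif sub == "glucose":
        p = params.phi_ppp
        glyc_weight = {pos: (1.0 - p) + (p * (1.0 - params.a_pent) if pos != 1 else 0.0)
                       for pos in range(1, 7)}
        for pos in sorted(isotopomer.labeled_positions):
            g = glyc_weight[pos]
            rel_p, res_p = pyr[GLYCOLYTIC_MAP[pos]]
            rel = g * rel_p
            res = g * res_p
            if pos == 1:
                rel += p  # immediate oxidative-PPP decarboxylation
            positions[pos] = PositionFate(rel, 1.0 - rel - res, res)
    else:
        raise UnsupportedSubstrateError(f"unsupported substrate {sub!r}")
    rate = isotopomer.label_purity * sum(f.released for f in positions.values())
    return FatePrediction(isotopomer, positions, rate)


@dataclass(frozen=True)
class RatioPrediction:
    pair: str
    value: float


def theoretical_ratio(pair: str, params: FluxParameters,
                      purity: float = 0.99) -> RatioPrediction:
    """Predicted ¹³CO₂ production-rate ratio for an isotopomer pair.

    Substrates within a pair are dosed at equal substrate-carbon, hence equal
    moles; orientations are fixed: glucose U:1, pyruvate 1:(2,3),
    acetate 1:2.  Label purity applies symmetrically and cancels.
    """
    try:
        num, den = PAIRS[pair]
    except KeyError:
        raise UnsupportedSubstrateError(f"unknown pair {pair!r}") from None
    num = replace(num, label_purity=purity)
    den = replace(den, label_purity=purity)
    rate_num = predict_fates(num, params).co2_rate
    rate_den = predict_fates(den, params).co2_rate
    if rate_den == 0.0:
        raise UndefinedRatioError(f"denominator of pair {pair!r} releases no label")
    return RatioPrediction(pair, rate_num / rate_den)


# -- parameter fitting ------------------------------------------------------

DEFAULT_FREE = ("phi_ppp", "a_ac", "a_tca")


@dataclass
class FitResult:
    params: FluxParameters
    objective: float
    degenerate: frozenset
    flat: bool

    @property
    def identifiable(self) -> frozenset:
        return frozenset(self.free) - self.degenerate

    free: tuple = ()


def _objective(theta, free, observed, fixed: FluxParameters):
    kwargs = {n: getattr(fixed, n) for n in _PARAM_NAMES}
    kwargs.update(dict(zip(free, np.clip(theta, 0.0, 1.0 - 1e-9))))
    params = FluxParameters(**kwargs)
    sse = 0.0
    for pair, obs in observed.items():
        try:
            pred = theoretical_ratio(pair, params).value
        except UndefinedRatioError:
            return 1e12
        if pred <= 0 or obs <= 0:
            return 1e12
        sse += (np.log(pred) - np.log(obs)) ** 2
    return sse


def fit_flux_params(observed_ratios: dict, free=DEFAULT_FREE,
                    bounds=(0.0, 0.99), grid_step: float | None = None,
                    tie_tol: float = 1e-9) -> FitResult:
    """Fit partition parameters to observed isotopomer-pair ratios.

    Minimizes the sum of squared log-ratio residuals over a coarse Cartesian
    grid on the free parameters, refined by bounded local search from the
    best grid points.  Exact ties (within ``tie_tol``) are broken by the
    smallest L1 parameter norm — a documented response to the model's
    structural non-identifiability: a whole-substrate diversion (``a_pyr``)
    rescales both members of a pair identically, so it is excluded from the
    default free set, and flat directions that remain are reported in
    ``degenerate``.
    """
    if not observed_ratios:
        raise ValueError("at least one observed ratio is required")
    unknown = set(observed_ratios) - set(PAIRS)
    if unknown:
        raise UnsupportedSubstrateError(f"unknown pairs: {sorted(unknown)}")
    free = tuple(free)
    fixed = FluxParameters()
    lo, hi = bounds
    if grid_step is None:
        grid_step = 0.1 if len(free) <= 3 else 0.2

    grid_axis = np.arange(lo, hi + 1e-12, grid_step)
    cands = sorted(
        (( _objective(np.array(theta), free, observed_ratios, fixed), theta)
         for theta in product(grid_axis, repeat=len(free))),
        key=lambda t: t[0],
    )[:10]

    results = []
    for _, theta0 in cands:
        res = optimize.minimize(
            _objective, np.array(theta0), args=(free, observed_ratios, fixed),
            method="L-BFGS-B", bounds=[(lo, hi)] * len(free),
            options={"ftol": 1e-14, "gtol": 1e-12},
        )
        results.append((res.fun, res.x))
    best = min(r[0] for r in results)
    tied = [x for f, x in results if f <= best + tie_tol]
    theta = min(tied, key=lambda x: np.abs(x).sum())
    obj = _objective(theta, free, observed_ratios, fixed)

    degenerate, flat = _profile_degeneracy(theta, free, observed_ratios,
                                           fixed, (lo, hi), obj)
    kwargs = {n: 0.0 for n in _PARAM_NAMES}
    kwargs.update(dict(zip(free, np.clip(theta, 0.0, 1.0))))
    return FitResult(FluxParameters(**kwargs), obj, degenerate, flat, free=free)


def _profile_degeneracy(theta, free, observed, fixed, bounds, best_obj,
                        delta: float = 0.1, tol: float = 1e-7):
    """Detect unidentified parameters by profiling the objective.

    Each free parameter is pinned ``delta`` away from its estimate (either
    side that the box allows) while the remaining parameters are
    re-optimized.  If the pinned fit matches the unconstrained optimum, the
    data do not pin the parameter at the ``delta`` scale — it sits on a flat
    direction or an exact ridge (e.g. phi_ppp with a_pyr both free) — and it
    is flagged degenerate.  The flatness threshold scales with the residual
    noise floor (a 1-df chi-square test on the profile objective increase),
    so parameters whose apparent sensitivity is below the measurement noise
    are also reported as unidentified.
    """
    lo, hi = bounds
    k = len(free)
    tol = max(tol, 3.84 * best_obj / max(len(observed), 1))
    deg = set()
    for i in range(k):
        for pinned in (min(theta[i] + delta, hi), max(theta[i] - delta, lo)):
            if abs(pinned - theta[i]) < delta / 2:
                continue  # boundary leaves no room on this side
            if k == 1:
                prof = _objective(np.array([pinned]), free, observed, fixed)
            else:
                others = [j for j in range(k) if j != i]

                def prof_obj(sub, _i=i, _pinned=pinned, _others=others):
                    full = theta.copy()
                    full[_i] = _pinned
                    full[_others] = sub
                    return _objective(full, free, observed, fixed)

                res = optimize.minimize(
                    prof_obj, theta[others], method="L-BFGS-B",
                    bounds=[(lo, hi)] * (k - 1),
                    options={"ftol": 1e-14, "gtol": 1e-12})
                prof = res.fun
            if prof - best_obj < tol:
                deg.add(free[i])
                break
    flat = len(deg) == k
    return frozenset(deg), flat
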