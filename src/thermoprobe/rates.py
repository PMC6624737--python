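"""APE production-rate fitting and the ratio-of-slopes statistics.

A microcosm's ¹³CO₂ return is summarized by the ordinary-least-squares slope
of atom percent excess (APE, percentage points) against incubation time in
hours.  Because APE is defined relative to the time-zero atmosphere baseline,
an exact (0 h, 0 APE) anchor is included by default.

For an isotopomer pair measured in triplicate, the site-level statistic is
the set of all numerator/denominator slope pairings (3 × 3 = 9 ratios); the
field protocol's hypothesis tests treat these nine ratios as independent
draws.  That convention is replicated here, with the caveat that the nine
ratios derive from only six independent slopes, so the one-sample t-test is
anti-conservative; a bootstrap alternative over microcosms is provided.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class InsufficientDataError(ValueError):
    pass


@dataclass
class SlopeEstimate:
    """OLS fit of APE on time for one microcosm."""

    microcosm_id: str
    slope: float  # APE percentage points per hour
    intercept: float
    r_squared: float
    n_points: int
    stderr: float = float("nan")


def fit_production_rate(points, microcosm_id: str = "",
                        anchor_t0: bool = True) -> SlopeEstimate:
    """Fit the APE production rate of one microcosm by OLS.

    ``points`` is a sequence of (time_h, ape) pairs.  When ``anchor_t0`` is
    true and no measurement exists at t = 0, an exact (0, 0) point is added,
    reflecting the definition of APE relative to time zero.
    """
    pts = [(float(t), float(a)) for t, a in points]
    if anchor_t0 and not any(t == 0.0 for t, _ in pts):
        pts.append((0.0, 0.0))
    t = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if len(np.unique(t)) < 2:
        raise InsufficientDataError("need at least two distinct times")
    res = stats.linregress(t, y)
    return SlopeEstimate(microcosm_id, float(res.slope), float(res.intercept),
                         float(res.rvalue**2), len(pts), float(res.stderr))


@dataclass
class RatioSample:
    """All pairwise numerator/denominator slope ratios for one site & pair."""

    site_id: str
    pair: str
    ratios: np.ndarray
    mean: float
    sem: float

    @property
    def n(self) -> int:
        return len(self.ratios)


def ratio_of_slopes(slopes_num, slopes_den, site_id: str = "",
                    pair: str = "") -> RatioSample:
    """Form every numerator/denominator slope ratio (n = 9 for triplicates).

    Zero denominator slopes are excluded with a warning, reducing the count.
    """
    num = np.asarray([getattr(s, "slope", s) for s in slopes_num], dtype=float)
    den = np.asarray([getattr(s, "slope", s) for s in slopes_den], dtype=float)
    if np.any(den == 0.0):
        warnings.warn("zero denominator slope excluded from ratio sample",
                      stacklevel=2)
        den = den[den != 0.0]
    if len(num) == 0 or len(den) == 0:
        raise InsufficientDataError("empty slope list")
    ratios = (num[:, None] / den[None, :]).ravel()
    sem = float(stats.sem(ratios)) if len(ratios) > 1 else 0.0
    return RatioSample(site_id, pair, ratios, float(ratios.mean()), sem)


@dataclass
class TestResult:
    method: str
    statistic: float
    df: object
    p_value: float
    groups: tuple = ()
    note: str = ""


def one_sample_t(ratios: RatioSample, mu0: float) -> TestResult:
    """Two-sided one-sample t-test of the ratio sample against a theoretical
    (e.g. complete-oxidation) ratio; df = n − 1."""
    x = np.asarray(ratios.ratios, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("need at least two ratios")
    if np.ptp(x) == 0.0:
        return TestResult("one-sample-t", np.nan, len(x) - 1, np.nan,
                          note="undefined-statistic: zero variance")
    t, p = stats.ttest_1samp(x, mu0)
    return TestResult("one-sample-t", float(t), len(x) - 1, float(p),
                      note="n pairwise ratios treated as independent "
                           "(pseudo-replicated; see bootstrap_ratio_test)")


def bootstrap_ratio_test(slopes_num, slopes_den, mu0: float,
                         n_boot: int = 10_000, seed: int = 0) -> TestResult:
    """Calibrated alternative to :func:`one_sample_t`.

    Resamples microcosms (slopes) with replacement within each isotopomer,
    recomputes the mean pairwise ratio, and reports the two-sided bootstrap
    p-value for the null that the mean ratio equals ``mu0``.
    """
    num = np.asarray([getattr(s, "slope", s) for s in slopes_num], dtype=float)
    den = np.asarray([getattr(s, "slope", s) for s in slopes_den], dtype=float)
    rng = np.random.default_rng(seed)
    obs = (num[:, None] / den[None, :]).mean()
    means = np.empty(n_boot)
    for b in range(n_boot):
        nb = rng.choice(num, size=len(num), replace=True)
        db = rng.choice(den, size=len(den), replace=True)
        means[b] = (nb[:, None] / db[None, :]).mean()
    # percentile-interval inversion: p = 2 * min(P(boot <= mu0), P(boot >= mu0))
    lo = np.mean(means <= mu0)
    hi = np.mean(means >= mu0)
    p = min(1.0, 2.0 * min(lo, hi))
    return TestResult("bootstrap", float(obs - mu0), n_boot, float(p))


@dataclass
class SiteComparison:
    anova: TestResult
    tukey: list
    welch: list
    letters: dict


def _compact_letters(groups, nonsig_pairs) -> dict:
    """Standard insert-and-absorb compact letter display.

    Groups that are not significantly different share at least one letter.
    """
    sig = {frozenset(p) for p in itertools.combinations(groups, 2)} - {
        frozenset(p) for p in nonsig_pairs}
    sets: list[set] = [set(groups)]
    for a, b in (tuple(s) for s in sig):
        for s in list(sets):
            if a in s and b in s:
                sets.remove(s)
                for drop in (a, b):
                    ns = s - {drop}
                    if ns and not any(ns <= o for o in sets):
                        sets.append(ns)
    # absorb: drop sets contained in others
    sets = [s for s in sets if not any(s < o for o in sets)]
    sets.sort(key=lambda s: sorted(groups.index(g) for g in s))
    letters = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in sorted(s, key=groups.index):
            letters[g] += letter
    return letters


def compare_sites(site_ratios: dict, alpha: float = 0.05) -> SiteComparison:
    """Omnibus and pairwise comparison of ratio samples across sites.

    One-way ANOVA, Tukey HSD on all pairs at family-wise ``alpha``, Welch
    two-sample t-tests per pair, and a compact letter display in which sites
    sharing a letter are not distinguishable by Tukey HSD.
    """
    sites = list(site_ratios)
    if len(sites) < 2:
        raise InsufficientDataError("need at least two sites")
    samples = [np.asarray(getattr(site_ratios[s], "ratios", site_ratios[s]),
                          dtype=float) for s in sites]
    if any(len(x) < 2 for x in samples):
        raise InsufficientDataError("each site needs at least two ratios")
    f, p = stats.f_oneway(*samples)
    k = len(samples)
    n = sum(len(x) for x in samples)
    anova = TestResult("anova", float(f), (k - 1, n - k), float(p))

    hsd = stats.tukey_hsd(*samples)
    tukey = []
    nonsig = []
    for i, j in itertools.combinations(range(k), 2):
        pij = float(hsd.pvalue[i, j])
        tukey.append(TestResult("tukey-hsd", float(hsd.statistic[i, j]), None,
                                pij, groups=(sites[i], sites[j])))
        if pij >= alpha:
            nonsig.append((sites[i], sites[j]))

    welch = []
    for i, j in itertools.combinations(range(k), 2):
        t, pij = stats.ttest_ind(samples[i], samples[j], equal_var=False)
        welch.append(TestResult("welch-t", float(t), None, float(pij),
                                groups=(sites[i], sites[j])))

    letters = _compact_letters(sites, nonsig)
    return SiteComparison(anova, tukey, welch, letters)


def annotate_significance(p: float) -> str:
    """Asterisk annotation for deviation from complete catabolic use
    (convention: * p<0.001, ** p<0.0001, *** p<0.00001)."""
    if p < 1e-5:
        return "***"
    if p < 1e-4:
        return "**"
    if p < 1e-3:
        return "*"
    return ""


def control_summary(live_slopes, control_slopes: dict,
                    subtract: bool = False) -> pd.DataFrame:
    """Summarize poisoned-control slopes against live microcosm slopes.

    Controls are reported, not subtracted, by default (set ``subtract`` to
    correct live slopes by the mean control rate).  A live:control mean-slope
    ratio near 1 is flagged abiotic-dominated; near-zero controls are flagged
    clean.
    """
    live = np.asarray([getattr(s, "slope", s) for s in live_slopes], float)
    if live.size == 0 or not control_slopes:
        raise InsufficientDataError("need live and control slopes")
    live_mean = live.mean()
    rows = []
    for treatment, slopes in control_slopes.items():
        ctrl = np.asarray([getattr(s, "slope", s) for s in slopes], float)
        cmean = ctrl.mean()
        ratio = np.inf if cmean == 0 else live_mean / cmean
        if cmean == 0 or abs(ratio) > 20:
            flag = "clean"
        elif abs(ratio - 1.0) < 0.25:
            flag = "abiotic-dominated"
        else:
            flag = ""
        rows.append({"treatment": treatment, "n": len(ctrl),
                     "control_mean_slope": cmean,
                     "live_mean_slope": live_mean - (cmean if subtract else 0.0),
                     "live_control_ratio": ratio, "flag": flag})
    return pd.DataFrame(rows)
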