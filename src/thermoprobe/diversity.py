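"""Alpha diversity and rarefaction for OTU count tables.

Implements the community statistics reported for 16S rRNA amplicon samples:
observed richness, classic Chao1 with its standard error, Shannon (natural
log by default), Simpson (1 − Σp²), inverse Simpson, and Fisher's alpha.
Simpson-family statistics are computed from the dominance Σp² so that
``inv_simpson == 1/(1 − simpson)`` holds identically; scikit-bio provides an
independent cross-check in the test suite.

Rarefaction subsamples reads without replacement to a common depth
(repeated, seeded, averaged), the approach of rarefaction toolkits used for
comparing samples with unequal sequencing effort.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class DiversityResult:
    sample_id: str
    observed_richness: float
    chao1: float
    chao1_se: float
    shannon: float
    simpson: float
    inv_simpson: float
    fisher_alpha: float


def _check_counts(counts) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    if counts.sum() == 0:
        raise ValueError("all-zero sample")
    return counts.astype(float)


def chao1_estimate(counts) -> tuple[float, float]:
    """Classic (non-bias-corrected) Chao1 richness estimate and its SE.

    chao1 = S_obs + F1²/(2·F2); when no doubletons exist the F2 → 0 limit
    S_obs + F1(F1−1)/2 is used.  The SE follows the standard asymptotic
    variance formula for each case (0 when there are no singletons).
    """
    counts = _check_counts(counts)
    s_obs = float(np.count_nonzero(counts))
    f1 = float(np.sum(counts == 1))
    f2 = float(np.sum(counts == 2))
    if f1 == 0:
        return s_obs, 0.0
    if f2 > 0:
        est = s_obs + f1 * f1 / (2.0 * f2)
        r = f1 / f2
        var = f2 * (r**2 / 2.0 + r**3 + r**4 / 4.0)
    else:
        est = s_obs + f1 * (f1 - 1.0) / 2.0
        var = (f1 * (f1 - 1.0) / 2.0 + f1 * (2.0 * f1 - 1.0) ** 2 / 4.0
               - f1**4 / (4.0 * est))
    return float(est), float(np.sqrt(max(var, 0.0)))


def fisher_alpha(counts, tol: float = 1e-10) -> float:
    """Fisher's log-series alpha: solves S = α·ln(1 + N/α) by bracketed
    root finding.  Undefined (NaN) when every individual is a distinct OTU."""
    counts = _check_counts(counts)
    s = float(np.count_nonzero(counts))
    n = float(counts.sum())
    if s >= n:
        return float("nan")

    def f(a):
        return a * np.log1p(n / a) - s

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e12:
            return float("nan")
    return float(optimize.brentq(f, lo, hi, xtol=tol))


def alpha_diversity(counts, sample_id: str = "", shannon_base: float = np.e
                    ) -> DiversityResult:
    """All alpha-diversity statistics for one sample's OTU counts."""
    counts = _check_counts(counts)
    nz = counts[counts > 0]
    p = nz / nz.sum()
    shannon = float(-(p * (np.log(p) / np.log(shannon_base))).sum())
    dominance = float((p**2).sum())
    est, se = chao1_estimate(counts)
    return DiversityResult(
        sample_id=sample_id,
        observed_richness=float(len(nz)),
        chao1=est,
        chao1_se=se,
        shannon=shannon,
        simpson=1.0 - dominance,
        inv_simpson=1.0 / dominance,
        fisher_alpha=fisher_alpha(counts),
    )


def rarefy(counts, depth: int, reps: int = 1000, seed: int = 0,
           sample_id: str = "") -> DiversityResult:
    """Rarefied diversity: average statistics over ``reps`` independent
    subsamples without replacement at ``depth`` reads.  Deterministic given
    ``seed``."""
    counts = _check_counts(counts).astype(np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds sample total {total}")
    if depth == total:
        return alpha_diversity(counts, sample_id)
    rng = np.random.default_rng(seed)
    acc = None
    numeric = [f.name for f in fields(DiversityResult) if f.name != "sample_id"]
    for _ in range(reps):
        sub = rng.multivariate_hypergeometric(counts, depth)
        res = alpha_diversity(sub, sample_id)
        vals = np.array([getattr(res, n) for n in numeric])
        acc = vals if acc is None else acc + vals
    acc = acc / reps
    return DiversityResult(sample_id, *acc)


def read_otu_table(path, sep=None) -> pd.DataFrame:
    """Read an OTU table: first column OTU id, remaining columns samples."""
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate OTU or sample ids")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return df


def diversity_table(otu_table: pd.DataFrame, rarefy_depth: int | None = None,
                    reps: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-sample diversity statistics for an OTUs × samples table."""
    rows = []
    for sample in otu_table.columns:
        counts = otu_table[sample].to_numpy()
        if rarefy_depth is None:
            res = alpha_diversity(counts, sample_id=sample)
        else:
            res = rarefy(counts, rarefy_depth, reps=reps, seed=seed,
                         sample_id=sample)
        rows.append(vars(res))
    return pd.DataFrame(rows).set_index("sample_id")
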