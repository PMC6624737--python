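"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator returns ``(data, manifest)`` where the manifest records the
generating truth (flux parameters, planted features, true richness), so each
pipeline stage can be scored against a known answer without any downloads.

The microcosm generator emulates the field design: triplicate live
microcosms per substrate isotopomer, duplicate poisoned controls with a
small abiotic decarboxylation rate, headspace sampling at 2, 4 and 8 h, and
n=3 atmosphere samples defining the time-zero baseline.  ¹³CO₂ return is
linear in time (zero-order uptake, matching the near-linear label return
observed in such incubations), and instrument noise is Gaussian on δ¹³C —
noise arises at the spectrometer — with an sd of 0.5 ‰ typical of cavity
ring-down analyzers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fate as _fate
from .fate import FluxParameters, SubstrateIsotopomer, predict_fates
from .isotope import VPDB, IsotopeStandard, atom_fraction_to_delta, delta_to_atom_fraction

DEFAULT_ISOTOPOMERS = tuple(
    iso for pair in _fate.PAIRS.values() for iso in pair
)


def _isotopomer_label(iso: SubstrateIsotopomer) -> str:
    pos = sorted(iso.labeled_positions)
    if iso.substrate == "glucose" and len(pos) == iso.n_carbons:
        return "glucose-U"
    return f"{iso.substrate}-{','.join(map(str, pos))}"


@dataclass
class SiteScenario:
    """Generating conditions for one site's microcosm experiment."""

    site_id: str
    temperature: float = 85.0
    flux_params: FluxParameters = field(default_factory=FluxParameters)
    uptake_scale: float = 0.05  # APE %/h per unit release fraction
    noise_sd: float = 0.5  # permil, on delta
    abiotic_rate: float = 0.002  # APE %/h in poisoned controls
    n_replicates: int = 3
    n_control_replicates: int = 2
    timepoints: tuple = (0.0, 2.0, 4.0, 8.0)

    def __post_init__(self):
        if self.noise_sd < 0 or self.abiotic_rate < 0:
            raise ValueError("noise_sd and abiotic_rate must be nonnegative")


def gen_microcosm_experiment(
    scenarios,
    isotopomers=DEFAULT_ISOTOPOMERS,
    background_co2: float = 410.0,
    baseline_delta: float = -8.5,
    standard: IsotopeStandard = VPDB,
    seed: int = 0,
):
    """Generate a gas measurement table for the given site scenarios.

    True APE(t) of a live microcosm is ``uptake_scale × Σ_labeled released ×
    purity × t`` from the forward carbon-fate model; poisoned controls
    accumulate at ``abiotic_rate``.  δ¹³C values carry Gaussian noise of
    ``noise_sd`` ‰.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    x0 = delta_to_atom_fraction(baseline_delta, standard)
    rows = []
    manifest = {"seed": seed, "baseline_delta": baseline_delta,
                "background_co2": background_co2, "sites": {}}
    for sc in scenarios:
        site_truth = {
            "temperature": sc.temperature,
            "flux_params": dataclasses.asdict(sc.flux_params),
            "uptake_scale": sc.uptake_scale,
            "noise_sd": sc.noise_sd,
            "abiotic_rate": sc.abiotic_rate,
            "true_ratios": {
                pair: _fate.theoretical_ratio(pair, sc.flux_params).value
                for pair in _fate.PAIRS
            },
            "true_slopes": {},
        }
        for k in range(3):  # n=3 atmosphere samples define the baseline
            rows.append({
                "site_id": sc.site_id, "microcosm_id": f"{sc.site_id}-atm{k+1}",
                "substrate": "atmosphere", "treatment": "atmosphere",
                "time_h": 0.0,
                "delta_c13": baseline_delta + rng.normal(0.0, sc.noise_sd),
                "co2_conc": background_co2,
            })
        for iso in isotopomers:
            label = _isotopomer_label(iso)
            fates = predict_fates(iso, sc.flux_params)
            rate = sc.uptake_scale * fates.co2_rate  # APE %/h
            site_truth["true_slopes"][label] = rate
            for rep in range(1, sc.n_replicates + 1):
                mid = f"{sc.site_id}-{label}-r{rep}"
                for t in sc.timepoints:
                    if t == 0.0:
                        continue
                    x = x0 + rate * t / 100.0
                    delta = atom_fraction_to_delta(x, standard)
                    rows.append({
                        "site_id": sc.site_id, "microcosm_id": mid,
                        "substrate": label, "treatment": "live", "time_h": t,
                        "delta_c13": delta + rng.normal(0.0, sc.noise_sd),
                        "co2_conc": background_co2,
                    })
            for rep in range(1, sc.n_control_replicates + 1):
                mid = f"{sc.site_id}-{label}-ctrl{rep}"
                for t in sc.timepoints:
                    if t == 0.0:
                        continue
                    x = x0 + sc.abiotic_rate * t / 100.0
                    delta = atom_fraction_to_delta(x, standard)
                    rows.append({
                        "site_id": sc.site_id, "microcosm_id": mid,
                        "substrate": label, "treatment": "poisoned-glut",
                        "time_h": t,
                        "delta_c13": delta + rng.normal(0.0, sc.noise_sd),
                        "co2_conc": background_co2,
                    })
        manifest["sites"][sc.site_id] = site_truth
    return pd.DataFrame(rows), manifest


def gen_ko_counts(
    n_features: int = 1000,
    n_differential: int = 50,
    effect_fold: float = 8.0,
    totals: dict | None = None,
    metagenome_sizes: dict | None = None,
    lognormal_mu: float = 0.0,
    lognormal_sigma: float = 1.5,
    gene_fraction: float = 0.1,
    seed: int = 0,
):
    """KO inventory tables with planted differential features.

    Baseline relative abundances are log-normal; planted features are
    multiplied by ``effect_fold`` in the last sample; counts are multinomial
    at each sample's total; distinct gene counts are binomial sub-samples of
    copies.  Returns ``(inventories, sizes, manifest)``.
    """
    if n_differential > n_features:
        raise ValueError("n_differential exceeds n_features")
    rng = np.random.default_rng(seed)
    if totals is None:
        totals = {"GBS60": 1_000_000, "GBS85": 1_000_000}
    if metagenome_sizes is None:
        metagenome_sizes = {
            s: {"unassembled_bp": 20_000_000_000, "assembled_bp": 400_000_000}
            for s in totals
        }
    features = [f"K{i:05d}" for i in range(1, n_features + 1)]
    base = rng.lognormal(lognormal_mu, lognormal_sigma, n_features)
    planted = sorted(rng.choice(features, size=n_differential, replace=False))
    planted_idx = np.isin(features, planted)
    samples = list(totals)
    rows = []
    for si, sample in enumerate(samples):
        weights = base.copy()
        if si == len(samples) - 1:
            weights[planted_idx] *= effect_fold
        counts = rng.multinomial(int(totals[sample]), weights / weights.sum())
        genes = rng.binomial(counts, gene_fraction)
        for f, c, g in zip(features, counts, genes):
            rows.append({"sample_id": sample, "feature_id": f,
                         "estimated_copies": int(c), "gene_count": int(g)})
    inventories = pd.DataFrame(rows)
    manifest = {"seed": seed, "planted_features": planted,
                "effect_fold": effect_fold, "effect_sample": samples[-1],
                "n_features": n_features}
    return inventories, metagenome_sizes, manifest


# -- random module definitions with an independent truth-table oracle -------

def _render(node) -> str:
    kind = node[0]
    if kind == "ko":
        return node[1]
    if kind == "or":
        return ",".join(
            f"({_render(c)})" if c[0] == "and_space" else _render(c)
            for c in node[1])
    if kind == "and_plus":
        def wrap(c):
            return f"({_render(c)})" if c[0] in ("or", "and_space") else _render(c)
        out = wrap(node[1][0])
        for c in node[1][1:]:
            if c[0] == "opt":
                out += "-" + _render(c[1])
            else:
                out += "+" + wrap(c)
        return out
    if kind == "and_space":
        return " ".join(
            f"({_render(c)})" if c[0] == "or" else _render(c) for c in node[1])
    if kind == "opt":
        return "-" + _render(node[1])
    raise ValueError(node)


def _truth_eval(node, present: set):
    """Truth-table evaluation on the generated tree — independent of the
    text parser.  Returns True/False or None for optional-only parts."""
    kind = node[0]
    if kind == "ko":
        return node[1] in present
    if kind == "opt":
        return None
    if kind == "or":
        vals = [v for v in (_truth_eval(c, present) for c in node[1])
                if v is not None]
        return any(vals) if vals else None
    if kind in ("and_plus", "and_space"):
        vals = [v for v in (_truth_eval(c, present) for c in node[1])
                if v is not None]
        return all(vals) if vals else None
    raise ValueError(node)


def gen_module_set(n_modules: int = 100, steps_range=(1, 6),
                   p_present: float = 0.5, seed: int = 0):
    """Random module definitions exercising the full grammar, a random KO
    presence set, and truth MCRs evaluated directly on the generated trees.

    Returns ``(definitions, present_kos, manifest)`` where ``definitions``
    is a list of (module_id, definition_text) and the manifest maps module
    ids to their truth MCR (percent, one decimal).
    """
    lo, hi = steps_range
    if lo < 1:
        raise ValueError("steps_range must be >= 1")
    rng = np.random.default_rng(seed)
    counter = [0]

    def new_ko():
        counter[0] += 1
        return ("ko", f"K{counter[0]:05d}")

    def random_step(depth=0):
        r = rng.random()
        if r < 0.35 or depth >= 2:
            return new_ko()
        if r < 0.60:
            return ("or", tuple(random_step(depth + 1)
                                for _ in range(rng.integers(2, 4))))
        if r < 0.80:
            members = [random_step(depth + 1)
                       for _ in range(rng.integers(2, 4))]
            if rng.random() < 0.4:
                members.append(("opt", new_ko()))
            return ("and_plus", tuple(members))
        return ("and_space", tuple(random_step(depth + 1)
                                   for _ in range(rng.integers(2, 3))))

    all_kos = set()

    def collect(node):
        if node[0] == "ko":
            all_kos.add(node[1])
        elif node[0] == "opt":
            collect(node[1])
        else:
            for c in node[1]:
                collect(c)

    modules = []
    for m in range(1, n_modules + 1):
        n_steps = int(rng.integers(lo, hi + 1))
        steps = [random_step() for _ in range(n_steps)]
        for s in steps:
            collect(s)
        modules.append((f"M{m:05d}", steps))

    present = {k for k in sorted(all_kos) if rng.random() < p_present}

    definitions = []
    truth = {}
    for mid, steps in modules:
        text = " ".join(
            f"({_render(s)})" if s[0] == "and_space" else _render(s)
            for s in steps)
        definitions.append((mid, text))
        vals = [_truth_eval(s, present) for s in steps]
        mandatory = [v for v in vals if v is not None]
        truth[mid] = (round(100.0 * sum(mandatory) / len(mandatory), 1)
                      if mandatory else 0.0)
    manifest = {"seed": seed, "p_present": p_present, "true_mcr": truth}
    return definitions, present, manifest


def gen_otu_table(
    n_samples: int = 4,
    richness=(491, 326, 211, 113),
    lognormal_sigma: float = 1.2,
    depth: int = 20000,
    seed: int = 0,
):
    """OTU count table along a temperature-like richness gradient.

    Species abundances are log-normal; reads are multinomial at ``depth``.
    Default richness values follow the observed span of hot-spring amplicon
    richness from 60 to 95 °C.  Returns ``(otu_table, manifest)``.
    """
    richness = list(richness)[:n_samples]
    if len(richness) < n_samples:
        raise ValueError("need a richness value per sample")
    if min(richness) < 1:
        raise ValueError("richness must be >= 1")
    rng = np.random.default_rng(seed)
    max_rich = max(richness)
    otus = [f"OTU{i:04d}" for i in range(1, max_rich + 1)]
    table = {}
    for s, rich in enumerate(richness):
        sample = f"S{s+1}"
        abund = np.zeros(max_rich)
        chosen = rng.choice(max_rich, size=rich, replace=False)
        abund[chosen] = rng.lognormal(0.0, lognormal_sigma, rich)
        table[sample] = rng.multinomial(depth, abund / abund.sum())
    otu = pd.DataFrame(table, index=otus)
    manifest = {"seed": seed, "depth": depth,
                "true_richness": {f"S{s+1}": int(r)
                                  for s, r in enumerate(richness)}}
    return otu, manifest
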