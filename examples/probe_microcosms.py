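"""Full microcosm probing workflow on synthetic data.

Generates a two-site 13C-labeling experiment (triplicate microcosms, 0.5
permil instrument noise), converts delta-13C readings to atom percent excess,
fits production rates, forms the n=9 ratio-of-slopes statistics, tests them
against complete catabolic oxidation, and recovers the generating flux
parameters from the observed ratios.
"""

from thermoprobe import (
    FluxParameters,
    SiteScenario,
    fit_flux_params,
    gen_microcosm_experiment,
)
from thermoprobe.pipeline import RunConfig, probe_stage

scenarios = [
    SiteScenario("GBS60", 60.0, FluxParameters(phi_ppp=0.3, a_ac=0.2)),
    SiteScenario("GBS95", 95.0, FluxParameters()),  # catabolic-only
]
gas, manifest = gen_microcosm_experiment(scenarios, seed=42)
print(f"Generated {len(gas)} gas measurements for {len(scenarios)} sites.\n")

slopes, ratios, letters = probe_stage(gas, RunConfig())
print("Ratio-of-slopes statistics (mean of the 9 pairwise slope ratios):")
cols = ["site_id", "pair", "mean", "sem", "mu0_catabolic", "p_value", "annotation"]
print(ratios[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("p_value: one-sample t-test against the complete-oxidation ratio;")
print("small p at GBS60 flags anabolic retention / fermentation there. Note")
print("the test treats the 9 pairwise ratios as independent although they")
print("come from 6 slopes, so it over-rejects (see the catabolic GBS95 rows);")
print("rates.bootstrap_ratio_test resamples microcosms instead.\n")

obs = (ratios[ratios["site_id"] == "GBS60"]
       .set_index("pair")["mean"].to_dict())
fit = fit_flux_params(obs)
print("Flux parameters fitted to the GBS60 ratios "
      f"(truth: phi_ppp=0.30, a_ac=0.20):")
print(f"  phi_ppp={fit.params.phi_ppp:.3f}  a_ac={fit.params.a_ac:.3f}  "
      f"a_tca={fit.params.a_tca:.3f}")
if fit.degenerate:
    print(f"  not identifiable from these ratios: {sorted(fit.degenerate)}")
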