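"""End-to-end orchestration with a single run configuration.

`run_all` executes the configured stages — isotope conversion → rate fitting
→ ratio statistics → hypothesis tests, functional profiling, and diversity —
and writes tab-separated result tables plus a JSON manifest recording the
configuration hash and seeds, so a rerun with the same configuration is
reproducible.  This package is used from Python; the configuration object
and the stage functions are the interface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as _diversity
from . import fate as _fate
from . import funcprofile as _func
from . import isotope as _isotope
from . import rates as _rates


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and offender."""


@dataclass
class RunConfig:
    """Paths and options for a full run.  Unset stage inputs are skipped."""

    out_dir: str = "results"
    gas_table: str | None = None
    modules_file: str | None = None
    inventories_file: str | None = None
    otu_table: str | None = None

    r_std: float = _isotope.VPDB_R13
    baseline: float | None = None  # fixed t0 atom fraction; default: atmosphere mean
    anchor_t0: bool = True
    pairs: dict = field(default_factory=lambda: {
        "glucose": ("glucose-U", "glucose-1"),
        "pyruvate": ("pyruvate-1", "pyruvate-2,3"),
        "acetate": ("acetate-1", "acetate-2"),
    })
    alpha: float = 0.05
    sizes: dict = field(default_factory=dict)  # sample_id -> bp sizes
    module_q_values: dict = field(default_factory=dict)
    differential_threshold: float = 0.9
    rarefy_depth: int | None = None
    rarefy_reps: int = 1000
    seed: int = 0


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def probe_stage(gas: pd.DataFrame, config: RunConfig):
    """Gas table → slopes, n=9 ratio samples, and hypothesis tests."""
    standard = _isotope.IsotopeStandard(config.r_std)
    ape = _isotope.ape_table(gas, standard, baseline=config.baseline)

    slope_rows = []
    slopes: dict = {}
    for (site, sub, mc, treat), grp in ape.groupby(
            ["site_id", "substrate", "microcosm_id", "treatment"]):
        est = _rates.fit_production_rate(
            list(zip(grp["time_h"], grp["ape"])), microcosm_id=mc,
            anchor_t0=config.anchor_t0)
        slopes.setdefault((site, sub, treat), []).append(est)
        slope_rows.append({"site_id": site, "substrate": sub,
                           "treatment": treat, "microcosm_id": mc,
                           "slope": est.slope, "intercept": est.intercept,
                           "r_squared": est.r_squared, "n_points": est.n_points})
    slopes_df = pd.DataFrame(slope_rows)

    ratio_rows = []
    ratio_samples: dict = {}
    for pair, (num_label, den_label) in config.pairs.items():
        for site in slopes_df["site_id"].unique():
            num = slopes.get((site, num_label, "live"))
            den = slopes.get((site, den_label, "live"))
            if not num or not den:
                continue
            rs = _rates.ratio_of_slopes(num, den, site_id=site, pair=pair)
            ratio_samples.setdefault(pair, {})[site] = rs
            mu0 = _fate.CATABOLIC_RATIOS[pair]
            test = _rates.one_sample_t(rs, mu0)
            ratio_rows.append({
                "site_id": site, "pair": pair, "n": rs.n, "mean": rs.mean,
                "sem": rs.sem, "mu0_catabolic": mu0, "t": test.statistic,
                "df": test.df, "p_value": test.p_value,
                "annotation": _rates.annotate_significance(test.p_value),
            })
    ratios_df = pd.DataFrame(ratio_rows)

    letter_rows = []
    for pair, by_site in ratio_samples.items():
        if len(by_site) < 2:
            continue
        cmp = _rates.compare_sites(by_site, alpha=config.alpha)
        for site, letters in cmp.letters.items():
            letter_rows.append({"pair": pair, "site_id": site,
                                "letters": letters,
                                "anova_p": cmp.anova.p_value})
    letters_df = pd.DataFrame(letter_rows)
    return slopes_df, ratios_df, letters_df


def run_all(config: RunConfig) -> dict:
    """Run every configured stage; returns the result bundle and writes
    tables plus a run manifest under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    for path in (config.gas_table, config.modules_file,
                 config.inventories_file, config.otu_table):
        if path is not None and not Path(path).exists():
            raise StageError(f"input: missing input file {path}")

    if config.gas_table:
        try:
            gas = _isotope.read_gas_table(config.gas_table)
            slopes, ratios, letters = probe_stage(gas, config)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"probe: {exc}") from exc
        slopes.to_csv(out / "slopes.tsv", sep="\t", index=False)
        ratios.to_csv(out / "ratios.tsv", sep="\t", index=False)
        letters.to_csv(out / "letters.tsv", sep="\t", index=False)
        bundle.update(slopes=slopes, ratios=ratios, letters=letters)

    if config.modules_file and config.inventories_file:
        try:
            modules = _func.read_module_definitions(config.modules_file)
            inv = pd.read_csv(config.inventories_file, sep="\t")
            mcr_rows = []
            for sample, grp in inv.groupby("sample_id"):
                present = set(grp.loc[grp["estimated_copies"] > 0, "feature_id"])
                for mod in modules:
                    res = _func.mcr(mod, present,
                                    q_value=config.module_q_values.get(
                                        (sample, mod.module_id)))
                    mcr_rows.append({"sample_id": sample,
                                     "module_id": res.module_id,
                                     "satisfied": res.satisfied_steps,
                                     "total": res.total_steps, "mcr": res.mcr,
                                     "q_value": res.q_value,
                                     "feasible": res.biologically_feasible})
            mcr_df = pd.DataFrame(mcr_rows)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"funcprofile: {exc}") from exc
        mcr_df.to_csv(out / "mcr.tsv", sep="\t", index=False)
        bundle["mcr"] = mcr_df

    if config.otu_table:
        try:
            otu = _diversity.read_otu_table(config.otu_table)
            div = _diversity.diversity_table(
                otu, rarefy_depth=config.rarefy_depth,
                reps=config.rarefy_reps, seed=config.seed)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"diversity: {exc}") from exc
        div.to_csv(out / "diversity.tsv", sep="\t")
        bundle["diversity"] = div

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    bundle["manifest"] = manifest
    return bundle
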