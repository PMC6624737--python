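"""δ¹³C / atom-fraction arithmetic and headspace gas mixing.

Cavity ring-down analyzers report CO₂ carbon isotope composition as δ¹³C in
per mil relative to a reference standard (VPDB by default).  All label
bookkeeping in this package is done in atom-fraction space — mixing two CO₂
pools is exact when atom fractions are weighted by CO₂ moles, whereas
averaging δ values is only approximate at tracer-level enrichment.

The spike/dilution model mirrors a field protocol in which low-CO₂ headspace
samples are mixed 1:1 with a CO₂-spiked atmosphere (a jar of air injected
with pure CO₂) and then diluted with CO₂-free gas to reach the analyzer's
working range.  CO₂-free dilution gas carries no carbon and therefore never
enters the isotope balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: ¹³C/¹²C ratio of the Vienna Pee Dee Belemnite standard.
VPDB_R13 = 0.0111802

GAS_TABLE_COLUMNS = [
    "site_id",
    "microcosm_id",
    "substrate",
    "treatment",
    "time_h",
    "delta_c13",
    "co2_conc",
]

TREATMENTS = {"live", "poisoned-Hg", "poisoned-glut", "poisoned-both", "atmosphere"}


class InvalidMeasurementError(ValueError):
    """A δ¹³C or concentration value outside its physical domain."""


@dataclass(frozen=True)
class IsotopeStandard:
    """Isotope reference defining the δ scale.

    Parameters
    ----------
    r_std : float
        ¹³C/¹²C ratio of the reference material (dimensionless, > 0).
    """

    r_std: float = VPDB_R13

    def __post_init__(self) -> None:
        if not self.r_std > 0:
            raise ValueError(f"r_std must be positive, got {self.r_std}")


VPDB = IsotopeStandard(VPDB_R13)


def delta_to_atom_fraction(delta, standard: IsotopeStandard = VPDB):
    """Convert δ¹³C (per mil) to ¹³C atom fraction.

    x = r / (1 + r) with r = r_std * (1 + δ/1000).  Strictly increasing
    in δ; δ = −1000 ‰ (no ¹³C) maps to 0.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < -1000):
        raise InvalidMeasurementError("delta below -1000 permil is unphysical")
    r = standard.r_std * (1.0 + delta / 1000.0)
    out = r / (1.0 + r)
    return out if out.ndim else float(out)


def atom_fraction_to_delta(x, standard: IsotopeStandard = VPDB):
    """Exact inverse of :func:`delta_to_atom_fraction`.

    Valid for atom fractions in [0, 1).
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x >= 1)):
        raise InvalidMeasurementError("atom fraction must lie in [0, 1)")
    r = x / (1.0 - x)
    out = (r / standard.r_std - 1.0) * 1000.0
    return out if out.ndim else float(out)


def ape(x_sample, x_t0):
    """Atom percent excess: (x_sample − x_t0) × 100, in percentage points."""
    x_sample = np.asarray(x_sample, dtype=float)
    x_t0 = np.asarray(x_t0, dtype=float)
    if np.any((x_sample < 0) | (x_sample > 1)) or np.any((x_t0 < 0) | (x_t0 > 1)):
        raise InvalidMeasurementError("atom fractions must lie in [0, 1]")
    out = (x_sample - x_t0) * 100.0
    return out if out.ndim else float(out)


def spike_gas_concentration(jar_volume_ml, pure_co2_added_ml, ambient_co2_conc):
    """CO₂ mole fraction (μmol mol⁻¹) of a jar of air injected with pure CO₂.

    Ideal-gas volume mixing: the jar holds ``jar_volume_ml`` of atmosphere at
    ``ambient_co2_conc`` μmol mol⁻¹ and receives ``pure_co2_added_ml`` of
    pure CO₂.
    """
    if jar_volume_ml <= 0 or pure_co2_added_ml < 0 or ambient_co2_conc < 0:
        raise ValueError("volumes must be positive and concentration nonnegative")
    co2_ml = pure_co2_added_ml + ambient_co2_conc * 1e-6 * jar_volume_ml
    return co2_ml / (jar_volume_ml + pure_co2_added_ml) * 1e6


def unmix_spike(x_mix, n_sample_co2, n_spike_co2, x_spike):
    """Recover the sample atom fraction from a sample/spike mixture.

    Solves the CO₂-mole-weighted balance
    ``x_mix * (n_s + n_k) = x_s * n_s + x_k * n_k`` for the sample value
    ``x_s``.  Mixing is always performed on atom fractions weighted by CO₂
    moles (any proportional unit), never on δ values.  CO₂-free dilution gas
    contributes no moles and needs no term.
    """
    if n_sample_co2 <= 0:
        raise InvalidMeasurementError("sample contains no CO2; cannot unmix")
    if n_spike_co2 < 0:
        raise ValueError("spike moles must be nonnegative")
    if not (0 <= x_mix <= 1 and 0 <= x_spike <= 1):
        raise InvalidMeasurementError("atom fractions must lie in [0, 1]")
    x_s = x_mix + (n_spike_co2 / n_sample_co2) * (x_mix - x_spike)
    if not 0 <= x_s <= 1:
        warnings.warn(
            f"unmixed atom fraction {x_s:.6g} outside [0, 1]; "
            "mole weights and mixture value are inconsistent",
            stacklevel=2,
        )
    return x_s


def read_gas_table(path_or_buffer, sep=None) -> pd.DataFrame:
    """Read a microcosm gas measurement table (TSV or CSV).

    Required columns: site_id, microcosm_id, substrate, treatment, time_h,
    delta_c13 (‰), co2_conc (μmol mol⁻¹).
    """
    df = pd.read_csv(path_or_buffer, sep=sep, engine="python")
    missing = set(GAS_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gas table missing columns: {sorted(missing)}")
    df = df[GAS_TABLE_COLUMNS].copy()
    validate_gas_table(df)
    return df


def validate_gas_table(df: pd.DataFrame) -> None:
    if (df["delta_c13"] < -1000).any():
        raise InvalidMeasurementError("delta_c13 below -1000 permil")
    if (df["co2_conc"] < 0).any():
        raise InvalidMeasurementError("negative CO2 concentration")
    if (df["time_h"] < 0).any():
        raise InvalidMeasurementError("negative time")
    bad = set(df["treatment"].unique()) - TREATMENTS
    if bad:
        raise ValueError(f"unknown treatments: {sorted(bad)}")


def baseline_atom_fraction(
    gas: pd.DataFrame,
    standard: IsotopeStandard = VPDB,
    fixed: float | None = None,
) -> pd.Series:
    """Time-zero atom fraction per site.

    By default the mean atom fraction of each site's ``atmosphere`` rows
    (the field protocol's n=3 air samples); a fixed value can be supplied
    instead.
    """
    sites = gas["site_id"].unique()
    if fixed is not None:
        return pd.Series(fixed, index=sites)
    atm = gas[gas["treatment"] == "atmosphere"]
    if atm.empty:
        raise ValueError("no atmosphere rows to estimate the time-zero baseline")
    x = delta_to_atom_fraction(atm["delta_c13"].to_numpy(), standard)
    base = pd.Series(x, index=atm["site_id"].to_numpy()).groupby(level=0).mean()
    missing = set(sites) - set(base.index)
    if missing:
        raise ValueError(f"sites without atmosphere baseline: {sorted(missing)}")
    return base.reindex(sites)


def ape_table(
    gas: pd.DataFrame,
    standard: IsotopeStandard = VPDB,
    baseline: float | None = None,
) -> pd.DataFrame:
    """Convert a gas measurement table to an APE table.

    Each non-atmosphere measurement's δ¹³C is converted to atom fraction and
    referenced to the site's time-zero baseline.  Returns the same keys plus
    an ``ape`` column (percentage points).
    """
    validate_gas_table(gas)
    base = baseline_atom_fraction(gas, standard, fixed=baseline)
    out = gas[gas["treatment"] != "atmosphere"].copy()
    x = delta_to_atom_fraction(out["delta_c13"].to_numpy(), standard)
    x0 = base.loc[out["site_id"]].to_numpy()
    out["ape"] = ape(x, x0)
    return out.reset_index(drop=True)
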