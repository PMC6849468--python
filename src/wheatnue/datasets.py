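"""Bundled reference tables from a published 15-variety wheat pot screen.

Three small CSVs ship with the package for worked examples and desk checks:

* ``reference_splitline_fits`` — split-line regression parameters
  (breakpoint DAS/EB coordinates and the two segment slopes) for 15 wheat
  varieties at low (5 mM, 0.147 g N/pot) and optimum (20 mM, 0.588 g N/pot)
  nitrogen.
* ``reference_harvest_means`` — variety means at maturity: total dry biomass
  DW (g/pot), grain yield GY (g/pot), water-soluble carbohydrates (%), and
  shoot/grain N concentrations (%).
* ``reference_vegetative_means`` — variety means at the vegetative stage:
  measured fresh biomass MB (g/pot) and leaf area LA (cm²/pot) at 49 DAS,
  and the digital traits EB and TVA (kPix/pot) at 54 DAS.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_reference_fits",
    "load_reference_harvest",
    "load_reference_vegetative",
]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("wheatnue.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_reference_fits() -> pd.DataFrame:
    """Split-line fit parameters per variety and N level (30 rows)."""
    return _read("reference_splitline_fits.csv")


def load_reference_harvest() -> pd.DataFrame:
    """Harvest-trait variety means per N level (30 rows)."""
    return _read("reference_harvest_means.csv")


def load_reference_vegetative() -> pd.DataFrame:
    """Vegetative-stage variety means per N level (30 rows)."""
    return _read("reference_vegetative_means.csv")
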