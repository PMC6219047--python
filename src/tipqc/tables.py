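"""Published device-characterisation tables, shipped as package data.

Three summary tables from the gravimetric and imaging characterisation of
the reference dispenser (16 step levels, 40-640 by 40, five replicates per
level; only mean/STD summaries were published, not raw replicates):

* ``mass_table`` — reagent mass on the chemical balance per step level;
* ``volume_length_table`` — image-measured volume length per step level;
* ``step_error_table`` — RMS deviation of image-based step estimates from
  the commanded steps.

The ``cv_printed`` / ``rel_dev_printed`` columns transcribe the originally
published derived rows verbatim for cross-checking; everything else this
package reports is recomputed from mean/std.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open("rb") as fh:
        return pd.read_csv(fh)


def mass_table() -> pd.DataFrame:
    """Columns: steps, mean, std, cv_printed (percent)."""
    return _load("mass_replicates.csv")


def volume_length_table() -> pd.DataFrame:
    """Columns: steps, mean, std, cv_printed (percent); lengths in pixels."""
    return _load("volume_length_replicates.csv")


def step_error_table() -> pd.DataFrame:
    """Columns: steps, dev (RMS from true steps), rel_dev_printed (percent)."""
    return _load("step_estimation_error.csv")
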