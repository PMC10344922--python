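"""Bundled case-score fixture tables (transcribed verbatim).

Three CSVs ship with the package:

* ``table2.csv`` — two users' automated HER2 scores/statuses, 12 cases;
* ``table6.csv`` — clinical vs automated scores with and without automatic
  ROI selection, 12 cases;
* ``table7.csv`` — test vs retest scores/statuses, 12 cases.

Note the published sources carry two internal inconsistencies, preserved
here verbatim: table2 case 6 user-2 score (1.65) differs from table6's 1.75
for the same cell, and table7 cases 4-5 print "Neg" despite scores >= 2.0.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_table2", "load_table6", "load_table7"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("slideroi.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_table2() -> pd.DataFrame:
    return _load("table2.csv")


def load_table6() -> pd.DataFrame:
    return _load("table6.csv")


def load_table7() -> pd.DataFrame:
    return _load("table7.csv")
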