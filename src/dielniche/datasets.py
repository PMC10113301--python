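"""Packaged reference datasets from the Atlantic-forest plant-hummingbird study.

Two small fixtures ship with the package:

* the observed hummingbird x plant visit-count matrix (4 species x 12 plants,
  488 independent legitimate visits), and
* the per-species floral table: mean anther height (cm) and the fitted
  log-quadratic nectar-secretion coefficients (log-µg scale).

Both are used by the demo pipeline, the ``paper_like`` synthetic scenario and
the test suite.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_visit_matrix", "load_floral_table", "load_nectar_curves", "load_anther_heights"]


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("dielniche.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, **kwargs)


def load_visit_matrix() -> pd.DataFrame:
    """Observed visit counts, hummingbird rows x plant columns (matrix M1)."""
    return _read("visit_matrix.csv", index_col="pollinator").rename_axis(columns="plant")


def load_floral_table() -> pd.DataFrame:
    """Anther heights and nectar-curve coefficients, indexed by plant species."""
    return _read("nectar_curves.csv", index_col="plant")


def load_nectar_curves() -> pd.DataFrame:
    """The (b0, b1, b2) log-quadratic nectar coefficients per plant species."""
    return load_floral_table()[["b0", "b1", "b2"]]


def load_anther_heights() -> pd.Series:
    """Mean anther height (cm) per plant species."""
    return load_floral_table()["anther_height_cm"]
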