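"""Access to the bundled fixtures and small CSV/YAML helpers."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import ParameterSpace
from .lookup import SuccessCriteria

_SPACES = {
    "niederer": "niederer_space.yaml",
    "land": "land_space.yaml",
}
_FITTED = {
    "niederer": "niederer_fitted_sets.csv",
    "niederer_reduced": "niederer_reduced_fitted_sets.csv",
}


def _data(name: str):
    return resources.files("zoomfit.data").joinpath(name)


def load_bundled_space(name: str) -> ParameterSpace:
    """Ranges + hard constraints for a bundled contraction model ('niederer', 'land')."""
    if name not in _SPACES:
        raise KeyError(f"unknown bundled space '{name}' (have {sorted(_SPACES)})")
    with _data(_SPACES[name]).open() as fh:
        return ParameterSpace.from_config(fh)


def load_fitted_sets(name: str) -> pd.DataFrame:
    """Bundled example tables of fitted parameter sets (columns = sets).

    'niederer' holds the three feasible sets of the full-model fit;
    'niederer_reduced' the four sets found with the fast relaxation term
    disabled (alpha_r2 = 0).
    """
    if name not in _FITTED:
        raise KeyError(f"unknown fitted-set table '{name}' (have {sorted(_FITTED)})")
    with _data(_FITTED[name]).open() as fh:
        return pd.read_csv(fh, index_col="parameter")


def load_bundled_criteria(name: str = "niederer") -> SuccessCriteria:
    """The mouse-twitch success bands used for the bundled Niederer-model fit."""
    if name != "niederer":
        raise KeyError("only the 'niederer' criteria are bundled")
    with _data("niederer_success_criteria.yaml").open() as fh:
        return SuccessCriteria.from_config(fh)
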