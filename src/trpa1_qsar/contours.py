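"""STDEV*COEFF contour fields from a fitted PLS model.

The displayed quantity at each grid point is the product of the column's
standard deviation across the training compounds and its PLS coefficient —
the conventional way of showing where a field channel drives predicted
activity up (favored) or down (disfavored). Contour levels are set by
cumulative-contribution mass: with the default 80/20 split, the favored
level isolates the top 20% of the positive |stdev*coeff| mass and the
disfavored level the bottom 20% of the negative mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import FieldMatrix
from .pls import PLSModel

__all__ = ["ContourField", "stdev_coeff", "contour_levels"]


@dataclass(frozen=True)
class ContourField:
    channel: str
    values: np.ndarray          # per grid point; zero at filtered columns
    favored_level: float
    disfavored_level: float
    grid: "object"              # GridSpec


def stdev_coeff(model: PLSModel, fm: FieldMatrix, channel: str,
                favored_pct: float = 80.0, disfavored_pct: float = 20.0) -> ContourField:
    """Per-point sigma_j * coef_j for one channel; filtered columns are 0."""
    if channel not in fm.channels:
        raise KeyError(f"unknown channel {channel!r}; have {fm.channels}")
    if model.channel_of_column is None:
        raise ValueError("model carries no channel labels")
    model_channels = [str(c) for c in dict.fromkeys(model.channel_of_column)]
    if channel not in model_channels:
        raise KeyError(f"channel {channel!r} not part of this model ({model_channels})")
    X = fm.channel_block(model_channels)
    labels = fm.channel_of_column(model_channels)
    if X.shape[1] != model.column_mask.size:
        raise ValueError("field matrix does not match the model's column layout")
    full = np.zeros(X.shape[1])
    sigma = X[:, model.column_mask].std(axis=0, ddof=1)
    full[model.column_mask] = sigma * model.coefficients
    values = full[labels == channel]
    fav, dis = contour_levels_from_values(values, favored_pct, disfavored_pct)
    return ContourField(channel=channel, values=values, favored_level=fav,
                        disfavored_level=dis, grid=fm.grid)


def contour_levels_from_values(
    values: np.ndarray, favored_pct: float = 80.0, disfavored_pct: float = 20.0
) -> tuple[float, float]:
    """Contour-by-contribution thresholds for a stdev*coeff field.

    Favored: the smallest positive value v such that the mass of values >= v
    is at most (100 - favored_pct)% of the total positive mass. Disfavored:
    mirrored on the negative side with disfavored_pct. An all-zero side
    yields a 0 level.
    """
    values = np.asarray(values, float)

    def _tail_level(mags: np.ndarray, tail_frac: float) -> float:
        # smallest magnitude kept so that the kept tail holds <= tail_frac
        # of the total magnitude mass (within one grid point's mass)
        if mags.size == 0 or mags.sum() == 0:
            return 0.0
        order = np.sort(mags)[::-1]
        cum = np.cumsum(order)
        keep = cum <= tail_frac * mags.sum()
        if not keep.any():
            return float(order[0])
        return float(order[keep.sum() - 1])

    fav = _tail_level(values[values > 0], (100.0 - favored_pct) / 100.0)
    dis = -_tail_level(-values[values < 0], disfavored_pct / 100.0)
    return fav, dis


def contour_levels(field: ContourField, favored_pct: float = 80.0,
                   disfavored_pct: float = 20.0) -> tuple[float, float]:
    """Recompute the (favored, disfavored) levels for an existing field."""
    return contour_levels_from_values(field.values, favored_pct, disfavored_pct)
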