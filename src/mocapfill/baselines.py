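"""Conventional gap-filling baselines: per-coordinate interpolation.

These are the methods practitioners reach for first — a natural cubic
spline or a straight line through each coordinate's observed samples —
and they serve as the reference the subspace reconstruction is compared
against.  They use no inter-marker information, so their error grows
quickly with gap length.

Gaps at the very start or end of a trajectory have support on one side
only; both fillers extrapolate there with the nearest observed value
(polynomial extrapolation over a boundary gap diverges and a constant is
the safe conventional choice).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import CubicSpline

from .dataset import MarkerDataset

logger = logging.getLogger(__name__)

__all__ = ["fill_spline", "fill_linear"]


def _fill_columns(dataset: MarkerDataset, interpolate) -> MarkerDataset:
    data = dataset.data.copy()
    t = np.arange(dataset.n_frames, dtype=float)
    for c in range(data.shape[1]):
        y = data[:, c]
        gaps = np.isnan(y)
        if not gaps.any():
            continue
        obs = ~gaps
        n_obs = int(obs.sum())
        if n_obs == 0:
            logger.warning("column %d has no observed samples; left as gaps", c)
            continue
        if n_obs == 1:
            logger.warning(
                "column %d has a single observed sample; constant fill", c
            )
            data[gaps, c] = y[obs][0]
            continue
        t_obs = t[obs]
        fill = interpolate(t_obs, y[obs], t)
        # boundary gaps: constant extrapolation from the nearest endpoint
        fill[t < t_obs[0]] = y[obs][0]
        fill[t > t_obs[-1]] = y[obs][-1]
        data[gaps, c] = fill[gaps]
    return dataset.with_data(data)


def fill_spline(dataset: MarkerDataset) -> MarkerDataset:
    """Fill each coordinate's gaps with a natural cubic spline through its
    observed samples."""

    def _spline(t_obs, y_obs, t):
        return CubicSpline(t_obs, y_obs, bc_type="natural")(t)

    return _fill_columns(dataset, _spline)


def fill_linear(dataset: MarkerDataset) -> MarkerDataset:
    """Fill each coordinate's gaps by straight-line interpolation."""

    def _linear(t_obs, y_obs, t):
        return np.interp(t, t_obs, y_obs)

    return _fill_columns(dataset, _linear)
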