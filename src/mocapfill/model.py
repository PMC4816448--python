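"""Model/Results interface to the gap-filling algorithm.

:class:`PCAGapFill` treats the reconstruction as a model fitted to data:
the complete frames of a corrupted trial are the training set, the pair of
truncated PC bases (full and zeroed) plus the transition matrix between
their score spaces are the fitted parameters, and applying them to the
zero-filled measurement matrix yields the estimate of the missing
coordinates.  ``fit()`` returns a :class:`GapFillResults` carrying the
filled dataset, per-marker diagnostics and, when the truth is known (e.g.
for artificially corrupted data), accuracy metrics.

    >>> model = PCAGapFill(corrupted, strategy="r2")
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.filled          # the gap-free MarkerDataset
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MarkerDataset
from .evaluation import ReconstructionError, score
from .strategies import FillReport, fill_gaps
from .weighting import ReconstructionParams

__all__ = ["PCAGapFill", "GapFillResults"]


class PCAGapFill:
    """Missing-marker reconstruction model for one corrupted trial.

    Parameters
    ----------
    dataset : MarkerDataset
        The corrupted trial (NaN = missing marker-frame).
    strategy : str
        ``"r1"`` (simultaneous), ``"r2"`` (consecutive, default) or one of
        the interpolation baselines ``"spline"`` / ``"linear"``.
    params : ReconstructionParams, optional
        The four algorithm parameters; defaults are w_mm=0.02,
        sigma=200 mm, theta_lambda=0.99, theta_d=0.5.
    """

    def __init__(
        self,
        dataset: MarkerDataset,
        strategy: str = "r2",
        params: ReconstructionParams | None = None,
    ):
        self.dataset = dataset
        self.strategy = strategy
        self.params = params or ReconstructionParams()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        frame_rate: float = 100.0,
        strategy: str = "r2",
        params: ReconstructionParams | None = None,
    ) -> "PCAGapFill":
        """Build the model from a ``<label>_X/_Y/_Z``-column DataFrame."""
        return cls(
            MarkerDataset.from_dataframe(df, frame_rate=frame_rate),
            strategy=strategy,
            params=params,
        )

    def fit(self) -> "GapFillResults":
        """Run the reconstruction and return its results."""
        filled, report = fill_gaps(self.dataset, self.strategy, self.params)
        return GapFillResults(model=self, filled=filled, report=report)


@dataclass
class GapFillResults:
    """Results of a gap-filling fit."""

    model: PCAGapFill
    filled: MarkerDataset
    report: FillReport
    _score: ReconstructionError | None = field(default=None, repr=False)

    @property
    def params(self) -> ReconstructionParams:
        return self.model.params

    @property
    def n_gap_frames(self) -> int:
        return self.report.n_gap_frames

    def score(self, truth: MarkerDataset) -> ReconstructionError:
        """Accuracy against the pristine trial (artificial-gap workflows)."""
        self._score = score(truth, self.filled, self.model.dataset.gap_mask)
        return self._score

    def gap_table(self) -> pd.DataFrame:
        """Per-marker gap counts and fill status."""
        rows = []
        for label, count in self.report.gap_counts.items():
            rows.append(
                {
                    "marker": label,
                    "gap_frames": count,
                    "filled": label not in self.report.unfilled,
                    "reason_unfilled": self.report.unfilled.get(label, ""),
                }
            )
        return pd.DataFrame(rows, columns=["marker", "gap_frames", "filled", "reason_unfilled"])

    def summary(self) -> str:
        """A readable summary table of the fit."""
        p = self.params
        d = self.model.dataset
        lines = [
            "        Missing-marker reconstruction",
            "=" * 48,
            f"strategy:        {self.report.strategy}",
            f"markers:         {d.n_markers}",
            f"frames:          {d.n_frames} @ {d.frame_rate:g} Hz",
            f"gap frames:      {self.n_gap_frames} in "
            f"{len(self.report.gap_counts)} marker(s)",
        ]
        if self.report.strategy in ("r1", "r2"):
            lines += [
                f"w_mm:            {p.w_mm:g}",
                f"sigma:           {p.sigma:g} mm",
                f"theta_lambda:    {p.theta_lambda:g}",
                f"theta_d:         {p.theta_d:g}",
            ]
        if self.report.unfilled:
            lines.append(f"UNFILLED:        {sorted(self.report.unfilled)}")
        else:
            lines.append("all gaps filled")
        if self._score is not None:
            lines += [
                "-" * 48,
                f"mean Euclidean error: {self._score.mean_euclidean:.3f} mm "
                f"over {self._score.n_gap_samples} gap samples",
            ]
        lines.append("=" * 48)
        return "\n".join(lines)

    def plot_marker(self, marker, truth: MarkerDataset | None = None, ax=None):
        """Plot one marker's filled trajectory (vertical axis by default)."""
        import matplotlib.pyplot as plt

        j = self.filled.marker_index(marker)
        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(self.filled.n_frames) / self.filled.frame_rate
        gaps = self.model.dataset.gap_mask.missing[:, j]
        z = self.filled.marker(j)[:, 2]
        ax.plot(t, np.where(gaps, np.nan, z), "k-", lw=0.8, label="observed")
        ax.plot(t, np.where(gaps, z, np.nan), "b-", lw=1.2, label="reconstructed")
        if truth is not None:
            ax.plot(t, truth.marker(j)[:, 2], "k:", lw=0.8, label="reference")
        ax.set_xlabel("time [s]")
        ax.set_ylabel("vertical position [mm]")
        ax.set_title(self.filled.labels[j])
        ax.legend(loc="best", fontsize="small")
        return ax
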