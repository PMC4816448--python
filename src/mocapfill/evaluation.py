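"""Error metrics, replicate experiments and parameter sensitivity sweeps.

Reconstruction accuracy is the mean Euclidean distance (mm) between the
filled and the true marker positions, pooled over every gap marker-frame
of a trial.  The replicate experiment repeats a randomized corruption of a
gap-free trial (50 copies by default), fills each copy, and summarizes the
per-copy accuracies by their median.  The sensitivity sweep varies one of
the four algorithm parameters at a time over its standard grid, on a set
of corrupted copies, and reports per-copy-centered mean errors: each
copy's across-grid mean is subtracted before averaging so that the curve
shows the parameter's effect rather than between-copy difficulty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .dataset import GapMask, MarkerDataset
from .exceptions import MocapFillError, ParameterError
from .strategies import fill_gaps
from .synthetic import GapSpec, corrupt_with_gaps
from .weighting import ReconstructionParams

logger = logging.getLogger(__name__)

__all__ = [
    "ReconstructionError",
    "ReplicateResult",
    "SensitivityGrid",
    "score",
    "replicate_experiment",
    "sensitivity_sweep",
    "default_grid",
]

#: the standard one-at-a-time sweep grids for the four parameters
DEFAULT_GRIDS = {
    "w_mm": np.logspace(-5, 0, 15),
    "sigma": np.linspace(100.0, 1500.0, 15),
    "theta_lambda": np.linspace(0.86, 1.0, 15),
    "theta_d": np.linspace(0.0, 2.0, 11),
}


def default_grid(parameter: str) -> np.ndarray:
    """The standard sweep grid for one of the four parameters."""
    try:
        return DEFAULT_GRIDS[parameter].copy()
    except KeyError:
        raise ParameterError(
            f"unknown parameter {parameter!r}; choose one of {sorted(DEFAULT_GRIDS)}"
        ) from None


@dataclass(frozen=True)
class ReconstructionError:
    """Accuracy metrics over the gap samples of one reconstruction."""

    mean_euclidean: float  # mm, pooled over all gap marker-frames
    per_axis_mae: tuple[float, float, float]  # mm, X/Y/Z
    per_marker: dict[str, float]  # label -> mean Euclidean error, mm
    n_gap_samples: int

    def to_dict(self) -> dict:
        return {
            "mean_euclidean_mm": self.mean_euclidean,
            "per_axis_mae_mm": list(self.per_axis_mae),
            "per_marker_mm": dict(self.per_marker),
            "n_gap_samples": self.n_gap_samples,
        }


def score(
    truth: MarkerDataset, filled: MarkerDataset, gap_mask: GapMask
) -> ReconstructionError:
    """Compare a filled dataset against the pristine truth over the gaps."""
    if truth.data.shape != filled.data.shape:
        raise ParameterError("truth and filled datasets have different shapes")
    missing = gap_mask.missing
    if missing.shape != (truth.n_frames, truth.n_markers):
        raise ParameterError("gap mask shape does not match the datasets")
    if not missing.any():
        raise ParameterError("gap mask is empty; nothing to score")

    t = truth.data.reshape(truth.n_frames, truth.n_markers, 3)
    f = filled.data.reshape(truth.n_frames, truth.n_markers, 3)
    diff = f - t
    dist = np.linalg.norm(diff, axis=2)  # (n, m)

    mean_euclid = float(dist[missing].mean())
    abs_diff = np.abs(diff[missing])  # (n_gap_samples, 3)
    per_axis = tuple(float(v) for v in abs_diff.mean(axis=0))
    per_marker = {
        truth.labels[j]: float(dist[missing[:, j], j].mean())
        for j in range(truth.n_markers)
        if missing[:, j].any()
    }
    return ReconstructionError(
        mean_euclidean=mean_euclid,
        per_axis_mae=per_axis,
        per_marker=per_marker,
        n_gap_samples=int(missing.sum()),
    )


@dataclass
class ReplicateResult:
    """Per-replicate accuracies of one method under a corruption protocol."""

    method: str
    errors: np.ndarray  # (n_replicates,), NaN where the method failed
    gap_fractions: np.ndarray  # fraction of frames containing a gap

    @property
    def median(self) -> float:
        return float(np.nanmedian(self.errors))

    @property
    def n_failed(self) -> int:
        return int(np.isnan(self.errors).sum())


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic child seeds below 2**31 from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2**31)


def replicate_experiment(
    dataset: MarkerDataset,
    gap_spec: GapSpec,
    method: str,
    params: ReconstructionParams | None = None,
    n_replicates: int = 50,
    seed: int = 0,
) -> ReplicateResult:
    """Corrupt-fill-score a gap-free dataset ``n_replicates`` times.

    ``method`` is one of ``r1``, ``r2``, ``spline``, ``linear``, or a
    callable mapping a corrupted MarkerDataset to a filled one.  A method
    failure on a replicate is recorded as NaN, not raised.
    """
    if dataset.has_gaps:
        raise ParameterError("replicate experiments need a gap-free dataset")
    seeds = _replicate_seeds(seed, n_replicates)
    errors = np.full(n_replicates, np.nan)
    gap_fractions = np.zeros(n_replicates)
    name = method if isinstance(method, str) else getattr(method, "__name__", "custom")
    for r in range(n_replicates):
        spec_r = _dc_replace(gap_spec, seed=int(seeds[r]))
        corrupted, _ = corrupt_with_gaps(dataset, spec_r)
        mask = corrupted.gap_mask
        gap_fractions[r] = float(mask.missing.any(axis=1).mean())
        try:
            if callable(method):
                filled = method(corrupted)
            else:
                filled, _ = fill_gaps(corrupted, method, params)
            errors[r] = score(dataset, filled, mask).mean_euclidean
        except MocapFillError as exc:
            logger.warning("replicate %d: %s failed: %s", r, name, exc)
    return ReplicateResult(method=name, errors=errors, gap_fractions=gap_fractions)


def plot_error_boxplot(results: dict[str, "ReplicateResult"], ax=None):
    """Boxplots of per-replicate accuracies, one box per method (log scale)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = list(results)
    data = [results[k].errors[~np.isnan(results[k].errors)] for k in labels]
    ax.boxplot(data, tick_labels=labels)
    ax.set_yscale("log")
    ax.set_ylabel("reconstruction error [mm]")
    return ax


@dataclass
class SensitivityGrid:
    """Result of a one-at-a-time parameter sweep."""

    parameter: str
    values: np.ndarray
    centered_mean: np.ndarray  # mm, averaged over copies after per-copy centering
    sem: np.ndarray  # standard error of the mean over copies
    per_copy: np.ndarray = field(repr=False)  # (n_copies_total, n_grid), centered

    def optimum(self) -> float:
        """Grid value with the lowest centered mean error."""
        return float(self.values[np.nanargmin(self.centered_mean)])


def sensitivity_sweep(
    datasets,
    parameter: str,
    grid=None,
    params_default: ReconstructionParams | None = None,
    n_copies: int = 20,
    seed: int = 0,
    method: str = "r2",
) -> SensitivityGrid:
    """One-at-a-time sensitivity of the reconstruction to one parameter.

    ``datasets`` is a sequence of ``(MarkerDataset, GapSpec)`` pairs (the
    gap-free trial and its corruption protocol).  For every corrupted copy
    the whole grid is evaluated; each copy's across-grid mean error is
    subtracted (so copies of different difficulty are comparable) and the
    centered curves are averaged, with their standard error.
    """
    params_default = params_default or ReconstructionParams()
    if parameter not in DEFAULT_GRIDS:
        raise ParameterError(
            f"unknown parameter {parameter!r}; choose one of {sorted(DEFAULT_GRIDS)}"
        )
    grid = np.asarray(default_grid(parameter) if grid is None else grid, dtype=float)
    datasets = list(datasets)
    rows = []
    copy_seeds = _replicate_seeds(seed, n_copies * len(datasets))
    s_idx = 0
    for dataset, gap_spec in datasets:
        for _ in range(n_copies):
            spec_c = _dc_replace(gap_spec, seed=int(copy_seeds[s_idx]))
            s_idx += 1
            corrupted, _ = corrupt_with_gaps(dataset, spec_c)
            mask = corrupted.gap_mask
            errs = np.full(grid.size, np.nan)
            for g, value in enumerate(grid):
                try:
                    p = _dc_replace(params_default, **{parameter: float(value)})
                    filled, _ = fill_gaps(corrupted, method, p)
                    errs[g] = score(dataset, filled, mask).mean_euclidean
                except MocapFillError as exc:
                    logger.warning(
                        "%s=%g failed on one copy: %s", parameter, value, exc
                    )
            rows.append(errs - np.nanmean(errs))
    per_copy = np.array(rows)
    n_ok = np.sum(~np.isnan(per_copy), axis=0)
    centered_mean = np.nanmean(per_copy, axis=0)
    sem = np.nanstd(per_copy, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
    return SensitivityGrid(
        parameter=parameter,
        values=grid,
        centered_mean=centered_mean,
        sem=sem,
        per_copy=per_copy,
    )
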