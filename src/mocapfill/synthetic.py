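"""Synthetic gait-like marker data and artificial gap corruption.

The generator emulates the statistical structure the reconstruction
algorithm relies on: a near-low-rank measurement matrix of highly
intercorrelated marker coordinates.  Markers are grouped into body-segment
clusters placed in a body-sized volume, mirroring how real marker sets
attach several markers to each limb segment.  Movement is a small number
of latent oscillations at harmonics of the stride frequency (plus a slow
drift); each segment has its own loading on every latent component, shared
by the segment's markers up to a small marker-specific perturbation (a
soft-tissue-like wobble), and one component is common to the whole body
(sway).  This segment structure gives the properties of real gait data
that matter here: markers on the same segment move near-rigidly (so mean
inter-marker distances are anatomy-like and Gaussian distance weighting is
informative and well-conditioned), markers on different segments are
correlated only through the shared latents, and the whole matrix has
numerical rank ``latent_rank + 1`` before noise.  Optional
extras emulate the harder cases: a mid-trial regime switch (walk-to-run)
that changes the correlation structure, and stride-phase irregularity
(impaired, less repetitive gait).  White measurement noise of a fraction
of a millimetre mimics optical capture noise.

Gap corruption follows the randomized protocols used for evaluation:
a uniform number of gaps, each on a uniformly random marker at a uniformly
random onset with uniform duration; gaps on the same marker may overlap
(their union is taken).  Configurations leaving fewer than 5% of frames
complete are redrawn so the subspace methods always have training rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .dataset import MarkerDataset
from .exceptions import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "GaitModelParams",
    "GapSpec",
    "Gap",
    "generate_gait",
    "corrupt_with_gaps",
    "make_single_marker_gap",
    "walkl_like",
    "cp_gait_like",
    "walkrun_like",
]

#: minimum fraction of frames that must stay complete after corruption
COMPLETE_FRAME_FLOOR = 0.05


@dataclass(frozen=True)
class GaitModelParams:
    """Parameters of the synthetic gait model.

    ``amplitude_scale`` is the RMS excursion (mm) of the dominant movement
    component; higher harmonics decay as 1/(l+1).  ``irregularity`` (rad)
    adds slow random stride-phase modulation, emulating less repetitive
    gait.  ``articulation`` (fraction of ``amplitude_scale``) adds a tail
    of weak second-order interaction components with their own segment
    windows, emulating the rotational kinematics that make real marker
    data only approximately low-rank; with it the matrix is near-low-rank
    rather than exactly low-rank.  ``soft_tissue_sd`` (mm) adds smooth,
    marker-specific artifact motion (skin-mounted markers moving relative
    to bone) that no other marker can predict; it sets a realistic floor
    on reconstruction accuracy.  ``transition_frame`` switches to a
    second movement regime (new loadings, 1.5x stride frequency) with a
    short smooth blend.
    """

    n_markers: int = 37
    n_frames: int = 2000
    frame_rate: float = 240.0
    stride_frequency: float = 0.9
    amplitude_scale: float = 300.0
    latent_rank: int = 8
    noise_sd: float = 0.5
    irregularity: float = 0.0
    articulation: float = 0.0
    soft_tissue_sd: float = 0.0
    transition_frame: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_markers < 2 or self.n_frames < 2:
            raise ParameterError("need at least 2 markers and 2 frames")
        if not 1 <= self.latent_rank < 3 * self.n_markers:
            raise ParameterError("latent_rank must be in [1, 3*n_markers)")
        if self.noise_sd < 0 or self.soft_tissue_sd < 0:
            raise ParameterError("noise amplitudes must be >= 0")
        if self.frame_rate <= 0 or self.stride_frequency <= 0:
            raise ParameterError("rates must be positive")
        if self.transition_frame is not None and not (
            0 < self.transition_frame < self.n_frames
        ):
            raise ParameterError("transition_frame must fall inside the trial")


class Gap(NamedTuple):
    """One realized artificial gap."""

    marker: int
    start: int
    length: int


@dataclass(frozen=True)
class GapSpec:
    """Randomized corruption protocol: gap count and duration ranges."""

    n_gaps_range: tuple[int, int] = (5, 15)
    gap_len_range: tuple[int, int] = (20, 480)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.n_gaps_range
        llo, lhi = self.gap_len_range
        if lo < 1 or hi < lo or llo < 1 or lhi < llo:
            raise ParameterError("gap count/length ranges must be positive and ordered")


def _latent(params: GaitModelParams, rng: np.random.Generator, stride: float) -> np.ndarray:
    """(n, r) unit-RMS latent time courses: stride harmonics plus drift."""
    n, r = params.n_frames, params.latent_rank
    t = np.arange(n) / params.frame_rate

    def phase_mod() -> np.ndarray:
        """Slow random phase modulation: irregular stride timing.  Each
        component gets its own modulation, so the relative phase between
        movement components (e.g. between limbs) drifts over the trial the
        way inter-limb coordination does in real gait."""
        out = np.zeros(n)
        if params.irregularity > 0:
            for _ in range(3):
                f = rng.uniform(0.05, 0.3)
                out += (
                    params.irregularity
                    * rng.normal()
                    * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
                )
        return out

    cols = []
    for l in range(r - 1):
        harmonic = 1 + l % 4
        phi = rng.uniform(0, 2 * np.pi)
        cols.append(
            np.sin(2 * np.pi * stride * harmonic * t + phi + harmonic * phase_mod())
        )
    # slow drift (postural sway / treadmill drift)
    cols.append(np.sin(2 * np.pi * (stride / 20.0) * t + rng.uniform(0, 2 * np.pi)))
    latent = np.column_stack(cols)
    rms = np.sqrt((latent**2).mean(axis=0))
    return latent / np.where(rms > 0, rms, 1.0)


#: within-segment loading perturbation relative to the segment loading
#: (soft-tissue-like wobble of individual markers)
_WOBBLE = 0.02


def _segment_layout(
    params: GaitModelParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Assign markers to body-segment clusters; return (base, segment_of)."""
    m = params.n_markers
    n_segments = max(3, m // 4)
    centers = np.column_stack(
        [
            rng.uniform(-200, 200, n_segments),
            rng.uniform(-200, 200, n_segments),
            rng.uniform(0, 1800, n_segments),
        ]
    )
    # order the chain along the body axis so that segments adjacent in the
    # chain (which share latent components) are also spatial neighbours
    centers = centers[np.argsort(centers[:, 2])]
    segment_of = np.arange(m) % n_segments
    base = centers[segment_of] + rng.normal(0, 60.0, size=(m, 3))
    return base, segment_of


def _loadings(
    params: GaitModelParams,
    rng: np.random.Generator,
    segment_of: np.ndarray,
) -> np.ndarray:
    """(r, 3m) loadings with kinematic-chain locality.

    The first component is whole-body common mode (sway) and the last a
    global posture drift; each intermediate component loads only on a
    contiguous window of the segment chain, like limb-specific movement
    components.  Within an active segment the loading is shared by the
    segment's markers up to a small soft-tissue-like wobble.
    """
    r = params.latent_rank
    m = params.n_markers
    n_segments = int(segment_of.max()) + 1
    width = max(2, -(-n_segments // 3))
    n_local = max(r - 2, 0)
    a = np.empty((r, 3 * m))
    for l in range(r):
        amp = params.amplitude_scale / (l + 1)
        if l == 0 or l == r - 1 or n_local == 0:
            active = np.ones(n_segments, dtype=bool)
        else:
            start = round((l - 1) * max(n_segments - width, 0) / max(n_local - 1, 1))
            active = np.zeros(n_segments, dtype=bool)
            active[start : start + width] = True
        for ax in range(3):
            if l == 0:  # whole-body sway, identical for every segment
                gamma = np.full(n_segments, rng.normal())
            else:
                gamma = np.where(active, rng.normal(size=n_segments), 0.0)
            per_marker = gamma[segment_of] + _WOBBLE * rng.normal(size=m) * active[
                segment_of
            ]
            a[l, ax::3] = amp * per_marker
    return a


def _articulation_motion(
    params: GaitModelParams,
    rng: np.random.Generator,
    latent: np.ndarray,
    segment_of: np.ndarray,
) -> np.ndarray:
    """Weak second-order interaction components (articulated kinematics).

    Products of latent pairs add many individually-small components with
    random segment windows; together they form the near-low-rank tail of
    the singular spectrum that rotational joint kinematics produce in real
    marker data.
    """
    n_pairs = max(2 * params.latent_rank, 8)
    n_segments = int(segment_of.max()) + 1
    width = max(2, -(-n_segments // 3))
    m = params.n_markers
    total = np.zeros((params.n_frames, 3 * m))
    amp = params.articulation * params.amplitude_scale / np.sqrt(n_pairs)
    for _ in range(n_pairs):
        i, j = rng.choice(latent.shape[1], size=2, replace=False)
        comp = latent[:, i] * latent[:, j]
        rms = float(np.sqrt((comp**2).mean()))
        comp = comp / (rms if rms > 0 else 1.0)
        start = int(rng.integers(0, n_segments - width + 1))
        active = np.zeros(n_segments, dtype=bool)
        active[start : start + width] = True
        for ax in range(3):
            gamma = np.where(active, rng.normal(size=n_segments), 0.0)
            total[:, ax::3] += amp * comp[:, None] * gamma[segment_of][None, :]
    return total


def _soft_tissue_artifact(
    params: GaitModelParams, rng: np.random.Generator
) -> np.ndarray:
    """Smooth, marker-specific artifact motion, RMS ``soft_tissue_sd`` mm.

    Low-pass filtered white noise per coordinate (cutoff at twice the
    stride frequency), independent between markers, emulating skin
    movement relative to the underlying bone.
    """
    from scipy.signal import butter, filtfilt

    n = params.n_frames
    p = 3 * params.n_markers
    cutoff = min(2.0 * params.stride_frequency, 0.45 * params.frame_rate)
    b, a = butter(2, cutoff, fs=params.frame_rate)
    raw = rng.normal(size=(n, p))
    smooth = filtfilt(b, a, raw, axis=0)
    rms = np.sqrt((smooth**2).mean(axis=0))
    return params.soft_tissue_sd * smooth / np.where(rms > 0, rms, 1.0)


def generate_gait(params: GaitModelParams) -> MarkerDataset:
    """Generate a gap-free, gait-like marker dataset (mm). Deterministic
    given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    m, n = params.n_markers, params.n_frames
    base, segment_of = _segment_layout(params, rng)
    latent = _latent(params, rng, params.stride_frequency)
    motion = latent @ _loadings(params, rng, segment_of)
    if params.articulation > 0:
        motion = motion + _articulation_motion(params, rng, latent, segment_of)
    if params.transition_frame is not None:
        motion2 = _latent(params, rng, 1.5 * params.stride_frequency) @ _loadings(
            params, rng, segment_of
        )
        tau = max(params.frame_rate * 0.1, 1.0)
        blend = 1.0 / (
            1.0 + np.exp(-(np.arange(n) - params.transition_frame) / tau)
        )
        motion = (1 - blend[:, None]) * motion + blend[:, None] * motion2
    data = np.repeat(base[None, :, :], n, axis=0).reshape(n, 3 * m) + motion
    if params.soft_tissue_sd > 0:
        data = data + _soft_tissue_artifact(params, rng)
    if params.noise_sd > 0:
        data = data + rng.normal(0, params.noise_sd, size=data.shape)
    labels = [f"M{j + 1}" for j in range(m)]
    return MarkerDataset(
        data=data, labels=labels, frame_rate=params.frame_rate, units="mm"
    )


def corrupt_with_gaps(
    dataset: MarkerDataset, spec: GapSpec, max_redraws: int = 200
) -> tuple[MarkerDataset, list[Gap]]:
    """Apply the randomized gap protocol to a gap-free dataset.

    Returns the corrupted copy and the realized gap list.  The whole
    configuration is redrawn when fewer than 5% of frames stay complete.
    """
    if dataset.has_gaps:
        raise ParameterError("corruption requires a gap-free dataset")
    n, m = dataset.n_frames, dataset.n_markers
    if spec.gap_len_range[1] >= n:
        raise ParameterError(
            f"maximum gap length {spec.gap_len_range[1]} does not fit in "
            f"{n} frames"
        )
    rng = np.random.default_rng(spec.seed)
    for attempt in range(max_redraws):
        n_gaps = int(rng.integers(spec.n_gaps_range[0], spec.n_gaps_range[1] + 1))
        gaps = []
        mask = np.zeros((n, m), dtype=bool)
        for _ in range(n_gaps):
            marker = int(rng.integers(0, m))
            length = int(
                rng.integers(spec.gap_len_range[0], spec.gap_len_range[1] + 1)
            )
            start = int(rng.integers(0, n - length + 1))
            mask[start : start + length, marker] = True
            gaps.append(Gap(marker=marker, start=start, length=length))
        complete = ~mask.any(axis=1)
        if complete.sum() >= COMPLETE_FRAME_FLOOR * n:
            if attempt:
                logger.info(
                    "gap configuration accepted after %d redraws", attempt
                )
            data = dataset.data.copy()
            data[np.repeat(mask, 3, axis=1)] = np.nan
            return dataset.with_data(data), gaps
    raise ParameterError(
        f"could not draw a gap configuration leaving {COMPLETE_FRAME_FLOOR:.0%} "
        f"of frames complete in {max_redraws} attempts"
    )


def make_single_marker_gap(
    dataset: MarkerDataset, marker: int | str, start_frame: int, end_frame: int
) -> MarkerDataset:
    """Blank one marker over the inclusive frame range [start, end]."""
    j = dataset.marker_index(marker)
    if end_frame < start_frame:
        return dataset.copy()
    if start_frame < 0 or end_frame >= dataset.n_frames:
        raise ParameterError(
            f"frame range [{start_frame}, {end_frame}] outside 0..{dataset.n_frames - 1}"
        )
    data = dataset.data.copy()
    data[start_frame : end_frame + 1, 3 * j : 3 * j + 3] = np.nan
    return dataset.with_data(data)


# ----------------------------------------------------------------------
# presets mirroring the three study conditions

def walkl_like(seed: int = 0, n_frames: int = 4300) -> GaitModelParams:
    """Long treadmill walking: 37 markers at 240 Hz.

    Mild stride-phase variability and a weak articulation tail reflect that
    even steady treadmill gait is only approximately cyclic and its marker
    matrix only approximately low-rank.
    """
    return GaitModelParams(
        n_markers=37,
        n_frames=n_frames,
        frame_rate=240.0,
        irregularity=0.3,
        articulation=0.1,
        soft_tissue_sd=1.0,
        seed=seed,
    )


def cp_gait_like(seed: int = 0) -> GaitModelParams:
    """Short, irregular gait: 35 markers, 600 frames at 200 Hz."""
    return GaitModelParams(
        n_markers=35,
        n_frames=600,
        frame_rate=200.0,
        stride_frequency=0.8,
        irregularity=0.6,
        articulation=0.15,
        soft_tissue_sd=2.0,
        seed=seed,
    )


def walkrun_like(seed: int = 0) -> GaitModelParams:
    """Walk-to-run transition: 30 markers, 400 frames at 120 Hz, regime
    switch mid-trial."""
    return GaitModelParams(
        n_markers=30,
        n_frames=400,
        frame_rate=120.0,
        stride_frequency=0.9,
        irregularity=0.3,
        articulation=0.1,
        soft_tissue_sd=1.5,
        transition_frame=160,
        seed=seed,
    )
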