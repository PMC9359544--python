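"""Articulated low-rank synthetic motion with known ground truth.

Real marker trajectories are smooth, highly correlated across markers (the
skeleton moves as a small number of coordinated degrees of freedom), and
observed with small sensor noise.  The generator emulates exactly that: a few
latent smooth time courses (sinusoids with random frequencies, phases and
amplitudes) multiplied by a random loading matrix give an m x 3n matrix of
exact rank ``latent_rank`` before noise; white Gaussian noise of standard
deviation ``noise_sd`` is added on top.  An optional *burst* adds a sharp
localized oscillation around one marker — the "big fluctuations" regime in
which gaps are hardest to fill — loaded on the burst marker and its skeleton
neighbours only, and windowed in time.

Gap simulation reproduces the experimental protocols used throughout the
package: a single long gap on one marker (default length 380 of 400 frames),
G gaps on G distinct markers, or one run of G consecutive wholly missing
frames, all placed uniformly at random.

All randomness flows through one seeded :class:`numpy.random.Generator`, so a
(seed, config) pair reproduces every sample bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motion_io import FrameGapSpec, GapSpec, MotionSample, SkeletonModel

__all__ = [
    "BurstConfig",
    "SynthConfig",
    "generate_motion",
    "generate_motion_family",
    "simulate_gaps",
    "make_training_windows",
]


@dataclass
class BurstConfig:
    """A sharp localized oscillation: ``amplitude * sin(2 pi freq t)`` under a
    Hann window of ``width`` frames centered at ``center``, loaded on
    ``marker`` and its skeleton neighbours within graph distance ``radius``."""

    marker: int
    center: int
    width: int = 60
    amplitude: float = 1.5
    frequency: float = 0.15  # cycles per frame
    radius: int = 1
    every: int | None = None  # repeat the burst every `every` frames (recurring motif)


@dataclass
class SynthConfig:
    """Generator settings.

    Defaults mirror the experimental geometry used throughout: 400-frame
    samples, 41 markers.  ``latent_rank`` counts the independent smooth
    degrees of freedom; ``noise_sd`` is in the same (arbitrary) length units
    as the positions, whose latent scale is O(1).
    """

    n_markers: int = 41
    m_frames: int = 400
    latent_rank: int = 8
    noise_sd: float = 0.02
    topology: str = "tree"
    burst: BurstConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank > min(self.m_frames, 3 * self.n_markers):
            raise ValueError(
                f"latent_rank {self.latent_rank} exceeds min(m, 3n) = "
                f"{min(self.m_frames, 3 * self.n_markers)}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.topology not in ("chain", "tree"):
            raise ValueError(f"unknown topology {self.topology!r}")


def _skeleton(n: int, topology: str) -> SkeletonModel:
    if topology == "chain":
        edges = [(j, j + 1) for j in range(n - 1)]
    else:  # balanced binary tree: parent (j-1)//2
        edges = [((j - 1) // 2, j) for j in range(1, n)]
    return SkeletonModel.from_edges(n, edges)


def generate_motion(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[MotionSample, SkeletonModel]:
    """Generate one smooth low-rank motion sample plus its skeleton.

    The latent courses are ``a_r sin(2 pi f_r t + phi_r)`` with frequencies
    in [0.002, 0.02] cycles/frame (1-10 periods across 500 frames), amplitudes
    in [0.5, 2], i.i.d. Gaussian loadings scaled by 1/sqrt(rank); the noiseless
    matrix has exact rank ``latent_rank`` (generically).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m, n, r = config.m_frames, config.n_markers, config.latent_rank
    t = np.arange(m)
    freqs = rng.uniform(0.002, 0.02, size=r)
    phases = rng.uniform(0, 2 * np.pi, size=r)
    amps = rng.uniform(0.5, 2.0, size=r)
    courses = amps * np.sin(2 * np.pi * freqs * t[:, None] + phases)  # m x r
    loadings = rng.normal(size=(r, 3 * n)) / np.sqrt(r)
    values = courses @ loadings

    skeleton = _skeleton(n, config.topology)
    if config.burst is not None:
        values = values + _burst_component(config.burst, m, n, skeleton, rng)
    if config.noise_sd > 0:
        values = values + rng.normal(scale=config.noise_sd, size=values.shape)
    names = [f"M{j}" for j in range(n)]
    return MotionSample(values=values, marker_names=names), skeleton


def generate_motion_family(
    config: SynthConfig, count: int, rng: np.random.Generator | None = None
) -> tuple[list[MotionSample], SkeletonModel]:
    """Samples sharing one set of latent time courses, independent loadings.

    All samples are driven by the same smooth courses (the same motion
    pattern) expressed through different random marker loadings, so they
    share their frame-correlation (Gram) structure exactly — the regime the
    whole-frame recovery model assumes.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m, n, r = config.m_frames, config.n_markers, config.latent_rank
    t = np.arange(m)
    freqs = rng.uniform(0.002, 0.02, size=r)
    phases = rng.uniform(0, 2 * np.pi, size=r)
    amps = rng.uniform(0.5, 2.0, size=r)
    courses = amps * np.sin(2 * np.pi * freqs * t[:, None] + phases)
    skeleton = _skeleton(n, config.topology)
    names = [f"M{j}" for j in range(n)]
    samples = []
    for _ in range(count):
        values = courses @ (rng.normal(size=(r, 3 * n)) / np.sqrt(r))
        if config.noise_sd > 0:
            values = values + rng.normal(scale=config.noise_sd, size=values.shape)
        samples.append(MotionSample(values=values, marker_names=names))
    return samples, skeleton


def _burst_component(
    burst: BurstConfig, m: int, n: int, skeleton: SkeletonModel, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(m)
    half = burst.width / 2
    offset = t - burst.center
    if burst.every is not None:  # recurring motif: nearest repetition of the center
        offset = (offset + burst.every / 2) % burst.every - burst.every / 2
    inside = np.abs(offset) <= half
    window = np.where(inside, 0.5 * (1 + np.cos(np.pi * offset / half)), 0.0)
    course = burst.amplitude * window * np.sin(2 * np.pi * burst.frequency * t)
    import networkx as nx

    dists = nx.single_source_dijkstra_path_length(skeleton.graph, burst.marker, weight="weight")
    load = np.zeros(3 * n)
    for j, d in dists.items():
        if d <= burst.radius:
            load[3 * j : 3 * j + 3] = rng.normal(size=3) * (0.5 ** d)
    return course[:, None] * load[None, :]


def simulate_gaps(
    shape: tuple[int, int],
    protocol: str,
    count: int = 1,
    gap_length: int = 380,
    seed: int | np.random.Generator = 0,
) -> list[GapSpec] | list[FrameGapSpec]:
    """Randomly place gaps following one of the three protocols.

    ``single``: one gap of ``gap_length`` frames on one random marker;
    ``multiple``: ``count`` gaps of ``gap_length`` frames on distinct random
    markers; ``frames``: one run of ``count`` consecutive wholly missing
    frames.  Start positions are uniform over the feasible range; all draws
    come from the given seed or generator.
    """
    m, n = shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if protocol in ("single", "multiple"):
        g = 1 if protocol == "single" else int(count)
        if gap_length > m:
            raise ValueError(f"gap_length {gap_length} exceeds {m} frames")
        if g > n:
            raise ValueError(f"{g} gaps need {g} distinct markers but only {n} exist")
        markers = rng.choice(n, size=g, replace=False)
        starts = rng.integers(0, m - gap_length + 1, size=g)
        return [
            GapSpec(marker=int(j), start=int(s), end=int(s) + gap_length)
            for j, s in zip(markers, starts)
        ]
    if protocol == "frames":
        g = int(count)
        if g > m:
            raise ValueError(f"{g} missing frames exceed {m} frames")
        s = int(rng.integers(0, m - g + 1))
        return [FrameGapSpec(start=s, end=s + g)]
    raise ValueError(f"unknown protocol {protocol!r}")


def make_training_windows(
    sequence: MotionSample,
    window: int = 400,
    count: int | None = None,
    stride: int | None = None,
) -> list[MotionSample]:
    """Cut training samples of ``window`` consecutive frames from a sequence.

    Windows are non-overlapping by default (``stride = window``); ``count``
    limits how many are taken (from the start) and errors if the sequence is
    too short to supply them.
    """
    stride = window if stride is None else stride
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be positive")
    starts = list(range(0, sequence.n_frames - window + 1, stride))
    if count is not None:
        if count > len(starts):
            raise ValueError(
                f"requested {count} windows of {window} frames but only "
                f"{len(starts)} fit in {sequence.n_frames} frames at stride {stride}"
            )
        starts = starts[:count]
    if not starts:
        raise ValueError(f"sequence of {sequence.n_frames} frames is shorter than window {window}")
    return [
        MotionSample(
            values=sequence.values[s : s + window].copy(),
            marker_names=sequence.marker_names,
            mask=sequence.mask[s : s + window].copy(),
            frame_rate=sequence.frame_rate,
        )
        for s in starts
    ]
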