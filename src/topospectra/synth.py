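"""Synthetic paired-modality study generator.

Emulates the inputs of a bimodal connectome/electrophysiology study: for each
subject and condition a BOLD-like regional time-series matrix whose empirical
correlation structure contains planted high-correlation rings (guaranteeing
H1 features downstream), and a paired MEG-like matrix whose regional signals
are 1/f^chi aperiodic processes plus narrowband oscillators.  A coupling
parameter ties the planted task-vs-rest change of each region's cycle
participation to a change of its aperiodic exponent, so that the
theta-alpha aperiodic band power moves in the same direction as the planted
persistence-centrality change.

The BOLD-like generator is a Gaussian latent-factor construction: it targets
a correlation matrix with ring-adjacent entries high and chords low, projects
it to the nearest valid (positive semi-definite, unit-diagonal) correlation
matrix, and samples via its Cholesky-like square root.  Randomness is split
into independent streams keyed by (modality, subject, condition, region) so
subsets are reproducible.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .connectome import FunctionalConnectome

__all__ = [
    "PlantedRing",
    "SyntheticStudyConfig",
    "RegionalTimeSeriesSet",
    "generate_bold_like",
    "generate_meg_like",
    "fixture_ring_connectome",
    "planted_delta_pc_signs",
]

DEFAULT_CONDITIONS = (
    "rest",
    "motor_lh", "motor_rh", "motor_lf", "motor_rf",
    "wm_0b_faces", "wm_0b_tools", "wm_2b_faces", "wm_2b_tools",
)


@dataclasses.dataclass(frozen=True)
class PlantedRing:
    """A ring of regions with per-state adjacent correlations.

    Consecutive regions (cyclically) correlate at ``r_within_rest`` during
    rest and ``r_within_task`` during tasks; chords and edges to the rest of
    the cortex sit at ``r_cross``.  The planted persistence-centrality change
    of the ring's members has the sign of ``r_within_task - r_within_rest``.
    """

    regions: tuple[int, ...]
    r_within_rest: float
    r_within_task: float
    r_cross: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if len(self.regions) < 4:
            raise ValueError(
                "ring subsets need >= 4 regions (a 3-clique fills immediately "
                "and yields no H1 feature)"
            )
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("ring regions must be distinct")
        for r in (self.r_within_rest, self.r_within_task, self.r_cross):
            if not (-1.0 < r < 1.0):
                raise ValueError("correlations must lie in (-1, 1)")
        if self.r_within_rest <= self.r_cross and self.r_within_task <= self.r_cross:
            raise ValueError("ring correlation must exceed the chord correlation")

    def r_within(self, condition_is_rest: bool) -> float:
        return self.r_within_rest if condition_is_rest else self.r_within_task

    @property
    def delta_sign(self) -> int:
        return int(np.sign(self.r_within_task - self.r_within_rest))


def _default_rings() -> tuple[PlantedRing, ...]:
    # one ring dissolving and one forming under task demand: negative planted
    # dPC on the first, positive on the second
    return (
        PlantedRing(regions=tuple(range(0, 6)), r_within_rest=0.55,
                    r_within_task=0.25, r_cross=0.1),
        PlantedRing(regions=tuple(range(6, 12)), r_within_rest=0.25,
                    r_within_task=0.55, r_cross=0.1),
    )


@dataclasses.dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study-level parameters shared by both modality generators."""

    n_subjects: int = 10
    n_regions: int = 30
    n_timepoints_bold: int = 400
    fs_meg: float = 500.0
    duration_meg: float = 12.0
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    planted_rings: tuple[PlantedRing, ...] = dataclasses.field(
        default_factory=_default_rings
    )
    chi_baseline: float = 2.0
    chi_offset: float = 0.4
    peak_specs: tuple[tuple[float, float, float], ...] = ((10.0, 0.3, 1.0),)
    measurement_noise: float = 0.05
    coupling_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "planted_rings", tuple(self.planted_rings))
        object.__setattr__(
            self, "peak_specs", tuple(tuple(p) for p in self.peak_specs)
        )
        if self.n_subjects < 1 or self.n_regions < 1:
            raise ValueError("need at least one subject and one region")
        if not self.conditions or self.conditions[0] != "rest":
            raise ValueError("conditions must start with the 'rest' label")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.chi_baseline <= 0:
            raise ValueError("aperiodic exponent must be positive")
        for ring in self.planted_rings:
            if max(ring.regions) >= self.n_regions:
                raise ValueError("planted ring references a region out of range")
        for (center, _amp, _bw) in self.peak_specs:
            if not (0.0 < center < self.fs_meg / 2.0):
                raise ValueError("peak center must lie in (0, fs/2)")
        if self.duration_meg < 12.0:
            raise ValueError(
                "duration_meg below 12 s cannot support 2-s Welch windows "
                "with enough segments"
            )

    @property
    def region_labels(self) -> tuple[str, ...]:
        return tuple(f"R{i:03d}" for i in range(self.n_regions))

    @property
    def task_conditions(self) -> tuple[str, ...]:
        return self.conditions[1:]


@dataclasses.dataclass(frozen=True)
class RegionalTimeSeriesSet:
    """(subject x region x time) series for one condition of one modality."""

    data: np.ndarray
    modality: str  # "bold-like" | "meg-like"
    fs: float
    condition: str
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ValueError("expected (subjects x regions x time) data")
        if not np.all(np.isfinite(d)):
            raise ValueError("time series contain non-finite values")
        if np.any(d.std(axis=-1) == 0):
            raise ValueError("constant time series generated")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


def _rng(config: SyntheticStudyConfig, modality: int, subject: int,
         condition_idx: int, region: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=config.seed, spawn_key=(modality, subject, condition_idx, region)
        )
    )


def planted_delta_pc_signs(config: SyntheticStudyConfig) -> np.ndarray:
    """Per-region sign (+1/-1/0) of the planted task-minus-rest PC change."""
    signs = np.zeros(config.n_regions, dtype=int)
    for ring in config.planted_rings:
        for r in ring.regions:
            signs[r] = ring.delta_sign
    return signs


def _target_correlation(config: SyntheticStudyConfig, is_rest: bool) -> np.ndarray:
    n = config.n_regions
    C = np.zeros((n, n))
    for ring in config.planted_rings:
        members = ring.regions
        k = len(members)
        for a in members:
            C[a, list(members)] = ring.r_cross
            cross = [j for j in range(n) if j not in members]
            C[a, cross] = np.maximum(C[a, cross], ring.r_cross)
            C[cross, a] = C[a, cross]
        for idx in range(k):
            a, b = members[idx], members[(idx + 1) % k]
            C[a, b] = C[b, a] = ring.r_within(is_rest)
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0
    return C


def _nearest_psd_correlation(C: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping followed by unit-diagonal rescaling."""
    vals, vecs = np.linalg.eigh(C)
    if vals.min() >= eps:
        return C
    vals = np.clip(vals, eps, None)
    C2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(C2))
    C2 = C2 / np.outer(d, d)
    np.fill_diagonal(C2, 1.0)
    return (C2 + C2.T) / 2.0


def _correlation_root(C: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def generate_bold_like(
    config: SyntheticStudyConfig, condition: str
) -> RegionalTimeSeriesSet:
    """Gaussian regional series whose correlations contain the planted rings."""
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if config.n_timepoints_bold < 3 * config.n_regions:
        warnings.warn(
            "fewer than 3 x n_regions timepoints: empirical correlations "
            "will be unstable",
            stacklevel=2,
        )
    is_rest = condition == "rest"
    cond_idx = config.conditions.index(condition)
    C = _nearest_psd_correlation(_target_correlation(config, is_rest))
    L = _correlation_root(C)
    T = config.n_timepoints_bold
    data = np.empty((config.n_subjects, config.n_regions, T))
    for s in range(config.n_subjects):
        Z = np.stack(
            [
                _rng(config, 0, s, cond_idx, r).standard_normal(T)
                for r in range(config.n_regions)
            ]
        )
        data[s] = L @ Z
    return RegionalTimeSeriesSet(
        data=data,
        modality="bold-like",
        fs=1.0,
        condition=condition,
        region_labels=config.region_labels,
    )


def _chi_for(config: SyntheticStudyConfig, condition: str) -> np.ndarray:
    """Per-region aperiodic exponent for a condition.

    Under task demand the exponent moves opposite to the planted dPC sign
    (a flatter spectrum raises theta-alpha band power relative to the
    low-frequency bulk at the baseline exponent of ~2), scaled by the
    coupling strength.
    """
    chi = np.full(config.n_regions, config.chi_baseline)
    if condition != "rest":
        signs = planted_delta_pc_signs(config)
        chi = chi - config.coupling_strength * config.chi_offset * signs
    return chi


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, chi: float) -> np.ndarray:
    """Unit-variance noise with PSD proportional to f^-chi above 1 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    above = freqs >= 1.0
    shape[above] = freqs[above] ** (-chi / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_meg_like(
    config: SyntheticStudyConfig, condition: str
) -> RegionalTimeSeriesSet:
    """1/f^chi aperiodic noise + narrowband oscillators + measurement noise."""
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cond_idx = config.conditions.index(condition)
    n = int(round(config.fs_meg * config.duration_meg))
    t = np.arange(n) / config.fs_meg
    chi = _chi_for(config, condition)
    data = np.empty((config.n_subjects, config.n_regions, n))
    for s in range(config.n_subjects):
        for r in range(config.n_regions):
            rng = _rng(config, 1, s, cond_idx, r)
            x = _shaped_noise(rng, n, config.fs_meg, chi[r])
            for (center, amp, _bw) in config.peak_specs:
                phase = rng.uniform(0.0, 2.0 * np.pi)
                x = x + amp * np.sqrt(2.0) * np.sin(2.0 * np.pi * center * t + phase)
            x = x + config.measurement_noise * rng.standard_normal(n)
            data[s, r] = x
    return RegionalTimeSeriesSet(
        data=data,
        modality="meg-like",
        fs=config.fs_meg,
        condition=condition,
        region_labels=config.region_labels,
    )


def fixture_ring_connectome(
    n: int, ring_r: float, chord_r: float
) -> FunctionalConnectome:
    """Exact n-ring correlation matrix: consecutive pairs at ``ring_r``,
    every other pair at ``chord_r``.

    With the pseudo-distance transform this yields exactly one H1 interval
    [1 - ring_r, 1 - chord_r) whose volume-optimal cycle is the ring.
    """
    if n < 4:
        raise ValueError("need n >= 4 (a triangle fills and has no H1)")
    if not (0.0 < chord_r < ring_r < 1.0):
        raise ValueError("require 0 < chord_r < ring_r < 1")
    r = np.full((n, n), chord_r)
    for i in range(n):
        j = (i + 1) % n
        r[i, j] = r[j, i] = ring_r
    np.fill_diagonal(r, 1.0)
    return FunctionalConnectome.from_matrix(r)
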