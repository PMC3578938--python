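"""Ensembles of trajectories, empirical densities and modality detection.

An ensemble is a set of independent runs on a common output grid.  The
empirical density of a species at one grid time is the normalized histogram
of its copy number across runs (unit integer bins by default); the
density-vs-time matrix stacks those columns and is the empirical counterpart
of the master-equation solution for the marginal.  Modes are counted on a
kernel-smoothed version of a density with a prominence criterion, since the
underlying multimodality claims are about well-separated peaks, not
histogram roughness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .engine import SimulationConfig, Trajectory, ssan_run
from .network import ReactionNetwork
from .noise import NoiseChannel

__all__ = [
    "TrajectoryEnsemble",
    "EmpiricalDensity",
    "run_ensemble",
    "mean_std",
    "empirical_density",
    "density_vs_time",
    "count_modes",
    "first_peak_mass",
    "column_periodicity",
]


@dataclass
class TrajectoryEnsemble:
    """Counts of all runs sampled on a common record grid."""

    record_times: np.ndarray
    counts: np.ndarray  # (n_runs, n_record, n_species)
    species_names: list[str]
    seeds: np.ndarray
    noise: Optional[np.ndarray] = None  # (n_runs, n_record, n_channels)

    @property
    def n_runs(self) -> int:
        return self.counts.shape[0]

    def species(self, name: str) -> np.ndarray:
        """(n_runs, n_record) copy numbers of one species."""
        return self.counts[:, :, self.species_names.index(name)]

    def time_index(self, t: float) -> int:
        return int(np.argmin(np.abs(self.record_times - t)))


@dataclass
class EmpiricalDensity:
    """Normalized histogram of a species' copy number at one time."""

    species: str
    time: float
    support: np.ndarray  # integer copy numbers (bin centers)
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        s = self.probabilities.sum()
        if not math.isclose(s, 1.0, rel_tol=1e-9):
            raise ValueError(f"density must sum to 1, got {s}")
        if np.any(self.probabilities < 0):
            raise ValueError("negative probabilities")


def run_ensemble(
    network: ReactionNetwork,
    x0: Sequence[int],
    channels: Sequence[NoiseChannel],
    config: SimulationConfig,
    n_runs: int,
    base_seed: int = 0,
    record_noise: bool = False,
) -> TrajectoryEnsemble:
    """``n_runs`` independent runs with derived seeds ``base_seed + i``.

    Runs are mutually independent (each derives its own jump and noise
    sub-streams from its seed), so the result does not depend on execution
    order.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rec = config.record_grid
    counts = np.empty((n_runs, rec.size, network.n_species), dtype=np.int64)
    noise = (
        np.empty((n_runs, rec.size, len(channels))) if record_noise else None
    )
    seeds = base_seed + np.arange(n_runs)
    for i in range(n_runs):
        cfg = SimulationConfig(
            t0=config.t0, T=config.T, record_grid=rec,
            rng_seed=int(seeds[i]), root_tolerance=config.root_tolerance,
            max_events=config.max_events,
        )
        try:
            traj = ssan_run(network, x0, channels, cfg)
        except Exception as exc:  # annotate with the failing run index
            raise RuntimeError(f"run {i} (seed {seeds[i]}) failed: {exc}") from exc
        counts[i] = traj.counts
        if record_noise:
            noise[i] = traj.noise
    return TrajectoryEnsemble(
        record_times=rec.copy(),
        counts=counts,
        species_names=list(network.species_names),
        seeds=seeds,
        noise=noise,
    )


def mean_std(ensemble: TrajectoryEnsemble, species: str):
    """Per-grid-time sample mean and (unbiased) standard deviation."""
    x = ensemble.species(species).astype(float)
    ddof = 1 if ensemble.n_runs > 1 else 0
    return x.mean(axis=0), x.std(axis=0, ddof=ddof)


def empirical_density(
    ensemble: TrajectoryEnsemble, species: str, t: float
) -> EmpiricalDensity:
    """Normalized unit-bin histogram of a species across runs at grid time t."""
    idx = ensemble.time_index(t)
    x = ensemble.species(species)[:, idx]
    support = np.arange(int(x.max()) + 1)
    probs = np.bincount(x, minlength=support.size).astype(float)
    probs /= probs.sum()
    return EmpiricalDensity(
        species=species, time=float(ensemble.record_times[idx]),
        support=support, probabilities=probs,
    )


def density_vs_time(ensemble: TrajectoryEnsemble, species: str):
    """Empirical density matrix over (copy number, grid time).

    Returns ``(support, times, matrix)`` with ``matrix[c, k]`` the
    probability of copy number ``support[c]`` at ``times[k]``; every column
    sums to 1.  Row order is ascending count, column order ascending time
    (heatmap convention).
    """
    x = ensemble.species(species)
    max_count = int(x.max())
    support = np.arange(max_count + 1)
    n_t = ensemble.record_times.size
    mat = np.empty((max_count + 1, n_t))
    for k in range(n_t):
        col = np.bincount(x[:, k], minlength=max_count + 1).astype(float)
        mat[:, k] = col / col.sum()
    return support, ensemble.record_times.copy(), mat


def _rule_of_thumb_bandwidth(density: EmpiricalDensity, n: Optional[int]) -> float:
    """Silverman's rule 1.06 * sigma * n^(-1/5) on the density's own scale."""
    mu = float(np.sum(density.support * density.probabilities))
    var = float(np.sum((density.support - mu) ** 2 * density.probabilities))
    sigma = math.sqrt(max(var, 1e-12))
    n_eff = n if n is not None else 1000
    return max(1.06 * sigma * n_eff ** (-0.2), 0.5)


def count_modes(
    density: EmpiricalDensity,
    smoothing_bandwidth: Optional[float] = None,
    min_prominence: float = 0.05,
    n_samples: Optional[int] = None,
) -> int:
    """Number of well-separated local maxima of the smoothed density.

    The probability vector is convolved with a Gaussian kernel (bandwidth in
    copy-number units; default Silverman rule on the density itself) and
    peaks are kept when their prominence exceeds ``min_prominence`` times the
    global maximum.  Boundary maxima count as peaks.
    """
    p = density.probabilities
    if p.size == 0:
        raise ValueError("empty density")
    bw = smoothing_bandwidth or _rule_of_thumb_bandwidth(density, n_samples)
    half = int(math.ceil(4 * bw))
    xs = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (xs / bw) ** 2)
    kern /= kern.sum()
    smooth = np.convolve(p, kern, mode="full")
    # pad with zeros so peaks at the support boundary are detected
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _ = signal.find_peaks(
        padded, prominence=min_prominence * padded.max()
    )
    return int(peaks.size)


def first_peak_mass(
    density: EmpiricalDensity,
    smoothing_bandwidth: Optional[float] = None,
    n_samples: Optional[int] = None,
    cut: Optional[float] = None,
) -> float:
    """Probability mass of the first (lowest-count) density peak.

    With ``cut`` given, the basin boundary is fixed at that copy number
    (appropriate when the inter-mode valley of the system is known and the
    minor mode is broad).  Otherwise the basin extends to the first local
    minimum of the kernel-smoothed density; for a unimodal density this is 1.
    """
    p = density.probabilities
    if cut is not None:
        return float(p[density.support <= cut].sum())
    bw = smoothing_bandwidth or _rule_of_thumb_bandwidth(density, n_samples)
    half = int(math.ceil(4 * bw))
    xs = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (xs / bw) ** 2)
    kern /= kern.sum()
    smooth = np.convolve(p, kern, mode="same")
    valleys, _ = signal.find_peaks(-smooth, prominence=0.05 * smooth.max())
    if valleys.size == 0:
        return 1.0
    return float(p[: valleys[0] + 1].sum())


def column_periodicity(
    times: np.ndarray,
    matrix: np.ndarray,
    lag_range: tuple[float, float],
    t_min: float = 0.0,
) -> float:
    """Best period of the column-wise density oscillation.

    Correlates density columns at increasing lags (restricted to
    ``t >= t_min`` to skip transients) and returns the lag in
    ``lag_range = (lo, hi)`` maximizing the mean column-to-column Pearson
    correlation.  Requires a uniform time grid.
    """
    dt = float(times[1] - times[0])
    if not np.allclose(np.diff(times), dt):
        raise ValueError("column_periodicity requires a uniform record grid")
    keep = times >= t_min
    cols = matrix[:, keep]
    n = cols.shape[1]
    # remove each count-row's time-mean (static structure) so only the
    # oscillatory component drives the correlation
    centered = cols - cols.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    norms[norms == 0] = 1.0
    unit = centered / norms
    lo = max(1, int(round(lag_range[0] / dt)))
    hi = min(n - 2, int(round(lag_range[1] / dt)))
    corr = np.array([
        float(np.mean(np.sum(unit[:, : n - lag] * unit[:, lag:], axis=0)))
        for lag in range(lo, hi + 1)
    ])
    k = int(np.argmax(corr))
    best = lo + k
    # parabolic refinement of the correlation peak
    if 0 < k < corr.size - 1:
        y0, y1, y2 = corr[k - 1], corr[k], corr[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            best = best + 0.5 * (y0 - y2) / denom
    return float(best * dt)
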