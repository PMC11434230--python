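"""Synthetic data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here with
planted parameters, so each downstream stage is testable by parameter
recovery without any external data:

* worm tracks sampled from an exact continuous-time Markov chain at a fixed
  frame rate with random frame drops,
* inbred-line phenotype panels whose line effects are drawn from a known
  genetic covariance matrix ``G`` (between-line covariance ``2G``, so that
  half the between-line covariance recovers ``G``),
* line fitness generated from a known quadratic selection surface, and
* an individual-based infinitesimal-model drift simulation tracking the
  realized ``G`` per generation.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import RATE_NAMES, STATES, TRAIT_COLUMNS
from .ctmc import InvalidRateMatrixError, RateMatrix, stationary_distribution

COVARIATES = ("T", "H", "D")  # temperature, humidity, density


def _check_psd(m: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=tol):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(m)
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ValueError(f"{name} must be positive semidefinite (min eig {w.min():.3g})")
    return m


@dataclass
class TrackSimConfig:
    """Configuration of the track simulator.

    Tracks are exact CTMC sample paths (exponential holding times with rate
    ``q_i``, jump probabilities ``q_ij / q_i``) started from the stationary
    distribution and observed at regular frames, with i.i.d. frame drops to
    produce a mixture of observation lags.
    """

    Q_true: RateMatrix
    n_tracks: int = 100
    mean_track_duration: float = 60.0  # seconds
    frame_rate: float = 4.0  # Hz
    burn_in_discard: float = 300.0  # seconds of recording producing no output
    gap_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.Q_true, RateMatrix):
            self.Q_true = RateMatrix(np.asarray(self.Q_true))
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.mean_track_duration <= 0:
            raise ValueError("mean_track_duration must be > 0")
        if not 0 <= self.gap_probability < 1:
            raise ValueError("gap_probability must be in [0, 1)")
        if self.n_tracks <= 0:
            raise ValueError("n_tracks must be positive")


def _sample_path(
    q: np.ndarray, f0: np.ndarray, t_end: float, rng: np.random.Generator
) -> tuple[list[float], list[int]]:
    """Gillespie path on [0, t_end]: jump times and states (state[i] holds
    on [jump[i], jump[i+1]))."""
    rates = -np.diag(q)
    state = int(rng.choice(3, p=f0))
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        r = rates[state]
        if r <= 0:
            break  # absorbing under this Q
        t += rng.exponential(1.0 / r)
        if t >= t_end:
            break
        p = q[state].copy()
        p[state] = 0.0
        state = int(rng.choice(3, p=p / r))
        times.append(t)
        states.append(state)
    return times, states


def simulate_tracks(config: TrackSimConfig, n_plates: int = 1) -> pd.DataFrame:
    """Simulate worm tracks on ``n_plates`` plates.

    Returns a table with columns ``track_id, plate_id, time_s, state``.
    Observations start after the burn-in interval; timestamps are relative
    to the recording start (so the first possible frame is at
    ``burn_in_discard``).  A zero rate matrix yields constant tracks.
    """
    rng = np.random.default_rng(config.seed)
    q = config.Q_true.q
    rates = -np.diag(q)
    if np.all(rates == 0):
        f0 = np.full(3, 1.0 / 3.0)  # all states absorbing; uniform start
    else:
        try:
            f0 = stationary_distribution(config.Q_true)
        except ValueError as err:
            raise InvalidRateMatrixError(
                f"Q_true has no unique stationary distribution: {err}"
            ) from err
    frame_dt = 1.0 / config.frame_rate
    rows: list[tuple[str, str, float, str]] = []
    track_counter = 0
    for plate in range(n_plates):
        plate_id = f"plate{plate:03d}"
        for _ in range(config.n_tracks):
            track_counter += 1
            track_id = f"tr{track_counter:06d}"
            duration = rng.exponential(config.mean_track_duration)
            t_end = config.burn_in_discard + duration
            jt, js = _sample_path(q, f0, t_end, rng)
            n_frames = int(np.floor((t_end - config.burn_in_discard) / frame_dt)) + 1
            frame_times = config.burn_in_discard + frame_dt * np.arange(n_frames)
            keep = rng.random(n_frames) >= config.gap_probability
            frame_times = frame_times[keep]
            if len(frame_times) == 0:
                continue
            idx = np.searchsorted(jt, frame_times, side="right") - 1
            for t, i in zip(frame_times, idx):
                rows.append((track_id, plate_id, float(t), STATES[js[i]]))
    return pd.DataFrame(rows, columns=["track_id", "plate_id", "time_s", "state"])


@dataclass
class PanelSimConfig:
    """Configuration of the inbred-line phenotype panel simulator.

    Line effects are 6-variate normal with covariance ``2 * G_true`` so the
    broad-sense G estimated as half the between-line covariance recovers
    ``G_true``.  Block effects, standardized environmental covariates with
    fixed effects, and residual noise are added on top.
    """

    G_true: np.ndarray
    n_lines: int = 100
    blocks_per_line: int = 3
    covariate_effect_matrix: np.ndarray | None = None  # 6 x 3 for (T, H, D)
    block_sd: np.ndarray | float = 0.1
    residual_cov: np.ndarray | None = None
    grand_mean: np.ndarray | None = None
    population: str = "A6140"
    seed: int = 0

    def __post_init__(self) -> None:
        self.G_true = _check_psd(self.G_true, "G_true")
        if self.G_true.shape != (6, 6):
            raise ValueError("G_true must be 6x6")
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2 (no between-line variance otherwise)")
        if self.blocks_per_line < 2:
            raise ValueError("blocks_per_line must be >= 2")
        if self.covariate_effect_matrix is None:
            self.covariate_effect_matrix = np.zeros((6, len(COVARIATES)))
        self.covariate_effect_matrix = np.asarray(
            self.covariate_effect_matrix, dtype=float
        )
        if self.covariate_effect_matrix.shape != (6, len(COVARIATES)):
            raise ValueError("covariate_effect_matrix must be 6x3")
        self.block_sd = np.broadcast_to(
            np.asarray(self.block_sd, dtype=float), (6,)
        ).copy()
        if self.residual_cov is None:
            self.residual_cov = 0.05 * np.eye(6)
        self.residual_cov = _check_psd(self.residual_cov, "residual_cov")
        if self.grand_mean is None:
            self.grand_mean = np.log(np.full(6, 2.0))  # rates around 2/s on log scale
        self.grand_mean = np.broadcast_to(
            np.asarray(self.grand_mean, dtype=float), (6,)
        ).copy()


def simulate_line_phenotypes(config: PanelSimConfig) -> pd.DataFrame:
    """Simulate a line phenotype table (one row per technical replicate).

    Each line is phenotyped in ``blocks_per_line`` distinct blocks; blocks are
    shared across lines.  Covariates vary per replicate (they are plate-level
    environmental measurements) and are standardized to mean 0, sd 1 across
    rows.  Columns: ``line_id, population, block_id, T, H, D`` and the six
    trait columns (log transition rates).
    """
    rng = np.random.default_rng(config.seed)
    n_blocks = max(config.blocks_per_line, 4)
    line_eff = rng.multivariate_normal(
        np.zeros(6), 2.0 * config.G_true, size=config.n_lines, method="svd"
    )
    block_eff = rng.standard_normal((n_blocks, 6)) * config.block_sd
    rows = []
    for li in range(config.n_lines):
        blocks = rng.choice(n_blocks, size=config.blocks_per_line, replace=False)
        for b in blocks:
            rows.append((li, int(b)))
    rows_arr = np.array(rows)
    cov_rows = rng.standard_normal((len(rows), len(COVARIATES)))
    cov_std = (cov_rows - cov_rows.mean(axis=0)) / cov_rows.std(axis=0)
    resid = rng.multivariate_normal(
        np.zeros(6), config.residual_cov, size=len(rows), method="svd"
    )
    y = (
        config.grand_mean
        + line_eff[rows_arr[:, 0]]
        + block_eff[rows_arr[:, 1]]
        + cov_std @ config.covariate_effect_matrix.T
        + resid
    )
    table = pd.DataFrame(
        {
            "line_id": [f"L{li:04d}" for li in rows_arr[:, 0]],
            "population": config.population,
            "block_id": [f"B{b:03d}" for b in rows_arr[:, 1]],
        }
    )
    for j, c in enumerate(COVARIATES):
        table[c] = cov_std[:, j]
    for j, c in enumerate(TRAIT_COLUMNS):
        table[c] = y[:, j]
    return table


@dataclass
class FitnessSimConfig:
    """Configuration for generating line fitness from a quadratic surface."""

    gamma_true: np.ndarray
    alpha: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.gamma_true = np.asarray(self.gamma_true, dtype=float)
        if self.gamma_true.shape != (6, 6) or not np.allclose(
            self.gamma_true, self.gamma_true.T
        ):
            raise ValueError("gamma_true must be symmetric 6x6")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_fitness(
    traits: pd.DataFrame, config: FitnessSimConfig
) -> pd.DataFrame:
    """Generate relative fitness per line from a planted quadratic surface.

    ``traits`` must contain ``line_id`` and the six trait columns, already
    centered per the convention of the selection analysis (deviations z).
    ``w = alpha + 1/2 sum_k gamma_kk z_k^2 + sum_{k1<k2} gamma_k1k2 z_k1 z_k2
    + eps``.
    """
    missing = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing:
        raise ValueError(f"traits table missing columns {missing}")
    z = traits[list(TRAIT_COLUMNS)].to_numpy(dtype=float)
    g = config.gamma_true
    quad = 0.5 * np.einsum("ij,jk,ik->i", z, g, z)  # includes both halves of cross terms
    rng = np.random.default_rng(config.seed)
    w = config.alpha + quad + rng.normal(0.0, config.noise_sd, size=len(z))
    return pd.DataFrame({"line_id": traits["line_id"].to_numpy(), "fitness": w})


def simulate_drift_panel(
    G0: np.ndarray,
    Ne: int,
    generations: int,
    seed: int = 0,
    record_every: int = 1,
) -> list[np.ndarray]:
    """Individual-based drift of a 6-trait breeding-value distribution.

    ``Ne`` diploid parents carry 6-variate breeding values; each offspring is
    the mean of two random parents plus a segregation deviation with
    covariance half the current realized ``G``.  Under this infinitesimal
    recursion the expected total variance decays as ``(1 - 1/(2 Ne))^t``.

    Returns the realized covariance matrix at generation 0 and after every
    ``record_every`` generations.
    """
    G0 = _check_psd(G0, "G0")
    if Ne < 2:
        raise ValueError("Ne must be >= 2")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    rng = np.random.default_rng(seed)
    d = G0.shape[0]
    bv = rng.multivariate_normal(np.zeros(d), G0, size=Ne, method="svd")
    out = [np.cov(bv, rowvar=False, ddof=1)]
    for gen in range(1, generations + 1):
        g_real = np.cov(bv, rowvar=False, ddof=1)
        # project to PSD for the segregation draw (sampling noise can leave
        # tiny negative eigenvalues)
        w, v = np.linalg.eigh(g_real)
        g_psd = (v * np.clip(w, 0.0, None)) @ v.T
        dams = rng.integers(Ne, size=Ne)
        sires = rng.integers(Ne, size=Ne)
        midparent = 0.5 * (bv[dams] + bv[sires])
        seg = rng.multivariate_normal(np.zeros(d), 0.5 * g_psd, size=Ne, method="svd")
        bv = midparent + seg
        if gen % record_every == 0 or gen == generations:
            out.append(np.cov(bv, rowvar=False, ddof=1))
    return out
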