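"""Three-state continuous-time Markov model of movement behavior.

A worm track is a sequence of movement states (still, forward, backward)
observed at discrete times.  The underlying model is a time-homogeneous
continuous-time Markov chain with rate matrix ``Q`` whose six off-diagonal
entries ``q_ij >= 0`` are the transition rates (per second) and whose
diagonal is ``-sum`` of the row's off-diagonals, so that the transition
probability over a lag ``dt`` is the matrix exponential ``P(dt) = expm(dt*Q)``.

Observed tracks are compressed to transition-count matrices indexed by the
observation lag ``dt``; the log-likelihood is then a sum of Hadamard products
of count matrices with elementwise-log probability matrices, which is exactly
equal to the naive per-pair sum but far cheaper to evaluate.

Estimation places independent log-normal priors ``ln q_ij ~ N(ln 2, 0.6^2)``
on the rates and reports the posterior mode (MAP) with a Laplace
approximation on the log scale; a full MCMC treatment (affine-invariant
ensemble sampler) is available for checking the Laplace intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import spearmanr

from . import RATE_NAMES, STATES

N_STATES = 3
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
# (rate name -> (row, col)) for the six free rates, canonical order
RATE_POSITIONS = tuple(
    (STATE_INDEX[name[0]], STATE_INDEX[name[1]]) for name in RATE_NAMES
)


class InvalidRateMatrixError(ValueError):
    """Raised when a rate matrix violates the CTMC constraints."""


@dataclass(frozen=True)
class RateMatrix:
    """Transition-rate matrix of the three-state chain.

    Parameters
    ----------
    theta
        The six non-self rates in canonical order
        (SF, SB, FS, FB, BS, BF), units 1/s.
    """

    theta: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.shape != (6,):
            raise InvalidRateMatrixError(
                f"theta must have shape (6,), got {theta.shape}"
            )
        if not np.all(np.isfinite(theta)):
            raise InvalidRateMatrixError("rates must be finite")
        if np.any(theta < 0):
            bad = [RATE_NAMES[i] for i in np.flatnonzero(theta < 0)]
            raise InvalidRateMatrixError(
                f"off-diagonal rates must be >= 0; negative: {bad}"
            )
        object.__setattr__(self, "theta", theta)

    @property
    def q(self) -> np.ndarray:
        """Full 3x3 rate matrix with zero row sums."""
        q = np.zeros((N_STATES, N_STATES))
        for rate, (i, j) in zip(self.theta, RATE_POSITIONS):
            q[i, j] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    @classmethod
    def from_q(cls, q: np.ndarray, atol: float = 1e-8) -> "RateMatrix":
        q = np.asarray(q, dtype=float)
        if q.shape != (N_STATES, N_STATES):
            raise InvalidRateMatrixError(f"Q must be 3x3, got {q.shape}")
        if np.any(np.abs(q.sum(axis=1)) > atol):
            raise InvalidRateMatrixError("rows of Q must sum to 0")
        theta = np.array([q[i, j] for (i, j) in RATE_POSITIONS])
        return cls(theta)

    @classmethod
    def from_rates(cls, **rates: float) -> "RateMatrix":
        """Build from keyword rates, e.g. ``RateMatrix.from_rates(SF=2.0, ...)``."""
        unknown = set(rates) - set(RATE_NAMES)
        if unknown:
            raise InvalidRateMatrixError(f"unknown rate names: {sorted(unknown)}")
        return cls(np.array([rates.get(n, 0.0) for n in RATE_NAMES]))

    def as_series(self) -> pd.Series:
        return pd.Series(self.theta, index=list(RATE_NAMES))


def transition_probability(Q: RateMatrix | np.ndarray, dt: float) -> np.ndarray:
    """P(dt) = expm(dt*Q); rows sum to 1, entries clipped to [0, 1]."""
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    q = Q.q if isinstance(Q, RateMatrix) else RateMatrix.from_q(np.asarray(Q)).q
    p = expm(dt * q)
    # expm can leave tiny negatives; clip without disturbing row sums materially
    return np.clip(p, 0.0, 1.0)


def stationary_distribution(Q: RateMatrix | np.ndarray) -> np.ndarray:
    """Long-run state frequencies f with f Q = 0 and sum(f) = 1.

    Solved as the null space of ``Q^T`` via least squares with the
    normalization constraint appended; raises if the chain is reducible
    (the stationary distribution is then not unique/strictly positive).
    """
    q = Q.q if isinstance(Q, RateMatrix) else RateMatrix.from_q(np.asarray(Q)).q
    # irreducibility: every state reachable from every other along positive rates
    adj = (q > 0).astype(int) + np.eye(N_STATES, dtype=int)
    reach = np.linalg.matrix_power(adj, N_STATES) > 0
    if not reach.all():
        raise ValueError(
            "rate matrix is reducible (an absorbing state or closed set); "
            "the stationary distribution is a boundary case"
        )
    a = np.vstack([q.T, np.ones(N_STATES)])
    b = np.zeros(N_STATES + 1)
    b[-1] = 1.0
    f, *_ = np.linalg.lstsq(a, b, rcond=None)
    resid = np.abs(f @ q).max()
    if resid > 1e-8 or np.any(f < -1e-10):
        raise ValueError(
            "chain appears reducible (no unique positive stationary "
            f"distribution); residual={resid:.2e}, f={f}"
        )
    f = np.clip(f, 0.0, None)
    return f / f.sum()


@dataclass
class TransitionCountTensor:
    """Transition counts n(i, j, dt) compressed over all observation pairs.

    ``dts[k]`` is the k-th distinct observation lag and ``counts[k]`` the
    3x3 matrix of transitions observed at that lag.
    """

    dts: np.ndarray
    counts: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dts = np.asarray(self.dts, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.dts), N_STATES, N_STATES):
            raise ValueError("counts must have shape (len(dts), 3, 3)")
        if np.any(self.dts <= 0):
            raise ValueError("all dt values must be > 0")
        if len(np.unique(self.dts)) != len(self.dts):
            raise ValueError("dt values must be unique within the tensor")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "TransitionCountTensor") -> "TransitionCountTensor":
        dts = np.union1d(self.dts, other.dts)
        counts = np.zeros((len(dts), N_STATES, N_STATES))
        counts[np.searchsorted(dts, self.dts)] += self.counts
        counts[np.searchsorted(dts, other.dts)] += other.counts
        return TransitionCountTensor(dts, counts)


def _track_pairs(tracks: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (state_from, state_to, dt) arrays over consecutive pairs."""
    s = tracks["state"].map(STATE_INDEX)
    if s.isna().any():
        bad = tracks.loc[s.isna(), "state"].unique()
        raise ValueError(f"unknown state symbols: {list(bad)}")
    order = tracks.sort_values(["track_id", "time_s"], kind="stable")
    state = order["state"].map(STATE_INDEX).to_numpy(dtype=np.int64)
    t = order["time_s"].to_numpy(dtype=float)
    tid = order["track_id"].to_numpy()
    same = tid[1:] == tid[:-1]
    dt = t[1:] - t[:-1]
    if np.any(same & (dt <= 0)):
        bad = np.unique(tid[1:][same & (dt <= 0)])
        raise ValueError(f"non-increasing timestamps within track(s): {list(bad[:5])}")
    return state[:-1][same], state[1:][same], dt[same]


def compress_tracks(
    tracks: pd.DataFrame, dt_tolerance: float = 1e-6
) -> TransitionCountTensor:
    """Compress a track table into transition counts per observation lag.

    Consecutive observation pairs within each track are binned by their lag
    ``dt``; lags closer than ``dt_tolerance`` are merged (greedy clustering of
    the sorted unique lags, represented by the cluster mean).  Tracks with
    fewer than two observations contribute nothing.
    """
    if dt_tolerance < 0:
        raise ValueError("dt_tolerance must be >= 0")
    if len(tracks) == 0:
        return TransitionCountTensor(np.empty(0), np.empty((0, N_STATES, N_STATES)))
    s_from, s_to, dt = _track_pairs(tracks)
    if len(dt) == 0:
        return TransitionCountTensor(np.empty(0), np.empty((0, N_STATES, N_STATES)))
    uniq = np.unique(dt)
    # greedy merge of sorted lags within tolerance
    edges = [0]
    for i in range(1, len(uniq)):
        if uniq[i] - uniq[edges[-1]] > dt_tolerance:
            edges.append(i)
    starts = uniq[edges]
    cluster_of_uniq = np.searchsorted(starts, uniq, side="right") - 1
    cluster = cluster_of_uniq[np.searchsorted(uniq, dt)]
    n_clusters = len(starts)
    dts = np.bincount(cluster, weights=dt, minlength=n_clusters) / np.bincount(
        cluster, minlength=n_clusters
    )
    counts = np.zeros((n_clusters, N_STATES, N_STATES))
    np.add.at(counts, (cluster, s_from, s_to), 1)
    prov = {}
    if "plate_id" in tracks.columns:
        prov["plates"] = sorted(map(str, tracks["plate_id"].unique()))
    return TransitionCountTensor(dts, counts, prov)


def log_likelihood(Q: RateMatrix, counts: TransitionCountTensor) -> float:
    """Compressed CTMC log-likelihood sum_k 1' (N_k (.) ln P(dt_k)) 1.

    Cells with zero count contribute 0 even where the probability is 0;
    a positive count on a zero-probability cell yields ``-inf``.
    """
    total = 0.0
    for dt, n in zip(counts.dts, counts.counts):
        p = transition_probability(Q, dt)
        mask = n > 0
        if np.any(p[mask] <= 0):
            return -np.inf
        total += float(np.sum(n[mask] * np.log(p[mask])))
    return total


@dataclass
class RatePosterior:
    """Posterior over the six transition rates.

    ``samples`` holds draws of the rates on the natural scale (n, 6);
    ``map_rates`` is the posterior mode.  Summaries use equal-tailed
    quantile intervals at 83% and 95%.
    """

    samples: np.ndarray
    map_rates: np.ndarray
    method: str
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        qs = np.quantile(self.samples, [0.025, 0.085, 0.915, 0.975], axis=0)
        return pd.DataFrame(
            {
                "rate": list(RATE_NAMES),
                "mode": self.map_rates,
                "mean": self.samples.mean(axis=0),
                "q2.5": qs[0],
                "q8.5": qs[1],
                "q91.5": qs[2],
                "q97.5": qs[3],
            }
        )

    @property
    def map_matrix(self) -> RateMatrix:
        return RateMatrix(self.map_rates)


def _neg_log_posterior(
    x: np.ndarray,
    counts: TransitionCountTensor,
    prior_log_mean: float,
    prior_log_sd: float,
) -> float:
    ll = log_likelihood(RateMatrix(np.exp(x)), counts)
    if not np.isfinite(ll):
        return np.inf
    lp = -0.5 * np.sum(((x - prior_log_mean) / prior_log_sd) ** 2)
    return -(ll + lp)


def _numerical_hessian(f, x0: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x0)
    hess = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            xpp = x0.copy(); xpp[i] += h; xpp[j] += h
            xpm = x0.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x0.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x0.copy(); xmm[i] -= h; xmm[j] -= h
            hess[i, j] = hess[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    if not np.all(np.isfinite(hess)):
        raise RuntimeError(f"non-finite Hessian at the mode (f0={f0})")
    return hess


def fit_transition_rates(
    counts: TransitionCountTensor,
    prior_log_mean: float = float(np.log(2.0)),
    prior_log_sd: float = 0.6,
    method: str = "laplace",
    n_samples: int = 2000,
    mcmc_steps: int = 1500,
    mcmc_burn: int = 500,
    seed: int = 0,
) -> RatePosterior:
    """Estimate the six transition rates from compressed counts.

    The prior is independent log-normal, ``ln q_ij ~ N(prior_log_mean,
    prior_log_sd^2)``.  ``method='laplace'`` (default) reports the MAP with a
    Gaussian approximation of the log-rate posterior at the mode;
    ``method='mcmc'`` runs an affine-invariant ensemble sampler initialised
    at the MAP.  Both are seeded and reproducible.
    """
    if counts.total == 0:
        raise ValueError("count tensor is empty; cannot estimate rates")
    visited = counts.counts.sum(axis=(0, 2)) > 0  # rows with any outgoing pair
    if not np.all(visited):
        missing = [STATES[i] for i in np.flatnonzero(~visited)]
        warnings.warn(
            f"state(s) {missing} never observed as origin; "
            "their outgoing rates are prior-dominated",
            stacklevel=2,
        )

    def nlp(x: np.ndarray) -> float:
        return _neg_log_posterior(x, counts, prior_log_mean, prior_log_sd)

    x0 = np.full(6, prior_log_mean)
    res = minimize(nlp, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    res = minimize(nlp, res.x, method="BFGS", options={"gtol": 1e-6})
    x_map = res.x
    # BFGS can report precision loss at an already-converged optimum; accept
    # when the gradient is small relative to the objective scale
    grad_ok = bool(np.max(np.abs(res.jac)) < 1e-5 * (1.0 + abs(res.fun)))
    converged = bool(res.success) or grad_ok
    diagnostics: dict = {"converged": converged, "neg_log_post": float(res.fun)}
    if not converged:
        warnings.warn(f"MAP optimisation did not fully converge: {res.message}",
                      stacklevel=2)
    rng = np.random.default_rng(seed)

    if method == "laplace":
        hess = _numerical_hessian(nlp, x_map)
        cov = np.linalg.inv(hess)
        # symmetrize and guard against tiny negative eigenvalues
        cov = (cov + cov.T) / 2
        w, v = np.linalg.eigh(cov)
        cov = (v * np.clip(w, 1e-12, None)) @ v.T
        draws = rng.multivariate_normal(x_map, cov, size=n_samples,
                                        method="cholesky")
        return RatePosterior(np.exp(draws), np.exp(x_map), "laplace", diagnostics)

    if method == "mcmc":
        import emcee

        hess = _numerical_hessian(nlp, x_map)
        scale = np.sqrt(np.diag(np.linalg.inv(hess)))
        n_walkers = 24

        def log_prob(x: np.ndarray) -> float:
            return -nlp(x)

        p0 = x_map + 0.5 * scale * rng.standard_normal((n_walkers, 6))
        sampler = emcee.EnsembleSampler(n_walkers, 6, log_prob)
        sampler.random_state = np.random.RandomState(seed).get_state()
        sampler.run_mcmc(p0, mcmc_steps, progress=False)
        chain = sampler.get_chain(discard=mcmc_burn, flat=True)
        try:
            tau = sampler.get_autocorr_time(discard=mcmc_burn, quiet=True)
            diagnostics["autocorr_time"] = tau.tolist()
            ess = chain.shape[0] / np.max(tau)
            diagnostics["ess_min"] = float(ess)
            if ess < 100:
                warnings.warn(
                    f"MCMC effective sample size low ({ess:.0f} < 100)",
                    stacklevel=2,
                )
        except Exception:  # autocorr estimation can fail on short chains
            diagnostics["autocorr_time"] = None
        idx = rng.choice(chain.shape[0], size=min(n_samples, chain.shape[0]),
                         replace=False)
        return RatePosterior(np.exp(chain[idx]), np.exp(x_map), "mcmc", diagnostics)

    raise ValueError(f"unknown method {method!r}")


def predicted_state_frequencies(
    Q: RateMatrix, tracks: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Observed per-plate state frequencies vs model stationary frequencies.

    Diagnostic for the Markov assumption: under the model, time-in-state
    fractions should fall on the identity line against the stationary
    distribution of the fitted ``Q``.  Returns the per-plate table and a
    summary with the rank correlation and regression slope through the
    pooled points.
    """
    f = stationary_distribution(Q)
    rows = []
    group_col = "plate_id" if "plate_id" in tracks.columns else "track_id"
    for plate, sub in tracks.groupby(group_col):
        obs = sub["state"].value_counts(normalize=True)
        for i, s in enumerate(STATES):
            rows.append(
                {"plate_id": plate, "state": s,
                 "observed": float(obs.get(s, 0.0)), "stationary": float(f[i])}
            )
    table = pd.DataFrame(rows)
    summary: dict = {"n_plates": table["plate_id"].nunique()}
    if len(table) >= 3 and table["stationary"].nunique() > 1:
        rho = spearmanr(table["observed"], table["stationary"]).statistic
        x = table["stationary"].to_numpy()
        y = table["observed"].to_numpy()
        slope = float(np.sum(x * y) / np.sum(x * x))
        summary.update({"rank_correlation": float(rho), "slope": slope})
    return table, summary
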