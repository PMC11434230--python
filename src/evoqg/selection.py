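"""Quadratic selection surface estimation and canonical analysis.

Relative fitness per inbred line is regressed on the squared and
cross-product deviations of the six (centered) log transition rates:

    w_l = alpha + 1/2 sum_k gamma_kk z_kl^2
              + sum_{k1<k2} gamma_k1k2 z_k1,l z_k2,l + eps

The 1/2 is built into the diagonal design columns so the fitted partial
regression coefficients are the quadratic selection gradients gamma
directly (no post-hoc doubling).  The fit is a conjugate Bayesian linear
regression (flat prior on coefficients, Jeffreys prior on the residual
variance), whose exact posterior is sampled analytically.

Canonical analysis rotates the surface onto its principal axes,
``Lambda = U' gamma U``: positive eigenvalues mark disruptive, negative
stabilizing selection.  G-matrices are rotated into the same frame with
``G' = U' G U``; significance of the rotated eigenvalues is judged against
a permutation null built by shuffling fitness across lines, refitting, and
rotating by the fixed observed U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from . import TRAIT_COLUMNS

N_TRAITS = 6
PAIRS = tuple(combinations(range(N_TRAITS), 2))


def prepare_relative_fitness(raw: np.ndarray | pd.Series) -> np.ndarray:
    """Turn log-scale fertility estimates into relative fitness.

    The raw values are exponentiated and divided by their mean, so the
    output is non-negative with mean exactly 1.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("fertility estimates must be finite")
    w = np.exp(raw)
    return w / w.mean()


def line_trait_means(
    table: pd.DataFrame, adjust_covariates: bool = True
) -> pd.DataFrame:
    """Per-line trait means from a phenotype table, covariate-adjusted by OLS.

    When ``adjust_covariates`` is true, the traits are residualized on the
    standardized T, H, D covariates (main effects and all interactions)
    before averaging within line; the grand mean is added back so means stay
    on the trait scale.
    """
    from .gmatrix import design_matrix, validate_phenotype_table

    table = validate_phenotype_table(table)
    y = table[list(TRAIT_COLUMNS)].to_numpy(dtype=float)
    if adjust_covariates:
        x = design_matrix(table)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        adj = y - x[:, 1:] @ beta[1:]  # keep the intercept in
    else:
        adj = y
    out = pd.DataFrame(adj, columns=list(TRAIT_COLUMNS))
    out["line_id"] = table["line_id"].to_numpy()
    return out.groupby("line_id", as_index=False).mean()


def gamma_design(z: np.ndarray) -> np.ndarray:
    """Design columns for the quadratic regression: 6 x (1/2)z_k^2 then the
    15 cross products z_k1 z_k2 (k1 < k2), preceded by the intercept."""
    cols = [np.ones(len(z))]
    cols += [0.5 * z[:, k] ** 2 for k in range(N_TRAITS)]
    cols += [z[:, k1] * z[:, k2] for k1, k2 in PAIRS]
    return np.column_stack(cols)


def _coef_to_gamma(coef: np.ndarray) -> np.ndarray:
    """Map the 21 regression coefficients (after the intercept) to gamma."""
    g = np.zeros(coef.shape[:-1] + (N_TRAITS, N_TRAITS))
    for k in range(N_TRAITS):
        g[..., k, k] = coef[..., k]
    for idx, (k1, k2) in enumerate(PAIRS):
        g[..., k1, k2] = g[..., k2, k1] = coef[..., N_TRAITS + idx]
    return g


@dataclass
class GammaMatrix:
    """Posterior over the quadratic selection matrix gamma."""

    draws: np.ndarray  # (n_draws, 6, 6)
    point: np.ndarray  # posterior mean (= OLS estimate under the flat prior)
    alpha: float
    residual_diagnostics: dict = field(default_factory=dict)

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def element_summary(self) -> pd.DataFrame:
        qs = np.quantile(self.draws, [0.025, 0.085, 0.915, 0.975], axis=0)
        rows = []
        for i in range(N_TRAITS):
            for j in range(i, N_TRAITS):
                rows.append(
                    {
                        "row_trait": TRAIT_COLUMNS[i],
                        "col_trait": TRAIT_COLUMNS[j],
                        "estimate": float(self.point[i, j]),
                        "q2.5": float(qs[0, i, j]),
                        "q8.5": float(qs[1, i, j]),
                        "q91.5": float(qs[2, i, j]),
                        "q97.5": float(qs[3, i, j]),
                    }
                )
        return pd.DataFrame(rows)


def fit_gamma(
    traits: pd.DataFrame,
    fitness: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_draws: int = 1000,
    include_linear: bool = False,
    seed: int = 0,
) -> GammaMatrix:
    """Fit the quadratic selection surface by exact Bayesian regression.

    ``traits`` holds per-line trait means (columns ``line_id`` + traits);
    they are centered internally.  ``fitness`` holds ``line_id`` and
    ``fitness`` (relative, mean ~1).  Optional per-line standardized
    covariates are appended as nuisance columns; ``include_linear`` adds the
    directional terms z_k (off by default — directional selection is not
    expected after adaptation, and the quadratic gradients are the target).
    """
    merged = traits.merge(fitness, on="line_id", how="inner")
    if len(merged) < len(traits) or len(merged) < len(fitness):
        warnings.warn(
            f"line_id mismatch: using {len(merged)} matched lines", stacklevel=2
        )
    z = merged[list(TRAIT_COLUMNS)].to_numpy(dtype=float)
    z = z - z.mean(axis=0)
    w = merged["fitness"].to_numpy(dtype=float)
    x = gamma_design(z)
    n_gamma_cols = x.shape[1]
    if include_linear:
        x = np.hstack([x, z])
    if covariates is not None:
        cov = merged[list(covariates)].to_numpy(dtype=float) if isinstance(
            covariates, (list, tuple)
        ) else covariates.drop(columns="line_id", errors="ignore").to_numpy(dtype=float)
        x = np.hstack([x, cov])
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more lines ({n}) than parameters ({p})")
    if n < 10 * (p - 1):
        warnings.warn(
            f"only {n} lines for {p} parameters; gamma will be noisy", stacklevel=2
        )
    q, r = np.linalg.qr(x)
    diag_r = np.abs(np.diag(r))
    if np.any(diag_r < 1e-10 * diag_r.max()):
        bad = list(np.flatnonzero(diag_r < 1e-10 * diag_r.max()))
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    coef_hat = np.linalg.solve(r, q.T @ w)
    resid = w - x @ coef_hat
    dof = n - p
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    rng = np.random.default_rng(seed)
    # exact posterior under flat prior + Jeffreys: sigma2 ~ s2*dof/chi2_dof,
    # coef | sigma2 ~ N(coef_hat, sigma2 (X'X)^-1)
    sig2 = s2 * dof / rng.chisquare(dof, size=n_draws) if s2 > 0 else np.zeros(n_draws)
    r_inv = np.linalg.inv(r)
    noise = rng.standard_normal((n_draws, p)) @ r_inv.T * np.sqrt(sig2)[:, None]
    coef_draws = coef_hat + noise
    # residual normality / homoscedasticity report (diagnostic only)
    from scipy.stats import pearsonr, shapiro

    diag: dict = {"sigma": float(np.sqrt(s2)), "n_lines": n}
    if 3 <= n <= 5000 and s2 > 0:
        diag["shapiro_p"] = float(shapiro(resid).pvalue)
        diag["scale_trend_r"] = float(pearsonr(x @ coef_hat, np.abs(resid)).statistic)
    return GammaMatrix(
        draws=_coef_to_gamma(coef_draws[:, 1:n_gamma_cols]),
        point=_coef_to_gamma(coef_hat[1:n_gamma_cols]),
        alpha=float(coef_hat[0]),
        residual_diagnostics=diag,
    )


@dataclass
class CanonicalDecomposition:
    """Principal axes of the selection surface: Lambda = U' gamma U."""

    U: np.ndarray  # orthogonal, columns = canonical axes y_1..y_6
    lambdas: np.ndarray  # descending; >0 disruptive, <0 stabilizing
    lambda_draws: np.ndarray | None = None  # per-draw spectra (sorted desc)

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, lam in enumerate(self.lambdas):
            row = {
                "axis": f"y{i + 1}",
                "lambda": float(lam),
                "regime": "disruptive" if lam > 0 else "stabilizing",
            }
            if self.lambda_draws is not None:
                q = np.quantile(self.lambda_draws[:, i], [0.025, 0.085, 0.915, 0.975])
                row.update({"q2.5": q[0], "q8.5": q[1], "q91.5": q[2], "q97.5": q[3]})
            rows.append(row)
        return pd.DataFrame(rows)


def canonical_analysis(
    gamma: GammaMatrix | np.ndarray, atol: float = 1e-9
) -> CanonicalDecomposition:
    """Eigendecompose gamma; U from the point estimate, spectra per draw."""
    from .gcompare import eigen_decompose

    if isinstance(gamma, GammaMatrix):
        point = gamma.point
        draws = gamma.draws
    else:
        point = np.asarray(gamma, dtype=float)
        draws = None
    es = eigen_decompose(point, atol=atol)
    lambda_draws = None
    if draws is not None:
        lambda_draws = np.array(
            [np.sort(np.linalg.eigvalsh((g + g.T) / 2))[::-1] for g in draws]
        )
    return CanonicalDecomposition(es.eigenvectors, es.eigenvalues, lambda_draws)


def rotate_gmatrix(g: np.ndarray, u: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """G' = U' G U; broadcasts over a stack of posterior draws."""
    u = np.asarray(u, dtype=float)
    if np.max(np.abs(u.T @ u - np.eye(u.shape[1]))) > atol:
        raise ValueError("U is not orthogonal")
    g = np.asarray(g, dtype=float)
    return np.einsum("ki,...kl,lj->...ij", u, g, u)


def null_lambda_distribution(
    traits: pd.DataFrame,
    fitness: pd.DataFrame,
    u_fixed: np.ndarray,
    n_perm: int = 1000,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Permutation null of the rotated surface curvature.

    Fitness values are shuffled across lines, gamma refit, and the diagonal
    of ``U' gamma_perm U`` extracted with the *fixed* observed rotation U.
    Returns (n_perm, 6) in the axis order of U's columns.
    """
    rng = np.random.default_rng(seed)
    out = np.empty((n_perm, N_TRAITS))
    w = fitness["fitness"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_perm):
            perm = fitness.copy()
            perm["fitness"] = rng.permutation(w)
            fit = fit_gamma(
                traits, perm, covariates=covariates, n_draws=1,
                seed=int(rng.integers(2**31 - 1)),
            )
            out[k] = np.diag(rotate_gmatrix(fit.point, u_fixed))
    return out


def alignment_correlations(
    tensor_vectors: dict[str, np.ndarray],
    gamma: GammaMatrix,
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson correlations between divergence directions and canonical axes.

    ``tensor_vectors`` maps labels (e.g. ``e11``, ``e12``) to unit
    6-vectors.  For each of ``n_draws`` posterior draws of gamma the
    canonical axes are recomputed and the correlation of their loadings with
    each tensor vector recorded; the summary reports the point-estimate
    correlation, its absolute value, and 95% equal-tailed intervals.
    """
    from .gcompare import eigen_decompose

    rng = np.random.default_rng(seed)
    n_avail = len(gamma.draws)
    idx = rng.choice(n_avail, size=min(n_draws, n_avail), replace=n_draws > n_avail)
    u_point = canonical_analysis(gamma.point).U
    rows = []
    for label, vec in tensor_vectors.items():
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (N_TRAITS,):
            raise ValueError(f"{label}: tensor vectors must be 6-vectors")
        r_draws = np.empty((len(idx), N_TRAITS))
        for d, i in enumerate(idx):
            u = eigen_decompose((gamma.draws[i] + gamma.draws[i].T) / 2).eigenvectors
            for ax in range(N_TRAITS):
                r_draws[d, ax] = np.corrcoef(vec, u[:, ax])[0, 1]
        for ax in range(N_TRAITS):
            r_point = float(np.corrcoef(vec, u_point[:, ax])[0, 1])
            q = np.quantile(np.abs(r_draws[:, ax]), [0.025, 0.975])
            rows.append(
                {
                    "vector": label,
                    "axis": f"y{ax + 1}",
                    "r": r_point,
                    "abs_r": abs(r_point),
                    "abs_r_q2.5": float(q[0]),
                    "abs_r_q97.5": float(q[1]),
                }
            )
    return pd.DataFrame(rows)
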