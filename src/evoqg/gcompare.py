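"""G-matrix size, shape, divergence and differentiation statistics.

Size is the trace; shape is summarized by the eigenstructure (the leading
eigenvector being g_max, the trait combination with most genetic variance)
and by angles between eigenvectors folded to [0, 90] degrees.  The null for
"no alignment" of two directions is the angle distribution of random vector
pairs with i.i.d. Uniform(-1, 1) coordinates.

Divergence/differentiation among a set of G-matrices uses the fourth-order
genetic covariance tensor: each 6x6 symmetric matrix is half-vectorized to a
21-vector with off-diagonals scaled by sqrt(2) so that the Euclidean
geometry of the vectors equals the Frobenius geometry of the matrices; the
covariance of these vectors across populations (denominator m-1) is a 21x21
representation of the tensor, whose eigenvectors map back to orthonormal
symmetric eigentensors E_i with eigenvalues alpha_i.  A finite-line sampling
null for the alpha_i is obtained by drawing line-effect samples from a
pooled G and re-estimating the tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import TRAIT_COLUMNS

N_TRAITS = 6
N_VECH = N_TRAITS * (N_TRAITS + 1) // 2  # 21


def _vech_indices() -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.tril_indices(N_TRAITS)
    return rows, cols


_VECH_ROWS, _VECH_COLS = _vech_indices()
_VECH_SCALE = np.where(_VECH_ROWS == _VECH_COLS, 1.0, np.sqrt(2.0))


def vech_scaled(g: np.ndarray) -> np.ndarray:
    """Half-vectorize symmetric matrices with sqrt(2)-scaled off-diagonals.

    Accepts (..., 6, 6); returns (..., 21).  Preserves the Frobenius inner
    product: ``vech(A) . vech(B) == <A, B>_F``.
    """
    g = np.asarray(g, dtype=float)
    return g[..., _VECH_ROWS, _VECH_COLS] * _VECH_SCALE


def unvech_scaled(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vech_scaled`."""
    v = np.asarray(v, dtype=float)
    out = np.zeros(v.shape[:-1] + (N_TRAITS, N_TRAITS))
    vals = v / _VECH_SCALE
    out[..., _VECH_ROWS, _VECH_COLS] = vals
    out[..., _VECH_COLS, _VECH_ROWS] = vals
    return out


def matrix_trace(g: np.ndarray) -> float | np.ndarray:
    """Trace; broadcasts over a stack of posterior draws."""
    g = np.asarray(g, dtype=float)
    if g.shape[-1] != g.shape[-2]:
        raise ValueError("trace needs a square matrix")
    return np.trace(g, axis1=-2, axis2=-1)


def _fix_sign(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-magnitude loading of each column positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


@dataclass
class EigenStructure:
    """Descending eigenstructure of a symmetric (co)variance matrix."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, unit norm, sign-fixed

    @property
    def gmax(self) -> np.ndarray:
        return self.eigenvectors[:, 0]

    @property
    def proportion(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else np.zeros_like(self.eigenvalues)


def eigen_decompose(g: np.ndarray, atol: float = 1e-9) -> EigenStructure:
    """Spectral decomposition with descending eigenvalues and fixed signs."""
    g = np.asarray(g, dtype=float)
    if np.max(np.abs(g - g.T)) > atol:
        raise ValueError("matrix is asymmetric beyond tolerance")
    g = (g + g.T) / 2
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1]
    return EigenStructure(w[order], _fix_sign(v[:, order]))


def project_variance(g: np.ndarray, v: np.ndarray) -> float | np.ndarray:
    """Genetic variance along unit direction v: v' G v (broadcasts over draws)."""
    v = np.asarray(v, dtype=float)
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("direction vector must be nonzero")
    if not np.isclose(nrm, 1.0, atol=1e-8):
        raise ValueError("direction vector must have unit norm")
    g = np.asarray(g, dtype=float)
    return np.einsum("i,...ij,j->...", v, g, v)


def angle_between(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Angle between two directions in degrees, folded to [0, 90].

    Because v and -v span the same axis, angles above 90 are reflected.
    """
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    ni, nj = np.linalg.norm(g_i), np.linalg.norm(g_j)
    if ni == 0 or nj == 0:
        raise ValueError("angle undefined for zero vectors")
    c = np.clip(np.dot(g_i, g_j) / (ni * nj), -1.0, 1.0)
    theta = np.degrees(np.arccos(c))
    return float(180.0 - theta if theta > 90.0 else theta)


def angle_posterior(
    draws: np.ndarray, reference: np.ndarray, axis: int = 0
) -> np.ndarray:
    """Posterior of the angle between a reference direction and eigenvector
    ``axis`` of each G draw."""
    return np.array(
        [angle_between(eigen_decompose(g).eigenvectors[:, axis], reference)
         for g in draws]
    )


def null_angle_distribution(
    dim: int = 6, n_pairs: int = 1000, seed: int = 0
) -> np.ndarray:
    """Angles between random vector pairs with i.i.d. Uniform(-1,1) coordinates.

    This is the null for "no alignment" between two directions; returns the
    folded angles in degrees.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1, 1, size=(n_pairs, dim))
    b = rng.uniform(-1, 1, size=(n_pairs, dim))
    c = np.einsum("ij,ij->i", a, b) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    )
    theta = np.degrees(np.arccos(np.clip(c, -1, 1)))
    return np.where(theta > 90.0, 180.0 - theta, theta)


@dataclass
class CovarianceTensor:
    """Posterior-averaged 21x21 tensor representation and per-draw pieces."""

    S: np.ndarray  # (21, 21) posterior mean tensor
    S_draws: np.ndarray  # (n_draws, 21, 21)
    centered_vechs: np.ndarray  # (n_draws, m, 21) matrices centered across pops
    populations: tuple[str, ...] = ()


@dataclass
class EigentensorDecomposition:
    """Eigentensors E_i of the covariance tensor with eigenvalues alpha_i."""

    alphas: np.ndarray  # (21,) descending
    eigentensors: np.ndarray  # (21, 6, 6), unit Frobenius norm
    eigenvectors: list[EigenStructure]  # per-tensor spectral structure
    coordinates: np.ndarray  # (m, 21): <G_pop - Gbar, E_i>_F at posterior mean
    alpha_draws: np.ndarray | None = None  # (n_draws, 21) when built per draw
    populations: tuple[str, ...] = ()

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.alphas):
            row = {
                "eigentensor": f"E{i + 1}",
                "alpha": float(a),
                "alpha_fraction": float(a / self.alphas.sum())
                if self.alphas.sum() > 0
                else 0.0,
            }
            if self.alpha_draws is not None:
                q = np.quantile(self.alpha_draws[:, i], [0.025, 0.085, 0.915, 0.975])
                row.update(
                    {"q2.5": q[0], "q8.5": q[1], "q91.5": q[2], "q97.5": q[3]}
                )
            rows.append(row)
        return pd.DataFrame(rows)


def build_covariance_tensor(
    g_draws_by_pop: list[np.ndarray], populations: list[str] | None = None
) -> CovarianceTensor:
    """Covariance tensor of a set of G-matrix posteriors.

    ``g_draws_by_pop`` holds one (n_draws, 6, 6) array per population; draws
    are paired by index across populations so posterior uncertainty
    propagates into the tensor.  For each draw the m matrices are scaled-
    half-vectorized, centered across populations, and their covariance
    (denominator m-1) accumulated; the returned ``S`` is the posterior mean.
    """
    if len(g_draws_by_pop) < 2:
        raise ValueError("need >= 2 populations to compare")
    n_draws = min(len(g) for g in g_draws_by_pop)
    stacks = np.stack([np.asarray(g)[:n_draws] for g in g_draws_by_pop], axis=1)
    if stacks.shape[-2:] != (N_TRAITS, N_TRAITS):
        raise ValueError("G draws must be 6x6")
    vechs = vech_scaled(stacks)  # (n_draws, m, 21)
    centered = vechs - vechs.mean(axis=1, keepdims=True)
    m = stacks.shape[1]
    s_draws = np.einsum("dmi,dmj->dij", centered, centered) / (m - 1)
    return CovarianceTensor(
        S=s_draws.mean(axis=0),
        S_draws=s_draws,
        centered_vechs=centered,
        populations=tuple(populations or [f"pop{i}" for i in range(m)]),
    )


def eigentensor_decompose(
    tensor: CovarianceTensor | np.ndarray, atol: float = 1e-8
) -> EigentensorDecomposition:
    """Eigendecompose the 21x21 tensor into symmetric eigentensors.

    Eigenvalues alpha_i come in descending order; eigenvectors map back to
    unit-Frobenius-norm symmetric matrices E_i.  Population coordinates are
    Frobenius inner products of the centered matrices with each E_i.  With m
    matrices at most m-1 alphas are nonzero.
    """
    if isinstance(tensor, CovarianceTensor):
        s = tensor.S
        centered = tensor.centered_vechs.mean(axis=0)  # posterior-mean centered vechs
        pops = tensor.populations
        s_draws = tensor.S_draws
    else:
        s = np.asarray(tensor, dtype=float)
        centered = None
        pops = ()
        s_draws = None
    if s.shape != (N_VECH, N_VECH):
        raise ValueError(f"tensor representation must be {N_VECH}x{N_VECH}")
    if np.max(np.abs(s - s.T)) > atol:
        raise ValueError("tensor representation must be symmetric")
    w = np.linalg.eigvalsh((s + s.T) / 2)
    if w.min() < -atol * max(1.0, w.max()):
        raise ValueError(f"tensor not PSD beyond tolerance (min eig {w.min():.3g})")
    es = eigen_decompose((s + s.T) / 2, atol=atol)
    alphas = np.clip(es.eigenvalues, 0.0, None)
    tensors = np.array([unvech_scaled(es.eigenvectors[:, i]) for i in range(N_VECH)])
    per_tensor = [eigen_decompose(t) for t in tensors]
    if centered is not None:
        coords = centered @ es.eigenvectors  # (m, 21), Frobenius inner products
    else:
        coords = np.zeros((0, N_VECH))
    alpha_draws = None
    if s_draws is not None:
        alpha_draws = np.array(
            [np.sort(np.linalg.eigvalsh((sd + sd.T) / 2))[::-1] for sd in s_draws]
        )
        alpha_draws = np.clip(alpha_draws, 0.0, None)
    return EigentensorDecomposition(
        alphas=alphas,
        eigentensors=tensors,
        eigenvectors=per_tensor,
        coordinates=coords,
        alpha_draws=alpha_draws,
        populations=pops,
    )


def tensor_sampling_null(
    g_pooled: np.ndarray,
    n_populations: int,
    n_lines: int,
    n_rep: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Finite-line sampling null for the tensor eigenvalues alpha_i.

    Under the null all populations share ``g_pooled``; each replicate draws
    ``n_lines`` line effects per population from N(0, 2*g_pooled), estimates
    each population's G as half the sample line covariance, and records the
    tensor eigenvalues of the resulting matrix set.  Returns (n_rep, 21)
    descending alphas.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    g_pooled = np.asarray(g_pooled, dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty((n_rep, N_VECH))
    w, v = np.linalg.eigh((g_pooled + g_pooled.T) / 2)
    chol_like = v * np.sqrt(np.clip(2.0 * w, 0.0, None))
    for r in range(n_rep):
        mats = []
        for _ in range(n_populations):
            eff = rng.standard_normal((n_lines, N_TRAITS)) @ chol_like.T
            mats.append(0.5 * np.cov(eff, rowvar=False, ddof=1))
        vechs = vech_scaled(np.array(mats))
        centered = vechs - vechs.mean(axis=0)
        s = centered.T @ centered / (n_populations - 1)
        out[r] = np.sort(np.linalg.eigvalsh(s))[::-1]
    return np.clip(out, 0.0, None)


def gmax_table(g_draws: np.ndarray, population: str = "") -> pd.DataFrame:
    """Loadings of g_max from the posterior-mean matrix with per-draw lambda1."""
    es = eigen_decompose(np.asarray(g_draws).mean(axis=0))
    lam1 = np.array([eigen_decompose(g).eigenvalues[0] for g in g_draws])
    q = np.quantile(lam1, [0.025, 0.975])
    return pd.DataFrame(
        {
            "population": population,
            "trait": list(TRAIT_COLUMNS),
            "gmax_loading": es.gmax,
            "lambda1_mean": lam1.mean(),
            "lambda1_q2.5": q[0],
            "lambda1_q97.5": q[1],
        }
    )
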