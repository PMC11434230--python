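"""End-to-end synthetic analysis pipeline.

Mirrors the full study workflow on generated data with known ground truth:

1. simulate worm tracks and estimate movement-state transition rates,
2. simulate inbred-line panels (ancestral + drift-derived populations) and
   estimate their G-matrices,
3. compare G-matrices (traces, g_max angles with the random-vector null,
   covariance tensor with the finite-line sampling null),
4. estimate the quadratic selection surface from simulated line fitness,
   canonical analysis, permutation nulls and alignment correlations,
5. compare per-axis genetic variance against the drift expectation.

All randomness flows from the single config seed; rerunning with the same
config reproduces every artifact byte for byte.  A JSON manifest records
the config, its hash, derived stage seeds and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import RATE_NAMES, TRAIT_COLUMNS, __version__
from . import ctmc, drift, gcompare, io, selection, synthetic
from .gmatrix import GibbsConfig, fit_line_model

logger = logging.getLogger("evoqg")

# Planted study conditions for the synthetic demonstration: heterogeneous
# transition rates (per second), an elliptical ancestral G with positive
# covariance between the still-exit rates, and a saddle-shaped selection
# surface with its strongest (stabilizing) curvature on the last axes.
DEFAULT_THETA_TRUE = np.array([0.35, 0.6, 1.6, 0.25, 2.1, 0.5])


def default_g0() -> np.ndarray:
    # strongly elliptical: a dominant g_max-like axis with positive loadings
    # on all rates (largest on the still-exit rates) carrying ~80% of the
    # genetic variance, plus small independent variance per trait
    load = np.array([0.55, 0.5, 0.35, 0.25, 0.3, 0.2])
    g = np.diag([0.05, 0.05, 0.04, 0.04, 0.04, 0.03]) + np.outer(load, load)
    return (g + g.T) / 2


def default_gamma_true() -> np.ndarray:
    return np.diag([0.08, 0.05, 0.02, -0.04, -0.15, -0.35])


@dataclass
class PipelineConfig:
    """Configuration of the synthetic end-to-end run."""

    out_dir: str = "evoqg_run"
    seed: int = 0
    # tracks
    n_tracks: int = 150
    n_plates: int = 3
    gap_probability: float = 0.15
    # panel
    n_lines_ancestral: int = 100
    n_lines_derived: int = 60
    blocks_per_line: int = 3
    generations: tuple[int, ...] = (50, 100)
    ne: int = 1000
    # mcmc / nulls
    gibbs_iter: int = 2500
    gibbs_burn: int = 500
    gibbs_thin: int = 10
    n_perm_lambda: int = 200
    n_rep_tensor_null: int = 300
    n_angle_null: int = 1000
    fitness_noise_sd: float = 0.05

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generations"] = list(self.generations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generations" in d:
            d["generations"] = tuple(d["generations"])
        return cls(**d)


def _stage_seeds(seed: int, n: int = 16) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=io.FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic data; return the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": io.config_hash(config.to_dict()),
        "version": __version__,
        "stage_seeds": seeds,
        "stages": {},
    }

    # ---- stage 1: tracks and transition rates -------------------------------
    logger.info("stage tracks: simulating %d tracks", config.n_tracks)
    q_true = ctmc.RateMatrix(DEFAULT_THETA_TRUE)
    track_cfg = synthetic.TrackSimConfig(
        Q_true=q_true,
        n_tracks=config.n_tracks,
        gap_probability=config.gap_probability,
        seed=seeds[0],
    )
    tracks = synthetic.simulate_tracks(track_cfg, n_plates=config.n_plates)
    io.write_tracks(tracks, out / "tracks.tsv")
    counts = ctmc.compress_tracks(tracks)
    posterior = ctmc.fit_transition_rates(counts, seed=seeds[1])
    summary = posterior.summary()
    summary["true_rate"] = DEFAULT_THETA_TRUE
    _write_csv(summary, out / "rate_posterior.csv")
    freq_table, freq_summary = ctmc.predicted_state_frequencies(
        posterior.map_matrix, tracks
    )
    _write_csv(freq_table, out / "state_frequencies.csv")
    manifest["stages"]["rates"] = {
        "seed": [seeds[0], seeds[1]],
        "frequency_diagnostic": freq_summary,
        "map_rates": dict(zip(RATE_NAMES, map(float, posterior.map_rates))),
    }

    # ---- stage 2: panels and G-matrices ------------------------------------
    g0 = default_g0()
    io.write_matrix_csv(g0, out / "G_true_ancestral.csv")
    drift_real = synthetic.simulate_drift_panel(
        g0, Ne=config.ne, generations=max(config.generations), seed=seeds[2]
    )
    g_truth_by_gen = {0: g0}
    for gen in config.generations:
        g_truth_by_gen[gen] = drift_real[gen]

    gibbs = GibbsConfig(
        n_iter=config.gibbs_iter, burn_in=config.gibbs_burn, thin=config.gibbs_thin
    )
    populations = [("A0", 0, config.n_lines_ancestral)] + [
        (f"D{gen}", gen, config.n_lines_derived) for gen in config.generations
    ]
    g_posteriors: dict[str, np.ndarray] = {}
    gen_of_pop: dict[str, int] = {}
    for k, (pop, gen, n_lines) in enumerate(populations):
        logger.info("stage gmatrix: fitting %s (generation %d)", pop, gen)
        panel_cfg = synthetic.PanelSimConfig(
            G_true=g_truth_by_gen[gen],
            n_lines=n_lines,
            blocks_per_line=config.blocks_per_line,
            population=pop,
            seed=seeds[3] + k,
        )
        table = synthetic.simulate_line_phenotypes(panel_cfg)
        io.write_phenotypes(table, out / f"phenotypes_{pop}.csv")
        fit = fit_line_model(
            table, GibbsConfig(**{**asdict(gibbs), "seed": seeds[4] + k})
        )
        g_posteriors[pop] = fit.draws
        gen_of_pop[pop] = gen
        fit.to_long().to_csv(
            out / f"G_posterior_{pop}.csv", index=False, float_format=io.FLOAT_FORMAT
        )
        _write_csv(fit.element_summary(), out / f"G_summary_{pop}.csv")
    manifest["stages"]["gmatrix"] = {
        "populations": {p: gen_of_pop[p] for p in g_posteriors},
        "n_draws": int(next(iter(g_posteriors.values())).shape[0]),
    }

    # ---- stage 3: comparison ------------------------------------------------
    logger.info("stage compare: traces, angles, covariance tensor")
    pop_names = list(g_posteriors)
    trace_rows = []
    for pop in pop_names:
        tr = gcompare.matrix_trace(g_posteriors[pop])
        q = np.quantile(tr, [0.025, 0.085, 0.915, 0.975])
        trace_rows.append(
            {
                "population": pop,
                "trace_mean": float(np.mean(tr)),
                "q2.5": q[0], "q8.5": q[1], "q91.5": q[2], "q97.5": q[3],
                "trace_true": float(np.trace(g_truth_by_gen[gen_of_pop[pop]])),
            }
        )
    _write_csv(pd.DataFrame(trace_rows), out / "traces.csv")

    anc_gmax = gcompare.eigen_decompose(g_posteriors[pop_names[0]].mean(axis=0)).gmax
    null_angles = gcompare.null_angle_distribution(
        6, config.n_angle_null, seed=seeds[5]
    )
    angle_rows = []
    for pop in pop_names[1:]:
        draws = gcompare.angle_posterior(g_posteriors[pop], anc_gmax)
        point = gcompare.angle_between(
            gcompare.eigen_decompose(g_posteriors[pop].mean(axis=0)).gmax, anc_gmax
        )
        angle_rows.append(
            {
                "population": pop,
                "theta_vs_ancestral_gmax": point,
                "theta_q2.5": float(np.quantile(draws, 0.025)),
                "theta_q97.5": float(np.quantile(draws, 0.975)),
                "null_q5": float(np.quantile(null_angles, 0.05)),
                "null_median": float(np.quantile(null_angles, 0.5)),
            }
        )
    _write_csv(pd.DataFrame(angle_rows), out / "gmax_angles.csv")

    tensor = gcompare.build_covariance_tensor(
        [g_posteriors[p] for p in pop_names], populations=pop_names
    )
    decomp = gcompare.eigentensor_decompose(tensor)
    pooled = np.mean([g_posteriors[p].mean(axis=0) for p in pop_names], axis=0)
    null_alpha = gcompare.tensor_sampling_null(
        pooled,
        n_populations=len(pop_names),
        n_lines=config.n_lines_derived,
        n_rep=config.n_rep_tensor_null,
        seed=seeds[6],
    )
    alpha_tab = decomp.summary()
    alpha_tab["null_q95"] = np.quantile(null_alpha, 0.95, axis=0)
    _write_csv(alpha_tab.head(len(pop_names)), out / "eigentensor_alphas.csv")
    e_vectors = {
        "e11": decomp.eigenvectors[0].eigenvectors[:, 0],
        "e12": decomp.eigenvectors[0].eigenvectors[:, 1],
    }
    _write_csv(
        pd.DataFrame({"trait": list(TRAIT_COLUMNS), **{
            k: v for k, v in e_vectors.items()
        }}),
        out / "eigentensor_vectors.csv",
    )
    manifest["stages"]["compare"] = {
        "alpha1": float(decomp.alphas[0]),
        "alpha1_null_q95": float(np.quantile(null_alpha[:, 0], 0.95)),
    }

    # ---- stage 4: selection surface ----------------------------------------
    logger.info("stage selection: gamma fit, canonical analysis, nulls")
    gamma_true = default_gamma_true()
    io.write_matrix_csv(gamma_true, out / "gamma_true.csv")
    anc_table = io.read_phenotypes(out / f"phenotypes_{pop_names[0]}.csv")
    traits = selection.line_trait_means(anc_table)
    centered = traits.copy()
    centered[list(TRAIT_COLUMNS)] -= centered[list(TRAIT_COLUMNS)].mean()
    fitness = synthetic.simulate_fitness(
        centered,
        synthetic.FitnessSimConfig(
            gamma_true=gamma_true, noise_sd=config.fitness_noise_sd, seed=seeds[7]
        ),
    )
    fitness["fitness"] = np.clip(fitness["fitness"], 0.0, None)
    io.write_fitness(fitness, out / "fitness.csv")
    gamma_fit = selection.fit_gamma(traits, fitness, seed=seeds[8])
    _write_csv(gamma_fit.element_summary(), out / "gamma_posterior.csv")
    canon = selection.canonical_analysis(gamma_fit)
    null_lambda = selection.null_lambda_distribution(
        traits, fitness, canon.U, n_perm=config.n_perm_lambda, seed=seeds[9]
    )
    canon_tab = canon.summary()
    canon_tab["null_q2.5"] = np.quantile(null_lambda, 0.025, axis=0)
    canon_tab["null_q97.5"] = np.quantile(null_lambda, 0.975, axis=0)
    canon_tab["significant"] = (canon_tab["lambda"] < canon_tab["null_q2.5"]) | (
        canon_tab["lambda"] > canon_tab["null_q97.5"]
    )
    _write_csv(canon_tab, out / "canonical_analysis.csv")
    align = selection.alignment_correlations(
        e_vectors, gamma_fit, n_draws=500, seed=seeds[10]
    )
    _write_csv(align, out / "alignment_correlations.csv")
    manifest["stages"]["selection"] = {
        "lambda": [float(x) for x in canon.lambdas],
        "n_significant_axes": int(canon_tab["significant"].sum()),
    }

    # ---- stage 5: drift envelope -------------------------------------------
    logger.info("stage drift: per-axis envelope at Ne=%d", config.ne)
    g_by_gen = {gen_of_pop[p]: g_posteriors[p] for p in pop_names}
    drift_tab = drift.drift_envelope_compare(g_by_gen, canon.U, ne=config.ne)
    _write_csv(drift_tab, out / "drift_envelope.csv")
    manifest["stages"]["drift"] = {
        "n_flagged": int(drift_tab["flagged"].sum()),
        "ne": config.ne,
    }

    # ---- manifest -----------------------------------------------------------
    outputs = sorted(p.name for p in out.glob("*.csv")) + ["tracks.tsv"]
    manifest["outputs"] = {name: _sha256(out / name) for name in outputs}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
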