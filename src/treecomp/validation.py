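"""Simulation studies validating the whole stack against known ground truth.

Each study simulates forests from the generator, runs the full pipeline
(assembly, conjugate fit, permutation test or spatial CV), and summarises the
outcome.  They serve two purposes: calibration evidence (is the permutation
test valid? do credible intervals cover?) and reproduction of the method's
qualitative behaviour (in-sample optimism of over-parameterized groupings
that buffered spatial CV exposes).

Study sizes are module defaults chosen so each study runs in minutes on one
core; all accept explicit arguments.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .neighborhood import NeighborhoodConfig, count_parameters
from .permutation import permutation_test_assembled
from .pipeline import assemble, fit_growth_model
from .spatial_cv import spatial_cv
from .synthetic import SyntheticSpec, h0_spec, recovery_report, simulate_forest

__all__ = [
    "null_spec",
    "strong_alternative_spec",
    "permutation_calibration",
    "permutation_power",
    "overfitting_study",
    "coverage_study",
]


def null_spec(J: int = 4, plot_side: float = 100.0) -> SyntheticSpec:
    """Generator truth satisfying the no-identity null: lambda_jk = lambda_j."""
    return h0_spec(SyntheticSpec(plot_extent=(0.0, plot_side, 0.0, plot_side), J=J))


def strong_alternative_spec(J: int = 4, plot_side: float = 140.0) -> SyntheticSpec:
    """Strongly identity-specific competition: lambda spread ~2e-4 across k.

    The spread is an order of magnitude above the default competitive effect,
    so competitor identity carries a clear growth signal.
    """
    jj, kk = np.meshgrid(np.arange(J), np.arange(J), indexing="ij")
    lam = -2e-5 - 2e-4 * ((jj + kk) % J) / max(J - 1, 1)
    return SyntheticSpec(
        plot_extent=(0.0, plot_side, 0.0, plot_side), J=J, true_lambda=lam
    )


def _spawn_seeds(seed: Optional[int], n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def permutation_calibration(
    n_datasets: int = 200,
    B: int = 99,
    seed: Optional[int] = None,
    spec: Optional[SyntheticSpec] = None,
) -> dict:
    """Null calibration: p-values on freshly simulated null forests.

    Under the null the p-value is (super-)uniform on its attainable grid
    {1/(B+1), ..., 1}, so the rejection rate at level alpha should not
    exceed alpha by more than Monte-Carlo noise.
    """
    spec = spec or null_spec()
    seeds = _spawn_seeds(seed, 2 * n_datasets)
    p_values = np.empty(n_datasets)
    for i in range(n_datasets):
        rng = np.random.default_rng(seeds[2 * i])
        c1, c2 = simulate_forest(spec, rng)
        asm = assemble(c1, c2, spec.true_grouping(), NeighborhoodConfig(radius=spec.radius))
        res = permutation_test_assembled(asm, B=B, seed=int(seeds[2 * i + 1]))
        p_values[i] = res.p_value
    return {
        "p_values": p_values,
        "rejection_rate_05": float(np.mean(p_values <= 0.05)),
        "rejection_rate_10": float(np.mean(p_values <= 0.10)),
        "n_datasets": n_datasets,
        "B": B,
    }


def permutation_power(
    n_replicates: int = 40,
    B: int = 99,
    seed: Optional[int] = None,
    spec: Optional[SyntheticSpec] = None,
) -> dict:
    """Power against the strong alternative: fraction of runs at the minimal p."""
    spec = spec or strong_alternative_spec()
    seeds = _spawn_seeds(seed, 2 * n_replicates)
    p_min = 1.0 / (B + 1)
    hits = 0
    for i in range(n_replicates):
        rng = np.random.default_rng(seeds[2 * i])
        c1, c2 = simulate_forest(spec, rng)
        asm = assemble(c1, c2, spec.true_grouping(), NeighborhoodConfig(radius=spec.radius))
        res = permutation_test_assembled(asm, B=B, seed=int(seeds[2 * i + 1]))
        hits += res.p_value == p_min
    return {
        "power_at_min_p": hits / n_replicates,
        "n_replicates": n_replicates,
        "B": B,
    }


def overfitting_study(
    n_replicates: int = 50,
    seed: Optional[int] = None,
    cell_size: float = 50.0,
) -> dict:
    """In-sample optimism of an over-parameterized grouping, exposed by CV.

    Forests are generated from a coarse truth (3 dynamic groups, each split
    into 4 species labels with identical dynamics, ~600 focal trees).  The
    species-level fit (J = K = 12) has far more parameters than the truth
    supports at this sample size, so its in-sample RMSE flatters it while
    buffered spatial CV does not — and CV does not rank it above the true
    coarse grouping.
    """
    seeds = _spawn_seeds(seed, n_replicates)
    cv_exceeds_insample = 0
    cv_prefers_small = 0
    rows = []
    for i in range(n_replicates):
        spec = SyntheticSpec(
            plot_extent=(0.0, 200.0, 0.0, 200.0), J=3, species_per_group=4,
            stem_density=170.0,
        )
        rng = np.random.default_rng(seeds[i])
        c1, c2 = simulate_forest(spec, rng)
        cfg = NeighborhoodConfig(radius=spec.radius)
        asm_true = assemble(c1, c2, spec.true_grouping(), cfg)
        asm_species = assemble(c1, c2, spec.species_grouping(), cfg)
        ins_s = fit_growth_model(asm_species.dataset).rmse_insample
        cv_s = spatial_cv(asm_species.dataset, cell_size=cell_size).mean_rmse
        ins_t = fit_growth_model(asm_true.dataset).rmse_insample
        cv_t = spatial_cv(asm_true.dataset, cell_size=cell_size).mean_rmse
        cv_exceeds_insample += cv_s > ins_s
        cv_prefers_small += cv_t <= cv_s
        rows.append((ins_s, cv_s, ins_t, cv_t))
    arr = np.asarray(rows)
    return {
        "frac_cv_exceeds_insample": cv_exceeds_insample / n_replicates,
        "frac_cv_prefers_small_model": cv_prefers_small / n_replicates,
        "mean_insample_rmse_species": float(arr[:, 0].mean()),
        "mean_cv_rmse_species": float(arr[:, 1].mean()),
        "mean_insample_rmse_true": float(arr[:, 2].mean()),
        "mean_cv_rmse_true": float(arr[:, 3].mean()),
        "parameters_species": count_parameters(12, 12),
        "parameters_true": count_parameters(3, 3),
        "n_replicates": n_replicates,
    }


def coverage_study(
    n_replicates: int = 100,
    seed: Optional[int] = None,
    spec: Optional[SyntheticSpec] = None,
) -> dict:
    """Frequentist coverage of the 95% marginal-t credible intervals."""
    spec = spec or SyntheticSpec(plot_extent=(0.0, 170.0, 0.0, 170.0), J=4)
    rep = recovery_report(spec, n_replicates, np.random.default_rng(seed))
    return {
        "overall_coverage": float(rep["coverage"].mean()),
        "min_parameter_coverage": float(rep["coverage"].min()),
        "mean_abs_bias": float(rep["bias"].abs().mean()),
        "n_replicates": n_replicates,
        "n_parameters": len(rep),
        "report": rep,
    }
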