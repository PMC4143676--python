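"""Reference simulation studies at the package's standard operating points.

These functions pin down the simulation designs used to characterize the
methods — empirical type-I error of the permutation tests, power across an
effect-size ladder, robustness to mixed effect directions versus a plain
burden collapse, and per-variant selection power of the sparse selectors —
so that the test suite and the reproduction script exercise identical
conditions.  Problem sizes are desk-scale: a few hundred samples, tens of
variants, hundreds of permutations and replicates.
"""

from __future__ import annotations

import pandas as pd

from .power import estimate_selection_power, estimate_test_power
from .synthetic import Covariate, Scenario, mixed_maf_spectrum

__all__ = [
    "null_scenario",
    "type_i_error_study",
    "effect_ladder_study",
    "direction_study",
    "selection_study",
    "selection_count_study",
]

#: mixed rare/common panel used throughout: 5 rare + 15 common variants
_PANEL = dict(n_rare=5, n_common=15)


def _panel_mafs() -> tuple:
    return mixed_maf_spectrum(seed=101, **_PANEL)


def null_scenario(n_samples: int = 200) -> Scenario:
    """No-association cohort: one covariate plus noise, zero genetic effect."""
    return Scenario(
        n_samples=n_samples,
        mafs=_panel_mafs(),
        covariates=(Covariate("z1", "normal", (0.0, 1.0), 0.5),),
        noise_sd=1.0,
        seed=0,
    )


def type_i_error_study(method: str = "tow", n_replicates: int = 500,
                       alpha: float = 0.05, n_permutations: int = 499,
                       seed: int = 0, n_samples: int = 200):
    """Empirical rejection rate of a test on null replicates (target: alpha)."""
    return estimate_test_power(
        null_scenario(n_samples), method=method, n_replicates=n_replicates,
        alpha=alpha, n_permutations=n_permutations, seed=seed,
        scenario_name="null",
    )


def _ladder_scenario(beta: float, n_samples: int) -> Scenario:
    """Three causal common variants of shared effect size ``beta``."""
    mafs = _panel_mafs()
    common = [j for j, m in enumerate(mafs) if m >= 0.05][:3]
    return Scenario(
        n_samples=n_samples, mafs=mafs,
        causal_indices=tuple(common),
        effect_sizes=(beta,) * len(common),
        covariates=(Covariate("z1", "normal", (0.0, 1.0), 0.5),),
        noise_sd=1.0, seed=0,
    )


def effect_ladder_study(betas=(0.0, 0.08, 0.2), n_samples: int = 500,
                        n_replicates: int = 200, alpha: float = 0.05,
                        n_permutations: int = 499, seed: int = 0,
                        method: str = "tow") -> pd.DataFrame:
    """TOW power across an effect-size ladder (null, small, large)."""
    rows = []
    for i, beta in enumerate(betas):
        rep = estimate_test_power(
            _ladder_scenario(beta, n_samples), method=method,
            n_replicates=n_replicates, alpha=alpha,
            n_permutations=n_permutations, seed=seed, scenario_index=i,
            scenario_name=f"beta={beta}",
        )
        rows.append({"beta": beta, **rep.to_dict()})
    return pd.DataFrame(rows)


def direction_scenario(beta: float = 0.35, n_samples: int = 300) -> Scenario:
    """Two common causal variants with equal-and-opposite effects (+b, -b)."""
    mafs = _panel_mafs()
    common = [j for j, m in enumerate(mafs) if m >= 0.2][:2]
    return Scenario(
        n_samples=n_samples, mafs=mafs,
        causal_indices=tuple(common), effect_sizes=(beta, -beta),
        noise_sd=1.0, seed=0,
    )


def direction_study(beta: float = 0.35, n_samples: int = 300,
                    n_replicates: int = 200, alpha: float = 0.05,
                    n_permutations: int = 499, seed: int = 0):
    """TOW vs unweighted burden power when effect directions are mixed."""
    scn = direction_scenario(beta, n_samples)
    tow = estimate_test_power(scn, "tow", n_replicates=n_replicates,
                              alpha=alpha, n_permutations=n_permutations,
                              seed=seed, scenario_name="mixed-direction")
    burden = estimate_test_power(scn, "burden", n_replicates=n_replicates,
                                 alpha=alpha, n_permutations=n_permutations,
                                 seed=seed, scenario_name="mixed-direction")
    return tow, burden


def selection_scenario(beta: float = 0.5, n_samples: int = 500,
                       n_noise: int = 20) -> Scenario:
    """One strong common causal variant among ``n_noise`` null variants."""
    rng_mafs = mixed_maf_spectrum(0, n_noise, seed=202)
    mafs = (0.3,) + rng_mafs
    return Scenario(
        n_samples=n_samples, mafs=mafs, causal_indices=(0,),
        effect_sizes=(beta,), noise_sd=1.0, seed=0,
    )


def selection_study(method: str = "lasso", n_replicates: int = 100,
                    seed: int = 0, tuning="cv") -> pd.DataFrame:
    """Per-variant selection frequency for the planted-causal scenario."""
    return estimate_selection_power(
        selection_scenario(), method=method, n_replicates=n_replicates,
        tuning=tuning, seed=seed,
    )


def selection_count_study(method: str = "lasso", target: int = 5,
                          n_replicates: int = 50, seed: int = 0) -> float:
    """Mean selected-set size under count-targeted tuning."""
    out = estimate_selection_power(
        selection_scenario(), method=method, n_replicates=n_replicates,
        tuning=("target_count", target), seed=seed,
    )
    return float(out["mean_selected"].iloc[0])
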