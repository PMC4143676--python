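"""Replicated simulation studies: type-I error, power, and selection power.

Each study draws R independent datasets from a :class:`~towgene.synthetic.Scenario`
(per-replicate seeds derived from one master seed via a counter), runs the
requested test or selector on each, and tabulates rejection or selection
frequencies with Monte-Carlo standard errors sqrt(p(1-p)/R).

Rejection uses p <= alpha: the permutation p-value (b+1)/(B+1) is uniform on
its discrete support under the null, so this rule has exact size whenever
alpha*(B+1) is an integer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .adjust import build_residual_data
from .selection import lasso_select, spls_select
from .synthetic import Scenario, generate_dataset
from .tow import BurdenTest, TOWTest
from .vwtow import VWTOWTest

__all__ = [
    "PowerReport",
    "estimate_test_power",
    "estimate_selection_power",
    "run_power_study",
    "replicate_seed",
]

_TESTS = {"tow": TOWTest, "burden": BurdenTest}


def replicate_seed(master_seed: int, scenario_index: int, rep: int) -> int:
    """Deterministic per-replicate seed (< 2^31) from a master seed."""
    ss = np.random.SeedSequence((int(master_seed), int(scenario_index), int(rep)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PowerReport:
    """One cell of a power table: a rejection-rate estimate with its SE."""

    scenario: str
    method: str
    trait: str
    n_replicates: int
    alpha: float
    rejections: int

    @property
    def power(self) -> float:
        return self.rejections / self.n_replicates

    @property
    def mc_se(self) -> float:
        p = self.power
        return float(np.sqrt(p * (1.0 - p) / self.n_replicates))

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "method": self.method,
            "trait": self.trait,
            "n_replicates": self.n_replicates,
            "alpha": self.alpha,
            "rejections": self.rejections,
            "power": self.power,
            "mc_se": self.mc_se,
        }


def _replicate_pvalue(scenario: Scenario, method: str, trait: str,
                      n_permutations: int, maf_threshold: float,
                      perm_seed: int) -> float:
    gm, pheno = generate_dataset(scenario)
    if trait == "MAP" and "MAP" not in pheno.data.columns:
        pheno = pheno.with_map()
    resid = build_residual_data(gm, pheno, trait)
    if method == "vwtow":
        maf = gm.maf
        rare = np.flatnonzero(maf < maf_threshold)
        common = np.flatnonzero(maf >= maf_threshold)
        res = VWTOWTest(resid, rare, common).fit(
            n_permutations=n_permutations, seed=perm_seed
        )
    else:
        res = _TESTS[method](resid).fit(n_permutations=n_permutations, seed=perm_seed)
    return res.p_value


def estimate_test_power(scenario: Scenario, method: str = "tow", trait: str = "y",
                        n_replicates: int = 200, alpha: float = 0.05,
                        n_permutations: int = 999, seed: int = 0,
                        maf_threshold: float = 0.01,
                        scenario_index: int = 0,
                        scenario_name: str | None = None) -> PowerReport:
    """Empirical rejection rate of a test over R simulated replicates.

    ``method`` is ``"tow"``, ``"vwtow"`` or ``"burden"``; on a null scenario
    the estimate is the empirical type-I error.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rejections = 0
    for rep in range(n_replicates):
        s = replicate_seed(seed, scenario_index, rep)
        scn = replace(scenario, seed=s)
        p = _replicate_pvalue(scn, method, trait, n_permutations, maf_threshold,
                              perm_seed=replicate_seed(seed, scenario_index + 10_000, rep))
        if p <= alpha:
            rejections += 1
    return PowerReport(
        scenario=scenario_name or f"scenario{scenario_index}",
        method=method,
        trait=trait,
        n_replicates=n_replicates,
        alpha=alpha,
        rejections=rejections,
    )


def estimate_selection_power(scenario: Scenario, method: str = "lasso",
                             trait: str = "y", n_replicates: int = 100,
                             tuning="cv", seed: int = 0,
                             scenario_index: int = 0) -> pd.DataFrame:
    """Per-variant selection frequency across replicates.

    Returns a DataFrame with one row per variant: selection frequency,
    whether the variant is truly causal, and the mean selected-set size
    (repeated per row for convenience).
    """
    select = {"lasso": lasso_select, "spls": spls_select}[method]
    counts = np.zeros(scenario.n_variants)
    sizes = []
    vids = None
    for rep in range(n_replicates):
        s = replicate_seed(seed, scenario_index, rep)
        scn = replace(scenario, seed=s)
        gm, pheno = generate_dataset(scn)
        if trait == "MAP" and "MAP" not in pheno.data.columns:
            pheno = pheno.with_map()
        resid = build_residual_data(gm, pheno, trait)
        res = select(resid, tuning=tuning)
        vids = resid.variant_ids
        sizes.append(res.n_selected)
        sel = set(res.selected_variant_ids)
        counts += np.array([v in sel for v in vids], dtype=float)
    causal = np.zeros(scenario.n_variants, dtype=bool)
    causal[list(scenario.causal_indices)] = True
    return pd.DataFrame(
        {
            "variant_id": vids,
            "method": method,
            "causal": causal,
            "selection_freq": counts / n_replicates,
            "n_replicates": n_replicates,
            "mean_selected": float(np.mean(sizes)),
        }
    )


def run_power_study(scenarios: dict, methods=("tow", "vwtow"), traits=None,
                    n_replicates: int = 200, alpha: float = 0.05,
                    n_permutations: int = 999, seed: int = 0,
                    maf_threshold: float = 0.01) -> pd.DataFrame:
    """Power table over named scenarios x methods x traits.

    ``scenarios`` maps name -> Scenario.  ``traits=None`` uses each
    scenario's own trait list (plus MAP when both SBP and DBP exist).
    Re-running with the same master seed reproduces the table exactly.
    """
    rows = []
    for s_idx, (name, scenario) in enumerate(scenarios.items()):
        trait_list = traits
        if trait_list is None:
            trait_list = list(scenario.trait_names)
            if {"SBP", "DBP"} <= set(trait_list):
                trait_list.append("MAP")
        for method in methods:
            for trait in trait_list:
                rep = estimate_test_power(
                    scenario, method=method, trait=trait,
                    n_replicates=n_replicates, alpha=alpha,
                    n_permutations=n_permutations, seed=seed,
                    maf_threshold=maf_threshold, scenario_index=s_idx,
                    scenario_name=name,
                )
                rows.append(rep.to_dict())
    return pd.DataFrame(rows)
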