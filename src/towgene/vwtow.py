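"""Variable-weight TOW: combining rare- and common-variant evidence.

Rare and common variants in a region may carry signal in different
proportions.  VW-TOW computes the TOW statistic separately on the rare
subset (T_r) and the common subset (T_c), standardizes each by its
permutation variance, and scans the convex combinations

    T_lambda = lambda * T_r / var(T_r) + (1 - lambda) * T_c / var(T_c)

over the discrete grid lambda_k = k/K, k = 0..K.  The test statistic is the
minimum over the grid of the per-lambda permutation p-values; because that
minimum is itself selected data-dependently, it is recalibrated against the
permutation distribution of min-p values (each permutation is treated as
"observed" in turn against the full permutation set, which contains it, so
observed and permuted minima are exchangeable).

var(T_r) and var(T_c) are estimated as sample variances of the permuted
statistics — the permutation distribution is already in hand and the
estimate needs no further assumptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .adjust import ResidualData
from .tow import TOWTest, TOWResults, permutation_indices

__all__ = ["VWTOWTest", "VWTOWResults", "vwtow_test"]


@dataclass
class VWTOWResults:
    """VW-TOW permutation results with per-lambda detail.

    ``per_lambda`` holds one row per grid point: (lambda, observed
    T_lambda, p_lambda).  ``p_value`` is the recalibrated min-p and carries
    the usual 1/(B+1) floor.  When one subset is empty or degenerate the
    test collapses to plain TOW on the other subset and ``collapsed_to``
    records which.
    """

    p_value: float
    per_lambda: pd.DataFrame
    K: int
    var_rare: float
    var_common: float
    n_rare: int
    n_common: int
    n_permutations: int
    seed: object = None
    min_p_observed: float = np.nan
    trait_name: str = "y"
    collapsed_to: str | None = None
    tow_result: TOWResults | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            f"VW-TOW permutation test ({self.trait_name})",
            f"  rare / common variants : {self.n_rare} / {self.n_common}",
            f"  lambda grid            : k/{self.K}, k = 0..{self.K}",
            f"  permutations           : {self.n_permutations}",
        ]
        if self.collapsed_to:
            lines.append(f"  collapsed to plain TOW on {self.collapsed_to} subset")
        else:
            lines.append(f"  observed min-p over grid: {self.min_p_observed:.6g}")
        lines.append(f"  p-value                : {self.p_value:.6g}")
        return "\n".join(lines)


class VWTOWTest:
    """Variable-weight TOW test over a rare/common split of one region.

    Parameters
    ----------
    resid : ResidualData
        Covariate-adjusted residuals covering the full variant set.
    rare_subset, common_subset : array-like of int
        Disjoint column indices into ``resid.x_resid``.
    """

    def __init__(self, resid: ResidualData, rare_subset, common_subset):
        self.resid = resid
        self.rare = np.asarray(rare_subset, dtype=int)
        self.common = np.asarray(common_subset, dtype=int)
        if np.intersect1d(self.rare, self.common).size:
            raise ValueError("rare and common subsets must be disjoint")
        if self.rare.size == 0 and self.common.size == 0:
            raise ValueError("both variant subsets are empty")

    def fit(self, K: int = 10, n_permutations: int = 999, seed=None,
            permutations=None) -> VWTOWResults:
        if K < 1:
            raise ValueError("lambda grid needs K >= 1")
        if permutations is None:
            permutations = permutation_indices(
                self.resid.n_samples, n_permutations, seed
            )
        else:
            permutations = np.asarray(permutations)
            n_permutations = permutations.shape[0]
        B = n_permutations

        if self.rare.size == 0 or self.common.size == 0:
            which = "common" if self.rare.size == 0 else "rare"
            return self._collapse(which, K, permutations, seed)

        # T_r, T_c for observed (index 0) and each permutation, shared stream.
        t_r = self._stat_series(self.rare, permutations)
        t_c = self._stat_series(self.common, permutations)
        var_r = float(np.var(t_r[1:], ddof=1))
        var_c = float(np.var(t_c[1:], ddof=1))
        if var_r == 0.0 or var_c == 0.0:
            which = "common" if var_r == 0.0 else "rare"
            warnings.warn(
                f"degenerate permutation variance for the "
                f"{'rare' if which == 'common' else 'common'} subset; "
                f"collapsing to plain TOW on the {which} subset",
                stacklevel=2,
            )
            res = self._collapse(which, K, permutations, seed)
            res.var_rare, res.var_common = var_r, var_c
            res.n_rare, res.n_common = self.rare.size, self.common.size
            return res

        lambdas = np.arange(K + 1) / K
        N = B + 1
        # p_lambda for EVERY b (0 = observed): share of the pooled set with a
        # statistic at least as large.  For b = 0 this equals the usual
        # (#{perm >= obs} + 1)/(B + 1) since the observed value counts itself.
        p_matrix = np.empty((K + 1, N))
        t_obs = np.empty(K + 1)
        for k, lam in enumerate(lambdas):
            t_lam = lam * t_r / var_r + (1.0 - lam) * t_c / var_c
            t_obs[k] = t_lam[0]
            p_matrix[k] = (N - rankdata(t_lam, method="min") + 1) / N
        min_p = p_matrix.min(axis=0)
        p_value = (int(np.sum(min_p[1:] <= min_p[0])) + 1) / N

        per_lambda = pd.DataFrame(
            {"lambda": lambdas, "t_lambda": t_obs, "p_lambda": p_matrix[:, 0]}
        )
        return VWTOWResults(
            p_value=p_value,
            per_lambda=per_lambda,
            K=K,
            var_rare=var_r,
            var_common=var_c,
            n_rare=self.rare.size,
            n_common=self.common.size,
            n_permutations=B,
            seed=seed,
            min_p_observed=float(min_p[0]),
            trait_name=self.resid.trait_name,
        )

    # ------------------------------------------------------------------ #
    def _stat_series(self, subset, permutations) -> np.ndarray:
        """Observed statistic followed by one statistic per permutation."""
        test = TOWTest(self.resid, subset)
        yc = test._yc
        perm_stats = test._stats_for(yc[permutations])
        return np.concatenate([[test.statistic], perm_stats])

    def _collapse(self, which: str, K: int, permutations, seed) -> VWTOWResults:
        subset = self.common if which == "common" else self.rare
        tow = TOWTest(self.resid, subset).fit(permutations=permutations, seed=seed)
        return VWTOWResults(
            p_value=tow.p_value,
            per_lambda=pd.DataFrame(columns=["lambda", "t_lambda", "p_lambda"]),
            K=K,
            var_rare=np.nan,
            var_common=np.nan,
            n_rare=self.rare.size,
            n_common=self.common.size,
            n_permutations=tow.n_permutations,
            seed=seed,
            trait_name=self.resid.trait_name,
            collapsed_to=which,
            tow_result=tow,
        )


def vwtow_test(resid: ResidualData, rare_subset, common_subset, K: int = 10,
               n_permutations: int = 999, seed=None,
               permutations=None) -> VWTOWResults:
    """Functional wrapper around :class:`VWTOWTest`."""
    return VWTOWTest(resid, rare_subset, common_subset).fit(
        K=K, n_permutations=n_permutations, seed=seed, permutations=permutations
    )
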