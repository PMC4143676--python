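"""Test for the effect of an Optimally Weighted combination of variants (TOW).

TOW scores a region of M variants against a quantitative trait after both
have been residualized on covariates.  Each variant m receives the weight

    w_m = sum_i (y~_i - ybar)(x~_im - xbar_m) / sum_i (x~_im - xbar_m)^2,

the simple-regression slope of the adjusted trait on the adjusted dosage;
the statistic is the trait covariance with the weighted dosage combination,

    T = sum_i (y~_i - ybar)(x^o_i - xbar^o),   x^o_i = sum_m w_m x~_im,

which algebraically equals sum_m [cov numerator]^2 / [var numerator] and is
therefore non-negative, with mixed-direction effects contributing additively
rather than cancelling.  Significance is assessed by permuting the trait
residuals; the weights depend on the trait, so they are recomputed inside
every permutation.

The public surface follows the statsmodels convention: build a
:class:`TOWTest` (or :class:`BurdenTest`) from residual data, call
``fit()``, and read the returned results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjust import ResidualData

__all__ = [
    "TOWTest",
    "BurdenTest",
    "TOWResults",
    "optimal_weights",
    "tow_statistic",
    "permutation_pvalue",
    "permutation_indices",
]


def permutation_indices(n: int, n_permutations: int, seed=None) -> np.ndarray:
    """A ``(n_permutations, n)`` matrix of sample orderings.

    One shared matrix can drive every region in a run, which both speeds the
    scan and lets rare/common/combined p-values be compared under identical
    permutations.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(n_permutations)])


def _subset_matrix(resid: ResidualData, variant_subset):
    if variant_subset is None:
        return resid.x_resid
    idx = np.asarray(variant_subset)
    if idx.size == 0:
        raise ValueError("variant subset is empty")
    return resid.x_resid[:, idx]


def optimal_weights(resid: ResidualData, variant_subset=None):
    """Per-variant optimal weights w_m (regression slopes of y~ on x~_m).

    Variants whose residual dosage has zero variance get weight 0 and are
    flagged out of the statistic.  Returns ``(weights, informative_mask)``.
    """
    X = _subset_matrix(resid, variant_subset)
    if resid.n_samples < 2:
        raise ValueError("need at least two samples")
    yc = resid.y_resid - resid.y_resid.mean()
    Xc = X - X.mean(axis=0)
    denom = np.einsum("ij,ij->j", Xc, Xc)
    informative = denom > 0
    w = np.zeros(X.shape[1])
    w[informative] = (yc @ Xc[:, informative]) / denom[informative]
    return w, informative


def tow_statistic(resid: ResidualData, variant_subset=None) -> float:
    """Observed TOW statistic; 0 (with a warning) if no variant is informative."""
    return TOWTest(resid, variant_subset).statistic


@dataclass
class TOWResults:
    """Permutation-test results for a TOW (or burden) statistic.

    ``p_value`` uses the (b+1)/(B+1) estimator, where b counts permutation
    statistics at least as large as the observed one, so it is bounded below
    by 1/(B+1) and never exactly zero.
    """

    statistic: float
    p_value: float
    n_permutations: int
    seed: object = None
    weights: np.ndarray | None = None
    n_variants_tested: int = 0
    method: str = "TOW"
    trait_name: str = "y"
    perm_statistics: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            f"{self.method} permutation test ({self.trait_name})",
            f"  variants tested : {self.n_variants_tested}",
            f"  statistic       : {self.statistic:.6g}",
            f"  permutations    : {self.n_permutations}",
            f"  p-value         : {self.p_value:.6g}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": self.method,
                    "trait": self.trait_name,
                    "n_variants": self.n_variants_tested,
                    "statistic": self.statistic,
                    "p_value": self.p_value,
                    "n_permutations": self.n_permutations,
                }
            ]
        )


class _PermutationScoreTest:
    """Shared machinery: a score of centered y~ versus fixed columns, permuted."""

    method = "score"

    def __init__(self, resid: ResidualData, variant_subset=None):
        self.resid = resid
        self.variant_subset = (
            None if variant_subset is None else np.asarray(variant_subset)
        )
        X = _subset_matrix(resid, variant_subset)
        self._yc = resid.y_resid - resid.y_resid.mean()
        self._Xc = X - X.mean(axis=0)
        self._denom = np.einsum("ij,ij->j", self._Xc, self._Xc)
        self._informative = self._denom > 0
        if not self._informative.any():
            warnings.warn(
                "no variant varies after residualization; statistic is 0",
                stacklevel=3,
            )

    @property
    def n_variants(self) -> int:
        return self._Xc.shape[1]

    def _stats_for(self, Y: np.ndarray) -> np.ndarray:
        """Statistic for each row of ``Y`` (rows are centered y~ vectors)."""
        raise NotImplementedError

    @property
    def statistic(self) -> float:
        return float(self._stats_for(self._yc[None, :])[0])

    def fit(self, n_permutations: int = 999, seed=None, permutations=None) -> TOWResults:
        """Permutation p-value: p = (#{T_perm >= T_obs} + 1) / (B + 1).

        ``permutations`` may supply a precomputed index matrix (shared
        across regions/tests); otherwise one is drawn from ``seed``.
        """
        if permutations is None:
            permutations = permutation_indices(
                self.resid.n_samples, n_permutations, seed
            )
        else:
            permutations = np.asarray(permutations)
            n_permutations = permutations.shape[0]
        if n_permutations < 1:
            raise ValueError("need at least one permutation")
        obs = self.statistic
        perm_stats = self._stats_for(self._yc[permutations])
        b = int(np.sum(perm_stats >= obs))
        w, _ = optimal_weights(self.resid, self.variant_subset)
        return TOWResults(
            statistic=obs,
            p_value=(b + 1) / (n_permutations + 1),
            n_permutations=n_permutations,
            seed=seed,
            weights=w,
            n_variants_tested=self.n_variants,
            method=self.method,
            trait_name=self.resid.trait_name,
            perm_statistics=perm_stats,
        )


class TOWTest(_PermutationScoreTest):
    """Optimally weighted combination test on residualized data.

    Parameters
    ----------
    resid : ResidualData
        Covariate-adjusted trait and dosage residuals.
    variant_subset : array-like of int, optional
        Column indices restricting the test to a sub-region (e.g. the rare
        or common split); ``None`` tests every variant.
    """

    method = "TOW"

    def _stats_for(self, Y: np.ndarray) -> np.ndarray:
        # T = sum_m (y.x_m)^2 / (x_m.x_m); weights are implicit, so they are
        # re-derived from each permuted trait vector automatically.
        S = Y @ self._Xc[:, self._informative]
        return (S * S / self._denom[self._informative]).sum(axis=1)

    @property
    def weights(self) -> np.ndarray:
        w, _ = optimal_weights(self.resid, self.variant_subset)
        return w


class BurdenTest(_PermutationScoreTest):
    """Unweighted burden comparator: squared trait score of the dosage sum.

    Collapses the region to s_i = sum_m x~_im and tests (sum_i y~_i s_i)^2
    by the same permutation scheme as TOW.  Mixed-direction effects cancel
    inside s_i, which is exactly the weakness TOW's signed weights avoid.
    """

    method = "burden"

    def __init__(self, resid: ResidualData, variant_subset=None):
        super().__init__(resid, variant_subset)
        s = self._Xc.sum(axis=1)
        self._sc = s - s.mean()

    def _stats_for(self, Y: np.ndarray) -> np.ndarray:
        return (Y @ self._sc) ** 2


def permutation_pvalue(resid: ResidualData, variant_subset=None,
                       n_permutations: int = 999, seed=None,
                       permutations=None) -> TOWResults:
    """Functional wrapper: TOW permutation test in one call."""
    return TOWTest(resid, variant_subset).fit(
        n_permutations=n_permutations, seed=seed, permutations=permutations
    )
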