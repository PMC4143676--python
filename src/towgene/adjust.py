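"""Composite traits, sample filtering, and covariate residualization.

Association testing here is covariate-adjusted in two steps: the trait and
every genotype column are each regressed on the covariates (plus an
intercept) by ordinary least squares, and the tests operate entirely on the
residuals.  This module builds the composite mean-arterial-pressure trait,
drops samples with incomplete phenotype/covariate records, and produces the
:class:`ResidualData` bundle the tests consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeTable",
    "ResidualData",
    "mean_arterial_pressure",
    "drop_incomplete",
    "residualize",
    "residualize_genotypes",
    "build_residual_data",
    "read_phenotypes",
]


def mean_arterial_pressure(sbp, dbp):
    """Mean arterial pressure, MAP = (2/3)*DBP + (1/3)*SBP, in mmHg.

    Accepts scalars or arrays and broadcasts elementwise.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if not (np.all(np.isfinite(sbp)) and np.all(np.isfinite(dbp))):
        raise ValueError("SBP/DBP values must be finite")
    out = (2.0 / 3.0) * dbp + (1.0 / 3.0) * sbp
    return float(out) if out.ndim == 0 else out


@dataclass
class PhenotypeTable:
    """Phenotype and covariate columns for a set of samples.

    ``data`` is indexed by sample id; ``trait_cols`` and ``covariate_cols``
    name the columns holding traits (e.g. SBP, DBP, MAP) and covariates.
    """

    data: pd.DataFrame
    trait_cols: tuple = ()
    covariate_cols: tuple = ()

    def __post_init__(self):
        self.trait_cols = tuple(self.trait_cols)
        self.covariate_cols = tuple(self.covariate_cols)
        missing = [
            c for c in self.trait_cols + self.covariate_cols if c not in self.data.columns
        ]
        if missing:
            raise ValueError(f"columns not present in phenotype table: {missing}")

    @property
    def sample_ids(self) -> list:
        return [str(s) for s in self.data.index]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def trait(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def covariates(self, names=None) -> np.ndarray:
        names = self.covariate_cols if names is None else tuple(names)
        if not names:
            return np.empty((self.n_samples, 0))
        return self.data[list(names)].to_numpy(dtype=float)

    def with_map(self, sbp: str = "SBP", dbp: str = "DBP", name: str = "MAP") -> "PhenotypeTable":
        """Return a copy with the composite MAP trait added."""
        data = self.data.copy()
        data[name] = mean_arterial_pressure(data[sbp], data[dbp])
        traits = self.trait_cols if name in self.trait_cols else self.trait_cols + (name,)
        return PhenotypeTable(data, traits, self.covariate_cols)


def read_phenotypes(path, traits, covariates, sample_col="sample_id",
                    na_values=("NA", "")) -> PhenotypeTable:
    """Read a phenotype/covariate TSV with an explicit missing-value token."""
    df = pd.read_csv(path, sep="\t", na_values=list(na_values), keep_default_na=True)
    if sample_col not in df.columns:
        raise ValueError(f"sample id column {sample_col!r} not found in {path}")
    df = df.set_index(df[sample_col].astype(str)).drop(columns=[sample_col])
    return PhenotypeTable(df, tuple(traits), tuple(covariates))


def drop_incomplete(pheno: PhenotypeTable):
    """Drop samples with any missing trait or covariate value.

    Returns ``(filtered_table, n_removed)``; raises if no sample survives.
    """
    cols = list(pheno.trait_cols + pheno.covariate_cols)
    keep = ~pheno.data[cols].isna().any(axis=1) if cols else pd.Series(True, index=pheno.data.index)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("every sample has a missing phenotype or covariate")
    if n_removed:
        logger.info("dropped %d of %d samples with incomplete records",
                    n_removed, pheno.n_samples)
    out = PhenotypeTable(pheno.data.loc[keep].copy(), pheno.trait_cols, pheno.covariate_cols)
    return out, n_removed


# ---------------------------------------------------------------------- #
# OLS residualization (QR-based)
# ---------------------------------------------------------------------- #
def _design_q(Z: np.ndarray, names=None) -> np.ndarray:
    """Orthonormal basis Q of the span of [1, Z]; raises on rank deficiency."""
    n = Z.shape[0]
    D = np.column_stack([np.ones(n), Z])
    if n <= D.shape[1]:
        raise ValueError(
            f"residualization needs more samples ({n}) than design columns ({D.shape[1]})"
        )
    q, r = np.linalg.qr(D)
    diag = np.abs(np.diag(r))
    tol = max(D.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    dep = np.flatnonzero(diag < tol)
    if dep.size:
        names = list(names) if names is not None else [f"z{j}" for j in range(Z.shape[1])]
        labels = ["intercept" if j == 0 else names[j - 1] for j in dep]
        raise ValueError(f"collinear covariates in design: {labels}")
    return q


def residualize(y, Z=None, covariate_names=None) -> np.ndarray:
    """OLS residuals of ``y`` on an intercept plus covariate columns ``Z``.

    With ``Z`` empty or ``None`` this is simple mean-centering.  The
    projection uses a QR decomposition, so residuals are orthogonal to the
    intercept and to every covariate at machine precision.
    """
    y = np.asarray(y, dtype=float)
    if Z is None:
        Z = np.empty((y.shape[0], 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != y.shape[0]:
        raise ValueError("y and Z have different numbers of samples")
    q = _design_q(Z, covariate_names)
    return y - q @ (q.T @ y)


def residualize_genotypes(X, Z=None, covariate_names=None) -> np.ndarray:
    """Residualize every (mean-imputed) dosage column on [1, Z] at once.

    Dosage is treated as numeric additive coding; missing entries are
    mean-imputed per variant before the fit.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x variants)")
    if np.isnan(X).any():
        X = X.copy()
        col_mean = np.zeros(X.shape[1])
        seen = ~np.all(np.isnan(X), axis=0)
        col_mean[seen] = np.nanmean(X[:, seen], axis=0)
        miss = np.isnan(X)
        X[miss] = np.broadcast_to(col_mean, X.shape)[miss]
    if Z is None:
        Z = np.empty((X.shape[0], 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    q = _design_q(Z, covariate_names)
    return X - q @ (q.T @ X)


@dataclass
class ResidualData:
    """Covariate-adjusted phenotype and genotype residuals.

    ``y_resid`` and each column of ``x_resid`` are OLS residuals on the same
    intercept-plus-covariates design, so all have (numerically) zero mean.
    """

    y_resid: np.ndarray
    x_resid: np.ndarray
    trait_name: str = "y"
    variant_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.y_resid = np.asarray(self.y_resid, dtype=float)
        self.x_resid = np.asarray(self.x_resid, dtype=float)
        if self.x_resid.ndim != 2 or self.x_resid.shape[0] != self.y_resid.shape[0]:
            raise ValueError("x_resid must be (n_samples, n_variants) matching y_resid")
        if not self.variant_ids:
            self.variant_ids = [f"v{j}" for j in range(self.x_resid.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.y_resid.shape[0]

    @property
    def n_variants(self) -> int:
        return self.x_resid.shape[1]


def build_residual_data(genotypes, phenotypes: PhenotypeTable, trait: str,
                        covariates=None) -> ResidualData:
    """Align samples, adjust trait and dosages for covariates, bundle residuals.

    ``genotypes`` and ``phenotypes`` must cover the same samples; the
    genotype matrix is reordered/subset to the phenotype table's samples
    (raising if any phenotype sample lacks genotypes).
    """
    geno_index = {s: i for i, s in enumerate(genotypes.sample_ids)}
    missing = [s for s in phenotypes.sample_ids if s not in geno_index]
    if missing:
        raise ValueError(
            f"{len(missing)} phenotype samples have no genotypes "
            f"(first few: {missing[:5]})"
        )
    order = [geno_index[s] for s in phenotypes.sample_ids]
    gm = genotypes.subset_samples(order)
    Z = phenotypes.covariates()
    names = phenotypes.covariate_cols
    y_res = residualize(phenotypes.trait(trait), Z, names)
    x_res = residualize_genotypes(gm.dosages, Z, names)
    return ResidualData(
        y_resid=y_res,
        x_resid=x_res,
        trait_name=trait,
        variant_ids=list(gm.variant_ids),
        sample_ids=list(gm.sample_ids),
    )
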