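"""Genotype dosage container with variant metadata and VCF/TSV I/O.

The central in-memory object is :class:`GenotypeMatrix`: an ``n_samples x
n_variants`` matrix of additive dosages (minor-allele copy counts, coded
0/1/2, ``NaN`` for missing) together with per-variant chromosome, position
and identifiers.  Minor-allele frequencies are always recomputed from the
current non-missing entries, so any sample subsetting automatically
refreshes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """Sample-by-variant dosage matrix.

    Parameters
    ----------
    sample_ids : list of str
        One identifier per row of ``dosages``.
    variant_ids : list of str
        One identifier per column of ``dosages``.
    chrom : ndarray of str
        Chromosome per variant.
    pos : ndarray of int
        1-based base-pair position per variant.
    dosages : ndarray, shape (n_samples, n_variants)
        Entries in {0, 1, 2} or ``NaN`` for missing.
    """

    sample_ids: list
    variant_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x variants) array")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} dosage rows")
        if not (len(self.variant_ids) == len(self.chrom) == len(self.pos) == m):
            raise ValueError("variant metadata length does not match dosage columns")
        with np.errstate(invalid="ignore"):
            bad = ~(np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage for sample {self.sample_ids[i]!r}, variant "
                f"{self.variant_ids[j]!r} is {self.dosages[i, j]!r}; "
                "expected 0, 1, 2 or missing"
            )

    # ------------------------------------------------------------------ #
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant, from non-missing entries.

        Allele frequencies above 0.5 are folded (``1 - f``) so the returned
        values lie in ``[0, 0.5]``; variants with no observed genotypes get
        ``NaN``.
        """
        with np.errstate(invalid="ignore"):
            f = np.nanmean(self.dosages, axis=0) / 2.0
        return np.where(f > 0.5, 1.0 - f, f)

    # ------------------------------------------------------------------ #
    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            variant_ids=list(self.variant_ids),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            dosages=self.dosages[index, :].copy(),
        )

    def subset_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=[self.variant_ids[j] for j in index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            dosages=self.dosages[:, index].copy(),
        )

    def mean_imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the variant mean.

        Variants that are entirely missing are imputed to 0.  This is the
        smallest-impact missing-data policy: mean imputation leaves the
        centered dosage column, hence every downstream statistic, unchanged
        for the observed samples.
        """
        out = self.dosages.copy()
        col_mean = np.zeros(self.n_variants)
        seen = ~np.all(np.isnan(out), axis=0)
        col_mean[seen] = np.nanmean(out[:, seen], axis=0)
        miss = np.isnan(out)
        out[miss] = np.broadcast_to(col_mean, out.shape)[miss]
        return out

    # ------------------------------------------------------------------ #
    # Text I/O
    # ------------------------------------------------------------------ #
    def to_tsv(self, path) -> None:
        """Write a plain dosage table: variants as rows, samples as columns."""
        df = pd.DataFrame(
            self.dosages.T,
            index=pd.Index(self.variant_ids, name="variant_id"),
            columns=self.sample_ids,
        )
        df.insert(0, "chrom", self.chrom)
        df.insert(1, "pos", self.pos)
        df.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="variant_id", na_values=["NA", ""])
        chrom = df.pop("chrom").astype(str).to_numpy(dtype=object)
        pos = df.pop("pos").to_numpy(dtype=np.int64)
        return cls(
            sample_ids=[str(c) for c in df.columns],
            variant_ids=[str(v) for v in df.index],
            chrom=chrom,
            pos=pos,
            dosages=df.to_numpy(dtype=float).T,
        )

    def to_vcf(self, path) -> None:
        """Write a minimal VCF 4.2 file (GT only, one ALT per site).

        Alleles are synthetic placeholders (REF=A, ALT=C); dosage d is
        encoded as 0/0, 0/1, 1/1 and missing as ./. .
        """
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in sorted(set(self.chrom.astype(str))):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(str(s) for s in self.sample_ids)
                + "\n"
            )
            order = np.lexsort((self.pos, self.chrom.astype(str)))
            for j in order:
                gts = [
                    code.get(d, "./.") if not np.isnan(d) else "./."
                    for d in self.dosages[:, j]
                ]
                fh.write(
                    f"{self.chrom[j]}\t{self.pos[j]}\t{self.variant_ids[j]}"
                    f"\tA\tC\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read genotypes from a VCF via cyvcf2 (first ALT, additive coding)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)  # gt_types: 0,1,2 = dosage; 3 = missing
        samples = list(vcf.samples)
        chrom, pos, vids, rows = [], [], [], []
        for var in vcf:
            chrom.append(var.CHROM)
            pos.append(var.POS)
            vids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
            g = var.gt_types.astype(float)
            g[g == 3] = np.nan
            rows.append(g)
        vcf.close()
        if not rows:
            raise ValueError(f"no variant records in {path}")
        return cls(
            sample_ids=samples,
            variant_ids=vids,
            chrom=np.array(chrom, dtype=object),
            pos=np.array(pos, dtype=np.int64),
            dosages=np.vstack(rows).T,
        )
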