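"""Region mapping: annotation parsing, monomorphic filtering, MAF split."""

import io

import numpy as np
import pytest

from towgene.genotype import GenotypeMatrix
from towgene.regions import (
    drop_monomorphic,
    map_to_regions,
    parse_annotation,
    write_regions_bed,
)


def refgene_row(name, chrom, tx_start, tx_end, symbol):
    # 16-column UCSC refGene layout; only chrom/txStart/txEnd/name2 matter here
    return "\t".join([
        "0", name, chrom, "+", str(tx_start), str(tx_end), str(tx_start),
        str(tx_end), "1", f"{tx_start},", f"{tx_end},", "0", symbol, "cmpl",
        "cmpl", "0,",
    ])


def make_gm(positions, dosage_cols, chrom="3"):
    D = np.array(dosage_cols, dtype=float).T
    M = D.shape[1]
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(D.shape[0])],
        variant_ids=[f"v{j}" for j in range(M)],
        chrom=np.full(M, chrom, dtype=object),
        pos=np.asarray(positions),
        dosages=D,
    )


# ---------------------------------------------------------------------- #
class TestParseAnnotation:
    def test_transcript_union_and_coordinate_shift(self):
        # [100,200) and [150,300) 0-based half-open -> 101..300 1-based inclusive
        text = "\n".join([
            refgene_row("NM_a", "3", 100, 200, "GENE1"),
            refgene_row("NM_b", "3", 150, 300, "GENE1"),
        ])
        spans = parse_annotation(io.StringIO(text))
        assert len(spans) == 1
        sp = spans[0]
        assert (sp.name, sp.chrom, sp.start, sp.end) == ("GENE1", "3", 101, 300)

    def test_malformed_row_skipped_with_warning(self, caplog):
        text = "\n".join([
            refgene_row("NM_a", "3", 100, 200, "GENE1"),
            "0\tNM_b\t3\t+\tnot_a_number\t300",
        ])
        with caplog.at_level("WARNING"):
            spans = parse_annotation(io.StringIO(text))
        assert len(spans) == 1
        assert any("malformed" in r.message for r in caplog.records)

    def test_empty_file_is_error(self):
        with pytest.raises(ValueError, match="no parseable"):
            parse_annotation(io.StringIO(""))

    def test_three_gene_fixture(self):
        text = "\n".join([
            refgene_row("NM_1", "3", 1000, 2000, "A"),
            refgene_row("NM_2", "3", 5000, 6000, "B"),
            refgene_row("NM_3", "5", 100, 400, "C"),
        ])
        spans = {s.name: s for s in parse_annotation(io.StringIO(text))}
        assert (spans["A"].start, spans["A"].end) == (1001, 2000)
        assert (spans["B"].start, spans["B"].end) == (5001, 6000)
        assert (spans["C"].chrom, spans["C"].start, spans["C"].end) == ("5", 101, 400)

    def test_gzipped_annotation(self, tmp_path):
        import gzip

        p = tmp_path / "ann.txt.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(refgene_row("NM_1", "3", 10, 20, "G") + "\n")
        spans = parse_annotation(p)
        assert spans[0].start == 11 and spans[0].end == 20


# ---------------------------------------------------------------------- #
class TestDropMonomorphic:
    def test_constant_and_varying_columns(self):
        gm = make_gm(
            [1, 2, 3],
            dosage_cols=[[0, 0, 0], [0, 0, 1], [2, 2, 2]],
        )
        out, n_removed = drop_monomorphic(gm)
        assert n_removed == 2
        assert out.variant_ids == ["v1"]

    def test_fixture_counts(self):
        cols = [[0, 1, 2]] * 7 + [[0, 0, 0], [1, 1, 1], [2, 2, 2]]
        gm = make_gm(range(10), dosage_cols=cols)
        out, n_removed = drop_monomorphic(gm)
        assert (out.n_variants, n_removed) == (7, 3)

    def test_all_missing_column_counts_as_monomorphic(self):
        gm = make_gm([1, 2], dosage_cols=[[np.nan, np.nan, np.nan], [0, 1, 2]])
        out, n_removed = drop_monomorphic(gm)
        assert n_removed == 1 and out.variant_ids == ["v1"]

    def test_all_monomorphic_returns_empty_with_warning(self, caplog):
        gm = make_gm([1], dosage_cols=[[1, 1, 1]])
        with caplog.at_level("WARNING"):
            out, n_removed = drop_monomorphic(gm)
        assert out.n_variants == 0 and n_removed == 1
        assert any("monomorphic" in r.message for r in caplog.records)


# ---------------------------------------------------------------------- #
def two_gene_layout():
    """10 variants: 3 in GENE1 (1000-2000), 3 between, 2 in GENE2 (5000-6000), flanks."""
    positions = [500, 1000, 1500, 2000, 3000, 3500, 4000, 5000, 6000, 7000]
    # common column [0,1,2,...] pattern; last two variants made rare-ish via dosage
    cols = []
    for j in range(10):
        col = [0, 1, 2, 1, 0, 1] if j < 8 else [0, 0, 0, 0, 0, 1]
        cols.append(col)
    text = "\n".join([
        refgene_row("NM_1", "3", 999, 2000, "GENE1"),   # 1-based 1000..2000
        refgene_row("NM_2", "3", 4999, 6000, "GENE2"),  # 1-based 5000..6000
    ])
    return make_gm(positions, cols), parse_annotation(io.StringIO(text))


class TestMapToRegions:
    def test_gene_and_intergenic_partition(self):
        gm, spans = two_gene_layout()
        rs = map_to_regions(gm, spans, maf_threshold=0.01)
        by_name = {r.name: r for r in rs}
        assert set(by_name) == {
            "GENE1", "GENE2", "upstream_GENE1", "between_GENE1_GENE2",
            "downstream_GENE2",
        }
        assert list(by_name["GENE1"].variant_indices) == [1, 2, 3]
        assert list(by_name["GENE2"].variant_indices) == [7, 8]
        assert list(by_name["between_GENE1_GENE2"].variant_indices) == [4, 5, 6]
        # boundary positions (first/last base of a span) map into the gene
        assert 1 in by_name["GENE1"].variant_indices
        assert 3 in by_name["GENE1"].variant_indices
        # gene-vs-intergenic partition covers every variant exactly once
        all_idx = np.concatenate([r.variant_indices for r in rs])
        assert sorted(all_idx) == list(range(10))

    def test_rare_common_split_and_boundary(self):
        gm, spans = two_gene_layout()
        maf = gm.maf
        threshold = 0.2
        rs = map_to_regions(gm, spans, maf_threshold=threshold)
        for r in rs:
            assert set(r.variant_indices) == set(r.rare_indices) | set(r.common_indices)
            assert not set(r.rare_indices) & set(r.common_indices)
            assert all(maf[j] < threshold for j in r.rare_indices)
            assert all(maf[j] >= threshold for j in r.common_indices)
        # a variant with MAF exactly at the threshold is common (strict <)
        exact = float(maf[0])
        rs2 = map_to_regions(gm, spans, maf_threshold=exact)
        region0 = [r for r in rs2 if 0 in r.variant_indices][0]
        assert 0 in region0.common_indices

    def test_threshold_monotonicity(self):
        gm, spans = two_gene_layout()
        thresholds = [0.01, 0.1, 0.3, 0.49]
        n_rare = [
            sum(r.rare_indices.size for r in map_to_regions(gm, spans, t))
            for t in thresholds
        ]
        assert n_rare == sorted(n_rare)

    def test_unannotated_chromosome_gets_catchall_region(self, caplog):
        gm = make_gm([100, 200], dosage_cols=[[0, 1, 2], [0, 0, 1]], chrom="7")
        _, spans = two_gene_layout()
        with caplog.at_level("INFO"):
            rs = map_to_regions(gm, spans, maf_threshold=0.01)
        assert len(rs) == 1
        r = rs.regions[0]
        assert r.kind == "intergenic" and r.name == "intergenic_7"
        assert list(r.variant_indices) == [0, 1]

    def test_overlapping_genes_duplicate_variant(self):
        text = "\n".join([
            refgene_row("NM_1", "3", 99, 300, "A"),
            refgene_row("NM_2", "3", 199, 400, "B"),
        ])
        spans = parse_annotation(io.StringIO(text))
        gm = make_gm([250], dosage_cols=[[0, 1, 2]])
        rs = map_to_regions(gm, spans, 0.01)
        hosts = [r.name for r in rs if 0 in r.variant_indices]
        assert set(hosts) == {"A", "B"}

    def test_empty_gaps_produce_no_region(self):
        gm, spans = two_gene_layout()
        keep = [1, 2, 3, 7, 8]  # only in-gene variants
        rs = map_to_regions(gm.subset_variants(keep), spans, 0.01)
        assert all(r.kind == "gene" for r in rs)

    def test_invalid_threshold_rejected(self):
        gm, spans = two_gene_layout()
        for bad in (0.0, 0.5, -0.1):
            with pytest.raises(ValueError):
                map_to_regions(gm, spans, bad)


def test_write_regions_bed(tmp_path):
    import pandas as pd

    gm, spans = two_gene_layout()
    rs = map_to_regions(gm, spans, 0.01)
    out = tmp_path / "regions.tsv"
    write_regions_bed(rs, out)
    df = pd.read_csv(out, sep="\t")
    assert set(df.columns) == {"chrom", "start", "end", "name", "kind", "n_rare", "n_common"}
    assert len(df) == len(rs)
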