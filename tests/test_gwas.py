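"""Single-marker scan, genomic control, scores, gene context, Manhattan order."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tetrags import (
    GeneAnnotation,
    annotate_gene_context,
    association_score,
    genomic_control,
    gwas_scan,
    manhattan_table,
    marker_r2,
    marker_scan,
)
from tetrags.gwas import CHI2_1DF_MEDIAN, assign_pseudo_chromosome


@pytest.fixture()
def annotation():
    genes = pd.DataFrame(
        {
            "gene_id": ["geneA", "geneB"],
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 40_000],
            "end": [20_000, 45_000],
        }
    )
    exons = pd.DataFrame(
        {
            "gene_id": ["geneA", "geneA", "geneB"],
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [10_000, 15_000, 40_000],
            "end": [12_000, 16_000, 45_000],
        }
    )
    return GeneAnnotation(genes, exons)


class TestMarkerScan:
    def test_causal_marker_attains_maximum_statistic(self, rng):
        n, p = 120, 60
        X = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        y = 2.0 * X[:, 7] + rng.normal(0, 0.5, n)
        res = marker_scan(X, y)
        assert res["chi2"].idxmax() == 7
        assert res.loc[7, "effect"] == pytest.approx(2.0, abs=0.2)

    def test_monomorphic_marker_flagged_without_p(self, rng):
        X = rng.binomial(2, 0.5, size=(50, 3)).astype(float)
        X[:, 1] = 2.0
        res = marker_scan(X, rng.normal(size=50))
        assert res.loc[1, "monomorphic"]
        assert np.isnan(res.loc[1, "p_raw"])
        assert not res.loc[0, "monomorphic"]

    def test_sample_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            marker_scan(rng.binomial(2, 0.5, (10, 4)), rng.normal(size=9))

    def test_null_p_values_uniform(self, rng):
        """Permuted phenotypes give approximately uniform raw p-values."""
        n, p = 80, 40
        X = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        y = rng.normal(size=n)
        pvals = []
        for _ in range(200):
            pvals.extend(marker_scan(X, rng.permutation(y))["p_raw"])
        stat = stats.kstest(np.asarray(pvals), "uniform")
        assert stat.pvalue > 0.01


class TestGenomicControl:
    def test_null_median_gives_unit_lambda(self):
        chi2 = np.full(100, CHI2_1DF_MEDIAN)
        lam, p_adj = genomic_control(chi2)
        assert lam == pytest.approx(1.0)
        assert p_adj == pytest.approx(np.full(100, 0.5))

    def test_scale_equivariance(self, rng):
        chi2 = stats.chi2.rvs(1, size=500, random_state=7) * 1.8
        lam1, p1 = genomic_control(chi2)
        lam2, p2 = genomic_control(2.0 * chi2)
        assert lam2 == pytest.approx(2.0 * lam1)
        np.testing.assert_allclose(p1, p2)

    def test_deflation_floored_at_one(self):
        chi2 = np.full(200, 0.1)  # heavily deflated
        lam, p_adj = genomic_control(chi2)
        assert lam == 1.0
        np.testing.assert_allclose(p_adj, stats.chi2.sf(chi2, 1))

    def test_rank_order_of_p_preserved(self, rng):
        chi2 = stats.chi2.rvs(1, size=300, random_state=8) * 3.0
        lam, p_adj = genomic_control(chi2)
        raw_p = stats.chi2.sf(chi2, 1)
        assert np.array_equal(np.argsort(raw_p), np.argsort(p_adj))

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            genomic_control(np.array([]))


class TestAssociationScore:
    def test_threshold_value(self):
        assert association_score(0.001) == pytest.approx(3.0)
        assert association_score(1.0) == pytest.approx(0.0)
        assert association_score(0.05) == pytest.approx(1.3010, abs=1e-4)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValueError):
            association_score(bad)


class TestMarkerR2:
    def test_perfect_fit(self):
        codes = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        assert marker_r2(codes, codes) == pytest.approx(1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            marker_r2(np.ones(10), np.arange(10.0))

    def test_independent_phenotype_r2_small(self):
        small = 0
        n_sim = 60
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            codes = rng.binomial(2, 0.4, 154).astype(float)
            y = rng.normal(size=154)
            small += marker_r2(codes, y) < 0.05
        assert small >= 0.9 * n_sim

    def test_tuned_correlation_recovers_expected_r2(self):
        """y = code + noise tuned to r ~ 0.45 gives r2 near 0.20."""
        r2s = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            codes = rng.binomial(2, 0.4, 154).astype(float)
            sd = codes.std() * np.sqrt(1 / 0.45**2 - 1)
            y = codes + rng.normal(0, sd, 154)
            r2s.append(marker_r2(codes, y))
        se = np.std(r2s) / np.sqrt(len(r2s))
        assert abs(np.mean(r2s) - 0.2025) < 3 * se + 0.01


class TestGeneContext:
    def test_exonic(self, annotation):
        assert annotate_gene_context("chr1", 11_000, annotation) == ("C", "geneA")

    def test_intronic(self, annotation):
        assert annotate_gene_context("chr1", 13_000, annotation) == ("I", "geneA")

    def test_flanking_boundary_2999(self, annotation):
        ctx, gid = annotate_gene_context("chr1", 22_999, annotation)
        assert (ctx, gid) == ("F", "geneA")

    def test_flanking_boundary_exactly_3000_is_intergenic(self, annotation):
        assert annotate_gene_context("chr1", 23_000, annotation) == ("0", None)

    def test_far_from_all_genes(self, annotation):
        assert annotate_gene_context("chr1", 30_000, annotation) == ("0", None)

    def test_other_chromosome_is_intergenic(self, annotation):
        assert annotate_gene_context("chr2", 11_000, annotation) == ("0", None)

    def test_nearest_gene_wins_ambiguous_flank(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "chrom": ["chr1", "chr1"],
                "start": [1_000, 6_000],
                "end": [2_000, 7_000],
            }
        )
        ann = GeneAnnotation(genes, pd.DataFrame(columns=genes.columns))
        ctx, gid = annotate_gene_context("chr1", 4_100, ann)  # 2100 vs 1900
        assert (ctx, gid) == ("F", "g2")

    def test_contexts_partition_positions(self, annotation):
        """Every position maps to exactly one of C/I/F/0."""
        for pos in range(9_000, 50_000, 500):
            ctx, gid = annotate_gene_context("chr1", pos, annotation)
            assert ctx in {"C", "I", "F", "0"}
            assert (gid is None) == (ctx == "0")

    def test_malformed_span_rejected(self):
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "start": [100], "end": [50]}
        )
        with pytest.raises(ValueError):
            GeneAnnotation(genes, pd.DataFrame(columns=genes.columns))


class TestManhattanTable:
    def _records(self):
        return pd.DataFrame(
            {
                "marker": ["m1", "m2", "m3", "m4", "m5"],
                "chromosome": ["chr2", None, "chr1", "chr8", None],
                "position": [500.0, np.nan, 900.0, 100.0, np.nan],
                "score": [1.0, 2.0, 3.5, 0.5, 4.0],
            }
        )

    def test_all_aligned_no_pseudo_chromosome(self):
        rec = self._records().dropna(subset=["chromosome"])
        table, meta = manhattan_table(rec)
        assert meta["pseudo_chromosome"] is None
        assert list(table["marker"]) == ["m3", "m1", "m4"]

    def test_unaligned_block_trails_after_chromosome_8(self):
        table, meta = manhattan_table(self._records())
        assert meta["pseudo_chromosome"] == "chr9"
        assert list(table["marker"]) == ["m3", "m1", "m4", "m2", "m5"]
        assert list(table["chromosome"][-2:]) == ["chr9", "chr9"]
        assert meta["threshold"] == 3.0

    def test_matches_oracle_sort(self, rng):
        n = 200
        chroms = rng.choice([f"chr{i}" for i in range(1, 9)] + [None], size=n)
        rec = pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(n)],
                "chromosome": chroms,
                "position": rng.integers(1, 10_000, n).astype(float),
            }
        )
        table, _ = manhattan_table(rec)
        labeled = assign_pseudo_chromosome(rec["chromosome"])
        oracle = rec.assign(chromosome=labeled, _i=np.arange(n))
        oracle["key"] = [
            (99, r["_i"]) if r["chromosome"] == "chr9" else (int(r["chromosome"][3:]), r["position"])
            for _, r in oracle.iterrows()
        ]
        oracle = oracle.sort_values("key", kind="stable")
        assert list(table["marker"]) == list(oracle["marker"])


def test_load_gff3_extracts_gene_and_exon_spans(tmp_path):
    gff = tmp_path / "ann.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1000\t5000\t.\t+\t.\tID=geneX\n"
        "chr1\tsrc\tmRNA\t1000\t5000\t.\t+\t.\tID=geneX.1;Parent=geneX\n"
        "chr1\tsrc\texon\t1000\t1500\t.\t+\t.\tID=geneX.1.e1;Parent=geneX.1\n"
        "chr1\tsrc\texon\t4000\t5000\t.\t+\t.\tID=geneX.1.e2;Parent=geneX.1\n"
    )
    from tetrags.gwas import load_gff3

    ann = load_gff3(gff)
    assert list(ann.genes["gene_id"]) == ["geneX"]
    assert len(ann.exons) == 2
    assert annotate_gene_context("chr1", 1200, ann) == ("C", "geneX")
    assert annotate_gene_context("chr1", 2000, ann) == ("I", "geneX")
    assert annotate_gene_context("chr1", 6000, ann) == ("F", "geneX")


def test_gwas_scan_end_to_end(small_dataset, rng):
    _, genos, _, phenos, truth = small_dataset
    from tetrags import collapse_tetraploid, progeny_blups, DiploidCodedMatrix

    codes = collapse_tetraploid(genos.dosage)
    m = DiploidCodedMatrix(codes, genos.sample_ids, genos.marker_ids)
    y = progeny_blups(phenos).reindex(genos.sample_ids).to_numpy()
    records, lam = gwas_scan(m, y)
    assert lam >= 1.0
    assert records["score"].dropna().min() >= 0.0
    assert set(records.columns) >= {"marker", "effect", "p_raw", "p_adj", "score", "significant"}
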