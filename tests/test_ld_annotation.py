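"""Proxy discovery, biofeature annotation, classification, loci, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from riskenhancer import (GenomeSpec, HaplotypePanel, IndexSNP, TrackSet,
                          annotate_biofeatures, classify_functional,
                          cluster_matrix, find_correlated_snps,
                          intersect_populations, merge_loci,
                          simulate_haplotype_panel, snp_biofeature_matrix)
from riskenhancer.intervals import IntervalTrack
from riskenhancer.ld_annotation import CorrelatedSNP, Variant
from riskenhancer.panel import MonomorphicVariantError, r2_from_columns


def make_panel(columns, positions, population="EUR", chrom="chr1"):
    n = len(columns)
    variants = pd.DataFrame({
        "id": [f"v{i}" for i in range(n)], "chrom": chrom,
        "pos": positions, "ref": "A", "alt": "G"})
    return HaplotypePanel(population, variants, np.column_stack(columns))


@pytest.fixture
def ld_panel():
    rng = np.random.default_rng(5)
    base = (rng.random(200) < 0.4).astype(np.int8)
    noisy = base.copy()
    noisy[:20] = 1 - noisy[:20]                      # strong but imperfect proxy
    indep = (rng.random(200) < 0.4).astype(np.int8)
    far = base.copy()                                # perfect proxy, too far away
    return make_panel([base, base.copy(), noisy, indep, far],
                      [500_000, 510_000, 520_000, 530_000, 1_500_000])


class TestFindCorrelated:
    def test_perfect_proxy_found_distant_excluded(self, ld_panel):
        index = IndexSNP(Variant("v0", "chr1", 500_000, "A", "G"), ("EUR",))
        out = find_correlated_snps({"EUR": ld_panel}, index)
        ids = {c.variant.id for c in out}
        assert "v1" in ids                   # r2 = 1 proxy inside the window
        assert "v0" in ids                   # the index itself is retained
        assert "v4" not in ids               # r2 = 1 but beyond +/- 500 kb
        v1 = next(c for c in out if c.variant.id == "v1")
        assert v1.r2["EUR"] == pytest.approx(1.0)

    def test_matches_all_pairs_scan(self, small_genome):
        panel = simulate_haplotype_panel(small_genome, 300, 30,
                                         block_len=100_000,
                                         within_block_r2=0.8, seed=6)
        vid = panel.variants.iloc[10]
        index = IndexSNP(Variant(vid.id, vid.chrom, int(vid.pos), vid.ref,
                                 vid.alt), ("POP",))
        out = {c.variant.id: c.r2["POP"]
               for c in find_correlated_snps({"POP": panel}, index,
                                             window=400_000, r2_min=0.5)}
        # oracle: brute-force scan over every variant
        expected = {}
        for row in panel.variants.itertuples():
            if abs(row.pos - vid.pos) > 200_000:
                continue
            try:
                r2 = r2_from_columns(panel.column(vid.id), panel.column(row.id))
            except MonomorphicVariantError:
                continue
            if r2 >= 0.5 or row.id == vid.id:
                expected[row.id] = r2
        assert set(out) == set(expected)
        for k in out:
            assert out[k] == pytest.approx(expected[k], abs=1e-12)

    def test_order_invariance(self, ld_panel):
        shuffled = HaplotypePanel(
            "EUR", ld_panel.variants.iloc[::-1], ld_panel.haplotypes[:, ::-1])
        index = IndexSNP(Variant("v0", "chr1", 500_000, "A", "G"), ("EUR",))
        a = find_correlated_snps({"EUR": ld_panel}, index)
        b = find_correlated_snps({"EUR": shuffled}, index)
        assert [c.variant.id for c in a] == [c.variant.id for c in b]

    def test_missing_index_errors(self, ld_panel):
        index = IndexSNP(Variant("nope", "chr1", 500_000, "A", "G"), ("EUR",))
        with pytest.raises(KeyError):
            find_correlated_snps({"EUR": ld_panel}, index)


class TestIntersectPopulations:
    def make(self, r2):
        return CorrelatedSNP("ix", Variant("p", "chr1", 100, "A", "G"), r2)

    def test_tiers(self):
        recs = [self.make({"AFR": 0.9, "EUR": 0.85}),
                self.make({"AFR": 0.9, "EUR": 0.6}),
                self.make({"AFR": 0.9, "EUR": 0.3})]
        out = intersect_populations(recs, {"AFR", "EUR"})
        tiers = [c.tier for c in out]
        assert tiers == ["shared_high", "shared"]

    def test_absent_population_errors(self):
        with pytest.raises(KeyError):
            intersect_populations([self.make({"AFR": 0.9})], {"EUR"})

    def test_empty_result_is_valid(self):
        out = intersect_populations(
            [self.make({"AFR": 0.9, "EUR": 0.1})], {"AFR", "EUR"})
        assert out == []


class TestAnnotateAndClassify:
    @pytest.fixture
    def snps(self):
        mk = lambda i, pos: CorrelatedSNP(
            "ix", Variant(f"s{i}", "chr1", pos, "A", "G"), {"EUR": 0.9})
        return [mk(0, 1001), mk(1, 1200), mk(2, 5000)]

    def test_memberships_and_half_open_edge(self, snps):
        tracks = TrackSet.from_frames({
            "H3K27Ac": pd.DataFrame({"chrom": ["chr1"], "start": [900],
                                     "end": [1200]})})
        out = annotate_biofeatures(snps, tracks)
        # pos 1001 -> 0-based 1000, inside [900, 1200)
        assert out[0].memberships == {"H3K27Ac"}
        # pos 1200 -> 0-based 1199, last covered base
        assert out[1].memberships == {"H3K27Ac"}
        assert out[2].memberships == set()
        assert out[2].functional_class == "unclassified"

    def test_membership_matches_linear_scan(self, small_genome):
        from riskenhancer import generate_biofeature_tracks
        rng = np.random.default_rng(3)
        tracks_frames = generate_biofeature_tracks(
            small_genome, ["a", "b", "c"], density=30, seed=4)
        tracks = TrackSet.from_frames(tracks_frames)
        snps = [CorrelatedSNP("ix", Variant(f"s{i}", "chr1", int(p), "A", "G"),
                              {"EUR": 1.0})
                for i, p in enumerate(rng.integers(1, 2_000_000, 200))]
        out = annotate_biofeatures(snps, tracks)
        for a in out:
            expect = {name for name, frame in tracks_frames.items()
                      if ((frame["chrom"] == a.variant.chrom)
                          & (frame["start"] <= a.variant.pos - 1)
                          & (a.variant.pos - 1 < frame["end"])).any()}
            assert a.memberships == expect

    def gene_tracks(self):
        tss = IntervalTrack("tss", pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [10_000, 50_000],
             "end": [10_001, 50_001], "name": ["g+", "g-"], "score": [0, 0],
             "strand": ["+", "-"]}))
        exon = IntervalTrack("coding_exon", pd.DataFrame(
            {"chrom": ["chr1"], "start": [30_000], "end": [30_500]}))
        utr3 = IntervalTrack("utr3", pd.DataFrame(
            {"chrom": ["chr1"], "start": [40_000], "end": [40_500]}))
        utr5 = IntervalTrack("utr5", pd.DataFrame(
            {"chrom": ["chr1"], "start": [41_000], "end": [41_500]}))
        mir = IntervalTrack("mir_target", pd.DataFrame(
            {"chrom": ["chr1"], "start": [40_100], "end": [40_200]}))
        return {"tss": tss, "coding_exon": exon, "utr3": utr3,
                "utr5": utr5, "mir_target": mir}

    def classify_at(self, pos, memberships=frozenset()):
        snp = CorrelatedSNP("ix", Variant("s", "chr1", pos, "A", "G"),
                            {"EUR": 0.9})
        from riskenhancer.ld_annotation import AnnotatedSNP
        annotated = [AnnotatedSNP(snp, frozenset(memberships))]
        return classify_functional(annotated, self.gene_tracks())[0]

    def test_promoter_windows_are_strand_aware(self):
        # + strand TSS at 0-based 10000: window [-1000, +100]
        assert self.classify_at(10_000 - 500 + 1).functional_class == "promoter"
        assert self.classify_at(10_000 + 100 + 1).functional_class == "promoter"
        assert self.classify_at(10_000 + 101 + 1).functional_class == "unclassified"
        # - strand TSS at 0-based 50000: upstream is to the right
        assert self.classify_at(50_000 + 500 + 1).functional_class == "promoter"
        assert self.classify_at(50_000 - 100 + 1).functional_class == "promoter"
        assert self.classify_at(50_000 - 101 + 1).functional_class == "unclassified"

    def test_precedence(self):
        assert self.classify_at(30_100, {"H3K27Ac"}).functional_class == "coding_exon"
        assert self.classify_at(40_150, {"H3K27Ac"}).functional_class == "mir_utr"
        # in a UTR but not a miR target site: falls through to enhancer
        assert self.classify_at(40_400, {"DNaseI"}).functional_class == "enhancer"
        assert self.classify_at(200_000, {"DNaseI"}).functional_class == "enhancer"

    def test_classes_partition(self, small_genome):
        from riskenhancer import generate_biofeature_tracks
        frames = generate_biofeature_tracks(small_genome, ["d"], 20, seed=9)
        tracks = TrackSet.from_frames(frames)
        rng = np.random.default_rng(1)
        snps = [CorrelatedSNP("ix", Variant(f"s{i}", "chr1", int(p), "A", "G"),
                              {"EUR": 1.0})
                for i, p in enumerate(rng.integers(1, 2_000_000, 300))]
        out = classify_functional(annotate_biofeatures(snps, tracks),
                                  self.gene_tracks())
        assert len(out) == 300
        counts = pd.Series([a.functional_class for a in out]).value_counts()
        assert counts.sum() == 300       # every SNP in exactly one class


class TestMergeLoci:
    def panels_for(self, columns, positions):
        return {"EUR": make_panel(columns, positions)}

    def test_chain_merges_transitively(self):
        rng = np.random.default_rng(8)
        a = (rng.random(400) < 0.5).astype(np.int8)
        b = a.copy(); b[:50] = 1 - b[:50]            # a~b: r2 ~ 0.56
        c = b.copy(); c[-50:] = 1 - c[-50:]          # b~c strong, a~c ~ 0.25
        panels = self.panels_for([a, b, c], [100_000, 200_000, 300_000])
        indexes = [IndexSNP(Variant(f"v{i}", "chr1", p, "A", "G"), ("EUR",))
                   for i, p in enumerate([100_000, 200_000, 300_000])]
        loci = merge_loci(indexes, {}, panels, merge_r2=0.5)
        assert len(loci) == 1
        assert loci[0].index_snps == ("v0", "v1", "v2")

    def test_unlinked_stay_apart(self):
        rng = np.random.default_rng(9)
        cols = [(rng.random(400) < 0.5).astype(np.int8) for _ in range(2)]
        panels = self.panels_for(cols, [100_000, 900_000])
        indexes = [IndexSNP(Variant(f"v{i}", "chr1", p, "A", "G"), ("EUR",))
                   for i, p in enumerate([100_000, 900_000])]
        loci = merge_loci(indexes, {}, panels)
        assert len(loci) == 2
        assert [l.number for l in loci] == [1, 2]

    def test_shared_proxy_merge(self):
        rng = np.random.default_rng(10)
        cols = [(rng.random(400) < 0.5).astype(np.int8) for _ in range(2)]
        panels = self.panels_for(cols, [100_000, 900_000])
        indexes = [IndexSNP(Variant(f"v{i}", "chr1", p, "A", "G"), ("EUR",))
                   for i, p in enumerate([100_000, 900_000])]
        shared = [CorrelatedSNP("v0", Variant(f"p{j}", "chr1", 500_000 + j,
                                              "A", "G"), {"EUR": 0.8})
                  for j in range(3)]
        tables = {"v0": shared, "v1": shared}
        loci = merge_loci(indexes, tables, panels, shared_min=3)
        assert len(loci) == 1


class TestClustering:
    def test_identical_rows_merge_first_disjoint_at_one(self):
        mat = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
            index=["s1", "s2", "s3"], columns=list("abcd"))
        out = cluster_matrix(mat)
        from scipy.cluster import hierarchy
        link = out["row_linkage"]
        # first merge joins the two identical rows at distance 0
        assert link[0, 2] == pytest.approx(0.0)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}
        assert link[1, 2] == pytest.approx(1.0)

    def test_linkage_matches_brute_force_average_jaccard(self):
        rng = np.random.default_rng(12)
        mat = pd.DataFrame(rng.integers(0, 2, (6, 4)),
                           index=[f"s{i}" for i in range(6)],
                           columns=list("wxyz"))
        mat.iloc[0] = [1, 0, 1, 0]  # ensure non-zero
        out = cluster_matrix(mat)

        # oracle: naive agglomeration with average linkage on jaccard
        def jaccard(u, v):
            union = np.logical_or(u, v).sum()
            return 0.0 if union == 0 else np.logical_xor(u, v).sum() / union

        rows = [np.asarray(r, dtype=bool) for _, r in
                mat.sort_index().iterrows()]
        clusters = {i: [i] for i in range(len(rows))}
        heights = []
        while len(clusters) > 1:
            best = None
            for i, j in itertools.combinations(sorted(clusters), 2):
                d = np.mean([jaccard(rows[a], rows[b])
                             for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
            d, i, j = best
            heights.append(d)
            new_key = max(clusters) + 1
            clusters[new_key] = clusters.pop(i) + clusters.pop(j)
        np.testing.assert_allclose(sorted(out["row_linkage"][:, 2]),
                                   sorted(heights), atol=1e-12)

    def test_all_zero_rejected(self):
        mat = pd.DataFrame(np.zeros((3, 3), dtype=int))
        with pytest.raises(ValueError):
            cluster_matrix(mat)

    def test_matrix_from_annotations(self):
        from riskenhancer.ld_annotation import AnnotatedSNP
        snp = lambda i, m: AnnotatedSNP(
            CorrelatedSNP("ix", Variant(f"s{i}", "chr1", 100 + i, "A", "G"),
                          {"EUR": 1.0}), frozenset(m))
        mat = snp_biofeature_matrix([snp(0, {"a", "b"}), snp(1, {"b"})])
        assert mat.loc["s0", "a"] == 1 and mat.loc["s1", "a"] == 0
        assert list(mat.columns) == ["a", "b"]
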