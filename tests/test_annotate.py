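"""Genomic-context assignment, set comparisons, densities and QTL overlap."""

import numpy as np
import pandas as pd
import pytest

import oracles
from methylstage import annotate
from methylstage.methio import AnnotationBundle


def genes_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])


def track_df(rows, label_col):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand", label_col])


class TestFlanks:
    def test_promoter_plus_strand(self):
        p = annotate.derive_promoters(genes_df([("chr_1", 5000, 7000, "+", "g1")]))
        assert (p.iloc[0].start, p.iloc[0].end) == (3000, 5000)

    def test_promoter_minus_strand(self):
        p = annotate.derive_promoters(genes_df([("chr_1", 5000, 7000, "-", "g1")]))
        assert (p.iloc[0].start, p.iloc[0].end) == (7000, 9000)

    def test_promoter_clipped_at_zero(self):
        p = annotate.derive_promoters(genes_df([("chr_1", 500, 2000, "+", "g1")]))
        assert (p.iloc[0].start, p.iloc[0].end) == (0, 500)

    def test_downstream_mirrors(self):
        d = annotate.derive_downstream(genes_df([("chr_1", 5000, 7000, "+", "g1")]))
        assert (d.iloc[0].start, d.iloc[0].end) == (7000, 9000)
        d = annotate.derive_downstream(genes_df([("chr_1", 5000, 7000, "-", "g1")]))
        assert (d.iloc[0].start, d.iloc[0].end) == (3000, 5000)

    def test_downstream_at_chromosome_end_dropped(self):
        d = annotate.derive_downstream(
            genes_df([("chr_1", 5000, 7000, "+", "g1")]), {"chr_1": 7000}
        )
        assert len(d) == 0

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            annotate.derive_promoters(genes_df([("chr_1", 10, 20, ".", "g1")]))

    def test_intron_inference_complements_exons(self):
        genes = genes_df([("chr_1", 100, 400, "+", "g1")])
        exons = genes_df([("chr_1", 100, 150, "+", "g1"), ("chr_1", 300, 400, "+", "g1")])
        introns = annotate.infer_introns(genes, exons)
        assert [(r.start, r.end) for r in introns.itertuples()] == [(150, 300)]


def feature_row(fid, chrom, start, end):
    return {"feature_id": fid, "chrom": chrom, "start": start, "end": end}


class TestAssignContext:
    @pytest.fixture()
    def bundle(self):
        genes = genes_df([("chr_1", 5000, 7000, "+", "g1")])
        te = track_df([("chr_1", 2500, 3500, "te1", "+", "LTR/Copia")], "te_class")
        qtl = track_df([], "trait")
        return AnnotationBundle(genes=genes, exons=genes.iloc[0:0], te=te, qtl=qtl,
                                chrom_lengths={"chr_1": 100_000})

    def test_te_beats_promoter(self, bundle):
        # promoter of g1 is [3000, 5000); TE covers 2500-3500
        feats = pd.DataFrame([feature_row("f1", "chr_1", 3200, 3201)])
        got = annotate.assign_context(feats, bundle).iloc[0]
        assert got.primary_context == "TE"
        assert got.gene_relative_context == "promoter"
        assert got.te_overlap and got.te_class == "LTR/Copia"

    def test_nothing_overlapping_is_intergenic(self, bundle):
        feats = pd.DataFrame([feature_row("f1", "chr_1", 50_000, 50_001)])
        got = annotate.assign_context(feats, bundle).iloc[0]
        assert got.primary_context == "intergenic" and not got.te_overlap

    def test_unknown_chromosome_rejected(self, bundle):
        feats = pd.DataFrame([feature_row("f1", "chr_9", 10, 11)])
        with pytest.raises(ValueError, match="chr_9"):
            annotate.assign_context(feats, bundle)

    def test_largest_te_overlap_wins(self):
        te = track_df(
            [
                ("chr_1", 100, 120, "a", "+", "LTR/Ty3"),
                ("chr_1", 110, 200, "b", "+", "LTR/Copia"),
            ],
            "te_class",
        )
        bundle = AnnotationBundle(
            genes=genes_df([]), exons=genes_df([]), te=te,
            qtl=track_df([], "trait"), chrom_lengths={"chr_1": 1000},
        )
        feats = pd.DataFrame([feature_row("f1", "chr_1", 105, 150)])
        assert annotate.assign_context(feats, bundle).iloc[0].te_class == "LTR/Copia"

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(61)
        L = 10_000
        genes = genes_df(
            [
                ("chr_1", s, s + int(rng.integers(100, 800)), rng.choice(["+", "-"]), f"g{i}")
                for i, s in enumerate(sorted(rng.choice(np.arange(2500, L - 3500), 5, replace=False)))
            ]
        )
        te = track_df(
            [
                ("chr_1", s, s + int(rng.integers(50, 600)), f"t{i}", "+", "LTR/Ty3")
                for i, s in enumerate(rng.integers(0, L - 700, size=8))
            ],
            "te_class",
        )
        bundle = AnnotationBundle(
            genes=genes, exons=genes.iloc[0:0], te=te,
            qtl=track_df([], "trait"), chrom_lengths={"chr_1": L},
        )
        feats = pd.DataFrame(
            [feature_row(f"f{i}", "chr_1", int(s), int(s) + int(rng.integers(1, 120)))
             for i, s in enumerate(rng.integers(0, L - 200, size=300))]
        )
        got = annotate.assign_context(feats, bundle)
        promoters = annotate.derive_promoters(genes, bundle.chrom_lengths)
        downstream = annotate.derive_downstream(genes, bundle.chrom_lengths)
        tracks = {
            "TE": [(r.chrom, r.start, r.end) for r in te.itertuples()],
            "promoter": [(r.chrom, r.start, r.end) for r in promoters.itertuples()],
            "gene": [(r.chrom, r.start, r.end) for r in genes.itertuples()],
            "downstream": [(r.chrom, r.start, r.end) for r in downstream.itertuples()],
        }
        for f, row in zip(feats.itertuples(index=False), got.itertuples(index=False)):
            expected = oracles.brute_assign_context(
                (f.chrom, f.start, f.end), tracks, annotate.DEFAULT_PRECEDENCE
            )
            assert row.primary_context == expected
        # partition property: every feature gets exactly one primary context
        assert got["primary_context"].value_counts().sum() == len(feats)


class TestCrosstabAndSets:
    def test_crosstab_counts(self):
        assignments = pd.DataFrame(
            {
                "feature_id": ["a", "b", "c"],
                "primary_context": ["TE"] * 3,
                "te_overlap": True,
                "te_class": ["LTR/Copia", "LTR/Copia", "LTR/Ty3"],
                "gene_relative_context": ["promoter"] * 3,
            }
        )
        tab = annotate.te_context_crosstab(assignments)
        assert tab.loc["LTR/Copia", "promoter"] == 2
        assert tab.loc["LTR/Ty3", "promoter"] == 1
        assert tab.to_numpy().sum() == 3

    def test_crosstab_empty(self):
        empty = pd.DataFrame(columns=["feature_id", "te_overlap", "te_class", "gene_relative_context"])
        empty["te_overlap"] = empty["te_overlap"].astype(bool)
        assert annotate.te_context_crosstab(empty).empty

    def test_marginals_consistent(self, small_dataset, small_annotation, small_matrix):
        coords = small_matrix.coords
        assignments = annotate.assign_context(coords, small_annotation)
        tab = annotate.te_context_crosstab(assignments)
        assert tab.to_numpy().sum() == int(assignments["te_overlap"].sum())
        sub = assignments[assignments["te_overlap"]]
        for cls, n in tab.sum(axis=1).items():
            assert n == (sub["te_class"] == cls).sum()

    def make_set(self, ids, kind="cytosine", chrom="chr_1", start=0):
        return pd.DataFrame(
            {
                "feature_id": list(ids),
                "chrom": chrom,
                "start": np.arange(start, start + len(ids)) * 10,
                "end": np.arange(start, start + len(ids)) * 10 + (1 if kind == "cytosine" else 8),
                "kind": kind,
            }
        )

    def test_pairwise_and_exclusive_counts(self):
        sets = {"A": self.make_set(["a", "b"]), "B": self.make_set(["b", "c"])}
        got = annotate.compare_feature_sets(sets)
        assert got["pairwise_shared"][("A", "B")] == 1
        assert got["exclusive"][frozenset({"A"})] == 1
        assert got["exclusive"][frozenset({"B"})] == 1
        assert got["exclusive"][frozenset({"A", "B"})] == 1

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            annotate.compare_feature_sets(
                {"A": self.make_set(["a", "a"]), "B": self.make_set(["b"])}
            )

    def test_cytosine_in_region_colocalization(self):
        cyt = pd.DataFrame(
            [{"feature_id": "chr_1_151", "chrom": "chr_1", "start": 150, "end": 151, "kind": "cytosine"}]
        )
        reg = pd.DataFrame(
            [{"feature_id": "chr_1_101_200", "chrom": "chr_1", "start": 100, "end": 200, "kind": "region"}]
        )
        got = annotate.compare_feature_sets({"cyt": cyt, "reg": reg})
        assert got["cytosines_in_regions"][("cyt", "reg")] == 1

    def test_random_sets_match_set_algebra_oracle(self):
        rng = np.random.default_rng(67)
        for _ in range(100):
            universe = [f"f{i}" for i in range(30)]
            sets = {
                name: self.make_set(
                    sorted(rng.choice(universe, size=rng.integers(1, 20), replace=False))
                )
                for name in ("A", "B", "C")
            }
            got = annotate.compare_feature_sets(sets)
            ids = {n: set(df["feature_id"]) for n, df in sets.items()}
            assert got["pairwise_shared"][("A", "B")] == len(ids["A"] & ids["B"])
            assert got["pairwise_shared"][("B", "C")] == len(ids["B"] & ids["C"])
            assert sum(got["exclusive"].values()) == len(ids["A"] | ids["B"] | ids["C"])


class TestDensityAndQTL:
    def test_density_window_assignment(self):
        feats = pd.DataFrame(
            [
                {"feature_id": "a", "chrom": "chr_1", "start": 500_000, "end": 500_001, "kind": "cytosine"},
                {"feature_id": "b", "chrom": "chr_1", "start": 1_500_000, "end": 1_500_001, "kind": "cytosine"},
            ]
        )
        dens = annotate.density_windows(feats, {"chr_1": 2_000_000})
        assert dens["n_cytosine"].tolist() == [1, 1]

    def test_empty_track_all_zero(self):
        feats = pd.DataFrame(columns=["feature_id", "chrom", "start", "end", "kind"])
        dens = annotate.density_windows(feats, {"chr_1": 2_500_000})
        assert len(dens) == 3

    def test_feature_beyond_end_rejected(self):
        feats = pd.DataFrame(
            [{"feature_id": "a", "chrom": "chr_1", "start": 99, "end": 100, "kind": "cytosine"}]
        )
        with pytest.raises(ValueError, match="beyond"):
            annotate.density_windows(feats, {"chr_1": 50})

    def test_matches_floor_division_oracle(self):
        rng = np.random.default_rng(71)
        feats = pd.DataFrame(
            {
                "feature_id": [f"f{i}" for i in range(200)],
                "chrom": rng.choice(["chr_1", "chr_2"], 200),
                "start": rng.integers(0, 900_000, 200),
                "kind": rng.choice(["cytosine", "region"], 200),
            }
        )
        feats["end"] = feats["start"] + 1
        dens = annotate.density_windows(feats, {"chr_1": 1_000_000, "chr_2": 1_000_000}, window=100_000)
        expected = oracles.brute_density(
            list(zip(feats["chrom"], feats["start"], feats["kind"])), None, 100_000
        )
        for row in dens.itertuples(index=False):
            for kind in ("cytosine", "region"):
                assert getattr(row, f"n_{kind}") == expected.get((row.chrom, row.window, kind), 0)

    def test_qtl_overlap_rules(self):
        qtl = track_df(
            [("chr_4", 25_000_000, 26_000_000, "q1", "+", "CR")], "trait"
        )
        feats = pd.DataFrame(
            [
                {"feature_id": "hit", "chrom": "chr_4", "start": 25_100_000, "end": 25_200_000, "kind": "region"},
                {"feature_id": "off", "chrom": "chr_1", "start": 25_100_000, "end": 25_200_000, "kind": "region"},
            ]
        )
        got = annotate.qtl_colocalization(feats, qtl)
        cr = got[got["trait"] == "CR"].iloc[0]
        assert cr.n_features == 1 and cr.feature_ids == ["hit"]

    def test_qtl_matches_bruteforce(self, small_annotation, small_matrix):
        feats = small_matrix.coords
        got = annotate.qtl_colocalization(feats, small_annotation.qtl)
        for row in got.itertuples(index=False):
            sub = small_annotation.qtl[small_annotation.qtl["trait"] == row.trait]
            expected = set()
            for f in feats.itertuples(index=False):
                for q in sub.itertuples(index=False):
                    if f.chrom == q.chrom and oracles.brute_overlap(f.start, f.end, q.start, q.end):
                        expected.add(f.feature_id)
            assert set(row.feature_ids) == expected


class TestTEFractionAndBed:
    def test_half_genome(self):
        te = track_df([("chr_1", 0, 50_000, "t", "+", "LTR/Ty3")], "te_class")
        assert annotate.te_genome_fraction(te, {"chr_1": 100_000}) == 0.5

    def test_duplicates_counted_once(self):
        te = track_df(
            [("chr_1", 0, 50_000, "t", "+", "LTR/Ty3"), ("chr_1", 0, 50_000, "t2", "+", "LTR/Copia")],
            "te_class",
        )
        assert annotate.te_genome_fraction(te, {"chr_1": 100_000}) == 0.5

    def test_matches_union_oracle(self):
        rng = np.random.default_rng(73)
        for _ in range(100):
            starts = rng.integers(0, 900, size=12)
            te = track_df(
                [("chr_1", int(s), int(s) + int(rng.integers(1, 150)), f"t{i}", "+", "X")
                 for i, s in enumerate(starts)],
                "te_class",
            )
            got = annotate.te_genome_fraction(te, {"chr_1": 1_200})
            intervals = [(r.chrom, r.start, r.end) for r in te.itertuples()]
            assert got == pytest.approx(oracles.brute_union_fraction(intervals, 1_200))

    def test_bed_round_trip_and_printed_ids(self, tmp_path):
        feats = pd.DataFrame(
            [
                {"feature_id": "chr_4_31092165", "chrom": "chr_4", "start": 31092164, "end": 31092165, "kind": "cytosine"},
                {"feature_id": "chr_3_9331371_9331488", "chrom": "chr_3", "start": 9331370, "end": 9331488, "kind": "region"},
            ]
        )
        p = tmp_path / "f.bed"
        annotate.write_bed(feats, p)
        lines = p.read_text().strip().split("\n")
        assert lines[0].split("\t")[:4] == ["chr_3", "9331370", "9331488", "chr_3_9331371_9331488"]
        assert lines[1].split("\t")[:4] == ["chr_4", "31092164", "31092165", "chr_4_31092165"]
        back = annotate.read_feature_bed(p)
        assert set(back["feature_id"]) == set(feats["feature_id"])
        assert list(back["kind"]) == ["region", "cytosine"]
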