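"""Feature-extraction unit and property tests.

Hand-enumerated toy cases for every fragment builder, plus the
brute-force interval-overlap oracle for conserved-element assignment.
"""

import numpy as np
import pandas as pd
import pytest

from qtgrank.features import (
    AnnotatedVariant,
    ConservedElement,
    EffectRule,
    FeatureTable,
    GeneModel,
    aggregate_go_features,
    attach_paralog_counts,
    compute_percent_absence,
    count_cns_polymorphisms,
    encode_variant_features,
    merge_feature_fragments,
)

SCHEMA = {
    "is_nonsyn_deleterious": EffectRule(
        frozenset({"missense_variant"}), require_deleterious=True
    ),
    "is_synonymous": EffectRule(frozenset({"synonymous_variant"})),
    "is_frameshift": EffectRule(frozenset({"frameshift_variant"})),
}


def gene(gid, start, end, chrom="chr1"):
    return GeneModel(gid, chrom, start, end)


class TestVariantFlags:
    def test_gene_without_variants_has_all_zero_flags(self):
        table = encode_variant_features([], [gene("g1", 0, 100)], SCHEMA)
        assert table.values.loc["g1"].sum() == 0

    def test_deleterious_missense_sets_flag(self):
        v = AnnotatedVariant(
            "chr1", 10, "SNP", "g1", frozenset({"missense_variant"}), True
        )
        table = encode_variant_features([v], [gene("g1", 0, 100)], SCHEMA)
        assert table.values.at["g1", "is_nonsyn_deleterious"] == 1

    def test_missense_without_deleterious_call_cannot_set_flag(self):
        for flag in (False, None):
            v = AnnotatedVariant(
                "chr1", 10, "SNP", "g1", frozenset({"missense_variant"}), flag
            )
            table = encode_variant_features([v], [gene("g1", 0, 100)], SCHEMA)
            assert table.values.at["g1", "is_nonsyn_deleterious"] == 0

    def test_hand_enumerated_toy_matrix(self):
        # 5 variants over 3 genes: 2 synonymous (g1), 1 deleterious
        # missense (g2), 1 frameshift indel (g3), 1 intergenic
        genes = [gene("g1", 0, 100), gene("g2", 200, 300), gene("g3", 400, 500)]
        variants = [
            AnnotatedVariant("chr1", 5, "SNP", "g1", frozenset({"synonymous_variant"})),
            AnnotatedVariant("chr1", 8, "SNP", "g1", frozenset({"synonymous_variant"})),
            AnnotatedVariant(
                "chr1", 250, "SNP", "g2", frozenset({"missense_variant"}), True
            ),
            AnnotatedVariant("chr1", 450, "indel", "g3", frozenset({"frameshift_variant"})),
            AnnotatedVariant("chr1", 900, "SNP", None, frozenset()),
        ]
        table = encode_variant_features(variants, genes, SCHEMA)
        expected = pd.DataFrame(
            [[0, 1, 0], [1, 0, 0], [0, 0, 1]],
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
            columns=["is_nonsyn_deleterious", "is_synonymous", "is_frameshift"],
        )
        pd.testing.assert_frame_equal(table.values, expected)

    def test_unknown_gene_is_an_error_naming_the_id(self):
        v = AnnotatedVariant("chr1", 10, "SNP", "ghost", frozenset({"synonymous_variant"}))
        with pytest.raises(KeyError, match="ghost"):
            encode_variant_features([v], [gene("g1", 0, 100)], SCHEMA)

    def test_uncovered_effect_term_warns_and_skips(self):
        v = AnnotatedVariant("chr1", 10, "SNP", "g1", frozenset({"exotic_term"}))
        with pytest.warns(UserWarning, match="not covered"):
            table = encode_variant_features([v], [gene("g1", 0, 100)], SCHEMA)
        assert table.values.loc["g1"].sum() == 0


class TestConservedElementCounts:
    def test_no_element_in_window_gives_zero(self):
        genes = [gene("g1", 5000, 8000)]
        elements = [ConservedElement("e1", "chr1", 100, 200, "CE")]
        variants = [AnnotatedVariant("chr1", 150, "SNP")]
        table = count_cns_polymorphisms(variants, elements, genes)
        assert table.values.loc["g1"].sum() == 0

    def test_upstream_element_counts_by_class_and_kind(self):
        genes = [gene("g1", 5000, 8000)]
        elements = [ConservedElement("e1", "chr1", 4500, 4800, "CE")]
        variants = [
            AnnotatedVariant("chr1", 4600, "SNP"),
            AnnotatedVariant("chr1", 4700, "SNP"),
            AnnotatedVariant("chr1", 4750, "indel"),
        ]
        table = count_cns_polymorphisms(variants, elements, genes)
        row = table.values.loc["g1"]
        assert row["CE_snp"] == 2 and row["CE_indel"] == 1
        assert row["TFBS_snp"] == 0 and row["TFBS_indel"] == 0

    def test_element_beyond_window_excluded(self):
        # CE ends 1500 bp upstream of the gene start: outside the 1 kb flank
        genes = [gene("g1", 5000, 8000)]
        elements = [ConservedElement("e1", "chr1", 3000, 3500, "CE")]
        variants = [AnnotatedVariant("chr1", 3200, "SNP")]
        table = count_cns_polymorphisms(variants, elements, genes)
        assert table.values.loc["g1"].sum() == 0

    def test_shared_element_counts_for_both_genes(self):
        genes = [gene("ga", 1000, 2000), gene("gb", 2500, 3500)]
        elements = [ConservedElement("e1", "chr1", 2100, 2400, "CE")]
        variants = [AnnotatedVariant("chr1", 2200, "SNP")]
        table = count_cns_polymorphisms(variants, elements, genes)
        assert table.values.at["ga", "CE_snp"] == 1
        assert table.values.at["gb", "CE_snp"] == 1

    def test_overlapping_same_kind_elements_count_variant_once_per_gene(self):
        genes = [gene("g1", 1000, 2000)]
        elements = [
            ConservedElement("e1", "chr1", 500, 900, "CE"),
            ConservedElement("e2", "chr1", 600, 950, "CE"),
        ]
        variants = [AnnotatedVariant("chr1", 700, "SNP")]
        table = count_cns_polymorphisms(variants, elements, genes)
        assert table.values.at["g1", "CE_snp"] == 1

    def test_invalid_element_rejected(self):
        with pytest.raises(ValueError, match="start"):
            ConservedElement("bad", "chr1", 500, 500, "CE")

    def test_matches_brute_force_overlap_scan(self):
        """Oracle equivalence: tree-based assignment vs all-pairs scan."""
        rng = np.random.default_rng(99)
        n_genes, n_elem, n_var, window = 60, 120, 300, 1000
        genes = []
        for i in range(n_genes):
            s = int(rng.integers(0, 200_000))
            genes.append(gene(f"g{i}", s, s + int(rng.integers(500, 5000))))
        elements = []
        for j in range(n_elem):
            s = int(rng.integers(0, 205_000))
            kind = "CE" if rng.random() < 0.5 else "TFBS"
            elements.append(
                ConservedElement(f"e{j}", "chr1", s, s + int(rng.integers(50, 800)), kind)
            )
        variants = [
            AnnotatedVariant(
                "chr1", int(rng.integers(0, 210_000)),
                "SNP" if rng.random() < 0.6 else "indel",
            )
            for _ in range(n_var)
        ]
        table = count_cns_polymorphisms(variants, elements, genes)

        # brute force: all pairs, each variant once per (gene, feature)
        seen = set()
        for g in genes:
            lo, hi = g.start - window, g.end + window
            for e in elements:
                if e.start < hi and e.end > lo:  # interval overlap
                    for i, v in enumerate(variants):
                        if e.start <= v.pos < e.end:
                            suffix = "snp" if v.variant_class == "SNP" else "indel"
                            seen.add((g.gene_id, f"{e.element_kind}_{suffix}", i))
        brute = pd.DataFrame(0, index=table.values.index, columns=table.values.columns)
        for gid, fname, _ in seen:
            brute.at[gid, fname] += 1
        pd.testing.assert_frame_equal(table.values, brute)


class TestPercentAbsence:
    def test_all_present_is_zero(self):
        pav = pd.DataFrame([[0, 0, 0]], index=["g1"], columns=["a", "b", "c"])
        assert compute_percent_absence(pav).values.at["g1", "percent_absence"] == 0.0

    def test_20_of_80_accessions_absent_is_quarter(self):
        row = [1] * 20 + [0] * 60
        pav = pd.DataFrame([row], index=["g1"], columns=[f"acc{i}" for i in range(80)])
        assert compute_percent_absence(pav).values.at["g1", "percent_absence"] == 0.25

    def test_all_absent_is_one(self):
        pav = pd.DataFrame([[1, 1]], index=["g1"], columns=["a", "b"])
        assert compute_percent_absence(pav).values.at["g1", "percent_absence"] == 1.0

    def test_duplicating_every_accession_column_is_invariant(self):
        rng = np.random.default_rng(1)
        pav = pd.DataFrame(
            rng.integers(0, 2, size=(10, 7)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"a{j}" for j in range(7)],
        )
        doubled = pd.concat(
            [pav, pav.rename(columns=lambda c: c + "_dup")], axis=1
        )
        pd.testing.assert_frame_equal(
            compute_percent_absence(pav).values, compute_percent_absence(doubled).values
        )

    def test_non_binary_cell_is_a_parse_error_with_coordinates(self):
        pav = pd.DataFrame([[0, 2]], index=["g1"], columns=["a", "b"])
        with pytest.raises(ValueError, match="g1.*'b'"):
            compute_percent_absence(pav)


class TestGoAggregation:
    SLIM_SCHEMA = {"GO:S1": "is_transporter", "GO:S2": "is_transcription_factor"}
    SLIM_MAP = {
        "GO:C1": {"GO:S1"},
        "GO:C2": {"GO:S2"},
        "GO:C3": {"GO:S1", "GO:S2"},
    }

    def test_unannotated_gene_gets_zero_flags(self):
        table = aggregate_go_features({"g1": set()}, self.SLIM_MAP, self.SLIM_SCHEMA)
        assert table.values.loc["g1"].sum() == 0

    def test_term_with_transporter_ancestor_sets_flag(self):
        table = aggregate_go_features({"g1": {"GO:C1"}}, self.SLIM_MAP, self.SLIM_SCHEMA)
        assert table.values.at["g1", "is_transporter"] == 1
        assert table.values.at["g1", "is_transcription_factor"] == 0

    def test_four_gene_toy_closure(self):
        annotations = {
            "g1": {"GO:C1"},
            "g2": {"GO:C2"},
            "g3": {"GO:C3"},
            "g4": {"GO:S1"},  # direct slim annotation
        }
        table = aggregate_go_features(annotations, self.SLIM_MAP, self.SLIM_SCHEMA)
        expected = pd.DataFrame(
            [[1, 0], [0, 1], [1, 1], [1, 0]],
            index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
            columns=["is_transporter", "is_transcription_factor"],
        )
        pd.testing.assert_frame_equal(table.values, expected)

    def test_unmapped_terms_reported_in_diagnostics(self):
        diag = {}
        aggregate_go_features({"g1": {"GO:NOWHERE"}}, self.SLIM_MAP, self.SLIM_SCHEMA, diag)
        assert diag["unmapped_terms"] == ["GO:NOWHERE"]


class TestParalogCounts:
    def test_singleton_gene_copy_number_one(self):
        table = attach_paralog_counts({}, {}, "sp", ["g1"])
        assert table.values.at["g1", "paralog_copy_number"] == 1

    def test_three_member_group_gives_each_three(self):
        g2g = {"g1": "OG1", "g2": "OG1", "g3": "OG1"}
        counts = {"OG1": {"sp": 3}}
        table = attach_paralog_counts(g2g, counts, "sp", ["g1", "g2", "g3"])
        assert (table.values["paralog_copy_number"] == 3).all()

    def test_count_is_own_species_count(self):
        g2g = {"g1": "OG1"}
        counts = {"OG1": {"sp": 2, "other": 5}}
        table = attach_paralog_counts(g2g, counts, "sp", ["g1"])
        assert table.values.at["g1", "paralog_copy_number"] == 2


class TestMergeFragments:
    def _binary_frag(self, data: dict) -> FeatureTable:
        df = pd.DataFrame(data).T
        df.index.name = "gene_id"
        return FeatureTable(df, {c: "binary" for c in df.columns})

    def test_identity_merge(self):
        frag = self._binary_frag({"g1": {"f1": 1}, "g2": {"f1": 0}})
        merged = merge_feature_fragments([frag], ["g1", "g2"])
        pd.testing.assert_frame_equal(merged.values, frag.values, check_dtype=False)

    def test_missing_gene_imputed_zero_and_paralog_one(self):
        frag = self._binary_frag({"g1": {"is_synonymous": 1}})
        paralog = FeatureTable(
            pd.DataFrame({"paralog_copy_number": [4]}, index=pd.Index(["g1"], name="gene_id")),
            {"paralog_copy_number": "count"},
        )
        merged = merge_feature_fragments([frag, paralog], ["g1", "g2"])
        assert merged.values.at["g2", "is_synonymous"] == 0
        assert merged.values.at["g2", "paralog_copy_number"] == 1

    def test_three_overlapping_fragments_assemble_by_hand(self):
        fa = self._binary_frag({"g1": {"fa": 1}, "g2": {"fa": 0}})
        fb = self._binary_frag({"g2": {"fb": 1}, "g3": {"fb": 1}})
        fc = self._binary_frag({"g1": {"fc": 0}, "g3": {"fc": 1}})
        merged = merge_feature_fragments([fa, fb, fc], ["g1", "g2", "g3"])
        expected = pd.DataFrame(
            [[1, 0, 0], [0, 1, 0], [0, 1, 1]],
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
            columns=["fa", "fb", "fc"],
        )
        pd.testing.assert_frame_equal(merged.values, expected, check_dtype=False)

    def test_duplicate_feature_name_is_error(self):
        fa = self._binary_frag({"g1": {"f": 1}})
        with pytest.raises(ValueError, match="duplicate feature"):
            merge_feature_fragments([fa, fa], ["g1"])


class TestFeatureTableInvariants:
    def test_binary_range_enforced(self):
        df = pd.DataFrame({"f": [2]}, index=["g1"])
        with pytest.raises(ValueError, match="binary"):
            FeatureTable(df, {"f": "binary"})

    def test_fraction_range_enforced(self):
        df = pd.DataFrame({"f": [1.5]}, index=["g1"])
        with pytest.raises(ValueError, match="fraction"):
            FeatureTable(df, {"f": "fraction"})

    def test_negative_count_rejected(self):
        df = pd.DataFrame({"f": [-1]}, index=["g1"])
        with pytest.raises(ValueError, match="count"):
            FeatureTable(df, {"f": "count"})

    def test_input_order_invariance(self):
        """Shuffling variant, element and gene input order never changes values."""
        rng = np.random.default_rng(3)
        genes = [gene(f"g{i}", i * 3000, i * 3000 + 1000) for i in range(10)]
        elements = [
            ConservedElement(f"e{i}", "chr1", i * 3000 + 1200, i * 3000 + 1500, "CE")
            for i in range(10)
        ]
        variants = [
            AnnotatedVariant("chr1", int(rng.integers(0, 31_000)), "SNP")
            for _ in range(60)
        ]
        base = count_cns_polymorphisms(variants, elements, genes)
        for _ in range(3):
            sv, se, sg = variants[:], elements[:], genes[:]
            rng.shuffle(sv), rng.shuffle(se), rng.shuffle(sg)
            shuffled = count_cns_polymorphisms(sv, se, sg)
            pd.testing.assert_frame_equal(
                base.values.sort_index(), shuffled.values.sort_index()
            )
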