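"""Tag extraction, cleaning, mapping, TPM normalization and copy spectra."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dgetag.simulate import (
    ReferenceCatalog,
    generate_reference,
    plan_truth,
    simulate_libraries,
)
from dgetag.tags import (
    CleanLibrary,
    TagLibrary,
    build_count_table,
    clean_tags,
    copy_number_distribution,
    extract_reference_tags,
    map_tags,
    normalize_tpm,
)


def catalog(*records):
    return ReferenceCatalog(records=tuple(records))


class TestExtractReferenceTags:
    def test_hand_extraction(self):
        cat = catalog(("g1", "AAACATGAAAAAAAAAAAAAAAAATTT"))
        index = extract_reference_tags(cat, anchor="CATG", body_length=17)
        assert set(index.tag_to_genes) == {"CATG" + "A" * 17}
        assert index.signature_tags["g1"] == "CATG" + "A" * 17

    def test_gene_without_anchor_contributes_nothing(self):
        cat = catalog(("g1", "AAATTTCCCGGGAAATTTCCCGGG"))
        index = extract_reference_tags(cat)
        assert len(index) == 0 and "g1" not in index.signature_tags

    def test_shared_tag_flagged_ambiguous(self):
        site = "CATG" + "ACGTACGTACGTACGTA"
        cat = catalog(("g1", "TTT" + site + "GGG"), ("g2", "AAA" + site + "CCC"))
        index = extract_reference_tags(cat)
        assert index.is_ambiguous(site)
        assert index.tag_to_genes[site] == ("g1", "g2")

    def test_signature_is_three_prime_most(self):
        first = "CATG" + "A" * 17
        second = "CATG" + "C" * 17
        cat = catalog(("g1", first + "TT" + second))
        index = extract_reference_tags(cat)
        assert index.signature_tags["g1"] == second


class TestCleanTags:
    def test_worked_example(self):
        # five distinct raw tags; rules remove the N-containing, the
        # adaptor-prefixed and the singleton tag, leaving 5 copies / 2 tags
        raw = TagLibrary(
            condition="SYA",
            tags={
                "CATG" + "A" * 17: 3,
                "CATG" + "C" * 17: 1,
                "CATG" + "N" + "A" * 16: 5,
                "GATCGGAAG" + "T" * 12: 4,
                "CATG" + "G" * 17: 2,
            },
        )
        clean = clean_tags(raw, adaptor="GATCGGAAG", min_copies=2)
        assert clean.tags == {"CATG" + "A" * 17: 3, "CATG" + "G" * 17: 2}
        assert clean.total_clean == 5 and clean.distinct_clean == 2
        assert clean.filter_log["non_acgt"] == {"distinct": 1, "copies": 5}
        assert clean.filter_log["adaptor_prefix"] == {"distinct": 1, "copies": 4}
        assert clean.filter_log["low_copy"] == {"distinct": 1, "copies": 1}

    def test_empty_library(self):
        clean = clean_tags(TagLibrary("SYA", {}), adaptor="GATC", min_copies=2)
        assert clean.total_clean == 0
        assert all(v == {"distinct": 0, "copies": 0}
                   for v in clean.filter_log.values())

    def test_all_valid_passes_through(self):
        tags = {"CATG" + "A" * 17: 5, "CATG" + "C" * 17: 2}
        clean = clean_tags(TagLibrary("SR", tags), adaptor="GATCGGAAG")
        assert clean.tags == tags

    def test_idempotent(self):
        raw = TagLibrary("NR", {"CATG" + "A" * 17: 9, "CATG" + "T" * 17: 2,
                                "CATG" + "C" * 17: 1})
        once = clean_tags(raw, adaptor="GATCGGAAG", min_copies=2)
        twice = clean_tags(TagLibrary("NR", once.tags),
                           adaptor="GATCGGAAG", min_copies=2)
        assert once.tags == twice.tags

    def test_rejects_nonpositive_copies(self):
        with pytest.raises(ValueError):
            TagLibrary("SYA", {"CATG" + "A" * 17: 0})


def _toy_index():
    base = "CATG" + "ACGTACGTACGTACGTA"
    other = "CATG" + "TTTTTTTTTTTTTTTTT"
    shared = "CATG" + "GGGGGGGGGGGGGGGGG"
    cat = catalog(
        ("g1", "AA" + base),
        ("g2", "AA" + other + "CC" + shared),
        ("g3", "TT" + shared),
    )
    return base, other, shared, extract_reference_tags(cat)


class TestMapTags:
    def test_exact_unique_mapping(self):
        base, other, shared, index = _toy_index()
        clean = CleanLibrary("SYA", {base: 7}, {})
        counts, stats = map_tags(clean, index)
        assert counts["g1"] == 7
        assert stats["mapped_unambiguous"] == 7 and stats["mapped_fraction"] == 1.0

    def test_ambiguous_tag_counts_to_no_gene(self):
        base, other, shared, index = _toy_index()
        clean = CleanLibrary("SYA", {shared: 4}, {})
        counts, stats = map_tags(clean, index)
        assert counts.empty
        assert stats["mapped_ambiguous"] == 4

    def test_hamming1_rescue_unique(self):
        base, other, shared, index = _toy_index()
        variant = base[:-1] + ("C" if base[-1] != "C" else "G")
        clean = CleanLibrary("SYA", {variant: 3}, {})
        counts, _ = map_tags(clean, index, max_mismatch=1)
        assert counts["g1"] == 3
        counts0, stats0 = map_tags(clean, index, max_mismatch=0)
        assert counts0.empty and stats0["unmapped"] == 3

    def test_copy_conservation(self):
        base, other, shared, index = _toy_index()
        clean = CleanLibrary(
            "SYA",
            {base: 5, shared: 3, "CATG" + "AAAAAAAAAAAAAAAAA": 2},
            {},
        )
        _, stats = map_tags(clean, index)
        assert (
            stats["mapped_unambiguous"] + stats["mapped_ambiguous"]
            + stats["unmapped"] == stats["total_clean"] == 10
        )

    def test_hamming1_agrees_with_bruteforce_scan(self):
        # randomized index vs an all-pairs Hamming-distance oracle
        rng = np.random.default_rng(21)
        cat = generate_reference(150, (60, 160), seed=21)
        index = extract_reference_tags(cat)
        index_tags = list(index.tag_to_genes)
        queries = []
        for _ in range(120):
            tag = index_tags[rng.integers(len(index_tags))]
            pos = rng.integers(len(tag))
            sub = "ACGT"[rng.integers(4)]
            queries.append(tag[:pos] + sub + tag[pos + 1 :])
        clean = CleanLibrary("SYA", {q: 1 for q in set(queries)}, {})
        counts, stats = map_tags(clean, index, max_mismatch=1)

        def hamming(a, b):
            return sum(c1 != c2 for c1, c2 in zip(a, b))

        expected = {}
        n_unambig = n_ambig = n_unmapped = 0
        for q in clean.tags:
            if q in index.tag_to_genes:
                genes = index.tag_to_genes[q]
                hits = [q]
            else:
                hits = [t for t in index_tags if hamming(q, t) == 1]
                genes = index.tag_to_genes[hits[0]] if len(hits) == 1 else None
            if genes is None and not hits:
                n_unmapped += 1
            elif genes is not None and len(genes) == 1 and len(hits) == 1:
                expected[genes[0]] = expected.get(genes[0], 0) + 1
                n_unambig += 1
            else:
                n_ambig += 1
        assert counts.to_dict() == expected
        assert stats["mapped_unambiguous"] == n_unambig
        assert stats["mapped_ambiguous"] == n_ambig
        assert stats["unmapped"] == n_unmapped

    def test_rejects_length_mismatch(self):
        _, _, _, index = _toy_index()
        clean = CleanLibrary("SYA", {"CATGAA": 1}, {})
        with pytest.raises(ValueError):
            map_tags(clean, index)


class TestCountTableAndTpm:
    def test_tpm_arithmetic(self):
        counts = pd.DataFrame({"SYA": [600, 0, 1]},
                              index=pd.Index(["g1", "g2", "g3"], name="gene_id"))
        table = normalize_tpm(counts, pd.Series({"SYA": 6_000_000}))
        assert table.tpm.loc["g1", "SYA"] == pytest.approx(100.0)
        assert table.tpm.loc["g2", "SYA"] == 0.0
        table2 = normalize_tpm(counts, pd.Series({"SYA": 5_654_488}))
        assert table2.tpm.loc["g3", "SYA"] == pytest.approx(1 / 5_654_488 * 1e6)

    def test_rejects_zero_size_with_counts(self):
        counts = pd.DataFrame({"SYA": [5]}, index=pd.Index(["g1"], name="gene_id"))
        with pytest.raises(ValueError):
            normalize_tpm(counts, pd.Series({"SYA": 0}))

    def test_tpm_sums_to_million_iff_fully_unambiguous(self):
        cat = generate_reference(80, (100, 250), seed=9)
        truth = plan_truth(cat, class_sizes={}, depths=30_000, seed=9)
        libs = simulate_libraries(cat, truth, error_rate=0.0, adaptor_rate=0.0)
        index = extract_reference_tags(cat)
        clean = {c: clean_tags(l, adaptor="GATCGGAAG", min_copies=1)
                 for c, l in libs.items()}
        table = build_count_table(clean, index, cat)
        assert np.allclose(table.tpm.sum(axis=0), 1e6)


class TestCopyNumberDistribution:
    def test_worked_binning(self):
        clean = CleanLibrary("SYA", {"A" * 21: 2, "C" * 21: 2,
                                     "G" * 21: 5, "T" * 21: 100}, {})
        df = copy_number_distribution(clean, [2, 6])
        assert list(df["distinct_fraction"]) == pytest.approx([3 / 4, 1 / 4])
        assert list(df["total_fraction"]) == pytest.approx([9 / 109, 100 / 109])

    def test_single_tag(self):
        clean = CleanLibrary("SYA", {"A" * 21: 7}, {})
        df = copy_number_distribution(clean, [2, 6, 11])
        assert list(df["distinct_fraction"]) == [0.0, 1.0, 0.0]

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=2, max_value=500), min_size=1, max_size=40))
    def test_fractions_sum_to_one(self, copies):
        clean = CleanLibrary(
            "SYA", {f"TAG{i:018d}": c for i, c in enumerate(copies)}, {}
        )
        df = copy_number_distribution(clean, [2, 6, 11, 21, 51, 101])
        assert df["distinct_fraction"].sum() == pytest.approx(1.0)
        assert df["total_fraction"].sum() == pytest.approx(1.0)

    def test_rejects_empty_or_bad_edges(self):
        with pytest.raises(ValueError):
            copy_number_distribution(CleanLibrary("SYA", {}, {}), [2, 6])
        clean = CleanLibrary("SYA", {"A" * 21: 3}, {})
        with pytest.raises(ValueError):
            copy_number_distribution(clean, [6, 2])
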