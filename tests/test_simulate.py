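"""Reference generator, planted truth, library simulation and recovery metrics."""

import numpy as np
import pytest

from dgetag.simulate import (
    BASELINE,
    CONDITIONS,
    ReferenceCatalog,
    adaptor_tag,
    evaluate_recovery,
    generate_annotations,
    generate_reference,
    plan_truth,
    simulate_libraries,
)
from dgetag.tags import extract_reference_tags


def find_tag_sites(seq: str, anchor: str = "CATG", body: int = 17) -> int:
    """Independent string scan: anchor occurrences with a full body after."""
    count = 0
    for i in range(len(seq) - len(anchor) - body + 1):
        if seq[i : i + len(anchor)] == anchor:
            count += 1
    return count


class TestGenerateReference:
    def test_single_gene_hosts_a_tag(self):
        cat = generate_reference(1, (30, 30), seed=7)
        gene_id, seq = cat.records[0]
        assert len(seq) == 30
        assert find_tag_sites(seq) >= 1

    def test_deterministic_for_fixed_seed(self):
        a = generate_reference(500, (100, 300), seed=7)
        b = generate_reference(500, (100, 300), seed=7)
        assert a == b
        c = generate_reference(500, (100, 300), seed=8)
        assert a != c

    def test_every_gene_has_extractable_tag(self):
        cat = generate_reference(500, (100, 300), seed=7)
        frac = np.mean([find_tag_sites(seq) >= 1 for _, seq in cat.records])
        assert frac == 1.0

    def test_rejects_impossible_inputs(self):
        with pytest.raises(ValueError):
            generate_reference(0, (100, 200), seed=0)
        with pytest.raises(ValueError):
            generate_reference(5, (10, 15), seed=0)  # cannot host anchor+body

    def test_catalog_invariants_enforced(self):
        with pytest.raises(ValueError):
            ReferenceCatalog(records=(("g1", "ACGT"), ("g1", "ACGT")))
        with pytest.raises(ValueError):
            ReferenceCatalog(records=(("g1", "ACGN"),))


class TestPlanTruth:
    def test_no_planting_means_flat_design(self, small_catalog):
        truth = plan_truth(small_catalog, class_sizes={}, depths=1000, seed=0)
        base = truth.expected_weights(BASELINE)
        for cond in CONDITIONS:
            assert truth.expected_weights(cond) == base

    def test_microcycle_fold_change_is_exact(self, small_catalog):
        truth = plan_truth(
            small_catalog, class_sizes={"microcycle_up": 10}, fold_change=8.0,
            depths=1000, seed=1,
        )
        sya = truth.expected_weights("SYA")
        sr = truth.expected_weights("SR")
        for gene in truth.class_members("microcycle_up"):
            assert sya[gene] / sr[gene] == pytest.approx(8.0)

    def test_nutrient_genes_zero_off_medium(self, small_catalog):
        truth = plan_truth(
            small_catalog, class_sizes={"sucrose_specific": 5}, fold_change=8.0,
            depths=1000, seed=1,
        )
        for cond in ("NR", "PR", "SDAY"):
            weights = truth.expected_weights(cond)
            for gene in truth.class_members("sucrose_specific"):
                assert weights[gene] == 0.0

    def test_classes_disjoint_and_abundance_normalized(self, small_catalog):
        truth = plan_truth(
            small_catalog,
            class_sizes={"normal_up": 5, "microcycle_up": 5, "nitrate_specific": 5},
            depths=1000, seed=2,
        )
        classes = [truth.class_members(c)
                   for c in ("normal_up", "microcycle_up", "nitrate_specific")]
        assert sum(len(c) for c in classes) == len(set().union(*classes))
        assert sum(truth.abundance.values()) == pytest.approx(1.0, abs=1e-9)

    def test_rejects_oversized_classes(self, small_catalog):
        with pytest.raises(ValueError):
            plan_truth(small_catalog, class_sizes={"normal_up": 10_000}, depths=10)
        with pytest.raises(ValueError):
            plan_truth(small_catalog, class_sizes={"normal_up": 5},
                       fold_change=1.0, depths=10)


class TestSimulateLibraries:
    def test_depth_conservation_and_determinism(self, small_catalog, small_truth):
        libs1 = simulate_libraries(small_catalog, small_truth,
                                   error_rate=0.002, adaptor_rate=0.01)
        libs2 = simulate_libraries(small_catalog, small_truth,
                                   error_rate=0.002, adaptor_rate=0.01)
        for cond in CONDITIONS:
            assert libs1[cond].total_raw == small_truth.condition_depths[cond]
            assert libs1[cond].tags == libs2[cond].tags

    def test_zero_depth_gives_empty_library(self, small_catalog):
        truth = plan_truth(small_catalog, class_sizes={},
                           depths={"SYA": 0, "SR": 100, "NR": 100,
                                   "PR": 100, "SDAY": 100}, seed=3)
        libs = simulate_libraries(small_catalog, truth, error_rate=0.0)
        assert libs["SYA"].total_raw == 0 and libs["SYA"].distinct_raw == 0

    def test_error_free_tags_all_reference(self, small_catalog, small_truth):
        libs = simulate_libraries(small_catalog, small_truth,
                                  error_rate=0.0, adaptor_rate=0.0)
        index = extract_reference_tags(small_catalog)
        signature = set(index.signature_tags.values())
        for lib in libs.values():
            assert set(lib.tags) <= signature

    def test_nutrient_genes_unsampled_off_medium(self, small_catalog, small_truth):
        libs = simulate_libraries(small_catalog, small_truth, error_rate=0.0)
        index = extract_reference_tags(small_catalog)
        for cond in ("NR", "PR", "SDAY"):
            for gene in small_truth.class_members("sucrose_specific"):
                assert libs[cond].tags.get(index.signature_tags[gene], 0) == 0

    def test_marginal_copy_count_matches_binomial_expectation(self):
        # one gene at relative abundance 0.01, depth 100k: mean copies over
        # 50 seeds should fall within 4 standard errors of 1000
        cat = generate_reference(100, (60, 120), seed=4)
        truth = plan_truth(cat, class_sizes={}, depths=100_000, seed=4,
                           abundance_scale=1.0)
        # override to a known abundance vector: gene 0 at exactly 0.01
        abundance = dict(truth.abundance)
        rest = 0.99 / (len(abundance) - 1)
        forced = {g: (0.01 if i == 0 else rest)
                  for i, g in enumerate(cat.gene_ids)}
        truth = type(truth)(
            gene_ids=truth.gene_ids, abundance=forced, membership=truth.membership,
            fold_change=truth.fold_change, seed=truth.seed,
            condition_depths=truth.condition_depths,
            nutrient_sya_factor=truth.nutrient_sya_factor,
        )
        index = extract_reference_tags(cat)
        sig = index.signature_tags[cat.gene_ids[0]]
        counts = []
        for seed in range(50):
            libs = simulate_libraries(cat, truth, error_rate=0.0, seed=seed)
            counts.append(libs["SYA"].tags.get(sig, 0))
        se = np.sqrt(100_000 * 0.01 * 0.99 / 50)
        assert abs(np.mean(counts) - 1000) < 4 * se

    def test_adaptor_fraction_replaced(self, small_catalog, small_truth):
        libs = simulate_libraries(small_catalog, small_truth,
                                  error_rate=0.0, adaptor_rate=0.2)
        lib = libs["SYA"]
        frac = lib.tags[adaptor_tag(21)] / lib.total_raw
        assert frac == pytest.approx(0.2, abs=0.02)

    def test_rejects_bad_rates(self, small_catalog, small_truth):
        with pytest.raises(ValueError):
            simulate_libraries(small_catalog, small_truth, error_rate=1.0)
        with pytest.raises(ValueError):
            simulate_libraries(small_catalog, small_truth, adaptor_rate=-0.1)


class TestEvaluateRecovery:
    @pytest.mark.parametrize(
        "called,truth,expected",
        [
            ({"a", "b"}, {"a", "b"}, (1.0, 1.0)),
            (set(), {"a"}, (0.0, 0.0)),
            ({"a", "b", "x"}, {"a", "b", "c", "d"}, (2 / 3, 1 / 2)),
            (set(), set(), (1.0, 1.0)),
            ({"a"}, set(), (0.0, 1.0)),
        ],
    )
    def test_conventions(self, called, truth, expected):
        assert evaluate_recovery(called, truth) == pytest.approx(expected)


class TestGenerateAnnotations:
    def test_planted_term_annotates_exactly_its_genes(self, small_catalog):
        planted = set(list(small_catalog.gene_ids)[:8])
        ann = generate_annotations(small_catalog.gene_ids, n_terms=10, seed=0,
                                   planted_term="TERM:planted",
                                   planted_genes=planted)
        assert ann.term_to_genes["TERM:planted"] == frozenset(planted)
        # inverse consistency is enforced by the constructor
        assert ann.annotated_genes <= set(small_catalog.gene_ids)
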