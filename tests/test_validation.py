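"""Enrichment, replication accounting and miRNA-target recall procedures."""

import numpy as np
import pytest

import corrbrowser as cb
from corrbrowser.expression import ARRAY


@pytest.fixture(scope="module")
def annotated_and_universe(small_cohort):
    _, truth = small_cohort
    annotated = cb.simulate_annotation(truth)
    return annotated, set(truth.array_features())


class TestEnrichment:
    def test_saturated_annotation(self, small_store, annotated_and_universe):
        _, universe = annotated_and_universe
        res = cb.topk_binding_enrichment(small_store, "HUB01", 20,
                                         annotated_set=set(universe),
                                         universe=universe, n_resamples=50, rng_seed=0)
        assert res.fraction_annotated == 1.0
        assert res.baseline_mean == 1.0 and res.baseline_sd == 0.0
        assert res.empirical_p == 1.0

    def test_disjoint_annotation(self, small_store, annotated_and_universe):
        _, universe = annotated_and_universe
        res = cb.topk_binding_enrichment(small_store, "HUB01", 20,
                                         annotated_set={"NOT_A_GENE"},
                                         universe=universe, n_resamples=50, rng_seed=0)
        assert res.fraction_annotated == 0.0

    def test_empirical_p_never_zero_and_reproducible(self, small_store,
                                                     annotated_and_universe):
        annotated, universe = annotated_and_universe
        kw = dict(annotated_set=annotated, universe=universe,
                  n_resamples=200, rng_seed=42)
        a = cb.topk_binding_enrichment(small_store, "HUB01", 30, **kw)
        b = cb.topk_binding_enrichment(small_store, "HUB01", 30, **kw)
        assert a == b
        assert a.empirical_p > 0
        assert a.empirical_p == (1 + 0) / 201  # enriched top-k beats every draw

    def test_baseline_converges_to_universe_rate(self, small_store,
                                                 annotated_and_universe):
        annotated, universe = annotated_and_universe
        res = cb.topk_binding_enrichment(small_store, "HUB01", 30,
                                         annotated_set=annotated, universe=universe,
                                         n_resamples=2000, rng_seed=7)
        pool = universe - {"HUB01"}
        rate = len(annotated & pool) / len(pool)
        assert abs(res.baseline_mean - rate) <= 3 * res.baseline_sd / np.sqrt(2000)

    def test_super_uniform_under_shuffled_null(self, small_store,
                                               annotated_and_universe, rng):
        # annotation labels shuffled independently of correlation structure:
        # empirical p should not be systematically small
        _, universe = annotated_and_universe
        pool = sorted(universe)
        ps = []
        for trial in range(40):
            labels = set(rng.choice(pool, size=len(pool) // 2, replace=False))
            res = cb.topk_binding_enrichment(small_store, "HUB01", 25,
                                             annotated_set=labels, universe=universe,
                                             n_resamples=99, rng_seed=trial)
            ps.append(res.empirical_p)
        for alpha in (0.05, 0.25, 0.5):
            assert np.mean(np.array(ps) <= alpha) <= alpha + 3 * np.sqrt(alpha / 40)

    def test_k_exceeding_universe_rejected(self, small_store, annotated_and_universe):
        annotated, universe = annotated_and_universe
        with pytest.raises(ValueError, match="exceeds universe"):
            cb.topk_binding_enrichment(small_store, "HUB01", len(universe) + 5,
                                       annotated_set=annotated, universe=universe,
                                       n_resamples=10)


class TestReplication:
    def _replication_fixture(self, n_pairs=200, n_absent=14, n_null=6, n=300, seed=5):
        """Seed + partners: most strongly coupled, a few null, a few absent."""
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        ids = ["SEED"] + [f"P{i:03d}" for i in range(n_pairs)]
        rows = [z]
        for i in range(n_pairs):
            if i < n_null:  # independent noise: fails Bonferroni
                rows.append(rng.standard_normal(n))
            else:
                rows.append(0.8 * z + 0.6 * rng.standard_normal(n))
        pairs = [("SEED", f"P{i:03d}") for i in range(n_pairs)]
        present = ids[:1] + [f"P{i:03d}" for i in range(n_pairs - n_absent)]
        keep = [ids.index(f) for f in present]
        matrix = cb.ExpressionMatrix(
            feature_ids=present, sample_ids=[f"S{j}" for j in range(n)],
            values=np.array(rows)[keep],
            platform=np.array([ARRAY] * len(present), dtype=object),
        )
        return pairs, matrix

    def test_discovery_carryover_accounting(self):
        # 200 pairs, 14 partners absent, 6 detected-but-null -> 180 significant
        pairs, matrix = self._replication_fixture()
        res = cb.replicate_associations(pairs, matrix, alpha=0.05)
        assert res.n_discovery == 200
        assert res.n_undetected == 14
        assert res.n_nonsignificant == 6
        assert res.n_significant == 180

    def test_counts_partition_discovery(self):
        pairs, matrix = self._replication_fixture(n_pairs=40, n_absent=9, n_null=3)
        res = cb.replicate_associations(pairs, matrix)
        assert res.n_discovery == res.n_undetected + res.n_significant + res.n_nonsignificant
        assert len(res.table) == res.n_discovery
        assert set(res.table["status"]) <= {"undetected", "significant", "nonsignificant"}

    def test_self_replication_all_significant(self, small_cohort, small_spec):
        matrix, truth = small_cohort
        arr = matrix.subset(truth.array_features())
        pairs = [(h, r) for h, rs in truth.responders.items() for r in rs]
        res = cb.replicate_associations(pairs, arr, alpha=0.05)
        assert res.n_significant == res.n_discovery and res.n_undetected == 0

    def test_two_cohort_preset_replicates_planted_pairs(self, small_spec):
        _, truth = cb.simulate_cohort(small_spec)
        rep = cb.simulate_replication(small_spec, truth)
        pairs = [(h, r) for h, rs in truth.responders.items() for r in rs]
        res = cb.replicate_associations(pairs, rep, alpha=0.05)
        detected = res.n_significant + res.n_nonsignificant
        assert detected > 0
        assert res.n_significant / detected >= 0.95

    def test_discovery_r_carried_into_table(self):
        pairs, matrix = self._replication_fixture(n_pairs=5, n_absent=0, n_null=0)
        res = cb.replicate_associations([(a, b, 0.9) for a, b in pairs], matrix)
        assert (res.table["discovery_r"] == 0.9).all()

    def test_empty_pairs_rejected(self, small_cohort):
        matrix, _ = small_cohort
        with pytest.raises(ValueError, match="empty"):
            cb.replicate_associations([], matrix)

    def test_family_size_must_cover_pairs(self):
        pairs, matrix = self._replication_fixture(n_pairs=10, n_absent=0, n_null=0)
        with pytest.raises(ValueError):
            cb.replicate_associations(pairs, matrix, family_size=5)


class TestMirnaRecall:
    def test_planted_pairs_nominal_and_negative(self, small_store, small_cohort):
        _, truth = small_cohort
        pairs = cb.TargetPairSet(tuple(truth.mirna_targets.items()), source="planted")
        report = cb.mirna_target_recall(small_store, pairs, alpha=0.05)
        assert report.n_pairs_input == len(truth.mirna_targets)
        assert report.n_detected >= 1
        assert report.fraction_nominal >= 0.8
        assert report.n_nominal_negative == report.n_nominal  # coupling is negative

    def test_fraction_arithmetic(self, small_store, small_cohort):
        _, truth = small_cohort
        planted = list(truth.mirna_targets.items())
        decoys = [(m, "BG%05d" % (i + 50)) for i, (m, _) in enumerate(planted)]
        report = cb.mirna_target_recall(
            small_store, cb.TargetPairSet(tuple(planted + decoys)), alpha=0.05)
        assert report.n_detected == len(planted) + len(decoys)
        assert report.fraction_nominal == pytest.approx(
            report.n_nominal / report.n_detected)

    def test_invariant_to_input_order(self, small_store, small_cohort):
        _, truth = small_cohort
        items = list(truth.mirna_targets.items())
        a = cb.mirna_target_recall(small_store, cb.TargetPairSet(tuple(items)))
        b = cb.mirna_target_recall(small_store, cb.TargetPairSet(tuple(items[::-1])))
        assert a == b

    def test_all_undetected_reports_nan(self, small_store):
        pairs = cb.TargetPairSet((("ghost1", "ghost2"), ("ghost3", "ghost4")))
        report = cb.mirna_target_recall(small_store, pairs)
        assert report.n_detected == 0
        assert np.isnan(report.fraction_nominal)

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cb.TargetPairSet((("a", "b"), ("a", "b")))


class TestFileFormats:
    def test_gene_set_comments_and_blanks(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("# header\nG1\n\nG2  \nG3 # trailing\n")
        assert cb.read_gene_set(p) == {"G1", "G2", "G3"}

    def test_pairs_header_optional(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("id_a\tid_b\nm1\tg1\nm2\tg2\n")
        assert cb.read_pairs(p).pairs == (("m1", "g1"), ("m2", "g2"))
        q = tmp_path / "nohdr.tsv"
        q.write_text("m1\tg1\n")
        assert cb.read_pairs(q).pairs == (("m1", "g1"),)
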