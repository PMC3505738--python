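import math

import numpy as np
import pytest

from usrcatkit import (
    FixtureSpec,
    ScreenConfig,
    TargetSet,
    UsrcatMethod,
    Weights,
    average_ef,
    build_benchmark_set,
    enrichment_factor,
    run_benchmark,
    scaffold_hop_counts,
    tanimoto_topological,
)
from usrcatkit.benchmark import BenchmarkResult, EfRecord, ef_records_to_frame


class TestEnrichmentFactor:
    def test_printed_formula(self):
        ef, flag = enrichment_factor(2, 8, 10, 500)
        assert ef == pytest.approx(12.5)
        assert not flag

    def test_dataset_ratio_gives_one(self):
        # retrieval at the dataset active:decoy ratio is the normalisation point
        ef, _ = enrichment_factor(1, 50, 10, 500)
        assert ef == pytest.approx(1.0)

    def test_zero_decoys_substitutes_one_and_flags(self):
        ef, flag = enrichment_factor(3, 0, 10, 500)
        assert ef == pytest.approx(150.0)
        assert flag

    def test_zero_actives_gives_zero(self):
        assert enrichment_factor(0, 5, 10, 500) == (0.0, False)

    def test_standard_convention(self):
        ef, _ = enrichment_factor(2, 3, 10, 490, convention="standard")
        assert ef == pytest.approx((2 / 5) / (10 / 500))

    def test_invalid_totals_rejected(self):
        with pytest.raises(ValueError):
            enrichment_factor(0, 0, 0, 10)

    def test_random_ranking_mean_near_one(self):
        rng = np.random.default_rng(0)
        labels = np.array([1] * 10 + [0] * 490)
        n_ret = math.ceil(0.01 * 500)
        efs = []
        for _ in range(500):
            top = labels[rng.permutation(500)][:n_ret]
            a = int(top.sum())
            ef, _ = enrichment_factor(a, n_ret - a, 10, 490)
            efs.append(ef)
        efs = np.asarray(efs)
        se = efs.std(ddof=1) / np.sqrt(len(efs))
        assert abs(efs.mean() - 1.0) <= 3 * se


class TestAverageEf:
    def _rec(self, target, query, ef, level=1.0):
        return EfRecord(target, query, level, 1, 1, ef)

    def test_single_record_passthrough(self):
        out = average_ef([self._rec("t1", "q1", 7.5)])
        overall = out[out.target_id == "__overall__"]
        assert overall.ef.iloc[0] == pytest.approx(7.5)

    def test_two_stage_mean_is_not_query_weighted(self):
        records = (
            [self._rec("t1", f"q{i}", 2.0) for i in range(5)]
            + [self._rec("t2", "q0", 4.0)]
        )
        out = average_ef(records)
        overall = out[out.target_id == "__overall__"]
        assert overall.ef.iloc[0] == pytest.approx(3.0)

    def test_matches_manual_recomputation(self):
        rng = np.random.default_rng(3)
        records = [
            self._rec(f"t{t}", f"q{q}", float(rng.uniform(0, 20)))
            for t in range(3)
            for q in range(2)
        ]
        out = average_ef(records)
        per_target = {}
        for r in records:
            per_target.setdefault(r.target_id, []).append(r.ef)
        expected = np.mean([np.mean(v) for v in per_target.values()])
        overall = out[out.target_id == "__overall__"]
        assert overall.ef.iloc[0] == pytest.approx(expected)


class TestFingerprints:
    def test_identical_molecule_scores_one(self, ethanol):
        for kind in ("circular", "path", "tree", "maccs"):
            assert tanimoto_topological(ethanol.mol, ethanol.mol, kind) == 1.0

    def test_regression_value_ethanol_vs_propanol(self):
        from rdkit import Chem

        a = Chem.MolFromSmiles("CCO")
        b = Chem.MolFromSmiles("CCCO")
        t = tanimoto_topological(a, b, "circular", 2048)
        assert 0.0 < t < 1.0
        assert t == pytest.approx(0.5555555555555556, abs=1e-12)
        assert t == tanimoto_topological(a, b, "circular", 2048)  # stable

    def test_unsupported_kind_rejected(self, ethanol):
        with pytest.raises(ValueError):
            tanimoto_topological(ethanol.mol, ethanol.mol, "quantum")


def _result_from_registry(target, level, registry):
    return BenchmarkResult(
        target_id=target, levels=(level,), ef_records=[], query_hits={},
        retrieved_actives={(q, level): frozenset(s) for q, s in registry.items()},
    )


class TestScaffoldHopCounts:
    def test_equal_registries_give_zero(self):
        reg = {"q1": {"a1", "a2"}, "q2": {"a3"}}
        shape = _result_from_registry("t", 0.25, reg)
        fp = _result_from_registry("t", 0.25, reg)
        summary = scaffold_hop_counts(shape, fp, 0.25)
        assert (summary.min, summary.max, summary.avg) == (0, 0, 0.0)
        assert summary.n_queries == 2

    def test_all_queries_excluded_when_fp_retrieves_nothing(self):
        shape = _result_from_registry("t", 0.25, {"q1": {"a1"}, "q2": {"a2"}})
        fp = _result_from_registry("t", 0.25, {"q1": set(), "q2": set()})
        summary = scaffold_hop_counts(shape, fp, 0.25)
        assert summary.n_queries == 0
        assert summary.min is None and summary.max is None and summary.avg is None

    def test_hand_built_counts_summary(self):
        # 25 queries with exclusive-hit counts spanning 1..25, mean 6.48
        counts = [1, 25] + [6] * 20 + [8, 6, 2]
        shape_reg = {}
        fp_reg = {}
        for i, c in enumerate(counts):
            q = f"q{i:02d}"
            shape_reg[q] = {f"x{i}_{j}" for j in range(c)} | {"shared"}
            fp_reg[q] = {"shared"}
        summary = scaffold_hop_counts(
            _result_from_registry("t", 0.25, shape_reg),
            _result_from_registry("t", 0.25, fp_reg),
            0.25,
        )
        assert (summary.min, summary.max) == (1, 25)
        assert summary.avg == pytest.approx(6.48)

    def test_mismatched_query_sets_rejected(self):
        shape = _result_from_registry("t", 0.25, {"q1": {"a1"}})
        fp = _result_from_registry("t", 0.25, {"q2": {"a1"}})
        with pytest.raises(ValueError, match="different query sets"):
            scaffold_hop_counts(shape, fp, 0.25)


@pytest.fixture(scope="module")
def small_target_set():
    spec = FixtureSpec(
        seed=11, n_actives=5, n_decoys=40, twin_fraction=1.0,
        jitter_sigma=0.15, n_conformers=2,
    )
    return build_benchmark_set(spec)


class TestRunBenchmark:
    def test_byte_identical_reruns(self, small_target_set):
        cfg = ScreenConfig(top_fraction=1.0)
        method = UsrcatMethod()
        r1 = run_benchmark(small_target_set, method, cfg, levels=(1.0, 0.5))
        r2 = run_benchmark(small_target_set, method, cfg, levels=(1.0, 0.5))
        assert r1.ef_records == r2.ef_records
        assert r1.query_hits == r2.query_hits

    def test_query_molecule_fully_excluded(self, small_target_set):
        cfg = ScreenConfig(top_fraction=1.0)
        res = run_benchmark(small_target_set, UsrcatMethod(), cfg, levels=(100.0,))
        for query, hits in res.query_hits.items():
            assert all(h.mol_id != query for h in hits)
            # the whole remaining set is retrieved at the 100% level
            assert len(hits) == small_target_set.A + small_target_set.D - 1

    def test_ef_scale_consistency_under_duplication(self):
        # duplicating every molecule of a fixed ranking (actives and decoys
        # alike) leaves EF at matched fractional levels unchanged
        rng = np.random.default_rng(12)
        labels = rng.permutation([1] * 10 + [0] * 40)
        doubled = np.repeat(labels, 2)
        for frac in (0.1, 0.2, 0.5):
            n1 = math.ceil(frac * labels.size)
            n2 = math.ceil(frac * doubled.size)
            a1 = int(labels[:n1].sum())
            a2 = int(doubled[:n2].sum())
            ef1, _ = enrichment_factor(a1, n1 - a1, 10, 40)
            ef2, _ = enrichment_factor(a2, n2 - a2, 20, 80)
            assert ef1 == pytest.approx(ef2)

    def test_indistinguishable_sets_flagged(self, small_target_set):
        ts = small_target_set
        # decoys that are exact copies of the actives' geometry and labels
        decoys = []
        for i, m in enumerate(ts.actives):
            mol_id = f"copy_{i}"
            confs = [
                type(c)(mol_id=mol_id, conf_id=c.conf_id, coords=c.coords,
                        elements=c.elements, is_hydrogen=c.is_hydrogen)
                for c in m.conformers
            ]
            decoys.append(type(m)(mol_id=mol_id, conformers=confs, subsets=m.subsets))
        degenerate = TargetSet("degenerate", actives=ts.actives, decoys=decoys)
        res = run_benchmark(
            degenerate, UsrcatMethod(), ScreenConfig(top_fraction=1.0), levels=(100.0,)
        )
        # every query finds its own exact copy at similarity 1.0
        assert all(
            any(h.score == 1.0 for h in hits) for hits in res.query_hits.values()
        )

    def test_zero_radius_on_generic_data_retrieves_nothing(self, small_target_set):
        # with distinct moments, a zero-width box holds only the query's own
        # conformers, which are excluded: zero retrieved, EF 0
        res = run_benchmark(
            small_target_set, UsrcatMethod(),
            ScreenConfig(top_fraction=1.0, probe_radius=0.0), levels=(1.0,),
        )
        assert all(r.a == 0 and r.d == 0 and r.ef == 0.0 for r in res.ef_records)
        assert all(hits == [] for hits in res.query_hits.values())

    def test_records_frame_shape(self, small_target_set):
        res = run_benchmark(
            small_target_set, UsrcatMethod(), ScreenConfig(top_fraction=1.0),
            levels=(1.0, 0.5, 0.25),
        )
        frame = ef_records_to_frame(res.ef_records)
        assert len(frame) == small_target_set.A * 3
        assert (frame.a + frame.d >= 1).all()
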