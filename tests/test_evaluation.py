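import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugcombo.data_model import (CombinationNetwork, DrugSet, RunConfig,
                                  read_report, write_report)
from drugcombo.evaluation import (EvaluationReport, Metrics, compute_metrics,
                                  downsample_negatives, leave_one_drug_out,
                                  make_folds, run_experiment)

from conftest import random_instance


def auroc_oracle(labels, scores):
    """Brute-force pairwise-comparison probability with half-credit ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestDownsample:
    def _net(self, rng, n=12, edge_p=0.2):
        _, net = random_instance(rng, n, edge_p)
        return net

    def test_counts(self, rng):
        net = self._net(rng)
        n_pos = len(net.positive_pairs)
        labeled = downsample_negatives(net, ratio=1, seed=0)
        assert len(labeled) == 2 * n_pos
        labels = [y for _, _, y in labeled]
        assert sum(labels) == n_pos

    def test_deterministic_per_seed(self, rng):
        net = self._net(rng)
        assert downsample_negatives(net, 2, seed=5) == \
            downsample_negatives(net, 2, seed=5)
        assert downsample_negatives(net, 2, seed=5) != \
            downsample_negatives(net, 2, seed=6)

    def test_insufficient_pool_rejected(self, rng):
        net = self._net(rng, n=6, edge_p=0.9)
        with pytest.raises(ValueError, match="pool"):
            downsample_negatives(net, ratio=12, seed=0)

    def test_negatives_are_non_edges(self, rng):
        net = self._net(rng)
        for a, b, y in downsample_negatives(net, 3, seed=1):
            assert net.has_edge(a, b) == bool(y)

    def test_paper_scale_pool(self):
        # 606 drugs, 1,196 positives -> 182,119 candidate negatives
        ids = tuple(f"D{i:03d}" for i in range(606))
        drugs = DrugSet(ids)
        pairs = []
        k = 0
        for i in range(606):
            for j in range(i + 1, 606):
                pairs.append((ids[i], ids[j]))
                k += 1
                if k == 1196:
                    break
            if k == 1196:
                break
        net = CombinationNetwork(drugs, tuple(pairs))
        assert net.n_non_edges() == 182119
        assert len(net.non_edge_pairs()) == 182119


class TestMakeFolds:
    def _pairs(self, n, n_pos):
        return [(f"L{i}", f"R{i}", int(i < n_pos)) for i in range(n)]

    def test_equal_fold_sizes(self):
        fa = make_folds(self._pairs(100, 50), k=5, seed=0)
        sizes = np.bincount(fa.folds)
        assert np.all(sizes == 20)

    def test_stratified_positive_balance(self):
        fa = make_folds(self._pairs(100, 50), k=10, seed=0)
        for f in range(10):
            rows = fa.test_rows(f)
            assert sum(1 for r in rows if r < 50) == 5

    @pytest.mark.parametrize("k", [3, 5, 10])
    def test_standard_ks(self, k):
        fa = make_folds(self._pairs(60, 30), k=k, seed=1)
        assert fa.k == k and len(np.unique(fa.folds)) == k

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            make_folds(self._pairs(4, 2), k=5, seed=0)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="fewer than k"):
            make_folds(self._pairs(50, 2), k=5, seed=0)

    def test_partition(self):
        pairs = self._pairs(53, 21)
        fa = make_folds(pairs, k=5, seed=3)
        all_rows = np.concatenate([fa.test_rows(f) for f in range(5)])
        assert sorted(all_rows) == list(range(53))


class TestComputeMetrics:
    def test_hand_confusion_counts(self):
        # TP=2, FP=1, FN=2 at threshold 0.5
        labels = [1, 1, 1, 1, 0, 0, 0]
        scores = [0.9, 0.8, 0.1, 0.2, 0.7, 0.3, 0.1]
        m = compute_metrics(labels, scores, threshold=0.5)
        assert m.recall == pytest.approx(0.5)
        assert m.precision == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(4 / 7)

    def test_perfect_ranking(self):
        labels = [0, 0, 1, 1]
        scores = [0.1, 0.2, 0.8, 0.9]
        m = compute_metrics(labels, scores)
        assert m.auroc == 1.0 and m.aupr == 1.0

    def test_null_scores_near_half(self, rng):
        n = 2000
        labels = rng.integers(0, 2, n)
        scores = rng.random(n)
        assert abs(compute_metrics(labels, scores).auroc - 0.5) < 0.03

    def test_auroc_equals_mann_whitney_on_fixed_toy(self):
        labels = [1, 0, 1, 0, 1, 0, 0, 1, 0, 0]
        scores = [0.9, 0.8, 0.8, 0.6, 0.55, 0.5, 0.5, 0.3, 0.2, 0.1]
        m = compute_metrics(labels, scores)
        assert m.auroc == pytest.approx(auroc_oracle(labels, scores), abs=1e-12)

    def test_auroc_equals_oracle_on_random_inputs(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)  # force ties
            m = compute_metrics(labels, scores)
            assert m.auroc == pytest.approx(auroc_oracle(labels, scores),
                                            abs=1e-12)

    def test_zero_predicted_positives_flagged(self):
        m = compute_metrics([1, 0, 1], [0.1, 0.2, 0.3], threshold=0.9)
        assert m.precision == 0.0
        assert m.no_predicted_positives

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_metrics([1, 1], [0.5, 0.6])

    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.floats(0, 1, allow_nan=False)),
                    min_size=4, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_f1_between_precision_and_recall(self, rows):
        labels = [y for y, _ in rows]
        if len(set(labels)) < 2:
            return
        scores = [s for _, s in rows]
        m = compute_metrics(labels, scores)
        assert min(m.precision, m.recall) - 1e-12 <= m.f1
        assert m.f1 <= max(m.precision, m.recall) + 1e-12
        for v in (m.recall, m.precision, m.f1, m.auroc, m.aupr):
            assert 0.0 <= v <= 1.0


class TestRunExperiment:
    def test_bit_identical_given_seed(self, rng, tmp_path):
        S, A = random_instance(rng, 20, edge_p=0.3)
        cfg = RunConfig(k=3, repeats=2, seed=17)
        r1 = run_experiment(cfg, "nrm:rand", {"rand": S}, A)
        r2 = run_experiment(cfg, "nrm:rand", {"rand": S}, A)
        assert r1.per_repeat == r2.per_repeat
        p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        write_report(r1, p1)
        write_report(r2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self, rng):
        S, A = random_instance(rng, 20, edge_p=0.3)
        r1 = run_experiment(RunConfig(k=3, repeats=2, seed=1), "glm",
                            {"rand": S}, A)
        r2 = run_experiment(RunConfig(k=3, repeats=2, seed=2), "glm",
                            {"rand": S}, A)
        assert r1.per_repeat != r2.per_repeat

    def test_aggregate_matches_recomputation(self, rng):
        S, A = random_instance(rng, 16, edge_p=0.3)
        cfg = RunConfig(k=3, repeats=3, seed=5)
        rep = run_experiment(cfg, "nb", {"rand": S}, A)
        agg = rep.aggregate("nb", 3)
        rows = rep.per_repeat[("nb", 3)]
        assert len(rows) == 3
        for metric, (mean, sd) in agg.items():
            vals = np.array([r[metric] for r in rows])
            assert mean == pytest.approx(vals.mean())
            assert sd == pytest.approx(vals.std(ddof=1))

    def test_unknown_model_rejected(self, rng):
        S, A = random_instance(rng, 10)
        with pytest.raises(ValueError, match="unknown model"):
            run_experiment(RunConfig(repeats=1), "boost", {"rand": S}, A)

    def test_report_round_trip_through_files(self, rng, tmp_path):
        S, A = random_instance(rng, 16, edge_p=0.3)
        rep = run_experiment(RunConfig(k=3, repeats=2, seed=0), "glm",
                             {"rand": S}, A)
        path = tmp_path / "report.tsv"
        write_report(rep, path)
        again = read_report(path)
        for metric, (mean, sd) in rep.aggregate("glm", 3).items():
            got = again.aggregate("glm", 3)[metric]
            assert got[0] == pytest.approx(mean, abs=1e-9)
            assert got[1] == pytest.approx(sd, abs=1e-9)

    def test_planted_signal_high_auroc(self, default_bundle):
        bundle, mats = default_bundle
        cfg = RunConfig(k=5, repeats=2, seed=8)
        rep = run_experiment(cfg, "ensemble", mats, bundle.network)
        assert rep.aggregate("ensemble", 5)["auroc"][0] > 0.8


class TestLeaveOneDrugOut:
    def test_unknown_drug_rejected(self, default_bundle):
        bundle, mats = default_bundle
        with pytest.raises(KeyError):
            leave_one_drug_out(bundle.network, mats, "NOPE")

    def test_table_layout_and_ordering(self, default_bundle):
        bundle, mats = default_bundle
        target = bundle.drugs.ids[0]
        df = leave_one_drug_out(bundle.network, mats, target, seed=2,
                                include_all=True)
        assert list(df.columns) == ["Rank", "Drug1", "Drug2", "Possibility"]
        assert list(df["Rank"]) == list(range(1, len(df) + 1))
        assert np.all(np.diff(df["Possibility"].to_numpy()) <= 0)
        assert np.all(df["Drug1"] < df["Drug2"])

    def test_threshold_filters(self, default_bundle):
        bundle, mats = default_bundle
        target = bundle.drugs.ids[0]
        df = leave_one_drug_out(bundle.network, mats, target, seed=2,
                                threshold=0.5)
        assert (df["Possibility"] >= 0.5).all()

    def test_isolated_target_empty_candidates(self, rng):
        # a drug with zero similarity everywhere cannot clear the threshold
        n = 12
        ids = tuple(f"D{i:02d}" for i in range(n))
        drugs = DrugSet(ids)
        v = rng.random((n, n))
        v = (v + v.T) / 2
        v[0, :] = v[:, 0] = 0.0
        np.fill_diagonal(v, 1.0)
        from drugcombo.data_model import SimilarityMatrix
        S = SimilarityMatrix("c", drugs, v)
        edges = tuple((ids[i], ids[j]) for i in range(1, n)
                      for j in range(i + 1, n)
                      if rng.random() < 0.3)
        net = CombinationNetwork(drugs, edges)
        df = leave_one_drug_out(net, {"c": S}, ids[0], seed=0, threshold=0.5)
        assert len(df) == 0

    def test_true_partners_outrank_decoys(self):
        from drugcombo.synthetic_data import GeneratorConfig, generate
        bundle = generate(GeneratorConfig(n_drugs=60, seed=4))
        mats = bundle.matrices()
        target = bundle.drugs.ids[0]
        partners = {d for p in bundle.network.positive_pairs
                    for d in p if target in p and d != target}
        df = leave_one_drug_out(bundle.network, mats, target, seed=4,
                                include_all=True)
        ranks = {}
        for row in df.itertuples():
            other = row.Drug1 if row.Drug2 == target else row.Drug2
            ranks[other] = row.Rank
        partner_ranks = [ranks[d] for d in partners]
        decoy_ranks = [r for d, r in ranks.items() if d not in partners]
        assert np.median(partner_ranks) < np.median(decoy_ranks)
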