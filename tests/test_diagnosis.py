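import numpy as np
import pytest

from netmark.diagnosis import (
    DiagnosisRecord,
    classify,
    cohort_similarity,
    cross_validate,
    evaluate,
    mapping_errors,
    random_network_baseline,
    summary_from_counts,
)
from netmark.errors import ContractError, PipelineError
from netmark.expression import CANCER, NONCANCER, ExpressionMatrix, znormalize
from netmark.inference import AssociationNetwork, build_association_network
from netmark.interactions import InteractionSet
from netmark.synthetic import combine_cohorts, generate_network_pair, simulate_expression

from conftest import make_matrix


def net(proteins, entries, phenotype=CANCER):
    k = len(proteins)
    m = np.zeros((k, k))
    for (i, j), v in entries.items():
        m[i, j] = m[j, i] = v
    return AssociationNetwork(proteins=proteins, matrix=m, phenotype=phenotype)


def ppi_from_truth(truth):
    ppi = InteractionSet()
    for a, b in truth.rough_true.edges():
        ppi.add(a, b)
    return ppi


class TestMappingErrors:
    def test_zero_vector(self):
        c = net(["A", "B"], {(0, 1): 0.5})
        n = net(["A", "B"], {}, NONCANCER)
        assert mapping_errors(np.zeros(2), c, n) == (0.0, 0.0)

    def test_zero_matrix_reduces_to_norm(self):
        c = net(["A", "B"], {})
        n = net(["A", "B"], {}, NONCANCER)
        z = np.array([3.0, 4.0])
        me_c, _ = mapping_errors(z, c, n)
        assert me_c == pytest.approx(5.0)

    def test_hand_evaluated_example(self):
        c = net(["A", "B"], {(0, 1): 0.5})
        n = net(["A", "B"], {}, NONCANCER)
        z = np.array([1.0, 1.0])
        me_c, me_n = mapping_errors(z, c, n)
        assert me_c == pytest.approx(np.sqrt(0.5), abs=1e-9)
        assert me_n == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_length_mismatch_rejected(self):
        c = net(["A", "B"], {})
        n = net(["A", "B"], {}, NONCANCER)
        with pytest.raises(ContractError):
            mapping_errors(np.zeros(3), c, n)

    def test_one_homogeneous(self):
        rng = np.random.default_rng(0)
        k = 6
        m = np.triu(rng.normal(size=(k, k)) * 0.2, 1)
        prots = [f"P{i}" for i in range(k)]
        c = AssociationNetwork(prots, m + m.T, CANCER)
        n = net(prots, {}, NONCANCER)
        z = rng.normal(size=k)
        me_c, me_n = mapping_errors(z, c, n)
        me_c2, me_n2 = mapping_errors(2.0 * z, c, n)
        assert me_c2 == 2.0 * me_c  # exact for a power-of-two scale
        assert me_n2 == 2.0 * me_n


class TestClassify:
    def cohort(self, vals, labels=None):
        return ExpressionMatrix(
            entity_ids=["A", "B"],
            sample_ids=[f"s{i}" for i in range(vals.shape[1])],
            values=vals,
            labels=labels,
            normalized=True,
        )

    def test_decision_rule(self):
        c = net(["A", "B"], {(0, 1): 0.9})
        n = net(["A", "B"], {}, NONCANCER)
        # sample [1, 1]: me_c < me_n -> cancer; [1, -1]: me_c > me_n -> noncancer
        x = self.cohort(np.array([[1.0, 1.0], [1.0, -1.0]]))
        records = classify(x, c, n)
        assert records[0].predicted == CANCER
        assert records[1].predicted == NONCANCER

    def test_tie_goes_to_noncancer(self, caplog):
        c = net(["A", "B"], {})
        n = net(["A", "B"], {}, NONCANCER)
        x = self.cohort(np.array([[1.0], [0.0]]))
        with caplog.at_level("WARNING"):
            records = classify(x, c, n)
        assert records[0].predicted == NONCANCER
        assert "tie" in caplog.text

    def test_empty_cohort_rejected(self):
        c = net(["A", "B"], {})
        n = net(["A", "B"], {}, NONCANCER)
        x = ExpressionMatrix(["A", "B"], [], np.zeros((2, 0)), normalized=True)
        with pytest.raises(ContractError):
            classify(x, c, n)

    def test_missing_proteins_imputed_zero(self, caplog):
        c = net(["A", "B", "C"], {(0, 1): 0.5})
        n = net(["A", "B", "C"], {}, NONCANCER)
        x = ExpressionMatrix(["A", "B"], ["s0"], np.array([[1.0], [1.0]]), normalized=True)
        with caplog.at_level("INFO"):
            records = classify(x, c, n)
        assert "imputed" in caplog.text
        assert records[0].z.shape == (3,)
        assert records[0].z[2] == 0.0

    def test_scale_invariant_predictions(self):
        rng = np.random.default_rng(1)
        truth = generate_network_pair(10, 20, 0.5, seed=2)
        xc = simulate_expression(truth, CANCER, 20, 0.1, 3)
        x = znormalize(xc)
        c, n = truth.cpan_true, truth.npan_true
        doubled = ExpressionMatrix(x.entity_ids, x.sample_ids, x.values * 2.0,
                                   x.labels, normalized=True)
        p1 = [r.predicted for r in classify(x, c, n)]
        p2 = [r.predicted for r in classify(doubled, c, n)]
        assert p1 == p2


class TestEvaluate:
    def rec(self, predicted, truth):
        return DiagnosisRecord("s", np.zeros(1), 0.0, 0.0, predicted, truth)

    def test_perfect(self):
        records = [self.rec(CANCER, CANCER), self.rec(NONCANCER, NONCANCER)]
        s = evaluate(records)
        assert (s.accuracy, s.sensitivity, s.specificity) == (100.0, 100.0, 100.0)

    def test_printed_confusion_structure(self):
        s = summary_from_counts(tp=15, fn=3, tn=11, fp=6)
        assert round(s.sensitivity, 2) == 83.33
        assert round(s.specificity, 2) == 64.71
        assert round(s.accuracy, 2) == 74.29

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(2)
        records = [
            self.rec(rng.choice([CANCER, NONCANCER]), rng.choice([CANCER, NONCANCER]))
            for _ in range(37)
        ]
        s = evaluate(records)
        assert s.tp + s.tn + s.fp + s.fn == s.n == 37

    def test_missing_truth_rejected(self):
        with pytest.raises(ContractError):
            evaluate([self.rec(CANCER, None)])

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            evaluate([])


class TestRandomNetworkBaseline:
    def setup_data(self, shared, seed=3):
        truth = generate_network_pair(40, 80, shared, seed=seed)
        xc = simulate_expression(truth, CANCER, 60, 0.1, seed + 1)
        xn = simulate_expression(truth, NONCANCER, 60, 0.1, seed + 2)
        train = znormalize(combine_cohorts(xc, xn))
        tc = simulate_expression(truth, CANCER, 30, 0.1, seed + 11)
        tn = simulate_expression(truth, NONCANCER, 30, 0.1, seed + 12)
        test = znormalize(combine_cohorts(tc, tn))
        return truth, ppi_from_truth(truth), train, test

    def test_chance_level_on_label_randomized_cohort(self):
        truth, ppi, train, test = self.setup_data(0.0)
        rng = np.random.default_rng(0)
        shuffled = list(test.labels)
        rng.shuffle(shuffled)
        test_shuffled = ExpressionMatrix(test.entity_ids, test.sample_ids, test.values,
                                         shuffled, normalized=True)
        acc = random_network_baseline(15, truth.rough_true.proteins, ppi, train,
                                      test_shuffled, reps=20, seed=4)
        # 3 standard errors around 50% for 20 x 60 correlated predictions
        assert 30.0 < acc < 70.0

    def test_deterministic_under_seed(self):
        truth, ppi, train, test = self.setup_data(0.5)
        a1 = random_network_baseline(10, truth.rough_true.proteins, ppi, train, test,
                                     reps=1, seed=8)
        a2 = random_network_baseline(10, truth.rough_true.proteins, ppi, train, test,
                                     reps=1, seed=8)
        assert a1 == a2

    def test_true_network_beats_random_baseline(self):
        truth, ppi, train, test = self.setup_data(0.0)
        cpan = build_association_network(truth.rough_true, train, CANCER)
        npan = build_association_network(truth.rough_true, train, NONCANCER)
        acc_true = evaluate(classify(test, cpan, npan)).accuracy
        acc_rand = random_network_baseline(15, truth.rough_true.proteins, ppi, train,
                                           test, reps=20, seed=5)
        assert acc_true > acc_rand

    def test_oversized_pool_rejected(self):
        truth, ppi, train, test = self.setup_data(0.5)
        with pytest.raises(ContractError):
            random_network_baseline(10_000, truth.rough_true.proteins, ppi, train,
                                    test, reps=1, seed=0)


class TestCrossValidate:
    def make_cohort(self, shared, mean_shift, seed=3):
        truth = generate_network_pair(40, 80, shared, seed=seed)
        xc = simulate_expression(truth, CANCER, 60, 0.1, seed + 1, mean_shift=mean_shift)
        xn = simulate_expression(truth, NONCANCER, 60, 0.1, seed + 2)
        return truth, combine_cohorts(xc, xn)

    def test_distinct_networks_beat_chance(self):
        truth, x = self.make_cohort(0.0, mean_shift=0.3)
        _, mean = cross_validate(x, ppi_from_truth(truth), folds=3, seed=9)
        assert mean.accuracy >= 60.0

    def test_null_cohort_has_no_differential_pool(self):
        # with identical generators and no shift there are no differential
        # proteins, so the pipeline correctly refuses to build a pool
        truth, x = self.make_cohort(1.0, mean_shift=0.0)
        with pytest.raises(PipelineError):
            cross_validate(x, ppi_from_truth(truth), folds=3, seed=9)

    def test_deterministic_under_seed(self):
        truth, x = self.make_cohort(0.0, mean_shift=0.3)
        per1, mean1 = cross_validate(x, ppi_from_truth(truth), folds=3, seed=4)
        per2, mean2 = cross_validate(x, ppi_from_truth(truth), folds=3, seed=4)
        assert mean1 == mean2
        assert per1 == per2

    def test_invalid_folds_rejected(self):
        truth, x = self.make_cohort(0.0, mean_shift=0.3)
        with pytest.raises(ContractError):
            cross_validate(x, ppi_from_truth(truth), folds=1, seed=0)
        with pytest.raises(ContractError):
            cross_validate(x, ppi_from_truth(truth), folds=10_000, seed=0)


class TestCohortSimilarity:
    def test_identical_samples(self):
        col = np.array([1.0, 2.0, 5.0, -1.0])
        vals = np.column_stack([col] * 4)
        x = ExpressionMatrix([f"G{i}" for i in range(4)], [f"s{i}" for i in range(4)],
                             vals, [CANCER, CANCER, NONCANCER, NONCANCER])
        r_c, r_n, r_all = cohort_similarity(x)
        assert r_c == pytest.approx(1.0)
        assert r_n == pytest.approx(1.0)
        assert r_all == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        col = np.array([1.0, 2.0, 5.0, -1.0])
        vals = np.column_stack([col, -col, col, -col])
        x = ExpressionMatrix([f"G{i}" for i in range(4)], [f"s{i}" for i in range(4)],
                             vals, [CANCER, CANCER, NONCANCER, NONCANCER])
        r_c, _, _ = cohort_similarity(x)
        assert r_c == pytest.approx(-1.0)

    def test_independent_gaussian_near_zero(self):
        rng = np.random.default_rng(5)
        n_genes = 1000
        vals = rng.normal(size=(n_genes, 10))
        x = ExpressionMatrix([f"G{i}" for i in range(n_genes)],
                             [f"s{i}" for i in range(10)], vals,
                             [CANCER] * 5 + [NONCANCER] * 5)
        r_c, r_n, r_all = cohort_similarity(x)
        bound = 3.0 / np.sqrt(n_genes)
        assert abs(r_c) < bound and abs(r_n) < bound and abs(r_all) < bound

    def test_small_group_rejected(self):
        x = make_matrix({"A": [1.0, 2.0, 3.0], "B": [1.0, 0.0, 2.0]},
                        labels=[CANCER, NONCANCER, NONCANCER], normalized=False)
        with pytest.raises(ContractError):
            cohort_similarity(x)
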