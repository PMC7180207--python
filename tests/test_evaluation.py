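"""ARI/NMI correctness (brute-force + reference cross-checks) and harnesses."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn import metrics as skm

from scdmfk.data_io import CountMatrix, LabelVector, ValidationError
from scdmfk.evaluation import (
    adjusted_rand_index,
    contingency_table,
    downsample_experiment,
    k_perturbation,
    mask_experiment,
    metric_report,
    normalized_mutual_info,
)


def brute_force_ari(truth, pred):
    """Pair-counting ARI computed by explicit enumeration of all pairs."""
    n = len(truth)
    both = same_t = same_p = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        pairs += 1
        t = truth[i] == truth[j]
        p = pred[i] == pred[j]
        both += t and p
        same_t += t
        same_p += p
    expected = same_t * same_p / pairs
    max_index = 0.5 * (same_t + same_p)
    return (both - expected) / (max_index - expected)


class TestARI:
    def test_identical(self):
        assert adjusted_rand_index([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_relabeling_invariance(self):
        truth = [0, 0, 1, 1, 2, 2]
        assert adjusted_rand_index(truth, ["b", "b", "c", "c", "a", "a"]) == 1.0

    def test_six_cell_example_brute_force(self):
        truth = [0, 0, 1, 1, 2, 2]
        pred = [0, 0, 1, 2, 2, 2]
        assert adjusted_rand_index(truth, pred) == pytest.approx(
            brute_force_ari(truth, pred), abs=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            adjusted_rand_index([0, 1], [0, 1, 2])

    def test_random_permutation_centered_at_zero(self):
        rng = np.random.default_rng(0)
        truth = np.repeat(np.arange(4), 25)
        vals = [
            adjusted_rand_index(truth, rng.permutation(truth)) for _ in range(200)
        ]
        assert abs(np.mean(vals)) < 0.01


class TestNMI:
    def test_identical(self):
        assert normalized_mutual_info([0, 1, 0, 1], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_independent_partitions(self):
        # product contingency: every (t, p) combination equally often
        truth = [0, 0, 1, 1] * 3
        pred = [0, 1] * 6
        assert normalized_mutual_info(truth, pred) == pytest.approx(0.0, abs=1e-12)

    def test_six_cell_example_hand_entropy(self):
        truth = [0, 0, 1, 1, 2, 2]
        pred = [0, 0, 1, 2, 2, 2]
        C = contingency_table(truth, pred).astype(float)
        n = 6.0
        h_t = -sum(r / n * np.log(r / n) for r in C.sum(1))
        h_p = -sum(c / n * np.log(c / n) for c in C.sum(0))
        mi = sum(
            C[i, j] / n * np.log(C[i, j] * n / (C.sum(1)[i] * C.sum(0)[j]))
            for i in range(3)
            for j in range(3)
            if C[i, j] > 0
        )
        assert normalized_mutual_info(truth, pred) == pytest.approx(
            mi / (0.5 * (h_t + h_p)), abs=1e-12
        )

    def test_single_cluster_conventions(self):
        assert normalized_mutual_info([0, 0, 0], [0, 0, 0]) == 1.0
        assert normalized_mutual_info([0, 0, 0], [0, 1, 2]) == 0.0


class TestAgainstReference:
    @settings(deadline=None, max_examples=100)
    @given(seed=st.integers(0, 10_000))
    def test_matches_scikit_learn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        truth = rng.integers(0, 4, size=n)
        pred = rng.integers(0, 5, size=n)
        assert adjusted_rand_index(truth, pred) == pytest.approx(
            skm.adjusted_rand_score(truth, pred), abs=1e-10
        )
        assert normalized_mutual_info(truth, pred) == pytest.approx(
            skm.normalized_mutual_info_score(truth, pred, average_method="arithmetic"),
            abs=1e-10,
        )

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_relabeling_invariance_property(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 3, size=30)
        pred = rng.integers(0, 3, size=30)
        relabel = rng.permutation(3)
        assert adjusted_rand_index(truth, pred) == pytest.approx(
            adjusted_rand_index(relabel[truth], pred), abs=1e-12
        )
        assert normalized_mutual_info(truth, pred) == pytest.approx(
            normalized_mutual_info(truth, relabel[pred]), abs=1e-12
        )


def test_metric_report_contingency_sums():
    truth = [0, 0, 1, 1, 2, 2]
    pred = [0, 0, 1, 2, 2, 2]
    rep = metric_report(truth, pred)
    assert rep.contingency.sum() == rep.n_cells == 6


# -- harnesses on a tiny synthetic dataset (fast pipeline settings) -----------

FAST = dict(
    n_top_genes=100,
    pretrain_epochs=40,
    max_epochs=10,
    seed=0,
)


@pytest.fixture(scope="module")
def tiny_dataset():
    from scdmfk.simulator import SimParams, simulate

    sim = simulate(
        SimParams(
            n_groups=3,
            cells_per_group=[60, 60, 60],
            n_genes=250,
            de_fac_scale=0.5,
            de_fac_loc=0.3,
            dropout=False,
            seed=2,
        )
    )
    return sim.counts, sim.labels


def test_downsample_subset_sizes_and_reports(tiny_dataset):
    counts, labels = tiny_dataset
    reports = downsample_experiment(
        counts, labels, fraction=0.5, reps=2, pipeline_config=FAST, seed=1
    )
    assert len(reports) == 2
    for rep in reports:
        assert rep.n_cells == 90  # round(0.5 * 180)
        assert -1.0 <= rep.ari <= 1.0


def test_mask_experiment_masks_only_nonzeros(tiny_dataset):
    counts, labels = tiny_dataset
    reports = mask_experiment(
        counts, labels, prob=0.15, reps=1, pipeline_config=FAST, seed=3
    )
    assert len(reports) == 1
    assert reports[0].n_cells == 180


def test_mask_zero_prob_identity(tiny_dataset):
    """prob=0 reproduces the plain run exactly (same seed, same pipeline)."""
    from scdmfk.pipeline import run_pipeline

    counts, labels = tiny_dataset
    plain = run_pipeline(counts, 3, **FAST).labels
    masked = mask_experiment(
        counts, labels, prob=0.0, reps=1, pipeline_config=FAST, seed=4
    )
    # masked run's ARI vs truth equals plain run's ARI vs truth
    assert masked[0].ari == pytest.approx(
        metric_report(labels.labels, plain).ari, abs=1e-12
    )


def test_k_perturbation_table(tiny_dataset):
    """One row per valid K in {k-2..k+2}; the true-K row equals a plain run;
    the true K scores at least as well as a badly under-specified K."""
    from scdmfk.evaluation import k_perturbation
    from scdmfk.pipeline import run_pipeline

    counts, labels = tiny_dataset
    table = k_perturbation(counts, labels, true_k=3, pipeline_config=FAST)
    assert set(table) == {1, 2, 3, 4, 5}
    plain = run_pipeline(counts, 3, **FAST).labels
    assert table[3].ari == pytest.approx(
        metric_report(labels.labels, plain).ari, abs=1e-12
    )
    assert table[3].ari >= table[1].ari


def test_k_perturbation_skips_invalid_k(tiny_dataset):
    counts, labels = tiny_dataset
    with pytest.warns(UserWarning):
        table = k_perturbation(
            counts, labels, true_k=2,
            pipeline_config={**FAST, "pretrain_epochs": 5, "max_epochs": 1},
        )
    assert set(table) == {1, 2, 3, 4}


def test_mask_fraction_binomial(tiny_dataset):
    counts, _ = tiny_dataset
    rng = np.random.default_rng(5)
    dense = counts.dense()
    mask = (dense > 0) & (rng.random(dense.shape) < 0.15)
    frac = mask.sum() / (dense > 0).sum()
    assert frac == pytest.approx(0.15, abs=0.01)
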