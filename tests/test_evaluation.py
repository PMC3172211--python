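import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from mannosite.datasets import PatternDataset
from mannosite.evaluation import (
    ConfusionCounts,
    UndefinedMetricWarning,
    confusion_at_threshold,
    five_fold_cv,
    metrics_from_counts,
    metrics_from_rates,
    roc_auc,
    round_half_up,
)
from mannosite.model import SvmConfig
from mannosite.patterns import Pattern


class TestMetricsFromCounts:
    def test_chance_level_gives_zero_mcc(self):
        sen, spe, acc, mcc = metrics_from_counts(ConfusionCounts(5, 5, 5, 5))
        assert (sen, spe, acc, mcc) == (50.0, 50.0, 50.0, 0.0)

    def test_perfect_separation(self):
        sen, spe, acc, mcc = metrics_from_counts(ConfusionCounts(10, 0, 30, 0))
        assert (sen, spe, acc) == (100.0, 100.0, 100.0)
        assert mcc == pytest.approx(1.0)

    def test_degenerate_denominator_mcc_zero(self):
        # everything predicted positive: tn+fn factor is 0
        *_, mcc = metrics_from_counts(ConfusionCounts(10, 10, 0, 0))
        assert mcc == 0.0

    def test_empty_class_flags_undefined(self):
        with pytest.warns(UndefinedMetricWarning):
            sen, *_ = metrics_from_counts(ConfusionCounts(0, 3, 7, 0))
        assert np.isnan(sen)

    def test_label_swap_negates_mcc(self):
        c = ConfusionCounts(tp=8, fp=3, tn=12, fn=2)
        swapped = ConfusionCounts(tp=c.fn, fp=c.tn, tn=c.fp, fn=c.tp)
        assert metrics_from_counts(swapped)[3] == pytest.approx(
            -metrics_from_counts(c)[3]
        )


class TestMetricsFromRates:
    @pytest.mark.parametrize(
        "sen,spe,n_pos,n_neg,acc,mcc",
        [
            (77.03, 82.89, 1029, 1029, 79.96, 0.60),
            (80.37, 92.91, 1029, 1029, 86.64, 0.74),
            (73.51, 57.80, 1029, 1029, 65.66, 0.32),
            (80.27, 89.89, 1029, 10320, 89.02, 0.54),
        ],
    )
    def test_reconstructs_published_style_cells(self, sen, spe, n_pos, n_neg, acc, mcc):
        got_acc, got_mcc = metrics_from_rates(sen, spe, n_pos, n_neg)
        assert round_half_up(got_acc) == acc
        assert round_half_up(got_mcc) == mcc

    def test_perfect_rates(self):
        acc, mcc = metrics_from_rates(100, 100, 50, 500)
        assert acc == 100.0 and mcc == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_rates(101, 50, 10, 10)


class TestRocAuc:
    def test_constant_scores_auc_half(self):
        _, auc = roc_auc([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3])
        assert auc == pytest.approx(0.5)

    def test_perfect_ranking_auc_one(self):
        _, auc = roc_auc([0, 0, 1, 1], [-2.0, -1.0, 0.5, 3.0])
        assert auc == pytest.approx(1.0)

    def test_matches_rank_statistic_and_sklearn(self):
        rng = np.random.default_rng(12)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]  # both classes present
        scores = rng.normal(size=30) + labels
        _, auc = roc_auc(labels, scores)
        n_pos, n_neg = labels.sum(), (1 - labels).sum()
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert auc == pytest.approx(u / (n_pos * n_neg), abs=1e-9)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        labels = np.r_[np.ones(10), np.zeros(15)].astype(int)
        scores = rng.normal(size=25)
        _, a = roc_auc(labels, scores)
        _, b = roc_auc(labels, np.exp(3 * scores) + 7)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.1, 0.2])


def dataset_from_arrays(windows, labels, window=17):
    pats = [
        Pattern(window=w, positive=bool(l), source=("c", i + 1))
        for i, (w, l) in enumerate(zip(windows, labels))
    ]
    return PatternDataset(
        patterns=pats,
        n_pos=int(sum(labels)),
        n_neg=int(len(labels) - sum(labels)),
        window=window,
        seed=0,
    )


@pytest.fixture()
def separable_dataset():
    # composition alone separates: positives S/T-rich, negatives A/V-rich
    rng = np.random.default_rng(6)
    windows, labels = [], []
    for _ in range(40):
        windows.append("".join(rng.choice(list("STNDY"), size=17)))
        labels.append(1)
        windows.append("".join(rng.choice(list("AVLIK"), size=17)))
        labels.append(0)
    return dataset_from_arrays(windows, labels)


class TestFiveFold:
    def test_folds_partition_dataset_stratified(self, separable_dataset):
        report = five_fold_cv(separable_dataset, "cpp", SvmConfig(g=5, c=2, j=1))
        assert len(report.fold_rows) == len(report.fold_sizes) == 5
        pos_sizes = [p for p, _ in report.fold_sizes]
        neg_sizes = [n for _, n in report.fold_sizes]
        # folds are disjoint and cover the dataset ...
        assert sum(pos_sizes) == separable_dataset.n_pos
        assert sum(neg_sizes) == separable_dataset.n_neg
        # ... and are stratified: per-class sizes differ by at most one
        assert max(pos_sizes) - min(pos_sizes) <= 1
        assert max(neg_sizes) - min(neg_sizes) <= 1

    def test_separable_dataset_near_perfect_at_zero(self, separable_dataset):
        report = five_fold_cv(separable_dataset, "cpp", SvmConfig(g=5, c=2, j=1))
        sen, spe, acc, mcc = report.averaged[0.0]
        assert acc > 99.0
        assert mcc > 0.95

    def test_threshold_sweep_monotone(self, separable_dataset):
        report = five_fold_cv(separable_dataset, "cpp", SvmConfig(g=5))
        sens = [report.pooled[t][0] for t in report.thresholds]
        spes = [report.pooled[t][1] for t in report.thresholds]
        assert all(a >= b - 1e-9 for a, b in zip(sens, sens[1:]))
        assert all(b >= a - 1e-9 for a, b in zip(spes, spes[1:]))

    def test_averaged_close_to_pooled(self, separable_dataset):
        report = five_fold_cv(separable_dataset, "cpp", SvmConfig(g=5, c=2, j=1))
        for t in (0.0, 0.3):
            assert report.averaged[t][2] == pytest.approx(
                report.pooled[t][2], abs=1.0
            )

    def test_too_few_patterns_per_class_rejected(self):
        ds = dataset_from_arrays(["A" * 17] * 6, [1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError, match="at least"):
            five_fold_cv(ds, "cpp", SvmConfig())


class TestReportOutput:
    def test_tsv_and_json_round_numbers(self, separable_dataset, tmp_path):
        report = five_fold_cv(separable_dataset, "cpp", SvmConfig(g=5))
        report.to_tsv(tmp_path / "r.tsv")
        report.to_json(tmp_path / "r.json")
        report.roc_to_csv(tmp_path / "r.csv")
        lines = (tmp_path / "r.tsv").read_text().splitlines()
        assert lines[1].split("\t") == ["threshold", "sen", "spe", "acc", "mcc"]
        assert len(lines) == 2 + len(report.thresholds)

    def test_round_half_up_matches_table_convention(self):
        assert round_half_up(79.955) == 79.96
        assert round_half_up(0.595) == 0.6
        assert round_half_up(-0.125) == -0.13
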