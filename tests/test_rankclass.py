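"""Mutual information, mRMR ranking, SVM cross-validation and taxonomy
collapse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dermprof import (
    SKIN_TAXONOMY,
    collapse_taxonomy,
    incremental_curves,
    knn_mutual_information,
    mrmr_rank,
    svm_cross_validate,
)
from dermprof.rankclass import MRMRRanker


class TestMutualInformation:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_independent_continuous_near_zero(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=2000), rng.normal(size=2000)
        assert knn_mutual_information(x, y, discrete_y=False) < 0.02

    @pytest.mark.parametrize("seed", [0, 1])
    def test_independent_discrete_near_zero(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=2000)
        y = rng.choice(["a", "b", "c"], size=2000)
        assert knn_mutual_information(x, y, discrete_y=True) < 0.02

    def test_bivariate_gaussian_closed_form(self):
        rho, n = 0.9, 5000
        rng = np.random.default_rng(3)
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        expected = -0.5 * np.log(1 - rho**2)  # 0.8303 nats
        assert knn_mutual_information(x, y, discrete_y=False) == pytest.approx(
            expected, abs=0.05
        )

    def test_disjoint_classes_reach_label_entropy(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(20, 1, 100)])
        y = np.array(["lo"] * 100 + ["hi"] * 100)
        assert knn_mutual_information(x, y, discrete_y=True) == pytest.approx(
            np.log(2), abs=0.05
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=1500)
        y = 0.8 * x + 0.6 * rng.normal(size=1500)
        base = knn_mutual_information(x, y, discrete_y=False)
        warped = knn_mutual_information(np.exp(x), y, discrete_y=False)
        assert abs(base - warped) < 0.02

    def test_matches_sklearn_discrete_estimator(self):
        from sklearn.feature_selection import mutual_info_classif

        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 1, 150), rng.normal(1.5, 1, 150)])
        y = np.array([0] * 150 + [1] * 150)
        ours = knn_mutual_information(x, y, k=3, discrete_y=True)
        ref = float(
            mutual_info_classif(
                x[:, None], y, n_neighbors=3, discrete_features=False, random_state=0
            )[0]
        )
        assert ours == pytest.approx(ref, abs=0.03)

    def test_small_class_reduces_k_with_warning(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=23)
        y = np.array(["a"] * 20 + ["b"] * 3)
        with pytest.warns(UserWarning, match="k reduced"):
            value = knn_mutual_information(x, y, k=3, discrete_y=True)
        assert value >= 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            knn_mutual_information([1.0, 2.0], [1.0, 2.0], k=3)
        with pytest.raises(ValueError):
            knn_mutual_information([1.0] * 10, [1.0] * 9)


class TestMRMR:
    def test_singleton_gene_ranked_first(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(1, 40)), index=["only"],
                            columns=[f"s{i}" for i in range(40)])
        labels = ["a"] * 20 + ["b"] * 20
        assert mrmr_rank(expr, labels).order == ["only"]

    def test_first_gene_maximizes_relevance(self):
        rng = np.random.default_rng(1)
        labels = np.array(["a"] * 30 + ["b"] * 30)
        informative = np.where(labels == "a", 0.0, 4.0) + rng.normal(0, 1, 60)
        noise = rng.normal(size=(4, 60))
        expr = pd.DataFrame(np.vstack([noise[:2], informative, noise[2:]]),
                            index=["n1", "n2", "sig", "n3", "n4"],
                            columns=[f"s{i}" for i in range(60)])
        res = mrmr_rank(expr, labels)
        assert res.order[0] == "sig"
        assert res.relevance["sig"] == max(res.relevance.values())

    def test_greedy_sequence_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        labels = np.array(["a"] * 25 + ["b"] * 25)
        x = rng.normal(size=(5, 50))
        x[0] += np.where(labels == "a", 0, 3)
        x[1] = x[0] + rng.normal(0, 0.1, 50)  # redundant copy
        x[2] += np.where(labels == "a", 0, 1.5)
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(50)])
        res = mrmr_rank(expr, labels, jitter_seed=0)

        # oracle: re-evaluate the mRMR objective exhaustively at every step
        genes = list(expr.index)
        rel = {
            g: knn_mutual_information(
                expr.loc[g].to_numpy(), labels, discrete_y=True,
                jitter_seed=0 + genes.index(g),
            )
            for g in genes
        }

        def red(a, b):
            i, j = sorted([genes.index(a), genes.index(b)])
            return knn_mutual_information(
                expr.iloc[i].to_numpy(), expr.iloc[j].to_numpy(),
                discrete_y=False, jitter_seed=0 + 7919 + i * len(genes) + j,
            )

        selected = []
        remaining = sorted(genes)
        while remaining:
            scores = {
                g: rel[g]
                - (np.mean([red(g, s) for s in selected]) if selected else 0.0)
                for g in remaining
            }
            best = max(sorted(scores), key=lambda g: scores[g])
            selected.append(best)
            remaining.remove(best)
        assert res.order == selected

    def test_redundant_duplicates_deprioritized(self):
        rng = np.random.default_rng(3)
        labels = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        shifts = {"a": 0.0, "b": 3.0, "c": 6.0}
        base = np.vstack([
            np.array([shifts[l] for l in labels]) * w + rng.normal(0, 0.7, 90)
            for w in (1.0, -1.0, 0.8, -0.6, 1.2)
        ])
        dupes = base + rng.normal(0, 0.01, base.shape)
        noise = rng.normal(size=(40, 90))
        expr = pd.DataFrame(
            np.vstack([base, dupes, noise]),
            index=[f"info{i}" for i in range(5)]
            + [f"dup{i}" for i in range(5)]
            + [f"noise{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(90)],
        )
        res = mrmr_rank(expr, labels, jitter_seed=1)
        top5 = res.order[:5]
        pairs = [(f"info{i}", f"dup{i}") for i in range(5)]
        assert not any(a in top5 and b in top5 for a, b in pairs)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(6, 40)),
                            index=[f"g{i}" for i in range(6)],
                            columns=[f"s{i}" for i in range(40)])
        labels = ["a"] * 20 + ["b"] * 20
        assert mrmr_rank(expr, labels, jitter_seed=5).order == mrmr_rank(
            expr, labels, jitter_seed=5
        ).order


class TestSVMCrossValidation:
    def _blobs(self, n_per=15, spread=0.3, n_classes=2, seed=0):
        rng = np.random.default_rng(seed)
        parts, labels = [], []
        for c in range(n_classes):
            parts.append(rng.normal(5 * c, spread, size=(3, n_per)))
            labels += [f"C{c}"] * n_per
        expr = pd.DataFrame(np.hstack(parts), index=["g1", "g2", "g3"],
                            columns=[f"s{i}" for i in range(n_per * n_classes)])
        return expr, np.array(labels)

    def test_separable_blobs_perfect_kfold_accuracy(self):
        expr, labels = self._blobs()
        entry = svm_cross_validate(expr, labels, scheme="kfold")
        assert entry.accuracy == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(5, 210)),
                            index=[f"g{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(210)])
        labels = np.repeat([f"C{i}" for i in range(7)], 30)
        entry = svm_cross_validate(expr, rng.permutation(labels), scheme="kfold")
        assert abs(entry.accuracy - 1 / 7) < 0.05

    @pytest.mark.parametrize("scheme", ["kfold", "loo"])
    def test_confusion_total_conserved(self, scheme):
        expr, labels = self._blobs(n_per=8, spread=2.0, n_classes=3, seed=2)
        entry = svm_cross_validate(expr, labels, scheme=scheme)
        assert entry.confusion.to_numpy().sum() == len(labels)

    def test_empty_subset_rejected(self):
        expr, labels = self._blobs()
        with pytest.raises(ValueError, match="non-empty"):
            svm_cross_validate(expr, labels, gene_subset=[])


class TestTaxonomyCollapse:
    def test_printed_diagonal_counts(self):
        counts = {"BCC": 43, "SCC": 84, "MCC": 33, "PRIMEL": 118,
                  "METMEL": 118, "NSK": 250, "NEV": 32}
        confusion = pd.DataFrame(np.diag(list(counts.values())),
                                 index=list(counts), columns=list(counts))
        three, acc3 = collapse_taxonomy(confusion, SKIN_TAXONOMY.three_class)
        assert three.loc["carcinoma", "carcinoma"] == 160
        assert three.loc["melanoma", "melanoma"] == 236
        assert three.loc["healthy", "healthy"] == 282
        two, acc2 = collapse_taxonomy(three, SKIN_TAXONOMY.two_class)
        assert two.loc["tumor", "tumor"] == 396
        assert two.loc["healthy", "healthy"] == 282
        assert acc3 == 1.0 and acc2 == 1.0

    def test_unmapped_label_rejected(self):
        confusion = pd.DataFrame([[1]], index=["XXX"], columns=["XXX"])
        with pytest.raises(ValueError, match="XXX"):
            collapse_taxonomy(confusion, SKIN_TAXONOMY.three_class)

    def test_composition_gives_two_class_map(self):
        composed = SKIN_TAXONOMY.composed_two_class()
        assert composed == {
            "BCC": "tumor", "SCC": "tumor", "MCC": "tumor",
            "PRIMEL": "tumor", "METMEL": "tumor",
            "NSK": "healthy", "NEV": "healthy",
        }

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.integers(0, 20), min_size=49, max_size=49))
    def test_collapse_conserves_totals_and_never_decreases_accuracy(self, cells):
        labels = list(SKIN_TAXONOMY.three_class)
        confusion = pd.DataFrame(
            np.asarray(cells).reshape(7, 7), index=labels, columns=labels
        )
        total = confusion.to_numpy().sum()
        if total == 0:
            return
        acc7 = np.trace(confusion.to_numpy()) / total
        three, acc3 = collapse_taxonomy(confusion, SKIN_TAXONOMY.three_class)
        two, acc2 = collapse_taxonomy(three, SKIN_TAXONOMY.two_class)
        assert three.to_numpy().sum() == total == two.to_numpy().sum()
        assert acc3 >= acc7 - 1e-12
        assert acc2 >= acc3 - 1e-12


class TestIncrementalCurves:
    def test_curves_shape_and_separable_limit(self):
        rng = np.random.default_rng(5)
        labels = np.array(["a"] * 12 + ["b"] * 14 + ["c"] * 16)
        x = np.vstack([
            np.where(labels == "a", 0, 4) + rng.normal(0, 0.3, 42),
            np.where(labels == "c", 4, 0) + rng.normal(0, 0.3, 42),
            rng.normal(size=42),
        ])
        expr = pd.DataFrame(x, index=["g1", "g2", "g3"],
                            columns=[f"s{i}" for i in range(42)])
        ranking = mrmr_rank(expr, labels)
        report = incremental_curves(expr, labels, ranking, schemes=("kfold",))
        table = report.curve_table()
        assert len(table) == 3
        best = table["accuracy_7class"].max()
        assert best == 1.0  # separable at some k <= full
        assert table.loc[table.n_genes == 1, "accuracy_7class"].iloc[0] <= best
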