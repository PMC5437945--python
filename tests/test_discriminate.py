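import numpy as np
import pandas as pd
import pytest

from leafmorph.discriminate import (
    LeaveOneOutLDA,
    confusion_matrix,
    feature_set_comparison,
    fit_lda,
    loo_predict,
    node_rank_rho,
)


class TestFitLDA:
    def test_two_gaussian_classes_boundary_at_midpoint(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)])[:, None]
        y = np.array(["a"] * 50 + ["b"] * 50)
        model = fit_lda(x, y)
        grid = np.linspace(0, 10, 2001)[:, None]
        pred = model.predict(grid)
        boundary = grid[np.argmax(pred == "b"), 0]
        assert boundary == pytest.approx(5.0, abs=0.5)

    def test_duplicate_trait_column_tolerated(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(40, 3))
        df = pd.DataFrame(np.hstack([base, base[:, :1]]), columns=["a", "b", "c", "dup"])
        y = ["u"] * 20 + ["v"] * 20
        df.iloc[20:, 0] += 6.0
        model = fit_lda(df, y)  # collinear columns handled by the SVD solver
        assert model.score(df, y) > 0.9

    def test_singleton_class_rejected(self):
        x = np.arange(10, dtype=float)[:, None]
        y = ["a"] * 9 + ["b"]
        with pytest.raises(ValueError, match="b"):
            fit_lda(x, y)

    def test_all_constant_traits_rejected(self):
        x = np.ones((10, 3))
        y = ["a"] * 5 + ["b"] * 5
        with pytest.raises(ValueError, match="(?i)constant"):
            fit_lda(x, y)

    def test_priors_are_class_frequencies(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 2))
        y = ["a"] * 10 + ["b"] * 20
        model = fit_lda(x, y)
        np.testing.assert_allclose(sorted(model.priors_), [1 / 3, 2 / 3])


class TestLooPredict:
    def test_well_separated_classes(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(10, 1, (30, 3))])
        y = ["a"] * 30 + ["b"] * 30
        res = loo_predict(x, y)
        acc = float((res["predicted"] == res["actual"]).mean())
        assert acc >= 0.98
        # posteriors are proper probabilities
        probs = res[[c for c in res.columns if c.startswith("p_")]].to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_permuted_labels_are_chance_level(self):
        """With labels shuffled, LOO accuracy over 4 balanced classes must sit
        at chance (0.25), averaged over replicates."""
        from scipy.stats import binomtest

        rng = np.random.default_rng(4)
        n, k = 200, 4
        accs, rejections = [], 0
        for _ in range(20):
            x = rng.normal(size=(n, 5))
            y = np.repeat([f"c{i}" for i in range(k)], n // k)
            rng.shuffle(y)
            res = loo_predict(pd.DataFrame(x), y)
            correct = int((res["predicted"] == res["actual"]).sum())
            accs.append(correct / n)
            if binomtest(correct, n, 1 / k).pvalue < 0.01:
                rejections += 1
        assert np.mean(accs) == pytest.approx(0.25, abs=0.08)
        assert rejections <= 4  # chance-level: few replicates reject H0 at 1%

    def test_smallest_valid_input(self):
        x = np.array([[0.0], [0.1], [5.0], [5.1]])
        y = ["a", "a", "b", "b"]
        res = loo_predict(x, y)
        assert len(res) == 4

    def test_accuracy_invariant_to_column_rescaling(self, default_traits):
        meta, lm, _ = default_traits
        sub = lm.iloc[:80]
        labels = meta["species"].iloc[:80]
        base = loo_predict(sub, labels)
        scaled = sub.copy()
        scaled["x3"] = scaled["x3"] * 1000.0 - 7.0
        alt = loo_predict(scaled, labels)
        assert (base["predicted"] == alt["predicted"]).mean() == pytest.approx(1.0, abs=1e-6)

    def test_node_prediction_degrades_when_gradient_flattens(self):
        """A heteroblastic gradient that saturates with node index makes late
        nodes near-indistinguishable: their LOO recall must drop below that of
        the early nodes."""
        from leafmorph.procrustes import GeneralizedProcrustesAlignment
        from leafmorph.synth import LeafParams, synth_leaf

        rng = np.random.default_rng(5)
        configs, nodes = [], []
        for node in range(1, 9):
            depth = 0.15 + 0.35 * np.sqrt((node - 1) / 7.0)  # flattening profile
            for _ in range(12):
                p = LeafParams(
                    distal_sinus_depth=float(np.clip(depth + rng.normal(0, 0.02), 0, 0.9))
                )
                lm, _ = synth_leaf(p)
                configs.append(lm)
                nodes.append(node)
        est = GeneralizedProcrustesAlignment()
        traits = pd.DataFrame(est.fit_transform(np.stack(configs)),
                              columns=est.get_feature_names_out())
        res = loo_predict(traits, nodes)
        correct = (res["predicted"] == res["actual"]).to_numpy()
        nodes = np.asarray(nodes)
        early = correct[nodes <= 4].mean()
        late = correct[nodes >= 5].mean()
        assert early > late


class TestConfusionMatrix:
    def test_row_normalization(self):
        cm = confusion_matrix(["A", "A", "B"], ["A", "B", "B"])
        np.testing.assert_allclose(cm.proportions.loc["A"], [0.5, 0.5])
        np.testing.assert_allclose(cm.proportions.loc["B"], [0.0, 1.0])

    def test_perfect_prediction_is_identity(self):
        y = ["a", "b", "c", "a", "b", "c"]
        cm = confusion_matrix(y, y)
        np.testing.assert_allclose(cm.proportions.to_numpy(), np.eye(3))
        assert cm.accuracy() == 1.0

    def test_predicted_only_label_gets_column(self):
        cm = confusion_matrix(["a", "a", "b", "b"], ["a", "z", "b", "b"])
        assert "z" in cm.proportions.columns
        assert "z" not in cm.proportions.index
        np.testing.assert_allclose(cm.proportions.sum(axis=1), 1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_matrix(["a"], ["a", "b"])


class TestNodeRankRho:
    def test_identity(self):
        nodes = np.arange(1, 11)
        rho, p = node_rank_rho(nodes, nodes)
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_reversed(self):
        nodes = np.arange(1, 11)
        rho, _ = node_rank_rho(nodes, nodes[::-1])
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="(?i)constant"):
            node_rank_rho([1, 2, 3, 4, 5], [2, 2, 2, 2, 2])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            node_rank_rho([1, 2, 3], [1, 2, 3])


class TestFeatureSetComparison:
    def test_identical_informative_sets_tie_to_both(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(40, 2))
        base[20:] += 4.0
        lm = pd.DataFrame(base, columns=["x1", "y1"])
        ef = pd.DataFrame(base.copy(), columns=["A2", "D2"])
        y = ["a"] * 20 + ["b"] * 20
        table = feature_set_comparison(lm, ef, y)
        assert (table["max"] == "both").all()
        assert table["tied"].all()
        assert (table["landmark_pct"] == table["efd_pct"]).all()

    def test_landmark_only_signal_favors_landmarks(self):
        """Species differing only in a landmark-visible feature (vein width)
        must be better discriminated by landmark traits than by EFD traits of
        outlines that do not carry the vein."""
        from leafmorph.efd import EllipticalFourierFeaturizer
        from leafmorph.procrustes import GeneralizedProcrustesAlignment
        from leafmorph.synth import LeafParams, synth_leaf

        rng = np.random.default_rng(7)
        configs, outlines, labels = [], [], []
        for sp, width in (("narrow", 0.01), ("wide", 0.05)):
            for _ in range(15):
                p = LeafParams(
                    vein_half_width=width * float(rng.uniform(0.9, 1.1)),
                    distal_sinus_depth=float(np.clip(rng.normal(0.35, 0.01), 0, 0.9)),
                )
                lmk, outl = synth_leaf(p)
                configs.append(lmk)
                outlines.append(outl)
                labels.append(sp)
        gpa_est = GeneralizedProcrustesAlignment()
        lm = pd.DataFrame(gpa_est.fit_transform(np.stack(configs)),
                          columns=gpa_est.get_feature_names_out())
        feat = EllipticalFourierFeaturizer(n_harmonics=10, n_resample=300)
        ef = pd.DataFrame(feat.fit_transform(outlines),
                          columns=feat.get_feature_names_out())
        table = feature_set_comparison(lm, ef, labels)
        assert (table["landmark_pct"] > table["efd_pct"]).all()

    def test_singleton_group_excluded_with_warning(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(9, 2))
        lm = pd.DataFrame(x, columns=["x1", "y1"])
        ef = pd.DataFrame(rng.normal(size=(9, 2)), columns=["A2", "B2"])
        y = ["a"] * 4 + ["b"] * 4 + ["solo"]
        with pytest.warns(UserWarning, match="solo"):
            table = feature_set_comparison(lm, ef, y)
        assert "solo" not in table.index

    def test_mismatched_sample_ids_rejected(self):
        lm = pd.DataFrame(np.zeros((4, 1)), columns=["x1"], index=list("abcd"))
        ef = pd.DataFrame(np.zeros((4, 1)), columns=["A2"], index=list("abce"))
        with pytest.raises(ValueError, match="sample ids"):
            feature_set_comparison(lm, ef, ["u", "u", "v", "v"])
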