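import numpy as np
import pytest

import irdecide as ir


class TestTrain:
    def test_two_point_max_margin(self):
        """Hand-solved 2-point problem: standardized values are -+1/sqrt(2);
        the max-margin hyperplane gives d(0) = -1 and d(2) = +1."""
        g1 = ir.make_grid(1000, 1000, 2)
        lab = ir.LabeledSpectra([[0.0], [2.0]], [-1, 1], ["A", "B"], g1)
        eq, svs = ir.train(lab, C=10.0)
        d = ir.decide(eq, lab.spectra)
        assert np.allclose(d, [-1.0, 1.0], atol=1e-6)
        assert np.isclose(eq.bias, 0.0, atol=1e-6)

    def test_duplication_invariance(self, small_labeled):
        # hard-margin data: the decision function is unchanged by duplicating
        # the training rows; agreement is limited by the solver tolerance
        eq1, _ = ir.train(small_labeled, C=10.0, tol=1e-8)
        doubled = ir.LabeledSpectra(
            np.vstack([small_labeled.spectra] * 2),
            np.concatenate([small_labeled.labels] * 2),
            np.concatenate([small_labeled.case_ids] * 2),
            small_labeled.grid,
        )
        eq2, _ = ir.train(doubled, C=10.0, tol=1e-8)
        d1 = ir.decide(eq1, small_labeled.spectra)
        d2 = ir.decide(eq2, small_labeled.spectra)
        assert np.abs(d1 - d2).max() <= 1e-6

    def test_beta_equals_dual_sum(self, small_labeled):
        """The primal weight vector equals sum_i alpha_i y_i scaled-SV_i."""
        eq, svs = ir.train(small_labeled)
        zsv = ir.scale(svs.sv, eq.scaler)
        beta_dual = (svs.alpha * svs.y) @ zsv
        assert np.abs(eq.beta - beta_dual).max() <= 1e-8

    def test_one_class_errors(self, small_labeled):
        one = small_labeled.subset(small_labeled.labels == 1)
        with pytest.raises(ValueError):
            ir.train(one)

    def test_permutation_invariance(self, small_labeled):
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_labeled.n)
        shuffled = ir.LabeledSpectra(
            small_labeled.spectra[perm],
            small_labeled.labels[perm],
            small_labeled.case_ids[perm],
            small_labeled.grid,
        )
        d1 = ir.decide(ir.train(small_labeled, tol=1e-8)[0], small_labeled.spectra)
        d2 = ir.decide(ir.train(shuffled, tol=1e-8)[0], small_labeled.spectra)
        assert np.abs(d1 - d2).max() <= 1e-6


class TestDecide:
    def test_train_mean_gives_bias(self, small_labeled):
        eq, _ = ir.train(small_labeled)
        d = ir.decide(eq, eq.train_mean)
        assert np.isclose(d, eq.bias)

    def test_zero_beta_gives_bias(self, small_labeled):
        eq, _ = ir.train(small_labeled)
        eq.beta = np.zeros_like(eq.beta)
        d = ir.decide(eq, np.random.default_rng(0).normal(size=(5, eq.grid.count)))
        assert np.allclose(d, eq.bias)

    def test_grid_mismatch_errors(self, small_labeled):
        eq, _ = ir.train(small_labeled)
        with pytest.raises(ValueError):
            ir.decide(eq, np.zeros(eq.grid.count + 3))

    def test_dual_and_primal_forms_agree(self, small_labeled):
        """Support-vector (dual) and beta-spectrum (primal) evaluations are
        the same function, algebraically."""
        eq, svs = ir.train(small_labeled)
        rng = np.random.default_rng(1)
        tests = rng.normal(size=(100, eq.grid.count))
        d_primal = ir.decide(eq, tests)
        d_dual = ir.decide_sv_form(svs, eq.scaler, eq.bias, tests)
        assert np.abs(d_primal - d_dual).max() <= 1e-8

    def test_empty_sv_set_gives_bias(self, small_labeled):
        eq, _ = ir.train(small_labeled)
        empty = ir.SupportVectorSet(
            np.empty((0, eq.grid.count)), np.empty(0), np.empty(0, dtype=int)
        )
        d = ir.decide_sv_form(empty, eq.scaler, eq.bias, np.zeros((3, eq.grid.count)))
        assert np.allclose(d, eq.bias)

    def test_single_sv_one_term(self, small_labeled):
        eq, _ = ir.train(small_labeled)
        rng = np.random.default_rng(2)
        sv = rng.normal(size=eq.grid.count)
        test = rng.normal(size=(1, eq.grid.count))
        svs = ir.SupportVectorSet(sv[None, :], [1.0], [1])
        d = ir.decide_sv_form(svs, eq.scaler, eq.bias, test)
        expected = eq.bias + ir.scale(sv, eq.scaler)[0] @ ir.scale(test, eq.scaler)[0]
        assert np.isclose(d[0], expected)


class TestClassMeans:
    def test_single_spectrum_per_class(self):
        g = ir.make_grid(1010, 1000, 2)
        spectra = np.arange(12.0).reshape(2, 6)
        lab = ir.LabeledSpectra(spectra, [1, -1], ["A", "B"], g)
        t, nt = ir.class_means(lab)
        assert np.array_equal(t, spectra[0]) and np.array_equal(nt, spectra[1])

    def test_balanced_duplicates_unchanged(self, small_labeled):
        t1, nt1 = ir.class_means(small_labeled)
        doubled = ir.LabeledSpectra(
            np.vstack([small_labeled.spectra] * 2),
            np.concatenate([small_labeled.labels] * 2),
            np.concatenate([small_labeled.case_ids] * 2),
            small_labeled.grid,
        )
        t2, nt2 = ir.class_means(doubled)
        assert np.allclose(t1, t2) and np.allclose(nt1, nt2)

    def test_missing_class_errors(self, small_labeled):
        with pytest.raises(ValueError):
            ir.class_means(small_labeled.subset(small_labeled.labels == -1))


class TestDecisionContribution:
    def test_equal_means_zero_delta(self, small_labeled):
        eq, _ = ir.train(small_labeled)
        m = small_labeled.spectra.mean(axis=0)
        dcs = ir.decision_contribution(eq, m, m)
        assert np.allclose(dcs.delta, 0)

    def test_conservation(self, small_labeled):
        eq, _ = ir.train(small_labeled)
        t, nt = ir.class_means(small_labeled)
        dcs = ir.decision_contribution(eq, t, nt)
        gap = dcs.d_tumor_mean - dcs.d_nontumor_mean
        assert np.isclose(dcs.delta.sum(), gap, rtol=1e-8, atol=1e-12)

    def test_per_spectrum_conservation(self, small_labeled):
        """Per-step contributions of any single spectrum sum to d_k - b."""
        eq, _ = ir.train(small_labeled)
        x = small_labeled.spectra[3]
        contrib = ir.scale(x, eq.scaler)[0] * eq.beta
        assert np.isclose(contrib.sum(), ir.decide(eq, x) - eq.bias)


class TestTopFeatures:
    def _dcs(self, delta):
        g = ir.make_grid(1000 + 2 * (len(delta) - 1), 1000, 2)
        return ir.DecisionContributionSpectrum(
            g, np.asarray(delta, float), np.zeros(len(delta)), np.zeros(len(delta)), 0, 0
        )

    def test_single_nonzero(self):
        top = ir.top_features(self._dcs([0, 0, 0.5, 0]), 1)
        assert top[0][1] == 0.5

    def test_all_zero_tie_rule(self):
        top = ir.top_features(self._dcs([0.0] * 5), 3)
        wns = [wn for wn, _ in top]
        assert wns == sorted(wns, reverse=True)  # ties -> higher wavenumber first

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        delta = rng.normal(size=40)
        dcs = self._dcs(delta)
        top = ir.top_features(dcs, 10)
        brute = sorted(
            zip(dcs.grid.values.tolist(), delta.tolist()),
            key=lambda t: (-abs(t[1]), -t[0]),
        )[:10]
        assert np.allclose([d for _, d in top], [d for _, d in brute])

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            ir.top_features(self._dcs([0.0] * 5), 6)


class TestEquationFile:
    def test_round_trip_preserves_decisions(self, tmp_path, small_labeled):
        eq, _ = ir.train(small_labeled)
        t, nt = ir.class_means(small_labeled)
        path = tmp_path / "eq.csv"
        ir.export_equation(eq, t, nt, path)
        eq2, t2, nt2 = ir.import_equation(path)
        rng = np.random.default_rng(0)
        tests = rng.normal(size=(50, eq.grid.count))
        assert np.array_equal(ir.decide(eq, tests), ir.decide(eq2, tests))
        assert np.array_equal(t, t2) and np.array_equal(nt, nt2)

    def test_missing_bias_errors(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "wavenumber,train_mean,train_sd,beta,tumor_mean,nontumor_mean\n"
            "1000.0,0.0,1.0,1.0,0.0,0.0\n"
        )
        with pytest.raises(ValueError, match="bias"):
            ir.import_equation(path)

    def test_hand_written_file(self, tmp_path):
        """Pencil-and-paper: d = b + sum_j (x_j - mean_j)/sd_j * beta_j."""
        path = tmp_path / "hand.csv"
        path.write_text(
            "# bias = 0.5\n"
            "wavenumber,train_mean,train_sd,beta,tumor_mean,nontumor_mean\n"
            "1004.0,0.0,1.0,1.0,0.0,0.0\n"
            "1002.0,0.0,1.0,2.0,0.0,0.0\n"
            "1000.0,0.0,1.0,3.0,0.0,0.0\n"
        )
        eq, _, _ = ir.import_equation(path)
        # x = (1,1,1): d = 0.5 + 1 + 2 + 3 = 6.5
        assert np.isclose(ir.decide(eq, np.ones(3)), 6.5)

    def test_malformed_line_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "# bias = 0.0\n"
            "wavenumber,train_mean,train_sd,beta,tumor_mean,nontumor_mean\n"
            "1000.0,0.0,1.0\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            ir.import_equation(path)
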