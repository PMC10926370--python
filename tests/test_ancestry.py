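"""Admixture model: likelihood, EM ascent, recovery, projection, purity."""

import numpy as np
import pytest

from helihybrid import (
    AdmixtureEM, SimConfig, classify_purity, em_step, fit_supervised,
    loglikelihood, panel_frequencies, simulate_dataset,
)

ARM, ZEA = "armigera", "zea"


def brute_force_loglik(G, Q, F):
    """Independent elementwise oracle for the binomial admixture model."""
    total = 0.0
    for i in range(G.shape[0]):
        for j in range(G.shape[1]):
            g = G[i, j]
            if np.isnan(g):
                continue
            p = sum(Q[i, k] * F[k, j] for k in range(Q.shape[1]))
            total += g * np.log(p) + (2 - g) * np.log(1 - p)
    return total


class TestLoglikelihood:
    def test_k1_uniform_frequency_closed_form(self):
        J = 7
        G = np.array([[0.0, 1, 2, 1, 0, 2, 1]])
        Q = np.array([[1.0]])
        F = np.full((1, J), 0.5)
        assert loglikelihood(G, Q, F) == pytest.approx(2 * J * np.log(0.5))

    def test_degenerate_mixture_reduces_to_k1(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, (3, 9)).astype(float)
        F = rng.uniform(0.1, 0.9, (2, 9))
        Q2 = np.tile([1.0, 0.0], (3, 1))
        Q1 = np.ones((3, 1))
        assert loglikelihood(G, Q2, F) == pytest.approx(
            loglikelihood(G, Q1, F[:1]), abs=1e-10)

    def test_matches_hand_oracle_with_missing(self):
        G = np.array([[0.0, 1.0, np.nan], [2.0, 1.0, 0.0]])
        Q = np.array([[0.7, 0.3], [0.2, 0.8]])
        F = np.array([[0.1, 0.5, 0.9], [0.6, 0.2, 0.4]])
        assert loglikelihood(G, Q, F) == pytest.approx(
            brute_force_loglik(G, Q, F), abs=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            loglikelihood(np.zeros((2, 3)), np.ones((2, 2)) / 2,
                          np.full((2, 4), 0.5))


class TestEMStep:
    def test_monotone_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n, j = rng.integers(2, 7), rng.integers(3, 15)
            G = rng.integers(0, 3, (n, j)).astype(float)
            G[rng.random((n, j)) < 0.1] = np.nan
            G[:, 0] = rng.integers(0, 3, n)  # keep everyone partially called
            Q = rng.dirichlet([1, 1], size=n)
            F = rng.uniform(0.05, 0.95, (2, j))
            l0 = loglikelihood(G, Q, F)
            Qn, Fn = em_step(G, Q, F)
            assert loglikelihood(G, Qn, Fn) >= l0 - 1e-9
            assert np.allclose(Qn.sum(axis=1), 1.0, atol=1e-9)

    def test_stationary_point_is_fixed(self):
        # pure individuals with F equal to their empirical frequencies
        G = np.array([[0.0, 2.0, 1.0, 1.0],
                      [2.0, 0.0, 1.0, 1.0],
                      [2.0, 2.0, 0.0, 2.0],
                      [0.0, 0.0, 2.0, 0.0]])
        Q = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        F = np.vstack([G[:2].mean(0) / 2, G[2:].mean(0) / 2])
        F = np.clip(F, 1e-6, 1 - 1e-6)
        Qn, Fn = em_step(G, Q, F)
        assert np.abs(Qn - Q).max() < 1e-8

    def test_indistinguishable_populations_leave_q_unchanged(self):
        G = np.array([[1.0, 0.0, 2.0]])
        f = np.array([0.3, 0.4, 0.6])
        Qn, _ = em_step(G, np.array([[0.5, 0.5]]), np.vstack([f, f]))
        assert np.allclose(Qn, 0.5)


@pytest.fixture(scope="module")
def fitted_reference(reference_cohort):
    ds = reference_cohort
    labels = ds.sheet.labels_for(ds.table.samples)
    model = AdmixtureEM(random_state=17).fit(ds.table.dosage,
                                             sample_labels=labels)
    return ds, model


class TestUnsupervisedFit:
    def test_recovers_truth_for_pure_and_f1(self, fitted_reference):
        ds, model = fitted_reference
        ia = model.population_labels_.index(ARM)
        q_est = model.Q_[:, ia]
        q_true = ds.truth.q_true["q_armigera"].to_numpy()
        pure = q_true != 0.5
        assert np.abs(q_est[pure] - q_true[pure]).max() < 0.02
        assert np.abs(q_est[~pure] - 0.5).max() < 0.05

    def test_loglik_trace_non_decreasing(self, fitted_reference):
        _, model = fitted_reference
        assert (np.diff(model.loglik_trace_) >= -1e-9).all()
        assert model.converged_

    def test_q_rows_on_simplex(self, fitted_reference):
        _, model = fitted_reference
        assert np.abs(model.Q_.sum(axis=1) - 1.0).max() < 1e-9

    def test_seeded_determinism(self, reference_cohort):
        ds = reference_cohort
        labels = ds.sheet.labels_for(ds.table.samples)
        a = AdmixtureEM(random_state=5).fit(ds.table.dosage, labels)
        b = AdmixtureEM(random_state=5).fit(ds.table.dosage, labels)
        assert np.array_equal(a.Q_, b.Q_)
        assert np.array_equal(a.F_, b.F_)

    def test_label_symmetry(self, reference_cohort):
        # swapping the species labels everywhere swaps the Q columns exactly
        ds = reference_cohort
        labels = ds.sheet.labels_for(ds.table.samples)
        swap = {ARM: ZEA, ZEA: ARM}
        swapped = [swap.get(l) if l in swap else l for l in labels]
        a = AdmixtureEM(random_state=5).fit(ds.table.dosage, labels)
        b = AdmixtureEM(random_state=5).fit(ds.table.dosage, swapped)
        assert np.array_equal(a.Q_, b.Q_[:, ::-1])

    def test_no_anchors_warns_and_uses_generic_labels(self, reference_cohort):
        ds = reference_cohort
        with pytest.warns(UserWarning):
            model = AdmixtureEM(random_state=2, max_iter=50).fit(
                ds.table.dosage[:, :200])
        assert model.population_labels_ == ["pop1", "pop2"]

    def test_supervised_agrees_with_unsupervised(self, fitted_reference):
        ds, model = fitted_reference
        classes = ds.sheet.frame["truth_class"].to_numpy()
        pa = ds.table.dosage[classes == "pure_armigera"]
        pz = ds.table.dosage[classes == "pure_zea"]
        q_sup = fit_supervised(ds.table.dosage, panel_frequencies(pa, pz))
        ia = model.population_labels_.index(ARM)
        assert np.abs(q_sup[:, 0] - model.Q_[:, ia]).max() < 0.02


class TestSupervisedProjection:
    def test_analytic_het_point(self):
        eps = 1e-6
        F = np.vstack([np.full(30, eps), np.full(30, 1 - eps)])
        q = fit_supervised(np.ones((1, 30)), F)
        assert np.allclose(q, 0.5, atol=1e-6)

    def test_pure_zea_like_query(self, reference_cohort):
        ds = reference_cohort
        classes = ds.sheet.frame["truth_class"].to_numpy()
        F = panel_frequencies(ds.table.dosage[classes == "pure_armigera"],
                              ds.table.dosage[classes == "pure_zea"])
        q = fit_supervised(ds.table.dosage[classes == "pure_zea"], F)
        assert (q[:, 1] >= 0.99).all()

    def test_all_missing_individual_reported_missing(self):
        F = np.vstack([np.full(5, 0.2), np.full(5, 0.8)])
        G = np.vstack([np.full(5, np.nan), np.ones(5)])
        q = fit_supervised(G, F)
        assert np.isnan(q[0]).all() and not np.isnan(q[1]).any()

    def test_unclipped_frequencies_rejected(self):
        with pytest.raises(ValueError):
            fit_supervised(np.ones((1, 2)), np.array([[0.0, 1.0], [1.0, 0.0]]))

    def test_reference_bias_is_monotone_in_masked_fraction(self,
                                                           reference_cohort):
        # zeroing coverage (-> reference calls) at a growing fraction of
        # diagnostic sites drags a pure zea genome toward armigera
        ds = reference_cohort
        classes = ds.sheet.frame["truth_class"].to_numpy()
        F = panel_frequencies(ds.table.dosage[classes == "pure_armigera"],
                              ds.table.dosage[classes == "pure_zea"])
        query = ds.table.dosage[classes == "pure_zea"][:1].copy()
        diag = np.flatnonzero(F[1] - F[0] > 0.8)
        rng = np.random.default_rng(1)
        order = rng.permutation(diag)
        q_arm = []
        for m in (0.0, 0.1, 0.2, 0.3):
            corrupted = query.copy()
            corrupted[0, order[:int(m * len(order))]] = 0.0  # DP=0 ref call
            q_arm.append(fit_supervised(corrupted, F)[0, 0])
        assert all(b > a for a, b in zip(q_arm, q_arm[1:]))


class TestPurity:
    def test_boundaries_and_midpoint(self):
        Q = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0], [0.991, 0.009]])
        pa, pz, hyb = classify_purity(Q, [ARM, ZEA],
                                      ["a", "f1", "z", "almost"])
        assert pa == ["a", "almost"] and pz == ["z"] and hyb == ["f1"]

    def test_recovers_panel_split(self, fitted_reference):
        ds, model = fitted_reference
        pa, pz, hyb = classify_purity(model.Q_, model.population_labels_,
                                      ds.table.samples)
        classes = ds.sheet.frame["truth_class"]
        assert len(pa) == (classes == "pure_armigera").sum()
        assert len(pz) == (classes == "pure_zea").sum()
        assert len(hyb) == (classes == "F1").sum()
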