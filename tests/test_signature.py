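"""Glycan signatures: scaling, normalization, LDA, two-step classifier,
monitoring, drug-efficacy index and prognostic stratification."""

import numpy as np
import pandas as pd
import pytest

from evglyco import signature as sig
from evglyco.synthdata import (CohortSpec, gen_diagnostic_cohort,
                               gen_longitudinal_cohort)


def toy_table(values, **extra):
    df = pd.DataFrame(values, columns=list(sig.LECTINS))
    for k, v in extra.items():
        df[k] = v
    return df


class TestMinMax:
    def test_maps_training_onto_unit_interval(self):
        tr = toy_table([[2, 2, 2], [4, 4, 4], [6, 6, 6]])
        params = sig.fit_minmax(tr)
        scaled = sig.apply_minmax(tr, params)
        assert np.allclose(scaled[list(sig.LECTINS)], [[0, 0, 0], [0.5, 0.5, 0.5], [1, 1, 1]])

    def test_validation_values_clipped(self):
        tr = toy_table([[2, 2, 2], [6, 6, 6]])
        params = sig.fit_minmax(tr)
        val = toy_table([[10, 1, 4]])
        scaled = sig.apply_minmax(val, params)
        assert scaled.loc[0, "ConA"] == 1.0
        assert scaled.loc[0, "WGA"] == 0.0
        assert scaled.loc[0, "RCA_I"] == 0.5

    def test_idempotent_on_scaled_training_data(self):
        rng = np.random.default_rng(1)
        tr = toy_table(rng.random((10, 3)) * 100)
        params = sig.fit_minmax(tr)
        once = sig.apply_minmax(tr, params)
        again = sig.apply_minmax(once, sig.fit_minmax(once))
        assert np.allclose(once[list(sig.LECTINS)], again[list(sig.LECTINS)])

    def test_constant_column_rejected(self):
        tr = toy_table([[2, 5, 2], [2, 7, 4]])
        with pytest.raises(ValueError):
            sig.fit_minmax(tr)


class TestBaselineNormalize:
    def test_simple_ratio(self):
        df = toy_table([[10, 10, 10], [15, 20, 5]],
                       patient_id="P1", timepoint=[0, 30])
        out = sig.baseline_normalize(df)
        assert np.allclose(out.loc[1, list(sig.LECTINS)], [1.5, 2.0, 0.5])
        assert np.allclose(out.loc[0, list(sig.LECTINS)], 1.0)

    def test_per_patient_against_bruteforce(self):
        rng = np.random.default_rng(3)
        rows = []
        for pid in ["A", "B", "C"]:
            for t in [0, 30, 60]:
                rows.append({"patient_id": pid, "timepoint": t,
                             **{lec: rng.uniform(5, 50) for lec in sig.LECTINS}})
        df = pd.DataFrame(rows)
        out = sig.baseline_normalize(df)
        # brute-force oracle: explicit per-patient, per-lectin division
        for _, row in df.iterrows():
            base = df[(df.patient_id == row.patient_id) & (df.timepoint == 0)].iloc[0]
            for lec in sig.LECTINS:
                expected = row[lec] / base[lec]
                got = out.loc[row.name, lec]
                assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_baseline_rejected(self):
        df = toy_table([[0, 10, 10], [15, 20, 5]],
                       patient_id="P1", timepoint=[0, 30])
        with pytest.raises(ValueError):
            sig.baseline_normalize(df)

    def test_missing_baseline_rejected(self):
        df = toy_table([[10, 10, 10]], patient_id="P1", timepoint=[30])
        with pytest.raises(ValueError):
            sig.baseline_normalize(df)


class TestLDA:
    def test_weight_direction_recovered_within_5_degrees(self):
        rng = np.random.default_rng(0)
        n = 10_000
        X0 = rng.standard_normal((n, 3))
        X1 = rng.standard_normal((n, 3)) + np.array([2.0, 0.0, 0.0])
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], n)
        model = sig.fit_lda(X, y, positive_label=1)
        w = model.weights / np.linalg.norm(model.weights)
        angle = np.degrees(np.arccos(abs(w[0])))
        assert angle < 5.0

    def test_separated_1d_data_classified_perfectly(self):
        X = np.array([[0.0], [0.1], [0.2], [1.8], [1.9], [2.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = sig.fit_lda(X, y, positive_label=1)
        assert (model.predict(X) == y).all()

    def test_shuffled_labels_give_no_information(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 3))
        accs = []
        for _ in range(200):
            y = np.zeros(200, dtype=int)
            y[rng.choice(200, 80, replace=False)] = 1
            model = sig.fit_lda(X, y, positive_label=1)
            accs.append((model.predict(X) == y).mean())
        nir = 0.6  # majority class fraction
        assert nir - 0.03 < np.mean(accs) < nir + 0.08  # small refit optimism

    def test_matches_sklearn_reference(self):
        """Dual-route check: in-package closed form vs sklearn's LDA."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(11)
        X = rng.standard_normal((120, 3)) + rng.standard_normal((120, 1))
        y = (rng.random(120) < 0.45).astype(int)
        X[y == 1] += [0.8, -0.4, 0.2]
        ours = sig.fit_lda(X, y, positive_label=1)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        assert (ours.predict(X) == ref.predict(X)).all()
        ratio = ours.weights / ref.coef_[0]
        assert np.allclose(ratio, ratio[0], rtol=1e-6)  # same direction

    def test_flipping_labels_flips_weights(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 3))
        y = np.repeat([0, 1], 30)
        X[y == 1] += 1.0
        m01 = sig.fit_lda(X, y, positive_label=1)
        m10 = sig.fit_lda(X, y, positive_label=0)
        assert np.allclose(m01.weights, -m10.weights)

    def test_requires_two_classes(self):
        with pytest.raises(ValueError):
            sig.fit_lda(np.ones((4, 3)), np.zeros(4))


class TestDiagnosticTwoStep:
    def test_separable_cohort_classified_perfectly(self):
        cohort = gen_diagnostic_cohort(CohortSpec(seed=1))
        model = sig.fit_diagnostic(cohort)
        pred = sig.predict_diagnostic(model, cohort)
        assert (pred["predicted"] == cohort["group"]).mean() == 1.0

    def test_hd_centroid_called_hd(self):
        cohort = gen_diagnostic_cohort(CohortSpec(seed=4))
        model = sig.fit_diagnostic(cohort)
        centroid = cohort[cohort.group == "HD"][list(sig.LECTINS)].mean()
        probe = toy_table([centroid.values])
        assert sig.predict_diagnostic(model, probe)["predicted"].iloc[0] == "HD"

    def test_composition_matches_two_independent_binary_fits(self):
        """Brute-force oracle: scale, fit the two binary LDAs separately and
        compose the routing by hand; calls must agree with the pipeline."""
        cohort = gen_diagnostic_cohort(CohortSpec(seed=9))
        model = sig.fit_diagnostic(cohort)
        pred = sig.predict_diagnostic(model, cohort)["predicted"].to_numpy()

        params = sig.fit_minmax(cohort)
        X = sig.apply_minmax(cohort, params)[list(sig.LECTINS)].to_numpy()
        y1 = np.where(cohort.group.isin(["TNBC", "otherBC"]), "BC", "HD")
        lda1 = sig.fit_lda(X, y1, positive_label="BC")
        mask = cohort.group.isin(["TNBC", "otherBC"]).to_numpy()
        lda2 = sig.fit_lda(X[mask], cohort.group[mask].to_numpy(),
                           positive_label="TNBC")
        manual = np.where(lda1.predict(X) == "HD", "HD", lda2.predict(X))
        assert (pred == manual).all()

    def test_hd_calls_never_routed_to_subtype(self):
        cohort = gen_diagnostic_cohort(CohortSpec(seed=12))
        model = sig.fit_diagnostic(cohort)
        rng = np.random.default_rng(0)
        probe = toy_table(rng.uniform(100, 6000, size=(200, 3)))
        pred = sig.predict_diagnostic(model, probe)
        scaled = sig.apply_minmax(probe, model.scaling)[list(sig.LECTINS)].to_numpy()
        hd_by_step1 = model.models["bc_vs_hd"].predict(scaled) == "HD"
        assert (pred.loc[hd_by_step1, "predicted"] == "HD").all()

    def test_invariant_to_affine_lectin_rescaling(self):
        cohort = gen_diagnostic_cohort(CohortSpec(seed=2))
        model = sig.fit_diagnostic(cohort)
        pred = sig.predict_diagnostic(model, cohort)["predicted"]
        rescaled = cohort.copy()
        for i, lec in enumerate(sig.LECTINS):
            rescaled[lec] = cohort[lec] * (3.7 + i) + 100.0 * (i + 1)
        model2 = sig.fit_diagnostic(rescaled)
        pred2 = sig.predict_diagnostic(model2, rescaled)["predicted"]
        assert (pred == pred2).all()

    def test_vanishing_separation_gives_no_information_rate(self):
        no_effect = {lec: 1.0 for lec in sig.LECTINS}
        spec = CohortSpec(seed=8, bc_effect=no_effect, tnbc_effect=no_effect)
        model = sig.fit_diagnostic(gen_diagnostic_cohort(spec))
        big = CohortSpec(seed=21, n_tnbc=200, n_otherbc=200, n_hd=200,
                         bc_effect=no_effect, tnbc_effect=no_effect)
        val = gen_diagnostic_cohort(big)
        acc = (sig.predict_diagnostic(model, val)["predicted"] == val["group"]).mean()
        # max prior of the training cohort is 25/64; binomial MC slack at n=600
        assert abs(acc - 25 / 64) < 0.10

    def test_missing_lectin_rejected(self):
        cohort = gen_diagnostic_cohort(CohortSpec(seed=1))
        with pytest.raises(ValueError):
            sig.fit_diagnostic(cohort.drop(columns=["WGA"]))


class TestMonitoring:
    def test_constructed_cohort_fully_discriminated(self):
        cohort = gen_longitudinal_cohort(CohortSpec(seed=7))
        model = sig.fit_monitoring(cohort)
        scores = sig.score_monitoring(model, cohort)
        follow = cohort[cohort.timepoint > 0]
        pd_scores = scores[follow[follow.response == "PD"].index]
        rest = scores[follow[follow.response != "PD"].index]
        lda = model.models["pd_vs_prsd"]
        calls_pd = (pd_scores >= lda.threshold).mean()
        calls_rest = (rest < lda.threshold).mean()
        assert calls_pd == 1.0 and calls_rest == 1.0

    def test_identical_followups_score_identically(self):
        base = [[10.0, 20.0, 30.0]]
        rows = []
        for pid in ["P1", "P2"]:
            rows.append({"patient_id": pid, "timepoint": 0, "response": "BS",
                         **dict(zip(sig.LECTINS, base[0]))})
            rows.append({"patient_id": pid, "timepoint": 30,
                         "response": "PD" if pid == "P1" else "SD",
                         **dict(zip(sig.LECTINS, base[0]))})
        df = pd.DataFrame(rows)
        model_cohort = gen_longitudinal_cohort(CohortSpec(seed=7))
        model = sig.fit_monitoring(model_cohort)
        scores = sig.score_monitoring(model, df)
        assert scores.nunique() == 1  # every row normalizes to (1,1,1)

    def test_single_class_rejected(self):
        cohort = gen_longitudinal_cohort(CohortSpec(seed=7))
        only_resp = cohort[cohort.responder]
        with pytest.raises(ValueError):
            sig.fit_monitoring(only_resp)


class TestEtaEV:
    def test_halving_score_gives_plus_half(self):
        assert sig.eta_ev(2.0, 1.0) == pytest.approx(0.5)

    def test_constant_score_gives_zero(self):
        assert sig.eta_ev(3.3, 3.3) == 0.0

    def test_rate_form(self):
        assert sig.eta_ev(2.0, 1.0, days=100, rate=True) == pytest.approx(0.005)

    def test_nonpositive_scores_rejected(self):
        with pytest.raises(ValueError):
            sig.eta_ev(-1.0, 2.0)
        with pytest.raises(ValueError):
            sig.eta_ev(2.0, 0.0)


class TestPrognostic:
    def test_median_patient_goes_high_for_odd_n(self):
        groups = sig.stratify_median([1.0, 2.0, 3.0, 4.0, 5.0])
        assert list(groups) == ["low", "low", "high", "high", "high"]

    def test_even_split_for_distinct_scores(self):
        groups = sig.stratify_median(np.arange(10, dtype=float))
        assert (groups == "high").sum() == 5
        assert (groups == "low").sum() == 5

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            sig.stratify_median([1.0, 2.0, 3.0])

    def test_risk_score_tracks_event_labels_on_separable_data(self):
        rng = np.random.default_rng(6)
        n = 40
        X = np.exp(rng.normal(np.log(100), 0.1, size=(n, 3)))
        event = np.repeat([0, 1], n // 2)
        X[event == 1] *= [2.0, 2.0, 0.5]
        df = toy_table(X, event=event)
        model = sig.fit_prognostic(df)
        scores = sig.score_prognostic(model, df)
        assert scores[event == 1].min() > scores[event == 0].max()
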