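import numpy as np
import pandas as pd
import pytest

import drugsig as ds

from conftest import shared_mechanism_config


def random_model(rng, n_transcripts=40, n_drugs=8, n_mechs=4):
    A = pd.DataFrame(
        rng.normal(size=(n_mechs, n_transcripts)),
        index=[f"m{i}" for i in range(n_mechs)],
        columns=[f"t{i:03d}" for i in range(n_transcripts)],
    )
    B = pd.DataFrame(
        rng.uniform(0.5, 2.0, size=(n_drugs, n_mechs)),
        index=[f"d{i}" for i in range(n_drugs)],
        columns=A.index,
    )
    E = (B.to_numpy() @ A.to_numpy()).T
    E = pd.DataFrame(E, index=A.columns, columns=B.index)
    return A, B, E


class TestKiToBinding:
    def test_one_nanomolar_maps_to_four(self):
        ki = pd.DataFrame({"m": [1.0]}, index=["d"])
        assert ds.ki_to_binding(ki).loc["d", "m"] == pytest.approx(4.0)

    def test_missing_affinity_is_zero(self):
        ki = pd.DataFrame({"m1": [1.0], "m2": [np.nan]}, index=["d"])
        B = ds.ki_to_binding(ki)
        assert B.loc["d", "m2"] == 0.0

    def test_weak_binding_floored_to_zero(self):
        ki = pd.DataFrame({"m": [50_000.0]}, index=["d"])  # 50 uM
        assert ds.ki_to_binding(ki).loc["d", "m"] == 0.0

    def test_tighter_binding_gives_larger_engagement(self):
        ki = pd.DataFrame({"m": [1.0, 100.0]}, index=["tight", "loose"])
        B = ds.ki_to_binding(ki)
        assert B.loc["tight", "m"] > B.loc["loose", "m"]

    def test_nonpositive_ki_rejected(self):
        ki = pd.DataFrame({"m": [-1.0]}, index=["d"])
        with pytest.raises(ValueError, match="positive"):
            ds.ki_to_binding(ki)


class TestFitSensitivity:
    def test_identity_binding_returns_expression(self):
        rng = np.random.default_rng(0)
        E = pd.DataFrame(
            rng.normal(size=(10, 3)),
            index=[f"t{i}" for i in range(10)],
            columns=["d1", "d2", "d3"],
        )
        B = pd.DataFrame(np.eye(3), index=E.columns, columns=["m1", "m2", "m3"])
        A = ds.fit_sensitivity(E, B)
        np.testing.assert_allclose(A.to_numpy(), E.to_numpy().T, atol=1e-12)

    def test_exact_recovery_with_full_rank_binding(self):
        A_true, B, E = random_model(np.random.default_rng(1))
        A_hat = ds.fit_sensitivity(E, B)
        np.testing.assert_allclose(A_hat.to_numpy(), A_true.to_numpy(), atol=1e-8)

    def test_reconstruction_exact_in_span(self):
        A_true, B, E = random_model(np.random.default_rng(2))
        A_hat = ds.fit_sensitivity(E, B)
        recon = (B.to_numpy() @ A_hat.to_numpy()).T
        np.testing.assert_allclose(recon, E.to_numpy(), atol=1e-8)

    def test_minimum_norm_under_rank_deficiency(self):
        rng = np.random.default_rng(3)
        A_true, B, E = random_model(rng, n_drugs=3, n_mechs=4)  # underdetermined
        A_hat = ds.fit_sensitivity(E, B)
        recon = (B.to_numpy() @ A_hat.to_numpy()).T
        np.testing.assert_allclose(recon, E.to_numpy(), atol=1e-8)
        # any other exact solution has a larger norm than the lstsq one
        assert np.linalg.norm(A_hat.to_numpy()) <= np.linalg.norm(A_true.to_numpy()) + 1e-8

    def test_recovery_improves_with_more_drugs(self):
        errs = []
        for n_drugs in (6, 10, 14):
            per_seed = []
            for seed in range(10):
                rng = np.random.default_rng(1000 + seed)
                A_true, B, E = random_model(rng, n_drugs=n_drugs, n_mechs=4)
                E_noisy = E + rng.normal(0, 0.3, size=E.shape)
                A_hat = ds.fit_sensitivity(E_noisy, B)
                per_seed.append(np.median(np.abs(A_hat.to_numpy() - A_true.to_numpy())))
            errs.append(np.mean(per_seed))
        assert errs[0] > errs[1] > errs[2]

    def test_all_zero_binding_rejected(self):
        E = pd.DataFrame(np.ones((3, 2)), columns=["d1", "d2"])
        B = pd.DataFrame(np.zeros((2, 2)), index=["d1", "d2"], columns=["m1", "m2"])
        with pytest.raises(ValueError, match="all zero"):
            ds.fit_sensitivity(E, B)


class TestReduceSensitive:
    def test_disjoint_top_lists_union(self):
        A = pd.DataFrame(0.0, index=["m1", "m2"], columns=[f"t{i:02d}" for i in range(20)])
        A.loc["m1", [f"t{i:02d}" for i in range(5)]] = [5, 4, 3, 2, 1]
        A.loc["m2", [f"t{i:02d}" for i in range(10, 15)]] = [5, 4, 3, 2, 1]
        idx, A_red = ds.reduce_sensitive(A, top_k=3)
        assert len(idx) == 6
        assert A_red.shape == (2, 6)

    def test_identical_profiles_fully_overlap(self):
        rng = np.random.default_rng(4)
        row = rng.normal(size=30)
        A = pd.DataFrame([row, row], index=["m1", "m2"], columns=[f"t{i:02d}" for i in range(30)])
        idx, _ = ds.reduce_sensitive(A, top_k=7)
        assert len(idx) == 7

    def test_magnitude_not_sign_drives_selection(self):
        A = pd.DataFrame(
            [[-9.0, 1.0, 2.0]], index=["m"], columns=["t0", "t1", "t2"]
        )
        idx, _ = ds.reduce_sensitive(A, top_k=1)
        assert list(idx) == ["t0"]

    def test_invalid_top_k(self):
        A = pd.DataFrame(np.ones((1, 3)))
        with pytest.raises(ValueError, match="top_k"):
            ds.reduce_sensitive(A, top_k=0)
        with pytest.raises(ValueError, match="exceeds"):
            ds.reduce_sensitive(A, top_k=5)


class TestPredictMechanisms:
    def test_zero_signature_gives_zero_activation(self):
        A = pd.DataFrame(np.eye(3), index=["m1", "m2", "m3"], columns=["t1", "t2", "t3"])
        pred = ds.predict_mechanisms(pd.Series(0.0, index=["t1", "t2", "t3"]), A)
        assert (pred.activation == 0).all()
        assert pred.residual_norm == 0.0

    def test_training_drug_recovers_its_binding_row(self):
        A_true, B, E = random_model(np.random.default_rng(5))
        A_hat = ds.fit_sensitivity(E, B)
        idx, A_red = ds.reduce_sensitive(A_hat, top_k=30)
        pred = ds.predict_mechanisms(E.loc[idx, "d3"], A_red)
        np.testing.assert_allclose(
            pred.activation.to_numpy(), B.loc["d3"].to_numpy(), atol=1e-6
        )

    def test_scale_equivariance(self):
        A_true, B, E = random_model(np.random.default_rng(6))
        A_hat = ds.fit_sensitivity(E, B)
        idx, A_red = ds.reduce_sensitive(A_hat, top_k=30)
        p1 = ds.predict_mechanisms(E.loc[idx, "d0"], A_red)
        p3 = ds.predict_mechanisms(3.0 * E.loc[idx, "d0"], A_red)
        np.testing.assert_allclose(
            p3.activation.to_numpy(), 3.0 * p1.activation.to_numpy(), atol=1e-8
        )

    def test_held_out_single_mechanism_drug_recovered(self):
        # full pipeline: generate -> fold changes -> summary -> fit -> predict
        ok = 0
        for seed in range(25):
            cfg = shared_mechanism_config(seed=seed)
            em, truth = ds.generate_experiment(cfg)
            fct = ds.fold_changes(em, vehicle_map=truth.vehicle_map)
            E = ds.drug_response_summary(fct)
            train = [d for d in E.columns if d != "d1"]
            A = ds.fit_sensitivity(E[train], truth.B_true.loc[train])
            idx, A_red = ds.reduce_sensitive(A, top_k=50)
            pred = ds.predict_mechanisms(E.loc[idx, "d1"], A_red)
            if pred.top_mechanism() == "m1":
                ok += 1
        assert ok >= 23  # >= 90% of seeds


class TestLooValidate:
    def test_noiseless_full_rank_gives_perfect_cosines(self):
        A_true, B, E = random_model(np.random.default_rng(7))
        loo = ds.loo_validate(E, B, top_k=30)
        np.testing.assert_allclose(loo["cosine"].to_numpy(), 1.0, atol=1e-6)
        assert (loo["rank_of_truth"] == 1).all()

    def test_noisy_pipeline_cosine_is_high(self):
        cosines = []
        for seed in range(5):
            cfg = shared_mechanism_config(seed=100 + seed)
            em, truth = ds.generate_experiment(cfg)
            fct = ds.fold_changes(em, vehicle_map=truth.vehicle_map)
            E = ds.drug_response_summary(fct)
            loo = ds.loo_validate(E, truth.B_true.loc[E.columns], top_k=50)
            cosines.append(loo["cosine"].median())
        assert np.median(cosines) >= 0.8

    def test_orphan_mechanism_drug_flagged_unpredictable(self):
        rng = np.random.default_rng(8)
        A_true, B, E = random_model(rng, n_drugs=5, n_mechs=3)
        B.iloc[:, 2] = 0.0
        B.loc["d4"] = [0.0, 0.0, 1.0]  # only drug engaging m2
        E = pd.DataFrame((B.to_numpy() @ A_true.to_numpy()).T, index=A_true.columns, columns=B.index)
        loo = ds.loo_validate(E, B, top_k=30)
        assert not loo.loc["d4", "predictable"]
        assert np.isnan(loo.loc["d4", "rank_of_truth"])

    def test_fewer_than_three_drugs_rejected(self):
        A_true, B, E = random_model(np.random.default_rng(9), n_drugs=2)
        with pytest.raises(ValueError, match=">= 3 drugs"):
            ds.loo_validate(E, B)
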