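"""Genotype preparation and the rrBLUP mixed model."""

import numpy as np
import pandas as pd
import pytest

import netgs
from netgs.errors import DegenerateInputError, ValidationError
from netgs.gs import load_model_set, save_model_set


def random_genotypes(rng, n=80, p=60, prefix="m"):
    freqs = rng.uniform(0.1, 0.9, p)
    d = rng.binomial(2, freqs, size=(n, p)).astype(float)
    return pd.DataFrame(d, index=[f"a{i}" for i in range(n)],
                        columns=[f"{prefix}{j}" for j in range(p)])


class TestPrepareGenotypes:
    def test_rare_allele_removed(self, rng):
        raw = random_genotypes(rng, n=100, p=10)
        raw["rare"] = 0.0
        raw.loc[raw.index[:3], "rare"] = 1.0  # allele frequency 0.015
        G = netgs.prepare_genotypes(raw, maf_threshold=0.05)
        assert "rare" not in G.marker_ids

    def test_zero_threshold_keeps_polymorphic(self, rng):
        raw = random_genotypes(rng, n=50, p=20)
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        kept = {m for m in raw.columns if raw[m].std() > 0}
        assert set(G.marker_ids) == kept

    def test_constant_column_removed(self, rng):
        raw = random_genotypes(rng, n=10, p=5)
        raw["const"] = 1.0
        G = netgs.prepare_genotypes(raw)
        assert "const" not in G.marker_ids

    def test_missing_values_imputed_with_warning(self, rng):
        raw = random_genotypes(rng, n=40, p=10)
        raw.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="imputing"):
            G = netgs.prepare_genotypes(raw)
        assert np.isfinite(G.dosages).all()

    def test_class_filter(self, rng):
        raw = random_genotypes(rng, n=40, p=6)
        classes = {m: ("enzymatic" if j < 3 else "genome_wide")
                   for j, m in enumerate(raw.columns)}
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0, class_filter="enzymatic",
                                    marker_classes=classes)
        assert all(classes[m] == "enzymatic" for m in G.marker_ids)

    def test_empty_result_is_error(self, rng):
        raw = pd.DataFrame({"m0": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
        with pytest.raises(ValidationError, match="no markers"):
            netgs.prepare_genotypes(raw)


class TestComputePCs:
    def test_duplicated_accessions_have_identical_scores(self, rng):
        raw = random_genotypes(rng, n=20, p=30)
        raw.iloc[1] = raw.iloc[0]
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        pcs = netgs.compute_pcs(G, k=4)
        np.testing.assert_allclose(pcs[0], pcs[1], atol=1e-10)

    def test_variance_non_increasing(self, rng):
        raw = random_genotypes(rng, n=40, p=50)
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        pcs = netgs.compute_pcs(G, k=5)
        var = pcs.var(axis=0)
        assert (np.diff(var) <= 1e-9).all()

    def test_rank_one_recovers_axis(self, rng):
        load = rng.normal(size=30)
        scores = rng.normal(size=20)
        d = np.clip(1.0 + 0.2 * np.outer(scores, load), 0, 2)
        G = netgs.GenotypeMatrix([f"a{i}" for i in range(20)],
                                 [f"m{j}" for j in range(30)], d)
        pcs = netgs.compute_pcs(G, k=1)[:, 0]
        r = abs(np.corrcoef(pcs, scores)[0, 1])
        assert r > 0.999

    def test_k_too_large(self, rng):
        raw = random_genotypes(rng, n=5, p=10)
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        with pytest.raises(ValidationError):
            netgs.compute_pcs(G, k=5)


class TestRrblup:
    def test_single_marker_trait_fits_perfectly(self, rng):
        raw = random_genotypes(rng, n=60, p=30)
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        y = G.dosages[:, 3].copy()
        model = netgs.fit_rrblup(G, y)
        fitted = netgs.predict_gebv(model, G)
        assert np.corrcoef(fitted, y)[0, 1] >= 0.99

    def test_fixed_lambda_matches_closed_form_ridge(self, rng):
        raw = random_genotypes(rng, n=40, p=25)
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        y = rng.normal(size=40)
        lam = 3.7
        model = netgs.fit_rrblup(G, y, lam=lam)
        Z = G.dosages - G.dosages.mean(axis=0)
        # GLS intercept, then ridge effects (Z'Z + lam I)^-1 Z' (y - mu)
        Vinv = np.linalg.inv(Z @ Z.T + lam * np.eye(40))
        mu = float((np.ones(40) @ Vinv @ y) / (np.ones(40) @ Vinv @ np.ones(40)))
        expect = np.linalg.solve(Z.T @ Z + lam * np.eye(Z.shape[1]), Z.T @ (y - mu))
        np.testing.assert_allclose(model.marker_effects, expect, atol=1e-8)

    def test_marker_permutation_invariance(self, rng):
        raw = random_genotypes(rng, n=50, p=20)
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        y = rng.normal(size=50)
        m1 = netgs.fit_rrblup(G, y)
        perm = rng.permutation(G.n_markers)
        Gp = netgs.GenotypeMatrix(
            G.accession_ids, [G.marker_ids[j] for j in perm], G.dosages[:, perm]
        )
        m2 = netgs.fit_rrblup(Gp, y)
        # effects permute with the columns; GEBVs are unchanged
        eff1 = dict(zip(m1.marker_ids, m1.marker_effects))
        eff2 = dict(zip(m2.marker_ids, m2.marker_effects))
        for k in eff1:
            assert eff1[k] == pytest.approx(eff2[k], abs=1e-8)
        np.testing.assert_allclose(
            netgs.predict_gebv(m1, G), netgs.predict_gebv(m2, G), atol=1e-8
        )

    def test_gebv_shift_equivariance(self, rng):
        raw = random_genotypes(rng, n=50, p=20)
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        y = rng.normal(size=50)
        p1 = netgs.predict_gebv(netgs.fit_rrblup(G, y), G)
        p2 = netgs.predict_gebv(netgs.fit_rrblup(G, y + 7.5), G)
        np.testing.assert_allclose(p2, p1 + 7.5, atol=1e-6)

    def test_covariates_consumed(self, rng):
        raw = random_genotypes(rng, n=60, p=30)
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        C = rng.normal(size=(60, 2))
        y = 2.0 * C[:, 0] + rng.normal(size=60)
        model = netgs.fit_rrblup(G, y, covariates=C)
        assert model.covariate_effects is not None
        assert model.covariate_effects[0] == pytest.approx(2.0, abs=0.5)
        with pytest.raises(ValidationError, match="covariates"):
            netgs.predict_gebv(model, G)

    def test_zero_variance_trait_rejected(self, rng):
        raw = random_genotypes(rng, n=20, p=10)
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        with pytest.raises(DegenerateInputError):
            netgs.fit_rrblup(G, np.ones(20))

    def test_missing_marker_at_prediction(self, rng):
        raw = random_genotypes(rng, n=30, p=10)
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        model = netgs.fit_rrblup(G, rng.normal(size=30))
        G2 = netgs.GenotypeMatrix(G.accession_ids, ["other0"],
                                  G.dosages[:, :1])
        with pytest.raises(ValidationError, match="lacks markers"):
            netgs.predict_gebv(model, G2)


class TestFluxModelSet:
    def test_identical_columns_identical_effects(self, rng):
        raw = random_genotypes(rng, n=40, p=20)
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        y = rng.normal(size=40)
        fm = pd.DataFrame({"R1": y, "R2": y.copy()}, index=G.accession_ids)
        ms = netgs.fit_flux_models(G, fm)
        np.testing.assert_allclose(
            ms.models["R1"].marker_effects, ms.models["R2"].marker_effects, atol=1e-10
        )

    def test_constant_column_becomes_constant(self, rng):
        raw = random_genotypes(rng, n=40, p=20)
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        fm = pd.DataFrame(
            {"R1": rng.normal(size=40), "R2": np.full(40, 2.5)}, index=G.accession_ids
        )
        with pytest.warns(UserWarning, match="constant"):
            ms = netgs.fit_flux_models(G, fm)
        assert "R2" not in ms.models
        assert ms.constants["R2"] == pytest.approx(2.5)
        assert set(ms.models) == {"R1"}

    def test_cv_accuracy_recorded_and_bounded(self, rng):
        raw = random_genotypes(rng, n=60, p=30)
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        y = G.dosages[:, :5].sum(axis=1) + 0.3 * rng.normal(size=60)
        fm = pd.DataFrame({"R1": y}, index=G.accession_ids)
        plan = netgs.make_cv_plan(G.accession_ids, 3, 1, seed=0)
        folds = [(tr, te) for _, _, tr, te in plan.evaluations()]
        ms = netgs.fit_flux_models(G, fm, cv_folds=folds)
        acc = ms.models["R1"].cv_accuracy
        assert -1.0 <= acc <= 1.0
        assert acc > 0.3  # strongly genetic trait must be predictable

    def test_round_trip_serialization(self, rng, tmp_path):
        raw = random_genotypes(rng, n=30, p=15)
        G = netgs.prepare_genotypes(raw, maf_threshold=0.0)
        fm = pd.DataFrame(
            {"R1": rng.normal(size=30), "R2": np.full(30, 1.0)}, index=G.accession_ids
        )
        with pytest.warns(UserWarning):
            ms = netgs.fit_flux_models(G, fm)
        save_model_set(ms, tmp_path / "archive")
        back = load_model_set(tmp_path / "archive")
        assert set(back.models) == set(ms.models)
        assert back.constants == ms.constants
        np.testing.assert_allclose(
            netgs.predict_gebv(back.models["R1"], G),
            netgs.predict_gebv(ms.models["R1"], G), atol=1e-12,
        )
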