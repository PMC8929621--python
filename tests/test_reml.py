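"""REML engine: likelihood correctness, EM behaviour, oracles and BLUPs."""

import numpy as np
import pandas as pd
import pytest

import forestqg as fq
from forestqg.errors import StructuralError
from forestqg.reml import ModelSpec, VarianceComponents, blup_at, reml_loglik
from oracles import anova_halfsib


def uni_vc(sa, se):
    return VarianceComponents(
        responses=["y"],
        sigma_a=np.array([[sa]]),
        sigma_e=np.array([[se]]),
        structural_zero=np.zeros((1, 1), bool),
    )


def identity_K(ids, kind="A"):
    return fq.RelationshipMatrix(ids=ids, values=np.eye(len(ids)), kind=kind)


@pytest.fixture()
def toy5(rng):
    ids = [f"i{k}" for k in range(5)]
    K = np.eye(5)
    K[0, 1] = K[1, 0] = 0.5
    Krm = fq.RelationshipMatrix(ids=ids, values=K, kind="A")
    df = pd.DataFrame(
        {
            "tree": ids,
            "site": "S",
            "replication": "R1",
            "group": ["a", "a", "b", "b", "b"],
            "y": rng.normal(0, 1, 5),
        }
    )
    return df, Krm


class TestRemlLoglik:
    def test_matches_dense_oracle(self, toy5):
        df, Krm = toy5
        spec = ModelSpec(responses=[("y", None)], groups="group")
        ll = reml_loglik(spec, df, Krm, uni_vc(0.7, 0.4))
        X = np.column_stack(
            [(df["group"] == "a").astype(float), (df["group"] == "b").astype(float)]
        )
        V = 0.7 * Krm.values + 0.4 * np.eye(5)
        Vi = np.linalg.inv(V)
        P = Vi - Vi @ X @ np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi
        y = df["y"].to_numpy()
        oracle = -0.5 * (
            np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(X.T @ Vi @ X)[1]
            + y @ P @ y
        )
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_scaling_identity(self, toy5):
        df, Krm = toy5
        spec = ModelSpec(responses=[("y", None)], groups="group")
        ll = reml_loglik(spec, df, Krm, uni_vc(0.7, 0.4))
        c = 2.5
        df2 = df.assign(y=c * df["y"])
        ll2 = reml_loglik(spec, df2, Krm, uni_vc(0.7 * c**2, 0.4 * c**2))
        assert ll2 - ll == pytest.approx(-(5 - 2) * np.log(c), abs=1e-9)

    def test_aliased_fixed_effects_raise(self, toy5):
        df, Krm = toy5
        df = df.copy()
        df["group"] = "only"  # one level per response is fine...
        spec = ModelSpec(responses=[("y", None), ("y", None)], groups="group")
        # duplicating the same response duplicates its design columns only
        # within separate blocks (full rank); instead alias by a constant
        # group plus a second constant trait column in one response is not
        # expressible -> test the explicit rank check
        from forestqg.reml import _check_rank

        X = np.ones((5, 2))
        with pytest.raises(StructuralError, match="aliased"):
            _check_rank(X, ["c1", "c2"])


class TestUnivariateFit:
    def test_null_signal_with_family_structure(self):
        # true s2_a = 0 under an informative half-sib K: h2 estimates near 0
        rng = np.random.default_rng(61)
        ids, dams = [], []
        for d in range(100):
            for k in range(10):
                ids.append(f"P{d}_{k}")
                dams.append(f"D{d}")
        ped = fq.validate_and_order(
            fq.Pedigree(ids=ids, sires=[fq.UNKNOWN] * 1000, dams=dams)
        )
        A = fq.compute_A(ped)
        df = pd.DataFrame(
            {"tree": ids, "site": "S", "replication": "R", "group": "g",
             "y": rng.normal(0, 1, 1000)}
        )
        est = fq.AnimalModelREML(response="y", groups=None).fit(df, A)
        assert est.heritability_ < 0.05

    def test_matches_anova_oracle_on_balanced_halfsibs(self):
        rng = np.random.default_rng(62)
        n_dams, k = 100, 10
        ids, dams, y = [], [], []
        dam_bv = rng.normal(0, np.sqrt(0.4), n_dams)
        for d in range(n_dams):
            for j in range(k):
                ids.append(f"P{d}_{j}")
                dams.append(f"D{d}")
                y.append(
                    0.5 * dam_bv[d]
                    + rng.normal(0, np.sqrt(0.3))
                    + rng.normal(0, np.sqrt(0.6))
                )
        ped = fq.validate_and_order(
            fq.Pedigree(ids=ids, sires=[fq.UNKNOWN] * len(ids), dams=dams)
        )
        A = fq.compute_A(ped)
        df = pd.DataFrame(
            {"tree": ids, "site": "S", "replication": "R", "group": "g", "y": y}
        )
        est = fq.AnimalModelREML(response="y", groups=None).fit(df, A)
        s2a_oracle, s2e_oracle = anova_halfsib(np.array(y), np.array(dams))
        assert est.sigma_a_ == pytest.approx(s2a_oracle, abs=1e-4)
        assert est.sigma_e_ == pytest.approx(s2e_oracle, abs=1e-4)

    def test_loglik_trace_nondecreasing(self, single_site_phenotypes):
        table, A = single_site_phenotypes
        est = fq.AnimalModelREML(response="T1", groups=None, max_iter=300).fit(
            table, A
        )
        tr = est.loglik_trace_
        assert np.all(np.diff(tr) >= -1e-8 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_identity_K_paths_agree_exactly(self, rng):
        ids = [f"i{k}" for k in range(150)]
        df = pd.DataFrame(
            {"tree": ids, "site": "S", "replication": "R", "group": "g",
             "y": rng.normal(0, 1, 150)}
        )
        ea = fq.AnimalModelREML(response="y", groups=None).fit(df, identity_K(ids, "A"))
        eg = fq.AnimalModelREML(response="y", groups=None).fit(df, identity_K(ids, "G"))
        assert ea.sigma_a_ == eg.sigma_a_
        assert ea.sigma_e_ == eg.sigma_e_

    def test_permutation_invariance(self, single_site_phenotypes, rng):
        table, A = single_site_phenotypes
        e1 = fq.AnimalModelREML(response="T1", groups=None, tol=1e-10).fit(table, A)
        perm = rng.permutation(len(table))
        e2 = fq.AnimalModelREML(response="T1", groups=None, tol=1e-10).fit(
            table.iloc[perm].reset_index(drop=True), A
        )
        assert e2.sigma_a_ == pytest.approx(e1.sigma_a_, abs=1e-8)
        assert e2.sigma_e_ == pytest.approx(e1.sigma_e_, abs=1e-8)

    def test_replication_effect_recovered(self):
        rng = np.random.default_rng(63)
        ids, dams, reps, y = [], [], [], []
        rep_eff = {"R1": -0.8, "R2": 0.8}
        for d in range(40):
            for j in range(8):
                ids.append(f"P{d}_{j}")
                dams.append(f"D{d}")
                r = f"R{(j % 2) + 1}"
                reps.append(r)
                y.append(rep_eff[r] + rng.normal(0, 1))
        ped = fq.validate_and_order(
            fq.Pedigree(ids=ids, sires=[fq.UNKNOWN] * len(ids), dams=dams)
        )
        A = fq.compute_A(ped)
        df = pd.DataFrame(
            {"tree": ids, "site": "S", "replication": reps, "group": "g", "y": y}
        )
        est = fq.AnimalModelREML(
            response="y", groups=None, replication="replication",
            tol=1e-6, max_iter=400,
        ).fit(df, A)
        assert est.sigma_d_ > 0.1  # the large block contrast is picked up


class TestMultivariateFit:
    def test_duplicated_trait_correlation_near_one(self, single_site_phenotypes):
        table, A = single_site_phenotypes
        rng = np.random.default_rng(64)
        table = table.copy()
        table["T1b"] = table["T1"] + 0.01 * rng.normal(size=len(table))
        est = fq.MultiTraitREML(
            responses=[("T1", "S1"), ("T1b", "S1")], groups=None, tol=1e-7
        ).fit(table, A)
        assert est.genetic_correlations_["r_a"].iloc[0] >= 0.99

    def test_disjoint_sites_zero_residual_covariance(self):
        truth = fq.simulate_pedigree(40, 6, 60, seed=65)
        A = fq.compute_A(truth.true_pedigree)
        from forestqg.simulate import TraitConfig, assign_sites_and_reps

        site_of, rep_of = assign_sites_and_reps(truth, sites=["S1", "S2"], seed=66)
        cfg = TraitConfig(
            traits=["HT"], sites=["S1", "S2"],
            heritability={("HT", "S1"): 0.5, ("HT", "S2"): 0.5},
            genetic_correlation=np.array([[1.0, 0.6], [0.6, 1.0]]),
            replication_sd=0.0,
        )
        pheno = fq.simulate_phenotypes(truth, A, cfg, site_of, rep_of, seed=67)
        est = fq.MultiTraitREML(
            responses=[("HT", "S1"), ("HT", "S2")], groups=None,
            tol=1e-6, max_iter=600,
        ).fit(pheno, A)
        vc = est.result_.vc
        assert vc.sigma_e[0, 1] == 0.0  # structural, exact
        r_a = est.genetic_correlations_["r_a"].iloc[0]
        assert np.isfinite(r_a) and -1 <= r_a <= 1

    def test_genetic_correlation_recovered_single_seed(self, single_site_phenotypes):
        table, A = single_site_phenotypes
        est = fq.MultiTraitREML(
            responses=[("T1", "S1"), ("T2", "S1")], groups=None, tol=1e-7
        ).fit(table, A)
        r_a = est.genetic_correlations_["r_a"].iloc[0]
        se = est.genetic_correlations_["se"].iloc[0]
        assert abs(r_a - 0.6) <= 3 * max(se, 0.1)

    def test_missing_rows_deleted_per_response(self, single_site_phenotypes):
        table, A = single_site_phenotypes
        table = table.copy()
        table.loc[table.index[:30], "T2"] = np.nan
        est = fq.MultiTraitREML(
            responses=[("T1", "S1"), ("T2", "S1")], groups=None,
            tol=1e-6, max_iter=400,
        ).fit(table, A)
        tr = est.loglik_trace_
        assert np.all(np.diff(tr) >= -1e-8 * np.maximum(1.0, np.abs(tr[:-1])))
        assert est.result_.n_obs == 2 * len(table) - 30


class TestBlup:
    def test_total_shrinkage_limit(self, rng):
        ids = [f"i{k}" for k in range(40)]
        df = pd.DataFrame(
            {"tree": ids, "site": "S", "replication": "R", "group": "g",
             "y": rng.normal(0, 1, 40)}
        )
        spec = ModelSpec(responses=[("y", None)], groups="group")
        b = blup_at(spec, df, identity_K(ids), uni_vc(1e-12, 1.0))
        assert b["blup"].abs().max() < 1e-9

    def test_no_shrinkage_limit(self, rng):
        ids = [f"i{k}" for k in range(40)]
        y = rng.normal(3, 1, 40)
        df = pd.DataFrame(
            {"tree": ids, "site": "S", "replication": "R", "group": "g", "y": y}
        )
        spec = ModelSpec(responses=[("y", None)], groups="group")
        b = blup_at(spec, df, identity_K(ids), uni_vc(1.0, 1e-10)).set_index("id")
        expected = pd.Series(y - y.mean(), index=ids)
        assert (b["blup"] - expected).abs().max() < 1e-7

    def test_accuracy_increases_with_heritability(self):
        from forestqg.simulate import TraitConfig

        cors = []
        for h2 in (0.1, 0.5, 0.9):
            truth = fq.simulate_pedigree(60, 6, 80, seed=68)
            A = fq.compute_A(truth.true_pedigree)
            cfg = TraitConfig(
                traits=["T"], sites=["S1"],
                heritability={("T", "S1"): h2}, replication_sd=0.0,
            )
            pheno = fq.simulate_phenotypes(
                truth, A, cfg,
                {t: "S1" for t in truth.progeny},
                {t: "R1" for t in truth.progeny},
                seed=69,
            )
            est = fq.AnimalModelREML(response="T", groups=None, tol=1e-6).fit(
                pheno, A
            )
            bv = est.breeding_values_.set_index("id")["blup"]
            true_bv = truth.true_breeding_values["T@S1"]
            common = true_bv.index.intersection(bv.index)
            cors.append(np.corrcoef(bv.loc[common], true_bv.loc[common])[0, 1])
        assert cors[0] < cors[1] < cors[2]

    def test_predict_blup_returns_copy(self, single_site_phenotypes):
        table, A = single_site_phenotypes
        est = fq.AnimalModelREML(response="T1", groups=None, tol=1e-5).fit(table, A)
        out = fq.predict_blup(est.result_)
        out.loc[:, "blup"] = 0.0
        assert not (est.breeding_values_["blup"] == 0).all()


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        est = fq.AnimalModelREML(response="HT", tol=1e-6)
        params = est.get_params()
        est2 = fq.AnimalModelREML(**params)
        assert est2.get_params() == params

    def test_clone_compatible(self):
        from sklearn.base import clone

        est = clone(fq.MultiTraitREML(responses=[("a", None), ("b", None)]))
        assert est.responses == [("a", None), ("b", None)]
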