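"""Synthetic-data generators: known-truth properties and replayability."""

import numpy as np
import pytest

import forestqg as fq
from forestqg.errors import ParameterError
from forestqg.pedigree import UNKNOWN
from forestqg.simulate import TraitConfig


class TestSimulatePedigree:
    def test_zero_contamination_records_true_dams(self):
        truth = fq.simulate_pedigree(10, 4, 20, contamination_rate=0.0, seed=1)
        rec = dict(zip(truth.recorded_pedigree.ids, truth.recorded_pedigree.dams))
        true = dict(zip(truth.true_pedigree.ids, truth.true_pedigree.dams))
        for child in truth.progeny:
            assert rec[child] == true[child]
        assert truth.contamination_events == []

    def test_progeny_count(self):
        truth = fq.simulate_pedigree(80, 8, 100, seed=2)
        assert len(truth.progeny) == 640

    def test_contamination_rate_binomial_bound(self):
        rate, n = 0.3, 1000
        truth = fq.simulate_pedigree(125, 8, 50, contamination_rate=rate, seed=3)
        frac = len(truth.contamination_events) / n
        bound = 3 * np.sqrt(rate * (1 - rate) / n)
        assert abs(frac - rate) <= bound

    def test_recorded_pedigree_hides_sires(self):
        truth = fq.simulate_pedigree(5, 3, 10, seed=4)
        assert all(s == UNKNOWN for s in truth.recorded_pedigree.sires)
        prog_sires = [
            s
            for i, s in zip(truth.true_pedigree.ids, truth.true_pedigree.sires)
            if i in set(truth.progeny)
        ]
        assert all(s != UNKNOWN for s in prog_sires)

    def test_invalid_rate_raises(self):
        with pytest.raises(ParameterError):
            fq.simulate_pedigree(5, 3, 10, contamination_rate=1.5, seed=0)

    def test_replay_identical(self):
        a = fq.simulate_pedigree(12, 5, 30, contamination_rate=0.2, seed=9)
        b = fq.simulate_pedigree(12, 5, 30, contamination_rate=0.2, seed=9)
        assert a.to_json() == b.to_json()

    def test_truth_json_round_trip(self):
        a = fq.simulate_pedigree(6, 3, 8, contamination_rate=0.3, seed=10)
        b = fq.SimulationTruth.from_json(a.to_json())
        assert b.to_json() == a.to_json()


class TestSimulateGenotypes:
    def test_mendelian_fixed_case(self):
        # both parents homozygous reference at a locus -> all offspring 0
        truth = fq.simulate_pedigree(4, 6, 6, seed=20)
        gm = fq.simulate_genotypes(truth, n_snps=300, seed=21)
        idx = {i: k for k, i in enumerate(gm.ids)}
        ped = truth.true_pedigree
        for child, s, d in zip(ped.ids, ped.sires, ped.dams):
            if s == UNKNOWN:
                continue
            both_zero = (gm.M[idx[s]] == 0) & (gm.M[idx[d]] == 0)
            assert np.all(gm.M[idx[child]][both_zero] == 0)

    def test_offspring_mean_near_midparent(self):
        truth = fq.simulate_pedigree(30, 8, 40, seed=22)
        gm = fq.simulate_genotypes(truth, n_snps=400, seed=23)
        idx = {i: k for k, i in enumerate(gm.ids)}
        ped = truth.true_pedigree
        diffs = []
        for child, s, d in zip(ped.ids, ped.sires, ped.dams):
            if s == UNKNOWN:
                continue
            mid = 0.5 * (gm.M[idx[s]] + gm.M[idx[d]])
            diffs.append(gm.M[idx[child]] - mid)
        diffs = np.concatenate(diffs)
        # each deviation has variance <= 0.5; mean over all loci x progeny
        se = np.sqrt(0.5 / diffs.size)
        assert abs(diffs.mean()) <= 3 * se

    def test_replay_and_missingness(self):
        truth = fq.simulate_pedigree(6, 4, 10, seed=24)
        a = fq.simulate_genotypes(truth, n_snps=200, missing_rate=0.3, seed=25)
        b = fq.simulate_genotypes(truth, n_snps=200, missing_rate=0.3, seed=25)
        assert np.array_equal(a.M, b.M, equal_nan=True)
        frac = np.isnan(a.M).mean()
        assert abs(frac - 0.3) < 0.03

    def test_realized_relationships_near_tabular_A(self, op_truth):
        gm = fq.simulate_genotypes(op_truth, n_snps=5000, seed=26)
        G = fq.compute_G(gm)
        A = fq.compute_A(op_truth.true_pedigree)
        devs = []
        ped = op_truth.true_pedigree
        for child, dam in zip(ped.ids, ped.dams):
            if dam != UNKNOWN:
                devs.append(G.loc(child, dam) - A.loc(child, dam))
        assert np.mean(np.abs(devs)) < 0.03


class TestSimulatePhenotypes:
    def _setup(self, truth, h2, r=None, seed=30):
        A = fq.compute_A(truth.true_pedigree)
        site_of = {t: "S1" for t in truth.progeny}
        rep_of = {t: "R1" for t in truth.progeny}
        traits = ["T1", "T2"] if r is not None else ["T1"]
        cfg = TraitConfig(
            traits=traits,
            sites=["S1"],
            heritability={(t, "S1"): h2 for t in traits},
            genetic_correlation=None if r is None else np.array([[1, r], [r, 1]]),
            replication_sd=0.0,
        )
        table = fq.simulate_phenotypes(truth, A, cfg, site_of, rep_of, seed=seed)
        return table, A

    def test_zero_heritability_no_family_signal(self, op_truth):
        table, _ = self._setup(op_truth, h2=0.0, seed=31)
        dam_of = dict(
            zip(op_truth.recorded_pedigree.ids, op_truth.recorded_pedigree.dams)
        )
        table["fam"] = table["tree"].map(dam_of)
        fam_means = table.groupby("fam")["T1"].mean()
        k = table.groupby("fam").size().iloc[0]
        # with no genetic signal the family-mean variance is ~ 1/k
        assert fam_means.var() < 3.0 / k

    def test_breeding_value_variance_matches_truth(self):
        truth = fq.simulate_pedigree(250, 8, 300, seed=32)
        table, A = self._setup(truth, h2=0.5, seed=33)
        bv = truth.true_breeding_values["T1@S1"]
        n = len(bv)
        se = 0.5 * np.sqrt(2.0 / n)  # rough sampling SE of a variance
        assert abs(bv.var() - 0.5) <= 3 * se

    def test_breeding_value_correlation_matches_truth(self):
        truth = fq.simulate_pedigree(250, 8, 300, seed=34)
        table, A = self._setup(truth, h2=0.5, r=0.9, seed=35)
        bv = truth.true_breeding_values
        r_hat = np.corrcoef(bv["T1@S1"], bv["T2@S1"])[0, 1]
        assert abs(r_hat - 0.9) <= 0.05

    def test_offspring_on_midfamily_bv_slope_one(self):
        truth = fq.simulate_pedigree(120, 8, 150, seed=36)
        table, A = self._setup(truth, h2=0.5, seed=37)
        bv = truth.true_breeding_values["T1@S1"]
        y = table.set_index("tree")["T1"]
        x = bv.loc[y.index]
        slope = np.polyfit(x, y, 1)[0]
        se = np.sqrt((y.var() / x.var() - slope**2) / (len(y) - 2))
        assert abs(slope - 1.0) <= 3 * max(se, 0.02)

    def test_non_psd_rejected(self, op_truth):
        A = fq.compute_A(op_truth.true_pedigree)
        cfg = TraitConfig(
            traits=["T1", "T2"],
            sites=["S1"],
            heritability={("T1", "S1"): 0.5, ("T2", "S1"): 0.5},
            genetic_correlation=np.array([[1.0, 1.5], [1.5, 1.0]]),
        )
        with pytest.raises(ParameterError):
            fq.simulate_phenotypes(
                op_truth, A, cfg,
                {t: "S1" for t in op_truth.progeny},
                {t: "R1" for t in op_truth.progeny},
                seed=1,
            )


class TestSimulateRingSeries:
    def test_no_drought_no_noise_resistance_one(self, op_truth):
        rings = fq.simulate_ring_series(
            op_truth, drought_severity=0.0, sensitivity_noise=0.0, seed=40
        )
        for s in list(rings.values())[:20]:
            assert fq.resistance(s, 2015) == pytest.approx(1.0)

    def test_default_severity_calibrated_to_population_mean(self):
        truth = fq.simulate_pedigree(100, 8, 120, seed=41)
        rings = fq.simulate_ring_series(truth, seed=42)
        res = [fq.resistance(s, 2015) for s in rings.values()]
        assert np.mean(res) == pytest.approx(0.57, abs=0.03)

    def test_sensitivity_increases_with_noise(self, op_truth):
        means = []
        for noise in (0.05, 0.2, 0.5):
            rings = fq.simulate_ring_series(
                op_truth, sensitivity_noise=noise, seed=43
            )
            means.append(np.mean([fq.mean_sensitivity(s) for s in rings.values()]))
        assert means[0] < means[1] < means[2]

    def test_empty_years_raise(self, op_truth):
        with pytest.raises(ParameterError):
            fq.simulate_ring_series(op_truth, years=range(0), seed=1)


class TestDegradePedigree:
    def test_zero_rate_identity(self, op_truth):
        out = fq.degrade_pedigree(op_truth, 0.0, seed=50)
        assert out.to_frame().equals(op_truth.recorded_pedigree.to_frame())

    def test_rate_one_two_families_swaps_all(self):
        truth = fq.simulate_pedigree(2, 5, 4, seed=51)
        out = fq.degrade_pedigree(truth, 1.0, seed=52)
        rec = dict(zip(truth.recorded_pedigree.ids, truth.recorded_pedigree.dams))
        new = dict(zip(out.ids, out.dams))
        for child in truth.progeny:
            assert new[child] != rec[child]

    def test_swap_count_within_binomial_interval(self):
        truth = fq.simulate_pedigree(80, 8, 100, seed=53)
        fq.degrade_pedigree(truth, 0.05, seed=54)
        n, p = 640, 0.05
        k = len(truth.swap_events)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(k - n * p) <= 2.58 * sd  # 99% interval
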