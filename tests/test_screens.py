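"""Drug, mutation and survival screens against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ppiscore.metrics import ppi_key
from ppiscore.screens import (
    DrugScreenInput,
    by_correction,
    correlate_drug_sensitivity,
    differential_essentiality,
    drug_screen,
    logrank_test,
    patient_status_records,
    ppi_presence_from_patient,
    qq_expected,
    rank_sum_test,
    survival_screen,
    target_enrichment,
)


class TestCorrelation:
    def test_perfect_positive(self):
        x = pd.Series(np.arange(10, dtype=float))
        r, p, n = correlate_drug_sensitivity(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_perfect_negative(self):
        x = pd.Series(np.arange(10, dtype=float))
        r, _, _ = correlate_drug_sensitivity(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_definitional_formulas(self):
        rng = np.random.default_rng(8)
        x = pd.Series(rng.random(8))
        y = pd.Series(rng.random(8))
        r, p, n = correlate_drug_sensitivity(x, y)
        # brute-force Pearson r and the t transform with n-2 df
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
        t = r_oracle * math.sqrt((n - 2) / (1 - r_oracle**2))
        p_oracle = 2 * stats.t.sf(abs(t), df=n - 2)
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_missing_lines_excluded(self):
        x = pd.Series([0.1, np.nan, 0.5, 0.9, 0.2], index=list("abcde"))
        y = pd.Series([1.0, 2.0, 3.0, 4.0, np.nan], index=list("abcde"))
        _, _, n = correlate_drug_sensitivity(x, y)
        assert n == 3

    def test_zero_variance_errors(self):
        x = pd.Series([0.5] * 5)
        y = pd.Series(np.arange(5, dtype=float))
        with pytest.raises(ValueError, match="variance"):
            correlate_drug_sensitivity(x, y)


class TestRankSum:
    def test_u_statistic_matches_pair_counting(self):
        a = np.array([3.1, 0.2, 5.5, 2.2])
        b = np.array([1.0, 0.5, 4.0])
        u, _ = rank_sum_test(a, b, alternative="greater")
        u_oracle = sum(
            1.0 if ai > bi else 0.5 if ai == bi else 0.0
            for ai in a for bi in b
        )
        assert u == pytest.approx(u_oracle)

    def test_exact_p_matches_label_enumeration(self):
        # enumerate all C(8, 4) group assignments of the pooled sample
        a = np.array([2.3, 4.1, 5.0, 6.7])
        b = np.array([1.1, 0.4, 3.3, 2.9])
        u_obs, p = rank_sum_test(a, b, alternative="greater", method="exact")
        pooled = np.concatenate([a, b])
        n_ge = 0
        combos = list(itertools.combinations(range(8), 4))
        for idx in combos:
            mask = np.zeros(8, bool)
            mask[list(idx)] = True
            u = sum(
                1.0 if x > y else 0.5 if x == y else 0.0
                for x in pooled[mask] for y in pooled[~mask]
            )
            if u >= u_obs:
                n_ge += 1
        assert p == pytest.approx(n_ge / len(combos), abs=1e-12)


class TestTargetEnrichment:
    def _planted_matrix(self, seed=0):
        # 8 target-touching PPIs score high (Beta(8,2)); 70 background PPIs
        # on 140 further genes score low (Beta(2,8)). The ~150-gene universe
        # mirrors a small pathway network, where a permutation redrawing the
        # planted target itself is a ~1/150 event.
        rng = np.random.default_rng(seed)
        target = "T00"
        keys = [ppi_key(target, f"P{i:02d}") for i in range(8)]
        keys += [ppi_key(f"Q{i:03d}", f"R{i:03d}") for i in range(70)]
        vals = {
            k: (rng.beta(8, 2, size=12) if target in k.split("_") else rng.beta(2, 8, size=12))
            for k in keys
        }
        return pd.DataFrame(vals).T, {target}

    def test_planted_effect_recovered(self):
        matrix, targets = self._planted_matrix()
        res = target_enrichment(matrix, targets, n_perm=1000, seed=1)
        assert res.evaluable
        assert res.p_value < 1e-6
        assert res.adjusted < 0.01

    def test_no_target_ppis_not_evaluable(self):
        matrix, _ = self._planted_matrix()
        res = target_enrichment(matrix, {"ZZZ"}, n_perm=100, seed=1)
        assert not res.evaluable

    def test_targets_covering_all_ppis_error(self):
        matrix, _ = self._planted_matrix()
        all_genes = {g for k in matrix.index for g in k.split("_")}
        with pytest.raises(ValueError, match="non-target"):
            target_enrichment(matrix, all_genes, n_perm=100, seed=1)

    def test_deterministic_given_seed(self):
        matrix, targets = self._planted_matrix()
        r1 = target_enrichment(matrix, targets, n_perm=200, seed=7)
        r2 = target_enrichment(matrix, targets, n_perm=200, seed=7)
        assert r1.adjusted == r2.adjusted

    def test_fdr_floor(self):
        matrix, targets = self._planted_matrix()
        res = target_enrichment(matrix, targets, n_perm=1000, seed=3)
        assert res.adjusted >= 1 / 1000


class TestDifferentialEssentiality:
    def _matrix(self, n_ppis=40, n_mut=8, n_wt=12, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        cols = [f"M{i}" for i in range(n_mut)] + [f"W{i}" for i in range(n_wt)]
        base = rng.normal(0.5, 0.1, size=(n_ppis, n_mut + n_wt))
        base[: n_ppis // 4, :n_mut] += shift
        m = pd.DataFrame(base, columns=cols,
                         index=[ppi_key(f"A{i}", f"B{i}") for i in range(n_ppis)])
        labels = {c: ("mutant" if c.startswith("M") else "wildtype") for c in cols}
        return m, labels

    def test_planted_shift_tops_ranking(self):
        m, labels = self._matrix(shift=0.3, seed=1)
        res = differential_essentiality(m, labels)
        planted = {f"A{i}_B{i}" for i in range(10)}
        top10 = {r.unit for r in res[:10]}
        assert len(top10 & planted) >= 9
        assert all(r.statistic > 0 for r in res[:10])

    def test_bh_matches_statsmodels(self):
        m, labels = self._matrix(shift=0.2, seed=2)
        res = differential_essentiality(m, labels)
        res_by_unit = {r.unit: r for r in res}
        p = np.array([res_by_unit[u].p_value for u in m.index])
        adj = multipletests(p, method="fdr_bh")[1]
        for u, a in zip(m.index, adj):
            assert res_by_unit[u].adjusted == pytest.approx(a)

    def test_null_uniformish(self):
        m, labels = self._matrix(shift=0.0, seed=3, n_ppis=200)
        res = differential_essentiality(m, labels)
        frac = np.mean([r.p_value < 0.05 for r in res])
        assert frac < 0.12

    def test_single_ppi_equal_groups(self):
        m = pd.DataFrame(
            [[0.5, 0.6, 0.5, 0.6]], index=["A_B"], columns=["M0", "M1", "W0", "W1"]
        )
        labels = {"M0": "mutant", "M1": "mutant", "W0": "wildtype", "W1": "wildtype"}
        res = differential_essentiality(m, labels)
        assert res[0].statistic == pytest.approx(0.0, abs=1e-12)
        assert res[0].p_value == pytest.approx(1.0)

    def test_empty_group_errors(self):
        m, labels = self._matrix()
        labels = {c: "mutant" for c in labels}
        with pytest.raises(ValueError):
            differential_essentiality(m, labels)

    def test_underpowered_rows_skipped(self):
        m, labels = self._matrix(n_ppis=5)
        m.iloc[0, :7] = np.nan  # only 1 mutant value left
        res = differential_essentiality(m, labels)
        assert len(res) == 4


class TestPPIPresence:
    @pytest.mark.parametrize(
        "muts,expected",
        [
            ([("A", "nonsense", "normal")], False),
            ([("B", "missense", "normal")], True),
            ([], True),
            ([("B", "frameshift", "normal")], False),
            ([("A", "missense", "homozygous_deletion")], False),
            ([("C", "nonsense", "normal")], True),  # not a partner
        ],
    )
    def test_absence_rule(self, muts, expected):
        assert ppi_presence_from_patient(muts, ("A", "B")) is expected

    def test_unknown_variant_ignored(self, caplog):
        assert ppi_presence_from_patient([("A", "weird_class", "normal")], ("A", "B"))


class TestLogrank:
    def test_identical_groups_null(self):
        times = [5, 10, 15, 5, 10, 15]
        events = [1, 1, 0, 1, 1, 0]
        groups = [0, 0, 0, 1, 1, 1]
        chi2, p = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_oracle(self):
        # group a: events at 2, 4; censored at 5. group b: events at 6, 8; censored at 9.
        times = [2, 4, 5, 6, 8, 9]
        events = [1, 1, 0, 1, 1, 0]
        groups = list("aaabbb")
        # risk tables by hand:
        # t=2: N=6, N_a=3, d=1, d_a=1 -> E=0.5,  V=1*(3/6)*(3/6)*(5/5)=0.25
        # t=4: N=5, N_a=2, d=1, d_a=1 -> E=0.4,  V=(2/5)*(3/5)*(4/4)=0.24
        # t=6: N=3, N_a=0, d=1, d_a=0 -> E=0.0,  V=0
        # t=8: N=2, N_a=0, d=1, d_a=0 -> E=0.0,  V=0
        o_minus_e = (1 - 0.5) + (1 - 0.4)
        var = 0.25 + 0.24
        chi2_expected = o_minus_e**2 / var
        chi2, p = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(chi2_expected, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(chi2_expected, 1), abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(9)
        t1 = rng.exponential(10, 40)
        t2 = rng.exponential(20, 35)
        c1, c2 = t1 < 15, t2 < 15
        chi2, p = logrank_test(
            np.concatenate([np.minimum(t1, 15), np.minimum(t2, 15)]),
            np.concatenate([c1, c2]),
            np.array([0] * 40 + [1] * 35),
        )
        ll = ll_logrank(np.minimum(t1, 15), np.minimum(t2, 15), c1, c2)
        assert chi2 == pytest.approx(ll.test_statistic, rel=1e-9)
        assert p == pytest.approx(ll.p_value, rel=1e-9)

    def test_planted_hazard_detected(self):
        rng = np.random.default_rng(11)
        n = 100
        t1 = rng.exponential(1.0, n)  # hazard 1
        t2 = rng.exponential(1 / 3.0, n)  # hazard 3
        times = np.concatenate([t1, t2])
        events = np.ones(2 * n, bool)
        _, p = logrank_test(times, events, np.repeat([0, 1], n))
        assert p < 0.01

    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestBYCorrection:
    def test_single_p_unchanged(self):
        assert by_correction([0.03])[0] == pytest.approx(0.03)

    def test_harmonic_formula_oracle(self):
        p = [0.01, 0.01, 0.01, 0.01]
        c4 = 1 + 1 / 2 + 1 / 3 + 1 / 4  # 25/12
        # all equal: step-up gives p * m * c(m) / m = p * c(m)... via the
        # smallest ratio at j=4: 0.01 * 4 * c4 / 4, then min-accumulate
        expected = min(1.0, 0.01 * 4 * c4 / 4)
        got = by_correction(p)
        assert np.allclose(got, expected)
        assert c4 == pytest.approx(25 / 12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        got = by_correction(p)
        ref = multipletests(p, method="fdr_by")[1]
        assert np.allclose(got, ref, atol=1e-12)

    def test_inflation_ordering(self):
        rng = np.random.default_rng(5)
        p = rng.random(30)
        bh = multipletests(p, method="fdr_bh")[1]
        by = by_correction(p)
        assert (by >= bh - 1e-12).all()
        assert (by >= p - 1e-12).all()
        assert (by <= 1.0).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            by_correction([0.5, 1.2])


class TestQQ:
    def test_small_example(self):
        df = qq_expected([0.5, 0.1, 0.9])
        assert np.allclose(df["expected"], [0.25, 0.5, 0.75])
        assert np.allclose(df["observed"], [0.1, 0.5, 0.9])

    def test_uniform_null_near_diagonal(self):
        p = np.random.default_rng(3).random(1000)
        df = qq_expected(p)
        assert np.max(np.abs(df["expected"] - df["observed"])) < 0.05

    def test_planted_signal_lifts_early_quantiles(self):
        rng = np.random.default_rng(4)
        p = np.concatenate([rng.random(900), rng.random(100) * 1e-4])
        df = qq_expected(p)
        early = df.iloc[:100]
        assert (early["neglog10_observed"] > early["neglog10_expected"]).all()


class TestSurvivalScreen:
    def _records(self, seed, n_patients=120, planted_ppi=None, ppis=None, hr=3.0):
        rng = np.random.default_rng(seed)
        ppis = ppis or [f"A{i}_B{i}" for i in range(6)]
        records = []
        presence = {ppi: rng.random(n_patients) < 0.5 for ppi in ppis}
        for i in range(n_patients):
            base = rng.exponential(1000)
            for ppi in ppis:
                present = bool(presence[ppi][i])
                if ppi == planted_ppi:
                    t = rng.exponential(1000 / (hr if present else 1.0))
                else:
                    t = base
                records.append(
                    dict_to_status(f"P{i}", ppi, present, min(t, 3000), t <= 3000)
                )
        return records, ppis

    def test_planted_ppi_flagged_alone(self):
        records, ppis = self._records(seed=0, planted_ppi="A0_B0", n_patients=200)
        ks = {p: (0.8 if p == "A0_B0" else 0.1) for p in ppis}
        table = survival_screen(records, ks)
        assert table["passes"].sum() == 1
        assert table.index[table["passes"]][0] == "A0_B0"

    def test_unattainable_ks_gate_empty(self):
        records, ppis = self._records(seed=1, planted_ppi="A0_B0")
        ks = {p: 0.9 for p in ppis}
        table = survival_screen(records, ks, ks_threshold=1.0)
        assert table["passes"].sum() == 0

    def test_by_at_least_nominal(self):
        records, ppis = self._records(seed=2)
        table = survival_screen(records, {p: 0.0 for p in ppis})
        ev = table["evaluable"]
        assert (table.loc[ev, "p_by"] >= table.loc[ev, "p"] - 1e-12).all()

    def test_one_sided_group_not_evaluable(self):
        records, ppis = self._records(seed=3, ppis=["X_Y"])
        for r in records:
            r.present = True
        table = survival_screen(records, {"X_Y": 0.9})
        assert not table["evaluable"].any()


def dict_to_status(patient, ppi, present, time, event):
    from ppiscore.screens import PatientPPIStatus

    return PatientPPIStatus(patient=patient, ppi=ppi, present=present,
                            time=float(time), event=bool(event))


class TestPatientStatusRecords:
    def test_presence_crossed_with_clinical(self):
        mutations = pd.DataFrame(
            [("P1", "A", "nonsense", "normal"), ("P2", "C", "missense", "normal")],
            columns=["patient", "gene", "variant_class", "copy_state"],
        )
        clinical = pd.DataFrame(
            [("P1", 100.0, 1), ("P2", 300.0, 0)],
            columns=["patient", "time_days", "event"],
        )
        recs = patient_status_records(mutations, clinical, ["A_B", "C_D"])
        by = {(r.patient, r.ppi): r for r in recs}
        assert not by[("P1", "A_B")].present
        assert by[("P1", "C_D")].present
        assert by[("P2", "C_D")].present  # missense does not remove
        assert by[("P2", "C_D")].time == 300.0
        assert by[("P2", "C_D")].event is False


class TestDrugScreenWrapper:
    def test_planted_compound_flagged(self, small_world):
        from ppiscore.pipeline import build_matrix
        from ppiscore.simulate import planted_choices

        world = small_world
        matrix = build_matrix(world["sp"], world["shrna"], contexts=world["contexts"])
        results = drug_screen(matrix, world["drug"], n_perm=200, seed=5)
        by_unit = {r.unit: r for r in results}
        planted = by_unit["planted-compound"]
        # at this reduced network scale the permutation FDR resolution is
        # limited by the ~55-gene universe; the planted compound must still
        # dominate the decoys and be overwhelmingly nominally significant
        assert planted.p_value < 1e-10
        assert planted.adjusted <= min(r.adjusted for r in results if r.evaluable)
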