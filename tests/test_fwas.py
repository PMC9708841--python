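"""Association layer: preprocessing, pruning, linear and Cox FWAS, FDR,
enrichment, reaction-system annotation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import personaflux as pf
from personaflux.exceptions import ValidationError
from personaflux.fwas import one_sided_fisher_p


def _ids(n, prefix="i"):
    return [f"{prefix}{k:04d}" for k in range(n)]


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert pf.bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_step_up(self):
        assert pf.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=40))
        adj = pf.bh_adjust(p)
        assert (np.diff(adj) >= -1e-15).all()
        assert (adj <= 1).all() and (adj >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            pf.bh_adjust([0.5, 1.5])

    def test_matches_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.max(np.abs(pf.bh_adjust(p) - ref)) < 1e-12


class TestPreprocessFeatures:
    def _raw(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        idx = _ids(n)
        raw = pd.DataFrame(
            {"f1": rng.normal(size=n), "f2": rng.normal(size=n)}, index=idx
        )
        cov = pd.DataFrame({"age": rng.uniform(40, 70, n), "sex": rng.integers(0, 2, n)},
                           index=idx)
        return raw, cov

    def test_mostly_missing_feature_dropped(self):
        raw, cov = self._raw()
        raw.loc[raw.index[:32], "f2"] = np.nan  # 80% missing
        out = pf.preprocess_features(raw, cov)
        assert "f2" in out.dropped["missing"]
        assert "f2" not in out.values.columns

    def test_discrepant_variance_dropped(self):
        raw, cov = self._raw()
        sd_other = pd.Series({"f1": raw["f1"].std(ddof=1), "f2": raw["f2"].std(ddof=1) / 3})
        out = pf.preprocess_features(raw, cov, sd_other=sd_other)
        assert "f2" in out.dropped["variance_ratio"]
        assert "f1" in out.values.columns

    def test_orthogonal_feature_unchanged_up_to_scale(self):
        raw, cov = self._raw()
        out = pf.preprocess_features(raw, covariates=None)
        r = np.corrcoef(out.values["f1"], raw["f1"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)
        assert out.values["f1"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out.values["f1"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_residualisation_removes_covariate_correlation(self):
        raw, cov = self._raw(n=200, seed=3)
        raw["f1"] = raw["f1"] + 0.1 * cov["age"]
        out = pf.preprocess_features(raw, cov)
        assert abs(np.corrcoef(out.values["f1"], cov["age"])[0, 1]) < 1e-10

    def test_all_features_dropped_errors(self):
        raw = pd.DataFrame({"f1": [np.nan] * 10}, index=_ids(10))
        with pytest.raises(ValidationError):
            pf.preprocess_features(raw)


class TestPruneCorrelated:
    def test_uncorrelated_columns_all_kept(self):
        rng = np.random.default_rng(1)
        cols = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        assert pf.prune_correlated(cols, 0.9) == list("abcd")

    def test_duplicated_column_loses_exactly_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        cols = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)})
        kept = pf.prune_correlated(cols, 0.9)
        assert len(kept) == 2 and "c" in kept
        assert len({"a", "b"} & set(kept)) == 1

    def test_hub_column_removed(self):
        # hub correlates ~0.67 with each spoke, spokes ~uncorrelated: the
        # greedy rule must drop the hub (largest mean absolute correlation)
        rng = np.random.default_rng(3)
        z1, z2 = rng.normal(size=(2, 4000))
        hub = z1 + z2
        s1 = z1 + 0.32 * rng.normal(size=4000)
        s2 = z2 + 0.32 * rng.normal(size=4000)
        cols = pd.DataFrame({"hub": hub / hub.std(), "s1": s1, "s2": s2})
        corr = cols.corr().abs()
        assert corr.loc["hub", "s1"] > 0.6 and corr.loc["hub", "s2"] > 0.6
        assert corr.loc["s1", "s2"] < 0.6
        assert pf.prune_correlated(cols, 0.6) == ["s1", "s2"]

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(300, 3))
        cols = pd.DataFrame(
            np.column_stack([base, base[:, 0] + 0.1 * rng.normal(size=300)]),
            columns=list("abcd"),
        )
        kept = pf.prune_correlated(cols, 0.9)
        assert pf.prune_correlated(cols[kept], 0.9) == kept


class TestLinearFwas:
    def test_perfect_fit(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        fluxes = pd.DataFrame({"R": x}, index=_ids(100))
        feats = pd.DataFrame({"f": x}, index=_ids(100))
        res = pf.LinearFwas(fluxes, feats).fit()
        row = res.table.iloc[0]
        assert row["effect"] == pytest.approx(1.0, abs=1e-12)
        assert row["p"] == 0.0
        assert row["r_squared"] == pytest.approx(1.0)

    def test_null_type_one_error_rate(self):
        # global null: 200 independent flux-feature pairs, n = 1000
        rng = np.random.default_rng(106)
        n = 1000
        fluxes = pd.DataFrame(rng.normal(size=(n, 20)),
                              columns=[f"R{k}" for k in range(20)], index=_ids(n))
        feats = pd.DataFrame(rng.normal(size=(n, 10)),
                             columns=[f"f{k}" for k in range(10)], index=_ids(n))
        res = pf.LinearFwas(fluxes, feats).fit()
        assert len(res.table) == 200
        frac = (res.table["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_null_p_values_uniform(self):
        # Kolmogorov-Smirnov on 500 independent pairs should not reject
        rng = np.random.default_rng(77)
        n = 400
        fluxes = pd.DataFrame(rng.normal(size=(n, 25)),
                              columns=[f"R{k}" for k in range(25)], index=_ids(n))
        feats = pd.DataFrame(rng.normal(size=(n, 20)),
                             columns=[f"f{k}" for k in range(20)], index=_ids(n))
        res = pf.LinearFwas(fluxes, feats).fit()
        assert len(res.table) == 500
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_effect_recovered_within_three_se(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.normal(size=n)
        fluxes = pd.DataFrame({"R": x}, index=_ids(n))
        feats = pd.DataFrame({"f": 0.3 * x + rng.normal(size=n)}, index=_ids(n))
        row = pf.LinearFwas(fluxes, feats).fit().table.iloc[0]
        assert abs(row["effect"] - 0.3) < 3 * row["se"]

    def test_zero_variance_flux_skipped_with_note(self):
        rng = np.random.default_rng(9)
        fluxes = pd.DataFrame(
            {"R": rng.normal(size=50), "flat": np.ones(50)}, index=_ids(50)
        )
        feats = pd.DataFrame({"f": rng.normal(size=50)}, index=_ids(50))
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pf.LinearFwas(fluxes, feats).fit()
        assert set(res.table["flux"]) == {"R"}

    def test_insufficient_overlap_errors(self):
        fluxes = pd.DataFrame({"R": np.arange(5.0)}, index=_ids(5))
        feats = pd.DataFrame({"f": np.arange(5.0)}, index=_ids(5))
        with pytest.raises(ValidationError, match="overlap"):
            pf.LinearFwas(fluxes, feats).fit()

    def test_adjustment_spans_all_pairs_jointly(self):
        rng = np.random.default_rng(10)
        n = 200
        fluxes = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"), index=_ids(n))
        feats = pd.DataFrame(rng.normal(size=(n, 2)), columns=["f1", "f2"], index=_ids(n))
        res = pf.LinearFwas(fluxes, feats).fit()
        assert np.max(np.abs(
            pf.bh_adjust(res.table["p"].to_numpy()) - res.table["adjusted_p"].to_numpy()
        )) < 1e-15
        assert (res.table["adjusted_p"] >= res.table["p"] - 1e-15).all()


class TestCoxFwas:
    def _fluxes(self, n, k=1, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, k)),
                            columns=[f"R{j}" for j in range(k)], index=_ids(n))

    def test_null_hazard_ratio_near_one(self):
        fluxes = self._fluxes(2000, seed=11)
        surv = pf.simulate_survival(fluxes, log_hrs={}, seed=11)
        row = pf.CoxFwas(fluxes, surv).fit().table.iloc[0]
        assert abs(row["log_hr"]) < 3 * row["se"]

    def test_planted_log_hr_recovered(self):
        fluxes = self._fluxes(5000, seed=12)
        surv = pf.simulate_survival(fluxes, log_hrs={"R0": 0.1}, censoring=0.7, seed=12)
        row = pf.CoxFwas(fluxes, surv).fit().table.iloc[0]
        assert abs(row["log_hr"] - 0.1) < 3 * row["se"]

    def test_duplicated_flux_identical_results(self):
        fluxes = self._fluxes(500, seed=13)
        fluxes["copy"] = fluxes["R0"]
        surv = pf.simulate_survival(fluxes[["R0"]], log_hrs={"R0": 0.2}, seed=13)
        table = pf.CoxFwas(fluxes, surv).fit().table.set_index("flux")
        assert table.loc["R0", "log_hr"] == pytest.approx(table.loc["copy", "log_hr"])
        assert table.loc["R0", "p"] == pytest.approx(table.loc["copy", "p"])

    def test_too_few_events_per_stratum_errors(self):
        fluxes = self._fluxes(30, seed=14)
        surv = pf.simulate_survival(fluxes, seed=14)
        surv.loc[surv["sex"] == "male", "event"] = False
        with pytest.raises(ValidationError, match="stratum"):
            pf.CoxFwas(fluxes, surv).fit()


class TestFisherEnrichment:
    def test_closed_form_tail(self):
        # table a=5, b=5, c=10, d=80 -> P(X >= 5 | N=100, K=15, n=10)
        want = sum(
            math.comb(15, a) * math.comb(85, 10 - a) / math.comb(100, 10)
            for a in range(5, 11)
        )
        assert one_sided_fisher_p(5, 5, 10, 80) == pytest.approx(want, rel=1e-12)

    def test_matches_scipy_fisher_exact_spot_checks(self):
        for table in [(3, 7, 2, 38), (0, 10, 5, 35), (8, 2, 1, 39)]:
            a, b, c, d = table
            _, want = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            assert one_sided_fisher_p(a, b, c, d) == pytest.approx(want, rel=1e-9)

    def test_zero_hit_label_not_enriched(self):
        universe = {f"x{i}" for i in range(20)}
        groups = {i: ("L" if i < "x2" else "M") for i in universe}
        hits = {i for i in universe if groups[i] == "M"}
        table = pf.fisher_enrichment(hits, universe, groups).set_index("label")
        assert table.loc["L", "p"] >= 0.5

    def test_hits_equal_universe_all_p_one(self):
        universe = {f"x{i}" for i in range(10)}
        groups = {i: ("A" if i < "x5" else "B") for i in universe}
        table = pf.fisher_enrichment(universe, universe, groups)
        assert (table["p"] == 1.0).all()

    def test_unlabelled_items_excluded(self):
        universe = {"a", "b", "c", "d"}
        groups = {"a": "L", "b": "L"}
        table = pf.fisher_enrichment({"a"}, universe, groups)
        assert table["hits_in"].sum() + table["nonhits_in"].sum() == 2

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            pf.fisher_enrichment({"z"}, {"a"}, {"a": "L"})


class TestSystemAnnotation:
    def _net(self):
        mets = [
            pf.Metabolite("ala_c", "c"), pf.Metabolite("ala_e", "e"),
            pf.Metabolite("na1_c", "c"), pf.Metabolite("na1_e", "e"),
            pf.Metabolite("orphan", "c"),
        ]
        rxns = [
            pf.Reaction("AAT1", {"ala_c": -1, "na1_c": 1}, 0, 10,
                        subsystem="Amino acid metabolism"),
            pf.Reaction("AAT2", {"ala_c": 1}, 0, 10, subsystem="Amino acid metabolism"),
            pf.Reaction("AAT3", {"ala_c": -1}, 0, 10, subsystem="Amino acid metabolism"),
            pf.Reaction("GLY1", {"ala_c": -1, "na1_c": -1}, 0, 10, subsystem="Glycolysis"),
            pf.Reaction("SYM", {"ala_e": -1, "na1_e": -1, "ala_c": 1, "na1_c": 1},
                        0, 10, subsystem="Transport reactions"),
            pf.Reaction("UNI", {"ala_e": 1}, 0, 10, subsystem="Exchange reactions"),
        ]
        return pf.MetabolicNetwork(mets, rxns)

    def test_metabolite_gets_modal_system(self):
        labels, ties = pf.assign_metabolite_system(self._net())
        assert labels["ala_c"] == "Amino acid metabolism"  # 3 votes vs 1
        assert not ties["ala_c"]

    def test_single_reaction_metabolite(self):
        net = self._net()
        labels, _ = pf.assign_metabolite_system(net)
        assert labels["ala_e"] == "Miscellaneous"  # only transport touches it

    def test_orphan_is_miscellaneous(self):
        labels, _ = pf.assign_metabolite_system(self._net())
        assert labels["orphan"] == "Miscellaneous"

    def test_subsystem_merge_applied(self):
        labels, _ = pf.assign_metabolite_system(
            self._net(), subsystem_merge={"Amino acid metabolism": "AA"}
        )
        assert labels["ala_c"] == "AA"

    def test_symporter_inherits_cargo_system(self):
        net = self._net()
        met_labels = pd.Series(
            {"ala_c": "Amino acid metabolism", "ala_e": "Amino acid metabolism",
             "na1_c": "Miscellaneous", "na1_e": "Miscellaneous"}
        )
        labels, ties = pf.assign_transport_system(net, met_labels)
        assert labels["SYM"] == "Amino acid metabolism"
        assert not ties["SYM"]

    def test_uniport_takes_metabolite_system(self):
        labels, _ = pf.assign_transport_system(
            self._net(), pd.Series({"ala_e": "Amino acid metabolism"})
        )
        assert labels["UNI"] == "Amino acid metabolism"

    def test_balanced_vote_is_tie(self):
        net = pf.MetabolicNetwork(
            [pf.Metabolite("x_e"), pf.Metabolite("y_e")],
            [pf.Reaction("T", {"x_e": -1, "y_e": 1}, 0, 1, subsystem="Transport reactions")],
        )
        labels, ties = pf.assign_transport_system(
            net, pd.Series({"x_e": "SystemA", "y_e": "SystemB"})
        )
        assert labels["T"] == "Miscellaneous"
        assert ties["T"]
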