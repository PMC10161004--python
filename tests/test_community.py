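"""CTI, census filters, and the counterfactual demographic decomposition."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_trees, random_community, random_subplot_trees
from forestcti import (
    basal_area,
    classify_recruit_origin,
    community_temperature_index,
    conifer_basal_fraction,
    counterfactual_t2,
    decompose,
    filter_census_trees,
    sapling_cti,
)
from forestcti.community import MissingSpeciesIndexError, census_view


class TestBasalArea:
    def test_census_threshold_value(self):
        assert basal_area(12.7) == pytest.approx(126.6769, abs=1e-4)

    def test_unit_circle(self):
        assert basal_area(2.0) == pytest.approx(np.pi)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(1, 100, 20)
        assert np.allclose(basal_area(2 * d), 4 * basal_area(d))

    @pytest.mark.parametrize("bad", [0.0, -3.0, np.nan])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            basal_area(bad)


def _view(rows):
    df = make_trees(rows)
    df["dbh"] = df["dbh_t1_cm"]
    return df


class TestCensusFilter:
    def test_distance_boundary(self):
        df = _view(
            [
                (0, 0, 0, 0, 20.0, np.nan, 7.33, "died", "main"),
                (1, 0, 0, 0, 20.0, np.nan, 7.32, "died", "main"),
            ]
        )
        kept = filter_census_trees(df)
        assert list(kept["tree_id"]) == [1]

    def test_dbh_boundary_inclusive(self):
        df = _view([(0, 0, 0, 0, 12.7, np.nan, 7.32, "died", "main")])
        assert len(filter_census_trees(df)) == 1

    def test_empty_input(self):
        df = _view([])
        assert len(filter_census_trees(df)) == 0


class TestCTI:
    def test_single_species_identity(self):
        com = pd.DataFrame({"species_id": [0, 0, 0], "dbh": [13.0, 40.0, 55.0]})
        assert community_temperature_index(com, {0: 9.5}) == pytest.approx(9.5)

    def test_weighted_mean_example(self):
        # BA ratio 1:3 via dbh 2 and 2*sqrt(3)
        com = pd.DataFrame({"species_id": [0, 1], "dbh": [2.0, 2.0 * np.sqrt(3)]})
        got = community_temperature_index(com, {0: 5.0, 1: 10.0})
        assert got == pytest.approx(8.75, abs=1e-12)

    def test_matches_per_individual_brute_force(self):
        rng = np.random.default_rng(1)
        idx = {s: 5.0 + 0.8 * s for s in range(5)}
        for _ in range(200):
            com = random_community(rng)
            got = community_temperature_index(com, idx)
            num = den = 0.0
            for _, t in com.iterrows():
                ba = np.pi * (t["dbh"] / 2) ** 2
                num += ba * idx[t["species_id"]]
                den += ba
            assert got == pytest.approx(num / den, rel=1e-12)

    def test_bounded_by_present_species_indices(self):
        rng = np.random.default_rng(2)
        idx = {s: rng.uniform(0, 20) for s in range(5)}
        for _ in range(50):
            com = random_community(rng)
            vals = [idx[s] for s in com["species_id"]]
            cti = community_temperature_index(com, idx)
            assert min(vals) - 1e-12 <= cti <= max(vals) + 1e-12

    def test_invariant_to_splitting_a_tree(self):
        com = pd.DataFrame({"species_id": [0, 1], "dbh": [30.0, 40.0]})
        # replace the 40 cm tree by two trees with the same total basal area
        half = 40.0 / np.sqrt(2)
        split = pd.DataFrame(
            {"species_id": [0, 1, 1], "dbh": [30.0, half, half]}
        )
        idx = {0: 5.0, 1: 12.0}
        assert community_temperature_index(split, idx) == pytest.approx(
            community_temperature_index(com, idx), rel=1e-12
        )

    def test_zero_basal_area_is_undefined_not_a_crash(self):
        com = pd.DataFrame({"species_id": [], "dbh": []})
        assert np.isnan(community_temperature_index(com, {0: 5.0}))

    def test_missing_species_index_named(self):
        com = pd.DataFrame({"species_id": [3], "dbh": [20.0]})
        with pytest.raises(MissingSpeciesIndexError, match="3"):
            community_temperature_index(com, {0: 5.0})


@pytest.fixture
def toy_subplot():
    """One dies, three grow, one recruits."""
    return make_trees(
        [
            (0, 0, 0, 0, 30.0, np.nan, 3.0, "died", "main"),
            (1, 0, 0, 0, 20.0, 24.0, 2.0, "survivor", "main"),
            (2, 0, 0, 1, 25.0, 27.0, 4.0, "survivor", "main"),
            (3, 0, 0, 1, 40.0, 45.0, 5.0, "survivor", "main"),
            (4, 0, 0, 1, np.nan, 13.0, 1.0, "recruit", "main"),
        ]
    )


class TestCounterfactuals:
    def test_mortality_scenario_toy(self, toy_subplot):
        cf = counterfactual_t2(toy_subplot, "mortality")
        # survivors held at first-census size; the dead tree is removed
        # (mortality is the acting process) and the recruit is omitted
        assert len(cf) == 3
        assert set(cf["fate"]) == {"survivor"}
        assert np.allclose(cf["dbh"], cf["dbh_t1_cm"])

    def test_growth_scenario_keeps_dead_at_t1_size(self, toy_subplot):
        cf = counterfactual_t2(toy_subplot, "growth")
        assert len(cf) == 4
        dead = cf[cf["fate"] == "died"]
        assert np.allclose(dead["dbh"], dead["dbh_t1_cm"])

    def test_recruitment_scenario_count(self, toy_subplot):
        cf = counterfactual_t2(toy_subplot, "recruitment")
        n_t1 = (toy_subplot["fate"] != "recruit").sum()
        n_rec = (toy_subplot["fate"] == "recruit").sum()
        assert len(cf) == n_t1 + n_rec

    def test_all_scenario_is_observed_t2(self, toy_subplot):
        cf = counterfactual_t2(toy_subplot, "all")
        obs = census_view(toy_subplot, 2)
        assert sorted(cf["tree_id"]) == sorted(obs["tree_id"])

    def test_static_community_identical_under_all_scenarios(self):
        static = make_trees(
            [(i, 0, 0, i % 2, 20.0 + i, 20.0 + i, 3.0, "survivor", "main")
             for i in range(4)]
        )
        frames = [counterfactual_t2(static, s) for s in
                  ("all", "mortality", "growth", "recruitment")]
        for f in frames[1:]:
            assert np.allclose(
                np.sort(f["dbh"].to_numpy()), np.sort(frames[0]["dbh"].to_numpy())
            )

    def test_unknown_scenario_rejected(self, toy_subplot):
        with pytest.raises(ValueError):
            counterfactual_t2(toy_subplot, "immigration")


class TestDecomposition:
    IDX = {s: 4.0 + 1.7 * s for s in range(6)}

    def test_fig_style_toy_mortality_component(self, toy_subplot):
        idx = {0: 5.0, 1: 12.0}
        res = decompose(toy_subplot, idx)
        # the death removes species-0 (cool) basal area -> warming of the index
        assert res.delta_mortality > 0
        assert np.isfinite(res.delta_total)

    def test_mortality_only_equals_total(self):
        t = make_trees(
            [
                (0, 0, 0, 0, 30.0, np.nan, 3.0, "died", "main"),
                (1, 0, 0, 1, 20.0, 20.0, 2.0, "survivor", "main"),
                (2, 0, 0, 2, 25.0, 25.0, 2.5, "survivor", "main"),
            ]
        )
        res = decompose(t, self.IDX)
        assert res.delta_mortality == res.delta_total
        assert res.delta_growth == 0.0
        assert res.delta_recruitment == 0.0

    def test_killing_coolest_species_raises_cti(self):
        t = make_trees(
            [
                (0, 0, 0, 0, 30.0, np.nan, 3.0, "died", "main"),  # coolest index
                (1, 0, 0, 5, 30.0, 30.0, 2.0, "survivor", "main"),
            ]
        )
        assert decompose(t, self.IDX).delta_mortality > 0

    def test_scenario_identities_on_random_subplots(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            t = random_subplot_trees(rng)
            res = decompose(t, self.IDX)
            if not np.isfinite(res.cti_t1):
                continue  # decomposition requires a defined baseline CTI
            if not (t["fate"] == "died").any():
                assert res.delta_mortality == 0.0
            if not (t["fate"] == "recruit").any():
                assert res.delta_recruitment == 0.0
            frozen = t.copy()
            surv = frozen["fate"] == "survivor"
            frozen.loc[surv, "dbh_t2_cm"] = frozen.loc[surv, "dbh_t1_cm"]
            assert decompose(frozen, self.IDX).delta_growth == 0.0

    def test_components_match_independent_reimplementation(self):
        # brute force: apply the scenario rules with explicit loops
        rng = np.random.default_rng(4)

        def brute(t, scenario):
            num = den = 0.0
            for _, r in t.iterrows():
                if r["fate"] == "survivor":
                    dbh = (
                        r["dbh_t2_cm"] if scenario in ("all", "growth")
                        else r["dbh_t1_cm"]
                    )
                elif r["fate"] == "died":
                    if scenario in ("all", "mortality"):
                        continue
                    dbh = r["dbh_t1_cm"]
                else:
                    if scenario in ("mortality", "growth"):
                        continue
                    dbh = r["dbh_t2_cm"]
                if dbh < 12.7 or r["dist_m"] > 7.32:
                    continue
                ba = np.pi * (dbh / 2) ** 2
                num += ba * self.IDX[r["species_id"]]
                den += ba
            return num / den if den > 0 else np.nan

        def brute_t1(t):
            num = den = 0.0
            for _, r in t.iterrows():
                if r["fate"] == "recruit" or r["dist_m"] > 7.32:
                    continue
                if r["dbh_t1_cm"] < 12.7:
                    continue
                ba = np.pi * (r["dbh_t1_cm"] / 2) ** 2
                num += ba * self.IDX[r["species_id"]]
                den += ba
            return num / den if den > 0 else np.nan

        for _ in range(100):
            t = random_subplot_trees(rng)
            res = decompose(t, self.IDX)
            cti1 = brute_t1(t)
            for scen, got in [
                ("all", res.delta_total),
                ("mortality", res.delta_mortality),
                ("growth", res.delta_growth),
                ("recruitment", res.delta_recruitment),
            ]:
                want = brute(t, scen) - cti1
                if np.isnan(want):
                    assert not np.isfinite(got)
                else:
                    assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


class TestConiferFraction:
    FLAGS = {0: True, 1: False}

    def _com(self, rows):
        return pd.DataFrame(rows, columns=["species_id", "dbh"])

    def test_all_conifer(self):
        assert conifer_basal_fraction(self._com([(0, 20.0), (0, 30.0)]), self.FLAGS) == 1.0

    def test_quarter(self):
        com = self._com([(0, 2.0), (1, 2.0 * np.sqrt(3))])  # BA 1:3
        assert conifer_basal_fraction(com, self.FLAGS) == pytest.approx(0.25)

    def test_none(self):
        assert conifer_basal_fraction(self._com([(1, 25.0)]), self.FLAGS) == 0.0

    def test_empty_undefined(self):
        assert np.isnan(conifer_basal_fraction(self._com([]), self.FLAGS))


class TestRecruitOrigin:
    SAPS = pd.DataFrame(
        {"plot_id": [0], "subplot_id": [0], "species_id": [2]}
    )
    SEEDS = pd.DataFrame(
        {"plot_id": [0, 0], "subplot_id": [0, 0], "species_id": [3, 4],
         "count": [2, 0]}
    )

    def _recruit(self, species):
        return {"plot_id": 0, "subplot_id": 0, "species_id": species}

    def test_sapling_match_wins(self):
        assert classify_recruit_origin(self._recruit(2), self.SAPS, self.SEEDS) == "sapling"

    def test_seedling_fallback(self):
        assert classify_recruit_origin(self._recruit(3), self.SAPS, self.SEEDS) == "seedling"

    def test_not_germinated(self):
        assert (
            classify_recruit_origin(self._recruit(9), self.SAPS, self.SEEDS)
            == "not_germinated"
        )

    def test_zero_count_seedling_does_not_match(self):
        assert (
            classify_recruit_origin(self._recruit(4), self.SAPS, self.SEEDS)
            == "not_germinated"
        )


class TestSaplingCTI:
    def test_no_saplings_undefined(self):
        t = make_trees([(0, 0, 0, 0, 20.0, 22.0, 3.0, "survivor", "main")])
        assert np.isnan(sapling_cti(t, {0: 5.0}, 1))

    def test_single_sapling_identity(self):
        t = make_trees([(0, 0, 0, 0, 5.0, 6.0, 3.0, "survivor", "sapling")])
        assert sapling_cti(t, {0: 7.5}, 1) == pytest.approx(7.5)

    def test_independent_of_main_class(self):
        sap = make_trees([(0, 0, 0, 0, 5.0, 6.0, 3.0, "survivor", "sapling")])
        both = make_trees(
            [
                (0, 0, 0, 0, 5.0, 6.0, 3.0, "survivor", "sapling"),
                (1, 0, 0, 1, 50.0, 55.0, 3.0, "survivor", "main"),
            ]
        )
        idx = {0: 7.5, 1: 15.0}
        assert sapling_cti(both, idx, 1) == sapling_cti(sap, idx, 1)
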