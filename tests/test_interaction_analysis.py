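"""Interaction extraction rules, CFC, normalization, hubs, cliques, shares."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from cecoflux.interaction_analysis import (
    cluster_cliques,
    contribution_shares,
    cross_feeding_coefficient,
    extract_interactions,
    filter_nondietary,
    identify_hubs,
    interaction_profile_matrix,
    normalize_across_samples,
    select_keystone_metabolites,
    top_contributors,
)
from cecoflux.synthetic_community import generate_diet


def records_from(rows):
    """rows: (replicate, iteration, species, metabolite, flux, amount)."""
    return pd.DataFrame(
        rows, columns=["replicate", "iteration", "species", "metabolite", "flux", "amount"]
    )


class TestExtractInteractions:
    def test_exporter_feeds_importer(self):
        recs = records_from(
            [(0, 1, "A", "ac", 5.0, 5e-12), (0, 1, "B", "ac", -2.0, -2e-12)]
        )
        table = extract_interactions(recs)
        assert table.to_dict("records") == [
            {"producer": "A", "consumer": "B", "metabolite": "ac"}
        ]

    def test_sub_threshold_fluxes_are_noise(self):
        recs = records_from(
            [(0, 1, "A", "ac", 1e-8, 1e-20), (0, 1, "B", "ac", -2.0, -2e-12)]
        )
        assert extract_interactions(recs).empty

    def test_dual_role_species_never_pairs_with_itself(self):
        recs = records_from(
            [
                (0, 1, "A", "lac", 5.0, 5e-12),
                (0, 2, "A", "lac", -3.0, -3e-12),
                (0, 1, "B", "lac", -1.0, -1e-12),
                (0, 1, "C", "lac", 2.0, 2e-12),
            ]
        )
        table = extract_interactions(recs)
        pairs = set(zip(table["producer"], table["consumer"]))
        assert ("A", "A") not in pairs
        assert {("A", "B"), ("C", "B"), ("C", "A")} == pairs

    def test_invariant_to_row_order_and_replicate_split(self):
        rows = [
            (0, 1, "A", "ac", 3.0, 3e-12),
            (1, 1, "A", "ac", 4.0, 4e-12),
            (0, 2, "B", "ac", -2.0, -2e-12),
            (1, 3, "C", "glc", -9.0, -9e-12),
            (0, 1, "A", "glc", 8.0, 8e-12),
        ]
        base = extract_interactions(records_from(rows))
        shuffled = extract_interactions(records_from(rows[::-1]))
        merged = extract_interactions(
            pd.concat([records_from(rows[:2]), records_from(rows[2:])], ignore_index=True)
        )
        for other in (shuffled, merged):
            pd.testing.assert_frame_equal(base, other)

    def test_empty_records_give_empty_table(self):
        assert extract_interactions(records_from([])).empty


class TestCrossFeedingCoefficient:
    def test_one_directed_pair_of_two_species(self):
        table = pd.DataFrame(
            [("A", "B", "ac")], columns=["producer", "consumer", "metabolite"]
        )
        assert cross_feeding_coefficient(table, 2) == 0.5

    def test_bounds_and_errors(self):
        empty = pd.DataFrame(columns=["producer", "consumer", "metabolite"])
        assert cross_feeding_coefficient(empty, 4) == 0.0
        full = pd.DataFrame(
            [(a, b, "m") for a, b in itertools.permutations("ABC", 2)],
            columns=["producer", "consumer", "metabolite"],
        )
        assert cross_feeding_coefficient(full, 3) == 1.0
        with pytest.raises(ValueError):
            cross_feeding_coefficient(full, 1)

    def test_matches_brute_force_and_is_monotone(self):
        rng = np.random.default_rng(0)
        species = list("ABCDE")
        rows = []
        prev = 0.0
        for _ in range(30):
            p, c = rng.choice(species, size=2, replace=False)
            rows.append((p, c, rng.choice(["ac", "lac", "glc"])))
            table = pd.DataFrame(rows, columns=["producer", "consumer", "metabolite"])
            brute = len({(r[0], r[1]) for r in rows}) / (5 * 4)
            cfc = cross_feeding_coefficient(table, 5)
            assert cfc == pytest.approx(brute)
            assert cfc >= prev  # adding interactions never decreases CFC
            prev = cfc


class TestNormalizeAcrossSamples:
    def test_pair_in_every_sample_has_unit_weight(self):
        tbl = pd.DataFrame([("A", "B", "ac")], columns=["producer", "consumer", "metabolite"])
        out = normalize_across_samples({"s1": tbl, "s2": tbl, "s3": tbl})
        assert out["weight"].tolist() == [1.0]
        assert out["n_samples_present"].tolist() == [3]
        assert out["occurrences"].tolist() == [3]

    def test_multi_metabolite_pair_in_one_sample(self):
        tbl = pd.DataFrame(
            [("A", "B", m) for m in ("ac", "lac", "glc")],
            columns=["producer", "consumer", "metabolite"],
        )
        empty = pd.DataFrame(columns=["producer", "consumer", "metabolite"])
        out = normalize_across_samples({"s1": tbl, "s2": empty})
        assert set(out["weight"]) == {3.0}
        assert set(out["n_samples_present"]) == {1}

    def test_empty_inputs_give_empty_output(self):
        assert normalize_across_samples({}).empty


class TestHubs:
    def _table(self, n_partners, n_mets):
        rows = []
        for i in range(n_partners):
            for j in range(n_mets):
                rows.append(("X", f"p{i}", f"m{j}"))
        return pd.DataFrame(rows, columns=["producer", "consumer", "metabolite"])

    def test_thresholds_are_inclusive(self):
        hubs = identify_hubs(self._table(10, 12))
        assert bool(hubs.set_index("species").loc["X", "is_hub"])

    def test_partner_shortfall_disqualifies(self):
        hubs = identify_hubs(self._table(9, 30))
        assert not bool(hubs.set_index("species").loc["X", "is_hub"])

    def test_both_roles_count_toward_partners(self):
        table = pd.DataFrame(
            [("X", "a", "m1"), ("b", "X", "m2")],
            columns=["producer", "consumer", "metabolite"],
        )
        hubs = identify_hubs(table, min_partners=2, min_metabolites=2)
        row = hubs.set_index("species").loc["X"]
        assert row["n_partners"] == 2 and row["n_metabolites"] == 2 and row["is_hub"]

    def test_empty_table_has_no_hubs(self):
        empty = pd.DataFrame(columns=["producer", "consumer", "metabolite"])
        assert identify_hubs(empty).empty


class TestCliques:
    def test_block_structure_recovered_at_k2(self):
        rng = np.random.default_rng(1)
        block = np.zeros((6, 4))
        block[:3, :2] = 5 + rng.random((3, 2))
        block[3:, 2:] = 5 + rng.random((3, 2))
        profiles = pd.DataFrame(block, index=[f"t{i}" for i in range(6)])
        labels = cluster_cliques(profiles, k=2)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_identical_profiles_share_a_cluster(self):
        profiles = pd.DataFrame([[1.0, 2.0]] * 3 + [[9.0, 9.0]], index=list("abcd"))
        labels = cluster_cliques(profiles, k=2)
        assert len(set(labels[:3])) == 1

    def test_k_equals_n_gives_singletons(self):
        profiles = pd.DataFrame(np.eye(4), index=list("abcd"))
        labels = cluster_cliques(profiles, k=4)
        assert len(set(labels)) == 4

    def test_k_above_n_rejected(self):
        profiles = pd.DataFrame(np.eye(3), index=list("abc"))
        with pytest.raises(ValueError):
            cluster_cliques(profiles, k=5)

    def test_matches_independent_agglomerative_implementation(self):
        from sklearn.cluster import AgglomerativeClustering

        rng = np.random.default_rng(7)
        X = rng.random((12, 5))
        profiles = pd.DataFrame(X, index=[f"t{i}" for i in range(12)])
        ours = cluster_cliques(profiles, k=3)
        theirs = AgglomerativeClustering(n_clusters=3, linkage="complete").fit_predict(X)
        # same partition up to label permutation
        mapping = {}
        for a, b in zip(ours, theirs):
            mapping.setdefault(a, b)
            assert mapping[a] == b


class TestContributionShares:
    def test_sole_producer_owns_the_metabolite(self):
        recs = records_from([(0, 1, "A", "ac", 2.0, 4.0)])
        shares = contribution_shares(recs)
        assert shares.loc[0, "share_pct"] == 100.0

    def test_three_to_one_split(self):
        recs = records_from(
            [(0, 1, "A", "ac", 1.0, 3.0), (0, 1, "B", "ac", 1.0, 1.0)]
        )
        shares = contribution_shares(recs).set_index("species")
        assert shares.loc["A", "share_pct"] == pytest.approx(75.0)
        assert shares.loc["B", "share_pct"] == pytest.approx(25.0)

    def test_shares_sum_to_hundred_per_metabolite_and_role(self, six_species_simulation):
        result, _, _ = six_species_simulation
        shares = contribution_shares(result.records)
        sums = shares.groupby(["metabolite", "role"])["share_pct"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_top_contributors_filters_rank_and_share(self):
        rows = [(0, 1, f"sp{i}", "ac", 1.0, amt) for i, amt in enumerate([50, 30, 12, 5, 3])]
        shares = contribution_shares(records_from(rows))
        top = top_contributors(shares, top_n=3, min_share_pct=5.0)
        assert top["species"].tolist() == ["sp0", "sp1", "sp2"]


class TestNondietaryFilter:
    def test_dietary_influx_metabolites_dropped(self):
        diet = generate_diet()  # starch has influx; glc is fully absorbed
        table = pd.DataFrame(
            [("A", "B", "starch"), ("A", "B", "glc"), ("A", "B", "ac")],
            columns=["producer", "consumer", "metabolite"],
        )
        out = filter_nondietary(table, diet)
        assert set(out["metabolite"]) == {"glc", "ac"}

    def test_explicitly_fed_glucose_dropped(self):
        diet = generate_diet({"glc": (10.0, 0.0)})
        table = pd.DataFrame(
            [("A", "B", "glc")], columns=["producer", "consumer", "metabolite"]
        )
        assert filter_nondietary(table, diet).empty

    def test_empty_diet_changes_nothing(self):
        diet = generate_diet({m: (0.0, 0.0) for m in generate_diet().entries})
        table = pd.DataFrame(
            [("A", "B", "starch")], columns=["producer", "consumer", "metabolite"]
        )
        pd.testing.assert_frame_equal(filter_nondietary(table, diet), table)


class TestKeystoneMetaboliteFilters:
    @staticmethod
    def _shares(rows):
        return pd.DataFrame(
            rows, columns=["metabolite", "species", "role", "amount", "share_pct"]
        )

    def test_full_criteria_selects_shifted_keystone_metabolite(self):
        hb = self._shares(
            [
                ("ac", "K", "producer", 40.0, 40.0),
                ("ac", "X", "producer", 35.0, 35.0),
                ("ac", "W", "producer", 25.0, 25.0),
                ("ac", "Y", "consumer", 2.0, 100.0),
            ]
        )
        nb = self._shares(
            [
                ("ac", "X", "producer", 90.0, 90.0),
                ("ac", "Z", "producer", 10.0, 10.0),
                ("ac", "Y", "consumer", 5.0, 100.0),
            ]
        )
        assert select_keystone_metabolites(hb, nb, ["K"]) == ["ac"]

    def test_same_top_producer_in_both_groups_excluded(self):
        hb = self._shares(
            [
                ("ac", "K", "producer", 60.0, 60.0),
                ("ac", "X", "producer", 40.0, 40.0),
                ("ac", "Y", "consumer", 2.0, 100.0),
            ]
        )
        nb = self._shares(
            [
                ("ac", "X", "producer", 90.0, 90.0),
                ("ac", "Y", "consumer", 5.0, 100.0),
            ]
        )
        assert select_keystone_metabolites(hb, nb, ["K"]) == ["ac"]
        hb_same_top = self._shares(
            [
                ("ac", "X", "producer", 70.0, 70.0),
                ("ac", "K", "producer", 30.0, 30.0),
                ("ac", "Y", "consumer", 2.0, 100.0),
            ]
        )
        assert select_keystone_metabolites(hb_same_top, nb, ["K"]) == []

    def test_low_keystone_share_excluded(self):
        hb = self._shares(
            [
                ("ac", "K", "producer", 20.0, 20.0),
                ("ac", "X", "producer", 80.0, 80.0),
                ("ac", "Y", "consumer", 2.0, 100.0),
            ]
        )
        nb = self._shares([("ac", "Z", "producer", 100.0, 100.0)])
        assert select_keystone_metabolites(hb, nb, ["K"]) == []
        # ... unless the share filter is toggled off (and others pass)
        assert select_keystone_metabolites(
            hb, nb, ["K"], require_keystone_share=False
        ) == ["ac"]

    def test_uncrossfed_metabolite_excluded(self):
        hb = self._shares(
            [
                ("ac", "K", "producer", 40.0, 40.0),
                ("ac", "X", "producer", 60.0, 60.0),
                ("ac", "Y", "consumer", 0.1, 100.0),  # below 1% of 100 produced
            ]
        )
        nb = self._shares([("ac", "X", "producer", 100.0, 100.0)])
        assert select_keystone_metabolites(hb, nb, ["K"]) == []

    def test_unknown_keystone_rejected(self):
        hb = self._shares([("ac", "X", "producer", 100.0, 100.0)])
        with pytest.raises(ValueError, match="unknown keystone"):
            select_keystone_metabolites(hb, hb, ["NOPE"])


class TestPlantedEdgeRecovery:
    def test_most_planted_edges_recovered_with_no_false_pairs(
        self, six_species_simulation
    ):
        result, truth, _ = six_species_simulation
        table = extract_interactions(result.records)
        found = set(zip(table["producer"], table["metabolite"], table["consumer"]))
        reordered = {(p, m, c) for p, c, m in zip(
            table["producer"], table["consumer"], table["metabolite"]
        )}
        recovered = truth.edges & reordered
        spurious = reordered - truth.edges
        assert len(recovered) >= 0.8 * len(truth.edges)
        assert len(spurious) <= 1
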