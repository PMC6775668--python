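"""Marker-role derivation, co-occurrence clustering, and the weighted scores."""

import numpy as np
import pandas as pd
import pytest

from geval.markers import (
    MarkerCluster,
    MarkerRoleSet,
    MarkerSetEstimator,
    cluster_markers,
    completeness,
    contamination,
    derive_markers,
    evaluate_counts,
    load_marker_sets,
    save_marker_sets,
    select_grouping,
)


def _frame(columns: dict) -> pd.DataFrame:
    return pd.DataFrame(columns)


class TestDeriveMarkers:
    def test_97_of_100_single_copy_is_marker(self):
        counts = _frame({"m": [1] * 97 + [0, 2, 0]})
        assert derive_markers(counts) == {"m"}

    def test_96_of_100_is_not(self):
        counts = _frame({"m": [1] * 96 + [0, 0, 2, 0]})
        assert derive_markers(counts) == set()

    def test_multi_copy_occurrences_do_not_count_as_single(self):
        counts = _frame({"m": [2] * 100})
        assert derive_markers(counts) == set()


class TestClusterMarkers:
    def test_always_co_occurring_markers_form_one_cluster(self):
        counts = _frame({"a": [1] * 10, "b": [1] * 10, "c": [1] * 10})
        clusters = cluster_markers({"a", "b", "c"}, counts)
        assert [c.roles for c in clusters] == [frozenset({"a", "b", "c"})]

    def test_disjoint_markers_form_singletons(self):
        counts = _frame({"a": [1] * 5 + [0] * 5, "b": [0] * 5 + [1] * 5})
        clusters = cluster_markers({"a", "b"}, counts)
        assert sorted(sorted(c.roles) for c in clusters) == [["a"], ["b"]]

    def test_components_match_union_find_oracle(self):
        """Connected components equal a transitive closure of the pairwise test."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            n_roles, n_genomes = 8, 40
            counts = pd.DataFrame(
                rng.integers(0, 2, size=(n_genomes, n_roles)),
                columns=[f"r{j}" for j in range(n_roles)],
            )
            markers = set(counts.columns)
            clusters = cluster_markers(markers, counts, 0.3)

            parent = {r: r for r in markers}

            def find(r):
                while parent[r] != r:
                    parent[r] = parent[parent[r]]
                    r = parent[r]
                return r

            roles = sorted(markers)
            for i, a in enumerate(roles):
                for b in roles[i + 1:]:
                    both = ((counts[a] > 0) & (counts[b] > 0)).mean()
                    if both >= 0.3:
                        parent[find(a)] = find(b)
            oracle = {}
            for r in roles:
                oracle.setdefault(find(r), set()).add(r)
            assert sorted(sorted(c.roles) for c in clusters) == sorted(
                sorted(s) for s in oracle.values()
            )


class TestSelectGrouping:
    def _sets(self, *grouping_ids):
        return [
            MarkerRoleSet(g, "any", [MarkerCluster(frozenset({f"{g}.m"}))], 10)
            for g in grouping_ids
        ]

    def test_deepest_available_wins(self):
        chosen = select_grouping(
            ["familyX", "genusY", "speciesZ"], self._sets("familyX", "genusY")
        )
        assert chosen.grouping_id == "genusY"

    def test_falls_back_to_coarser_rank(self):
        chosen = select_grouping(
            ["familyX", "genusY", "speciesZ"], self._sets("familyX")
        )
        assert chosen.grouping_id == "familyX"

    def test_disjoint_lineage_rejected(self):
        with pytest.raises(LookupError):
            select_grouping(["familyX"], self._sets("familyQ"))

    def test_no_marker_sets_rejected(self):
        with pytest.raises(ValueError):
            select_grouping(["familyX"], [])


def _marker_set(clusters):
    return MarkerRoleSet("speciesZ", "species", clusters, 10)


PAIR_AND_SINGLETON = _marker_set(
    [MarkerCluster(frozenset({"a", "b"})), MarkerCluster(frozenset({"c"}))]
)


class TestEquations:
    def test_all_single_copy_gives_zero_contamination(self):
        assert contamination({"a": 1, "b": 1, "c": 1}, PAIR_AND_SINGLETON) == 0.0

    def test_hand_evaluated_contamination(self):
        # cluster {a,b} with N=2, singleton {c}; a=2, b=1, c=0:
        # numerator (2-1)/2 = 0.5; denominator 2/2 + 1/2 = 1.5
        value = contamination({"a": 2, "b": 1, "c": 0}, PAIR_AND_SINGLETON)
        assert value == pytest.approx(100 * 0.5 / 1.5)

    def test_hand_evaluated_completeness(self):
        # only a,b present: (1/2 + 1/2) / (1/2 + 1/2 + 1) = 0.5
        value = completeness({"a": 1, "b": 1, "c": 0}, PAIR_AND_SINGLETON)
        assert value == pytest.approx(50.0)

    def test_all_present_is_complete(self):
        assert completeness({"a": 1, "b": 1, "c": 1}, PAIR_AND_SINGLETON) == 100.0

    def test_nothing_present(self):
        assert completeness({}, PAIR_AND_SINGLETON) == 0.0
        assert contamination({}, PAIR_AND_SINGLETON) == 0.0

    @pytest.mark.parametrize("k", [1, 2, 3, 10, 100])
    def test_uniform_count_k_has_closed_form(self, k):
        """Every occurring marker at count k gives 100*(k-1)/k, below 100."""
        counts = {"a": k, "b": k, "c": k}
        value = contamination(counts, PAIR_AND_SINGLETON)
        assert value == pytest.approx(100 * (k - 1) / k)
        assert value < 100.0

    def test_duplicating_every_marker_gives_50(self):
        counts = {r: 2 for r in PAIR_AND_SINGLETON.marker_roles}
        assert contamination(counts, PAIR_AND_SINGLETON) == pytest.approx(50.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            contamination({"a": -1}, PAIR_AND_SINGLETON)
        with pytest.raises(ValueError, match="negative"):
            completeness({"a": -1}, PAIR_AND_SINGLETON)

    def test_empty_marker_set_rejected_for_completeness(self):
        with pytest.raises(ValueError, match="empty marker set"):
            completeness({}, _marker_set([]))

    def test_monotone_under_count_increments(self):
        """Duplicating an occurring marker never lowers contamination, and
        any increment never lowers completeness.  (A 0 -> 1 increment adds a
        clean single-copy marker, which legitimately dilutes contamination.)"""
        rng = np.random.default_rng(31)
        for _ in range(50):
            ms = _random_marker_set(rng)
            counts = {r: int(rng.integers(0, 4)) for r in ms.marker_roles}
            base_cont = contamination(counts, ms)
            base_comp = completeness(counts, ms)
            for role in ms.marker_roles:
                bumped = dict(counts)
                bumped[role] += 1
                if counts[role] > 0:
                    assert contamination(bumped, ms) >= base_cont - 1e-12
                assert completeness(bumped, ms) >= base_comp - 1e-12


def _random_marker_set(rng) -> MarkerRoleSet:
    n_roles = int(rng.integers(1, 12))
    roles = [f"m{j}" for j in range(n_roles)]
    clusters, i = [], 0
    while i < n_roles:
        size = int(rng.integers(1, min(4, n_roles - i) + 1))
        clusters.append(MarkerCluster(frozenset(roles[i : i + size])))
        i += size
    return MarkerRoleSet("g", "species", clusters, 5)


def test_equations_match_brute_force_on_random_sets():
    """Weighted-score formulas agree with explicit loops over M and O."""
    rng = np.random.default_rng(32)
    for _ in range(1000):
        ms = _random_marker_set(rng)
        counts = {r: int(rng.integers(0, 5)) for r in ms.marker_roles}
        weights = ms.weights()
        occurring = [x for x in weights if counts[x] > 0]
        cont_num = sum((counts[x] - 1) / weights[x] for x in occurring)
        cont_den = sum(counts[x] / weights[x] for x in occurring)
        expected_cont = 100 * cont_num / cont_den if cont_den else 0.0
        expected_comp = (
            100
            * sum(1 / weights[x] for x in occurring)
            / sum(1 / weights[x] for x in weights)
        )
        assert contamination(counts, ms) == pytest.approx(expected_cont)
        assert completeness(counts, ms) == pytest.approx(expected_comp)
        assert contamination(counts, ms) < 100.0


class TestEstimator:
    def test_planted_universal_roles_recovered_exactly(
        self, marker_estimator, small_corpus
    ):
        _, labels = small_corpus
        species_sets = [
            ms for ms in marker_estimator.marker_sets_ if ms.rank == "species"
        ]
        assert len(species_sets) == 3
        for ms in species_sets:
            assert ms.marker_roles == set(labels.universal_roles)

    def test_intact_genomes_score_near_complete_and_clean(
        self, marker_estimator, small_corpus
    ):
        genomes, _ = small_corpus
        for genome in genomes[:10]:
            result = marker_estimator.evaluate(genome)
            assert result.completeness >= 85.0
            assert result.contamination <= 15.0
            assert not result.no_markers_found
            assert result.rank == "species"

    def test_empty_counts_flagged(self, marker_estimator):
        ms = marker_estimator.marker_sets_[0]
        result = evaluate_counts({}, ms)
        assert result.no_markers_found
        assert result.completeness == 0.0
        assert result.contamination == 0.0

    def test_small_groupings_skipped(self, small_corpus):
        genomes, _ = small_corpus
        estimator = MarkerSetEstimator(min_group_size=60).fit(genomes)
        # 50-genome species/genus groupings are skipped; 100-genome family kept
        assert {ms.rank for ms in estimator.marker_sets_} == {"family"}

    def test_save_load_round_trip(self, marker_estimator, tmp_path):
        save_marker_sets(marker_estimator.marker_sets_, tmp_path / "markers")
        loaded = load_marker_sets(tmp_path / "markers")
        original = {
            ms.grouping_id: sorted(sorted(c.roles) for c in ms.clusters)
            for ms in marker_estimator.marker_sets_
        }
        restored = {
            ms.grouping_id: sorted(sorted(c.roles) for c in ms.clusters)
            for ms in loaded
        }
        assert restored == original
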