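import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

import rareset as rs


def bulk_matrix(profiles: dict[tuple[str, int], list[int]]) -> rs.BulkMatrix:
    index = pd.MultiIndex.from_tuples(profiles.keys(), names=["accession", "bulk"])
    ncol = len(next(iter(profiles.values())))
    B = max(b for _, b in profiles)
    return rs.BulkMatrix(
        data=pd.DataFrame(
            list(profiles.values()), index=index, columns=[f"M{j}_x" for j in range(ncol)]
        ),
        bulks_per_accession=B,
    )


class TestPairwiseDistances:
    def test_hand_values_and_identity(self):
        m = bulk_matrix({("A", 1): [1, 1, 0], ("A", 2): [0, 1, 1], ("B", 1): [1, 1, 0],
                         ("B", 2): [1, 1, 0]})
        d = rs.pairwise_distances(m)
        assert d["A·1", "A·2"] == pytest.approx(np.sqrt(2))
        assert d["A·1", "B·1"] == 0.0

    def test_orthogonal_profiles_scale_as_sqrt_M(self):
        M = 278
        data = pd.DataFrame(
            [np.ones(M, dtype=int), np.zeros(M, dtype=int)],
            index=["A", "B"],
            columns=[f"M{j}_x" for j in range(M)],
        )
        d = rs.pairwise_distances(rs.AccessionMatrix(data=data))
        assert d["A", "B"] == pytest.approx(np.sqrt(M))

    def test_single_entity_rejected(self):
        data = pd.DataFrame([[1]], index=["A"], columns=["M_x"])
        with pytest.raises(ValueError, match="at least 2"):
            rs.pairwise_distances(rs.AccessionMatrix(data=data))


class TestWithinBetweenStats:
    def test_degenerate_separation(self):
        m = bulk_matrix({("A", 1): [1, 0], ("A", 2): [1, 0],
                         ("B", 1): [0, 1], ("B", 2): [0, 1]})
        st = rs.within_between_stats(rs.pairwise_distances(m))
        assert st.mean_within == 0.0
        assert st.mean_between > 0.0

    def test_all_identical_bulks_have_undefined_t(self):
        m = bulk_matrix({("A", 1): [1, 0], ("A", 2): [1, 0],
                         ("B", 1): [1, 0], ("B", 2): [1, 0]})
        st = rs.within_between_stats(rs.pairwise_distances(m))
        assert st.mean_within == st.mean_between == 0.0
        assert np.isnan(st.t_statistic) and np.isnan(st.p_value)
        assert "undefined" in st.note

    def test_means_match_explicit_pair_enumeration(self):
        profiles = {("A", 1): [1, 1, 0, 0], ("A", 2): [1, 0, 1, 0],
                    ("B", 1): [0, 0, 1, 1], ("B", 2): [0, 1, 1, 1]}
        m = bulk_matrix(profiles)
        st = rs.within_between_stats(rs.pairwise_distances(m))
        dist = {}
        for (ka, va), (kb, vb) in itertools.combinations(profiles.items(), 2):
            dist[(ka, kb)] = np.sqrt(sum((x - y) ** 2 for x, y in zip(va, vb)))
        within = [v for (ka, kb), v in dist.items() if ka[0] == kb[0]]
        between = [v for (ka, kb), v in dist.items() if ka[0] != kb[0]]
        assert st.n_within_pairs == len(within) == 2
        assert st.n_between_pairs == len(between) == 4
        assert st.mean_within == pytest.approx(np.mean(within))
        assert st.mean_between == pytest.approx(np.mean(between))
        assert st.ratio_between_over_within == pytest.approx(
            np.mean(between) / np.mean(within)
        )

    def test_pair_counts_formula(self):
        bulk, _, _ = rs.simulate_collection(
            rs.SimConfig(n_accessions=7, n_markers=2, alleles_per_marker=4,
                         n_races=2, seed=4)
        )
        st = rs.within_between_stats(rs.pairwise_distances(bulk))
        N, B = 7, 3
        assert st.n_within_pairs == N * B * (B - 1) // 2
        assert st.n_between_pairs == B * B * N * (N - 1) // 2

    def test_single_bulk_per_accession_rejected(self, f1):
        with pytest.raises(ValueError, match="within"):
            rs.within_between_stats(rs.pairwise_distances(f1.bulk))


class TestUpgma:
    def test_three_leaf_worked_example(self):
        d = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=["A", "B", "C"])
        tree = rs.upgma(d)
        assert rs.to_newick(tree) == "((A:1.0,B:1.0):1.0,C:2.0);"
        coph = rs.cophenetic_matrix(tree)
        assert coph["A", "B"] == pytest.approx(2.0)
        assert coph["A", "C"] == pytest.approx(4.0)
        assert coph["B", "C"] == pytest.approx(4.0)

    def test_two_leaves_cherry_at_half_distance(self):
        d = DistanceMatrix([[0, 5], [5, 0]], ids=["X", "Y"])
        tree = rs.upgma(d)
        assert rs.to_newick(tree) == "(X:2.5,Y:2.5);"

    @pytest.mark.parametrize("seed", range(5))
    def test_ultrametricity_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(9, 4))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"L{i}" for i in range(9)])
        tree = rs.upgma(d)
        root = tree
        depths = [tip.accumulate_to_ancestor(root) for tip in tree.tips()]
        assert max(depths) - min(depths) < 1e-9

    def test_matches_scipy_average_linkage_cophenetics(self):
        # tie-free random instance: both implementations must agree exactly
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(8, 5))
        condensed = pdist(pts)
        ids = [f"L{i}" for i in range(8)]
        tree = rs.upgma(DistanceMatrix(squareform(condensed), ids=ids))
        ours = rs.cophenetic_matrix(tree).filter(ids).condensed_form()
        theirs = cophenet(linkage(condensed, method="average"))
        np.testing.assert_allclose(ours, theirs, rtol=1e-10)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(7, 3))
        ids = [f"L{i}" for i in range(7)]
        d1 = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        perm = list(rng.permutation(7))
        d2 = DistanceMatrix(squareform(pdist(pts[perm])), ids=[ids[i] for i in perm])
        c1 = rs.cophenetic_matrix(rs.upgma(d1)).filter(sorted(ids))
        c2 = rs.cophenetic_matrix(rs.upgma(d2)).filter(sorted(ids))
        np.testing.assert_allclose(c1.data, c2.data, rtol=1e-12)

    def test_asymmetric_input_rejected(self):
        class Fake:
            ids = ["A", "B"]
            data = np.array([[0.0, 1.0], [2.0, 0.0]])

        with pytest.raises(ValueError, match="symmetric"):
            rs.upgma(Fake())


class TestJackknife:
    def test_constant_column_insensitive_and_duplicates_equivalent(self):
        rng = np.random.default_rng(1)
        z = rng.integers(0, 4, size=(6, 4))
        data = pd.DataFrame(z, index=[f"A{i}" for i in range(6)],
                            columns=[f"M{j}_x" for j in range(4)])
        data["M8_const"] = 2
        data["M9_dup"] = data["M0_x"]
        a = rs.AccessionMatrix(data=data)
        table = rs.jackknife_columns(a).set_index("column")
        # a zero-variance column contributes nothing to any distance
        assert table.loc["M8_const", "sensitivity"] == pytest.approx(0.0, abs=1e-12)
        # identical columns are interchangeable: excluding either copy yields
        # the same reduced distances, hence the same sensitivity
        assert table.loc["M9_dup", "sensitivity"] == pytest.approx(
            table.loc["M0_x", "sensitivity"], abs=1e-12
        )

    def test_two_columns_match_direct_single_column_trees(self):
        data = pd.DataFrame(
            [[0, 3], [1, 1], [3, 0], [2, 2]],
            index=list("ABCD"),
            columns=["M0_x", "M1_x"],
        )
        a = rs.AccessionMatrix(data=data)
        table = rs.jackknife_columns(a).set_index("column")
        full = rs.cophenetic_matrix(rs.upgma(rs.pairwise_distances(a)))
        ids = sorted(a.accession_ids)
        fullv = full.filter(ids).condensed_form()
        for kept, dropped in (("M0_x", "M1_x"), ("M1_x", "M0_x")):
            single = rs.AccessionMatrix(data=data[[kept]])
            coph = rs.cophenetic_matrix(rs.upgma(rs.pairwise_distances(single)))
            vec = coph.filter(ids).condensed_form()
            r = np.corrcoef(fullv, vec)[0, 1]
            assert table.loc[dropped, "sensitivity"] == pytest.approx(1 - r)

    def test_single_column_rejected(self):
        data = pd.DataFrame({"M_x": [0, 1, 2]}, index=list("ABC"))
        with pytest.raises(ValueError, match="at least 2 columns"):
            rs.jackknife_columns(rs.AccessionMatrix(data=data))


class TestGeoGenetic:
    def test_quarter_meridian_haversine(self):
        assert rs.haversine_km(0.0, 0.0, 0.0, 90.0) == pytest.approx(
            6371 * np.pi / 2, rel=1e-9
        )

    def test_coincident_sites_give_undefined_correlation(self, f1):
        meta = f1.metadata.copy()
        meta["lat"] = 19.0
        meta["lon"] = -98.0
        d = rs.pairwise_distances(f1.accession)
        res = rs.geo_genetic_correlation(meta, d, permutations=0)
        assert np.isnan(res["r"]) and res["mantel_p"] is None

    def test_constructed_perfect_correlation(self):
        # genetic distance proportional to geographic distance -> r = 1
        lats = np.array([0.0, 0.1, 0.25, 0.4, 0.6, 0.9])
        ids = [f"A{i}" for i in range(6)]
        meta = pd.DataFrame(
            {"lat": lats, "lon": 0.0, "race1": "X", "race2": None,
             "kernel_color": "white", "masl": 1000.0},
            index=pd.Index(ids, name="accession"),
        )
        geo = rs.geographic_distances(meta, ids)
        genetic = DistanceMatrix(geo.data * 3.5, ids=ids)
        perms = 199
        res = rs.geo_genetic_correlation(meta, genetic, permutations=perms, seed=1)
        assert res["r"] == pytest.approx(1.0)
        assert res["mantel_p"] <= 2 / (perms + 1)

    def test_missing_coordinates_listed(self, f1):
        meta = f1.metadata.copy()
        meta.loc["B", "lat"] = np.nan
        with pytest.raises(ValueError, match="B"):
            rs.geo_genetic_correlation(meta, rs.pairwise_distances(f1.accession))
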