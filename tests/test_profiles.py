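"""Profile-matrix assembly, normalization and similarity ranking."""

import numpy as np
import pandas as pd
import pytest

from qfascreen import (
    DegenerateColumnError,
    InconsistencyError,
    NoProfileError,
    ProfileMatrix,
    build_profile_matrix,
    normalize_profiles,
    rank_similar_profiles,
    simulate_profile_matrix,
)

from conftest import make_fitness_table


def matrix_from_dict(values, value_kind="fitness"):
    """{orf: {screen: value}} -> ProfileMatrix (NaN where absent)."""
    df = pd.DataFrame.from_dict(values, orient="index").sort_index()
    df.index.name = "orf"
    return ProfileMatrix(values=df, value_kind=value_kind)


class TestBuildProfileMatrix:
    def test_complete_union(self):
        tables = [make_fitness_table({o: [1.0] for o in "ABC"},
                                     screen_id=f"S{i}") for i in range(3)]
        pm = build_profile_matrix(tables)
        assert pm.values.shape == (3, 3)
        assert not pm.values.isna().any().any()
        assert pm.genes == ["A", "B", "C"]

    def test_partial_gene_has_missing_entries(self):
        tables = [make_fitness_table({"A": [1.0], "B": [2.0]}, screen_id="S0"),
                  make_fitness_table({"A": [1.0], "D": [3.0]}, screen_id="S1"),
                  make_fitness_table({"A": [1.0], "B": [2.0]}, screen_id="S2")]
        pm = build_profile_matrix(tables)
        assert int(pm.values.loc["D"].isna().sum()) == 2

    def test_duplicate_screen_condition_rejected(self):
        tables = [make_fitness_table({"A": [1.0]}, screen_id="S0"),
                  make_fitness_table({"A": [1.0]}, screen_id="S0")]
        with pytest.raises(InconsistencyError):
            build_profile_matrix(tables)

    def test_screens_keep_input_order_genes_sorted(self):
        tables = [make_fitness_table({"B": [1.0], "A": [2.0]}, screen_id="Z"),
                  make_fitness_table({"A": [1.0], "B": [2.0]}, screen_id="A")]
        pm = build_profile_matrix(tables)
        assert pm.screens == ["Z|chronic", "A|chronic"]
        assert pm.genes == ["A", "B"]


class TestNormalizeProfiles:
    def test_unit_sd_column_closed_form(self):
        pm = matrix_from_dict({"A": {"S": 1.0}, "B": {"S": 2.0}, "C": {"S": 3.0}})
        out = normalize_profiles(pm)
        assert np.allclose(out.values["S"], [-1.0, 0.0, 1.0])

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        pm = matrix_from_dict({f"G{i}": {f"S{j}": rng.normal() for j in range(4)}
                               for i in range(8)})
        once = normalize_profiles(pm)
        twice = normalize_profiles(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_columns_centered_and_scaled(self):
        rng = np.random.default_rng(2)
        pm = matrix_from_dict({f"G{i}": {f"S{j}": 5 + 3 * rng.normal()
                                         for j in range(3)} for i in range(20)})
        out = normalize_profiles(pm)
        assert np.all(np.abs(out.values.mean()) < 1e-12)
        assert np.all(np.abs(out.values.std(ddof=1) - 1) < 1e-12)

    def test_missing_mask_preserved(self):
        pm = matrix_from_dict({"A": {"S0": 1.0, "S1": 1.0},
                               "B": {"S0": 2.0, "S1": 2.0},
                               "C": {"S0": 3.0, "S1": 4.0},
                               "D": {"S0": np.nan, "S1": 8.0}})
        out = normalize_profiles(pm)
        assert np.isnan(out.values.loc["D", "S0"])
        assert out.values.notna().sum().sum() == 7

    def test_zero_spread_column_named_in_error(self):
        pm = matrix_from_dict({o: {"FLAT": 1.0, "OK": float(i)}
                               for i, o in enumerate("ABCD")})
        with pytest.raises(DegenerateColumnError, match="FLAT"):
            normalize_profiles(pm)

    def test_sparse_column_rejected(self):
        pm = matrix_from_dict({"A": {"S": 1.0}, "B": {"S": 2.0},
                               "C": {"S": np.nan}})
        with pytest.raises(DegenerateColumnError):
            normalize_profiles(pm)


class TestRankSimilarProfiles:
    def base_matrix(self):
        rng = np.random.default_rng(5)
        vals = {f"G{i:02d}": {f"S{j}": float(rng.normal()) for j in range(6)}
                for i in range(10)}
        vals["QRY"] = {f"S{j}": float(j) for j in range(6)}
        vals["TWIN"] = {f"S{j}": 2.0 * j + 1.0 for j in range(6)}   # r = +1
        vals["ANTI"] = {f"S{j}": -3.0 * j for j in range(6)}        # r = -1
        return matrix_from_dict(vals)

    def test_identical_profile_ranks_first(self):
        ranking = rank_similar_profiles(self.base_matrix(), "QRY")
        top = ranking.table.iloc[0]
        assert top.orf == "TWIN"
        assert top.position == 1
        assert top.similarity == pytest.approx(1.0)

    def test_negated_profile_ranks_last(self):
        ranking = rank_similar_profiles(self.base_matrix(), "QRY")
        bottom = ranking.table.iloc[-1]
        assert bottom.orf == "ANTI"
        assert bottom.similarity == pytest.approx(-1.0)

    def test_query_excluded_and_similarity_non_increasing(self):
        ranking = rank_similar_profiles(self.base_matrix(), "QRY")
        assert "QRY" not in set(ranking.table["orf"])
        sims = ranking.table["similarity"].to_numpy()
        assert np.all(np.diff(sims) <= 1e-12)

    def test_ties_break_lexicographically(self):
        vals = {"QRY": {"S0": 0.0, "S1": 1.0, "S2": 2.0, "S3": 3.0}}
        for orf in ("BBB", "AAA", "CCC"):
            vals[orf] = {"S0": 1.0, "S1": 2.0, "S2": 3.0, "S3": 4.0}
        ranking = rank_similar_profiles(matrix_from_dict(vals), "QRY", min_overlap=4)
        assert list(ranking.table["orf"]) == ["AAA", "BBB", "CCC"]

    def test_min_overlap_excludes_sparse_genes(self):
        vals = {"QRY": {f"S{j}": float(j) for j in range(6)},
                "FULL": {f"S{j}": float(j) for j in range(6)},
                "SPARSE": {"S0": 0.0, "S1": 1.0, "S2": 2.0}}
        ranking = rank_similar_profiles(matrix_from_dict(vals), "QRY", min_overlap=4)
        assert set(ranking.table["orf"]) == {"FULL"}
        assert (ranking.table["n_overlap"] >= 4).all()

    def test_missing_query_profile_raises(self):
        pm = matrix_from_dict({"A": {"S0": 1.0, "S1": 2.0},
                               "QRY": {"S0": np.nan, "S1": np.nan}})
        with pytest.raises(NoProfileError):
            rank_similar_profiles(pm, "QRY", min_overlap=2)
        with pytest.raises(NoProfileError):
            rank_similar_profiles(pm, "ABSENT", min_overlap=2)

    def test_euclidean_metric_orders_by_distance(self):
        vals = {"QRY": {f"S{j}": float(j) for j in range(4)},
                "NEAR": {f"S{j}": j + 0.1 for j in range(4)},
                "FAR": {f"S{j}": j + 5.0 for j in range(4)}}
        ranking = rank_similar_profiles(matrix_from_dict(vals), "QRY",
                                        metric="euclidean", min_overlap=4)
        assert list(ranking.table["orf"]) == ["NEAR", "FAR"]
        assert ranking.table["similarity"].iloc[0] == pytest.approx(-0.1)

    def test_normalized_ranking_invariant_to_per_screen_affine_rescaling(self):
        # per-screen affine maps (different units/temperatures per screen)
        # are absorbed by column z-scoring, so the normalize-then-rank
        # pipeline yields identical rankings
        pm = self.base_matrix()
        rescaled = pm.values * np.array([2.0, 0.5, 3.0, 1.0, 10.0, 0.1]) + \
            np.array([1.0, -2.0, 0.0, 5.0, 0.3, 7.0])
        pm2 = ProfileMatrix(values=rescaled, value_kind="fitness")
        r1 = rank_similar_profiles(normalize_profiles(pm), "QRY")
        r2 = rank_similar_profiles(normalize_profiles(pm2), "QRY")
        assert list(r1.table["orf"]) == list(r2.table["orf"])
        assert np.allclose(r1.table["similarity"], r2.table["similarity"], atol=1e-9)

    @pytest.mark.parametrize("metric", ["pearson", "euclidean"])
    def test_symmetry_on_complete_data(self, metric):
        pm = self.base_matrix()

        def sim(a, b):
            ranking = rank_similar_profiles(pm, a, metric=metric)
            return ranking.table.set_index("orf").loc[b, "similarity"]

        assert sim("QRY", "G03") == pytest.approx(sim("G03", "QRY"), rel=1e-12)

    def test_deterministic_ranking(self):
        pm, _ = simulate_profile_matrix(n_genes=80, seed=3)
        a = rank_similar_profiles(pm, pm.genes[0])
        b = rank_similar_profiles(pm, pm.genes[0])
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_planted_module_members_cluster(self):
        pm, members = simulate_profile_matrix(n_genes=200, n_screens=12,
                                              module_size=10, noise_sd=0.3, seed=3)
        ranking = rank_similar_profiles(normalize_profiles(pm), members[0])
        top20 = set(ranking.table.head(20)["orf"])
        assert len(top20 & set(members[1:])) >= 8
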