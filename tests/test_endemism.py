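import itertools

import numpy as np
import pandas as pd
import pytest

from bioregion import (
    alpha_index,
    area_richness_r2,
    arrhenius_fit,
    build_occurrence_matrix,
    indval,
    load_checklist,
    occurrence_distance,
    richness_summary,
)
from bioregion.endemism import Checklist, _indval_components


def write_checklist(tmp_path, rows, units=("1", "2", "3")):
    cols = ["taxon", "family", "genus", "rank"] + [f"unit:{u}" for u in units]
    df = pd.DataFrame(rows, columns=cols)
    path = tmp_path / "cl.csv"
    df.to_csv(path, index=False)
    return str(path)


class TestChecklist:
    def test_toy_counts_match_hand_tally(self, tmp_path):
        rows = [
            ["Aa bb", "F1", "Aa", "species", 1, 0, 0],
            ["Cc dd", "F1", "Cc", "species", 1, 1, 0],
            ["Ee ff", "F2", "Ee", "species", 0, 0, 1],
        ]
        cl = load_checklist(write_checklist(tmp_path, rows))
        assert cl.n_taxa == 3
        assert cl.presence().sum().tolist() == [2, 1, 1]

    def test_duplicates_collapse_to_union(self, tmp_path):
        rows = [
            ["Aa bb", "F1", "Aa", "species", 1, 0, 0],
            ["Aa bb", "F1", "Aa", "species", 0, 1, 0],
        ]
        with pytest.warns(UserWarning, match="duplicate"):
            cl = load_checklist(write_checklist(tmp_path, rows))
        assert cl.n_taxa == 1
        assert cl.presence().loc["Aa bb"].tolist() == [1, 1, 0]

    def test_missing_columns_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"name": ["x"], "unit:1": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="taxon"):
            load_checklist(str(path))
        path2 = tmp_path / "bad2.csv"
        pd.DataFrame({"taxon": ["x"], "family": ["F"]}).to_csv(path2, index=False)
        with pytest.raises(ValueError, match="unit"):
            load_checklist(str(path2))

    def test_xlsx_round_trip(self, tmp_path):
        rows = [["Aa bb", "F1", "Aa", "species", 1, 0, 1]]
        df = pd.DataFrame(rows, columns=["taxon", "family", "genus", "rank", "unit:1", "unit:2", "unit:3"])
        path = tmp_path / "cl.xlsx"
        df.to_excel(path, index=False)
        cl = load_checklist(str(path))
        assert cl.presence().loc["Aa bb"].tolist() == [1, 0, 1]


class TestOccurrenceMatrix:
    def test_one_by_one(self, tmp_path):
        cl = load_checklist(write_checklist(tmp_path, [["A a", "F", "A", "species", 1]], units=("1",)))
        M = build_occurrence_matrix(cl)
        assert M.shape == (1, 1) and M.iloc[0, 0] == 1

    def test_zero_presence_taxon_dropped(self, tmp_path):
        rows = [["A a", "F", "A", "species", 1, 0, 0], ["B b", "F", "B", "species", 0, 0, 0]]
        cl = load_checklist(write_checklist(tmp_path, rows))
        with pytest.warns(UserWarning, match="no presences"):
            M = build_occurrence_matrix(cl, drop_empty_units=False)
        assert list(M.columns) == ["A a"]

    def test_empty_unit_excluded_by_default_kept_on_request(self, tmp_path):
        rows = [["A a", "F", "A", "species", 1, 1, 0]]
        cl = load_checklist(write_checklist(tmp_path, rows))
        with pytest.warns(UserWarning, match="no endemic"):
            M = build_occurrence_matrix(cl)
        assert list(M.index) == ["1", "2"]
        M_all = build_occurrence_matrix(cl, drop_empty_units=False)
        assert list(M_all.index) == ["1", "2", "3"]

    def test_toy_matrix_matches_hand_layout(self, tmp_path):
        rows = [
            ["A a", "F", "A", "species", 1, 0, 1],
            ["B b", "F", "B", "species", 0, 1, 1],
            ["C c", "F", "C", "species", 1, 1, 1],
        ]
        cl = load_checklist(write_checklist(tmp_path, rows))
        M = build_occurrence_matrix(cl)
        np.testing.assert_array_equal(M.to_numpy(), [[1, 0, 1], [0, 1, 1], [1, 1, 1]])


class TestOccurrenceDistance:
    def test_identical_rows_distance_zero(self):
        M = pd.DataFrame([[1, 0, 1], [1, 0, 1]], index=["u1", "u2"])
        assert occurrence_distance(M).loc["u1", "u2"] == 0

    def test_disjoint_rows_euclidean(self):
        M = pd.DataFrame([[1, 1, 0, 0, 0], [0, 0, 1, 1, 1]], index=["u1", "u2"])
        assert occurrence_distance(M).loc["u1", "u2"] == pytest.approx(np.sqrt(5))

    def test_jaccard_toy(self):
        M = pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["u1", "u2"])
        # shared 1 of 3 taxa present in either → jaccard distance 2/3
        assert occurrence_distance(M, "jaccard").loc["u1", "u2"] == pytest.approx(2 / 3)


def exhaustive_indval_p(M, classes):
    """Independent oracle: per-taxon loops over every distinct label arrangement."""
    units = list(M.index)
    labels = [classes[u] for u in units]
    names = sorted(set(labels))
    X = M.to_numpy(dtype=float)

    def stat(assignment, t):
        best = 0.0
        for cname in names:
            members = [i for i, a in enumerate(assignment) if a == cname]
            m_j = np.mean([X[i, t] for i in members])
            total = sum(
                np.mean([X[i, t] for i, a in enumerate(assignment) if a == c]) for c in names
            )
            A = m_j / total if total > 0 else 0.0
            B = np.mean([X[i, t] > 0 for i in members])
            best = max(best, 100.0 * A * B)
        return best

    ps = []
    for t in range(X.shape[1]):
        obs = stat(labels, t)
        perms = set(itertools.permutations(labels))
        count = sum(stat(list(p), t) >= obs - 1e-12 for p in perms)
        ps.append(count / len(perms))
    return np.array(ps)


class TestIndval:
    def _matrix(self, rows, units):
        return pd.DataFrame(rows, index=units, columns=[f"t{j}" for j in range(len(rows[0]))])

    def test_perfect_indicator_scores_100(self):
        M = self._matrix([[1], [1], [0], [0]], ["a1", "a2", "b1", "b2"])
        classes = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        res = indval(M, classes, n_perm=50, seed=0)
        assert res.table["indval"].iloc[0] == pytest.approx(100.0)
        assert res.table["best_class"].iloc[0] == "A"

    def test_ubiquitous_taxon_scores_100_over_k(self):
        M = self._matrix([[1], [1], [1], [1]], ["a1", "a2", "b1", "b2"])
        classes = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        res = indval(M, classes, n_perm=50, seed=0)
        assert res.table["indval"].iloc[0] == pytest.approx(100.0 / 2)

    def test_specificity_sums_to_one(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, (6, 20))
        X[:, X.sum(axis=0) == 0] = 1
        G = np.zeros((3, 6))
        G[[0, 0, 1, 1, 2, 2], np.arange(6)] = 1
        A, B, IV = _indval_components(X.astype(float), G)
        np.testing.assert_allclose(A.sum(axis=0), 1.0, atol=1e-12)
        assert (IV >= 0).all() and (IV <= 100 + 1e-9).all()

    def test_exact_p_matches_exhaustive_oracle_four_units(self):
        M = self._matrix([[1, 1], [1, 0], [0, 1], [0, 0]], ["u1", "u2", "u3", "u4"])
        classes = {"u1": "A", "u2": "A", "u3": "B", "u4": "B"}
        res = indval(M, classes, method="exact")
        np.testing.assert_allclose(res.table["p_value"].to_numpy(), exhaustive_indval_p(M, classes), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exact_p_matches_exhaustive_oracle_random_six_units(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, (6, 8))
        X[:, X.sum(axis=0) == 0] = 1
        M = self._matrix(X.tolist(), [f"u{i}" for i in range(6)])
        classes = {f"u{i}": ["A", "A", "B", "B", "C", "C"][i] for i in range(6)}
        res = indval(M, classes, method="exact")
        np.testing.assert_allclose(res.table["p_value"].to_numpy(), exhaustive_indval_p(M, classes), atol=1e-12)

    def test_monte_carlo_reproducible_and_near_exact(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, (6, 5))
        X[:, X.sum(axis=0) == 0] = 1
        M = self._matrix(X.tolist(), [f"u{i}" for i in range(6)])
        classes = {f"u{i}": ["A", "A", "B", "B", "C", "C"][i] for i in range(6)}
        mc1 = indval(M, classes, n_perm=2000, seed=7)
        mc2 = indval(M, classes, n_perm=2000, seed=7)
        pd.testing.assert_frame_equal(mc1.table, mc2.table)
        exact = indval(M, classes, method="exact")
        np.testing.assert_allclose(
            mc1.table["p_value"].to_numpy(), exact.table["p_value"].to_numpy(), atol=0.06
        )

    def test_absent_taxon_excluded_with_warning(self):
        M = self._matrix([[1, 0], [0, 0], [1, 0], [0, 0]], ["u1", "u2", "u3", "u4"])
        classes = {"u1": "A", "u2": "A", "u3": "B", "u4": "B"}
        with pytest.warns(UserWarning, match="absent"):
            res = indval(M, classes, n_perm=20, seed=0)
        assert list(res.table.index) == ["t0"]

    def test_degenerate_one_unit_per_class_supported(self):
        M = self._matrix([[1, 0], [1, 1], [0, 1]], ["u1", "u2", "u3"])
        res = indval(M, None, n_perm=100, seed=0)
        assert (res.table["p_value"] > 0).all()


class TestRichness:
    def test_exclusive_counts_match_hand_tally(self):
        M = pd.DataFrame(
            [[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 0, 1], [0, 0, 0, 1]],
            index=["u1", "u2", "u3", "u4"],
            columns=["t1", "t2", "t3", "t4"],
        )
        out = richness_summary(M)
        assert out["total_taxa"].tolist() == [2, 2, 1, 1]
        assert out["exclusive_taxa"].tolist() == [1, 1, 0, 0]

    def test_zero_unit(self):
        M = pd.DataFrame([[1], [0]], index=["u1", "u2"], columns=["t1"])
        out = richness_summary(M)
        assert out.loc["u2"].tolist() == [0, 0]

    def test_family_totals(self, tmp_path):
        rows = [
            ["A a", "Asteraceae", "A", "species", 1, 1, 0],
            ["B b", "Asteraceae", "B", "species", 1, 0, 0],
            ["C c", "Fabaceae", "C", "species", 0, 1, 1],
        ]
        df = pd.DataFrame(rows, columns=["taxon", "family", "genus", "rank", "unit:1", "unit:2", "unit:3"])
        path = tmp_path / "cl.csv"
        df.to_csv(path, index=False)
        cl = load_checklist(str(path))
        M = build_occurrence_matrix(cl, drop_empty_units=False)
        out = richness_summary(M, cl)
        assert out["family:Asteraceae"].tolist() == [2, 1, 0]
        assert out["family:Fabaceae"].tolist() == [0, 1, 1]

    def test_exclusive_counts_bounded_by_totals(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame(rng.integers(0, 2, (5, 30)))
        out = richness_summary(M)
        assert (out["exclusive_taxa"] <= out["total_taxa"]).all()
        assert out["exclusive_taxa"].sum() <= M.shape[1]


class TestSpeciesArea:
    def _units(self, A, E):
        return pd.DataFrame({"area_km2": A, "endemics": E})

    def test_noiseless_power_law_exact(self):
        A = np.array([10.0, 100.0, 1000.0, 5000.0])
        fit = arrhenius_fit(self._units(A, 2.0 * A**0.25))
        assert fit.c == pytest.approx(2.0, abs=1e-9)
        assert fit.z == pytest.approx(0.25, abs=1e-9)
        assert fit.r2_loglog == pytest.approx(1.0)

    def test_two_units_error(self):
        with pytest.raises(ValueError):
            arrhenius_fit(self._units([1.0, 2.0], [3.0, 4.0]))

    def test_zero_endemic_units_excluded_from_fit(self):
        A = np.array([10.0, 100.0, 1000.0, 777.0])
        E = np.array([2.0 * a**0.25 for a in A[:3]] + [0.0])
        fit = arrhenius_fit(self._units(A, E))
        assert fit.n_units == 3 and fit.z == pytest.approx(0.25, abs=1e-9)

    def test_alpha_on_curve_is_one_and_scales(self):
        A = np.array([10.0, 100.0, 1000.0])
        E = 2.0 * A**0.25
        fit = arrhenius_fit(self._units(A, E))
        table = alpha_index(fit, self._units(A, E))
        np.testing.assert_allclose(table["alpha"], 1.0, atol=1e-9)
        doubled = alpha_index(fit, self._units(A, 2 * E))
        np.testing.assert_allclose(doubled["alpha"], 2.0, atol=1e-9)

    def test_alpha_geometric_mean_identity(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(10, 1e5, 20)
        E = 3.0 * A**0.3 * np.exp(rng.normal(0, 0.4, 20))
        units = self._units(A, E)
        table = alpha_index(arrhenius_fit(units), units)
        assert np.exp(np.log(table["alpha"]).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_endemics_alpha_undefined_but_listed(self):
        A = np.array([10.0, 100.0, 1000.0, 50.0])
        E = np.array([5.0, 8.0, 14.0, 0.0])
        table = alpha_index(arrhenius_fit(self._units(A, E)), self._units(A, E))
        assert len(table) == 4 and np.isnan(table["alpha"].iloc[3])

    def test_r2_linear_exact_and_toy(self):
        A = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert area_richness_r2(self._units(A, 3 * A)) == pytest.approx(1.0)
        # hand OLS on a 6-point toy: r = cov/sd product
        E = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        r = np.corrcoef(A, E)[0, 1]
        assert area_richness_r2(self._units(A, E)) == pytest.approx(r**2)

    def test_independent_richness_r2_near_zero(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(1, 100, 500)
        E = rng.uniform(1, 100, 500)
        assert area_richness_r2(self._units(A, E)) < 0.02
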