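"""Community classification, filters and income covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from urbancfd import assembly
from urbancfd.containers import CommunityMatrix, IncomeGrid


def make_matrix(presence: np.ndarray, nonnative_idx=(), countries=None, fuas=None):
    n_cells, n_sp = presence.shape
    species = [f"sp{j}" for j in range(n_sp)]
    cells = [f"c{i}" for i in range(n_cells)]
    flags = pd.Series([j in set(nonnative_idx) for j in range(n_sp)], index=species)
    meta = pd.DataFrame(
        {
            "fua": fuas if fuas is not None else ["f0"] * n_cells,
            "country": countries if countries is not None else ["ES"] * n_cells,
        },
        index=cells,
    )
    return CommunityMatrix(
        presence=pd.DataFrame(presence, index=cells, columns=species),
        cell_meta=meta,
        nonnative=flags,
    )


class TestClassification:
    def test_single_alien_makes_invaded(self):
        pres = np.zeros((1, 11), dtype=int)
        pres[0, :] = 1
        m = make_matrix(pres, nonnative_idx=[0])
        assert assembly.classify_communities(m)["c0"] == "invaded"

    def test_no_alien_is_noninvaded(self):
        pres = np.ones((1, 5), dtype=int)
        m = make_matrix(pres)
        assert assembly.classify_communities(m)["c0"] == "non-invaded"

    def test_empty_cell_noninvaded(self):
        pres = np.zeros((1, 5), dtype=int)
        m = make_matrix(pres, nonnative_idx=[0])
        assert assembly.classify_communities(m)["c0"] == "non-invaded"

    @given(st.integers(0, 2**20 - 1))
    @settings(max_examples=30, deadline=None)
    def test_commutes_with_min_richness_filter(self, bits):
        pres = np.array([[int(b) for b in f"{bits:020b}"]]).reshape(4, 5)
        m = make_matrix(pres, nonnative_idx=[0])
        a = assembly.classify_communities(assembly.min_richness_filter(m))
        b = assembly.classify_communities(m).loc[a.index]
        assert (a == b).all()


class TestNoAlien:
    def test_aliens_removed(self):
        pres = np.ones((1, 7), dtype=int)
        m = make_matrix(pres, nonnative_idx=[0, 1])
        na = assembly.derive_no_alien(m)
        assert na.richness()["c0"] == 5

    def test_richness_never_increases(self):
        rng = np.random.default_rng(8)
        pres = (rng.random((10, 12)) < 0.5).astype(int)
        pres[:, 0] = 1  # every cell invaded
        m = make_matrix(pres, nonnative_idx=[0, 1])
        na = assembly.derive_no_alien(m)
        assert (na.richness() <= m.richness().loc[na.cells]).all()

    def test_filter_composition_drops_small_no_alien_cells(self):
        # invaded cell with 2 natives + 2 aliens: no-alien version has 2
        # species -> excluded from dispersion and the paired comparison
        pres = np.array([[1, 1, 1, 1], [1, 0, 1, 1]])
        m = make_matrix(pres, nonnative_idx=[0, 1])
        na = assembly.derive_no_alien(m)
        kept = assembly.min_richness_filter(na)
        assert "c1" not in kept.cells  # 2 natives only
        assert "c0" not in kept.cells or na.richness()["c0"] >= 3

    def test_requires_invaded_cells(self):
        m = make_matrix(np.ones((2, 4), dtype=int))
        with pytest.raises(ValueError, match="invaded"):
            assembly.derive_no_alien(m)


class TestOccurrenceFilter:
    @pytest.mark.parametrize("n_cells,expected", [(709, 7), (111, 1), (100, 1), (250, 3)])
    def test_printed_thresholds(self, n_cells, expected):
        assert assembly.occurrence_threshold(n_cells) == expected

    def test_boundary_species_retained(self):
        # 300 cells -> threshold 3; a species in exactly 3 cells stays
        pres = np.zeros((300, 2), dtype=int)
        pres[:3, 0] = 1
        pres[:2, 1] = 1
        m = make_matrix(pres)
        out = assembly.occurrence_filter(m)
        assert list(out.species) == ["sp0"]

    def test_per_country_union_rule(self):
        # rare in the big country but common in the small one -> kept
        pres = np.zeros((300, 1), dtype=int)
        pres[:2, 0] = 1  # 2 occurrences, both in the 4-cell country
        countries = ["PT"] * 4 + ["ES"] * 296
        m = make_matrix(pres, countries=countries)
        out = assembly.occurrence_filter(m)
        assert list(out.species) == ["sp0"]

    def test_fraction_validation(self):
        m = make_matrix(np.ones((2, 2), dtype=int))
        with pytest.raises(ValueError):
            assembly.occurrence_filter(m, fraction=0.0)


class TestMinRichness:
    def test_boundary(self):
        pres = np.zeros((2, 4), dtype=int)
        pres[0, :2] = 1  # richness 2 -> removed
        pres[1, :3] = 1  # richness 3 -> kept
        m = make_matrix(pres)
        out = assembly.min_richness_filter(m)
        assert out.cells == ["c1"]

    def test_identity_when_all_rich(self):
        pres = np.ones((3, 5), dtype=int)
        m = make_matrix(pres)
        assert assembly.min_richness_filter(m).cells == m.cells


class TestFuaOverlap:
    def test_inside_and_boundary_and_below(self):
        fua = box(0, 0, 10, 10)
        cells = {
            "inside": box(1, 1, 3, 3),
            "half": box(8, 0, 12, 10),  # exactly 50%
            "less": box(8 + 1e-6, 0, 12 + 1e-6, 10),  # 50% - epsilon
            "outside": box(20, 20, 22, 22),
        }
        kept = assembly.fua_overlap_filter(cells, [fua])
        assert set(kept) == {"inside", "half"}

    def test_union_of_fuas(self):
        cells = {"c": box(0, 0, 2, 1)}
        fuas = [box(0, 0, 1, 1), box(1, 0, 2, 1)]  # jointly cover the cell
        assert assembly.fua_overlap_filter(cells, fuas) == ["c"]


class TestCellIncome:
    def test_weighted_mean_3_to_1(self):
        cell = {"c": box(0, 0, 4, 1)}
        nbs = [(box(0, 0, 3, 1), 10000.0), (box(3, 0, 4, 1), 20000.0)]
        inc = assembly.cell_income(cell, nbs)
        assert inc["c"] == pytest.approx(12500.0)

    def test_full_cover_identity(self):
        cell = {"c": box(0, 0, 1, 1)}
        inc = assembly.cell_income(cell, [(box(-1, -1, 2, 2), 31400.0)])
        assert inc["c"] == pytest.approx(31400.0)

    def test_equal_overlaps_arithmetic_mean(self):
        cell = {"c": box(0, 0, 2, 1)}
        nbs = [(box(0, 0, 1, 1), 10000.0), (box(1, 0, 2, 1), 20000.0)]
        assert assembly.cell_income(cell, nbs)["c"] == pytest.approx(15000.0)

    def test_invariant_to_polygon_splitting(self):
        cell = {"c": box(0, 0, 2, 2)}
        whole = [(box(0, 0, 2, 1), 12000.0), (box(0, 1, 2, 2), 30000.0)]
        split = [
            (box(0, 0, 1, 1), 12000.0),
            (box(1, 0, 2, 1), 12000.0),
            (box(0, 1, 2, 2), 30000.0),
        ]
        a = assembly.cell_income(cell, whole)["c"]
        b = assembly.cell_income(cell, split)["c"]
        assert a == pytest.approx(b)

    def test_no_overlap_is_missing_not_zero(self):
        cell = {"c": box(0, 0, 1, 1)}
        inc = assembly.cell_income(cell, [(box(5, 5, 6, 6), 10000.0)])
        assert np.isnan(inc["c"])

    def test_nonpositive_income_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            assembly.cell_income({"c": box(0, 0, 1, 1)}, [(box(0, 0, 1, 1), 0.0)])


class TestStandardizeIncome:
    def _grid(self, incomes, countries):
        t = pd.DataFrame(
            {
                "income": incomes,
                "fua": ["f0"] * len(incomes),
                "country": countries,
            },
            index=[f"c{i}" for i in range(len(incomes))],
        )
        return IncomeGrid(table=t)

    def test_unit_variance_example(self):
        g = assembly.standardize_income(self._grid([1.0, 2.0, 3.0], ["ES"] * 3))
        assert np.allclose(g.table["z_income"], [-1.0, 0.0, 1.0])

    def test_per_country_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        incomes = list(rng.uniform(1e4, 3e4, 20))
        countries = ["ES"] * 12 + ["PT"] * 8
        g = assembly.standardize_income(self._grid(incomes, countries))
        for c in ("ES", "PT"):
            z = g.table.loc[g.table["country"] == c, "z_income"]
            assert abs(z.mean()) < 1e-12
            assert z.std(ddof=1) == pytest.approx(1.0)

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_currency_conversion(self, scale):
        incomes = [1.2e4, 1.8e4, 2.4e4, 3.1e4]
        a = assembly.standardize_income(self._grid(incomes, ["ES"] * 4))
        b = assembly.standardize_income(self._grid([x * scale for x in incomes], ["ES"] * 4))
        assert np.allclose(a.table["z_income"], b.table["z_income"])

    def test_single_cell_country_rejected(self):
        with pytest.raises(ValueError, match="< 2 cells"):
            assembly.standardize_income(self._grid([1e4, 2e4, 3e4], ["ES", "ES", "PT"]))


class TestPipeline:
    def test_stage_counts_logged_in_order(self, small_study):
        m, inc, labels, log = assembly.assemble(
            small_study.communities,
            small_study.income,
            cells_geom=small_study.landscape.cells,
            fuas_geom=list(small_study.landscape.fuas.values()),
        )
        stages = [s["stage"] for s in log.stages]
        assert stages == ["input", "fua_overlap", "min_richness", "income_join"]
        counts = [s["n_cells"] for s in log.stages]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert set(labels.index) == set(m.cells)
        assert (inc.table.index == m.presence.index).all()
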