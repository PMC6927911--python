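"""Metabolic zone assignment and community summaries."""

import numpy as np
import pytest

from nanosip import (
    Category,
    CellClassification,
    InputDomainError,
    UndefinedResultError,
    classify_cell,
    classify_cells,
    co_enrichment_fraction,
    summarize_community,
    weighted_average_percent,
)
from nanosip.classify import round_half_away

DL_C, DL_N = 0.38, 0.07


class TestClassifyCell:
    @pytest.mark.parametrize(
        "c_net, n_net, ec, en, expected",
        [
            (0.0, 0.0, False, False, Category.INACTIVE),
            (0.1, 0.5, False, True, Category.I_EXCL_HETERO),
            (1.0, 0.8, True, True, Category.II_EXCL_AUTO),
            (0.5, 2.0, True, True, Category.III_PRIM_HETERO),
            (1.0, 1.5, True, True, Category.IV_PRIM_AUTO),
            # enriched in 13C only: chemoautotroph even with zero N_net
            (1.0, 0.0, True, False, Category.II_EXCL_AUTO),
        ],
    )
    def test_rule_examples(self, c_net, n_net, ec, en, expected):
        assert classify_cell(c_net, n_net, DL_C, DL_N, ec, en) is expected

    def test_boundary_one_to_one_goes_to_II(self):
        assert classify_cell(1.0, 1.0, DL_C, DL_N, True, True) is Category.II_EXCL_AUTO

    def test_boundary_two_to_one_goes_to_III(self):
        assert classify_cell(1.0, 2.0, DL_C, DL_N, True, True) is Category.III_PRIM_HETERO

    def test_invalid_inputs(self):
        with pytest.raises(InputDomainError):
            classify_cell(1.0, 1.0, 0.0, DL_N, True, True)
        with pytest.raises(InputDomainError):
            classify_cell(-0.1, 1.0, DL_C, DL_N, True, True)


class TestPartition:
    def test_grid_partition_exhaustive(self):
        """Every active point of a 500x500 net-assimilation grid receives
        exactly one of zones I-IV; zone geometry matches the 1:1 and 2:1
        boundary lines."""
        axis = np.linspace(0.0, 5.0, 500)
        c, n = np.meshgrid(axis, axis)
        c, n = c.ravel(), n.ravel()
        flags = np.ones_like(c, dtype=bool)
        cats = classify_cells(c, n, DL_C, DL_N, flags, flags)
        active = {
            Category.I_EXCL_HETERO,
            Category.II_EXCL_AUTO,
            Category.III_PRIM_HETERO,
            Category.IV_PRIM_AUTO,
        }
        assert set(cats) <= active  # all active, each exactly one category
        on_diag = np.isclose(n, c) & (c > DL_C)
        assert all(cat is Category.II_EXCL_AUTO for cat in cats[on_diag])
        on_two = np.isclose(n, 2 * c) & (c > DL_C) & (n > 0)
        assert all(cat is Category.III_PRIM_HETERO for cat in cats[on_two])

    def test_vectorized_matches_per_cell_oracle(self):
        rng = np.random.default_rng(5)
        n_cells = 10**4
        c = rng.uniform(0, 3, n_cells)
        n = rng.uniform(0, 3, n_cells)
        ec = c > DL_C
        en = n > DL_N
        vec = classify_cells(c, n, DL_C, DL_N, ec, en)
        oracle = [
            classify_cell(c[i], n[i], DL_C, DL_N, bool(ec[i]), bool(en[i]))
            for i in range(n_cells)
        ]
        assert all(a is b for a, b in zip(vec, oracle))

    def test_enrichment_and_detection_limit_are_same_transform(self):
        """A cell cannot have both nets below their detection limits while an
        at.% sits above its threshold: the enrichment flag and the DL are the
        same linear transform of the same measurement."""
        from nanosip import ControlStats, SubstratePool, detection_limit, net_assimilation

        stats = ControlStats("C", 1.11, 0.0152, 262)
        pool = SubstratePool("C", 2.62e-3, 13.1)
        dl = detection_limit(stats, pool)
        rng = np.random.default_rng(17)
        for a_meas in rng.uniform(1.11, 13.1, 500):
            enriched = a_meas > stats.threshold_atpct
            net = net_assimilation(a_meas, stats.mean_atpct, pool.tracer_atpct).x_net_pct
            assert enriched == (net > dl)


def _cc(cid, ec, en, cat, c=0.0, n=0.0, taxon="none", **kw):
    return CellClassification(
        cell_id=cid, enriched_c=ec, enriched_n=en, category=cat,
        c_net_pct=c, n_net_pct=n, taxon_label=taxon, **kw
    )


class TestSummaries:
    def test_all_inactive(self):
        cells = [_cc(f"c{i}", False, False, Category.INACTIVE) for i in range(10)]
        summary = summarize_community(cells, group_keys=())
        assert summary.overall.pct_active == 0.0
        assert summary.overall.pct_chemoauto_of_active is None

    def test_ninety_one_percent_active(self):
        cells = [_cc(f"a{i}", False, True, Category.I_EXCL_HETERO, n=1.0) for i in range(91)]
        cells += [_cc(f"i{i}", False, False, Category.INACTIVE) for i in range(9)]
        summary = summarize_community(cells, group_keys=())
        assert summary.overall.pct_active == 91.0

    def test_known_composition_recovered_exactly(self):
        composition = {
            Category.I_EXCL_HETERO: 40,
            Category.II_EXCL_AUTO: 25,
            Category.III_PRIM_HETERO: 20,
            Category.IV_PRIM_AUTO: 5,
            Category.INACTIVE: 10,
        }
        cells = []
        for cat, count in composition.items():
            active = cat is not Category.INACTIVE
            cells += [
                _cc(f"{cat.value}_{i}", active, active, cat) for i in range(count)
            ]
        summary = summarize_community(cells, group_keys=())
        assert summary.overall.counts == {c.value: n for c, n in composition.items()}
        assert summary.overall.pct_chemoauto_of_active == pytest.approx(100 * 30 / 90)
        assert summary.overall.pct_hetero_of_active == pytest.approx(100 * 60 / 90)
        assert (
            summary.overall.pct_chemoauto_of_active + summary.overall.pct_hetero_of_active
            == pytest.approx(100.0)
        )

    def test_per_group_breakdown(self):
        cells = [
            _cc("a", True, True, Category.II_EXCL_AUTO, site="SPOT", bottle="A7"),
            _cc("b", False, True, Category.I_EXCL_HETERO, site="SPOT", bottle="A8"),
            _cc("c", False, False, Category.INACTIVE, site="SPOT", bottle="A8"),
        ]
        summary = summarize_community(cells, group_keys=("site", "bottle"))
        assert summary.groups[("SPOT", "A7")].pct_active == 100.0
        assert summary.groups[("SPOT", "A8")].pct_active == 50.0

    def test_empty_collection_rejected(self):
        with pytest.raises(InputDomainError):
            summarize_community([], group_keys=())


class TestWeightedAverage:
    def test_printed_antibiotic_bottles(self):
        # 25% of 71 cells and 20% of 182 cells -> 21% weighted
        assert round_half_away(weighted_average_percent([(25, 71), (20, 182)])) == 21

    def test_single_group_identity(self):
        assert weighted_average_percent([(37.5, 12)]) == 37.5

    def test_equal_weights(self):
        assert weighted_average_percent([(10, 5), (30, 5)]) == 20.0

    def test_errors(self):
        with pytest.raises(InputDomainError):
            weighted_average_percent([])
        with pytest.raises(InputDomainError):
            weighted_average_percent([(10, 0)])


class TestCoEnrichment:
    def _thaum(self, n_only, both):
        cells = [
            _cc(f"n{i}", False, True, Category.I_EXCL_HETERO, taxon="thaumarchaeota")
            for i in range(n_only)
        ]
        cells += [
            _cc(f"b{i}", True, True, Category.II_EXCL_AUTO, taxon="thaumarchaeota")
            for i in range(both)
        ]
        return cells

    def test_printed_fifteen_percent(self):
        # 13 15N-enriched Thaumarchaeota, 2 also 13C-enriched -> 15%
        frac = co_enrichment_fraction(self._thaum(11, 2), "thaumarchaeota", "N", "C")
        assert round_half_away(frac) == 15

    def test_all_co_enriched(self):
        assert co_enrichment_fraction(self._thaum(0, 4), "thaumarchaeota", "N", "C") == 100.0

    def test_none_co_enriched(self):
        assert co_enrichment_fraction(self._thaum(6, 0), "thaumarchaeota", "N", "C") == 0.0

    def test_zero_denominator_is_undefined(self):
        cells = [_cc("x", True, False, Category.II_EXCL_AUTO, taxon="bacteria")]
        with pytest.raises(UndefinedResultError):
            co_enrichment_fraction(cells, "thaumarchaeota", "N", "C")


@pytest.mark.parametrize("x, expected", [(20.5, 21), (21.4, 21), (-0.5, -1), (0.4, 0)])
def test_round_half_away(x, expected):
    assert round_half_away(x) == expected
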