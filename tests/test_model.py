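"""Unit and property tests for the deterministic cost model."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteocost.model import (
    STAGES,
    Basis,
    BatchConfig,
    Category,
    ModelConfig,
    ResourceItem,
    ThroughputConfig,
    aggregate,
    allocate_item_cost,
    apply_overheads,
    batches_for_throughput,
    category_shares,
    round_half_up,
)

CFG = ModelConfig()


def item(**kwargs):
    base = dict(name="x", stage="pbmc_isolation", category="consumable",
                basis="per_patient", quantity=1.0, unit_cost=1.0)
    base.update(kwargs)
    return ResourceItem(**base)


class TestAllocation:
    @pytest.mark.parametrize(
        "basis,quantity,unit_cost,expected",
        [
            ("per_batch", 1.0, 60.0, 10.0),       # 6 patients per batch
            ("per_sample", 1.0, 2.0, 6.0),        # 3 replicates per patient
            ("per_patient", 1.0, 54.0, 54.0),
            ("annual_fixed", 1.0, 36_500.0, 36_500.0 / 986),  # direct division
        ],
    )
    def test_allocation_bases(self, basis, quantity, unit_cost, expected):
        it = item(basis=basis, quantity=quantity, unit_cost=unit_cost)
        assert allocate_item_cost(it, CFG) == pytest.approx(expected, rel=1e-12)

    def test_annual_fixed_example_magnitude(self):
        # $36,500/year over 986 patients/year is ~$37 per patient
        it = item(basis="annual_fixed", unit_cost=36_500.0)
        assert allocate_item_cost(it, CFG) == pytest.approx(37.02, abs=0.005)

    def test_unknown_basis_rejected(self):
        with pytest.raises(ValueError):
            item(basis="per_banana")

    def test_zero_patients_per_batch_guard(self):
        cfg = dataclasses.replace(
            CFG, batch=BatchConfig(samples_per_batch=6, control_samples=6))
        with pytest.raises(ValueError, match="0 patients per batch"):
            allocate_item_cost(item(basis="per_batch"), cfg)

    def test_zero_annual_throughput_guard(self):
        cfg = dataclasses.replace(
            CFG, throughput=ThroughputConfig(annual_patients=0))
        with pytest.raises(ValueError, match="0 patients per year"):
            allocate_item_cost(item(basis="annual_fixed"), cfg)

    def test_reanalysis_multiplier_on_flagged_labor(self):
        plain = item(category="labor", unit_cost=100.0)
        flagged = item(category="labor", unit_cost=100.0,
                       flags=frozenset({"reanalysis"}))
        assert allocate_item_cost(flagged, CFG) == pytest.approx(
            allocate_item_cost(plain, CFG) * 1.02)

    def test_utilization_rescales_equipment_only(self):
        cfg = dataclasses.replace(
            CFG, throughput=ThroughputConfig(utilization_rate=0.5))
        eq = item(category="equipment", unit_cost=100.0)
        lab = item(category="labor", unit_cost=100.0)
        assert allocate_item_cost(eq, cfg) == pytest.approx(
            allocate_item_cost(eq, CFG) * 1.5)
        assert allocate_item_cost(lab, cfg) == allocate_item_cost(lab, CFG)

    def test_uncertainty_must_bracket_point_estimate(self):
        with pytest.raises(ValueError, match="bracket"):
            item(unit_cost=5.0, uncertainty=(6.0, 9.0)).validate()


TABLE1_CELLS = {
    ("pbmc_isolation", "consumable"): 45.0,
    ("pbmc_isolation", "equipment"): 1.0,
    ("pbmc_isolation", "labor"): 8.0,
    ("protein_quantification", "consumable"): 7.0,
    ("protein_quantification", "equipment"): 2.0,
    ("protein_quantification", "labor"): 12.0,
    ("spin_column_digestion", "consumable"): 49.0,
    ("spin_column_digestion", "equipment"): 2.0,
    ("spin_column_digestion", "labor"): 10.0,
    ("lcms", "consumable"): 42.0,
    ("lcms", "equipment"): 192.0,
    ("lcms", "labor"): 109.0,
    ("bioinformatics", "equipment"): 4.0,
    ("bioinformatics", "labor"): 122.0,
    ("reporting", "equipment"): 0.3,
    ("reporting", "labor"): 135.0,
    ("data_archiving", "equipment"): 8.0,
}


def table1_fixture():
    return [
        item(name=f"{s}/{c}", stage=s, category=c, unit_cost=v)
        for (s, c), v in TABLE1_CELLS.items()
    ]


class TestAggregate:
    def test_published_cell_fixture_reproduces_category_totals(self):
        bd = aggregate(table1_fixture(), CFG)
        cats = bd.category_totals
        assert cats["consumable"] == pytest.approx(143.0)
        assert cats["equipment"] == pytest.approx(209.3)
        assert cats["labor"] == pytest.approx(396.0)
        assert bd.pre_overhead_total == pytest.approx(748.3)

    def test_single_item_single_cell(self):
        bd = aggregate([item(unit_cost=54.0)], CFG)
        assert bd.pre_overhead_total == pytest.approx(54.0)
        assert (bd.matrix.to_numpy() != 0).sum() == 1

    def test_order_invariance(self):
        items = table1_fixture()
        bd1 = aggregate(items, CFG)
        bd2 = aggregate(list(reversed(items)), CFG)
        assert bd1.matrix.equals(bd2.matrix)

    def test_totals_consistency(self):
        bd = aggregate(table1_fixture(), CFG)
        assert bd.stage_totals.sum() == pytest.approx(bd.pre_overhead_total, rel=1e-14)
        assert bd.category_totals.sum() == pytest.approx(bd.pre_overhead_total, rel=1e-14)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], CFG)

    def test_undeclared_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown stage"):
            aggregate([item(stage="shipping")], CFG)


random_items = st.lists(
    st.builds(
        item,
        stage=st.sampled_from(STAGES),
        category=st.sampled_from([c.value for c in Category]),
        basis=st.sampled_from([b.value for b in Basis]),
        quantity=st.floats(0, 100, allow_nan=False),
        unit_cost=st.floats(0, 50, allow_nan=False),
    ),
    min_size=1,
    max_size=40,
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(random_items)
def test_aggregate_matches_item_enumeration_oracle(items):
    """Aggregation equals a brute-force sum over items, cell by cell."""
    bd = aggregate(items, CFG)
    cells = {}
    total = 0.0
    for it in items:
        c = allocate_item_cost(it, CFG)
        cells[(it.stage, it.category.value)] = cells.get(
            (it.stage, it.category.value), 0.0) + c
        total += c
    for (stage, cat), v in cells.items():
        assert bd.matrix.loc[stage, cat] == pytest.approx(v, rel=1e-12, abs=1e-12)
    assert bd.pre_overhead_total == pytest.approx(total, rel=1e-12, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.sampled_from([b.value for b in Basis]),
    st.floats(0.01, 100, allow_nan=False),
    st.floats(0, 50, allow_nan=False),
    st.floats(0.01, 0.99),
)
def test_splitting_an_item_preserves_the_breakdown(basis, quantity, unit_cost, frac):
    whole = [item(basis=basis, quantity=quantity, unit_cost=unit_cost)]
    split = [
        item(name="a", basis=basis, quantity=quantity * frac, unit_cost=unit_cost),
        item(name="b", basis=basis, quantity=quantity * (1 - frac), unit_cost=unit_cost),
    ]
    np.testing.assert_allclose(
        aggregate(whole, CFG).matrix.to_numpy(),
        aggregate(split, CFG).matrix.to_numpy(),
        rtol=1e-12, atol=1e-12,
    )


class TestOverheads:
    def test_examples(self):
        assert apply_overheads(100.0, 0.20) == pytest.approx(120.0)
        assert apply_overheads(748.0, 0.20) == pytest.approx(897.6)
        assert apply_overheads(55.5, 0.0) == 55.5

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            apply_overheads(100.0, -0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 1e6), st.floats(0, 1e6), st.floats(0, 10), st.floats(0, 1))
    def test_linearity(self, a, b, k, rate):
        assert apply_overheads(a + b, rate) == pytest.approx(
            apply_overheads(a, rate) + apply_overheads(b, rate), rel=1e-9, abs=1e-9)
        assert apply_overheads(k * a, rate) == pytest.approx(
            k * apply_overheads(a, rate), rel=1e-9, abs=1e-9)


class TestCategoryShares:
    def test_published_totals_round_to_printed_percentages(self):
        bd = aggregate(table1_fixture(), CFG)
        shares = category_shares(bd)
        rounded = {k: round_half_up(v * 100) for k, v in shares.items()}
        assert rounded == {"consumable": 19, "equipment": 28, "labor": 53}

    def test_degenerate_single_category(self):
        bd = aggregate([item(category="consumable", unit_cost=1.0)], CFG)
        assert category_shares(bd)["consumable"] == 1.0

    def test_shares_sum_to_one_and_invert(self):
        bd = aggregate(table1_fixture(), CFG)
        shares = category_shares(bd)
        assert sum(shares.values()) == pytest.approx(1.0, rel=1e-14)
        for cat, s in shares.items():
            assert s * bd.pre_overhead_total == pytest.approx(
                bd.category_totals[cat], rel=1e-12)

    def test_zero_total_rejected(self):
        bd = aggregate([item(unit_cost=0.0)], CFG)
        with pytest.raises(ValueError):
            category_shares(bd)


class TestThroughputPlumbing:
    @pytest.mark.parametrize("patients,expected", [(986, 164), (6, 1), (0, 0), (5, 0)])
    def test_batches_for_throughput(self, patients, expected):
        assert batches_for_throughput(patients, BatchConfig()) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            batches_for_throughput(-1, BatchConfig())

    def test_batch_partition_invariant(self):
        with pytest.raises(ValueError):
            BatchConfig(samples_per_batch=24, control_samples=5).validate()


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(0.5) == 1.0
    assert round_half_up(1.5) == 2.0
    assert round_half_up(897.6) == 898.0
    assert round_half_up(13.985, 1) == 14.0
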