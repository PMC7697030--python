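import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from littersim import (
    GridSpec,
    classify_butts,
    classify_sharp,
    classify_stack,
    compute_cci,
    compute_hii,
    exceedance_probability,
    indices_by_sector,
    summarize_risk,
)
from littersim.cosimulation import RealizationStack
from littersim.exceptions import PartitionError
from littersim.risk import BUTT_LABELS, SHARP_LABELS


def _stack(values, grid=None):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = GridSpec(nx=values.shape[1], ny=1)
    return RealizationStack(
        points=grid.node_coords(),
        values=values,
        var_names=("butts_per_m2", "sharp_per_m2"),
        master_seed=0,
        realization_seeds=np.arange(values.shape[0], dtype=np.uint32),
        samples=pd.DataFrame(),
        tables=(),
        grid=grid,
    )


class TestIndices:
    def test_cci_survey_scale_example(self):
        res = compute_cci(41_550, 7_500)
        assert res.value == pytest.approx(110.8)
        assert res.category == "Extremely Dirty"

    def test_cci_trivial_and_boundary(self):
        assert compute_cci(0, 7_500).value == 0.0
        assert compute_cci(0, 7_500).category == "Very Clean"
        edge = compute_cci(750, 7_500)
        assert edge.value == pytest.approx(2.0)
        assert edge.category == "Very Clean"

    def test_hii_survey_scale_example(self):
        res = compute_hii(17_925, 44_700, 7_500)
        assert res.value == pytest.approx(17_925 / np.log10(44_700) / 7_500 * 20)
        assert res.value == pytest.approx(10.28, abs=0.01)
        assert res.category == "V"

    def test_hii_trivial_and_reported_value_category(self):
        assert compute_hii(0, 44_700, 7_500).value == 0.0
        assert compute_hii(0, 44_700, 7_500).category == "I"
        from littersim.risk import hii_category

        assert hii_category(9.4) == "V"

    def test_hii_variant_flag(self):
        a = compute_hii(100, 1000, 50, variant="hazard_over_log_total")
        b = compute_hii(100, 1000, 50, variant="hazard_times_log_total")
        assert b.value == pytest.approx(a.value * np.log10(1000) ** 2)

    def test_index_errors(self):
        with pytest.raises(ValueError):
            compute_cci(10, 0)
        with pytest.raises(ValueError):
            compute_hii(5, 8, 100)  # log10 guard: total <= 10
        with pytest.raises(ValueError):
            compute_hii(50, 20, 100)  # hazardous > total
        with pytest.raises(ValueError):
            compute_hii(-1, 100, 100)

    @given(
        st.floats(min_value=0.0, max_value=1e6),
        st.floats(min_value=11.0, max_value=1e7),
        st.floats(min_value=1.0, max_value=1e5),
    )
    def test_formulas_match_brute_force(self, hazard, total, area):
        hazard = min(hazard, total)
        cci = compute_cci(total, area)
        assert cci.value == pytest.approx(total / area * 20.0)
        # doubling all counts doubles CCI
        assert compute_cci(2 * total, area).value == pytest.approx(2 * cci.value)
        hii = compute_hii(hazard, total, area)
        expected = (hazard / np.log10(total)) / area * 20.0 if hazard else 0.0
        assert hii.value == pytest.approx(expected)


class TestClassifiers:
    @pytest.mark.parametrize(
        "density,label",
        [(0.0, "Very Clean"), (0.5, "Very Clean"), (1.0, "Clean"),
         (2.0, "Dirty"), (5.99, "Dirty"), (6.0, "Very Dirty"), (24.0, "Very Dirty")],
    )
    def test_butt_bins_half_open(self, density, label):
        assert BUTT_LABELS[classify_butts(density)] == label

    @pytest.mark.parametrize(
        "density,label",
        [(0.0, "Low risk"), (0.99, "Low risk"), (1.0, "Moderate risk"),
         (3.0, "High risk"), (12.0, "High risk")],
    )
    def test_sharp_bins_half_open(self, density, label):
        assert SHARP_LABELS[classify_sharp(density)] == label

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            classify_butts([-0.1])
        with pytest.raises(ValueError):
            classify_sharp(-1.0)

    def test_classify_stack_partitions_grid(self, rng):
        surface = rng.lognormal(0.9, 0.9, size=200)
        codes, freq = classify_stack(surface, classify_butts)
        assert freq.sum() == 200
        assert codes.shape == (200,)
        constant, cfreq = classify_stack(np.full(50, 0.5), classify_butts)
        assert cfreq["Very Clean"] == 50


class TestExceedance:
    def test_worked_example_80_of_100(self):
        vals = np.zeros((100, 1, 2))
        vals[:80, 0, 1] = 3.0  # exactly at the threshold counts as exceeding
        vals[80:, 0, 1] = 2.9
        stack = _stack(vals)
        p = exceedance_probability(stack, "sharp_per_m2", 3.0)
        assert p[0] == 0.80

    def test_threshold_extremes(self, rng):
        vals = rng.lognormal(0.5, 0.8, size=(30, 10, 2))
        stack = _stack(vals)
        assert np.all(exceedance_probability(stack, 1, 0.0) == 1.0)
        assert np.all(exceedance_probability(stack, 1, vals.max() + 1) == 0.0)

    @given(st.lists(st.floats(min_value=0, max_value=20), min_size=2, max_size=8))
    def test_monotone_in_threshold(self, thresholds):
        rng = np.random.default_rng(3)
        stack = _stack(rng.lognormal(0.5, 0.9, size=(40, 12, 2)))
        t = np.sort(np.asarray(thresholds))
        surfaces = [exceedance_probability(stack, 1, x) for x in t]
        for a, b in zip(surfaces, surfaces[1:]):
            assert np.all(a >= b - 1e-12)
            assert np.all((a >= 0) & (a <= 1))


class TestSectors:
    def test_single_sector_equals_global(self, rng):
        grid = GridSpec(nx=6, ny=8)
        stack = _stack(rng.lognormal(1.0, 0.8, size=(20, grid.n_nodes, 2)), grid)
        summary = summarize_risk(stack)
        table = indices_by_sector(stack, np.zeros(grid.n_nodes, dtype=int))
        assert table.loc[0, "cci_mean"] == pytest.approx(summary.cci.value)
        assert table.loc[0, "hii_mean"] == pytest.approx(summary.hii.value)

    def test_constant_stack_halves_match(self):
        grid = GridSpec(nx=4, ny=6)
        stack = _stack(np.full((5, grid.n_nodes, 2), 2.5), grid)
        labels = (stack.points[:, 1] > 3.0).astype(int)
        table = indices_by_sector(stack, labels)
        assert table.loc[0, "cci_mean"] == pytest.approx(table.loc[1, "cci_mean"])

    def test_area_weighted_sector_ccis_average_to_global(self, rng):
        grid = GridSpec(nx=5, ny=9)
        stack = _stack(rng.lognormal(1.2, 0.7, size=(15, grid.n_nodes, 2)), grid)
        labels = rng.integers(0, 3, size=grid.n_nodes)
        table = indices_by_sector(stack, labels)
        weighted = (table["cci_mean"] * table["area_m2"]).sum() / grid.area
        assert weighted == pytest.approx(summarize_risk(stack).cci.value, rel=1e-12)

    def test_bad_partitions_rejected(self, rng):
        grid = GridSpec(nx=3, ny=3)
        stack = _stack(rng.lognormal(1, 0.5, size=(4, 9, 2)), grid)
        with pytest.raises(PartitionError):
            indices_by_sector(stack, [np.arange(5), np.arange(4, 9)])  # overlap
        with pytest.raises(PartitionError):
            indices_by_sector(stack, [np.arange(5)])  # gap


class TestSummarizeRisk:
    def test_realization_wise_indices_and_maps(self, rng):
        grid = GridSpec(nx=10, ny=12)
        vals = rng.lognormal(1.0, 0.9, size=(40, grid.n_nodes, 2))
        stack = _stack(vals, grid)
        s = summarize_risk(stack)
        totals = vals.sum(axis=(1, 2))
        assert s.cci.value == pytest.approx((totals / grid.area * 20).mean())
        assert s.butt_class_freq.sum() == grid.n_nodes
        assert s.sharp_class_freq.sum() == grid.n_nodes
        assert np.all((s.exceedance >= 0) & (s.exceedance <= 1))
        assert s.cci_sd > 0
        d = s.to_dict()
        assert set(d["hii"]) >= {"value", "category", "variant"}
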