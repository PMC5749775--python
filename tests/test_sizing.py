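"""IOD integration, pair/arm aggregation, proportional DNA allocation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icmkaryo import reference, sizing
from icmkaryo.errors import ValidationError
from icmkaryo.fcm import NuclearDNAEstimate


class TestIntegrateIOD:
    def test_published_chromosome10_product(self):
        """Printed area 4.652 um^2 at mean OD 1.117 gives IOD 5.196."""
        res = sizing.integrate_iod(np.array([[1.117]]), np.array([[True]]), 4.652)
        assert round(res.iod, 3) == 5.196

    def test_zero_od_mask(self):
        res = sizing.integrate_iod(np.zeros((5, 5)), np.ones((5, 5), bool), 0.01)
        assert res.iod == 0.0

    def test_matches_per_pixel_oracle(self, measured_plate):
        """area x mean OD equals a brute-force per-pixel summation."""
        a = measured_plate.od.pixel_area_um2
        for mask in measured_plate.masks[:5]:
            res = sizing.integrate_iod(measured_plate.od, mask)
            brute = 0.0
            for r, c in zip(*np.nonzero(mask)):
                brute += measured_plate.od.od[r, c] * a
            assert res.iod == pytest.approx(brute, rel=1e-9)
            assert res.area_um2 == pytest.approx(mask.sum() * a, rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            sizing.integrate_iod(np.ones((3, 3)), np.zeros((3, 3), bool))


def _meta(pairs):
    """Helper: one metaphase record {pair: [homolog dicts]}."""
    out = {}
    for pid, homologs in pairs.items():
        out[pid] = [
            {"total": sum(arms.values()), "arms": dict(arms)} for arms in homologs
        ]
    return out


class TestAggregation:
    def test_single_metaphase_sums_homologs(self):
        recs = sizing.aggregate_pair_iod(
            [_meta({1: [{"S": 1.0, "L": 2.0}, {"S": 1.1, "L": 2.1}]})]
        )
        assert recs[1].iod_c == pytest.approx(6.2)
        assert recs[1].arm_iod_b == pytest.approx({"S": 2.1, "L": 4.1})

    def test_mean_invariance_for_identical_metaphases(self):
        meta = _meta({1: [{"S": 1.5, "L": 1.5}, {"S": 1.5, "L": 1.5}]})
        one = sizing.aggregate_pair_iod([meta])
        many = sizing.aggregate_pair_iod([meta, meta, meta])
        assert many[1].iod_c == pytest.approx(one[1].iod_c)
        assert many[1].n == 3

    def test_incomplete_metaphase_excluded_with_warning(self):
        metas = [
            _meta({1: [{"S": 1.0, "L": 2.0}, {"S": 1.0, "L": 2.0}]}),
            _meta({1: [{"S": 9.0, "L": 9.0}]}),  # one homolog missing
        ]
        with pytest.warns(UserWarning, match="excluded"):
            recs = sizing.aggregate_pair_iod(metas)
        assert recs[1].iod_c == pytest.approx(6.0)
        assert recs[1].n == 1

    def test_noisy_aggregate_matches_brute_force_mean(self, maize_spec):
        rng = np.random.default_rng(42)
        metas, oracle = [], []
        for _ in range(51):
            homologs = [
                {"S": 1.0 + rng.normal(0, 0.05), "L": 2.0 + rng.normal(0, 0.05)}
                for _ in range(2)
            ]
            metas.append(_meta({3: homologs}))
            oracle.append(sum(sum(h.values()) for h in metas[-1][3] for h in [h["arms"]]))
        recs = sizing.aggregate_pair_iod(metas)
        brute = np.mean(
            [sum(h["total"] for h in meta[3]) for meta in metas]
        )
        assert recs[3].iod_c == pytest.approx(brute, rel=1e-12)


class TestAllocation:
    def test_equal_iods_split_evenly(self):
        alloc = sizing.allocate_2C(6.10, {i: 1.0 for i in range(1, 11)})
        for e in alloc.pairs.values():
            assert e.pg == pytest.approx(0.610)

    def test_published_pair_totals_recovered_from_proportional_iods(self):
        """IODs proportional to the published pair totals allocate back to
        those totals (chromosome 9 -> 0.561 pg)."""
        iods = {
            pid: 13.3 * reference.pair_total_2c_pg(pid)
            for pid in reference.TABLE_2C_ARM_PG
        }
        alloc = sizing.allocate_2C(reference.NUCLEAR_2C_PG, iods)
        assert round(alloc.pairs[9].pg, 3) == 0.561
        total = sum(e.pg for e in alloc.pairs.values())
        assert total == pytest.approx(reference.NUCLEAR_2C_PG, rel=1e-12)

    def test_arm_allocation_conserves_exactly(self):
        recs = sizing.aggregate_pair_iod(
            [
                _meta(
                    {
                        1: [{"S": 2.0, "L": 3.0}, {"S": 2.0, "L": 3.0}],
                        2: [{"S": 1.0, "L": 4.0}, {"S": 1.2, "L": 3.8}],
                    }
                )
            ]
        )
        alloc = sizing.allocate_arm_2C(6.0, recs)
        for pid, e in alloc.pairs.items():
            arm_sum = sum(
                a.pg for (p, _), a in alloc.arms.items() if p == pid
            )
            assert arm_sum == pytest.approx(e.pg, rel=1e-12)
        assert sum(e.pg for e in alloc.pairs.values()) == pytest.approx(6.0, rel=1e-12)

    def test_arm_split_follows_iod_share(self):
        recs = sizing.aggregate_pair_iod(
            [_meta({1: [{"S": 2.0, "L": 3.0}, {"S": 2.0, "L": 3.0}]})]
        )
        alloc = sizing.allocate_arm_2C(1.0, recs)
        assert alloc.arms[(1, "S")].pg == pytest.approx(0.4)
        assert alloc.arms[(1, "L")].pg == pytest.approx(0.6)

    def test_published_satellite_share(self):
        iods = {
            pid: {
                arm: 13.3 * v[0] for arm, v in arms.items()
            }
            for pid, arms in reference.TABLE_2C_ARM_PG.items()
        }
        metas = [_meta({pid: [dict(arms), {a: 0.0 for a in arms}] })
                 for pid, arms in iods.items()]
        # merge into a single metaphase record: one homolog carries the full
        # pair IOD, the other zero; the pair sums are what matters
        merged = {}
        for meta in metas:
            merged.update(meta)
        alloc = sizing.allocate_arm_2C(reference.NUCLEAR_2C_PG, sizing.aggregate_pair_iod([merged]))
        assert round(alloc.arms[(6, "SAT")].pg, 3) == 0.053

    def test_zero_total_iod_rejected(self):
        with pytest.raises(ValidationError):
            sizing.allocate_2C(6.10, {})

    @settings(derandomize=True, max_examples=40)
    @given(
        iods=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=12),
        k=st.floats(0.01, 100.0),
    )
    def test_allocation_invariant_to_iod_rescaling(self, iods, k):
        base = sizing.allocate_2C(6.10, dict(enumerate(iods)))
        scaled = sizing.allocate_2C(6.10, {i: v * k for i, v in enumerate(iods)})
        for pid in base.pairs:
            assert scaled.pairs[pid].pg == pytest.approx(base.pairs[pid].pg, rel=1e-9)

    def test_accepts_nuclear_estimate_object(self):
        nuclear = NuclearDNAEstimate((6.1, 6.1), 2, 6.1, 0.0)
        alloc = sizing.allocate_2C(nuclear, {1: 2.0, 2: 2.0})
        assert alloc.pairs[1].pg == pytest.approx(3.05)


class TestConversions:
    @pytest.mark.parametrize(
        "two_c,expected_e9",
        [(0.376, 0.184), (0.053, 0.026), (0.803, 0.393), (0.0, 0.0)],
    )
    def test_published_1c_bp_values(self, two_c, expected_e9):
        one_c_bp = sizing.pg_to_bp(sizing.two_c_to_one_c(two_c))
        assert round(one_c_bp / 1e9, 3) == expected_e9

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            sizing.pg_to_bp(-1.0)
        with pytest.raises(ValidationError):
            sizing.two_c_to_one_c(-0.1)

    def test_allocation_table_mirrors_published_layout(self):
        iods = {
            pid: 13.3 * reference.pair_total_2c_pg(pid)
            for pid in reference.TABLE_2C_ARM_PG
        }
        recs = {}
        for pid, arms in reference.TABLE_2C_ARM_PG.items():
            recs[pid] = sizing.IODRecord(
                pid,
                iods[pid],
                {a: 13.3 * v[0] for a, v in arms.items()},
                1,
            )
        table = sizing.allocate_arm_2C(reference.NUCLEAR_2C_PG, recs).to_table()
        assert set(table.columns) == {"chromosome", "portion", "2C_pg", "sd_pg", "1C_bp_e9"}
        assert len(table) == 21  # 10 pairs x 2 arms + satellite
        row = table[(table.chromosome == 1) & (table.portion == "S")].iloc[0]
        assert row["2C_pg"] == pytest.approx(0.376, abs=5e-4)
        assert row["1C_bp_e9"] == pytest.approx(0.184, abs=5e-4)
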