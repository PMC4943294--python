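import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcnl_bloodloss import (
    Sex,
    body_surface_area,
    estimate_patient,
    estimated_blood_volume,
    rbc_loss,
    total_blood_loss,
)
from pcnl_bloodloss.errors import DomainError, EstimationError

from conftest import make_record, random_records


def chain_oracle(record, final_tp="h72"):
    """Straight-line recomputation of the whole chain, independent of the
    implementation's composition (plain arithmetic on the record fields)."""
    bsa = 0.0235 * record.height_cm**0.42246 * record.weight_kg**0.51456
    ebv = bsa * (2530.0 if record.sex is Sex.MALE else 2430.0)
    h0 = record.hct.pre_op
    hf = record.hct.get(final_tp)
    transfused_rbc = (
        record.transfused_intraop_ml + record.transfused_postop_ml
    ) * record.product_hct
    total_rbc = ebv * h0 - ebv * hf + transfused_rbc
    return total_rbc / ((h0 + hf) / 2.0)


class TestBodySurfaceArea:
    def test_unit_inputs_give_the_coefficient(self):
        assert body_surface_area(1.0, 1.0) == pytest.approx(0.0235)

    @pytest.mark.parametrize(
        "height,weight,expected",
        [
            (170.0, 70.0, 1.8312893134),  # frozen from the power-law evaluated by hand
            (160.0, 55.0, 1.5766722199),
        ],
    )
    def test_reference_values(self, height, weight, expected):
        assert body_surface_area(height, weight) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("height,weight", [(0, 70), (170, 0), (-1, 70)])
    def test_nonpositive_inputs_rejected(self, height, weight):
        with pytest.raises(DomainError):
            body_surface_area(height, weight)

    @given(
        h=st.floats(100, 220),
        w=st.floats(30, 160),
        dh=st.floats(0.1, 30),
        dw=st.floats(0.1, 30),
    )
    @settings(derandomize=True, max_examples=50)
    def test_strictly_increasing_in_height_and_weight(self, h, w, dh, dw):
        base = body_surface_area(h, w)
        assert body_surface_area(h + dh, w) > base
        assert body_surface_area(h, w + dw) > base


class TestEstimatedBloodVolume:
    def test_sex_factors(self):
        assert estimated_blood_volume(Sex.MALE, 2.0) == pytest.approx(5060.0)
        assert estimated_blood_volume(Sex.FEMALE, 2.0) == pytest.approx(4860.0)

    def test_reference_value(self):
        assert estimated_blood_volume(Sex.FEMALE, 1.577) == pytest.approx(3832.11, abs=0.01)

    def test_nonpositive_bsa_rejected(self):
        with pytest.raises(DomainError):
            estimated_blood_volume(Sex.MALE, 0.0)


class TestRbcLoss:
    def test_forced_arithmetic(self):
        assert rbc_loss(5000, 0.40, 0.35, 0) == pytest.approx((250.0, 0.0, 250.0))

    def test_no_shift_identity(self):
        assert rbc_loss(5000, 0.40, 0.40, 0) == pytest.approx((0.0, 0.0, 0.0))

    def test_with_transfusion(self):
        u, c, t = rbc_loss(3832.1, 0.40, 0.35, 350)
        assert u == pytest.approx(191.6, abs=0.1)
        assert c == pytest.approx(350.0)
        assert t == pytest.approx(541.6, abs=0.1)

    def test_negative_uncompensated_propagates(self):
        u, _, t = rbc_loss(5000, 0.35, 0.40, 0)
        assert u == pytest.approx(-250.0)
        assert t == pytest.approx(-250.0)

    @pytest.mark.parametrize("h0,hf", [(0.0, 0.35), (0.40, 1.0), (1.2, 0.35)])
    def test_hct_domain(self, h0, hf):
        with pytest.raises(DomainError):
            rbc_loss(5000, h0, hf, 0)


class TestTotalBloodLoss:
    def test_forced_division(self):
        assert total_blood_loss(250, 0.40, 0.35) == pytest.approx(666.67, abs=0.01)

    def test_zero_loss_identity(self):
        assert total_blood_loss(0, 0.40, 0.40) == 0.0

    def test_chain_value(self):
        assert total_blood_loss(541.6, 0.40, 0.35) == pytest.approx(1444.3, abs=0.5)


class TestEstimatePatient:
    def test_full_chain_female_example(self):
        rec = make_record(sex=Sex.FEMALE, height_cm=160, weight_kg=55,
                          hct_pre=0.40, hct_72=0.35)
        est = estimate_patient(rec)
        assert est.bsa_m2 == pytest.approx(1.577, abs=1e-3)
        # 3832.1 from the rounded BSA 1.577; full precision gives 3831.3
        assert est.ebv_ml == pytest.approx(3832.1, abs=1.0)
        assert est.total_blood_loss_ml == pytest.approx(511.0, abs=0.5)

    def test_no_shift_no_transfusion_is_zero(self):
        rec = make_record(hct_pre=0.40, hct_72=0.40)
        assert estimate_patient(rec).total_blood_loss_ml == 0.0

    def test_sex_proportionality(self):
        female = make_record(sex=Sex.FEMALE)
        male = make_record(sex=Sex.MALE)
        ratio = (
            estimate_patient(male).total_blood_loss_ml
            / estimate_patient(female).total_blood_loss_ml
        )
        assert ratio == pytest.approx(2530 / 2430, rel=1e-12)

    def test_missing_final_hct_raises_with_patient_id(self):
        from pcnl_bloodloss import HematocritSeries, PatientRecord

        rec = PatientRecord(
            patient_id="NOFINAL",
            sex=Sex.FEMALE,
            age=40,
            height_cm=160,
            weight_kg=55,
            stone_burden_mm2=500,
            hct=HematocritSeries(pre_op=0.40, h24=0.36),
        )
        with pytest.raises(EstimationError, match="NOFINAL"):
            estimate_patient(rec)

    def test_internal_consistency_invariants(self):
        for rec in random_records(50, seed=3):
            est = estimate_patient(rec)
            assert est.initial_rbc_ml == pytest.approx(est.ebv_ml * est.hct_initial, rel=1e-9)
            assert est.final_rbc_ml == pytest.approx(est.ebv_ml * est.hct_final, rel=1e-9)
            assert est.total_rbc_loss_ml == pytest.approx(
                est.uncompensated_rbc_loss_ml + est.compensated_rbc_loss_ml, rel=1e-9
            )
            assert est.compensated_rbc_loss_ml >= 0

    def test_matches_straight_line_oracle(self):
        for rec in random_records(200, seed=5):
            est = estimate_patient(rec)
            assert est.total_blood_loss_ml == pytest.approx(chain_oracle(rec), rel=1e-9)


class TestScaleAndMonotonicity:
    @given(
        c=st.floats(0.5, 1.6),
        h0=st.floats(0.25, 0.55),
        hf=st.floats(0.18, 0.50),
        ebv=st.floats(2500, 7000),
    )
    @settings(derandomize=True, max_examples=60)
    def test_common_hct_scaling_cancels_without_transfusion(self, c, h0, hf, ebv):
        """TBL is invariant to rescaling both hematocrits when nothing
        was transfused (the hct scale cancels between numerator and
        denominator of the hemodilution correction)."""
        if not (0 < c * h0 < 1 and 0 < c * hf < 1):
            return
        _, _, t1 = rbc_loss(ebv, h0, hf, 0)
        _, _, t2 = rbc_loss(ebv, c * h0, c * hf, 0)
        tbl1 = total_blood_loss(t1, h0, hf)
        tbl2 = total_blood_loss(t2, c * h0, c * hf)
        assert tbl2 == pytest.approx(tbl1, rel=1e-9)

    def test_increasing_in_hct_shift_at_fixed_mean(self):
        ebv = 4000.0
        losses = []
        for shift in (0.01, 0.03, 0.05, 0.08):
            h0, hf = 0.375 + shift / 2, 0.375 - shift / 2
            _, _, t = rbc_loss(ebv, h0, hf, 0)
            losses.append(total_blood_loss(t, h0, hf))
        assert losses == sorted(losses)
        assert len(set(losses)) == len(losses)

    def test_increasing_in_transfused_volume(self):
        rec0 = make_record(transfused_intraop_ml=0)
        rec1 = make_record(transfused_intraop_ml=200)
        rec2 = make_record(transfused_intraop_ml=400)
        tbls = [estimate_patient(r).total_blood_loss_ml for r in (rec0, rec1, rec2)]
        assert tbls == sorted(tbls)
        assert tbls[0] < tbls[2]
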