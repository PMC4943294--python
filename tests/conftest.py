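import numpy as np
import pytest

from pcnl_bloodloss import (
    HematocritSeries,
    PatientRecord,
    Sex,
    StoneType,
    SyntheticCohortConfig,
    generate,
)


def make_record(
    patient_id="P1",
    sex=Sex.FEMALE,
    age=45.0,
    height_cm=160.0,
    weight_kg=55.0,
    stone_burden_mm2=900.0,
    hct_pre=0.40,
    hct_72=0.35,
    crossmatched_ml=400.0,
    transfused_intraop_ml=0.0,
    transfused_postop_ml=0.0,
    product_hct=1.0,
    stone_type=StoneType.NON_STAGHORN,
):
    """Convenience constructor for a valid patient record."""
    return PatientRecord(
        patient_id=patient_id,
        sex=sex,
        age=age,
        height_cm=height_cm,
        weight_kg=weight_kg,
        stone_burden_mm2=stone_burden_mm2,
        stone_type=stone_type,
        hct=HematocritSeries(pre_op=hct_pre, h72=hct_72),
        crossmatched_ml=crossmatched_ml,
        transfused_intraop_ml=transfused_intraop_ml,
        transfused_postop_ml=transfused_postop_ml,
        product_hct=product_hct,
    )


def random_records(n, seed):
    """n random valid patient records spanning the physiological ranges."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        pre = rng.uniform(0.25, 0.55)
        final = rng.uniform(0.18, 0.50)
        transfused = rng.choice([0.0, rng.uniform(50, 700)], p=[0.7, 0.3])
        records.append(
            make_record(
                patient_id=f"R{i}",
                sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
                age=rng.uniform(18, 85),
                height_cm=rng.uniform(140, 195),
                weight_kg=rng.uniform(40, 110),
                stone_burden_mm2=rng.uniform(0, 4000),
                hct_pre=pre,
                hct_72=final,
                crossmatched_ml=rng.uniform(0, 900),
                transfused_intraop_ml=transfused * rng.random(),
                transfused_postop_ml=transfused * rng.random(),
                product_hct=rng.uniform(0.4, 1.0),
            )
        )
    return records


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort at a fixed seed (shared, read-only)."""
    return generate(SyntheticCohortConfig(seed=7))
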