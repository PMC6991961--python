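import pytest
from hypothesis import settings

import chwplan as cp
from chwplan import reference as ref

settings.register_profile("suite", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sed_pu_diaries() -> cp.DiaryDataset:
    """Synthetic Sedibeng peri-urban diaries at the study sample size."""
    return cp.generate_diaries(
        cp.default_config(ref.SEDIBENG, cp.SiteClass.PERI_URBAN, seed=101)
    )


@pytest.fixture(scope="session")
def umz_dr_diaries() -> cp.DiaryDataset:
    """Synthetic uMzinyathi deep-rural diaries at the study sample size."""
    return cp.generate_diaries(
        cp.default_config(ref.UMZINYATHI, cp.SiteClass.DEEP_RURAL, seed=202)
    )


@pytest.fixture()
def tiny_dataset() -> cp.DiaryDataset:
    """Three hand-made home-visit episodes in one cell."""
    entries = [
        cp.DiaryEntry(
            chw_id="X-1",
            district="Sedibeng",
            site_class=cp.SiteClass.PERI_URBAN,
            day_index=1,
            activity_code="home_visit_other",
            travel_minutes=15,
            activity_minutes=m,
            content_codes=("screening",) if m != 60 else (),
            condition_codes=("hiv",),
            recipient_types=("adult",),
        )
        for m in (40, 60, 50)
    ]
    return cp.DiaryDataset(entries=entries, provenance="handmade")
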