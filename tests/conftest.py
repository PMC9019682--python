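import pytest

from avipbk.store import StudyRecord, load_fixture_tables


@pytest.fixture(scope="session")
def fixture_records():
    """All packaged table fixtures, loaded once per session."""
    return load_fixture_tables()


def make_records(values, parameter="albumin_g_dL", unit="g/dL",
                 species="chicken", sex="female", repro_state="immature"):
    return [
        StudyRecord(study_id=f"s{i}", species=species, sex=sex,
                    repro_state=repro_state, parameter=parameter,
                    value=float(v), unit=unit)
        for i, v in enumerate(values)
    ]
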