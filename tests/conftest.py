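import numpy as np
import pytest

from prostaging.record_model import GleasonInfo, PathologyRecord, TnmCode
from prostaging.synthetic_data import GeneratorConfig, generate_corpus


def tnm(category: str, code: str, prefix: str = "p") -> TnmCode:
    return TnmCode(prefix=prefix, category=category, code=code)


def make_record(
    report_id="R1",
    patient_id="P1",
    t=None,
    n=None,
    m=None,
    gg=None,
    primary=None,
    secondary=None,
    pct_secondary=None,
    psa=None,
    epe=None,
    svi=None,
    nodes_examined=None,
    nodes_with_metastasis=None,
    **kwargs,
):
    """Terse record builder for tests; None means missing."""
    from prostaging.record_model import NOT_MENTIONED

    def or_missing(v):
        return NOT_MENTIONED if v is None else v

    gleason = GleasonInfo(
        primary_pattern=or_missing(primary),
        secondary_pattern=or_missing(secondary),
        pct_secondary=or_missing(pct_secondary),
        reported_grade_group=or_missing(gg),
    )
    return PathologyRecord(
        patient_id=patient_id,
        report_id=report_id,
        t_stage=or_missing(tnm("T", t) if isinstance(t, str) else t),
        n_stage=or_missing(tnm("N", n) if isinstance(n, str) else n),
        m_stage=or_missing(tnm("M", m, prefix="c") if isinstance(m, str) else m),
        gleason=gleason,
        psa_ng_ml=or_missing(psa),
        epe=or_missing(epe),
        svi=or_missing(svi),
        nodes_examined=or_missing(nodes_examined),
        nodes_with_metastasis=or_missing(nodes_with_metastasis),
        **kwargs,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def small_bundle():
    """200 mixed-dialect records with realistic missingness."""
    return generate_corpus(GeneratorConfig(n_patients=200, seed=11))


@pytest.fixture(scope="session")
def coherent_records():
    """300 fully-populated coherent records (no missing fields)."""
    return list(generate_corpus(GeneratorConfig(n_patients=300, seed=2, missing_rates={})).records)
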