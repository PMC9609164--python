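import numpy as np
import pandas as pd
import pytest

from perizygote import phenotype_similarity as ps
from perizygote import synthetic_trio as st


@pytest.fixture(scope="session")
def default_sim():
    """One full default-condition synthetic trio shared across tests."""
    return st.simulate_trio(st.SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_trio_row(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    child_gt="0/1",
    father_gt="0/0",
    mother_gt="0/0",
    child_ad=(15, 15),
    father_ad=(30, 0),
    mother_ad=(30, 0),
    gq=99,
    child_adf=None,
    child_adr=None,
    repeat_masked=False,
    near_indel=False,
):
    if child_adf is None:
        child_adf = child_ad[1] // 2
    if child_adr is None:
        child_adr = child_ad[1] - child_adf
    return {
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "child_gt": child_gt,
        "father_gt": father_gt,
        "mother_gt": mother_gt,
        "child_ref": child_ad[0],
        "child_alt": child_ad[1],
        "father_ref": father_ad[0],
        "father_alt": father_ad[1],
        "mother_ref": mother_ad[0],
        "mother_alt": mother_ad[1],
        "child_gq": gq,
        "father_gq": gq,
        "mother_gq": gq,
        "child_adf": child_adf,
        "child_adr": child_adr,
        "repeat_masked": repeat_masked,
        "near_indel": near_indel,
    }


def make_trio_table(rows):
    return pd.DataFrame([make_trio_row(**r) for r in rows])


@pytest.fixture()
def toy_corpus():
    """Toy ontology R -> {t1, t2}, t1 -> t3 with entities annotated
    {t3}, {t3}, {t1}, {t2}: IC(t1) = ln(4/3), IC(t2) = ln 4, IC(t3) = ln 2."""
    onto = ps.OntologyGraph({"R": [], "t1": ["R"], "t2": ["R"], "t3": ["t1"]})
    corpus = ps.AnnotationCorpus(
        onto, {"e1": ["t3"], "e2": ["t3"], "e3": ["t1"], "e4": ["t2"]}
    )
    return onto, corpus
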