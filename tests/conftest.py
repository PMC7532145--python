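import numpy as np
import pandas as pd
import pytest

from bmx.data_model import ClinicalTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_clinical(n, rng, pcr_rate=0.3, treated_frac=0.5):
    """Random clinical table with independent receptor status and outcome."""
    n_treated = int(round(n * treated_frac))
    arm = np.array(["control"] * (n - n_treated) + ["treated"] * n_treated)
    rng.shuffle(arm)
    df = pd.DataFrame(
        {
            "arm": arm,
            "hr": rng.binomial(1, 0.5, n),
            "her2": rng.binomial(1, 0.25, n),
            "mp_class": "unknown",
            "pcr": rng.binomial(1, pcr_rate, n),
        },
        index=pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id"),
    )
    return ClinicalTable(df)


@pytest.fixture
def toy_clinical_file(tmp_path):
    """4-row clinical TSV, all fields valid."""
    path = tmp_path / "clinical.tsv"
    path.write_text(
        "patient_id\tarm\thr\ther2\tmp_class\tpcr\n"
        "P1\tcontrol\t1\t0\tMP1\t0\n"
        "P2\ttreated\t0\t0\tMP2\t1\n"
        "P3\ttreated\t1\t1\tMP1\t1\n"
        "P4\tcontrol\t0\t1\tMP2\t0\n"
    )
    return path


@pytest.fixture
def toy_matrix_file(tmp_path):
    path = tmp_path / "matrix.tsv"
    path.write_text(
        "feature\tP1\tP2\tP3\n"
        "g1\t1.5\t2.25\t-0.125\n"
        "g2\t0.1\t0.2\t0.3\n"
        "g3\t7\t8\t9\n"
    )
    return path
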