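import pandas as pd
import pytest

from usigma import EQAReplicateSet, IQCSeries


@pytest.fixture
def iqc_csv(tmp_path):
    """Write a tidy IQC CSV from (lab, analyte, level, run, value) rows."""

    def _write(rows, name="iqc.csv"):
        path = tmp_path / name
        pd.DataFrame(rows, columns=["lab", "analyte", "level", "run", "value"]).to_csv(
            path, index=False
        )
        return path

    return _write


@pytest.fixture
def eqa_csv(tmp_path):
    """Write a tidy EQA CSV from (lab, analyte, level, replicate, value, target) rows."""

    def _write(rows, name="eqa.csv"):
        path = tmp_path / name
        pd.DataFrame(
            rows, columns=["lab", "analyte", "level", "replicate", "value", "target"]
        ).to_csv(path, index=False)
        return path

    return _write


@pytest.fixture
def make_series():
    def _make(values, lab="L1", analyte="K", level="level1"):
        return IQCSeries(lab, analyte, level, tuple(values))

    return _make


@pytest.fixture
def make_eqa():
    def _make(values, target, lab="L1", analyte="K", level="level1"):
        return EQAReplicateSet(lab, analyte, level, tuple(values), target)

    return _make
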