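import pandas as pd
import pytest

from wrkykit import io_gene_models as io


@pytest.fixture(scope="session")
def family_rows():
    return io.load_family_table()


@pytest.fixture
def fasta_file(tmp_path):
    def write(records, name="seqs.fasta"):
        path = tmp_path / name
        io.write_fasta(records, path)
        return path

    return write


@pytest.fixture
def ct_table():
    rows = []
    for rep in range(3):
        rows.append({"gene": "gA", "condition": "treated", "ct_target": 25.0, "ct_reference": 20.0, "replicate": rep})
        rows.append({"gene": "gA", "condition": "untreated", "ct_target": 27.0, "ct_reference": 20.0, "replicate": rep})
    return pd.DataFrame(rows)
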