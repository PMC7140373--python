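from __future__ import annotations

import pytest

from mdm import Contig, datasets


@pytest.fixture
def write_fasta(tmp_path):
    """Write records to a temp FASTA file and return its path."""

    def _write(records: dict[str, str], name: str = "test.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def write_bed_file(tmp_path):
    def _write(lines: list[str], name: str = "test.bed"):
        path = tmp_path / name
        path.write_text("".join(line + "\n" for line in lines))
        return path

    return _write


@pytest.fixture(scope="session")
def observed_table():
    return datasets.load_observed_composition()


@pytest.fixture(scope="session")
def human_params():
    return datasets.context_probabilities_for("human")


@pytest.fixture
def contig():
    def _make(seq: str, cid: str = "c1") -> Contig:
        return Contig(id=cid, seq=seq)

    return _make
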