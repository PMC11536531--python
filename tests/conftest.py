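import pytest

from adapterpurge.fasta_io import Assembly, Contig


@pytest.fixture
def tiny_assembly():
    return Assembly(
        name="tiny",
        contigs=[Contig(id="c1", seq="ACGT"), Contig(id="c2", seq="GGGG")],
    )


@pytest.fixture
def write_tmp_fasta(tmp_path):
    def _write(text, name="asm.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
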