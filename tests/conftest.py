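import numpy as np
import pytest

from kmerphylo import Genome, GenomeRecord, count_kmers


@pytest.fixture
def fasta_writer(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text, name="genome.fasta"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


def make_genome(*sequences, taxon_id="test"):
    records = tuple(
        GenomeRecord(record_id=f"r{i + 1}", sequence=s.upper())
        for i, s in enumerate(sequences)
    )
    return Genome(taxon_id=taxon_id, records=records)


def random_genome(length, rng, taxon_id="rand"):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return make_genome(seq, taxon_id=taxon_id)


@pytest.fixture
def random_counts():
    """k=4 counts of a 20 kb random genome — small but fully populated."""
    rng = np.random.default_rng(1234)
    return count_kmers(random_genome(20_000, rng), k=4)
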