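"""Shared fixtures: all data is generated programmatically at test time."""

import numpy as np
import pytest

from metacover.profiles import SequencingProfile
from metacover.simulate import random_genome


def make_fastq(records) -> str:
    """Render (read_id, bases, phred_scores) triples as Sanger FASTQ text."""
    chunks = []
    for read_id, bases, quals in records:
        qual = "".join(chr(q + 33) for q in quals)
        chunks.append(f"@{read_id}\n{bases}\n+\n{qual}\n")
    return "".join(chunks)


@pytest.fixture
def phred_exact_profile():
    """A profile whose error probabilities sit exactly on integer phred
    scores, so quality quantisation in the simulator is lossless and
    closed-loop comparisons test sampling error only."""
    qs = np.round(np.linspace(30, 20, 150)).astype(int)
    return SequencingProfile(
        name="phred-exact",
        reads_per_run=10_000,
        length_mean=120.0,
        length_sd=10.0,
        max_length=150,
        per_position_error=[10.0 ** (-q / 10.0) for q in qs],
    )


@pytest.fixture
def four_genomes():
    """Four distinct 20 kb random genomes."""
    return [(f"genome_{i}", random_genome(20_000, seed=100 + i)) for i in range(4)]


@pytest.fixture
def genome_fasta(tmp_path, four_genomes):
    path = tmp_path / "genomes.fasta"
    with open(path, "w") as fh:
        for gid, seq in four_genomes:
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    return path
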