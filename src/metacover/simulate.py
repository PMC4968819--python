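"""Simulated viral metagenome read sets with exact ground truth.

Reads are drawn from a weighted community of genomes under a sequencing
profile: species chosen multinomially by abundance weight, read length from a
rounded normal, start position uniform along the (linear) genome, strand
uniform.  Substitution errors are injected per position at the profile's
error probability and marked by lowercasing the erroneous base, so the truth
is recoverable from the FASTQ alone; a key CSV additionally records, for
every read, its source genome, 0-based half-open coordinates on the forward
strand, strand, and error count.

Only substitutions are simulated — the lowercase-marking convention is
position-preserving, which indels would break.  Genomes are treated as linear
for read placement, matching how reference FASTA is stored (the coverage
theory's circular model differs at genome ends; see the package docs).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO

from .profiles import SequencingProfile

__all__ = [
    "CommunityMember",
    "KeyRecord",
    "SimulatedRead",
    "KEY_FIELDS",
    "build_community",
    "draw_read",
    "inject_errors",
    "simulate_run",
    "read_genomes",
    "load_key",
    "random_genome",
]

KEY_FIELDS = ("read_id", "genome_id", "start", "end", "strand", "n_errors")

QUALITY_MIN = 2
QUALITY_MAX = 41

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ALTERNATIVES = {b: "ACGT".replace(b, "") for b in "ACGT"}
_ALTERNATIVES["N"] = "ACGT"


@dataclass(frozen=True)
class CommunityMember:
    """One genome in the simulated community with its abundance weight."""

    genome_id: str
    sequence: str
    weight: float

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id!r} has an empty sequence")
        if not (0 < self.weight <= 1):
            raise ValueError(f"weight must lie in (0, 1], got {self.weight}")


@dataclass(frozen=True)
class KeyRecord:
    """Ground truth for one simulated read (forward-strand coordinates)."""

    read_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    n_errors: int


@dataclass(frozen=True)
class SimulatedRead:
    """A read with lowercase bases at error positions and aligned qualities."""

    read_id: str
    bases: str
    qualities: List[int]


def random_genome(length: int, seed: int, gc: float = 0.45) -> str:
    """Generate a random nucleotide sequence at the given GC content.

    Convenience for demonstrations and simulation studies when no reference
    FASTA is at hand; i.i.d. bases, so no repeats or codon structure.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def read_genomes(fasta: Union[str, Path]) -> List[Tuple[str, str]]:
    """Load (id, uppercase sequence) pairs from a multi-FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta), "fasta")]


def build_community(
    genomes: Union[str, Path, Sequence[Tuple[str, str]]],
    n_species: int,
    distribution: str = "uniform",
    decay: float = 0.5,
    seed: int = 0,
) -> List[CommunityMember]:
    """Sample ``n_species`` genomes without replacement and assign weights.

    ``uniform`` gives every member weight 1/n; ``exponential`` gives member at
    rank i (in sampling order) weight proportional to exp(-decay * i),
    normalised, emulating the steep rank-abundance curves of real viromes.
    """
    if isinstance(genomes, (str, Path)):
        genomes = read_genomes(genomes)
    genomes = list(genomes)
    if n_species < 1:
        raise ValueError(f"n_species must be positive, got {n_species}")
    if len(genomes) < n_species:
        raise ValueError(
            f"collection holds {len(genomes)} genomes, need at least {n_species}"
        )
    if distribution not in ("uniform", "exponential"):
        raise ValueError(f"distribution must be uniform or exponential, got {distribution!r}")
    if decay <= 0:
        raise ValueError(f"decay must be positive, got {decay}")

    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(genomes), size=n_species, replace=False)
    if distribution == "uniform":
        weights = np.full(n_species, 1.0 / n_species)
    else:
        weights = np.exp(-decay * np.arange(n_species))
        weights /= weights.sum()
    return [
        CommunityMember(genome_id=genomes[i][0], sequence=genomes[i][1], weight=float(w))
        for i, w in zip(chosen, weights)
    ]


def inject_errors(
    bases: str, error_probs: Sequence[float], rng: np.random.Generator
) -> Tuple[str, int]:
    """Substitute each base independently with its positional error
    probability; erroneous bases become a uniformly chosen *different*
    nucleotide, written in lowercase.  Returns (mutated bases, error count)."""
    n = len(bases)
    if len(error_probs) < n:
        raise ValueError(
            f"need {n} error probabilities, got {len(error_probs)}"
        )
    probs = np.asarray(error_probs[:n], dtype=float)
    hits = rng.random(n) < probs
    if not hits.any():
        return bases, 0
    out = list(bases)
    # draw substitution choices in one call to keep the RNG stream compact
    picks = rng.integers(0, 3, size=int(hits.sum()))
    for pos, pick in zip(np.flatnonzero(hits), picks):
        alts = _ALTERNATIVES.get(out[pos], "ACGT")
        out[pos] = alts[pick % len(alts)].lower()
    return "".join(out), int(hits.sum())


def _quality_string(error_probs: Sequence[float]) -> List[int]:
    return [
        min(max(round(-10.0 * math.log10(p)), QUALITY_MIN), QUALITY_MAX)
        for p in error_probs
    ]


def draw_read(
    member: CommunityMember,
    profile: SequencingProfile,
    rng: np.random.Generator,
    read_id: str = "read",
) -> Tuple[SimulatedRead, KeyRecord]:
    """Draw one read from ``member`` under ``profile``.

    Length ~ round(Normal(length_mean, length_sd)), truncated to
    [1, min(max_length, genome length)]; start uniform; strand uniform; the
    (reverse-complemented, for minus strand) substring is then error-injected.
    """
    genome_len = len(member.sequence)
    length = int(round(rng.normal(profile.length_mean, profile.length_sd)))
    length = max(1, min(length, profile.max_length, genome_len))

    start = int(rng.integers(0, genome_len - length + 1))
    end = start + length
    strand = "+" if rng.random() < 0.5 else "-"

    template = member.sequence[start:end]
    if strand == "-":
        template = template.translate(_COMPLEMENT)[::-1]

    bases, n_errors = inject_errors(template, profile.per_position_error, rng)
    qualities = _quality_string(profile.per_position_error[:length])

    read = SimulatedRead(read_id=read_id, bases=bases, qualities=qualities)
    key = KeyRecord(
        read_id=read_id,
        genome_id=member.genome_id,
        start=start,
        end=end,
        strand=strand,
        n_errors=n_errors,
    )
    return read, key


def simulate_run(
    community: Sequence[CommunityMember],
    profile: SequencingProfile,
    n_reads: int,
    seed: int,
    fastq_path: Union[str, Path],
    key_path: Union[str, Path],
) -> Tuple[Path, Path]:
    """Simulate ``n_reads`` reads and write a Sanger FASTQ plus a key CSV.

    Species are assigned multinomially by community weight.  The same seed,
    community, profile and read count reproduce byte-identical outputs.
    """
    if n_reads < 1:
        raise ValueError(f"n_reads must be positive, got {n_reads}")
    weights = np.array([m.weight for m in community], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"community weights sum to {weights.sum()}, expected 1")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    assignment = rng.choice(len(community), size=n_reads, p=weights)

    fastq_path, key_path = Path(fastq_path), Path(key_path)
    width = max(6, len(str(n_reads)))
    try:
        with open(fastq_path, "w") as fq, open(key_path, "w", newline="") as kf:
            writer = csv.writer(kf)
            writer.writerow(KEY_FIELDS)
            for i, member_idx in enumerate(assignment):
                read_id = f"read_{i:0{width}d}"
                read, key = draw_read(
                    community[member_idx], profile, rng, read_id=read_id
                )
                qual = "".join(chr(q + 33) for q in read.qualities)
                fq.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")
                writer.writerow(
                    [key.read_id, key.genome_id, key.start, key.end, key.strand, key.n_errors]
                )
    except OSError as exc:
        raise OSError(
            f"failed writing simulation output ({fastq_path}, {key_path}): {exc}"
        ) from exc
    return fastq_path, key_path


def load_key(key_path: Union[str, Path]) -> List[KeyRecord]:
    """Read a key CSV back into KeyRecord objects."""
    records = []
    with open(key_path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            records.append(
                KeyRecord(
                    read_id=row["read_id"],
                    genome_id=row["genome_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    n_errors=int(row["n_errors"]),
                )
            )
    return records
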