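"""Community construction, error injection, and ground-truth soundness."""

import collections
import math

import numpy as np
import pytest
from Bio import SeqIO

from metacover.profiles import SequencingProfile, infer_profile
from metacover.simulate import (
    build_community,
    draw_read,
    inject_errors,
    load_key,
    random_genome,
    simulate_run,
)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def oriented_substring(genome, key):
    sub = genome[key.start : key.end]
    return sub.translate(COMPLEMENT)[::-1] if key.strand == "-" else sub


class TestBuildCommunity:
    def test_uniform_weights(self, four_genomes):
        comm = build_community(four_genomes, 4, "uniform", seed=1)
        assert [m.weight for m in comm] == pytest.approx([0.25] * 4)

    def test_exponential_weights_hand_normalized(self, four_genomes):
        # weights proportional to (1, e^-0.5, e^-1), normalised by hand
        comm = build_community(four_genomes, 3, "exponential", decay=0.5, seed=1)
        z = 1 + math.exp(-0.5) + math.exp(-1.0)
        expected = [1 / z, math.exp(-0.5) / z, math.exp(-1.0) / z]
        assert [m.weight for m in comm] == pytest.approx(expected, abs=1e-5)
        assert expected == pytest.approx([0.50648, 0.30720, 0.18632], abs=1e-5)

    def test_single_genome_gets_unit_weight(self, four_genomes):
        for dist in ("uniform", "exponential"):
            comm = build_community(four_genomes, 1, dist, seed=1)
            assert comm[0].weight == pytest.approx(1.0)

    def test_weights_sum_to_one(self, four_genomes):
        comm = build_community(four_genomes, 4, "exponential", decay=1.3, seed=5)
        assert sum(m.weight for m in comm) == pytest.approx(1.0, abs=1e-9)

    def test_sampling_without_replacement(self, four_genomes):
        comm = build_community(four_genomes, 4, "uniform", seed=2)
        assert len({m.genome_id for m in comm}) == 4

    def test_too_few_genomes_rejected(self, four_genomes):
        with pytest.raises(ValueError, match="genomes"):
            build_community(four_genomes, 5, "uniform")

    def test_reads_fasta_path(self, genome_fasta):
        comm = build_community(genome_fasta, 2, "uniform", seed=1)
        assert len(comm) == 2
        assert all(set(m.sequence) <= set("ACGTN") for m in comm)


class TestInjectErrors:
    def test_zero_error_is_identity(self):
        rng = np.random.default_rng(0)
        seq = random_genome(500, seed=1)
        out, n = inject_errors(seq, [1e-300] * 500, rng)
        assert out == seq
        assert n == 0

    def test_certain_error_mutates_every_base(self):
        rng = np.random.default_rng(0)
        seq = random_genome(300, seed=2)
        out, n = inject_errors(seq, [1.0] * 300, rng)
        assert n == 300
        assert all(c.islower() for c in out)
        assert all(a.upper() != b for a, b in zip(out, seq))

    def test_error_count_in_binomial_band(self):
        rng = np.random.default_rng(7)
        seq = random_genome(10_000, seed=3)
        _, n = inject_errors(seq, [0.1] * 10_000, rng)
        assert 1000 - 4 * math.sqrt(900) <= n <= 1000 + 4 * math.sqrt(900)

    def test_lowercase_marks_exactly_the_errors(self):
        rng = np.random.default_rng(11)
        seq = random_genome(2000, seed=4)
        out, n = inject_errors(seq, [0.2] * 2000, rng)
        lower = [i for i, c in enumerate(out) if c.islower()]
        assert len(lower) == n
        for i in lower:
            assert out[i].upper() != seq[i]
        for i in set(range(2000)) - set(lower):
            assert out[i] == seq[i]

    def test_insufficient_probabilities_rejected(self):
        with pytest.raises(ValueError):
            inject_errors("ACGT", [0.1, 0.1], np.random.default_rng(0))


class TestDrawRead:
    def test_near_zero_error_reproduces_genome(self, four_genomes):
        prof = SequencingProfile(
            name="clean", reads_per_run=1, length_mean=100.0, length_sd=5.0,
            max_length=120, per_position_error=[1e-9] * 120,
        )
        member = build_community(four_genomes, 1, "uniform", seed=1)[0]
        rng = np.random.default_rng(42)
        for _ in range(100):
            read, key = draw_read(member, prof, rng)
            assert read.bases == oriented_substring(member.sequence, key)
            assert key.n_errors == 0
            assert read.bases.isupper()

    def test_genome_shorter_than_mean_truncates(self):
        from metacover.simulate import CommunityMember

        prof = SequencingProfile(
            name="long", reads_per_run=1, length_mean=150.0, length_sd=0.0,
            max_length=200, per_position_error=[0.01] * 200,
        )
        member = CommunityMember("tiny", random_genome(40, seed=9), 1.0)
        read, key = draw_read(member, prof, np.random.default_rng(0))
        assert key.end - key.start == 40
        assert len(read.bases) == 40

    def test_deterministic_under_seed(self, four_genomes, phred_exact_profile):
        member = build_community(four_genomes, 1, "uniform", seed=1)[0]
        a = draw_read(member, phred_exact_profile, np.random.default_rng(5))
        b = draw_read(member, phred_exact_profile, np.random.default_rng(5))
        assert a == b

    def test_qualities_clamped_and_aligned(self, four_genomes):
        prof = SequencingProfile(
            name="extremes", reads_per_run=1, length_mean=50.0, length_sd=0.0,
            max_length=50, per_position_error=[1e-9] * 25 + [0.9] * 25,
        )
        member = build_community(four_genomes, 1, "uniform", seed=1)[0]
        read, _ = draw_read(member, prof, np.random.default_rng(1))
        assert len(read.qualities) == len(read.bases)
        assert all(2 <= q <= 41 for q in read.qualities)


class TestSimulateRun:
    @pytest.fixture
    def run_outputs(self, tmp_path, four_genomes, phred_exact_profile):
        comm = build_community(four_genomes, 4, "uniform", seed=3)
        fq, key = simulate_run(
            comm, phred_exact_profile, 1000, seed=42,
            fastq_path=tmp_path / "sim.fastq", key_path=tmp_path / "sim.key.csv",
        )
        return comm, fq, key

    def test_read_ids_bijective_between_outputs(self, run_outputs):
        _, fq, key = run_outputs
        fastq_ids = [rec.id for rec in SeqIO.parse(str(fq), "fastq")]
        key_ids = [k.read_id for k in load_key(key)]
        assert len(fastq_ids) == 1000
        assert sorted(fastq_ids) == sorted(key_ids)
        assert len(set(fastq_ids)) == 1000

    def test_species_counts_in_multinomial_band(self, run_outputs):
        _, _, key = run_outputs
        counts = collections.Counter(k.genome_id for k in load_key(key))
        band = 4 * math.sqrt(1000 * 0.25 * 0.75)
        for genome_id, n in counts.items():
            assert 250 - band <= n <= 250 + band, genome_id

    def test_ground_truth_revert_property(self, run_outputs):
        # uppercasing the read and substituting the genome base at each
        # lowercase position must reproduce the source substring exactly
        comm, fq, key = run_outputs
        genomes = {m.genome_id: m.sequence for m in comm}
        keys = {k.read_id: k for k in load_key(key)}
        for rec in SeqIO.parse(str(fq), "fastq"):
            k = keys[rec.id]
            template = oriented_substring(genomes[k.genome_id], k)
            read = str(rec.seq)
            lower = {i for i, c in enumerate(read) if c.islower()}
            assert len(lower) == k.n_errors
            assert k.n_errors <= k.end - k.start
            rebuilt = "".join(
                template[i] if i in lower else read[i] for i in range(len(read))
            )
            assert rebuilt == template

    def test_fastq_parses_as_strict_sanger(self, run_outputs):
        _, fq, _ = run_outputs
        n = 0
        for rec in SeqIO.parse(str(fq), "fastq-sanger"):
            quals = rec.letter_annotations["phred_quality"]
            assert all(2 <= q <= 41 for q in quals)
            n += 1
        assert n == 1000

    def test_key_coordinates_within_genome(self, run_outputs):
        comm, _, key = run_outputs
        lengths = {m.genome_id: len(m.sequence) for m in comm}
        for k in load_key(key):
            assert 0 <= k.start < k.end <= lengths[k.genome_id]
            assert k.strand in "+-"

    def test_byte_identical_under_same_seed(self, tmp_path, four_genomes, phred_exact_profile):
        comm = build_community(four_genomes, 2, "uniform", seed=3)
        paths = []
        for tag in ("a", "b"):
            fq, key = simulate_run(
                comm, phred_exact_profile, 50, seed=7,
                fastq_path=tmp_path / f"{tag}.fastq",
                key_path=tmp_path / f"{tag}.key.csv",
            )
            paths.append((fq.read_bytes(), key.read_bytes()))
        assert paths[0] == paths[1]

    def test_realized_error_rate_tracks_profile(self, tmp_path, four_genomes):
        # constant error probability: pooled error count over all simulated
        # bases must sit in its binomial 4-sigma band
        p_err = 0.01
        prof = SequencingProfile(
            name="flat", reads_per_run=1, length_mean=100.0, length_sd=0.0,
            max_length=100, per_position_error=[p_err] * 100,
        )
        comm = build_community(four_genomes, 1, "uniform", seed=1)
        _, key = simulate_run(
            comm, prof, 2000, seed=8,
            fastq_path=tmp_path / "e.fastq", key_path=tmp_path / "e.key.csv",
        )
        records = load_key(key)
        total_bases = sum(k.end - k.start for k in records)
        total_errors = sum(k.n_errors for k in records)
        assert total_bases == 200_000
        mean = total_bases * p_err
        band = 4 * math.sqrt(total_bases * p_err * (1 - p_err))
        assert mean - band <= total_errors <= mean + band


class TestClosedLoop:
    def test_profile_recovered_from_simulated_reads(
        self, tmp_path, four_genomes, phred_exact_profile
    ):
        """Simulate under P, infer from the FASTQ, recover P.

        The fixture profile's error probabilities sit exactly on integer
        phred scores, so quality quantisation is lossless and any
        discrepancy reflects a real defect, not rounding.
        """
        comm = build_community(four_genomes, 4, "uniform", seed=3)
        n_reads = 4000
        fq, _ = simulate_run(
            comm, phred_exact_profile, n_reads, seed=21,
            fastq_path=tmp_path / "cl.fastq", key_path=tmp_path / "cl.key.csv",
        )
        inferred = infer_profile(str(fq), "closed-loop")
        assert inferred.reads_per_run == n_reads
        tol = 3 * phred_exact_profile.length_sd / math.sqrt(n_reads)
        assert inferred.length_mean == pytest.approx(
            phred_exact_profile.length_mean, abs=tol + 0.5  # 0.5 for rounding
        )
        for j in range(inferred.max_length):
            assert inferred.per_position_error[j] == pytest.approx(
                phred_exact_profile.per_position_error[j], rel=1e-9
            )
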