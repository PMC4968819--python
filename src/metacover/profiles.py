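"""Statistical sequencing profiles: inference from FASTQ, serialisation, presets.

A profile is a deliberately simple summary of a sequencing run — read count,
read-length mean and standard deviation, and the mean phred-implied error
probability at each read position — sufficient to drive both the run planner
(which needs reads-per-run and mean length) and the read simulator (which
additionally needs the per-position error curve).

Inference expects Sanger-encoded FASTQ (phred+33).  The per-position error at
position ``j`` averages ``10^(-Q_j/10)`` over the reads long enough to reach
``j``; averaging probabilities rather than phred scores keeps the profile
faithful to the expected error *rate*, which is what the simulator reproduces.

Seven editable platform presets ship with the package.  Their numbers are
representative of published platform characteristics (read-length regimes and
typical raw error rates), not measurements from any specific run; regenerate
a preset from your own data with :func:`infer_profile` for anything
quantitative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Dict, List, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequencingProfile",
    "ProfileFormatError",
    "EncodingError",
    "infer_profile",
    "save_profile",
    "load_profile",
    "preset_profiles",
    "PRESET_NAMES",
]

PRESET_NAMES = (
    "IonTorrent",
    "IonProton",
    "Illumina MiSeq",
    "Illumina HiSeq",
    "Illumina NextSeq",
    "PacBio",
    "Oxford Nanopore",
)


class ProfileFormatError(ValueError):
    """A profile file is missing or corrupts a required field."""


class EncodingError(ValueError):
    """FASTQ quality characters fall outside the Sanger phred+33 range."""


@dataclass(frozen=True)
class SequencingProfile:
    """Summary statistics of one sequencing run."""

    name: str
    reads_per_run: int
    length_mean: float
    length_sd: float
    max_length: int
    per_position_error: List[float] = field(repr=False)

    def __post_init__(self):
        if self.reads_per_run < 1:
            raise ValueError(f"reads_per_run must be positive, got {self.reads_per_run}")
        if self.length_mean <= 0:
            raise ValueError(f"length_mean must be positive, got {self.length_mean}")
        if self.length_sd < 0:
            raise ValueError(f"length_sd must be non-negative, got {self.length_sd}")
        if self.max_length < 1:
            raise ValueError(f"max_length must be positive, got {self.max_length}")
        if self.length_mean > self.max_length:
            raise ValueError(
                f"length_mean {self.length_mean} exceeds max_length {self.max_length}"
            )
        if len(self.per_position_error) != self.max_length:
            raise ValueError(
                f"per_position_error has length {len(self.per_position_error)}, "
                f"expected max_length = {self.max_length}"
            )
        for j, p in enumerate(self.per_position_error):
            if not (0 < p <= 1):
                raise ValueError(
                    f"per_position_error[{j}] = {p} outside (0, 1]"
                )


def infer_profile(reads, name: str = "inferred") -> SequencingProfile:
    """Build a profile from Sanger FASTQ records.

    ``reads`` may be a file path, an open text handle, or an iterable of
    Biopython ``SeqRecord`` objects carrying ``phred_quality`` annotations.
    Positions are averaged only over the reads that reach them, so mixed-length
    inputs extend the error vector to the longest read seen.
    """
    records = _as_records(reads)

    lengths: List[int] = []
    err_sum = np.zeros(0)
    err_n = np.zeros(0, dtype=np.int64)
    try:
        for rec in records:
            quals = rec.letter_annotations.get("phred_quality")
            if quals is None:
                raise EncodingError(f"read {rec.id!r} carries no quality scores")
            n = len(quals)
            lengths.append(n)
            if n > err_sum.size:
                err_sum = np.pad(err_sum, (0, n - err_sum.size))
                err_n = np.pad(err_n, (0, n - err_n.size))
            p = 10.0 ** (-np.asarray(quals, dtype=float) / 10.0)
            err_sum[:n] += p
            err_n[:n] += 1
    except ValueError as exc:
        if isinstance(exc, (EncodingError, ProfileFormatError)):
            raise
        # Biopython signals malformed/out-of-range Sanger qualities this way
        raise EncodingError(f"invalid Sanger (phred+33) FASTQ: {exc}") from exc

    if not lengths:
        raise ValueError("cannot infer a profile from an empty FASTQ input")

    arr = np.asarray(lengths, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SequencingProfile(
        name=name,
        reads_per_run=len(lengths),
        length_mean=float(arr.mean()),
        length_sd=sd,
        max_length=int(err_sum.size),
        per_position_error=list(err_sum / err_n),
    )


def _as_records(reads):
    if isinstance(reads, (str, Path)):
        return SeqIO.parse(str(reads), "fastq")
    if hasattr(reads, "read"):
        return SeqIO.parse(reads, "fastq")
    return iter(reads)


def save_profile(profile: SequencingProfile, destination: Union[str, Path, IO[str]]) -> None:
    """Write a profile as JSON (floats at full precision, human-editable)."""
    payload = {
        "name": profile.name,
        "reads_per_run": profile.reads_per_run,
        "length_mean": profile.length_mean,
        "length_sd": profile.length_sd,
        "max_length": profile.max_length,
        "per_position_error": list(profile.per_position_error),
    }
    if hasattr(destination, "write"):
        json.dump(payload, destination)
    else:
        with open(destination, "w") as fh:
            json.dump(payload, fh)


_REQUIRED_FIELDS = {
    "name": str,
    "reads_per_run": int,
    "length_mean": (int, float),
    "length_sd": (int, float),
    "max_length": int,
    "per_position_error": list,
}


def load_profile(source: Union[str, Path, IO[str]]) -> SequencingProfile:
    """Read a JSON profile, validating every field by name."""
    if hasattr(source, "read"):
        raw = source.read()
    else:
        raw = Path(source).read_text()
    try:
        data = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise ProfileFormatError(f"profile file is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ProfileFormatError("profile file must hold a JSON object")
    for fname, ftype in _REQUIRED_FIELDS.items():
        if fname not in data:
            raise ProfileFormatError(f"profile file missing field {fname!r}")
        if not isinstance(data[fname], ftype) or isinstance(data[fname], bool):
            raise ProfileFormatError(
                f"profile field {fname!r} has wrong type {type(data[fname]).__name__}"
            )
    try:
        return SequencingProfile(
            name=data["name"],
            reads_per_run=data["reads_per_run"],
            length_mean=float(data["length_mean"]),
            length_sd=float(data["length_sd"]),
            max_length=data["max_length"],
            per_position_error=[float(p) for p in data["per_position_error"]],
        )
    except (TypeError, ValueError) as exc:
        raise ProfileFormatError(f"invalid profile contents: {exc}") from exc


def _error_ramp(n: int, start: float, end: float) -> List[float]:
    """Geometric interpolation from start to end error rate across n positions."""
    if n == 1:
        return [start]
    ratio = (end / start) ** (1.0 / (n - 1))
    return list(start * ratio ** np.arange(n))


# (reads_per_run, length_mean, length_sd, max_length, error at start, at end).
# Read-length regimes and raw error magnitudes follow well-known platform
# characteristics; they are editable stand-ins, not run measurements.
_PRESET_PARAMS = {
    "IonTorrent": (5_000_000, 200.0, 50.0, 400, 0.005, 0.02),
    "IonProton": (60_000_000, 175.0, 50.0, 300, 0.005, 0.02),
    "Illumina MiSeq": (25_000_000, 250.0, 10.0, 300, 0.001, 0.01),
    "Illumina HiSeq": (300_000_000, 125.0, 5.0, 150, 0.001, 0.005),
    "Illumina NextSeq": (400_000_000, 145.0, 5.0, 150, 0.001, 0.008),
    "PacBio": (500_000, 10_000.0, 5_000.0, 60_000, 0.1, 0.1),
    "Oxford Nanopore": (1_000_000, 8_000.0, 7_000.0, 100_000, 0.1, 0.1),
}


def preset_profiles() -> Dict[str, SequencingProfile]:
    """The seven built-in platform presets, keyed by name.

    Use :func:`save_profile` to materialise one as an editable JSON file.
    """
    out = {}
    for pname in PRESET_NAMES:
        reads, mean, sd, max_len, e0, e1 = _PRESET_PARAMS[pname]
        out[pname] = SequencingProfile(
            name=pname,
            reads_per_run=reads,
            length_mean=mean,
            length_sd=sd,
            max_length=max_len,
            per_position_error=_error_ramp(max_len, e0, e1),
        )
    return out
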