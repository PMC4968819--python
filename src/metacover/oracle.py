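"""Monte-Carlo validation of the coverage model.

Simulates the generative model directly — each of R community reads lands on
the target with probability alpha, on-target reads cover arcs of length l
starting uniformly on a circle of circumference L — and tallies the empirical
distribution of the gap count B.  Because the analytic series and this
simulator share nothing but the model, agreement between them validates both.

Positions are continuous reals, matching the continuous-circle theorem; a
gap of exactly zero length (arcs touching end-to-start) counts as covered,
which is a measure-zero event under the continuous model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .coverage import CoverageQuery

__all__ = ["GapCountSample", "simulate_gap_counts", "count_gaps"]


@dataclass(frozen=True)
class GapCountSample:
    """Empirical gap-count tallies for one design point."""

    query: CoverageQuery
    trials: int
    counts: Dict[int, int]
    seed: int

    def frequency(self, k: int) -> float:
        return self.counts.get(k, 0) / self.trials


def count_gaps(starts: np.ndarray, arc_length: float, circumference: float) -> int:
    """Number of maximal uncovered intervals left by equal-length arcs on a
    circle.

    With equal arc lengths an arc never extends past a later-starting arc's
    end, so after sorting the starts a gap exists between consecutive arcs
    (including the wrap from last to first) iff their spacing strictly
    exceeds the arc length.
    """
    starts = np.asarray(starts, dtype=float)
    if starts.size == 0:
        return 0
    if arc_length >= circumference:
        return 0
    s = np.sort(starts)
    gaps = int(np.count_nonzero(np.diff(s) > arc_length))
    if s[0] + circumference - s[-1] > arc_length:
        gaps += 1
    return gaps


def simulate_gap_counts(
    query: CoverageQuery, trials: int, seed: int
) -> GapCountSample:
    """Tally B over ``trials`` independent draws of the coverage model.

    Trials with zero on-target reads count as B = 0: an empty assembly has
    no gaps, mirroring the convention of the analytic series.
    """
    if trials < 1:
        raise ValueError(f"trials must be positive, got {trials}")
    rng = np.random.default_rng(seed)
    R = query.reads
    l, L, alpha = query.read_length, query.genome_length, query.abundance

    counts: Dict[int, int] = {}
    if R == 0:
        return GapCountSample(query, trials, {0: trials}, seed)

    on_target = rng.random((trials, R)) < alpha
    starts = rng.uniform(0.0, L, size=(trials, R))
    m = on_target.sum(axis=1)

    n_empty = int(np.count_nonzero(m == 0))
    if n_empty:
        counts[0] = n_empty

    for mm in np.unique(m[m > 0]):
        rows = m == mm
        s = starts[rows][on_target[rows]].reshape(-1, mm)
        if l >= L:
            counts[0] = counts.get(0, 0) + s.shape[0]
            continue
        s.sort(axis=1)
        b = (np.diff(s, axis=1) > l).sum(axis=1)
        b += (s[:, 0] + L - s[:, -1]) > l
        ks, tallies = np.unique(b, return_counts=True)
        for k, t in zip(ks, tallies):
            counts[int(k)] = counts.get(int(k), 0) + int(t)

    return GapCountSample(query, trials, counts, seed)
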