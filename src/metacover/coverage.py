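"""Exact coverage probabilities for abundance-thinned shotgun sequencing.

The model: a circular target genome of length ``L`` receives ``R`` community
reads of mean length ``l``.  Each read independently originates from the
target with probability ``alpha`` (the species' abundance in the community);
an on-target read covers an arc of length ``l`` whose start is uniform on the
circle.  ``B`` is the number of maximal uncovered intervals ("gaps") in the
resulting ideal assembly.  This module evaluates the generalisation of
Stevens' circle-covering theorem to this thinned setting:

    P(B = k) = C(R,k) * sum_{beta=k}^{eta} C(R-k, beta-k) (-1)^(beta-k)
               alpha^beta (1 - beta*phi)^(beta-1) (1 - beta*phi*alpha)^(R-beta)

with ``phi = l/L`` the per-read coverage probability of a fixed position and
``eta`` the series limiter (the largest usable inclusion-exclusion index).
``P(B = 0)``, the full-coverage probability, is the ``k = 0`` case.

The alternating series suffers catastrophic cancellation for large ``R``
(binomial coefficients dwarf the final probability), so every evaluation runs
at escalating binary precision via :func:`evaluate_stable` and is only
accepted once two successive precision doublings agree.

Note that ``B = 0`` includes the event that *no* read lands on the target: an
empty assembly has no gaps.  The full-coverage probability therefore does not
vanish as ``alpha -> 0``; it tends to 1.  This is a property of the exact
model, verified by enumeration, and the raw series value is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Dict, Tuple

import mpmath

__all__ = [
    "CoverageQuery",
    "GapDistribution",
    "NonConvergenceError",
    "series_limiter",
    "gap_probability",
    "full_coverage_probability",
    "gap_distribution",
    "evaluate_stable",
    "DEFAULT_REL_TOL",
    "DEFAULT_START_BITS",
    "DEFAULT_MAX_BITS",
]

DEFAULT_REL_TOL = 1e-12
DEFAULT_START_BITS = 128
DEFAULT_MAX_BITS = 1_048_576

# Below this magnitude two estimates are considered equal regardless of
# relative error; avoids demanding 12 digits of agreement on pure noise.
_ABS_FLOOR = 1e-300

# Probabilities may overshoot [0, 1] by at most this much before clamping;
# anything larger is treated as a failed evaluation, never silently clamped.
_CLAMP_TOL = 1e-12


class NonConvergenceError(ArithmeticError):
    """Raised when precision escalation hits its ceiling without two
    successive evaluations agreeing.  Carries both estimates so the caller
    can inspect the disagreement."""

    def __init__(self, message: str, last: float, previous: float):
        super().__init__(f"{message} (estimates {previous!r} -> {last!r})")
        self.last = last
        self.previous = previous


def series_limiter(R: int, phi) -> int:
    """Largest usable summation index: ``min(R, max{beta >= 0 : 1 - beta*phi > 0})``.

    The strict inequality matters: at integer ``1/phi`` the boundary term has
    ``1 - beta*phi = 0`` and a ``0^(beta-1)`` factor that poisons the series
    (e.g. ``phi = 1`` would yield P(B=0) = 0 for a read spanning the whole
    genome).  The comparison is exact: ``phi`` is converted to a rational, so
    no floating-point rounding can flip the boundary.
    """
    if R < 0:
        raise ValueError(f"R must be non-negative, got {R}")
    phi_exact = Fraction(phi)
    if phi_exact <= 0:
        raise ValueError(f"phi must be positive, got {phi}")
    inv = 1 / phi_exact
    # largest integer strictly below inv (for inv = p/q this is (p-1)//q)
    b_max = (inv.numerator - 1) // inv.denominator
    return min(R, max(b_max, 0))


@dataclass(frozen=True)
class CoverageQuery:
    """A sequencing-design point: R reads of length l against a genome of
    length L at abundance alpha.  phi and eta are derived on construction."""

    reads: int
    read_length: float
    genome_length: float
    abundance: float

    phi: float = field(init=False)
    eta: int = field(init=False)

    def __post_init__(self):
        if not isinstance(self.reads, int) or self.reads < 0:
            raise ValueError(f"reads must be a non-negative integer, got {self.reads!r}")
        if self.read_length <= 0:
            raise ValueError(f"read_length must be positive, got {self.read_length}")
        if self.genome_length <= 0:
            raise ValueError(f"genome_length must be positive, got {self.genome_length}")
        if not (0 < self.abundance <= 1):
            raise ValueError(f"abundance must lie in (0, 1], got {self.abundance}")
        object.__setattr__(self, "phi", self.read_length / self.genome_length)
        # exact rational l/L, immune to the float division above at the
        # integer-1/phi boundary
        phi_exact = Fraction(self.read_length) / Fraction(self.genome_length)
        object.__setattr__(self, "eta", series_limiter(self.reads, phi_exact))


@dataclass(frozen=True)
class GapDistribution:
    """P(B = k) for k = 0..k_max, plus the working precision at which the
    series stabilised."""

    query: CoverageQuery
    probabilities: Dict[int, float]
    precision_bits: int

    def __getitem__(self, k: int) -> float:
        return self.probabilities[k]

    def total(self) -> float:
        return float(sum(self.probabilities.values()))


def evaluate_stable(
    term_series: Callable[[int], "mpmath.mpf"],
    start_bits: int = DEFAULT_START_BITS,
    max_bits: int = DEFAULT_MAX_BITS,
    rel_tol: float = DEFAULT_REL_TOL,
) -> Tuple[float, int]:
    """Evaluate ``term_series(prec_bits)`` at doubling precision until stable.

    ``term_series`` must return the series value computed entirely at the
    given binary precision.  Two successive evaluations agreeing to
    ``rel_tol`` relative (or both below 1e-300 absolute) are accepted; the
    later value is returned together with the precision at which the result
    had already stabilised.  Exhausting ``max_bits`` raises
    :class:`NonConvergenceError` with both estimates.
    """
    if start_bits < 64:
        raise ValueError("start_bits must be at least 64")
    if max_bits < start_bits:
        raise ValueError("max_bits must be at least start_bits")

    prec = start_bits
    with mpmath.workprec(prec):
        prev = cur = term_series(prec)
    while prec < max_bits:
        stable_at = prec
        prec = min(prec * 2, max_bits)
        prev = cur
        with mpmath.workprec(prec):
            cur = term_series(prec)
            scale = max(abs(prev), abs(cur))
            if scale < _ABS_FLOOR or abs(cur - prev) <= rel_tol * scale:
                # report the precision at which the value was already stable
                return float(cur), stable_at
    raise NonConvergenceError(
        f"series failed to stabilise at {max_bits} bits", float(cur), float(prev)
    )


def _gap_series(query: CoverageQuery, k: int) -> Callable[[int], "mpmath.mpf"]:
    """Build the precision-parametrised evaluator for the k-gap series."""
    R, eta = query.reads, query.eta
    l, L, alpha = query.read_length, query.genome_length, query.abundance

    def evaluate(prec_bits: int) -> "mpmath.mpf":
        mpf = mpmath.mpf
        phi = mpf(l) / mpf(L)
        a = mpf(alpha)
        terms = []
        # C(R-k, beta-k) built incrementally with exact integers
        comb = 1
        for beta in range(k, eta + 1):
            one_minus_bphi = 1 - beta * phi
            one_minus_bphia = 1 - beta * phi * a
            # beta = 0 only occurs for k = 0: term is 1 * 1^(-1) * 1^R = 1
            term = (
                mpf(comb)
                * a**beta
                * one_minus_bphi ** (beta - 1)
                * one_minus_bphia ** (R - beta)
            )
            if (beta - k) % 2:
                term = -term
            terms.append(term)
            comb = comb * (R - beta) // (beta - k + 1)
        return mpf(math.comb(R, k)) * mpmath.fsum(terms)

    return evaluate


def _finalize_probability(value: float, what: str) -> float:
    if value < -_CLAMP_TOL or value > 1 + _CLAMP_TOL:
        raise NonConvergenceError(
            f"{what} evaluated outside [0,1] beyond tolerance: {value}",
            value,
            value,
        )
    return min(max(value, 0.0), 1.0)


def gap_probability(
    query: CoverageQuery,
    k: int,
    rel_tol: float = DEFAULT_REL_TOL,
    start_bits: int = DEFAULT_START_BITS,
    max_bits: int = DEFAULT_MAX_BITS,
) -> float:
    """P(B = k): probability the ideal assembly has exactly k gaps.

    Returns 0 for k beyond the series limiter (an empty sum: more than eta
    disjoint uncovered intervals cannot fit on the circle).
    """
    if k < 0 or k > query.reads:
        raise ValueError(f"k must lie in [0, R={query.reads}], got {k}")
    if k > query.eta:
        return 0.0
    value, _ = evaluate_stable(_gap_series(query, k), start_bits, max_bits, rel_tol)
    return _finalize_probability(value, f"P(B={k})")


def full_coverage_probability(
    query: CoverageQuery,
    rel_tol: float = DEFAULT_REL_TOL,
    start_bits: int = DEFAULT_START_BITS,
    max_bits: int = DEFAULT_MAX_BITS,
) -> float:
    """P(B = 0): probability the target is fully covered (no gaps).

    Includes the zero-on-target-reads event, whose empty assembly counts as
    gapless; see the module docstring.
    """
    return gap_probability(query, 0, rel_tol, start_bits, max_bits)


def gap_distribution(
    query: CoverageQuery,
    k_max: int,
    rel_tol: float = DEFAULT_REL_TOL,
    start_bits: int = DEFAULT_START_BITS,
    max_bits: int = DEFAULT_MAX_BITS,
) -> GapDistribution:
    """P(B = k) for k = 0..k_max.  With k_max = R the probabilities sum to 1."""
    if k_max < 0 or k_max > query.reads:
        raise ValueError(f"k_max must lie in [0, R={query.reads}], got {k_max}")
    probs: Dict[int, float] = {}
    bits_used = DEFAULT_START_BITS
    for k in range(k_max + 1):
        if k > query.eta:
            probs[k] = 0.0
            continue
        value, bits = evaluate_stable(
            _gap_series(query, k), start_bits, max_bits, rel_tol
        )
        probs[k] = _finalize_probability(value, f"P(B={k})")
        bits_used = max(bits_used, bits)
    return GapDistribution(query=query, probabilities=probs, precision_bits=bits_used)
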