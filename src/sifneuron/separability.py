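"""Partial Boolean functions and linear-separability certification.

A function f on {0,1}^n is *linearly separable* when some weight vector w
and threshold Theta satisfy f(X) = 1 iff w.X >= Theta.  This module
represents possibly partial truth tables, builds the compact
feature-binding problem (cFBP) family — the canonical four-row table whose
clustered input pairs map to 0 and scattered pairs to 1 — and certifies
separability either by linear-programming feasibility or by exhaustive
integer search.  A dedicated check reproduces the pairing argument that
proves the cFBP inseparable: two disjoint 0-rows and two disjoint 1-rows
covering the same inputs force w1+..+wn both <= 2*Theta and > 2*Theta.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import CapabilityError, DomainError

__all__ = [
    "PartialBooleanTable",
    "SeparabilityCertificate",
    "PairingCertificate",
    "make_cfbp",
    "make_xor",
    "make_and",
    "make_or",
    "is_linearly_separable",
    "check_pairing_contradiction",
    "find_pairing_certificate",
]

EXHAUSTIVE_MAX_INPUTS = 4
EXHAUSTIVE_WEIGHT_BOUND = 8
EXHAUSTIVE_THETA_BOUND = 32


@dataclass(frozen=True)
class PartialBooleanTable:
    """A Boolean function specified on a subset of input patterns.

    ``rows`` holds (pattern, output) pairs; each pattern is a tuple of n
    bits read left to right as inputs 1..n.  Patterns absent from the
    table are unconstrained.  Duplicate patterns must agree on the output.
    """

    n_inputs: int
    rows: tuple[tuple[tuple[int, ...], int], ...]

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise DomainError(f"n_inputs must be positive, got {self.n_inputs}")
        seen: dict[tuple[int, ...], int] = {}
        norm = []
        for pattern, output in self.rows:
            pattern = tuple(int(b) for b in pattern)
            output = int(output)
            if len(pattern) != self.n_inputs:
                raise DomainError(
                    f"pattern {pattern} has {len(pattern)} bits, expected {self.n_inputs}"
                )
            if any(b not in (0, 1) for b in pattern) or output not in (0, 1):
                raise DomainError(f"non-binary entry in row {pattern} -> {output}")
            if seen.get(pattern, output) != output:
                raise DomainError(f"conflicting outputs for pattern {pattern}")
            seen[pattern] = output
            norm.append((pattern, output))
        object.__setattr__(self, "rows", tuple(norm))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def patterns(self, output: int | None = None) -> list[tuple[int, ...]]:
        """Patterns in table order, optionally restricted to one output class."""
        return [p for p, o in self.rows if output is None or o == output]

    def pattern_strings(self) -> list[str]:
        return ["".join(map(str, p)) for p in self.patterns()]

    @staticmethod
    def from_strings(rows: Sequence[tuple[str, int]]) -> "PartialBooleanTable":
        """Build a table from ('0101', 1)-style rows."""
        if not rows:
            raise DomainError("table needs at least one row")
        n = len(rows[0][0])
        parsed = tuple(
            (tuple(int(c) for c in pattern), int(out)) for pattern, out in rows
        )
        return PartialBooleanTable(n_inputs=n, rows=parsed)


@dataclass(frozen=True)
class PairingCertificate:
    """The inseparability witness of the pairing argument.

    Two disjoint 0-rows and two disjoint 1-rows whose active-input unions
    coincide: summing the 0-row constraints gives sum(w over the union)
    <= 2*Theta while the 1-rows give > 2*Theta — a contradiction for any
    weights, so no separating threshold exists.
    """

    zero_rows: tuple[tuple[int, ...], tuple[int, ...]]
    one_rows: tuple[tuple[int, ...], tuple[int, ...]]


@dataclass(frozen=True)
class SeparabilityCertificate:
    """Verdict of a separability check, with a witness when separable.

    When ``separable`` the witness (w, Theta) reproduces every table row
    exactly under the rule f(X) = 1 iff w.X >= Theta; the constructor
    verifies this.  ``method`` records which search produced the verdict.
    """

    separable: bool
    method: str
    weights: tuple[float, ...] | None = None
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.separable and (self.weights is None or self.theta is None):
            raise DomainError("separable certificate requires a witness")

    def predict(self, pattern: Sequence[int]) -> int:
        if not self.separable:
            raise DomainError("no witness on a non-separable certificate")
        dot = sum(w * x for w, x in zip(self.weights, pattern))
        return 1 if dot >= self.theta else 0

    def verify(self, table: PartialBooleanTable) -> bool:
        """Replay the witness through every row of ``table``."""
        if not self.separable:
            return False
        return all(self.predict(p) == o for p, o in table.rows)


def make_cfbp(m: int = 2) -> PartialBooleanTable:
    """The compact feature-binding problem over 2m inputs.

    Inputs split into clusters A = {1..m} and B = {m+1..2m}.  The two
    0-rows activate exactly one full cluster each (clustered drive); the
    two 1-rows are a complementary pair of m-tuples each straddling both
    clusters (scattered drive).  For m = 2 this is the canonical table
    0011->0, 1100->0, 0101->1, 1010->1.  Every member of the family is
    linearly inseparable by the pairing argument.
    """
    if m < 2:
        raise DomainError(f"cFBP requires m >= 2, got {m}")
    n = 2 * m

    def indicator(active: set[int]) -> tuple[int, ...]:
        return tuple(1 if i + 1 in active else 0 for i in range(n))

    cluster_a = set(range(1, m + 1))
    cluster_b = set(range(m + 1, n + 1))
    s1 = set(range(1, m - m // 2 + 1)) | set(range(m + 1, m + m // 2 + 1))
    s2 = (cluster_a | cluster_b) - s1
    rows = (
        (indicator(cluster_b), 0),
        (indicator(cluster_a), 0),
        (indicator(s2), 1),
        (indicator(s1), 1),
    )
    return PartialBooleanTable(n_inputs=n, rows=rows)


def make_xor() -> PartialBooleanTable:
    """The full 2-input exclusive-or table (the classic inseparable function)."""
    return PartialBooleanTable.from_strings([("00", 0), ("01", 1), ("10", 1), ("11", 0)])


def make_and() -> PartialBooleanTable:
    return PartialBooleanTable.from_strings([("00", 0), ("01", 0), ("10", 0), ("11", 1)])


def make_or() -> PartialBooleanTable:
    return PartialBooleanTable.from_strings([("00", 0), ("01", 1), ("10", 1), ("11", 1)])


def _separable_lp(table: PartialBooleanTable) -> SeparabilityCertificate:
    # Feasibility of {w.X >= Theta on 1-rows, w.X <= Theta - 1 on 0-rows}.
    # The unit margin is harmless: any strict separator can be rescaled to
    # satisfy it, so feasibility is equivalent to separability.
    n = table.n_inputs
    a_ub = []
    b_ub = []
    for pattern, output in table.rows:
        x = np.asarray(pattern, dtype=float)
        if output == 1:
            a_ub.append(np.concatenate([-x, [1.0]]))  # -w.X + Theta <= 0
            b_ub.append(0.0)
        else:
            a_ub.append(np.concatenate([x, [-1.0]]))  # w.X - Theta <= -1
            b_ub.append(-1.0)
    res = linprog(
        c=np.zeros(n + 1),
        A_ub=np.asarray(a_ub),
        b_ub=np.asarray(b_ub),
        bounds=[(None, None)] * (n + 1),
        method="highs",
    )
    if res.status == 2:  # infeasible
        return SeparabilityCertificate(separable=False, method="lp")
    if not res.success:
        raise RuntimeError(f"linprog failed unexpectedly: {res.message}")
    weights = tuple(float(w) for w in res.x[:n])
    theta = float(res.x[n])
    cert = SeparabilityCertificate(
        separable=True, method="lp", weights=weights, theta=theta
    )
    if not cert.verify(table):
        raise RuntimeError("LP witness failed row replay; numerical degeneracy")
    return cert


def _separable_exhaustive(table: PartialBooleanTable) -> SeparabilityCertificate:
    # Integer search over w in {-8..8}^n.  For a candidate w a threshold
    # exists iff max(w.X over 0-rows) < min(w.X over 1-rows); the smallest
    # 1-row dot product is then itself a valid integer Theta (|Theta| <= 32
    # automatically for n <= 4).
    n = table.n_inputs
    if n > EXHAUSTIVE_MAX_INPUTS:
        raise CapabilityError(
            f"exhaustive search supports n <= {EXHAUSTIVE_MAX_INPUTS}, got {n}"
        )
    ones = np.asarray(table.patterns(1), dtype=int)
    zeros = np.asarray(table.patterns(0), dtype=int)
    weight_range = range(-EXHAUSTIVE_WEIGHT_BOUND, EXHAUSTIVE_WEIGHT_BOUND + 1)
    w_all = np.asarray(list(itertools.product(weight_range, repeat=n)), dtype=int)
    dots_one = w_all @ ones.T if ones.size else None
    dots_zero = w_all @ zeros.T if zeros.size else None
    min_one = (
        dots_one.min(axis=1)
        if dots_one is not None
        else np.full(len(w_all), EXHAUSTIVE_THETA_BOUND)
    )
    max_zero = (
        dots_zero.max(axis=1)
        if dots_zero is not None
        else np.full(len(w_all), -EXHAUSTIVE_THETA_BOUND - 1)
    )
    feasible = np.flatnonzero(min_one > max_zero)
    if feasible.size == 0:
        return SeparabilityCertificate(separable=False, method="exhaustive")
    idx = int(feasible[0])
    cert = SeparabilityCertificate(
        separable=True,
        method="exhaustive",
        weights=tuple(float(w) for w in w_all[idx]),
        theta=float(min_one[idx]),
    )
    assert cert.verify(table)
    return cert


def is_linearly_separable(
    table: PartialBooleanTable, method: str = "lp"
) -> SeparabilityCertificate:
    """Decide linear separability of a (partial) truth table.

    ``method="lp"`` solves the feasibility LP over real weights (any n);
    ``method="exhaustive"`` brute-forces small integer weights (n <= 4)
    and serves as an independent oracle.  Both return a replay-verified
    witness when separable.  Tables with a single output class are
    trivially separable.
    """
    if method == "lp":
        return _separable_lp(table)
    if method == "exhaustive":
        return _separable_exhaustive(table)
    raise DomainError(f"unknown method {method!r}")


def find_pairing_certificate(
    table: PartialBooleanTable,
) -> PairingCertificate | None:
    """Search for the pairing-argument inseparability certificate.

    Looks for two 0-rows with disjoint active inputs and two 1-rows with
    disjoint active inputs such that the two unions of active inputs are
    the same multiset (equal bit-wise sums).  Every row must actually
    activate something: the empty pattern is not a tuple of active inputs,
    so e.g. XOR (0-rows 00 and 11) is left to the generic checkers.
    Returns the first qualifying quadruple in row order, or None.
    """
    zeros = [p for p in table.patterns(0) if any(p)]
    ones = [p for p in table.patterns(1) if any(p)]

    def disjoint_pairs(rows):
        for p, q in itertools.combinations(rows, 2):
            if all(a + b <= 1 for a, b in zip(p, q)):
                yield p, q

    for z1, z2 in disjoint_pairs(zeros):
        union0 = tuple(a + b for a, b in zip(z1, z2))
        for o1, o2 in disjoint_pairs(ones):
            union1 = tuple(a + b for a, b in zip(o1, o2))
            if union0 == union1:
                return PairingCertificate(zero_rows=(z1, z2), one_rows=(o1, o2))
    return None


def check_pairing_contradiction(table: PartialBooleanTable) -> bool:
    """True iff the pairing-argument certificate exists (sufficient for
    inseparability: the certificate's summed constraints demand both
    sum(w) <= 2*Theta and sum(w) > 2*Theta over the shared union)."""
    return find_pairing_certificate(table) is not None
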