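"""Normalized assembly probabilities, the Int-Ext index, combinatorial nulls
and exact binomial asymmetry tests.

Because each area contributes a different number of recorded units, raw
assembly counts are normalized by the number of *possible* configurations of
that type on the recorded unit sets:

* external pairs between areas A and B:        ``N / (|A| |B|)``
* internal pairs within A:                     ``N / C(|A|, 2)``
* loop-like triplets (either structure):       ``2 N / (|A||B|(|A|-1) + |B||A|(|B|-1))``
* loop-like triplets with fixed A->B->A chain: ``2 N / (|A||B|(|A|-1))``

The factor 2 reflects that each unordered loop-like unit-triple supports two
chain orientations of its structure class, while counts N are of detected
(unordered) assemblies.

The Int-Ext index ``P_ext / (P_ext + P_int)`` lies in [0, 1]: exactly 0.5
when the two probabilities are equal, above 0.5 when a focal unit is more
likely to pair externally than internally.

Asymmetry tests are exact binomial tests: directionality (from vs to the
focal area) at null probability 0.5, and loop structure (A->B->A vs B->A->B)
at the combinatorial null ``P_expected = (|A|-1) / (|A|+|B|-2)``, which is
the ratio of possible A->B->A chains to all possible loop-like chains.
Tests run only when at least ``min_total`` (default 10) assemblies of the
relevant kind were detected.  Multi-session pooling sums numerators and
denominators separately before dividing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Literal, Sequence

import pandas as pd
from scipy.stats import binom, binomtest

from .io_spikes import Session
from .motifs import MotifRecord

#: Minimum number of detected assemblies for an asymmetry test to run.
MIN_ASSEMBLIES_FOR_TEST = 10


def p_pairs_ext(n_pairs: int, n_a: int, n_b: int) -> float:
    """Probability of an external pair: detected pairs over ``|A| * |B|``."""
    if n_a < 1 or n_b < 1:
        raise ValueError("unit counts must be >= 1")
    return n_pairs / (n_a * n_b)


def p_pairs_int(n_pairs: int, n_a: int) -> float:
    """Probability of an internal pair: detected pairs over ``C(|A|, 2)``."""
    if n_a < 2:
        raise ValueError("need at least 2 units for internal pairs")
    return n_pairs / comb(n_a, 2)


def _loop_denominator(n_a: int, n_b: int) -> int:
    return n_a * n_b * (n_a - 1) + n_b * n_a * (n_b - 1)


def p_looplike(n_loops: int, n_a: int, n_b: int) -> float:
    """Probability of a loop-like triplet of either structure."""
    if n_a < 1 or n_b < 1:
        raise ValueError("unit counts must be >= 1")
    denom = _loop_denominator(n_a, n_b)
    if denom == 0:
        raise ValueError("no loop-like triplet possible with |A| = |B| = 1")
    return 2 * n_loops / denom


def p_looplike_structured(n_aba: int, n_a: int, n_b: int) -> float:
    """Probability of a loop-like triplet with fixed A->B->A structure."""
    if n_a < 2:
        raise ValueError("A->B->A requires at least 2 units in A")
    if n_b < 1:
        raise ValueError("unit counts must be >= 1")
    return 2 * n_aba / (n_a * n_b * (n_a - 1))


def int_ext_index(p_ext: float, p_int: float) -> float:
    """``P_ext / (P_ext + P_int)`` in [0, 1]; 0.5 means the probabilities are
    equal.  Undefined (raises) when both probabilities are zero."""
    if p_ext < 0 or p_int < 0:
        raise ValueError("probabilities must be non-negative")
    if p_ext + p_int == 0:
        raise ValueError("Int-Ext index undefined when both probabilities are 0")
    return p_ext / (p_ext + p_int)


def expected_loop_prob(n_a: int, n_b: int) -> float:
    """Null probability of the A->B->A structure among loop-like chains:
    ``(|A|-1) / (|A|+|B|-2)``, the ratio of possible chain counts."""
    if n_a < 1 or n_b < 1:
        raise ValueError("unit counts must be >= 1")
    if n_a + n_b < 3:
        raise ValueError("no loop-like triplet possible with |A| = |B| = 1")
    return (n_a - 1) / (n_a + n_b - 2)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one asymmetry test; ``tested=False`` (with ``p_value``
    absent) below the inclusion threshold."""

    tested: bool
    p_value: float | None
    estimate: float | None
    null_prob: float | None
    n: int


def _binom_two_sided(
    k: int, n: int, p0: float, method: Literal["minlike", "doubled"]
) -> float:
    if method == "minlike":
        return float(binomtest(k, n, p0, alternative="two-sided").pvalue)
    lower = float(binom.cdf(k, n, p0))
    upper = float(binom.sf(k - 1, n, p0))
    return min(1.0, 2.0 * min(lower, upper))


def binom_direction_test(
    n_from: int,
    n_to: int,
    min_total: int = MIN_ASSEMBLIES_FOR_TEST,
    method: Literal["minlike", "doubled"] = "minlike",
) -> TestResult:
    """Exact two-sided binomial test of directional asymmetry at p0 = 0.5.

    The two directions are equiprobable under the null.  Not run (and
    ``p_value`` absent) below ``min_total`` directional assemblies.
    """
    if n_from < 0 or n_to < 0:
        raise ValueError("counts must be non-negative")
    n = n_from + n_to
    if n < min_total:
        return TestResult(False, None, None, None, n)
    if n == 0:  # possible only with min_total = 0: no evidence either way
        return TestResult(True, 1.0, None, 0.5, 0)
    p = _binom_two_sided(n_from, n, 0.5, method)
    return TestResult(True, p, n_from / n, 0.5, n)


def binom_loop_test(
    n_aba: int,
    n_total: int,
    n_a: int,
    n_b: int,
    min_total: int = MIN_ASSEMBLIES_FOR_TEST,
    method: Literal["minlike", "doubled"] = "minlike",
) -> TestResult:
    """Exact two-sided binomial test of loop-structure asymmetry.

    The null probability of the A->B->A structure is the combinatorial
    ``expected_loop_prob(n_a, n_b)``.  The default two-sided rule is the
    minimum-likelihood method (sum of probabilities of outcomes no more
    likely than the observed one); ``method="doubled"`` doubles the smaller
    tail instead.
    """
    if n_aba < 0 or n_total < n_aba:
        raise ValueError("need 0 <= n_aba <= n_total")
    p0 = expected_loop_prob(n_a, n_b)
    if n_total < min_total:
        return TestResult(False, None, None, None, n_total)
    p = _binom_two_sided(n_aba, n_total, p0, method)
    return TestResult(True, p, n_aba / n_total, p0, n_total)


@dataclass
class AreaPairStats:
    """Counts and denominators for one (focal, partner) area pair.

    ``area_a`` is the focal side.  Denominators are computed from the
    per-session unit counts on construction and are summed (not recomputed)
    when pooling, so that pooled probabilities are sums of numerators over
    sums of denominators.
    """

    area_a: str
    area_b: str
    n_a: int
    n_b: int
    n_pairs_ext: int = 0
    n_pairs_from: int = 0
    n_pairs_to: int = 0
    n_pairs_sync: int = 0
    n_pairs_int_a: int = 0
    n_loops_total: int = 0
    n_loops_aba: int = 0
    n_loops_bab: int = 0
    sessions: tuple[str, ...] = ()
    denom_ext: int | None = None
    denom_int_a: int | None = None
    denom_loop: int | None = None
    denom_aba: int | None = None

    def __post_init__(self) -> None:
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("unit counts must be >= 1")
        if self.n_pairs_from + self.n_pairs_to + self.n_pairs_sync != self.n_pairs_ext:
            raise ValueError("from + to + sync must equal n_pairs_ext")
        if self.n_loops_aba + self.n_loops_bab != self.n_loops_total:
            raise ValueError("ABA + BAB must equal n_loops_total")
        if self.denom_ext is None:
            self.denom_ext = self.n_a * self.n_b
        if self.denom_int_a is None:
            self.denom_int_a = comb(self.n_a, 2)
        if self.denom_loop is None:
            self.denom_loop = _loop_denominator(self.n_a, self.n_b)
        if self.denom_aba is None:
            self.denom_aba = self.n_a * self.n_b * (self.n_a - 1)

    # pooled-safe probabilities (numerator over stored denominator)
    @property
    def p_ext(self) -> float:
        return self.n_pairs_ext / self.denom_ext

    @property
    def p_int_a(self) -> float:
        if self.denom_int_a == 0:
            raise ValueError("no internal pair possible with |A| < 2")
        return self.n_pairs_int_a / self.denom_int_a

    @property
    def p_sync(self) -> float:
        return self.n_pairs_sync / self.denom_ext

    @property
    def p_from(self) -> float:
        return self.n_pairs_from / self.denom_ext

    @property
    def p_to(self) -> float:
        return self.n_pairs_to / self.denom_ext

    @property
    def p_loop(self) -> float:
        if self.denom_loop == 0:
            raise ValueError("no loop-like triplet possible")
        return 2 * self.n_loops_total / self.denom_loop

    @property
    def p_loop_aba(self) -> float:
        if self.denom_aba == 0:
            raise ValueError("A->B->A requires at least 2 units in A")
        return 2 * self.n_loops_aba / self.denom_aba

    @property
    def int_ext(self) -> float:
        return int_ext_index(self.p_ext, self.p_int_a)

    def direction_test(self, **kw) -> TestResult:
        return binom_direction_test(self.n_pairs_from, self.n_pairs_to, **kw)

    def loop_test(self, **kw) -> TestResult:
        return binom_loop_test(
            self.n_loops_aba, self.n_loops_total, self.n_a, self.n_b, **kw
        )


def collect_area_pair_stats(
    records: Sequence[MotifRecord], session: Session
) -> list[AreaPairStats]:
    """Aggregate classified motifs of one session into per-partner-area
    counts (focal side = ``session.focal_area``)."""
    focal = session.focal_area
    n_focal = sum(1 for tr in session.trains if tr.area == focal)
    n_by_area = {a: sum(1 for tr in session.trains if tr.area == a) for a in session.areas}
    n_int = sum(1 for r in records if r.klass == "pair_internal_focal")

    out = []
    for area in session.areas:
        if area == focal:
            continue
        sel = [r for r in records if r.partner_area == area]
        n_from = sum(1 for r in sel if r.klass == "pair_from_focal")
        n_to = sum(1 for r in sel if r.klass == "pair_to_focal")
        n_sync = sum(1 for r in sel if r.klass == "pair_synchronous")
        n_aba = sum(1 for r in sel if r.klass == "triplet_loop_focal")
        n_bab = sum(1 for r in sel if r.klass == "triplet_loop_external")
        out.append(
            AreaPairStats(
                area_a=focal,
                area_b=area,
                n_a=n_focal,
                n_b=n_by_area[area],
                n_pairs_ext=n_from + n_to + n_sync,
                n_pairs_from=n_from,
                n_pairs_to=n_to,
                n_pairs_sync=n_sync,
                n_pairs_int_a=n_int,
                n_loops_total=n_aba + n_bab,
                n_loops_aba=n_aba,
                n_loops_bab=n_bab,
                sessions=(session.session_id,),
            )
        )
    return out


def pool_sessions(per_session: Sequence[AreaPairStats]) -> AreaPairStats:
    """Pool one area pair across sessions: numerators and denominators are
    summed separately before division (never a mean of per-session ratios).
    """
    if not per_session:
        raise ValueError("nothing to pool")
    first = per_session[0]
    for s in per_session[1:]:
        if (s.area_a, s.area_b) != (first.area_a, first.area_b):
            raise ValueError("cannot pool different area pairs")
    return AreaPairStats(
        area_a=first.area_a,
        area_b=first.area_b,
        n_a=sum(s.n_a for s in per_session),
        n_b=sum(s.n_b for s in per_session),
        n_pairs_ext=sum(s.n_pairs_ext for s in per_session),
        n_pairs_from=sum(s.n_pairs_from for s in per_session),
        n_pairs_to=sum(s.n_pairs_to for s in per_session),
        n_pairs_sync=sum(s.n_pairs_sync for s in per_session),
        n_pairs_int_a=sum(s.n_pairs_int_a for s in per_session),
        n_loops_total=sum(s.n_loops_total for s in per_session),
        n_loops_aba=sum(s.n_loops_aba for s in per_session),
        n_loops_bab=sum(s.n_loops_bab for s in per_session),
        sessions=tuple(sid for s in per_session for sid in s.sessions),
        denom_ext=sum(s.denom_ext for s in per_session),
        denom_int_a=sum(s.denom_int_a for s in per_session),
        denom_loop=sum(s.denom_loop for s in per_session),
        denom_aba=sum(s.denom_aba for s in per_session),
    )


def rank_areas(
    stats: Sequence[AreaPairStats],
    metric: Literal["pairs", "loops", "sync"] = "pairs",
) -> pd.DataFrame:
    """Rank partner areas by a normalized probability, descending; ties are
    broken alphabetically by area."""
    if not stats:
        raise ValueError("no area-pair statistics to rank")
    getter = {"pairs": "p_ext", "loops": "p_loop", "sync": "p_sync"}
    try:
        attr = getter[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None
    rows = [
        {"area": s.area_b, "probability": getattr(s, attr), "n_a": s.n_a, "n_b": s.n_b}
        for s in stats
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["probability", "area"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df
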