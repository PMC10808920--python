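"""CAD-style cell-assembly detection on parallel spike trains.

The detector follows the two-stage logic of agglomerative assembly detection
(Russo-Durstewitz style) at desk scale:

1. **Pairwise stage.**  For every unit pair and every temporal resolution in
   a bin-size grid, count lagged coincidences
   ``c(l) = sum_t min(xA(t), xB(t+l))`` on binarized binned trains for
   ``l in [-max_lag, +max_lag]``, pick the lag maximizing the count, and test
   it against a non-stationarity-corrected parametric null: the session is
   split into ``n_chunks`` contiguous blocks, the expected coincidence count
   is ``sum_k T_k * pA_k * pB_k`` with per-block empirical occupancies, and
   the null total is modeled as Poisson with that mean.  The upper-tail
   p-value is Bonferroni-corrected for the ``2*max_lag + 1`` tested lags.

2. **Agglomerative stage.**  Each significant pair becomes a new pseudo-unit
   (the element-wise AND of the two aligned binarized trains) and is tested
   against every remaining unit with the same pairwise test; significant
   extensions become order-3 assemblies whose lag structure composes the
   pair's lag with the new unit's lag.  Agglomeration stops at triplets.

Multiple-comparison control uses Holm step-down.  By default a single Holm
family spans all pair tests across the whole grid (``holm_scope="grid"``),
which bounds the probability of *any* false assembly in a run by ``alpha``;
``"per_resolution"`` reproduces the looser per-bin-size control.  Assemblies
with identical unit sets found at several resolutions collapse to the one
with minimal p (its bin size is the assembly's optimal temporal resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import poisson

from .io_spikes import BinnedSession, Session, bin_session

#: Bin sizes (s) and matching maximal lags (bins) of the default grid: a
#: characteristic temporal precision below 100 ms with at most 200 ms between
#: consecutive activations (max over the grid: 0.01 * 19 = 190 ms).
DEFAULT_BIN_SIZES = (0.01, 0.015, 0.02, 0.025, 0.03, 0.04, 0.05, 0.06, 0.08, 0.1)
DEFAULT_MAX_LAGS = (19, 12, 9, 7, 6, 4, 3, 2, 2, 1)


@dataclass
class BinGrid:
    """Parallel lists of temporal resolutions and maximal lags."""

    bin_sizes: tuple[float, ...] = DEFAULT_BIN_SIZES
    max_lags: tuple[int, ...] = DEFAULT_MAX_LAGS

    def __post_init__(self) -> None:
        self.bin_sizes = tuple(float(b) for b in self.bin_sizes)
        self.max_lags = tuple(int(l) for l in self.max_lags)
        if len(self.bin_sizes) != len(self.max_lags):
            raise ValueError("bin_sizes and max_lags must be parallel")
        if any(b <= 0 for b in self.bin_sizes) or any(l < 0 for l in self.max_lags):
            raise ValueError("bin sizes must be positive, max lags non-negative")

    def __iter__(self):
        return iter(zip(self.bin_sizes, self.max_lags))

    @property
    def max_delay(self) -> float:
        """Largest testable delay (s): max over the grid of bin * max_lag."""
        return max(b * l for b, l in zip(self.bin_sizes, self.max_lags))


@dataclass
class DetectionConfig:
    grid: BinGrid = field(default_factory=BinGrid)
    alpha: float = 0.05
    n_chunks: int = 5
    binarize: bool = True
    max_order: int = 3
    holm_scope: str = "grid"  # or "per_resolution"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_chunks < 1:
            raise ValueError("n_chunks must be >= 1")
        if self.max_order not in (2, 3):
            raise ValueError("max_order must be 2 or 3")
        if self.holm_scope not in ("grid", "per_resolution"):
            raise ValueError("holm_scope must be 'grid' or 'per_resolution'")


@dataclass(frozen=True)
class AssemblyPattern:
    """A detected assembly in canonical orientation.

    Units are ordered by activation: lags are non-negative, non-decreasing
    integers with ``lags_bins[0] == 0``.  A fully synchronous assembly (all
    lags zero) is ordered lexicographically by unit id.  ``p_value`` is the
    lag-corrected pairwise (or extension) p-value at the assembly's optimal
    temporal resolution.
    """

    unit_ids: tuple[str, ...]
    areas: tuple[str, ...]
    lags_bins: tuple[int, ...]
    bin_size: float
    coincidence_count: int
    p_value: float

    @property
    def order(self) -> int:
        return len(self.unit_ids)

    @property
    def delays_s(self) -> tuple[float, ...]:
        """Delay of each unit relative to the first, in seconds
        (``lag * bin_size``)."""
        return tuple(l * self.bin_size for l in self.lags_bins)

    @property
    def synchronous(self) -> bool:
        return all(l == 0 for l in self.lags_bins)

    def to_dict(self) -> dict:
        return {
            "unit_ids": list(self.unit_ids),
            "areas": list(self.areas),
            "lags_bins": list(self.lags_bins),
            "bin_size": self.bin_size,
            "coincidence_count": self.coincidence_count,
            "p_value": self.p_value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssemblyPattern":
        return cls(
            tuple(d["unit_ids"]), tuple(d["areas"]), tuple(int(l) for l in d["lags_bins"]),
            float(d["bin_size"]), int(d["coincidence_count"]), float(d["p_value"]),
        )


class PairTest(NamedTuple):
    best_lag: int
    count: int
    p_value: float
    expected: float


def _lag_scan_order(max_lag: int) -> list[int]:
    # tie-break: smallest |l| first, then negative before positive
    return sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l > 0))


def coincidence_profile(
    xa: np.ndarray, xb: np.ndarray, max_lag: int, binarize: bool = True
) -> np.ndarray:
    """Lagged coincidence counts ``c(l)`` for ``l in [-max_lag, +max_lag]``.

    ``c(l) = sum_t min(xa(t), xb(t+l))`` over valid ``t``; index ``l +
    max_lag`` in the returned array.  Symmetric under swapping the trains and
    negating the lag.
    """
    xa = np.asarray(xa)
    xb = np.asarray(xb)
    if xa.shape != xb.shape or xa.ndim != 1:
        raise ValueError("xa and xb must be 1-d vectors of equal length")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if binarize:
        xa = (xa > 0).astype(np.int64)
        xb = (xb > 0).astype(np.int64)
    T = xa.size
    prof = np.zeros(2 * max_lag + 1, dtype=np.int64)
    for l in range(0, max_lag + 1):
        if l >= T:
            break
        prof[max_lag + l] = int(np.minimum(xa[: T - l], xb[l:]).sum())
        prof[max_lag - l] = int(np.minimum(xb[: T - l], xa[l:]).sum())
    return prof


def _chunk_occupancy(x_bin: np.ndarray, n_chunks: int) -> tuple[np.ndarray, np.ndarray]:
    chunks = np.array_split(x_bin, n_chunks)
    p = np.array([c.mean() if c.size else 0.0 for c in chunks])
    t = np.array([c.size for c in chunks], dtype=float)
    return p, t


def expected_coincidences(
    xa_bin: np.ndarray, xb_bin: np.ndarray, n_chunks: int
) -> float:
    """Chunk-wise independence expectation ``sum_k T_k * pA_k * pB_k``."""
    pa, tk = _chunk_occupancy(xa_bin, n_chunks)
    pb, _ = _chunk_occupancy(xb_bin, n_chunks)
    return float(np.sum(tk * pa * pb))


def pair_test(
    xa: np.ndarray,
    xb: np.ndarray,
    max_lag: int,
    config: DetectionConfig | None = None,
) -> PairTest:
    """Lag-optimized, lag-corrected coincidence test for one unit pair.

    The best lag maximizes the coincidence profile (ties resolved toward the
    smallest ``|l|``, negative before positive); the p-value is the Poisson
    upper tail at the chunked independence expectation, multiplied by the
    number of tested lags and capped at 1.  All-zero trains yield p = 1.
    """
    config = config or DetectionConfig()
    prof = coincidence_profile(xa, xb, max_lag, binarize=config.binarize)
    best_lag, best_c = 0, -1
    for l in _lag_scan_order(max_lag):
        c = int(prof[l + max_lag])
        if c > best_c:
            best_lag, best_c = l, c
    xa_b = (np.asarray(xa) > 0).astype(np.int8)
    xb_b = (np.asarray(xb) > 0).astype(np.int8)
    mu = expected_coincidences(xa_b, xb_b, config.n_chunks)
    p_single = float(poisson.sf(best_c - 1, mu))
    p = min(1.0, (2 * max_lag + 1) * p_single)
    return PairTest(best_lag, best_c, p, mu)


# --------------------------------------------------------------------------
# session-level scan (vectorized over pairs; identical results to pair_test)
# --------------------------------------------------------------------------

class _PairRecord(NamedTuple):
    res: int  # grid index
    i: int
    j: int
    best_lag: int
    count: int
    p_value: float


def _scan_resolution(
    X: np.ndarray, max_lag: int, n_chunks: int, res: int
) -> list[_PairRecord]:
    """All-pairs lag-optimized tests on a binarized (n_units, T) matrix.

    Uses one BLAS matmul per non-negative lag: for binary vectors the
    coincidence count equals a dot product, and ``c_ij(-l) = c_ji(l)``.
    """
    n, T = X.shape
    Xf = np.ascontiguousarray(X, dtype=np.float32)
    L_eff = min(max_lag, T - 1)
    C = np.empty((L_eff + 1, n, n), dtype=np.float64)
    for l in range(L_eff + 1):
        a = Xf[:, : T - l] if l else Xf
        b = Xf[:, l:]
        C[l] = a @ b.T

    idx = np.array_split(np.arange(T), n_chunks)
    P = np.stack([X[:, ix].mean(axis=1) if ix.size else np.zeros(n) for ix in idx], axis=1)
    Tk = np.array([ix.size for ix in idx], dtype=float)
    Mu = (P * Tk) @ P.T

    order = [l for l in _lag_scan_order(max_lag) if abs(l) <= L_eff]
    n_lags = 2 * max_lag + 1
    recs: list[tuple[int, int, int, int]] = []
    counts, mus = [], []
    for i in range(n):
        for j in range(i + 1, n):
            best_lag, best_c = 0, -1
            for l in order:
                c = int(round(C[l, i, j] if l >= 0 else C[-l, j, i]))
                if c > best_c:
                    best_lag, best_c = l, c
            recs.append((i, j, best_lag, best_c))
            counts.append(best_c)
            mus.append(Mu[i, j])
    p_single = poisson.sf(np.asarray(counts) - 1, np.asarray(mus))
    p = np.minimum(1.0, n_lags * p_single)
    return [
        _PairRecord(res, i, j, lag, c, float(pv))
        for (i, j, lag, c), pv in zip(recs, p)
    ]


def _holm_reject(pvals: Sequence[float], alpha: float) -> np.ndarray:
    if len(pvals) == 0:
        return np.zeros(0, dtype=bool)
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(np.asarray(pvals, dtype=float), alpha=alpha, method="holm")
    return reject


def _canonical_members(
    members: list[tuple[str, str, int]]
) -> tuple[tuple[str, ...], tuple[str, ...], tuple[int, ...]]:
    """Canonical activation order: by lag, ties lexicographic by unit id;
    lags shifted to start at 0."""
    members = sorted(members, key=lambda m: (m[2], m[0]))
    base = members[0][2]
    units = tuple(m[0] for m in members)
    areas = tuple(m[1] for m in members)
    lags = tuple(m[2] - base for m in members)
    return units, areas, lags


def _pair_activation(X: np.ndarray, i: int, j: int, lag: int) -> tuple[np.ndarray, int, int, int]:
    """AND of the two binarized trains aligned at the pair's best lag, in the
    leader's time frame.  Returns (activation, leader, follower, lag >= 0)."""
    T = X.shape[1]
    if lag >= 0:
        leader, follower, l = i, j, lag
    else:
        leader, follower, l = j, i, -lag
    act = np.zeros(T, dtype=X.dtype)
    if l == 0:
        act = (X[leader] & X[follower]).astype(X.dtype)
    else:
        act[: T - l] = X[leader][: T - l] & X[follower][l:]
    return act, leader, follower, l


def agglomerate(
    binned: BinnedSession,
    significant_pairs: list[_PairRecord],
    config: DetectionConfig,
) -> list[AssemblyPattern]:
    """Extend significant pairs to order-3 assemblies at one resolution.

    For each significant pair, its activation vector is tested against every
    unit outside the pair; extension p-values are Holm-corrected within the
    resolution, and significant extensions become triplets whose lag
    structure composes the pair's lag with the new unit's lag (relative to
    the pair's leading unit).  Duplicate unit sets keep the minimal p.
    """
    if config.max_order < 3 or not significant_pairs:
        return []
    X = (binned.counts > 0).astype(np.int8)
    n = X.shape[0]
    max_lag = None
    # resolution is shared by all records in the call
    grid = dict(zip(config.grid.bin_sizes, config.grid.max_lags))
    max_lag = grid.get(binned.bin_size)
    if max_lag is None:
        raise ValueError("binned resolution not in the configured grid")

    candidates = []
    for rec in significant_pairs:
        act, leader, follower, l = _pair_activation(X, rec.i, rec.j, rec.best_lag)
        if not act.any():
            continue
        for k in range(n):
            if k in (rec.i, rec.j):
                continue
            t = pair_test(act, X[k], max_lag, config)
            candidates.append((rec, leader, follower, l, k, t))
    if not candidates:
        return []
    reject = _holm_reject([c[5].p_value for c in candidates], config.alpha)

    best: dict[frozenset, AssemblyPattern] = {}
    for (rec, leader, follower, l, k, t), ok in zip(candidates, reject):
        if not ok:
            continue
        members = [
            (binned.unit_ids[leader], binned.areas[leader], 0),
            (binned.unit_ids[follower], binned.areas[follower], l),
            (binned.unit_ids[k], binned.areas[k], t.best_lag),
        ]
        units, areas, lags = _canonical_members(members)
        pat = AssemblyPattern(units, areas, lags, binned.bin_size, t.count, t.p_value)
        key = frozenset(units)
        if key not in best or pat.p_value < best[key].p_value:
            best[key] = pat
    return list(best.values())


def detect(session: Session, config: DetectionConfig | None = None) -> list[AssemblyPattern]:
    """Run the full multi-resolution detection on a session.

    Returns order-2 and order-3 assemblies, each at its optimal temporal
    resolution (minimal p across the grid for a given unit set), sorted by
    (order, p, unit ids).  Deterministic given the input.
    """
    config = config or DetectionConfig()
    if session.n_units < 2:
        raise ValueError("need at least 2 units to detect assemblies")

    binned_per_res: list[BinnedSession] = []
    records: list[_PairRecord] = []
    for res, (bin_size, max_lag) in enumerate(config.grid):
        bs = bin_session(session, bin_size)
        binned_per_res.append(bs)
        if config.binarize:
            X = (bs.counts > 0).astype(np.int8)
            records.extend(_scan_resolution(X, max_lag, config.n_chunks, res))
        else:
            # generic-count path: per-pair profiles with min() coincidences
            for i in range(bs.counts.shape[0]):
                for j in range(i + 1, bs.counts.shape[0]):
                    t = pair_test(bs.counts[i], bs.counts[j], max_lag, config)
                    records.append(_PairRecord(res, i, j, t.best_lag, t.count, t.p_value))

    # Holm step-down over the chosen family
    if config.holm_scope == "grid":
        reject = _holm_reject([r.p_value for r in records], config.alpha)
        sig_flags = dict(zip(range(len(records)), reject))
    else:
        sig_flags = {}
        for res in range(len(config.grid.bin_sizes)):
            idxs = [k for k, r in enumerate(records) if r.res == res]
            rej = _holm_reject([records[k].p_value for k in idxs], config.alpha)
            for k, ok in zip(idxs, rej):
                sig_flags[k] = ok

    best: dict[frozenset, AssemblyPattern] = {}

    def _keep(pat: AssemblyPattern) -> None:
        key = frozenset(pat.unit_ids)
        cur = best.get(key)
        if cur is None or (pat.p_value, pat.bin_size) < (cur.p_value, cur.bin_size):
            best[key] = pat

    for res, bs in enumerate(binned_per_res):
        sig = [r for k, r in enumerate(records) if r.res == res and sig_flags[k]]
        for r in sig:
            i, j, lag = r.i, r.j, r.best_lag
            if lag > 0:
                members = [
                    (bs.unit_ids[i], bs.areas[i], 0),
                    (bs.unit_ids[j], bs.areas[j], lag),
                ]
            elif lag < 0:
                members = [
                    (bs.unit_ids[j], bs.areas[j], 0),
                    (bs.unit_ids[i], bs.areas[i], -lag),
                ]
            else:
                members = [
                    (bs.unit_ids[i], bs.areas[i], 0),
                    (bs.unit_ids[j], bs.areas[j], 0),
                ]
            units, areas, lags = _canonical_members(members)
            _keep(AssemblyPattern(units, areas, lags, bs.bin_size, r.count, r.p_value))
        for pat in agglomerate(bs, sig, config):
            _keep(pat)

    out = sorted(best.values(), key=lambda a: (a.order, a.p_value, a.unit_ids))
    return out
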