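"""Span-overlap predicate, overlap counting, and nearest-peak distances.

Two peaks overlap under a *fractional span* rule: the shared span must cover
at least a threshold fraction (default 25%) of a peak's width. Three modes
are supported because published analyses phrase the rule both ways:

``reciprocal``
    the shared span covers >= threshold of BOTH peaks' widths;
``query_fraction``
    >= threshold of the query peak's width only;
``reference_fraction``
    >= threshold of the reference peak's width only.

The comparison is inclusive (>=): "at least 25%" admits exactly 25%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import GenomeModel, Peak, PeakSet

__all__ = [
    "OverlapConfig",
    "OverlapResult",
    "DistanceRecord",
    "NearestDistanceResult",
    "overlap_fraction",
    "peaks_overlap",
    "count_overlapped",
    "nearest_distances",
]

Mode = Literal["reciprocal", "query_fraction", "reference_fraction"]


@dataclass(frozen=True)
class OverlapConfig:
    """Overlap rule: mode and inclusive threshold in (0, 1]."""

    mode: Mode = "reciprocal"
    threshold: float = 0.25

    def __post_init__(self):
        if self.mode not in ("reciprocal", "query_fraction", "reference_fraction"):
            raise ValueError(f"unknown overlap mode {self.mode!r}")
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")


@dataclass
class OverlapResult:
    """Bookkeeping from counting overlaps of a query set against a reference.

    ``matched[i]`` lists the global indices of reference peaks satisfying the
    overlap rule for query peak ``i`` (global = chromosome order, then start).
    """

    n_query: int
    n_reference: int
    n_query_overlapped: int
    n_reference_overlapped: int
    n_pairs: int
    matched: list[list[int]] | None = None

    @property
    def fraction_query_overlapped(self) -> float:
        return self.n_query_overlapped / self.n_query if self.n_query else 0.0


@dataclass(frozen=True)
class DistanceRecord:
    """Signed midpoint distance from a query peak to its nearest reference
    peak on the same chromosome (reference midpoint - query midpoint)."""

    query_index: int
    nearest_reference_index: int
    signed_distance: int


@dataclass
class NearestDistanceResult:
    records: list[DistanceRecord]
    n_omitted: int  # query peaks with no same-chromosome reference

    @property
    def distances(self) -> np.ndarray:
        return np.asarray([r.signed_distance for r in self.records], dtype=np.int64)

    def abs_distances(self) -> np.ndarray:
        return np.abs(self.distances)


def overlap_fraction(a: Peak, b: Peak) -> tuple[float, float]:
    """Fractions of each peak's width covered by the shared span.

    Returns ``(I/width_a, I/width_b)`` where ``I`` is the intersection length
    (0 when the peaks sit on different chromosomes). Symmetric up to swapping
    the returned pair.
    """
    if a.chrom != b.chrom:
        return 0.0, 0.0
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    return inter / a.width, inter / b.width


def peaks_overlap(a: Peak, b: Peak, cfg: OverlapConfig = OverlapConfig()) -> bool:
    """Whether peak ``a`` (query) overlaps peak ``b`` (reference) under ``cfg``."""
    fa, fb = overlap_fraction(a, b)
    t = cfg.threshold
    if cfg.mode == "reciprocal":
        return fa >= t and fb >= t
    if cfg.mode == "query_fraction":
        return fa >= t
    return fb >= t


# ---------------------------------------------------------------------------
# vectorized sweep


def _candidate_pairs(qs, qe, rs, re_):
    """Index pairs (qi, rj) of query/reference intervals with intersection > 0.

    Arrays must be sorted by start within the chromosome. Candidates are found
    with two searchsorted passes using the maximum reference width as a window;
    the positive-intersection filter then removes false candidates.
    """
    if len(qs) == 0 or len(rs) == 0:
        return (np.empty(0, np.int64),) * 2
    maxw = int(np.max(re_ - rs))
    lo = np.searchsorted(rs, qs - maxw, side="left")
    hi = np.searchsorted(rs, qe, side="left")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return (np.empty(0, np.int64),) * 2
    qi = np.repeat(np.arange(len(qs), dtype=np.int64), counts)
    offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
    rj = np.arange(total, dtype=np.int64) - np.repeat(offsets, counts) + np.repeat(lo, counts)
    inter = np.minimum(qe[qi], re_[rj]) - np.maximum(qs[qi], rs[rj])
    keep = inter > 0
    return qi[keep], rj[keep]


def _overlap_mask(qs, qe, rs, re_, mode: Mode, t: float):
    """(qi, rj) pairs satisfying the overlap rule, per chromosome arrays."""
    qi, rj = _candidate_pairs(qs, qe, rs, re_)
    if len(qi) == 0:
        return qi, rj
    inter = np.minimum(qe[qi], re_[rj]) - np.maximum(qs[qi], rs[rj])
    fq = inter / (qe[qi] - qs[qi])
    fr = inter / (re_[rj] - rs[rj])
    if mode == "reciprocal":
        ok = (fq >= t) & (fr >= t)
    elif mode == "query_fraction":
        ok = fq >= t
    else:
        ok = fr >= t
    return qi[ok], rj[ok]


def _count_stats(query_arrays, reference_arrays, mode: Mode, t: float):
    """Fast path over dicts ``chrom -> (starts, ends)``; returns the three
    counts (query peaks overlapped, reference peaks overlapped, pairs)."""
    nq_ov = nr_ov = npairs = 0
    for chrom, (qs, qe) in query_arrays.items():
        ref = reference_arrays.get(chrom)
        if ref is None:
            continue
        rs, re_ = ref
        qi, rj = _overlap_mask(qs, qe, rs, re_, mode, t)
        if len(qi):
            npairs += len(qi)
            nq_ov += len(np.unique(qi))
            nr_ov += len(np.unique(rj))
    return nq_ov, nr_ov, npairs


def _arrays_of(ps: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return {c: (ps.starts(c), ps.ends(c)) for c in ps.chroms_with_peaks}


def count_overlapped(
    query: PeakSet,
    reference: PeakSet,
    cfg: OverlapConfig = OverlapConfig(),
    collect_matches: bool = True,
) -> OverlapResult:
    """Count query peaks overlapped by >= 1 reference peak under ``cfg``.

    Uses a per-chromosome sorted sweep; the result is identical to the
    all-pairs brute force. Both sets must be bound to the same genome.
    """
    if query.genome != reference.genome:
        raise ValueError("query and reference are bound to different genomes")
    q_off = query.chrom_offsets()
    r_off = reference.chrom_offsets()
    nq_ov = nr_ov = npairs = 0
    matched: list[list[int]] | None = [[] for _ in range(len(query))] if collect_matches else None
    for chrom in query.chroms_with_peaks:
        qs, qe = query.starts(chrom), query.ends(chrom)
        rs, re_ = reference.starts(chrom), reference.ends(chrom)
        qi, rj = _overlap_mask(qs, qe, rs, re_, cfg.mode, cfg.threshold)
        if len(qi) == 0:
            continue
        npairs += len(qi)
        nq_ov += len(np.unique(qi))
        nr_ov += len(np.unique(rj))
        if matched is not None:
            qo, ro = q_off[chrom], r_off[chrom]
            for i, j in zip(qi, rj):
                matched[qo + int(i)].append(ro + int(j))
    return OverlapResult(
        n_query=len(query),
        n_reference=len(reference),
        n_query_overlapped=nq_ov,
        n_reference_overlapped=nr_ov,
        n_pairs=npairs,
        matched=matched,
    )


# ---------------------------------------------------------------------------
# nearest distances


def _nearest_arrays(q_mids, r_mids_sorted, r_starts_sorted, r_order):
    """For each query midpoint: (signed distance, reference index in original
    per-chromosome order). Reference arrays must be sorted by (midpoint,
    start); ``r_order`` maps sorted position -> original position.

    Ties on |distance| resolve to the candidate with the smaller start; a
    midpoint block's first entry has the block's smallest start by the sort.
    """
    pos = np.searchsorted(r_mids_sorted, q_mids, side="left")
    n = len(r_mids_sorted)
    left = np.clip(pos - 1, 0, n - 1)
    right = np.clip(pos, 0, n - 1)
    # collapse each candidate to the first entry of its midpoint block
    left = np.searchsorted(r_mids_sorted, r_mids_sorted[left], side="left")
    right = np.searchsorted(r_mids_sorted, r_mids_sorted[right], side="left")
    dl = np.abs(q_mids - r_mids_sorted[left])
    dr = np.abs(q_mids - r_mids_sorted[right])
    use_right = (dr < dl) | ((dr == dl) & (r_starts_sorted[right] < r_starts_sorted[left]))
    chosen = np.where(use_right, right, left)
    signed = r_mids_sorted[chosen] - q_mids
    return signed, r_order[chosen]


def nearest_distances(query: PeakSet, reference: PeakSet) -> NearestDistanceResult:
    """Signed midpoint distance from each query peak to the nearest reference
    peak on the same chromosome (reference midpoint - query midpoint).

    Ties on |distance| break toward the reference peak with the smaller start.
    Query peaks on chromosomes with no reference peaks are omitted from the
    record list and tallied in ``n_omitted``.
    """
    if query.genome != reference.genome:
        raise ValueError("query and reference are bound to different genomes")
    q_off = query.chrom_offsets()
    r_off = reference.chrom_offsets()
    records: list[DistanceRecord] = []
    n_omitted = 0
    for chrom in query.chroms_with_peaks:
        nq = query.count(chrom)
        if reference.count(chrom) == 0:
            n_omitted += nq
            continue
        q_mids = query.midpoints(chrom)
        r_mids = reference.midpoints(chrom)
        r_starts = reference.starts(chrom)
        order = np.lexsort((r_starts, r_mids))
        signed, ref_idx = _nearest_arrays(
            q_mids, r_mids[order], r_starts[order], order
        )
        qo, ro = q_off[chrom], r_off[chrom]
        for i in range(nq):
            records.append(
                DistanceRecord(qo + i, ro + int(ref_idx[i]), int(signed[i]))
            )
    return NearestDistanceResult(records=records, n_omitted=n_omitted)


def _nearest_distances_fast(query_mids: dict, reference_arrays: dict) -> np.ndarray:
    """Distances only, over dicts ``chrom -> mids`` / ``chrom -> (starts, ends)``."""
    out = []
    for chrom, q_mids in query_mids.items():
        ref = reference_arrays.get(chrom)
        if ref is None or len(ref[0]) == 0:
            continue
        rs, re_ = ref
        r_mids = np.sort((rs + re_) // 2)
        pos = np.searchsorted(r_mids, q_mids, side="left")
        n = len(r_mids)
        left = np.clip(pos - 1, 0, n - 1)
        right = np.clip(pos, 0, n - 1)
        dl = r_mids[left] - q_mids
        dr = r_mids[right] - q_mids
        out.append(np.where(np.abs(dr) < np.abs(dl), dr, dl))
    if not out:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(out)
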