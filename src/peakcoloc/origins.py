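"""Active/dormant replication-origin classification and class coverage.

Licensed origins are marked by the replicative-helicase subunit (Mcm5 peaks);
an origin counts as *active* (fired) when its Mcm5 peak overlaps a PCNA peak
— the sliding clamp is loaded only at fired origins — and *dormant*
otherwise. The default overlap rule is reciprocal >= 25% of both spans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PeakSet
from .overlap import OverlapConfig, count_overlapped

__all__ = ["OriginClassification", "CoverageReport", "classify_origins", "class_coverage"]


@dataclass
class OriginClassification:
    active: PeakSet
    dormant: PeakSet
    n_active: int
    n_dormant: int
    active_mask: np.ndarray  # per input Mcm peak, global order

    @property
    def n_total(self) -> int:
        return self.n_active + self.n_dormant


@dataclass
class CoverageReport:
    query_label: str
    class_label: str
    n_class: int
    n_covered: int
    fraction_covered: float
    empty_class: bool = False


def classify_origins(
    mcm: PeakSet,
    pcna: PeakSet,
    cfg: OverlapConfig = OverlapConfig(),
) -> OriginClassification:
    """Partition licensed origins (Mcm peaks) into active and dormant.

    An Mcm peak is active when >= 1 PCNA peak satisfies the overlap rule.
    The partition is exact: every input peak lands in exactly one class, with
    order and coordinates preserved.
    """
    if mcm.genome != pcna.genome:
        raise ValueError("mcm and pcna are bound to different genomes")
    res = count_overlapped(mcm, pcna, cfg, collect_matches=True)
    mask = np.asarray([len(m) > 0 for m in res.matched], dtype=bool)
    active = mcm.subset(mask, label=f"{mcm.label}_active")
    dormant = mcm.subset(~mask, label=f"{mcm.label}_dormant")
    return OriginClassification(
        active=active,
        dormant=dormant,
        n_active=int(mask.sum()),
        n_dormant=int((~mask).sum()),
        active_mask=mask,
    )


def class_coverage(
    query: PeakSet,
    origin_class: PeakSet,
    cfg: OverlapConfig = OverlapConfig(),
    direction: str = "class",
) -> CoverageReport:
    """Fraction of an origin class covered by a query factor's peaks.

    ``direction="class"`` (default): fraction of class peaks overlapped by
    >= 1 query peak — the natural reading of "the overlap between factor X
    and the active origins was f%". ``direction="query"`` flips it: fraction
    of query peaks overlapping >= 1 class peak.

    An empty class yields fraction 0 with ``empty_class=True``.
    """
    if query.genome != origin_class.genome:
        raise ValueError("query and origin class are bound to different genomes")
    if direction not in ("class", "query"):
        raise ValueError("direction must be 'class' or 'query'")
    if direction == "class":
        res = count_overlapped(origin_class, query, cfg, collect_matches=False)
        n_class, n_covered = len(origin_class), res.n_query_overlapped
    else:
        res = count_overlapped(query, origin_class, cfg, collect_matches=False)
        n_class, n_covered = len(query), res.n_query_overlapped
    empty = n_class == 0
    return CoverageReport(
        query_label=query.label,
        class_label=origin_class.label,
        n_class=n_class,
        n_covered=n_covered,
        fraction_covered=0.0 if empty else n_covered / n_class,
        empty_class=empty,
    )
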