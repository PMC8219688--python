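"""Synthetic genomes and peak sets with controlled colocalization structure.

Generates the fixtures every statistical stage is exercised on: anchor peaks
placed length-proportionally across chromosomes, query peaks of which a
controlled fraction ``rho`` is planted at (or near) anchors, and licensed
origin scenarios where a known fraction of origins carries a planted clamp
(PCNA) peak. Peak widths default to a lognormal with median ~200 bp,
mimicking the fragment size of micrococcal-nuclease ChIP libraries, truncated
to [50, 10000] bp.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import GenomeModel, PeakSet

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "default_genome",
    "generate_anchor_peaks",
    "generate_query_peaks",
    "generate_origin_scenario",
    "plant_at_anchors",
]

WIDTH_MIN, WIDTH_MAX = 50, 10_000


def default_genome(n_chrom: int = 5, length: int = 50_000_000) -> GenomeModel:
    """Demo genome: 5 chromosomes x 50 Mb — sparse enough that background
    overlap between a few thousand ~200 bp peaks is rare, small enough for
    seconds-scale permutation runs."""
    return GenomeModel([(f"chr{i + 1}", length) for i in range(n_chrom)])


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    ``rho`` is the fraction of query peaks planted at anchors; ``offset_sd``
    the SD (bp) of the planted midpoint's Gaussian offset from its anchor
    midpoint. ``width_dist`` is ``("fixed", w)`` or
    ``("lognormal", mean_log, sd_log)`` truncated to [50, 10000] bp.
    ``origin_params = (n_origins, fraction_active)`` drives the origin
    scenario.
    """

    genome_spec: tuple[tuple[str, int], ...] = tuple(
        (f"chr{i + 1}", 50_000_000) for i in range(5)
    )
    n_anchor: int = 1000
    n_query: int = 1000
    rho: float = 0.8
    offset_sd: float = 100.0
    width_dist: tuple = ("lognormal", math.log(200.0), 0.35)
    seed: int = 0
    origin_params: tuple[int, float] = (1000, 0.6)
    n_pcna_background: int = 0

    def __post_init__(self):
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        n_origins, frac = self.origin_params
        if not (0.0 <= frac <= 1.0):
            raise ValueError("fraction_active must be in [0, 1]")
        if min(self.n_anchor, self.n_query, n_origins, self.n_pcna_background) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def genome(self) -> GenomeModel:
        return GenomeModel(self.genome_spec)


@dataclass
class SyntheticTruth:
    """Ground truth for parameter recovery: which query peaks were planted
    at anchors, and which origins are truly active. Both arrays follow the
    emitted PeakSet's global (sorted) peak order."""

    planted_flags: np.ndarray | None = None
    origin_labels: np.ndarray | None = None
    n_clamped: int = 0  # planted peaks clamped to chromosome bounds


def _rng_of(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def _draw_widths(cfg: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = cfg.width_dist[0]
    if kind == "fixed":
        w = np.full(n, int(cfg.width_dist[1]), dtype=np.int64)
    elif kind == "lognormal":
        _, mean_log, sd_log = cfg.width_dist
        w = np.rint(rng.lognormal(mean_log, sd_log, size=n)).astype(np.int64)
    else:
        raise ValueError(f"unknown width distribution {kind!r}")
    return np.clip(w, WIDTH_MIN, WIDTH_MAX)


def _independent_placement(
    cfg: SyntheticConfig, n: int, rng: np.random.Generator, label: str
):
    """Arrays for n peaks: chromosome ~ length-proportional, start uniform."""
    genome = cfg.genome
    names = genome.names
    lengths = np.asarray([genome.length_of(c) for c in names], dtype=np.float64)
    widths = _draw_widths(cfg, n, rng)
    if np.any(widths > lengths.max()):
        raise ValueError("a drawn width exceeds every chromosome length")
    ci = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    # re-draw chromosomes too short for the width (rare with default genome)
    for _ in range(100):
        bad = widths > lengths[ci]
        if not bad.any():
            break
        ci[bad] = rng.choice(len(names), size=int(bad.sum()), p=lengths / lengths.sum())
    starts = rng.integers(0, (lengths[ci] - widths + 1).astype(np.int64))
    chroms = [names[i] for i in ci]
    return chroms, starts, starts + widths


def generate_anchor_peaks(
    cfg: SyntheticConfig, rng: np.random.Generator | int | None = None
) -> PeakSet:
    """n_anchor peaks placed independently: chromosome chosen with probability
    proportional to its length, width from ``width_dist``, start uniform in
    ``[0, L - w]``. Warns when expected density exceeds 1 peak / 10 kb."""
    rng = _rng_of(rng if rng is not None else cfg.seed)
    genome = cfg.genome
    if cfg.n_anchor > 0 and genome.total_length / max(cfg.n_anchor, 1) < 10_000:
        warnings.warn("peak density above 1 per 10 kb; background overlap will be common")
    if cfg.n_anchor == 0:
        return PeakSet("anchors", genome, [])
    chroms, starts, ends = _independent_placement(cfg, cfg.n_anchor, rng, "anchors")
    names = [f"anchor_{i}" for i in range(cfg.n_anchor)]
    return PeakSet.from_arrays("anchors", genome, chroms, starts, ends, names)


def _plant_near(
    genome: GenomeModel,
    anchor_chroms: list[str],
    anchor_mids: np.ndarray,
    widths: np.ndarray,
    offset_sd: float,
    rng: np.random.Generator,
):
    """Starts/ends for peaks centred near given anchor midpoints; peaks are
    clamped into their chromosome (clamping events counted)."""
    offsets = np.rint(rng.normal(0.0, offset_sd, size=len(widths))).astype(np.int64)
    mids = anchor_mids + offsets
    starts = mids - widths // 2
    ends = starts + widths
    n_clamped = 0
    lengths = np.asarray([genome.length_of(c) for c in anchor_chroms], dtype=np.int64)
    under = starts < 0
    over = ends > lengths
    n_clamped = int(under.sum() + over.sum())
    starts = np.where(under, 0, starts)
    ends = starts + widths
    shift = np.maximum(ends - lengths, 0)
    starts -= shift
    ends -= shift
    return starts, ends, n_clamped


def generate_query_peaks(
    anchors: PeakSet,
    cfg: SyntheticConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[PeakSet, SyntheticTruth]:
    """Query peaks with colocalization fraction ``rho``.

    ``round(rho * n_query)`` peaks are planted: an anchor is chosen uniformly
    (with replacement) and the peak's midpoint offset from the anchor midpoint
    by Normal(0, offset_sd), clamped to the chromosome. The rest are placed
    independently, as anchors are. Truth flags follow the emitted sorted order.
    """
    rng = _rng_of(rng if rng is not None else cfg.seed + 1)
    genome = cfg.genome
    n_planted = int(round(cfg.rho * cfg.n_query))
    if n_planted > 0 and len(anchors) == 0:
        raise ValueError("rho > 0 requires non-empty anchors")
    chrom_l: list[str] = []
    start_l: list[np.ndarray] = []
    end_l: list[np.ndarray] = []
    flags: list[np.ndarray] = []
    n_clamped = 0
    if n_planted > 0:
        a_df = anchors.to_dataframe()
        idx = rng.integers(0, len(anchors), size=n_planted)
        a_chroms = a_df["chrom"].to_numpy()[idx].tolist()
        a_mids = ((a_df["start"].to_numpy() + a_df["end"].to_numpy()) // 2)[idx]
        widths = _draw_widths(cfg, n_planted, rng)
        starts, ends, n_clamped = _plant_near(
            genome, a_chroms, a_mids, widths, cfg.offset_sd, rng
        )
        chrom_l.extend(a_chroms)
        start_l.append(starts)
        end_l.append(ends)
        flags.append(np.ones(n_planted, dtype=bool))
    n_indep = cfg.n_query - n_planted
    if n_indep > 0:
        chroms, starts, ends = _independent_placement(cfg, n_indep, rng, "query")
        chrom_l.extend(chroms)
        start_l.append(starts)
        end_l.append(ends)
        flags.append(np.zeros(n_indep, dtype=bool))
    if not chrom_l:
        return PeakSet("query", genome, []), SyntheticTruth(
            planted_flags=np.empty(0, dtype=bool)
        )
    starts = np.concatenate(start_l)
    ends = np.concatenate(end_l)
    flag_arr = np.concatenate(flags)
    # sort exactly as PeakSet will, to keep truth aligned with peak order
    order = _global_order(genome, chrom_l, starts, ends)
    chroms_sorted = [chrom_l[i] for i in order]
    ps = PeakSet.from_arrays(
        "query", genome, chroms_sorted, starts[order], ends[order],
        [f"q_{i}" for i in range(len(order))],
    )
    return ps, SyntheticTruth(planted_flags=flag_arr[order], n_clamped=n_clamped)


def _global_order(genome, chroms, starts, ends) -> np.ndarray:
    rank = {c: i for i, c in enumerate(genome.names)}
    ci = np.asarray([rank[c] for c in chroms])
    return np.lexsort((ends, starts, ci))


def generate_origin_scenario(
    cfg: SyntheticConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[PeakSet, PeakSet, SyntheticTruth]:
    """Licensed-origin fixture: Mcm peaks plus PCNA planted on active origins.

    ``n_origins`` Mcm peaks are placed as anchors; a uniformly chosen subset
    of exactly ``round(fraction_active * n_origins)`` origins is truly active
    and receives a planted PCNA peak (matched width, midpoint offset
    Normal(0, offset_sd)). ``cfg.n_pcna_background`` additional PCNA peaks are
    placed independently. Truth labels follow the Mcm set's sorted order.
    """
    rng = _rng_of(rng if rng is not None else cfg.seed + 2)
    genome = cfg.genome
    n_origins, frac_active = cfg.origin_params
    if n_origins < 1:
        raise ValueError("n_origins must be >= 1")
    mcm_cfg = replace(cfg, n_anchor=n_origins)
    chroms, starts, ends = _independent_placement(mcm_cfg, n_origins, rng, "mcm")
    order = _global_order(genome, chroms, starts, ends)
    chroms = [chroms[i] for i in order]
    starts, ends = starts[order], ends[order]
    mcm = PeakSet.from_arrays(
        "Mcm5", genome, chroms, starts, ends,
        [f"origin_{i}" for i in range(n_origins)],
    )
    n_active = int(round(frac_active * n_origins))
    labels = np.zeros(n_origins, dtype=bool)
    active_idx = rng.choice(n_origins, size=n_active, replace=False)
    labels[active_idx] = True
    pcna_parts = []
    n_clamped = 0
    if n_active > 0:
        a_chroms = [chroms[i] for i in active_idx]
        a_mids = ((starts + ends) // 2)[active_idx]
        widths = (ends - starts)[active_idx]  # matched widths
        p_starts, p_ends, n_clamped = _plant_near(
            genome, a_chroms, a_mids, widths, cfg.offset_sd, rng
        )
        pcna_parts.append((a_chroms, p_starts, p_ends))
    if cfg.n_pcna_background > 0:
        bg = _independent_placement(cfg, cfg.n_pcna_background, rng, "pcna_bg")
        pcna_parts.append(bg)
    if pcna_parts:
        all_chroms = sum((list(p[0]) for p in pcna_parts), [])
        all_starts = np.concatenate([p[1] for p in pcna_parts])
        all_ends = np.concatenate([p[2] for p in pcna_parts])
        pcna = PeakSet.from_arrays("PCNA", genome, all_chroms, all_starts, all_ends)
    else:
        pcna = PeakSet("PCNA", genome, [])
    return mcm, pcna, SyntheticTruth(origin_labels=labels, n_clamped=n_clamped)


def plant_at_anchors(
    anchors: PeakSet,
    fraction: float,
    offset_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    label: str = "planted",
) -> PeakSet:
    """One peak planted on each of a uniformly chosen ``round(fraction * n)``
    subset of anchors, matched widths, Gaussian midpoint offset. Used to build
    coverage fixtures where a factor hits a known share of an origin class."""
    rng = _rng_of(rng)
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    n = len(anchors)
    k = int(round(fraction * n))
    if k == 0:
        return PeakSet(label, anchors.genome, [])
    df = anchors.to_dataframe()
    idx = np.sort(rng.choice(n, size=k, replace=False))
    chroms = df["chrom"].to_numpy()[idx].tolist()
    starts_a = df["start"].to_numpy()[idx]
    ends_a = df["end"].to_numpy()[idx]
    widths = ends_a - starts_a
    mids = (starts_a + ends_a) // 2
    starts, ends, _ = _plant_near(anchors.genome, chroms, mids, widths, offset_sd, rng)
    return PeakSet.from_arrays(label, anchors.genome, chroms, starts, ends)
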