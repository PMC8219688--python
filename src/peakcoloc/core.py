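"""Core genomic-interval data model.

Coordinates are 0-based, half-open (BED convention) throughout the package:
a peak ``[start, end)`` has width ``end - start`` and covers the bases
``start .. end-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenomeModel", "Peak", "PeakSet"]


class FormatError(ValueError):
    """Malformed input file (bad line, bad coordinate, unknown chromosome)."""


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names and lengths; the universe peaks live in
    and the space the randomization null draws positions from.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_bp)`` pairs, in file order.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        seen: set[str] = set()
        for name, length in chroms:
            if not name:
                raise ValueError("empty chromosome name")
            if name in seen:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            seen.add(name)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> Mapping[str, int]:
        return dict(self.chromosomes)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return any(n == chrom for n, _ in self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)


@dataclass(frozen=True)
class Peak:
    """A single called peak: a half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid peak interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor of (start+end)/2."""
        return (self.start + self.end) // 2


class PeakSet:
    """A labelled collection of peaks bound to a genome.

    Peaks are stored grouped by chromosome as numpy arrays, sorted by
    (start, end) within each chromosome. Iteration and indexing follow the
    global order: genome chromosome order, then start, then end. That order
    is the canonical peak index used by overlap and distance reports.
    """

    def __init__(self, label: str, genome: GenomeModel, peaks: Iterable[Peak] = ()):
        rows = [(p.chrom, p.start, p.end, p.name, p.score) for p in peaks]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
        self._init_from_df(label, genome, df)

    def _init_from_df(self, label: str, genome: GenomeModel, df: pd.DataFrame) -> None:
        self.label = str(label)
        self.genome = genome
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._names: dict[str, np.ndarray] = {}
        self._scores: dict[str, np.ndarray] = {}
        if len(df) > 0:
            bad = set(df["chrom"]) - set(genome.names)
            if bad:
                raise FormatError(
                    f"peaks on chromosomes absent from genome: {sorted(bad)}"
                )
            starts = df["start"].to_numpy(dtype=np.int64)
            ends = df["end"].to_numpy(dtype=np.int64)
            if np.any(starts < 0) or np.any(starts >= ends):
                raise ValueError("every peak needs 0 <= start < end")
            lengths = genome.lengths
            for chrom, sub in df.groupby("chrom", sort=False):
                if int(sub["end"].max()) > lengths[str(chrom)]:
                    raise ValueError(
                        f"peak end exceeds length of chromosome {chrom}"
                    )
        for chrom in genome.names:
            sub = df[df["chrom"] == chrom] if len(df) else df
            if len(sub) == 0:
                continue
            s = sub["start"].to_numpy(dtype=np.int64)
            e = sub["end"].to_numpy(dtype=np.int64)
            order = np.lexsort((e, s))
            self._starts[chrom] = s[order]
            self._ends[chrom] = e[order]
            self._names[chrom] = sub["name"].to_numpy(dtype=object)[order]
            self._scores[chrom] = sub["score"].to_numpy(dtype=object)[order]

    @classmethod
    def from_arrays(
        cls,
        label: str,
        genome: GenomeModel,
        chrom: Sequence[str] | np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        name: Sequence | None = None,
        score: Sequence | None = None,
    ) -> "PeakSet":
        n = len(start)
        df = pd.DataFrame(
            {
                "chrom": list(chrom),
                "start": np.asarray(start, dtype=np.int64),
                "end": np.asarray(end, dtype=np.int64),
                "name": list(name) if name is not None else [None] * n,
                "score": list(score) if score is not None else [None] * n,
            }
        )
        obj = cls.__new__(cls)
        obj._init_from_df(label, genome, df)
        return obj

    # -- accessors ---------------------------------------------------------

    @property
    def chroms_with_peaks(self) -> list[str]:
        return [c for c in self.genome.names if c in self._starts]

    def starts(self, chrom: str) -> np.ndarray:
        return self._starts.get(chrom, np.empty(0, dtype=np.int64))

    def ends(self, chrom: str) -> np.ndarray:
        return self._ends.get(chrom, np.empty(0, dtype=np.int64))

    def names(self, chrom: str) -> np.ndarray:
        return self._names.get(chrom, np.empty(0, dtype=object))

    def widths(self, chrom: str) -> np.ndarray:
        return self.ends(chrom) - self.starts(chrom)

    def midpoints(self, chrom: str) -> np.ndarray:
        return (self.starts(chrom) + self.ends(chrom)) // 2

    def count(self, chrom: str) -> int:
        return len(self.starts(chrom))

    def counts_by_chrom(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._starts.items()}

    def chrom_offsets(self) -> dict[str, int]:
        """Global index of the first peak on each chromosome."""
        offsets, running = {}, 0
        for c in self.genome.names:
            if c in self._starts:
                offsets[c] = running
                running += len(self._starts[c])
        return offsets

    def __len__(self) -> int:
        return sum(len(s) for s in self._starts.values())

    def __iter__(self) -> Iterator[Peak]:
        for chrom in self.genome.names:
            if chrom not in self._starts:
                continue
            for s, e, n, sc in zip(
                self._starts[chrom],
                self._ends[chrom],
                self._names[chrom],
                self._scores[chrom],
            ):
                yield Peak(chrom, int(s), int(e), n, sc)

    def __getitem__(self, i: int) -> Peak:
        if i < 0:
            i += len(self)
        for chrom in self.genome.names:
            n = self.count(chrom)
            if i < n:
                return Peak(
                    chrom,
                    int(self._starts[chrom][i]),
                    int(self._ends[chrom][i]),
                    self._names[chrom][i],
                    self._scores[chrom][i],
                )
            i -= n
        raise IndexError("peak index out of range")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.chrom, p.start, p.end, p.name, p.score) for p in self],
            columns=["chrom", "start", "end", "name", "score"],
        )

    def subset(self, mask: np.ndarray, label: str | None = None) -> "PeakSet":
        """New PeakSet keeping peaks where ``mask`` (global order) is True."""
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != len(self):
            raise ValueError("mask length must equal peak count")
        df = self.to_dataframe()[mask]
        obj = PeakSet.__new__(PeakSet)
        obj._init_from_df(label or self.label, self.genome, df)
        return obj

    @staticmethod
    def concat(label: str, sets: Sequence["PeakSet"]) -> "PeakSet":
        if not sets:
            raise ValueError("need at least one PeakSet")
        genome = sets[0].genome
        if any(ps.genome is not genome and ps.genome != genome for ps in sets):
            raise ValueError("all PeakSets must share one genome")
        df = pd.concat([ps.to_dataframe() for ps in sets], ignore_index=True)
        obj = PeakSet.__new__(PeakSet)
        obj._init_from_df(label, genome, df)
        return obj

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return (
            self.genome == other.genome
            and self.counts_by_chrom() == other.counts_by_chrom()
            and all(
                np.array_equal(self.starts(c), other.starts(c))
                and np.array_equal(self.ends(c), other.ends(c))
                for c in self.chroms_with_peaks
            )
        )

    def __repr__(self) -> str:
        return f"PeakSet({self.label!r}, n={len(self)}, chroms={len(self.chroms_with_peaks)})"
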