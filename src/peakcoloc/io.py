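"""Readers and writers for chrom.sizes and BED interval files.

chrom.sizes is the UCSC two-column ``name<TAB>length`` convention. BED input
accepts BED3 through BED6 plus extra columns (ignored beyond column 6);
``track``, ``browser`` and ``#`` comment lines are skipped. Output is BED3,
or BED4 when any peak carries a name. All coordinates 0-based half-open.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path
from typing import IO, Iterable, Union

from .core import FormatError, GenomeModel, PeakSet

__all__ = ["read_chrom_sizes", "read_bed", "write_bed"]

TextSource = Union[str, Path, IO[str], Iterable[str]]


def _as_lines(source: TextSource):
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            yield from fh
    else:
        yield from source


def read_chrom_sizes(source: TextSource) -> GenomeModel:
    """Parse a chrom.sizes table into a :class:`GenomeModel`.

    Raises :class:`FormatError` naming the offending line on malformed,
    non-positive or duplicate entries.
    """
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            fields = line.split()
        if len(fields) < 2:
            raise FormatError(f"chrom.sizes line {lineno}: expected name<TAB>length: {line!r}")
        name = fields[0]
        try:
            length = int(fields[1])
        except ValueError:
            raise FormatError(
                f"chrom.sizes line {lineno}: non-integer length {fields[1]!r}"
            ) from None
        if length <= 0:
            raise FormatError(f"chrom.sizes line {lineno}: non-positive length {length}")
        if name in seen:
            raise FormatError(f"chrom.sizes line {lineno}: duplicate chromosome {name!r}")
        seen.add(name)
        chroms.append((name, length))
    return GenomeModel(chroms)


_HEADER_PREFIXES = ("track", "browser", "#")


def read_bed(
    source: TextSource,
    genome: GenomeModel,
    label: str = "",
    unknown_chrom: str = "error",
) -> PeakSet:
    """Parse BED3+ lines into a :class:`PeakSet` bound to ``genome``.

    Parameters
    ----------
    unknown_chrom
        ``"error"`` (default): a chromosome absent from the genome raises;
        ``"drop"``: such lines are dropped with a warning (peak files often
        carry unplaced scaffolds absent from the analysis genome).
    """
    if unknown_chrom not in ("error", "drop"):
        raise ValueError("unknown_chrom must be 'error' or 'drop'")
    chrom_l, start_l, end_l, name_l, score_l = [], [], [], [], []
    n_dropped = 0
    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith(_HEADER_PREFIXES):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"BED line {lineno}: fewer than 3 columns: {line!r}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(f"BED line {lineno}: non-integer coordinates") from None
        if start < 0 or start >= end:
            raise FormatError(
                f"BED line {lineno}: invalid interval [{start}, {end})"
            )
        if chrom not in genome:
            if unknown_chrom == "drop":
                n_dropped += 1
                continue
            raise FormatError(f"BED line {lineno}: unknown chromosome {chrom!r}")
        if end > genome.length_of(chrom):
            raise FormatError(
                f"BED line {lineno}: end {end} beyond length of {chrom}"
            )
        name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
        score = None
        if len(fields) >= 5 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError:
                score = None
        chrom_l.append(chrom)
        start_l.append(start)
        end_l.append(end)
        name_l.append(name)
        score_l.append(score)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} BED line(s) on unknown chromosomes")
    import numpy as np

    return PeakSet.from_arrays(
        label,
        genome,
        chrom_l,
        np.asarray(start_l, dtype=np.int64),
        np.asarray(end_l, dtype=np.int64),
        name_l,
        score_l,
    )


def write_bed(ps: PeakSet, dest: Union[str, Path, IO[str]]) -> None:
    """Write a PeakSet as BED3 (BED4 when any peak has a name).

    Round-trip contract: ``read_bed(write_bed(ps))`` reproduces identical
    coordinates in identical order.
    """
    own = isinstance(dest, (str, Path))
    fh: IO[str] = open(dest, "wt") if own else dest  # type: ignore[assignment]
    try:
        any_name = any(p.name is not None for p in ps)
        for p in ps:
            if any_name:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name if p.name is not None else '.'}\n")
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
    finally:
        if own:
            fh.close()


def bed_string(ps: PeakSet) -> str:
    buf = _io.StringIO()
    write_bed(ps, buf)
    return buf.getvalue()
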