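"""Core interval model, chrom.sizes/BED I/O, overlap predicate, nearest distances."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakcoloc import (
    GenomeModel,
    OverlapConfig,
    Peak,
    PeakSet,
    count_overlapped,
    nearest_distances,
    overlap_fraction,
    peaks_overlap,
    read_bed,
    read_chrom_sizes,
    write_bed,
)
from peakcoloc.core import FormatError

from conftest import random_peakset


# ---------------------------------------------------------------------- types


def test_genome_model_invariants():
    g = GenomeModel([("chrT", 1000)])
    assert g.names == ("chrT",)
    assert g.length_of("chrT") == 1000
    with pytest.raises(ValueError):
        GenomeModel([("chrA", 500), ("chrA", 600)])
    with pytest.raises(ValueError):
        GenomeModel([("chrA", 0)])
    with pytest.raises(ValueError):
        GenomeModel([("", 100)])


def test_peak_invariants():
    p = Peak("chrT", 100, 200)
    assert p.width == 100 and p.midpoint == 150
    with pytest.raises(ValueError):
        Peak("chrT", 200, 100)
    with pytest.raises(ValueError):
        Peak("chrT", -1, 100)


def test_peakset_sorts_and_validates(toy_genome):
    ps = PeakSet("x", toy_genome, [Peak("chrA", 500, 600), Peak("chrA", 100, 200)])
    assert [p.start for p in ps] == [100, 500]
    with pytest.raises(FormatError):
        PeakSet("x", toy_genome, [Peak("chrZ", 0, 10)])
    with pytest.raises(ValueError):
        PeakSet("x", toy_genome, [Peak("chrA", 0, 99_999)])  # beyond chrA


# ------------------------------------------------------------------------ I/O


def test_read_chrom_sizes():
    g = read_chrom_sizes(io.StringIO("chrT\t1000\n"))
    assert g.chromosomes == (("chrT", 1000),)
    g = read_chrom_sizes(io.StringIO("chrA\t500\nchrB\t2000\n"))
    assert g.names == ("chrA", "chrB")
    for bad in ("chrA\t-5\n", "chrA\tfoo\n", "chrA\t10\nchrA\t20\n", "justonefield\n"):
        with pytest.raises(FormatError):
            read_chrom_sizes(io.StringIO(bad))


def test_read_bed_basics(toy_genome):
    ps = read_bed(io.StringIO("chrA\t100\t200\tp1\t50\t+\n"), toy_genome)
    p = ps[0]
    assert (p.chrom, p.start, p.end, p.name, p.score) == ("chrA", 100, 200, "p1", 50.0)
    ps = read_bed(io.StringIO("track name=x\n# comment\nchrA\t0\t10\n"), toy_genome)
    assert len(ps) == 1
    with pytest.raises(FormatError) as exc:
        read_bed(io.StringIO("chrA\t0\t10\nchrA\t200\t100\n"), toy_genome)
    assert "line 2" in str(exc.value)


def test_read_bed_unknown_chrom(toy_genome):
    lines = "chrA\t0\t10\nchrUn_scaffold\t5\t10\n"
    with pytest.raises(FormatError):
        read_bed(io.StringIO(lines), toy_genome)
    with pytest.warns(UserWarning):
        ps = read_bed(io.StringIO(lines), toy_genome, unknown_chrom="drop")
    assert len(ps) == 1


def test_bed_write_empty_and_single(toy_genome):
    buf = io.StringIO()
    write_bed(PeakSet("e", toy_genome, []), buf)
    assert buf.getvalue() == ""
    buf = io.StringIO()
    write_bed(PeakSet("s", toy_genome, [Peak("chrA", 100, 200, "p")]), buf)
    assert buf.getvalue() == "chrA\t100\t200\tp\n"


@st.composite
def peaksets(draw):
    genome = GenomeModel([("chrA", 5000), ("chrB", 3000)])
    n = draw(st.integers(0, 30))
    peaks = []
    for _ in range(n):
        chrom = draw(st.sampled_from(["chrA", "chrB"]))
        L = genome.length_of(chrom)
        s = draw(st.integers(0, L - 1))
        e = draw(st.integers(s + 1, L))
        peaks.append(Peak(chrom, s, e))
    return PeakSet("hyp", genome, peaks)


@given(peaksets())
@settings(max_examples=50, deadline=None)
def test_bed_round_trip_identity(ps):
    """read(write(ps)) reproduces coordinates and order exactly."""
    buf = io.StringIO()
    write_bed(ps, buf)
    back = read_bed(io.StringIO(buf.getvalue()), ps.genome, label=ps.label)
    assert [(p.chrom, p.start, p.end) for p in back] == [
        (p.chrom, p.start, p.end) for p in ps
    ]


# -------------------------------------------------------------------- overlap


@pytest.mark.parametrize(
    "a,b,expect",
    [
        (Peak("c", 100, 200), Peak("c", 100, 200), (1.0, 1.0)),
        (Peak("c", 100, 200), Peak("c", 150, 260), (0.50, 50 / 110)),
        (Peak("c", 0, 100), Peak("c", 95, 300), (0.05, 5 / 205)),
        (Peak("c", 0, 100), Peak("d", 0, 100), (0.0, 0.0)),
        (Peak("c", 0, 100), Peak("c", 100, 200), (0.0, 0.0)),  # abutting
    ],
)
def test_overlap_fraction(a, b, expect):
    fa, fb = overlap_fraction(a, b)
    assert fa == pytest.approx(expect[0])
    assert fb == pytest.approx(expect[1])


@given(
    st.integers(0, 900), st.integers(1, 100),
    st.integers(0, 900), st.integers(1, 100),
)
@settings(max_examples=200, deadline=None)
def test_overlap_fraction_symmetry(sa, wa, sb, wb):
    a, b = Peak("c", sa, sa + wa), Peak("c", sb, sb + wb)
    assert overlap_fraction(a, b) == overlap_fraction(b, a)[::-1]


def test_peaks_overlap_modes():
    t = OverlapConfig(threshold=0.25)
    a, b = Peak("c", 100, 200), Peak("c", 150, 260)
    for mode in ("reciprocal", "query_fraction", "reference_fraction"):
        assert peaks_overlap(a, a, OverlapConfig(mode=mode))
        assert not peaks_overlap(
            Peak("c", 0, 100), Peak("c", 95, 300), OverlapConfig(mode=mode)
        )
    assert peaks_overlap(a, b, t)  # 0.50 and 0.4545 both >= 0.25
    # exact-threshold inclusivity: shared span exactly 25% of both
    a, b = Peak("c", 0, 100), Peak("c", 75, 175)
    assert peaks_overlap(a, b, OverlapConfig(threshold=0.25))
    # asymmetry of one-sided mode on width-unequal peaks
    small, big = Peak("c", 100, 200), Peak("c", 0, 1000)
    one_sided = OverlapConfig(mode="query_fraction", threshold=0.25)
    assert peaks_overlap(small, big, one_sided)
    assert not peaks_overlap(big, small, one_sided)
    # reciprocal is symmetric there
    rec = OverlapConfig(mode="reciprocal", threshold=0.25)
    assert peaks_overlap(small, big, rec) == peaks_overlap(big, small, rec)


def brute_force_counts(query, reference, cfg):
    """O(n*m) oracle for count_overlapped."""
    q = list(query)
    r = list(reference)
    pairs = [(i, j) for i, a in enumerate(q) for j, b in enumerate(r)
             if peaks_overlap(a, b, cfg)]
    return (
        len({i for i, _ in pairs}),
        len({j for _, j in pairs}),
        len(pairs),
    )


def test_count_overlapped_identity_and_disjoint(toy_genome):
    ps = PeakSet("q", toy_genome, [Peak("chrA", 10, 60), Peak("chrB", 0, 30)])
    res = count_overlapped(ps, ps)
    assert res.n_query_overlapped == len(ps)
    other = PeakSet("r", toy_genome, [Peak("chrB", 100, 130)])
    only_a = PeakSet("q", toy_genome, [Peak("chrA", 10, 60)])
    assert count_overlapped(only_a, other).n_query_overlapped == 0


def test_count_overlapped_mismatched_genomes(toy_genome):
    other_genome = GenomeModel([("chrA", 10_000)])
    a = PeakSet("a", toy_genome, [Peak("chrA", 0, 10)])
    b = PeakSet("b", other_genome, [Peak("chrA", 0, 10)])
    with pytest.raises(ValueError):
        count_overlapped(a, b)


@pytest.mark.parametrize("mode", ["reciprocal", "query_fraction", "reference_fraction"])
@pytest.mark.parametrize("threshold", [0.1, 0.25, 0.5, 1.0])
def test_count_overlapped_matches_brute_force(toy_genome, mode, threshold):
    """Sweep result equals the all-pairs brute force across random instances."""
    rng = np.random.default_rng(42)
    cfg = OverlapConfig(mode=mode, threshold=threshold)
    for _ in range(40):
        q = random_peakset(toy_genome, int(rng.integers(0, 51)), rng)
        r = random_peakset(toy_genome, int(rng.integers(0, 51)), rng)
        res = count_overlapped(q, r, cfg)
        assert (
            res.n_query_overlapped,
            res.n_reference_overlapped,
            res.n_pairs,
        ) == brute_force_counts(q, r, cfg)


def test_count_monotone_in_threshold(toy_genome):
    """Lowering the threshold never decreases any count."""
    rng = np.random.default_rng(7)
    q = random_peakset(toy_genome, 40, rng)
    r = random_peakset(toy_genome, 40, rng)
    prev = None
    for t in (1.0, 0.75, 0.5, 0.25, 0.1, 0.01):
        res = count_overlapped(q, r, OverlapConfig(threshold=t))
        cur = (res.n_query_overlapped, res.n_reference_overlapped, res.n_pairs)
        if prev is not None:
            assert all(c >= p for c, p in zip(cur, prev))
        prev = cur


def test_matched_indices_are_global(toy_genome):
    q = PeakSet("q", toy_genome, [Peak("chrA", 0, 100), Peak("chrB", 0, 100)])
    r = PeakSet("r", toy_genome, [Peak("chrA", 500, 600), Peak("chrB", 10, 110)])
    res = count_overlapped(q, r)
    assert res.matched == [[], [1]]


# ------------------------------------------------------------------ distances


def test_nearest_distances_examples(toy_genome):
    q = PeakSet("q", toy_genome, [Peak("chrA", 100, 200)])  # mid 150
    r = PeakSet("r", toy_genome, [Peak("chrA", 0, 100), Peak("chrA", 450, 550)])
    res = nearest_distances(q, r)
    rec = res.records[0]
    assert rec.signed_distance == -100  # nearest mid 50
    assert rec.nearest_reference_index == 0
    # coincident midpoints
    res = nearest_distances(q, q)
    assert res.records[0].signed_distance == 0
    # no same-chromosome reference -> omitted and counted
    r_b = PeakSet("r", toy_genome, [Peak("chrB", 0, 100)])
    res = nearest_distances(q, r_b)
    assert res.records == [] and res.n_omitted == 1


def test_nearest_distance_tie_breaks_to_smaller_start(toy_genome):
    # mids 50 and 250, query mid 150: tie -> reference with smaller start
    q = PeakSet("q", toy_genome, [Peak("chrA", 100, 200)])
    r = PeakSet("r", toy_genome, [Peak("chrA", 0, 100), Peak("chrA", 200, 300)])
    rec = nearest_distances(q, r).records[0]
    assert rec.nearest_reference_index == 0 and rec.signed_distance == -100
    # equidistant but the RIGHT midpoint's peak has the smaller start
    r = PeakSet("r", toy_genome, [Peak("chrA", 139, 141), Peak("chrA", 130, 190)])
    # mids: 140 (start 139) and 160 (start 130); query mid 150 -> tie
    rec = nearest_distances(q, r).records[0]
    assert rec.signed_distance == 10
    assert r[rec.nearest_reference_index].start == 130


def test_nearest_distances_brute_force(toy_genome):
    """Minimal |midpoint distance| against an exhaustive scan."""
    rng = np.random.default_rng(11)
    for _ in range(30):
        q = random_peakset(toy_genome, int(rng.integers(1, 20)), rng)
        r = random_peakset(toy_genome, int(rng.integers(1, 20)), rng)
        res = nearest_distances(q, r)
        r_list = list(r)
        k = 0
        for i, qp in enumerate(q):
            same = [(j, rp) for j, rp in enumerate(r_list) if rp.chrom == qp.chrom]
            if not same:
                continue
            best = min(abs(rp.midpoint - qp.midpoint) for _, rp in same)
            rec = res.records[k]
            assert rec.query_index == i
            assert abs(rec.signed_distance) == best
            k += 1
        assert k == len(res.records)
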