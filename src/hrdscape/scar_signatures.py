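"""Genomic scar scores: LOH, LST, TAI and their unweighted sum (HRD score).

The three scar counts quantify structural footprints of homologous
recombination deficiency on an allele-specific copy-number (ASCN) profile:

* LOH  — loss-of-heterozygosity regions larger than 15 Mb that do not cover
  a whole chromosome;
* LST  — large-scale state transitions: chromosomal breaks between adjacent
  regions of at least 10 Mb after removing interstitial segments shorter
  than 3 Mb, evaluated per chromosome arm;
* TAI  — allelic-imbalance regions that reach a telomere without crossing
  the centromere and without spanning the whole chromosome.

HRD score = LOH + LST + TAI (unweighted, linear sum).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .reference_io import ASCNSegment, GenomeBuild, sort_segments

__all__ = [
    "ScarParams",
    "ScarScores",
    "count_loh",
    "count_lst",
    "count_tai",
    "smooth_segments",
    "score_sample",
    "score_cohort",
]


@dataclass(frozen=True)
class ScarParams:
    """Size thresholds of the scar definitions, in base pairs."""

    loh_min_len: int = 15_000_000
    lst_min_segment: int = 10_000_000
    lst_smooth_len: int = 3_000_000
    tai_min_len: int = 0

    def __post_init__(self) -> None:
        if min(self.loh_min_len, self.lst_min_segment,
               self.lst_smooth_len, self.tai_min_len) < 0:
            raise ValueError("scar thresholds must be non-negative")
        if self.lst_smooth_len >= self.lst_min_segment:
            raise ValueError("lst_smooth_len must be below lst_min_segment")


@dataclass(frozen=True)
class ScarScores:
    sample: str
    loh: int
    lst: int
    tai: int
    hrd: int

    def __post_init__(self) -> None:
        if min(self.loh, self.lst, self.tai) < 0:
            raise ValueError("scar counts must be non-negative")
        if self.hrd != self.loh + self.lst + self.tai:
            raise ValueError("hrd must equal loh + lst + tai")


def _per_chrom(segments: Iterable[ASCNSegment]) -> dict[str, list[ASCNSegment]]:
    samples = {s.sample for s in segments}
    if len(samples) > 1:
        raise ValueError(f"profile mixes samples: {sorted(samples)}")
    out: dict[str, list[ASCNSegment]] = {}
    for seg in sort_segments(segments):
        out.setdefault(seg.chrom, []).append(seg)
    return out


def _merge_runs(segs: Sequence[ASCNSegment], member) -> list[tuple[int, int]]:
    """Maximal runs of abutting segments satisfying ``member``.

    A run breaks at any coverage gap or at a non-member segment.
    """
    runs: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = None
    prev_end: int | None = None
    for seg in segs:
        contiguous = prev_end is not None and seg.start == prev_end + 1
        if member(seg):
            if cur is not None and contiguous:
                cur = (cur[0], seg.end)
            else:
                if cur is not None:
                    runs.append(cur)
                cur = (seg.start, seg.end)
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
        prev_end = seg.end
    if cur is not None:
        runs.append(cur)
    return runs


def count_loh(
    segments: Iterable[ASCNSegment],
    genome: GenomeBuild,
    params: ScarParams = ScarParams(),
) -> int:
    """LOH regions larger than ``loh_min_len`` not covering a whole chromosome.

    Homozygous deletions (0, 0) carry no allele signal and break LOH runs.
    """
    n = 0
    for chrom, segs in _per_chrom(segments).items():
        chrom_len = genome.chrom_length(chrom)
        runs = _merge_runs(
            segs, lambda s: s.n_minor == 0 and s.n_major >= 1
        )
        for start, end in runs:
            if end - start + 1 <= params.loh_min_len:
                continue
            if start == 1 and end == chrom_len:
                continue  # whole-chromosome LOH is excluded
            n += 1
    return n


def smooth_segments(
    segments: Iterable[ASCNSegment], min_len: int
) -> list[ASCNSegment]:
    """Remove segments shorter than ``min_len``, conserving covered span.

    The removed segment's span is split at its midpoint between its two
    neighbours (at a boundary the single neighbour absorbs it); abutting
    neighbours that then share an identical allele state merge.  Iterates
    until every remaining segment is at least ``min_len`` long.
    """
    out: list[ASCNSegment] = []
    for chrom, segs in _per_chrom(segments).items():
        sample = segs[0].sample
        # smoothing redistributes spans between abutting segments only, so
        # it runs per contiguous block; coverage gaps are never filled
        block: list[ASCNSegment] = []
        for seg in segs:
            if block and seg.start != block[-1].end + 1:
                out.extend(_smooth_block(block, min_len, sample, chrom))
                block = []
            block.append(seg)
        if block:
            out.extend(_smooth_block(block, min_len, sample, chrom))
    return sort_segments(out)


def _smooth_block(
    block: Sequence[ASCNSegment], min_len: int, sample: str, chrom: str
) -> list[ASCNSegment]:
    rows = [[s.start, s.end, s.n_major, s.n_minor] for s in block]
    while True:
        _coalesce(rows)
        short = [
            (e - s + 1, i) for i, (s, e, *_rest) in enumerate(rows)
            if e - s + 1 < min_len
        ]
        if not short:
            break
        _, i = min(short)
        s, e, *_rest = rows[i]
        if len(rows) == 1:
            break  # lone short segment: nothing to absorb it
        if i == 0:
            rows[1][0] = s
        elif i == len(rows) - 1:
            rows[i - 1][1] = e
        else:
            mid = (s + e) // 2
            rows[i - 1][1] = mid
            rows[i + 1][0] = mid + 1
        del rows[i]
    return [
        ASCNSegment(sample, chrom, s, e, nmaj, nmin)
        for s, e, nmaj, nmin in rows
    ]


def _coalesce(rows: list[list[int]]) -> None:
    """Merge abutting rows with identical allele state, in place."""
    i = 0
    while i + 1 < len(rows):
        a, b = rows[i], rows[i + 1]
        if b[0] == a[1] + 1 and a[2:] == b[2:]:
            a[1] = b[1]
            del rows[i + 1]
        else:
            i += 1


def _split_at_arm(
    segs: Sequence[ASCNSegment], boundary: int
) -> tuple[list[ASCNSegment], list[ASCNSegment]]:
    p, q = [], []
    for seg in segs:
        if seg.end <= boundary:
            p.append(seg)
        elif seg.start > boundary:
            q.append(seg)
        else:
            p.append(replace(seg, end=boundary))
            q.append(replace(seg, start=boundary + 1))
    return p, q


def count_lst(
    segments: Iterable[ASCNSegment],
    genome: GenomeBuild,
    params: ScarParams = ScarParams(),
) -> int:
    """Breaks between adjacent >= ``lst_min_segment`` regions within an arm.

    Segments are split at the centromere midpoint, smoothed with
    ``lst_smooth_len``, and a transition counts when the two flanking
    segments differ in allele state, both reach ``lst_min_segment``, and the
    coverage gap between them is at most ``lst_smooth_len``.
    """
    n = 0
    for chrom, segs in _per_chrom(segments).items():
        for arm in _split_at_arm(segs, genome.arm_boundary(chrom)):
            if not arm:
                continue
            smoothed = smooth_segments(arm, params.lst_smooth_len)
            for a, b in zip(smoothed, smoothed[1:]):
                if a.state == b.state:
                    continue
                if a.length < params.lst_min_segment:
                    continue
                if b.length < params.lst_min_segment:
                    continue
                if b.start - a.end - 1 > params.lst_smooth_len:
                    continue
                n += 1
    return n


def count_tai(
    segments: Iterable[ASCNSegment],
    genome: GenomeBuild,
    params: ScarParams = ScarParams(),
) -> int:
    """Allelic-imbalance runs that reach a telomere.

    A run (maximal stretch of abutting segments with ``n_major != n_minor``)
    counts when it touches the first or last base of its chromosome, does
    not extend across the centromere, does not span the whole chromosome,
    and is longer than ``tai_min_len``.
    """
    n = 0
    for chrom, segs in _per_chrom(segments).items():
        chrom_len = genome.chrom_length(chrom)
        cen_start, cen_end = genome.centromere(chrom)
        runs = _merge_runs(segs, lambda s: s.n_major != s.n_minor)
        for start, end in runs:
            if start != 1 and end != chrom_len:
                continue  # does not reach a telomere
            if start == 1 and end == chrom_len:
                continue  # whole chromosome
            if start < cen_start and end > cen_end:
                continue  # crosses the centromere
            if end - start + 1 <= params.tai_min_len:
                continue
            n += 1
    return n


def score_sample(
    segments: Iterable[ASCNSegment],
    genome: GenomeBuild,
    params: ScarParams = ScarParams(),
) -> ScarScores:
    """LOH, LST, TAI and HRD score of a single-sample ASCN profile."""
    segments = list(segments)
    if not segments:
        raise ValueError("empty profile")
    sample = segments[0].sample
    loh = count_loh(segments, genome, params)
    lst = count_lst(segments, genome, params)
    tai = count_tai(segments, genome, params)
    return ScarScores(sample, loh, lst, tai, loh + lst + tai)


def score_cohort(
    segments: Iterable[ASCNSegment],
    genome: GenomeBuild,
    params: ScarParams = ScarParams(),
) -> pd.DataFrame:
    """Score every sample in a multi-sample segment collection."""
    by_sample: dict[str, list[ASCNSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)
    rows = [
        score_sample(segs, genome, params).__dict__
        for _, segs in sorted(by_sample.items())
    ]
    return pd.DataFrame(rows, columns=["sample", "loh", "lst", "tai", "hrd"])
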