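"""Independent brute-force re-implementations of the scoring rules.

Everything here paints segments onto per-base arrays and applies each
textual rule literally; nothing is shared with the package's fast
implementations.  Only usable on tiny genomes (the mini fixture).
"""

from __future__ import annotations

import numpy as np


def _paint(segments, length):
    maj = np.full(length + 1, -1, dtype=int)  # index 0 unused (1-based)
    mnr = np.full(length + 1, -1, dtype=int)
    for s in segments:
        maj[s.start : s.end + 1] = s.n_major
        mnr[s.start : s.end + 1] = s.n_minor
    return maj, mnr


def _runs(mask):
    """Maximal runs of True as (start, end), 1-based inclusive."""
    out = []
    start = None
    for i in range(1, mask.size):
        if mask[i] and start is None:
            start = i
        elif not mask[i] and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, mask.size - 1))
    return out


def oracle_loh(segments, genome, params):
    n = 0
    for chrom, length in genome.chromosomes:
        on = [s for s in segments if s.chrom == chrom]
        maj, mnr = _paint(on, length)
        mask = (mnr == 0) & (maj >= 1)
        mask[0] = False
        for start, end in _runs(mask):
            if end - start + 1 > params.loh_min_len and not (
                start == 1 and end == length
            ):
                n += 1
    return n


def oracle_tai(segments, genome, params):
    n = 0
    for chrom, length in genome.chromosomes:
        on = [s for s in segments if s.chrom == chrom]
        maj, mnr = _paint(on, length)
        cs, ce = genome.centromere(chrom)
        mask = (maj >= 0) & (maj != mnr)
        mask[0] = False
        for start, end in _runs(mask):
            touches = start == 1 or end == length
            whole = start == 1 and end == length
            crosses = start < cs and end > ce
            if touches and not whole and not crosses and (
                end - start + 1 > params.tai_min_len
            ):
                n += 1
    return n


def _state_runs(states):
    """Maximal covered same-state runs as (start, end, state)."""
    out = []
    start = None
    prev = None
    for i in range(1, len(states)):
        s = states[i]
        if s is None:
            if start is not None:
                out.append((start, i - 1, prev))
                start = None
            prev = None
        elif s != prev:
            if start is not None:
                out.append((start, i - 1, prev))
            start, prev = i, s
    if start is not None:
        out.append((start, len(states) - 1, prev))
    return out


def oracle_lst(segments, genome, params):
    n = 0
    for chrom, length in genome.chromosomes:
        on = [s for s in segments if s.chrom == chrom]
        maj, mnr = _paint(on, length)
        cs, ce = genome.centromere(chrom)
        mid = (cs + ce) // 2
        for lo, hi in ((1, mid), (mid + 1, length)):
            states = [None] * (length + 1)
            for i in range(lo, hi + 1):
                if maj[i] >= 0:
                    states[i] = (maj[i], mnr[i])
            # smoothing: repeatedly drop the shortest (< floor) run that has
            # an abutting neighbour, splitting its bases at the midpoint
            while True:
                runs = _state_runs(states)
                removable = []
                for idx, (s, e, _st) in enumerate(runs):
                    if e - s + 1 >= params.lst_smooth_len:
                        continue
                    left = idx > 0 and runs[idx - 1][1] == s - 1
                    right = idx < len(runs) - 1 and runs[idx + 1][0] == e + 1
                    if left or right:
                        removable.append((e - s + 1, s, idx, left, right))
                if not removable:
                    break
                _len, _s, idx, left, right = min(removable)
                s, e, _st = runs[idx]
                m = (s + e) // 2
                for i in range(s, e + 1):
                    if left and right:
                        states[i] = runs[idx - 1][2] if i <= m else runs[idx + 1][2]
                    elif left:
                        states[i] = runs[idx - 1][2]
                    else:
                        states[i] = runs[idx + 1][2]
            runs = _state_runs(states)
            for (s1, e1, st1), (s2, e2, st2) in zip(runs, runs[1:]):
                if (
                    st1 != st2
                    and e1 - s1 + 1 >= params.lst_min_segment
                    and e2 - s2 + 1 >= params.lst_min_segment
                    and s2 - e1 - 1 <= params.lst_smooth_len
                ):
                    n += 1
    return n


def oracle_aneuploidy(segments, genome, frac=0.9):
    n = 0
    for chrom, length in genome.chromosomes:
        on = [s for s in segments if s.chrom == chrom]
        maj, mnr = _paint(on, length)
        total = maj + mnr
        covered = maj >= 0
        gained = float(((total > 2) & covered)[1:].sum()) / length
        lost = float(((total < 2) & covered)[1:].sum()) / length
        if gained > frac or lost > frac:
            n += 1
    return n


def oracle_interval_hits(classified, intervals):
    """Per-interval (gains, losses) via per-base painting."""
    out = []
    for chrom, lo, hi in intervals:
        gains = losses = 0
        for c in classified:
            if c.chrom != chrom or c.call == "neutral":
                continue
            if any(lo <= b <= hi for b in range(c.start, c.end + 1)):
                if c.call == "gain":
                    gains += 1
                else:
                    losses += 1
        out.append((gains, losses))
    return out
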