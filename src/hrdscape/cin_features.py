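"""Chromosomal-instability (CIN) features from copy-number segments.

Gain/loss calls come either from allele-specific total copy number
(gain iff total > 2, loss iff total < 2) or from log2 copy ratios
(gain iff L2R > 0.1, loss iff L2R < -0.1, with high-level amplification at
> 0.7 and deep deletion at < -0.7).  Derived features: per-chromosome
gain/loss counts, fraction of genome altered, aneuploidy events
(chromosomes > 90% gained or lost), per-cytoband alteration counts, and the
HRR-CIN score (gain/loss events hitting a catalog of HRR pathway genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .reference_io import (
    ASCNSegment,
    GeneLocus,
    GenomeBuild,
    L2RSegment,
    sort_segments,
)

__all__ = [
    "CINParams",
    "ClassifiedSegment",
    "CINProfile",
    "classify_segments",
    "merge_call_runs",
    "chromosome_cin",
    "fraction_genome_altered",
    "aneuploidy_events",
    "cytoband_cin",
    "hrr_cin_score",
    "cin_profile",
]


@dataclass(frozen=True)
class CINParams:
    """Thresholds of the gain/loss calling rules (all strict inequalities)."""

    ascn_neutral_cn: int = 2
    l2r_gain: float = 0.1
    l2r_loss: float = -0.1
    l2r_amp: float = 0.7
    l2r_deepdel: float = -0.7
    aneuploidy_frac: float = 0.9

    def __post_init__(self) -> None:
        if not (self.l2r_loss < 0 < self.l2r_gain):
            raise ValueError("need l2r_loss < 0 < l2r_gain")
        if not (self.l2r_deepdel < self.l2r_loss and self.l2r_gain < self.l2r_amp):
            raise ValueError("high-level thresholds must lie beyond gain/loss")
        if not (0 < self.aneuploidy_frac <= 1):
            raise ValueError("aneuploidy_frac must be in (0, 1]")


@dataclass(frozen=True)
class ClassifiedSegment:
    segment: ASCNSegment | L2RSegment
    call: str  # gain | loss | neutral
    high_level: str = "none"  # amplification | deep_deletion | none

    def __post_init__(self) -> None:
        if self.call not in ("gain", "loss", "neutral"):
            raise ValueError(f"bad call {self.call!r}")
        if self.high_level == "amplification" and self.call != "gain":
            raise ValueError("amplification implies a gain call")
        if self.high_level == "deep_deletion" and self.call != "loss":
            raise ValueError("deep deletion implies a loss call")

    @property
    def chrom(self) -> str:
        return self.segment.chrom

    @property
    def start(self) -> int:
        return self.segment.start

    @property
    def end(self) -> int:
        return self.segment.end

    @property
    def length(self) -> int:
        return self.segment.length


def classify_segments(
    segments: Iterable[ASCNSegment] | Iterable[L2RSegment],
    params: CINParams = CINParams(),
) -> list[ClassifiedSegment]:
    """Call each segment gain/loss/neutral; mode inferred from segment type."""
    segments = list(segments)
    kinds = {type(s) for s in segments}
    if len(kinds) > 1:
        raise ValueError("mixed ASCN and L2R segments in one call")
    out = []
    for seg in segments:
        if isinstance(seg, ASCNSegment):
            if seg.total > params.ascn_neutral_cn:
                call, high = "gain", "none"
            elif seg.total < params.ascn_neutral_cn:
                call, high = "loss", "none"
            else:
                call, high = "neutral", "none"
        elif isinstance(seg, L2RSegment):
            if seg.l2r > params.l2r_gain:
                call = "gain"
                high = "amplification" if seg.l2r > params.l2r_amp else "none"
            elif seg.l2r < params.l2r_loss:
                call = "loss"
                high = "deep_deletion" if seg.l2r < params.l2r_deepdel else "none"
            else:
                call, high = "neutral", "none"
        else:
            raise TypeError(f"unsupported segment type {type(seg)}")
        out.append(ClassifiedSegment(seg, call, high))
    return out


def merge_call_runs(classified: Sequence[ClassifiedSegment]) -> list[ClassifiedSegment]:
    """Merge abutting same-call segments of one sample into single runs.

    Removes segmentation-granularity sensitivity from segment-count
    features; merged runs keep a high-level flag only when all members
    agree.
    """
    ordered = sorted(
        classified, key=lambda c: (c.segment.sample, c.chrom, c.start)
    )
    out: list[ClassifiedSegment] = []
    for c in ordered:
        if out:
            prev = out[-1]
            if (
                prev.segment.sample == c.segment.sample
                and prev.chrom == c.chrom
                and prev.call == c.call
                and c.start == prev.end + 1
            ):
                seg = prev.segment
                if isinstance(seg, L2RSegment):
                    merged = L2RSegment(seg.sample, seg.chrom, seg.start,
                                        c.end, seg.l2r)
                else:
                    merged = ASCNSegment(seg.sample, seg.chrom, seg.start,
                                         c.end, seg.n_major, seg.n_minor)
                high = prev.high_level if prev.high_level == c.high_level else "none"
                out[-1] = ClassifiedSegment(merged, prev.call, high)
                continue
        out.append(c)
    return out


def chromosome_cin(
    classified: Sequence[ClassifiedSegment],
    genome: GenomeBuild,
    merge_runs: bool = True,
) -> pd.DataFrame:
    """Per-chromosome (gains, losses, total) segment counts.

    With ``merge_runs`` (the default) abutting same-call segments count
    once; the raw segment-count semantics is available with
    ``merge_runs=False``.
    """
    if merge_runs:
        classified = merge_call_runs(classified)
    counts = {c: [0, 0] for c in genome.chrom_names}
    for c in classified:
        if c.chrom not in counts:
            continue
        if c.call == "gain":
            counts[c.chrom][0] += 1
        elif c.call == "loss":
            counts[c.chrom][1] += 1
    rows = [
        {"chrom": chrom, "gains": g, "losses": l, "total": g + l}
        for chrom, (g, l) in counts.items()
    ]
    return pd.DataFrame(rows)


def _altered_lengths(
    classified: Sequence[ClassifiedSegment], genome: GenomeBuild
) -> dict[str, list[int]]:
    """Per-chromosome [gained bp, lost bp]; uncovered genome is neutral."""
    acc = {c: [0, 0] for c in genome.chrom_names}
    for c in classified:
        if c.chrom not in acc:
            continue
        if c.call == "gain":
            acc[c.chrom][0] += c.length
        elif c.call == "loss":
            acc[c.chrom][1] += c.length
    return acc


def fraction_genome_altered(
    classified: Sequence[ClassifiedSegment], genome: GenomeBuild
) -> tuple[float, float, float, pd.DataFrame]:
    """(fga_gain, fga_loss, fga_total) plus per-chromosome altered fractions."""
    acc = _altered_lengths(classified, genome)
    total_len = genome.total_length
    gain_bp = sum(v[0] for v in acc.values())
    loss_bp = sum(v[1] for v in acc.values())
    per_chrom = pd.DataFrame(
        [
            {
                "chrom": chrom,
                "frac_gain": g / genome.chrom_length(chrom),
                "frac_loss": l / genome.chrom_length(chrom),
                "frac_altered": (g + l) / genome.chrom_length(chrom),
            }
            for chrom, (g, l) in acc.items()
        ]
    )
    return gain_bp / total_len, loss_bp / total_len, (gain_bp + loss_bp) / total_len, per_chrom


def aneuploidy_events(
    classified: Sequence[ClassifiedSegment],
    genome: GenomeBuild,
    params: CINParams = CINParams(),
) -> tuple[int, pd.DataFrame]:
    """Chromosomes whose gained or lost fraction exceeds ``aneuploidy_frac``."""
    acc = _altered_lengths(classified, genome)
    rows = []
    for chrom, (g, l) in acc.items():
        length = genome.chrom_length(chrom)
        flagged = g / length > params.aneuploidy_frac or l / length > params.aneuploidy_frac
        rows.append({"chrom": chrom, "aneuploid": flagged})
    df = pd.DataFrame(rows)
    return int(df["aneuploid"].sum()), df


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    # 1-based inclusive intervals; >= 1 bp shared
    return a_start <= b_end and b_start <= a_end


def cytoband_cin(
    classified: Sequence[ClassifiedSegment], genome: GenomeBuild
) -> pd.DataFrame:
    """Gain/loss segment counts per cytoband (>= 1 bp overlap)."""
    rows = []
    for chrom in genome.chrom_names:
        on_chrom = [c for c in classified if c.chrom == chrom and c.call != "neutral"]
        for band, bs, be in genome.cytobands[chrom]:
            gains = sum(
                1 for c in on_chrom
                if c.call == "gain" and _overlaps(c.start, c.end, bs, be)
            )
            losses = sum(
                1 for c in on_chrom
                if c.call == "loss" and _overlaps(c.start, c.end, bs, be)
            )
            rows.append(
                {"chrom": chrom, "band": band, "start": bs, "end": be,
                 "gains": gains, "losses": losses, "total": gains + losses}
            )
    return pd.DataFrame(rows)


def hrr_cin_score(
    classified: Sequence[ClassifiedSegment],
    catalog: Sequence[GeneLocus],
) -> int:
    """CIN restricted to the HRR gene catalog.

    Each gene contributes 1 if any gain segment overlaps its locus and 1 if
    any loss segment overlaps it, so the score is bounded by twice the
    catalog size.
    """
    if not catalog:
        raise ValueError("empty HRR catalog")
    score = 0
    for gene in catalog:
        hit_gain = any(
            c.call == "gain" and c.chrom == gene.chrom
            and _overlaps(c.start, c.end, gene.start, gene.end)
            for c in classified
        )
        hit_loss = any(
            c.call == "loss" and c.chrom == gene.chrom
            and _overlaps(c.start, c.end, gene.start, gene.end)
            for c in classified
        )
        score += int(hit_gain) + int(hit_loss)
    return score


@dataclass
class CINProfile:
    """All CIN features of one sample."""

    sample: str
    chrom_counts: pd.DataFrame
    fga_gain: float
    fga_loss: float
    fga_total: float
    per_chrom_fraction: pd.DataFrame
    aneuploidy_count: int
    aneuploidy_flags: pd.DataFrame
    cytoband_counts: pd.DataFrame
    hrr_cin: int | None = None

    def summary_row(self) -> dict:
        return {
            "sample": self.sample,
            "fga_gain": self.fga_gain,
            "fga_loss": self.fga_loss,
            "fga_total": self.fga_total,
            "aneuploidy": self.aneuploidy_count,
            "hrr_cin": self.hrr_cin,
        }


def cin_profile(
    segments: Iterable[ASCNSegment] | Iterable[L2RSegment],
    genome: GenomeBuild,
    params: CINParams = CINParams(),
    catalog: Sequence[GeneLocus] | None = None,
    merge_runs: bool = True,
) -> CINProfile:
    """Compute the full CIN feature set for a single-sample profile."""
    segments = sort_segments(segments)
    if not segments:
        raise ValueError("empty profile")
    samples = {s.sample for s in segments}
    if len(samples) > 1:
        raise ValueError(f"profile mixes samples: {sorted(samples)}")
    classified = classify_segments(segments, params)
    fga_gain, fga_loss, fga_total, per_chrom = fraction_genome_altered(
        classified, genome
    )
    aneu_count, aneu_flags = aneuploidy_events(classified, genome, params)
    return CINProfile(
        sample=segments[0].sample,
        chrom_counts=chromosome_cin(classified, genome, merge_runs=merge_runs),
        fga_gain=fga_gain,
        fga_loss=fga_loss,
        fga_total=fga_total,
        per_chrom_fraction=per_chrom,
        aneuploidy_count=aneu_count,
        aneuploidy_flags=aneu_flags,
        cytoband_counts=cytoband_cin(classified, genome),
        hrr_cin=hrr_cin_score(classified, catalog) if catalog else None,
    )
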