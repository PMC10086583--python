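"""Synthetic-data generators with explicit truth ledgers.

Every pipeline input can be generated at desk scale: allele-specific
copy-number profiles with implanted scar events (LOH blocks, large-scale
transitions, telomeric allelic imbalances, near-whole-chromosome gains), a
bimodal HRR-CIN cohort with group-shifted expression, and two-drug
dose-response matrices sampled under a chosen synergy reference model.

Scar events are packed so they cannot interfere: every implanted block is
at least 3 Mb (the LST smoothing floor leaves it untouched), events are
flanked by short (< 10 Mb) balanced buffer blocks so no unintended
large-segment transition arises, LOH and imbalance blocks stay clear of
telomeres and centromeres unless the event requires them, and events are
separated by >= 3 Mb of diploid heterozygous (1, 1) filler.  Implanted
counts are therefore exact by construction; infeasible requests raise
after a bounded number of randomized packing attempts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .drug_response import DoseMatrix, DoseResponseCurve, _loewe_cell, fourpl
from .reference_io import (
    ASCNSegment,
    ExpressionMatrix,
    GeneLocus,
    GenomeBuild,
    L2RSegment,
    hrr_gene_catalog,
    load_genome_build,
)

__all__ = [
    "ScarTruth",
    "simulate_profile",
    "simulate_cohort",
    "simulate_dose_matrix",
    "SARC_HRD_SHIFT",
]

MB = 1_000_000
_BUF = 3 * MB  # buffer / spacer floor: >= smoothing floor, < LST segment
_LOH_MIN = 16 * MB
_LST_BLOCK = 10 * MB
_TAI_MIN = 10 * MB

#: simulated log2 up-shift of the SARC-HRD genes in HRD-high samples
SARC_HRD_SHIFT = 1.0


@dataclass(frozen=True)
class ScarTruth:
    """Implanted per-sample ground truth."""

    sample: str
    group: str  # hrd_high | hrd_low
    loh_events: int
    lst_events: int
    tai_events: int
    aneuploid_chromosomes: int
    hrr_cin: int | None
    seed: int

    def __post_init__(self) -> None:
        if min(self.loh_events, self.lst_events, self.tai_events,
               self.aneuploid_chromosomes) < 0:
            raise ValueError("implanted counts must be non-negative")


# --- event layouts: lists of (length, n_major, n_minor) -------------------


def _unit_loh(rng, slack: int) -> tuple[list, int, int]:
    loh_len = _LOH_MIN + int(rng.integers(0, max(slack, 1)))
    blocks = [(_BUF, 3, 3), (loh_len, 1, 0), (_BUF, 3, 3)]
    return blocks, 1, 0


def _unit_combo(rng, k: int, slack: int) -> tuple[list, int, int]:
    # LOH block abutting k distinct >= 10 Mb balanced blocks -> k LSTs
    loh_len = _LOH_MIN + int(rng.integers(0, max(slack, 1)))
    blocks = [(_BUF, 3, 3)]
    if k == 2:
        blocks.append((_LST_BLOCK, 2, 2))
    blocks.append((loh_len, 1, 0))
    blocks.append((_LST_BLOCK, 2, 2))
    blocks.append((_BUF, 3, 3))
    return blocks, 1, k


def _unit_chain(rng, k: int, slack: int) -> tuple[list, int, int]:
    # k+1 alternating balanced blocks -> k LSTs
    states = [(2, 2), (4, 4)]
    blocks = [(_BUF, 3, 3)]
    extra = int(rng.integers(0, max(slack, 1)))
    for i in range(k + 1):
        blocks.append((_LST_BLOCK + (extra if i == 0 else 0), *states[i % 2]))
    blocks.append((_BUF, 3, 3))
    return blocks, 0, k


def _unit_size(blocks) -> int:
    return sum(b[0] for b in blocks)


@dataclass
class _Arm:
    chrom: str
    side: str  # p | q
    start: int  # usable interior start (1-based)
    end: int  # usable interior end
    tai: tuple[list, int] | None = None  # (blocks telomere-outward, span)
    units: list = None

    def __post_init__(self):
        self.units = []

    @property
    def free(self) -> int:
        used = sum(_unit_size(b) + _BUF for b in self.units)
        tai_span = self.tai[1] + _BUF if self.tai else 0
        return (self.end - self.start + 1) - used - tai_span


def _make_arms(genome: GenomeBuild, chroms: Sequence[str]) -> list[_Arm]:
    arms = []
    for chrom in chroms:
        cs, ce = genome.centromere(chrom)
        length = genome.chrom_length(chrom)
        p = _Arm(chrom, "p", 1, cs - 1)
        q = _Arm(chrom, "q", ce + 1, length)
        for arm in (p, q):
            if arm.end - arm.start + 1 >= _LST_BLOCK + 2 * _BUF:
                arms.append(arm)
    return arms


def _attempt_pack(
    rng, genome, chroms, n_loh, n_lst, n_tai, tight: bool
) -> list[_Arm] | None:
    arms = _make_arms(genome, chroms)
    arms = [arms[i] for i in rng.permutation(len(arms))]
    # telomere-anchored TAI events
    tai_arms = [a for a in arms if a.end - a.start + 1 >= _TAI_MIN + 3 * _BUF]
    if len(tai_arms) < n_tai:
        return None
    for arm in tai_arms[:n_tai]:
        t = _TAI_MIN if tight else _TAI_MIN + int(
            rng.integers(0, max((arm.end - arm.start + 1) // 4, 1))
        )
        t = min(t, arm.end - arm.start + 1 - 3 * _BUF)
        arm.tai = ([(t, 2, 1), (_BUF, 2, 2)], t + _BUF)
    # interior units: combined LOH+LST events, LST chains, lone LOH blocks
    units = []
    loh, lst = n_loh, n_lst
    slack = 0 if tight else 8 * MB
    while loh > 0:
        k = min(lst, int(rng.integers(0, 3)))
        units.append(
            _unit_combo(rng, k, slack) if k else _unit_loh(rng, slack)
        )
        loh -= 1
        lst -= k
    while lst > 0:
        k = min(lst, 1 + int(rng.integers(0, 3)))
        units.append(_unit_chain(rng, k, slack))
        lst -= k
    # first-fit decreasing
    for blocks, u_loh, u_lst in sorted(
        units, key=lambda u: -_unit_size(u[0])
    ):
        size = _unit_size(blocks)
        home = next((a for a in arms if a.free >= size + _BUF), None)
        if home is None:
            return None
        home.units.append(blocks)
    return arms


def _materialize(
    sample: str, genome: GenomeBuild, arms: list[_Arm],
    aneuploid: Sequence[str],
) -> list[ASCNSegment]:
    """Lay out packed arms into a fully covered, abutting segment profile."""
    pieces: dict[str, list[tuple[int, int, int, int]]] = {
        c: [] for c in genome.chrom_names
    }
    for chrom in aneuploid:
        length = genome.chrom_length(chrom)
        gain_end = length - 7 * MB
        pieces[chrom] += [
            (1, gain_end, 2, 2),
            (gain_end + 1, gain_end + 4 * MB, 3, 3),
            (gain_end + 4 * MB + 1, length, 1, 1),
        ]
    for arm in arms:
        if arm.tai is not None:
            blocks, span = arm.tai
            if arm.side == "p":
                pos = 1
                for length, nmaj, nmin in blocks:
                    pieces[arm.chrom].append((pos, pos + length - 1, nmaj, nmin))
                    pos += length
            else:
                pos = arm.end  # q-arm telomere is the chromosome end
                for length, nmaj, nmin in blocks:
                    pieces[arm.chrom].append((pos - length + 1, pos, nmaj, nmin))
                    pos -= length
        # interior units grow rightwards, after the TAI reservation on p arms
        cursor = arm.start
        if arm.tai is not None and arm.side == "p":
            cursor = arm.tai[1] + 1
        for blocks in arm.units:
            cursor += _BUF  # (1, 1) filler spacer before each unit
            for length, nmaj, nmin in blocks:
                pieces[arm.chrom].append((cursor, cursor + length - 1, nmaj, nmin))
                cursor += length
    # fill the remainder of every chromosome with diploid heterozygous (1,1)
    segments: list[ASCNSegment] = []
    for chrom in genome.chrom_names:
        length = genome.chrom_length(chrom)
        placed = sorted(pieces[chrom])
        cursor = 1
        rows = []
        for s, e, nmaj, nmin in placed:
            if s > cursor:
                rows.append((cursor, s - 1, 1, 1))
            rows.append((s, e, nmaj, nmin))
            cursor = e + 1
        if cursor <= length:
            rows.append((cursor, length, 1, 1))
        for s, e, nmaj, nmin in rows:
            segments.append(ASCNSegment(sample, chrom, s, e, nmaj, nmin))
    return segments


def simulate_profile(
    genome: GenomeBuild,
    loh_events: int = 0,
    lst_events: int = 0,
    tai_events: int = 0,
    aneuploid_chromosomes: int = 0,
    sample: str = "S1",
    seed: int = 0,
    group: str = "hrd_high",
    max_attempts: int = 1000,
) -> tuple[list[ASCNSegment], ScarTruth]:
    """ASCN profile with exactly the requested scar event counts.

    Starts from a diploid heterozygous genome and implants non-interfering
    events; raises when the request cannot be packed on the genome.
    """
    rng = np.random.default_rng(seed)
    chrom_names = list(genome.chrom_names)
    if aneuploid_chromosomes > len(chrom_names):
        raise ValueError("more aneuploid chromosomes requested than exist")
    for attempt in range(max_attempts):
        tight = attempt >= max_attempts // 2
        aneuploid = list(
            rng.choice(chrom_names, size=aneuploid_chromosomes, replace=False)
        )
        rest = [c for c in chrom_names if c not in aneuploid]
        arms = _attempt_pack(
            rng, genome, rest, loh_events, lst_events, tai_events, tight
        )
        if arms is not None:
            truth = ScarTruth(
                sample, group, loh_events, lst_events, tai_events,
                aneuploid_chromosomes, None, seed,
            )
            return _materialize(sample, genome, arms, aneuploid), truth
    raise ValueError(
        f"could not pack ({loh_events} LOH, {lst_events} LST, "
        f"{tai_events} TAI, {aneuploid_chromosomes} aneuploid) "
        f"on genome {genome.name!r}"
    )


# --- cohort ---------------------------------------------------------------


def _hrr_cin_segments(
    rng, sample: str, catalog: Sequence[GeneLocus], target: int
) -> list[L2RSegment]:
    """Gene-level L2R segments realising an exact HRR-CIN score.

    Draws ``target`` distinct (gene, class) events; a gene hit by both a
    gain and a loss gets its locus split in half so segments stay disjoint.
    """
    target = int(min(target, 2 * len(catalog)))
    events = rng.choice(2 * len(catalog), size=target, replace=False)
    by_gene: dict[int, set[str]] = {}
    for ev in events:
        by_gene.setdefault(int(ev) // 2, set()).add(
            "gain" if ev % 2 == 0 else "loss"
        )
    segs = []
    for gi, classes in sorted(by_gene.items()):
        g = catalog[gi]
        l2r = {"gain": 0.5, "loss": -0.5}
        if len(classes) == 1:
            cls = next(iter(classes))
            segs.append(L2RSegment(sample, g.chrom, g.start, g.end, l2r[cls]))
        else:
            mid = (g.start + g.end) // 2
            segs.append(L2RSegment(sample, g.chrom, g.start, mid, l2r["gain"]))
            segs.append(L2RSegment(sample, g.chrom, mid + 1, g.end, l2r["loss"]))
    return segs


def simulate_cohort(
    n_high: int,
    n_low: int,
    genome: GenomeBuild | None = None,
    seed: int = 0,
    n_background_genes: int = 190,
) -> dict:
    """Bimodal cohort: scar profiles, HRR-gene CN, expression, truth ledger.

    HRD-high samples draw HRR-CIN ~ round(N(50, 8)) and heavy scar loads;
    HRD-low samples draw HRR-CIN ~ round(N(8, 3)) and light loads.  The
    expression matrix carries a +1 log2 shift of the 10 SARC-HRD genes in
    the high group over a log-normal baseline (per-gene log2 means
    U(3, 10), within-gene SD 0.5).

    Returns a dict with ``segments`` (ASCN, all samples), ``gene_cn``
    (L2R segments over the 70-gene catalog), ``expression``
    (ExpressionMatrix), ``truth`` (DataFrame) and ``catalog``.
    """
    if n_high + n_low < 20:
        raise ValueError("cohort too small for mixture fitting (need >= 20)")
    if genome is None:
        genome = load_genome_build("hg38")
    catalog = hrr_gene_catalog(genome if genome.name == "hg38"
                               else load_genome_build("hg38"))
    rng = np.random.default_rng(seed)
    from .expression_signature import SARC_HRD

    segments: list[ASCNSegment] = []
    gene_cn: list[L2RSegment] = []
    truth_rows = []
    labels = ["hrd_high"] * n_high + ["hrd_low"] * n_low
    for i, group in enumerate(labels):
        sample = f"SIM{i + 1:03d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if group == "hrd_high":
            loh = int(np.clip(round(rng.normal(12, 3)), 5, 20))
            lst = int(np.clip(round(rng.normal(18, 4)), 8, 28))
            tai = int(np.clip(round(rng.normal(8, 2)), 3, 14))
            aneu = int(np.clip(rng.poisson(3), 0, 5))
            hrr = int(np.clip(round(rng.normal(50, 8)), 0, 2 * len(catalog)))
        else:
            loh = int(np.clip(rng.poisson(1.0), 0, 3))
            lst = int(np.clip(rng.poisson(1.5), 0, 4))
            tai = int(np.clip(rng.poisson(1.0), 0, 3))
            aneu = int(np.clip(rng.poisson(0.5), 0, 2))
            hrr = int(np.clip(round(rng.normal(8, 3)), 0, 2 * len(catalog)))
        profile, _ = simulate_profile(
            genome, loh, lst, tai, aneu, sample=sample, seed=sub_seed,
            group=group,
        )
        segments.extend(profile)
        gene_cn.extend(_hrr_cin_segments(rng, sample, catalog, hrr))
        truth_rows.append(
            ScarTruth(sample, group, loh, lst, tai, aneu, hrr, sub_seed)
        )
    truth = pd.DataFrame([t.__dict__ for t in truth_rows])

    gene_names = list(SARC_HRD.genes) + [
        f"BG{i + 1:04d}" for i in range(n_background_genes)
    ]
    mu = rng.uniform(3.0, 10.0, size=len(gene_names))
    log2 = rng.normal(
        mu[:, None], 0.5, size=(len(gene_names), len(labels))
    )
    is_high = np.array([g == "hrd_high" for g in labels])
    log2[: len(SARC_HRD.genes), is_high] += SARC_HRD_SHIFT
    values = pd.DataFrame(
        np.power(2.0, log2), index=gene_names, columns=truth["sample"]
    )
    groups = pd.Series(labels, index=truth["sample"], name="group")
    return {
        "segments": segments,
        "gene_cn": gene_cn,
        "expression": ExpressionMatrix(values, groups),
        "truth": truth,
        "catalog": catalog,
    }


# --- dose-response matrices ----------------------------------------------


def simulate_dose_matrix(
    model: str = "bliss",
    params1: tuple[float, float, float, float] = (0.0, 1.0, 1e-6, 1.0),
    params2: tuple[float, float, float, float] = (0.0, 1.0, 3e-6, 1.0),
    doses1: Sequence[float] | None = None,
    doses2: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    drug1: str = "drug1",
    drug2: str = "drug2",
) -> tuple[DoseMatrix, dict]:
    """Viability grid sampled under a synergy reference model (null).

    ``params`` are 4PL viability parameters (bottom, top, ic50, hill).
    Returns the matrix and a truth ledger recording model and parameters.
    """
    if doses1 is None:
        doses1 = np.concatenate(([0.0], np.geomspace(1e-8, 1e-4, 6)))
    if doses2 is None:
        doses2 = np.concatenate(([0.0], np.geomspace(1e-8, 1e-4, 6)))
    d1 = np.asarray(doses1, dtype=float)
    d2 = np.asarray(doses2, dtype=float)
    rng = np.random.default_rng(seed)

    def inh(params, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = np.clip(1.0 - fourpl(x[pos], *params), 0.0, 1.0)
        return out

    y1 = inh(params1, d1)
    y2 = inh(params2, d2)
    eff = np.zeros((d1.size, d2.size))
    eff[:, 0] = y1
    eff[0, :] = y2
    if model in ("bliss", "zip"):
        eff[1:, 1:] = y1[1:, None] + y2[None, 1:] - y1[1:, None] * y2[None, 1:]
    elif model == "hsa":
        eff[1:, 1:] = np.maximum(y1[1:, None], y2[None, 1:])
    elif model == "loewe":
        c1 = DoseResponseCurve(drug1, d1[1:], 1 - y1[1:], *params1, 0.0, True)
        c2 = DoseResponseCurve(drug2, d2[1:], 1 - y2[1:], *params2, 0.0, True)
        for i in range(1, d1.size):
            for j in range(1, d2.size):
                eff[i, j] = _loewe_cell(d1[i], d2[j], c1, c2)
    else:
        raise ValueError(f"unknown synergy model {model!r}")
    viability = 1.0 - eff
    if noise_sd > 0:
        viability = viability + rng.normal(0.0, noise_sd, size=viability.shape)
    matrix = DoseMatrix(drug1, drug2, d1, d2, viability)
    ledger = {
        "model": model,
        "params1": tuple(params1),
        "params2": tuple(params2),
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return matrix, ledger
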