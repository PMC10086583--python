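"""Genome model, gene catalogs, and readers/writers for the tabular inputs.

All coordinates are 1-based inclusive (SEG/ASCAT convention); interval
lengths are ``end - start + 1``.  Chromosome names are normalised to the
``chr`` prefix; chrY and mitochondria are dropped from scoring scope
because allele-specific copy number is not defined there.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBuild",
    "ASCNSegment",
    "L2RSegment",
    "SomaticVariant",
    "GeneLocus",
    "ExpressionMatrix",
    "load_genome_build",
    "hrr_gene_catalog",
    "read_ascn_segments",
    "write_ascn_segments",
    "read_l2r_segments",
    "write_l2r_segments",
    "read_maf_minimal",
    "read_expression",
    "normalize_chrom",
]

_DROP_CHROMS = {"chrY", "chrM", "chrMT"}

#: closed vocabulary for somatic variant classes
VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "splice", "other")


def normalize_chrom(name: str) -> str | None:
    """Normalise a chromosome name; return None for out-of-scope contigs."""
    name = str(name).strip()
    if not name.startswith("chr"):
        name = "chr" + name
    if name in _DROP_CHROMS:
        return None
    return name


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths, centromeres and cytobands of one assembly.

    ``cytobands`` maps a chromosome to an ordered tuple of
    ``(band_name, start, end)`` that tiles the chromosome without overlap.
    """

    name: str
    chromosomes: tuple[tuple[str, int], ...]
    centromeres: Mapping[str, tuple[int, int]]
    cytobands: Mapping[str, tuple[tuple[str, int, int], ...]]
    coordinates: str = "1-based inclusive"

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if any(l <= 0 for l in lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        for chrom, (cs, ce) in self.centromeres.items():
            if not (1 <= cs <= ce <= lengths[chrom]):
                raise ValueError(f"centromere of {chrom} outside chromosome")
        for chrom, bands in self.cytobands.items():
            pos = 1
            for band, s, e in bands:
                if s != pos or e < s:
                    raise ValueError(
                        f"cytobands of {chrom} do not tile the chromosome "
                        f"(band {band} starts at {s}, expected {pos})"
                    )
                pos = e + 1
            if pos != lengths[chrom] + 1:
                raise ValueError(f"cytobands of {chrom} do not reach the end")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def chrom_length(self, chrom: str) -> int:
        for c, l in self.chromosomes:
            if c == chrom:
                return l
        raise KeyError(chrom)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def centromere(self, chrom: str) -> tuple[int, int]:
        return self.centromeres[chrom]

    def arm_boundary(self, chrom: str) -> int:
        """Midpoint of the centromere: last base assigned to the p arm."""
        cs, ce = self.centromeres[chrom]
        return (cs + ce) // 2


@dataclass(frozen=True)
class ASCNSegment:
    """One allele-specific copy-number interval of one sample."""

    sample: str
    chrom: str
    start: int
    end: int
    n_major: int
    n_minor: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end in {self}")
        if self.start < 1:
            raise ValueError(f"non-positive coordinate in {self}")
        if self.n_major < 0 or self.n_minor < 0:
            raise ValueError(f"negative copy number in {self}")
        if self.n_minor > self.n_major:
            raise ValueError(f"n_minor > n_major in {self}")

    @property
    def total(self) -> int:
        return self.n_major + self.n_minor

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def state(self) -> tuple[int, int]:
        return (self.n_major, self.n_minor)


@dataclass(frozen=True)
class L2RSegment:
    """One log2 copy-ratio interval of one sample."""

    sample: str
    chrom: str
    start: int
    end: int
    l2r: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end in {self}")
        if self.start < 1:
            raise ValueError(f"non-positive coordinate in {self}")
        if not np.isfinite(self.l2r):
            raise ValueError(f"non-finite l2r in {self}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SomaticVariant:
    sample: str
    gene: str
    classification: str  # one of VARIANT_CLASSES
    filter_status: str

    def __post_init__(self) -> None:
        if self.classification not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.classification!r}")


@dataclass(frozen=True)
class GeneLocus:
    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad interval for {self.symbol}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with optional sample groups."""

    values: pd.DataFrame  # index = gene symbols, columns = samples
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene symbols in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# genome builds


def _toy_build() -> GenomeBuild:
    # 3 x 100 Mb chromosomes, centromere [45, 55] Mb, four 25 Mb bands each;
    # keeps all worked examples arithmetic-friendly.
    n = 100_000_000
    chroms = tuple((f"chr{i}", n) for i in (1, 2, 3))
    cen = {c: (45_000_000, 55_000_000) for c, _ in chroms}
    bands = {
        c: (
            ("p2", 1, 25_000_000),
            ("p1", 25_000_001, 50_000_000),
            ("q1", 50_000_001, 75_000_000),
            ("q2", 75_000_001, n),
        )
        for c, _ in chroms
    }
    return GenomeBuild("toy", chroms, cen, bands)


def _hg38_build() -> GenomeBuild:
    path = importlib.resources.files("hrdscape.data") / "hg38_chromosomes.tsv"
    df = pd.read_csv(path, sep="\t")
    chroms = tuple(zip(df["chrom"], df["length"].astype(int)))
    cen = {
        r.chrom: (int(r.cen_start), int(r.cen_end)) for r in df.itertuples()
    }
    # arm-resolution bands: p = [1, centromere midpoint], q = rest
    bands = {}
    for chrom, length in chroms:
        cs, ce = cen[chrom]
        mid = (cs + ce) // 2
        bands[chrom] = (("p", 1, mid), ("q", mid + 1, length))
    return GenomeBuild("hg38", chroms, cen, bands)


def _build_from_cytoband_file(path: Path) -> GenomeBuild:
    """Parse a UCSC cytoBand.txt-layout file (0-based half-open intervals)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "band", "stain"],
    )
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df = df.dropna(subset=["chrom"])
    df = df[~df["chrom"].str.contains("_")]
    chroms, cen, bands = [], {}, {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        length = int(sub["end"].max())
        chroms.append((chrom, length))
        acen = sub[sub["stain"] == "acen"]
        if len(acen):
            cen[chrom] = (int(acen["start"].min()) + 1, int(acen["end"].max()))
        else:
            raise ValueError(f"no centromere (acen) bands for {chrom}")
        bands[chrom] = tuple(
            (str(r.band), int(r.start) + 1, int(r.end)) for r in sub.itertuples()
        )
    order = sorted(chroms, key=lambda c: _chrom_sort_key(c[0]))
    return GenomeBuild(Path(path).stem, tuple(order), cen, bands)


def _chrom_sort_key(chrom: str):
    body = chrom[3:]
    return (0, int(body)) if body.isdigit() else (1, body)


def load_genome_build(name_or_path: str) -> GenomeBuild:
    """Load a packaged build (``toy``, ``hg38``) or a UCSC cytoband file."""
    if name_or_path == "toy":
        return _toy_build()
    if name_or_path == "hg38":
        return _hg38_build()
    path = Path(name_or_path)
    if path.exists():
        return _build_from_cytoband_file(path)
    raise ValueError(f"unknown genome build {name_or_path!r}")


# ---------------------------------------------------------------------------
# gene catalogs

_TOY_CATALOG = tuple(
    GeneLocus(f"TOY{i + 1}", chrom, start, start + 999_999)
    for i, (chrom, start) in enumerate(
        [
            ("chr1", 5_000_000),
            ("chr1", 30_000_000),
            ("chr1", 70_000_000),
            ("chr1", 90_000_000),
            ("chr2", 10_000_000),
            ("chr2", 40_000_000),
            ("chr2", 80_000_000),
            ("chr3", 20_000_000),
            ("chr3", 60_000_000),
            ("chr3", 95_000_000),
        ]
    )
)


def hrr_gene_catalog(genome: GenomeBuild) -> tuple[GeneLocus, ...]:
    """The HRR pathway gene catalog for a genome build.

    The hg38 catalog holds 70 genes involved in HRR regulation (see the
    packaged table; coordinates are approximate).  The toy build carries 10
    synthetic loci for tests.
    """
    if genome.name == "toy":
        catalog = _TOY_CATALOG
    elif genome.name == "hg38":
        path = (
            importlib.resources.files("hrdscape.data")
            / "hrr_catalog_hg38_synthetic.tsv"
        )
        df = pd.read_csv(path, sep="\t", comment="#")
        catalog = tuple(
            GeneLocus(r.symbol, r.chrom, int(r.start), int(r.end))
            for r in df.itertuples()
        )
    else:
        raise ValueError(f"no HRR catalog packaged for build {genome.name!r}")
    lengths = dict(genome.chromosomes)
    for g in catalog:
        if g.chrom not in lengths or g.end > lengths[g.chrom]:
            raise ValueError(f"locus {g.symbol} outside chromosome bounds")
    return catalog


# ---------------------------------------------------------------------------
# segment tables

_ASCN_COLS = ["sample", "chrom", "start", "end", "n_major", "n_minor"]
_L2R_COLS = ["sample", "chrom", "start", "end", "l2r"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns: {missing}")


def _check_sorted_disjoint(segments: Sequence) -> None:
    by_key: dict[tuple[str, str], list] = {}
    for seg in segments:
        by_key.setdefault((seg.sample, seg.chrom), []).append(seg)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping segments for {sample} on {chrom}: "
                    f"[{a.start}, {a.end}] and [{b.start}, {b.end}]"
                )


def sort_segments(segments: Iterable) -> list:
    return sorted(
        segments, key=lambda s: (s.sample, _chrom_sort_key(s.chrom), s.start)
    )


def read_ascn_segments(path) -> list[ASCNSegment]:
    """Read an allele-specific segment TSV; validated, sorted, disjoint."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _ASCN_COLS, "ASCN segment table")
    segments = []
    for r in df.itertuples():
        chrom = normalize_chrom(r.chrom)
        if chrom is None:
            continue
        segments.append(
            ASCNSegment(
                str(r.sample), chrom, int(r.start), int(r.end),
                int(r.n_major), int(r.n_minor),
            )
        )
    _check_sorted_disjoint(segments)
    return sort_segments(segments)


def write_ascn_segments(segments: Iterable[ASCNSegment], path) -> None:
    df = pd.DataFrame(
        [(s.sample, s.chrom, s.start, s.end, s.n_major, s.n_minor)
         for s in segments],
        columns=_ASCN_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_l2r_segments(path) -> list[L2RSegment]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _L2R_COLS, "L2R segment table")
    segments = []
    for r in df.itertuples():
        chrom = normalize_chrom(r.chrom)
        if chrom is None:
            continue
        segments.append(
            L2RSegment(str(r.sample), chrom, int(r.start), int(r.end),
                       float(r.l2r))
        )
    _check_sorted_disjoint(segments)
    return sort_segments(segments)


def write_l2r_segments(segments: Iterable[L2RSegment], path) -> None:
    df = pd.DataFrame(
        [(s.sample, s.chrom, s.start, s.end, s.l2r) for s in segments],
        columns=_L2R_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


# MAF Variant_Classification -> closed vocabulary; configurable at call site
MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Ins": "frameshift",
    "Frame_Shift_Del": "frameshift",
    "Splice_Site": "splice",
}


def read_maf_minimal(
    path, require_pass: bool = True, class_map: Mapping[str, str] | None = None
) -> list[SomaticVariant]:
    """Read the minimal MAF columns; optionally keep only FILTER == PASS."""
    class_map = MAF_CLASS_MAP if class_map is None else class_map
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(
        df,
        ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification",
         "FILTER"],
        "MAF table",
    )
    out = []
    for r in df.itertuples():
        if require_pass and str(r.FILTER) != "PASS":
            continue
        out.append(
            SomaticVariant(
                str(r.Tumor_Sample_Barcode),
                str(r.Hugo_Symbol),
                class_map.get(str(r.Variant_Classification), "other"),
                str(r.FILTER),
            )
        )
    return out


def read_expression(
    path, genes_path=None, samples_path=None, groups: pd.Series | None = None
) -> ExpressionMatrix:
    """Read a genes x samples TSV, or an MTX with row/column label files."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        values = np.asarray(mmread(path).todense())
        genes = [l.strip() for l in Path(genes_path).read_text().splitlines() if l.strip()]
        samples = [l.strip() for l in Path(samples_path).read_text().splitlines() if l.strip()]
        df = pd.DataFrame(values, index=genes, columns=samples)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, groups)
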