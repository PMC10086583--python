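"""Gene x sample alteration matrices (the oncoprint data model).

Cells carry sets of categorical alterations — variant classes from a
filtered MAF plus gene-level copy-number categories — with per-sample
totals (counted as (gene, category) events) and per-gene altered
fractions over the sample roster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cin_features import CINParams
from .reference_io import GeneLocus, SomaticVariant

__all__ = [
    "ALTERATION_CATEGORIES",
    "AlterationMatrix",
    "classify_gene_cn",
    "build_alteration_matrix",
    "total_alterations",
]

ALTERATION_CATEGORIES = (
    "missense",
    "truncating",
    "splice",
    "other_variant",
    "amplification",
    "deep_deletion",
    "gain",
    "loss",
)

# closed variant vocabulary -> oncoprint category
_VARIANT_TO_CATEGORY = {
    "missense": "missense",
    "nonsense": "truncating",
    "frameshift": "truncating",
    "splice": "splice",
    "other": "other_variant",
}

# GDC gene-level categorical copy-number codes
_GDC_CODES = {-2: "deep_deletion", -1: "loss", 0: None, 1: "gain",
              2: "amplification"}


def classify_gene_cn(
    value: float,
    mode: str = "l2r",
    params: CINParams = CINParams(),
) -> str | None:
    """Categorise a per-gene copy-number value.

    ``l2r`` mode uses the segment thresholds (amplification above 0.7,
    deep deletion below -0.7, gain/loss at +/-0.1, strict); ``gdc`` mode
    maps the categorical codes {-2, -1, 0, 1, 2}.
    """
    if mode == "gdc":
        code = int(value)
        if code not in _GDC_CODES:
            raise ValueError(f"unknown GDC copy-number code {value!r}")
        return _GDC_CODES[code]
    if mode != "l2r":
        raise ValueError(f"unknown mode {mode!r}")
    if not np.isfinite(value):
        raise ValueError("non-finite copy-number value")
    if value > params.l2r_amp:
        return "amplification"
    if value > params.l2r_gain:
        return "gain"
    if value < params.l2r_deepdel:
        return "deep_deletion"
    if value < params.l2r_loss:
        return "loss"
    return None


@dataclass
class AlterationMatrix:
    genes: tuple[str, ...]
    samples: tuple[str, ...]
    cells: Mapping[tuple[str, str], frozenset[str]]

    def cell(self, gene: str, sample: str) -> frozenset[str]:
        return self.cells.get((gene, sample), frozenset())

    def gene_altered_fraction(self) -> pd.Series:
        """Fraction of roster samples with any alteration, per gene."""
        frac = {
            g: sum(1 for s in self.samples if self.cell(g, s)) / len(self.samples)
            for g in self.genes
        }
        return pd.Series(frac, name="altered_fraction")

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": s, "gene": g, "category": cat}
            for (g, s), cats in sorted(self.cells.items())
            for cat in sorted(cats)
        ]
        return pd.DataFrame(rows, columns=["sample", "gene", "category"])


def build_alteration_matrix(
    variants: Iterable[SomaticVariant],
    gene_cn: pd.DataFrame | None,
    genes: Sequence[GeneLocus] | Sequence[str],
    samples: Sequence[str],
    cn_mode: str = "l2r",
    params: CINParams = CINParams(),
) -> AlterationMatrix:
    """Union of variant and copy-number categories per (gene, sample) cell.

    ``gene_cn`` is a genes x samples value table (log2 ratios or GDC
    codes).  Samples with no events stay in the matrix as empty columns;
    a variant naming a sample outside the roster is an error.  Variants
    and CN values for genes outside the catalog are ignored.
    """
    gene_names = tuple(
        g.symbol if isinstance(g, GeneLocus) else str(g) for g in genes
    )
    if not gene_names:
        raise ValueError("empty gene catalog")
    samples = tuple(str(s) for s in samples)
    roster = set(samples)
    cells: dict[tuple[str, str], set[str]] = {}
    for v in variants:
        if v.sample not in roster:
            raise ValueError(f"variant sample {v.sample!r} absent from roster")
        if v.gene not in gene_names:
            continue
        cells.setdefault((v.gene, v.sample), set()).add(
            _VARIANT_TO_CATEGORY[v.classification]
        )
    if gene_cn is not None:
        for gene in gene_cn.index.intersection(gene_names):
            for sample in gene_cn.columns:
                if sample not in roster:
                    continue
                value = gene_cn.loc[gene, sample]
                if pd.isna(value):
                    continue
                cat = classify_gene_cn(float(value), cn_mode, params)
                if cat is not None:
                    cells.setdefault((gene, sample), set()).add(cat)
    return AlterationMatrix(
        genes=gene_names,
        samples=samples,
        cells={k: frozenset(v) for k, v in cells.items()},
    )


def total_alterations(matrix: AlterationMatrix) -> pd.Series:
    """Per-sample count of (gene, category) events."""
    totals = dict.fromkeys(matrix.samples, 0)
    for (_, sample), cats in matrix.cells.items():
        totals[sample] += len(cats)
    return pd.Series(totals, name="total_alterations")
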