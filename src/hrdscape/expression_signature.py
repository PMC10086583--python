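"""SARC-HRD expression-signature scoring and the fold-change/p DE filter.

The SARC-HRD signature is a set of 10 HRR genes up-regulated in HRD-high
sarcoma (BRCA1, BRCA2, BLM, EME1, FANCB, FANCD2, FANCI, RAD51, RAD54L,
XRCC2).  The score operationalises the signature as the mean per-gene
z-score of log2(x+1) expression across the cohort — a standard summary of
a directed gene set; the cohort mean of scores is ~0 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference_io import ExpressionMatrix

__all__ = ["SignatureDefinition", "SARC_HRD", "signature_score", "de_filter"]


@dataclass(frozen=True)
class SignatureDefinition:
    name: str
    genes: tuple[str, ...]
    direction: str = "up"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty signature")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")


SARC_HRD = SignatureDefinition(
    "SARC-HRD",
    ("BRCA1", "BRCA2", "BLM", "EME1", "FANCB", "FANCD2", "FANCI",
     "RAD51", "RAD54L", "XRCC2"),
)


def signature_score(
    expr: ExpressionMatrix, sig: SignatureDefinition = SARC_HRD
) -> pd.Series:
    """Mean z-score over the signature genes, per sample.

    Values are log2(x+1)-transformed and z-scored per gene across samples.
    At least half the signature genes must be present; zero-variance genes
    are dropped with a warning.
    """
    present = [g for g in sig.genes if g in expr.values.index]
    if len(present) < len(sig.genes) / 2:
        raise ValueError(
            f"only {len(present)}/{len(sig.genes)} signature genes present"
        )
    missing = set(sig.genes) - set(present)
    if missing:
        warnings.warn(f"signature genes absent: {sorted(missing)}", stacklevel=2)
    log = np.log2(expr.values.loc[present].astype(float) + 1.0)
    sd = log.std(axis=1, ddof=0)
    flat = sd[sd == 0].index
    if len(flat):
        warnings.warn(f"zero-variance genes dropped: {list(flat)}", stacklevel=2)
        log = log.drop(index=flat)
        sd = sd.drop(index=flat)
        if log.empty:
            raise ValueError("no informative signature genes")
    z = log.sub(log.mean(axis=1), axis=0).div(sd, axis=0)
    score = z.mean(axis=0)
    score.name = sig.name
    return score


def de_filter(
    records: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differential-expression threshold filter on precomputed statistics.

    Keeps genes with at least ``fc_threshold``-fold change in either
    direction (|log2FC| >= log2(fc_threshold)) and p <= ``p_threshold``;
    both boundaries inclusive.  ``records`` needs columns ``gene``,
    ``log2fc``, ``p``.
    """
    missing = {"gene", "log2fc", "p"} - set(records.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if len(records) and (
        not np.isfinite(records["log2fc"]).all()
        or ((records["p"] < 0) | (records["p"] > 1)).any()
    ):
        raise ValueError("non-finite log2FC or p outside [0, 1]")
    keep = (records["log2fc"].abs() >= np.log2(fc_threshold)) & (
        records["p"] <= p_threshold
    )
    return records.loc[keep].reset_index(drop=True)
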