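"""qPCR quantification: standard curves, copy ratios and 2^-ddCt expression.

Absolute abundances (copies per gram dry soil) come from a dilution-series
standard curve, ``Ct = intercept + slope * log10(copies)`` with a negative
slope (about −3.32 cycles per decade at perfect efficiency). Relative
expression between paired treatments uses the classical 2^−ΔΔCT estimator:
per replicate, ΔCt = Ct(transcript) − Ct(gene) normalises transcripts to
gene copies in the same sample; ΔΔCt compares the two treatments and the
fold change is 2^−ΔΔCt, with values above 1 meaning upregulation in the
second treatment of the pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidCurveError, InvalidInputError

__all__ = [
    "QpcrRecord",
    "CopyQuant",
    "RelativeExpression",
    "copies_from_ct",
    "copy_ratio",
    "delta_delta_ct",
]


@dataclass(frozen=True)
class QpcrRecord:
    """One well: assay, sample, template type, threshold cycle and its curve."""

    assay: str  # e.g. "total-mcrA", "Methanosarcina-mcrA", "archaeal-16S", "katE-Methanocella"
    sample_id: str
    template: str  # "DNA" or "cDNA"
    replicate: int
    ct: float  # cycles
    curve_slope: float  # cycles per log10(copies), < 0
    curve_intercept: float  # cycles at 1 copy

    def __post_init__(self) -> None:
        if self.template not in ("DNA", "cDNA"):
            raise InvalidInputError("template must be 'DNA' or 'cDNA'")
        if self.ct <= 0:
            raise InvalidInputError("Ct must be > 0")
        if self.curve_slope >= 0:
            raise InvalidCurveError("standard-curve slope must be negative")


@dataclass(frozen=True)
class CopyQuant:
    """Absolute quantification result, copies per gram dry soil."""

    copies_per_gdw: float
    log10_copies: float

    def __post_init__(self) -> None:
        if self.copies_per_gdw <= 0:
            raise InvalidInputError("copies_per_gdw must be > 0")


@dataclass(frozen=True)
class RelativeExpression:
    """2^-ddCt fold change between a matched treatment pair."""

    fold_change: float
    standard_error: float  # nan with a single replicate pair
    pair: tuple[str, str]
    n_pairs: int

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise InvalidInputError("fold_change must be > 0")


def copies_from_ct(
    ct: float,
    curve_slope: float,
    curve_intercept: float,
    dilution_factor: float = 1.0,
    gdw_in_extraction: float = 1.0,
) -> CopyQuant:
    """Invert the standard curve: copies in the reaction, scaled to per-gdw.

    ``copies_in_reaction = 10 ** ((ct − intercept)/slope)``, multiplied by the
    template dilution factor and divided by the dry weight that went into the
    nucleic-acid extraction.
    """
    if curve_slope >= 0:
        raise InvalidCurveError("standard-curve slope must be negative")
    if gdw_in_extraction <= 0 or dilution_factor <= 0:
        raise InvalidInputError("dilution_factor and gdw_in_extraction must be > 0")
    copies_rxn = 10.0 ** ((ct - curve_intercept) / curve_slope)
    per_gdw = copies_rxn * dilution_factor / gdw_in_extraction
    return CopyQuant(copies_per_gdw=per_gdw, log10_copies=math.log10(per_gdw))


def copy_ratio(taxon: CopyQuant | float, total: CopyQuant | float) -> tuple[float, bool]:
    """Taxon-to-total copy ratio; returns ``(ratio, exceeds_one)``.

    Ratios above 1 are possible (different assays target genes with different
    per-cell copy numbers) and are flagged rather than rejected.
    """
    t = taxon.copies_per_gdw if isinstance(taxon, CopyQuant) else float(taxon)
    tot = total.copies_per_gdw if isinstance(total, CopyQuant) else float(total)
    if tot <= 0:
        raise InvalidInputError("total copies must be > 0")
    if t < 0:
        raise InvalidInputError("taxon copies must be >= 0")
    ratio = t / tot
    return ratio, ratio > 1.0


def delta_delta_ct(
    delta_ct_a: Sequence[float],
    delta_ct_b: Sequence[float],
    pair: tuple[str, str] = ("A", "B"),
    pairing: str = "paired",
    averaging: str = "arithmetic",
) -> RelativeExpression:
    """2^-ddCt fold change of treatment B relative to treatment A.

    ``delta_ct_*`` are per-replicate ΔCt values (transcript Ct on cDNA minus
    gene Ct on DNA for the same sample). With ``pairing="paired"`` replicates
    are matched by index and the fold change is the mean (arithmetic by
    default, geometric optionally) of per-pair ``2^−(ΔCt_B − ΔCt_A)`` with the
    SE across pairs; ``pairing="pooled"`` uses group-mean ΔCt values with the
    SE propagated from both groups.
    """
    a = np.asarray(delta_ct_a, dtype=float)
    b = np.asarray(delta_ct_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups need at least one replicate")
    if pairing == "paired":
        if a.size != b.size:
            raise InvalidInputError("paired mode needs equal replicate counts")
        folds = 2.0 ** (-(b - a))
        if averaging == "arithmetic":
            fold = float(folds.mean())
        elif averaging == "geometric":
            fold = float(np.exp(np.mean(np.log(folds))))
        else:
            raise InvalidInputError(f"unknown averaging {averaging!r}")
        se = float(np.std(folds, ddof=1) / np.sqrt(folds.size)) if folds.size > 1 else float("nan")
    elif pairing == "pooled":
        ddct = float(b.mean() - a.mean())
        fold = 2.0**-ddct
        var = 0.0
        for g in (a, b):
            if g.size > 1:
                var += float(np.var(g, ddof=1)) / g.size
        # first-order propagation through 2^-x
        se = float(math.log(2.0) * fold * math.sqrt(var)) if var > 0 else float("nan")
        if a.size == 1 and b.size == 1:
            se = float("nan")
    else:
        raise InvalidInputError(f"unknown pairing {pairing!r}")
    return RelativeExpression(
        fold_change=fold, standard_error=se, pair=pair, n_pairs=int(min(a.size, b.size))
    )
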