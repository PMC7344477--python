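"""Relative quantification of Cq values by the 2^-dCt method.

dCt for a target gene g in sample s is Cq_gs minus the sample's reference
Cq (so a higher cycle number means lower expression), and relative
expression is 2^-dCt.  The reference Cq is the geometric mean of the
reference genes' cycles in that sample; the study default is the two-gene
set miRNA-100 / miRNA-143, with the four-gene alternative (adding
miRNA-126 and miRNA-125b) available.  PCR efficiency is assumed to be 100%
for every assay; no per-gene efficiency correction is applied.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .exceptions import InsufficientDataError
from .io import CqMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

#: Two-gene reference used throughout the downstream analysis.
DEFAULT_REFERENCE: tuple[str, ...] = ("miRNA-100", "miRNA-143")
#: The stable four-gene set before excluding the two cancer-involved miRNAs.
FOUR_GENE_REFERENCE: tuple[str, ...] = (
    "miRNA-100", "miRNA-143", "miRNA-126", "miRNA-125b")


@dataclass(frozen=True)
class ReferenceSpec:
    """The genes whose geometric-mean Cq serves as the per-sample reference."""

    genes: tuple[str, ...] = DEFAULT_REFERENCE

    def __post_init__(self):
        if not self.genes:
            raise ValueError("reference gene set must be non-empty")
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))

    def validate_against(self, cq: CqMatrix) -> None:
        missing = [g for g in self.genes if g not in cq.values.index]
        if missing:
            raise ValueError(
                f"reference gene(s) absent from matrix: {missing}")


def _as_spec(ref) -> ReferenceSpec:
    if ref is None:
        return ReferenceSpec()
    if isinstance(ref, ReferenceSpec):
        return ref
    return ReferenceSpec(tuple(ref))


def reference_cq(cq: CqMatrix, ref=None, sample: str | None = None):
    """Geometric mean of the reference genes' Cq, per sample.

    Returns a Series over all samples, or a scalar if ``sample`` is given.
    The reference is missing for samples where any reference gene is
    missing.
    """
    spec = _as_spec(ref)
    spec.validate_against(cq)
    sub = cq.values.loc[list(spec.genes)]
    out = pd.Series(
        np.where(sub.isna().any(axis=0), np.nan, gmean(sub, axis=0)),
        index=cq.values.columns, name="reference_cq")
    if sample is not None:
        if sample not in out.index:
            raise ValueError(f"unknown sample: {sample!r}")
        return float(out[sample])
    return out


def relative_expression(cq: CqMatrix, ref=None) -> ExpressionMatrix:
    """Relative expression 2^-(Cq_g - reference Cq) for every target gene.

    Reference genes are excluded from the output rows.  Samples missing the
    reference propagate as all-missing columns (with a warning); if every
    sample misses the reference this is an error.
    """
    spec = _as_spec(ref)
    spec.validate_against(cq)
    ref_cq = reference_cq(cq, spec)
    if ref_cq.isna().all():
        raise InsufficientDataError(
            "reference Cq is missing in every sample; no expression "
            "values can be computed")
    n_missing = int(ref_cq.isna().sum())
    if n_missing:
        logger.warning(
            "reference Cq missing in %d/%d samples; their expression "
            "columns are set to missing", n_missing, len(ref_cq))
    targets = [g for g in cq.genes if g not in spec.genes]
    dct = cq.values.loc[targets].sub(ref_cq, axis=1)
    values = np.power(2.0, -dct)
    return ExpressionMatrix(values, reference_genes=spec.genes)
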