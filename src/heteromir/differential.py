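"""Region-pair differential expression by the Mann-Whitney U test.

The U statistic is implemented from its counting definition,

    U_x = #{(i, j): x_i > y_j} + 1/2 * #{(i, j): x_i = y_j},

with two p-value routes:

* exact — the full null distribution of U (all C(n+m, n) equally likely
  rank assignments), computed by the classic count recursion; used
  automatically for tie-free samples with n + m <= 16;
* asymptotic — normal approximation with tie-corrected variance and a
  0.5 continuity correction.

Comparisons between intratumor regions are unpaired: every sample of
region a against every sample of region b, all patients pooled.  No
multiple-testing correction is applied; significance is the raw two-sided
p < alpha (default 0.05).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import VocabularyError
from .io import REGIONS, ExpressionMatrix, SampleSheet

logger = logging.getLogger(__name__)

#: Largest pooled size for which the exact null distribution is enumerated.
EXACT_LIMIT = 16

#: The ten region contrasts of the five-region design, in report order.
DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("N", "B"), ("N", "C"), ("N", "P1"), ("N", "P2"),
    ("B", "C"), ("B", "P1"), ("B", "P2"),
    ("C", "P1"), ("C", "P2"), ("P1", "P2"),
)


class MannWhitneyResult(NamedTuple):
    u: float
    p: float
    method: str


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of rank assignments giving each U value 0..n*m.

    Recursion on whether the largest pooled rank belongs to the x group:
    N(u; n, m) = N(u - m; n - 1, m) + N(u; n, m - 1).
    """
    if n == 0 or m == 0:
        return (1,)  # U = 0 is the only outcome
    a = _u_counts(n - 1, m)  # largest rank in x: contributes m to U
    b = _u_counts(n, m - 1)  # largest rank in y
    size = n * m + 1
    out = [0] * size
    for u, c in enumerate(a):
        if c:
            out[u + m] += c
    for u, c in enumerate(b):
        if c:
            out[u] += c
    return tuple(out)


def _exact_two_sided_p(u: float, n: int, m: int) -> float:
    counts = _u_counts(n, m)
    total = math.comb(n + m, n)
    u_int = int(round(u))
    lo = min(u_int, n * m - u_int)
    hi = n * m - lo
    p = (sum(counts[: lo + 1]) + sum(counts[hi:])) / total
    return min(1.0, p)


def mann_whitney_u(x, y, method: str = "auto",
                   continuity: bool = True) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    Parameters
    ----------
    x, y
        Numeric samples (each non-empty; NaNs are not allowed here — drop
        them upstream).
    method
        "auto" (exact when tie-free and n+m <= EXACT_LIMIT, else
        asymptotic), "exact", or "asymptotic".
    continuity
        Apply the 0.5 continuity correction in the normal approximation.

    Returns the U statistic of the first sample and the two-sided p.
    When every pooled value is tied the test is degenerate and p = 1 by
    convention (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("samples must not contain missing values")
    n, m = x.size, y.size
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if tie_counts.size == 1:
        logger.info("all %d pooled values tied; degenerate test, p = 1", n + m)
        return MannWhitneyResult(u=u, p=1.0, method="degenerate")

    if method == "auto":
        method = ("exact" if (not has_ties and n + m <= EXACT_LIMIT)
                  else "asymptotic")
    if method == "exact":
        # EXACT_LIMIT only gates automatic selection; a forced exact test
        # runs at any size (the count recursion stays cheap well past it).
        if has_ties:
            raise ValueError("exact method requires tie-free samples")
        return MannWhitneyResult(u=u, p=_exact_two_sided_p(u, n, m),
                                 method="exact")
    if method != "asymptotic":
        raise ValueError(f"unknown method: {method!r}")

    N = n + m
    mu = n * m / 2.0
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (N * (N - 1)))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        logger.info("zero-variance pooled ranks; degenerate test, p = 1")
        return MannWhitneyResult(u=u, p=1.0, method="degenerate")
    num = abs(u - mu)
    if continuity:
        num = max(num - 0.5, 0.0)
    z = num / math.sqrt(var)
    return MannWhitneyResult(u=u, p=min(1.0, 2.0 * float(norm.sf(z))),
                             method="asymptotic")


def contrast_label(contrast: Sequence[str]) -> str:
    a, b = contrast
    return f"{a}_vs_{b}"


@dataclass
class ComparisonTable:
    """Gene x region-pair table of two-sided Mann-Whitney p-values.

    ``mask`` is True where p < alpha (strict), False for missing p.
    ``n_a`` / ``n_b`` hold the per-cell effective group sizes after
    dropping missing expression values; ``methods`` records which p-value
    route each cell used.
    """

    p_values: pd.DataFrame
    contrasts: list[tuple[str, str]]
    alpha: float = 0.05
    n_a: pd.DataFrame | None = None
    n_b: pd.DataFrame | None = None
    methods: pd.DataFrame | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        arr = self.p_values.to_numpy(dtype=float)
        ok = np.isnan(arr) | ((arr >= 0.0) & (arr <= 1.0))
        if not ok.all():
            raise ValueError("p-values must lie in [0, 1]")
        for a, b in self.contrasts:
            if a not in REGIONS or b not in REGIONS:
                raise VocabularyError(
                    f"contrast ({a}, {b}) outside region vocabulary")
        expected = [contrast_label(c) for c in self.contrasts]
        if list(self.p_values.columns) != expected:
            raise ValueError("p-value columns must match the contrast list")

    @property
    def genes(self) -> list[str]:
        return list(self.p_values.index)

    @property
    def mask(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore"):
            return self.p_values < self.alpha

    def significance_count(self, contrast: Sequence[str]) -> int:
        lab = contrast_label(contrast)
        if lab not in self.p_values.columns:
            raise ValueError(f"unknown contrast: {tuple(contrast)}")
        return int(self.mask[lab].sum())

    def consistent_markers(
            self, contrasts: Sequence[Sequence[str]] | None = None
    ) -> list[str]:
        if contrasts is None:
            contrasts = self.contrasts
        contrasts = list(contrasts)
        if not contrasts:
            raise ValueError("contrast list must be non-empty")
        labs = [contrast_label(c) for c in contrasts]
        unknown = [l for l in labs if l not in self.p_values.columns]
        if unknown:
            raise ValueError(f"unknown contrasts: {unknown}")
        m = self.mask[labs].all(axis=1)
        return [g for g in self.genes if m[g]]

    def summary(self) -> str:
        counts = {contrast_label(c): self.significance_count(c)
                  for c in self.contrasts}
        lines = [
            f"Mann-Whitney region comparisons (alpha = {self.alpha})",
            "significant genes per contrast: "
            + ", ".join(f"{k}: {v}" for k, v in counts.items()),
            "consistent markers (all contrasts): "
            + (", ".join(self.consistent_markers()) or "none"),
            self.p_values.to_string(
                float_format=lambda x: f"{x:.6f}"),
        ]
        return "\n".join(lines)


class RegionComparison:
    """Per-gene region-pair testing of an expression matrix.

    Parameters
    ----------
    expr
        Relative-expression matrix (reference genes already excluded).
    sheet
        Sample sheet mapping samples to patients and regions.
    contrasts
        Region pairs to test (default: all ten pairs of the five-region
        design).
    alpha
        Strict significance threshold for the mask.

    ``fit()`` returns a :class:`ComparisonTable`.  Tests are unpaired;
    missing expression values are dropped per gene and the effective
    group sizes recorded.
    """

    def __init__(self, expr: ExpressionMatrix, sheet: SampleSheet,
                 contrasts: Sequence[Sequence[str]] | None = None,
                 alpha: float = 0.05):
        self.expr = expr
        self.sheet = sheet
        self.contrasts = [tuple(c) for c in (contrasts or DEFAULT_CONTRASTS)]
        self.alpha = alpha
        for a, b in self.contrasts:
            if a not in REGIONS or b not in REGIONS:
                raise VocabularyError(f"contrast ({a}, {b}) outside "
                                      "region vocabulary")

    def fit(self) -> ComparisonTable:
        expr_df = self.expr.values
        region_samples: dict[str, list[str]] = {}
        for r in {r for c in self.contrasts for r in c}:
            samples = [s for s in self.sheet.samples_in_region(r)
                       if s in expr_df.columns]
            if not samples:
                raise ValueError(f"region {r!r} has no samples")
            region_samples[r] = samples

        labels = [contrast_label(c) for c in self.contrasts]
        genes = list(expr_df.index)
        p = pd.DataFrame(np.nan, index=genes, columns=labels)
        na = pd.DataFrame(0, index=genes, columns=labels, dtype=int)
        nb = pd.DataFrame(0, index=genes, columns=labels, dtype=int)
        meth = pd.DataFrame("", index=genes, columns=labels, dtype=object)
        for (a, b), lab in zip(self.contrasts, labels):
            xa = expr_df[region_samples[a]]
            xb = expr_df[region_samples[b]]
            for g in genes:
                x = xa.loc[g].dropna().to_numpy()
                y = xb.loc[g].dropna().to_numpy()
                na.loc[g, lab] = x.size
                nb.loc[g, lab] = y.size
                if x.size == 0 or y.size == 0:
                    logger.warning("gene %r, contrast %s: empty group after "
                                   "dropping missing values", g, lab)
                    continue
                res = mann_whitney_u(x, y)
                p.loc[g, lab] = res.p
                meth.loc[g, lab] = res.method
                logger.debug("%s %s: n=(%d,%d) U=%.1f p=%.6g (%s)",
                             g, lab, x.size, y.size, res.u, res.p, res.method)
        return ComparisonTable(p_values=p, contrasts=self.contrasts,
                               alpha=self.alpha, n_a=na, n_b=nb, methods=meth)


def compare_regions(expr: ExpressionMatrix, sheet: SampleSheet,
                    contrasts: Sequence[Sequence[str]] | None = None,
                    alpha: float = 0.05) -> ComparisonTable:
    """Functional wrapper around :class:`RegionComparison`."""
    return RegionComparison(expr, sheet, contrasts, alpha).fit()


def significance_count(table: ComparisonTable,
                       contrast: Sequence[str]) -> int:
    """Number of genes significant (p < alpha) for one contrast."""
    return table.significance_count(contrast)


def consistent_markers(table: ComparisonTable,
                       contrasts: Sequence[Sequence[str]] | None = None
                       ) -> list[str]:
    """Genes significant in every listed contrast, in table row order."""
    return table.consistent_markers(contrasts)
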