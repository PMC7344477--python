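"""Packaged transcriptions of the published region-pair p-value tables.

Each TSV transcribes the printed two-sided Mann-Whitney p-values of one
published comparison table verbatim; a trailing ``*`` on a cell copies the
table's own significance star (p < 0.05).  The loader returns both the
numeric :class:`~heteromir.differential.ComparisonTable` and the printed
star mask so the two can be checked against each other.

Gene-name normalization: the border-contrast table prints one row as
"miRNA-451" where every other table writes "miRNA-451a"; both are the same
species and are normalized to "miRNA-451a" on load.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from ..differential import ComparisonTable, contrast_label
from ..exceptions import FormatError

#: Published per-region group size (33 patients, one sample per region).
PUBLISHED_N = 33

GENE_ALIASES = {"miRNA-451": "miRNA-451a", "miR-451": "miRNA-451a"}

TABLE_FILES = {
    "normal_vs_regions": "table2_pvalues.tsv",
    "border_vs_regions": "table3_pvalues.tsv",
    "center_vs_periphery": "table4_pvalues.tsv",
}

TABLE_CONTRASTS = {
    "normal_vs_regions": [("N", "B"), ("N", "C"), ("N", "P1"), ("N", "P2")],
    "border_vs_regions": [("B", "C"), ("B", "P1"), ("B", "P2")],
    "center_vs_periphery": [("C", "P1"), ("C", "P2"), ("P1", "P2")],
}


def load_published_pvalues(which: str, alpha: float = 0.05
                           ) -> tuple[ComparisonTable, pd.DataFrame]:
    """Load one published table as (ComparisonTable, printed star mask)."""
    if which not in TABLE_FILES:
        raise ValueError(
            f"unknown table {which!r}; expected one of {sorted(TABLE_FILES)}")
    text = (resources.files(__name__) / TABLE_FILES[which]).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    contrasts = TABLE_CONTRASTS[which]
    expected = [contrast_label(c) for c in contrasts]
    if header[1:] != expected:
        raise FormatError(
            f"fixture {which}: header {header[1:]} != {expected}")
    genes, pvals, stars = [], [], []
    for ln in lines[1:]:
        cells = ln.split("\t")
        gene = GENE_ALIASES.get(cells[0], cells[0])
        row_p, row_s = [], []
        for cell in cells[1:]:
            cell = cell.strip()
            starred = cell.endswith("*")
            row_s.append(starred)
            row_p.append(float(cell.rstrip("*").strip()))
        genes.append(gene)
        pvals.append(row_p)
        stars.append(row_s)
    p = pd.DataFrame(pvals, index=genes, columns=expected, dtype=float)
    star_mask = pd.DataFrame(stars, index=genes, columns=expected, dtype=bool)
    n = pd.DataFrame(PUBLISHED_N, index=genes, columns=expected, dtype=int)
    table = ComparisonTable(p_values=p, contrasts=list(contrasts),
                            alpha=alpha, n_a=n, n_b=n.copy())
    return table, star_mask


def verify_published_counts(alpha: float = 0.05) -> dict:
    """Recompute every per-contrast significance count and the consistent
    marker set from the packaged tables by masking at ``alpha``."""
    out: dict = {"alpha": alpha, "counts": {}, "mask_matches_stars": {}}
    for which in TABLE_FILES:
        table, stars = load_published_pvalues(which, alpha=alpha)
        for c in table.contrasts:
            out["counts"][contrast_label(c)] = table.significance_count(c)
        out["mask_matches_stars"][which] = bool(
            table.mask.equals(stars.astype(bool)))
    normal, _ = load_published_pvalues("normal_vs_regions", alpha=alpha)
    out["consistent_markers_normal"] = normal.consistent_markers()
    return out
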