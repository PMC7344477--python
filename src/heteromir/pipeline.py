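"""End-to-end orchestration: ingest/simulate -> geNorm -> 2^-dCt -> tests.

One call produces, in the output directory:

* ``matrix.tsv`` / ``samples.tsv`` / ``truth.json`` (simulated runs only)
* ``stability.tsv`` — geNorm table (gene, rank, M, V(n/n+1), NF stability)
* ``expr.tsv`` — relative expression against the chosen reference
* ``pvals_normal.tsv`` / ``pvals_border.tsv`` / ``pvals_center_periphery.tsv``
  — the three contrast families of the five-region design
* ``counts.json`` — per-contrast significant-gene counts, consistent-marker
  sets and the reference actually used
* ``run.log`` — versions, seed, effective n and per-cell method decisions

Reference mode "auto" takes the terminal (most stable) pair of the geNorm
ranking after removing genes on the exclusion list; the default exclusion
list holds miRNA-126 and miRNA-125b, which are stable reference candidates
but have documented functional roles in breast cancer.
"""
from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .differential import DEFAULT_CONTRASTS, RegionComparison, contrast_label
from .exceptions import ConfigError, PipelineError
from .genorm import GeNormStability
from .io import (CqMatrix, SampleSheet, read_cq_matrix, read_sample_sheet,
                 write_cq_matrix, write_sample_sheet, write_table)
from .quantify import relative_expression
from .simulate import generate_cohort, preset

logger = logging.getLogger(__name__)

#: Stable reference candidates excluded from "auto" reference selection
#: because of their documented involvement in breast cancer biology.
DEFAULT_REFERENCE_EXCLUSIONS: tuple[str, ...] = ("miRNA-126", "miRNA-125b")

CONTRAST_FAMILIES = {
    "normal": [c for c in DEFAULT_CONTRASTS if c[0] == "N"],
    "border": [c for c in DEFAULT_CONTRASTS if c[0] == "B"],
    "center_periphery": [c for c in DEFAULT_CONTRASTS
                         if c[0] in ("C", "P1") and c[1] != "B"],
}


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of (``cq_path`` + ``sheet_path``) or ``preset`` must be
    supplied.  ``reference`` is either "auto" or an explicit gene list.
    """

    out_dir: str | Path
    cq_path: str | Path | None = None
    sheet_path: str | Path | None = None
    preset: str | None = None
    seed: int | None = None
    reference: str | Sequence[str] = "auto"
    reference_exclusions: Sequence[str] = DEFAULT_REFERENCE_EXCLUSIONS
    ranking_mode: str = "iterative"
    nf_scale: str = "cq"
    contrasts: Sequence[Sequence[str]] = DEFAULT_CONTRASTS
    alpha: float = 0.05

    def __post_init__(self):
        have_paths = self.cq_path is not None and self.sheet_path is not None
        have_preset = self.preset is not None
        if have_paths == have_preset:
            raise ConfigError(
                "supply exactly one of (cq_path and sheet_path) or preset")
        if have_preset and self.seed is None:
            raise ConfigError("simulated runs require a seed")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.ranking_mode not in ("iterative", "single_pass"):
            raise ConfigError(f"unknown ranking mode {self.ranking_mode!r}")


def _select_auto_reference(ranking: Sequence[str],
                           exclusions: Sequence[str]) -> list[str]:
    eligible = [g for g in ranking if g not in set(exclusions)]
    if len(eligible) < 2:
        raise ConfigError(
            "fewer than 2 ranked genes remain after applying the "
            "reference exclusion list")
    return eligible[:2]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain; returns the counts bundle as a dict.

    Any stage failure is re-raised as :class:`PipelineError` carrying the
    stage name, after removing partial outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("heteromir")
    old_level = root.level
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    stage = "setup"
    try:
        logger.info("heteromir %s on python %s; numpy %s, pandas %s",
                    __version__, platform.python_version(),
                    np.__version__, pd.__version__)
        logger.info("config: preset=%s seed=%s reference=%s mode=%s "
                    "alpha=%g", config.preset, config.seed, config.reference,
                    config.ranking_mode, config.alpha)

        stage = "input"
        if config.preset is not None:
            cq, sheet, truth = generate_cohort(
                preset(config.preset, seed=config.seed))
            write_cq_matrix(cq, out_dir / "matrix.tsv")
            write_sample_sheet(sheet, out_dir / "samples.tsv")
            (out_dir / "truth.json").write_text(
                json.dumps(truth, indent=2, sort_keys=True))
            written += [out_dir / "matrix.tsv", out_dir / "samples.tsv",
                        out_dir / "truth.json"]
        else:
            cq = read_cq_matrix(config.cq_path)
            sheet = read_sample_sheet(config.sheet_path)

        stage = "genorm"
        report = GeNormStability(cq, mode=config.ranking_mode,
                                 nf_scale=config.nf_scale).fit()
        write_table(report.to_frame(), out_dir / "stability.tsv")
        written.append(out_dir / "stability.tsv")

        stage = "reference"
        if config.reference == "auto":
            reference = _select_auto_reference(report.ranking,
                                               config.reference_exclusions)
            logger.info("auto reference: %s (terminal pair after excluding "
                        "%s)", reference, list(config.reference_exclusions))
        else:
            reference = list(config.reference)

        stage = "quantify"
        expr = relative_expression(cq, reference)
        write_table(expr, out_dir / "expr.tsv")
        written.append(out_dir / "expr.tsv")

        stage = "compare"
        table = RegionComparison(expr, sheet, config.contrasts,
                                 alpha=config.alpha).fit()
        requested = {tuple(c) for c in config.contrasts}
        for family, members in CONTRAST_FAMILIES.items():
            members = [c for c in members if tuple(c) in requested]
            if not members:
                continue
            cols = [contrast_label(c) for c in members]
            path = out_dir / f"pvals_{family}.tsv"
            write_table(table.p_values[cols], path)
            written.append(path)

        stage = "report"
        counts = {
            "alpha": config.alpha,
            "reference_genes": reference,
            "ranking_mode": config.ranking_mode,
            "stability_ranking": report.ranking,
            "contrast_counts": {
                contrast_label(c): table.significance_count(c)
                for c in table.contrasts},
            "consistent_markers": {
                family: table.consistent_markers(
                    [c for c in members if tuple(c) in requested])
                for family, members in CONTRAST_FAMILIES.items()
                if any(tuple(c) in requested for c in members)},
            "effective_n": {
                contrast_label(c): {
                    "a": int(table.n_a[contrast_label(c)].min()),
                    "b": int(table.n_b[contrast_label(c)].min())}
                for c in table.contrasts},
        }
        (out_dir / "counts.json").write_text(
            json.dumps(counts, indent=2, sort_keys=True) + "\n")
        written.append(out_dir / "counts.json")
        logger.info("wrote %d result files to %s", len(written), out_dir)
        return counts
    except Exception as exc:
        _cleanup(written)
        raise PipelineError(stage, str(exc)) from exc
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()


def _cleanup(paths: list[Path]) -> None:
    for p in paths:
        try:
            p.unlink(missing_ok=True)
        except OSError:  # pragma: no cover - best effort
            pass
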