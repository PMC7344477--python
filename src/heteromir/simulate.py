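"""Synthetic multi-region qPCR cohorts.

Emulates the study design the analysis chain expects: 33 patients, five
tissue regions per patient (adjacent normal N, tumor border B, tumor
center C, two opposite peripheries P1/P2), and a 22-species small-RNA
panel (16 target miRNAs, the snRNAs U6/U54/U58, and the reference
candidates miRNA-100/-143/-204).

The generative model is additive on the Cq scale (equivalently
multiplicative / lognormal on the expression scale):

    Cq[g, (p, r)] = mu_g + shift_g[r] + u_{g,p} + eps

with a per-patient random intercept u ~ N(0, patient_sd_g^2) drawn
independently per gene, residual noise eps ~ N(0, noise_sd_g^2), and the
normal region N anchored at zero shift.  A negative shift means higher
expression in that region (fewer cycles to threshold).  Everything is
deterministic given the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import REGIONS, CqMatrix, SampleSheet

__all__ = ["GeneSpec", "CohortConfig", "generate_cohort", "preset",
           "PANEL", "TARGET_MIRNAS"]

#: The 22-species assay panel, in published stability order.
PANEL: tuple[str, ...] = (
    "miRNA-143", "miRNA-100", "miRNA-126", "miRNA-125b", "miRNA-145",
    "miRNA-20a", "miRNA-21", "miRNA-222", "miRNA-181a", "miRNA-221",
    "miRNA-204", "miRNA-214", "miRNA-30a", "U6", "U58", "miRNA-191",
    "miRNA-99a", "miRNA-200a", "U54", "miRNA-200b", "miRNA-205",
    "miRNA-451a",
)

#: The 16 miRNAs whose regional expression the study reports on.
TARGET_MIRNAS: tuple[str, ...] = (
    "miRNA-20a", "miRNA-21", "miRNA-125b", "miRNA-126", "miRNA-181a",
    "miRNA-200b", "miRNA-205", "miRNA-221", "miRNA-222", "miRNA-451a",
    "miRNA-99a", "miRNA-145", "miRNA-200a", "miRNA-214", "miRNA-30a",
    "miRNA-191",
)


@dataclass
class GeneSpec:
    """Generative parameters for one small RNA.

    mu is the baseline Cq in cycles; region_shift maps region -> delta-Cq
    (N fixed at 0; negative = up-regulated in that region); patient_sd and
    noise_sd are the standard deviations, in cycles, of the per-patient
    intercept and the residual noise.
    """

    name: str
    mu: float
    region_shift: Mapping[str, float] = field(default_factory=dict)
    patient_sd: float = 0.0
    noise_sd: float = 0.5

    def __post_init__(self):
        if not 10.0 <= self.mu <= 40.0:
            raise ConfigError(
                f"gene {self.name!r}: baseline Cq {self.mu} outside the "
                "plausible qPCR range [10, 40]")
        if self.patient_sd < 0 or self.noise_sd < 0:
            raise ConfigError(f"gene {self.name!r}: negative s.d.")
        bad = set(self.region_shift) - set(REGIONS)
        if bad:
            raise ConfigError(
                f"gene {self.name!r}: unknown region(s) in shift map: "
                f"{sorted(bad)}")
        if self.region_shift.get("N", 0.0) != 0.0:
            raise ConfigError(
                f"gene {self.name!r}: region N is the zero-shift anchor")

    def shift(self, region: str) -> float:
        return float(self.region_shift.get(region, 0.0))


@dataclass
class CohortConfig:
    """Design of a synthetic cohort; the seed is mandatory."""

    genes: Sequence[GeneSpec]
    seed: int
    n_patients: int = 33
    regions: Sequence[str] = REGIONS
    #: s.d. of an additional patient intercept shared by all genes (models
    #: sample-quality variation); off by default to keep genes independent.
    shared_patient_sd: float = 0.0
    #: probability that any single Cq measurement is masked as missing.
    missing_rate: float = 0.0
    #: genes designated stable in the ground-truth record.
    stable_genes: tuple[str, ...] = ()
    cq_baseline_range: tuple[float, float] = (20.0, 32.0)

    def __post_init__(self):
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        if self.seed is None:
            raise ConfigError("a seed is mandatory for reproducibility")
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate gene names in config")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        unknown = set(self.regions) - set(REGIONS)
        if unknown:
            raise ConfigError(f"unknown regions: {sorted(unknown)}")


def generate_cohort(config: CohortConfig
                    ) -> tuple[CqMatrix, SampleSheet, dict]:
    """Draw one cohort; returns (CqMatrix, SampleSheet, ground truth).

    One sample per (patient, region); sample identifiers are
    ``<patient>-<region>``.  The ground-truth record echoes every
    generative parameter plus the designated stable genes.
    """
    rng = np.random.default_rng(config.seed)
    patients = [f"PT{i + 1:02d}" for i in range(config.n_patients)]
    regions = list(config.regions)
    samples = [f"{p}-{r}" for p in patients for r in regions]
    n_p, n_r = len(patients), len(regions)

    shared = (rng.normal(0.0, config.shared_patient_sd, n_p)
              if config.shared_patient_sd > 0 else np.zeros(n_p))

    rows = []
    for spec in config.genes:
        u = rng.normal(0.0, spec.patient_sd, n_p) if spec.patient_sd > 0 \
            else np.zeros(n_p)
        eps = rng.normal(0.0, spec.noise_sd, (n_p, n_r)) if spec.noise_sd > 0 \
            else np.zeros((n_p, n_r))
        shifts = np.array([spec.shift(r) for r in regions])
        cq = spec.mu + shifts[None, :] + (u + shared)[:, None] + eps
        rows.append(cq.reshape(-1))
    values = np.vstack(rows) if rows else np.empty((0, len(samples)))
    values = np.maximum(values, 1e-3)  # Cq must stay positive

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    cq = CqMatrix.from_arrays([g.name for g in config.genes], samples, values)
    sheet = SampleSheet.from_records(
        {"sample_id": f"{p}-{r}", "patient_id": p, "region": r}
        for p in patients for r in regions)
    truth = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "regions": regions,
        "stable_genes": list(config.stable_genes),
        "genes": {
            g.name: {
                "mu": g.mu,
                "region_shift": {r: g.shift(r) for r in regions},
                "patient_sd": g.patient_sd,
                "noise_sd": g.noise_sd,
            } for g in config.genes
        },
    }
    return cq, sheet, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# Baseline cycles per species, fixed (arbitrary but plausible, within the
# 20-32 cycle window typical of miRNA RT-qPCR on tissue imprints).
_BASELINES = {name: 20.0 + (i * 7) % 12 + 0.5 * (i % 2)
              for i, name in enumerate(PANEL)}

# Qualitative regional shift pattern for the target miRNAs (cycles on the
# Cq scale; negative = up in tumor).  Magnitudes span 0-2 cycles and are
# largest in P2, echoing the published tables' qualitative pattern: the
# four consistent markers shift in every tumor region, others in some.
_PAPER_LIKE_SHIFTS: dict[str, dict[str, float]] = {
    "miRNA-21":   {"B": -0.8, "C": -1.5, "P1": -1.4, "P2": -2.0},
    "miRNA-200b": {"B": -1.4, "C": -1.6, "P1": -0.8, "P2": -1.6},
    "miRNA-200a": {"B": -1.4, "C": -1.6, "P1": -1.4, "P2": -2.0},
    "miRNA-191":  {"B": -1.2, "C": -0.9, "P1": -1.0, "P2": -2.0},
    "miRNA-20a":  {"B": -0.2, "C": -0.6, "P1": -0.5, "P2": -1.6},
    "miRNA-125b": {"B": 0.2, "C": 0.8, "P1": 1.1, "P2": -1.6},
    "miRNA-126":  {"B": 0.8, "C": 0.1, "P1": 0.1, "P2": 1.1},
    "miRNA-181a": {"B": -0.6, "C": -1.5, "P1": -1.1, "P2": -1.9},
    "miRNA-205":  {"B": 0.0, "C": -0.7, "P1": -0.5, "P2": -1.9},
    "miRNA-221":  {"B": -0.8, "C": -0.1, "P1": 0.0, "P2": -1.8},
    "miRNA-222":  {"B": -0.8, "C": -0.1, "P1": 0.0, "P2": -1.1},
    "miRNA-451a": {"B": 0.4, "C": 0.4, "P1": 1.8, "P2": 0.3},
    "miRNA-99a":  {"B": 1.7, "C": 1.7, "P1": 1.2, "P2": 0.6},
    "miRNA-145":  {"B": 1.1, "C": 0.8, "P1": 0.2, "P2": -1.5},
    "miRNA-214":  {"B": -0.5, "C": 0.0, "P1": -0.3, "P2": -1.1},
    "miRNA-30a":  {"B": -0.8, "C": -1.1, "P1": -1.0, "P2": -0.4},
}

#: Reference candidates kept quiet in paper_like / null presets.
_QUIET = {"miRNA-100": 0.2, "miRNA-143": 0.2, "miRNA-204": 0.35}
_SNRNA_SHIFT = {"U6": {"B": -0.4, "C": 0.6, "P1": 0.5, "P2": -0.9},
                "U54": {"B": 0.5, "C": -0.5, "P1": 0.7, "P2": 1.0},
                "U58": {"B": 0.6, "C": 0.4, "P1": -0.6, "P2": 0.8}}


def _paper_like_genes() -> list[GeneSpec]:
    genes = []
    for name in PANEL:
        mu = _BASELINES[name]
        if name in _QUIET:
            genes.append(GeneSpec(name, mu, {}, patient_sd=0.15,
                                  noise_sd=_QUIET[name]))
        elif name in _SNRNA_SHIFT:
            genes.append(GeneSpec(name, mu, _SNRNA_SHIFT[name],
                                  patient_sd=0.6, noise_sd=0.6))
        else:
            genes.append(GeneSpec(name, mu, _PAPER_LIKE_SHIFTS[name],
                                  patient_sd=0.7, noise_sd=0.5))
    return genes


def preset(name: str, seed: int = 1) -> CohortConfig:
    """Named study conditions.

    "paper_like"
        Full 22-gene panel, heterogeneous 0-2 cycle regional shifts
        (largest in P2), per-patient intercepts; miRNA-100/-143 quiet.
    "null"
        Same panel with every regional shift and every patient intercept
        set to zero — pure measurement noise, for type-I calibration.
    "two_stable_refs"
        Two designated genes (miRNA-100/-143) with 0.05-cycle noise and no
        effects; the other 20 genes noisy (s.d. >= 0.5) with nonzero
        regional shifts — for reference-recovery checks.
    """
    if name == "paper_like":
        return CohortConfig(genes=_paper_like_genes(), seed=seed,
                            stable_genes=("miRNA-100", "miRNA-143"))
    if name == "null":
        genes = []
        for gname in PANEL:
            noise = _QUIET.get(gname, 0.5)
            genes.append(GeneSpec(gname, _BASELINES[gname], {},
                                  patient_sd=0.0, noise_sd=noise))
        return CohortConfig(genes=genes, seed=seed,
                            stable_genes=("miRNA-100", "miRNA-143"))
    if name == "two_stable_refs":
        stable = ("miRNA-100", "miRNA-143")
        genes = []
        i = 0
        for gname in PANEL:
            if gname in stable:
                genes.append(GeneSpec(gname, _BASELINES[gname], {},
                                      patient_sd=0.0, noise_sd=0.05))
                continue
            s = 0.5 + 0.1 * (i % 5)
            shifts = {"B": s, "C": -s, "P1": 0.5 * s + 0.2, "P2": -s - 0.5}
            genes.append(GeneSpec(gname, _BASELINES[gname], shifts,
                                  patient_sd=0.5,
                                  noise_sd=0.5 + 0.05 * (i % 6)))
            i += 1
        return CohortConfig(genes=genes, seed=seed, stable_genes=stable)
    raise ValueError(f"unknown preset: {name!r}")
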