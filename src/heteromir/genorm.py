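"""geNorm-style reference-gene stability analysis for qPCR Cq matrices.

The stability machinery works on pairwise log2 expression ratios.  With
relative expression defined as a = 2^(-Cq) (100% PCR efficiency assumed),
the per-sample log2 ratio between genes j and k reduces to a difference of
cycles::

    A_jk[s] = log2(a_sj / a_sk) = Cq_sk - Cq_sj

The pairwise variation V_jk is the sample standard deviation of A_jk, and a
gene's stability M_j is the arithmetic mean of its V_jk over all other
candidates; lower M means more stable expression.  Iterative ranking
repeatedly drops the least stable gene (highest M) until two genes — the
jointly most stable pair — remain.

Normalization factors (NF) are, by default, per-sample geometric means of
the raw cycles of the n most stable genes ("cq" scale); an expression-scale
variant (geometric mean of 2^-Cq) is available behind ``nf_scale``.
V(n/n+1), the standard deviation of log2(NFn/NF(n+1)) across samples, is
the usual criterion for how many reference genes suffice.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError
from .io import CqMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "log_ratio_vector", "pairwise_variation", "pairwise_variation_matrix",
    "stability_m", "rank_genes", "normalization_factor",
    "nf_pairwise_variation", "nf_stability", "StabilityReport",
    "GeNormStability",
]


def log_ratio_vector(cq: CqMatrix, j: str, k: str) -> pd.Series:
    """Per-sample log2 expression ratio A_jk between genes j and k.

    Equals Cq_k - Cq_j elementwise (expression a = 2^-Cq).  Samples where
    either gene is missing are omitted; sample order is preserved.
    """
    if j == k:
        raise ValueError("log ratio requires two distinct genes")
    a = cq.row(j)
    b = cq.row(k)
    vec = (b - a).dropna()
    if len(vec) < 2:
        raise InsufficientDataError(
            f"fewer than 2 samples complete for pair ({j!r}, {k!r})")
    return vec


def pairwise_variation(a) -> float:
    """Sample standard deviation (ddof=1) of a log-ratio vector."""
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise InsufficientDataError(
            "pairwise variation needs a 1-D vector of length >= 2")
    return float(np.std(arr, ddof=1))


def _as_candidate_array(cq: CqMatrix, candidates: Sequence[str] | None
                        ) -> tuple[list[str], np.ndarray]:
    cand = list(candidates) if candidates is not None else cq.genes
    if len(cand) != len(set(cand)):
        raise ValueError("candidate list contains duplicates")
    missing = [g for g in cand if g not in cq.values.index]
    if missing:
        raise ValueError(f"unknown genes: {missing}")
    return cand, cq.values.loc[cand].to_numpy()


def pairwise_variation_matrix(cq: CqMatrix,
                              candidates: Sequence[str] | None = None
                              ) -> pd.DataFrame:
    """Symmetric matrix of V_jk over every candidate pair (NaN diagonal).

    Each pair uses the samples complete for that pair; a pair with fewer
    than 2 complete samples is an error.
    """
    cand, X = _as_candidate_array(cq, candidates)
    K = len(cand)
    # D[j, k, s] = Cq_ks - Cq_js = A_jk[s]
    D = X[None, :, :] - X[:, None, :]
    valid = ~np.isnan(D)
    n = valid.sum(axis=2)
    off = ~np.eye(K, dtype=bool)
    if np.any(n[off] < 2):
        jj, kk = np.argwhere((n < 2) & off)[0]
        raise InsufficientDataError(
            f"fewer than 2 samples complete for pair "
            f"({cand[jj]!r}, {cand[kk]!r})")
    Dz = np.where(valid, D, 0.0)
    mean = Dz.sum(axis=2) / np.maximum(n, 1)
    ss = np.where(valid, (D - mean[:, :, None]) ** 2, 0.0).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        V = np.sqrt(ss / np.maximum(n - 1, 1))
    np.fill_diagonal(V, np.nan)
    return pd.DataFrame(V, index=cand, columns=cand)


def stability_m(cq: CqMatrix, j: str,
                candidates: Sequence[str] | None = None) -> float:
    """Stability M_j: mean pairwise variation of gene j with each other
    candidate."""
    cand = list(candidates) if candidates is not None else cq.genes
    if j not in cand:
        raise ValueError(f"gene {j!r} not among candidates")
    if len(cand) < 2:
        raise InsufficientDataError("stability needs at least 2 candidates")
    V = pairwise_variation_matrix(cq, cand)
    return float(V.loc[j].mean(skipna=True))


@dataclass
class StabilityReport:
    """Result of a stability analysis; mirrors the layout of a geNorm table.

    Attributes
    ----------
    ranking
        Gene names from most to least stable.
    m_values
        Gene -> stability M recorded at the step the gene was excluded
        (iterative mode) or from the single full-set pass.
    exclusion_step
        Gene -> 1-based exclusion step; the terminal pair shares the last
        step.  Empty in single-pass mode.
    nf_variation
        n -> V(n/n+1) for n = 1..K-1 (None until computed).
    nf_stability
        n -> NF-stability score for n = 1..K (reconstructed definition; the
        value for n = K is NaN because no candidate remains).
    """

    ranking: list[str]
    m_values: dict[str, float]
    mode: str
    exclusion_step: dict[str, int] = field(default_factory=dict)
    nf_variation: dict[int, float] | None = None
    nf_stability: dict[int, float] | None = None
    nf_scale: str = "cq"

    @property
    def terminal_pair(self) -> tuple[str, str]:
        return tuple(self.ranking[:2])  # type: ignore[return-value]

    def to_frame(self) -> pd.DataFrame:
        """Table shaped like a published geNorm summary: one row per gene in
        stability order with M, V(n/n+1) and the NF-stability trace."""
        rows = []
        K = len(self.ranking)
        for i, gene in enumerate(self.ranking, start=1):
            v = (self.nf_variation or {}).get(i - 1, np.nan) if i >= 2 else np.nan
            s = (self.nf_stability or {}).get(i, np.nan) if i >= 2 else np.nan
            rows.append({
                "gene": gene,
                "rank": i,
                "M": self.m_values.get(gene, np.nan),
                "V_name": f"V{i - 1}/{i}" if i >= 2 else "",
                "NF_variation": v,
                "NF_stability_reconstructed": s,
            })
        return pd.DataFrame(rows).set_index("gene")

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"geNorm stability analysis ({self.mode} mode, "
            f"NF scale: {self.nf_scale})",
            f"most stable pair: {self.terminal_pair[0]}, "
            f"{self.terminal_pair[1]}",
            "(NF stability column uses a reconstructed definition)",
            df.to_string(float_format=lambda x: f"{x:.6f}"),
        ]
        return "\n".join(lines)


def _rank_iterative(cq: CqMatrix, cand: list[str]
                    ) -> tuple[list[str], dict[str, float], dict[str, int]]:
    current = list(cand)
    excluded: list[str] = []
    m_values: dict[str, float] = {}
    steps: dict[str, int] = {}
    step = 0
    while len(current) > 2:
        step += 1
        V = pairwise_variation_matrix(cq, current)
        M = V.mean(axis=1, skipna=True)
        worst_m = M.max()
        tied = sorted(g for g in current if M[g] == worst_m)
        if len(tied) > 1:
            logger.info("stability tie at M=%.6g among %s; excluding %r",
                        worst_m, tied, tied[-1])
        worst = tied[-1]  # lexicographically last leaves names ordered
        m_values[worst] = float(M[worst])
        steps[worst] = step
        excluded.append(worst)
        current.remove(worst)
    # terminal pair: mutual M (equal by construction), shared final step
    step += 1
    V = pairwise_variation_matrix(cq, current)
    final_m = float(V.iloc[0, 1])
    pair = sorted(current)
    for g in pair:
        m_values[g] = final_m
        steps[g] = step
    ranking = pair + excluded[::-1]
    return ranking, m_values, steps


def rank_genes(cq: CqMatrix, candidates: Sequence[str] | None = None,
               mode: str = "iterative") -> StabilityReport:
    """Rank candidate genes from most to least stable.

    Iterative mode performs classic stepwise exclusion of the highest-M
    gene until two remain; single-pass mode ranks by one full-set M
    computation.  Ties in M are broken lexicographically by gene name.
    """
    cand, _ = _as_candidate_array(cq, candidates)
    if len(cand) < 3:
        raise ValueError("ranking needs at least 3 candidate genes")
    if mode == "iterative":
        ranking, m_values, steps = _rank_iterative(cq, cand)
        return StabilityReport(ranking=ranking, m_values=m_values,
                               mode=mode, exclusion_step=steps)
    if mode == "single_pass":
        V = pairwise_variation_matrix(cq, cand)
        M = V.mean(axis=1, skipna=True)
        ranking = sorted(cand, key=lambda g: (M[g], g))
        return StabilityReport(ranking=ranking,
                               m_values={g: float(M[g]) for g in cand},
                               mode=mode)
    raise ValueError(f"unknown ranking mode: {mode!r}")


def normalization_factor(cq: CqMatrix, genes: Sequence[str],
                         scale: str = "cq") -> pd.Series:
    """Per-sample normalization factor over the listed genes.

    ``scale="cq"`` (default): geometric mean of the raw quantification
    cycles, in cycles.  ``scale="expression"``: geometric mean of the
    relative quantities 2^-Cq, i.e. 2^(-mean Cq).  Samples missing any
    listed gene get a missing NF.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("normalization factor needs at least one gene")
    missing = [g for g in genes if g not in cq.values.index]
    if missing:
        raise ValueError(f"unknown genes: {missing}")
    sub = cq.values.loc[genes]
    if scale == "cq":
        nf = np.exp(np.log(sub).mean(axis=0, skipna=False))
    elif scale == "expression":
        nf = np.power(2.0, -sub.mean(axis=0, skipna=False))
    else:
        raise ValueError(f"unknown NF scale: {scale!r}")
    nf.name = f"NF{len(genes)}"
    return nf


def nf_pairwise_variation(cq: CqMatrix, ranking: Sequence[str], n: int,
                          scale: str = "cq") -> float:
    """V(n/n+1): s.d. across samples of log2(NFn / NF(n+1)).

    NFn uses the n most stable genes of ``ranking``.  Note the cq-scale NF
    is not invariant to additive shifts of a member gene's cycles (the
    geometric mean of shifted cycles is not the shifted geometric mean),
    unlike the M statistic.
    """
    ranking = list(ranking)
    if not 1 <= n < len(ranking):
        raise ValueError(f"n={n} out of range for ranking of {len(ranking)}")
    nf_n = normalization_factor(cq, ranking[:n], scale=scale)
    nf_n1 = normalization_factor(cq, ranking[:n + 1], scale=scale)
    ratio = np.log2(nf_n / nf_n1).dropna()
    if len(ratio) < 2:
        raise InsufficientDataError(
            f"fewer than 2 samples complete for NF{n}/NF{n + 1}")
    return float(np.std(ratio, ddof=1))


def nf_stability(cq: CqMatrix, ranking: Sequence[str], n: int,
                 candidates: Sequence[str] | None = None,
                 scale: str = "cq") -> float:
    """M-like stability of NFn against the candidates outside the top n.

    Reconstructed definition (not part of the classic algorithm): treat
    log2(NFn) as a pseudo-gene expression profile and average, over every
    candidate g not among the n most stable, the sample standard deviation
    of log2(NFn_s) - log2(a_sg) with a_sg = 2^-Cq_sg.  Returns NaN when no
    candidate remains (n equal to the panel size).
    """
    ranking = list(ranking)
    if not 1 <= n <= len(ranking):
        raise ValueError(f"n={n} out of range for ranking of {len(ranking)}")
    cand = list(candidates) if candidates is not None else ranking
    rest = [g for g in cand if g not in ranking[:n]]
    if not rest:
        return float("nan")
    log_nf = np.log2(normalization_factor(cq, ranking[:n], scale=scale))
    vs = []
    for g in rest:
        # log2 a_sg = -Cq_sg, so the ratio vector is log2(NFn) + Cq_g
        a = (log_nf + cq.row(g)).dropna()
        if len(a) < 2:
            raise InsufficientDataError(
                f"fewer than 2 samples complete for NF{n} vs {g!r}")
        vs.append(np.std(a, ddof=1))
    return float(np.mean(vs))


class GeNormStability:
    """Stability analysis of a Cq matrix, model-object style.

    Parameters
    ----------
    cq
        Gene-by-sample Cq matrix.
    candidates
        Genes to rank (default: every gene in the matrix).
    mode
        "iterative" (classic stepwise exclusion, default) or "single_pass".
    nf_scale
        "cq" (geometric mean of cycles, default) or "expression".

    ``fit()`` returns a :class:`StabilityReport` with the ranking, the M
    values, the successive-NF pairwise variations V(n/n+1) and the
    (reconstructed) NF-stability trace.
    """

    def __init__(self, cq: CqMatrix, candidates: Sequence[str] | None = None,
                 mode: str = "iterative", nf_scale: str = "cq"):
        self.cq = cq
        self.candidates = list(candidates) if candidates is not None else cq.genes
        self.mode = mode
        self.nf_scale = nf_scale

    def fit(self) -> StabilityReport:
        report = rank_genes(self.cq, self.candidates, mode=self.mode)
        K = len(report.ranking)
        report.nf_variation = {
            n: nf_pairwise_variation(self.cq, report.ranking, n,
                                     scale=self.nf_scale)
            for n in range(1, K)
        }
        report.nf_stability = {
            n: nf_stability(self.cq, report.ranking, n, self.candidates,
                            scale=self.nf_scale)
            for n in range(1, K + 1)
        }
        report.nf_scale = self.nf_scale
        return report
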