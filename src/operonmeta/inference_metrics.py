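"""Decision and evaluation statistics on posterior probabilities of
differential expression.

Genes are called differentially expressed when D >= gamma (closed
inequality).  The integration-driven discovery rate (IDR) is the fraction
of meta-analysis calls not made by any individual study at the same
threshold; tIDR restricts both numerator and denominator to genes simulated
as truly differentially expressed.  The posterior expected false discovery
rate (peFDR) of a call set is the mean of (1 - D) over the called genes; it
estimates the expected fraction of false calls without reference to truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CallSet",
    "TruthSet",
    "call_genes",
    "compute_idr",
    "compute_tidr",
    "compute_pefdr",
    "genes_at_pefdr",
    "true_fdr",
    "top_k_true",
]


@dataclass
class CallSet:
    """Genes called differentially expressed at threshold ``gamma``."""

    gamma: float
    called: frozenset[int]
    source: str = "meta"


@dataclass
class TruthSet:
    """Gene indices simulated as differentially expressed."""

    true_genes: frozenset[int]

    def __init__(self, true_genes) -> None:
        object.__setattr__(self, "true_genes", frozenset(int(g) for g in true_genes))


def _as_probs(D) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 1:
        raise ValueError("D must be a 1-D vector of probabilities")
    if np.any((D < 0) | (D > 1)):
        raise ValueError("D entries must lie in [0, 1]")
    return D


def call_genes(D, gamma: float, source: str = "meta") -> CallSet:
    """Call every gene with D >= gamma."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    D = _as_probs(D)
    return CallSet(
        gamma=gamma, called=frozenset(np.flatnonzero(D >= gamma).tolist()), source=source
    )


def compute_idr(meta: CallSet, per_study: list[CallSet]) -> float:
    """Fraction of meta-analysis calls made by no individual study."""
    if not meta.called:
        raise ValueError("IDR undefined: empty meta-analysis call set")
    union: set[int] = set()
    for cs in per_study:
        union |= cs.called
    return len(meta.called - union) / len(meta.called)


def compute_tidr(meta: CallSet, per_study: list[CallSet], truth: TruthSet) -> float:
    """IDR restricted to truly differentially expressed genes: the fraction
    of true meta-analysis discoveries missed by every individual study."""
    base = meta.called & truth.true_genes
    if not base:
        raise ValueError("tIDR undefined: no true genes called in meta-analysis")
    union: set[int] = set()
    for cs in per_study:
        union |= cs.called
    return len(base - union) / len(base)


def compute_pefdr(D, gamma: float) -> float:
    """Posterior expected FDR of the call set at gamma: mean of (1 - D)
    over called genes.  Bounded above by 1 - gamma."""
    D = _as_probs(D)
    called = D >= gamma
    if not called.any():
        raise ValueError(f"peFDR undefined: no gene called at gamma={gamma}")
    return float((1.0 - D[called]).mean())


def _pefdr_prefix_size(D, target: float) -> int:
    D = _as_probs(D)
    order = np.argsort(-D, kind="stable")
    running = np.cumsum(1.0 - D[order]) / np.arange(1, len(D) + 1)
    ok = np.flatnonzero(running <= target)
    return 0 if ok.size == 0 else int(ok[-1]) + 1


def genes_at_pefdr(D, target: float, truth: TruthSet | None = None) -> int:
    """Size of the largest D-ranked prefix whose running peFDR stays at or
    below ``target``; with ``truth``, the number of true genes in that
    prefix.  Ties in D are broken by stable input order."""
    if not 0.0 < target < 1.0:
        raise ValueError("target must lie in (0, 1)")
    k = _pefdr_prefix_size(D, target)
    if truth is None:
        return k
    D = _as_probs(D)
    order = np.argsort(-D, kind="stable")[:k]
    return sum(1 for g in order if int(g) in truth.true_genes)


def true_fdr(calls: CallSet, truth: TruthSet) -> float:
    """Realised FDR of a call set against simulated truth."""
    if not calls.called:
        raise ValueError("true FDR undefined: empty call set")
    return len(calls.called - truth.true_genes) / len(calls.called)


def top_k_true(D, truth: TruthSet, k: int) -> int:
    """Number of true genes among the top-k genes ranked by D (stable
    tie-break by input order)."""
    D = _as_probs(D)
    if not 1 <= k <= len(D):
        raise ValueError("k out of range")
    order = np.argsort(-D, kind="stable")[:k]
    return sum(1 for g in order if int(g) in truth.true_genes)
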