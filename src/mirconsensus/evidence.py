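"""Confidence tiers from expression votes and prediction-tool consensus.

Down-votes D(g) (number of transfection experiments calling the gene
down) are combined with prediction votes P(g) (number of sequence-based
target-prediction tools, out of 12, that call the gene a target) into
explicit tiers:

    high_confidence : (D >= 3 and P >= 10) or D >= 4
    top_candidate   : D >= 3
    candidate       : D >= 2
    none            : otherwise

A gene with P >= 1 is a "potential" predicted target. Enrichment of
predicted targets among the top candidates (relative to the rest of the
candidate set) is tested with a one-sided Fisher exact test computed by
exact log-factorial arithmetic — no normal approximation; the two-sided
p is reported alongside for transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .diffexp import DownVoteTable, harmonize

__all__ = [
    "TierThresholds",
    "Tier",
    "PredictionMatrix",
    "GeneEvidence",
    "EnrichmentResult",
    "classify_tier",
    "evidence_table",
    "enrichment_test",
    "fisher_exact_greater",
]

#: The 12 prediction tools of the consensus (10 aggregator tools plus two
#: stand-alone databases).
DEFAULT_TOOLS = (
    "DIANAmT",
    "miRanda",
    "microCosm",
    "miRDB",
    "miRWalk",
    "RNAhybrid",
    "PicTar4",
    "PicTar5",
    "PITA",
    "RNA22",
    "TargetScan5",
    "TargetScanHuman6",
)


@dataclass(frozen=True)
class TierThresholds:
    """Vote thresholds defining the confidence tiers (all in vote counts)."""

    candidate_min_votes: int = 2  # D for candidate
    top_min_votes: int = 3  # D for top candidate
    alt_high_votes: int = 4  # D alone sufficient for high confidence
    high_min_tools: int = 10  # P required with D >= top_min_votes

    def __post_init__(self) -> None:
        if min(
            self.candidate_min_votes, self.top_min_votes, self.alt_high_votes, self.high_min_tools
        ) <= 0:
            raise ValueError("tier thresholds must be positive")


Tier = str  # "high_confidence" | "top_candidate" | "candidate" | "none"

_TIER_RANK = {"none": 0, "candidate": 1, "top_candidate": 2, "high_confidence": 3}


def classify_tier(D: int, P: int, thresholds: TierThresholds | None = None) -> Tier:
    """Deterministic tier from vote counts D and P (monotone in both)."""
    if D < 0 or P < 0:
        raise ValueError("vote counts must be non-negative")
    t = thresholds or TierThresholds()
    if (D >= t.top_min_votes and P >= t.high_min_tools) or D >= t.alt_high_votes:
        return "high_confidence"
    if D >= t.top_min_votes:
        return "top_candidate"
    if D >= t.candidate_min_votes:
        return "candidate"
    return "none"


@dataclass
class PredictionMatrix:
    """Gene x tool boolean matrix of target predictions.

    ``P`` is the row sum: how many tools predict each gene. Gene symbols
    are harmonized to uppercase.
    """

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.matrix.copy()
        m.index = [harmonize(g) for g in m.index]
        if m.index.has_duplicates:
            raise ValueError("duplicate gene symbols in prediction matrix")
        self.matrix = m.astype(bool)

    @property
    def tools(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def P(self) -> pd.Series:
        return self.matrix.sum(axis=1).astype(int)

    def votes(self, gene: str) -> int:
        g = harmonize(gene)
        if g in self.matrix.index:
            return int(self.matrix.loc[g].sum())
        return 0

    @property
    def predicted_set(self) -> set[str]:
        """Genes predicted by at least one tool ("potential" targets)."""
        p = self.P
        return set(p.index[p >= 1])


@dataclass(frozen=True)
class GeneEvidence:
    gene: str
    D: int
    P: int
    predicted: bool
    tier: Tier


def evidence_table(
    votes: DownVoteTable,
    predictions: PredictionMatrix,
    thresholds: TierThresholds | None = None,
) -> pd.DataFrame:
    """Ranked per-gene evidence: D, P, predicted flag and tier.

    Sorted by descending D, then P, then symbol; includes every gene in
    the vote table (tools that never saw a gene contribute P=0).
    """
    t = thresholds or TierThresholds()
    rows = []
    for gene in votes.genes:
        d = int(votes.D[gene])
        p = predictions.votes(gene)
        rows.append(
            {
                "gene": gene,
                "D": d,
                "P": p,
                "predicted": p >= 1,
                "tier": classify_tier(d, p, t),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["D", "P", "gene"], ascending=[False, False, True], ignore_index=True
    )
    return df


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for the 2x2 table [[a,b],[c,d]].

    Exact hypergeometric tail via log-factorials: probability of drawing
    >= a successes in a+b draws from a population of a+b+c+d containing
    a+c successes. Deterministic, no continuity or normal approximation.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    N = a + b + c + d
    K = a + c  # successes in population
    n = a + b  # draws
    if N == 0:
        raise ValueError("empty table")
    kmax = min(n, K)
    denom = _log_comb(N, n)
    p = 0.0
    for k in range(a, kmax + 1):
        p += math.exp(_log_comb(K, k) + _log_comb(N - K, n - k) - denom)
    return min(p, 1.0)


def _fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of all tables (at fixed margins) with
    point probability <= that of the observed table (with a small
    relative tolerance against floating-point ties)."""
    N = a + b + c + d
    K = a + c
    n = a + b
    denom = _log_comb(N, n)
    kmin = max(0, n - (N - K))
    kmax = min(n, K)
    logp_obs = _log_comb(K, a) + _log_comb(N - K, n - a) - denom
    p = 0.0
    for k in range(kmin, kmax + 1):
        logp = _log_comb(K, k) + _log_comb(N - K, n - k) - denom
        if logp <= logp_obs + 1e-9:
            p += math.exp(logp)
    return min(p, 1.0)


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 enrichment of predicted targets among top candidates.

    Table rows: top candidates vs remaining candidates; columns:
    predicted (P>=1) vs not. ``p`` is the one-sided (greater) exact p;
    ``p_two_sided`` is reported for transparency. ``odds_ratio`` is the
    sample cross-product ratio (inf when the off-diagonal is empty).
    """

    top_predicted: int
    top_unpredicted: int
    rest_predicted: int
    rest_unpredicted: int
    odds_ratio: float
    p: float
    p_two_sided: float


def enrichment_test(
    candidate_set: set[str],
    top_set: set[str],
    predicted_set: set[str],
) -> EnrichmentResult:
    """Are predicted targets over-represented among the top candidates?

    Splits the candidate set by top membership x predicted membership and
    applies the one-sided exact test in the "enriched" direction.
    """
    if not candidate_set:
        raise ValueError("empty candidate set")
    if not top_set <= candidate_set:
        raise ValueError("top set must be a subset of the candidate set")
    rest = candidate_set - top_set
    a = len(top_set & predicted_set)
    b = len(top_set - predicted_set)
    c = len(rest & predicted_set)
    d = len(rest - predicted_set)
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = math.inf if a * d > 0 else math.nan
    return EnrichmentResult(
        top_predicted=a,
        top_unpredicted=b,
        rest_predicted=c,
        rest_unpredicted=d,
        odds_ratio=odds,
        p=fisher_exact_greater(a, b, c, d),
        p_two_sided=_fisher_exact_two_sided(a, b, c, d),
    )
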