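"""Calibrator-anchored down-regulation voting across expression experiments.

Each transfection-vs-control experiment contributes one boolean vote per
gene. For fold-change experiments the down-regulation threshold is not a
fixed cutoff but the fold change of a calibrator gene — a known,
experimentally confirmed target of the transfected miRNA (MTOR for the
miR-99 family) — measured in that same experiment: a gene is down when
its linear fold change is equal to or less than the calibrator's.
Literature-derived experiments contribute a precomputed binary down-list
instead. Votes are summed into D(g), the number of independent
experiments calling gene g down; candidate targets require D >= 2 and
top candidates D >= 3.

Gene symbols are harmonized across species by case-folding to uppercase
(mouse "Hoxa1" and human "HOXA1" merge); no orthology mapping is applied.
Fold changes are linear ratios treated/control throughout — a gene absent
from an experiment's measured universe simply contributes no vote there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

__all__ = [
    "ExperimentMode",
    "ExpressionExperiment",
    "DownVoteTable",
    "calibrator_threshold",
    "down_flags",
    "down_votes",
]


class ExperimentMode(str, Enum):
    FOLD_CHANGE = "fold_change"
    BINARY_LIST = "binary_list"


def harmonize(symbol: str) -> str:
    """Cross-species symbol harmonization: case-fold to uppercase."""
    return symbol.strip().upper()


@dataclass
class ExpressionExperiment:
    """One miRNA-transfection-vs-control expression experiment.

    mode="fold_change": ``fc`` maps gene symbol -> linear fold change
    (treated/control) and ``calibrator`` must name a gene present in
    ``fc``. mode="binary_list": ``down_list`` is a precomputed set of
    down-regulated symbols (e.g. extracted from a publication).
    """

    id: str
    mode: ExperimentMode
    species: str = "human"
    fc: dict[str, float] = field(default_factory=dict)
    down_list: set[str] = field(default_factory=set)
    calibrator: str | None = None
    #: down-list symbols exactly as supplied (pre-harmonization), kept so
    #: species-specific casing round-trips to disk
    raw_down_list: frozenset[str] = field(default_factory=frozenset, repr=False)

    def __post_init__(self) -> None:
        self.mode = ExperimentMode(self.mode)
        if self.mode is ExperimentMode.FOLD_CHANGE:
            if not self.fc:
                raise ValueError(f"experiment {self.id}: empty fold-change table")
            harmonized: dict[str, float] = {}
            for g, v in self.fc.items():
                key = harmonize(g)
                if key in harmonized:
                    raise ValueError(
                        f"experiment {self.id}: duplicate gene {key!r} (ambiguous fold change)"
                    )
                if not v > 0:
                    raise ValueError(f"experiment {self.id}: non-positive fold change for {key!r}")
                harmonized[key] = float(v)
            self.fc = harmonized
            if self.calibrator is None:
                raise ValueError(f"experiment {self.id}: fold-change mode requires a calibrator")
            self.calibrator = harmonize(self.calibrator)
            if self.calibrator not in self.fc:
                raise ValueError(
                    f"experiment {self.id}: calibrator {self.calibrator!r} not measured; "
                    "cannot self-calibrate the down-regulation threshold"
                )
        else:
            if not self.down_list:
                raise ValueError(f"experiment {self.id}: empty down-regulated gene list")
            self.raw_down_list = frozenset(str(g).strip() for g in self.down_list)
            self.down_list = {harmonize(g) for g in self.down_list}

    @property
    def universe(self) -> set[str]:
        """Harmonized symbols measured (or listed) in this experiment."""
        if self.mode is ExperimentMode.FOLD_CHANGE:
            return set(self.fc)
        return set(self.down_list)


def calibrator_threshold(exp: ExpressionExperiment) -> float:
    """The experiment's down-regulation threshold: the calibrator's own fold change."""
    if exp.mode is not ExperimentMode.FOLD_CHANGE:
        raise ValueError(f"experiment {exp.id}: no calibrator threshold in binary-list mode")
    return exp.fc[exp.calibrator]


def down_flags(exp: ExpressionExperiment) -> dict[str, bool]:
    """Per-gene down-regulation call for one experiment.

    Fold-change mode: fc <= calibrator fold change, inclusive at equality
    (a gene tied with the calibrator counts as down). Binary mode: list
    membership. Keys are harmonized uppercase symbols.
    """
    if exp.mode is ExperimentMode.FOLD_CHANGE:
        thr = calibrator_threshold(exp)
        return {g: fc <= thr for g, fc in exp.fc.items()}
    return {g: True for g in exp.down_list}


@dataclass
class DownVoteTable:
    """Vote matrix and per-gene vote counts across experiments.

    ``flags`` is a gene x experiment boolean DataFrame (genes sorted,
    experiment columns in input order); ``D`` its row sum. Genes never
    seen in an experiment's universe contribute False in that column —
    absence of evidence, not missing data.
    """

    flags: pd.DataFrame
    D: pd.Series
    candidate_min_votes: int = 2
    top_min_votes: int = 3

    @property
    def genes(self) -> list[str]:
        return list(self.flags.index)

    @property
    def candidate_set(self) -> set[str]:
        return set(self.D.index[self.D >= self.candidate_min_votes])

    @property
    def top_set(self) -> set[str]:
        return set(self.D.index[self.D >= self.top_min_votes])


def down_votes(
    experiments: list[ExpressionExperiment],
    *,
    candidate_min_votes: int = 2,
    top_min_votes: int = 3,
) -> DownVoteTable:
    """Aggregate per-experiment down calls into D(g) vote counts.

    D is invariant to experiment order and monotone under adding
    experiments.
    """
    if not experiments:
        raise ValueError("at least one experiment required")
    ids = [e.id for e in experiments]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate experiment ids")
    per_exp = {e.id: down_flags(e) for e in experiments}
    genes = sorted(set().union(*(f.keys() for f in per_exp.values())))
    flags = pd.DataFrame(
        {eid: [per_exp[eid].get(g, False) for g in genes] for eid in ids},
        index=pd.Index(genes, name="gene"),
        dtype=bool,
    )
    return DownVoteTable(
        flags=flags,
        D=flags.sum(axis=1).astype(int),
        candidate_min_votes=candidate_min_votes,
        top_min_votes=top_min_votes,
    )
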