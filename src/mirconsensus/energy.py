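"""Intermolecular RNA:RNA duplex minimum free energy.

Scores the hybridization of a microRNA against a target-site context
window with a nearest-neighbor dynamic program, in the spirit of
hybridization-only tools: base pairs must be monotone along both strands
(the duplex is antiparallel, so miRNA 5'->3' positions pair with target
positions running 3'->5'), neither strand may fold back on itself, and
interior loops / bulges are bounded per side by ``max_loop``.

Energy model::

    E = duplex_init + sum(stack energies over adjacent pair doublets)
                    + sum(loop penalties over non-adjacent pair gaps)

Stacking applies only to immediately adjacent pairs; a gap of a unpaired
miRNA nucleotides and b unpaired target nucleotides between consecutive
pairs costs a size-dependent bulge (a or b zero) or interior-loop penalty.
Watson-Crick and G:U wobble pairs are allowed. Parameters ship as a
versioned TSV (`data/stack_params.tsv`); dangling-end and loop-asymmetry
terms are deliberately omitted.

A duplex is only reported if it contains at least two consecutive
(stacked) base pairs; otherwise there is "no stable duplex" and the mfe
is ``None``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .sites import MatureMiRNA, TargetSite, TranscriptRecord, normalize_rna

__all__ = [
    "EnergyParameters",
    "DuplexResult",
    "duplex_mfe",
    "score_sites",
    "structure_energy",
    "load_parameters",
]

#: Base pairs permitted in the duplex (miRNA base, target base).
ALLOWED_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)
_WC_PAIRS = frozenset([("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")])


def _reverse_doublet(key: str) -> str:
    # XY/WZ read from the other end of the duplex is ZW/YX
    x, y, w, z = key[0], key[1], key[3], key[4]
    return f"{z}{w}/{y}{x}"


@dataclass(frozen=True)
class EnergyParameters:
    """Nearest-neighbor parameter set for intermolecular duplex scoring.

    ``stack_energy`` maps every doublet key "XY/WZ" (5'-XY-3' over
    3'-WZ-5') formed from allowed pairs to kcal/mol; the table is closed
    under reversal symmetry. Loop penalties are ``base + c*ln(size)`` with
    separate bases for bulges and interior loops; they are non-negative
    and non-decreasing in size.
    """

    stack_energy: dict[str, float]
    duplex_init: float
    bulge_base: float
    internal_base: float
    loop_log_coeff: float
    max_loop: int
    source: str = "builtin"

    def __post_init__(self) -> None:
        for key, e in self.stack_energy.items():
            p1 = (key[0], key[3])
            p2 = (key[1], key[4])
            if p1 in _WC_PAIRS and p2 in _WC_PAIRS and e >= 0:
                raise ValueError(f"Watson-Crick stack {key} must be stabilizing, got {e}")
            rev = _reverse_doublet(key)
            if not math.isclose(self.stack_energy.get(rev, math.nan), e):
                raise ValueError(f"stack table not reversal-symmetric at {key}/{rev}")

    def loop_penalty(self, a: int, b: int) -> float:
        """Penalty for a gap of ``a`` unpaired miRNA and ``b`` target nt."""
        total = a + b
        if total <= 0:
            raise ValueError("loop penalty undefined for adjacent pairs")
        base = self.bulge_base if (a == 0 or b == 0) else self.internal_base
        return base + self.loop_log_coeff * math.log(total)

    def stack(self, x1: str, x2: str, w1: str, w2: str) -> float:
        """Stack energy for pairs x1:w1 and x2:w2 read 5'-x1x2-3'/3'-w1w2-5'."""
        return self.stack_energy[f"{x1}{x2}/{w1}{w2}"]


def load_parameters(path: str | Path | None = None) -> EnergyParameters:
    """Load duplex parameters from TSV (defaults to the shipped table)."""
    if path is None:
        text = resources.files("mirconsensus.data").joinpath("stack_params.tsv").read_text()
        source = "builtin:stack_params.tsv"
    else:
        text = Path(path).read_text()
        source = str(path)
    stacks: dict[str, float] = {}
    params: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("record\t"):
            continue
        kind, key, value = line.split("\t")
        if kind == "stack":
            stacks[key] = float(value)
            stacks.setdefault(_reverse_doublet(key), float(value))
        elif kind == "param":
            params[key] = float(value)
        else:
            raise ValueError(f"unknown record type {kind!r} in {source}")
    return EnergyParameters(
        stack_energy=stacks,
        duplex_init=params["duplex_init"],
        bulge_base=params["bulge_base"],
        internal_base=params["internal_base"],
        loop_log_coeff=params["loop_log_coeff"],
        max_loop=int(params["max_loop"]),
        source=source,
    )


_DEFAULT_PARAMS: EnergyParameters | None = None


def default_parameters() -> EnergyParameters:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = load_parameters()
    return _DEFAULT_PARAMS


@dataclass
class DuplexResult:
    """Outcome of hybridizing one miRNA against one target window.

    ``pairing`` lists (miRNA position, target position), both 1-based,
    miRNA positions strictly increasing and target positions strictly
    decreasing (antiparallel duplex). ``mfe`` is ``None`` when no
    structure with at least two consecutive pairs exists.
    """

    mirna_seq: str
    target_seq: str
    mfe: float | None
    pairing: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    def render(self) -> str:
        """Text rendering: target 5'->3' on top, miRNA 3'->5' below."""
        if self.mfe is None:
            return "no stable duplex"
        t, m = self.target_seq, self.mirna_seq
        top, bars, bot = [], [], []
        # walk the duplex from the target 5' side; miRNA runs 3'->5'
        pairs = sorted(self.pairing, key=lambda p: p[1])  # ascending target pos
        ti = 1
        mi = len(m)  # current unplaced miRNA pos (3' side first)
        for mpos, tpos in pairs:  # target ascending = miRNA descending
            gap_t = t[ti - 1 : tpos - 1]
            gap_m = m[mpos:mi][::-1]
            w = max(len(gap_t), len(gap_m))
            top.append(gap_t.ljust(w, "-"))
            bars.append(" " * w)
            bot.append(gap_m.ljust(w, "-"))
            top.append(t[tpos - 1])
            bars.append("|")
            bot.append(m[mpos - 1])
            ti = tpos + 1
            mi = mpos - 1
        tail_t = t[ti - 1 :]
        tail_m = m[:mi][::-1]
        w = max(len(tail_t), len(tail_m))
        top.append(tail_t.ljust(w, "-"))
        bars.append(" " * w)
        bot.append(tail_m.ljust(w, "-"))
        return (
            f"target 5' {''.join(top)} 3'\n"
            f"          {''.join(bars)}\n"
            f"miRNA  3' {''.join(bot)} 5'\n"
            f"mfe: {self.mfe:.2f} kcal/mol"
        )


def structure_energy(
    pairing: tuple[tuple[int, int], ...] | list[tuple[int, int]],
    mirna_seq: str,
    target_seq: str,
    params: EnergyParameters | None = None,
) -> float:
    """Total energy of an explicit pairing under the parameter set.

    Independent of the DP: walks the pairing, summing initiation, stacks
    for adjacent pairs and loop penalties for gapped ones. Raises on
    non-monotone or disallowed pairings.
    """
    params = params or default_parameters()
    x = normalize_rna(str(mirna_seq), what="miRNA")
    y = normalize_rna(str(target_seq), what="target window")
    pairs = sorted(pairing)
    if not pairs:
        raise ValueError("empty pairing")
    for mi, tj in pairs:
        if not (1 <= mi <= len(x) and 1 <= tj <= len(y)):
            raise ValueError(f"pair ({mi},{tj}) out of range")
        if (x[mi - 1], y[tj - 1]) not in ALLOWED_PAIRS:
            raise ValueError(f"disallowed pair ({mi},{tj}): {x[mi-1]}:{y[tj-1]}")
    e = params.duplex_init
    for (m1, t1), (m2, t2) in zip(pairs, pairs[1:]):
        if m2 <= m1 or t2 >= t1:
            raise ValueError("pairing not monotone (antiparallel) in both strands")
        a, b = m2 - m1 - 1, t1 - t2 - 1
        if a == 0 and b == 0:
            e += params.stack(x[m1 - 1], x[m2 - 1], y[t1 - 1], y[t2 - 1])
        else:
            e += params.loop_penalty(a, b)
    return e


def duplex_mfe(
    mirna: MatureMiRNA | str,
    window: str,
    params: EnergyParameters | None = None,
    *,
    max_loop: int | None = None,
) -> DuplexResult:
    """Minimum-free-energy intermolecular duplex between miRNA and window.

    Dynamic program over pairs (i, j): miRNA position i (5'->3') against
    target position j, monotone antiparallel, with per-side gap bound
    ``max_loop``. Ties are broken toward more paired bases, then the
    lexicographically smallest pairing, so results are reproducible.
    """
    params = params or default_parameters()
    ml = params.max_loop if max_loop is None else max_loop
    x = normalize_rna(str(mirna.sequence if isinstance(mirna, MatureMiRNA) else mirna), what="miRNA")
    y = normalize_rna(str(window), what="target window")
    if len(y) < 2:
        raise ValueError("target window must be at least 2 nt")
    m, n = len(x), len(y)
    yr = y[::-1]  # yr[j] is y position n-j (1-based)

    # cell value: (energy, -n_pairs, pairing) with pairing in original
    # coordinates; tuple comparison implements the tie-break.
    free: list[list[tuple | None]] = [[None] * n for _ in range(m)]  # no stack yet
    stk: list[list[tuple | None]] = [[None] * n for _ in range(m)]  # >=1 stack
    best: tuple | None = None

    for i in range(m):
        xi = x[i]
        for j in range(n):
            if (xi, yr[j]) not in ALLOWED_PAIRS:
                continue
            pair = (i + 1, n - j)
            cand_free: tuple | None = (params.duplex_init, -1, (pair,))
            cand_stk: tuple | None = None
            for pi in range(max(0, i - 1 - ml), i):
                a = i - pi - 1
                for pj in range(max(0, j - 1 - ml), j):
                    b = j - pj - 1
                    if a == 0 and b == 0:
                        for prev in (free[pi][pj], stk[pi][pj]):
                            if prev is None:
                                continue
                            de = params.stack_energy[x[pi] + xi + "/" + yr[pj] + yr[j]]
                            cand = (prev[0] + de, prev[1] - 1, prev[2] + (pair,))
                            if cand_stk is None or cand < cand_stk:
                                cand_stk = cand
                    else:
                        de = params.loop_penalty(a, b)
                        prev = free[pi][pj]
                        if prev is not None:
                            cand = (prev[0] + de, prev[1] - 1, prev[2] + (pair,))
                            if cand < cand_free:
                                cand_free = cand
                        prev = stk[pi][pj]
                        if prev is not None:
                            cand = (prev[0] + de, prev[1] - 1, prev[2] + (pair,))
                            if cand_stk is None or cand < cand_stk:
                                cand_stk = cand
            free[i][j] = cand_free
            stk[i][j] = cand_stk
            if cand_stk is not None and (best is None or cand_stk < best):
                best = cand_stk

    if best is None:
        return DuplexResult(mirna_seq=x, target_seq=y, mfe=None)
    return DuplexResult(mirna_seq=x, target_seq=y, mfe=best[0], pairing=best[2])


def score_sites(
    sites: list[TargetSite],
    tx: TranscriptRecord,
    mirna: MatureMiRNA,
    params: EnergyParameters | None = None,
) -> list[TargetSite]:
    """Fill each site's mfe from its context window; returns the same sites."""
    params = params or default_parameters()
    for site in sites:
        if site.transcript_id != tx.id:
            raise ValueError(f"site transcript {site.transcript_id} != {tx.id}")
        window = tx.rna[site.window_start - 1 : site.window_end]
        site.mfe = duplex_mfe(mirna, window, params).mfe
    return sites
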