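"""Independent brute-force oracles used across the test suite.

Everything here deliberately avoids the package's optimized code paths:
duplex energies come from exhaustive enumeration of monotone pairings,
Fisher p-values from direct enumeration of 2x2 tables at fixed margins,
seed sites from a naive character-by-character substring check, and
vote counts from recounting the raw emitted files.
"""

from __future__ import annotations

import csv
import math
from fractions import Fraction
from pathlib import Path

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_ALLOWED = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def enumerate_duplex_mfe(x: str, y: str, params, max_loop: int | None = None):
    """Minimum energy over ALL monotone antiparallel pairings, by DFS.

    Returns None when no structure with at least two consecutive pairs
    exists. Energy arithmetic mirrors the stated model (initiation +
    stacks + loop penalties) but shares no code with the DP.
    """
    ml = params.max_loop if max_loop is None else max_loop
    m, n = len(x), len(y)
    yr = y[::-1]
    cells = [(i, j) for i in range(m) for j in range(n) if (x[i], yr[j]) in _ALLOWED]
    best: list[float | None] = [None]

    def extend(i: int, j: int, energy: float, has_stack: bool) -> None:
        if has_stack and (best[0] is None or energy < best[0]):
            best[0] = energy
        for i2 in range(i + 1, min(m, i + 2 + ml)):
            a = i2 - i - 1
            for j2 in range(j + 1, min(n, j + 2 + ml)):
                if (x[i2], yr[j2]) not in _ALLOWED:
                    continue
                b = j2 - j - 1
                if a == 0 and b == 0:
                    de = params.stack_energy[x[i] + x[i2] + "/" + yr[j] + yr[j2]]
                    extend(i2, j2, energy + de, True)
                else:
                    extend(i2, j2, energy + params.loop_penalty(a, b), has_stack)

    for i, j in cells:
        extend(i, j, params.duplex_init, False)
    return best[0]


def fisher_greater_exact(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p by exact rational enumeration of tables."""
    N, K, n = a + b + c + d, a + c, a + b
    total = Fraction(math.comb(N, n))
    p = Fraction(0)
    for k in range(a, min(n, K) + 1):
        if n - k > N - K:
            continue
        p += Fraction(math.comb(K, k) * math.comb(N - K, n - k))
    return float(p / total)


def naive_seed_sites(sequence: str, seed: str) -> list[int]:
    """1-based start positions where the seed's reverse complement sits,
    checked base by base (no str.find)."""
    rna = sequence.upper().replace("T", "U")
    needle = [_COMPLEMENT[c] for c in reversed(seed)]
    out = []
    for start in range(len(rna) - 6):
        if all(rna[start + k] == needle[k] for k in range(7)):
            out.append(start + 1)
    return out


def recount_votes_from_files(data_dir: Path) -> dict[str, int]:
    """Re-derive D(g) straight from the emitted experiment files."""
    data_dir = Path(data_dir)
    votes: dict[str, int] = {}
    for fc_file in sorted(data_dir.glob("*.fc.tsv")):
        rows = list(csv.DictReader(fc_file.open(), delimiter="\t"))
        table = {r["gene"].upper(): float(r["fold_change"]) for r in rows}
        threshold = table["MTOR"]
        for gene, fc in table.items():
            if fc <= threshold:
                votes[gene] = votes.get(gene, 0) + 1
            else:
                votes.setdefault(gene, 0)
    for list_file in sorted(data_dir.glob("*.down.tsv")):
        for line in list_file.read_text().splitlines():
            gene = line.strip().upper()
            if gene:
                votes[gene] = votes.get(gene, 0) + 1
    return votes


def recount_predictions_from_file(path: Path) -> dict[str, int]:
    """Re-derive P(g) from the emitted prediction matrix."""
    out: dict[str, int] = {}
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            gene = row.pop("gene").upper()
            out[gene] = sum(int(v) for v in row.values())
    return out


def pearson_manual(x, y) -> float:
    """Product-moment r from raw sums, no numpy."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
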