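"""Seed-complementary target-site discovery on annotated transcripts.

A canonical microRNA target site is defined by perfect Watson-Crick
complementarity between the miRNA seed (nucleotides 2-8 of the mature
sequence, 1-based) and the mRNA sense strand.  The scanner reports every
such 7-nt match, labels it with the transcript region that contains it
(5'UTR / CDS / 3'UTR), and attaches a context window used downstream for
duplex free-energy scoring.  Reporter-construct helpers extract arbitrary
1-based-inclusive fragments and abolish a site by replacing its 7-nt seed
match with a poly-T/poly-U run, mirroring standard luciferase-assay
mutagenesis of seed pairing.

All coordinates in this module are 1-based and inclusive at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "MatureMiRNA",
    "Region",
    "TranscriptRecord",
    "TargetSite",
    "Fragment",
    "seed_sequence",
    "scan_seed_sites",
    "extract_fragment",
    "mutate_seed_match",
    "reverse_complement_rna",
]

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_VALID_RNA = frozenset("ACGU")

#: Flank added on each side of a seed match to form the energy-scoring
#: context window (nt).  Approximates the ~54-57 nt fragments typically
#: cloned into reporter constructs.
DEFAULT_WINDOW_FLANK = 25


def normalize_rna(seq: str, *, what: str = "sequence") -> str:
    """Uppercase and convert T->U; reject non-ACGU characters."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - _VALID_RNA
    if bad:
        raise ValueError(f"{what} contains invalid characters: {sorted(bad)}")
    return s


def reverse_complement_rna(seq: str) -> str:
    return "".join(_RNA_COMPLEMENT[c] for c in reversed(seq))


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature microRNA, stored 5'->3' as RNA.

    The seed is nucleotides 2-8 (1-based inclusive), the principal
    determinant of canonical target recognition.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence, what=f"miRNA {self.name}"))
        if len(self.sequence) < 8:
            raise ValueError(
                f"miRNA {self.name}: sequence must be at least 8 nt to define a seed "
                f"(got {len(self.sequence)})"
            )

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 (7 nt)."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class Region:
    """One annotated transcript region, 1-based inclusive."""

    label: str  # 5UTR | CDS | 3UTR
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region span {self.label}:{self.start}-{self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


_REGION_ORDER = {"5UTR": 0, "CDS": 1, "3UTR": 2}


@dataclass(frozen=True)
class TranscriptRecord:
    """An mRNA sequence (sense strand, 5'->3') with region annotations.

    The raw input alphabet (DNA or RNA, any case) is preserved in
    ``sequence``; scanning happens on a normalized RNA copy.
    """

    id: str
    sequence: str
    regions: tuple[Region, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        rna = normalize_rna(self.sequence, what=f"transcript {self.id}")
        object.__setattr__(self, "_rna", rna)
        n = len(rna)
        prev_end = 0
        prev_order = -1
        for r in self.regions:
            if r.end > n:
                raise ValueError(f"transcript {self.id}: region {r.label} exceeds length {n}")
            if r.start <= prev_end:
                raise ValueError(f"transcript {self.id}: overlapping/unordered regions")
            order = _REGION_ORDER.get(r.label)
            if order is None:
                raise ValueError(f"transcript {self.id}: unknown region label {r.label!r}")
            if order <= prev_order:
                raise ValueError(f"transcript {self.id}: regions out of 5UTR<CDS<3UTR order")
            prev_end = r.end
            prev_order = order

    @property
    def rna(self) -> str:
        """Normalized RNA copy of the sequence."""
        return self._rna  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self.sequence)

    def region_at(self, pos: int) -> str:
        """Region label containing 1-based position ``pos`` ("unannotated" if none)."""
        for r in self.regions:
            if r.contains(pos):
                return r.label
        return "unannotated"


@dataclass
class TargetSite:
    """One seed-complementary site on a transcript.

    ``seed_match_start``..``seed_match_end`` (1-based inclusive, length 7)
    hold the reverse complement of the miRNA seed on the transcript sense
    strand.  ``site_class`` is "8mer" when the nucleotide opposite miRNA
    position 1 (immediately 3' of the seed match on the target) is an A,
    else "7mer-m8"; the class annotates but never gates a site call.
    ``mfe`` (kcal/mol) is filled by the energy module.
    """

    transcript_id: str
    seed_match_start: int
    seed_match_end: int
    region_label: str
    window_start: int
    window_end: int
    site_class: str = "7mer-m8"
    mfe: float | None = None

    def __post_init__(self) -> None:
        if self.seed_match_end - self.seed_match_start + 1 != 7:
            raise ValueError("seed match must span exactly 7 nt")


@dataclass(frozen=True)
class Fragment:
    """A transcript subsequence that remembers its 1-based coordinates."""

    transcript_id: str
    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def seed_sequence(mirna: MatureMiRNA) -> str:
    """Return the 7-nt seed: mature-sequence positions 2-8, 1-based inclusive."""
    return mirna.seed


def scan_seed_sites(
    tx: TranscriptRecord,
    mirna: MatureMiRNA,
    *,
    window_flank: int = DEFAULT_WINDOW_FLANK,
) -> list[TargetSite]:
    """Find every perfect seed-complementary site on the transcript.

    Reports each position where the sense strand contains the reverse
    complement of the miRNA seed, Watson-Crick pairing only (no G:U in the
    seed).  Only the given strand is searched: mRNA targeting is
    single-stranded by nature.  Sites are returned 5'->3' by start.
    """
    rna = tx.rna
    if len(rna) < 7:
        return []
    needle = reverse_complement_rna(mirna.seed)
    sites: list[TargetSite] = []
    pos = rna.find(needle)
    while pos != -1:
        start = pos + 1  # to 1-based
        end = start + 6
        # miRNA position 1 sits opposite the target nt just 3' of the match
        t1 = rna[end] if end < len(rna) else ""
        site_class = "8mer" if t1 == "A" else "7mer-m8"
        sites.append(
            TargetSite(
                transcript_id=tx.id,
                seed_match_start=start,
                seed_match_end=end,
                region_label=tx.region_at(start),
                window_start=max(1, start - window_flank),
                window_end=min(len(rna), end + window_flank),
                site_class=site_class,
            )
        )
        pos = rna.find(needle, pos + 1)
    return sites


def extract_fragment(tx: TranscriptRecord, start: int, end: int) -> Fragment:
    """Extract positions ``start``..``end`` (1-based inclusive).

    The returned fragment length is ``end - start + 1`` and the original
    input alphabet is preserved.
    """
    if not (1 <= start <= end <= len(tx.sequence)):
        raise ValueError(
            f"fragment {start}-{end} out of bounds for transcript {tx.id} "
            f"of length {len(tx.sequence)}"
        )
    return Fragment(tx.id, start, end, tx.sequence[start - 1 : end])


def mutate_seed_match(fragment: Fragment, site: TargetSite) -> Fragment:
    """Replace the site's 7-nt seed match with a poly-T (poly-U) run.

    Mirrors reporter-assay mutagenesis: the seed-pairing nucleotides are
    replaced wholesale, abolishing the site while leaving fragment length
    and every other base unchanged.  The replacement uses T for DNA-alphabet
    fragments and U for RNA-alphabet ones.
    """
    if site.transcript_id != fragment.transcript_id:
        raise ValueError("site and fragment come from different transcripts")
    if not (fragment.start <= site.seed_match_start and site.seed_match_end <= fragment.end):
        raise ValueError(
            f"site {site.seed_match_start}-{site.seed_match_end} lies outside "
            f"fragment {fragment.start}-{fragment.end}"
        )
    off = site.seed_match_start - fragment.start
    base = "U" if "U" in fragment.sequence.upper() else "T"
    mutated = fragment.sequence[:off] + base * 7 + fragment.sequence[off + 7 :]
    return replace(fragment, sequence=mutated)
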