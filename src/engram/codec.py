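"""Barcode vocabularies, insertion extraction and editing statistics.

Recorders write short insertional barcodes ("symbols") to a DNA Tape; this
module designs distance-separated barcode sets, pulls insertions out of
amplicon reads by exact flank matching, error-corrects them against the
vocabulary (unique Hamming-1 neighbours), applies the minimum-read filter,
and computes the plasmid-normalised editing score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping

from ._util import BASES, check_nucleotides, hamming, reverse_complement, rng_for

UNEDITED_KEY = "__unedited__"
UNASSIGNED_KEY = "__unassigned__"


class CapacityError(ValueError):
    """Requested vocabulary size is infeasible for (k, min_dist)."""


class UndefinedScoreError(ZeroDivisionError):
    """Editing score undefined (zero plasmid count or no edited reads)."""


@dataclass(frozen=True)
class BarcodeVocabulary:
    """A set of equal-length barcodes with guaranteed pairwise separation.

    Parameters
    ----------
    k:
        Barcode length in bp.
    entries:
        Mapping symbol_id -> barcode sequence (A/C/G/T, length ``k``).
    min_dist:
        Minimum pairwise Hamming distance enforced at construction
        (default 3, which makes Hamming-1 correction unambiguous).
    """

    k: int
    entries: Mapping[str, str]
    min_dist: int = 3

    def __post_init__(self) -> None:
        for sym, seq in self.entries.items():
            check_nucleotides(seq)
            if len(seq) != self.k:
                raise ValueError(f"barcode {sym!r}={seq!r} is not length {self.k}")
        if len(set(self.entries.values())) != len(self.entries):
            raise ValueError("duplicate barcode sequences in vocabulary")
        for (sa, a), (sb, b) in combinations(self.entries.items(), 2):
            d = hamming(a, b)
            if d < self.min_dist:
                raise ValueError(
                    f"barcodes {sa!r}/{sb!r} at Hamming distance {d} < {self.min_dist}"
                )

    @property
    def symbols(self) -> list[str]:
        return list(self.entries)

    def sequence_to_symbol(self) -> dict[str, str]:
        return {seq: sym for sym, seq in self.entries.items()}

    def correct(self, seq: str) -> str | None:
        """Assign a sequence to a symbol: exact match, else unique Hamming-1
        neighbour; ``None`` if unassignable (distance >1 everywhere, or tied).
        """
        if len(seq) != self.k:
            raise ValueError(f"sequence {seq!r} is not length {self.k}")
        hits = [sym for sym, bc in self.entries.items() if bc == seq]
        if hits:
            return hits[0]
        near = [sym for sym, bc in self.entries.items() if hamming(bc, seq) == 1]
        if len(near) == 1:
            return near[0]
        if len(near) > 1 and self.min_dist >= 3:
            raise AssertionError(
                "Hamming-1 tie is impossible for a min_dist>=3 vocabulary"
            )
        return None


def design_vocabulary(
    k: int, n: int, min_dist: int = 3, seed: int = 0, max_attempts: int | None = None
) -> BarcodeVocabulary:
    """Greedy random design of ``n`` length-``k`` barcodes with pairwise
    Hamming distance >= ``min_dist``.

    Deterministic given ``seed``. Raises :class:`CapacityError` when the
    requested set cannot be assembled after a bounded number of rejected
    draws (including the trivially infeasible ``min_dist > k`` with n > 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1 <= min_dist <= k:
        if n > 1:
            raise CapacityError(f"min_dist {min_dist} > k {k}: no two k-mers qualify")
        min_dist = k  # single barcode: separation is vacuous
    rng = rng_for(seed, f"vocab/k={k}/n={n}/d={min_dist}")
    if max_attempts is None:
        max_attempts = 2000 * n
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < n:
        if attempts >= max_attempts:
            raise CapacityError(
                f"could not place {n} barcodes (k={k}, min_dist={min_dist}) "
                f"after {max_attempts} draws; got {len(chosen)}"
            )
        attempts += 1
        cand = "".join(BASES[i] for i in rng.integers(0, 4, size=k))
        if all(hamming(cand, prev) >= min_dist for prev in chosen):
            chosen.append(cand)
    entries = {f"S{i + 1:03d}": seq for i, seq in enumerate(chosen)}
    return BarcodeVocabulary(k=k, entries=entries, min_dist=min_dist)


@dataclass(frozen=True)
class TargetContext:
    """Flanking sequence context of the insertion site in the amplicon."""

    left_flank: str
    right_flank: str
    insertion_len: int

    def __post_init__(self) -> None:
        check_nucleotides(self.left_flank)
        check_nucleotides(self.right_flank)
        if not self.left_flank or not self.right_flank:
            raise ValueError("flanks must be non-empty")
        if self.insertion_len < 1:
            raise ValueError("insertion_len must be >= 1")


@dataclass
class CountTable:
    """Per-symbol read counts for one sample.

    Invariant: ``sum(counts) + unedited + unassigned == total_reads``.
    """

    counts: dict[str, int] = field(default_factory=dict)
    unedited: int = 0
    unassigned: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()) or self.unedited < 0 or self.unassigned < 0:
            raise ValueError("counts must be non-negative")

    @property
    def edited_total(self) -> int:
        return sum(self.counts.values())

    @property
    def total_reads(self) -> int:
        return self.edited_total + self.unedited + self.unassigned


def extract_insertions(
    reads: Iterable, context: TargetContext
) -> tuple[dict[str, int], int, int]:
    """Tally raw insertion sequences from amplicon reads by exact flank match.

    A read yields an insertion iff ``left_flank`` and ``right_flank`` occur
    exactly, separated by exactly ``insertion_len`` bases; zero separation is
    unedited; anything else (including flank mismatches) is unassigned.
    Reads are normalised to reference orientation (the reverse complement is
    tried when the left flank is absent).

    Returns ``(raw_counts, unedited, unassigned)``.
    """
    raw: dict[str, int] = {}
    unedited = 0
    unassigned = 0
    lf, rf, k = context.left_flank, context.right_flank, context.insertion_len
    for read in reads:
        seq = str(getattr(read, "seq", read)).upper()
        i = seq.find(lf)
        if i < 0:
            seq = reverse_complement(seq)
            i = seq.find(lf)
        if i < 0:
            unassigned += 1
            continue
        after = i + len(lf)
        if seq.startswith(rf, after):
            unedited += 1
        elif seq.startswith(rf, after + k):
            ins = seq[after : after + k]
            raw[ins] = raw.get(ins, 0) + 1
        else:
            unassigned += 1
    return raw, unedited, unassigned


def correct_barcodes(
    raw: Mapping[str, int],
    vocabulary: BarcodeVocabulary,
    unedited: int = 0,
    unassigned: int = 0,
) -> CountTable:
    """Assign raw insertion sequences to vocabulary symbols.

    Exact matches count directly; a sequence with exactly one vocabulary
    entry at Hamming distance 1 is corrected to it; everything else moves to
    the unassigned tally.
    """
    counts = {sym: 0 for sym in vocabulary.symbols}
    for seq, n in raw.items():
        sym = vocabulary.correct(seq)
        if sym is None:
            unassigned += n
        else:
            counts[sym] += n
    return CountTable(counts=counts, unedited=unedited, unassigned=unassigned)


def filter_low_counts(table: CountTable, min_reads: int = 5) -> CountTable:
    """Drop symbols observed fewer than ``min_reads`` times (strict), moving
    their reads to unassigned so the sample total stays auditable."""
    kept: dict[str, int] = {}
    dropped = 0
    for sym, n in table.counts.items():
        if n >= min_reads:
            kept[sym] = n
        else:
            dropped += n
    return replace(table, counts=kept, unassigned=table.unassigned + dropped)


def editing_score(genomic: CountTable, plasmid: CountTable, symbol_id: str) -> float:
    """Plasmid-normalised write efficiency of one symbol:
    (symbol's share of edited genomic reads) / (symbol's share of total
    plasmid reads)."""
    p_s = plasmid.counts.get(symbol_id, 0)
    if p_s <= 0:
        raise UndefinedScoreError(f"no plasmid reads for {symbol_id!r}")
    g_total = genomic.edited_total
    if g_total <= 0:
        raise UndefinedScoreError("no edited genomic reads")
    g_s = genomic.counts.get(symbol_id, 0)
    return (g_s / g_total) / (p_s / plasmid.total_reads)


def editing_fraction(table: CountTable) -> float:
    """Fraction of assignable tape molecules that carry any insertion;
    unassigned reads are excluded from the denominator."""
    denom = table.edited_total + table.unedited
    if denom == 0:
        raise ValueError("table has no edited or unedited reads")
    return table.edited_total / denom
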