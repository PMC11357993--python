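"""Decoding of sequential multi-unit tape reads and order statistics.

Reads of the tape amplicon are parsed by a deterministic left-to-right
flank walk (insertions have fixed lengths, so every feature sits at a
computable offset), giving an ordered symbol list per read. Per-site symbol
proportions (unigrams) and adjacent-site symbol-pair proportions (bigrams)
summarise a sample; the log2 bigram ratio infers which of two signals came
first, and the unigram+bigram vector is the feature encoding used for
programme classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import hamming, reverse_complement
from .simulate import DEFAULT_LEFT_FLANK, DEFAULT_RIGHT_FLANK, TapeSpec, tape_amplicon


@dataclass(frozen=True)
class TapeReference:
    """Unedited tape amplicon and the derived unit insertion offsets."""

    spec: TapeSpec
    left_flank: str = DEFAULT_LEFT_FLANK
    right_flank: str = DEFAULT_RIGHT_FLANK

    @property
    def amplicon(self) -> str:
        return tape_amplicon(self.spec, (), self.left_flank, self.right_flank)

    @property
    def unit_offsets(self) -> tuple[int, ...]:
        """Insertion point of each unit in the unedited amplicon (0-based)."""
        base = len(self.left_flank) + len(self.spec.full_site_prefix)
        step = len(self.spec.unit_seq)
        return tuple(base + i * step for i in range(self.spec.n_units))


@dataclass(frozen=True)
class ParsedTape:
    """Ordered symbols recovered from one read."""

    symbols: tuple[str, ...]

    @property
    def n_edited(self) -> int:
        return len(self.symbols)


def _matches(read: str, pos: int, ref: str, max_mismatch: int) -> bool:
    seg = read[pos : pos + len(ref)]
    if len(seg) < len(ref):
        return False
    if max_mismatch == 0:
        return seg == ref
    return hamming(seg, ref) <= max_mismatch


def parse_tape_read(read, reference: TapeReference,
                    max_flank_mismatch: int = 0) -> ParsedTape | None:
    """Parse one amplicon read into its ordered symbol list.

    Walks units left to right from the fixed anchor; at each unit either the
    unedited unit sequence follows (recording stopped there) or a
    barcode+key insertion is read, with the variable part corrected against
    the tape vocabulary (unique Hamming-1 neighbour). Returns ``None`` for
    unparseable reads (anchor/key/unit mismatch beyond ``max_flank_mismatch``,
    or an uncorrectable barcode); the contiguous-prefix structure of the tape
    makes any successful parse a valid prefix by construction.
    """
    spec = reference.spec
    seq = str(getattr(read, "seq", read)).upper()
    anchor = reference.left_flank + spec.full_site_prefix
    pos = seq.find(anchor)
    if pos < 0 and max_flank_mismatch == 0:
        seq = reverse_complement(seq)
        pos = seq.find(anchor)
    if pos < 0:
        if max_flank_mismatch == 0:
            return None
        pos = 0 if _matches(seq, 0, anchor, max_flank_mismatch) else -1
        if pos < 0:
            seq = reverse_complement(seq)
            pos = 0 if _matches(seq, 0, anchor, max_flank_mismatch) else -1
        if pos < 0:
            return None
    pos += len(anchor)
    unit, key, blen = spec.unit_seq, spec.key_seq, spec.barcode_len
    symbols: list[str] = []
    for i in range(spec.n_units):
        if _matches(seq, pos, unit, max_flank_mismatch):
            pos += len(unit)
            # recording stopped at this unit; remaining units must be unedited
            for _ in range(i + 1, spec.n_units):
                if not _matches(seq, pos, unit, max_flank_mismatch):
                    return None
                pos += len(unit)
            break
        barcode = seq[pos : pos + blen]
        if len(barcode) < blen or not _matches(seq, pos + blen, key, max_flank_mismatch):
            return None
        sym = spec.vocabulary.correct(barcode)
        if sym is None:
            return None
        if not _matches(seq, pos + blen + len(key), unit, max_flank_mismatch):
            return None
        symbols.append(sym)
        pos += blen + len(key) + len(unit)
    return ParsedTape(tuple(symbols))


@dataclass
class GramSummary:
    """Per-site unigram and adjacent-pair bigram statistics of a sample.

    Proportions are relative to all parsed reads (one denominator for every
    variable); the raw counts back the bigram ratio statistic. Sites are
    1-based; pair ``(i, i+1)`` covers adjacent units.
    """

    unigram_counts: dict[tuple[int, str], int]
    bigram_counts: dict[tuple[tuple[int, int], tuple[str, str]], int]
    read_count: int
    discarded: int = 0

    @property
    def unigram(self) -> dict[tuple[int, str], float]:
        return {k: v / self.read_count for k, v in self.unigram_counts.items()}

    @property
    def bigram(self) -> dict[tuple[tuple[int, int], tuple[str, str]], float]:
        return {k: v / self.read_count for k, v in self.bigram_counts.items()}


def summarize_grams(parsed: Iterable[ParsedTape | None], spec: TapeSpec) -> GramSummary:
    """Tabulate unigram/bigram counts over parsed reads; ``None`` entries
    (unparseable reads) are tallied as discarded."""
    uni: dict[tuple[int, str], int] = {}
    bi: dict[tuple[tuple[int, int], tuple[str, str]], int] = {}
    n = 0
    discarded = 0
    for p in parsed:
        if p is None:
            discarded += 1
            continue
        n += 1
        syms = p.symbols
        for i, s in enumerate(syms, start=1):
            uni[(i, s)] = uni.get((i, s), 0) + 1
        for i in range(len(syms) - 1):
            k = ((i + 1, i + 2), (syms[i], syms[i + 1]))
            bi[k] = bi.get(k, 0) + 1
    if n == 0:
        raise ValueError("no parseable reads to summarise")
    return GramSummary(unigram_counts=uni, bigram_counts=bi, read_count=n,
                       discarded=discarded)


def bigram_log_ratio(summary: GramSummary, sym_first: str, sym_second: str,
                     pseudocount: float = 0.5,
                     pairs: Sequence[tuple[int, int]] | None = None) -> float:
    """log2 of (sym_first -> sym_second) versus (sym_second -> sym_first)
    adjacent-pair counts; positive means ``sym_first`` is inferred to have
    been written first.

    Counts aggregate over all adjacent site pairs unless ``pairs`` restricts
    them (e.g. ``[(1, 2)]``); the pseudocount keeps the statistic finite and
    sign-faithful when one direction is unobserved.
    """
    fwd = rev = 0
    for (pair, (a, b)), c in summary.bigram_counts.items():
        if pairs is not None and pair not in tuple(map(tuple, pairs)):
            continue
        if (a, b) == (sym_first, sym_second):
            fwd += c
        elif (a, b) == (sym_second, sym_first):
            rev += c
    return float(np.log2((fwd + pseudocount) / (rev + pseudocount)))


def feature_names(spec: TapeSpec, symbols: Sequence[str] | None = None) -> list[str]:
    """Names of the programme-feature encoding, in its fixed order: unigram
    proportions (sites ascending, symbols lexicographic) then bigram
    proportions (adjacent pairs ascending, symbol pairs lexicographic)."""
    if symbols is None:
        symbols = sorted(spec.vocabulary.symbols)
    else:
        symbols = sorted(symbols)
    names = [f"uni_site{i}_{s}" for i in range(1, spec.n_units + 1) for s in symbols]
    names += [
        f"bi_sites{i}{i + 1}_{a}>{b}"
        for i in range(1, spec.n_units)
        for a in symbols
        for b in symbols
    ]
    return names


def encode_programme_features(summary: GramSummary, spec: TapeSpec,
                              symbols: Sequence[str] | None = None) -> np.ndarray:
    """Fixed-order feature vector of unigram and bigram proportions.

    For S symbols and n units the length is S*n + S^2*(n-1) — 26 for the
    canonical two-symbol, five-unit tape.
    """
    if symbols is None:
        symbols = sorted(spec.vocabulary.symbols)
    else:
        symbols = sorted(symbols)
    uni = summary.unigram
    bi = summary.bigram
    vec = [uni.get((i, s), 0.0) for i in range(1, spec.n_units + 1) for s in symbols]
    vec += [
        bi.get(((i, i + 1), (a, b)), 0.0)
        for i in range(1, spec.n_units)
        for a in symbols
        for b in symbols
    ]
    return np.asarray(vec)


def run_length_distribution(
    parsed: Iterable[ParsedTape | None],
) -> dict[tuple[str, int], int]:
    """Counts of maximal homopolymeric symbol runs across reads; longer
    signal exposures leave longer runs of the corresponding symbol."""
    out: dict[tuple[str, int], int] = {}
    for p in parsed:
        if p is None or not p.symbols:
            continue
        run_sym = p.symbols[0]
        run_len = 1
        for s in p.symbols[1:]:
            if s == run_sym:
                run_len += 1
            else:
                out[(run_sym, run_len)] = out.get((run_sym, run_len), 0) + 1
                run_sym, run_len = s, 1
        out[(run_sym, run_len)] = out.get((run_sym, run_len), 0) + 1
    return out
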