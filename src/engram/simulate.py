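"""Stochastic simulation of signal-dependent insertional recording.

Cells carry many copies of a DNA Tape; recorder channels write short
barcode "symbols" onto the tape at Hill-coupled, signal-dependent rates.
Two tape geometries are simulated:

* a sequential multi-unit tape (DNA Typewriter style) where each insertion
  carries a key that activates the next unit, so writes occupy a contiguous
  prefix and preserve temporal order;
* a single-site tape written by a pool of recorders in proportion to
  activity x plasmid abundance x insertion-efficiency bias.

Time is discretised into small Bernoulli-competition steps (at most one
write per tape per step) rather than exact event-driven simulation; the
enforced bound ``sum(rate)*dt < 0.2`` keeps discretisation error small at
realistic write rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import BASES, check_nucleotides, rng_for
from .codec import BarcodeVocabulary, CountTable, TargetContext
from .programmes import AgonistChannel, SignalProgramme, hill_rate

# Fixed amplicon constants flanking the tape array in all synthetic designs.
DEFAULT_LEFT_FLANK = "ATCGCTGAAGCGCATACCGT"
DEFAULT_RIGHT_FLANK = "TGCAACGGTCATCGGATCAC"


class ConfigError(ValueError):
    """Simulation configuration violates a stated bound."""


def default_tape_vocabulary() -> BarcodeVocabulary:
    """Two 3-bp tape symbols at full Hamming separation (insertions are
    barcode+key hexamers, NNN+GGA)."""
    return BarcodeVocabulary(k=3, entries={"TET": "ACT", "WNT": "GTA"})


@dataclass(frozen=True)
class TapeSpec:
    """Geometry of a sequential multi-unit tape.

    Each write inserts ``barcode_len`` variable bases plus ``key_seq``; the
    key completes the next truncated unit, advancing the write pointer.
    ``full_site_prefix`` completes the first unit so the tape starts active.
    """

    n_units: int = 5
    barcode_len: int = 3
    key_seq: str = "GGA"
    unit_seq: str = "TCGTATGCAGTCTA"
    full_site_prefix: str = "GGA"
    vocabulary: BarcodeVocabulary = field(default_factory=default_tape_vocabulary)

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        for seq in (self.key_seq, self.unit_seq, self.full_site_prefix):
            check_nucleotides(seq)
        if self.vocabulary.k != self.barcode_len:
            raise ValueError("vocabulary barcode length must equal barcode_len")

    @property
    def insertion_len(self) -> int:
        return self.barcode_len + len(self.key_seq)

    def render_insertion(self, symbol_id: str) -> str:
        return self.vocabulary.entries[symbol_id] + self.key_seq


@dataclass(frozen=True)
class TapeState:
    """Ordered symbols written to one tape copy (contiguous prefix)."""

    symbols: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class SimConfig:
    n_cells: int = 2000
    tapes_per_cell: int = 20
    dt_days: float = 0.05
    seed: int = 0
    efficiency_bias: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.tapes_per_cell < 1:
            raise ValueError("n_cells and tapes_per_cell must be >= 1")
        if self.dt_days <= 0:
            raise ValueError("dt_days must be > 0")

    @property
    def n_tapes(self) -> int:
        return self.n_cells * self.tapes_per_cell

    def bias_for(self, symbol_id: str) -> float:
        if self.efficiency_bias is None:
            return 1.0
        return float(self.efficiency_bias.get(symbol_id, 1.0))


@dataclass(frozen=True)
class ReadModel:
    """Amplicon read sampling: uniform over tape copies, i.i.d. substitution
    errors, no PCR bias."""

    reads_per_sample: int = 10_000
    per_base_error: float = 0.001
    read_length: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.per_base_error < 0.25:
            raise ValueError("per_base_error must be in [0, 0.25)")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")


def tape_amplicon(spec: TapeSpec, symbols: Sequence[str] = (),
                  left_flank: str = DEFAULT_LEFT_FLANK,
                  right_flank: str = DEFAULT_RIGHT_FLANK) -> str:
    """Render the amplicon sequence of a tape carrying ``symbols``.

    Insertions interleave with the unit array: each written unit becomes
    barcode+key followed by the (still truncated) unit sequence.
    """
    if len(symbols) > spec.n_units:
        raise ValueError("more symbols than tape units")
    parts = [left_flank, spec.full_site_prefix]
    for i in range(spec.n_units):
        if i < len(symbols):
            parts.append(spec.render_insertion(symbols[i]))
        parts.append(spec.unit_seq)
    parts.append(right_flank)
    return "".join(parts)


def _step_rates(programme: SignalProgramme, channels: Sequence[AgonistChannel],
                config: SimConfig, dt: float) -> np.ndarray:
    """Per-step, per-channel write probabilities (n_steps x n_channels)."""
    n_steps = int(round(programme.duration_days / dt))
    probs = np.empty((n_steps, len(channels)))
    for j, ch in enumerate(channels):
        bias = config.bias_for(ch.symbol_id)
        for k in range(n_steps):
            t = (k + 0.5) * dt
            probs[k, j] = hill_rate(programme.concentration(ch.name, t), ch) * bias * dt
    return probs


def simulate_tapes(programme: SignalProgramme, channels: Sequence[AgonistChannel],
                   spec: TapeSpec, config: SimConfig) -> list[TapeState]:
    """Simulate every tape copy in a cell population through a programme.

    Per time step each unfull tape writes at most one symbol; the writing
    channel is chosen with probability proportional to its current
    bias-weighted rate. Deterministic given ``config.seed``.
    """
    names = [ch.symbol_id for ch in channels]
    if len(set(names)) != len(names):
        raise ValueError("channel symbol_ids must be distinct")
    probs = _step_rates(programme, channels, config, config.dt_days)
    p_tot = probs.sum(axis=1)
    if p_tot.max(initial=0.0) >= 0.2:
        raise ConfigError(
            f"total write probability per step reaches {p_tot.max():.3f} >= 0.2; "
            "reduce dt_days"
        )
    rng = rng_for(config.seed, f"tapes/{programme.label}")
    n = config.n_tapes
    written = np.full((n, spec.n_units), -1, dtype=np.int16)
    pointer = np.zeros(n, dtype=np.int64)
    for k in range(probs.shape[0]):
        if p_tot[k] == 0.0:
            continue
        u = rng.random(n)
        writes = (u < p_tot[k]) & (pointer < spec.n_units)
        idx = np.nonzero(writes)[0]
        if idx.size == 0:
            continue
        cum = np.cumsum(probs[k])
        choice = np.searchsorted(cum, rng.random(idx.size) * p_tot[k], side="right")
        written[idx, pointer[idx]] = choice
        pointer[idx] += 1
    out: list[TapeState] = []
    for row, m in zip(written, pointer):
        out.append(TapeState(tuple(names[row[i]] for i in range(m))))
    return out


def _mutate(seq: str, n_err: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_err, replace=False):
        old = chars[pos]
        chars[pos] = BASES[(BASES.index(old) + rng.integers(1, 4)) % 4]
    return "".join(chars)


def _sample_read_strings(sequences: Sequence[str], weights: np.ndarray,
                         model: ReadModel, rng: np.random.Generator) -> list[str]:
    """Draw reads from a discrete pool of template sequences with i.i.d.
    substitution errors."""
    picks = rng.choice(len(sequences), size=model.reads_per_sample, p=weights)
    reads: list[str] = []
    for i in picks:
        seq = sequences[i]
        if model.read_length is not None and model.read_length < len(seq):
            raise ConfigError(
                f"read_length {model.read_length} shorter than amplicon {len(seq)}"
            )
        if model.per_base_error > 0:
            n_err = rng.binomial(len(seq), model.per_base_error)
            if n_err:
                seq = _mutate(seq, n_err, rng)
        reads.append(seq)
    return reads


def generate_reads(tapes: Sequence[TapeState], spec: TapeSpec, model: ReadModel,
                   seed: int, as_strings: bool = False):
    """Sample amplicon sequencing reads from a tape population.

    Returns Biopython ``SeqRecord`` objects (phred-30 placeholder qualities)
    or plain strings when ``as_strings`` is set. Deterministic given ``seed``.
    """
    if not tapes:
        raise ValueError("tapes must be non-empty")
    rng = rng_for(seed, "reads")
    # tapes collapse onto few distinct states; render each template once
    state_index: dict[tuple[str, ...], int] = {}
    counts: list[int] = []
    for t in tapes:
        j = state_index.setdefault(t.symbols, len(state_index))
        if j == len(counts):
            counts.append(0)
        counts[j] += 1
    templates = [tape_amplicon(spec, s) for s in state_index]
    weights = np.asarray(counts, dtype=float) / len(tapes)
    reads = _sample_read_strings(templates, weights, model, rng)
    if as_strings:
        return reads
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for i, seq in enumerate(reads):
        rec = SeqRecord(Seq(seq), id=f"read_{i}", description="")
        rec.letter_annotations["phred_quality"] = [30] * len(seq)
        records.append(rec)
    return records


def simulate_hek3_sample(activities: Mapping[str, float], vocabulary: BarcodeVocabulary,
                         plasmid_props: Mapping[str, float], config: SimConfig,
                         duration_days: float,
                         plasmid_reads: int = 200_000) -> tuple[CountTable, CountTable]:
    """Simulate one single-site recording sample plus its plasmid pool.

    Each recorder writes at rate activity x plasmid proportion x efficiency
    bias; a tape copy is edited with probability ``1 - exp(-sum(rates)*t)``
    and carries a symbol drawn in proportion to the per-recorder rates.
    Returns ``(genomic_counts, plasmid_counts)``; genomic counts are tape
    molecules, equivalent to reads under uniform sampling.
    """
    for r in activities:
        if r not in vocabulary.entries:
            raise KeyError(f"recorder {r!r} missing from vocabulary")
    if any(v < 0 for v in activities.values()):
        raise ValueError("activities must be >= 0")
    props = np.asarray([plasmid_props[r] for r in activities], dtype=float)
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValueError("plasmid_props must sum to 1")
    rng = rng_for(config.seed, "hek3")
    recs = list(activities)
    lam = np.asarray(
        [activities[r] * plasmid_props[r] * config.bias_for(r) for r in recs]
    )
    total = lam.sum()
    n = config.n_tapes
    if total == 0:
        genomic = CountTable(counts={r: 0 for r in recs}, unedited=n)
    else:
        p_edit = 1.0 - np.exp(-total * duration_days)
        edited = int(rng.binomial(n, p_edit))
        sym_counts = rng.multinomial(edited, lam / total)
        genomic = CountTable(
            counts=dict(zip(recs, map(int, sym_counts))), unedited=n - edited
        )
    plasmid = CountTable(
        counts=dict(zip(recs, map(int, rng.multinomial(plasmid_reads, props))))
    )
    return genomic, plasmid


def render_hek3_reads(table: CountTable, vocabulary: BarcodeVocabulary,
                      context: TargetContext, per_base_error: float,
                      seed: int) -> list[str]:
    """Render single-site amplicon reads realising a genomic count table
    (one read per counted tape molecule), with substitution errors."""
    rng = rng_for(seed, "hek3-reads")
    reads: list[str] = []
    for sym, n in table.counts.items():
        seq = context.left_flank + vocabulary.entries[sym] + context.right_flank
        reads.extend([seq] * n)
    reads.extend([context.left_flank + context.right_flank] * table.unedited)
    if per_base_error > 0:
        for i, seq in enumerate(reads):
            n_err = rng.binomial(len(seq), per_base_error)
            if n_err:
                reads[i] = _mutate(seq, n_err, rng)
    return reads


def default_hek3_context(insertion_len: int = 5) -> TargetContext:
    """Synthetic single-site amplicon context (stand-in flanks, not the
    genomic locus sequence)."""
    return TargetContext(
        left_flank=DEFAULT_LEFT_FLANK, right_flank=DEFAULT_RIGHT_FLANK,
        insertion_len=insertion_len,
    )


def simulate_dose_response(channel: AgonistChannel, doses: Iterable[float],
                           duration_days: float, config: SimConfig) -> pd.DataFrame:
    """Edited tape fraction across an agonist dilution series.

    Per dose the edited fraction is a binomial draw around
    ``1 - exp(-rate(dose) * duration)`` over all tape copies.
    """
    rng = rng_for(config.seed, "dose")
    rows = []
    n = config.n_tapes
    for dose in doses:
        rate = hill_rate(dose, channel) * config.bias_for(channel.symbol_id)
        p = 1.0 - np.exp(-rate * duration_days)
        rows.append({"dose": float(dose),
                     "edited_fraction": rng.binomial(n, p) / n})
    return pd.DataFrame(rows)


def sample_efficiency_bias(symbols: Sequence[str], seed: int,
                           fold_range: float = 4.0) -> dict[str, float]:
    """Draw a per-symbol multiplicative efficiency bias, log-uniform within
    ``fold_range`` (most barcodes sit within a fourfold efficiency band)."""
    rng = rng_for(seed, "bias")
    lo, hi = -0.5 * np.log(fold_range), 0.5 * np.log(fold_range)
    return {s: float(np.exp(rng.uniform(lo, hi))) for s in symbols}
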