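"""Agonist channels and temporal signalling programmes.

A channel couples an agonist concentration to a tape write rate through a
Hill response (basal rate + saturable signal-dependent component); a
programme is a labelled piecewise-constant concentration timeline per
channel. The enumerator generates the canonical serial / layered / pulse
programme families used for temporal-order recording experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

Segment = tuple[float, float, float]  # (start_day, end_day, concentration)


@dataclass(frozen=True)
class AgonistChannel:
    """A signal-responsive recorder channel.

    Parameters
    ----------
    name:
        Channel (pathway/agonist) name, e.g. ``"TET"`` for a Tet-On recorder.
    symbol_id:
        Symbol written to tape, keys into a :class:`~engram.codec.BarcodeVocabulary`.
    ec50:
        Half-maximal agonist concentration, in the channel's own units (>0).
    hill_n:
        Hill coefficient (>0); larger values give more switch-like responses.
    basal_rate:
        Signal-independent background write rate, writes/day (>=0).
    max_rate:
        Saturating write rate, writes/day (> basal_rate).
    """

    name: str
    symbol_id: str
    ec50: float
    hill_n: float = 1.0
    basal_rate: float = 0.0
    max_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be > 0")
        if self.basal_rate < 0:
            raise ValueError("basal_rate must be >= 0")
        if self.max_rate <= self.basal_rate:
            raise ValueError("max_rate must exceed basal_rate")


def hill_rate(conc: float, channel: AgonistChannel) -> float:
    """Write rate (writes/day) at agonist concentration ``conc``.

    ``rate(c) = basal + (max - basal) * c^n / (c^n + EC50^n)``; monotone
    non-decreasing in ``conc`` and bounded in ``[basal_rate, max_rate)``.
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if conc == 0:
        return channel.basal_rate
    cn = conc**channel.hill_n
    return channel.basal_rate + (channel.max_rate - channel.basal_rate) * cn / (
        cn + channel.ec50**channel.hill_n
    )


@dataclass(frozen=True)
class SignalProgramme:
    """A labelled agonist-exposure timeline.

    ``segments`` maps channel name to ordered, non-overlapping
    ``(start_day, end_day, concentration)`` intervals within
    ``[0, duration_days]``; concentration is zero outside all segments.
    ``pattern`` / ``first_channel`` carry the programme-family metadata used
    by the order-recovery analyses (``first_channel`` is None for patterns
    with simultaneous onset).
    """

    label: str
    duration_days: float
    segments: Mapping[str, tuple[Segment, ...]]
    pattern: str = "custom"
    first_channel: str | None = None

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration_days must be > 0")
        for name, segs in self.segments.items():
            prev_end = 0.0
            for start, end, conc in segs:
                if conc < 0:
                    raise ValueError(f"{name}: negative concentration")
                if not (0 <= start < end <= self.duration_days):
                    raise ValueError(
                        f"{name}: segment ({start},{end}) outside [0,{self.duration_days}]"
                    )
                if start < prev_end:
                    raise ValueError(f"{name}: segments overlap or are unsorted")
                prev_end = end

    def concentration(self, channel_name: str, t: float) -> float:
        """Concentration seen by ``channel_name`` at time ``t`` (days)."""
        for start, end, conc in self.segments.get(channel_name, ()):
            if start <= t < end:
                return conc
        return 0.0

    def onset(self, channel_name: str) -> float | None:
        segs = self.segments.get(channel_name, ())
        return segs[0][0] if segs else None


def enumerate_programmes(
    intervals_days: Sequence[float] = (1, 2, 3),
    total_days: float = 6.0,
    channels: Sequence[str] = ("TET", "WNT"),
    concs: Mapping[str, float] | None = None,
    pulse_days: Sequence[float] = (0, 2, 4),
    pulse_channel: str | None = None,
    pulse_conc: float | None = None,
    pulse_len_days: float = 1.0,
    include_pulse: bool = True,
) -> list[SignalProgramme]:
    """Enumerate the canonical two-channel temporal programme families.

    * serial: first agonist on ``[0, d)``, second on ``[d, 2d)`` — for each
      interval ``d`` and both channel orders;
    * layered: first agonist throughout ``[0, total)``, second joining at
      ``d`` — for each interval and both orders;
    * pulse: a short strong pulse of one channel at each of ``pulse_days``
      against continuous stimulation by the other.

    Defaults give 6 serial + 6 layered + 3 pulse = 15 uniquely labelled
    programmes (12 without the pulse family).
    """
    if any(d <= 0 or d > total_days for d in intervals_days):
        raise ValueError("intervals must be positive and <= total_days")
    a, b = channels
    if concs is None:
        concs = {a: 0.1, b: 3.0}  # saturating-range doses in channel units
    if pulse_channel is None:
        pulse_channel = a
    if pulse_conc is None:
        pulse_conc = 5 * concs[pulse_channel]
    out: list[SignalProgramme] = []
    for d in intervals_days:
        for first, second in ((a, b), (b, a)):
            out.append(
                SignalProgramme(
                    label=f"serial_{first}_first_d{d:g}",
                    duration_days=total_days,
                    segments={
                        first: ((0.0, float(d), concs[first]),),
                        second: ((float(d), min(2.0 * d, total_days), concs[second]),),
                    },
                    pattern="serial",
                    first_channel=first,
                )
            )
            out.append(
                SignalProgramme(
                    label=f"layered_{first}_first_d{d:g}",
                    duration_days=total_days,
                    segments={
                        first: ((0.0, total_days, concs[first]),),
                        second: ((float(d), total_days, concs[second]),),
                    },
                    pattern="layered",
                    first_channel=first,
                )
            )
    # interleave into serial-block then layered-block ordering
    serial = [p for p in out if p.pattern == "serial"]
    layered = [p for p in out if p.pattern == "layered"]
    out = serial + layered
    if include_pulse:
        background = b if pulse_channel == a else a
        for day in pulse_days:
            end = min(day + pulse_len_days, total_days)
            out.append(
                SignalProgramme(
                    label=f"pulse_{pulse_channel}_day{day:g}",
                    duration_days=total_days,
                    segments={
                        pulse_channel: ((float(day), end, pulse_conc),),
                        background: ((0.0, total_days, concs[background]),),
                    },
                    pattern="pulse",
                    first_channel=None,
                )
            )
    labels = [p.label for p in out]
    assert len(set(labels)) == len(labels)
    return out


def default_tape_channels(
    symbols: Mapping[str, str] | None = None,
    basal_rate: float = 2.5e-4,
    max_rate: float = 0.5,
) -> list[AgonistChannel]:
    """The two DNA-Typewriter recorder channels used throughout examples.

    TET: doxycycline-driven Tet-On recorder, EC50 0.17 ug/ml.
    WNT: CHIR99021-driven TCF-LEF recorder, EC50 2.2 uM.

    Rates are calibrated so a 6-day unstimulated tape shows ~0.15% background
    and sustained saturating stimulation writes mostly to the first two
    tape units.
    """
    if symbols is None:
        symbols = {"TET": "TET", "WNT": "WNT"}
    return [
        AgonistChannel("TET", symbols["TET"], ec50=0.17, hill_n=1.5,
                       basal_rate=basal_rate, max_rate=max_rate),
        AgonistChannel("WNT", symbols["WNT"], ec50=2.2, hill_n=2.0,
                       basal_rate=basal_rate, max_rate=max_rate),
    ]


def default_hek3_channels() -> list[AgonistChannel]:
    """Three single-site recorder channels (Tet-On, NF-kB, WNT) with the
    reported half-maximal agonist concentrations in their native units
    (0.17 ug/ml doxycycline, 2.5 ng/ml TNF, 2.2 uM CHIR99021).

    Rates are calibrated to the reported 48-h endpoint fractions: basal
    recording of ~0.15% of tape copies, and maximal stimulation 11.5-,
    19.0- and 22.6-fold above background for the three channels.
    """
    basal = 7.5e-4  # 1 - exp(-2*basal) ~ 0.15% over a 48-h assay
    return [
        AgonistChannel("TET", "TET", ec50=0.17, hill_n=1.5, basal_rate=basal,
                       max_rate=11.5 * basal),
        AgonistChannel("NFKB", "NFKB", ec50=2.5, hill_n=1.2, basal_rate=basal,
                       max_rate=19.0 * basal),
        AgonistChannel("WNT", "WNT", ec50=2.2, hill_n=2.0, basal_rate=basal,
                       max_rate=22.6 * basal),
    ]
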