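"""Phase-to-delay conversion, block-sign assignment, and ambiguity flagging.

The group phase at the stimulus frequency maps to a response delay in
seconds after A-block onset.  A delay peaking during (most of) the A block
gets sign +1, during the B block -1, under the rule that a response
peaking no less than 2 s into a block and no more than 2 s into the next
belongs to that block — a peak in the first 2 s TR of a block is more
plausibly driven by the preceding block.  As a further precaution,
responses peaking within one TR of the A<->B crossover (the first four
seconds of either block) keep their sign but are never declared
significant, which guarantees that significant positive and negative
responses peak at least 2 TRs (4 s) apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DesignTiming",
    "SignedResponse",
    "phase_to_delay",
    "assign_sign",
    "flag_ambiguous",
    "signed_amplitude",
]


@dataclass(frozen=True)
class DesignTiming:
    """Timing constants of the block design.

    ``slice_time_shift`` is the +TR/2 correction for series resampled to
    TR centers during slice-timing correction (1 s at TR 2 s);
    ``assoc_margin`` is how far into a block a peak may fall and still be
    credited to the previous block (2 s = 1 TR); ``ambiguity_window`` is
    the initial stretch of each block (4 s = 2 TRs) whose peaks are
    sign-assigned but never significant.
    """

    block_seconds: float = 12.0
    tr_seconds: float = 2.0
    slice_time_shift: float = 1.0
    assoc_margin: float = 2.0
    ambiguity_window: float = 4.0

    def __post_init__(self):
        if not (0 <= self.assoc_margin < self.block_seconds / 2):
            raise ValueError("assoc_margin must lie in [0, block/2)")
        if self.ambiguity_window < 0:
            raise ValueError("ambiguity_window must be nonnegative")

    @property
    def period(self) -> float:
        return 2.0 * self.block_seconds


@dataclass(frozen=True)
class SignedResponse:
    """A sign-assigned response delay with its significance verdict."""

    delay: float
    sign: int
    ambiguous: bool
    significant: bool

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.significant and self.ambiguous:
            raise ValueError("an ambiguous response can never be significant")


def phase_to_delay(phase: float, timing: DesignTiming = DesignTiming()) -> float:
    """Convert a response phase (radians) to a delay after A-block onset.

    delay = ((-phase / 2π) · period + slice_time_shift) mod period.
    With the e^(-iωt) spectral convention, a response peaking at sample 0
    of the retained series maps to ``slice_time_shift`` seconds.
    """
    if not np.isfinite(phase):
        raise ValueError("phase must be finite")
    delay = (-phase / (2 * np.pi)) * timing.period + timing.slice_time_shift
    return float(np.mod(delay, timing.period))


def assign_sign(delay: float, timing: DesignTiming = DesignTiming()) -> int:
    """+1 if the delay associates with the A block, -1 for the B block.

    With defaults: delays in [2, 14) s → +1 and [14, 24) ∪ [0, 2) s → -1,
    half-open so an exact boundary belongs to the later block.
    """
    if not (0 <= delay < timing.period):
        raise ValueError(f"delay {delay} outside [0, {timing.period})")
    a_lo = timing.assoc_margin
    a_hi = timing.block_seconds + timing.assoc_margin
    return +1 if a_lo <= delay < a_hi else -1


def flag_ambiguous(delay: float, timing: DesignTiming = DesignTiming()) -> bool:
    """True if the peak falls in the first ``ambiguity_window`` of a block.

    With defaults this is [0, 4) ∪ [12, 16) s — within one TR of the
    crossover point in either direction.
    """
    if not (0 <= delay < timing.period):
        raise ValueError(f"delay {delay} outside [0, {timing.period})")
    into_block = np.mod(delay, timing.block_seconds)
    return bool(into_block < timing.ambiguity_window)


def signed_amplitude(stat, timing: DesignTiming = DesignTiming(),
                     alpha: float = 0.05) -> tuple[SignedResponse, float]:
    """Sign the group amplitude by delay and apply the significance rule.

    ``stat`` is a :class:`~freqtag.vecstats.GroupVectorStat` (anything
    exposing ``phase``, ``amplitude`` and ``p_value``).  A response is
    significant iff p < alpha and its delay is not crossover-ambiguous.
    """
    delay = phase_to_delay(stat.phase, timing)
    sign = assign_sign(delay, timing)
    ambiguous = flag_ambiguous(delay, timing)
    significant = bool(stat.p_value < alpha) and not ambiguous
    return (SignedResponse(delay=delay, sign=sign, ambiguous=ambiguous,
                           significant=significant),
            sign * stat.amplitude)
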