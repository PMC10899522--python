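"""Dictator-game trial structure, payoff conversion, and allocation choice sets.

The task is a modified dictator game: on each round the dictator receives a
budget of ``T`` tokens and splits it between themself (``T_s`` kept) and an
anonymous recipient (``T_o`` sent).  Tokens convert to cents through a pair of
exchange ratios, ``r_self`` cents per kept token and ``r_other`` cents per sent
token.  In the gain frame tokens convert to monetary gains for both players; in
the loss frame they convert to losses (represented here as negative cents, so
that a purely selfish dictator keeps everything in the gain frame and nothing
in the loss frame).  Decisions are made either for oneself (first-party role)
or on behalf of another dictator (third-party role); the payoff arithmetic is
identical, ``m_self`` then denoting the represented dictator's payoff.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "Role",
    "Frame",
    "Condition",
    "ExchangeRatio",
    "Trial",
    "Allocation",
    "PayoffPair",
    "DESIGN_RATIOS",
    "choice_set",
    "payoffs",
    "kept_fraction",
    "equal_fraction",
]


class Role(enum.Enum):
    """Whose payoff is at stake: the decider's own or a represented dictator's."""

    FIRST_PARTY = "first"
    THIRD_PARTY = "third"


class Frame(enum.Enum):
    """Whether tokens convert to monetary gains or to monetary losses."""

    GAIN = "gain"
    LOSS = "loss"


#: The canonical condition indexing: k=1 first/gain, k=2 first/loss,
#: k=3 third/gain, k=4 third/loss.
_CONDITION_ORDER = [
    (Role.FIRST_PARTY, Frame.GAIN),
    (Role.FIRST_PARTY, Frame.LOSS),
    (Role.THIRD_PARTY, Frame.GAIN),
    (Role.THIRD_PARTY, Frame.LOSS),
]


@dataclass(frozen=True)
class Condition:
    """A Role x Frame cell of the within-subject design.

    The index ``k`` in 1..4 maps bijectively onto (role, frame):
    1 = first-party/gain, 2 = first-party/loss, 3 = third-party/gain,
    4 = third-party/loss.
    """

    role: Role
    frame: Frame

    @property
    def k(self) -> int:
        return _CONDITION_ORDER.index((self.role, self.frame)) + 1

    @classmethod
    def from_k(cls, k: int) -> "Condition":
        if not 1 <= k <= 4:
            raise ValueError(f"condition index k must be in 1..4, got {k}")
        role, frame = _CONDITION_ORDER[k - 1]
        return cls(role, frame)


#: The five exchange ratios of the study design, as (r_self, r_other).
DESIGN_RATIOS: tuple[tuple[int, int], ...] = ((3, 1), (2, 1), (1, 1), (1, 2), (1, 3))


@dataclass(frozen=True)
class ExchangeRatio:
    """Cents-per-token conversion for the dictator (``r_self``) and recipient
    (``r_other``).  Any positive pair is accepted; the study design uses
    3:1, 2:1, 1:1, 1:2 and 1:3."""

    r_self: int
    r_other: int

    def __post_init__(self) -> None:
        if self.r_self <= 0 or self.r_other <= 0:
            raise ValueError(
                f"exchange ratio components must be positive, got "
                f"{self.r_self}:{self.r_other}"
            )

    @property
    def in_design(self) -> bool:
        return (self.r_self, self.r_other) in DESIGN_RATIOS

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.r_self}:{self.r_other}"


@dataclass(frozen=True)
class Trial:
    """One round: a condition, an exchange ratio and a token budget ``T``."""

    condition: Condition
    ratio: ExchangeRatio
    total_tokens: int
    block: int = 1
    round: int = 1

    def __post_init__(self) -> None:
        if self.total_tokens < 0:
            raise ValueError(f"total_tokens must be >= 0, got {self.total_tokens}")
        if self.block < 1 or self.round < 1:
            raise ValueError("block and round indices start at 1")


@dataclass(frozen=True)
class Allocation:
    """A split of the trial budget: ``tokens_kept`` (T_s) + ``tokens_sent`` (T_o)."""

    tokens_kept: int
    tokens_sent: int

    def __post_init__(self) -> None:
        if self.tokens_kept < 0 or self.tokens_sent < 0:
            raise ValueError("token counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tokens_kept + self.tokens_sent


@dataclass(frozen=True)
class PayoffPair:
    """Monetary consequences in signed cents: ``m_self`` (Ms) and ``m_other`` (Mo).

    Both components are nonnegative in the gain frame and nonpositive in the
    loss frame."""

    m_self: float
    m_other: float


def choice_set(trial: Trial) -> list[Allocation]:
    """All allocations available on a trial, ordered by tokens kept.

    Tokens are discrete, so a budget of T yields exactly T+1 options,
    from keeping nothing to keeping everything.  This ordered sequence is the
    option set the softmax choice rule normalizes over.
    """
    T = trial.total_tokens
    return [Allocation(ts, T - ts) for ts in range(T + 1)]


def payoffs(trial: Trial, allocation: Allocation) -> PayoffPair:
    """Convert an allocation to signed cent payoffs.

    Gain frame: ``Ms = r_self * T_s``, ``Mo = r_other * T_o``.  Loss frame:
    the same magnitudes with negative sign — keeping a token means keeping a
    loss, so the selfish optimum flips from keep-everything (gain) to
    keep-nothing (loss).  Role does not alter the arithmetic.
    """
    if allocation.total != trial.total_tokens:
        raise ValueError(
            f"allocation ({allocation.tokens_kept}+{allocation.tokens_sent}) does "
            f"not exhaust the trial budget T={trial.total_tokens}"
        )
    ms = trial.ratio.r_self * allocation.tokens_kept
    mo = trial.ratio.r_other * allocation.tokens_sent
    if trial.condition.frame is Frame.LOSS:
        ms, mo = -ms, -mo
    return PayoffPair(float(ms), float(mo))


def kept_fraction(allocation: Allocation, trial: Trial) -> float:
    """Fraction of the budget kept, ``T_s / T``.  Undefined for T = 0."""
    if trial.total_tokens == 0:
        raise ZeroDivisionError("kept fraction is undefined for a zero token budget")
    if allocation.total != trial.total_tokens:
        raise ValueError("allocation does not match the trial budget")
    return allocation.tokens_kept / trial.total_tokens


def equal_fraction(ratio: ExchangeRatio) -> float:
    """Kept fraction that equalizes both players' payoffs.

    Equal payoffs require ``r_self * T_s = r_other * T_o``, i.e. a kept
    fraction of ``r_other / (r_self + r_other)``; the rule is frame independent
    (both payoffs flip sign together in the loss frame).  E.g. ratio 1:3 gives
    0.75, ratio 1:1 gives 0.5.
    """
    return float(Fraction(ratio.r_other, ratio.r_self + ratio.r_other))
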