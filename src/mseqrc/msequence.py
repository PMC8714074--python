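"""Maximal-length shift-register (m-)sequences.

An m-sequence of order ``n`` is the ±1-valued output of a binary linear
feedback shift register (LFSR) with a primitive feedback polynomial over
GF(2).  One period has length ``N = 2**n - 1`` and satisfies three defining
properties:

1. balance — ``2**(n-1)`` values of +1 and ``2**(n-1) - 1`` values of −1;
2. subword uniqueness — every circular subword of length ``n`` occurs
   exactly once (the all-(−1) word never occurs);
3. shift-and-product closure — the elementwise product of the sequence
   with any nonzero circular shift of itself is another circular shift of
   the same sequence.

These imply the delta-like circular autocorrelation (``N`` at lag 0, −1
elsewhere) that makes m-sequences suitable white-noise probes: here each
value sets the polarity of one stimulus impulse.

The LFSR is in Fibonacci configuration: stages are numbered 1..n, the
output is taken from stage ``n``, and the feedback bit (XOR over the tap
stages) is shifted in at stage 1.  Bits map to signs as 1 → +1, 0 → −1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MSequence",
    "MSequenceReport",
    "PRIMITIVE_TAPS",
    "generate_msequence",
    "random_msequence",
    "verify_msequence",
    "extend_circular",
]

# One or more known primitive feedback tap sets per order (stage numbers,
# including stage n).  Each entry yields the full period 2**n - 1;
# generate_msequence re-checks this at run time.
PRIMITIVE_TAPS: dict[int, tuple[tuple[int, ...], ...]] = {
    2: ((2, 1),),
    3: ((3, 2), (3, 1)),
    4: ((4, 3), (4, 1)),
    5: ((5, 3), (5, 2)),
    6: ((6, 5), (6, 1)),
    7: ((7, 6), (7, 3), (7, 1)),
    8: ((8, 6, 5, 4), (8, 6, 5, 3), (8, 7, 6, 1), (8, 6, 5, 2)),
    9: ((9, 5), (9, 4)),
    10: ((10, 7), (10, 3)),
    11: ((11, 9), (11, 2)),
    12: ((12, 6, 4, 1),),
    13: ((13, 4, 3, 1),),
    14: ((14, 5, 3, 1),),
    15: ((15, 14), (15, 1)),
    16: ((16, 15, 13, 4),),
}


@dataclass(frozen=True)
class MSequence:
    """One full period of a ±1 m-sequence plus its generating register."""

    order: int
    taps: tuple[int, ...]
    initial_state: tuple[int, ...]
    values: np.ndarray
    phase: int = 0
    label: str = ""

    @property
    def period(self) -> int:
        return 2**self.order - 1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.int8)
        )
        if len(self.values) != self.period:
            raise ValueError(
                f"values length {len(self.values)} != 2**{self.order}-1"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "order": self.order,
                "taps": list(self.taps),
                "initial_state": list(self.initial_state),
                "phase": self.phase,
                "label": self.label,
                "values": [int(v) for v in self.values],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MSequence":
        d = json.loads(text)
        return cls(
            order=d["order"],
            taps=tuple(d["taps"]),
            initial_state=tuple(d["initial_state"]),
            values=np.asarray(d["values"], dtype=np.int8),
            phase=d.get("phase", 0),
            label=d.get("label", ""),
        )

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, fmt="%d")


@dataclass
class MSequenceReport:
    """Result of checking the three defining m-sequence properties."""

    valid_length: bool
    balance: bool
    subword_unique: bool
    shift_closure: bool
    order: int | None = None
    reason: str = ""

    @property
    def passed(self) -> bool:
        return (
            self.valid_length
            and self.balance
            and self.subword_unique
            and self.shift_closure
        )


def _lfsr_bits(order: int, taps: tuple[int, ...], state: tuple[int, ...],
               n_steps: int) -> tuple[list[int], list[tuple[int, ...]]]:
    """Run the Fibonacci LFSR, returning output bits and visited states."""
    bits: list[int] = []
    states: list[tuple[int, ...]] = []
    s = list(state)
    tap_idx = [t - 1 for t in taps]
    for _ in range(n_steps):
        states.append(tuple(s))
        bits.append(s[-1])
        fb = 0
        for i in tap_idx:
            fb ^= s[i]
        s = [fb] + s[:-1]
    return bits, states


def generate_msequence(
    order: int,
    taps: tuple[int, ...] | set[int],
    initial_state: tuple[int, ...] | str,
    label: str = "",
) -> MSequence:
    """Generate one full period from an explicit register description.

    Parameters
    ----------
    order
        Register length ``n`` (≥ 2).
    taps
        Stage numbers (1..n) XOR-ed into the feedback; must describe a
        primitive polynomial, otherwise the observed short period is
        reported in the error.
    initial_state
        ``n`` bits, e.g. ``(1, 1, 1)`` or ``"111"``; must not be all zero.
    """
    if order < 2:
        raise ValueError(f"order must be >= 2, got {order}")
    taps = tuple(sorted(set(int(t) for t in taps), reverse=True))
    if not taps or max(taps) > order or min(taps) < 1:
        raise ValueError(f"taps {taps} outside stages 1..{order}")
    if isinstance(initial_state, str):
        initial_state = tuple(int(c) for c in initial_state)
    initial_state = tuple(int(b) for b in initial_state)
    if len(initial_state) != order:
        raise ValueError(
            f"initial_state has {len(initial_state)} bits, expected {order}"
        )
    if not any(initial_state):
        raise ValueError("initial_state must not be all zero")
    period = 2**order - 1
    bits, states = _lfsr_bits(order, taps, initial_state, period)
    # A non-primitive polynomial revisits the initial state early.
    seen = {}
    for i, st in enumerate(states):
        if st in seen:
            raise ValueError(
                f"taps {taps} are not primitive for order {order}: "
                f"observed period {i - seen[st]} < {period}"
            )
        seen[st] = i
    values = np.where(np.asarray(bits, dtype=np.int8) == 1, 1, -1).astype(
        np.int8
    )
    return MSequence(
        order=order,
        taps=taps,
        initial_state=initial_state,
        values=values,
        label=label,
    )


def random_msequence(order: int, rng: np.random.Generator,
                     label: str = "") -> MSequence:
    """Draw a random m-sequence of the given order.

    Randomises three things, each reproducible from ``rng``: the primitive
    polynomial (from :data:`PRIMITIVE_TAPS`), the nonzero initial register
    state, and a circular phase of the emitted period.
    """
    if order not in PRIMITIVE_TAPS:
        raise ValueError(
            f"order {order} unsupported; catalog covers "
            f"{sorted(PRIMITIVE_TAPS)}"
        )
    taps = PRIMITIVE_TAPS[order][rng.integers(len(PRIMITIVE_TAPS[order]))]
    state_int = int(rng.integers(1, 2**order))
    state = tuple((state_int >> i) & 1 for i in range(order))
    seq = generate_msequence(order, taps, state, label=label)
    phase = int(rng.integers(seq.period))
    return MSequence(
        order=order,
        taps=taps,
        initial_state=state,
        values=np.roll(seq.values, -phase),
        phase=phase,
        label=label,
    )


def verify_msequence(values: np.ndarray) -> MSequenceReport:
    """Check the three defining m-sequence properties of a ±1 vector.

    A length that is not of the form ``2**n - 1`` fails the report (with a
    reason) rather than raising.
    """
    values = np.asarray(values)
    if not np.all(np.isin(values, (-1, 1))):
        raise ValueError("values must contain only -1 and +1")
    n_float = np.log2(len(values) + 1)
    order = int(round(n_float))
    if 2**order - 1 != len(values):
        return MSequenceReport(
            valid_length=False,
            balance=False,
            subword_unique=False,
            shift_closure=False,
            reason=f"length {len(values)} is not of the form 2**n - 1",
        )
    N = len(values)
    balance = (
        int(np.sum(values == 1)) == 2 ** (order - 1)
        and int(np.sum(values == -1)) == 2 ** (order - 1) - 1
    )
    ext = np.concatenate([values, values[: order - 1]])
    words = {
        tuple(ext[i : i + order]) for i in range(N)
    }
    subword_unique = len(words) == N and tuple([-1] * order) not in words
    # Shift-and-product closure, checked over GF(2) where it is
    # convention-free: the XOR of the bit sequence with any nonzero
    # circular shift of itself must be another circular shift.  In ±1
    # terms this is exactly product closure under the (-1)**bit sign
    # convention; under this package's display convention (1 → +1) the
    # elementwise product equals the negation of a circular shift.
    bits = values == 1
    bit_shifts = {tuple(np.roll(bits, s)) for s in range(N)}
    shift_closure = all(
        tuple(bits ^ np.roll(bits, s)) in bit_shifts for s in range(1, N)
    )
    return MSequenceReport(
        valid_length=True,
        balance=balance,
        subword_unique=subword_unique,
        shift_closure=shift_closure,
        order=order,
    )


def extend_circular(
    mseq: MSequence | np.ndarray, total_length: int | None = None
) -> np.ndarray:
    """Circularly tile a period so the FINAL period entries are one full cycle.

    The leading ``total_length - N`` entries serve as warm-up to absorb
    onset transients; only the final ``N`` impulses enter the analysis.
    With the default ``total_length=400`` for an order-8 sequence, entries
    146–400 (1-indexed) are exactly one period.
    """
    values = mseq.values if isinstance(mseq, MSequence) else np.asarray(mseq)
    N = len(values)
    if total_length is None:
        total_length = 400
    if total_length < N:
        raise ValueError(
            f"total_length {total_length} < period {N}"
        )
    reps = int(np.ceil(total_length / N))
    return np.tile(values, reps)[-total_length:].astype(np.int8)
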