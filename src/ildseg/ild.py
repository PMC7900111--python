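"""Sequence-level input dropout with inverse-keep-probability reweighting.

The central idea: a 2.5D segmentation network is trained not only on the
full set of ``S`` co-registered MRI sequences but on every admissible
subset of them.  During training, entire sequences (all ``k`` slab slices
of a sequence, never individual slices) are stochastically replaced by
zeros, and the surviving channels are upweighted by ``1/(1-p)`` where
``p`` is the fraction of sequences dropped.  The same zero-fill +
upweighting is applied at inference time to declare sequences a site does
not acquire, so a single trained model serves sites with different
protocols.  Dropping *all* sequences is never admissible: it would hand
the network an all-zero tensor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AllSequencesDroppedError",
    "AvailabilityPattern",
    "DropoutPolicy",
    "sample_pattern",
    "apply_input_dropout",
]


class AllSequencesDroppedError(ValueError):
    """Raised when a pattern (or dropout request) would zero every sequence."""


@dataclass(frozen=True)
class AvailabilityPattern:
    """Which of the S input sequences are present.

    ``p`` is the dropout proportion: the fraction of sequences that are
    absent.  At least one sequence must be available, so ``p < 1`` always.
    """

    available: tuple[bool, ...]

    def __post_init__(self) -> None:
        avail = tuple(bool(a) for a in self.available)
        object.__setattr__(self, "available", avail)
        if len(avail) == 0:
            raise ValueError("pattern must cover at least one sequence")
        if not any(avail):
            raise AllSequencesDroppedError(
                "all sequences unavailable: the model would receive an "
                "all-zero input tensor"
            )

    @property
    def n_sequences(self) -> int:
        return len(self.available)

    @property
    def n_dropped(self) -> int:
        return sum(not a for a in self.available)

    @property
    def p(self) -> float:
        """Proportion of dropped sequences, exactly n_dropped / S."""
        return self.n_dropped / self.n_sequences

    @property
    def dropped_indices(self) -> tuple[int, ...]:
        return tuple(i for i, a in enumerate(self.available) if not a)

    @classmethod
    def all_available(cls, n_sequences: int) -> "AvailabilityPattern":
        return cls(available=(True,) * n_sequences)

    @classmethod
    def from_string(cls, bits: str) -> "AvailabilityPattern":
        """Parse a bit-string such as ``"0111"`` (1 = available).

        Order follows the manifest / study sequence order.
        """
        if not bits or any(c not in "01" for c in bits):
            raise ValueError(f"availability string must be over {{0,1}}, got {bits!r}")
        return cls(available=tuple(c == "1" for c in bits))

    def to_string(self) -> str:
        return "".join("1" if a else "0" for a in self.available)


@dataclass(frozen=True)
class DropoutPolicy:
    """Distribution over how many sequences to drop in one training sample.

    A number dropped ``d`` is drawn from ``weights`` over ``{0..max_dropped}``,
    then a uniformly random subset of that size is zeroed.  ``max_dropped``
    must stay below S so the all-dropped pattern can never occur.
    """

    max_dropped: int = 3
    weights: tuple[float, ...] | None = None  # over {0..max_dropped}; None = uniform
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_dropped < 0:
            raise ValueError("max_dropped must be >= 0")
        if self.weights is not None:
            w = tuple(float(x) for x in self.weights)
            if len(w) != self.max_dropped + 1:
                raise ValueError(
                    f"need {self.max_dropped + 1} weights over d in "
                    f"{{0..{self.max_dropped}}}, got {len(w)}"
                )
            if any(x < 0 for x in w) or not np.isclose(sum(w), 1.0):
                raise ValueError("weights must be nonnegative and sum to 1")
            object.__setattr__(self, "weights", w)

    def effective_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.max_dropped + 1, 1.0 / (self.max_dropped + 1))
        return np.asarray(self.weights, dtype=float)

    @classmethod
    def never_drop(cls, seed: int = 0) -> "DropoutPolicy":
        """The no-dropout baseline policy: always keep every sequence."""
        return cls(max_dropped=0, weights=(1.0,), seed=seed)

    def make_rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def sample_pattern(
    policy: DropoutPolicy, n_sequences: int, rng: np.random.Generator
) -> AvailabilityPattern:
    """Draw one availability pattern: d ~ policy weights, subset uniform.

    Never emits the all-dropped pattern (enforced structurally by
    ``max_dropped <= S-1``).
    """
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    if policy.max_dropped >= n_sequences:
        raise ValueError(
            f"max_dropped={policy.max_dropped} would allow dropping all "
            f"{n_sequences} sequences; it must be <= S-1"
        )
    w = policy.effective_weights()
    d = int(rng.choice(len(w), p=w))
    available = [True] * n_sequences
    if d > 0:
        for idx in rng.choice(n_sequences, size=d, replace=False):
            available[int(idx)] = False
    return AvailabilityPattern(available=tuple(available))


def apply_input_dropout(slab, pattern: AvailabilityPattern):
    """Zero every channel of each dropped sequence; upweight survivors by 1/(1-p).

    Applied identically during training (with sampled patterns) and at
    inference (with the site's declared pattern).  Sequence atomicity is
    structural: the whole k-slice block of a sequence is zeroed, never a
    partial slab.

    Parameters
    ----------
    slab : SlabStack
        A channel-first 2.5D stack with ``S*k`` channels grouped by sequence.
    pattern : AvailabilityPattern
        Which sequences survive.  Must cover the slab's S sequences.
    """
    k = slab.slab_width
    n_channels = slab.values.shape[0]
    if n_channels % k != 0:
        raise ValueError("channel count is not a multiple of the slab width")
    n_seq = n_channels // k
    if pattern.n_sequences != n_seq:
        raise ValueError(
            f"pattern covers {pattern.n_sequences} sequences, slab has {n_seq}"
        )
    scale = 1.0 / (1.0 - pattern.p)
    values = slab.values * np.asarray(scale, dtype=slab.values.dtype)
    for s in pattern.dropped_indices:
        values[s * k : (s + 1) * k] = 0
    return replace(slab, values=values, pattern=pattern)


def admissible_patterns(n_sequences: int) -> list[AvailabilityPattern]:
    """Enumerate all 2^S - 1 admissible patterns (everything but all-dropped)."""
    out = []
    for code in range(1, 2**n_sequences):
        bits = tuple(bool((code >> i) & 1) for i in range(n_sequences))
        out.append(AvailabilityPattern(available=bits))
    return out
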