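"""Discrete position representation and the binary QPSO operators.

Particle positions are fixed-length 0/1 strings (here: one bit per candidate
gene, 1 = gene included in the subset).  The binary quantum-behaved PSO
replaces the continuous QPSO geometry with Hamming distance and three
string operators:

* ``get_mbest`` — the mean-best position, a per-bit majority vote over all
  personal bests, ties broken uniformly at random;
* ``get_local_attractor`` — the point a particle is perturbed toward, an
  offspring of one-point crossover between its personal best and the global
  best (so every bit of the attractor comes from one of the two parents);
* ``jump_length`` / ``mutate_toward`` — the stochastic jump: an integer jump
  length ``b = ceil(ce * d_H(x, mbest) * ln(1/mu))`` with ``mu ~ U(0,1)``,
  converted to a per-bit flip probability ``Pr = min(b/l, 1)`` and applied
  as independent bit flips of the attractor.

All operators take an explicit :class:`numpy.random.Generator`; given the
same generator state they are fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Bits",
    "ParticleLayout",
    "JumpDraw",
    "as_bits",
    "bits_to_string",
    "hamming",
    "get_mbest",
    "get_local_attractor",
    "jump_length",
    "jump_from_mu",
    "mutate_toward",
]

#: A particle position: 1-D ``uint8`` array of 0/1 values.
Bits = np.ndarray


def as_bits(x: str | Sequence[int] | np.ndarray) -> Bits:
    """Coerce a 0/1 text string, sequence or array to a ``uint8`` bit array.

    Raises ``ValueError`` if any element is not exactly 0 or 1.
    """
    if isinstance(x, str):
        arr = np.frombuffer(x.encode("ascii"), dtype=np.uint8) - ord("0")
    else:
        arr = np.asarray(x, dtype=np.uint8)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("a bit string must be a non-empty 1-D sequence")
    if not np.all((arr == 0) | (arr == 1)):
        raise ValueError("bit strings may contain only 0 and 1")
    return arr


def bits_to_string(bits: Bits) -> str:
    """Serialize a bit array as a plain ``"0101..."`` text string."""
    return "".join("1" if b else "0" for b in bits)


@dataclass(frozen=True)
class ParticleLayout:
    """Partition of a particle into decision-variable substrings.

    For gene selection a particle has a single decision variable whose
    length equals the size of the prefiltered search space (50 genes by
    default), so ``substring_lengths == [total_length]``.
    """

    substring_lengths: tuple[int, ...] = (50,)

    def __post_init__(self) -> None:
        if not self.substring_lengths or any(l < 1 for l in self.substring_lengths):
            raise ValueError("substring lengths must be positive")

    @property
    def num_variables(self) -> int:
        return len(self.substring_lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.substring_lengths))

    @classmethod
    def single(cls, length: int) -> "ParticleLayout":
        """Layout with one decision variable of the given length."""
        return cls((int(length),))


@dataclass(frozen=True)
class JumpDraw:
    """One stochastic jump: the uniform draw, integer jump length and the
    resulting per-bit mutation probability."""

    mu: float
    b: int
    pr: float


def _check_equal_length(a: Bits, b: Bits) -> None:
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"bit strings have unequal lengths ({a.shape[0]} vs {b.shape[0]})"
        )


def hamming(a: str | Bits, b: str | Bits) -> int:
    """Hamming distance: the count of positions at which two equal-length
    bit strings differ."""
    a, b = as_bits(a), as_bits(b)
    _check_equal_length(a, b)
    return int(np.count_nonzero(a != b))


def get_mbest(pbests: Iterable[str | Bits], rng: np.random.Generator) -> Bits:
    """Mean-best position: per-bit strict majority over all personal bests.

    Where 1 and 0 occur equally often the bit is set to 0 or 1 uniformly at
    random, with a fresh draw on every call.
    """
    mat = [as_bits(p) for p in pbests]
    if not mat:
        raise ValueError("get_mbest requires at least one pbest")
    lengths = {m.shape[0] for m in mat}
    if len(lengths) > 1:
        raise ValueError("all pbest strings must have equal length")
    stacked = np.stack(mat)
    ones = stacked.sum(axis=0, dtype=np.int64)
    n = stacked.shape[0]
    out = (2 * ones > n).astype(np.uint8)
    ties = 2 * ones == n
    if ties.any():
        out[ties] = rng.integers(0, 2, size=int(ties.sum()), dtype=np.uint8)
    return out


def _one_point_crossover(a: Bits, b: Bits, cut: int) -> tuple[Bits, Bits]:
    """The two offspring of a one-point crossover cut after position ``cut``
    (1-based count of head bits, 1 <= cut <= l-1)."""
    return (
        np.concatenate([a[:cut], b[cut:]]),
        np.concatenate([b[:cut], a[cut:]]),
    )


def get_local_attractor(
    pbest: str | Bits,
    gbest: str | Bits,
    rng: np.random.Generator,
    mode: str = "one-point",
) -> Bits:
    """Local attractor: a crossover offspring of ``pbest`` and ``gbest``.

    ``mode="one-point"`` (default) draws a uniform cut position and returns
    one of the two offspring uniformly at random; ``mode="multipoint"`` uses
    two cut points.  Either way each bit of the result equals the bit of one
    of the parents at the same position, so the attractor lies between its
    parents in Hamming geometry.
    """
    a, b = as_bits(pbest), as_bits(gbest)
    _check_equal_length(a, b)
    l = a.shape[0]
    if l == 1:
        return (a if rng.random() < 0.5 else b).copy()
    if mode == "one-point":
        cut = int(rng.integers(1, l))
        kids = _one_point_crossover(a, b, cut)
    elif mode == "multipoint":
        # two-point crossover: swap the segment between the cuts
        if l == 2:
            c1, c2 = 1, 1
        else:
            c1, c2 = sorted(int(c) for c in rng.choice(l - 1, size=2, replace=False) + 1)
        k1, k2 = a.copy(), b.copy()
        k1[c1:c2], k2[c1:c2] = b[c1:c2], a[c1:c2]
        kids = (k1, k2)
    else:
        raise ValueError(f"unknown crossover mode: {mode!r}")
    return kids[int(rng.integers(0, 2))].copy()


def jump_from_mu(
    hamming_distance: int, ce_coefficient: float, mu: float, substring_length: int
) -> JumpDraw:
    """Deterministic part of the jump draw, for a given uniform variate.

    ``b = ceil(ce * d_H * ln(1/mu))`` and ``Pr = min(b / l, 1)``.
    """
    if not 0.0 < mu < 1.0:
        raise ValueError("mu must lie in the open interval (0, 1)")
    if ce_coefficient <= 0:
        raise ValueError("contraction-expansion coefficient must be positive")
    b = math.ceil(ce_coefficient * hamming_distance * math.log(1.0 / mu))
    pr = min(b / substring_length, 1.0)
    return JumpDraw(mu=mu, b=int(b), pr=pr)


def jump_length(
    x: str | Bits,
    mbest: str | Bits,
    ce_coefficient: float,
    rng: np.random.Generator,
) -> JumpDraw:
    """Draw the stochastic jump length of a particle toward ``mbest``.

    ``mu`` is drawn uniformly in the open interval (0, 1); the jump length
    scales with the Hamming distance from the current position to the mean
    best, so a particle sitting on ``mbest`` does not move (b = 0).
    """
    a, m = as_bits(x), as_bits(mbest)
    _check_equal_length(a, m)
    # 1 - random() lies in (0, 1]; ln(1/1) = 0 so mu = 1 is harmless, but
    # redraw to honour the open-interval contract exactly.
    mu = 1.0 - rng.random()
    while mu >= 1.0:  # pragma: no cover - probability 2**-53
        mu = 1.0 - rng.random()
    return jump_from_mu(hamming(a, m), ce_coefficient, mu, a.shape[0])


def mutate_toward(p: str | Bits, draw: JumpDraw, rng: np.random.Generator) -> Bits:
    """Mutate the attractor: flip each bit independently with probability
    ``draw.pr``.  Expected Hamming displacement is ``l * pr`` (= b when
    b <= l), realising the jump-length contract in expectation."""
    bits = as_bits(p).copy()
    if not 0.0 <= draw.pr <= 1.0:
        raise ValueError("mutation probability must lie in [0, 1]")
    if draw.pr == 0.0:
        return bits
    flips = rng.random(bits.shape[0]) < draw.pr
    bits[flips] ^= 1
    return bits
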