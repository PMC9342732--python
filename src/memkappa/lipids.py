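"""Mapping experimental lipid species onto a coarse-grained lipid library.

Experimental lipidomics reports acyl tails as ``carbons:double_bonds`` pairs
(e.g. ``18:2-14:1``). A coarse-grained force field offers a finite lipid
library, so each experimental species is assigned the library lipid with the
smallest integer error score

    E = E_sat + E_tail,

where ``E_sat`` sums per-tail absolute differences in double-bond count and
``E_tail`` sums per-tail absolute differences in carbon count. Tails are
paired so as to minimise the total score. Leaflet asymmetry is applied per
species by splitting its population between the two leaflets at a fixed ratio
(largest-remainder rounding so counts are conserved).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "LipidSpec",
    "MappingError",
    "LeafletAssignment",
    "mapping_error",
    "best_match",
    "leaflet_split",
]


@dataclass(frozen=True)
class LipidSpec:
    """A lipid described by its acyl tails.

    ``tails`` is an ordered tuple of ``(carbons, double_bonds)`` pairs;
    between one and four tails are allowed.
    """

    name: str
    tails: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        tails = tuple((int(c), int(b)) for c, b in self.tails)
        object.__setattr__(self, "tails", tails)
        if not 1 <= len(tails) <= 4:
            raise ValueError(f"{self.name}: expected 1-4 tails, got {len(tails)}")
        for c, b in tails:
            if c < 2:
                raise ValueError(f"{self.name}: tail carbon count must be >= 2, got {c}")
            if b < 0:
                raise ValueError(f"{self.name}: double-bond count must be >= 0, got {b}")

    @classmethod
    def from_string(cls, text: str, name: str | None = None) -> "LipidSpec":
        """Parse a tail descriptor such as ``"18:2-14:1"``.

        Accepts ``-``, ``/`` or ``_`` as tail separators and the typographic
        en-dash occasionally found in published tables.
        """
        cleaned = text.strip().replace("–", "-").replace("/", "-").replace("_", "-")
        tails = []
        for part in cleaned.split("-"):
            c, sep, b = part.partition(":")
            if not sep:
                raise ValueError(f"malformed tail {part!r} in {text!r}")
            tails.append((int(c), int(b)))
        return cls(name=name if name is not None else cleaned, tails=tuple(tails))

    def __str__(self) -> str:
        return "-".join(f"{c}:{b}" for c, b in self.tails)


@dataclass(frozen=True)
class MappingError:
    """Decomposed lipid-mapping score: ``total = e_sat + e_tail``."""

    e_sat: int
    e_tail: int

    @property
    def total(self) -> int:
        return self.e_sat + self.e_tail


def mapping_error(experimental: LipidSpec, candidate: LipidSpec) -> MappingError:
    """Score a candidate library lipid against an experimental one.

    The tails of the two lipids are paired by the permutation of the
    candidate's tails that minimises the summed score; the published example
    (18:2-14:1 vs 18:1-16:1 → E = 1 + 2 = 3) corresponds to the
    order-preserving pairing, which this rule reproduces.
    """
    if len(experimental.tails) != len(candidate.tails):
        raise ValueError(
            f"tail count mismatch: {experimental.name} has {len(experimental.tails)}, "
            f"{candidate.name} has {len(candidate.tails)}"
        )
    best: MappingError | None = None
    for perm in itertools.permutations(candidate.tails):
        e_sat = sum(abs(b1 - b2) for (_, b1), (_, b2) in zip(experimental.tails, perm))
        e_tail = sum(abs(c1 - c2) for (c1, _), (c2, _) in zip(experimental.tails, perm))
        if best is None or e_sat + e_tail < best.total:
            best = MappingError(e_sat=e_sat, e_tail=e_tail)
    assert best is not None
    return best


def best_match(
    experimental: LipidSpec, library: Sequence[LipidSpec]
) -> tuple[LipidSpec, MappingError, bool]:
    """Pick the library lipid with the smallest mapping error.

    Only library entries with the same tail count are comparable; ties are
    broken deterministically by library order. Returns
    ``(lipid, error, tied)`` where ``tied`` flags a non-unique minimum.
    """
    if not library:
        raise ValueError("lipid library is empty")
    scored = []
    for cand in library:
        if len(cand.tails) != len(experimental.tails):
            continue
        scored.append((cand, mapping_error(experimental, cand)))
    if not scored:
        raise ValueError(
            f"no library lipid has {len(experimental.tails)} tails like {experimental.name}"
        )
    best_lipid, best_err = min(scored, key=lambda it: it[1].total)
    tied = sum(1 for _, e in scored if e.total == best_err.total) > 1
    return best_lipid, best_err, tied


@dataclass(frozen=True)
class LeafletAssignment:
    """Integer split of one lipid species between the two leaflets."""

    species: str
    upper_fraction: float
    upper: int
    lower: int

    def __post_init__(self) -> None:
        if self.upper + self.lower < 0 or min(self.upper, self.lower) < 0:
            raise ValueError("leaflet counts must be non-negative")


def leaflet_split(
    total: int, ratio_upper_to_lower: tuple[float, float], species: str = ""
) -> LeafletAssignment:
    """Split ``total`` molecules between leaflets at ratio ``a:b``.

    The target fraction a/(a+b) is converted to integer counts by
    largest-remainder rounding, which conserves the total exactly. Exactly
    half-integer targets round up for the upper leaflet (so 3:1 with 10
    molecules gives 8 upper / 2 lower).
    """
    a, b = ratio_upper_to_lower
    if total < 0:
        raise ValueError(f"total must be >= 0, got {total}")
    if not (a > 0 and b > 0):
        raise ValueError(f"ratio components must be positive, got {a}:{b}")
    frac = a / (a + b)
    exact_upper = frac * total
    upper = int(exact_upper)
    remainder = exact_upper - upper
    # one leftover molecule goes to the leaflet with the larger remainder;
    # the upper leaflet wins ties.
    if remainder >= (1.0 - remainder) - 1e-12 and upper < total:
        upper += 1
    return LeafletAssignment(
        species=species, upper_fraction=frac, upper=upper, lower=total - upper
    )
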