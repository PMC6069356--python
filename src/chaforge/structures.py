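"""Pseudoknot-free secondary structures and their loop decomposition.

A structure lives on one or more ordered strands (a *complex ordering*); base
indices run over the 5'->3' concatenation, with a *nick* between consecutive
strands. Pairs must be non-crossing with respect to that ordering. The free
energy model is loop-based, so the central operation here is the exact
partition of a structure into loops: hairpin, stack, bulge, interior,
multiloop, exterior.

Conventions
-----------
* A hairpin loop that contains no nick must enclose at least 3 unpaired bases.
* Any loop containing a nick is classified (and scored) as an *exterior* loop;
  a loop of a connected complex can contain at most one nick.
* Loop membership partitions the bases: each unpaired base belongs to the loop
  it sits in, and each paired base belongs to the loop its pair *closes* (so a
  stack loop owns exactly the two bases of its closing pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["SecondaryStructure", "Loop", "decompose_loops", "StructureError"]


class StructureError(ValueError):
    """Raised for crossing pairs, bad pairings or undersized hairpins."""


@dataclass(frozen=True)
class Loop:
    """One face of the base-pairing graph.

    ``closing`` is the pair (i, j) that closes the loop, or ``None`` for the
    exterior face. ``branches`` are the pairs directly accessible from inside
    the loop; ``unpaired`` the unpaired bases it contains; ``nicks`` the strand
    breaks exposed in the loop (positions p with a break between p and p+1).
    """

    kind: str  # hairpin | stack | bulge | interior | multiloop | exterior
    closing: tuple[int, int] | None
    branches: tuple[tuple[int, int], ...]
    unpaired: tuple[int, ...]
    nicks: tuple[int, ...] = ()

    @property
    def members(self) -> tuple[int, ...]:
        bases = list(self.unpaired)
        if self.closing is not None:
            bases.extend(self.closing)
        return tuple(sorted(bases))

    @property
    def size(self) -> int:
        """Number of unpaired bases in the loop."""
        return len(self.unpaired)


@dataclass(frozen=True)
class SecondaryStructure:
    """An ordered-strand complex with a set of non-crossing pairs."""

    strands: tuple[str, ...]
    pairs: frozenset[tuple[int, int]]
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "strands", tuple(self.strands))
        norm = frozenset(
            (min(i, j), max(i, j)) for i, j in self.pairs
        )
        object.__setattr__(self, "pairs", norm)
        if self.validate:
            self._check()

    # -- geometry -----------------------------------------------------------

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.strands)

    @property
    def sequence(self) -> str:
        """Concatenated bases, nicks dropped."""
        return "".join(self.strands)

    @property
    def nick_positions(self) -> tuple[int, ...]:
        """Positions p such that a strand break lies between p and p+1."""
        out, pos = [], 0
        for s in self.strands[:-1]:
            pos += len(s)
            out.append(pos - 1)
        return tuple(out)

    def _check(self) -> None:
        n = self.length
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise StructureError(f"pair {(i, j)} out of bounds for length {n}")
            if i in seen or j in seen:
                raise StructureError(f"base in more than one pair near {(i, j)}")
            seen.update((i, j))
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1 :]:
                if k > j:
                    break
                if i < k <= j < l:
                    raise StructureError(
                        f"crossing pairs {(i, j)} and {(k, l)} (pseudoknot)"
                    )
        decompose_loops(self)  # enforces the hairpin >= 3 rule

    # -- dot-bracket --------------------------------------------------------

    def to_dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i], chars[j] = "(", ")"
        parts, pos = [], 0
        for s in self.strands:
            parts.append("".join(chars[pos : pos + len(s)]))
            pos += len(s)
        return "+".join(parts)

    @classmethod
    def from_dot_bracket(
        cls, strands: tuple[str, ...] | list[str] | str, dot_bracket: str
    ) -> "SecondaryStructure":
        if isinstance(strands, str):
            strands = (strands,)
        strands = tuple(strands)
        segs = dot_bracket.split("+")
        if len(segs) != len(strands) or any(
            len(seg) != len(s) for seg, s in zip(segs, strands)
        ):
            raise StructureError("dot-bracket does not match strand lengths")
        flat = "".join(segs)
        stack: list[int] = []
        pairs = set()
        for idx, ch in enumerate(flat):
            if ch == "(":
                stack.append(idx)
            elif ch == ")":
                if not stack:
                    raise StructureError("unbalanced ')' in dot-bracket")
                pairs.add((stack.pop(), idx))
            elif ch != ".":
                raise StructureError(f"invalid dot-bracket character {ch!r}")
        if stack:
            raise StructureError("unbalanced '(' in dot-bracket")
        return cls(strands, frozenset(pairs))


def decompose_loops(structure: SecondaryStructure) -> list[Loop]:
    """Exactly partition a structure into loops.

    Raises :class:`StructureError` for a nick-free hairpin loop enclosing
    fewer than 3 unpaired bases.
    """
    n = structure.length
    nicks = set(structure.nick_positions)
    partner = [-1] * n
    for i, j in structure.pairs:
        partner[i], partner[j] = j, i

    loops: list[Loop] = []

    def face(i: int | None, j: int | None) -> None:
        """Collect the loop closed by pair (i, j), or the exterior face."""
        lo = 0 if i is None else i + 1
        hi = n - 1 if j is None else j - 1
        unpaired: list[int] = []
        branches: list[tuple[int, int]] = []
        exposed: list[int] = []
        if i is not None and i in nicks:
            exposed.append(i)
        p = lo
        while p <= hi:
            if partner[p] > p:
                branches.append((p, partner[p]))
                p = partner[p]
            else:
                unpaired.append(p)
            if p < n - 1 and p in nicks and p <= hi:
                # nick immediately after element ending at p is in this face
                if j is None or p < j:
                    exposed.append(p)
            p += 1
        exposed = sorted(set(exposed))
        if i is None:
            kind = "exterior"
        elif exposed:
            kind = "exterior"  # nick loop, scored as an exterior face
        elif not branches:
            if len(unpaired) < 3:
                raise StructureError(
                    f"hairpin loop closed by {(i, j)} has "
                    f"{len(unpaired)} < 3 unpaired bases"
                )
            kind = "hairpin"
        elif len(branches) == 1:
            (k, l), = branches
            g1, g2 = k - i - 1, j - l - 1
            if g1 == 0 and g2 == 0:
                kind = "stack"
            elif g1 == 0 or g2 == 0:
                kind = "bulge"
            else:
                kind = "interior"
        else:
            kind = "multiloop"
        closing = None if i is None else (i, j)
        loops.append(Loop(kind, closing, tuple(branches), tuple(unpaired), tuple(exposed)))
        for k, l in branches:
            face(k, l)

    face(None, None)
    return loops
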