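"""Wildcard amino-acid patterns.

A pattern is an ordered list of elements, each one of:

* a fixed residue (``P``),
* a residue class (``[ST]`` — any listed residue matches), or
* a single-position wildcard (``.``).

Patterns are stored in trimmed form: the first and last elements are never
wildcards.  ``P..T.PR`` matches any 7-mer window whose positions 0, 3, 5 and 6
carry P, T, P and R.  Classes are produced by consensus building downstream;
the exhaustive search itself only enumerates fixed residues and wildcards.
"""

from __future__ import annotations

import re
from typing import Iterator

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

_TOKEN_RE = re.compile(r"\[([A-Z]+)\]|([A-Z])|(\.)")

Element = frozenset | None  # None encodes the wildcard


class Pattern:
    """Immutable wildcard pattern over the 20-letter amino-acid alphabet."""

    __slots__ = ("elements", "_hash")

    def __init__(self, elements):
        elems = tuple(None if e is None else frozenset(e) for e in elements)
        if not elems:
            raise ValueError("pattern must have at least one element")
        if elems[0] is None or elems[-1] is None:
            raise ValueError("pattern must be trimmed: first/last element cannot be a wildcard")
        for e in elems:
            if e is None:
                continue
            if not e or not e <= _AA_SET:
                raise ValueError(f"invalid residue set {set(e)!r}")
        if not any(e is not None and len(e) == 1 for e in elems):
            raise ValueError("pattern must contain at least one fixed residue")
        self.elements = elems
        self._hash = hash(elems)

    # -- construction ------------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "Pattern":
        """Parse a pattern string such as ``"P..T.[P]R"`` or ``"P[AYS][LI]TA.[REQ][GT][LDK]"``."""
        pos = 0
        elems: list[Element] = []
        for m in _TOKEN_RE.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse pattern {text!r} at position {pos}")
            pos = m.end()
            cls_body, fixed, wild = m.groups()
            if wild is not None:
                elems.append(None)
            elif fixed is not None:
                elems.append(frozenset(fixed))
            else:
                elems.append(frozenset(cls_body))
        if pos != len(text):
            raise ValueError(f"cannot parse pattern {text!r} at position {pos}")
        return cls(elems)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.elements)

    def __eq__(self, other) -> bool:
        return isinstance(other, Pattern) and self.elements == other.elements

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"Pattern({str(self)!r})"

    def __str__(self) -> str:
        out = []
        for e in self.elements:
            if e is None:
                out.append(".")
            elif len(e) == 1:
                out.append(next(iter(e)))
            else:
                out.append("[" + "".join(sorted(e)) + "]")
        return "".join(out)

    # -- semantics ---------------------------------------------------------
    @property
    def n_fixed(self) -> int:
        """Number of non-wildcard elements (fixed residues and classes)."""
        return sum(1 for e in self.elements if e is not None)

    def fixed_positions(self) -> Iterator[tuple[int, frozenset]]:
        for i, e in enumerate(self.elements):
            if e is not None:
                yield i, e

    def match(self, sequence: str) -> list[int]:
        """All 0-based offsets at which the pattern matches ``sequence``."""
        L = len(self.elements)
        hits = []
        for o in range(len(sequence) - L + 1):
            ok = True
            for i, e in enumerate(self.elements):
                if e is not None and sequence[o + i] not in e:
                    ok = False
                    break
            if ok:
                hits.append(o)
        return hits

    def matches(self, sequence: str) -> bool:
        return bool(self.match(sequence))

    def to_regex(self) -> str:
        """Regular-expression translation (no capture groups)."""
        out = []
        for e in self.elements:
            if e is None:
                out.append(".")
            elif len(e) == 1:
                out.append(next(iter(e)))
            else:
                out.append("[" + "".join(sorted(e)) + "]")
        return "".join(out)

    def compiled(self) -> re.Pattern:
        return re.compile(self.to_regex())


def match_pattern(pattern: Pattern | str, sequence: str) -> list[int]:
    """Offsets at which ``pattern`` matches ``sequence`` (0-based, increasing)."""
    if isinstance(pattern, str):
        pattern = Pattern.parse(pattern)
    return pattern.match(sequence)


def consensus_from_pwm(pwm, columns=None, fixed_freq: float = 0.5, class_freq: float = 0.2) -> str:
    """Consensus pattern string from a position-frequency matrix.

    ``pwm`` maps column index -> {residue: frequency} (each column summing to
    1, or empty).  A column becomes a fixed residue when one residue reaches
    ``fixed_freq``, a residue class when >=2 residues each reach
    ``class_freq``, and a wildcard otherwise.  Leading/trailing wildcards are
    trimmed.
    """
    ncol = len(pwm) if columns is None else columns
    toks = []
    for j in range(ncol):
        col = pwm[j]
        if not col:
            toks.append(".")
            continue
        best = max(sorted(col), key=lambda r: col[r])
        if col[best] >= fixed_freq:
            toks.append(best)
            continue
        klass = sorted(r for r, f in col.items() if f >= class_freq)
        if len(klass) >= 2:
            toks.append("[" + "".join(klass) + "]")
        else:
            toks.append(".")
    s = "".join(toks)
    return s.strip(".")
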