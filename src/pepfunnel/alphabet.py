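"""Canonical amino-acid alphabet and integer encoding.

The model vocabulary is the 20 canonical amino acids in alphabetical
one-letter order, ``ACDEFGHIKLMNPQRSTVWY``; residue index is position in
that string (A=0 ... Y=19).  There is no padding, gap or wildcard token:
sequences containing ambiguity codes (B, J, O, U, X, Z), gaps or stops are
rejected by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class SequenceError(ValueError):
    """A sequence violates the canonical-alphabet contract."""


@dataclass(frozen=True)
class ResidueAlphabet:
    """Ordered 20-letter amino-acid alphabet with a letter<->index bijection."""

    letters: str = "ACDEFGHIKLMNPQRSTVWY"
    index_of: dict[str, int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.letters) != 20 or len(set(self.letters)) != 20:
            raise ValueError("alphabet must contain 20 distinct letters")
        object.__setattr__(self, "index_of", {c: i for i, c in enumerate(self.letters)})

    def __len__(self) -> int:
        return len(self.letters)

    def __contains__(self, letter: str) -> bool:
        return letter in self.index_of


#: The package-wide default alphabet.
ALPHABET = ResidueAlphabet()


def validate_sequence(seq: str, alphabet: ResidueAlphabet = ALPHABET) -> str:
    """Upper-case *seq* and verify every character is a canonical residue.

    Returns the normalised sequence.  Raises :class:`SequenceError` naming the
    first offending position (1-based) and character, or on empty input.
    """
    if not seq:
        raise SequenceError("empty sequence")
    up = seq.upper()
    for pos, ch in enumerate(up, start=1):
        if ch not in alphabet:
            raise SequenceError(
                f"non-canonical residue {ch!r} at position {pos}"
            )
    return up


def encode(seq: str, alphabet: ResidueAlphabet = ALPHABET) -> list[int]:
    """Map a validated sequence to integer codes in {0..19}."""
    idx = alphabet.index_of
    try:
        return [idx[c] for c in seq]
    except KeyError as exc:  # pragma: no cover - callers validate first
        raise SequenceError(f"non-canonical residue {exc.args[0]!r}") from None


def decode(codes, alphabet: ResidueAlphabet = ALPHABET) -> str:
    """Inverse of :func:`encode`."""
    letters = alphabet.letters
    out = []
    for v in codes:
        v = int(v)
        if not 0 <= v < 20:
            raise SequenceError(f"residue code {v} outside 0..19")
        out.append(letters[v])
    return "".join(out)
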