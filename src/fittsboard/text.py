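"""Character alphabet and the shared text-normalization rule.

Digraph counting and transcription simulation must agree on what a corpus
character is, so normalization lives in one place: text is uppercased, runs
of whitespace (including newlines) collapse to a single space, and anything
outside the alphabet is dropped.  A dropped character breaks adjacency — the
digraph straddling it is not counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["Alphabet", "normalize_text", "DEFAULT_CHARS"]

DEFAULT_CHARS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ "

_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class Alphabet:
    """Ordered character set of the keyboard; the 26 letters plus space by default.

    Space is a first-class character: it occupies a key and participates in
    digraph flow like any letter.
    """

    chars: str = DEFAULT_CHARS

    def __post_init__(self) -> None:
        if len(set(self.chars)) != len(self.chars):
            raise ValueError("alphabet characters must be unique")
        if len(self.chars) < 2:
            raise ValueError("alphabet must contain at least two characters")

    def __len__(self) -> int:
        return len(self.chars)

    def __contains__(self, ch: str) -> bool:
        return ch in self.chars

    def __iter__(self):
        return iter(self.chars)

    def index(self, ch: str) -> int:
        i = self.chars.find(ch)
        if i < 0:
            raise KeyError(f"character {ch!r} not in alphabet")
        return i


def normalize_text(text: str) -> str:
    """Uppercase and collapse all whitespace runs to single spaces.

    Out-of-alphabet characters are *not* removed here; they are handled at
    the point of use so that they can break digraph adjacency rather than
    silently joining their neighbors.
    """
    return _WS.sub(" ", text).strip().upper()
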