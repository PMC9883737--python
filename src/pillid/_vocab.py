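"""Imprint vocabulary and tokenization.

Imprints are sequences over uppercase letters A-Z, digits 0-9 and the single
lowercase token "mg" (milligram), with "_" marking the boundary between the
front and back faces of the pill.  "mg" is one token everywhere: in
generation, detection classes, sequence modeling and edit-distance scoring.
"""

from __future__ import annotations

VOCAB_TOKENS: tuple[str, ...] = tuple(
    [chr(c) for c in range(ord("A"), ord("Z") + 1)]
    + [str(d) for d in range(10)]
    + ["mg"]
)
TOKEN_INDEX: dict[str, int] = {t: i for i, t in enumerate(VOCAB_TOKENS)}
SEPARATOR = "_"


def tokenize(text: str, strict: bool = False) -> list[str]:
    """Split an imprint string into tokens ("mg" and "_" are single tokens).

    With ``strict=False`` unknown symbols pass through as one-character
    tokens, which scoring needs (database imprints may contain symbols
    outside the generation vocabulary); with ``strict=True`` they raise.
    """
    tokens: list[str] = []
    i = 0
    while i < len(text):
        if text.startswith("mg", i):
            tokens.append("mg")
            i += 2
            continue
        ch = text[i]
        if strict and ch != SEPARATOR and ch not in TOKEN_INDEX:
            raise ValueError(f"symbol {ch!r} is not in the imprint vocabulary")
        tokens.append(ch)
        i += 1
    return tokens


def detokenize(tokens: list[str]) -> str:
    return "".join(tokens)


def split_faces(text: str) -> tuple[list[str], list[str]]:
    """Front/back token lists; text without "_" is all front."""
    if text.count(SEPARATOR) > 1:
        raise ValueError("imprint contains more than one front/back separator")
    if SEPARATOR in text:
        front, back = text.split(SEPARATOR)
    else:
        front, back = text, ""
    return tokenize(front), tokenize(back)
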