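"""SHELX instruction-file cards: one ordered text line each."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Card:
    """One line of a .ins file.

    ``keyword`` is the instruction mnemonic (TITL, CELL, SYMM, ...) or an
    atom label; ``payload`` the rest of the line; ``commented`` cards are
    written with a literal ``REM `` prefix so the user can activate them by
    deleting four characters.
    """

    keyword: str
    payload: str = ""
    commented: bool = False

    def __post_init__(self) -> None:
        if not self.keyword:
            raise ValueError("card keyword must be non-empty")

    @property
    def text(self) -> str:
        body = self.keyword if not self.payload else f"{self.keyword} {self.payload}"
        return f"REM {body}" if self.commented else body

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text
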