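"""SMILES string simplification.

Before sub-structure tokenization, SMILES strings are stripped of the
characters that encode branching and ring topology — round and square
brackets, decimal digits (ring-closure labels, charges, isotope counts)
and the ``%`` two-digit ring-closure prefix.  What remains is the linear
sequence of atom and bond symbols, which is what the data-driven
tokenizer segments into sub-structure patterns.  Spatial structure is
deliberately discarded; stereo markers (``@``, ``/``, ``\\``) are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

#: characters removed by :func:`simplify_smiles`
_REMOVED = set("()[]%") | set("0123456789")


@dataclass(frozen=True)
class SimplifiedSmiles:
    """A raw SMILES string together with its simplified form.

    The simplified form contains no brackets, digits or ``%`` and is a
    subsequence of the raw string; simplification is idempotent.
    """

    raw: str
    simplified: str

    def __post_init__(self) -> None:
        if not self.simplified.strip():
            raise ValueError(
                f"SMILES {self.raw!r} is empty after simplification"
            )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.simplified


def simplify_smiles(raw: str, removed_chars: frozenset[str] | None = None) -> SimplifiedSmiles:
    """Strip bracket and number-label characters from a SMILES string.

    Parameters
    ----------
    raw:
        Original SMILES string.  Must be non-empty after stripping
        whitespace.
    removed_chars:
        Optional override for the character set to delete.  Defaults to
        ``( ) [ ] %`` and the decimal digits.

    Returns
    -------
    SimplifiedSmiles
        The raw string and its simplified form, with all remaining
        characters preserved in order.

    Examples
    --------
    >>> simplify_smiles("C1=CC=CC=C1").simplified
    'C=CC=CC=C'
    >>> simplify_smiles("[NH4+].[Cl-]").simplified
    'NH+.Cl-'
    """
    if raw is None or not raw.strip():
        raise ValueError("SMILES input is empty or whitespace-only")
    removed = _REMOVED if removed_chars is None else set(removed_chars)
    raw = raw.strip()
    simplified = "".join(ch for ch in raw if ch not in removed)
    return SimplifiedSmiles(raw=raw, simplified=simplified)
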