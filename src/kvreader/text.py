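"""Natural-language tokenization for the text side of mixed sequences.

The text tokenizer is an opaque dependency of the mixed-sequence
builder: any object with a ``tokenize(str) -> list[str]`` method works.
The default here is a lower-casing word/punctuation splitter, which is
adequate for corpora whose vocabulary is closed (as the synthetic
corpora here are); swap in any subword tokenizer for open text.
"""

from __future__ import annotations

import re
from typing import Protocol


class TextTokenizer(Protocol):
    def tokenize(self, text: str) -> list[str]: ...


class WordTokenizer:
    """Lower-case word-level tokenizer splitting on non-alphanumerics.

    Punctuation characters are kept as singleton tokens so that the
    token stream remains invertible up to whitespace.
    """

    _pattern = re.compile(r"[A-Za-z0-9_'-]+|[^\sA-Za-z0-9_'-]")

    def __init__(self, lowercase: bool = True):
        self.lowercase = lowercase

    def tokenize(self, text: str) -> list[str]:
        if self.lowercase:
            text = text.lower()
        return self._pattern.findall(text)
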