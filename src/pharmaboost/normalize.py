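"""String normalization and tokenization shared by every module.

All drug names, side-effect terms and free-text strings pass through
:func:`normalize` before any comparison, so matching is deterministic across
the extraction, literature and evaluation stages: Unicode NFC, lowercase,
whitespace collapsed to single spaces, surrounding punctuation stripped.

Tokenization is the companion operation: a token is a maximal run of
alphanumeric characters, with internal hyphens kept (so catalogue-style drug
codes like ``uk-427857`` stay one token). Dictionary matching elsewhere is
defined on these token sequences, which is what gives "token boundary"
semantics: ``ici`` never matches inside ``toxicity``.
"""

from __future__ import annotations

import re
import unicodedata

_WS_RE = re.compile(r"\s+")
_TOKEN_RE = re.compile(r"[0-9a-z]+(?:-[0-9a-z]+)*")
_EDGE_PUNCT_RE = re.compile(r"^[^\w]+|[^\w]+$")


def normalize(s: str) -> str:
    """Canonical form of a name or term.

    NFC, lowercase, collapse internal whitespace, strip surrounding
    punctuation. Idempotent: ``normalize(normalize(s)) == normalize(s)``.
    """
    s = unicodedata.normalize("NFC", s)
    s = s.lower()
    s = _WS_RE.sub(" ", s).strip()
    s = _EDGE_PUNCT_RE.sub("", s)
    return s


def tokens(s: str) -> list[str]:
    """Token sequence of a normalized (or raw) string."""
    return _TOKEN_RE.findall(normalize(s))
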