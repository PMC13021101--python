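"""Lexicon matching with a fixed-window pre-term negation rule.

Splenomegaly is detected in clinical notes by matching a small term
lexicon ("splenomegaly", "big spleen", "organomegaly", "enlarged spleen")
and discarding mentions preceded, within a three-word window, by a
negation cue ("no", "none", "absence", "without", "negative").
Hemophagocytosis is detected in pathology reports by pattern match with
the same negation rule, unless a manual-review adjudication is supplied,
in which case that label wins.

A "word" is a maximal run of alphanumeric characters; punctuation
separates tokens and sentence boundaries are ignored (the window is
purely token distance).  The negation window is measured back from the
first token of a multi-word term.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .config import StudyConfig

__all__ = [
    "TermMention",
    "tokenize",
    "find_mentions",
    "is_negated",
    "note_positive_for_splenomegaly",
    "pathology_positive_for_hemophagocytosis",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class TermMention:
    """A lexicon term matched in a token stream."""

    term: str                # canonical (lower-case) lexicon entry
    start_token_index: int   # index of the term's first token
    negated: bool


def tokenize(text: str) -> list[str]:
    """Lower-case and split on runs of non-alphanumeric characters."""
    if not text:
        return []
    return _TOKEN_RE.findall(text.lower())


def find_mentions(
    text_or_tokens: str | Sequence[str], term_lexicon: Sequence[str]
) -> list[TermMention]:
    """All non-overlapping left-to-right lexicon matches in the text.

    Matching is case-insensitive over the token stream; at a given start
    position the longest matching phrase wins, and matching resumes after
    its last token.  Mentions are returned un-negated; combine with
    :func:`is_negated` or use the note-level helpers.
    """
    tokens = (
        tokenize(text_or_tokens)
        if isinstance(text_or_tokens, str)
        else [t.lower() for t in text_or_tokens]
    )
    phrases = sorted(
        {tuple(tokenize(term)) for term in term_lexicon if tokenize(term)},
        key=len,
        reverse=True,
    )
    mentions: list[TermMention] = []
    i = 0
    while i < len(tokens):
        hit = None
        for phrase in phrases:  # longest first
            if tuple(tokens[i : i + len(phrase)]) == phrase:
                hit = phrase
                break
        if hit is None:
            i += 1
        else:
            mentions.append(TermMention(" ".join(hit), i, negated=False))
            i += len(hit)
    return mentions


def is_negated(
    tokens: Sequence[str],
    mention_start: int,
    negation_terms: Sequence[str],
    window: int,
) -> bool:
    """True iff a negation cue occurs in the ``window`` tokens before
    ``mention_start``.  ``window=0`` is constantly false."""
    if not 0 <= mention_start < len(tokens):
        raise IndexError(f"mention_start {mention_start} out of range")
    if window < 0:
        raise ValueError("window must be >= 0")
    cues = {t.lower() for t in negation_terms}
    lo = max(0, mention_start - window)
    return any(tokens[i].lower() in cues for i in range(lo, mention_start))


def _positive_mentions(text: str, lexicon, config: StudyConfig) -> list[TermMention]:
    tokens = tokenize(text)
    out = []
    for m in find_mentions(tokens, lexicon):
        neg = is_negated(
            tokens, m.start_token_index, config.negation_terms, config.negation_window_words
        )
        out.append(TermMention(m.term, m.start_token_index, neg))
    return out


def note_positive_for_splenomegaly(note_text: str, config: StudyConfig) -> bool:
    """True iff the note has at least one non-negated splenomegaly term."""
    return any(
        not m.negated
        for m in _positive_mentions(note_text or "", config.splenomegaly_terms, config)
    )


def pathology_positive_for_hemophagocytosis(
    text: str,
    config: StudyConfig,
    adjudicated_positive: bool | None = None,
) -> bool:
    """Hemophagocytosis status of one pathology report.

    A manual-review adjudication, when present, overrides the text rule.
    Otherwise the report is positive iff any hemophagocytosis pattern
    matches with no negation cue in the preceding window.
    """
    if adjudicated_positive is not None:
        return bool(adjudicated_positive)
    # Patterns match as substrings of a token (e.g. "haemophagocytic"
    # inside "haemophagocytically"), unlike the exact-phrase note lexicon.
    tokens = tokenize(text or "")
    patterns = [p.lower() for p in config.hemophagocytosis_patterns]
    for i, tok in enumerate(tokens):
        if any(p in tok for p in patterns):
            if not is_negated(
                tokens, i, config.negation_terms, config.negation_window_words
            ):
                return True
    return False
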