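"""Polarity lexicons and modifier word lists.

A :class:`Lexicon` maps lowercase words to a binary polarity (+1 or -1) and
carries two modifier sets: *negators*, which invert the polarity of the
following sentiment-bearing word, and *intensifiers* (reinforcers), which
double it.  Real analyses merge several sources — a general-purpose polarity
lexicon, a domain-specific one, and an adjustment dictionary that overrides
or removes ambiguous words — with later sources taking precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Lexicon",
    "AdjustmentDictionary",
    "LexiconFormatError",
    "load_lexicon",
    "load_wordlist",
    "load_adjustments",
    "merge_lexicons",
    "demo_lexicon",
]

_POLARITY_TOKENS = {"+1": 1, "1": 1, "-1": -1, "−1": -1, "pos": 1, "neg": -1}


class LexiconFormatError(ValueError):
    """Raised for malformed lexicon / word-list / adjustment files."""


def _check_word(word: str, where: str) -> str:
    w = word.strip().lower()
    if not w or any(ch.isspace() for ch in w):
        raise LexiconFormatError(f"{where}: invalid word {word!r}")
    return w


@dataclass(frozen=True)
class Lexicon:
    """Merged polarity lexicon plus negator / intensifier sets.

    Parameters
    ----------
    entries
        Word -> polarity, polarity in {+1, -1}.
    negators
        Words that invert the following sentiment word.
    intensifiers
        Words that double the following sentiment word's score.
    provenance
        Ordered names of the sources merged into this lexicon.
    allow_modifier_overlap
        When False (default) a word may not be both a polarity entry and a
        modifier; the constructor rejects the overlap.
    """

    entries: Mapping[str, int] = field(default_factory=dict)
    negators: frozenset[str] = frozenset()
    intensifiers: frozenset[str] = frozenset()
    provenance: tuple[str, ...] = ()
    allow_modifier_overlap: bool = False

    def __post_init__(self) -> None:
        for w, p in self.entries.items():
            _check_word(w, "lexicon entry")
            if w != w.lower() or any(ch.isspace() for ch in w):
                raise LexiconFormatError(f"entry {w!r} not normalized")
            if p not in (1, -1):
                raise LexiconFormatError(f"entry {w!r}: polarity {p!r} not in {{+1, -1}}")
        both = self.negators & self.intensifiers
        if both:
            raise LexiconFormatError(f"words in both negators and intensifiers: {sorted(both)}")
        if not self.allow_modifier_overlap:
            overlap = (self.negators | self.intensifiers) & set(self.entries)
            if overlap:
                raise LexiconFormatError(
                    f"words are both polarity entries and modifiers: {sorted(overlap)}; "
                    "pass allow_modifier_overlap=True to permit this"
                )
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "negators", frozenset(self.negators))
        object.__setattr__(self, "intensifiers", frozenset(self.intensifiers))
        object.__setattr__(self, "provenance", tuple(self.provenance))

    def polarity(self, word: str) -> int | None:
        """Polarity of *word*, or None when the word bears no sentiment."""
        return self.entries.get(word)

    @property
    def modifiers(self) -> frozenset[str]:
        return self.negators | self.intensifiers

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class AdjustmentDictionary:
    """Post-merge corrections: words to drop and polarity overrides."""

    removals: frozenset[str] = frozenset()
    overrides: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clash = self.removals & set(self.overrides)
        if clash:
            raise LexiconFormatError(f"words both removed and overridden: {sorted(clash)}")
        object.__setattr__(self, "removals", frozenset(self.removals))
        object.__setattr__(self, "overrides", dict(self.overrides))


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def load_lexicon(path: str | Path, *, name: str | None = None) -> Lexicon:
    """Read a 2-column TSV polarity lexicon (word<TAB>polarity).

    Polarity tokens ``+1``/``-1``/``pos``/``neg`` are accepted; ``#`` lines are
    comments and a header line ``word<TAB>polarity`` is skipped.  Duplicate
    words with the same polarity are deduplicated; conflicting duplicates are
    an error.
    """
    path = Path(path)
    entries: dict[str, int] = {}
    first_data_line = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise LexiconFormatError(f"{path}:{lineno}: expected >=2 tab-separated fields")
        word, pol_tok = fields[0], fields[1].strip().lower()
        is_header = first_data_line and word.lower() == "word" and pol_tok not in _POLARITY_TOKENS
        first_data_line = False
        if is_header:
            continue
        if pol_tok not in _POLARITY_TOKENS:
            raise LexiconFormatError(f"{path}:{lineno}: unparseable polarity {fields[1]!r}")
        w = _check_word(word, f"{path}:{lineno}")
        pol = _POLARITY_TOKENS[pol_tok]
        if w in entries and entries[w] != pol:
            raise LexiconFormatError(f"{path}:{lineno}: conflicting polarity for {w!r}")
        entries[w] = pol
    return Lexicon(entries=entries, provenance=(name or path.stem,))


def load_wordlist(path: str | Path) -> frozenset[str]:
    """Read a one-word-per-line TSV list (negators, intensifiers, stopwords)."""
    path = Path(path)
    words = set()
    for lineno, line in _data_lines(path):
        words.add(_check_word(line.split("\t")[0], f"{path}:{lineno}"))
    return frozenset(words)


def load_adjustments(path: str | Path) -> AdjustmentDictionary:
    """Read an adjustment TSV: word<TAB>action, action in {remove, +1, -1}."""
    path = Path(path)
    removals: set[str] = set()
    overrides: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise LexiconFormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        w = _check_word(fields[0], f"{path}:{lineno}")
        action = fields[1].strip().lower()
        if action == "remove":
            removals.add(w)
        elif action in _POLARITY_TOKENS:
            overrides[w] = _POLARITY_TOKENS[action]
        else:
            raise LexiconFormatError(f"{path}:{lineno}: unknown action {fields[1]!r}")
    return AdjustmentDictionary(removals=frozenset(removals), overrides=overrides)


def merge_lexicons(
    primary: Lexicon,
    domain: Lexicon | None = None,
    adjustments: AdjustmentDictionary | None = None,
) -> Lexicon:
    """Merge a primary and a domain lexicon, then apply adjustments.

    Domain entries override primary entries on conflict; adjustment overrides
    are applied last and removal words are absent from the result.  Modifier
    sets are unioned.  The merge is idempotent: re-merging the result with an
    empty domain and empty adjustments is the identity.
    """
    domain = domain if domain is not None else Lexicon()
    adjustments = adjustments if adjustments is not None else AdjustmentDictionary()
    entries = dict(primary.entries)
    entries.update(domain.entries)
    entries.update(adjustments.overrides)
    for w in adjustments.removals:
        entries.pop(w, None)
    provenance = tuple(dict.fromkeys(primary.provenance + domain.provenance))
    return Lexicon(
        entries=entries,
        negators=primary.negators | domain.negators,
        intensifiers=primary.intensifiers | domain.intensifiers,
        provenance=provenance,
        allow_modifier_overlap=primary.allow_modifier_overlap or domain.allow_modifier_overlap,
    )


def demo_lexicon() -> Lexicon:
    """Bundled ~40-word Dutch demo lexicon with negators and intensifiers.

    For documentation, examples and tests only — real analyses require
    user-supplied lexicons.
    """
    data = Path(__file__).parent / "data"
    lex = load_lexicon(data / "demo_lexicon.tsv", name="demo")
    return Lexicon(
        entries=lex.entries,
        negators=load_wordlist(data / "demo_negators.tsv"),
        intensifiers=load_wordlist(data / "demo_intensifiers.tsv"),
        provenance=("demo",),
    )
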