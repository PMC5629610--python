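"""Knowledge-base and corpus data model plus derived lexicons.

File formats handled here:

* KB lexicon: UTF-8 TSV, columns ``concept_id  preferred_name  synonyms``
  where synonyms are pipe-separated and optional.
* Corpus: PubTator layout (``pmid|t|title`` / ``pmid|a|abstract`` /
  tab-separated annotation lines) or a plain TSV mention list
  ``doc_id  start  end  text  gold_id``.
* Word embeddings: whitespace-separated text, one word plus *t* floats
  per line.

Also defined here: the training-mention lexicon, per-document
abbreviation maps (Schwartz–Hearst style) and lexicon word statistics
used for the inverse-mention-frequency similarity feature.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from ._text import normalize, tokenize
from .stem import stem_tokens

__all__ = [
    "NIL_ID",
    "NIL_OUTPUT_LABEL",
    "ConceptEntry",
    "KnowledgeBase",
    "MentionRecord",
    "TrainingLexicon",
    "AbbreviationMap",
    "WordStats",
    "ParseError",
    "load_kb",
    "write_kb",
    "load_pubtator_corpus",
    "load_mention_tsv",
    "build_training_lexicon",
    "build_abbreviation_map",
    "compute_word_stats",
]

#: Internal sentinel for unlinkable (NIL) mentions.  Distinct from any
#: plausible concept identifier; rendered as "CUI-less" on output.
NIL_ID = "__NIL__"
NIL_OUTPUT_LABEL = "CUI-less"

#: Gold-identifier spellings that mean "no KB concept".
_NIL_ALIASES = {"-1", "CUI-less", "cui-less", "NIL", "__NIL__"}


class ParseError(ValueError):
    """Raised for malformed KB or corpus files."""


@dataclass(frozen=True)
class ConceptEntry:
    """One standard concept of the knowledge base."""

    concept_id: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()

    def names(self) -> tuple[str, ...]:
        return (self.preferred_name, *self.synonyms)


@dataclass(frozen=True)
class MentionRecord:
    """An annotated mention: document, 0-based half-open span, surface text.

    ``gold_id`` is a concept identifier, :data:`NIL_ID`, or ``None`` for
    unlabeled mentions.
    """

    doc_id: str
    start: int
    end: int
    text: str
    gold_id: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) for doc {self.doc_id}"
            )


class KnowledgeBase:
    """Concept entries plus the indices used for candidate generation.

    ``name_index`` maps normalized names to concept-id sets;
    ``word_index`` maps individual words to the ids of every concept with
    a name containing that word; ``stem_entries`` lists
    ``(stemmed_tokens, normalized_name, concept_id)`` for stem matching.
    """

    def __init__(self, entries: Iterable[ConceptEntry] = ()) -> None:
        self.entries: dict[str, ConceptEntry] = {}
        self.name_index: dict[str, set[str]] = defaultdict(set)
        self.word_index: dict[str, set[str]] = defaultdict(set)
        self.stem_entries: list[tuple[tuple[str, ...], str, str]] = []
        for entry in entries:
            self.add(entry)

    def add(self, entry: ConceptEntry) -> None:
        if entry.concept_id in self.entries:
            raise ParseError(f"duplicate concept_id {entry.concept_id!r}")
        self.entries[entry.concept_id] = entry
        for name in entry.names():
            norm = normalize(name)
            if not norm:
                raise ParseError(
                    f"empty name after normalization for {entry.concept_id!r}"
                )
            self.name_index[norm].add(entry.concept_id)
            for word in set(norm.split()):
                self.word_index[word].add(entry.concept_id)
            self.stem_entries.append(
                (tuple(stem_tokens(norm.split())), norm, entry.concept_id)
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.entries

    def names(self) -> set[str]:
        """All distinct normalized names."""
        return set(self.name_index)


@dataclass
class TrainingLexicon:
    """Normalized training-mention string -> set of observed gold ids."""

    mention_map: dict[str, set[str]] = field(default_factory=dict)

    def names(self) -> set[str]:
        return set(self.mention_map)


@dataclass
class AbbreviationMap:
    """Per-document short-form -> long-form map."""

    short_to_long: dict[str, str] = field(default_factory=dict)

    def expand(self, text: str) -> str | None:
        return self.short_to_long.get(text)


@dataclass
class WordStats:
    """Distinct-name document frequencies over the pooled lexicon.

    ``mention_frequency[w]`` counts the distinct normalized names (KB
    names plus training mentions) containing word ``w``;
    ``total_entries`` is the number of distinct names.
    """

    mention_frequency: dict[str, int]
    total_entries: int

    def imf(self, word: str) -> float:
        """Inverse mention frequency: log(N / (1 + df))."""
        if self.total_entries == 0:
            return 0.0
        df = self.mention_frequency.get(word, 0)
        return math.log(self.total_entries / (1 + df))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_kb(path: str | Path, format: str = "tsv") -> KnowledgeBase:
    """Load a KB from a TSV lexicon file.

    Each non-empty line: ``concept_id<TAB>preferred_name[<TAB>syn|syn|...]``.
    """
    if format != "tsv":
        raise ValueError(f"unsupported KB format {format!r}")
    kb = KnowledgeBase()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(f"{path}:{lineno}: malformed KB line {line!r}")
            synonyms = ()
            if len(fields) >= 3 and fields[2].strip():
                synonyms = tuple(
                    s.strip() for s in fields[2].split("|") if s.strip()
                )
            try:
                kb.add(ConceptEntry(fields[0].strip(), fields[1].strip(), synonyms))
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return kb


def write_kb(kb: KnowledgeBase, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for entry in kb.entries.values():
            handle.write(
                f"{entry.concept_id}\t{entry.preferred_name}\t"
                f"{'|'.join(entry.synonyms)}\n"
            )


def _canonical_gold(raw: str) -> str:
    raw = raw.strip()
    return NIL_ID if raw in _NIL_ALIASES else raw


def load_pubtator_corpus(
    path: str | Path,
) -> tuple[list[MentionRecord], dict[str, str]]:
    """Parse a PubTator file into mention records and document texts.

    Document text is ``title + " " + abstract`` with 0-based half-open
    annotation offsets validated against it.
    """
    titles: dict[str, str] = {}
    abstracts: dict[str, str] = {}
    annotations: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "|t|" in line and "\t" not in line:
                pmid, _, title = line.split("|", 2)
                titles[pmid] = title
                continue
            if "|a|" in line and "\t" not in line:
                pmid, _, abstract = line.split("|", 2)
                abstracts[pmid] = abstract
                continue
            annotations.append((lineno, line.split("\t")))

    docs = {
        pmid: (titles[pmid] + " " + abstracts[pmid]).rstrip()
        if pmid in abstracts
        else titles[pmid]
        for pmid in titles
    }

    records: list[MentionRecord] = []
    for lineno, fields in annotations:
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: short annotation line")
        pmid, start_s, end_s, text, _type, gold = fields[:6]
        start, end = int(start_s), int(end_s)
        doc = docs.get(pmid)
        if doc is None:
            raise ParseError(f"{path}:{lineno}: annotation for unknown doc {pmid}")
        if doc[start:end] != text:
            raise ParseError(
                f"{path}:{lineno}: doc {pmid} span [{start},{end}) reads "
                f"{doc[start:end]!r}, annotation says {text!r}"
            )
        records.append(
            MentionRecord(pmid, start, end, text, _canonical_gold(gold))
        )
    return records, docs


def load_mention_tsv(path: str | Path) -> list[MentionRecord]:
    """Plain mention list: ``doc_id  start  end  text  gold_id`` per line."""
    records = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: malformed mention line")
            gold = _canonical_gold(fields[4]) if len(fields) >= 5 else None
            records.append(
                MentionRecord(fields[0], int(fields[1]), int(fields[2]),
                              fields[3], gold)
            )
    return records


# ---------------------------------------------------------------------------
# Derived lexicons
# ---------------------------------------------------------------------------

def build_training_lexicon(records: Iterable[MentionRecord]) -> TrainingLexicon:
    """Map each normalized training mention to all gold ids it received."""
    mention_map: dict[str, set[str]] = defaultdict(set)
    for record in records:
        if record.gold_id is None:
            continue
        norm = normalize(record.text)
        if norm:
            mention_map[norm].add(record.gold_id)
    return TrainingLexicon(dict(mention_map))


# --- Schwartz–Hearst-style abbreviation detection --------------------------

def _valid_short_form(sf: str) -> bool:
    if not 2 <= len(sf) <= 10 or len(sf.split()) > 2:
        return False
    if not sf[0].isalpha():
        return False
    return any(ch.isalpha() for ch in sf)


def _find_long_form(short: str, before: str) -> str | None:
    """Right-to-left character matching of the short form inside the
    preceding text; the first short-form character must start a word."""
    s_index = len(short) - 1
    l_index = len(before) - 1
    while s_index >= 0:
        ch = short[s_index].lower()
        if not ch.isalnum():
            s_index -= 1
            continue
        while (l_index >= 0 and before[l_index].lower() != ch) or (
            s_index == 0 and l_index > 0 and before[l_index - 1].isalnum()
        ):
            l_index -= 1
        if l_index < 0:
            return None
        l_index -= 1
        s_index -= 1
    long_form = before[l_index + 1 :].strip()
    return long_form or None


def build_abbreviation_map(doc_text: str) -> AbbreviationMap:
    """Detect ``Long Form (SF)`` definitions in a document.

    Hyphenated short forms that fail to match in full are retried with
    the segment before the first hyphen (covers forms like "ADA-SCID").
    """
    result: dict[str, str] = {}
    pos = 0
    while True:
        open_paren = doc_text.find("(", pos)
        if open_paren < 0:
            break
        close_paren = doc_text.find(")", open_paren + 1)
        if close_paren < 0:
            break
        pos = close_paren + 1
        short = doc_text[open_paren + 1 : close_paren].strip()
        if not _valid_short_form(short):
            continue
        before = doc_text[:open_paren].rstrip()
        # limit the search window to a few words more than the short form
        words = before.split()
        window = min(len(short) + 5, 2 * len(short))
        before = " ".join(words[-window:])
        long_form = _find_long_form(short, before)
        if long_form is None and "-" in short:
            long_form = _find_long_form(short.split("-", 1)[0], before)
        if long_form is None:
            continue
        if len(short) < len(long_form) and short.lower() not in long_form.lower().split():
            result[short] = long_form
    return AbbreviationMap(result)


def compute_word_stats(
    kb: KnowledgeBase, lexicon: TrainingLexicon | None = None
) -> WordStats:
    """Word document frequencies over distinct pooled lexicon names."""
    names = kb.names()
    if lexicon is not None:
        names |= lexicon.names()
    freq: dict[str, int] = defaultdict(int)
    for name in names:
        for word in set(tokenize(name)):
            freq[word] += 1
    return WordStats(dict(freq), len(names))
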