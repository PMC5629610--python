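"""Tiered candidate generation.

Candidates are produced at three priority tiers:

* **CI** — the normalized mention exactly equals a training mention or a
  KB name.
* **CII** — an exact match exists after one morphological rewriting rule
  (abbreviation expansion, word-order swap, numeral rewriting,
  hyphenation, suffix alternation, word-level synonym substitution,
  stemming, or coordinated-phrase splitting).
* **CIII** — no exact or rewritten match, but the mention shares at least
  one content word with a lexicon name (partial match).

The highest non-empty tier becomes the mention's candidate set; when the
set is at tier CIII and NIL handling is enabled, a NIL candidate is added
so that "no concept" competes in ranking like any other label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources as importlib_resources
from pathlib import Path

from ._text import normalize, tokenize
from .lexicon import (
    NIL_ID,
    AbbreviationMap,
    KnowledgeBase,
    MentionRecord,
    TrainingLexicon,
)
from .stem import stem_tokens

__all__ = [
    "TIER_CI",
    "TIER_CII",
    "TIER_CIII",
    "Candidate",
    "CandidateSet",
    "GenConfig",
    "RuleResources",
    "CandidateIndex",
    "exact_match",
    "generate_morph_variants",
    "partial_match",
    "generate_candidates",
]

TIER_CI = "CI"
TIER_CII = "CII"
TIER_CIII = "CIII"

# fixed rule application order -> deterministic candidate ordering
_CII_RULES = (
    "abbreviation",
    "word_order",
    "numbers",
    "hyphenation",
    "suffixation",
    "synonyms",
    "stemming",
    "composite",
)

_COORDINATORS = {"and", "or"}

_DIGIT_TO_ROMAN = {
    1: "i", 2: "ii", 3: "iii", 4: "iv", 5: "v", 6: "vi", 7: "vii",
    8: "viii", 9: "ix", 10: "x", 11: "xi", 12: "xii", 13: "xiii",
    14: "xiv", 15: "xv", 16: "xvi", 17: "xvii", 18: "xviii", 19: "xix",
    20: "xx",
}
_DIGIT_TO_WORD = {
    1: "one", 2: "two", 3: "three", 4: "four", 5: "five", 6: "six",
    7: "seven", 8: "eight", 9: "nine", 10: "ten", 11: "eleven",
    12: "twelve", 13: "thirteen", 14: "fourteen", 15: "fifteen",
    16: "sixteen", 17: "seventeen", 18: "eighteen", 19: "nineteen",
    20: "twenty",
}
_ROMAN_TO_DIGIT = {v: str(k) for k, v in _DIGIT_TO_ROMAN.items()}
_WORD_TO_DIGIT = {v: str(k) for k, v in _DIGIT_TO_WORD.items()}

_ALPHA_NUM_RE = re.compile(r"^([a-z]+)(\d+)$")


def _read_resource(name: str) -> str:
    return (
        importlib_resources.files("mednorm.resources").joinpath(name)
        .read_text(encoding="utf-8")
    )


@dataclass(frozen=True)
class RuleResources:
    """Editable rule tables: stopwords, suffix pairs, word synonyms."""

    stopwords: frozenset[str]
    suffix_pairs: tuple[tuple[str, str], ...]
    synonyms: dict[str, frozenset[str]]

    @classmethod
    def default(cls) -> "RuleResources":
        return cls.from_text(
            _read_resource("stopwords.txt"),
            _read_resource("suffix_pairs.tsv"),
            _read_resource("synonyms.tsv"),
        )

    @classmethod
    def from_text(
        cls, stopwords_text: str, suffix_text: str, synonyms_text: str
    ) -> "RuleResources":
        stopwords = frozenset(
            w.strip().lower() for w in stopwords_text.splitlines() if w.strip()
        )
        pairs = []
        for line in suffix_text.splitlines():
            if line.strip():
                a, b = line.split("\t")[:2]
                pairs.append((a.strip().lower(), b.strip().lower()))
        synonyms: dict[str, set[str]] = {}
        for line in synonyms_text.splitlines():
            if line.strip():
                a, b = (w.strip().lower() for w in line.split("\t")[:2])
                synonyms.setdefault(a, set()).add(b)
                synonyms.setdefault(b, set()).add(a)
        return cls(
            stopwords,
            tuple(pairs),
            {w: frozenset(alts) for w, alts in synonyms.items()},
        )

    @classmethod
    def from_files(
        cls,
        stopwords: str | Path,
        suffix_pairs: str | Path,
        synonyms: str | Path,
    ) -> "RuleResources":
        return cls.from_text(
            Path(stopwords).read_text(encoding="utf-8"),
            Path(suffix_pairs).read_text(encoding="utf-8"),
            Path(synonyms).read_text(encoding="utf-8"),
        )


@dataclass(frozen=True)
class GenConfig:
    """Candidate-generation settings."""

    nil_enabled: bool = False
    partial_match_cap: int = 100
    resources: RuleResources = field(default_factory=RuleResources.default)


@dataclass(frozen=True)
class Candidate:
    concept_id: str
    matched_name: str
    source: str  # "KB" | "training" | "NIL"
    rule: str


@dataclass(frozen=True)
class CandidateSet:
    mention: MentionRecord
    tier: str
    candidates: tuple[Candidate, ...]
    nil_included: bool = False

    def concept_ids(self) -> list[str]:
        return [c.concept_id for c in self.candidates]

    def is_singleton(self) -> bool:
        return len(self.candidates) == 1


def _stems_compatible(a: str, b: str) -> bool:
    if a == b:
        return True
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    return len(short) >= 5 and long_.startswith(short)


class CandidateIndex:
    """Search structures over the pooled KB + training-mention lexicon.

    KB names take precedence over training mentions in output order;
    both are indexed and a candidate records which source produced it.
    """

    def __init__(
        self, kb: KnowledgeBase, lexicon: TrainingLexicon | None = None
    ) -> None:
        self.kb = kb
        # norm name -> ordered list of (concept_id, source)
        self.names: dict[str, list[tuple[str, str]]] = {}
        for norm, ids in kb.name_index.items():
            self.names[norm] = [(cid, "KB") for cid in sorted(ids)]
        if lexicon is not None:
            for norm, ids in lexicon.mention_map.items():
                bucket = self.names.setdefault(norm, [])
                seen = {cid for cid, _ in bucket}
                bucket.extend(
                    (cid, "training") for cid in sorted(ids) if cid not in seen
                )
        self.word_to_names: dict[str, set[str]] = {}
        self.stem_forms: dict[tuple[str, ...], set[str]] = {}
        for norm in self.names:
            tokens = norm.split()
            for word in set(tokens):
                self.word_to_names.setdefault(word, set()).add(norm)
            self.stem_forms.setdefault(tuple(stem_tokens(tokens)), set()).add(norm)

    def exact(
        self, norm: str, rule: str, exclude_surface: str | None = None
    ) -> list[Candidate]:
        """Candidates for one normalized name.  ``exclude_surface`` drops
        training-sourced matches of that surface (leave-one-surface-out
        when generating candidate sets for the training mentions
        themselves); KB-sourced matches are never excluded."""
        return [
            Candidate(cid, norm, source, rule)
            for cid, source in self.names.get(norm, ())
            if not (source == "training" and norm == exclude_surface)
        ]

    def stem_match(
        self, norm: str, exclude_surface: str | None = None
    ) -> list[Candidate]:
        query = tuple(stem_tokens(norm.split()))
        hits: list[Candidate] = []
        for form, norms in self.stem_forms.items():
            if len(form) != len(query):
                continue
            if all(_stems_compatible(a, b) for a, b in zip(query, form)):
                for name in sorted(norms):
                    hits.extend(self.exact(name, "stemming", exclude_surface))
        return hits


# ---------------------------------------------------------------------------
# Tier operations
# ---------------------------------------------------------------------------

def exact_match(
    mention_text: str,
    kb: KnowledgeBase,
    lexicon: TrainingLexicon | None = None,
    index: CandidateIndex | None = None,
) -> list[Candidate]:
    """All concepts whose normalized name equals the normalized mention."""
    index = index or CandidateIndex(kb, lexicon)
    return index.exact(normalize(mention_text), "exact")


def _number_variants(tokens: list[str]) -> set[str]:
    variants: set[str] = set()
    for i, tok in enumerate(tokens):
        subs: list[list[str]] = []
        if tok.isdigit() and int(tok) in _DIGIT_TO_ROMAN:
            n = int(tok)
            subs += [[_DIGIT_TO_ROMAN[n]], [_DIGIT_TO_WORD[n]]]
        elif tok in _ROMAN_TO_DIGIT:
            subs.append([_ROMAN_TO_DIGIT[tok]])
        elif tok in _WORD_TO_DIGIT:
            subs.append([_WORD_TO_DIGIT[tok]])
        else:
            m = _ALPHA_NUM_RE.match(tok)
            if m and int(m.group(2)) in _DIGIT_TO_ROMAN:
                base, n = m.group(1), int(m.group(2))
                subs += [
                    [base, _DIGIT_TO_ROMAN[n]],
                    [base, _DIGIT_TO_WORD[n]],
                    [base, str(n)],
                ]
        for sub in subs:
            variants.add(" ".join(tokens[:i] + sub + tokens[i + 1 :]))
    return variants


def _hyphen_variants(tokens: list[str]) -> set[str]:
    variants: set[str] = set()
    if any("-" in t for t in tokens):
        variants.add(" ".join(w for t in tokens for w in t.split("-") if w))
    for i in range(len(tokens) - 1):
        joined = tokens[:i] + [tokens[i] + "-" + tokens[i + 1]] + tokens[i + 2 :]
        variants.add(" ".join(joined))
    return variants


def _suffix_variants(
    tokens: list[str], pairs: tuple[tuple[str, str], ...]
) -> set[str]:
    variants: set[str] = set()
    for i, tok in enumerate(tokens):
        for a, b in pairs:
            for src, dst in ((a, b), (b, a)):
                if tok.endswith(src) and len(tok) > len(src) + 2:
                    swapped = tok[: -len(src)] + dst
                    variants.add(" ".join(tokens[:i] + [swapped] + tokens[i + 1 :]))
    return variants


def _synonym_variants(
    tokens: list[str], synonyms: dict[str, frozenset[str]]
) -> set[str]:
    variants: set[str] = set()
    for i, tok in enumerate(tokens):
        for alt in sorted(synonyms.get(tok, ())):
            variants.add(" ".join(tokens[:i] + [alt] + tokens[i + 1 :]))
    return variants


def _composite_variants(tokens: list[str]) -> set[str]:
    coords = [i for i, t in enumerate(tokens) if t in _COORDINATORS]
    if len(coords) != 1:
        return set()
    j = coords[0]
    left, right = tokens[:j], tokens[j + 1 :]
    if not left or len(right) < 2:
        return set()
    return {" ".join(left + right[1:]), " ".join(right)}


def generate_morph_variants(
    mention_text: str,
    abbrevs: AbbreviationMap | None = None,
    resources: RuleResources | None = None,
) -> set[tuple[str, str]]:
    """All single-rule morphological rewritings of the mention.

    Returns ``(normalized_variant, rule)`` pairs.  Each rule is applied
    independently to the original mention; the variant tagged
    ``"stemming"`` is the stemmed form and must be matched against a
    stemmed-name index rather than the plain name index.
    """
    resources = resources or RuleResources.default()
    tokens = tokenize(mention_text)
    norm = " ".join(tokens)
    out: set[tuple[str, str]] = set()

    def add(variants: set[str], rule: str) -> None:
        for v in variants:
            v = normalize(v)
            if v and v != norm:
                out.add((v, rule))

    if abbrevs is not None:
        stripped = mention_text.strip()
        long_form = abbrevs.expand(stripped)
        if long_form is None:
            for sf, lf in abbrevs.short_to_long.items():
                if sf.lower() == stripped.lower():
                    long_form = lf
                    break
        if long_form is not None:
            add({long_form}, "abbreviation")
    if len(tokens) >= 2:
        add({" ".join(reversed(tokens))}, "word_order")
    add(_number_variants(tokens), "numbers")
    add(_hyphen_variants(tokens), "hyphenation")
    add(_suffix_variants(tokens, resources.suffix_pairs), "suffixation")
    add(_synonym_variants(tokens, resources.synonyms), "synonyms")
    stemmed = " ".join(stem_tokens(tokens))
    if stemmed:
        out.add((stemmed, "stemming"))
    add(_composite_variants(tokens), "composite")
    return out


def partial_match(
    mention_text: str,
    kb: KnowledgeBase,
    lexicon: TrainingLexicon | None = None,
    index: CandidateIndex | None = None,
    config: GenConfig | None = None,
    exclude_surface: str | None = None,
) -> list[Candidate]:
    """Lexicon names sharing at least one content word with the mention.

    Ordered by descending shared-word count, then name; truncated to the
    configured cap after concept-id deduplication.
    """
    config = config or GenConfig()
    index = index or CandidateIndex(kb, lexicon)
    words = {
        t for t in tokenize(mention_text) if t not in config.resources.stopwords
    }
    overlap: dict[str, int] = {}
    for word in words:
        for name in index.word_to_names.get(word, ()):
            overlap[name] = overlap.get(name, 0) + 1
    ranked = sorted(overlap.items(), key=lambda kv: (-kv[1], kv[0]))
    out: list[Candidate] = []
    seen: set[str] = set()
    for name, _count in ranked:
        for cand in index.exact(name, "partial", exclude_surface):
            if cand.concept_id not in seen:
                seen.add(cand.concept_id)
                out.append(replace(cand, rule="partial"))
                if len(out) >= config.partial_match_cap:
                    return out
    return out


def _dedup(candidates: list[Candidate]) -> tuple[Candidate, ...]:
    seen: set[str] = set()
    out = []
    for cand in candidates:
        if cand.concept_id not in seen:
            seen.add(cand.concept_id)
            out.append(cand)
    return tuple(out)


def generate_candidates(
    mention: MentionRecord,
    kb: KnowledgeBase,
    lexicon: TrainingLexicon | None = None,
    config: GenConfig | None = None,
    abbrevs: AbbreviationMap | None = None,
    index: CandidateIndex | None = None,
    exclude_training_surface: str | None = None,
) -> CandidateSet:
    """Produce the mention's candidate set at the highest non-empty tier.

    ``exclude_training_surface`` suppresses training-lexicon matches of
    that normalized surface, so a training mention does not trivially
    match its own annotation when pairs are built.
    """
    config = config or GenConfig()
    index = index or CandidateIndex(kb, lexicon)
    excl = exclude_training_surface

    ci = index.exact(normalize(mention.text), "exact", excl)
    if ci:
        return CandidateSet(mention, TIER_CI, _dedup(ci))

    variants = generate_morph_variants(mention.text, abbrevs, config.resources)
    by_rule: dict[str, list[str]] = {}
    for variant, rule in variants:
        by_rule.setdefault(rule, []).append(variant)
    cii: list[Candidate] = []
    for rule in _CII_RULES:
        if rule == "stemming":
            if "stemming" in by_rule:
                # stem the original mention; matched against stemmed names
                cii.extend(index.stem_match(normalize(mention.text), excl))
            continue
        for variant in sorted(by_rule.get(rule, ())):
            cii.extend(index.exact(variant, rule, excl))
    if cii:
        return CandidateSet(mention, TIER_CII, _dedup(cii))

    ciii = partial_match(
        mention.text, kb, lexicon, index=index, config=config,
        exclude_surface=excl,
    )
    candidates = list(_dedup(ciii))
    nil_included = False
    if config.nil_enabled:
        candidates.append(Candidate(NIL_ID, "<NIL>", "NIL", "nil"))
        nil_included = True
    return CandidateSet(mention, TIER_CIII, tuple(candidates), nil_included)
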