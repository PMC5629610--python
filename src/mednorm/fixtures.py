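"""Self-contained synthetic KBs, corpora and embeddings.

Everything needed to exercise the full normalization stack without
external terminologies: a KB whose concepts live in "families" sharing a
head word (so partial match yields controlled multi-candidate sets),
mention corpora produced by *inverse* morphological rules (so candidate
generation can recover the gold concept), optional zero-word-overlap
synonym pairs that share a planted latent embedding vector (the
semantic-signal analogue of real synonymy), ambiguous surface forms, and
NIL mentions.  All randomness flows from the spec seed through one named
generator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._text import tokenize
from .lexicon import (
    NIL_ID,
    ConceptEntry,
    KnowledgeBase,
    MentionRecord,
    write_kb,
)
from .ranker import EmbeddingTable

__all__ = [
    "FixtureSpec",
    "FixtureLatents",
    "Fixture",
    "make_kb",
    "make_corpus",
    "make_embeddings",
    "make_fixture",
    "write_pubtator",
    "write_embeddings",
]

_PREFIXES = [
    "card", "neur", "hepat", "nephr", "gastr", "derm", "oste", "arthr",
    "cephal", "cyt", "hem", "myel", "fibr", "lip", "angi", "bronch",
    "enter", "gloss", "laryng", "mening", "splen", "thyr", "ven",
    "vascul", "pulmon",
]
_SUFFIXES = [
    "opathy", "itis", "osis", "oma", "algia", "emia", "oplasia",
    "otrophy", "ectomy", "ogenesis", "osclerosis", "omegaly", "optosis",
    "orrhea", "ostenosis",
]
_MODIFIERS = [
    "acute", "chronic", "focal", "diffuse", "primary", "secondary",
    "congenital", "idiopathic", "transient", "severe", "benign",
    "recurrent", "familial", "juvenile", "atypical",
]
_HEADS = [
    "syndrome", "disorder", "deficiency", "lesions", "polyps",
    "carcinoma", "tumor", "sclerosis", "dysplasia", "atrophy",
    "stenosis", "fibrosis", "edema", "necrosis", "cysts", "nodules",
    "ulcers", "palsy", "anomaly", "malformation",
]
# inverse suffix rewritings applicable to the generated descriptor words;
# mirrors pairs in resources/suffix_pairs.tsv
_GEN_SUFFIX_SWAPS = [
    ("pathy", "pathic"), ("osis", "otic"), ("emia", "emic"),
    ("itis", "itic"), ("oma", "omatous"),
]
# head-word synonyms present in resources/synonyms.tsv
_GEN_SYNONYMS = {"carcinoma": "cancer", "tumor": "tumour"}

_DEFAULT_MIX = {
    "exact": 0.35, "hyphen": 0.2, "swap": 0.15, "suffix": 0.1,
    "synonym": 0.0, "semantic": 0.2,
}


def _word_inventory() -> list[str]:
    return [p + s for p in _PREFIXES for s in _SUFFIXES]


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one synthetic dataset."""

    n_concepts: int = 50
    family_size: int = 5
    synonyms_per_concept: int = 0
    variant_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    semantic_pair_fraction: float = 0.0
    ambiguity_fraction: float = 0.0
    nil_fraction: float = 0.0
    n_mentions: int = 100
    embedding_dim: int = 20
    embedding_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("semantic_pair_fraction", "ambiguity_fraction",
                     "nil_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.n_concepts <= 0 or self.n_mentions <= 0:
            raise ValueError("counts must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        return cls(**json.loads(text))


@dataclass
class FixtureLatents:
    """Planted semantic structure: word -> concept index whose latent
    vector the word's embedding should sit near."""

    word_concept: dict[str, int]
    n_concepts: int


@dataclass
class Fixture:
    spec: FixtureSpec
    kb: KnowledgeBase
    latents: FixtureLatents
    records: list[MentionRecord]
    docs: dict[str, str]
    embeddings: EmbeddingTable


def _fresh_word(rng: np.random.Generator, used: set[str]) -> str:
    letters = "abcdefghijklmnopqrstuvw"
    while True:
        word = "zy" + "".join(rng.choice(list(letters), size=5))
        if word not in used:
            used.add(word)
            return word


def _head_word(family: int) -> str:
    base = _HEADS[family % len(_HEADS)]
    rep = family // len(_HEADS)
    return base if rep == 0 else f"{base}{rep + 1}"


def make_kb(spec: FixtureSpec) -> tuple[KnowledgeBase, FixtureLatents]:
    """Concepts in head-sharing families plus planted semantic synonyms."""
    rng = np.random.default_rng(spec.seed)
    inventory = _word_inventory()
    rng.shuffle(inventory)
    used = set(inventory) | set(_HEADS) | set(_MODIFIERS)
    word_concept: dict[str, int] = {}
    names: list[list[str]] = []
    for i in range(spec.n_concepts):
        if i < len(inventory):
            desc = inventory[i]
        else:
            desc = (_MODIFIERS[i % len(_MODIFIERS)] + "-" +
                    inventory[i % len(inventory)])
        head = _head_word(i // spec.family_size)
        word_concept[desc] = i
        names.append([desc, head])

    n_semantic = round(spec.semantic_pair_fraction * spec.n_concepts)
    semantic_ids = sorted(
        int(i) for i in rng.choice(spec.n_concepts, n_semantic, replace=False)
    )
    entries: list[ConceptEntry] = []
    for i in range(spec.n_concepts):
        desc, head = names[i]
        synonyms: list[str] = []
        if i in semantic_ids:
            a, b = _fresh_word(rng, used), _fresh_word(rng, used)
            word_concept[a] = i
            word_concept[b] = i
            synonyms.append(f"{a} {b}")
        for j in range(spec.synonyms_per_concept):
            synonyms.append(f"{_MODIFIERS[j % len(_MODIFIERS)]} {desc} {head}")
        entries.append(ConceptEntry(f"C{i:04d}", f"{desc} {head}",
                                    tuple(synonyms)))

    n_amb_pairs = round(spec.ambiguity_fraction * spec.n_concepts / 2)
    for k in range(n_amb_pairs):
        i, j = 2 * k, 2 * k + 1
        if j >= spec.n_concepts:
            break
        shared = f"{_fresh_word(rng, used)} {names[i][1]}"
        entries[i] = ConceptEntry(
            entries[i].concept_id, entries[i].preferred_name,
            entries[i].synonyms + (shared,),
        )
        entries[j] = ConceptEntry(
            entries[j].concept_id, entries[j].preferred_name,
            entries[j].synonyms + (shared,),
        )
    kb = KnowledgeBase(entries)
    return kb, FixtureLatents(word_concept, spec.n_concepts)


def _mention_for(
    mode: str,
    concept: int,
    kb: KnowledgeBase,
    latents: FixtureLatents,
    rng: np.random.Generator,
    used: set[str],
) -> str:
    desc, head = tokenize(kb.entries[f"C{concept:04d}"].preferred_name)[:2]
    if mode == "swap":
        return f"{head} {desc}"
    if mode == "hyphen":
        return f"{desc}-{head}"
    if mode == "suffix":
        for a, b in _GEN_SUFFIX_SWAPS:
            if desc.endswith(a):
                return f"{desc[: -len(a)] + b} {head}"
        return f"{desc}-{head}"  # no applicable suffix: fall back
    if mode == "synonym":
        if head in _GEN_SYNONYMS:
            return f"{desc} {_GEN_SYNONYMS[head]}"
        return f"{head} {desc}"  # fall back to a swap
    if mode == "semantic":
        u, v = _fresh_word(rng, used), _fresh_word(rng, used)
        latents.word_concept[u] = concept
        latents.word_concept[v] = concept
        return f"{u} {v} {head}"
    return f"{desc} {head}"  # exact


def make_corpus(
    spec: FixtureSpec,
    kb: KnowledgeBase,
    latents: FixtureLatents,
    mentions_per_doc: int = 8,
) -> tuple[list[MentionRecord], dict[str, str]]:
    """Mention records with gold ids plus PubTator-serializable documents."""
    rng = np.random.default_rng(spec.seed + 1)
    used = set(latents.word_concept) | {w for n in kb.names() for w in n.split()}

    nil_count = round(spec.nil_fraction * spec.n_mentions)
    amb_count = round(spec.ambiguity_fraction * spec.n_mentions)
    amb_surfaces = sorted(
        name for name, ids in kb.name_index.items() if len(ids) > 1
    )
    if not amb_surfaces:
        amb_count = 0
    modes = sorted(k for k, v in spec.variant_mix.items() if v > 0)
    probs = np.array([spec.variant_mix[m] for m in modes], dtype=float)
    probs /= probs.sum()

    texts: list[tuple[str, str | None]] = []  # (surface, gold)
    for _ in range(nil_count):
        texts.append(
            (f"{_fresh_word(rng, used)} {_fresh_word(rng, used)}", NIL_ID)
        )
    for k in range(amb_count):
        surface = amb_surfaces[k % len(amb_surfaces)]
        ids = sorted(kb.name_index[surface])
        texts.append((surface, ids[k % len(ids)]))
    for _ in range(spec.n_mentions - nil_count - amb_count):
        concept = int(rng.integers(spec.n_concepts))
        mode = str(rng.choice(modes, p=probs))
        texts.append(
            (_mention_for(mode, concept, kb, latents, rng, used),
             f"C{concept:04d}")
        )
    order = rng.permutation(len(texts))
    texts = [texts[int(i)] for i in order]

    records: list[MentionRecord] = []
    docs: dict[str, str] = {}
    for doc_index in range(0, len(texts), mentions_per_doc):
        chunk = texts[doc_index : doc_index + mentions_per_doc]
        doc_id = str(10000 + doc_index // mentions_per_doc)
        title = f"Synthetic case report {doc_id}."
        abstract_parts: list[str] = []
        offset = len(title) + 1  # title + single space
        spans: list[tuple[int, int, str, str | None]] = []
        for surface, gold in chunk:
            lead = "The patient presented with "
            start = offset + sum(len(p) for p in abstract_parts) + len(lead)
            sentence = f"{lead}{surface}."
            spans.append((start, start + len(surface), surface, gold))
            abstract_parts.append(sentence + " ")
        abstract = "".join(abstract_parts).rstrip()
        docs[doc_id] = title + " " + abstract
        for start, end, surface, gold in spans:
            assert docs[doc_id][start:end] == surface
            records.append(MentionRecord(doc_id, start, end, surface, gold))
    return records, docs


def make_embeddings(
    kb: KnowledgeBase,
    latents: FixtureLatents,
    noise: float,
    t: int,
    seed: int = 0,
    extra_words: set[str] | None = None,
) -> EmbeddingTable:
    """Embeddings with the planted signal: words assigned to a concept
    embed near that concept's unit latent vector; other words are
    independent near-orthogonal draws."""
    rng = np.random.default_rng(seed)
    lat = rng.normal(size=(latents.n_concepts, t))
    lat /= np.linalg.norm(lat, axis=1, keepdims=True)
    vocab = {w for name in kb.names() for w in name.split()}
    vocab |= set(latents.word_concept)
    if extra_words:
        vocab |= extra_words
    table = EmbeddingTable(t)
    for word in sorted(vocab):
        concept = latents.word_concept.get(word)
        if concept is None:
            vec = rng.normal(size=t) / np.sqrt(t)
        else:
            vec = lat[concept] + noise * rng.normal(size=t) / np.sqrt(t)
        table.set(word, vec)
    return table


def make_fixture(spec: FixtureSpec) -> Fixture:
    kb, latents = make_kb(spec)
    records, docs = make_corpus(spec, kb, latents)
    mention_words = {w for r in records for w in tokenize(r.text)}
    table = make_embeddings(
        kb, latents, spec.embedding_noise, spec.embedding_dim,
        seed=spec.seed + 2, extra_words=mention_words,
    )
    return Fixture(spec, kb, latents, records, docs, table)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_pubtator(
    records: list[MentionRecord], docs: dict[str, str], path: str | Path
) -> None:
    by_doc: dict[str, list[MentionRecord]] = {}
    for record in records:
        by_doc.setdefault(record.doc_id, []).append(record)
    with open(path, "w", encoding="utf-8") as handle:
        for doc_id in sorted(docs, key=lambda d: (len(d), d)):
            text = docs[doc_id]
            title, _, abstract = text.partition(". ")
            title += "."
            handle.write(f"{doc_id}|t|{title}\n")
            handle.write(f"{doc_id}|a|{abstract}\n")
            for rec in sorted(by_doc.get(doc_id, []), key=lambda r: r.start):
                gold = "-1" if rec.gold_id == NIL_ID else (rec.gold_id or "")
                handle.write(
                    f"{doc_id}\t{rec.start}\t{rec.end}\t{rec.text}\t"
                    f"Disease\t{gold}\n"
                )
            handle.write("\n")


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for word, row in sorted(table.index.items(), key=lambda kv: kv[1]):
            values = " ".join(f"{v:.8f}" for v in table.vectors[row])
            handle.write(f"{word} {values}\n")


def write_fixture(fixture: Fixture, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_kb(fixture.kb, out / "kb.tsv")
    write_pubtator(fixture.records, fixture.docs, out / "corpus.pubtator")
    write_embeddings(fixture.embeddings, out / "embeddings.txt")
    (out / "spec.json").write_text(fixture.spec.to_json(), encoding="utf-8")
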