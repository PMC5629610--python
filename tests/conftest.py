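import numpy as np
import pytest

from mednorm import (
    CandidateIndex,
    ConceptEntry,
    GenConfig,
    KnowledgeBase,
    MentionRecord,
    RankerParams,
    WordStats,
)

RULE_DEMO_CONCEPTS = [
    ("C1", "Coronary artery disease", ()),
    ("C2", "Suxamethonium chloride", ()),
    ("C3", "Gain weight", ()),
    ("C4", "Vitamin b ii", ()),
    ("C5", "5 hydroxytriptamine", ()),
    ("C6", "Hypotension", ()),
    ("C7", "Hypotensin", ()),
    ("C8", "Renal cell cancer", ()),
    ("C9", "Optic neuropathy", ()),
    ("C10", "Peripheral neuropathy", ()),
    ("C11", "Cardiac arrest", ()),
    ("C12", "Cardiac disorders", ()),
    ("C13", "Renal injury", ()),
]


@pytest.fixture(scope="session")
def rule_demo_kb() -> KnowledgeBase:
    """KB holding the rule-replay target names."""
    return KnowledgeBase(
        ConceptEntry(cid, name, syns) for cid, name, syns in RULE_DEMO_CONCEPTS
    )


@pytest.fixture(scope="session")
def rule_demo_index(rule_demo_kb) -> CandidateIndex:
    return CandidateIndex(rule_demo_kb)


@pytest.fixture
def gen_config() -> GenConfig:
    return GenConfig()


@pytest.fixture
def tiny_params() -> RankerParams:
    """Small random network: t=5, widths {2,3}, 2 filters each (p=4)."""
    rng = np.random.default_rng(42)
    return RankerParams.init(t=5, widths=(2, 3), p_per_width=2, hidden=4,
                             rng=rng)


@pytest.fixture
def tiny_stats() -> WordStats:
    return WordStats({"aa": 1, "bb": 2, "cc": 1, "polyps": 3}, 4)


def mention(text: str, gold: str | None = None) -> MentionRecord:
    return MentionRecord("doc", 0, len(text), text, gold)


@pytest.fixture
def make_mention():
    return mention
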