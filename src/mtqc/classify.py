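"""Motif-based haplogroup classification.

A profile is scored against every haplogroup with a symmetric two-way
coverage (Kulczynski) score,

    score = 1/2 * (M / |E|) + 1/2 * (M / |P|),

where E is the haplogroup's expected (cumulative) variant set, P the
profile's variant set (both minus hotspot-masked positions) and M the
weighted number of expected entries matched by the profile under the
wildcard matching semantics of :func:`mtqc.variants.variants_match`.
A ratio with an empty denominator is taken as 1, so the empty profile
scores 1.0 at the root (an rCRS-identical sample).  The score rewards
both completeness of the motif and parsimony of the profile.

Ranking ties break toward the deeper (more derived) node so the most
specific label wins, then lexicographically by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .phylo import MtPhylogeny
from .variants import (
    DEFAULT_HOTSPOT_MASK,
    Variant,
    VariantProfile,
    variants_match,
)


@dataclass(frozen=True)
class ClassifyConfig:
    """Scoring knobs.

    hotspot_mask
        Positions excluded from scoring on both sides (hypervariable or
        artifact-prone sites).
    heteroplasmy_weight
        Weight in (0, 1] given to an expected entry matched only by a
        heteroplasmic profile variant; 1.0 treats heteroplasmic calls as
        full lineage evidence.
    top_k
        Number of ranked calls returned by :func:`classify`.
    """

    hotspot_mask: frozenset[int] = DEFAULT_HOTSPOT_MASK
    heteroplasmy_weight: float = 1.0
    top_k: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.heteroplasmy_weight <= 1:
            raise ValueError("heteroplasmy_weight must be in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class HaplogroupCall:
    """One ranked assignment of a profile to a haplogroup.

    ``matched`` holds the profile variants explained by the expected set,
    ``private`` the remaining profile variants (so matched | private is
    the scored profile) and ``missing`` the expected entries the profile
    lacks (so the expected-side matches | missing is the expected set).
    """

    node_name: str
    score: float
    matched: frozenset[Variant]
    missing: frozenset[Variant]
    private: frozenset[Variant]

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 1 + 1e-12:
            raise ValueError(f"score {self.score} outside [0, 1]")


def score_against(
    profile: VariantProfile,
    tree: MtPhylogeny,
    node_name: str,
    config: ClassifyConfig = ClassifyConfig(),
) -> HaplogroupCall:
    """Score one profile against one haplogroup."""
    expected = {
        v for v in tree.expected_profile(node_name) if v.position not in config.hotspot_mask
    }
    scored = {v for v in profile.variants if v.position not in config.hotspot_mask}

    weighted = 0.0
    matched_expected: set[Variant] = set()
    matched_profile: set[Variant] = set()
    for e in expected:
        hits = [p for p in scored if variants_match(e, p)]
        if hits:
            matched_expected.add(e)
            matched_profile.update(hits)
            w = 1.0 if any(not p.heteroplasmic for p in hits) else config.heteroplasmy_weight
            weighted += w

    completeness = weighted / len(expected) if expected else 1.0
    parsimony = weighted / len(scored) if scored else 1.0
    score = min(1.0, 0.5 * completeness + 0.5 * parsimony)
    return HaplogroupCall(
        node_name=node_name,
        score=score,
        matched=frozenset(matched_profile),
        missing=frozenset(expected - matched_expected),
        private=frozenset(scored - matched_profile),
    )


def classify(
    profile: VariantProfile,
    tree: MtPhylogeny,
    config: ClassifyConfig = ClassifyConfig(),
) -> list[HaplogroupCall]:
    """Score every haplogroup and return the ``top_k`` ranked calls.

    The first element is the haplogroup call.  Ordering is total and
    deterministic: score descending, then node depth descending (prefer
    the most derived label), then name.
    """
    if len(tree) == 0:  # pragma: no cover - MtPhylogeny always has a root
        raise ValueError("empty phylogeny")
    calls = [score_against(profile, tree, node.name, config) for node in tree.nodes()]
    calls.sort(key=lambda c: (-c.score, -tree.node(c.node_name).depth, c.node_name))
    return calls[: config.top_k]


def best_call(
    profile: VariantProfile,
    tree: MtPhylogeny,
    config: ClassifyConfig = ClassifyConfig(),
) -> HaplogroupCall:
    """Convenience: the single top-ranked call."""
    return classify(profile, tree, config)[0]
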