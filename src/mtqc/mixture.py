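"""Two-lineage mixture detection within a single sample.

A contaminated or mixed sample carries the union of two maternal
lineages' variants, often with heteroplasmy at the discordant sites.
``detect_mixture`` asks whether a pair of haplogroups jointly explains a
profile substantially better than the best single haplogroup does:

* ``explained_fraction_k1`` — the best share of profile variants matched
  by a single haplogroup's expected set (over all nodes);
* ``explained_fraction_k2`` — the best share matched by the union of two
  expected sets, searched over pairs from the top ``candidate_pool``
  single-lineage calls (``exhaustive=True`` searches all node pairs);
* the sample is flagged a mixture when the gain ``k2 - k1`` reaches
  ``min_gain`` and each component uniquely explains at least
  ``min_unique_support`` variants.

Mixtures with more than two components are out of scope; pairwise
unions are what mixed-sample evidence in practice looks like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .classify import ClassifyConfig, classify, score_against
from .phylo import MtPhylogeny
from .variants import Variant, VariantProfile, variants_match

COMPONENT1 = "component1"
COMPONENT2 = "component2"
RESIDUAL = "residual"


@dataclass(frozen=True)
class MixtureConfig:
    min_gain: float = 0.2
    min_unique_support: int = 3
    candidate_pool: int = 10
    classify_config: ClassifyConfig = field(default_factory=ClassifyConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.min_gain <= 1:
            raise ValueError("min_gain must be in [0, 1]")
        if self.candidate_pool < 2:
            raise ValueError("candidate_pool must be >= 2")
        if self.min_unique_support < 1:
            raise ValueError("min_unique_support must be >= 1")


@dataclass(frozen=True)
class MixtureReport:
    sample_id: str
    components: tuple[str, ...]
    assignment: dict[Variant, str]
    explained_fraction_k1: float
    explained_fraction_k2: float
    gain: float
    is_mixture: bool
    #: (component_a, component_b, joint explained fraction) for the top
    #: candidate pairs, best first — exposes near-equivalent component
    #: labels (e.g. sister haplogroups) instead of forcing a choice.
    pair_ranking: tuple[tuple[str, str, float], ...] = ()


def _explained(
    profile_variants: frozenset[Variant], expected: frozenset[Variant]
) -> frozenset[Variant]:
    return frozenset(
        v for v in profile_variants if any(variants_match(v, e) for e in expected)
    )


def detect_mixture(
    profile: VariantProfile,
    tree: MtPhylogeny,
    config: MixtureConfig = MixtureConfig(),
    exhaustive: bool = False,
) -> MixtureReport:
    """Search for a pair of haplogroups jointly explaining the profile."""
    if not profile.variants:
        raise ValueError(f"sample {profile.sample_id!r}: cannot assess an empty profile")

    variants = profile.variants
    names = [n.name for n in tree.nodes()]
    explained_by = {name: _explained(variants, tree.expected_profile(name)) for name in names}
    total = len(variants)

    k1_best = max(names, key=lambda n: (len(explained_by[n]), -tree.node(n).depth))
    k1 = len(explained_by[k1_best]) / total

    if exhaustive:
        candidates = list(names)
    else:
        ranked = classify(
            profile,
            tree,
            ClassifyConfig(
                hotspot_mask=config.classify_config.hotspot_mask,
                heteroplasmy_weight=config.classify_config.heteroplasmy_weight,
                top_k=config.candidate_pool,
            ),
        )
        candidates = [c.node_name for c in ranked]
        if k1_best not in candidates:
            # guarantee k2 >= k1 even when coverage and score rankings differ
            candidates.append(k1_best)

    single_score = {
        name: score_against(profile, tree, name, config.classify_config).score
        for name in set(candidates)
    }

    scored_pairs: list[tuple[float, float, str, str]] = []
    for a, b in combinations(sorted(set(candidates)), 2):
        joint = len(explained_by[a] | explained_by[b]) / total
        scored_pairs.append((joint, single_score[a] + single_score[b], a, b))
    if not scored_pairs:  # single-node tree
        scored_pairs = [(k1, single_score.get(k1_best, 0.0) * 2, k1_best, k1_best)]
    scored_pairs.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))

    k2, _, best_a, best_b = scored_pairs[0]
    # order components by single-lineage score, best first
    if single_score.get(best_b, 0.0) > single_score.get(best_a, 0.0):
        best_a, best_b = best_b, best_a

    set_a, set_b = explained_by[best_a], explained_by[best_b]
    assignment: dict[Variant, str] = {}
    for v in sorted(variants):
        in_a, in_b = v in set_a, v in set_b
        if in_a and in_b:
            assignment[v] = COMPONENT1  # component1 has the higher single score
        elif in_a:
            assignment[v] = COMPONENT1
        elif in_b:
            assignment[v] = COMPONENT2
        else:
            assignment[v] = RESIDUAL

    unique_a = len(set_a - set_b)
    unique_b = len(set_b - set_a)
    gain = k2 - k1
    is_mixture = (
        gain >= config.min_gain
        and unique_a >= config.min_unique_support
        and unique_b >= config.min_unique_support
    )

    return MixtureReport(
        sample_id=profile.sample_id,
        components=(best_a, best_b),
        assignment=assignment,
        explained_fraction_k1=k1,
        explained_fraction_k2=k2,
        gain=gain,
        is_mixture=is_mixture,
        pair_ranking=tuple((a, b, f) for f, _, a, b in scored_pairs[:10]),
    )
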