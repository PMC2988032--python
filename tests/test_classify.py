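"""Haplogroup scoring and ranking."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtqc import (
    ClassifyConfig,
    Variant,
    VariantProfile,
    best_call,
    classify,
    make_profile,
    score_against,
    variants_match,
)


def naive_score(profile, tree, node_name, config=ClassifyConfig()):
    """Independent double-loop Kulczynski scorer."""
    E = [v for v in tree.expected_profile(node_name) if v.position not in config.hotspot_mask]
    P = [v for v in profile.variants if v.position not in config.hotspot_mask]
    M = 0.0
    for e in E:
        hits = [p for p in P if p.position == e.position and (
            p.alt_allele is None or e.alt_allele is None or p.alt_allele == e.alt_allele
        )]
        if hits:
            M += 1.0 if any(not p.heteroplasmic for p in hits) else config.heteroplasmy_weight
    left = M / len(E) if E else 1.0
    right = M / len(P) if P else 1.0
    return 0.5 * left + 0.5 * right


def test_perfect_match_scores_one(tree):
    for name in ("L1b", "K1a4a1a", "H1c3"):
        p = VariantProfile("s", "other", tree.expected_profile(name))
        assert score_against(p, tree, name).score == pytest.approx(1.0)
        assert best_call(p, tree).node_name == name


def test_empty_profile_scores_one_at_root(tree):
    p = VariantProfile("s", "other", frozenset())
    call = best_call(p, tree)
    assert call.node_name == tree.root.name
    assert call.score == pytest.approx(1.0)


def test_scores_match_naive_oracle_on_fixture(tree):
    rng = np.random.default_rng(5)
    names = list(tree.index)
    profiles = [
        VariantProfile("e", "other", frozenset()),
        make_profile("a", "other", ["A7146G"]),
        make_profile("h", "other", ["h12519", "h13506", "C6548T"]),
    ]
    # random subsets of random expected profiles plus noise
    for i in range(10):
        name = names[rng.integers(0, len(names))]
        base = sorted(tree.expected_profile(name))
        take = [v for v in base if rng.random() < 0.7]
        take.append(Variant(int(rng.integers(100, 400)), "A", "G"))
        profiles.append(VariantProfile(f"r{i}", "other", frozenset(take)))
    for profile in profiles:
        for name in names:
            got = score_against(profile, tree, name).score
            assert got == pytest.approx(naive_score(profile, tree, name))


def test_matched_private_partition_profile(tree):
    p = make_profile("s", "other", ["A7146G", "h12519", "A100G"])
    call = score_against(p, tree, "L2")
    assert call.matched | call.private == p.variants
    assert not call.matched & call.private
    expected = tree.expected_profile("L2")
    # expected-side: matched counterparts plus missing covers the expected set
    matched_expected = {
        e for e in expected if any(variants_match(e, v) for v in call.matched)
    }
    assert matched_expected | call.missing == expected


def test_a7146g_assigned_to_l2_path(tree):
    call = best_call(make_profile("s", "other", ["A7146G"]), tree)
    assert tree.is_ancestor("L2", call.node_name)


def test_ranking_is_deterministic_and_prefers_depth(tree):
    p = VariantProfile("s", "other", tree.expected_profile("K1a4a1a"))
    first = classify(p, tree)
    second = classify(p, tree)
    assert [c.node_name for c in first] == [c.node_name for c in second]
    assert first[0].node_name == "K1a4a1a"


def test_score_invariant_under_profile_ordering(tree):
    tokens = ["C6548T", "T6827C", "h12519", "A7146G"]
    a = make_profile("s", "other", tokens)
    b = make_profile("s", "other", tokens[::-1])
    for name in tree.index:
        assert score_against(a, tree, name).score == score_against(b, tree, name).score


@given(st.data())
@settings(max_examples=60, derandomize=True, deadline=None)
def test_score_monotonicity(tree, data):
    """Privates never raise a score; supplying a missing variant never lowers it."""
    names = sorted(tree.index)
    name = data.draw(st.sampled_from(names))
    subset = data.draw(
        st.sets(st.sampled_from(sorted(tree.expected_profile("K1a4a1a"))), max_size=8)
    )
    profile = VariantProfile("s", "other", frozenset(subset))
    base = score_against(profile, tree, name).score

    private = Variant(data.draw(st.integers(min_value=100, max_value=400)), "A", "G")
    if all(private.position != v.position for v in profile.variants):
        noisier = VariantProfile("s", "other", profile.variants | {private})
        assert score_against(noisier, tree, name).score <= base + 1e-12

    call = score_against(profile, tree, name)
    if call.missing:
        extra = sorted(call.missing)[0]
        if all(
            (extra.position, extra.alt_allele) != (v.position, v.alt_allele)
            for v in profile.variants
        ):
            fuller = VariantProfile("s", "other", profile.variants | {extra})
            assert score_against(fuller, tree, name).score >= base - 1e-12


def test_config_validation():
    with pytest.raises(ValueError):
        ClassifyConfig(heteroplasmy_weight=0.0)
    with pytest.raises(ValueError):
        ClassifyConfig(top_k=0)


def test_heteroplasmy_weight_downweights_het_only_matches(tree):
    p = make_profile("s", "other", ["h12519", "h14203"])
    full = score_against(p, tree, "L1b", ClassifyConfig(heteroplasmy_weight=1.0))
    half = score_against(p, tree, "L1b", ClassifyConfig(heteroplasmy_weight=0.5))
    assert half.score < full.score
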