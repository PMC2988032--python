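from __future__ import annotations

import numpy as np
import pytest

from mtqc import (
    MtPhylogeny,
    Variant,
    fixture_tree,
    load_phylogeny,
    make_profile,
    read_profiles,
)

CASE11_NORMAL_TOKENS = ["T12519C", "A14203G", "T16126C", "C16264T", "A9221G", "C13506T"]
CASE11_TUMOR_L1B_TOKENS = [
    "C6548T", "T6827C", "A6989G", "A7055G", "T7389C", "C7915T", "A8248G",
    "C16270T", "h12519", "h12693", "h14203", "h16126",
]
CASE11_TUMOR_L2_TOKENS = [
    "A7146G", "C8468T", "C8655T", "T10810C", "h11914", "h11944", "h13506",
    "h13590", "h13803", "h15301",
]


@pytest.fixture(scope="session")
def tree() -> MtPhylogeny:
    return fixture_tree()


@pytest.fixture(scope="session")
def case11_profiles(tree):
    import importlib.resources

    tsv = (
        importlib.resources.files("mtqc")
        .joinpath("data/case11_profiles.tsv")
        .read_text()
    )
    normal, tumor = read_profiles(tsv)
    return normal, tumor


@pytest.fixture()
def single_variant_profile():
    def build(*tokens: str, sample="s", tissue="other"):
        return make_profile(sample, tissue, tokens)

    return build


def random_tree(rng: np.random.Generator, n_nodes: int = 30) -> MtPhylogeny:
    """Random back-mutation-free tree with globally unique positions."""
    positions = rng.choice(np.arange(400, 16000), size=n_nodes * 3, replace=False)
    bases = "ACGT"
    partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
    pos_iter = iter(int(p) for p in positions)
    children: dict[int, list[int]] = {0: []}
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, i))
        children[parent].append(i)
        children[i] = []
    lines: list[str] = []

    def emit(node: int, depth: int) -> None:
        if node == 0:
            lines.append("ROOT")
        else:
            motif = []
            for _ in range(int(rng.integers(1, 4))):
                p = next(pos_iter)
                ref = bases[rng.integers(0, 4)]
                motif.append(f"{ref}{p}{partner[ref]}")
            lines.append("  " * depth + f"N{node}: " + ", ".join(motif))
        for c in children[node]:
            emit(c, depth + 1)

    emit(0, 0)
    return load_phylogeny("\n".join(lines))


@pytest.fixture()
def small_random_tree():
    return random_tree(np.random.default_rng(2024), n_nodes=30)
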