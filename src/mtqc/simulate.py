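"""Synthetic paired-profile studies with planted artifacts and truth tables.

The generator emulates the data situation the QC pipeline targets:
per patient, a germline haplogroup drawn from the tree's leaves (real
individuals carry terminal haplogroups), a clean normal profile equal to
the haplogroup's cumulative motif, and a tumor profile adding
Poisson-distributed private somatic variants.  Artifacts are planted on
top:

* **swap** — tumor profiles exchanged between two patients drawn from
  distinct root-level clades, the artificial-recombination signature of
  a sample mix-up;
* **mixture** — a tumor profile replaced by the union of the patient's
  lineage and a random distinct-clade lineage, with colliding positions
  marked heteroplasmic;
* **phantom** — recurrent spurious calls injected at fixed positions
  across a share of samples.

Private somatic variants are placed only at positions carried by no
motif anywhere in the tree, so planted truth and lineage signal never
collide and truth tables stay unambiguous.  Transitions outnumber
transversions 9:1, a generator default reflecting the strong transition
bias of mtDNA.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .phylo import MtPhylogeny
from .variants import MT_LENGTH, Variant, VariantProfile

_BASES = ("A", "C", "G", "T")
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class ScenarioSpec:
    """Study conditions for one simulated cohort."""

    tree: MtPhylogeny
    n_patients: int
    somatic_rate: float = 3.0
    swap_fraction: float = 0.0
    mixture_fraction: float = 0.0
    phantom_positions: frozenset[int] = frozenset()
    phantom_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.somatic_rate < 0:
            raise ValueError("somatic_rate must be >= 0")
        for name in ("swap_fraction", "mixture_fraction", "phantom_fraction"):
            f = getattr(self, name)
            if not 0 <= f <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.swap_fraction + self.mixture_fraction + self.phantom_fraction > 1:
            raise ValueError("artifact fractions must sum to at most 1")
        if self.swap_fraction > 0 and self.n_patients < 2:
            raise ValueError("swaps require at least 2 patients")


@dataclass(frozen=True)
class TruthRecord:
    patient_id: str
    true_normal_node: str
    true_tumor_node: str
    artifact: str = "none"  # none | swap | mixture | phantom
    swap_partner: str | None = None
    mixture_components: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.artifact not in ("none", "swap", "mixture", "phantom"):
            raise ValueError(f"unknown artifact {self.artifact!r}")
        if (self.artifact == "swap") != (self.swap_partner is not None):
            raise ValueError("swap_partner set iff artifact is 'swap'")
        if (self.artifact == "mixture") != (self.mixture_components is not None):
            raise ValueError("mixture_components set iff artifact is 'mixture'")


def _random_private_variant(
    rng: np.random.Generator, forbidden: set[int]
) -> Variant:
    while True:
        pos = int(rng.integers(1, MT_LENGTH + 1))
        if pos not in forbidden:
            break
    ref = _BASES[rng.integers(0, 4)]
    if rng.random() < 0.9:
        alt = _TRANSITION_PARTNER[ref]
    else:
        alt = [b for b in _BASES if b not in (ref, _TRANSITION_PARTNER[ref])][
            rng.integers(0, 2)
        ]
    return Variant(pos, ref, alt)


def simulate_profile(
    tree: MtPhylogeny,
    node: str,
    somatic_rate: float,
    rng: np.random.Generator,
    sample_id: str = "sim",
    tissue: str = "other",
) -> VariantProfile:
    """A haplogroup's cumulative motif plus Poisson(somatic_rate) privates.

    Private variants land only at positions absent from every motif in
    the tree (see module docstring).
    """
    if somatic_rate < 0:
        raise ValueError("somatic_rate must be >= 0")
    base = set(tree.expected_profile(node))
    forbidden = set(tree.all_positions())
    n_private = int(rng.poisson(somatic_rate))
    for _ in range(n_private):
        v = _random_private_variant(rng, forbidden)
        forbidden.add(v.position)
        base.add(v)
    return VariantProfile(sample_id, tissue, frozenset(base))


def _root_clade(tree: MtPhylogeny, name: str) -> str:
    path = tree.node(name).path_from_root()
    return path[1].name if len(path) > 1 else path[0].name


def _union_with_heteroplasmy(
    a: frozenset[Variant], b: frozenset[Variant]
) -> frozenset[Variant]:
    """Union of two variant sets, marking position collisions heteroplasmic."""
    positions_a = {v.position for v in a}
    positions_b = {v.position for v in b}
    collide = positions_a & positions_b
    merged: dict[tuple[int, str | None], Variant] = {}
    for v in list(a) + list(b):
        if v.position in collide:
            v = replace(v, heteroplasmic=True)
        merged.setdefault((v.position, v.alt_allele), v)
    return frozenset(merged.values())


def simulate_study(
    spec: ScenarioSpec,
) -> tuple[list[VariantProfile], list[TruthRecord]]:
    """Generate a paired tumor/normal cohort with planted artifacts.

    Returns one normal and one tumor profile per patient (sample ids
    ``P###-N`` / ``P###-T``) plus a truth table recording every planted
    artifact.  Counts of swapped/mixed/phantom patients are the rounded
    fractions of ``n_patients`` (swaps rounded down to an even count).
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    leaves = sorted(n.name for n in tree.leaves())
    n = spec.n_patients

    patients = [f"P{i:03d}" for i in range(1, n + 1)]
    nodes = {p: leaves[int(rng.integers(0, len(leaves)))] for p in patients}

    normals: dict[str, VariantProfile] = {}
    tumors: dict[str, VariantProfile] = {}
    for p in patients:
        normals[p] = simulate_profile(tree, nodes[p], 0.0, rng, f"{p}-N", "normal")
        tumors[p] = simulate_profile(
            tree, nodes[p], spec.somatic_rate, rng, f"{p}-T", "tumor"
        )

    truth = {
        p: TruthRecord(p, nodes[p], nodes[p]) for p in patients
    }

    # --- swaps: pair patients from distinct root-level clades -----------
    n_swap = int(round(n * spec.swap_fraction))
    n_swap -= n_swap % 2
    order = [patients[i] for i in rng.permutation(n)]
    # pair across the two largest clades each round so high swap fractions
    # remain satisfiable whenever a cross-clade matching exists
    clades: dict[str, list[str]] = {}
    for p in order:
        clades.setdefault(_root_clade(tree, nodes[p]), []).append(p)
    swapped: list[str] = []
    while len(swapped) < n_swap:
        ranked = sorted(
            (g for g in clades.items() if g[1]), key=lambda kv: (-len(kv[1]), kv[0])
        )
        if len(ranked) < 2:
            raise ValueError(
                "cannot plant the requested swaps: remaining patients share one clade"
            )
        a = ranked[0][1].pop(0)
        b = ranked[1][1].pop(0)
        tumors[a], tumors[b] = (
            replace(tumors[b], sample_id=f"{a}-T"),
            replace(tumors[a], sample_id=f"{b}-T"),
        )
        truth[a] = TruthRecord(a, nodes[a], nodes[b], "swap", swap_partner=b)
        truth[b] = TruthRecord(b, nodes[b], nodes[a], "swap", swap_partner=a)
        swapped += [a, b]

    # --- mixtures: tumor becomes a two-lineage union --------------------
    n_mix = int(round(n * spec.mixture_fraction))
    untouched = [p for p in order if truth[p].artifact == "none"]
    del order
    mixed = untouched[:n_mix]
    if len(mixed) < n_mix:
        raise ValueError("not enough unaffected patients to plant the requested mixtures")
    for p in mixed:
        own_clade = _root_clade(tree, nodes[p])
        foreign = [l for l in leaves if _root_clade(tree, l) != own_clade]
        contaminant = foreign[int(rng.integers(0, len(foreign)))]
        union = _union_with_heteroplasmy(
            tumors[p].variants, tree.expected_profile(contaminant)
        )
        tumors[p] = VariantProfile(f"{p}-T", "tumor", union)
        truth[p] = TruthRecord(
            p, nodes[p], nodes[p], "mixture",
            mixture_components=(nodes[p], contaminant),
        )

    # --- phantoms: recurrent spurious calls at fixed positions ----------
    n_phantom = int(round(n * spec.phantom_fraction))
    eligible = [p for p in untouched[n_mix:] if truth[p].artifact == "none"]
    if n_phantom and not spec.phantom_positions:
        raise ValueError("phantom_fraction > 0 requires phantom_positions")
    if len(eligible) < n_phantom:
        raise ValueError("not enough unaffected patients to plant the requested phantoms")
    phantom_alleles = {
        pos: _BASES[int(rng.integers(0, 4))] for pos in sorted(spec.phantom_positions)
    }
    for p in eligible[:n_phantom]:
        extra = set()
        for pos, ref in phantom_alleles.items():
            extra.add(Variant(pos, ref, _TRANSITION_PARTNER[ref], heteroplasmic=True))
        both = {(v.position, v.alt_allele) for v in tumors[p].variants}
        extra = {v for v in extra if (v.position, v.alt_allele) not in both}
        tumors[p] = VariantProfile(f"{p}-T", "tumor", tumors[p].variants | extra)
        truth[p] = TruthRecord(p, nodes[p], nodes[p], "phantom")

    profiles: list[VariantProfile] = []
    for p in patients:
        profiles += [normals[p], tumors[p]]
    return profiles, [truth[p] for p in patients]


def truth_table(records: Sequence[TruthRecord]) -> str:
    """Serialise truth records as TSV ('.' for missing fields)."""
    lines = ["patient\tnormal_node\ttumor_node\tartifact\tswap_partner\tmixture_components"]
    for r in records:
        comps = ",".join(r.mixture_components) if r.mixture_components else "."
        lines.append(
            f"{r.patient_id}\t{r.true_normal_node}\t{r.true_tumor_node}\t"
            f"{r.artifact}\t{r.swap_partner or '.'}\t{comps}"
        )
    return "\n".join(lines) + "\n"
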