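"""Tumor/normal pair concordance — the sample mix-up test.

mtDNA is maternally inherited and does not recombine, so a patient's
tumor and constitutional samples must lie on one maternal lineage: a
tumor may carry extra private somatic variants, but it cannot cross to
a different branch of the haplogroup tree.  When the set of "somatic"
differences between a pair instead reconstructs the phylogenetic path
between two divergent haplogroups, the parsimonious explanation is an
exchange of samples between individuals (artificial recombination),
because somatic mutagenesis cannot plausibly retrace evolutionary
history.

``compare_pair`` classifies both profiles, takes their symmetric
difference under wildcard matching, measures what fraction of those
differences lies on the path between the two called haplogroups, and
issues a verdict:

* ``CONCORDANT``     — calls coincide or are ancestor/descendant.
* ``SUSPECT_MIXUP``  — calls sit on divergent branches separated by at
  least ``min_divergent_branches`` edges and at least
  ``min_explained_fraction`` of the differences are lineage-defining.
* ``INDETERMINATE``  — divergent calls below those thresholds (or no
  usable data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .classify import ClassifyConfig, HaplogroupCall, classify
from .phylo import MtPhylogeny
from .variants import Variant, VariantProfile, variants_match

logger = logging.getLogger("mtqc")

CONCORDANT = "CONCORDANT"
SUSPECT_MIXUP = "SUSPECT_MIXUP"
INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class QcConfig:
    """Decision thresholds for the mix-up test.

    A single divergent branch can carry a genuine somatic hit at a
    recurrent site, and a handful of private differences should not
    outvote a clean lineage signal; the defaults (two divergent branches,
    70 % of differences lineage-explained) encode that caution and are
    engineering defaults, not published values.
    """

    min_divergent_branches: int = 2
    min_explained_fraction: float = 0.7
    classify_config: ClassifyConfig = field(default_factory=ClassifyConfig)

    def __post_init__(self) -> None:
        if self.min_divergent_branches < 1:
            raise ValueError("min_divergent_branches must be >= 1")
        if not 0 <= self.min_explained_fraction <= 1:
            raise ValueError("min_explained_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PairVerdict:
    patient_id: str
    normal_call: HaplogroupCall
    tumor_call: HaplogroupCall
    divergence: int
    somatic_diffs: frozenset[Variant]
    lineage_explained_fraction: float
    verdict: str


def _unmatched(a: frozenset[Variant], b: frozenset[Variant]) -> set[Variant]:
    return {v for v in a if not any(variants_match(v, w) for w in b)}


def somatic_differences(
    normal: VariantProfile, tumor: VariantProfile
) -> frozenset[Variant]:
    """Symmetric difference of two profiles under wildcard matching."""
    return frozenset(
        _unmatched(normal.variants, tumor.variants)
        | _unmatched(tumor.variants, normal.variants)
    )


def explain_differences(
    normal_call: HaplogroupCall,
    tumor_call: HaplogroupCall,
    somatic_diffs: frozenset[Variant],
    tree: MtPhylogeny,
) -> tuple[frozenset[Variant], frozenset[Variant]]:
    """Partition pair differences into (lineage_defining, private_somatic).

    A difference is lineage-defining when it matches a variant on the
    phylogenetic path between the two called haplogroups.
    """
    _, path_variants = tree.lineage_divergence(normal_call.node_name, tumor_call.node_name)
    lineage = {
        d for d in somatic_diffs if any(variants_match(d, p) for p in path_variants)
    }
    return frozenset(lineage), frozenset(somatic_diffs - lineage)


def compare_pair(
    normal: VariantProfile,
    tumor: VariantProfile,
    tree: MtPhylogeny,
    config: QcConfig = QcConfig(),
    patient_id: str | None = None,
) -> PairVerdict:
    """Compare a matched tumor/normal pair and issue a mix-up verdict."""
    patient_id = patient_id or normal.sample_id
    normal_call = classify(normal, tree, config.classify_config)[0]
    tumor_call = classify(tumor, tree, config.classify_config)[0]

    diffs = somatic_differences(normal, tumor)
    divergence, _ = tree.lineage_divergence(normal_call.node_name, tumor_call.node_name)
    lineage, _private = explain_differences(normal_call, tumor_call, diffs, tree)
    fraction = len(lineage) / len(diffs) if diffs else 0.0

    if not normal.variants and not tumor.variants:
        logger.warning("patient %s: both profiles empty, verdict indeterminate", patient_id)
        verdict = INDETERMINATE
    elif tree.is_ancestor(normal_call.node_name, tumor_call.node_name) or tree.is_ancestor(
        tumor_call.node_name, normal_call.node_name
    ):
        verdict = CONCORDANT
    else:
        branches = tree.path_branch_count(normal_call.node_name, tumor_call.node_name)
        if (
            branches >= config.min_divergent_branches
            and fraction >= config.min_explained_fraction
        ):
            verdict = SUSPECT_MIXUP
        else:
            verdict = INDETERMINATE

    return PairVerdict(
        patient_id=patient_id,
        normal_call=normal_call,
        tumor_call=tumor_call,
        divergence=divergence,
        somatic_diffs=diffs,
        lineage_explained_fraction=fraction,
        verdict=verdict,
    )
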