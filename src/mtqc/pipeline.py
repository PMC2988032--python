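"""End-to-end pipeline: classify everything, check pairs, screen mixtures.

``run_pipeline`` is the library entry point behind the ``mtqc run``
command: it classifies every profile, emits a pair verdict per patient
when a pairs table is given, screens every sample for two-lineage
mixtures, and produces a deterministic machine-readable report plus a
human-readable summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import yaml

from .classify import ClassifyConfig
from .concordance import PairVerdict, QcConfig, compare_pair
from .mixture import MixtureConfig, MixtureReport, detect_mixture
from .phylo import MtPhylogeny, fixture_tree, load_phylogeny_file
from .report import build_report, render_report, render_summary
from .variants import VariantParseError, VariantProfile, read_profiles

logger = logging.getLogger("mtqc")


@dataclass(frozen=True)
class RunConfig:
    """Run-wide configuration; optionally loaded from YAML."""

    tree_path: str | None = None  # None -> bundled fixture tree
    hotspot_mask: frozenset[int] | None = None
    qc: QcConfig = field(default_factory=QcConfig)
    mixture: MixtureConfig = field(default_factory=MixtureConfig)
    output_format: str = "json"
    log_level: str = "INFO"
    seed: int = 0
    exhaustive_mixture: bool = False

    def __post_init__(self) -> None:
        if self.output_format not in ("json", "tsv"):
            raise ValueError(f"unknown output format {self.output_format!r}")

    def resolved(self) -> "RunConfig":
        """Propagate a hotspot-mask override into both sub-configurations."""
        if self.hotspot_mask is None:
            return self
        cc = ClassifyConfig(
            hotspot_mask=frozenset(self.hotspot_mask),
            heteroplasmy_weight=self.qc.classify_config.heteroplasmy_weight,
            top_k=self.qc.classify_config.top_k,
        )
        return RunConfig(
            tree_path=self.tree_path,
            hotspot_mask=None,
            qc=QcConfig(
                min_divergent_branches=self.qc.min_divergent_branches,
                min_explained_fraction=self.qc.min_explained_fraction,
                classify_config=cc,
            ),
            mixture=MixtureConfig(
                min_gain=self.mixture.min_gain,
                min_unique_support=self.mixture.min_unique_support,
                candidate_pool=self.mixture.candidate_pool,
                classify_config=cc,
            ),
            output_format=self.output_format,
            log_level=self.log_level,
            seed=self.seed,
            exhaustive_mixture=self.exhaustive_mixture,
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path}: top level must be a mapping")
        qc_raw = raw.pop("qc", {}) or {}
        mix_raw = raw.pop("mixture", {}) or {}
        mask = raw.pop("hotspot_mask", None)
        known = {
            "tree_path",
            "output_format",
            "log_level",
            "seed",
            "exhaustive_mixture",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        return cls(
            hotspot_mask=frozenset(mask) if mask is not None else None,
            qc=QcConfig(**qc_raw),
            mixture=MixtureConfig(**mix_raw),
            **raw,
        )


def load_tree(config: RunConfig) -> MtPhylogeny:
    if config.tree_path is None:
        return fixture_tree()
    return load_phylogeny_file(config.tree_path)


def _read_pairs(path: str) -> list[tuple[str, str, str]]:
    """Pairs TSV: patient, normal_sample, tumor_sample."""
    pairs = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["patient", "normal_sample", "tumor_sample"]
        if header[:3] != required:
            raise VariantParseError(
                f"{path}: pairs table must start with columns {required}"
            )
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise VariantParseError(f"{path} row {i}: expected 3 columns")
            pairs.append((parts[0], parts[1], parts[2]))
    return pairs


def run_pipeline(
    config: RunConfig,
    profiles_path: str,
    pairs_path: str | None = None,
) -> tuple[dict[str, Any], str, str, int]:
    """Run the full QC pipeline.

    Returns ``(report_dict, rendered_report, summary_text, n_flags)``
    where ``n_flags`` counts SUSPECT_MIXUP verdicts plus mixture flags.
    """
    config = config.resolved()
    tree = load_tree(config)
    profiles = read_profiles(profiles_path)
    by_id: dict[str, VariantProfile] = {p.sample_id: p for p in profiles}

    verdicts: list[PairVerdict] = []
    if pairs_path is not None:
        for patient, normal_id, tumor_id in _read_pairs(pairs_path):
            for sid in (normal_id, tumor_id):
                if sid not in by_id:
                    raise VariantParseError(
                        f"pairs table references unknown sample {sid!r}"
                    )
            verdicts.append(
                compare_pair(
                    by_id[normal_id], by_id[tumor_id], tree, config.qc, patient_id=patient
                )
            )

    mixtures: list[MixtureReport] = []
    for p in profiles:
        if not p.variants:
            logger.info("sample %s: empty profile, skipped in mixture screen", p.sample_id)
            continue
        mixtures.append(
            detect_mixture(p, tree, config.mixture, exhaustive=config.exhaustive_mixture)
        )

    report = build_report(verdicts, mixtures)
    rendered = render_report(verdicts, mixtures, fmt=config.output_format)
    summary = render_summary(verdicts, mixtures)
    n_flags = sum(v.verdict == "SUSPECT_MIXUP" for v in verdicts) + sum(
        m.is_mixture for m in mixtures
    )
    return report, rendered, summary, n_flags
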