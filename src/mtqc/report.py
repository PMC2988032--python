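"""Deterministic machine-readable reports (JSON / TSV) and round-trips.

The JSON report carries no timestamps and fixes all orderings, so
identical inputs and configuration produce byte-identical output.  A
JSON Schema describing the format ships with the package
(``schemas/report.schema.json``); :func:`validate_report` performs the
equivalent structural check in-process.
"""

from __future__ import annotations

import json
from typing import Any, Mapping, Sequence

from .classify import HaplogroupCall
from .concordance import PairVerdict
from .mixture import MixtureReport
from .variants import Variant, format_variant, parse_variant

SCHEMA_ID = "mtqc-report/1"


def _tokens(variants: frozenset[Variant]) -> list[str]:
    return [format_variant(v) for v in sorted(variants)]


def _call_to_dict(call: HaplogroupCall) -> dict[str, Any]:
    return {
        "haplogroup": call.node_name,
        "score": call.score,
        "matched": _tokens(call.matched),
        "missing": _tokens(call.missing),
        "private": _tokens(call.private),
    }


def _call_from_dict(d: Mapping[str, Any]) -> HaplogroupCall:
    return HaplogroupCall(
        node_name=d["haplogroup"],
        score=d["score"],
        matched=frozenset(parse_variant(t) for t in d["matched"]),
        missing=frozenset(parse_variant(t) for t in d["missing"]),
        private=frozenset(parse_variant(t) for t in d["private"]),
    )


def verdict_to_dict(v: PairVerdict) -> dict[str, Any]:
    return {
        "patient": v.patient_id,
        "normal_call": _call_to_dict(v.normal_call),
        "tumor_call": _call_to_dict(v.tumor_call),
        "divergence": v.divergence,
        "somatic_diffs": _tokens(v.somatic_diffs),
        "lineage_explained_fraction": v.lineage_explained_fraction,
        "verdict": v.verdict,
    }


def verdict_from_dict(d: Mapping[str, Any]) -> PairVerdict:
    return PairVerdict(
        patient_id=d["patient"],
        normal_call=_call_from_dict(d["normal_call"]),
        tumor_call=_call_from_dict(d["tumor_call"]),
        divergence=d["divergence"],
        somatic_diffs=frozenset(parse_variant(t) for t in d["somatic_diffs"]),
        lineage_explained_fraction=d["lineage_explained_fraction"],
        verdict=d["verdict"],
    )


def mixture_to_dict(m: MixtureReport) -> dict[str, Any]:
    return {
        "sample": m.sample_id,
        "components": list(m.components),
        "assignment": {format_variant(v): lab for v, lab in sorted(m.assignment.items())},
        "explained_fraction_k1": m.explained_fraction_k1,
        "explained_fraction_k2": m.explained_fraction_k2,
        "gain": m.gain,
        "is_mixture": m.is_mixture,
        "pair_ranking": [[a, b, f] for a, b, f in m.pair_ranking],
    }


def mixture_from_dict(d: Mapping[str, Any]) -> MixtureReport:
    return MixtureReport(
        sample_id=d["sample"],
        components=tuple(d["components"]),
        assignment={parse_variant(t): lab for t, lab in d["assignment"].items()},
        explained_fraction_k1=d["explained_fraction_k1"],
        explained_fraction_k2=d["explained_fraction_k2"],
        gain=d["gain"],
        is_mixture=d["is_mixture"],
        pair_ranking=tuple((a, b, f) for a, b, f in d["pair_ranking"]),
    )


def build_report(
    verdicts: Sequence[PairVerdict] = (),
    mixture_reports: Sequence[MixtureReport] = (),
) -> dict[str, Any]:
    return {
        "schema": SCHEMA_ID,
        "pairs": [verdict_to_dict(v) for v in sorted(verdicts, key=lambda v: v.patient_id)],
        "mixtures": [
            mixture_to_dict(m)
            for m in sorted(mixture_reports, key=lambda m: m.sample_id)
        ],
    }


_PAIR_COLUMNS = (
    "patient",
    "normal_haplogroup",
    "normal_score",
    "tumor_haplogroup",
    "tumor_score",
    "divergence",
    "somatic_diffs",
    "lineage_explained_fraction",
    "verdict",
)
_MIX_COLUMNS = (
    "sample",
    "component1",
    "component2",
    "explained_fraction_k1",
    "explained_fraction_k2",
    "gain",
    "is_mixture",
    "residual_variants",
)


def render_report(
    verdicts: Sequence[PairVerdict] = (),
    mixture_reports: Sequence[MixtureReport] = (),
    fmt: str = "json",
) -> str:
    """Serialise verdicts and mixture reports as JSON or TSV.

    The TSV form holds a pair table and a mixture table separated by a
    blank line; missing values are written as ``.``.
    """
    if fmt == "json":
        return json.dumps(build_report(verdicts, mixture_reports), indent=2) + "\n"
    if fmt != "tsv":
        raise ValueError(f"unknown report format {fmt!r} (expected json or tsv)")

    lines = ["\t".join(_PAIR_COLUMNS)]
    for v in sorted(verdicts, key=lambda v: v.patient_id):
        diffs = ",".join(_tokens(v.somatic_diffs)) or "."
        lines.append(
            "\t".join(
                [
                    v.patient_id,
                    v.normal_call.node_name,
                    f"{v.normal_call.score:.6f}",
                    v.tumor_call.node_name,
                    f"{v.tumor_call.score:.6f}",
                    str(v.divergence),
                    diffs,
                    f"{v.lineage_explained_fraction:.6f}",
                    v.verdict,
                ]
            )
        )
    lines.append("")
    lines.append("\t".join(_MIX_COLUMNS))
    for m in sorted(mixture_reports, key=lambda m: m.sample_id):
        residual = ",".join(
            format_variant(v) for v, lab in sorted(m.assignment.items()) if lab == "residual"
        ) or "."
        comp1 = m.components[0] if m.components else "."
        comp2 = m.components[1] if len(m.components) > 1 else "."
        lines.append(
            "\t".join(
                [
                    m.sample_id,
                    comp1,
                    comp2,
                    f"{m.explained_fraction_k1:.6f}",
                    f"{m.explained_fraction_k2:.6f}",
                    f"{m.gain:.6f}",
                    str(m.is_mixture).lower(),
                    residual,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def parse_report(text: str) -> tuple[list[PairVerdict], list[MixtureReport]]:
    """Inverse of JSON :func:`render_report`."""
    data = json.loads(text)
    validate_report(data)
    return (
        [verdict_from_dict(d) for d in data["pairs"]],
        [mixture_from_dict(d) for d in data["mixtures"]],
    )


class ReportValidationError(ValueError):
    pass


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ReportValidationError(msg)


def validate_report(data: Mapping[str, Any]) -> None:
    """Structural validation mirroring the shipped JSON schema."""
    _require(isinstance(data, Mapping), "report must be an object")
    _require(data.get("schema") == SCHEMA_ID, f"schema must be {SCHEMA_ID!r}")
    _require(isinstance(data.get("pairs"), list), "pairs must be a list")
    _require(isinstance(data.get("mixtures"), list), "mixtures must be a list")
    for d in data["pairs"]:
        for key in (
            "patient",
            "normal_call",
            "tumor_call",
            "divergence",
            "somatic_diffs",
            "lineage_explained_fraction",
            "verdict",
        ):
            _require(key in d, f"pair entry missing {key!r}")
        _require(
            d["verdict"] in ("CONCORDANT", "SUSPECT_MIXUP", "INDETERMINATE"),
            f"unknown verdict {d['verdict']!r}",
        )
        for side in ("normal_call", "tumor_call"):
            call = d[side]
            for key in ("haplogroup", "score", "matched", "missing", "private"):
                _require(key in call, f"{side} missing {key!r}")
            _require(0 <= call["score"] <= 1, "score outside [0, 1]")
    for d in data["mixtures"]:
        for key in (
            "sample",
            "components",
            "assignment",
            "explained_fraction_k1",
            "explained_fraction_k2",
            "gain",
            "is_mixture",
            "pair_ranking",
        ):
            _require(key in d, f"mixture entry missing {key!r}")
        for lab in d["assignment"].values():
            _require(
                lab in ("component1", "component2", "residual"),
                f"unknown assignment label {lab!r}",
            )


def render_summary(
    verdicts: Sequence[PairVerdict] = (),
    mixture_reports: Sequence[MixtureReport] = (),
) -> str:
    """Human-readable summary of flagged findings."""
    flagged_pairs = [v for v in verdicts if v.verdict == "SUSPECT_MIXUP"]
    flagged_mixtures = [m for m in mixture_reports if m.is_mixture]
    lines = [
        "mtqc summary",
        f"  pairs checked:    {len(verdicts)} ({len(flagged_pairs)} flagged SUSPECT_MIXUP)",
        f"  samples screened: {len(mixture_reports)} ({len(flagged_mixtures)} flagged as mixtures)",
    ]
    for v in sorted(flagged_pairs, key=lambda v: v.patient_id):
        lines.append(
            f"  [mix-up] {v.patient_id}: normal={v.normal_call.node_name} "
            f"tumor={v.tumor_call.node_name} "
            f"lineage-explained {v.lineage_explained_fraction:.0%} "
            f"of {len(v.somatic_diffs)} differences"
        )
    for m in sorted(flagged_mixtures, key=lambda m: m.sample_id):
        lines.append(
            f"  [mixture] {m.sample_id}: components {m.components[0]} + {m.components[1]}, "
            f"explained {m.explained_fraction_k1:.0%} -> {m.explained_fraction_k2:.0%}"
        )
    if not flagged_pairs and not flagged_mixtures:
        lines.append("  no QC flags")
    return "\n".join(lines) + "\n"
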