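"""rCRS-anchored mtDNA variant nomenclature and sample profile I/O.

Variants are scored against the revised Cambridge Reference Sequence
(rCRS, 16 569 bp), using the compact notation common in mtDNA population
genetics and forensics:

* ``A7146G``  -- full form: reference base, 1-based position, derived base.
* ``16318t``  -- lowercase suffix: a transversion to that base; the
  reference base is not stated (two candidates remain).
* ``12519``   -- position only: a change at that site with unreported
  alleles (used for heteroplasmic calls in the source data).
* ``16166d``  -- deletion of the base at that position.
* ``h`` prefix on any form marks the call as heteroplasmic.

Tokens with an uppercase derived base but no reference base (``7028T``)
denote transitions by convention, so the reference base is recovered as
the transition partner.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("mtqc")

#: Length of the revised Cambridge Reference Sequence.
MT_LENGTH = 16569

#: Marker used for the alt allele of a deletion.
DELETION = "-"

#: Hypervariable / artifact-prone sites excluded from haplogroup scoring
#: by default.  An engineering default, configurable via ClassifyConfig.
DEFAULT_HOTSPOT_MASK = frozenset({146, 152, 195, 310, 16182, 16183, 16189, 16519})

_BASES = frozenset("ACGT")
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: Tissue vocabulary for sample profiles.
TISSUES = ("tumor", "normal", "salivary", "lymphocyte", "leukocyte", "other")


class VariantParseError(ValueError):
    """A variant token or profile table could not be parsed."""


def _is_transition(ref: str, alt: str) -> bool:
    return _TRANSITION_PARTNER[ref] == alt


@dataclass(frozen=True, order=True)
class Variant:
    """One rCRS-anchored sequence change.

    ``ref_allele``/``alt_allele`` are ``None`` when the source notation
    does not state them; ``alt_allele`` is :data:`DELETION` for deletions.
    The mutation class is derived from the alleles, not stored.
    """

    position: int
    ref_allele: str | None = None
    alt_allele: str | None = None
    heteroplasmic: bool = field(default=False, compare=True)

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise VariantParseError(
                f"position {self.position} outside rCRS range 1..{MT_LENGTH}"
            )
        if self.ref_allele is not None and self.ref_allele not in _BASES:
            raise VariantParseError(f"invalid reference allele {self.ref_allele!r}")
        if self.alt_allele is not None and self.alt_allele != DELETION:
            if self.alt_allele not in _BASES:
                raise VariantParseError(f"invalid derived allele {self.alt_allele!r}")
            if self.alt_allele == self.ref_allele:
                raise VariantParseError(
                    f"ref and alt both {self.alt_allele} at {self.position}"
                )
        if self.ref_allele is not None and self.alt_allele is None:
            raise VariantParseError(
                f"variant at {self.position} has a reference allele but no "
                "derived allele; position-only variants carry neither"
            )

    @property
    def is_deletion(self) -> bool:
        return self.alt_allele == DELETION

    @property
    def mutation_class(self) -> str:
        """One of ``transition``, ``transversion``, ``deletion``, ``unknown``."""
        if self.is_deletion:
            return "deletion"
        if self.alt_allele is None:
            return "unknown"
        if self.ref_allele is None:
            # only transversions are written without a recoverable ref base
            return "transversion"
        return "transition" if _is_transition(self.ref_allele, self.alt_allele) else "transversion"

    def without_heteroplasmy(self) -> "Variant":
        return replace(self, heteroplasmic=False) if self.heteroplasmic else self

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_variant(self)


_TOKEN_RE = re.compile(r"^([ACGT])?(\d+)([ACGTacgt]|d)?$")


def parse_variant(token: str) -> Variant:
    """Parse one variant token (see module docstring for the grammar)."""
    raw = token
    token = token.strip()
    if not token:
        raise VariantParseError("empty variant token")
    heteroplasmic = False
    if token[0] in "hH":
        heteroplasmic = True
        token = token[1:]
    if "+" in token or "." in token:
        raise VariantParseError(
            f"insertion notation not supported: {raw!r} (point variants and "
            "single-base deletions only)"
        )
    m = _TOKEN_RE.match(token)
    if m is None:
        raise VariantParseError(f"cannot parse variant token {raw!r}")
    ref, pos_s, suffix = m.groups()
    position = int(pos_s)
    if suffix is None:
        if ref is not None:
            raise VariantParseError(
                f"token {raw!r} has a reference base but no derived base"
            )
        return Variant(position, None, None, heteroplasmic)
    if suffix == "d":
        return Variant(position, ref, DELETION, heteroplasmic)
    if suffix.islower():
        alt = suffix.upper()
        if ref is not None and _is_transition(ref, alt):
            raise VariantParseError(
                f"token {raw!r} marks a transversion but {ref}>{alt} is a transition"
            )
        return Variant(position, ref, alt, heteroplasmic)
    alt = suffix
    if ref is None:
        # bare uppercase suffix denotes a transition; recover the ref base
        ref = _TRANSITION_PARTNER[alt]
    return Variant(position, ref, alt, heteroplasmic)


def format_variant(v: Variant) -> str:
    """Canonical token for a variant; inverse of :func:`parse_variant`."""
    h = "h" if v.heteroplasmic else ""
    if v.is_deletion:
        ref = v.ref_allele or ""
        return f"{h}{ref}{v.position}d"
    if v.alt_allele is None:
        return f"{h}{v.position}"
    if v.mutation_class == "transition":
        return f"{h}{v.ref_allele}{v.position}{v.alt_allele}"
    ref = v.ref_allele or ""
    return f"{h}{ref}{v.position}{v.alt_allele.lower()}"


def variants_match(a: Variant, b: Variant) -> bool:
    """Positional match with unknown alleles acting as wildcards.

    Heteroplasmy flags are ignored: the source data lists heteroplasmic
    calls by position only, yet treats them as evidence for the motif
    variant at that site.
    """
    if a.position != b.position:
        return False
    if a.alt_allele is None or b.alt_allele is None:
        return True
    return a.alt_allele == b.alt_allele


@dataclass(frozen=True)
class VariantProfile:
    """A sample's set of rCRS-anchored variants with a tissue label."""

    sample_id: str
    tissue: str
    variants: frozenset[Variant]

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(
                f"unknown tissue {self.tissue!r} for sample {self.sample_id!r}; "
                f"expected one of {', '.join(TISSUES)}"
            )
        keys = {(v.position, v.alt_allele) for v in self.variants}
        if len(keys) != len(self.variants):
            raise ValueError(
                f"profile {self.sample_id!r} repeats a (position, allele) pair"
            )

    def __len__(self) -> int:
        return len(self.variants)


def make_profile(sample_id: str, tissue: str, tokens: Iterable[str]) -> VariantProfile:
    """Build a profile from tokens, collapsing duplicate (position, alt) pairs."""
    seen: dict[tuple[int, str | None], Variant] = {}
    for tok in tokens:
        v = parse_variant(tok)
        key = (v.position, v.alt_allele)
        if key in seen:
            logger.warning(
                "sample %s: duplicate variant %s collapsed", sample_id, format_variant(v)
            )
            # keep the heteroplasmic mark if either copy carries it
            if v.heteroplasmic and not seen[key].heteroplasmic:
                seen[key] = v
            continue
        seen[key] = v
    return VariantProfile(sample_id, tissue, frozenset(seen.values()))


_SPLIT_RE = re.compile(r"[,\s]+")


def read_profiles(table: str | io.TextIOBase) -> list[VariantProfile]:
    """Read sample profiles from TSV content or a file path.

    Expected header: ``sample<TAB>tissue<TAB>variants`` with the variants
    cell holding comma- or whitespace-separated tokens (may be empty).
    """
    if isinstance(table, str) and "\t" in table:
        buf: io.TextIOBase | io.StringIO = io.StringIO(table)
    elif isinstance(table, str):
        buf = open(table, "r", encoding="utf-8")
    else:
        buf = table
    try:
        df = pd.read_csv(buf, sep="\t", dtype=str, keep_default_na=False)
    finally:
        if isinstance(table, str) and "\t" not in table:
            buf.close()
    for col in ("sample", "tissue", "variants"):
        if col not in df.columns:
            raise VariantParseError(f"profile table is missing column {col!r}")
    profiles = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        tokens = [t for t in _SPLIT_RE.split(str(row.variants).strip()) if t]
        try:
            profiles.append(make_profile(str(row.sample), str(row.tissue).strip().lower(), tokens))
        except (VariantParseError, ValueError) as exc:
            raise VariantParseError(f"row {i}: {exc}") from exc
    return profiles


def write_profiles(profiles: Sequence[VariantProfile]) -> str:
    """Serialise profiles back to the TSV dialect read by :func:`read_profiles`."""
    lines = ["sample\ttissue\tvariants"]
    for p in profiles:
        toks = ",".join(format_variant(v) for v in sorted(p.variants))
        lines.append(f"{p.sample_id}\t{p.tissue}\t{toks}")
    return "\n".join(lines) + "\n"


def read_vcf(path: str, sample_id: str | None = None, tissue: str = "other") -> VariantProfile:
    """Minimal VCF reader: ALT records on one mtDNA contig become Variants.

    SNVs and single-base deletions only; multi-allelic records are split,
    anything longer is skipped with a warning.  Heteroplasmy is flagged
    when a ``HET`` INFO key is present.
    """
    variants: list[str] = []
    contig = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise VariantParseError(f"malformed VCF record: {line.strip()!r}")
            chrom, pos_s, _id, ref, alts, _q, _f, info = parts[:8]
            if contig is None:
                contig = chrom
            elif chrom != contig:
                raise VariantParseError("VCF spans more than one contig")
            het = "HET" in info.split(";")
            for alt in alts.split(","):
                h = "h" if het else ""
                if len(ref) == 1 and len(alt) == 1 and alt in _BASES:
                    # transversions take the lowercase-suffix form
                    suffix = alt if _is_transition(ref, alt) else alt.lower()
                    variants.append(f"{h}{ref}{pos_s}{suffix}")
                elif len(ref) == 2 and len(alt) == 1 and ref[0] == alt:
                    variants.append(f"{h}{ref[1]}{int(pos_s) + 1}d")
                else:
                    logger.warning("skipping unsupported VCF allele %s>%s at %s", ref, alt, pos_s)
    return make_profile(sample_id or path, tissue, variants)
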