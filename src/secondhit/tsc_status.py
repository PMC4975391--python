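"""Per-specimen TSC1/TSC2 biallelic-inactivation classification.

Two layers: variant typing from HGVS strings (with an explicit-type
override, since annotation sources sometimes know better than string
inference — e.g. a deep-intronic change annotated as affecting splicing),
and a per-sample mechanism verdict following Knudson two-hit precedence:

1. ``homozygous_deletion`` — a genomic deletion removing both copies;
2. ``two_mutation``       — two distinct inactivating small variants at one
                            locus (germline + somatic, or two somatic);
3. ``mutation_plus_cnloh`` — one variant made homozygous by copy-neutral LOH
                            spanning the locus;
4. ``cnloh_only``          — LOH without any detected variant;
5. ``none``                — no second-hit evidence.

``biallelic`` is true exactly for the first three.  Phasing is unknowable
from short-read data; two distinct variants are assumed to lie in trans.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .loh_mapper import CopyStatus, LohRegion
from .variant_io import FixtureBundle, VariantCall, VariantType

__all__ = [
    "Mechanism",
    "SampleStatus",
    "TSC1_LOCUS",
    "TSC2_LOCUS",
    "classify_variant_type",
    "variant_type_with_override",
    "classify_sample_status",
    "classify_fixture_statuses",
]

logger = logging.getLogger(__name__)

#: hg19 gene spans (chrom, start, end), 1-based inclusive.
TSC1_LOCUS = ("9", 135_764_735, 135_822_020)
TSC2_LOCUS = ("16", 2_095_990, 2_140_713)


class Mechanism(str, Enum):
    two_mutation = "two_mutation"
    mutation_plus_cnloh = "mutation_plus_cnloh"
    homozygous_deletion = "homozygous_deletion"
    cnloh_only = "cnloh_only"
    none = "none"


_BIALLELIC = {
    Mechanism.two_mutation,
    Mechanism.mutation_plus_cnloh,
    Mechanism.homozygous_deletion,
}


@dataclass
class SampleStatus:
    sample_id: str
    locus: str  # "TSC1", "TSC2", or "none"
    mechanism: Mechanism
    hits: list[VariantCall] = field(default_factory=list)
    loh: LohRegion | str | None = None

    @property
    def biallelic(self) -> bool:
        return self.mechanism in _BIALLELIC

    @property
    def two_event(self) -> bool:
        """Both hits are discrete mutational events (no LOH involved)."""
        return self.mechanism in (Mechanism.two_mutation, Mechanism.homozygous_deletion)


# ---------------------------------------------------------------------------
# HGVS variant typing

_SPLICE_OFFSET = re.compile(r"c\.\d+([+-])(\d+)")
_RANGE = re.compile(r"c\.(\d+)_(\d+)(del|ins|dup)([ACGT]*)", re.IGNORECASE)
_POINT_DELINS = re.compile(r"c\.(\d+)(del|ins|dup)([ACGT]*)", re.IGNORECASE)
_SUBSTITUTION = re.compile(r"c\.\d+[ACGT]>[ACGT]$")


def classify_variant_type(cdna_change: str, protein_change: str = "") -> VariantType:
    """Infer the variant class from HGVS cDNA and protein strings.

    Order of evidence: a stop-gain protein annotation wins; ``_splice``
    protein annotations and near-exon intronic offsets (|offset| <= 2) call
    splice; a frameshift protein annotation forces the frameshift classes;
    otherwise deleted/inserted length modulo 3 separates in-frame from
    frameshift; a clean single-nucleotide substitution with a residue change
    is missense.  Unparseable input yields ``unknown`` with a warning.
    """
    cdna = cdna_change.strip()
    protein = protein_change.strip()

    if protein.endswith("*"):
        return VariantType.nonsense
    if "_splice" in protein:
        return VariantType.splice
    m = _SPLICE_OFFSET.match(cdna)
    if m and int(m.group(2)) <= 2:
        return VariantType.splice

    frameshift = protein.endswith("fs")
    m = _RANGE.match(cdna)
    if m:
        start, end, op, seq = int(m.group(1)), int(m.group(2)), m.group(3).lower(), m.group(4)
        if op == "ins":
            if frameshift:
                return VariantType.frameshift_ins
            if seq and len(seq) % 3 == 0:
                # in-frame insertions are not distinguished by this cohort's
                # vocabulary; report unknown rather than mislabel
                warnings.warn(f"in-frame insertion not classifiable: {cdna}")
                return VariantType.unknown
            return VariantType.frameshift_ins
        length = len(seq) if seq else end - start + 1
        if frameshift:
            return VariantType.frameshift_del
        return VariantType.inframe_del if length % 3 == 0 else VariantType.frameshift_del
    m = _POINT_DELINS.match(cdna)
    if m:
        op = m.group(2).lower()
        if op == "ins":
            return VariantType.frameshift_ins if frameshift else VariantType.unknown
        return VariantType.frameshift_del  # single-nucleotide del/dup shifts frame
    if frameshift:
        # e.g. insertions written with nonstandard separators; trust the
        # protein-level frameshift and the del/ins token
        if "ins" in cdna:
            return VariantType.frameshift_ins
        if "del" in cdna:
            return VariantType.frameshift_del
    if _SUBSTITUTION.match(cdna) and protein.startswith("p."):
        return VariantType.missense

    warnings.warn(f"could not classify HGVS strings {cdna!r} / {protein!r}")
    return VariantType.unknown


def variant_type_with_override(call: VariantCall) -> VariantType:
    """The call's effective type: an explicit table token overrides inference."""
    inferred = classify_variant_type(call.cdna_change, call.protein_change)
    if call.variant_type is not VariantType.unknown and call.variant_type is not inferred:
        logger.info(
            "explicit variant_type %s overrides inferred %s for %s %s",
            call.variant_type.value, inferred.value, call.sample_id, call.cdna_change,
        )
        return call.variant_type
    return inferred if call.variant_type is VariantType.unknown else call.variant_type


# ---------------------------------------------------------------------------
# per-sample mechanism


def _loh_spans_locus(loh: LohRegion | str | bool | None, locus: tuple[str, int, int]) -> bool:
    """True when the LOH evidence covers the locus with its confident span."""
    if loh is None or loh is False:
        return False
    if loh is True or isinstance(loh, str):
        return True  # annotation-level verdict, already locus-specific
    chrom, start, end = locus
    if loh.spans(chrom, start, end):
        return True
    if (
        loh.chrom == chrom
        and loh.uncertain_start <= start
        and end <= loh.uncertain_end
    ):
        warnings.warn(
            f"locus {chrom}:{start}-{end} lies only in the uncertainty flank of an "
            "LOH region; not counted as a second hit"
        )
    return False


def classify_sample_status(
    sample_id: str,
    variants: Sequence[VariantCall],
    loh_tsc2: LohRegion | str | bool | None = None,
    loh_tsc1: LohRegion | str | bool | None = None,
    genomic_del_status: CopyStatus = CopyStatus.homozygous_loss,
) -> SampleStatus:
    """Assign the biallelic-inactivation verdict for one specimen.

    ``variants`` are the specimen's filtered TSC1/TSC2 calls (germline and
    somatic).  LOH evidence per locus may be a delineated region, a bare
    annotation string, or a boolean.
    """
    tsc_variants = [v for v in variants if v.gene in ("TSC1", "TSC2")]
    loci = {v.gene for v in tsc_variants}
    if len(loci) > 1:
        raise ValueError(
            f"{sample_id}: variants at both TSC1 and TSC2; manual resolution required"
        )

    loh_by_locus = {
        "TSC2": _loh_spans_locus(loh_tsc2, TSC2_LOCUS),
        "TSC1": _loh_spans_locus(loh_tsc1, TSC1_LOCUS),
    }

    if not tsc_variants:
        loh_locus = next((g for g, has in loh_by_locus.items() if has), None)
        if loh_locus:
            return SampleStatus(
                sample_id, loh_locus, Mechanism.cnloh_only,
                loh=loh_tsc2 if loh_locus == "TSC2" else loh_tsc1,
            )
        return SampleStatus(sample_id, "none", Mechanism.none)

    locus = loci.pop()
    loh_evidence = loh_tsc2 if locus == "TSC2" else loh_tsc1
    has_loh = loh_by_locus[locus]

    genomic_dels = [v for v in tsc_variants if v.variant_type is VariantType.genomic_del]
    if genomic_dels and genomic_del_status is CopyStatus.homozygous_loss:
        return SampleStatus(
            sample_id, locus, Mechanism.homozygous_deletion, hits=genomic_dels
        )

    distinct = {v.cdna_change for v in tsc_variants}
    if len(distinct) >= 2:
        return SampleStatus(
            sample_id, locus, Mechanism.two_mutation, hits=list(tsc_variants)
        )
    if has_loh:
        return SampleStatus(
            sample_id, locus, Mechanism.mutation_plus_cnloh,
            hits=list(tsc_variants), loh=loh_evidence,
        )
    return SampleStatus(sample_id, locus, Mechanism.none, hits=list(tsc_variants))


def classify_fixture_statuses(bundle: FixtureBundle) -> dict[str, SampleStatus]:
    """Mechanism verdicts for all 32 packaged specimens.

    The packaged LOH column is the annotation-level verdict: ``Yes`` means
    copy-neutral 16p LOH spanning TSC2, ``9q LOH`` the analogue for TSC1.
    """
    by_sample: dict[str, list[VariantCall]] = {}
    for call in bundle.tsc_calls:
        by_sample.setdefault(call.sample_id, []).append(call)

    statuses = {}
    for sample_id, variants in by_sample.items():
        label = bundle.loh_annotations.get(sample_id, "")
        statuses[sample_id] = classify_sample_status(
            sample_id,
            variants,
            loh_tsc2="16p CN-LOH" if label == "Yes" else None,
            loh_tsc1="9q CN-LOH" if label == "9q LOH" else None,
        )
    return statuses
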