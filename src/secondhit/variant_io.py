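"""Tabular I/O for variant calls and SNP allele-count tracks.

The canonical interchange format is tab-delimited UTF-8 with a fixed header
(:data:`VARIANT_COLUMNS`).  Mutant allele fractions are always recomputed from
read counts; a printed-AF column, when present, is carried along for
cross-checking only.  Rows whose read-count cells are empty (e.g. a variant
annotated "no coverage" in one specimen of a pair) are loaded but flagged
uncovered and excluded from every downstream statistic.

Also houses the variant-review filter (minimum variant reads, bidirectional
support, minimum allele fraction) and the packaged transcriptions of the
study's two variant tables.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "VariantType",
    "Origin",
    "VariantCall",
    "SnpObservation",
    "VariantTableError",
    "FixtureIntegrityError",
    "VARIANT_COLUMNS",
    "read_variant_table",
    "write_variant_table",
    "read_snp_track",
    "write_snp_track",
    "filter_variant_calls",
    "load_fixtures",
    "variants_from_vcf",
]


class VariantType(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    splice = "splice"
    frameshift_del = "frameshift_del"
    frameshift_ins = "frameshift_ins"
    inframe_del = "inframe_del"
    genomic_del = "genomic_del"
    unknown = "unknown"


class Origin(str, Enum):
    germline = "germline"
    somatic = "somatic"
    unknown = "unknown"


class VariantTableError(ValueError):
    """Malformed variant table (bad header, row, or token)."""


class FixtureIntegrityError(RuntimeError):
    """Packaged fixture does not match its recorded checksum."""


#: Canonical column order of the variant TSV format.
VARIANT_COLUMNS = (
    "patient",
    "sample",
    "source",
    "gene",
    "variant_type",
    "cdna_change",
    "protein_change",
    "mutant_reads",
    "ref_reads",
    "printed_af",
    "origin",
    "bidirectional",
    "loh",
    "functional_class",
    "validation",
    "notes",
)

_TSC_GENES = frozenset({"TSC1", "TSC2"})


@dataclass
class VariantCall:
    """One small mutation or genomic deletion in one specimen.

    ``mutant_reads``/``ref_reads`` are ``None`` for calls without read
    support in this specimen ("no coverage"), in which case :attr:`covered`
    is False and :attr:`af` is ``None``.
    """

    patient_id: str
    sample_id: str
    gene: str
    variant_type: VariantType
    cdna_change: str
    protein_change: str = ""
    mutant_reads: int | None = None
    ref_reads: int | None = None
    origin: Origin = Origin.unknown
    bidirectional: bool = True
    functional_class: str = ""
    source: str = ""
    printed_af: str = ""
    loh_label: str = ""
    validation: str = ""
    notes: str = ""
    duplicate: bool = False  # literal repeat of another row in the same sample

    def __post_init__(self) -> None:
        if self.mutant_reads is not None and self.mutant_reads < 0:
            raise ValueError(f"negative mutant_reads for {self.key()}")
        if self.ref_reads is not None and self.ref_reads < 0:
            raise ValueError(f"negative ref_reads for {self.key()}")

    @property
    def depth(self) -> int:
        if self.mutant_reads is None or self.ref_reads is None:
            return 0
        return self.mutant_reads + self.ref_reads

    @property
    def covered(self) -> bool:
        return self.depth > 0

    @property
    def af(self) -> float | None:
        """Allele fraction recomputed from read counts; None at zero depth."""
        if not self.covered:
            return None
        return self.mutant_reads / self.depth

    @property
    def is_tsc(self) -> bool:
        return self.gene in _TSC_GENES

    def key(self) -> tuple[str, str, str]:
        """Identity of the mutation itself: (gene, cDNA change, protein)."""
        return (self.gene, self.cdna_change, self.protein_change)


@dataclass(frozen=True)
class SnpObservation:
    """Ref/alt read counts at one genomic SNP position (1-based)."""

    chrom: str
    pos: int
    normal_ref: int = 0
    normal_alt: int = 0
    tumor_ref: int = 0
    tumor_alt: int = 0
    paired: bool = True

    def __post_init__(self) -> None:
        for name in ("normal_ref", "normal_alt", "tumor_ref", "tumor_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative read count {name} at {self.chrom}:{self.pos}")

    @property
    def normal_depth(self) -> int:
        return self.normal_ref + self.normal_alt

    @property
    def tumor_depth(self) -> int:
        return self.tumor_ref + self.tumor_alt

    @property
    def normal_af(self) -> float | None:
        d = self.normal_depth
        return self.normal_alt / d if d else None

    @property
    def tumor_af(self) -> float | None:
        d = self.tumor_depth
        return self.tumor_alt / d if d else None


# ---------------------------------------------------------------------------
# variant table I/O


def _parse_int(cell: str, what: str, line_no: int) -> int | None:
    cell = cell.strip()
    if cell in ("", "NA", "."):
        return None
    try:
        value = int(cell)
    except ValueError as exc:
        raise VariantTableError(f"line {line_no}: bad {what} {cell!r}") from exc
    return value


def _validate_hgvs(cdna: str, line_no: int) -> None:
    # NA is allowed for calls (genomic deletions) that have no cDNA notation.
    if cdna in ("", "NA"):
        return
    if not cdna.startswith("c."):
        raise VariantTableError(f"line {line_no}: malformed HGVS cDNA string {cdna!r}")


def read_variant_table(path: str | Path) -> list[VariantCall]:
    """Read a canonical variant TSV into :class:`VariantCall` objects.

    Allele fractions are recomputed from the read-count columns; zero-depth
    rows come back with the uncovered flag (``covered`` False) rather than
    being dropped.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise VariantTableError(f"{path}: empty file")
        if tuple(header) != VARIANT_COLUMNS:
            raise VariantTableError(
                f"{path}: unexpected header {header!r}; expected {list(VARIANT_COLUMNS)}"
            )
        calls: list[VariantCall] = []
        for line_no, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            if len(row) != len(VARIANT_COLUMNS):
                raise VariantTableError(
                    f"{path} line {line_no}: {len(row)} fields, expected {len(VARIANT_COLUMNS)}"
                )
            rec = dict(zip(VARIANT_COLUMNS, row))
            try:
                vtype = VariantType(rec["variant_type"])
            except ValueError:
                raise VariantTableError(
                    f"{path} line {line_no}: unknown variant_type token {rec['variant_type']!r}"
                )
            try:
                origin = Origin(rec["origin"]) if rec["origin"] else Origin.unknown
            except ValueError:
                raise VariantTableError(
                    f"{path} line {line_no}: unknown origin token {rec['origin']!r}"
                )
            _validate_hgvs(rec["cdna_change"], line_no)
            bidir_cell = rec["bidirectional"].strip().lower()
            if bidir_cell in ("", "true", "yes", "1"):
                bidirectional = True  # fixtures carry no strand info
            elif bidir_cell in ("false", "no", "0"):
                bidirectional = False
            else:
                raise VariantTableError(
                    f"{path} line {line_no}: bad bidirectional token {rec['bidirectional']!r}"
                )
            calls.append(
                VariantCall(
                    patient_id=rec["patient"],
                    sample_id=rec["sample"],
                    gene=rec["gene"],
                    variant_type=vtype,
                    cdna_change=rec["cdna_change"],
                    protein_change=rec["protein_change"],
                    mutant_reads=_parse_int(rec["mutant_reads"], "mutant_reads", line_no),
                    ref_reads=_parse_int(rec["ref_reads"], "ref_reads", line_no),
                    origin=origin,
                    bidirectional=bidirectional,
                    functional_class=rec["functional_class"],
                    source=rec["source"],
                    printed_af=rec["printed_af"],
                    loh_label=rec["loh"],
                    validation=rec["validation"],
                    notes=rec["notes"],
                )
            )
    return calls


def write_variant_table(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write calls in the canonical TSV format (inverse of the reader)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for c in calls:
            row = (
                c.patient_id,
                c.sample_id,
                c.source,
                c.gene,
                c.variant_type.value,
                c.cdna_change,
                c.protein_change,
                "" if c.mutant_reads is None else str(c.mutant_reads),
                "" if c.ref_reads is None else str(c.ref_reads),
                c.printed_af,
                c.origin.value if c.origin is not Origin.unknown else "",
                "" if c.bidirectional else "false",
                c.loh_label,
                c.functional_class,
                c.validation,
                c.notes,
            )
            fh.write("\t".join(row) + "\n")


SNP_COLUMNS = ("chrom", "pos", "normal_ref", "normal_alt", "tumor_ref", "tumor_alt")


def read_snp_track(path: str | Path, paired: bool = True) -> list[SnpObservation]:
    """Read a per-SNP allele-count TSV, sorted and checked per chromosome.

    Positions must be strictly increasing within each chromosome.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header) != SNP_COLUMNS:
            raise VariantTableError(f"{path}: unexpected SNP header {header!r}")
        snps = []
        last: dict[str, int] = {}
        for line_no, row in enumerate(reader, start=2):
            chrom, pos, nr, na, tr, ta = row
            pos = int(pos)
            if chrom in last and pos <= last[chrom]:
                raise VariantTableError(
                    f"{path} line {line_no}: positions not strictly increasing on {chrom}"
                )
            last[chrom] = pos
            snps.append(
                SnpObservation(chrom, pos, int(nr), int(na), int(tr), int(ta), paired=paired)
            )
    return snps


def write_snp_track(snps: Sequence[SnpObservation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write("\t".join(SNP_COLUMNS) + "\n")
        for s in snps:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.normal_ref}\t{s.normal_alt}\t{s.tumor_ref}\t{s.tumor_alt}\n"
            )


# ---------------------------------------------------------------------------
# variant-call review filter


@dataclass(frozen=True)
class RejectedCall:
    call: VariantCall
    reason: str


def filter_variant_calls(
    calls: Iterable[VariantCall],
    min_alt_reads: int = 3,
    min_af: float = 0.05,
) -> tuple[list[VariantCall], list[RejectedCall]]:
    """Apply the variant-review filters.

    A call is rejected iff it is uncovered, has fewer than ``min_alt_reads``
    variant reads, lacks bidirectional read support, or has allele fraction
    below ``min_af``.  Boundaries are inclusive: exactly ``min_alt_reads``
    variant reads, or AF exactly ``min_af``, is kept.  Genomic deletions are
    not read-count calls and pass through untouched.
    """
    kept: list[VariantCall] = []
    rejected: list[RejectedCall] = []
    for call in calls:
        if call.variant_type is VariantType.genomic_del:
            kept.append(call)
            continue
        if not call.covered:
            rejected.append(RejectedCall(call, "no coverage"))
        elif call.mutant_reads < min_alt_reads:
            rejected.append(RejectedCall(call, f"variant reads < {min_alt_reads}"))
        elif not call.bidirectional:
            rejected.append(RejectedCall(call, "reads in one direction only"))
        elif call.af < min_af:
            rejected.append(RejectedCall(call, f"allele fraction < {min_af}"))
        else:
            kept.append(call)
    return kept, rejected


# ---------------------------------------------------------------------------
# packaged fixtures

_DATA_PACKAGE = "secondhit.data"
TABLE1_FILE = "table1_tsc_variants.tsv"
TABLE2_FILE = "table2_other_somatic.tsv"
P13_LOH_ANNOTATION_FILE = "synthetic_p13_loh_regions.tsv"


def _data_path(name: str) -> Path:
    return Path(resources.files(_DATA_PACKAGE) / name)


def _verify_checksums() -> None:
    sums = json.loads(_data_path("checksums.json").read_text())
    for name, expected in sums.items():
        got = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
        if got != expected:
            raise FixtureIntegrityError(f"fixture {name}: checksum mismatch")


def _mark_duplicates(calls: list[VariantCall]) -> None:
    seen: set[tuple] = set()
    for call in calls:
        ident = (call.sample_id, *call.key())
        if ident in seen:
            call.duplicate = True
        seen.add(ident)


@dataclass(frozen=True)
class FixtureBundle:
    """The packaged study tables plus per-sample annotations."""

    tsc_calls: list[VariantCall]  # TSC1/TSC2 findings, one row per printed row
    other_calls: list[VariantCall]  # somatic non-TSC coding calls (23 pairs)
    loh_annotations: dict[str, str]  # sample -> "Yes"/"No"/"2-hit"/"9q LOH"/"NA"
    tsc_patients: frozenset[str]  # patients with a TSC diagnosis
    paired_samples: tuple[str, ...]  # samples with a matched normal
    p13_loh_region_ids: dict[str, tuple[str, bool]]  # sample -> (region id, uncertain)

    @property
    def samples(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.tsc_calls:
            seen.setdefault(c.sample_id, None)
        return tuple(seen)

    @property
    def patients(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.tsc_calls:
            seen.setdefault(c.patient_id, None)
        return tuple(seen)

    def tsc_label(self, sample_id: str) -> str:
        """'TSC' or 'sporadic' for a specimen, from the diagnosis notes."""
        patient = next(c.patient_id for c in self.tsc_calls if c.sample_id == sample_id)
        return "TSC" if patient in self.tsc_patients else "sporadic"


def load_fixtures(verify: bool = True) -> FixtureBundle:
    """Load the packaged transcriptions of the study's variant tables.

    Returns all 32 specimens from 15 patients.  Literal duplicate rows
    (the repeated THBS3 call in S7) are retained but flagged ``duplicate``.
    """
    if verify:
        _verify_checksums()
    tsc_calls = read_variant_table(_data_path(TABLE1_FILE))
    other_calls = read_variant_table(_data_path(TABLE2_FILE))
    _mark_duplicates(other_calls)

    loh: dict[str, str] = {}
    tsc_patients: set[str] = set()
    paired: list[str] = []
    for c in tsc_calls:
        if c.loh_label and c.sample_id not in loh:
            loh[c.sample_id] = c.loh_label
        note_tokens = {t.strip() for t in c.notes.replace(";", ",").split(",")}
        if "TSC" in note_tokens:
            tsc_patients.add(c.patient_id)
        if c.sample_id not in paired:
            paired.append(c.sample_id)
    # samples flagged "no normal" have no matched normal; the rest are pairs
    unpaired = {
        c.sample_id for c in tsc_calls if "no normal" in c.notes
    }
    paired = [s for s in paired if s not in unpaired]

    ann_path = _data_path(P13_LOH_ANNOTATION_FILE)
    region_ids: dict[str, tuple[str, bool]] = {}
    with ann_path.open(newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            region_ids[rec["sample"]] = (rec["region_id"], rec["uncertain"] == "yes")

    return FixtureBundle(
        tsc_calls=tsc_calls,
        other_calls=other_calls,
        loh_annotations=loh,
        tsc_patients=frozenset(tsc_patients),
        paired_samples=tuple(paired),
        p13_loh_region_ids=region_ids,
    )


# ---------------------------------------------------------------------------
# optional VCF import


def variants_from_vcf(
    path: str | Path,
    sample: str,
    patient: str = "",
    origin: Origin = Origin.unknown,
) -> list[VariantCall]:
    """Import calls from a VCF 4.x file using the standard AD format field.

    Uses cyvcf2 when available, falling back to a minimal text parse of
    uncompressed VCF otherwise.  Only the first ALT allele is read.
    """
    path = Path(path)
    calls: list[VariantCall] = []
    try:
        from cyvcf2 import VCF  # optional dependency

        vcf = VCF(str(path))
        try:
            idx = vcf.samples.index(sample)
        except ValueError:
            raise VariantTableError(f"{path}: sample {sample!r} not in VCF")
        for rec in vcf:
            ad = rec.format("AD")
            if ad is None:
                continue
            ref_d, alt_d = int(ad[idx][0]), int(ad[idx][1])
            gene = dict(rec.INFO).get("GENE", "")
            calls.append(
                VariantCall(
                    patient_id=patient,
                    sample_id=sample,
                    gene=str(gene),
                    variant_type=VariantType.unknown,
                    cdna_change=f"c.{rec.POS}{rec.REF}>{rec.ALT[0]}" if rec.ALT else "NA",
                    mutant_reads=alt_d,
                    ref_reads=ref_d,
                    origin=origin,
                )
            )
        return calls
    except ImportError:
        pass

    with path.open(encoding="utf-8") as fh:
        sample_idx = None
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                try:
                    sample_idx = fields.index(sample)
                except ValueError:
                    raise VariantTableError(f"{path}: sample {sample!r} not in VCF")
                continue
            if sample_idx is None:
                raise VariantTableError(f"{path}: missing #CHROM header")
            fmt = fields[8].split(":")
            if "AD" not in fmt:
                continue
            ad = fields[sample_idx].split(":")[fmt.index("AD")].split(",")
            ref_d, alt_d = int(ad[0]), int(ad[1])
            info = dict(
                kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv
            )
            calls.append(
                VariantCall(
                    patient_id=patient,
                    sample_id=sample,
                    gene=info.get("GENE", ""),
                    variant_type=VariantType.unknown,
                    cdna_change=f"c.{fields[1]}{fields[3]}>{fields[4]}",
                    mutant_reads=alt_d,
                    ref_reads=ref_d,
                    origin=origin,
                )
            )
    return calls
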