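"""Copy-neutral LOH mapping from SNP allele fractions.

The mapping follows the B-allele-frequency logic used for exome data:

1. select germline heterozygous SNPs in the matched normal (depth > 19,
   normal AF in [0.40, 0.60]);
2. call each selected SNP *skewed* in the tumor when its tumor AF leaves the
   open interval (0.40, 0.60);
3. delineate maximal runs of skewed SNPs into LOH regions, with a confident
   span from the first to the last skewed SNP and uncertainty flanks
   extending to the nearest normal-AF SNP on each side (regions reaching the
   start of the observed track are flagged telomere-anchored — mitotic
   recombination produces LOH running from the telomere to the crossover
   breakpoint);
4. assess copy-neutrality of each region from windowed tumor/normal depth
   ratios, which also drive homozygous-deletion detection.

Thresholds are configuration with documented defaults; boundary AFs of
exactly 0.40/0.60 are assigned to "normal" (both the skewed and the normal
definition use strict inequalities there, and the conservative choice makes
fewer false LOH calls).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from statistics import median
from typing import Iterable, Sequence

from .variant_io import SnpObservation

__all__ = [
    "CopyStatus",
    "LohRegion",
    "CoverageWindow",
    "DeletionInterval",
    "SkewCall",
    "identify_het_snps",
    "identify_candidate_snps_unpaired",
    "call_skew",
    "delineate_loh_regions",
    "unassigned_skewed_snps",
    "assess_copy_neutrality",
    "detect_homozygous_deletion",
]


class CopyStatus(str, Enum):
    neutral = "neutral"
    single_loss = "single_loss"
    homozygous_loss = "homozygous_loss"
    gain = "gain"
    indeterminate = "indeterminate"


class SkewCall(str, Enum):
    skewed = "skewed"
    normal = "normal"


@dataclass
class LohRegion:
    """A delineated LOH interval (1-based inclusive coordinates).

    The confident span runs from the first to the last skewed SNP; the
    uncertainty flanks extend to the nearest flanking normal-AF SNP (or the
    track end).  The true recombination breakpoint lies somewhere inside the
    flank beyond the confident span.
    """

    chrom: str
    confident_start: int
    confident_end: int
    uncertain_start: int
    uncertain_end: int
    n_skewed: int
    n_discordant_interior: int = 0
    copy_status: CopyStatus = CopyStatus.indeterminate
    telomere_anchored: bool = False

    def __post_init__(self) -> None:
        if not (
            self.uncertain_start <= self.confident_start
            <= self.confident_end <= self.uncertain_end
        ):
            raise ValueError(f"inconsistent region bounds on {self.chrom}")

    @property
    def confident_width(self) -> int:
        return self.confident_end - self.confident_start + 1

    def spans(self, chrom: str, start: int, end: int) -> bool:
        """Whether the confident span covers the [start, end] locus."""
        return (
            chrom == self.chrom
            and self.confident_start <= start
            and end <= self.confident_end
        )


def identify_het_snps(
    track: Sequence[SnpObservation],
    min_depth: int = 20,
    af_low: float = 0.40,
    af_high: float = 0.60,
) -> list[SnpObservation]:
    """Germline heterozygous SNPs: normal depth > 19, normal AF in [0.40, 0.60].

    ``min_depth`` is the smallest acceptable depth (the classical filter
    "depth > 19" expressed inclusively).  Bounds on the AF are inclusive.
    """
    if any(not s.paired for s in track):
        raise ValueError(
            "track has unpaired observations; use identify_candidate_snps_unpaired"
        )
    kept = []
    for s in track:
        if s.normal_depth < min_depth:
            continue
        af = s.normal_af
        if af is not None and af_low <= af <= af_high:
            kept.append(s)
    return kept


def identify_candidate_snps_unpaired(
    track: Sequence[SnpObservation],
    af_low: float = 0.05,
    af_high: float = 0.95,
) -> list[SnpObservation]:
    """Likely-SNP sites in a tumor without matched normal: tumor AF in [0.05, 0.95]."""
    kept = []
    for s in track:
        af = s.tumor_af
        if af is not None and af_low <= af <= af_high:
            kept.append(s)
    return kept


def call_skew(
    snp: SnpObservation, af_low: float = 0.40, af_high: float = 0.60
) -> SkewCall:
    """Skewed iff tumor AF < af_low or > af_high (strict); boundary is normal."""
    af = snp.tumor_af
    if af is None:
        raise ValueError(f"zero tumor depth at {snp.chrom}:{snp.pos}")
    return SkewCall.skewed if (af < af_low or af > af_high) else SkewCall.normal


def _skew_calls(
    snps: Sequence[SnpObservation], af_low: float, af_high: float
) -> tuple[list[SnpObservation], list[SkewCall]]:
    usable, calls = [], []
    dropped = 0
    for s in snps:
        if s.tumor_depth == 0:
            dropped += 1
            continue
        usable.append(s)
        calls.append(call_skew(s, af_low, af_high))
    if dropped:
        warnings.warn(f"dropped {dropped} zero-tumor-depth site(s)", stacklevel=3)
    return usable, calls


def delineate_loh_regions(
    snps: Sequence[SnpObservation],
    min_skewed: int = 10,
    max_interior_discordant_frac: float = 0.1,
    af_low: float = 0.40,
    af_high: float = 0.60,
) -> list[LohRegion]:
    """Delineate LOH regions from skew calls on one chromosome.

    Maximal runs of skewed SNPs are grown greedily; isolated normal-AF SNPs
    inside a run do not split it as long as they remain at most
    ``max_interior_discordant_frac`` of the SNPs in the confident span.
    Runs with fewer than ``min_skewed`` skewed SNPs are discarded (their
    sites can be listed with :func:`unassigned_skewed_snps`).
    """
    if not snps:
        return []
    chroms = {s.chrom for s in snps}
    if len(chroms) > 1:
        raise ValueError("delineate_loh_regions expects a single-chromosome track")
    usable, calls = _skew_calls(snps, af_low, af_high)
    if not usable:
        return []
    if any(b.pos <= a.pos for a, b in zip(usable, usable[1:])):
        raise ValueError("SNPs must be sorted by strictly increasing position")

    # atomic runs of consecutive skewed SNPs ...
    runs: list[tuple[int, int, int, int]] = []  # (first_skew, last_skew, n_skew, n_interior)
    start = None
    for i, call in enumerate(calls):
        if call is SkewCall.skewed:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1, i - start, 0))
            start = None
    if start is not None:
        runs.append((start, len(calls) - 1, len(calls) - start, 0))

    # ... merged greedily while interior normal-AF SNPs stay below the cap.
    # Short skewed runs never drive a merge: at a per-site false-skew rate q
    # of a few percent, chance runs of 1-2 adjacent skewed SNPs are expected
    # on every track (O(n*q^2) doubles), and letting them extend a region
    # drags its boundary past the true breakpoint; chance triples (O(n*q^3))
    # are negligible.  Sub-threshold runs are left out and reportable via
    # unassigned_skewed_snps.
    min_run_to_merge = 3
    changed = True
    while changed:
        changed = False
        merged: list[tuple[int, int, int, int]] = []
        for run in runs:
            if not merged:
                merged.append(run)
                continue
            a0, a1, a_skew, a_int = merged[-1]
            b0, b1, b_skew, b_int = run
            gap = b0 - a1 - 1
            new_int = a_int + b_int + gap
            new_total = (b1 - a0 + 1)
            if (
                a_skew >= min_run_to_merge
                and b_skew >= min_run_to_merge
                and new_int / new_total <= max_interior_discordant_frac
            ):
                merged[-1] = (a0, b1, a_skew + b_skew, new_int)
                changed = True
            else:
                merged.append(run)
        runs = merged

    regions = []
    for first, last, n_skew, n_interior in runs:
        if n_skew < min_skewed:
            continue
        prev_normal = next(
            (usable[j].pos for j in range(first - 1, -1, -1) if calls[j] is SkewCall.normal),
            None,
        )
        next_normal = next(
            (usable[j].pos for j in range(last + 1, len(usable)) if calls[j] is SkewCall.normal),
            None,
        )
        regions.append(
            LohRegion(
                chrom=usable[0].chrom,
                confident_start=usable[first].pos,
                confident_end=usable[last].pos,
                uncertain_start=prev_normal if prev_normal is not None else usable[0].pos,
                uncertain_end=next_normal if next_normal is not None else usable[-1].pos,
                n_skewed=n_skew,
                n_discordant_interior=n_interior,
                telomere_anchored=prev_normal is None,
            )
        )
    return regions


def unassigned_skewed_snps(
    snps: Sequence[SnpObservation],
    regions: Sequence[LohRegion],
    af_low: float = 0.40,
    af_high: float = 0.60,
) -> list[SnpObservation]:
    """Skewed SNPs not inside any region's confident span (sub-threshold runs)."""
    usable, calls = _skew_calls(snps, af_low, af_high)
    out = []
    for s, c in zip(usable, calls):
        if c is not SkewCall.skewed:
            continue
        if not any(r.confident_start <= s.pos <= r.confident_end for r in regions):
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# copy-number assessment from windowed depth ratios


@dataclass(frozen=True)
class CoverageWindow:
    """Tumor/normal depth ratio over one genomic window, 1.0 = diploid."""

    chrom: str
    start: int
    end: int
    ratio: float

    @property
    def log2(self) -> float:
        if self.ratio <= 0:
            return -math.inf
        return math.log2(self.ratio)


@dataclass(frozen=True)
class DeletionInterval:
    chrom: str
    start: int
    end: int
    status: CopyStatus
    n_windows: int
    low_confidence: bool = False


_HOM_LOG2 = -1.5  # ≈ 0.35 of diploid coverage; a deep, two-allele depression


def _classify_log2(value: float, log2_tolerance: float) -> CopyStatus:
    if value <= _HOM_LOG2:
        return CopyStatus.homozygous_loss
    if value <= -log2_tolerance:
        return CopyStatus.single_loss
    if value >= log2_tolerance:
        return CopyStatus.gain
    return CopyStatus.neutral


def assess_copy_neutrality(
    region: LohRegion,
    coverage_ratios: Iterable[CoverageWindow],
    log2_tolerance: float = 0.3,
    min_windows: int = 5,
) -> CopyStatus:
    """Classify a region's copy state from the median windowed log2 ratio.

    Fewer than ``min_windows`` overlapping windows yields ``indeterminate``.
    The region's ``copy_status`` field is updated in place and returned.
    """
    overlapping = [
        w.log2
        for w in coverage_ratios
        if w.chrom == region.chrom
        and w.end >= region.confident_start
        and w.start <= region.confident_end
    ]
    if len(overlapping) < min_windows:
        status = CopyStatus.indeterminate
    else:
        status = _classify_log2(median(overlapping), log2_tolerance)
    region.copy_status = status
    return status


def detect_homozygous_deletion(
    windows: Sequence[CoverageWindow],
    log2_tolerance: float = 0.3,
) -> list[DeletionInterval]:
    """Find deletion intervals in a sorted window track.

    Maximal runs of windows at or below the single-loss threshold become
    intervals; runs of windows at or below the homozygous threshold nested
    inside them are reported as separate homozygous intervals, so a focal
    two-allele deletion inside a broader one-allele loss yields two nested
    intervals.  A run of a single window is flagged low-confidence.
    """
    if any(b.start <= a.start for a, b in zip(windows, windows[1:])):
        raise ValueError("coverage windows must be sorted by start position")

    lost = [
        _classify_log2(w.log2, log2_tolerance)
        in (CopyStatus.single_loss, CopyStatus.homozygous_loss)
        for w in windows
    ]
    hom = [w.log2 <= _HOM_LOG2 for w in windows]

    def runs(mask: list[bool]) -> list[tuple[int, int]]:
        out, start = [], None
        for i, flag in enumerate(mask):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                out.append((start, i - 1))
                start = None
        if start is not None:
            out.append((start, len(mask) - 1))
        return out

    intervals: list[DeletionInterval] = []
    for a, b in runs(lost):
        hom_runs = [(h0, h1) for h0, h1 in runs(hom) if a <= h0 and h1 <= b]
        envelope_is_hom = len(hom_runs) == 1 and hom_runs[0] == (a, b)
        status = CopyStatus.homozygous_loss if envelope_is_hom else CopyStatus.single_loss
        intervals.append(
            DeletionInterval(
                chrom=windows[a].chrom,
                start=windows[a].start,
                end=windows[b].end,
                status=status,
                n_windows=b - a + 1,
                low_confidence=(b == a),
            )
        )
        if not envelope_is_hom:
            for h0, h1 in hom_runs:
                intervals.append(
                    DeletionInterval(
                        chrom=windows[h0].chrom,
                        start=windows[h0].start,
                        end=windows[h1].end,
                        status=CopyStatus.homozygous_loss,
                        n_windows=h1 - h0 + 1,
                        low_confidence=(h1 == h0),
                    )
                )
    return intervals
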