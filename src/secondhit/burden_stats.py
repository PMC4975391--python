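"""Somatic mutation burden, spectrum, subclonality, and the mechanism contingency.

Burden is counted over tumor–normal pairs only, excluding the driver locus
genes themselves, and normalised by the exome capture territory (33 Mb by
default) using the cohort median — i.e. rate = median / territory.

Two denominators coexist deliberately: the raw per-specimen *call count*
(shared mutations counted once per specimen carrying them) and the
patient-level *unique-mutation set* (a mutation shared by several specimens
of one patient counts once; identical changes in different patients stay
separate).  Published cohort summaries mix the two, so both are computed and
labelled rather than reconciled.
"""

from __future__ import annotations

import math

import numpy as np
from dataclasses import dataclass
from statistics import median as _median
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .tsc_status import SampleStatus
from .variant_io import Origin, VariantCall

__all__ = [
    "BurdenSummary",
    "count_nonsyn_per_sample",
    "dedup_unique_mutations",
    "burden_summary",
    "subclonal_tally",
    "mechanism_contingency",
    "fisher_exact_two_sided",
]

DEFAULT_TERRITORY_MB = 33.0
_EXCLUDE_GENES = frozenset({"TSC1", "TSC2"})


def _countable(call: VariantCall, exclude_genes: frozenset[str]) -> bool:
    return (
        call.covered
        and call.origin is not Origin.germline
        and call.gene not in exclude_genes
    )


def count_nonsyn_per_sample(
    calls: Iterable[VariantCall],
    paired_samples: Sequence[str],
    exclude_genes: frozenset[str] = _EXCLUDE_GENES,
) -> dict[str, int]:
    """Somatic non-driver coding calls per tumor–normal pair.

    Uncovered rows are excluded; literal duplicate rows are *retained* here
    (each printed call row counts), matching the per-specimen arithmetic of
    the source tables.  Paired samples without any call count as zero.
    """
    counts = {s: 0 for s in paired_samples}
    for call in calls:
        if not _countable(call, exclude_genes):
            continue
        if call.sample_id in counts:
            counts[call.sample_id] += 1
    return counts


def dedup_unique_mutations(
    calls: Iterable[VariantCall],
    exclude_genes: frozenset[str] = _EXCLUDE_GENES,
) -> dict[tuple[str, str, str], list[VariantCall]]:
    """Patient-level unique mutations: key (patient, gene, cDNA) -> its calls.

    A mutation shared by several specimens of one patient collapses to one
    key; identical changes in different patients remain distinct; literal
    duplicate rows within one specimen collapse.
    """
    unique: dict[tuple[str, str, str], list[VariantCall]] = {}
    seen_rows: set[tuple[str, str, str, str]] = set()
    for call in calls:
        if not _countable(call, exclude_genes):
            continue
        row_id = (call.sample_id, call.gene, call.cdna_change, call.protein_change)
        if row_id in seen_rows:
            continue  # literal duplicate row
        seen_rows.add(row_id)
        unique.setdefault((call.patient_id, call.gene, call.cdna_change), []).append(call)
    return unique


@dataclass(frozen=True)
class BurdenSummary:
    per_sample_counts: dict[str, int]
    median: float
    range: tuple[int, int]
    territory_mb: float
    rate_per_mb: float
    rate_range_per_mb: tuple[float, float]
    unique_mutations: int
    call_count: int
    spectrum: dict[str, tuple[int, float]]  # variant_type -> (count, fraction of unique)
    subclonal: dict[str, dict[float, float]]  # denominator -> {threshold: fraction}

    def to_dict(self) -> dict:
        return {
            "per_sample_counts": self.per_sample_counts,
            "median": self.median,
            "range": list(self.range),
            "territory_mb": self.territory_mb,
            "rate_per_mb": self.rate_per_mb,
            "rate_range_per_mb": list(self.rate_range_per_mb),
            "unique_mutations": self.unique_mutations,
            "call_count": self.call_count,
            "spectrum": {k: list(v) for k, v in self.spectrum.items()},
            "subclonal": {
                k: {str(t): f for t, f in v.items()} for k, v in self.subclonal.items()
            },
        }


def subclonal_tally(
    calls: Sequence[VariantCall],
    thresholds: Sequence[float] = (0.15, 0.10),
    denominator: str = "calls",
    exclude_genes: frozenset[str] = _EXCLUDE_GENES,
) -> dict[float, tuple[int, int, float]]:
    """Fraction of mutations with allele fraction strictly below each threshold.

    ``denominator`` is either ``"calls"`` (every covered call row) or
    ``"unique"`` (patient-level unique mutations, each represented by the
    mean AF over its calls).  Returns {threshold: (count, denom, fraction)}.
    """
    if denominator == "calls":
        afs = [c.af for c in calls if _countable(c, exclude_genes)]
    elif denominator == "unique":
        unique = dedup_unique_mutations(calls, exclude_genes)
        afs = [
            sum(c.af for c in group) / len(group) for group in unique.values()
        ]
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    n = len(afs)
    out = {}
    for t in thresholds:
        k = sum(1 for af in afs if af < t)
        out[t] = (k, n, k / n if n else 0.0)
    return out


def burden_summary(
    calls: Sequence[VariantCall],
    paired_samples: Sequence[str],
    territory_mb: float = DEFAULT_TERRITORY_MB,
    exclude_genes: frozenset[str] = _EXCLUDE_GENES,
) -> BurdenSummary:
    """Full burden summary over the tumor–normal pairs."""
    counts = count_nonsyn_per_sample(calls, paired_samples, exclude_genes)
    if not counts:
        raise ValueError("no paired samples to summarise")
    values = list(counts.values())
    med = float(_median(values))
    lo, hi = min(values), max(values)
    unique = dedup_unique_mutations(calls, exclude_genes)

    spectrum_counts: dict[str, int] = {}
    for group in unique.values():
        vt = group[0].variant_type.value
        spectrum_counts[vt] = spectrum_counts.get(vt, 0) + 1
    n_unique = len(unique)
    spectrum = {
        vt: (k, k / n_unique if n_unique else 0.0)
        for vt, k in sorted(spectrum_counts.items())
    }

    call_count = sum(values)
    sub = {
        denom: {t: frac for t, (_, _, frac) in subclonal_tally(
            calls, (0.15, 0.10), denom, exclude_genes).items()}
        for denom in ("calls", "unique")
    }
    return BurdenSummary(
        per_sample_counts=counts,
        median=med,
        range=(lo, hi),
        territory_mb=territory_mb,
        rate_per_mb=med / territory_mb,
        rate_range_per_mb=(lo / territory_mb, hi / territory_mb),
        unique_mutations=n_unique,
        call_count=call_count,
        spectrum=spectrum,
        subclonal=sub,
    )


# ---------------------------------------------------------------------------
# mechanism contingency and Fisher's exact test


def mechanism_contingency(
    statuses: Mapping[str, SampleStatus],
    tsc_labels: Mapping[str, str],
) -> list[list[int]]:
    """2x2 table of two-event mechanisms by cohort.

    Rows are cohorts (sporadic, TSC); columns are mechanism classes
    (two-event — both hits discrete mutations/deletions — versus other).
    """
    table = [[0, 0], [0, 0]]
    for sample_id, status in statuses.items():
        if sample_id not in tsc_labels:
            raise ValueError(f"missing TSC/sporadic label for {sample_id}")
        label = tsc_labels[sample_id]
        if label not in ("sporadic", "TSC"):
            raise ValueError(f"bad label {label!r} for {sample_id}")
        row = 0 if label == "sporadic" else 1
        col = 0 if status.two_event else 1
        table[row][col] += 1
    return table


def fisher_exact_two_sided(table: Sequence[Sequence[int]], method: str = "point") -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    ``point`` (conventional): with margins fixed, sum the hypergeometric
    probabilities of every outcome no more likely than the observed one,
    accumulated in log space.  ``doubling``: twice the smaller one-sided
    tail, capped at 1.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    k_lo = max(0, row1 + col1 - n)
    k_hi = min(row1, col1)
    support = np.arange(k_lo, k_hi + 1)
    logp = hypergeom.logpmf(support, n, col1, row1)
    log_obs = logp[a - k_lo]
    eps = 1e-7  # tolerate roundoff when comparing equal point probabilities
    if method == "point":
        selected = logp[logp <= log_obs + eps]
        m = selected.max()
        total = math.exp(m) * float(np.exp(selected - m).sum())
        return min(1.0, total)
    if method == "doubling":
        lower = float(np.exp(logp[support <= a]).sum())
        upper = float(np.exp(logp[support >= a]).sum())
        return min(1.0, 2.0 * min(lower, upper))
    raise ValueError(f"unknown method {method!r}")
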