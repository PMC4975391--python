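"""Closed-form purity ⇄ allele-fraction relationships under copy-neutral LOH.

A tumor specimen is modelled as a two-component mixture: a fraction ``p``
(the purity) of diploid tumor cells and ``1 - p`` of diploid normal cells.
Copy-neutral LOH via mitotic recombination leaves every cell with exactly two
copies, so the expected allele fraction of a variant is simply

    E[AF] = (p * m_t + (1 - p) * m_n) / 2

where ``m_t`` and ``m_n`` are the mutant copy numbers in tumor and normal
cells.  The five genotype configurations of interest:

==============================  ====  ====  =============
configuration                   m_t   m_n   E[AF]
==============================  ====  ====  =============
germline het, no LOH             1     1    1/2 (constant)
germline het, CN-LOH retained    2     1    (1 + p) / 2
germline het, CN-LOH lost        0     1    (1 - p) / 2
somatic het, no LOH              1     0    p / 2
somatic, CN-LOH (homozygous)     2     0    p
==============================  ====  ====  =============

All maps except the first are strictly monotone in ``p`` and invert in closed
form, giving a single-variant purity estimate with a binomial confidence
interval pushed through the inverse.  This assumes the event is clonal
(cancer cell fraction 1); subclonal events dilute AF further and would bias
the estimate downward.  Non-copy-neutral states are rejected explicitly:
the cohort this package models showed no chromosomal gains or losses apart
from the events at the two loci of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from scipy.stats import beta as _beta

__all__ = [
    "GenotypeLabel",
    "GenotypeModel",
    "PurityEstimate",
    "MODELS",
    "expected_af",
    "estimate_purity",
]


class GenotypeLabel(str, Enum):
    germline_het_no_loh = "germline_het_no_loh"
    germline_het_cnloh_retained = "germline_het_cnloh_retained"
    germline_het_cnloh_lost = "germline_het_cnloh_lost"
    somatic_het_no_loh = "somatic_het_no_loh"
    somatic_cnloh = "somatic_cnloh"


@dataclass(frozen=True)
class GenotypeModel:
    """Mutant copy configuration of one variant; copy-neutral throughout."""

    label: GenotypeLabel
    mutant_copies_tumor: int
    mutant_copies_normal: int
    total_copies_tumor: int = 2

    def __post_init__(self) -> None:
        if self.total_copies_tumor != 2:
            raise ValueError(
                "only copy-neutral states (2 tumor copies) are modelled; "
                f"got total_copies_tumor={self.total_copies_tumor}"
            )
        if not 0 <= self.mutant_copies_tumor <= self.total_copies_tumor:
            raise ValueError("mutant_copies_tumor out of range")
        if self.mutant_copies_normal not in (0, 1):
            raise ValueError("mutant_copies_normal must be 0 (somatic) or 1 (germline het)")

    @property
    def slope(self) -> float:
        """d E[AF] / d purity."""
        return (self.mutant_copies_tumor - self.mutant_copies_normal) / 2.0

    @property
    def informative(self) -> bool:
        """Whether E[AF] depends on purity at all."""
        return self.slope != 0.0


MODELS: dict[GenotypeLabel, GenotypeModel] = {
    GenotypeLabel.germline_het_no_loh: GenotypeModel(GenotypeLabel.germline_het_no_loh, 1, 1),
    GenotypeLabel.germline_het_cnloh_retained: GenotypeModel(
        GenotypeLabel.germline_het_cnloh_retained, 2, 1
    ),
    GenotypeLabel.germline_het_cnloh_lost: GenotypeModel(
        GenotypeLabel.germline_het_cnloh_lost, 0, 1
    ),
    GenotypeLabel.somatic_het_no_loh: GenotypeModel(GenotypeLabel.somatic_het_no_loh, 1, 0),
    GenotypeLabel.somatic_cnloh: GenotypeModel(GenotypeLabel.somatic_cnloh, 2, 0),
}


def _as_model(model: GenotypeModel | GenotypeLabel | str) -> GenotypeModel:
    if isinstance(model, GenotypeModel):
        return model
    return MODELS[GenotypeLabel(model)]


def expected_af(model: GenotypeModel | GenotypeLabel | str, purity: float) -> float:
    """Expected variant allele fraction at the given tumor purity."""
    m = _as_model(model)
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must lie in [0, 1], got {purity}")
    return (purity * m.mutant_copies_tumor + (1.0 - purity) * m.mutant_copies_normal) / 2.0


@dataclass(frozen=True)
class PurityEstimate:
    purity: float
    model: GenotypeModel
    af_observed: float
    ci_low: float
    ci_high: float
    clipped: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.purity <= self.ci_high + 1e-12):
            raise ValueError("purity outside its confidence interval")


def _invert(m: GenotypeModel, af: float) -> float:
    # E[AF] = slope * p + m_n / 2  =>  p = (af - m_n/2) / slope
    return (af - m.mutant_copies_normal / 2.0) / m.slope


def _clip(p: float) -> tuple[float, bool]:
    if p < 0.0:
        return 0.0, True
    if p > 1.0:
        return 1.0, True
    return p, False


def _binomial_af_ci(af: float, depth: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) interval on the underlying allele fraction."""
    k = round(af * depth)
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(_beta.ppf(alpha / 2, k, depth - k + 1))
    hi = 1.0 if k == depth else float(_beta.ppf(1 - alpha / 2, k + 1, depth - k))
    return lo, hi


def estimate_purity(
    af: float,
    model: GenotypeModel | GenotypeLabel | str,
    depth: int = 0,
    conf: float = 0.95,
) -> PurityEstimate:
    """Invert the genotype model's AF map to a purity estimate.

    The estimate is clipped to [0, 1] (flagged) rather than rejected, since
    sampling noise at modest depth routinely pushes observed AFs slightly
    past the model's range.  With ``depth`` > 0 an exact binomial interval
    on the AF is propagated through the (monotone) inverse map.
    """
    m = _as_model(model)
    if not m.informative:
        raise ValueError(
            f"model {m.label.value} has constant expected AF; uninformative for purity"
        )
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele fraction must lie in [0, 1], got {af}")
    point, clipped = _clip(_invert(m, af))
    if depth > 0:
        af_lo, af_hi = _binomial_af_ci(af, depth, conf)
        p_a, _ = _clip(_invert(m, af_lo))
        p_b, _ = _clip(_invert(m, af_hi))
        ci_low, ci_high = min(p_a, p_b), max(p_a, p_b)
    else:
        ci_low = ci_high = point
    # the clipped point estimate must stay inside the (clipped) interval
    ci_low, ci_high = min(ci_low, point), max(ci_high, point)
    return PurityEstimate(point, m, af, ci_low, ci_high, clipped)
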