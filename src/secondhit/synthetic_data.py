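"""Synthetic paired tumor/normal data with known truth.

Emulates the structures the pipeline is built to detect: germline
heterozygous SNP tracks along a chromosome arm with a telomere-anchored
copy-neutral LOH segment (mitotic recombination running from the telomere to
a breakpoint), overdispersed sequencing depth, configurable tumor purity,
somatic second hits, and multi-tumor patients sharing truncal events.

Read counts are binomial given the genotype's expected allele fraction
(:mod:`secondhit.af_model`); per-site depth is negative-binomial with
variance ``depth_dispersion``x the mean (default 2x, a realistic level of
exome capture unevenness).  Which haplotype the alternate allele sits on is
randomised once per SNP, so inside the LOH segment the skew direction
alternates site to site — the two-sided scatter seen in real B-allele
frequency plots — while its magnitude is set by purity alone.  There is no
read-level error model; sampling noise is the only noise.

Everything is driven by a single integer seed and is bit-for-bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .af_model import GenotypeLabel, expected_af
from .loh_mapper import CoverageWindow
from .variant_io import Origin, SnpObservation, VariantCall, VariantType

__all__ = [
    "SimulationConfig",
    "TumorSpec",
    "TrackTruth",
    "PatientTruth",
    "PatientSimulation",
    "simulate_snp_track",
    "simulate_coverage_windows",
    "simulate_patient",
    "p13_like_config",
    "sporadic_two_hit_config",
    "homozygous_del_config",
]

#: synthetic stand-in for the TSC2 position on the simulated arm (bp)
DEFAULT_LOCUS = (2_095_990, 2_140_713)


@dataclass(frozen=True)
class TumorSpec:
    """Second-hit architecture of one simulated tumor."""

    tumor_id: str
    second_hit: Literal["cnloh", "point_mutation", "homozygous_del", "none"] = "cnloh"
    breakpoint: int | None = None  # LOH spans telomere (pos 1) .. breakpoint
    purity: float | None = None  # None -> drawn from config.purity_range
    group: str | None = None  # truncal-group label; same group => same breakpoint
    n_private: int = 2  # private somatic non-driver mutations


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chrom: str = "16"
    chrom_length: int = 30_000_000
    n_snps: int = 280
    snp_spacing: Literal["uniform", "random"] = "uniform"
    mean_depth: float = 80.0
    depth_dispersion: float = 2.0  # variance / mean of per-site depth
    purity: float = 0.5
    cnloh_breakpoint: int | None = None
    # patient-level architecture
    tumors: tuple[TumorSpec, ...] = ()
    truncal_mutations_shared: dict[str, int] = field(default_factory=dict)
    purity_range: tuple[float, float] = (0.4, 0.7)
    locus: tuple[int, int] = DEFAULT_LOCUS

    def validate(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must lie in [0, 1]")
        if self.cnloh_breakpoint is not None and not (
            0 < self.cnloh_breakpoint < self.chrom_length
        ):
            raise ValueError("cnloh_breakpoint must lie inside the chromosome")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if self.depth_dispersion < 1.0:
            raise ValueError("depth_dispersion must be >= 1 (1 = Poisson)")
        if not 0 <= self.purity_range[0] <= self.purity_range[1] <= 1:
            raise ValueError("invalid purity_range")
        groups = {t.group for t in self.tumors if t.group}
        missing = groups - set(self.truncal_mutations_shared)
        if missing:
            raise ValueError(f"truncal groups without shared-mutation spec: {missing}")


@dataclass(frozen=True)
class TrackTruth:
    chrom: str
    purity: float
    breakpoint: int | None
    positions: tuple[int, ...]
    retained_alt: tuple[bool, ...]  # per SNP: alt allele on the retained haplotype


def _draw_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    if dispersion == 1.0:
        return rng.poisson(mean, n)
    r = mean / (dispersion - 1.0)
    return rng.negative_binomial(r, r / (r + mean), n)


def _positions(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    if cfg.snp_spacing == "uniform":
        step = cfg.chrom_length // (cfg.n_snps + 1)
        return np.arange(1, cfg.n_snps + 1) * step
    pos = np.sort(rng.choice(np.arange(1, cfg.chrom_length), cfg.n_snps, replace=False))
    return pos


def simulate_snp_track(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[SnpObservation], TrackTruth]:
    """One paired tumor/normal SNP allele-count track.

    Every site is a true germline heterozygote.  Inside the LOH segment
    (telomere to ``cnloh_breakpoint``) the tumor draw uses the retained/lost
    copy-neutral genotype according to the site's simulated phase; outside,
    and everywhere when there is no breakpoint, the unaltered heterozygous
    model applies.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    pos = _positions(rng, cfg)
    retained_alt = rng.random(n) < 0.5
    depth_n = _draw_depths(rng, n, cfg.mean_depth, cfg.depth_dispersion)
    depth_t = _draw_depths(rng, n, cfg.mean_depth, cfg.depth_dispersion)

    af_in_loh_retained = expected_af(GenotypeLabel.germline_het_cnloh_retained, cfg.purity)
    af_in_loh_lost = expected_af(GenotypeLabel.germline_het_cnloh_lost, cfg.purity)
    in_loh = (
        pos <= cfg.cnloh_breakpoint
        if cfg.cnloh_breakpoint is not None
        else np.zeros(n, dtype=bool)
    )
    af_t = np.where(
        in_loh, np.where(retained_alt, af_in_loh_retained, af_in_loh_lost), 0.5
    )
    alt_n = rng.binomial(depth_n, 0.5)
    alt_t = rng.binomial(depth_t, af_t)

    snps = [
        SnpObservation(
            chrom=cfg.chrom,
            pos=int(pos[i]),
            normal_ref=int(depth_n[i] - alt_n[i]),
            normal_alt=int(alt_n[i]),
            tumor_ref=int(depth_t[i] - alt_t[i]),
            tumor_alt=int(alt_t[i]),
        )
        for i in range(n)
    ]
    truth = TrackTruth(
        chrom=cfg.chrom,
        purity=cfg.purity,
        breakpoint=cfg.cnloh_breakpoint,
        positions=tuple(int(p) for p in pos),
        retained_alt=tuple(bool(b) for b in retained_alt),
    )
    return snps, truth


def simulate_coverage_windows(
    chrom: str = "16",
    start: int = 2_000_000,
    end: int = 2_250_000,
    window: int = 10_000,
    purity: float = 0.8,
    hom_del: tuple[int, int] | None = None,
    single_loss: tuple[int, int] | None = None,
    noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
) -> list[CoverageWindow]:
    """Windowed tumor/normal depth ratios with optional nested deletions.

    Tumor copy number is 0 inside ``hom_del``, 1 inside ``single_loss``
    (outside the homozygous core), 2 elsewhere; mixing with normal cells at
    the given purity sets the expected ratio, jittered by lognormal noise.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    for w_start in range(start, end, window):
        w_end = min(w_start + window - 1, end)
        mid = (w_start + w_end) // 2
        copies = 2.0
        if hom_del and hom_del[0] <= mid <= hom_del[1]:
            copies = 0.0
        elif single_loss and single_loss[0] <= mid <= single_loss[1]:
            copies = 1.0
        tumor_copies = purity * copies + (1.0 - purity) * 2.0
        ratio = tumor_copies / 2.0 * float(np.exp(rng.normal(0.0, noise_sd)))
        out.append(CoverageWindow(chrom, w_start, w_end, ratio))
    return out


# ---------------------------------------------------------------------------
# patient-level simulation


@dataclass(frozen=True)
class PatientTruth:
    mechanisms: dict[str, str]  # tumor -> mechanism the classifier should find
    groups: tuple[frozenset, ...]  # truncal partition (definite groups only)
    breakpoints: dict[str, int | None]
    truncal_mutations: dict[str, tuple[tuple[str, str], ...]]  # group -> (gene, cdna)
    purities: dict[str, float]


@dataclass(frozen=True)
class PatientSimulation:
    patient_id: str
    tracks: dict[str, list[SnpObservation]]
    track_truths: dict[str, TrackTruth]
    variants: dict[str, list[VariantCall]]  # per tumor, incl. germline driver row
    truth: PatientTruth


_GERMLINE_DRIVER = ("TSC2", "c.1000delA", "p.K334fs", VariantType.frameshift_del)


def _draw_reads(
    rng: np.random.Generator, mean_depth: float, dispersion: float, af: float
) -> tuple[int, int]:
    depth = int(_draw_depths(rng, 1, mean_depth, dispersion)[0])
    depth = max(depth, 1)
    alt = int(rng.binomial(depth, af))
    return alt, depth - alt


def _synthetic_gene(i: int) -> str:
    return f"GENE{i:03d}"


def simulate_patient(
    cfg: SimulationConfig, patient_id: str = "SIM1"
) -> PatientSimulation:
    """Simulate a multifocal patient: per-tumor SNP tracks, variant tables, truth.

    Tumors sharing a ``group`` label share the group's truncal non-driver
    mutations and the same LOH breakpoint; every tumor carries the germline
    driver frameshift plus its own private mutations.
    """
    cfg.validate()
    if not cfg.tumors:
        raise ValueError("patient simulation needs at least one TumorSpec")
    rng = np.random.default_rng(cfg.seed)

    # truncal mutation identities per group
    gene_counter = 0
    truncal: dict[str, list[tuple[str, str]]] = {}
    for group in sorted(cfg.truncal_mutations_shared):
        muts = []
        for _ in range(cfg.truncal_mutations_shared[group]):
            gene_counter += 1
            muts.append((_synthetic_gene(gene_counter), f"c.{100 + gene_counter}A>G"))
        truncal[group] = muts

    group_breakpoints: dict[str, int] = {}
    tracks, track_truths, variants = {}, {}, {}
    mechanisms, breakpoints, purities = {}, {}, {}
    point_counter = 0

    for spec in cfg.tumors:
        purity = (
            spec.purity
            if spec.purity is not None
            else float(rng.uniform(*cfg.purity_range))
        )
        purities[spec.tumor_id] = purity

        if spec.second_hit == "cnloh":
            if spec.group is not None:
                bp = group_breakpoints.setdefault(
                    spec.group,
                    spec.breakpoint
                    if spec.breakpoint is not None
                    else int(rng.integers(cfg.locus[1] + 2_000_000, cfg.chrom_length - 1)),
                )
            else:
                bp = (
                    spec.breakpoint
                    if spec.breakpoint is not None
                    else int(rng.integers(cfg.locus[1] + 2_000_000, cfg.chrom_length - 1))
                )
            mechanisms[spec.tumor_id] = "mutation_plus_cnloh"
        else:
            bp = None
            mechanisms[spec.tumor_id] = {
                "point_mutation": "two_mutation",
                "homozygous_del": "homozygous_deletion",
                "none": "none",
            }[spec.second_hit]
        breakpoints[spec.tumor_id] = bp

        track_cfg = replace(
            cfg,
            seed=int(rng.integers(0, 2**31 - 1)),
            purity=purity,
            cnloh_breakpoint=bp,
            tumors=(),
            truncal_mutations_shared={},
        )
        snps, truth = simulate_snp_track(track_cfg)
        tracks[spec.tumor_id] = snps
        track_truths[spec.tumor_id] = truth

        calls: list[VariantCall] = []
        gene, cdna, prot, vtype = _GERMLINE_DRIVER
        germline_af = (
            expected_af(GenotypeLabel.germline_het_cnloh_retained, purity)
            if bp is not None
            else 0.5
        )
        alt, ref = _draw_reads(rng, cfg.mean_depth, cfg.depth_dispersion, germline_af)
        calls.append(
            VariantCall(
                patient_id=patient_id, sample_id=spec.tumor_id, gene=gene,
                variant_type=vtype, cdna_change=cdna, protein_change=prot,
                mutant_reads=alt, ref_reads=ref, origin=Origin.germline,
            )
        )
        if spec.second_hit == "point_mutation":
            point_counter += 1
            af = expected_af(GenotypeLabel.somatic_het_no_loh, purity)
            alt, ref = _draw_reads(rng, cfg.mean_depth, cfg.depth_dispersion, af)
            calls.append(
                VariantCall(
                    patient_id=patient_id, sample_id=spec.tumor_id, gene="TSC2",
                    variant_type=VariantType.nonsense,
                    cdna_change=f"c.{2000 + point_counter}C>T",
                    protein_change=f"p.Q{600 + point_counter}*",
                    mutant_reads=alt, ref_reads=ref, origin=Origin.somatic,
                )
            )
        shared = truncal.get(spec.group, []) if spec.second_hit == "cnloh" else []
        private = []
        for _ in range(spec.n_private):
            gene_counter += 1
            private.append((_synthetic_gene(gene_counter), f"c.{100 + gene_counter}A>G"))
        for g, c in [*shared, *private]:
            af = expected_af(GenotypeLabel.somatic_het_no_loh, purity)
            alt, ref = _draw_reads(rng, cfg.mean_depth, cfg.depth_dispersion, af)
            calls.append(
                VariantCall(
                    patient_id=patient_id, sample_id=spec.tumor_id, gene=g,
                    variant_type=VariantType.missense, cdna_change=c,
                    protein_change="p.M1V",
                    mutant_reads=alt, ref_reads=ref, origin=Origin.somatic,
                )
            )
        variants[spec.tumor_id] = calls

    groups_by_label: dict[str, set[str]] = {}
    for spec in cfg.tumors:
        if spec.group and spec.second_hit == "cnloh":
            groups_by_label.setdefault(spec.group, set()).add(spec.tumor_id)
    truth = PatientTruth(
        mechanisms=mechanisms,
        groups=tuple(
            frozenset(v) for _, v in sorted(groups_by_label.items()) if len(v) >= 2
        ),
        breakpoints=breakpoints,
        truncal_mutations={g: tuple(m) for g, m in truncal.items()},
        purities=purities,
    )
    return PatientSimulation(patient_id, tracks, track_truths, variants, truth)


# ---------------------------------------------------------------------------
# presets


def p13_like_config(seed: int = 0) -> SimulationConfig:
    """Sixteen tumors from one patient: a 3-tumor truncal group with two
    shared mutations, nine further CN-LOH tumors with distinct breakpoints,
    two point-mutation second hits, and two tumors with no second hit."""
    tumors = []
    for i in range(1, 4):
        tumors.append(TumorSpec(f"T{i:02d}", "cnloh", breakpoint=12_000_000, group="A"))
    # distinct, well-separated breakpoints for the independent CN-LOH tumors
    bps = [6, 8, 10, 14, 16, 18, 20, 22, 24]
    for i, bp in zip(range(4, 13), bps):
        tumors.append(TumorSpec(f"T{i:02d}", "cnloh", breakpoint=bp * 1_000_000))
    tumors.append(TumorSpec("T13", "point_mutation"))
    tumors.append(TumorSpec("T14", "point_mutation"))
    tumors.append(TumorSpec("T15", "none", n_private=0))
    tumors.append(TumorSpec("T16", "none", n_private=0))
    return SimulationConfig(
        seed=seed,
        tumors=tuple(tumors),
        truncal_mutations_shared={"A": 2},
        purity_range=(0.4, 0.7),
    )


def sporadic_two_hit_config(seed: int = 0) -> SimulationConfig:
    """One tumor with two somatic driver variants and no LOH."""
    return SimulationConfig(
        seed=seed,
        tumors=(TumorSpec("T01", "point_mutation", n_private=2),),
    )


def homozygous_del_config() -> dict:
    """Geometry of a focal two-allele deletion nested in a one-allele loss.

    50 kb homozygous core centred on the driver locus inside a 150 kb
    single-copy-loss envelope, at purity 0.8 (a deep, clearly two-allele
    depression, matching the depth of published MLPA/coverage calls).
    """
    centre = (DEFAULT_LOCUS[0] + DEFAULT_LOCUS[1]) // 2
    return {
        "hom_del": (centre - 25_000, centre + 25_000),
        "single_loss": (centre - 75_000, centre + 75_000),
        "purity": 0.8,
        "start": centre - 150_000,
        "end": centre + 150_000,
        "window": 5_000,
    }
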