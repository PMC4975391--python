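"""Clonal-phylogeny reconstruction for multifocal tumors of one patient.

The evidence hierarchy mirrors how multifocal second-hit tumors are
interpreted: two or more *identical somatic point mutations* shared between
specimens establish a common truncal precursor (``definite_shared``);
sharing only an indistinguishable LOH breakpoint is suggestive but not
conclusive (``possible_shared``), because exome SNP density limits boundary
resolution; a specimen with a unique LOH region or a unique second-hit
variant is of ``independent`` clonal origin; and specimens with no
second-hit evidence at all remain ``unresolved``.

The resulting tree is event-set logic, not a molecular-clock phylogeny:
definite groups become internal (truncal) nodes under the germline root,
everything else attaches directly to the root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import dendropy

from .loh_mapper import LohRegion
from .tsc_status import Mechanism, SampleStatus
from .variant_io import Origin, VariantCall

__all__ = [
    "CloneClass",
    "MatchResult",
    "CloneGroup",
    "CloneTree",
    "shared_mutation_groups",
    "loh_boundary_match",
    "matches_from_region_ids",
    "build_clone_tree",
    "export_tree",
    "parse_newick_leaf_sets",
]


class CloneClass(str, Enum):
    definite_shared = "definite_shared"
    possible_shared = "possible_shared"
    independent = "independent"
    unresolved = "unresolved"


class MatchResult(str, Enum):
    same = "same"
    different = "different"
    indeterminate = "indeterminate"


MutationKey = tuple[str, str]  # (gene, cDNA change)


@dataclass(frozen=True)
class CloneGroup:
    samples: frozenset[str]
    shared_mutations: frozenset[MutationKey]
    conflict: bool = False  # mutation-sharing contradicted by LOH boundaries


@dataclass
class CloneTree:
    patient_id: str
    germline_label: str
    groups: list[CloneGroup]
    classes: dict[str, CloneClass]
    private_events: dict[str, list[MutationKey]]
    possible_pairs: list[tuple[str, str, MutationKey]] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return sorted(self.classes)


# ---------------------------------------------------------------------------
# shared-mutation grouping


def _mutation_sets(
    calls: Sequence[VariantCall],
) -> dict[str, set[MutationKey]]:
    """Per-sample sets of somatic non-driver mutation identities."""
    sets: dict[str, set[MutationKey]] = {}
    for c in calls:
        if not c.covered or c.origin is Origin.germline or c.is_tsc:
            continue
        sets.setdefault(c.sample_id, set()).add((c.gene, c.cdna_change))
    return sets


def shared_mutation_groups(
    calls: Sequence[VariantCall],
    min_shared: int = 2,
) -> tuple[list[CloneGroup], list[tuple[str, str, MutationKey]]]:
    """Group a patient's samples by shared somatic mutations.

    Samples sharing at least ``min_shared`` identical mutations are merged
    transitively into groups.  Pairs sharing exactly one mutation are
    reported as *possible* links, never grouped — a single match could be a
    recurrent artifact.  Grouping is independent of input order.
    """
    patients = {c.patient_id for c in calls}
    if len(patients) > 1:
        raise ValueError("shared_mutation_groups expects calls from a single patient")
    sets = _mutation_sets(calls)
    samples = sorted(sets)
    parent = {s: s for s in samples}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    possible: list[tuple[str, str, MutationKey]] = []
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            shared = sets[a] & sets[b]
            if len(shared) >= min_shared:
                parent[find(a)] = find(b)
            elif len(shared) == 1:
                possible.append((a, b, next(iter(shared))))

    components: dict[str, set[str]] = {}
    for s in samples:
        components.setdefault(find(s), set()).add(s)
    groups = []
    for members in components.values():
        if len(members) < 2:
            continue
        shared = set.intersection(*(sets[m] for m in members))
        groups.append(
            CloneGroup(samples=frozenset(members), shared_mutations=frozenset(shared))
        )
    groups.sort(key=lambda g: sorted(g.samples))
    return groups, possible


# ---------------------------------------------------------------------------
# LOH boundary comparison


def _boundary_intervals(r: LohRegion) -> tuple[tuple[float, float], tuple[float, float]]:
    """The intervals known to contain the region's true start and end.

    The true boundary lies between the last concordant (normal-AF) SNP and
    the first skewed SNP, i.e. inside the uncertainty flank.  A missing flank
    (telomere-anchored start, or a region running to the end of the observed
    track) leaves that boundary unbounded.
    """
    start_lo: float = r.uncertain_start
    if r.telomere_anchored or r.uncertain_start == r.confident_start:
        start_lo = -math.inf
    end_hi: float = r.uncertain_end
    if r.uncertain_end == r.confident_end:
        end_hi = math.inf
    return (start_lo, r.confident_start), (r.confident_end, end_hi)


def loh_boundary_match(region_a: LohRegion, region_b: LohRegion) -> MatchResult:
    """Compare two LOH regions at the resolution of their uncertainty flanks.

    ``same``: both start and end boundary intervals overlap — the true
    breakpoints are indistinguishable given the informative SNPs (sparse
    flanking SNPs therefore bias toward ``same``, which is exactly the
    "identical to the resolution limits" reading).  ``different``: at least
    one boundary interval pair is disjoint.  The geometric comparison always
    resolves; ``indeterminate`` arises from annotation-level comparisons
    (:func:`matches_from_region_ids`) where boundaries are not recorded.
    """
    if region_a.chrom != region_b.chrom:
        raise ValueError(
            f"regions on different chromosomes ({region_a.chrom} vs {region_b.chrom})"
        )
    (a_start, a_end) = _boundary_intervals(region_a)
    (b_start, b_end) = _boundary_intervals(region_b)

    def overlap(x: tuple[float, float], y: tuple[float, float]) -> bool:
        return x[0] <= y[1] and y[0] <= x[1]

    if overlap(a_start, b_start) and overlap(a_end, b_end):
        return MatchResult.same
    return MatchResult.different


PairKey = frozenset


def matches_from_region_ids(
    region_ids: Mapping[str, tuple[str, bool]],
) -> dict[frozenset, MatchResult]:
    """Pairwise match verdicts from annotation-level region identities.

    ``region_ids`` maps sample -> (region id, uncertain flag); an empty id or
    an uncertain flag yields ``indeterminate`` against every other sample.
    """
    samples = sorted(region_ids)
    out: dict[frozenset, MatchResult] = {}
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            id_a, unc_a = region_ids[a]
            id_b, unc_b = region_ids[b]
            if unc_a or unc_b or not id_a or not id_b:
                out[frozenset((a, b))] = MatchResult.indeterminate
            elif id_a == id_b:
                out[frozenset((a, b))] = MatchResult.same
            else:
                out[frozenset((a, b))] = MatchResult.different
    return out


# ---------------------------------------------------------------------------
# tree construction


def build_clone_tree(
    patient_id: str,
    statuses: Mapping[str, SampleStatus],
    mutation_calls: Sequence[VariantCall],
    loh_matches: Mapping[frozenset, MatchResult] | None = None,
    germline_label: str = "",
    min_shared: int = 2,
) -> CloneTree:
    """Assemble the patient-level clone tree from all evidence layers.

    ``statuses`` covers every specimen of the patient; ``mutation_calls`` are
    the patient's somatic non-driver calls; ``loh_matches`` gives pairwise
    LOH-boundary verdicts (from :func:`loh_boundary_match` on delineated
    regions, or :func:`matches_from_region_ids` on annotations).

    Mutation evidence outranks boundary concordance: a mutation-sharing group
    whose members' LOH boundaries disagree is retained with a conflict flag,
    never dropped.
    """
    if not statuses:
        raise ValueError(f"no samples for patient {patient_id}")
    loh_matches = loh_matches or {}
    groups, possible = shared_mutation_groups(
        [c for c in mutation_calls if c.sample_id in statuses], min_shared
    )

    # flag groups whose internal LOH evidence is contradictory
    flagged: list[CloneGroup] = []
    for g in groups:
        members = sorted(g.samples)
        conflict = any(
            loh_matches.get(frozenset((a, b))) is MatchResult.different
            for i, a in enumerate(members)
            for b in members[i + 1:]
        )
        flagged.append(CloneGroup(g.samples, g.shared_mutations, conflict))
    groups = flagged

    grouped = {s for g in groups for s in g.samples}
    mutation_sets = _mutation_sets(mutation_calls)

    # somatic second-hit variants at the driver loci, per sample
    second_hits: dict[str, set[str]] = {}
    for s, status in statuses.items():
        second_hits[s] = {
            v.cdna_change for v in status.hits if v.origin is Origin.somatic
        }

    has_loh = {
        s for s, st in statuses.items()
        if st.mechanism in (Mechanism.mutation_plus_cnloh, Mechanism.cnloh_only)
    }

    classes: dict[str, CloneClass] = {}
    for s in statuses:
        if s in grouped:
            classes[s] = CloneClass.definite_shared
            continue
        others = [o for o in statuses if o != s]
        if s in has_loh:
            verdicts = [
                loh_matches.get(frozenset((s, o)))
                for o in others
                if o in has_loh
            ]
            verdicts = [v for v in verdicts if v is not None]
            if any(v is MatchResult.same for v in verdicts):
                classes[s] = CloneClass.possible_shared
                continue
            # indeterminate pairs are non-comparable; a region different from
            # every comparable neighbour is unique to this specimen
            if any(v is MatchResult.different for v in verdicts):
                classes[s] = CloneClass.independent
                continue
            if not verdicts and second_hits[s] == set():
                # the only LOH region of the patient is unique by default
                if not any(o in has_loh for o in others):
                    classes[s] = CloneClass.independent
                    continue
        # a somatic driver hit seen in no other specimen marks independence
        unique_hit = any(
            all(h not in second_hits[o] for o in others)
            for h in second_hits[s]
        )
        if unique_hit:
            classes[s] = CloneClass.independent
        else:
            classes[s] = CloneClass.unresolved

    truncal = {s: g.shared_mutations for g in groups for s in g.samples}
    private = {
        s: sorted(mutation_sets.get(s, set()) - truncal.get(s, frozenset()))
        for s in statuses
    }
    return CloneTree(
        patient_id=patient_id,
        germline_label=germline_label,
        groups=groups,
        classes=classes,
        private_events=private,
        possible_pairs=possible,
    )


# ---------------------------------------------------------------------------
# export


def export_tree(tree: CloneTree) -> tuple[str, dict]:
    """Render the clone tree as a newick string plus a JSON-able report.

    Internal nodes carry labels of the form ``truncal_n`` giving the number
    of shared truncal mutations supporting the node.
    """
    if not tree.classes:
        raise ValueError("empty clone tree")
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)
    dtree.seed_node.label = tree.patient_id
    grouped = set()
    for g in sorted(tree.groups, key=lambda g: sorted(g.samples)):
        node = dtree.seed_node.new_child()
        node.label = f"truncal_{len(g.shared_mutations)}"
        for s in sorted(g.samples):
            leaf = node.new_child()
            leaf.taxon = taxa.new_taxon(s)
            grouped.add(s)
    for s in tree.samples:
        if s not in grouped:
            leaf = dtree.seed_node.new_child()
            leaf.taxon = taxa.new_taxon(s)
    newick = dtree.as_string(schema="newick", suppress_rooting=True).strip()
    report = {
        "patient": tree.patient_id,
        "germline": tree.germline_label,
        "groups": [
            {
                "samples": sorted(g.samples),
                "shared_mutations": sorted(map(list, g.shared_mutations)),
                "conflict": g.conflict,
            }
            for g in tree.groups
        ],
        "classes": {s: c.value for s, c in sorted(tree.classes.items())},
        "private_events": {
            s: [list(m) for m in evs] for s, evs in sorted(tree.private_events.items())
        },
        "possible_pairs": [
            [a, b, list(m)] for a, b, m in tree.possible_pairs
        ],
    }
    return newick, report


def parse_newick_leaf_sets(newick: str) -> list[set[str]]:
    """Leaf-label sets of each internal node of a newick tree (round-trip aid)."""
    dtree = dendropy.Tree.get(data=newick, schema="newick")
    out = []
    for node in dtree.preorder_node_iter():
        if not node.is_leaf():
            out.append({leaf.taxon.label for leaf in node.leaf_iter()})
    return out
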