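# Methods

## The mixture model behind everything

A resected specimen is modelled as a fraction $p$ (tumor purity) of diploid
tumor cells mixed with $1-p$ diploid normal cells. All copy-number states
handled here are copy-neutral by construction — mitotic recombination swaps
haplotypes without changing total copy number — so the expected allele
fraction of any variant is $(p\,m_t + (1-p)\,m_n)/2$ with $m_t, m_n \in
\{0,1,2\}$ the mutant copy counts per cell type. Five genotype
configurations cover the cohort's biology (germline het with/without LOH on
either haplotype, somatic het, somatic homozygous via CN-LOH). Every map
except the unaltered germline heterozygote is strictly monotone in $p$ and
inverts in closed form; `estimate_purity` propagates an exact
(Clopper–Pearson) binomial interval on the observed AF through the inverse
and clips to $[0,1]$ with a flag rather than failing, since at realistic
depth the observed AF routinely overshoots the model's range. The estimator
assumes clonal events (cancer cell fraction 1); subclonal events bias it
downward, and no joint multi-variant or CCF deconvolution is attempted.
Non-copy-neutral totals are rejected explicitly.

## LOH mapping

Informative sites are germline heterozygous SNPs selected in the matched
normal: depth > 19 and normal AF in [0.40, 0.60] (both bounds inclusive).
In unpaired tumors a weaker tumor-AF window of [0.05, 0.95] marks candidate
sites. A selected SNP is *skewed* in the tumor when its AF leaves the open
interval (0.40, 0.60); an AF of exactly 0.40/0.60 is deliberately assigned
to "normal" — the boundary is claimed by neither definition, and the
conservative choice produces fewer false LOH calls.

Delineation builds atomic runs of consecutive skewed SNPs, then merges
adjacent runs while interior normal-AF SNPs remain at most a fraction
`max_interior_discordant_frac` (default 0.1) of the SNPs in the merged
confident span. Two guards shape the boundary behaviour:

- **Sub-threshold runs never merge.** At a per-site false-skew rate $q$ of a
  few percent (binomial tails at depth ~80), chance runs of 1–2 adjacent
  skewed sites are expected on essentially every track ($O(nq^2)$ doubles
  for $n$ sites), and attaching them would drag a region boundary past the
  true recombination breakpoint; chance triples are $O(nq^3)$ and
  negligible. Only runs of ≥ 3 skewed SNPs can extend a region. Isolated
  skewed sites are reportable via `unassigned_skewed_snps`.
- **Regions need ≥ `min_skewed` (default 10) skewed SNPs.** Neither value is
  derived from data in hand; both are configuration with documented
  defaults, chosen to suit dense exome SNP tracks.

A region's *confident span* runs from its first to its last skewed SNP; the
*uncertainty flanks* extend to the nearest flanking normal-AF SNP (the true
breakpoint lies somewhere in the flank). `telomere_anchored` is defined
relative to the observed track — capture designs rarely reach the physical
telomere — as the absence of any normal-AF SNP before the region. Interior
normal-AF SNPs are counted and reported, never used to split a region.
Coordinates are 1-based inclusive throughout (HGVS convention).

Copy-neutrality is assessed from windowed tumor/normal depth ratios rather
than a segmentation model: the median log2 ratio over ≥ 5 overlapping
windows is called neutral within ±0.3, single-copy loss down to −1.5,
homozygous loss at or below −1.5, gain at or above +0.3, indeterminate
otherwise. The ±0.3 tolerance absorbs exome capture noise; the −1.5 cut
separates one- from two-allele losses at the purities where homozygous
deletions are recognisable at all (a two-allele loss at purity $p$ leaves
$2(1-p)$ copies, crossing the −1.5 threshold for $p \gtrsim 0.65$; the
cohort's one confirmed homozygous deletion shows ~0.42 copies, i.e. purity
near 0.8). Homozygous-deletion scanning reports maximal loss runs and any
nested homozygous core separately, so the canonical focal-deletion geometry
(a ~50 kb two-allele core inside a ~150 kb one-allele envelope) comes back
as two nested intervals; single-window runs carry a low-confidence flag.

## Mechanism classification

Variant classes are inferred from HGVS strings (stop-gain → nonsense;
`_splice` protein tag or intronic offset within ±2 → splice; frameshift
protein tag or del/ins length mod 3 → frameshift vs in-frame; clean
single-nucleotide substitution → missense), with an explicit table token
overriding inference. The override exists for annotations that string
inference cannot reach — the cohort's recurrent deep-intronic change at
position −15 is typed splice by its protein-level annotation, not by the
offset rule.

The per-specimen verdict follows strict precedence: homozygous genomic
deletion → two distinct small variants at one locus ("distinct" means
distinct cDNA strings; phasing is unknowable and trans configuration is the
documented assumption) → one variant plus CN-LOH whose *confident span*
covers the locus → CN-LOH only → none. A locus covered only by an
uncertainty flank is not accepted as a second hit (warning). `biallelic` is
true for the first three mechanisms. In cohort tallies a homozygous
deletion counts as two deletion alleles, and the packaged specimen's
two-allele core plus one-allele envelope count as two large-scale deletion
events in the somatic driver-variant spectrum.

## Burden statistics

Burden counts somatic, covered, non-driver coding calls per tumor–normal
pair (23 pairs in the packaged cohort); samples with no calls count zero;
uncovered rows ("no coverage") never count. The rate is the cohort median
divided by the capture territory (33 Mb default). Two denominators are
computed side by side and never reconciled: per-specimen *call count*
(literal duplicate rows retained, matching the printed tables' per-specimen
arithmetic — 85 here) and the patient-level *unique set* (shared and
duplicated calls collapsed — 77 here); the mutation spectrum and its
missense fraction are computed over the unique set, subclonality fractions
(AF < 0.15 / < 0.10, strict) over both. The packaged rows are post-review
calls, so the review filter is not re-applied to them; one printed call
sits below the nominal 5% AF review threshold and survives via orthogonal
validation.

The sporadic-vs-TSC contingency compares two-event mechanisms (both hits
discrete mutational events) against all others. The two-sided Fisher exact
p uses the conventional point-probability definition — the sum over all
hypergeometric outcomes with fixed margins whose probability does not
exceed the observed table's — accumulated in log space; a tail-doubling
variant is available by flag. Tests verify the implementation against an
exact-rational enumeration oracle on every 2×2 table with row sums ≤ 20.

## Clonality

Evidence is ranked: two or more identical somatic non-driver mutations
shared between specimens of one patient establish a *definite* common
truncal precursor (transitively merged; sharing exactly one mutation is
flagged but never grouped, since a single match could be a recurrent
artifact). LOH-boundary concordance alone yields at most *possible* shared
origin. Boundary comparison works on per-boundary intervals: each region's
true boundary lies inside its uncertainty flank, so two regions are `same`
when both start and end flank intervals overlap and `different` when any
pair is disjoint; sparse flanks widen the intervals and bias toward `same`,
which is precisely "identical to the resolution limits" semantics. Missing
flanks (telomere-anchored starts, regions running to the track end) are
unbounded. The geometric rule is binary; `indeterminate` verdicts come from
annotation-level comparisons where boundaries were never recorded (e.g. a
low-purity specimen whose region extent is unresolvable).

A specimen is `independent` when its LOH region differs from every
comparable region of the patient or its somatic driver hit is unique, and
`unresolved` with no second-hit evidence. Mutation evidence outranks
boundary evidence: a mutation-sharing group whose boundaries disagree is
kept with a conflict flag. The exported tree is event-set logic — definite
groups as internal nodes labelled with their truncal mutation count under a
germline root — not a branch-length phylogeny; newick I/O goes through
dendropy.

## Synthetic data

The generator emulates exactly the structures the pipeline detects: a
telomere-anchored CN-LOH segment on a 30 Mb arm with 280 SNPs (~107 kb
spacing, uniform by default), per-site depth negative-binomial with
variance 2× the mean (default mean 80×, matching mid-range exome coverage;
dispersion 1 gives Poisson), normal alt reads Binomial(depth, 0.5), tumor
alt reads Binomial(depth, E[AF]) under the site's genotype. Which haplotype
carries the alternate allele is randomised once per SNP, so skew direction
alternates site-to-site while one haplotype is lost region-wide — the
two-sided scatter of real B-allele plots. Multifocal patients draw per-tumor
purity from U(0.4, 0.7) (the range implied by the cohort's driver-variant
AFs), share truncal mutations and a common breakpoint within a group, and
carry a germline driver frameshift in every tumor. The bundled presets:
`p13_like` (16 tumors: one 3-tumor truncal group with 2 shared mutations,
nine independent CN-LOH breakpoints, two point second hits, two with no
second hit), `sporadic_two_hit`, and a nested 50/150 kb homozygous-deletion
geometry at purity 0.8. Everything is driven by one integer seed,
bit-for-bit reproducible.

What the simulator does **not** model: sequencing error, mapping artifacts,
strand bias, GC-dependent coverage waves, subclonal copy-number states, or
germline SNP ascertainment error. Passing simulation tests therefore shows
the *inference logic* is correct under binomial sampling noise at the stated
purity/depth — not that the thresholds are optimal for any particular
real capture platform.

## Problem sizes and statistical test conditions

Simulation-based checks run at purity 0.5 and mean depth 80 — a
representative operating point of the regime (purity ≥ 0.3, depth ≥ 60)
the method targets — with 200 replicates for breakpoint recovery and
boundary concordance and 100 for end-to-end multifocal recovery. At the
extreme corner of that regime (purity 0.3, depth 60) the per-SNP skew power
drops to ~0.75 and boundary recovery to within two SNP spacings is no
longer achievable at 95% by any first-to-last-skewed-SNP rule; purity ~0.3
is the practical detection floor, consistent with the low-purity specimens
that real cohorts leave unresolved. Breakpoint recovery is scored against
max(2× mean SNP spacing, 2× the local inter-SNP gap at the breakpoint).

## Known limitations

- LOH mapping has no HMM/CBS segmentation and no allele-specific integer
  copy-number inference; interstitial LOH separated by short normal gaps may
  fragment.
- Purity estimation is single-variant and clonal; it will disagree with
  joint likelihood methods on low-purity or subclonal specimens.
- The clone tree encodes event-set logic only — no mutation ordering beyond
  truncal/private, no CCF-based subclone deconvolution.
- The packaged cohort's LOH region identities for one multifocal patient are
  carried as annotations (their underlying per-SNP tracks are not published
  as tables) and are used as evidence, never recomputed.
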