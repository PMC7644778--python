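# Methods

This note documents the models, conventions and numerical choices behind
`quantmg`, in the order the pipeline runs.

## Spike-in normalization

Each sample receives three internal genomic standards before DNA
extraction. With `S_s` protein-encoding standard reads recovered, `S_p`
protein-coding genes in the standard genome and `S_a` genome molecules
added, the recovery ratio is `R = (S_s/S_p)/S_a` — the fraction of added
genome copies that appear in the library. Any gene category with `G_s`
reads then contains `G_s/R` molecules in the sample, and `(G_s/R)/V` genes
per liter for `V` liters filtered. Genome equivalents use reads matching
*recA*, a conserved single-copy gene, so one counted read represents one
genome (no per-taxon copy-number correction is applied; that is a stated
non-goal).

Mass→molecules conversion uses the conventional dsDNA average of
650 g mol⁻¹ bp⁻¹ and the exact (2019 SI) Avogadro constant; both are module
constants (`quantification.BP_MOLAR_MASS`, `quantification.AVOGADRO`) and
function arguments, since the literature never states the conversion it
assumes. 4 ng of a 2 Mbp genome is ≈ 1.853×10⁶ molecules.

**Pooling.** The point estimate for a sample uses the arithmetic mean R of
the three standards; the three per-standard estimates are retained for the
95% CI (t distribution, df = 2, lower bound floored at 0) and the %CV
(sample sd with n−1 denominator over mean, ×100). Because the three
per-standard abundances differ only through 1/R, their %CV equals the %CV
of the 1/R values — an identity the tests exercise numerically.

**Detection limit.** Defined as the abundance whose expected recA read
count is 1, i.e. `1/(R·V)`. An alternative Poisson definition — the
abundance where P(≥1 read) reaches 95%, `−ln(0.05)/(R·V)` — is available
via `detection_limit(..., method="poisson")`. Taxa with zero counted reads
are reported as 0 cells L⁻¹ with the sample's detection limit attached,
never as missing, so "below detection" statements are well defined.

## Annotation arbitration

All cutoffs live in one table (`hit_filtering.THRESHOLDS`). Comparisons are
applied with the strictness they are stated with: identification cutoffs
written as strict inequalities (e-value < 0.001, %ID > 95, alignment > half
the read length, bit > 50) exclude the boundary, while removal rules
("remove if bit < 40 or %ID < 95") keep it. Top-hit selection takes the
maximal bit score per read; exact ties break to the lexicographically
smallest subject id, then input order, so results are deterministic.
"Duplicate hit" removal is implemented as per-read top-hit selection.

A bacterial annotation is replaced by a viral one only when the viral hit's
bit score is strictly higher; ties keep the bacterial call. recA membership
of a protein is decided by case-sensitive substring match of four product
title phrases ("recombinase RecA", "protein RecA", "recombinase A", "RecA
protein"); a case-insensitive switch exists for databases with uneven
capitalization. A read counts as recA when its top RecA-database hit
exceeds 50 bits *and* its all-protein annotation confirms a RecA product
title; when the two searches disagree on the taxon, the RecA search wins
and the conflict is tallied in the report (the all-protein search is used
only as confirmation). For translated (protein) searches the
alignment-length fraction would be evaluated as 3·aa/nt for unit
consistency; the standard-read length filter itself applies to the
nucleotide search.

## Community tables

Family values are exact sums of member taxa (unmapped taxa go to an
"unclassified" family). The four abundance classes use strict lower bounds
— dominant > 10⁸, abundant > 10⁷, minor > 10⁶, rare otherwise (cells L⁻¹) —
so exact boundary values fall to the lower class; thresholds are
configurable. Class assignment is per sample; cross-sample means can be
classified the same way where a single label per family is wanted.
Reference-bin recruitment uses competition ranking (ties share the minimum
rank of the tied block); entirely missing samples stay missing.

## Ordination and permutation tests

The composition matrix is percent-of-total per sample computed on the
*full* family table, then restricted to the top-100 families (ranked by
total abundance across samples, ties lexicographic), zeros replaced by
0.001 *percent* (log floor −3) and log10 transformed. PCA is a singular
value decomposition of the centered, unit-variance-scaled matrix;
zero-variance columns are dropped with a warning; each component's sign is
fixed so its largest-magnitude loading is positive; variance fractions are
squared singular values normalized over the retained components (at most
min(n−1, p)).

PERMANOVA takes sample *proportions* (not volumetric abundances — a flag
allows the latter), square-root transforms them, computes Bray–Curtis
dissimilarity `Σ|x−y|/Σ(x+y)`, and partitions squared distances:
`SS_total = Σ_{i<j} d²/n`, `SS_within = Σ_g Σ_{i<j∈g} d²/n_g`,
`F = (SS_between/(g−1))/(SS_within/(n−g))`, `R² = SS_between/SS_total`.
The permutation null relabels samples (labels are permuted, not distance
rows) with `numpy.random.default_rng(seed)`; p-values use the add-one rule,
so p ≥ 1/(n_perm+1); the default is 999 permutations and a seed is
mandatory in the CLI. Bray–Curtis is a semimetric, so the triangle
inequality is not asserted anywhere.

The dispersion test embeds the distance matrix by principal coordinates
keeping negative eigenvalues (axes scaled by √|λ|); a sample's squared
deviation from its *group centroid* subtracts the negative-axis
contribution from the positive-axis contribution and is floored at 0 before
the square root — the standard correction for semimetric distances. The
statistic is the one-way ANOVA F on the deviations, with labels permuted
over the fixed deviations. Centroids (not spatial medians) are used; this
matches the reference R implementation's `type="centroid"` option rather
than its default, and the tests pin the deviations to values computed with
that implementation.

## Seawater equation of state and mixed layer

Potential density σθ uses the UNESCO EOS-80 equation of state (density
polynomial plus secant bulk modulus) with potential temperature from the
Fofonoff–Millard adiabatic lapse-rate polynomial integrated by the standard
4th-order Runge–Kutta scheme; the implementation reproduces the published
check values (e.g. ρ(35, 25, 0) = 1023.34306 kg m⁻³, θ(40, 40, 10000 dbar)
= 36.89073 °C) to the printed precision. EOS-80 takes practical salinity
and differs from TEOS-10 by far less than the mixed-layer criterion.

The mixed-layer depth is the shallowest depth where σθ exceeds the *surface*
value — the shallowest valid record, since CTDs rarely sample 0 m — by more
than 0.35 kg m⁻³ (configurable). The crossing is linearly interpolated
between bracketing records by default; a bin mode returns the first record
exceeding the threshold. Profiles that never cross return their deepest
depth flagged as "extends beyond profile". Mixed-layer temperature and
salinity are depth-weighted trapezoidal means over [surface, MLD] (exact
for piecewise-linear profiles and insensitive to grid refinement), with the
value at MLD interpolated. When pressure is absent, decibars are
approximated by depth in meters — exact to well under 1% in the upper ocean.

## The synthetic survey generator

The generator emulates an archipelago survey: five regions ordered
west→east, a configurable number of sites per region, two sampling years,
2 L filtered per sample. Reference taxa get genome lengths log-uniform on
[1.3, 9] Mbp (marine streamlined cells through copiotrophs), protein-gene
counts of one gene per kilobase (rounded, ≥1) and exactly one recA gene.
The three standards have fixed genome sizes (2.13, 3.28, 6.09 Mbp) and 4 ng
each by default; note that a standard's expected read count, `S_a·S_p`,
depends only on the mass added, so equal masses give the three standards
equal coverage.

Baseline per-taxon abundances are log-normal (sd 1 log10 unit across taxa),
globally rescaled so the geometric-mean community total matches the target
(default 2×10⁹ cells L⁻¹, typical of surface pelagic water); samples whose
total leaves the configured bounds (default 10⁸–10¹⁰) are clamped to the
bound preserving composition (rare, warned). A tenth of families increase
by 10^span (default span 1.5) monotonically and log-linearly along the
west→east site axis and another tenth decrease — emulating the
upwelling-west/oligotrophic-east contrast; El Niño indicator families are
multiplied by their year effect in the disturbance year only. Per-sample
log-normal noise defaults to 0.3 log10 units (unspecified in the
literature; configurable), and within-site replicate noise has no separate
model — replicates, if simulated, share the same per-sample noise
parameter.

Sequencing draws `reads_per_sample` reads multinomially over taxa and
standards with gene-molecule weights (abundance × volume × gene count for
taxa; `S_a·S_p` for standards). Within a taxon's reads, recA status is
Bernoulli with p = 1/protein_gene_count, enforcing single-copy semantics
exactly. Annotation noise is per read: a 1% default misannotation rate
(community reads whose protein hit scores below 50 bits and is later
filtered) and a 1% default dual-hit rate (reads carrying both a bacterial
and a viral hit with iid bit scores, so the viral hit wins with probability
½). These defaults mean counted recA reads underestimate true recA reads by
≈ misannotation_rate + dual_hit_rate/2 (~1.5%); clean-recovery experiments
set both to zero. Reads are simulated at the annotation level (hit-table
rows), never as sequences: read QC, merging and the homology searches are
upstream of this package's boundary, and hit tables are materialized from
the same per-read draws as the counts table, so filtering the emitted
tables reproduces the counts exactly (asserted in the tests).

**El Niño scenario.** The disturbance the power analyses use applies
alternating 0.1×/10× multipliers to the four most abundant baseline
families (`elnino_indicator_defaults`). This mirrors the observed pattern —
an El Niño reorganizes the *dominant* fraction of the community, with
order-of-magnitude collapses of upwelling-adapted populations and blooms of
warm-water taxa — and is what makes a two-group PERMANOVA on ~10 samples
per year decisively significant; the same multipliers on arbitrary
(typically low-abundance) families produce a much weaker, often
undetectable signal at that sample size.

**What the simulator does not model**, and hence what passing tests do not
show about real data: sequencing error and chimeras, database
incompleteness and cross-mapping between related taxa, recA copy-number
deviations, GC/extraction bias between standards and community DNA,
fragment-length effects, and compositional coupling between families beyond
the shared multinomial constraint. Parameter-recovery results therefore
validate the estimator and arbitration logic, not the upstream annotation
accuracy of any particular reference database.

## Problem sizes and test design

The test suite validates properties at desk scale, chosen once: end-to-end
recovery uses 24 samples × 10⁶ reads (families qualify at ≥20 expected recA
reads per sample; tolerance three relative standard errors including both
Poisson counting and recovery-ratio noise, aggregate bias within ±3%);
detection-limit statistics use 500 libraries at an expected recA count of
0.2 (zero-read fraction e^−0.2 ± 4%); %CV–depth scaling fits four depths
from 10⁴ to 10⁷ reads (slope −0.5 ± 0.1); type-I error for PERMANOVA and
the dispersion test uses 1000 null simulations of 12 samples at 199
permutations (5% ± 2%); PERMANOVA power uses 20 seeds of the El Niño
scenario at 10 samples/year (≥90% rejections). Permutation tests are exact
in size by construction of the add-one p-value; all randomness flows
through explicit seeds, and scenario-level streams are spawned per sample
from the config seed so samples are independent yet byte-reproducible.
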