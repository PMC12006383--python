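# Methods

## The convergence model

The unit of observation is a UMI-collapsed, germline-annotated IGH
rearrangement: V/D/J gene calls, the IMGT junction (CDR-H3 with its
conserved C…W anchors) as nucleotide and amino-acid strings, a
constant-region (isotype) call, a UMI abundance, and an aligned
observed/germline V-region pair for mutation counting. Samples group
rearrangements under subject, tissue and group labels.

Two levels of clustering sit on top of this:

**Within-sample clones.** Rearrangements with the same V gene, J gene
and junction nucleotide length merge by single-linkage when their
normalized junction Hamming distance is ≤ `nt_threshold` (default
0.15). Single-linkage means chains connect: A–B and B–C close implies
one clone even when A–C is distant. The threshold is a conventional
operating point for junction-based clone inference and is exposed
rather than hidden; no attempt is made to fit a per-sample threshold
from the distance distribution. The clone representative junction is
the highest-UMI member (ties: lexicographically smallest junction).

**Cross-sample convergent clusters.** Clones from different samples are
considered the same public clonotype when they match in V gene, J gene
and CDR-H3 length and are ≥ 85% identical in CDR-H3 amino acids.
Because lengths are equal inside a bucket, identity is positional —
matching residues over length, equal to 1 − Hamming/length — with no
alignment step. Clustering is greedy best-representative: clones are
processed in descending UMI total (ties: descending member count, then
lexicographic junction, sample and clone ids — a total order, so the
result is permutation-stable); each clone joins the existing cluster
whose representative has the *highest* identity ≥ 0.85 (earliest
founded on exact ties) or founds a new cluster. These are the
semantics of CD-HIT's accurate mode (best-matching cluster rather than
first-found); greedy and single-linkage can genuinely differ, and the
greedy form is what the test oracles pin down. "At least 85%" is
inclusive: 17/20 clusters, 11/13 does not.

Sharing is counted at subject level (`carrier_subjects`) so a subject
contributing several samples cannot manufacture pseudo-sharing;
per-sample carrier sets remain available for tissue-level analyses.

## Sharing, disease lists, enrichment

**Depth-matched sharing.** Per iteration: draw `n_patients` eligible
patients without replacement, draw `n_clones` unique clones per patient
without replacement, cluster the union, count clusters with ≥ 2
distinct patient carriers. Patients below the clone floor are excluded
and logged, never resampled with replacement. Defaults mirror the
protocol scale this statistic is usually run at (8 patients × 1500
clones and 16 patients × 500 clones, 200 iterations); the bundled demo
scales to its own cohort (8 × 400 × 25). Results are reported as the
full iteration distribution; summaries use the median.

**Disease-associated lists.** Cases and controls are clustered
*jointly*; retained clusters have ≥ `min_case_carriers` (≥ 2) distinct
case subjects and no control member at all. Absence-in-controls is
thus evaluated at cluster level — a control clone within the 85%
radius disqualifies the cluster — which is the stricter and more
consistent reading of the convergence definition, rather than an
exact-string lookup. The optional refinement truncates each case
sample to its top-`n` clones by UMI total before clustering (default
3000, the published operating point; the demo uses 300 to match its
500-clone repertoires); controls are never truncated, since absence
must hold against the full control repertoire.

**Enrichment.** A query clone matches a list when its (V, J, length)
key equals a stored cluster's and its junction is ≥ 85% identical to
the stored representative. Per sample the score is matched/total over
unique clones, or the matched/total UMI-sum ratio when clonal
expansion should weigh in. Empty strata are omitted with a notice,
never reported as 0/0.

**Group comparison.** All group contrasts use the unpaired two-sample
Mann–Whitney rank-sum test. For combined n ≤ 12 the null distribution
of U is enumerated over every assignment of the pooled values (ties
handled exactly through half-credit pair counting, equivalent to
midranks); the two-sided p is 2·min(P≤, P≥) capped at 1. Larger
samples use the normal approximation with tie and continuity
correction (scipy). All-identical inputs return p = 1 with a notice.
When several isotype strata are tested together, p-values are
Benjamini–Hochberg adjusted across strata.

## Repertoire features

**SHM** is 100 × mismatches/comparable positions between the observed
V region and its germline, where positions with a gap (`.`, `-`) or N
in either string are excluded from numerator and denominator alike.
The unit of analysis is the clone: member sequences average to a
clone-level mean first, then clone means average (unweighted) per
sample and isotype, so expanded clones do not dominate sample
summaries. Lowly-mutated means strictly < 1%. Clones with isotype
`unknown` are retained in clone tables but excluded from
isotype-stratified statistics.

**Gene usage** is always unique-clone level — each VDJ counted once,
never read- or UMI-weighted — so differential mRNA content between
isotypes cannot skew proportions. The per-gene group contrast is the
difference index (mean disease − mean control)/(mean disease + mean
control) in [−1, 1] (antisymmetric; 0/0 reported as missing), with
per-gene rank-sum tests BH-adjusted across genes. J-gene composition
uses Pearson's chi-squared on the full contingency table without
continuity correction — keeping the closed-form Σ(O−E)²/E exact for
the oracle fixtures — followed by all 2×2 gene-pair sub-tables with
Bonferroni correction (p × number of pairs, capped at 1); an expected
cell < 1 attaches a warning but does not abort. Sub-isotype
composition reports within-family proportions for IgA (A1/A2) and IgG
(G1–G4).

## The synthetic cohort generator

The generator emulates exactly the structure the pipeline's claims
rest on, and nothing more:

* **Private clones** per subject: junction length from a discretized
  Gaussian over 9–23 aa centred near 15 (IMGT junction, anchors
  included), interior residues uniform over the 20 amino acids, V/J
  labels from realistic frequency vectors (IGHJ4-dominant J usage,
  a 16-gene V panel), isotypes from a plausible class-switched mix.
* **Public clones** planted across case subjects, each carried
  independently with probability `public_penetrance` (default 0.6 over
  16 cases) and — by default — absent from controls. Every carrier
  copy is perturbed by `public_variant_mismatches` (default 1) interior
  substitutions, so recovery requires the identity-threshold
  clustering, not exact string matching.
* **SHM** by per-base substitution of a fixed 300-nt toy germline at
  the isotype's configured rate (defaults 0.5% for IgM/IgD up to 3%
  for IgA). A single synthetic germline suffices because mutation
  quantification only needs an aligned pair; gene identity travels in
  the `v_call` label independently. `public_shm_multiplier` lets
  planted clones carry elevated SHM for effect-recovery tests.
* **Clone sizes** from a zipf power law (exponent 2.5), giving the
  heavy-tailed UMI counts that make top-n expansion refinement
  meaningful.

Seeding: one root seed spawns per-subject streams, so outputs are
bit-identical across runs and one subject's draws never perturb
another's. The public-prototype stream has its own seed
(`public_seed`, defaulting to the root), so a discovery and a
validation cohort can share identical planted clonotypes while their
subjects stay independent.

**Co-clusterability bound.** Planted junction lengths are restricted
to lengths L with 2·m/L ≤ 0.15 (L ≥ 14 for m = 1 mismatch). The
factor 2 matters: the unperturbed prototype is never itself a clone,
so the cluster representative is some carrier's copy, and two copies
each m substitutions from the prototype can differ at 2m positions. A
bound of m/L alone (identity to the prototype) would let planted
clones at shorter lengths shatter into singleton clusters and would
make planted-truth recovery systematically undercount. Configurations
where no length satisfies the bound are rejected at validation.

**What the generator does not emulate** — and therefore what passing
tests do not certify about real data: VDJ recombination biochemistry
(TdT insertions, exonuclease chewback, D-segment structure), SHM
hotspot/codon context and selection, clonal lineage structure within
samples (each simulated clone is one sequence), isotype–clone-size
coupling, repertoire contamination and index hopping, and annotation
errors upstream of the pipeline. Parameter-recovery results show the
estimators are consistent with their own generative model, not that
the model is a sufficient description of human repertoires.

## Numerical choices

* Identity/distance comparisons carry a 1e-12 (identity) / 1e-9
  (Hamming-count) guard so that exact rational boundaries like 17/20 =
  0.85 or 3/20 mismatches at threshold 0.15 are never lost to float
  rounding; the 85% and distance thresholds are inclusive.
* Every ordering that affects output is totalised (UMI, member count,
  junction, sample id, clone id), so clustering, truncation and clone
  ids are independent of input row order.
* Clone ids are assigned after sorting clusters by their smallest
  member sequence id; cluster ids are per-bucket ordinals.
* Degenerate inputs: zero comparable SHM positions skips the record
  with a notice; empty enrichment strata are omitted; all-identical
  rank-sum inputs give p = 1; 0/0 usage indices are missing values.
* The exact/asymptotic rank-sum crossover is combined n = 12
  (enumeration ≤ C(12,6) = 924 assignments).

## Problem sizes

The bundled demo and the test suite run at deliberately modest scale —
16 + 8 subjects at 500 clones (12 000 rearrangements), 25 sharing
iterations, 5 000 clones per isotype for SHM recovery, 10 seeds for
recall/power sweeps — chosen so the whole suite completes in about a
minute while keeping every statistical check inside its sampling
envelope. All sizes are ordinary config fields; scaling up changes
nothing structural.

## Known limitations

* Clone assignment requires equal junction lengths within a candidate
  group; indel-containing junction variants of the same lineage are
  treated as distinct clones.
* Greedy clustering is order-dependent by construction (the order is
  fixed and documented); a different abundance measure would yield a
  different — equally valid — partition.
* Enrichment membership tests against stored representatives only, so
  a list serialized to TSV carries no member-level information; two
  nearby clusters in a list can both match one query clone (counted
  once).
* The rank-sum normal approximation is used above combined n = 12;
  for small heavily-tied samples near that boundary the exact path is
  authoritative.
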