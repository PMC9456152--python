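# Methods

## The quantity being measured

Nuclear RNA of dividing cells contains nascent and partially spliced
pre-mRNA. When the removal of an intron is delayed, reads persist over its
body and, most visibly, over its terminal ~25 nt — the donor (5′SS) and
acceptor (3′SS) ends that the spliceosome engages. `risekit` quantifies this
accumulation per splice site as the **RISE index**: the per-nucleotide read
mean of the intron-terminal bin divided by the per-nucleotide read mean of
the adjacent exon. The exon normalization cancels gene expression, so the
index approximates the fraction of that gene's transcripts whose intron end
is still present — a unitless delay fraction, zero for instantly spliced
introns and approaching 1 (or beyond, for very unstable exons) when most
transcripts retain the intron end.

Because the spliceosome commits to a 5′SS–3′SS *pair*, the delays of paired
sites should covary. Correlation of log10 indexes across the two ends of the
same intron reflects intron definition; correlation across an exon (the
3′SS of the upstream intron with the 5′SS of the downstream intron) reflects
exon definition. These are the type I and type II pairings. A site may sit
in one of each; the ratio between its two candidate partners' indexes then
measures the balance between the two definitions, and condition-dependent
movement of that ratio indicates a definition shift.

## Binning and filtering rules

Introns are tiled into 25-nt bins in plus-strand genomic order starting at
the genomic left end, regardless of gene strand. A remainder of 1–12 nt is
merged into the last bin (merged terminal bins are 26–37 nt); a remainder of
13–24 nt stands as its own bin. Splice-site side labels are then assigned by
strand, so for minus-strand genes the merged terminal bin falls on the 5′SS
side; the asymmetry is a property of the stated procedure, not of the
implementation. Introns shorter than 13 nt cannot form a bin and are
rejected by the tiler; introns of 13–37 nt yield a single bin which is
labelled as the 5′SS bin and documented as such (they are excluded from the
analysis by the intron-length filter long before index computation).

Detection requires, as strict inequalities: bin mean > 8 reads/nt (applied
to the mean over replicates within a condition), intron length > 50 nt,
adjacent exon length > 12 nt, and adjacent exon base mean > 20. The base
mean comes from a supplied differential-exon-usage table (an external
whole-cell poly(A) analysis) and falls back to coverage when the exon is
absent from the table, with a logged notice. Terminal (3′-most) introns are
included. Indexes are computed per replicate and averaged per condition.
Coverage is per-base read depth of aligned blocks (CIGAR-aware; junction N
gaps contribute nothing), restricted to uniquely mapped, properly paired
reads in BAM mode; read depth rather than read starts is used because the
filter criteria are stated per nucleotide position. Introns with identical
coordinates shared by transcripts of one gene are collapsed to one
representative before index computation to avoid double counting.

## Statistical procedures

**Pairing correlation.** Pearson *r* on log10 indexes of pairs
both-detected in a condition (detection guarantees positivity, so no
pseudocount is needed). The randomization null shuffles 3′SS partners among
pairs — globally, or within each gene's pair set, which preserves gene-level
offsets and therefore isolates pairing beyond co-residence in a transcript.
Empirical p = (1 + #{null r ≥ observed}) / (1 + n_perm), valid by
construction.

**Condition effects.** For shared units (site indexes, or per-pair
5′SS/3′SS ratios) the net change Δ = B − A is summarized as mean ± SEM of
|Δ| with a one-sample t-test of |Δ| against zero. That test is stated
procedure but anti-conservative (|Δ| is nonnegative), so a
replicate-permutation baseline is reported alongside: replicate values are
shuffled between the two conditions within each unit and the mean |Δ|
recomputed. The baseline requires replicate-level tables; it is the number
to trust when asking whether a shift exceeds replicate noise, and it is
calibrated (uniform p under a no-effect simulation) in the test suite.
Whole-condition label swaps would leave |Δ| invariant, which is why the
permutation operates at replicate level. Pairs whose ratio moved by more
than 20% of the reference-condition ratio, in either direction, form the
"shifted" subset. The three-condition design is analysed as two ladder
comparisons: KCl vs NT, then KCl+5azaC vs KCl.

**Enrichment.** The fraction of regulated exons (usage p < α) among
RISE-adjacent exons is compared to the background fraction among all tested
exons; the p-value is the hypergeometric upper tail P(X ≥ k). The point-mass
P(X = k) is exposed as an option since the tail convention is a choice; the
upper tail is the default because enrichment is the direction of interest.

**Splice-site matrices.** Windows are 3 exonic + 10 intronic nt at the 5′SS
and 20 intronic + 2 exonic nt at the 3′SS, strand-aware, numbered without a
zero position (−3..−1, +1..+10 and −20..−1, +1..+2). Frequencies are counted
over {A, C, G, T} (other bases excluded per position); information content is
2 + Σ f log2 f bits. The site **matrix index** is the mean over positions of
f(observed)/f(consensus): 1 for the consensus, decreasing with each
deviation in proportion to the rarity of the observed base. No published
formula exists for this statistic beyond its fixed point (consensus = 1), so
this form was chosen as the simplest one with that property; a per-position
log-odds variant is emitted alongside for transparency. Groups of
RISE-associated sites are compared to the genome-background reference of 1
by one-sample t-test and to each other by two-sample t-test.

## The synthetic-data generator

The generator emulates the features of nuclear RNA-seq that the analysis
depends on, with known ground truth:

* **Gene structure** — log-normal exon lengths (median ~120 nt, log-sd
  0.45, floor 20 nt) and intron lengths (median ~400 nt, log-sd 0.7, floor
  60 nt), 4–9 exons per gene, 120 genes by default, random strand, genes
  laid head-to-tail on multi-gene contigs. The genome is random sequence
  with canonical donor/acceptor templates written at splice sites: the
  GT/AG anchors always, the remaining window positions with fidelity 0.85
  (per-position deviation probabilities are configurable to create
  specifically weakened sites).
* **Delays** — each site carries a latent delay fraction d = expit(μ + σz)
  with μ = logit(0.25) and σ = 0.8. Introns are assigned a type I pairing
  with probability 0.5 and internal exons a type II pairing with
  probability 0.4 (roughly the 61/39 split of pairing types among detected
  pairs). Pair members' z-scores are drawn with correlation ρ_I = 0.4 or
  ρ_II = 0.7; when a site already holds a z from an earlier pair, the
  partner is drawn conditionally (z₂ = ρz₁ + √(1−ρ²)ε), which preserves
  each pair's marginal N(0,1) and pairwise correlation exactly even for
  mixed sites shared between a type I and a type II pair.
* **Conditions** — NT, KCl, KCl+5azaC in triplicate. A 20% regulated subset
  of sites multiplies its delay by 1.5 under KCl; 5azaC removes 80% of that
  shift (multiplicative attenuation; no mechanistic DNA-methylation model is
  attempted). Delays are capped at 0.95.
* **Usage coupling** — exon usage ψ = base − 0.5 · (mean delay of flanking
  sites), clipped to [0.02, 0.99], with base ~ Uniform(0.6, 0.95), giving
  the inverse index–usage relation.
* **Reads** — exon positions draw Poisson(E) with E ~ log-normal (median
  100 reads/nt, log-sd 0.5); splice-site bins draw Poisson(E·d); intron
  bodies draw Poisson(0.01·E). The usage table's p-values come from a
  two-proportion z-test on binomial inclusion counts — a synthetic stand-in
  for an external differential-usage analysis, labelled as such.

Everything is reproducible bit-for-bit from the seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: positional coverage biases and fragment-length
effects; 5′→3′ co-transcriptional delay gradients along genes; multiple
transcripts per gene (isoform-shared introns are exercised by hand-built
fixtures instead); genuinely sparse site detection (most simulated sites
clear the detection thresholds, so the regulated-exon enrichment fold on
synthetic defaults is near 1, unlike sparse real data where RISE-adjacency
is selective); sequence-dependent read noise; and the long right tail of
mammalian intron lengths. Detected-pair correlations also sit below the
generating ρ values on the full detected set because coincidentally
detected unassigned pairs (independent delays) dilute them; recovery is
therefore assessed on the truth-assigned subset, which is available only in
simulation.

## Numerical choices and degenerate inputs

Strict inequalities at every threshold (a bin mean of exactly 8 fails).
Zero exon mean leaves the index undefined (NaN) and the site undetected.
Zero variance on a correlation axis or in a test group flags the statistic
undefined instead of raising. Consensus ties in frequency matrices break
alphabetically and are recorded. Permutation p-values include the observed
statistic in the numerator and denominator. Within-gene shuffles with all
single-pair genes are rejected (the shuffle would be the identity). Problem
sizes in the test suite (120–160 genes, 50 seeded repetitions for recovery
checks, 2000 repetitions at 199 permutations for null calibration) were
chosen to keep the sampling error of each asserted quantity well inside its
assertion band.

## Known limitations

The within-gene randomization exposes scope and grouping as parameters
rather than fixing a grouping rule, because no canonical grouping exists
for the mean-of-group-correlations design. GFF3 input, junction-read
counting, transcript assembly, branchpoint scoring and EM motif discovery
are out of scope. The N/C enrichment ratio applies a fixed 0.5-count
continuity offset to zero counts, which is conventional but arbitrary for
deeply sequenced libraries.
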