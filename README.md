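# risekit

Quantification and pairing analysis of **splicing-intermediate reads at
intron starts and ends (RISE)** from nuclear RNA-seq.

When an intron has not yet been removed from a nascent pre-mRNA, nuclear
RNA-seq reads accumulate at its first and last ~25 nt — the 5′ (donor) and
3′ (acceptor) splice-site bins. The relative abundance of those reads tracks
how delayed each splice site's usage is, and correlated delays between a 5′SS
and a 3′SS reveal how the spliceosome pairs them: across the same intron
(**intron definition**, type I) or across the exon between two introns
(**exon definition**, type II). `risekit` computes per-site indexes,
classifies and tests the pairings, measures how treatment conditions (e.g.,
KCl depolarization, with or without the DNA-methylation inhibitor 5-azaC)
shift them, scores the splice-site sequences against position frequency
matrices, and ships a fully seeded synthetic-data generator so every stage
is testable without external data.

## The statistic

For each intron of each transcript, the intron is tiled into 25-nt bins from
the plus-strand 5′ end (a remainder ≤ 12 nt is merged into the last bin, so
merged terminal bins run 26–37 nt; a remainder of 13–24 nt stands alone).
The **RISE index** of a splice site is

```
index = (mean reads/nt in the splice-site bin) / (mean reads/nt of the adjacent exon)
```

with the adjacent exon being the transcript-orientation upstream exon for a
5′SS and the downstream exon for a 3′SS. A site is *detected* when bin mean
> 8 reads/nt (on the replicate mean), intron > 50 nt, adjacent exon > 12 nt,
and the exon's base mean > 20 (from a differential-exon-usage table when
supplied). Detected sites are paired:

* **type I** — the 5′SS and 3′SS of the same intron;
* **type II** — the 3′SS of intron *k* and the 5′SS of intron *k + 1*,
  flanking the exon between them;
* **type III** — detected sites in neither adjacency (recorded, excluded
  from pairing statistics).

Pairing strength is the Pearson *r* of the log10 indexes across pairs,
tested against a randomization null that shuffles 3′SS partners (globally or
only within genes). Condition effects are summarized as the mean absolute
net change of indexes and of 5′SS/3′SS index ratios, with a one-sample
t-test and a replicate-permutation baseline. Splice-site strength is scored
as a consensus-normalized matrix index (mean over window positions of
f(observed)/f(consensus); the consensus scores exactly 1).

## Worked example

```python
from risekit import RiseModel, SimConfig

model, truth = RiseModel.from_simulation(SimConfig(n_genes=30), seed=5)
results = model.fit(seed=5)
print(results.summary())
```

prints

```
RISE analysis summary
=====================

Conditions: KCl, KCl_5azaC, NT
Detected (site, condition) records: 865
Pairs: 139 type I (56%), 110 type II (44%)

Paired-index correlations (log10, Pearson r):
  type I  KCl        r = +0.235 (n = 139)
  type I  KCl_5azaC  r = +0.328 (n = 138)
  type I  NT         r = +0.344 (n = 138)
  type II KCl        r = +0.338 (n = 110)
  type II KCl_5azaC  r = +0.278 (n = 109)
  type II NT         r = +0.258 (n = 109)

Condition comparison KCl vs NT:
  site_index mean |delta| = 0.0370 +/- 0.0038 (n = 288), one-sample t p = 1.93e-19, permutation baseline p = 0.001
  ss_ratio   mean |delta| = 0.1927 +/- 0.0168 (n = 247), one-sample t p = 9.05e-25

Condition comparison KCl_5azaC vs KCl:
  site_index mean |delta| = 0.0311 +/- 0.0030 (n = 288), one-sample t p = 4.69e-21, permutation baseline p = 0.001
  ss_ratio   mean |delta| = 0.1528 +/- 0.0128 (n = 247), one-sample t p = 2.52e-26

Competing-site (mixed I/II) configurations: 213
```

Reading the output: 139 of the detected splice-site pairs span introns and
110 span exons; the paired log10 indexes correlate positively within both
pairing types (each *r* is computed over the pairs detected in that
condition). KCl shifts the site indexes (mean absolute change 0.037, clearly
above the replicate-noise permutation baseline) and shifts the 5′SS/3′SS
ratios; a 213-strong set of splice sites participates in a type I and a type
II pair simultaneously, where the competing-partner index ratio measures
redistribution between intron and exon definition.

The same analysis runs from files (`RiseModel.from_files(gtf, coverage,
usage)`) or from the command line:

```
risekit simulate --out data --seed 1
risekit run --gtf data/annotation.gtf --fasta data/genome.fa \
    --coverage NT:rep1:data/coverage.NT.rep1.bedgraph ... \
    --usage data/exon_usage.tsv --out results
```

## Layout

```
src/risekit/annotation.py   GTF parsing, intron derivation, intron-end binning
src/risekit/coverage.py     BAM/bedGraph depth, RISE indexes, QC summaries
src/risekit/pairing.py      type I/II classification, correlations, nulls
src/risekit/condition.py    net changes, ratio shifts, enrichment, fractions
src/risekit/motif.py        splice-site frequency matrices and site scoring
src/risekit/simulate.py     seeded synthetic-data generator with ground truth
src/risekit/model.py        RiseModel / RiseResults facade
src/risekit/cli.py          command-line interface
docs/methods.md             model, assumptions, parameter choices, limitations
```
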