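# Methods

## The measurement

An RB-TnSeq screen has two sequencing modes.  TnSeq junction reads, produced
once per library, contain a 20-nt random barcode between fixed flanking
sequences followed by the transposon–genome junction; they establish which
barcode sits at which insertion site.  BarSeq amplicon reads, produced per
sample, contain only the flanked barcode; their counts measure strain
abundance.  Selection is read out as the change in a strain's relative
abundance between the Time0 inoculum and the sample recovered after growth —
here the rhizosphere and root compartments of five plant species (pea,
lentil, Lathyrus, alfalfa, barley) seven days after inoculation, pooled per
species so that each condition is a single column of counts without
independent replicates.

## Pool mapping

Coordinates are 1-based inclusive; an insertion site is keyed by the
plus-strand position of the T of its TA dinucleotide, regardless of the
transposon's orientation, which gives one unambiguous key per site.  The
junction segment of each read is located by exact match of a 30-nt seed
against both genome strands (a dictionary of all genomic 30-mers; desk-scale
genomes make mismatch-tolerant alignment unnecessary, and it is explicitly
out of scope).  A forward-strand hit starting at p places the junction at p;
a reverse-strand hit starting at q places it at q + L − 2, the T of the same
TA read from the other side.

Because mariner inserts only at TA sites, any candidate whose position is not
an indexed TA is removed outright.  A barcode is then retained iff it has at
least `min_reads = 5` TA-valid candidates of which at least
`min_fraction = 0.75` agree on a single (replicon, position, strand).  These
two thresholds are this package's operational definition of "reliable"
mapping — conventional values for this filter family, exposed as parameters —
and they guarantee rejection of chimeric barcodes whose reads split evenly
across two loci.  Barcodes containing N are discarded at parse time; a
segment matching several loci emits one candidate per locus and lets the
reliability rule arbitrate.

A retained insertion is attributed to a gene when it falls within the central
10–90% of the coding span, fraction `(pos − start)/(end − start)` on the plus
strand and mirrored on the minus strand, inclusive at both bounds (the
inclusive choice is fixed here; the boundary convention is not otherwise
determined).  Insertions central to several overlapping genes count for each
of them — this avoids an arbitrary tie-break and matches per-gene averaging.
Terminal 10% insertions often leave a functional protein, which is why they
are excluded from fitness attribution.

## Fitness estimation

With strain counts n₀ (Time0, all Time0 samples summed) and n_c (condition,
samples sharing a condition summed) and sample totals N₀, N_c over pool
barcodes:

* strain fitness  f = log2((n_c + ½)/N_c) − log2((n₀ + ½)/N₀).  The
  pseudocount of 0.5 reads is applied to counts, not abundances, and keeps
  zero counts finite.  f is invariant to rescaling either sample's depth.
* strains with n₀ < `min_reads0 = 3` are excluded: genes whose mutants were
  too rare in the inoculum stay unscored (NaN, never 0.0) rather than being
  assigned noise.
* strain weight  w = min(1/v, 1/v₍₂₀,₂₀₎) with v = (1/(1+n₀) + 1/(1+n_c))/ln²2,
  the delta-method variance of a log2 binomial ratio.  The cap at the
  20-read level stops deeply sequenced strains from dominating a gene's
  average.  The weight and the t-score below are this package's declared
  estimators; the screen literature uses this family of moderated statistics
  but does not pin down one formula.
* gene fitness is the weighted mean over contributing strains, then centered
  by the per-replicon median per condition ("the typical gene is neutral").
  The median, not the mean, operationalizes "typical" so that genuinely
  selected genes do not drag the baseline.  Normalization is a single
  per-replicon pass and is idempotent; chromosome and plasmids are
  normalized independently because replicon copy number shifts all genes of
  a replicon together.
* t = f / sqrt(1/Σw + τ²), τ = 0.1.  The variance floor keeps |t| bounded
  for genes with enormous read support, so t ≈ f/τ is the ceiling; genes
  need both a real effect and consistent strains to reach |t| ≥ 3.

Percent growth reduction of a mutant class is (1 − 2^f)·100, rounded to the
nearest integer: −0.42 → 25%, −1 → 50%, −2 → 75%.

## Phenotype bins and set logic

The bins partition the fitness line: severe f < −2, moderate [−2, −1),
mild [−1, −0.42], neutral (−0.42, 0.42), advantageous ≥ 0.42.  Endpoint
assignment is fixed so that "disadvantaged" is exactly f ≤ −0.42, which makes
the bin route and the threshold route to the common-determinant set provably
identical (a cross-checked test).

* **Common determinants** per compartment: f ≤ −0.42 in *all five* species.
  Genes unscored in any species are excluded, not imputed.
* **Plant-specific genes**: the maximal subset S = {species : f < −1} must be
  non-empty and proper, every species outside S must be neutral (f > −0.42),
  and every species in S must have |t| ≥ 3.  Species in the gray zone
  (−1 ≤ f ≤ −0.42) disqualify the gene.  Because the screen lacks replicates,
  the t-score filter is the only confidence control; |t| ≥ 3 is the
  conventional cutoff for this score family and is a parameter.
* **Cross-compartment labels**: progressive = common in both compartments;
  the set differences are rhizosphere-specific and colonization-specific.
  By construction |rhizosphere-specific| + |progressive| = |common
  rhizosphere| and symmetrically for the root set.

## Synthetic data

The generator emulates the statistical structure the estimator assumes, at a
scale that runs in seconds:

| parameter | default | why |
|---|---|---|
| replicons | 500 kb chromosome + 100 kb plasmid | exercises per-replicon normalization |
| genes | 200, 600–1500 bp, both strands, non-overlapping | desk-scale annotation |
| barcodes | 2000; 80% on central-region TA sites spread evenly over genes (~8 strains/gene), 20% intergenic | real pools are enriched for central insertions; ~8 strains give stable weighted means |
| true fitness | mixture 70% 0, 10% each −0.7/−1.5/−2.5, shared across conditions; 10 planted plant-specific genes at −2 in one species (both compartments) | spans all bins with known membership |
| depth | 5·10⁵ reads per sample | per-strain counts ~250, matching the regime where the weight cap binds |
| Time0 skew | Dirichlet, concentration 50 per strain | moderate unevenness of library representation |
| junction reads | 10 per barcode; 5% relocated uniformly at random; 2% chimeric barcodes split exactly 50/50 between two sites | the failure modes the TA filter and reliability rule exist for |

Selection acts once per experiment: expected condition abundance ∝ Time0
abundance × 2^f(gene), renormalized, counts multinomial at the configured
depth.  This mirrors the operational definition of fitness as a single log2
ratio against Time0 — no per-generation dynamics, so true and estimated
fitness live on the same scale by construction.  Intergenic strains are
neutral; chimeric barcodes carry no abundance (they are mapping artifacts).
At `fidelity="reads"` the counts are wrapped into FASTQ — junction reads for
mapping, BarSeq reads with a random 0–15 nt stagger prefix emulating the
staggered forward primers — and with error rates at zero the pipeline
recovers the count-level table exactly (a tested round trip).

What the generator does **not** model, and what passing tests therefore do
not show about real data: PCR and sequencing substitution errors in barcodes
(so no 1-mismatch barcode rescue is needed or implemented), uneven
per-sample depths, plant-side population bottlenecks, polar effects of
insertions on operons, and real genomes' non-uniform TA density and gene
overlap structure.  Recovery rates measured here are upper bounds on real
performance.

## Numerical and engineering choices

* All randomness flows from one integer seed; each simulation stage draws
  from an independent generator keyed by (stage, seed), so stages can be run
  separately with identical output, and full-pipeline runs are byte-identical
  under a fixed seed.
* Modal-site ties in reliability calling break deterministically (count,
  then lexicographic key).
* TSV floats are written with 4 decimals; unscored values are written as NA.
* Validation scale: the test suite and the acceptance script run the default
  configuration (counts fidelity) for estimator checks, and a reduced
  per-sample depth of 2·10⁴ reads for the end-to-end reads-fidelity
  determinism check — determinism is scale-free, so the reduced depth loses
  nothing.

## Known limitations

* No replicate-aware variance estimation: a screen with one pooled sample
  per condition cannot estimate between-replicate dispersion, which is why
  the t-score is a consistency measure, not a calibrated p-value.
* Exact-match flanks and seeds: reads with sequencing errors in the flank,
  barcode, or seed region are dropped, not rescued.
* Full-scale screens (hundreds of thousands of barcodes, tens of millions of
  reads) would want the seed index and counting loops vectorized or
  memory-mapped; the implementation targets library-scale clarity at desk
  scale.
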