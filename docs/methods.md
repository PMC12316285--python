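# Methods

`pulhaplo` re-implements, as a tested library, the survey machinery used to
map the porphyran polysaccharide utilization locus (PUL-PorB) of *Bacteroides
plebeius* across human gut genomes and metagenomes: locus detection in
assemblies, haplotype-group classification with recombinant detection,
exact-match probe screening of raw short reads, and cohort-level statistics.
This note records the models, the tunable parameters and their defaults, the
numerical choices, and what the synthetic cohorts do and do not establish.

## The locus model

PUL-PorB is modelled as six ordered CDSs — sulfatase S1_11, GH29, GH16
(methyl-porphyranase), SusD-like, SusC-like, GH2 (bacple_01701–01706) —
spanning 12,888 nt with intergenic spacers, coordinates 0-based half-open.
Real reference sequences are not redistributed: `build_reference` synthesizes
a locus with the authentic architecture (gene order, realistic CDS lengths,
authentic total span, stop-free frames).  Every screen in the package depends
only on identity/coverage thresholds relative to whatever reference it is
given, so the synthetic stand-in exercises the machinery faithfully; absolute
statements about the real locus sequence are of course out of reach of such a
stand-in.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, with
these study conditions as defaults:

| parameter | default | meaning |
|---|---|---|
| `prevalence` | 0.30 | per-sample carriage probability (East-Asian range) |
| `group_freqs` | GI .45 / GII .35 / GIII .15 / GIIIrec .05 | carrier group draw |
| `gii_identity_band` | (0.96, 1.00) | GII protein identity to the GI reference |
| `giii_identity_band` | (0.92, 0.98) | GIII protein identity to the GI reference |
| `within_group_identity` | 0.995 | per-sample micro-variation (nt) |
| `read_length` | 150 nt | single-end reads |
| `depth_bounds` | (5e3, 5e4), log-uniform | per-sample read count |
| `seq_error_rate` | 0 (set per experiment) | per-base substitution error |
| `background_genome_size` | 30,000 nt | i.i.d. ATGC host background |
| `mag_dropout` | 0 | per-gene deletion probability (incomplete MAGs) |

Group references are derived from the GI base per gene: exactly *n*
amino-acid positions are swapped to different non-stop residues so the
realized protein identity is `1 − n/n_aa`, landing inside the configured
band by construction, plus roughly *n*/2 synonymous codon swaps to diversify
the nucleotide sequence.  The GIIIrec reference is a GI × GIII mosaic —
sulfatase, GH29 and GH16[:bp] from GIII; the rest from GI — with the
crossover codon-aligned.  The crossover is drawn from the central 80% of
GH16 restricted to positions that a single 54-nt window can straddle while
separating all four groups; this mirrors the empirical fact that the
published mosaic admits exactly such a diagnostic window, and degenerate
configurations (e.g. a zero-divergence band) fall back to a plain central
draw, with probe design reporting its own failure if attempted.

Two deliberate departures from naive uniformity:

* **Within-group micro-variation never touches GH16.**  The probes are
  exact-match; what makes 54-nt probes viable in reality is that the GH16
  diagnostic region is conserved within groups.  Mutating it at the
  within-group rate would make probe sensitivity a coin-flip of the noise
  model rather than a property of the method.
* **Backgrounds are i.i.d. ATGC and reads substitution-only.**  The screens
  threshold on identity and exact substring matches, not composition; indels
  are excluded because the probe matcher is exact-match by design.

What the generator does **not** emulate: real community composition and
taxonomy, paired-end or quality-profiled reads, indels, assembly chimerism.
Passing tests therefore show the pipeline's logic and thresholds behave as
specified under the stated divergence structure, not that the screens are
robust to artefacts absent from the model.

## Assembly screening

Two regimes reproduce the two published surveys:

* `locus_scan` — positive on any hit at ≥ 80% identity to PUL-PorB sequence
  (per-gene or whole-locus query), partial hits included, no coverage filter.
  Samples positive only through hits shorter than the shortest gene are
  flagged `ambiguous_partial` rather than silently counted.
* `gene_strict` — each of the six genes at ≥ 80% identity and ≥ 95% query
  coverage, translated hits passing protein QC (no internal stop; length
  ≥ 95% of the reference protein; frame inferred from the alignment start).
  A sample is complete when all six genes pass, possibly across contigs.

Alignment is BLAST-like local alignment (Smith–Waterman, match +1, mismatch
−2, gap −4; `N` matches nothing) with identity computed over alignment
columns and coverage as the aligned fraction of the query.  Gap cost
strictly exceeds mismatch cost so substitution-only homologs never acquire
cosmetic gaps.  A minimum local score of 40 stands in for BLAST's E-value
cutoff, rejecting spurious short perfect matches in random sequence.

Large contigs are screened by exact 13-mer seeding; each seeded diagonal is
evaluated as a maximum-scoring gapless segment (a 1-D Kadane scan), with an
edlib edit-distance check to detect candidates where indels would help.
Those are re-aligned with the full DP, whose gapped result replaces the
gapless one only when it wins by more than two gaps' cost: a genuine
frameshift dwarfs the gapless score, while marginal rearrangements of a few
mismatches around repeats should not trigger a frameshift QC failure.
Small inputs skip the heuristics and are aligned exhaustively.

Redundancy collapse keeps one representative per identical concatenated
sequence within a species label; identical sequences from different species
are retained.

## Haplotype groups, recombinants, trees

Each detected gene is assigned to the nearest group representative by
percent identity; all identities < 80% → unassigned (divergent); a margin to
the runner-up below 0.5 percentage points → unassigned (tie).  Contig-level
labels follow: concordant genes → that group; two contiguous discordant
blocks in locus order → recombinant, with GIII→GI labelled GIIIrec and
GII→GI labelled GIrec (the "outgroup GI" pattern); partial loci take their
majority group with a `partial` flag (which slightly under-calls
recombinants, whose diagnosis needs genes from both blocks); otherwise
outgroup.  Genes of one fragmented locus spread over several contigs are
merged before labelling; genuinely duplicated genes across contigs yield a
multi-group sample.

Recombination breakpoints are localized by a sliding-window scan (window
60 nt, step 3 nt, codon-aligned) of per-window identity to the two parents
along a fixed end-to-end comparison; the reported interval spans from the
last window strictly closer to the upstream parent to the end of the first
window strictly closer to the downstream one.  An interval, never a point,
is reported — it provably contains the true crossover whenever the parents
diverge on both sides — and multiple switches are flagged as
multi-crossover.

Trees are neighbor joining (Saitou–Nei) on p-distances of concatenated
protein sequences in locus gene order (the distance model of the original
tree-building software is unstated; p-distance is the assumption-free
choice at within-locus divergences of ≤ 8%).  Pair selection ties break
lexicographically for determinism; negative branch lengths are clamped to
zero with the excess moved to the sister edge, preserving the pair path
length so additive matrices are still recovered exactly; the last three
clusters join at a trifurcation by the three-point formula.  Bootstrap
supports are column-resampled replicate fractions per original bipartition.

## Probe screen

`design_probes` picks the 54-nt window of the aligned GH16 sequences that
separates every pair of groups by ≥ 1 substitution (all groups probed at the
same offset, as in the published design), maximizing the number of
diagnostic columns, and verifies at design time that each probe matches its
own group's reference and no other's.  Reads count for a probe iff the probe
or its reverse complement is an exact substring (the 100% identity / 100%
coverage rule); reads shorter than 54 nt are skipped; a read matching
several probes counts once, for the first probe in fixed order, and is
flagged.  Per sample: positivity = ≥ 1 matching read; group characterization
requires ≥ 10 matching reads; `single` if one group holds all reads,
`dominant` if the major group's fraction is strictly above 0.80, else
`multi`.  Relative abundance is matching reads over total reads.

## Cohort statistics

Prevalence uses Wilson 95% intervals.  Probe validation reports
sensitivity = both/(both + truth-only) and specificity = TN/(TN + test-only).
Contingency tests are Pearson chi-squared without continuity correction
(zero margins dropped with a warning; expected counts < 5 warned).
"q-values" are Benjamini–Hochberg FDR within each test family (pairwise
population comparisons; per-group prevalence contrasts).  Abundance is
compared on the log10 scale by one-way ANOVA, reflecting its
orders-of-magnitude spread; coverage-vs-prevalence association is a Pearson
correlation over per-dataset means, refused below three datasets and
flagged degenerate when either variable is constant.

## Problem sizes

The shipped checks run at desk scale, chosen to give stable binomial
estimates while staying cheap: recovery cohorts of 300 samples (≈ 90
carriers) at prevalence 0.3; concordance cohorts of 150 samples at fixed
depth 10⁴; 200 chimeras for breakpoint localization; 200 random additive
matrices (n ≤ 12) for NJ exactness; 1,000 random pairs for the alignment
oracle; 500 replicates for null calibration.

## Known limitations

* The locus reference, group representatives and probes are synthetic
  stand-ins with the authentic architecture and divergence structure, not
  the real sequences; all reported recovery rates are conditional on the
  generator's model.
* The seeded screen assumes a clean k-mer seed survives (guaranteed down to
  ≈ 75% identity at these gene lengths); remote homology below the 80%
  threshold is out of scope, as is translated (protein-level) search.
* `scan_breakpoint` requires end-to-end alignable (equal-length) inputs and
  cannot place a crossover where the parents are locally identical.
* Multi-crossover mosaics are flagged but not phased; formal recombination
  statistics are out of scope.
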