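# Methods

This note records the statistical conventions, design choices and known
limitations of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate model

Features live on a circular genome with 1-based inclusive coordinates
(GenBank convention). A feature spanning the origin is stored with
`start > end` and has length `(L − start + 1) + end`. Strand labels H/L map
to GenBank `+`/`−`. All sequence-level statistics for a gene are computed
on its **sense** strand: an L-strand gene is the reverse complement of the
heavy-strand range. This is what makes the published pattern reproducible —
the single light-strand protein gene (ND6) shows skews of opposite sign to
every heavy-strand partition only when read on its own strand.

### Spacers and the overlap/IGN summary

The intergenic value attributed to a feature is the signed gap to the
**next** feature in annotation order, `next.start − end − 1`, with the last
feature wrapping to the first. The published table we transcribe prints
exactly these next-feature values (its footnote says "previous gene", but
the printed numbers — e.g. 20 on the tRNA-Val row for the Val→16S gap — are
unambiguous). Under this convention the telescoping identity
`Σ(length + spacer) = L` holds on every circular annotation, which the
suite checks on random layouts.

The genome-wide summary counts overlaps as negative spacers and intergenic
(IGN) regions as positive spacers **excluding** the spacer whose downstream
feature is the control region: the flank of the control region is treated
as part of that region's neighbourhood, not as an intergenic spacer. On the
bundled *R. luxiensis* table this exclusion (a single 16-bp tRNA-Pro →
D-LOOP gap) yields the published 17 regions / 84 bp; counting it gives
18 / 100. The behaviour is exposed as `count_dloop_flank` (CLI:
`--count-dloop-flank`), default off. The 32-bp NCR is an annotated feature,
not an IGN region. One transcription note: the published tRNA-Ser(GCT) row
prints length 67, but its own coordinates, the printed spacers on both
sides and the telescoping identity force 69; the package reports
coordinate-derived lengths throughout.

### Stop-codon classification

Complete stops are {TAA, TAG} (the genomic terminators of vertebrate
mitochondrial genes; the code-table stops AGA/AGG are not used as
annotation-level terminators). A sense length of 3k+2 with trailing `TA`
yields token `TA-`, 3k+1 with trailing `T` yields `T--` — the incomplete
stops completed to UAA by polyadenylation. Anything else yields `other`
with a warning, never an exception, since imperfect annotations are common.

## Composition and skews

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), computed from raw counts and
rounded only for reporting (default 2 decimals). Ambiguity codes are
excluded from numerator and denominator entirely — the simplest defensible
rule; fractional allocation would manufacture precision. A second path,
`skew_from_percentages`, applies the formulae directly to printed
percentage tables for auditing published work; the bundled *R. luxiensis*
composition table audits cleanly on every row at 2 dp. Partition rows are:
each protein gene (sense strand), concatenated rRNAs / tRNAs / control
region / all-PCGs in annotation order, and the whole heavy strand. PCG
partitions use full annotated ranges including stop codons.

## Codon usage and RSCU

The genetic code defaults to NCBI translation table 2 (vertebrate
mitochondrial, 60 sense codons) and is overridable; synonymous families are
derived from the code table at run time, never hardcoded. Serine is split
into Ser1 (TCN box) and Ser2 (AGY), the conventional reporting split
(different tRNAs decode the two boxes); leucine remains one six-codon
family, the largest in the code. Counting rules — the declared audit
convention: reading frame from position 1, start codons included, complete
terminal stops excluded, trailing partial codons (incomplete stops)
dropped, codons containing N tallied separately, internal stops warned and
excluded. RSCU(c) = count(c)·k/n for a family of size k with total n;
families with n = 0 are reported empty. Within every nonzero family RSCU
sums to k and averages to 1 (property-tested). Reports use the RNA
alphabet, as codon-usage figures conventionally do.

## Ka/Ks (Nei–Gojobori 1986, Jukes–Cantor corrected)

The estimator is implemented in full rather than wrapped, pinned to the
classical pathway-counting method:

* **Sites.** For each codon position, the fraction of the three possible
  point mutations that are synonymous, computed over mutations that do not
  create a stop codon; S = Σ fractions, N = 3 − S, so S + N = 3 × codons
  exactly.
* **Differences.** A codon pair differing at d positions averages the
  synonymous/nonsynonymous step classification over all d! orderings with
  equal weights; pathways through stop codons are excluded; if every
  pathway is blocked the codon pair is skipped and counted.
* **Correction.** pS = Sd/S̄, pN = Nd/N̄ with sites averaged over the two
  sequences; d = −(3/4)·ln(1 − 4p/3), undefined (flagged, never infinite)
  at p ≥ 3/4.
* **Aggregation.** Per gene, over all unordered taxon pairs: the ratio of
  mean distances (mean Ka / mean Ks), not the mean of ratios — per-pair
  ratios explode when a pairwise Ks is near zero; saturated pairs are
  excluded and counted.

Codon pairs with gaps or ambiguity in either sequence are skipped pairwise,
as are pairs involving a stop codon (untrimmed terminal stops are thereby
harmless). Equal pathway weighting and Jukes–Cantor correction are the
classical defaults of the standard desktop implementations of this method;
modified-NG (transition/transversion-weighted) and ML codon-model
estimators are deliberately out of scope. The implementation is verified
against an independent brute-force pathway-enumeration oracle to 1e−9 and
loosely cross-checked against Bio.codonalign's NG86 (whose handling of
stop-adjacent mutations differs slightly, so that check is at ~15%, not
exact).

## Monophyly

A genus with ≥ 2 tips is monophyletic on an unrooted tree iff some edge's
bipartition separates exactly its tips from the rest. The unrooted
criterion was chosen over a rooted-clade test because published figures'
rooting is an editorial choice; verdicts are invariant under rerooting
(tested). Singleton genera are labelled `trivial`; a genus covering all
tips is monophyletic by definition; tips on an explicit ignore list (e.g.
outgroups) are excluded, with bipartitions restricted to the mapped tips.
Genus extraction from tip labels defaults to the token before the first
underscore and is configurable by regex. Published genus-level verdicts for
a specific figure are reproducible only given a machine-readable tree for
that figure; none is bundled.

## Synthetic data

### Mitogenome generator

The default `GenomeSpec` is the published *R. luxiensis* layout: a
16,592 bp circle, 13 PCGs / 22 tRNAs / 2 rRNAs / NCR / control region at
the published coordinates, strands and planted start/stop codons — so the
generator plants, among other things, one GTG start (COX1-like), three
incomplete stops, ten overlaps (max 7 bp) and seventeen IGN regions.
Background sequence is i.i.d. from a heavy-strand base bias, default
A 0.320 / C 0.262 / G 0.157 / T 0.261 — the published whole-genome
composition of this mitogenome, i.e. the A- and C-rich heavy strand typical
of fish mitogenomes. PCG bodies are overwritten with codons sampled from
the product-of-base-bias distribution over sense codons; **light-strand
genes sample from the complement bias**, because the asymmetry is a
property of the strand, not the gene — this is what makes the ND6-like
gene's sense skews flip sign, as in real data. Start/stop codon positions
are hard locks applied after all writes; a repair pass resamples any codon
that an overlapping write turned into an in-frame stop, honouring locks
(mutually inconsistent locks raise an infeasible-layout error). The truth
record carries every planted discrete fact plus the exact per-base expected
counts and standard deviations of the heavy strand under the generative law
(locked positions contribute zero variance; the few repaired codons are
treated as ordinary codon positions, a negligible approximation at
~50 / 16,592 positions), so composition recovery is tested as a proper
z-score at 3 SE.

What the generator does **not** emulate: codon-position-specific
composition structure, tRNA secondary-structure constraints, control-region
tandem repeats, and any phylogenetic signal. Passing round-trip tests
therefore shows the characterisation arithmetic is correct on data with the
published annotation geometry and composition bias — not that the package
handles mis-annotated or structurally unusual real records.

### Codon-alignment simulator

Descendants evolve independently from a common ancestor on a **star tree**
under a continuous-time codon process: single-nucleotide changes only,
relative rate κ for transitions vs 1 for transversions, × ω when the change
is nonsynonymous, 0 into stops. The rate matrix is rescaled so one unit of
branch length equals one expected substitution per codon at the ancestral
distribution. Defaults: 10 taxa, 500 codons, ω 0.2, κ 2 (a standard
moderate transition bias), root-to-tip branch length 0.2 substitutions per
codon (pairwise divergence ≈ 0.4 per codon — clearly diverged, far from
saturation), ancestral codons uniform over the 60 sense codons with an
optional biased mode using the composition-bias weights. Exact stochastic
simulation (per-site jump chains), fully vectorised; every jump is logged
as synonymous or nonsynonymous and the truth record stores the realized
counts next to the process's expected nonsynonymous flux fraction, so the
simulator's fidelity to ω is itself tested. A star tree is sufficient for
exercising a pairwise estimator; it does not reproduce the covariance
structure a real phylogeny induces between pairs, which is a stated
limitation, not a target.

Estimator-recovery checks run at 10 taxa × 500 codons × 20 replicates per
ω ∈ {0.05, 0.2, 0.5, 1.0} — small enough to run in seconds, large enough
that rank concordance and the neutral band are stable. NG86 with κ > 1 has
a known mild downward bias at ω = 1 (transition bias concentrates change on
synonymous sites relative to the equal-weight site counting); at κ = 2 the
neutral runs average ≈ 0.85, within the documented 0.8–1.25 band.

## Numerical and degenerate-input conventions

* Skews and RSCU computed from raw counts; rounding only at report time
  (2 dp default, full precision in JSON).
* Undefined quantities (Ks = 0 ratios, saturated corrections, empty RSCU
  families, all-N composition) are flags/omissions or typed errors — never
  NaN or infinity in outputs.
* Frequency ties in top-codon reports break alphabetically.
* All randomness flows through explicit `numpy` generators seeded per spec;
  no global random state anywhere.
* Reports are written atomically (temp file + rename); every JSON report
  embeds package version, configuration and seed.

## Known limitations

* No de novo annotation, ORF finding, tRNA structure prediction, alignment
  construction or tree inference — inputs are assumed annotated/aligned.
* GenBank reading handles simple and origin-spanning join locations; exotic
  compound locations (multi-segment trans-splicing) are rejected.
* The Ka/Ks module offers NG86 only; for strong transition bias or high
  divergence, model-based estimators will differ.
* Monophyly verdicts are purely topological; support values are carried but
  not used to qualify calls.
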