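# Methods

This note documents the models and conventions behind `ensemblevar`:
what each stage computes, the parameters that matter, what the
synthetic generator does and does not emulate, and the choices made
where the design was genuinely open.

## Variant model

Every call is reduced to a biallelic, sequence-explicit record:
chromosome, 1-based position of the first REF base, REF/ALT alleles
over `{A,C,G,T,N}`, a diploid unordered genotype, and optional GQ
(Phred-like genotype quality) and DP (read depth). Multiallelic VCF
rows are split at parse time; for each split allele the genotype is
projected so that the kept ALT maps to index 1 and every other allele
(REF or a different ALT) to 0, i.e. carrier status for that allele.
Phase separators are ignored, haploid calls are promoted to homozygous
diploid, and half-missing genotypes (`./1`) are treated as fully
missing — they never support a consensus vote and never match a truth
genotype.

Classification uses the signed length `len(ALT) − len(REF)`:
|length| 1–49 bp is an indel, ≥ 50 bp an SV (INS or DEL by sign).
Inversions and duplications are SVs regardless of signed length
(an inversion's is 0); they are recognized from a symbolic ALT or an
`SVTYPE` INFO tag, which `write_vcf` also emits so that the class
survives a round trip. Length-0 substitutions without such a tag are
treated as SNP class; multi-base balanced substitutions are rare in
genotyper output and are never credited by the evaluator's
allele-identity rule for SNPs. For size comparisons, inversions and
duplications use their reference span (`end − pos + 1`); everything
else uses |length|. A tandem duplication is represented explicitly as
REF = the duplicated span, ALT = the span doubled, so its span and its
signed length agree.

## Input normalization and filtering

`reformat_vcf` resolves symbolic `<DEL>`, `<INV>` and `<DUP>` alleles
against the reference FASTA using their END coordinate; symbolic
insertions cannot be resolved (the inserted sequence is unknowable) and
are dropped with a logged reason, as is any record whose alleles
contain characters outside `{A,C,G,T,N}` (`*`, IUPAC codes, breakend
notation). Soft-masked lower-case bases are upper-cased rather than
rejected. Byte-identical records (same chrom/pos/REF/ALT) collapse to
the first occurrence.

MAF is computed over the alleles of non-missing genotypes only
(missing samples leave the denominator); the missing rate is the
fraction of samples without a call. Filtering is off by default; when
enabled, thresholds are inclusive on the keep side (MAF ≥ `min_maf`
and missing rate ≤ `max_missing_rate` are kept). A site where every
genotype is missing has undefined MAF and fails any MAF filter.

## Genotyper selection

`select_genotypers` is a pure function of genome size, read length,
depth, data type and mode. Short-read runs always include BayesTyper
and Paragraph (Paragraph restricted to SVs in fast mode, all variants
in precise mode); vg giraffe replaces vg map for genomes larger than
1 Gb (1 × 10⁹ bp, strict); GraphTyper2 joins when read length > 130 bp
**and** depth > 5×; PanGenie joins when depth < 5× **or** read length
< 130 bp. All inequalities are strict, so at exactly 130 bp or 5×
neither conditional tool is selected — a documented boundary
convention, since the two quoted conditions do not cover the equality
case. Long-read runs short-circuit to GraphAligner + vg. The plan also
carries the read-subsampling fraction
`min(1, target_depth / depth)` with a 15× default target; the
standalone `subsample_fraction` computes the same from total sequenced
bases. The plan is advisory metadata: this package never launches the
external genotypers, it merges whatever output VCFs are supplied.

## Merging

Clustering is anchored on the input (population) variant set: each
cluster has exactly one anchor, which defines the coordinates and
alleles of the merged record. This makes output coordinates
well-defined and mirrors the merge's purpose of restoring the
coordinates the per-tool outputs should correspond to. A call is
admissible for an anchor of the same class (and, for SVs, the same
type) when:

* SV: start-position difference < `sv_pos_tol` (200 bp) and
  length-difference ratio < `sv_len_ratio` (0.25), the anchor's
  length being the denominator (the input variant is the reference
  truth for its cluster; the ratio's denominator is otherwise
  ambiguous);
* indel: position difference < `indel_pos_tol` (10 bp), same ratio
  rule;
* SNP: exact position match (`snp_pos_tol` 0).

Merge position tolerances are strict ("less than"), while the
evaluator's SV tolerance is inclusive ("within") — both follow their
respective stated rules literally and both are configurable. The merge
tests only the start coordinate; the evaluator additionally tests the
end breakpoint. Among multiple admissible anchors the nearest by
position wins, ties broken by smaller length difference, then lower
anchor position. A tool contributes at most one call per node; a
tool's second-best call for an anchor is left unassigned rather than
spilled to another anchor. Unassigned calls are returned as data, not
errors.

Depth normalization is the per-tool Z-score `D' = (D − μ)/σ` with the
population standard deviation (divisor N) over all of the tool's
depth-bearing calls. σ = 0 maps every `D'` to 0 (depth carries no
information); calls without DP carry no `D'` and lose any depth
tie-break to a call that has one.

Consensus: the genotype with the highest support count wins. Small
variants require support ≥ 2, otherwise the variant is skipped. SV
nodes where every distinct genotype has support 1 take the genotype of
the call with smallest |D'|. Ties among equally supported genotypes
(support ≥ 2 each) are resolved by smallest |D'| as well — the natural
extension of the all-support-1 rule — with a final deterministic
fallback on lexical allele order. Merged records carry the supporting
tool list and count in INFO (`TOOLS`, `SUPPORT`).

## Evaluation

Presence and genotype correctness are scored per class (SNP, indel,
and SVs split into DEL/INS/INV/DUP):

* SV presence: |Δstart| ≤ 200 bp, |Δend| ≤ 200 bp, and size difference
  ≤ 25% of the true size (all inclusive). An insertion's end equals
  its start, so its end test degenerates to the start test.
* Indel presence: |Δposition| < 10 bp (strict). No size rule is
  applied by default; `MatchRule.indel_size_check` adds the
  clustering-style ratio test for users who want it.
* SNP presence: exact position **and** REF/ALT identity, so a
  mismatched substitution is never credited.
* Genotype level: presence plus unordered allele-pair equality.

Matching is one-to-one: greedy in genomic order, each call taking the
nearest still-unmatched truth variant within tolerance. On
deduplicated truth sets (anything spaced beyond twice the tolerance,
which merged benchmark sets are) this equals optimal bipartite
matching; the test suite verifies that equivalence against
`scipy`'s maximum bipartite matching on random instances. Precision =
TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R); ratios with empty
denominators are reported as undefined (`None`) rather than 0.

Precision–recall curves sweep the score threshold over a **fixed**
pairing computed once from all scored calls (the standard ranked
construction): at threshold t, TP counts pairs whose call scores ≥ t.
This keeps recall monotonically non-increasing in t and makes the
loosest point equal the overall metrics exactly. The score is GQ with
DP substituting when GQ is absent (or DP directly); calls with neither
are excluded from the sweep.

Stratified evaluation books each matched pair and each false negative
in the truth variant's stratum and each false positive in the call's
own stratum, so per-stratum counts sum exactly to the overall report.
Strata are either half-open signed-length bins or ordered BED region
sets (0-based half-open; first-listed set wins overlaps; "non-repeat"
fallback).

## Synthetic data

The generator replaces a read-simulation + genotyping stack at desk
scale. `make_reference` draws uniform A/C/G/T sequence.
`spike_variants` places the requested counts per class into evenly
spaced slots with random jitter, guaranteeing at least `min_spacing`
(default 600 bp, comfortably above the 200 bp clustering tolerance so
clusters are unambiguous) between events, and errors out when the
requested counts cannot be packed. Each variant is heterozygous with
probability `het_fraction` (default 0.5; applied to one random
haplotype) else homozygous; the returned haplotype sequences have the
variants applied, and haplotype length minus reference length equals
the sum of applied signed lengths — a bookkeeping invariant the tests
check.

`simulate_outputs` corrupts the truth per emulated tool: drop with
probability `fn_rate`, miscall the genotype with probability
`genotype_error_rate` (drawing a different genotype from {0/0, 0/1,
1/1}), jitter SV breakpoints and lengths with rounded zero-mean
Gaussians, draw DP from a truncated normal (min 1) and GQ around
separate means for correct (55) versus wrong (20) genotypes so
threshold sweeps are informative. One global seed fans out through
`numpy.random.SeedSequence`, so adding a tool never perturbs the
streams of existing tools.

Default experiment conditions (used by `scripts/acceptance.py` on a
single 2 Mb chromosome): 500 SNPs, 200 indels, 100 deletions, 100
insertions, 50 inversions, 50 duplications (1000 variants); three
tools with `fn_rate` 0.1, `genotype_error_rate` 0.05, and 5 bp
breakpoint/length jitter. These rates sit in the range where single
tools land near F ≈ 0.9 and majority voting visibly helps, the regime
the ensemble is designed for; the 2 Mb/1000-variant scale keeps the
full experiment under a few seconds while leaving ≥ 50 events in the
rarest class.

What the generator does **not** emulate: read-level error models,
repeat-derived insertion sequences, clustered or overlapping variants,
reference bias, or correlated tool errors (real genotypers sharing an
alignment step fail together more often than independently). Passing
the end-to-end tests therefore demonstrates the correctness of the
clustering/voting/evaluation machinery and the ensemble-gain mechanism
under independent errors — not genotyping accuracy on real genomes.

## Numerical conventions and degenerate inputs

* Population (divisor-N) standard deviation throughout the Z-score.
* σ = 0 → all D' = 0; missing DP → no D'; depth tie-break treats a
  missing D' as +∞.
* All position tolerances are integers of base pairs; ratio thresholds
  are dimensionless fractions.
* Empty truth → recall undefined; empty call set → precision
  undefined; both reported as `None`, never coerced to 0.
* Anchor length 0 in the ratio rule (only possible for a degenerate
  zero-span record) admits only calls of length 0.
* Iteration and output order is always (chromosome, position, REF,
  ALT) lexicographic, making every stage deterministic.

## Known limitations

* Biallelic, diploid, single-sample merging only; ploidy > 2 and
  joint multi-sample genotyping are out of scope.
* No sequence-resolved comparison: two insertions of similar length at
  the same position are considered the same event.
* No indel left-alignment/trimming; inputs are assumed normalized.
* BND/translocation records and symbolic insertions are rejected at
  the convert stage rather than modeled.
* The greedy evaluator pairing can in principle differ from optimal
  matching on adversarially dense truth sets (spacing below the
  tolerance); on deduplicated benchmark sets the two coincide.
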