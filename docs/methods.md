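# Methods

## Scope and model

The pipeline identifies candidate regulatory small RNAs (rsRNAs) from
pooled small-RNA sequencing over paired tumor/normal conditions without
assuming canonical miRNA biogenesis. Its working hypotheses are (i)
recurrence of the exact sequence across many independent conditions argues
against degradation noise, (ii) repression should leave an anti-correlation
footprint between the sRNA and its targets across samples, and (iii)
physical interaction data (Argonaute CLIP, CLASH chimeras) provides direct
evidence of target engagement. A candidate must satisfy *all* of:
abundance (≥ `min_reads` summed copies within some condition), recurrence
(non-zero count in ≥ `min_conditions` conditions), not a known mature
miRNA, a two-predictor consensus target site, CLIP or CLASH support, and a
≥ `fold_change_min` tumor/normal fold change in at least one condition.
All clauses are conjunctive, so the surviving set is independent of the
stage order; rejection statuses name the first failing stage in cascade
order (known-miRNA → abundance → recurrence → no target → no interaction →
not differentially expressed).

Biogenesis, anti-correlation and genomic annotation are descriptive layers
computed for survivors, not filters — mirroring how the cascade is meant to
be used: first establish regulatory existence, then characterize origin
and processing.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `min_reads` | 5 | copies summed within one condition ("at least five reads"); ≥ comparison |
| `min_conditions` | 2 | distinct conditions with non-zero count; presence = count ≥ 1 |
| `max_genome_mismatches` | 2 | Hamming budget for genome mapping (no indels, both strands) |
| `max_duplex_mismatches` | 2 | substitution budget of the full-length duplex predictor; G:U counts as a mismatch unless `wobble_allowance` > 0 |
| `flank_bp` | 100 | window half-width around the sRNA start for hairpin analysis; window = [start − 100, start + len + 100], extracted on the hit strand |
| `fold_change_min` | 2.0 | tumor/normal RPM fold change threshold, either direction |
| `pseudocount` | 0.5 | added to both RPM means so the fold change is defined at zero |
| `pcc_max`, `p_max` | −0.5, 0.05 | anti-correlation screen: Pearson r ≤ −0.5 and p ≤ 0.05 |
| `min_stem_pairs` | 16 | minimum base *pairs* in a detected stem (≈ 32 paired bases, a canonical pre-miRNA-scale stem) |
| `min_loop_nt` | 3 | minimum unpaired terminal loop |
| `max_bulge_nt` | 2 | total unpaired bulge nucleotides allowed along a stem (see below) |
| `cnnc_center` ± `cnnc_tolerance` | 17 ± 2 | downstream offset of the CNNC tetramer from the precursor 3′ end (offset 1 = first downstream base) |
| `basal_u_pos`, `basal_g_pos` | −14, −13 | upstream offsets of the basal U and G from the precursor 5′ end (offset −1 = immediately preceding base) |
| `stem_tolerance_nt` | 2 | an sRNA is "in the stem" if all but ≤ 2 of its bases lie within one arm |
| `clash_slop_nt` | 25 | slop added around the site when matching CLASH target fragments |
| `kd_absent_max` | 0 | "totally absent in knockdown" is encoded as count = 0 exactly; raise for noisy data |

RPM is always computed against the *full* pre-filter library size of each
sample: reads-per-million refers to the sequenced library, and normalizing
a filtered matrix against its own column sums would let library-composition
shifts cancel genuine fold changes.

## Hairpin detection

`detect_hairpin` maximizes the number of nested base pairs (Watson–Crick or
G:U) along a single stem — no multiloops — with the terminal loop holding at
least `min_loop_nt` unpaired bases. Unpaired bulge positions between
consecutive pairs are allowed, but their total along the stem is capped at
`max_bulge_nt`. The cap is essential: with unbounded (or merely per-step
bounded) bulges the objective degenerates into a longest-complementary-
subsequence problem, and essentially every ±100 bp window in random
sequence yields a long "stem" (each extension step offers ~16 candidate
anchor cells at 6/16 pairability), which would make hairpin presence
uninformative. With the default cap of 2, about one random 220-nt window in
five still reaches 16 pairs — hairpin-forming potential genuinely is
widespread in genomic sequence — so discrimination rests on the combination
of stem placement of the sRNA, the three Drosha motifs and knockdown
dependence, not on hairpin presence alone.

The search is an exact dynamic program over closed structures
`C[b][i,j] = 1 + max(0 if loop ok, max C[b−cost][i′,j′])` with bulge cost
`(i′−i−1) + (j−j′−1)`, evaluated anti-diagonally with numpy; ties break
toward the shorter precursor, then the leftmost, and the traceback prefers
the smallest bulge at every step, making the reported structure unique and
deterministic. The test suite checks the DP against a plain memoized
recursion on small windows. The pipeline runs hairpin/motif analysis only
for candidates already called DGCR8-dependent — the structural question is
whether Microprocessor-dependent candidates sit in a canonical pri-miRNA
context — which also keeps the quadratic DP off the critical path.

Motif scanning is anchored on the *detected* precursor interval, the only
self-contained boundary definition available. Insufficient flank for a
motif yields an indeterminate (None) flag, never an error. Internally all
sequence is DNA-alphabet (U→T on ingest), so the apical "UGU/GUG" is
scanned as TGT/GTG and basal U as T.

## Target predictors and interaction evidence

The seed predictor requires the 6-mer core complementary to sRNA positions
2–7 and classifies sites by the position-8 match and the A anchor opposite
position 1 (8mer / 7mer-m8 / 7mer-A1); bare 6-mers are dropped by default.
The duplex predictor slides a window of the sRNA's length and counts
non-pairing positions against the reverse complement. Consensus keeps
(sRNA, gene) pairs where a seed site and a duplex site overlap by ≥ 1
transcript nucleotide; the merged site spans their union and projects to
genomic coordinates through the exon structure (sites spanning junctions
project to multiple intervals, any of which may satisfy overlaps).

AGO support is the conjunction of peak overlap and read-set membership —
the stricter reading of "searched against the Argonaute sequencing data" —
with the disjunction available via `clip_require_read = false`. A
consequence of the near-perfect duplex criterion worth stating explicitly:
any target site complementary to the sRNA within the genome-mapping
mismatch budget is *itself* a genomic locus of the sRNA on the opposite
strand, so perfect-complement sRNA:target pairs are antisense-origin pairs
by construction. The antisense flag therefore reports a real geometric
fact, not an error.

## Genomic annotation

Loci are classed exon > ncRNA > repeat > intron > intergenic; a repeat
inside an intron is called repeat. Gene-model classes are strand-aware —
an sRNA only originates from an exon or intron transcribed in the gene's
sense; an antisense hit under an exon is not an exonic product — while
repeat and TAR overlap are strand-agnostic. Without strand awareness the
antisense geometry above would class every target site locus as "exon" and
make origin classification and the non-coding TAR denominator meaningless.
Percentages are reported against the total candidate count with 2-decimal
round-half-even. An `all_classes` summary mode counts an sRNA in every
class of its class set (and can therefore exceed the total), matching how
multi-locus molecules are sometimes tabulated.

Repeat meta-profiles map each hit's 5′ start onto the family consensus:
`consensus_offset` is the lowest consensus coordinate the copy covers;
position `rel` within the copy maps to `offset + rel` on a '+' copy and to
`offset + (copy_length − 1 − rel)` on a '−' copy. Out-of-consensus
positions are dropped with their weight counted, so profile mass plus
dropped weight always equals input weight.

## Statistics

Pearson correlations use pairwise-complete deletion (positions missing in
either vector are dropped) and the two-sided t approximation
`t = r·√((n−2)/(1−r²))` on n−2 degrees of freedom; |r| = 1 reports p = 0.
Fewer than 3 complete pairs or zero variance raise an explicit
undefined-correlation error; report tables show such rows as NA with a
reason. Correlations are computed on RPM vs RPKM/intensity/abundance as-is
by default (`log_transform_correlations` enables log2(x+1)). The
qPCR panel correlates raw Ct profiles; because Ct is inversely related to
abundance in both partners, repression still appears as a negative
coefficient. Reported coefficients are rounded to 2 decimals
(round-half-even) with full precision retained.

Welch's unequal-variance t-test backs both the per-condition expression
comparisons and the per-position repeat-profile tests; profile tests add
Benjamini–Hochberg q-values across consensus positions while the summary
counts raw p < 0.05, and gene-set enrichment uses the upper-tail
hypergeometric test with Bonferroni correction (the analysis this package
implements prescribes Bonferroni for enrichment; BH is reserved for the
positional tests).

## The synthetic cohort

The generator emulates the statistical structure the cascade assumes, at
desk scale: a 60 kb single-chromosome genome carrying 24 protein-coding
genes (3 exons, 2 introns, 250 nt 3′UTRs, a fifth of them on the minus
strand), 6 lincRNA genes, mutated copies of Alu-like (280 nt) and
LINE-like (500 nt) family consensi at 8% divergence with recorded
offset/orientation, and 6 intergenic stem-loops (perfect 30-pair arms
around a fixed apical loop, guarded by short non-pairable pads so the
detected precursor is exactly the designed one, with the three Drosha
motifs written at their configured offsets). Twenty rsRNAs are planted
across the four origin classes with complementary 3′UTR sites (8mer seed
kept intact, 0–2 recorded substitutions elsewhere), and twenty decoys each
probe exactly one filter: too rare, single-condition, identical to a known
miRNA, or lacking interaction support.

Counts follow a negative binomial with mean 50 and dispersion 0.1
(biological CV ≈ 30%, typical of abundant small RNAs) over 4 conditions ×
{tumor, normal} × 5 samples; each planted rsRNA is expressed in two home
conditions with a 4× fold change planted in the first. The background —
600 shared, condition-restricted sequences at mean 30 plus 50 one-copy
reads per sample — deliberately dominates library size, as in real sRNA
libraries, so that RPM fold changes track count fold changes; with a
candidate-only library, composition shifts between tumor and normal would
cancel much of the planted signal. Decoy counts are deterministic even in
the stochastic mode so that each decoy fails its designed clause by
construction. Anti-correlation is planted as a decreasing affine function
of the sRNA's RPM plus Gaussian noise with σ = sd(x)·√(1/r² − 1),
targeting r ≈ −0.8. Setting `nb_dispersion = None` switches to fully
deterministic counts (noiseless mode).

What passing tests on this cohort do show: the cascade's clauses implement
their definitions exactly (each decoy class is rejected at its designed
stage; planted entities survive), the algorithmic kernels agree with
brute-force reimplementations, and recovery is robust to realistic count
noise. What they do not show: performance on real libraries with
sequencing error, adapter remnants, PCR duplicates, isomiR heterogeneity,
multi-chromosome repeat structure, or batch effects — none of which the
generator models.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open everywhere (GFF3 converted on ingest;
abutting intervals do not overlap). The NA token in every TSV is `NA`;
reals serialize with 12 significant digits, making write→read round-trips
lossless at documented precision and repeated writes byte-identical.
Alignment order is deterministic (chrom, start, strand); identical (config,
seed) pairs reproduce byte-identical synthetic bundles. Zero-library
columns get all-zero RPM with a warning. Welch's test on two identical
constant groups returns (t = 0, p = 1). Empty read samples produce a zero
column with a warning, not an error.

## Known limitations

Alignment is Hamming-only (no indels or spliced alignment) by design, a
faithful re-implementation of fixed-mismatch ungapped mapping; quality
trimming and adapter removal are out of scope. The duplex predictor scores
substitution counts, not thermodynamics; an external folding backend could
replace the built-in stem maximizer but the shipped contract and tests
target the built-in. Multi-mapped sequences are counted once in the
expression matrix (expression is a property of the sequence); per-locus
attribution happens only in annotation. The default cohort sizes are a
package choice for reproducible desk-scale validation; all sizes are
configurable through `GeneratorConfig`.
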