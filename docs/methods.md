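# Methods

`lncforge` implements a desk-scale version of a plant lncRNA discovery and
functional-annotation workflow: starting from assembled transcripts it
identifies long non-coding RNAs by a coding-potential consensus vote,
classifies lncRNA–mRNA positional relationships, screens cis and trans
targets, detects miRNA decoy sites and precursor homologies, calls
differential expression between an early-flowering (EF) and a
normal-flowering (NF) variety across three bud stages (vegetative Vb,
transition Tb, reproductive Rb), and tests term enrichment. Because the
original sequencing data and genome build are not required, a synthetic
study generator with planted ground truth stands in for them; every stage
is validated against that truth or an independent brute-force oracle.

## lncRNA identification

Transcripts shorter than 200 nt are removed (inclusive boundary: 200 nt is
kept). Four coding-potential predictors are consumed as a score table,
never recomputed: CPC (< 0 votes non-coding), txCdspredict (< 500),
CNCI (< 0), and Pfam alignment (no alignment votes non-coding). A score
exactly at a threshold votes coding, following the "≥ threshold = mRNA"
convention. A transcript is called a lncRNA when at least 3 of the 4
predictors vote non-coding and it passed the length filter; everything
else is labelled mRNA. Transcripts with no score row are excluded and
logged rather than defaulted — absence of a predictor run is not evidence
in either direction. Both choices the inputs leave open (tie handling and
missing rows) are ours and configurable upstream of the vote.

## Positional pair taxonomy

Every overlapping lncRNA–mRNA pair is assigned exactly one of ten
categories spanned by three axes: same chain vs antisense, containment vs
partial overlap, and which partner contains the other. Containment means
the contained transcript's span (exon hull) lies within a *single* exon
or a *single* intron of the host — the singular reading; a transcript
straddling an exon–intron boundary of its host falls through to the
overlap categories. Checks run in a fixed priority (exon containment,
intron containment, lncRNA-in-mRNA before mRNA-in-lncRNA, then partial
overlap), which resolves ambiguous geometries deterministically;
identical spans resolve to a Lnc-CompleteIn category. Intervals are
0-based half-open internally; GTF I/O converts to and from the 1-based
inclusive convention. The classifier is checked against a per-base-position
set-containment oracle on 1,000+ random pairs and on a planted fixture
containing every category.

Cis candidates are mRNAs within 20 kb of a lncRNA span (overlap counts as
distance 0). The source rule names only a downstream bound, so the window
is symmetric ±20 kb by default, with independent upstream/downstream
window arguments; the output reports a signed distance (negative =
lncRNA upstream of the mRNA, in the mRNA's orientation) so either reading
can be applied as a filter.

## RNA–RNA interaction screens

**Duplex energy.** Trans-target screening needs a hybridization energy.
The scorer finds the optimal *gapless* antiparallel hybrid by dynamic
programming: a run of L stacked base pairs (Watson–Crick or G·U) scores
the sum of its L−1 nearest-neighbor stack terms from a built-in table
(kcal/mol at 37 °C; Watson–Crick entries follow the standard unified
parameters, G·U entries are representative values of the right magnitude,
and the table is rotationally symmetric so the energy is exactly
symmetric in its arguments). No bulges, internal loops or terminal
penalties are modelled — this is a deliberate simplification of full
secondary-structure hybridization tools, and externally computed energies
can be supplied to the trans screen in place of the built-in scorer. The
threshold "binding energy < 30" is read as ΔG ≤ −30 kcal/mol
(hybridization energies are negative; the printed rule drops the sign).
A trans target must additionally show Spearman ≥ 0.6 *and* Pearson ≥ 0.6
(inclusive) co-expression, computed across the six (variety × stage)
group means in the fixed order EF-Vb, EF-Tb, EF-Rb, NF-Vb, NF-Tb, NF-Rb;
a flag switches to replicate-level columns. Candidates inside the cis
window are excluded upstream. The pipeline evaluates the cheap
correlation criteria before the energy DP — a pure reordering of a
conjunction that does not change the reported set.

**miRNA decoy (target mimic) scan.** The reverse-complemented mature
miRNA (19–24 nt) slides along the lncRNA; each offset is scored per
position as perfect, G·U wobble (penalty 0.5) or mismatch (penalty 1),
with penalties doubled at miRNA positions 2–13, the seed-weighted scheme
of plant target-prediction servers. A site is reported when the summed
expectation is < 3 and mismatches + G·U pairs ≤ 4 ("no more than four
mismatches and G/U pairs" is read as a joint cap). Overlapping sites may
all be reported.

**Precursor matching.** Known hairpin precursors are locally aligned to
each lncRNA with BLASTN-like scores (match +2, mismatch −3, gap open −5,
gap extend −2); coverage is the aligned precursor fraction and a hit
requires coverage > 0.9 — strictly, so an exact 90 % insert is rejected.

## Expression statistics

FPKM is count / (length<sub>kb</sub> × library<sub>M fragments</sub>) and is used for
display and correlations only. Differential expression between two
(variety, stage) groups uses raw counts: median-of-ratios size factors; a
per-gene method-of-moments NB dispersion, α = max((s² − m̄)/m̄², 10⁻⁸),
pooled over the within-group residuals of *all* design groups (with the
full 18-library design that gives 12 residual df instead of the 4 df the
two contrast groups alone would give); and a Wald statistic for the log
ratio of pseudocounted group means, β = log(m̄_B + 1) − log(m̄_A + 1), with
SE² = Σ_g (1/m̄_g + α)/n_g. The statistic is referred to a **t**
distribution with the dispersion estimate's residual df: with triplicate
groups the plug-in variance makes a normal reference visibly
anticonservative (empirical type I ≈ 0.075 at α = 0.05 in our
simulations, vs ≈ 0.05 for the t reference). The cost is power at small n
— a deliberate trade toward calibrated error control. No dispersion
shrinkage or empirical-Bayes moderation is applied; each gene stands
alone. A transcript is differentially expressed at BH-adjusted P < 0.01
and linear fold change ≥ 1.2 applied two-sidedly (max(FC, 1/FC) ≥ 1.2),
since both up- and down-regulated sets are reported. The adjustment
procedure is Benjamini–Hochberg (the standard for RNA-seq), exposed as a
configuration choice.

Enrichment uses the exact hypergeometric upper tail
P(X ≥ m) for a term with M annotated genes in a population of N, given m
annotated among n sampled. The complement-of-lower-sum form
1 − Σ_{i<m} C(M,i)C(N−M,n−i)/C(N,n) is mathematically identical but loses
all precision for tails below ~1e-15, so the implementation sums the
upper tail directly with log-space binomials; m = 0 returns exactly 1.

## Synthetic study generator

The generator emulates the study design the pipeline expects — 2
varieties × 3 stages × 3 replicates = 18 libraries — and plants a known
truth for every stage: one lncRNA–mRNA pair fixture per positional
category; lncRNAs just inside (19,999 nt) and just beyond (20,001 nt) the
cis window; decoy sites as perturbed reverse complements with controlled
mismatch/G·U patterns (negative controls violate exactly one recorded
rule); precursor prefixes inserted at coverages 1.00/0.95 (positives),
0.85 (negatives) and exactly 0.90 (boundary control), with flanking bases
forced to mismatch the precursor tail so chance alignment extension
cannot move the measured coverage; and trans-target triples (complement +
shared stage profile; complement + anticorrelated profile; shared profile
without complementarity, re-drawn if a chance complementary stretch would
pass the energy cutoff). Counts are negative-binomial (variance
μ + αμ², a single shared α = 0.05 by default, the magnitude of
biological replicate variability in plant RNA-seq), with lognormal
baselines scaled to an expected 3 M fragments per library and a fold
change of 2 planted in the NF variety for designated genes. Predictor
scores land on the correct side of each threshold with probability
1 − predictor_noise (default 0.05), with an "exactly one dissenter" mode
for stressing the 3-of-4 vote. Transcripts occupy disjoint slots ≥ 30 kb
apart so no unplanned overlap or cis relationship arises. Everything is
deterministic given (config, seed).

What the generator does *not* emulate: read-level noise and mapping
artefacts, splice isoforms, codon structure (coding potential enters only
through the score table), GC or length bias, correlated dispersions, and
batch effects. Passing tests therefore demonstrate correctness of the
algorithms against their stated rules, not robustness to real-library
artefacts.

## Default problem sizes

The default study is 150 mRNAs + 150 lncRNAs on one 25-Mb chromosome —
small enough that the full pipeline runs in well under a minute while
still exercising every planted feature class. Checks that need specific
designs use their own sizes: the decoy screen uses 500 lncRNAs with 50
positive and 50 negative control sites; differential-expression
calibration uses 2,000 genes with 200 at fold change 2. On the planted
DE conditions (fold change 2, α = 0.05, n = 3) the calibrated test
attains sensitivity ≈ 0.1–0.15 at adjusted P < 0.01 with realized FDP ≈ 0
and null type I error ≈ 0.05; even with the dispersion known exactly, a
Wald test cannot exceed ≈ 0.65 sensitivity at these settings (E[z] ≈ 3.8
against a BH cutoff near z ≈ 3.3), so low sensitivity here reflects the
information in six counts per gene, not an implementation defect.

## Known limitations

- The duplex scorer is a stand-in for thermodynamic hybridization tools;
  absolute energies should not be compared across scorers, only through
  the configurable threshold, and external energies can be imported.
- The decoy expectation scheme reproduces the published seed-weighted
  convention but is isolated behind the scanner interface so external
  target-prediction scores could be substituted.
- The DE test deliberately omits dispersion shrinkage; with fewer than
  three replicates per group it refuses to run rather than guess.
- GO maps are taken as flat term → gene tables; no ontology-graph
  propagation is performed.
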