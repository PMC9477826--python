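# Methods

This note documents the models, conventions and deliberate simplifications
behind `picoccm`, in the spirit of a statistical-software methods appendix:
what each stage computes, which knobs matter, and what the synthetic-data
validation does and does not establish about real data.

## 1. Marker genotyping

**Panel.** 36 CCM gene families across six categories (RuBisCO, activases
and chaperones, Ci-responsive transcriptional regulators, carboxysome
components, carbonic anhydrases, inorganic-carbon transporters). Each family
carries reference sequences, thresholds and a search mode. Well-conserved
families use pairwise search (`score` mode); carbonic anhydrases and Ci
transporters, which diverge too far for a fixed identity cutoff, use a
position-specific profile (`profile` mode). The packaged panel is synthetic
(see §5); real panels ship as FASTA + `families.tsv` + aligned blocks.

**ORF extraction** is a six-frame scan: an ORF runs from a start codon
(ATG/GTG/TTG) to the next in-frame stop; per stop-bounded segment only the
longest ORF is kept; unterminated runs are dropped; coordinates are 0-based
half-open on the forward strand including the stop codon; the initiator
residue is reported as M. Default minimum length 60 codons. This is a
deliberately simple caller: it is exact on the well-separated ORFs the
simulator plants, and it is *not* a gene finder for real genomes — use a
dedicated caller there and load the proteome directly.

**Pairwise search** is exact Smith–Waterman with affine gaps (a length-k gap
costs `gap_open + k·gap_extend`; defaults BLOSUM62, 11/1). Reported
quantities: raw score; identity = matched columns / alignment length *with
gap columns in the denominator* (BLAST-style; switchable in interpretation
but this is what the 30% threshold is calibrated against); query coverage =
aligned query residues / query length. Ties between optimal alignments
resolve to the smallest (target end, query end), which makes output
deterministic. Kernels are numba-jitted; an independent plain-Python DP
oracle in the test suite pins down every convention.

**Detection rule** (score mode): a protein counts for a family when its best
hit is (i) significant — e-value ≤ 1e-3 under gapped Karlin–Altschul
statistics (λ = 0.267, K = 0.041) over the panel's score-reference search
space — and (ii) identity strictly > 30% with query coverage strictly > 75%
(per-family, overridable). The significance gate mirrors standard protein
search practice, where identity/coverage filters are applied to
e-value-thresholded hits; without it, short background ORFs occasionally
clear the bare percentage rule. Strict `>` comparisons are intentional: a
hit at exactly 30.0% identity or 75.0% coverage is excluded.

**Profile search**: per-column log-odds over a pre-aligned block,
`score(c, a) = log2(p_c(a)/bg(a))` with `p_c(a) = (n_c(a) + bg(a))/(N + 1)`
(one pseudocount spread by the uniform 1/20 background), local DP against
the profile with gap costs 4 + k bits, and a hit when the best local path
covers ≥ 50% of profile columns at ≥ 0.5 bits per covered column.

**Best-hit assignment**: each protein is credited to at most one family —
the best passing hit ranked by score, then identity, then lexicographic
family id — so paralogous shell proteins are never double counted. Copy
number is the count of distinct proteins assigned to the family.

**Genotype call**: α requires form 1A RuBisCO (`rbcL_1A` present,
`rbcL_1B` absent) *and* an α-carboxysome (`csoS1` and `csoS2`); β requires
the converse (`rbcL_1B`, `ccmK` + `ccmM`); everything else is `ambiguous`
(a value, not an error). Carbonic-anhydrase subfamilies are assigned by
best-scoring labelled reference, not by tree placement; on real data the
two can disagree for genuinely intermediate sequences.

## 2. Read recruitment and RPKG

Reads are seeded by exact k-mers (k = 21, both strands; a sparse
every-k-th-position pass with a dense fallback) and evaluated ungapped over
the full read length, so alignment length equals read length and identity is
the matching-base fraction. Per genome the best placement per read is kept;
across genomes, `best` mode (default) keeps the single highest-identity hit
per read (ties: longer alignment, then lexicographic genome id), while
`all` mode reproduces mapping each genome independently. Filters are strict:
identity > 95% and alignment length > 50 bp.

RPKG_g = hits_g / (genome length_g / 10³) / (metagenome bases / 10⁹). The
denominator is total bases, not read count, and depends only on summed
genome length (contig structure is irrelevant). Detection requires
RPKG > 2.0, strictly; sub-threshold genomes are zeroed for downstream
summaries with raw values preserved.

Dominance per metagenome: α-sum vs β-sum of thresholded RPKGs over genomes
with unambiguous calls (ambiguous genomes are excluded with a warning);
`alpha_dominant` uses strict `>`. Overall: the fraction of α-dominant
metagenomes, the ratio of medians (median α-sum / median β-sum), and a
paired Wilcoxon signed-rank test on the (α-sum, β-sum) pairs.

The built-in matcher is substitution-only by design, matched to the
simulator's error model so filter pass-rates have exact binomial
expectations. Real mappings (gapped, paired-end) should be produced
externally and imported as BLAST outfmt-6 or SAM.

## 3. Ordination and rank statistics

* **Kulczynski** (binary): `d = 1 − ½(a/(a+b) + a/(a+c))`. Degenerate rows:
  one all-zero row → d = 1; both all-zero → d = 0 (bounded, symmetric,
  logged when it happens).
* **Bray–Curtis** (non-negative abundances): `Σ|x−y| / Σ(x+y)`; two all-zero
  rows → 0.
* **PCO**: Gower double-centering of −½D∘D, symmetric eigendecomposition,
  coordinates `v_k·√λ_k` for λ_k > 0. Negative eigenvalues are reported but
  excluded from coordinates and from the variance-explained denominator (no
  Cailliez/Lingoes correction) — the simplest defensible convention; other
  software's "variance explained" can differ by a point or two on
  non-Euclidean matrices. Axis signs are fixed so each axis's
  largest-magnitude score is positive.
* **Per-gene axis drivers**: Pearson correlation between each gene's
  presence vector and the axis scores, ranked by |r| (constant vectors get
  r = 0). This is the vector-overlay reading of "per-gene eigenvalues":
  genes do not have eigenvalues in PCO, but their correlation with an axis
  measures how strongly they drive it.
* **nMDS**: Kruskal stress-1 with pool-adjacent-violators monotone
  regression of configuration distances on dissimilarity ranks
  (scipy's isotonic regression), Guttman-transform updates accepted only
  while stress decreases (per-start trajectories are monotone by
  construction), 20 random starts plus one PCO-seeded start, max 500
  iterations, tolerance 1e-6. The winning configuration is centered, scaled
  to unit RMS and rotated to its principal axes.
* **Wilcoxon signed-rank**: zero differences dropped, average ranks for
  ties, `W = min(W⁺, W⁻)`. Exact two-sided p by dynamic-programming
  enumeration of the null W⁺ distribution when n_effective ≤ 25 and no
  ties; otherwise the normal approximation
  `z = (W⁺ − n(n+1)/4) / √(n(n+1)(2n+1)/24 − Σ(t³−t)/48)` with a
  continuity correction by default. The correction is what makes the exact
  and normal paths interchangeable at the n = 25 switchover (worst-case
  two-sided-p gap 0.007 with it, 0.015 without — computed by full
  enumeration); pass `continuity_correction=False` for the plain deviate.
  Sign convention: z > 0 when the first member of the pairs tends larger;
  other software may report the opposite sign for the same data.

## 4. The synthetic-data generator

`generate_marker_variant` substitutes exactly `round((1−identity)·L)`
uniformly chosen positions to a uniformly chosen different residue, so
realized alignment identity tracks the target within ~2 percentage points
for L ≥ 50. `generate_genome` reverse-translates variants with uniform
codon choice (codon bias is irrelevant to protein-level search) and plants
each ORF as `ATG + codons + TAA` on a uniformly chosen strand, non-
overlapping, ≥ 100 bp apart, with an in-frame TAA guard immediately
upstream of each start so the six-frame caller recovers exactly the planted
span. `simulate_metagenome` draws each read's source genome proportional to
weight × length (length-weighted abundance), start positions uniformly, and
i.i.d. substitutions at the requested error rate; reads come from the
forward strand (the mapper searches both). All randomness derives from a
single integer seed per call; identical seeds give byte-identical output.

**What it emulates / what it does not.** It reproduces the features the
downstream statistics depend on: marker complements and copy numbers at
controlled divergence, known mixture weights, known per-base error. It does
*not* emulate genome architecture (operons, intergenic structure, real codon
usage), quality-score profiles, indels, chimeras, or inter-genome homology
(backgrounds are independent random DNA). Passing tests therefore establish
correctness of the computations and recoverability of planted parameters —
not performance on real genomes, where shared core genes make multi-mapping
and the best-hit policy genuinely consequential.

**Problem sizes.** Analyses and validation use 50-kb mini-genomes (the
generator's worked-example scale; marker complements fit comfortably with
wide spacers) in cohorts of 10 α + 10 β at planted identity 0.6, and 20
metagenomes of 10,000 × 150-bp reads at a 1% error rate mixed 7:1
(α:β summed abundance, split over 2 α + 2 β references). At these sizes the
full chain runs in about a minute; all sizes are parameters, and the
statistics scale with them in the obvious binomial way. One consequence of
the clean synthetic complements: within-group gene-content variation is
zero, so the gene-content PCO puts ~100% of the variance on axis 1 — real
collections spread variance across many axes.

## 5. The packaged panel is synthetic

`src/picoccm/data/synthetic_panel/` is generated by `scripts/build_panel.py`
from a fixed seed: per family, a random master sequence (160–300 aa,
starting with M) plus mutated companions (85% identity for score-mode
references; an aligned block at 75–85% for profile families). Family ids,
categories, search modes, thresholds and the α/β diagnostic structure are
the meaningful content; the residues themselves are simulated and carry no
biological signal. This is exactly what makes false-positive tests clean
(unrelated families share nothing) — and it means cross-family confusion on
real paralogs is untested here.

## 6. Known limitations

* The ORF caller and read matcher are validation-grade, not production
  gene-finding/mapping; real data enters through proteome FASTA and
  imported alignment tables.
* Identity uses alignment-length denominator; tools reporting
  match-column identity will disagree near thresholds.
* Nearest-reference subfamily assignment can disagree with phylogenetic
  placement for divergent carbonic anhydrases.
* Multi-mapping policy (`best` vs `all`) changes group sums when references
  share sequence; with independent synthetic genomes the two coincide.
* PCO variance-explained and axis-sign conventions vary across software;
  comparisons of single-axis percentages across tools carry a
  convention-dependent point or two of slack.
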