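# Methods

This note documents the models and procedures implemented in `rg4kit`, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical decisions taken where the design was open.

## RG4 prediction (`rg4kit.qgrs`)

A quadruplex-forming G-rich sequence (QGRS) is a window of at most
`max_qgrs_length` (default 30) nt containing four equal-length runs of
g ≥ `min_g_run` (default 2) guanines separated by three loops of length
`loop_min`–`loop_max` (defaults 0–36) nt. U and T are equivalent and input
is uppercased at ingest; `N` never counts as G. Only the sense strand is
scanned — quadruplex formation is a property of the transcript itself, so a
C-rich sequence yields no hits.

**Enumeration.** For every span (start, end) admitting at least one valid
four-run decomposition, the maximal-g decomposition is emitted; among
equal-g decompositions of the same span the highest-scoring is kept, ties
broken by lexicographically smallest loop vector. A quartic-time exhaustive
enumerator (`brute_force_qgrs`) with the same selection rule serves as the
oracle in tests and is never used in the pipeline itself.

**G-score.** The score must rank candidates the way quadruplex stability
does: strictly increasing in tetrad number, favouring shorter and more
even loops. We use the linear surrogate

    score = 20·(g − 2) + 0.5·(max_qgrs_length − 4g − Σ lᵢ) − (max lᵢ − min lᵢ)

which satisfies all four behavioural contracts (monotone in g; even-loop
optimal at fixed total; non-increasing in total loop length; the canonical
G3A2 motif GGGAAGGGAAGGGAAGGG scores 26, above the acceptance threshold of
19). The scorer identity (`surrogate-linear-v1`) is recorded in catalog
metadata so downstream consumers can detect a change of scoring scheme.
Candidates below `score_threshold` (default 19) are dropped; remaining
candidates are resolved greedily — highest score first, discarding any
candidate sharing ≥ 1 nt with an accepted one, ties by smaller start then
shorter span — so accepted hits never overlap. Hits are assigned to
5′UTR/CDS/3′UTR by their start position (a deterministic rule for
boundary-straddling hits). Coordinates are 0-based half-open (BED
convention) throughout.

Known limitation: two-tetrad candidates cannot reach the default threshold
under this scorer, so the default catalog contains only g ≥ 3 hits; the
threshold and scorer bounds are configurable.

## CLIP enrichment (`rg4kit.enrichment`)

Observed binding sites (validated BED6, strand required) are extended by
`flank` (default 25) nt on both ends, clipped to transcript bounds.
Background sites of exactly the rounded mean observed (unextended) site
length are placed uniformly over valid start positions; sampling is
**region-stratified** — the null for the 3′UTR contrast is drawn from
3′UTR sequence space — so RG4 enrichment is not confounded with region
composition. A pooled "all" contrast uses whole-transcript background.
Background sites are extended by the same flank before intersection, so
observed and null sites are treated symmetrically.

Per region the 2×2 table (sites with/without an RG4 overlap × observed/
background) is tested with a two-sided Fisher exact test implemented as the
sum of hypergeometric probabilities no greater than the observed table's
(relative tie tolerance 1e-12); odds ratios use the Haldane–Anscombe 0.5
correction when any cell is zero (flagged in the output). Overlap requires
≥ `min_overlap` (default 1) shared nt and is same-strand only. Densities
divide the number of catalog RG4s overlapping the site set by the merged
(double-count-free) site length and scale to events per Mb. The fraction of
RG4s bound is the share of accepted catalog hits in a region overlapped by
any extended site; it is non-decreasing in the flank by construction.

## Differential pull-down proteomics (`rg4kit.msdiff`)

Input is a MaxQuant-proteinGroups-like table with paired intensity columns
`WT_<pair>` / `7dG_<pair>`; zero or empty intensities are missing.
Contaminant- and reverse-flagged rows are removed; intensities are log2-
transformed; proteins are kept when at least `min_valid_per_condition`
(default 3) values are observed in **at least one** condition — the
permissive reading that makes one-sided binders (all-WT, no-7dG) testable
after imputation, which is their entire point; a strict both-conditions
mode is available (`require_both_conditions`).

**Imputation.** Missing values are drawn per sample column from
Normal(m − 1.8·s, (0.3·s)²) where m and s are the observed mean and sd
(ddof = 1) of that column — the standard downshifted-Gaussian model of
missing-not-at-random dropout at the low end of the intensity range. The
draw is seeded; imputed column means are always below observed means.

**Test.** Per protein, paired differences dᵢ = log2 WTᵢ − log2 7dGᵢ give

    t = mean(d) / (s0 + sd(d)/√n)

with the SAM-style variance-stabilisation offset `s0` defaulting to 0.1
log2 units. With only n = 4 pairs the plain t (s0 = 0) has 3 degrees of
freedom and proteins whose values are mostly imputed produce a heavy null
tail that floors the attainable FDR; a small positive s0 damps these
spurious statistics, and results are insensitive to its exact value over
s0 ∈ [0.05, 0.5]. s0 = 0 recovers the plain paired t.

The null is built by sign-flipping the difference vectors — exhaustive 2ⁿ
patterns for n ≤ 12 pairs, otherwise a seeded random sample — with each
pattern applied identically to all proteins. FDR(θ) is the mean count of
null |t| ≥ θ per pattern divided by the observed count of |t| ≥ θ; qᵢ is
the minimum FDR over thresholds ≤ |tᵢ| (hence monotone non-decreasing in
rank), capped at 1. The identity pattern and its sign-complement reproduce
the observed statistic exactly for every protein; with a 16-pattern
ensemble they would place each true effect in its own null and bound the
FDR below by 2/16, so they are excluded from the FDR null (they are kept in
the per-protein permutation p, which therefore never reaches zero).
Zero-variance differences with a non-zero mean map to ±∞ and are flagged;
an all-zero difference vector carries no evidence and maps to t = 0.

**Classification.** Proteins on an explicit background list (non-specific
bead/bait binders) are labelled `background`; significant proteins
(q ≤ 0.05) with linear WT/7dG ratio ≥ 1.5 are `RG4-BP`, with ratio ≤ 1/1.5
`G-rich-BP`; everything else is `unclassified` (or `excluded` at the
filter stage). The ratio is computed from post-imputation means (imputation
exists precisely to enable it); the observed-only ratio is emitted as a
diagnostic column. An unpaired two-sample permutation test is provided for
comparison; with batch (pair) effects present the paired test dominates it,
a property the test suite checks.

## Assay quantifications (`rg4kit.assays`)

All formulas are closed-form and scale-invariant:

- **ΔΔCT expression**: ΔCT = CT(target) − CT(reference) per condition,
  ΔΔCT = ΔCT(treated) − ΔCT(control), fold = 2^(−ΔΔCT). The sign follows
  the Livak convention (lower CT ⇒ more template); a `literal_sign` flag
  provides the 2^(+ΔΔCT) variant for sources that print the formula
  without the minus sign, which inverts fold directions.
- **RIP enrichment**: E = eff^(CT_IgG − CT_IP) per gene (normalising to
  input cancels), reported relative to a reference mRNA; primer efficiency
  `eff` defaults to 2 (100%-efficient PCR) and is configurable.
- **Translational efficiency**: TE = HP/(NP + LP + HP) over pooled
  non-polysomal, light and heavy polysome fraction amounts, plus a
  condition/control TE ratio.
- **Reporter ratio**: Rluc/Fluc, optionally normalised to a control pair.
- **Plating efficiency**: colonies/plated × 100 (%), survival fraction =
  PE(treated)/PE(control).

## Synthetic data (`rg4kit.simulate`)

The generators define the conditions under which the pipeline is validated.
All draw from `numpy.random.default_rng(seed)` with explicit seeds — no
global RNG state — and identical configs reproduce bit-identical outputs.

**Transcriptomes.** Region lengths are drawn per transcript from normals
(5′UTR 200 ± 50 nt, CDS 1200 ± 300 nt rounded to a multiple of 3, 3′UTR
800 ± 200 nt — roughly human mRNA medians), background bases are i.i.d.
with GC 0.45, and exact quadruplex motifs (default g = 3, loops 2,2,2: the
canonical G3A2 element, 18 nt) are planted at Poisson rates of 1.5 / 0.5 /
1.0 motifs per kb in 5′UTR / CDS / 3′UTR, reflecting the UTR-biased motif
distribution of real transcriptomes. Planted motifs never overlap and are
spaced ≥ 30 nt apart so no cross-motif candidate fits in a scanner window;
background is rejection-resampled until no quadruplex matching the planted
specification exists outside the planted spans. Truth tables are therefore
exact: with the default planted spec the catalog equals the truth table,
making sensitivity computable without slack. A region too short to host a
drawn motif rejects the config with a diagnostic.

**CLIP sites.** Candidate sites (length ~ Normal(40, 8) nt, anchored
uniformly, clipped to transcript bounds) are accepted with probability
proportional to `g4_enrichment_factor` when they overlap a planted motif
and 1 otherwise. Attaching the weight to the placed site's overlap status
(rather than to the anchor position alone) makes the two boundary cases
exact: factor 1 is uniform placement and factor 0 yields provably zero
overlapping sites.

**LFQ matrices.** Per protein: baseline log2 intensity ~ Normal(25, 2); a
fraction (default 10%) of proteins carries a condition effect (default
+1.5 log2, WT side; four replicate pairs); pair (batch) effects
~ Normal(0, 0.25) shared within a pair make the paired design strictly
better than an unpaired one; measurement noise ~ Normal(0, 0.25). Dropout
is missing-not-at-random: p(missing) = expit(−slope·(x − midpoint)) on the
true log2 intensity with midpoint 21.5 and slope 1.0 (≈ 3% dropout at the
baseline mean, 50% at the midpoint, ~15–20% overall — typical of pull-down
LFQ data); deletion happens on the raw intensity scale, where missing
values appear as zeros, exactly as the downstream pipeline expects. At
slope 0 the rule degenerates to intensity-independent 50% dropout (the
MCAR limit). The generator asserts on every matrix that missing entries
have lower mean true intensity than observed ones whenever slope > 0.

**Assay fixtures** are built by inverting the assay formulas, with fixed
anchor rows (fold 1.0, TE 0.30, PE 40%) plus randomised rows; every fixture
reproduces its construction parameter to 1e-9.

What the generators do **not** emulate: read-level CLIP data (sites are
simulated at called-peak level, with no crosslink-induced truncation or
peak-caller artefacts), peptide/spectrum-level MS (no shared peptides,
match-between-runs or ratio compression), transcript secondary structure
or composition beyond i.i.d. background, and between-transcript expression
differences. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated models, not robustness to every
artefact of real data.

## Problem sizes and numerical choices

The validation suite uses a 50-transcript transcriptome (~110 kb), 500-site
CLIP simulations against 10,000 background sites, 200 null and 100 enriched
replicates for calibration, and 1000-protein × 4-pair LFQ simulations
(20 null seeds, 10 effect seeds) — sizes at which every calibration
quantity is stable across seeds while the whole suite runs in a couple of
minutes on one CPU. Fisher p-values are validated against exact
integer-arithmetic hypergeometric enumeration (agreement < 1e-10); the
scanner against exhaustive enumeration on sequences ≤ 60 nt. Ties in
hypergeometric probabilities are detected with a 1e-12 relative gate,
well below the spacing of distinct probabilities at these table sizes.
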