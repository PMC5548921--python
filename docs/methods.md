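# Methods

`tastecells` implements the analysis chain used to compare two mouse taste-bud
cell populations — *Tas1r3*-expressing type II cells and physiologically
identified type III cells — from single-cell RNA-seq count matrices and
fura-2 calcium-imaging traces, together with synthetic-data generators that
carry ground truth for every stage. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data do
and do not establish.

## Calcium-response classification (`tastecells.calcium`)

Type III cells express voltage-gated calcium channels and respond to a
depolarizing 50 mM KCl stimulus with a large, prolonged rise in intracellular
calcium, read out as the F340/F380 fura-2 ratio in arbitrary units (AU). A
cell is classified as a responder when the ratio rises strictly more than
`k_sd` (default 10) baseline standard deviations above the baseline mean and
stays there for at least `min_duration_s` (default 10 s).

Baseline statistics come from the 120 s immediately preceding stimulus onset
(`baseline_window_s`); the sample at onset belongs to the response window.
The SD uses the n−1 denominator. Fewer than two in-window samples make the
trace unclassifiable — such cells are labelled, not silently dropped.

Traces are irregularly sampled (capture every 2 s during stimulus, 4–8 s
during the slow recovery, 30–60 s between presentations), so "above threshold
for 10 s consecutively" cannot mean one sample per second. A *run* is defined
as a maximal stretch of suprathreshold samples in which no inter-sample gap
exceeds `max_gap_s` (default 8 s, the largest recovery-phase interval), and
its duration is last-sample time minus first-sample time. This is the one
place where the classification rule needed an interpolation convention; the
gap bound is configurable, and the detector is validated sample-for-sample
against a brute-force pair-scan oracle on random irregular traces.

Consequences of the definitions: the call is invariant to rescaling a trace
by any positive constant, and tightening `k_sd` or `min_duration_s` can only
remove responders, never add them (both properties are tested).

## Synthetic data (`tastecells.simulate`)

**Traces.** The noiseless signal is a baseline level (default 1 AU), a step
of `response_amplitude_sd × noise_sd` lasting `plateau_s` (default 30 s),
then a linear decline at `recovery_slope` (default 0.002 AU/s) back to
baseline; i.i.d. Gaussian noise of SD `noise_sd` (default 0.01 AU) is added
at every sample. Gaussian noise is the simplest model that exercises an
SD-threshold rule; real traces add photobleaching drift, perfusion artefacts
and pipetting transients, none of which are simulated, so passing detector
tests demonstrate correctness of the rule, not robustness to rig artefacts.
The sampling schedule follows the acquisition protocol (2 s stimulus, 6 s
recovery, 30 s idle), with the capture rate ramping to 10 s for the 120-s
pre-stimulus window: the baseline SD that anchors a 10-SD threshold must rest
on ~12 samples, since an SD estimated from the 3 degrees of freedom that
30-s sampling would leave is so variable that both perfect sensitivity and
perfect specificity become unattainable for any amplitude. The default
response amplitude is 40 noise-SDs — a saturating KCl depolarization response,
far enough above threshold that baseline-estimation noise cannot flip a call.
Each trace's ground-truth responder flag is recorded from the generating
parameters (amplitude above threshold *and* plateau at least the minimum
duration), never inferred from the noisy samples.

**Counts.** Genes × cells matrices emulate the study design: 9 cells in
group A (*Tas1r3*⁺) versus 14 in group B (type III). Per-gene means are
log-normal (location log 100, scale 1.5 on the natural-log scale — spanning
~1 to ~10⁴ normalized counts, the observed dynamic range of single-cell aRNA
libraries). Counts are negative binomial with dispersion α (Var = μ + αμ²,
default α = 0.5, typical of single-cell data), scaled by per-cell depth
factors (log-normal, σ = 0.4, geometric mean fixed to 1), then optionally
zeroed by Bernoulli dropout (default probability 0; dropout is modelled as
mean-independent post-hoc zeroing — single-cell amplification is prone to
drop-out events, and this is the weakest assumption that produces them).
Differentially expressed genes shift group-B means by 2^log2FC with
magnitudes drawn from 5–15 (marker-gene scale) and random sign, or all
positive with `de_direction="up"`. The `"table1"` marker preset names the
first 17 genes after the canonical type II/type III markers (Plcb2, Trpm5,
Snap25, Pkd2l1, …) with group-A means and log2FC set to the published values,
so e.g. Plcb2's true group-mean ratio is 2^−14.4. What the generator does
*not* emulate: gene–gene correlation, cell subpopulations, 3′ coverage bias
at the count level, or mean-dependent dropout, so DE calibration results
transfer to real data only to the extent the NB-with-depth model does.

**Annotations.** Terms draw members uniformly from the declared universe;
planted enriched terms draw a stated fraction (default 0.8) of members from a
designated DE list. Truth tables record every term's status.

All generators derive their randomness from a seed held in the spec object;
fixed seeds reproduce byte-identical output.

## Normalization and QC (`tastecells.counts`)

Size factors use the median-of-ratios method: the per-gene reference is the
geometric mean across cells over genes expressed in every cell; a cell's
factor is the median ratio of its counts to the reference, and the factor
vector is rescaled to geometric mean 1 (the scale convention is arbitrary;
this one keeps normalized counts on the raw-count scale). The unit suite
cross-checks the factors elementwise against pydeseq2's implementation.
Sparse matrices may have no gene expressed everywhere; an opt-in
`positive_reference` mode uses geometric means over nonzero entries only and
announces itself with a warning, because it weakens the usual
most-genes-unchanged assumption.

Detected genes are counted per cell at thresholds of 1, 2, 5, 10, 20 and 50
normalized counts (non-increasing in the threshold by construction). The
variance-stabilizing transform is log2(x+1) — a deliberate surrogate for the
dispersion-fit transform, adequate because it feeds only PCA, distances and
visualisation. PCA takes the 500 highest-row-variance genes, centers per
gene, and reports ordered variance proportions; degenerate input (no
variance) is flagged rather than decomposed. Hierarchical clustering uses
Euclidean distances over all genes with complete linkage by default (no
linkage was specified upstream; complete is a conservative choice for
compact groups and is configurable), and the dendrogram is exported as
newick. Gene-body coverage takes pre-computed per-read positions in [0, 1]
along the 5′→3′ gene body (alignment parsing is out of scope), bins them
into 100 half-open quantile bins (last bin closed), and rescales so the
maximum bin reads 100%.

## Differential expression (`tastecells.de`)

The model: normalized counts for gene g in group k have mean μ_gk and NB
variance μ_gk + α_g μ_gk². The fold change is reported as

    log2FC = log2((mean_B + c) / (mean_A + c)),   c = 0.5,

oriented type III (B) over *Tas1r3*⁺ (A), so positive values are
up-regulated in type III cells. The pseudo-count keeps near-zero group means
finite (marker genes reach means of 0.1) and biases |log2FC| down by less
than 0.01 at means ≥ 50. No shrinkage toward zero is applied — the marker
effects of interest are 5–15 log2 units and are reported unshrunk.

Dispersion is estimated in three steps: (1) per-gene method of moments,
α̂ = max(0, (s² − μ̄)/μ̄²) within each group, pooled with df weights; (2) a
mean–dispersion trend α(μ) = a₀ + a₁/μ fit by least squares across genes;
(3) shrinkage of the raw estimate toward the trend with prior weight
`prior_df = 20` against the ~21 residual df of the design. This replaces
empirical-Bayes dispersion machinery; it is accurate where it matters here
(large effects, moderate means) and its calibration is verified directly.

The Wald statistic is log2FC over a delta-method SE,
SE² = Σ_k (μ_k + α μ_k²)/(n_k (μ_k + c)²) / ln²2, referred to a **Student-t
distribution with n_A + n_B − 2 degrees of freedom**. A normal reference is
visibly anti-conservative at these group sizes: the shrunk dispersion still
carries moment-estimation noise, which fattens the statistic's tails exactly
like a variance estimated on ~21 df, and on all-null simulations the normal
reference produced several spurious BH discoveries per 5,000 genes while the
t reference is calibrated (measured false-discovery proportion ≲ 0.05 at
FDR 0.05, p-value KS distance ~0.02 from uniform).

FDR uses Benjamini–Hochberg step-up after independent filtering: candidate
base-mean cutoffs are the 0–95th percentiles of base mean in 20 steps, the
cutoff maximizing discoveries at the target FDR wins (ties to the lowest
cutoff), genes below it get an undefined FDR and never enter the BH m. The
published gene-list filters are |fold change| ≥ 2, average expression ≥ 10
normalized counts and FDR ≤ 0.05 (broad list used for GO), with a ≥ 50-count
variant for the pathway-analysis focus list.

## Gene-set enrichment (`tastecells.enrich`)

Each term is tested with a 2×2 table of (in experimental list) × (in term)
using the Pearson chi-square closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)),
1 df, no continuity correction, screened at raw p < 10⁻³ with no
multiple-testing correction (a BH option exists but is off by default to
match the screen-then-summarize workflow). The comparison column excludes
the experimental list from the background so no gene is counted on both
sides of the proportion; the inclusive variant is available behind a flag.
The enrichment score is −log10(p). Two caveats are inherent to the test: the
uncorrected Pearson statistic on discrete tables runs slightly above its
nominal far-tail level unless expected cell counts are comfortable (the null
suite uses lists and terms large enough that the in-list overlap expectation
is ≥ 30), and annotations are taken as given — no propagation of gene
memberships up the ontology graph is performed.

Term redundancy is summarized by single-linkage clustering on the Jaccard
similarity of term member sets (threshold 0.7), keeping the lowest-p term of
each cluster as representative (ties broken lexicographically). Gene overlap
is a surrogate for semantic (ontology-graph) similarity and is labelled as
such; terms that overlap in genes but sit far apart in the ontology will be
merged where a semantic method would not.

## Co-expression quantification (`tastecells.coexpress`)

From double-label immunostaining counts (target-protein-positive cells,
marker-positive cells, double-positive cells) the two percentages are
100·double/target and 100·double/marker. Formatting truncates toward zero at
one decimal — computed in exact integer arithmetic ((1000·num)//den), since
floating-point truncation misrenders exact binary-unrepresentable fractions
like 24/50 — and prints without the decimal when the truncated value is
whole ("100", "41"). The published table this reproduces mixes truncation
and rounding from cell to cell; the packaged fixture carries the printed
strings, 20 of whose 24 percentage cells match this rule exactly, the other
four differing by under 0.15 percentage points. Raw percentages are always
reported alongside the formatted strings.

## Problem sizes and determinism

The test and acceptance suites use: 1,000 random irregular traces for
detector–oracle agreement and a 500-trace labelled cohort; 20 all-null count
replicates of 5,000 genes at 9 vs 14 cells and α = 0.5 for calibration; 200
effect genes inside a 2,000-gene null-majority matrix for fold-change
recovery; 100 random 2×2 tables against the generic contingency oracle; and
50 random-list replicates against 200 synthetic terms for the enrichment
null level, judged by a Poisson 99.9% envelope on the total count at the
nominal 10⁻³ level. Every stochastic step draws from an explicit seed;
`scripts/acceptance.py --seed N` fans one seed out to all stages through
`numpy.random.SeedSequence`.

## Known limitations

- The NB inference is a simplified stand-in (moment estimates, 1/μ trend,
  fixed prior weight, delta-method SE); genes with means ≲ 5 are handled by
  the independent filter rather than by careful small-count inference.
- log2(x+1) is not a true variance-stabilizing transform at low counts.
- The enrichment test inherits the chi-square approximation's discreteness;
  for very small terms or lists a Fisher exact test would be preferable.
- The redundancy summarizer knows nothing of the ontology graph.
- Generated data lack gene–gene correlation and mean-dependent dropout, so
  calibration results are statements about the stated model, not about
  arbitrary real libraries.
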