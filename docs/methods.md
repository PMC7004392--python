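# Methods

This note documents the statistical procedures `lcdstruct` implements, the
parameter choices that matter, the synthetic data model used for validation,
and the numerical conventions adopted where the design was genuinely open.

## LCD calling

Complexity is measured per fixed 12-residue window as the Shannon entropy of
its amino-acid composition, SE = −Σ (nᵢ/L)·log₂(nᵢ/L) in bits, bounded by
log₂ min(20, L) ≈ 3.585. The defaults — window length 12, threshold 2.2 bits
— are the classic SEG operating point for short low-complexity segments.
Windows, not variable-length segments, are the unit of calling: the original
SEG trigger/extension pass and its K2 measure are deliberately not
implemented, because overlapping extension makes "number of LCD regions"
ill-defined. Instead, every qualifying window is emitted, and maximal unions
of overlapping or adjacent same-type windows form *merged regions*, the unit
for region counts and residue-coverage statistics. Both raw window counts and
merged-region counts are reported (`n_windows`, `n_merged_regions`), since
either convention is defensible.

A window's type is the exact argmax set of its composition; ties make it
ambiguous, and an ambiguous window contributes to every tied type's region
and coverage statistics. A protein is assigned preferentially to a type's
unambiguous stratum (≥ 1 strictly-typed window) and otherwise to the
ambiguous stratum. Physicochemical group counts (hydrophobic AILMV, charged
DEHKR, polar CNQST, aromatic FWY, hydrophilic = charged ∪ polar) count a
protein or region once however many member types it attains — group totals
are not sums over members.

Windows containing a non-canonical residue (mapped to 'X' on input) are
excluded from every composition statistic. Disordered residues participate
fully in composition and entropy — composition is a property of the sequence;
the structure state is a separate annotation.

## Structure categories

Raw DSSP-style codes map to analysis categories: α-helix {H}, β-sheet {E},
3₁₀/π helix {G, I}, isolated bridge {B}, turn/bend {T, S}, irregular/coil
(space, '-', 'C' and '~' are all accepted coil spellings). A residue flagged
disordered overrides its code — an unresolved residue has no observed
conformation. The minor categories are kept distinct rather than folded into
a guessed grouping; `CategoryMap.merged` lets users fuse them.

## Composition-binned profiles

All statistics are window-level: overlapping windows contribute
independently, with no deduplication, because the dose–response question is
"given a window with k copies of amino acid a, what structure does it have?".
Bins are one per integer count k (percent composition 100·k/w), avoiding
arbitrary percentage edges. Empty bins report NaN, never 0. The
opposite-charge filter drops windows containing both a positive ({K, R}) and
a negative ({D, E}) residue; histidine, only partially protonated at
physiological pH, is excluded from the positive set by default.

## Propensity-scale regressions

The observed statistic for amino acid a in a window pool is the fraction of
a-occurrences annotated in the target category, with window multiplicity (a
residue covered by m pooled windows counts m times); occurrence counting is
symmetric between the enriched (≥ 50% a) and non-LCD (< 50% a) pools so the
two contexts are comparable. An alternative residue-level non-LCD statistic
(each occurrence once, excluding occurrences inside any enriched window of
that amino acid) is available via `nonlcd_mode="residue"`; the window mode is
the default because the pooled-window definition keeps both contexts on the
same footing.

OLS places the scale on x and the observed fraction on y, so a residual is
the vertical displacement of the observation from the fitted line (positive =
more structure than the scale predicts). Exclusions are machine-readable:
`proline_rule` (proline is an outlier or absent in most scales and is always
excluded), `scale_missing`, `scale_exclusion` (e.g. glycine for one sheet
scale), and `low_count` (< 50 occurrences of the defining residue, applied to
the enriched context, where sparse LCD classes would otherwise dominate the
fit). Scales declaring `lower_is_more` are sign-flipped before fitting (the
flip is logged); correlation rankings use |Pearson r| over pairwise-complete
amino acids and are therefore orientation-proof, with pairs sharing fewer
than 3 amino acids reported as NaN. Scale value sets themselves are inputs:
the package ships no transcription of published scales, and the test suite
uses clearly-labelled synthetic scales.

## Annotation enrichment

Annotations are mapped at chain level (fold annotations cannot generally be
localised within a chain). For each LCD type the 2×2 table compares the
type's chains against the **full** non-redundant chain set — including the
type's chains themselves. This subset-versus-superset reference is the
definition implemented, kept deliberately rather than "corrected", and noted
in the output manifest: it slightly deflates the test statistic (variance
factor (1−f)/(1+f) for subset fraction f), which is negligible when LCD
chains are a small fraction of the proteome. Fisher's exact test (two-sided,
raw counts) supplies p-values; lnOR uses the Haldane–Anscombe 0.5 pseudocount
only when a cell is zero (flagged per record); Holm–Šidák adjustment is
applied within each LCD type. Top-k reporting filters adjusted p ≤ α
(default 0.05, configurable — "significant" needs an explicit level) and
lnOR > 0, sorting by adjusted p with ties broken by descending lnOR then
annotation id.

## Dataset curation

Representative selection keeps the first cluster member present in the input
(cluster files are pre-sorted by structure quality); if the first member is
absent the next present member is taken, keeping one representative per
cluster. Terminal expression tags overlapping the first or last 20 residues
are trimmed together with everything terminal of them (linkers outside a tag
are expression artefacts); the longest matching tag wins and, within a tag,
the innermost qualifying occurrence is trimmed through — the choice that
makes trimming idempotent. The shipped default tag table (His-tags, HA,
FLAG, Myc, Strep, S-tag, T7, V5, protease sites) is a documented best effort
and fully user-overridable. Chains shorter than an analysis window are kept
at I/O time and skipped per-analysis, since window length is an analysis
parameter.

## Synthetic data model

The generator emulates the statistical structure the analyses assume — not
real amino-acid usage, fold grammar or protein families.

*Sequences.* Residues are drawn i.i.d. from a background vector (default
uniform 1/20); low-complexity blocks (default length 20) are planted at
uniform positions with a per-chain insertion probability, each block position
taking the block's amino acid with probability `composition`.

*Structure.* Each residue's category is sampled from a probability vector
determined by its local composition: the count k of a dosed amino acid in
the residue's centred, edge-truncated 12-mer window drives a logistic
g(k) = p_start + (p_end − p_start)/(1 + exp(−slope·(k − k₀))). At most one
dose is active per residue (the dosed amino acid with the largest local
count, ties by declaration order), so probabilities are always well defined;
undosed categories share the remainder in proportion to their baseline
weights (defaults: helix 0.32, sheet 0.21, 3₁₀/π 0.04, bridge 0.01,
turn/bend 0.12, irregular 0.30, roughly the composition of structured-protein
annotations). Disorder is one more category: probability 0.05 plus 0.05 for
polar residues. Sampling per residue keeps a single consistent per-residue
annotation string, as in real data.

*Annotations.* Planted effects are parameterised directly as the target
lnOR θ between a type's carrier chains and the whole proteome; the generator
solves (Brent's method) for the carrier-conditional annotation probability
achieving θ given the expected carrier fraction and baseline prevalence, so
the ground truth carries θ exactly.

*What passing tests do and do not show.* Recovery on these proteomes
demonstrates that the estimators measure what the generative model encodes —
binned means converge to the dose curves, enrichment recovers planted odds,
the caller finds planted blocks. It does not validate biological conclusions
on real proteomes, where composition, structure and annotations are coupled
in ways the i.i.d. background and logistic doses do not capture (codon and
repeat structure, fold-level correlation between windows, annotation
hierarchies).

## Verification design and problem sizes

Every statistic has an independent oracle: direct entropy evaluation on
10,000 random 12-mers (agreement ≤ 1e-12 bits); exact integer hypergeometric
enumeration for the Fisher test (all tables with margins ≤ 14 exhaustively
plus thousands of sampled tables with margins ≤ 30; agreement ≤ 1e-12);
closed-form normal equations for OLS (1,000 random datasets, ≤ 1e-10);
closed-form step-down Šidák (worked example plus 1,000 random vectors);
naive-loop recounts for window conservation and binned profiles (exact).

Dose-response recovery uses a 2,000-chain proteome with alanine blocks at
compositions 1.0/0.75/0.5 so every residue-count bin is populated. Because
generation is per-residue (each residue's probability depends on its own
local window) and overlapping windows reuse residue draws, the naive binomial
interval for a bin mean is wrong on both counts; the recovery report instead
computes the exact expectation and variance of the window-level bin mean as
a weighted sum of independent residue Bernoullis (weights = each residue's
multiplicity across the bin's windows) and checks 95% coverage over bins
with n ≥ 30.

Enrichment recovery plants lnOR = 1.39 (odds ratio 4) on 10%-carrier pure
alanine blocks in 2,000 chains; the sampling standard deviation of the
recovered lnOR under these conditions is ≈ 0.15. The null type-I study runs
at the chain-label level (type membership and annotations drawn
independently; sequences are irrelevant to the statistic under the null)
with 200 proteomes of 6,000 chains, 3% carriers and prevalences 0.3–0.5 —
sizes chosen so the exact test's discreteness is negligible and the
subset-reference deflation mild; with small tables the exact test is
markedly conservative and no configuration-independent 5% rate exists.

The end-to-end determinism check runs the full pipeline twice on a 500-chain
proteome and compares file hashes; no output carries a timestamp, and the
configuration hash excludes the output directory so bytes do not depend on
where results land.

## Known limitations

- The enrichment reference includes the tested subset (by definition); for
  proteomes where one LCD type covers a large chain fraction the test is
  conservative.
- Chain-level annotation mapping cannot say whether an LCD lies inside or
  merely co-occurs with an annotated region.
- The generator's independence assumptions (i.i.d. background, per-residue
  structure sampling) understate the correlation structure of real chains;
  interval widths calibrated on synthetic data are not transferable to real
  proteomes.
- The original SEG segment-extension algorithm is out of scope; region
  counts here are merged fixed-width windows.
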