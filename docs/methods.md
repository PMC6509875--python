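# Methods

## Model and procedure

The package infers which transcription factors plausibly drive a
two-condition gene-expression differentiation profile, given only genome
sequence and a PWM library.

**Differentiation.** Per gene, d = ln(e_treatment / e_control) on natural
logs; genes with a nonpositive abundance in either sample are dropped
before the logarithm (counted in the log). The directional components
d⁺ = max(d, 0) and d⁻ = max(−d, 0) are analysed separately, so an
activated regulator and a repressed one are both detectable, each on its
own side. The statistic is scale-free in d, so log base only matters for
interpretability; precomputed log-fold-change input is accepted as-is.

**Binding strength from motif counts.** For a factor with τ
above-threshold motif occurrences in a gene's promoter, modelling the τ
sites as independent Bernoulli trials with per-site binding probability p₀
gives P(bound) = 1 − (1 − p₀)^τ ≈ τ·p₀ for small p₀. The linear
approximation's signed error is nonnegative (union bound) and at most
τ(τ−1)p₀²/2. Because the BASE cumulative function is normalised by the
weighted total, the common factor p₀ cancels, so the default pipeline uses
b = τ directly; `counts_to_binding(..., p0=...)` retains the exact
probabilities for sensitivity analysis (the two give identical scores in
the p₀ → 0 limit, and visibly different ones at p₀ ≈ 0.5).

**Score.** Genes sorted by decreasing d_dir (stable order for ties);
f0 = normalised cumulative d_dir, f1 = normalised cumulative d_dir·b;
δ = max over sorted positions of f1 − f0, in [−1, 1]. Both cumulative
functions use the *directional* vector: accumulating raw signed d in f0
would make it non-monotone wherever the direction's component is zero and
would break the identity "constant b ⇒ δ = 0". A `literal_f0` argument to
`base_cdfs` exposes the signed-d variant for comparison.

**Null and p-value.** b is re-paired with genes by uniform random
permutation; p = #{δ* > δ}/K with strict inequality (default K = 10,000).
An `add_one` option returns (1+#)/(1+K) for users who need p > 0. For
N ≤ 8 an exact mode enumerates all N! pairings. Each (motif, direction)
pair draws its permutations from a stream seeded by (master seed,
sha256(motif id)), so results are reproducible and independent of motif
order. FDR is controlled per direction family: Benjamini–Hochberg by
default; Storey q-values (λ = 0.5 plug-in for π₀, floored at the raw p)
as an alternative.

**Rank-based variant.** `rank_based=True` replaces d_dir and b by their
average ranks before scoring (ties, including the zero block of d_dir,
share their mean rank). This trades power for robustness and makes the
result invariant under strictly increasing transforms of d.

## Tie handling

Within a run of tied d_dir values the partial sums of f0 and f1 depend on
the arbitrary input order of the tied genes, so a literal per-index
maximum would make δ — and its exact permutation p — depend on that order.
The gap is therefore evaluated at the closing index of each tied run. With
all-distinct values every index closes a run and the definition reduces to
the plain maximum; with ties both the observed score and the enumerated
null become order-invariant. The permutation p-value comparison uses a
1e-12 guard on the strict inequality so that a constant-weight motif
(all scores identically zero up to roundoff) reports p = 0 rather than
picking up floating-point noise.

## Degenerate cases

Kept in the output with a flag rather than dropped, so the motif ranking
stays total: Σd_dir = 0 ("no-differentiation", p = 1, δ = 0), Σd_dir·b = 0
("zero-weight", p = 1, δ = 0 — the motif is absent from every
differentiated gene and carries no evidence), and constant b
("constant-weights": δ = 0 exactly, p = 0 under strict inequality; the
flag marks it uninformative). Genes present in the expression profile but
absent from the count matrix are dropped (inner join, logged), never
zero-filled — zero-filling would manufacture apparent depletion.

## Promoters and scanning

One promoter per gene at the 5′-most transcript start (minimum start on
'+', maximum end on '−'): the count model assigns one binding vector per
gene, so alternative promoters are not aggregated — a documented choice,
since annotations rarely resolve which TSS is active. Default window
−1000/+200 bp around the TSS, clipped at chromosome ends (logged), with
minus-strand sequences stored reverse-complemented so index 0 is the most
5′ promoter base. Window overlap between neighbouring genes is ignored.

Scanning uses the information-weighted matrix similarity score
MSS = (Current − Min)/(Max − Min) with positional weights
I(pos) = Σ_b f·ln(4f) (ln 4 minus entropy, always ≥ 0). Count matrices are
normalised with pseudocount 0.5 per cell; matrices whose rows already sum
to 1 pass through. Both strands are always scanned; palindromic
double-hits are kept, because each detected site is one Bernoulli trial in
the binding model. Windows containing N score 0. A matrix with no
positional information (Max = Min) is flagged degenerate and scores 0
everywhere — scoring it 1 would flood the counts. τ is non-increasing in
the threshold by construction. The default threshold 0.85 is a
conventional matrix-similarity cutoff; vendor-specific per-motif threshold
profiles are not reproduced. `calibrate_threshold` instead targets a
per-window false-positive rate on shuffled background, returning the
smallest observed score *level* whose tail frequency meets the target —
a quantile would land inside a heavy level of the discrete score
distribution and overshoot the target FPR severalfold.

## Enrichment companion

Genes are ranked by signed d (average ranks for ties) and each gene set's
in-set ranks are compared with the out-set ranks by the two-sample
Wilcoxon/Mann–Whitney test, one-sided per direction; both one-sided
p-values are reported independently (an extreme p on one side pairs with a
p near 1 on the other). Exact distribution when the in-set count is below
10 and d has no ties (the exact method does not correct for ties);
otherwise the normal approximation with continuity and tie correction.
Sets with fewer than two members present, or spanning all genes, are
skipped with a log entry. A threshold-based Fisher-exact mode is included
for comparison only — its dependence on the differential-expression cutoff
is exactly what the rank-sum approach avoids.

## Synthetic ensembles and what they show

`simulate_null` draws d ~ i.i.d. Normal(0, noise_sd) and counts
τ ~ i.i.d. Poisson(background mean), independent of d — the
exchangeability null of the permutation test. `simulate_alternative`
inflates one motif's Poisson mean to background·(1 + effect·d⁺/max d⁺),
coupling counts to up-differentiation only. Defaults: 500 genes, 50
motifs, background mean 1, unit noise, effect size 3 — a realistic desk
scale at which ~10% of genes show twofold changes and a typical promoter
carries 0–4 sites of a given motif. A `folded` option draws
d = |Normal(0, noise_sd)|, giving every gene up-direction mass; this is
the profile used by the standard power study (with a signed profile half
the genes carry no up-signal and recovery is correspondingly weaker —
~75% top-rank instead of ~98% at these settings). A negative-binomial
switch (`nb_dispersion`) is available because real promoter counts are
overdispersed relative to Poisson.

These generators emulate count–expression coupling, not sequence reality:
no CpG islands, repeats, composition bias, motif clustering, or
inter-gene correlation. Passing calibration/power checks therefore
validates the statistic's null behaviour and directional power under the
stated model, not performance on any particular organism's annotation.
`make_toy_genome` complements them at the sequence level: exact-consensus
copies of a sharp 10-bp non-palindromic motif (0.97 per consensus base, so
a 0.95 MSS threshold admits only perfect matches and background false
positives are rare, ~2·4⁻¹⁰ per window) planted in promoter windows on
alternating strands, with an optional boundary-clipped first gene,
verifying the promoter-extraction/scanning path end-to-end against the
plant table.

## Standard experiment sizes

The shared experiments (`basetf.experiments`) use: 2000 null motif-tests
at 500 genes and K = 500 for type-I calibration (the strict-inequality p
puts the expected rate at (⌊αK⌋+1)/(K+1) ≈ 0.052 at α = 0.05); 100
replicates at effect 3 and K = 1000 for planted-regulator recovery, with
the down-direction check taken from the matched signed ensemble where
down-mass exists but is uncoupled from the planted counts. These sizes
keep binomial error well below the margins being checked while completing
in minutes on one core.

## Known limitations

Only proximal promoters are scanned — distal enhancers, which carry much
real regulation, are out of scope. The independence assumptions (sites
within a promoter, genes within a profile) are conveniences, not biology;
motif count is a proxy that ignores chromatin accessibility and
condition-specific occupancy. One motif is tested at a time: cooperative
or competing factors with overlapping motifs will share signal. The
method is strictly two-profile; multi-sample designs need external
summarisation to one log-fold-change vector per comparison.
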