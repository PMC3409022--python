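# Methods

## The screen

GINI (gene identification by nonsense-mediated mRNA decay inhibition)
looks for transcripts carrying premature termination codons (PTCs). NMD
normally degrades such transcripts; blocking NMD — here with caffeine —
stabilises them, and the stabilisation is visible as a small expression
increase on an array. In a multi-case family, a transcript carrying a
disease-segregating truncating mutation should be stabilised in affected
members and not in unaffected members, and should not belong to the
"global caffeine response" — genes that react to the drug in everyone.

The pipeline is: quantile-normalise raw intensities, log2-transform, fit
one treated-vs-untreated contrast per individual over its technical
replicate pairs, moderate gene-wise variances by empirical Bayes, call
significance (BH-adjusted p < α and positive B-statistic), then apply the
family selection logic. Candidates are validated by comparative-Ct qPCR.

## Statistical model

Per individual, probe *g* is fitted as a two-group comparison over *n*
replicate pairs: β̂_g = mean(treated) − mean(untreated), pooled variance
s²_g with d_g = 2n − 2 degrees of freedom, unscaled coefficient variance
v_g = 2/n. Pairing of replicates is not used in the fit; the "pair" is the
(individual, condition) structure of the design.

Gene-wise variances are shrunk assuming σ²_g follows a scaled inverse
chi-square prior with d₀ degrees of freedom and scale s₀²:

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
    t̃_g = β̂_g / √(s̃²_g · v_g)  ~  t(d₀ + d_g)  under the null.

(d₀, s₀²) are estimated from the marginal moments of log s²_g with the
digamma/trigamma equations, inverting the trigamma function by Newton
iteration (tolerance 1e−8; answers implying d₀ above 1e6 are capped there,
which is the homoscedastic limit). This engine was cross-checked against
Bioconductor limma 3.58.1 on a frozen fixture: d₀, s₀², coefficients,
moderated t and p-values agree to all printed digits, and the B-statistic
agrees when the same prior effect variance v₀ is supplied.

The B-statistic is the log posterior odds of differential expression under
a two-component mixture with prior DE probability p₁ = 0.01 and prior
effect variance v₀ (unscaled). v₀ is moment-matched from the top ⌈p₁·G⌉
moderated t² values against rank-matched Student-t quantiles; the implied
prior effect sd √(v₀·s₀²) is clamped to [0.1, 4] log2 units. This is a
simpler estimator than limma's tmixture (no null-proportion correction),
so B values differ from limma's unless v₀ is supplied; B > 0 still means
posterior probability above 50% by construction.

Benjamini–Hochberg adjustment delegates to
`statsmodels.stats.multitest.multipletests`; the test suite verifies it
against a literal min-over-tails step-up implementation.

## Candidate selection

Testing is per probe; candidacy is per gene. A gene's evidence is its best
probe — smallest adjusted p, ties broken by larger |log2FC|, then
lexicographic probe id. A gene is a family candidate when it is
significant-up in affected members (default: all of them; `at_least_k` is
available), not significant in any direction in any unaffected member of
the exclusion scope (default: same family; `all_families` implements the
alternative reading where unaffected members of the other families veto),
and not in the global caffeine response set. The global set is one pooled
unpaired contrast over all arrays (d_g = N_T + N_U − 2, v_g = 1/N_T +
1/N_U), thresholded in either direction. The unaffected veto is
direction-free because "not differentially expressed" is direction-free;
"upregulated" for affected members means β̂ > 0.

## qPCR quantification

ΔCt = mean Ct(target) − mean Ct(reference) per condition; ΔΔCt =
ΔCt(treated) − ΔCt(untreated); fold = 2^(−ΔΔCt), assuming perfect
doubling per cycle (no efficiency correction). The SEM is first-order
propagation: sem(fold) = fold·ln2·√Σ sem(mean Ct)². The stabilisation
call is fold ≥ 1.5, boundary inclusive. Calibration is to each
individual's own untreated control, which is the calling variant; the
display variant (calibrating to the lowest-expressing untreated sample)
is not implemented.

## Synthetic data

The generator emulates the statistical structure of the assay, not its
chemistry. Log2 signal for probe g on array a of individual i:

    y(g,a) = μ_g + b(g,i) + x(a)·δ(g,i) + ε(g,a),      raw = 2^(y+ζ_a)

with x = 1 iff caffeine-treated. Defaults (log2 units): baselines
μ_g ~ N(7, 1.5²); biological effect b ~ N(0, 0.10²) per gene × individual
(shared by both conditions, so it cancels in the within-individual
contrast); technical noise ε ~ N(0, 0.15²) per gene × array; array scale
ζ_a ~ N(0, 0.05²) (removed by quantile normalization); 15% of genes are
global responders with effect sign random and magnitude
`global_effect_min` + |N(0, 0.5)| shared by all individuals; planted PTC
genes carry δ = η(i)·Δ in carriers, where the NMD-inhibition efficiency
η(i) ~ U(0.5, 1.5) is drawn once per individual and reused across genes
(an individual-level property). Heterozygosity is not modelled at allele
level; the observable is a modest aggregate fold (Δ defaults to
log2 1.3 ≈ 0.38 in configs; the recovery analyses use log2 1.5). A
positive-control gene can be planted in `control`-status individuals at a
fixed realised fold (2.78 by default), without η scaling. Panels default
to 5,000 probes in 2-probe genes, roughly the probe/gene redundancy of
the HT-12 style arrays the screen used at a desk-scale size. Noise
magnitudes are plausible for technical replicates of bead arrays but are
not calibrated to any real dataset.

Simulated Ct values put the target's treated mean log2(fold) cycles below
its untreated mean, with N(0, 0.05²) replicate noise and a
treatment-independent reference gene.

What passing tests show: the inference machinery is calibrated (null
type-I error exact to Monte-Carlo precision, near-zero BH discoveries
under the null), the hyperparameter estimator recovers its generative
parameters, and the selection logic is exactly the stated set algebra.
What they do not show: performance on real arrays, where noise is
non-Gaussian, probes vary in quality, effects correlate with intensity,
and NMD efficiency is not uniform on an interval.

## Numerical and design choices

- Normalize-then-log2, matching the screen's stated preprocessing; no
  variance-stabilising transform, background correction or detection-p
  filtering.
- Quantile-normalization ties: tied values in a column receive the mean
  of the reference values over their tied rank span (deterministic and
  permutation-stable; note limma's `normalizeQuantiles` instead
  interpolates at the mean rank, so the two agree only on tie-free data).
- Missing values are errors, not imputed.
- Genes with zero sample variance (possible in noise-free synthetic data)
  get s̃² = d₀·s₀²/(d₀+d_g); if *every* variance is zero the hierarchy is
  degenerate and a tiny fixed prior (d₀ = cap, s₀² = 1e−8) keeps the
  statistics defined: exact-null genes get t = 0, true effects get
  arbitrarily large t.
- Hyperparameters are estimated independently within each per-individual
  contrast; joint multi-contrast estimation is out of scope.
- Seeds are mandatory in configs; identical config + seed reproduces
  every output byte-for-byte.

## Known limitations

- Quantile normalization under strong asymmetric differential expression
  displaces the ranks of null genes. With ~10% of genes shifted by ≥0.5
  log2 units in one condition, the pooled global-response contrast (72
  arrays per arm at the full design) is powerful enough to call these
  ~0.1 log2 artifacts significant, costing global-set precision
  (measured ≈0.8). On un-renormalised data precision and recall are both
  ≈1.0, so the operation-level truth-recovery checks feed log2 data
  directly.
- Recovery of a planted 1.5-fold PTC gene under the default study
  conditions is limited by the efficiency draw, not by the inference: a
  carrier at η ≈ 0.5 has a true effect of 0.29 log2 units against a
  fold-change standard error of ≈0.13 at n = 3 replicate pairs, so its
  detection power is ≈0.4 even with oracle thresholds, and the
  all-affected intersection rule multiplies the per-carrier
  probabilities. Measured recall across 50 simulated three-family
  studies is ≈0.3–0.4. This mirrors the assay's real sensitivity limit:
  heterozygous stabilisation near the array detection floor with
  person-to-person NMD-efficiency variation.
- Single-family designs additionally lose planted genes to the
  empirically-estimated global response (carriers are half the pooled
  arrays); multi-family designs dilute this.
- Problem sizes used by the bundled analyses (5,000-probe panels, 50-seed
  recovery runs, 200-contrast null calibration) are desk-scale choices
  that keep a full run under a minute each; they are not the array's real
  probe count.
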