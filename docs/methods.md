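# Methods

`fieldqsip` implements the quantitative stable isotope probing (qSIP)
calculation chain for ¹⁸O-water labeling experiments, together with the
statistics used to interpret taxon-specific growth in replicated warming
experiments, and a forward simulator of the whole measurement process.
This note records the models, the defaults and why, the numerical choices,
and the limits of what the simulation-based tests demonstrate.

## The qSIP measurement model

During a labeling assay, growing organisms synthesise DNA using ambient
water; if that water is enriched in ¹⁸O, new DNA is heavier and bands at a
higher buoyant density in a CsCl gradient. For each taxon *t* in each tube,
per-fraction copy numbers are reconstructed as

    y_i = p_i × N_i

where `p_i` is the taxon's relative abundance in fraction *i* (sequencing)
and `N_i` the fraction's total 16S copies (qPCR). The taxon's weighted
average density (WAD) is

    W = Σ x_i y_i / Σ y_i ,

with `x_i` the fraction's density (g mL⁻¹). The unlabeled density fixes the
taxon's GC content through the linear relation
`ρ_light = 1.646057 + 0.083506 G`, which in turn fixes the molecular weight
of its average nucleotide, `M_light = 0.496 G + 307.691` g mol⁻¹, and the
fully-¹⁸O-labeled maximum `M_heavymax = M_light + 12.07747`. The observed
density shift between the ¹⁸O tube and its paired ¹⁶O tube converts to a
labeled molecular weight `M_lab = (ΔW/W_light + 1) M_light`, and the excess
atom fraction (EAF) of ¹⁸O is

    EAF = (M_lab − M_light) / (M_heavymax − M_light) × (1 − 0.002000429),

the last factor removing natural ¹⁸O abundance. EAF is a unitless proxy for
relative growth during the assay. All constants live in one table
(`fieldqsip.constants`) shared by the estimator and the simulator, so
simulation → estimation round-trips are exact identities in the absence of
noise.

### Filtering, aggregation, uncertainty

* A taxon enters a tube's WAD calculation only if it occurs (non-zero
  abundance) in **three or more consecutive fractions** of that tube;
  `min_consecutive` is configurable.
* Per block, EAF is computed from the paired ¹⁶O/¹⁸O tubes. If the taxon
  fails the filter in the paired ¹⁶O tube, its mean unlabeled WAD across the
  treatment's passing ¹⁶O tubes is used instead (flagged
  `light_fallback`) — this retains taxa and mirrors common qSIP practice.
* The treatment estimate averages per-block EAFs (averaging per-block WAD
  shifts before one conversion is available via `block_average="wad"`; the
  two differ only at third order).
* Negative treatment means are truncated to zero and flagged; "growing"
  means a positive post-truncation mean. Per-block raw values are retained.
* Confidence intervals: 1000 bootstrap resamples of blocks, two-sided 90%
  percentile interval (level and count configurable).

### ΔEAF responses

The warming response of a taxon is `ΔEAF = EAF_treatment − EAF_control`,
computed for taxa growing in both arms. Its interval resamples each arm's
blocks independently (each treatment's tubes are an independent sample;
`pair_blocks=True` applies one joint draw when block pairing is meaningful)
over raw per-block values. Because only 4 blocks are available, the plain
percentile interval is systematically narrow — it misses both the
`sqrt(B/(B−1))` inflation and the t-versus-normal correction — so the
default interval reads the bootstrap distribution at *expanded percentile*
points (Hesterberg's small-sample adjustment): at B = 4 and a 90% nominal
level the replicate distribution is read at 0.33%/99.67% instead of 5%/95%.
Under a null simulation this yields per-tail responder rates of ~4–5%,
matching the nominal level; the plain interval yields 8–10%. A taxon is a
positive (negative) responder when the interval lies entirely above (below)
zero.

### Assemblage statistics

Treatment means are compared by one-way ANOVA with Tukey's HSD and a
compact letter display; the observation unit is the taxon, which
pseudo-replicates tubes — the caveat is inherited from the field's standard
presentation and the per-taxon bootstrap is the replication-aware
alternative. Growing-taxon sets are partitioned by treatment membership
(2^k − 1 categories) with per-category means compared by paired t test (two
member treatments) or ANOVA (three). Rank-level means and ΔEAF are reported
only for groups with ≥ 3 growing representatives in both the warming arm
and the control. Temperature sensitivity uses the van't Hoff form
`Q10 = ratio^(10/ΔT)` with ΔT defaulting to 1.6 °C — the soil warming
magnitude consistent with the reported response ratios; it is a parameter
everywhere it appears.

## Phylogenetic signal

Both statistics operate on the Brownian-motion covariance `C` implied by
the phylogeny (`C_ij` = root-to-MRCA branch length; tips without trait
values are pruned from `C`).

* **Blomberg's K** is the ratio of the observed
  `(xᵀx-type) / (xᵀC⁻¹x-type)` mean-square ratio (about the GLS grand mean
  `â = 1ᵀC⁻¹x / 1ᵀC⁻¹1`) to its BM expectation
  `(tr C − n/1ᵀC⁻¹1)/(n−1)`. K = 1 under BM; the p-value permutes trait
  values across tips (999 by default) with
  `p = (1 + #{K* ≥ K}) / (1 + n_perm)`.
* **Pagel's λ** rescales the off-diagonal of `C`; `σ²` and `â` are profiled
  analytically and the one-dimensional likelihood is maximised on [0, 1]
  (bounded Brent; the positive-definite upper bound can exceed 1 on request
  via `allow_lambda_gt1`). Significance is a likelihood-ratio test against
  λ = 0 on one chi-square degree of freedom; with λ̂ on the boundary this is
  conservative.

All solves are Cholesky-based; no explicit inverse is formed. Zero-length
terminal branches (common in insertion trees) are perturbed by 10⁻⁸ × tree
height with a warning; exact duplicates (zero-distance tips) are an error
naming the offending tips. On a star phylogeny K = 1 identically and λ is
unidentifiable — the latter raises rather than returning a number.

Calibration (Monte-Carlo, enforced by the test suite and the acceptance
script): BM traits on 100-tip trees give mean K within 10% of 1 and mean
λ̂ ≥ 0.9; shuffled traits give ~5% rejection for the K permutation test and
nominal-or-conservative rejection for the λ LRT.

## Nested taxonomic variance components

Trait variance is decomposed over nested ranks (default phylum…genus, plus
an among-taxon residual) with a random-intercepts model estimated by REML
under non-negativity constraints. Nesting is enforced by prefixing each
rank's labels with all coarser labels. The covariance matrix is
block-diagonal by the coarsest rank, so the REML criterion is evaluated
blockwise with batched Cholesky factorisations; optimisation is L-BFGS-B
from three starts followed by a Nelder–Mead polish (numerical-gradient
L-BFGS-B alone stalls around 10⁻⁵ relative precision; the balanced-design
tests require agreement with the expected-mean-squares closed form to
10⁻⁶). Shares are reported as percent of the summed components; estimates
may sit at the zero boundary. The overall test is a likelihood-ratio
against the no-grouping null on df = number of components — conservative
because every component is on the boundary under the null; a 50:50
chi-square mixture correction is available (`lrt(mixture=True)`).

## The simulator

`simulate_experiment` emulates the post-denoising measurement structure of
a replicated field experiment: by default 3 treatments (ambient control,
short-term warming STW, long-term warming LTW) × 4 blocks × paired
¹⁶O/¹⁸O tubes = 24 tubes, each fractionated into 18 bins spanning
1.640–1.760 g mL⁻¹.

* **Community.** A pure-birth phylogeny (unit height; terminal edges
  extended past the final speciation so no tip branch is zero), taxonomy
  from cutting the tree at fixed depths (strictly nested by construction),
  GC ~ Uniform(0.35, 0.65), lognormal biomass weights.
* **Growth truth.** A latent growth trait evolves by Brownian motion
  (σ² = 0.004, root 0.07) so growth has phylogenetic signal; treatments add
  0 / +0.025 / +0.106, and the result is clamped to [0, 0.6] — labeling
  water of ~66 atom % makes higher enrichment unattainable, and the
  defaults put growing-taxon assemblage means near 0.07 / 0.095 / 0.176.
  Clamping at zero creates genuinely non-growing taxa, which exercises
  truncation and the occurrence partition.
* **Measurement.** Each taxon's DNA mass is a Gaussian in density (sd
  0.006 g mL⁻¹, a diffusion-broadening approximation) centred at
  `ρ_light` or, in ¹⁸O tubes, at the density implied by its true EAF via
  the constants table; mass is integrated over fraction bins. qPCR totals
  are the fraction's share of 10⁸ copies times lognormal noise (CV 0.15);
  counts are multinomial at 10,000 reads per fraction after zeroing shares
  below a 10⁻³ detection floor (dropout of rare taxa in sparse fractions,
  which exercises the consecutive-fraction filter). `exact_abundances=True`
  bypasses the multinomial for noise-free analyses.
* **Reproducibility.** All randomness flows from one seed through a
  `numpy.random.SeedSequence` split (community stream first, then one child
  stream per tube in a fixed order); identical configs give byte-identical
  output files.

What the simulator does **not** emulate: compositional tube-to-tube density
drift, ultracentrifugation physics beyond the Gaussian profile, chimeras
and denoising artifacts, taxon-specific 16S copy-number variation, or
block-level environmental effects (blocks are pure replicates). Passing
recovery tests therefore show the calculation chain is correct and
well-calibrated under the stated noise model, not that field data are free
of these additional error sources.

## Problem sizes in the checks

The acceptance script and test suite use sizes chosen to make the
Monte-Carlo bands tight while keeping a desk-scale run: 200-taxon 24-tube
experiments for recovery (median |EAF̂ − EAF| < 0.02 at default noise,
< 0.01 noise-free), 200 simulations on 100-tip trees for signal
calibration, 100 simulations of 40 orders × 10 taxa for variance-component
recovery (order share 50%), and four null experiments (150 taxa) for ΔEAF
calibration.

## Known limitations

* With 4 blocks, interval estimates are coarse; the expanded-percentile
  correction fixes average calibration but per-experiment rates fluctuate
  because tube-level noise is shared across taxa.
* The ANOVA/Tukey assemblage contrast treats taxa as independent units;
  phylogenetic non-independence is quantified (K, λ) but not removed from
  that contrast.
* REML p-values at the boundary are conservative; the mixture correction is
  approximate.
* GC inference from `W_light` inherits any tube-level density calibration
  error; the linear density–GC relation is an empirical approximation.
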