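# Methods

## The codon substitution model

All rate estimation and sequence simulation share one model (`gy94`): a
continuous-time Markov chain on the 61 sense codons of the universal code
with

    q_ij = π_j · κ^[i→j is a transition] · ω^[i→j is nonsynonymous]

for codons differing at exactly one nucleotide (zero otherwise), κ the
transition/transversion rate ratio, ω = dN/dS the selective-constraint
parameter, and π the F3x4 codon frequencies (products of position-specific
nucleotide frequencies, floored at 1e-6 and renormalised so the chain stays
irreducible).  The generator is normalised to unit substitution flux, so a
branch length *t* is the expected number of nucleotide substitutions per
codon — the codeml convention.  The chain satisfies detailed balance, which
gives root-placement invariance of all likelihoods (asserted by test) and
lets transition matrices be computed by a symmetric eigendecomposition,
`P(t) = D^{-1/2} V e^{Λt} V' D^{1/2}`, exact and cheap enough to call inside
optimisation loops (decompositions are memoised per (κ, ω) because most
finite-difference steps move only branch lengths).

dN and dS are derived from (t, κ, ω) by the standard flux decomposition:
the synonymous fraction of substitutions is ρ_S(ω), the synonymous *site*
fraction is ρ_S(1) (same κ and π, ω = 1), and

    dS = t · ρ_S(ω) / (3 ρ_S(1)),   dN = t · ρ_N(ω) / (3 ρ_N(1)),

which makes dN/dS ≡ ω by construction.

## Pairwise estimation and its oracle

`codonrates.pairwise_dnds_ml` maximises the pairwise likelihood
Σ_sites log π_i P_ij(t) over (log t, log κ, log ω) with bounded L-BFGS-B,
three deterministic restarts (a heuristic start from the raw codon
difference fraction, times fixed perturbation factors), convergence at
ftol 1e-12, bounds t ∈ [1e-6, 20], κ ∈ [0.05, 50], ω ∈ [1e-4, 60].  Codon
columns with a gap or non-ACGT symbol in either sequence are deleted
pairwise; in-frame stops are an error, never silently dropped.  F3x4
frequencies come from the two sequences jointly, matching the pairwise
codeml practice the design follows.

`pairwise_dnds_ng86` is the independent check: Nei–Gojobori (1986) counting
with equal-weight site fractions (mutations to stops counted as
nonsynonymous), all-pathway averaging for multi-position codon differences
(pathways through stops excluded), and Jukes–Cantor correction.  It shares
no code with the likelihood route; the suite requires rank agreement
(Spearman ≥ 0.9) between the two.  One caveat is asserted rather than hidden:
NG86's equal-weight counting is only unbiased without
transition/transversion bias, so its ω ≈ 1 neutrality check simulates at
κ = 1 (at κ = 3 it underestimates ω by ~20%, the classical motivation for
κ-aware estimators).  When dS = 0 the ratio is reported undefined and the
dS ≥ 0.01 filter removes it downstream, so no 0/0 convention leaks into the
analysis.

## Branch models and the duplication LRTs

`branchlik` computes exact pruning-algorithm likelihoods over unique codon
columns (complete deletion of gapped columns, per-node rescaling) with a
per-branch-class ω.  Fits optimise all free branch lengths, κ and the class
ω's jointly with bounded L-BFGS-B in log space; the edge above the root is
held at zero (unidentifiable under reversibility).  The design calls for
coordinate rounds over (branch lengths | κ, ω); a single joint quasi-Newton
pass converged to the same optima (checked against multi-restart refits to
1e-7 log-likelihood units) and is what ships.  The alternative model of each
LRT is warm-started at the null optimum with the foreground ω split off,
which guarantees nesting up to optimiser tolerance; statistics are clipped
at zero.

Branch classes: the duplication node is the MRCA of the species' paralogs;
"post-duplication" means every edge strictly below it.  The asymmetry test
compares {ω0, shared paralog ω1} against one ω per paralog terminal branch
(internal post-duplication edges, which only exist with > 2 paralogs, stay
with the first paralog class), df = #paralogs − 1.  The acceleration test
compares a single ω against {background ω0, shared post-duplication ω1},
df = 1, with direction *faster* iff ω̂1 > ω̂0.  Per the study design the
dS ≥ 0.01 filter is dropped for the asymmetry analysis (recent duplications
legitimately have tiny dS) and applied for acceleration.

A finite-sample property matters for interpretation: with very recent
duplications the post-duplication branches carry few substitutions (at the
generator's defaults, ~0.002–0.015 substitutions/codon on each paralog
branch), and both LRTs are then *conservative* relative to χ² — never
anticonservative (measured QQ slopes 0.7–0.9 at 500 codons).  The
calibration tests therefore place the duplication deeper (paralog branches
0.06 substitutions/codon) and use 1,500 codons, where the asymptotics hold
(measured type-I error 0.050, QQ slope 0.97 at 3,000 codons).  The en-masse
machinery is exact: BH step-up FDR, Fisher's −2Σln p ~ χ²(2k), and the
exact two-sided binomial (minimum-likelihood definition) for the
faster/slower split.

## Covariate residualisation and the randomization test

LOWESS uses tricube-weighted local linear fits, span f = 0.3, three
robustness iterations (the statsmodels smoother, verified against a
brute-force per-point weighted-least-squares oracle), evaluated at the
observed covariate values by linear interpolation; a degenerate (constant)
covariate falls back to the mean, which provably leaves the Mann–Whitney p
unchanged.  The Mann–Whitney test uses exact enumeration for tie-free
samples of ≤ 20 per group and the tie-corrected continuity-corrected normal
approximation otherwise.

The randomization test reassigns the covariate values without replacement
(the value multiset, hence the interpolation domain, is unchanged),
recomputes the smooth and the residual contrast, and reports the number of
simulants as extreme or more extreme divided by the number of simulations —
deliberately without a +1 correction, following the procedure's stated
definition; a zero count is displayed as "< 1/n_sims".  Extremeness is
one-sided in the direction of the observed change (masking: p ≤ observed;
explaining: p ≥ observed).  Two properties are asserted: the median simulant
p tracks the uncorrected p (a flat average smooth preserves rank order), and
with a *fixed* direction the randomization p is uniform under an irrelevant
covariate by exchangeability.  Note that with auto-selected direction the
null distribution is folded, so calibration checks must fix the direction.

The 2D residual-space comparison uses the integrated squared difference of
the two groups' Gaussian KDEs with diagonal Scott plug-in bandwidths,
computed in closed form (sums of Gaussian cross-terms, no grid), with a
label-permutation p-value under the add-one rule.  dN~dS model selection is
ordinary least squares (dN ~ dS vs dN ~ dS + status + dS:status) compared by
AIC and the nested ANOVA F test.

## The synthetic generator: what it emulates, and what not

The species tree is the fixed catarrhine topology
(((((human, chimp), gorilla), orangutan), gibbon), macaque) with branch
lengths proportional to rough divergence times at 2.8e-3
substitutions/codon/My, chosen so the macaque–gibbon path is 0.14
substitutions/codon and its synonymous divergence lands at dS ≈ 0.09, the
scale of the reference medians the generator targets; no external
timetree is implied.  Defaults:
400 families, 5% duplicable (exact count, positions randomised), κ = 3,
per-family GC3 drawn N(56%, 8%) through the third-position frequencies.

Per-family ω is log-normal with class medians 0.36 (duplicable) and 0.27
(singleton) and σ_log = 0.30.  The dispersion is a design choice, not an
empirical fit: it is set so that the contrast the generator asserts is
detectable by the rank test at the default sample size (the generator's
stated contract), which makes it somewhat narrower than real mammalian
dN/dS spreads.  Duplications are placed uniformly on fraction [0.1, 0.9] of
a random great-ape terminal branch, so the distance rule holds on true
distances by construction and classification accuracy is essentially 100%;
one duplication per family by default, more paralogs or a distinct
post-duplication ω via config flags.

Covariates are linked to ω through its latent normal score z: expression
(log2-RPKM-like, mean 2.6, sd 1.8, floored at 0) with latent correlation
−0.365 and a +0.9 duplicable offset; CDS length log10-normal (mean 3.2, sd
0.25 in bp) with latent correlation −0.105 and a −0.14 duplicable offset;
genomic length as a log10 expansion of the CDS with a weak (−0.06) link;
GC3 with no group structure.  Because downstream correlations are computed
against *estimated* ω, estimation noise (~0.33 on the log scale for a
~500-codon macaque–gibbon pair) attenuates them: the measured ω–expression
Spearman is ≈ −0.24 for a latent −0.35.  The generator does not emulate
indels or alignment error, gene conversion, rate variation among sites,
expression measured across tissues (one median-like value per gene), or
biased gene conversion linking GC3 to rates — so passing tests demonstrate
the pipeline's statistical behaviour, not robustness to those artefacts.

Reproducibility: one root seed; family *i* uses the spawned stream
`SeedSequence(seed, spawn_key=(i,))`, covariates a dedicated stream, so any
family regenerates in isolation and identical configuration gives
byte-identical files (checksummed in the manifest).

## Problem sizes in the shipped tests

The suite exercises each claim at sizes chosen to keep the whole run in a
few minutes of CPU: pairwise recovery at 10,000 codons × 20 replicates and
the ML/NG86 rank agreement over 100 pairs; LRT null calibration at 200
replicates × 1,500 codons on the deep-duplication fixture; randomization
properties at n_sims = 1,000 (median tracking) and 10-seed scenario checks;
the end-to-end run at the default 400 families.  `scripts/acceptance.py`
uses 2,000 randomization draws per covariate (the procedure's reference
size is 10,000 draws; the analysis scripts default to that).

## Known limitations

* Finite-sample conservativeness of the duplication LRTs for very recent
  duplications (see above) — consistent with scarce significant LRTs when
  paralogs are young, but a power limitation, not a calibration error.
* F3x4 frequencies are plugged in empirically, not profiled out by ML, so
  likelihood-ratio degrees of freedom ignore their estimation (standard
  codeml-style practice).
* NG86 is a rank oracle, not an unbiased estimator, under κ ≠ 1.
* The ω ≤ 10 / dS ≥ 0.01 filter thresholds are taken as given constants of
  the design.
* Ambiguity codes are treated as missing (deleted), not marginalised.
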