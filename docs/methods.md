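# Methods

This note documents the models implemented in `fitscape`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data do and do not establish about real measurements.

## Library design statistics (`fitscape.library_design`)

Degenerate codons are expanded through the IUPAC ambiguity alphabet and
translated with the standard genetic code (both via Biopython); alternative
code tables can be loaded from CSV. Gene-level diversity is the product of
per-site codon-expansion sizes; protein-level diversity the product of
per-site distinct amino-acid counts with stop codons excluded (stops are
reported separately in repertoires, since designs like NNK encode them
even though NDT/NHT/VNG do not).

**Expected distinct variants.** Each protein variant encoded by m of the
design's M DNA sequences is sampled with probability m/M per transformant.
Variants are grouped into multiplicity classes by convolving per-site
multiplicity tallies, so the exact grouped-binomial sum
`Σ_classes count·(1 − (1 − m/M)^L)` is evaluated without enumerating
10⁸-scale libraries; `log1p` keeps `(1 − p)^L` accurate at p ≈ 10⁻⁹,
L ≈ 10⁸. The Poisson form `count·(1 − e^(−Lm/M))` is available and agrees
with the exact sum to <0.1% at library scale. Draws "wasted" on
stop-containing sequences are implicitly accounted for because class
probabilities sum to less than 1 when stops are encoded. For the
eight-codon nitroreductase design and 398 million transformants both forms
give ≈246.5 million distinct proteins; published completeness calculators
built on other assumptions can differ by a few percent, and no attempt is
made to match any particular one.

**Side-chain categories.** The five-way partition used for residue-profile
summaries is the common textbook one: nonpolar aliphatic {G,A,V,L,I,M,P},
aromatic {F,Y,W}, polar uncharged {S,T,C,N,Q}, positively charged {K,R,H},
negatively charged {D,E}.

## Landscape model (`fitscape.landscape`)

Fitness is the fold-improvement in EC50 over wild type, so the wild type
defines 1.0; if a landscape file omits the wild type it is inserted at
exactly 1.0, and if it supplies wild-type measurements (e.g. noisy controls
normalised per batch) they are kept as given. Genotypes are subsets of an
ordered substitution list (one alternative allele per residue position),
canonically written `S41Y+R225V` in ascending position order and held
internally as bitmasks; `WT` denotes the empty set.

When replicate EC50s carry batch identifiers pairing each variant with a
same-batch wild-type control, fold values are computed per batch and
averaged (cancelling day effects); otherwise the ratio of grand means is
used with first-order error propagation. Which convention a given dataset
needs depends on its assay structure; both are exposed.

Partition summaries (mean ± SD of genotypes containing vs lacking a
substitution) use the sample SD across per-genotype means — the question
being how variable the genotype means themselves are, not replicate-level
pooling. The wild type counts in the "lacking" group.

Lattice-wide operations require complete landscapes by default; an
explicit `allow_incomplete=True` downgrades missing genotypes to
skip-with-warning, because silently dropped paths bias accessibility
fractions.

## Trajectories (`fitscape.trajectories`)

Orderings are enumerated lazily (lexicographic `itertools.permutations`),
guarded at n ≤ 12. A step improves iff `f' > f·(1 + t)` with strict
inequality and default t = 0.16: the threshold already encodes typical
EC50 measurement error, so measurement SDs are not re-entered at this
stage, and a gain exactly at the threshold is not demonstrably upward.
The greedy most-plausible path maximises the *resulting* genotype's mean
fitness at each step — a single rule that picks the largest gain when one
exists and the smallest loss when none does — with ties broken toward the
lowest residue position for determinism. Tie and boundary handling are
declared conventions of this package, not inferences about any particular
historical analysis.

The mutation network is a `networkx.DiGraph` over all 2ⁿ genotypes with
n·2ⁿ⁻¹ substitution-gain edges (reversions are out of scope). GraphML
export uses networkx's writer; the DOT writer is a minimal hand-rolled one
(one node statement per genotype, greedy edges bold, non-improving edges
dashed); the edge CSV round-trips topology and attributes.

## Epistasis statistics (`fitscape.epistasis`)

The multiplicative null for a k-substitution genotype is `R = ∏ Xᵢ` over
single-substitution mean folds, with the propagated error generalised from
the three-term form to k terms: `δR = R·√(Σ (δXᵢ/Xᵢ)²)`. The wild-type
reference enters as the fixed constant 1 and contributes no error term.
This first-order formula matches Monte-Carlo resampling of independent
normal components to within a few percent at small CVs; at large CVs
(≳30%) the product distribution skews and the linearisation degrades.

Deviation is scored as `ε = ln(observed/R)`, zero under exact
multiplicativity. Pair classification uses a neutrality band: with
|ε| ≤ tol (default 0.05 on the log scale, required because measured data
are never exactly multiplicative) a pair is "none"; otherwise each
substitution's effect direction (sign of log-effect, directions within the
band counting as neutral) is compared between the wild-type and
other-substitution backgrounds — zero flips is magnitude, one is sign, two
is reciprocal-sign epistasis.

Group comparisons use the unpaired two-sample t-test from summary
statistics (scipy), pooled-variance Student by default with Welch behind a
flag; star labels use inclusive thresholds (*** ≤0.001, ** ≤0.01,
* ≤0.05). Two degenerate zero-spread groups with equal means report t = 0,
p = 1. No multiple-testing correction is applied.

## Dose-response fitting (`fitscape.dose_response`)

Percent inhibition is `100·(1 − ΔOD_challenged/ΔOD_control)` with ΔOD the
growth over the challenge window; a non-growing control is an assay
failure and rejected. The 4PL is fitted by unweighted least squares
(scipy `curve_fit`) in log₁₀-concentration space with a deterministic
initialisation (top/bottom from the response extremes, hill = 1, logEC50
at the concentration nearest the half-maximal response), so fits are
reproducible and invariant to row order; rescaling all concentrations
rescales the EC50 exactly. Plateau bounds [0, 100]% are optional and off
by default. Three diagnostics are attached rather than silently trusted:
optimiser convergence, EC50 inside the tested concentration span, and
fitted plateaus within half a response-span of the observed responses (the
last catches the degenerate near-linear solution that monotone,
plateau-free data produce). Technical-replicate fits are averaged within
each biological replicate before the across-replicate mean/SD/n is taken.

## Synthetic data (`fitscape.synthetic`)

**Landscape generator.** On the log scale,
`ln fold = Σ expressed single effects + Σ active interactions`; an
interaction is active when all its members are present, and when a gating
substitution is configured and absent, non-gate single effects are
multiplied by the masking strength (0 = fully gated, 1 = plain
multiplicative). Replicate folds are lognormal with the requested CV,
parameterised mean-unbiased (μ = ln(true) − σ²/2, σ² = ln(1 + CV²)) so
replicate means estimate the true fold and the empirical CV converges to
the requested CV. All randomness flows from the explicit seed;
identical specs give byte-identical tables.

**Default conditions.** The default spec emulates a seven-substitution
nitroreductase-style landscape: 128 genotypes, 4 replicates, CV 0.16
(matching the ~16% average EC50 error that motivates the step threshold),
gate R225V at ln 2.5 with masking 0.15, companion effects
{0.41, −0.51, 0.18, 0.04, 0.15, 0.22} and two interactions
((S41Y,T219Y) = +0.30 synergy; (H215C,S41Y) = +0.45 rescue of the one
deleterious substitution, a built-in sign-epistasis case). These were
fixed once to reproduce the qualitative structure of such selections: full
variant ≈9×, gate-containing genotypes averaging ≈4× versus ≈1.3× without,
zero fully-improving orderings among the 5040, and a greedy path that
acquires the gate first. True folds span ≈0.93–9.2; real intermediate
landscapes reach lower values (≈0.2×) through strongly deleterious
combinations the simple two-interaction model does not attempt, so
analyses specifically about severe deleterious intermediates should not
lean on the defaults.

**Dose-response generator.** Concentrations form a 1.5-fold dilution
series centred on the true EC50 (12 points by default, spanning ≈9× on
each side); responses follow the 4PL with multiplicative lognormal noise.
The default hill slope is 2, reflecting the steep inhibition transitions
antibiotic growth assays show over a short challenge window. This matters
for recovery benchmarks: with a shallow hill = 1 curve and 5%
multiplicative response noise, a 12-point series simply does not contain
enough information for <5% median EC50 error (measured ≈9% median over
200 seeds, and 6–8% even with far wider spans), whereas at hill = 2 the
median error is ≈3.3% at 5% noise. At 10% noise the median rises to ≈6%,
so the <5% recovery holds for CVs up to roughly 7% under the default
geometry.

**What passing tests show.** The simulators share the analysis code's
multiplicative/lognormal worldview, so recovery tests validate the
estimators' correctness and calibration under that model — they cannot
detect assay artefacts real data carry (batch drift, non-lognormal
outliers, fitness-dependent error, plate position effects). Conclusions
about a real landscape still require the real measurements.

## Problem sizes

Test and benchmark sizes were chosen to keep the full suite fast while
remaining informative: exhaustive brute-force cross-checks run at n ≤ 5
(120 orderings), full-lattice analyses at n = 7 (5040 orderings,
milliseconds), Monte-Carlo oracles at 10⁴–10⁵ draws, and EC50 recovery at
200 seeds.

## Known limitations

- Trajectory analysis treats mean folds as exact once the 16% rule is
  applied; no per-step uncertainty propagation or probabilistic path
  weighting (fixation models) is attempted.
- One alternative allele per position; nucleotide-level genotypes,
  reversions and back-mutations are out of scope.
- The coverage model assumes independent, identically distributed
  transformant draws (no cloning bias within a multiplicity class).
- The 4PL fit is unweighted; heteroscedastic weighting schemes used by
  some commercial packages will give slightly different EC50s on noisy
  curves.
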