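# fitscape

Analysis toolkit for combinatorial active-site mutagenesis studies: from
degenerate-codon library design through EC50 dose-response measurement to
exhaustive evolutionary-trajectory and epistasis analysis of the resulting
genotype–fitness landscape.

## The problem

Directed-evolution experiments that randomise several active-site residues
simultaneously (e.g. the *E. coli* nitroreductase NfsA selected for
chloramphenicol detoxification) produce three linked analysis tasks:

1. **Library design.** A degenerate codon such as NDT encodes a defined set
   of amino acids; a multi-site design encodes `∏ᵢ cᵢ` gene variants and
   `∏ᵢ aᵢ` protein variants (cᵢ = codons, aᵢ = distinct amino acids at site
   i). Given L transformants and per-variant sampling probabilities pᵥ, the
   expected number of distinct variants recovered is
   `E[V_obs] = Σᵥ (1 − (1 − pᵥ)^L)`, evaluated exactly over multiplicity
   classes or by the Poisson approximation `Σᵥ (1 − e^(−L pᵥ))`.
2. **Fitness measurement.** Growth inhibition at each drug concentration is
   `100 × (1 − ΔOD_challenged / ΔOD_control)`; the EC50 comes from the
   four-parameter variable-slope logistic
   `y = bottom + (top − bottom) / (1 + 10^((log₁₀EC50 − log₁₀x)·h))`, and
   fitness is the fold-improvement in EC50 over wild type.
3. **Landscape analysis.** With all 2ⁿ combinations of a variant's n
   substitutions measured, every one of the n! stepwise acquisition
   orderings can be replayed. A step is *improving* when fitness rises by
   more than a relative threshold (default 16%, the typical EC50
   measurement error); a trajectory is *accessible* when every step
   improves. The multiplicative null predicts a combination's fold as
   `R = ∏ᵢ Xᵢ` with propagated error `δR = R·√(Σᵢ (δXᵢ/Xᵢ)²)`; deviations
   are scored as `ε = ln(observed/R)` and pairs classified as magnitude,
   sign, or reciprocal-sign epistasis. The full subset lattice exports as a
   mutation network (GraphML / DOT / edge CSV) for rendering.

A ground-truth simulator generates replicate-level synthetic landscapes —
including a *gating* substitution whose presence is required before the
other substitutions' benefits manifest — and synthetic dose-response
plates, so the whole pipeline is testable end to end without any
measurement data.

## Worked example

Library statistics for the eight-codon nitroreductase design (NDT at six
positions, NHT at 219, VNG at 222), from a design CSV with columns
`position,wild_type,codon`:

```
$ fitscape design-stats design.csv --transformants 398000000
site  wt  codon  n_aa  stop  wt_in_repertoire  repertoire
41    S   NDT    12    0     true              C,D,F,G,H,I,L,N,R,S,V,Y
...
222   K   VNG    11    0     true              A,E,G,K,L,M,P,Q,Rx2,T,V
...
gene variants:    429,981,696
protein variants: 394,149,888
expected distinct variants from 398,000,000 transformants (exact): 246,526,589
```

That is: 12⁸ ≈ 430 million DNA sequences encoding 12⁷×11 ≈ 394 million
proteins, of which ~247 million distinct ones are expected among 398
million transformants.

Simulate a gated seven-substitution landscape (4 replicates per genotype,
16% CV) and analyse its trajectories:

```
$ fitscape simulate --n 7 --gate R225V --seed 1 --out reps.csv --truth truth.json
wrote 512 replicate rows (128 genotypes) to reps.csv
$ fitscape trajectories landscape.csv --greedy
substitutions:       7
total trajectories:  5040
accessible:          0
accessible fraction: 0.0000%
greedy path: R225V -> S41Y -> T219Y -> F227G -> K222V -> S224R -> H215C
```

No ordering improves at every step (the gate masks downstream benefits and
two late substitutions gain less than the 16% threshold), and the greedy
most-plausible path acquires the gating substitution first — the structure
such selections show in practice.

`fitscape export-graph landscape.csv --format graphml --out net.graphml`
writes the 128-node, 448-edge mutation network with fold-improvement,
step-classification and greedy-path attributes for styling;
`fitscape epistasis landscape.csv --pairs --test` tabulates multiplicative
predictions R ± δR, ε scores and t-test stars; `fitscape fit-ec50
plate.csv --out ec50.csv --summarise` turns raw plate OD readings into the
landscape CSV.

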