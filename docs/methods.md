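# Methods

This note documents the models and estimators implemented in `tetradkit`,
the defaults and why they were chosen, and what the simulation-based tests
do and do not demonstrate.

## Meiosis simulator (`sim_meiosis`)

Each tetrad is simulated per chromosome from four chromatids: two copies of
parental haplotype A and two of B. Crossover counts are Poisson with mean
`length_Mb × cos_per_mega` (no interference); each crossover sits at a
uniform position and reciprocally exchanges the chromosome arm distal to
that position between one uniformly chosen A-centromere chromatid and one
uniformly chosen B-centromere chromatid. Centromeres never change hands.
Exchanges are applied in order of distance from the centromere — following
each DNA molecule outward — because same-arm exchanges do not commute
(ascending-position application would build left arms walking inward and
subtly distort distal linkage). Meiosis I sends the two A-centromere
chromatids to one pole and the two B-centromere chromatids to the other
(pole orientation random per chromosome); meiosis II splits each pole into
two spores. Spores 0,1 of a tetrad are one pole's products, so every
chromosome shows the two-plus-two mirrored centromere pattern.

Genotyping noise flips each call independently with probability
`noise_rate`, then missingness masks each call independently with
probability `missing_rate` (the order is unobservable downstream; fixing it
makes runs reproducible). Markers are placed uniformly at random over the
genome (collisions resampled). All randomness derives from one seed; equal
seeds give bit-identical outputs.

Defaults: sacCer3 chromosome lengths and centromere midpoints (packaged),
`cos_per_mega = 6.0` crossovers·Mb⁻¹·meiosis⁻¹ (order of magnitude of the
~90 crossovers per *S. cerevisiae* meiosis over a 12 Mb genome), 100
tetrads, 1000 markers, 1% noise, 5% missing — the flagship simulated
regime. The simulator does **not** model gene conversion, crossover
interference, chromosome-specific recombination maps, aneuploidy, or
non-uniform marker ascertainment; conclusions from simulated runs carry
over to real data only to the extent those features behave like extra
noise (gene conversion in particular perturbs 2:2 segregation exactly the
way genotyping errors do).

## Information measures (`info_measures`)

All estimators are plug-in (maximum-likelihood) Shannon quantities in log
base 2, computed from the joint allele-pattern counts of a group over its
*complete-case* markers (markers where every group member has a call).
Interaction information uses the inclusion-exclusion form
`II(S) = Σ_{∅≠T⊆S} (−1)^{|T|+1} H(T)`, the sign convention under which a
pair's II is exactly its mutual information, a sister triple is negative
and a full tetrad positive. Delta is
`δ(S) = Π_{i∈S} [II(S) − II(S∖{i})]`; every subset II inside the product is
evaluated on the *full group's* complete-case markers so all factors share
one sample space. No bias correction is applied: thresholds are calibrated
by permutation on the same estimator, so the shared finite-sample bias
cancels at the decision boundary.

Closed forms on the ideal 2:2 distribution (six equiprobable patterns):
MI = 5/3 − log₂3, II₃ = 3 − 2log₂3, II₄ = 5 − 3log₂3,
δ₄ = (2 − log₂3)⁴, δ₃ = (4/3 − log₂3)³. These are frozen as package
constants and verified against an independent brute-force subset-entropy
oracle in the tests.

Degenerate inputs: a group with zero complete-case markers is unscorable
(error in the scalar API, NaN in the vectorized batch API, automatic
failure in verification).

## Recombination-density estimation (`centromere_clustering`)

The global crossover density `c` (COS_PER_MEGA) is estimated from allele
switches between consecutive non-missing markers. Naive counting
underestimates `c`: an exchange between two chromatids that already carry
the same allele at that point is invisible. Solving the four-chromatid
exchange chain gives the expected per-chromatid switch intensity at
distance `d` (Mb) from the centromere,

    λ(d) = c/3 + (c/6)·exp(−3cd/2),

which is `c/2` in the dilute limit and saturates at `c/3` distally. The
estimator integrates λ over every spore's observed marker spans (split at
the centromere; chromosomes without a known centromere are anchored at
their span midpoint) and solves `E[switches](c) = observed` by bisection.
On simulated data at `c = 6` this recovers the parameter to ~5% (residual
bias from interval-level cancellation of closely spaced exchanges);
the naive factor-2 count is ~20% low. `CEN_CALLING = false` skips
estimation and uses the configured default (useful on large inputs, or to
pin a published value).

## Centromere calling and clustering

For each spore and chromosome, the nearest non-missing marker on each side
of the centromere contributes a likelihood factor `1−r` for the matching
haplotype and `r` otherwise, with `r` from the Haldane map
`r = (1 − e^(−2m))/2`, `m = (c × d_Mb)/2` Morgans (the per-chromatid map
distance; a marker exactly at the centromere gives near-certainty). The
posterior `p_A = L(A)/(L(A)+L(B))`; chromosomes with no informative marker
get 0.5. Haldane is an approximation here — the chromatid allele process
under the exchange chain is not exactly Poisson — but the discrepancy is
second-order at flanking-marker distances.

Spore similarity is the absolute mean haplotype correlation
`|mean_c (2p_c−1)(2q_c−1)|`, high for matching *and* mirrored profiles, as
required by the two-plus-two pattern. Spores with similarity at or above
`SIMILARITY_COEFFICIENT` are joined by a weighted edge and communities are
extracted by greedy modularity maximization (networkx); singleton
communities are treated as unclustered. With 16 chromosomes the background
similarity of unrelated spores (a mean of 16 near-±1 terms) reaches ~0.7,
so small thresholds produce large mixed communities. That is acceptable —
clustering is purely a search-space pruning heuristic here, and the repair
and global phases recover anything it splits — but whole-tetrad
containment as a property holds from thresholds around 0.6. The default
threshold is 0.2 with noisy-data presets at 0.24; raising it is the main
lever when clusters come out too large or too mixed.

## Thresholds and the search (`tetrad_search`)

Null distributions are built once per run by scoring `N_PERMUTATIONS`
(default 10,000) uniformly random distinct-spore groups per level: delta
for 4- and 3-spore groups, MI for pairs. Thresholds are empirical
quantiles: right tail for δ₄ (`D4_PVALUE`, default 0.05) and MI
(`MI_PVALUE`, default 0.05), left tail for δ₃ (`D3_PVALUE`, default 0.01;
true triplets are negative). The nulls contain a small fraction of genuine
sister groups, which makes the cutoffs conservative; this is why the δ₃
and MI defaults are not pushed into the extreme tails — at p ≤ 0.001 the
quantile lands inside the sister-contaminated region and the thresholds
stop admitting true partial tetrads.

Candidate tetrads must exceed the δ₄ threshold *and* pass verification:
the fraction of complete-case markers segregating exactly 2:2 must exceed
`SEG_CUTOFF_D4` (default 0.9; triplets use 2:1 vs `SEG_CUTOFF_D3`, default
0.95). Under noise `q` per call, a true tetrad's expected 2:2 fraction is
`Σ_j [C(2,j) q^j (1−q)^{2−j}]²` (≈ 0.69 at q = 0.1), hence the documented
noisy-data presets 0.75/0.88 (5% noise) and 0.6/0.83 (10% noise).

Accepted groups are chosen greedily without overlap. Among candidates that
already cleared the delta threshold, acceptance ranks by segregation
fraction first and delta second (ties broken by spore indices). The
rationale: when two meioses happen to share a centromere segregation
pattern (probability 1/2^15 per pair, so likely *somewhere* among 100+
tetrads), a 2+2 chimeric group of their spores can out-score both true
tetrads on delta under noise, but its 2:2 fraction is structurally capped
(≈ 0.5 clean) below a true tetrad's; the verification score is therefore
the sharper ranking key, and on noise-free data it is exactly 1.0 for
every true tetrad. Candidates that fail verification return to the pool.

Search staging: per-cluster (exhaustive for clusters of ≤ 5 spores, else
shadow search with in-cluster extension), then per-cluster triple seeds
extended by *all* unassigned spores (repairing tetrads split by
clustering), then a global phase over the pooled remainder — shadow first,
and a direct exhaustive pass when the pool's 4-group count is at most
`DIRECT_SEARCH_LIMIT` (default 2,000,000 combinations; a search-space
bound chosen so a full run stays desk-scale). Shadow searches extend at
most `SHADOW_SEED_LIMIT` (default 20,000) of the strongest seed triples;
true sister triples sit orders of magnitude below the δ₃ threshold, so the
budget trims borderline false seeds.

After the tetrad phases a **refinement pass** challenges every accepted
tetrad with the quads obtained by exchanging one or two of its spores for
currently unassigned spores; a challenger replaces the incumbent only if
it passes the δ₄ threshold and strictly dominates the incumbent on *both*
the 2:2 fraction and delta (joint dominance keeps single-score sampling
noise from displacing true tetrads). The pass also repartitions pairs of
accepted tetrads: two collided tetrads can be accepted as two
complementary chimeras holding all eight spores between them, invisible
to pool exchanges; all 35 four-plus-four splits of each pair are scored
and a repartition is applied when both halves pass threshold and
verification and the pair strictly improves both summed scores.
Staged greedy acceptance can otherwise let a chimera of two
centromere-collided tetrads claim spores in an early stage where the true
tetrads were never co-candidates (a tetrad split 3+1 across clusters has a
single eligible seed triple, which noise can push past the δ₃ threshold);
the exchange search undoes such thefts, and a final direct pass over the
freed spores recovers the partner tetrad. The pass is a no-op on
noise-free data, where every true tetrad already sits at fraction 1.0.

Finally remaining spores are searched for triplets (δ₃ + 2:1
verification) and pairs (MI), and leftovers are labelled singles.

Determinism: one run seed drives the null draws (via spawned seed
sequences); simulation, clustering and greedy acceptance are deterministic
given their inputs, so fixed seed + fixed input gives an identical
assignment. Group ids are canonicalized (sorted by kind, then spore ids)
so equivalent runs produce byte-identical assignment files.

## Preprocessing

Duplicate spores are detected with the normalized mismatch distance over
shared non-missing positions (allele vectors are position-aligned, so
mismatch counting is the natural edit distance; `DUP_CUTOFF` default 0.05,
greedy first-kept pass), then spores with missing fraction strictly above
`MAX_MISSING` (default 0.5) are dropped. Both defaults are package
choices — reasonable hygiene levels, not values with a published source.

## Evaluation and problem sizes

`score_against_truth` counts a detected group as correct iff all its
spores share one ground-truth tetrad. The benchmark grid and the
acceptance script use 100 tetrads × 500 markers — the small benchmark at
its reduced marker count — which a single CPU completes in a few minutes
per cell; larger regimes (1000 tetrads, 10⁴–10⁵ markers, 10% noise) scale
the same algorithms but are long-running and are left to explicit CLI
invocations rather than the test suite.

## Known limitations

- Pair recovery by pooled marker-wise MI is physics-limited at high
  crossover density: pole-mate sisters agree near centromeres but
  anti-correlate distally (stationary agreement 1/3), so the genome-pooled
  MI of a leftover sister pair can sit inside the null. Triplets and
  tetrads do not suffer from this (delta uses higher-order structure).
- The similarity coefficient and the Haldane flank model are explicit
  reconstructions; their calibration (threshold defaults, cluster-size
  behaviour) was set empirically on simulated data.
- No gene-conversion awareness: markers violating 2:2 through conversion
  are treated as noise, so conversion-rich data effectively raises the
  noise level and calls for the relaxed verification presets.
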