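# Methods

This note records the models, estimators, parameter defaults and
numerical choices implemented in barcodekit, and what its simulators do
and do not emulate.

## Alignment handling (`msa_io`)

Aligned FASTA only; residues are uppercased and `U` mapped to `T`.
Taxonomy comes from headers matching `<id> <Genus> <epithet> ...`
(separator: whitespace or `_`); genus is the first name token, the
species binomial the first two. **Complete deletion** removes every
column containing a gap (`-`) or missing character (`N`, `?`) in any
sequence; it is the default preprocessing for distance, diversity and
tree computations, matching the common MEGA/DnaSP convention.
**Concatenation** is plain supermatrix joining on a shared key (species
or record id): one output row per key present in at least one locus,
missing loci padded with gap runs, per-locus column offsets recorded so
the inputs can be recovered by slicing. Combined length is exactly the
sum of input lengths; no trimming is applied.

## Composition and site classification (`composition`)

Codon position of column `c` is `((c − frame_offset) mod 3) + 1`.
Base frequencies are percentages over unambiguous residues. Pair
frequencies (`ii` identical, `si` transition, `sv` transversion;
transitions are A↔G and C↔T) are means over all unordered sequence
pairs, with `R = si/sv` left undefined when `sv = 0`. A column with at
least two observed unambiguous bases is *considered*; it is *conserved*
if one base is observed, otherwise *variable*; *parsimony-informative*
if at least two bases each occur at least twice; *singleton* if exactly
two bases are observed and the rarer occurs once.

## Distances (`distances`)

Kimura 2-parameter: with transition proportion `P` and transversion
proportion `Q` over jointly unambiguous sites,
`d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)`. When either log argument is ≤ 0 the
pair is *saturated*: a single pair raises `SaturatedPairError`; in a
matrix the cell becomes NaN and is flagged, and only an all-saturated
matrix is an error. Deletion policy is `complete` (default) or
`pairwise`.

## Diversity and neutrality (`popgen`)

All statistics are computed after complete deletion on the `L_eff`
remaining columns. `S` = segregating sites; `Eta` = total mutations,
counting a column with `m` distinct bases as `m − 1`; `k` = mean
pairwise differences per sequence; `π = k / L_eff`;
`θ_W = S / (a1 · L_eff)` with `a1 = Σ_{i<n} 1/i`; haplotype diversity
`Hd = n(1 − Σp_i²)/(n − 1)`.

**Tajima's D** uses the standard `a1, a2, b1, b2, c1, c2, e1, e2`
coefficients; `D = (k − S/a1)/√(e1·S + e2·S(S−1))`, undefined for
`S = 0` or `n < 4`. Significance bands use Tajima's beta approximation:
`Dmin = (2/n − 1/a1)/√e2`, `Dmax = (n/(2(n−1)) − 1/a1)/√e2`, with `D`
rescaled onto a Beta(β, α) distribution on `[Dmin, Dmax]`; we report
the band (`p > 0.10`, `> 0.05`, `< 0.05`, `< 0.01`, `< 0.001`) rather
than a pointwise p-value, as the approximation does not warrant more.

**Fu's Fs** sets `θ̂ = k` (per sequence) and computes
`S′ = Pr(K ≥ k_obs)` under the Ewens sampling distribution,
`Pr(K = j) = |S1(n, j)|·θ^j / θ^{(n)}`, with unsigned Stirling numbers
of the first kind evaluated in log space (`logaddexp` recurrence) for
numerical safety at large `n`; `Fs = ln(S′/(1−S′))`. `k_obs = 1` makes
`S′ = 1` exactly and `Fs` undefined. Significance bands come from 1000
seeded coalescent replicates at `θ̂` (Fs has no usable analytic null);
the replicate alignment length is `max(4·L_eff, 200)` so the
infinite-sites assumption holds.

**Mismatch distribution**: relative frequencies `x_0..x_max` of pairwise
difference counts; raggedness `r = Σ(x_i − x_{i−1})²` with `x_{−1} = 0`;
Ramos-Onsins & Rozas `R2 = √((1/n)·Σ(U_i − k/2)²)/S` with `U_i` the
number of singletons carried by sequence `i`; coefficient of variation
of the pairwise differences. **τ** is the package's own choice of
estimator (the source literature names τ without defining one): a
least-squares fit of a Poisson(τ) sudden-expansion curve to the observed
frequencies, on an 801-point grid over `[0, 2·d_max]`. The Poisson shape
is only a model of post-expansion (star-like) genealogies; on
constant-size coalescent data the fit is a descriptive summary, not an
estimate of anything.

## Trees (`phylo`)

Saitou & Nei neighbor joining with the Q-criterion; ties broken at the
lowest (row, column) index so results are deterministic. Negative branch
lengths are clamped to zero with the deficit transferred to the sibling
edge, preserving path lengths where possible; on additive matrices
recovery of topology and branch lengths is exact. Bootstrap resamples
alignment columns with replacement (`B` replicates, seeded), rebuilds
the NJ tree, and reports bipartition support as percentages; replicates
whose resampled matrix is unusable (e.g. fully saturated) are skipped
and the skipped fraction reported. Newick output quotes labels where
needed and serializes branch lengths to 6 decimals (round-trip paths are
therefore reproduced to ~1e−5, not exactly).

## Identification (`barcode_eval`)

Distances are partitioned into intraspecific and interspecific sets
(flagged/NaN cells counted separately). The **barcoding gap** is
`min(inter) − max(intra)`, with histograms on a common bin width
(default 0.005) and an overlap fraction. The **BCM threshold** is by
default the 95th percentile of intraspecific distances (Meier's
convention; `np.quantile` linear interpolation). **Best Close Match** is
leave-one-out: a query with no reference within the threshold is
`no_id`; otherwise its nearest references (ties within `tie_tol =
1e−12`) are examined — all conspecific → `correct`, none → `error`,
mixed → `fuzzy`. Summaries are reported over all queries and over the
subset whose species has more than one member (a singleton species can
never be identified correctly by construction). Note a percentile
threshold < 1.0 *by definition* leaves the top tail of intraspecific
distances above the threshold, so a few `no_id` on perfectly separated
data is expected behavior, not a defect.

## Diagnostic barcodes and QR codes (`snp_barcode`, `qr`)

A column is **diagnostic** for a species if every target sequence
carries the same unambiguous base and no non-target sequence carries it.
Around each diagnostic column a window (default `W = 40`) is cut from
the ungapped target sequence; a candidate fragment is kept only if it is
identical across all target sequences and occurs as an exact substring
of no ungapped non-target sequence (a deliberately conservative,
assembly-free specificity screen). Overlapping accepted windows are
merged and re-screened; fragments are ranked by diagnostic-site count,
then leftmost position, keeping `max_per_species` (default 2).

Payloads are `BEKv1|<species>|<locus>|<start-end, 1-based>|<fragment>`.
QR encoding is a self-contained model-2 implementation: byte mode,
versions 1–10, error-correction level M, Reed-Solomon over GF(256)
(polynomial 0x11d), all 8 mask patterns scored with the standard N1–N4
penalties (lowest penalty wins, ties to the lowest mask id — rendering
is fully deterministic), BCH-protected format/version words. Every
rendered image is first decoded back by a structural self-decoder
(format word, unmasking, deinterleaving, zero-syndrome check) and the
payload compared, so a written PNG is guaranteed readable. Payloads
beyond version-10/M capacity (213 bytes) raise an error; the pipeline
records these as skipped images, since the fragment itself is still a
valid barcode.

## Simulators (`synthetic_data`)

**Hierarchical simulator**: a root sequence mutates along a
genus → species → individual star hierarchy; each edge applies
`Poisson(d·L)` substitution events at uniform positions with
Jukes-Cantor-style uniform replacement bases (so repeat hits can
overwrite). Parameters `d_genus > d_species > d_intra ≥ 0` are
per-edge expected substitutions per site (defaults 0.10 / 0.08 / 0.005,
L = 800, 5 genera × 4 species × 4 sequences). Optional planted
diagnostic columns are written last from a state absent among
non-targets and self-verified (with seeded retries). An optional
`indel_rate` punches gap columns for exercising complete deletion.
*Not emulated*: rate heterogeneity, codon structure, realistic indels,
recombination, lineage sorting across the species boundary — the
simulator produces cleanly separated hierarchical data by construction,
which is exactly what the gap/BCM acceptance checks require.

**Coalescent simulator**: Kingman coalescent (exponential waiting times
with rate C(k,2)), mutations placed on branches as
`Poisson(θ/2 · total branch length)` under infinite sites on a
monomorphic background. Calibration: `E[S] = θ·a1`, `E[k] = θ`.
*Not emulated*: recombination, selection, migration, demographic change.

## Determinism

Every stochastic routine takes an explicit seed (`numpy`
`default_rng`/`SeedSequence`); the pipeline derives all stage seeds from
one config seed and records every effective setting in `manifest.json`,
making full report bundles byte-identical across reruns.
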