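# Methods

This note records the models, conventions and numerical choices behind
each module, what the simulator does and does not emulate, and the known
limitations.

## Probe design

A *seed site* is an L-bp strict-ACGT sequence (default L = 20, the length
of the genomic fragments the design targets). The SNV series of a seed is
its exact Hamming-1 neighborhood: 3L sequences, ordered position-major
with variant bases alphabetical, so that the seed plus its variants cover
all four bases at every position. Every unique sequence is expanded into
`n_rep` replicate spots per orientation (default 5 × 2 = 10); the
reverse-orientation spot carries the exact reverse complement of the
variable region. Probe IDs follow the grammar
`<seed_id>|<category>|p<pos>|<base>|<orient>|r<rep>` — self-describing,
sortable, and parseable.

**Scaffold.** The variable region sits at a fixed position inside a
constant scaffold (5′ flank + variable region + 3′ double-stranding
primer). Vendor primer sequences are proprietary, so the scaffold is pure
configuration; the default is an arbitrary fixed 24-nt placeholder. No
downstream computation depends on the scaffold content.

**Background probes.** Random uniform-composition sequences drawn by
rejection sampling, excluding (by default) the ETS core GGAA and the IRF
core GAAA on either strand, so the background set estimates genuinely
non-specific signal. The exclusion list is configurable and can be
disabled. Sampling is reproducible from the RNG seed and fails loudly if
the attempt budget is exhausted.

**Half-site ablations.** A composite element is ablated by replacing the
ETS (GGAA) or IRF (GAAAC) core span with a k-mer that differs at every
position and does not create a new core match on either strand. A
deterministic ladder of base-substitution maps is tried in order
(A↔C/G↔T transversions, then A↔T/C↔G, then transitions); the first map
passing verification wins. The ladder exists because the first map sends
GGAA to TTCC — the ETS core on the opposite strand — so a single fixed
map cannot satisfy the no-new-core constraint.

**Synthetic composites.** A weak site containing a GGAA core is upgraded
to the composite architecture GGAA-N₂-GAAA(C/G) by *overwriting* the
bases downstream of the 2-nt linker with the IRF consensus (default
GAAAC), preserving probe length; linker bases come from the weak site. If
the core is only present on the reverse strand the construction is done
in that frame. Cores too close to the 3′ edge fail with the seed named.

## Intensity processing

All work is on natural-log intensities; z-scores are invariant to the log
base, so this is a declared convention, not a modelling choice.

**Normalization.** Arrays are brought onto a common scale by regressing
each array's per-probe log-intensity profile (OLS, degree 1) onto the
across-array median profile and rescaling to slope 1 / intercept 0. The
reference and the rescaling are iterated to a fixed point (tolerance
1e-12, capped at 100 rounds), which makes re-application a no-op; the
total affine transform per array is reported so planted gains can be
recovered in tests. A single array passes through unchanged. This
preserves the property cross-array normalization must provide —
comparability — with a fully specified, testable contract; the module
boundary is an extension point for other normalization schemes.

**Aggregation.** Spots flagged bad (GenePix-style negative flags, or
non-positive intensity) are excluded; the per-sequence aggregate is the
median log-intensity over all remaining spots of both orientations
(orientation-collapsed, since one z-score per unique site is reported).
The median is the only robustness mechanism — no additional trimming, so
there are no hidden parameters; it tolerates up to ~40% flagged spots.

**z-scores.** z = (log-aggregate − mean of background aggregates) /
sample sd (n−1) of background aggregates, applied to every sequence
including the backgrounds, which therefore have mean 0 and sd 1 exactly
by construction. At least 20 background sequences are required; a
zero-variance background is a hard error. Whether population or sample sd
is used is a declared choice; with hundreds of backgrounds the difference
is negligible.

## SNV logos

The 4×L matrix holds the z-score of each variant at cell (base,
position); the seed's own base at each position carries the seed z-score.
Up to 10% of the 3L variants may be missing (real arrays drop spots);
more is an error listing the gaps. Δz subtracts the per-column median of
the four values (even-n median = mean of the middle two); columns with
fewer than four finite values are centered over what is available and
flagged. Two logo-height transforms are provided: `positive-clip`
(default; negative Δz clipped, columns rescaled to sum to the column
maximum) and `probability` (per-column softmax, temperature 1). Both are
monotone, so the dominant base per column is identical. Binding models
are only trusted when the seed probe itself scores z ≥ 2 (configurable):
below that, variant effects are not resolvable from background noise.

## Cooperativity

The reference relation between extract and IVT z-scores is a degree-2
polynomial fit by unweighted OLS to canonical probes; the quadratic term
absorbs curvature from concentration differences between experiments.
var(ε₁) is the sample variance (n−1). The composite score is
|ε₂|/var(ε₁); the signed residual is always reported so direction is
never lost. Note the score is scaled by a *variance*, so it is not a
z-like quantity; comparisons should be within one fitted reference.

Keeping composite probes out of the reference set is the caller's
responsibility and is enforced by manifest category labels: cooperative
outliers inside the fit would bias the curve toward them and deflate the
scores. No robust loss is used by default for the same reason — the
contamination risk is handled by design, not by estimation. No p-values
are attached; for context the empirical null |ε₁|/var(ε₁) over canonical
probes is exposed, and the workflow's default candidate cutoff is its
99th percentile with a positive-residual requirement (enhanced binding
only).

Fit preconditions: ≥ 10 canonical probes, > 3 distinct x values, finite
inputs; numerically perfect fits (residual variance below 1e-20 of the
response variance) are rejected because scores would be undefined.

## PWM scanning

Scores are natural-log odds against a uniform 0.25 background, summed
over positions, in keeping with the biophysical reading of per-base
energy contributions. PWM probabilities get a pseudocount of 1e-3 (then
renormalized) so zero-probability bases remain scoreable; pseudocount 0
is allowed, in which case impossible bases score −inf. The max-scan
evaluates every window on both strands; ties break to the smallest
forward-strand offset, then the forward strand. Windows containing
ambiguity codes are skipped, never scored.

Significance thresholds are the empirical 0.999 quantile (configurable)
of max-scan scores over ≥ 1000 random uniform sequences of length 200 —
a stand-in for score-threshold calibration against random backgrounds,
kept as configuration. When counting significant sites per region,
hits closer than one motif width are merged first, so a palindromic site
seen on both strands counts once. Region selection partitions inputs
into exactly-one-site (kept), multi-site (excluded) and weak (no
significant site; best-scoring window reported) — disjoint and
exhaustive.

## Genomic annotation

Coordinates are 0-based half-open throughout (BED convention). Overlap
means ≥ 1 shared base; "within 200 bases" is measured between closest
edges (0 when overlapping or book-ended); nearest-gene distance is site
midpoint to TSS. Neither reference point is forced by the rules
themselves, so both are configuration with these defaults.

Binding context: co-occupied with a cofactor when a reproducible peak
overlaps; "with_both" when ≥ 2 cofactors co-occur; "alone" only when the
nearest *relaxed-parameter* peak is > 200 bases away for every cofactor.
Sites in between (e.g. a relaxed peak at 150 bases but no reproducible
overlap) form an explicit ambiguous class rather than being silently
dropped. Enhancer state: active (both marks ≤ 200 bases, nearest gene
2–500 kb, expression strictly above the median RPKM), primed (H3K4me1
only, expression strictly below the median), unmarked (no mark within
200 bases); everything else — including expression exactly at the median
— is ambiguous. The median is taken over all genes in the supplied table
(configurable by pre-filtering the table to expressed genes).

Group comparisons use the two-sided Wilcoxon–Mann–Whitney test (exact
for small samples without ties, normal approximation with continuity
correction otherwise, via scipy); categories with n < 3 are summarized
but not tested.

## Simulator

Per-spot log-intensity is

    log I = offset + gain · (E(s) + c · Δ(s) · 1[extract]) + N(0, σ)

with autonomous energy E(s) = max(0, best PWM log-odds over both strands)
plus a small per-sequence jitter (sd 0.1) standing in for flank effects,
and cooperative term Δ granted only to composite-lineage sequences whose
EICE architecture is intact on either strand. That single rule produces
the qualitative behaviors the pipeline must detect: ETS-core SNVs lose
binding in both channels (PWM score collapses and the architecture
breaks), IRF-half-site SNVs lose only the extract boost (the PWM window
does not cover the IRF half-site), and flank/linker SNVs stay
cooperative. Concentration c scales only the cooperative term, modelling
an extract dilution series against a fixed IVT reference; a boost
multiplier of 0 models cofactor knockout or immune-depletion. Spot noise
is i.i.d. Gaussian on log-intensity; a configurable fraction of spots is
flagged bad.

Defaults are the emulated study conditions: 2499 canonical, 116
composite and 500 background probes, Δ = 3 z-units, c = 1, noise sd 0.5,
flag rate 1%, gain 1, offset 8. Unit tests use smaller set sizes purely
for speed; the acceptance checks run the full sizes.

Everything is a pure function of the config seed (independent
child streams for design, truth, and each channel), so identical configs
give byte-identical outputs and condition panels share sequences exactly.

**What the simulator does not emulate:** saturation (log-intensity is
linear in energy — non-physical at high occupancy), spatial artifacts
and scanner gradients, orientation-dependent double-stranding bias,
sequence-composition noise structure, and the obligate-dimer cofactor
channel (only hooked qualitatively). Passing closed-loop tests therefore
demonstrates that the *computational contracts* hold — recovery of
planted energies, boosts and orderings under Gaussian spot noise — not
that real arrays meet these assumptions.

## Problem sizes and runtime

Acceptance checks run 50 full-size simulated experiments for boost
recovery (~0.5 s each), one 5-condition panel, one SNV-series recovery at
500 backgrounds, a 1000-sequence scanning oracle, and fixture-based rule
checks; the whole suite completes in well under a minute on one core.
These sizes were chosen to match the emulated study's set sizes where
stated and to keep Monte-Carlo error far from the asserted margins
elsewhere.

## Known limitations

- The normalization is a declared stand-in contract (median-profile
  regression), not a port of any published microarray normalization
  algorithm; the module boundary allows swapping one in.
- Cooperativity scores are relative to one fitted reference; comparing
  magnitudes across references with different var(ε₁) is not meaningful.
- The logo-height transforms are display conventions, not
  information-content (bits) logos; no motif-database matching is
  provided.
- Threshold calibration quantiles are Monte-Carlo estimates; at the
  0.999 quantile with 10,000 draws, run-to-run variation of the
  threshold is expected and documented in tests.
- Binding-context labels assume the two-cofactor design ("with_both"
  for ≥ 2 co-occupancies); finer labels for ≥ 3 cofactors would need a
  set-valued context.
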