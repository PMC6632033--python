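# Methods

## Model and assumptions

The pipeline rests on three modeling assumptions.

1. **Comparative arrays measure ratios.** A two-channel tRNA microarray
   reports, per probe, the ratio of the sample pool to a co-hybridized
   reference pool, in arbitrary fluorescence units. In-vitro transcribed
   spike-in tRNAs added at equal amounts to both pools have a true ratio of
   1 and anchor the channel scale.
2. **A baseline tRNAome converts ratios to absolute fractions.** Given one
   model whose tRNAome is known in absolute units (fractions of total
   tRNA), dividing the sample-vs-reference ratio by the baseline-vs-
   reference ratio cancels the shared reference pool, and multiplying by
   the baseline's absolute fraction puts every model on the absolute
   scale. Non-spike fractions are renormalized to sum to 1.
3. **Elongation rate is proportional to cognate tRNA concentration.**
   Ribosome occupancy (relative dwell time) at a codon is the reciprocal of
   the codon's tRNA fraction, and the speed over a ribosome-sized window
   is the harmonic mean of the codon fractions inside it: dwell times add,
   so `v = w / Σ 1/f(c)`. Initiation, ribosome traffic, and mRNA structure
   are outside the model.

## Processing steps

- **Median ratio.** Per probe, the ratio is computed per spot and the
  median taken across technical replicates (not median per channel then
  ratio). Spots with a zero reference channel are scan artifacts; they are
  dropped and counted in a QC log, never floored.
- **Spike normalization.** All ratios are divided by the *median* of the
  spike-probe ratios — robust to a single misbehaving spike — after which
  the spike median is exactly 1 and the operation is idempotent.
- **Replicate QC.** Between two replicates, each probe gets
  CV = sd(n−1)/mean (with n = 2, `|a−b|/√2 / mean`); overall similarity is
  a two-sided two-sample KS test on the non-spike ratio vectors
  (`scipy.stats.ks_2samp`, exact null for small n). Spikes are excluded:
  they are pinned at 1 by construction. "Internal variation" of a
  replicate is operationalized as its mean pairwise CV against the other
  replicates, averaged over probes; the representative replicate minimizes
  it, ties resolving to the lowest index.
- **Codon allocation.** Each probe's fraction is split across its decoded
  codons proportionally to genomic codon usage (default: human genome-wide
  usage per thousand, shipped as a table; any positive scale is
  equivalent). Contributions to a codon from several probes are summed,
  then the 61-codon vector is renormalized. The decoding map is taken
  verbatim from the panel annotation, not re-derived from wobble theory;
  wobble rules are used only by the synthetic panel builder. The initiator
  Met probe is excluded from allocation (it does not elongate); internal
  AUG codons receive only the elongator Met probe. Renormalization happens
  *after* allocation, making the per-codon vector a proper distribution;
  the alternative order (renormalize first) differs only by a constant and
  yields the same distribution.
- **Ambiguity.** Isoacceptors differing by fewer than 8 nt are one
  ambiguity-grouped probe (in the default panel: the Pro group, decoding
  all four CCN codons). Such probes contribute to codon fractions
  normally, but their codons are flagged `ambiguous`, and any variant call
  touching an ambiguous codon returns `unresolvable` rather than a number.

## Velocity profiles

Window values are assigned to the window's **center** codon
(start + ⌊w/2⌋); truncated edge windows are not reported. Center
anchoring avoids a systematic phase shift; whether a windowed profile
should anchor first, last or center is a free choice and is declared here,
not derived. Window sums are computed per window (via convolution), not by
a running cumulative sum, so changing one codon provably cannot perturb
windows that do not contain it. With window = 1 the profile reduces to
the raw per-codon fraction sequence. The percentile band uses linear
interpolation between order statistics (the common statistical default).
Slow/fast regions are maximal runs of centers strictly below the 10th /
above the 90th percentile. Velocities are relative (fractions of total
tRNA); no conversion to codons/second is attempted. The 5'-terminal AUG is
profiled with the elongator Met fraction — a declared approximation.

## Cross-model comparison

Pairwise per-codon occupancy differences use Tukey fences
(Q1 − 1.5·IQR, Q3 + 1.5·IQR, strict exceedance) to flag outlier codons —
the boxplot idiom; the fence factor and the recurrence threshold
(default: flagged in more than 10 pairs) are configurable. Correlations
between models are Pearson r on isoacceptor (probe-level) fractions;
per-codon dispersion is the sample SD (n−1) of occupancy across models.

## Variant classification

For a synonymous variant with per-model speed ratio `R_m = f_wt/f_mut` and
reference ratio `R_ref`, classes are assigned with a single relative
tolerance `t` (default 0.2, configurable — the qualitative notions of
"equal" and "much lower" need a quantitative cut and this is it):

1. `unresolvable` — either codon is ambiguous in model m;
2. `reverted` — `R_m ≤ 1/(1+t)` while `R_ref > 1+t` (the variant speeds
   up where the reference slows down); checked before `no_effect` because
   its condition is a subset of the `no_effect` bound and the more
   specific call must win;
3. `no_effect` — `R_m ≤ 1+t` (the variant codon is not meaningfully
   slower);
4. `same` — `|log2 R_m − log2 R_ref| ≤ log2(1+t)`;
5. `stronger` — `R_m > R_ref·(1+t)`; otherwise `weaker`.

The reference model itself is labelled `same` by construction. An
unresolvable reference is an error: there is no anchor to compare
against (the analysis driver reports such variants as unresolvable in
every model). As `R_m` grows with all else fixed, the class moves
monotonically `reverted → no_effect → weaker → same → stronger`.

## Synthetic data

The generator emulates the full study design:

- **Truth tRNAomes** — per model, i.i.d. log-normal(μ=0, σ=1) draws per
  probe, normalized to sum 1; this reproduces the order-of-magnitude
  spread of measured tRNA abundances. Models are drawn independently.
- **Arrays** — sample-channel signal ∝ truth fraction × exp(N(0, σ_log));
  reference channel likewise from the reference tRNAome; spikes at one
  equal effective concentration in both channels; arbitrary per-replicate,
  per-channel scale factors so spike normalization is genuinely exercised.
  Defaults: σ_log = 0.1 (≈10% CV, a typical fluorescence replicate
  spread), 3 biological replicates, 24 technical replicates per probe,
  3 spikes. All generators are pure functions of their seeds.
- **Panel** — a synthetic human-like panel of 41 tRNA probes (+ spikes)
  built from standard wobble rules, covering all 61 sense codons, with an
  inosine-34 style multi-codon reader where no dedicated isoacceptor
  competes: Thr-AGU decodes ACU/ACC only, since ACG has its own
  isoacceptor; the Pro isoacceptors form a single ambiguity-grouped probe.
  It mirrors the *shape* of a real tDNA chip, not any published probe set.
- **Transcripts** — i.i.d. codon sampling from a weight table; the
  CFTR-like CDS (synthetic stand-in for the real transcript) has 1480
  codons drawn from human usage with the start codon and the three
  variant-site codons pinned (528 GAG, 854 ACU, 1290 CCA) so HGVS mapping
  lands on the documented residue numbers.
- **Variant scenarios** — codon-fraction tables engineered per effect
  class around a reference ratio R_ref = 4 (ALT ratios 16 / 4 / 2 / 1 /
  0.25, or an ambiguous variant codon), with jittered backgrounds. Margins
  to the class boundaries are at least one full tolerance factor; for the
  interior classes (`same`, `no_effect`) the band is only one tolerance
  wide on each side of its center, which bounds the achievable margin.

What the generator does **not** emulate: probe cross-hybridization,
dye-specific bias, spatial/block artifacts, correlated tRNAomes between
models, biological (as opposed to technical) replicate variability, and
realistic transcript codon autocorrelation. Passing tests therefore
demonstrate correctness of the computations under the stated noise model,
not robustness to these real-world effects.

## Problem sizes and tolerances

The test suite and acceptance script use the defaults above: 40-probe
generic panels or the 41-probe default panel, 1000 simulated arrays for
the spike-anchor check, 100 random instances for the profile-oracle check
(windows 2–30, sequences 30–120 codons), 20 seeds for noisy recovery and
the noise-degradation property, 50 seeds per variant class. Exact
identities are asserted to 1e-9 (sums, spike medians) or 1e-12 (oracle
agreement, mass conservation); statistical checks assert the documented
bounds (recovery median r ≥ 0.98 at σ_log = 0.1; replicate KS p ≥ 0.9).

## File formats

Tabular data are TSV: probe panel (probe_id, anticodons, amino_acid,
decoded_codons, ambiguity_group, is_spike), spot signals (model_id,
bio_replicate, probe_id, spot, sample_signal, reference_signal), ratios,
probe fractions, codon fractions (with ambiguity flags) and codon usage.
Coding sequences are FASTA (DNA or RNA; a trailing stop is trimmed; codon
keys are RNA uppercase internally). Profiles are TSV (center_codon,
value) with a JSON sidecar (window, band, slow/fast regions).

## Known limitations

- The ambiguity-group signal is not split among its isoacceptors — the
  array genuinely cannot resolve it, so no split is attempted and the
  affected codons carry a flag instead of a pretense of precision.
- Classification tolerance is a convention, not a fitted constant.
- The harmonic-mean window treats the ribosome footprint as a hard
  30-codon box; no positional weighting is applied.
- Occupancy ignores near-cognate competition and tRNA charging dynamics.
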