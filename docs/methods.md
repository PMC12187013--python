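# Methods

## Trace model and metrics

A trace is the nuclear enrichment of one fluorescent reporter in one cell,
sampled on an equispaced grid (default 21 frames every 5 minutes, 100
minutes total, matching the standard acquisition for pheromone-induction
movies; the stimulus is added just before the third frame). Nuclear
enrichment itself — nucleus minus cytoplasm fluorescence — is produced
upstream by image segmentation and is outside this package's scope.

Three per-trace metrics summarise induction:

* **basal** — arithmetic mean of the first 3 frames. The basal window may
  include the stimulus frame because the reporter response lags the
  stimulus by more than one frame interval.
* **EO (expression output)** — global maximum of the trace minus basal.
  The maximum is taken over the whole trace, basal frames included, which
  guarantees EO ≥ 0 whenever basal comes from the trace's own first
  frames.
* **RT (response time)** — time of the first frame whose value strictly
  exceeds `basal + 0.2·EO`. The comparison is strict (`>`, configurable)
  and no interpolation between frames is performed: RT lives on the
  acquisition grid. A trace that never crosses the threshold (in
  particular any flat trace, EO = 0) has no RT; the absence is an explicit
  `None`, never a sentinel value.

RT is scale-equivariant trivially (the threshold scales with the trace)
and shifts with the time axis; both properties are under test.

## Responder classification

Two independent criteria define an expressing cell:

1. **Sign test** — the last 5 frames minus basal must be significantly
   positive: one-sided exact sign test, exact ties dropped, among the *m*
   non-ties with *k* positive the p-value is `P(Bin(m, ½) ≥ k)`
   (scipy's exact binomial test), significant when p < 0.05. With the
   5-frame window the only significant tie-free outcome is 5/5 positives
   (p = 0.03125); an all-tied window is not significant with p = 1 by
   convention. The test is one-sided because only induction (not
   repression) is being called; the exact test is used because the window
   is far too small for a normal approximation.
2. **Expression threshold** — EO must strictly exceed 20 % of the mean EO
   of a designated reference strain, where the mean runs over *all*
   reference cells, responders and non-responders alike. Expressing cells
   with EO strictly above 50 % of the reference mean are *strong*, the
   rest *weak*. Both boundaries are strict ("exceeds"), configurable.

Cells satisfying only one criterion are non-expressing. No multiple-testing
correction is applied across cells, matching standard practice for this
assay.

**Known limitation.** The sign test treats basal as a known constant, but
basal is estimated from 3 frames of the same noisy trace, so its error is
correlated with the tested tail. For a flat trace with i.i.d. Gaussian
noise the probability of a spurious 5/5 pattern is
`E[(1 − Φ(Z/√3))⁵] ≈ 0.091` rather than the nominal `2⁻⁵ ≈ 0.031`,
independent of the noise scale. Together with the EO filter this biases
the classified responding fraction upward by roughly +0.03 at a
noise-to-amplitude ratio of 10 %. This is a property of the published
procedure itself, faithfully reproduced here; the recovery tests therefore
check the fraction averaged over cohort draws rather than per draw.

## Population statistics

* **Median dynamics** — per-timepoint median with 25th/75th percentile
  band; percentiles use linear interpolation between order statistics
  (numpy default), so three constant traces at 0/1/2 give the band
  [0.5, 1.5]. The convention is stated because band widths differ across
  percentile definitions.
* **ΔRT** — `RT(red test) − RT(yellow reference)` per cell, computed only
  in cells called expressing in both channels with both RTs defined. The
  shared (cell-cycle-driven) component of the onset cancels in the
  difference, which is what makes ΔRT a per-cell kinetic readout.
* **Between-strain tests** — two-sided Welch t-tests on replicate-level
  means (pooled-variance optional): expression output (flag **O**), timing
  via replicate-mean ΔRT (flag **T**), responding fraction (flag **F**),
  each flagged at p < 0.05. The timing flag uses mean ΔRT because that is
  the quantity the per-strain summaries encode; a mean-RT alternative is a
  one-line change in the summary column. ΔRT distributions are compared
  with the Wilcoxon rank-sum test (Mann-Whitney U, exact null for small
  tie-free samples, so 1-vs-1 can never be significant). With fewer than
  two replicates no test runs and no flag is set.
* **Channel correlation** — Spearman rank correlation between the two
  channels across cells at fixed time points (default 0/20/40/60 min).

Replicate exclusion is available only as an explicit user-supplied list —
there is no automated quality criterion to base it on.

## Synthetic cohorts

The generator emulates dual-reporter induction movies:

```
trace(t) = basal_c + R_c · A_c · f((t − τ_c,ch)/ρ) + ε(t)
f(x) = 1 − exp(−x)  for x > 0, else 0
```

with `R_c ~ Bernoulli(p)` the ground-truth responder flag,
`A_c` log-normal (mean `amplitude_mean`, CV `amplitude_cv`),
`τ_c,ch = stimulus_time + d_c + δ·[ch = red] + jitter_ch`,
`d_c ~ N(0, delay_shared_sd²)` shared between the two channels of a cell
(the cell-cycle component of pheromone-response timing),
`δ` the programmed test-vs-reference delay that ΔRT should recover, and
`ε i.i.d. N(0, σ²)`. The saturating-ramp shape was chosen because measured
nuclear-enrichment curves are monotone and saturating and two parameters
(onset, rise time) suffice; no mechanistic promoter-state model is
implied. Identical config + seed gives bit-identical cohorts.

Defaults (the magnitudes of real traces are not published, so these are
chosen as plausible for the assay, not fitted): basal 1.0 ± 0.1 a.u.,
amplitude 5.0 a.u. with CV 0.3 (log-normal, matching the broad single-cell
EO distributions such reporters show), shared delay sd 5 min, channel
jitter sd 1 min, rise time 15 min, noise sd 0.1 a.u., responder fraction
0.6. What the generator does **not** emulate: fluorophore maturation,
photobleaching, segmentation errors, basal drift (available behind a flag,
default off), cell division during the movie. Passing recovery tests
therefore validate the pipeline's logic, not its behaviour on every real
imaging artefact.

Synthetic promoters draw background bases from a configurable GC content
and plant the requested elements verbatim (PRE dimers in any of the four
orientations, single sites, PRE-like variants, 20-bp poly-dA/dT tracts,
nucleosome dyad annotations). Backgrounds are rejection-sampled: any
window outside the planted motifs matching a consensus or affinity-table
hexamer on either strand — including windows spanning dimer gaps and
element junctions — and any accidental ≥ 20-bp A/T run is rejected and
the background redrawn. This makes "every motif found was planted" a
generator guarantee that the round-trip tests rely on. The guarantee is
deliberately stronger than consensus-only rejection so it holds when
scanning with PRE-like tables enabled.

## Promoter grammar

* **Coordinates** — offsets are negative, from the 3' end of the supplied
  sequence (the end abutting the core promoter in the usual layout). Any
  cloning offset between the sequence end and the true start codon is the
  caller's responsibility to add.
* **Scanning** — exact hexamer lookup on both strands against an affinity
  table (consensus TGAAAC = 1.0, TaAAAC = 0.8, TGAgAC = TcAAAC = 0.05).
  Unlisted single-mismatch variants default to weight 0 — identifying
  functional PRE-like sites from sequence alone is unreliable, so the
  table is explicit and user-extensible rather than a mismatch heuristic.
* **Dimer calling** — every pair of sites with 0–40 bp strictly between
  the hexamers is reported; overlapping pairings are all kept (endogenous
  promoters carry overlapping site clusters and each geometric pairing is
  a candidate dimer). Orientation draws each motif as a 5'→3' arrow with
  the head at the arrowhead: diverging = tail-to-tail, converging =
  head-to-head, parallel = head-to-tail with the sub-type set by the arrow
  direction relative to the core promoter. The head/tail convention is
  invertible by flag since the literature uses both.
* **Conformation rule** — an exact spacing set, not helical arithmetic:
  TT functional at {3, 13, 23} bp (23 → low and slow), HH and both HT
  sub-types at {5, 15} bp (15 → reduced), everything else non-functional.
  The 10.5 bp/turn helical repeat is stored as the rationale constant (the
  increments restore the rotational phasing of the two bound monomers),
  but the validated larger TT spacing is 23 = 3 + 2×10, not
  round(3 + 2×10.5), so the exact set is authoritative; an optional ±1 bp
  tolerance flag exists for exploratory scans.
* **Chromatin** — nucleosome footprints are dyad ± 73 bp (canonical
  147 bp). A dimer is *covered* when its span reaches a footprint interior
  more than 30 bp (configurable margin) from both edges, *boundary* when
  it only grazes within the margin of an edge, *NDR* otherwise. Poly-dA/dT
  tracts are maximal pure-A or pure-T runs of ≥ 20 bp.
* **Induction prediction** — a qualitative rule cascade: non-functional
  conformation → no induction; covered → low/slow/stochastic unless a
  ≥ 20-bp poly-dA/dT tract lies within 6 bp of the dimer or ≥ 3 PRE sites
  cluster (nucleosome eviction is then favoured and behaviour becomes
  boundary-like); boundary → slow with level preserved; NDR → fast. The
  level is then downgraded one step (high → reduced → low) per: PRE-like
  member, large-gap conformation (TT-23 / HT-15 / HH-15), or dimer more
  than 350 bp from the core promoter. The cascade predicts classes only —
  no thermodynamic occupancy and no quantitative EO.

## Problem sizes and numerical choices

The statistical validation suites run at sizes chosen to make their
sampling distributions tight: recovery uses 20 cohorts of 1000 cells at a
noise-to-amplitude ratio of 10 %, null calibration uses 100 seed pairs of
3-replicate, 100-cell cohorts (observed false-flag rates 2–3 % against the
nominal 5 %), and the promoter round trip uses 100 random specs spanning
all four orientations and gaps 0–40. Percentile and t-test conventions are
fixed as above; degenerate inputs (empty cohorts, all-tie sign-test
windows, empty ΔRT distributions, promoters without nucleosomes) have
documented, tested behaviour rather than errors wherever a neutral answer
exists.
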