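# Methods

## The growth/division model

Single-cell area (μm², a proxy for cell size) follows a logistic curve
multiplied by a linear term:

```
A(t) = A0 · Amax · e^{rt} / (Amax + A0(e^{rt} − 1)) · (1 + (m/Amax)·t)
```

The curve is exponential (~e^{rt}) for small t and converges to a
straight line of slope `m` for large t; `A0` is the size at t = 0 and
`Amax` sets where growth crosses over from exponential to linear.
Defaults are `A0 = 20 μm²`, `Amax = 120 μm²`, and a reference
unperturbed cycle length `T = 100 min`.  The rate `r` is calibrated so
that an unperturbed cell starting at `A0` exactly doubles in one cycle
(with m = 0):

```
r = [ln(2(Amax − A0)) − ln(Amax − 2A0)] / T ≈ 0.0092 min⁻¹
```

This requires `Amax > 2·A0`; the doubling identity `A(T) = 2A0` holds
exactly at the calibration point and only there — the logistic part
grows sub-exponentially above `A0`, which is the mechanism that
stabilises sizes under long cycles.

Cycle lengths are phenomenological: unperturbed cells draw from
Normal(100, 10) min (negative draws, ~1e-23 probability, are rejected
and resampled so the stated moments are preserved); cells under chronic
spindle-assembly-checkpoint (SAC) activation draw from
200 min + Exponential(mean 200 min) — a minimum arrest plus a
memoryless slippage time (mean 400 min, CV 0.5).  Division halves the
area instantaneously and the cell jumps back to the curve position of
its new size.  At a division, the duration of the *next* cycle is drawn
from the regime active at that instant, so a regime switch at t = 0
affects the first duration drawn after t = 0.

**The slope `m` is a free parameter.**  The asymptotic linear slope is
not constrained by the doubling calibration; the default
`m = 0.3 μm²·min⁻¹` gives SAC-active cells a stable steady entry-size
distribution roughly eight-fold above `A0` (median ≈ 160 μm², CV ≈ 0.19)
— a large but bounded steady orbit.  Any analysis sensitive to the
absolute steady size should treat `m` as the knob that sets it.  With
`m = 0` the curve saturates at `Amax` and post-division sizes can
fractionally undershoot `A0` (the restart is then clamped to the curve
origin with a warning); with the default `m` this cannot occur.

Two in-silico experiments build on the lineage machinery:

- *SAC onset*: switch the duration distribution from unperturbed to
  SAC-active at t = 0.  Entry sizes rise to the steady orbit within a
  few cycles; cycle-time variability (CV 0.5) stays far above
  entry-size variability (CV ≈ 0.19).  Under pure exponential growth at
  rate `r` with the same duration draws, the log entry size performs a
  random walk with increment variance `r²·Var(T)` per cycle and
  diverges; the raw-variance ratio between cycles 30 and 10 is
  astronomically large, versus ≈ 1 for the combined curve.
- *Withdrawal*: after equilibrating in the SAC regime, switch back to
  unperturbed draws.  Entry-size medians decay monotonically toward the
  unperturbed steady state over about five cycles (each division
  roughly halves the excess), measured both directly and as a growing
  density overlap with the unperturbed entry-size distribution.

Problem sizes used throughout (tests, acceptance checks, analysis
scripts): 200–500 lineages and 15–30 cycles, which puts median/variance
estimates well inside the asserted tolerances.

## Trajectory filtering and smoothing

Extracted area series occasionally carry isolated spikes (segmentation
errors, altered phase contrast).  The filter operates on local
variations ΔA_i = A_{i+1} − A_i:

1. Pool (A_i, ΔA_i) pairs across a condition group and split them into
   three size clusters: A ≤ 40, 40 < A ≤ 80, 80 < A ≤ 120 μm².
2. Per cluster, fit Tukey fences `Q1 − 1.5·IQR` and `Q3 + 1.5·IQR` on
   the ΔA distribution.  Quartiles use linear interpolation (numpy
   default, type-7); the fences depend on this convention.  Clusters
   with fewer than four pairs stay unset, and pairs above 120 μm² fall
   outside all clusters — points there are never flagged
   (conservative).
3. Sweep each trajectory left to right: an interior point is replaced
   by the mean of its two neighbours when its variations violate the
   fences; endpoints are never replaced.  Sweeps repeat until nothing
   changes, at most 10 times.  Thresholds are fitted once and not
   refitted between sweeps.

**Which variations flag a point** was a genuinely open choice, since a
spike at position i perturbs both ΔA_{i−1} (into it) and ΔA_i (out of
it).  The default requires *both* sides to violate (`flag_mode="both"`):
that is the signature of an isolated spike, it repairs a single spike in
one sweep without touching its clean neighbours, and on the synthetic
recovery benchmark it detects ≥ 95% of injected spikes with < 1% false
flags.  One-sided rules are available (`"either"`, `"forward"`) but the
either-side rule necessarily replaces the two clean neighbours of every
spike as well, which inflates the false-flag rate and slows
convergence.  Adjacent double spikes are resolved over several sweeps
to within a few μm² of the clean level rather than exactly — acceptable
because genuinely adjacent corrupted frames are rare, and the generator
injects isolated spikes for the same reason.

Adjusted trajectories are smoothed with a centered moving average —
window 3 for unperturbed conditions, 8 for SAC-active ones (whose
trajectories are several-fold longer).  Even windows take the extra
point on the trailing side; at the edges the window shrinks to the
available points.  The local growth rate dA/dt is the central finite
difference of the smoothed series (one-sided at the ends, actual time
gaps used).  Derived quantities are binned in half-open windows
([k·w, (k+1)·w), 10 μm² for size, 70 or 100 a.u. for Clb2 levels), and
population mean trajectories — aligned on each cell's own start — keep
only timepoints with strictly more than five contributing cells.
Pixel counts convert to area at 0.05 μm²/px.

## Cycle statistics

- Mitotic length = anaphase onset − mitotic entry (Clb2 fall − Clb2
  rise); cell-cycle length = time between consecutive buddings.
  Censored cycles (death, end of imaging) keep whatever durations are
  observed and carry a flag.
- Fold increases of the SAC-active over the unperturbed condition use
  medians: `FOLD_mitosis = m_mit^SAC/m_mit^unp`,
  `FOLD_notmitosis = (m_cc^SAC − m_mit^SAC)/(m_cc^unp − m_mit^unp)`.
- Size control in mitosis: `G_mitosis = ln(A_ANA/A_PM)` regressed on
  `ln(A_PM)` by OLS; slope λ = 0 for a timer, −1 for a perfect sizer,
  with the slope p-value at α = 0.05.
- Normality gate: a sample is "normal" when at least 3 of 4 tests
  (Lilliefors, Anderson–Darling, Jarque–Bera, one-sample KS against a
  normal with sample-estimated moments) give p > α.  Pearson vs
  Spearman, and Welch's t vs Mann–Whitney, follow this gate.  The plain
  KS test with estimated parameters is anti-conservative, which only
  makes the gate stricter about calling normality.
- Duration comparisons between populations use the log-rank test
  (lifelines) so censored cycles contribute.
- Distribution overlap: Gaussian KDEs (Scott's rule) of both samples on
  a shared 512-point grid spanning the union of supports padded by
  three bandwidths; `O = ∫ min(f, g) dv` by trapezoidal quadrature,
  clipped to [0, 1].  O depends mildly (±0.02) on the bandwidth rule,
  which is why tests allow that slack around closed-form values.

## Aneuploidy estimator

One labelled chromosome (ChrV) is scored: R = n_mis/n_total.  Assuming
all 16 chromosomes mis-segregate equally (a deliberate first
approximation), `P(at least one aneuploid chromosome) = 1 − (1−R)^16`.
Replicates are aggregated by averaging per-replicate P values (each
replicate is its own estimate); pooling the counts first is exposed as
an alternative and differs by ~3 points at the rates involved.  For
R ≤ 0.005 the linearisation P ≈ 16R is accurate to 10%.

## SRI and clustering preparation

For log2 fold changes x_i over ESR-induced genes and y_j over
ESR-repressed genes,

```
SRI = [Σ x_i + Σ(−y_j)] / [Σ|x_i| + Σ|y_j|] ∈ [−1, 1]
```

+1 iff every induced gene is up and every repressed gene is down, −1
for the exact reversal; unrelated genes are ignored, and the statistic
is invariant to rescaling all fold changes by a positive factor.  The
package does not embed the published ESR gene lists — any user-supplied
induced/repressed annotation works, and the synthetic generator
(induced ~ N(+s, σ), repressed ~ N(−s, σ), unrelated ~ N(0, σ))
provides ground-truth fixtures.  For clustering, samples are
z-normalized (mean 0, sample SD 1) and compared with the correlation
distance d = 1 − Spearman ρ ∈ [0, 2] under complete linkage.  Null
profiles are uncorrelated with everything (d ≈ 1) and therefore attach
to dendrograms arbitrarily; conclusions should rest on the distances,
not on a forced flat cut.

## What the synthetic data does and does not emulate

The generators reproduce: growth along the stated curve; the two cycle
regimes; isolated additive spikes and multiplicative measurement noise
on trajectories; censoring; binomial mis-segregation counts;
ESR-structured fold-change vectors.  They do not emulate: correlated or
multi-frame segmentation failures, mother/daughter asymmetric division,
fluorescence-channel artefacts, per-chromosome heterogeneous
mis-segregation rates, or gene-gene correlation structure in the
proteome.  Passing recovery tests therefore shows the pipeline is
correct under its stated noise model, not that it is robust to every
failure mode of real imaging or proteomics data.

Within the cycle-record generator, unperturbed cycles spend a fixed
fraction (0.3) of the cycle in mitosis, while SAC-active cycles draw an
*independent* non-mitotic time (Normal(70, 10) min) and spend the rest
of the drawn cycle arrested in mitosis.  The independence matters: the
checkpoint arrest does not know how long interphase took, and tying
mitotic length to a fixed fraction of the cycle would inject the cycle
length into both axes of the size-growth plot and cancel the 1/A_PM
size-control signal exactly (measured λ ≈ 0 under the coupled variant,
λ ≈ −0.6 with p < 0.001 at n = 50 under the independent one).  80% of
the non-mitotic time precedes mitotic entry, the rest follows anaphase.

## Known limitations

- `m` is unconstrained by data shipped with the package; absolute
  steady-state sizes in the SAC regime scale with it.
- The filter never flags points above 120 μm², so spikes landing there
  survive; the clusters would need extending for very large cells.
- Fences are fitted on the corrupted data themselves; at spike rates
  far above a few percent the quartiles drift and detection degrades.
- The aneuploidy estimator inherits the equal-rates assumption; it is
  reported as the estimate of that model, not of the karyotype
  distribution.
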