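# Methods

`gcnet` infers directed ("Granger-causal") interaction networks from
multichannel time series and probes whether the *important* nodes of the
underlying system — the strongest senders — were even observed.  This note
records the models, the estimators, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Model and estimation

All inference is built on the vector autoregression of order `p`,

    X(t) = Σ_{r=1..p} A(r) X(t−r) + ε(t),    ε(t) ~ N(0, Σ),

with `A(r)[i, j]` the effect of channel `j` at lag `r` on channel `i`.
Stationarity is certified by the spectral radius of the companion matrix
being below 1; simulation refuses non-stationary models outright.

Coefficients are estimated by least squares written through the
lag-covariance normal equations: `Rp` collects the blocks
`(1/(T−p)) Σ_t X(t−h)X(t−ν)ᵀ` for `h, ν = 1..p`, `rp` the corresponding
lag-0 cross blocks, and `Âstack = rp Rp⁻¹`.  On any finite panel this equals
an ordinary least-squares regression of `X(t)` on the stacked lagged
regressors (the suite asserts agreement to 1e−8, and against `statsmodels`'
VAR with no trend).  No intercept is fitted — the data are assumed
zero-mean; a mean-centering toggle (`RunConfig.center`) is available for
real data.  The residual covariance divides the residual outer-product sum
by `T` by default, with `T−p` (the number of terms) selectable via
`sigma_divisor`; at the panel lengths used here the difference is
negligible, and the default follows the customary plug-in convention.

Order selection (`select_order`) minimizes AIC or BIC over `1..p_max`, or
returns a fixed configured order.  The pipelines default to a fixed `p = 2`,
the generating order of the benchmark; for real data BIC is the sensible
policy.  Note that a *sub*-system of a VAR is generally a VARMA process, so
no finite order is exactly right after channels are dropped — a fitted
VAR(2) captures the leading induced structure, which is precisely what the
sub-network analysis interrogates.

## Directed partial correlation (DPC)

Raw coefficients carry units, so their sizes cannot be compared across
pairs.  DPC rescales them into a correlation-like strength,

    π̂_ij(h) = Â_ij(h) / sqrt(Σ̂_ii · ρ̂_jj(h)),
    ρ̂_jj(h) = K̂_jj + Σ_{ν<h} Σ_{k,l} Â_kj(ν) K̂_kl Â_lj(ν) + Â_ij(h)²/Σ̂_ii,

with `K̂ = Σ̂⁻¹`.  The division-by-square-root form is the only reading of
the rescaling that is unitless and bounded like a correlation (every term of
`ρ̂` carries units of 1/var(X_j)); the suite checks `|π̂| ≤ 1 + 0.05` on
well-conditioned fits and a closed form on the bivariate single-edge model
(`π = c/√(1+c²)`).  Only positive lags are stored; the negative-lag
convention `π_ij(h) = π_ij(−h)` adds nothing.

**Significance** uses a percentile bootstrap over AAFT surrogates
(amplitude-adjusted Fourier transform).  Each surrogate channel (a) is
rank-remapped onto a Gaussian sample, (b) has its Fourier phases rotated by
independent uniform angles, (c) is rank-remapped back onto the original
amplitudes, and is then refined by alternately re-imposing the original
amplitude spectrum and the original value multiset until the relative
spectral mismatch improves by less than 1e−4 (or 100 rounds).  The final
step is always the amplitude remap, so every surrogate channel is an exact
permutation of the original values.  Phases are randomized *independently
per channel*: the surrogate keeps each channel's marginal distribution and
(approximately) its spectrum while destroying all cross-channel coupling,
which is exactly the no-causality null needed here.  Constant channels are
rejected (ranks are undefined up to ties; ties otherwise break by first
occurrence).

From `B` surrogates (default 10000; the harnesses use a few hundred, see
below) the interval per (target, source, lag) cell is
`[τ̂*(⌊αB⌋), τ̂*(⌊(1−α)B⌋)]` of the ascending surrogate values — e.g. the
500th and 9500th of 10000 at α = 0.05.  An edge is declared when its DPC
falls outside the interval at one or more lags, with no correction across
lags or pairs (a Bonferroni toggle exists, off by default).  **Caveat
(measured, deliberate):** an interval with α and 1−α percentile endpoints
covers 1 − 2α, so the outside-the-interval test at α = 0.05 has a true
per-cell level near 0.10 and a per-edge level (either of 2 lags) near
1 − 0.9² ≈ 0.19; the zero-coupling harness reports the per-edge rate it
actually measures (about 0.18).  The
interval convention is kept as the method's defining recipe; analysts who
want a strict 5% test should call the bootstrap with α = 0.025 per tail
and one lag, or enable the Bonferroni toggle.  One surrogate set is drawn
per panel and shared by all edges.

## Renormalized partial directed coherence (rPDC)

The Fourier transform of the coefficient stack,
`A(ω) = I − Σ_r Â(r) e^{−iωr}`, has off-diagonal entry `A_kj(ω)` identically
zero exactly when `j` does not directly drive `k`.  rPDC tests the 2-vector
`Z_kj(ω) = (Re A_kj(ω), Im A_kj(ω))` against its estimator covariance

    V_kj(ω) = Σ_{l,m} [Rp⁻¹]_{(l−1)n+j,(m−1)n+j} · Σ̂_kk · c_l c_mᵀ,
    c_l = (cos lω, −sin lω),

via `λ̂_kj(ω) = Ẑᵀ V⁻¹ Ẑ`; under the null `N·λ̂` is asymptotically χ² with
2 degrees of freedom (`N = T − p`, the points entering the fit), giving the
pointwise critical value `χ²_{2,1−α}/N`.

Two numerical points matter:

* **Sign of the sine terms.**  `c_l` must be the (Re, Im) pair of
  `e^{−ilω}`, i.e. `(cos lω, −sin lω)`.  Writing both cross terms with a
  positive sine — as the covariance is often typeset — silently pairs `Z`
  with the covariance of the opposite Fourier convention: the χ² calibration
  collapses and, at `p = 1`, the statistic acquires a spurious zero at
  ω = π/4 where `Z` leaves the covariance's column space.  With the
  consistent orientation the null 95th percentile of `N·λ̂` lands inside
  the finite-sample Monte-Carlo band [5.0, 7.2] the suite checks around
  the χ²₂ quantile 5.99 (slight upward inflation at short T is expected).
* **Rank.**  `V` has rank `min(2, p)`; at `p = 1` it is a rank-one outer
  product.  It is inverted by Moore–Penrose pseudo-inverse and the degrees
  of freedom of the critical value drop to the rank.

The default decision rule declares an edge only when `λ̂` clears the
critical value at *every* grid frequency (64 equally spaced ω in the open
interval (0, π) by default).  With `p = 2` the whole frequency profile is
driven by just two estimated coefficients, so the rule is only mildly
conservative: its per-pair false-positive rate at zero coupling, measured
by the calibration harness, sits essentially at the pointwise level
(≈ 0.05).  `any_frequency` and
`fraction`-of-frequencies rules are provided.  No correction is applied
across edges.

## Hub importance, sub-network scan, hidden-hub evidence

Node importance is out-degree: the count of links a node sends; the
*important nodes* of a graph are those attaining the maximum (an edgeless
graph has none).  The scan infers a network on all observed channels,
removes the important nodes (ties removed together), refits from scratch on
the survivors, and repeats — by default for at most 3 removal steps and
never below 3 channels, since both measures partial out "all other
processes" and partialization degenerates with 2 channels.

The marginal process of a sub-system hides its dropped drivers in
correlated, serially structured innovations; Granger methods then read
*induced* links between commonly driven survivors, in both directions.  A
reciprocal pair (2-cycle, "feedback structure") appearing after hub removal
in a system believed feed-forward is therefore treated as evidence of an
unobserved important component.  The evidence record flags any step with a
feedback pair, reports the union of participating nodes and — when several
steps show feedback — their intersection (the nodes a hidden hub would have
driven at every stage), plus the nodes whose out-degree grew between steps.
No single aggregated score is produced; feedback and out-link-gain evidence
are reported side by side.

## The synthetic benchmark

Six channels, VAR(2).  True edges (source → target):
2→1, 1→3, 1→5, 1→6, 2→4, 2→5, 3→4 — nodes 1 and 2 are the hubs with
out-degree 3.  Every node has self-dependence 0.5 at lag 1 and −0.1 at
lag 2 (complex AR roots, modulus √0.1 ≈ 0.316, giving each channel a
spectral peak so the frequency-domain measure has structure to resolve);
innovations are unit white noise; cross-edges carry a common lag-1
coupling `c`.  Because the cross-coupling graph is acyclic the companion
spectral radius equals the self-dynamics' 0.316 *for every* `c` —
stationarity never binds — but downstream variances grow with `c`.

**Default coupling `c = 0.6`.**  The phenomena the benchmark exists to
exhibit — induced links and feedback pairs among the survivors after hub
removal — are second- and third-order in the coupling (products of two or
three edge coefficients).  At weak coupling (c ≈ 0.3) they fall below any
reasonable detection threshold at T = 2000 and the scan sees nothing; the
default was therefore set to the smallest value at which the feedback
signatures after hub removal are robust across seeds — the harness
measures the {3,4} rate with hubs 1–2 hidden and the {4,5} rate with
1–2–3 hidden, both near 1 at c = 0.6.  `BenchmarkSpec` overrides every
constant.

Default panel length T = 2000 with a 500-sample burn-in from zero initial
state; all randomness flows from explicit seeds through named substreams,
so every simulation, surrogate set, and harness replicate is reproducible.

**What the benchmark does not emulate.**  Real recordings have
measurement noise, nonstationarity, unequal per-edge couplings, possibly
mixed lags and non-Gaussian innovations; the benchmark has none of these.
Passing tests show the estimators and decision rules behave as designed
under the model's own assumptions — not that the hidden-hub heuristic is
reliable on arbitrary real data.  Two concrete consequences of the uniform
coupling are worth knowing:

* With hub 1 hidden, the induced links 2→3 and 2→6 are statistically
  exchangeable (both are the lag-2 product of the 2→1 and 1→x
  coefficients), so the five-node sub-network is typically denser than a
  system with heterogeneous couplings would give — node 2 usually shows
  out-degree 4, and the children of node 1 ({3,5,6}) link up among
  themselves.  Sparser reconstructions require unequal couplings.
* The induced 4→5 link after hiding node 1 depends on node 2 driving 4
  and 5 *unequally*; with uniform couplings it rarely appears.

## Scenario and harness defaults

`run_scenario` simulates the full system, drops the scenario's channels
(`omit1`, `omit2`, `omit12`, `omit123`), and infers once with the chosen
method.  `power_curve` sweeps the coupling grid 0..0.5 in steps of 0.05
(every grid point stationary), simulating `R` independent realizations per
point and reporting each ordered pair's detection fraction; absent pairs'
fractions are the coverage (false-positive) analysis, from the same runs.

Monte-Carlo problem sizes are chosen so the full suite runs on a single
CPU at desk scale: rPDC power curves use R = 100 at T = 2000 over the full
11-point grid; DPC harness runs use B = 100 surrogates with the iterative
spectral refinement capped at 20 rounds (rather than the 10000 surrogates
and 100 rounds of a one-off analysis), R = 25 replicates, and the coarser
grid {0, 0.15, 0.3, 0.5}; null calibration uses 200 realizations per
method (T = 500 on the DPC side, where only the test's level — a property
of the interval, not of the series length — is at stake).  B = 10000 and
100 refinement rounds remain the defaults for a single DPC analysis.

## Known limitations

* The percentile-interval convention makes the DPC test anti-conservative
  by construction (see above); method comparisons inherit this: the DPC
  scan flags hidden-hub evidence at least as often as the conservative
  all-frequency rPDC scan on this benchmark, by liberality rather than
  sensitivity.
* The all-frequency rPDC rule's false-positive rate is essentially the
  pointwise level when `p` is small (the frequency profile has only `p`
  underlying degrees of freedom per pair), so exact graph recovery on 30
  ordered pairs is rare even when every true edge is found; readers should
  judge edge sets per edge, not per graph.
* Sub-network fits use a finite VAR order on what is truly a VARMA
  marginal; very long-memory induced structure can be missed at `p = 2`.
* The hidden-hub heuristic detects *common drivers*; a hidden chain node
  that merely relays influence produces induced links but no feedback pair.
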