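# Methods

## Scope and structure

`oxyvasc` is a hybrid multiscale model of an engineered tissue implant
during its first post-implantation week. A continuum layer (five scalar
fields on a square lattice) carries oxygen, VEGF, progenitor cells,
fibroblasts and fibrous matrix; a discrete layer carries individual
endothelial cells with intracellular Dll4–Notch state, organized into
sprouts that grow, branch and anastomose. Oxygen-generating beads couple
into the oxygen field as point sources with a shared release law. The
model is nondimensional by design: it is built to reproduce qualitative,
ordering-level contrasts between implant conditions, not calibrated
dissolved-oxygen time series.

## Unit conventions

* **Oxygen**: nondimensional, 1.0 ≡ 21% dissolved oxygen (atmospheric
  normoxia). The implant initializes at 3.7% (0.176), the anoxia and
  hypoxia classification bounds are 0.5% (0.0238) and 5% (0.238). Under
  this convention the release law's half-saturation `H_n = 0.11`
  corresponds to ≈2.3% dissolved oxygen — between the anoxia and hypoxia
  bounds, so bead release self-limits inside the hypoxic band.
* **Time**: one nondimensional unit = one day. Then `τ = 0.05`/day gives
  the sustained particles a release half-life of ≈13.9 days (a ~2-week
  release) and `τ = 0.5`/day gives the burst particles ≈1.4 days.
* **Space**: lattice spacing `dx` in mm; the default 100×100 grid at
  `dx = 0.04` mm represents a 4 mm implant cross-section. Diffusivities
  are in mm²/day.

## Bead release

```
rate(c, t) = G_n · H_n^h / (c^h + H_n^h) · exp(−τ t),   G_n = 2.2, H_n = 0.11, h = 6
```

The rate is bounded by `G_n exp(−τt)`, strictly decreasing in time and
non-increasing in local oxygen. At zero oxygen the cumulative release
has the closed form `(G_n/τ)(1 − exp(−τt))`, so the sustained (HOG)
particles deliver `τ_CPO/τ_HOG = 10×` the total oxygen of the burst
(CPO) particles at the same loading. Beads occupy single lattice sites,
are placed uniformly at random without replacement (the placement seed
is the only stochastic element in a scenario), and carry no depletion
state beyond the `exp(−τt)` clock started at implantation.

`fit_release_params` recovers `(G_n, τ)` from a sampled release curve by
bounded least squares with a deterministic initialization (G from the
curve maximum, τ from the end-to-end log slope). At zero oxygen the Hill
gate is identically 1, so `H_n` is structurally unidentifiable there and
the three-parameter fit refuses a zero-oxygen curve.

## Continuum tissue layer

With `c` oxygen, `g` VEGF, `m` progenitors, `f` fibroblasts, `mf`
matrix, `ρ(c) = c/(c + K)`:

```
∂c/∂t  = D_c ∇²c − k (m+f) c/(c+K) + Σ_beads rate(c,t) δ_site + w (c_vessel − c) δ_perfused
∂g/∂t  = D_g ∇²g + p (m + 10 f) φ(c) − λ g − u_ec g δ_EC
∂m/∂t  = D_m ∇²m + r ρ(c) m (1 − (m+f)/cap) − d_anx [c < c_anoxia] m     (f analogous)
∂mf/∂t = r_mx (m+f)(1 − mf)
```

`φ(c) = 1 + (φ_max − 1) K_φ^q/(c^q + K_φ^q)` is the hypoxic
amplification of VEGF output: production rises monotonically as oxygen
falls (φ_max = 10 at anoxia, →1 under normoxia), encoding the inverse
correlation between oxygen tension and VEGF secretion. Fibroblasts
produce VEGF at 10× the progenitor rate.

Discretization is explicit Euler with a 5-point Laplacian written in
flux form, so with reactions off the discrete total of every field is
conserved to roundoff and zero-flux boundaries are exact.
`validate_config` enforces `dt ≤ dx²/(4 max D)`; negatives produced by
the explicit step are clipped to zero, and any non-finite value aborts
with a stability error naming `dt`.

**Boundary conditions.** Oxygen edges are clamped to the host level
throughout; progenitor and fibroblast edges are held at 0.01 for the
first 3 days (host cell infiltration) and zero-flux afterwards; VEGF is
always zero-flux. The host boundary oxygen is set to 6% (capillary-like,
`c_host = 6/21`) rather than the implant's initial 3.7%: host tissue
adjacent to the implant is perfused, and — mechanistically important —
a hypoxic rim would itself be maximally VEGF-amplified, putting the VEGF
maximum in a thin boundary band and stalling sprouts along the rim
instead of drawing them inward.

## Endothelial agents

Eight species per cell: VEGFR-2 `V`, active VEGFR-2 `Va`, effective
active VEGFR-2 `Ve`, Notch1 `N`, active Notch1 `Na`, effective active
Notch1 `Ne`, Dll4 `D4`, actin `A`. Per explicit step (synchronous over
the network, neighbor states read at pre-step values):

```
V'  : logistic resupply β_V V(1−V) − activation drive
Va' : drive − δ_Va Va,          drive = k_act · VEGF · μ(c) · V
Ve  = Va / (1 + (k_inh Ne)²)                 (algebraic)
D4' : β_D Ve − δ_D D4
Na' : k_N ⟨neighbor D4⟩ N − δ_Na Na          (N resupplied logistically)
Ne' : fast rise toward Na (80/day), slow release (8/day)
A'  : relaxes toward Ve (40/day)
```

Three deliberate choices here, each forced by analysis or observed
failure modes:

1. **Cooperative inhibition (exponent 2).** With linear attenuation
   `Ve = Va/(1 + k Ne)` the two-cell fixed-point map is `x = M/(1+kx)`,
   whose homogeneous solution is *always* stable (the instability
   condition reduces to `x* < 0`), so lateral inhibition can never break
   symmetry. With exponent 2 the homogeneous state destabilizes once
   `k_inh Ne* > 1`; the defaults put `k_inh Ne* ≈ 2–3`. A ±10⁻³
   VEGFR-2 perturbation between two cells resolves to a single
   threshold-crossing winner in ≈1.6 days; a uniform row relaxes to the
   alternating (salt-and-pepper) tip pattern.
2. **Asymmetric effective-Notch tracking.** `Ne` rises at 80/day but
   releases at 8/day (persistent transcriptional repression). Stalk
   daughters are born Notch-activated (their `Na`, `Ne` equilibrated to
   the parent tip's Dll4, activity and actin reset): a daughter cloned
   from the winning tip state would compete symmetrically with its own
   tip and mutual inhibition would stall every sprout after one advance,
   while instantly released daughters re-enter tip competition within
   ~0.05 day and sprouts collapse into dense combs. The slow release
   spaces branch initiation roughly half a day (≈ 5–10 sites) behind the
   advancing tip.
3. **Metabolic gating, μ(c) = c²/(c² + c_anoxia²).** VEGFR-2 activation
   requires cellular energy; in anoxic tissue μ ≤ ½ and falls steeply,
   so sprouts stall at the anoxic frontier instead of migrating through
   dead tissue. This gate is what lets bead-oxygenated implants — and
   only those — be vascularized through their depth. When the agent
   update is not given an oxygen value (unit fixtures), cells are
   treated as metabolically unconstrained.

**Tip selection** promotes agents whose actin is ≥ `theta_tip` (0.15)
and strictly exceeds every lattice neighbor's (ties to the smaller
agent id), so two adjacent tips are impossible by construction. An agent
promoted while already carrying vessel segments starts a new sprout
(fresh sprout id) — branch initiation is a sprouting event — which keeps
every sprout to at most one tip.

**Growth and anastomosis.** Every `growth_interval = 0.05` days
(≈ 0.8 mm/day of potential advance, ~33 µm/h tip migration) each tip
moves to its unoccupied 4-neighbor site of maximal VEGF (ties resolved
in N, E, S, W order, making runs bit-for-bit reproducible), leaving a
stalk daughter and a connecting segment. A tip arriving adjacent to a
vessel tree it is not yet connected to (union–find over segments) fuses
with it and retires — anastomosis joins distinct trees; mere contact
with the tip's own tree adds nothing. Segments on shortest paths between
two distinct boundary roots are flagged perfused; perfused sites relax
oxygen toward `c_vessel = 6/21` at 1/day. Within `run_scenario` the
perfusion flags refresh on a 0.25-day clock rather than at every fusion
(nascent loops take hours to lumenize and carry flow; this also removes
the dominant graph-search cost from the inner loop).

## Calibration of the free constants

The printed constants (`G_n, H_n, τ`, initial conditions, boundary cell
influx, fibroblast multiplier, classification bounds) are fixed. The
remaining rates are the package's own, chosen once so that the model's
seven-day predictions express the phenomena it exists to study, and then
frozen:

* `k_consume = 0.3`/day, `r_prolif = 0.6`/day, `d_anoxic = 1`/day: the
  control implant's initial oxygen store is consumed by the growing cell
  population within ~2–3 days, while the mean supply of a 2% sustained
  bead loading (0.02 · G_n ≈ 0.044/day, Hill-gated) can carry tissue at
  the densities reached by day 7. This places 2% near the
  sufficiency point: 1% is genuinely insufficient (supply < demand,
  patchy anoxia), 4% is saturating — matching the dose–response the
  model is meant to exhibit.
* `D_oxygen = D_vegf = 0.05` mm²/day are *effective* transport
  coefficients setting the oxygen penetration depth from the host
  boundary to a few hundred µm — the diffusion-limit premise of the
  whole problem — not molecular diffusivities.
* `p_vegf = 0.6`/day, `φ_max = 10`, `K_φ = 2.5/21`, `q = 2` put rim VEGF
  near the tip threshold by day ~2 and interior VEGF of a surviving
  (hypoxic) implant well above it, with the gradient pointing inward.
* `vessel_relax_rate = 1`/day keeps nascent vessels a secondary oxygen
  source relative to beads over one week; with strong vessel delivery
  the control condition heals itself by chasing its own receding anoxic
  frontier, which inverts the intended contrasts.

With these defaults, day-7 medians over five bead placements are:
anoxic fraction control ≈ 0.55 > CPO-2% ≈ 0.47–0.54 > HOG-2% ≈ 0.16 >
HOG-4% ≈ 0.14, and vessel penetration control 0.80 mm < CPO-2%
0.84–0.92 mm < HOG-2% ≈ 1.7 mm ≈ HOG-4% ≈ 1.96 mm (the 2%→4% difference
is below 15% of the implant half-width). These numbers are recomputed by
the test suite, not asserted as constants.

## What the synthetic data emulates — and what it does not

`make_release_curve` produces the two qualitative release shapes (burst
vs ~2-week sustained) as the model's own law plus additive, homoscedastic
Gaussian noise clipped at zero; real optode traces have drift,
heteroscedastic error and sampling gaps, so parameter-recovery results
here bound only the estimator's behavior under well-specified noise.
VEGF ramps and agent rows are geometric fixtures for unit tests, not
biological data. Passing tests therefore demonstrate internal
consistency and the stated qualitative contrasts — not quantitative
agreement with any measured implant.

## Numerical choices and degenerate inputs

* Default `dt = 10⁻³` day: the diffusion bound allows 8×10⁻³, but the
  endothelial kinetics (rates up to 400/day) need `dt·rate ≲ 0.4` for a
  stable, accurate explicit update.
* Field negatives are clipped at zero each step; totals are conserved to
  1e-10 per 1000 steps in the diffusion-only regime.
* Ties: tip-selection ties break to the smaller agent id; migration ties
  to N, E, S, W order; both make full runs byte-identical given a seed.
* Degenerate inputs rejected with errors: negative oxygen/time in the
  release law, `τ = 0` in the cumulative closed form, all-zero release
  curves (estimation-degenerate), sprout spacing exceeding the edge
  length, fewer than 5 samples in a fit.
* An all-zero intracellular state with zero VEGF is an exact fixed point
  of the agent system; an isolated agent can never activate Notch.

## Known limitations

* 2D cross-section only; no 3D geometry, no mechanics, no hydrogen
  peroxide intermediate or its cytotoxicity, no pH/calcium effects, no
  immune field, no blood flow, vessel regression or pericyte maturation.
* The continuum layer is a 5-field reduction of a richer published
  tissue-model family (10 continuous variables); chemotaxis of the
  continuum cell fields is omitted — directed motion lives entirely in
  the endothelial tips.
* The intracellular Notch system is a minimal 8-species scheme that
  preserves the causal chain (VEGF → active VEGFR-2 → Dll4 → neighbor
  Notch → suppressed neighbor VEGFR-2 activity → suppressed actin), not
  a fitted signaling model; rate constants are order-of-magnitude
  choices.
* Perfusion flags are sound (every flagged segment lies on a path
  between two boundary roots) but not complete: they are the union of
  shortest root-to-root paths, so redundant parallel loops may carry no
  flag.
* Anoxic fraction is an oxygen-field metric: in regimes of very fast
  anoxic death, a *worse* implant can show a lower anoxic fraction
  because dead tissue stops consuming and passively re-oxygenates;
  viable cell mass and penetration depth should be read alongside it.
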