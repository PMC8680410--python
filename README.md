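# oxyvasc

Hybrid continuum / agent-based simulation of **self-oxygenating tissue
implants**: oxygen-generating micromaterials embedded in an engineered
implant, a reaction–diffusion description of oxygen, VEGF and cell
densities, and discrete endothelial cells that select migrating tips by
Dll4–Notch lateral inhibition, grow up VEGF gradients, and anastomose
into perfused vessels.

## The problem

During the pre-vascular phase after implantation, an engineered tissue
relies on diffusion from host tissue for oxygen. For implants of
clinically relevant size that means hypoxia (< 5% dissolved O₂) followed
by anoxia (< 0.5%), cell death, and implant failure before host vessels
can arrive. Embedding oxygen-generating particles — calcium peroxide
(CPO), or CPO encapsulated in polycaprolactone to form hydrophobic
oxygen generators (HOGs) — can bridge that phase. CPO hydrolyzes in a
fast burst; HOGs release oxygen slowly for roughly two weeks. This
package simulates the consequences for tissue survival, hypoxia-driven
VEGF production, and ingrowing vasculature, for anyone studying oxygen
delivery strategies in tissue engineering in silico.

## The model

**Bead release.** Each bead releases oxygen at

```
rate(c, t) = G_n · H_n^h / (c^h + H_n^h) · exp(−τ·t)
```

with peak rate `G_n = 2.2`, oxygen half-saturation `H_n = 0.11`
(nondimensional; 1.0 ≡ 21% dissolved O₂), Hill coefficient `h = 6`, and
depletion rate `τ = 0.5`/day (CPO) or `τ = 0.05`/day (HOG). The steep
Hill gate makes release self-limiting: it shuts down once local oxygen
exceeds ~2.3%, inside the hypoxic band, so beads transform anoxic stress
into hypoxic stimulation rather than hyperoxygenating the tissue.

**Tissue fields.** Five coupled fields on a lattice (default 100×100
sites, 0.04 mm spacing — a 4 mm implant cross-section — simulated for
7 days): oxygen with Michaelis–Menten cellular consumption, bead sources
and vessel delivery; VEGF produced by progenitors and fibroblasts (the
latter at 10× the rate) amplified under hypoxia; progenitor and
fibroblast densities with logistic proliferation, anoxic death and
boundary influx (Dirichlet 0.01 for the first 3 days); and deposited
fibrous matrix. Explicit finite differences, 5-point Laplacian,
zero-flux boundaries except where Dirichlet values are stated.

**Endothelial agents.** Each cell carries eight species — VEGFR-2,
active VEGFR-2, effective active VEGFR-2, Notch1, active Notch1,
effective active Notch1, Dll4, actin. VEGF activates VEGFR-2; effective
VEGFR-2 drives Dll4, which activates Notch in lattice neighbors and
cooperatively suppresses *their* effective VEGFR-2 and actin — classic
lateral inhibition yielding alternating tip/stalk patterns. Cells whose
actin exceeds a threshold and beats every neighbor become tips, advance
one site toward higher VEGF every 0.05 days, leave stalk daughters
behind, and fuse with unconnected vessel trees on contact (anastomosis);
loops linking two boundary roots are flagged perfused and deliver
oxygen.

## Worked example

```python
import oxyvasc as ox

p = ox.default_parameters()
cpo = ox.ReleaseParams.for_type("CPO", p)
hog = ox.ReleaseParams.for_type("HOG", p)
print("peak release rate (zero oxygen, t=0):", ox.bead_release_rate(0.0, 0.0, cpo))
print("CPO total oxygen (t->inf):", ox.cumulative_release_zero_oxygen(1e9, cpo))
print("HOG total oxygen (t->inf):", ox.cumulative_release_zero_oxygen(1e9, hog))

curve = ox.make_release_curve(G=2.2, tau=0.05, noise_sd=0.05, seed=1)
est, resid = ox.fit_release_params(curve, fix_H=True)
print(f"fitted G_n = {est['G_n']:.3f}, tau = {est['tau']:.4f} (residual {resid:.3f})")

for bead_type, fraction in [("none", 0.0), ("HOG", 0.02)]:
    cfg = ox.default_scenario(bead_type=bead_type, bead_fraction=fraction, seed=1)
    final = ox.run_scenario(cfg, p).metrics.iloc[-1]
    label = "control " if bead_type == "none" else "HOG-2%  "
    print(f"{label} day 7: anoxic fraction {final.anoxic_fraction:.3f}, "
          f"penetration {final.penetration_depth_mm:.2f} mm, "
          f"{int(final.n_vessel_segments)} vessel segments")
```

prints

```
peak release rate (zero oxygen, t=0): 2.2
CPO total oxygen (t->inf): 4.4
HOG total oxygen (t->inf): 44.0
fitted G_n = 2.205, tau = 0.0505 (residual 0.328)
control  day 7: anoxic fraction 0.546, penetration 0.80 mm, 4597 vessel segments
HOG-2%   day 7: anoxic fraction 0.168, penetration 1.56 mm, 7027 vessel segments
```

Reading it: the burst and sustained particles share the same peak rate,
but the sustained particles deliver 10× the total oxygen (G_n/τ). The
fit recovers the generating parameters from a noisy synthetic release
curve. At day 7 the control implant is anoxic over half its area and
vessels reach only 0.8 mm from the surface, while 2% sustained beads
keep most of the implant out of anoxia and vessels penetrate 1.56 mm of
the 1.98 mm half-width — the self-oxygenation contrast the model is
built to exhibit.

## Command line

```
oxyvasc simulate --bead-type HOG --bead-fraction 0.02 --seed 1 --out run/
oxyvasc sweep --replicates 5 --out sweep/        # control + CPO/HOG × 1/2/4%
oxyvasc fit-release --curve curve.tsv
oxyvasc synth --kind release-curve --tau 0.05 --out curve.tsv
oxyvasc bench encapsulation --total 100 --lost 8
```

Scenario files are plain YAML key/value text; every default is
overridable and the full configuration is echoed into each output
directory.

## Layout

| Module | Contents |
| --- | --- |
| `oxyvasc.params` | parameter/scenario records, unit conventions, validation, config files |
| `oxyvasc.beads` | release law, cumulative closed forms, placement, parameter fitting |
| `oxyvasc.continuum` | the five tissue fields and their explicit stepper |
| `oxyvasc.vasculature` | endothelial agents, Notch dynamics, tip selection, growth, anastomosis |
| `oxyvasc.experiments` | scenario orchestration, implant metrics, condition sweeps |
| `oxyvasc.synthetic` | release-curve / VEGF-field / agent-row fixture generators |
| `oxyvasc.bench` | closed-form bench calculators (encapsulation, loading, methacrylation, swelling) |
| `oxyvasc.cli` | the `oxyvasc` command |

See `docs/methods.md` for the model's assumptions, parameter rationale
and known limitations.
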