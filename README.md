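# petrange

Quasi-real-time range verification for ion-beam therapy with
**positron-emitting beams**, studied end-to-end in silico.

When the therapy beam itself is a β⁺ emitter (¹⁵O, ¹⁴O, ¹¹C, ¹⁰C), the
stopped projectiles decay at their stopping point and an in-beam PET
scanner sees an annihilation-activity peak at the beam range — no
patient repositioning, no washout delay. The clinically decisive
questions are *how few ions* and *how little time* are needed before the
peak position is known to better than ~1 mm. `petrange` provides the
pieces to answer them for a pulsed synchrotron beam implanted in a PMMA
phantom between two flat PET panels:

- **`yield_model`** — closed-form activation/decay bookkeeping for
  pulsed beams. With decay constant λ = ln2/t½, beam-ON time t_p,
  beam-OFF time t_r and cycle T = t_p + t_r:
  N₀ = I_s/(λ t_p) · (1 − e^{−λ t_p}), N_D = N₀ (1 − e^{−λ t_r}), and
  cumulatively N(n) = N_D Σ_{j=0}^{n−1} (n−j) e^{−λ j T}. Only beam-OFF
  decays are usable for imaging. A figure of merit (FOM) evaluates N(n)
  with all accelerator-dependent factors at unity, ranking candidate
  nuclides by half-life and production cross-section alone.
- **`synthetic_data`** — Monte-Carlo list-mode generator: pulsed
  implantation with range straggling, exponential decay of the primary
  plus fragment contaminants, positron-range blur, back-to-back photon
  tracing to two 225×220 mm² panels 35 cm apart with attenuation, 1 ms
  timestamps.
- **`reconstruction`** — mid-plane back-projection at 2×2 mm² pixels
  with closed-form solid-angle sensitivity and attenuation corrections.
- **`profile_analysis`** — lateral ±2σ integration to a depth profile;
  GE lineshape fit (Gaussian core, C¹-matched exponential tails; the
  Gaussian mean μ is the peak position); peak tracking over cumulative
  cycles with conclusiveness criteria (identifiable peak, within
  0.75 mm of the asymptotic position, μ_err ≤ 0.75 mm).
- **`pipeline` / `petrange` CLI** — one-config orchestration with
  manifests for bit-identical re-runs.

See `docs/methods.md` for the model details and assumptions.

## Worked example

Rank the four candidate nuclides for a 1 s cycle with 0.5 s beam-ON:

```
$ petrange fom --tp 0.5 --tr 0.5
isotope  half_life    value  relative
    15O    122.240 0.121568  1.000000
    10C     19.310 0.075805  0.623561
    11C   1220.840 0.013253  0.109021
    14O     70.606 0.005861  0.048215
```

`value` is the FOM (expected beam-OFF decays per cycle with unit system
factors); `relative` normalizes to ¹⁵O. Despite ¹⁰C's 6× shorter
half-life, ¹⁵O's 10× larger production cross-section puts it first —
and it stays first for any duty factor of a 1 s cycle.

Simulate and analyse a ¹⁵O implantation (2×10⁵ ions/pulse, 8 cycles of
1.0 s ON / 1.5 s OFF, 105 mm mean range):

```
$ cat cfg.yaml
seed: 1
isotopes: ["15O"]
run:
  ions_per_pulse: 200000
  n_cycles: 8
$ petrange run --config cfg.yaml --out demo_out
15O: conclusive after cycle 2 (asymptotic mu = 104.71 mm)
```

`demo_out/15O/evolution.csv` holds the peak trajectory — after cycle 1
the fit is not yet identifiable, after cycle 2 the peak sits at
104.39 ± 0.60 mm, already inside the 0.75 mm tolerances of the
asymptotic value (104.71 mm, itself within half a pixel of the true
simulated activity peak at 104.99 mm):

```
n_cycles,cumulative_ions,elapsed_time,mu,mu_err,identifiable
1,200000.0,2.5,,,False
2,400000.0,5.0,104.39353828159375,0.60330009920627,True
...
```

`demo_out/15O/verdict.json` records the first conclusive entry and the
criteria; `demo_out/manifest.json` the seed, config hash and output
checksums.

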