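# Methods

`petrange` models quasi-real-time range verification of ion beams that
are themselves positron emitters (¹⁵O, ¹⁴O, ¹¹C, ¹⁰C): the stopped
projectiles β⁺-decay at their stopping point, so the annihilation
activity imaged by an in-beam PET scanner peaks at the beam range. The
package has four layers — an analytic yield model, a Monte-Carlo
list-mode simulator, a 2D reconstruction, and a peak-tracking analysis —
plus an orchestration layer and CLI.

## Pulsed-beam activation/decay model

A synchrotron delivers the beam in cycles of `t_p` seconds ON and `t_r`
seconds OFF (`T = t_p + t_r`). With a secondary intensity of `I_s` ions
per pulse (`I_s = η I₀`, `η = σ_cs ρ_A ε`) arriving at a constant rate
during the spill, the emitters alive at the end of one spill are

    N₀ = I_s / (λ t_p) · (1 − e^{−λ t_p}),     λ = ln 2 / t_{1/2}.

Decays during one OFF window: `N_D = N₀ (1 − e^{−λ t_r})`. Only OFF-window
coincidences are usable (the ON windows are dominated by prompt γ rays
and millisecond-lived fragments), so `N_D` is the per-cycle count of
analysable decays. Accumulated over `n` cycles, with each earlier cohort
attenuated by a full period per cycle of age,

    N(n) = N_D · Σ_{j=0}^{n−1} (n − j) e^{−λ j T}.

All `1 − e^{−x}` factors are evaluated with `expm1` for numerical
stability; `n` must be a whole number of cycles. A per-pulse cohort
accumulation (loop over pulses and OFF windows) is kept in the test
suite as an independent oracle; the closed form agrees with it to
1 × 10⁻¹⁰ relative over random cycle structures.

The **figure of merit** evaluates `N(n)` with every accelerator-dependent
factor (`I₀`, `ρ_A`, `ε`) set to unity, so only the half-life, the
production cross-section and the cycle structure remain. Cross-sections
are stored as relative magnitudes because every use is a ratio between
nuclides. For a 1 s cycle at duty factors 0.1–0.9, ¹⁵O has the largest
figure of merit of the four candidates: its cross-section is an order of
magnitude above ¹⁰C/¹⁴O while its half-life is an order of magnitude
below ¹¹C.

## Synthetic list-mode data

The simulator emulates implantation of a separated secondary beam into a
350 × 120 × 250 mm PMMA phantom viewed by two flat 225 × 220 mm panels
350 mm apart (4 mm crystal pitch), one above and one below the beam
plane. Defaults, and what they represent:

| parameter | default | rationale |
|---|---|---|
| `mean_range` | 105 mm | mid-FoV stopping depth, typical of therapy-like runs |
| `range_straggling_sigma` | 4 mm | depth spread dominated by the secondary beam's ~2% FWHM momentum spread at ~10 cm range, not by intrinsic straggling |
| `lateral_sigma` | 5 mm | secondary-beam spot size |
| `positron_rms_range` | per nuclide (0.4–1.1 mm) | RMS annihilation-point blur in water, applied per axis |
| `per_photon_efficiency` | 0.6 | lumped 511 keV photopeak + energy-window efficiency of a 20 mm LSO crystal; geometry is simulated explicitly |
| `mu_511` | 0.01141 mm⁻¹ | PMMA linear attenuation at 511 keV |
| `beam_on_background_rate` | 5 × 10⁻⁴ /ion | uniform-LOR stand-in for prompt γ and ms-lived fragment signal during the spill |
| cycle | 1.0 s ON / 1.5 s OFF (oxygen), 2.0/2.8 (carbon) | the high-energy-run synchrotron cycle structures |

Each implanted ion arrives uniformly within its spill, stops at a
truncated-normal depth, and contributes Poisson-distributed emitters per
activity component: the primary nuclide at the stopping point
(yield 1), short-lived projectile fragments shifted a few mm upstream,
and long-lived target fragments uniform from the entrance face to the
stopping depth. Decay times are exponential; annihilation positions are
blurred isotropically by the positron range. Photon pairs are traced
along isotropic back-to-back axes; a pair is recorded when both photons
hit their panels, survive attenuation along their chords through the
phantom, and pass the per-photon efficiency. Hits are quantized to
crystal centres and timestamped at 1 ms.

Contaminant yields are **illustrative**: real fragment yields depend on
beam energy and target and are not bundled. The fragment default
(0.005 emitters/ion, 19.3 s half-life, 5 mm upstream) is chosen so that
the saturated fragment contributes a few percent of beam-OFF
coincidences — a slight but discernible distortion of the peak, the
regime expected for oxygen emitter beams. (A 19 s species saturates
within a few cycles, so even a 5% yield would contribute ~⅓ of all
beam-OFF events — no longer "slight".)

What the generator does *not* emulate: curved panels (flat-panel
approximation; second-order for profile positions), photon
acollinearity (~0.25° FWHM, negligible against 4 mm crystals at 35 cm),
scatter and randoms beyond the uniform ON-window background, detector
dead time, and biological washout (phantom study). Passing tests
therefore validate the analysis chain's statistical behaviour, not
detector microphysics.

## Reconstruction

Beam-OFF events are back-projected onto the mid-horizontal plane: for
parallel panels the LOR crosses that plane at the coordinate-wise mean
of the two hits, an unbiased estimator for mid-plane sources. Pixels are
2 × 2 mm². The grid is offset half a pixel from the panel edges so that
pixel centres coincide with the lattice of quantized-crystal LOR
midpoints; without the offset the midpoints fall exactly on pixel edges
and the image picks up a systematic half-pixel (1 mm) bias.

Sensitivity correction uses the exact pair-acceptance solid angle at
each pixel centre: for a mid-plane point the two hits are point
reflections of each other, so acceptance reduces to the solid angle of
the intersection of the panel rectangle with its own reflection,
evaluated with the four-corner arctan formula and normalized to unit
mean over the FoV. A `from_scan` mode emulates a stepped point-source
mapping measurement instead. Attenuation correction uses the vertical
chord through the phantom (`e^{−μ·120 mm} ≈ 0.254` inside the phantom);
oblique-LOR attenuation differences are accepted as a small residual.
Variance is propagated as `max(counts, 1)` times the squared correction
factor, with no inter-pixel covariance.

## Profile analysis and the GE lineshape

The 1D depth profile integrates the corrected image laterally over
±2 standard deviations of the lateral activity marginal (≈95% of
counts). The peak is modelled with the GE function: a Gaussian
`A·exp(−(x−μ)²/2σ²)` on `[μ−δ_L, μ+δ_R]` continued by exponentials
matched in value and first derivative at both junctions (C¹ by
construction); `μ` is the peak position. The fit window is the
contiguous run of bins around the maximum above 10% of the peak
amplitude (30% plus a free baseline for plateau-dominated profiles from
non-emitter beams); windows under 8 bins, or non-convergent fits, are
flagged as failures rather than raised. Weighted least squares uses
per-bin errors, followed by one reweighting pass with model-predicted
Poisson errors — weights from observed counts bias the fit and make the
covariance (hence `μ_err`) optimistic. The covariance is the Gauss–Newton
`(JᵀJ)⁻¹` without χ²-rescaling; `χ²_red` is reported separately. A peak
is *identifiable* when the fit converged, `A ≥ 5·SE(A)`, and `μ` lies
inside the phantom.

Tracking the fit over cumulative per-cycle profiles gives the peak
trajectory versus implanted ions and elapsed time. The reference
("asymptotic") position is the identifiable fit with the smallest
`μ_err` (ties toward more ions). A measurement is **conclusive** when
the peak is identifiable, within 0.75 mm of the asymptotic position,
and has `μ_err ≤ 0.75 mm` — tolerances chosen well inside the ~1 mm
precision at which range verification becomes clinically useful.

## Numerical and design choices

- Truncated-normal depths are sampled by resampling the (tiny)
  out-of-range tail; degenerate (zero-sigma) spreads are supported for
  deterministic tests.
- Rays exactly parallel to the panels are nudged (`v_z ≥ 10⁻¹²`);
  events are sorted by timestamp with coordinate tie-breaks so equal
  seeds give byte-identical list-mode files.
- The beam-ON flag is defined on the stored 1 ms timestamp:
  `(t mod T) < t_p`.
- `μ_err` coverage is checked at ~2 × 10⁴-count profiles, the statistics
  of the conclusive regime; at a few thousand counts the Gauss–Newton
  error is a few percent optimistic.
- Problem sizes in tests and in `scripts/acceptance.py` (e.g.
  2 × 10⁵ ions/pulse × 8 cycles for the end-to-end run, 10⁶ pairs for
  the acceptance check) are chosen so every statistical tolerance is
  comfortably resolved at interactive runtimes.

## Known limitations

- The midpoint back-projection is a deliberate stand-in for the full
  reconstruction used with the real scanner; it is exact only for
  mid-plane sources, and out-of-plane activity smears laterally (then
  integrated over anyway).
- Relative yields in `experimental` mode depend on measured conversion
  factors whose averaging window (per-pulse vs overall) is not further
  specified; they are used as given.
- The GE junction offsets are free parameters bounded at zero; for
  nearly Gaussian peaks they are weakly constrained (large values are
  equivalent), which is harmless for `μ` but makes `δ` estimates
  unstable there.
- Simulated half-lives, cross-sections and cycle structures are bundled
  for the four nuclides above plus ¹⁶O intensities; other nuclides
  require user-supplied `IsotopeSpec`s.
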