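"""Nuclide and beam constants for positron-emitting therapy beams.

Half-lives are evaluated nuclear-data values; positron ranges are RMS
effective ranges in water representing annihilation-point blurring;
production cross-sections are measured projectile-fragmentation values
(16O -> 15O/14O, 12C -> 11C/10C on a light production target).  The
cross-sections are stored as relative magnitudes: every use in this
package is a ratio, so the overall unit cancels.

Beam-line quantities (primary intensity, conversion factor, cycle
structure, average intensities) describe the in-flight production runs
at a fragment separator that this package emulates: a synchrotron-driven
pulsed secondary beam implanted into a PMMA phantom between two PET
panels.
"""

from __future__ import annotations

from .yield_model import BeamCycle, IsotopeSpec

#: Per-nuclide physical constants.
ISOTOPES: dict[str, IsotopeSpec] = {
    "15O": IsotopeSpec(
        name="15O",
        half_life=122.24,
        positron_rms_range=1.0,
        endpoint_energy=1.732,
        prompt_gamma=False,
        sigma_cs=43.0,
    ),
    "14O": IsotopeSpec(
        name="14O",
        half_life=70.606,
        positron_rms_range=1.1,
        endpoint_energy=1.808,
        prompt_gamma=True,
        sigma_cs=1.2,
    ),
    "11C": IsotopeSpec(
        name="11C",
        half_life=1220.84,
        positron_rms_range=0.4,
        endpoint_energy=0.96,
        prompt_gamma=False,
        sigma_cs=46.7,
    ),
    "10C": IsotopeSpec(
        name="10C",
        half_life=19.310,
        positron_rms_range=1.1,
        endpoint_energy=1.90,
        prompt_gamma=True,
        sigma_cs=4.3,
    ),
}

#: Primary-beam intensity I0 [ions/pulse] for the high-energy production runs,
#: keyed by the secondary nuclide produced.
PRIMARY_INTENSITY: dict[str, float] = {
    "15O": 3e9,
    "14O": 9e9,
    "11C": 8e9,
    "10C": 1e10,
}

#: Measured conversion factor eta = I_s / I_0 (high-energy runs).
CONVERSION_FACTOR: dict[str, float] = {
    "15O": 4.3e-3,
    "14O": 1.2e-4,
    "11C": 2.4e-3,
    "10C": 1.1e-4,
}

#: Synchrotron cycle structures used during implantation (high-energy runs):
#: oxygen beams 1.0 s extraction + 1.5 s pause, carbon beams 2.0 s + 2.8 s.
CYCLES: dict[str, BeamCycle] = {
    "15O": BeamCycle(t_p=1.0, t_r=1.5),
    "14O": BeamCycle(t_p=1.0, t_r=1.5),
    "11C": BeamCycle(t_p=2.0, t_r=2.8),
    "10C": BeamCycle(t_p=2.0, t_r=2.8),
}

#: Average overall beam intensity [ions/s] during the high-energy oxygen
#: implantation runs (total implanted ions / total run time).
OVERALL_INTENSITY_HIGH_ENERGY: dict[str, float] = {
    "16O": 2.6e7,
    "15O": 4.3e6,
    "14O": 4.3e5,
}

#: PMMA linear attenuation coefficient at 511 keV [1/mm]
#: (mass attenuation x density 1.19 g/cm^3).
MU_PMMA_511 = 0.01141
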