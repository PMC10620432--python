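"""Activation/decay bookkeeping for pulsed positron-emitting ion beams.

A synchrotron delivers a secondary beam of a beta+-emitting nuclide in
cycles of ``t_p`` seconds beam-ON followed by ``t_r`` seconds beam-OFF.
Ions implanted at a constant rate during beam-ON build up a population of
emitters that decays exponentially; only decays occurring during beam-OFF
windows produce usable PET coincidences (the beam-ON periods are swamped
by prompt gammas and millisecond-lived fragments and are discarded).

The closed forms implemented here give, per cycle and cumulatively over a
run, the expected number of beam-OFF decays, and a half-life- and
cross-section-based figure of merit that ranks candidate nuclides with
all accelerator-dependent factors set to unity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeSpec",
    "BeamCycle",
    "ProductionSpec",
    "YieldResult",
    "decay_constant",
    "secondary_intensity",
    "conversion_factor",
    "emitters_at_pulse_end",
    "decays_per_cycle",
    "cumulative_decays",
    "figure_of_merit",
    "rank_isotopes",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class IsotopeSpec:
    """Physical constants of one positron-emitting nuclide.

    Parameters
    ----------
    name : str
        Nuclide label, e.g. ``"15O"``.
    half_life : float
        Half-life in seconds.
    positron_rms_range : float
        RMS effective positron range in water, mm; models the blurring
        between emission and annihilation point.
    endpoint_energy : float
        Beta+ endpoint energy in MeV (informational).
    prompt_gamma : bool
        Whether the decay feeds a prompt gamma line.
    sigma_cs : float
        Production cross-section, stored as a relative magnitude (all
        uses in this package are ratios between nuclides).
    """

    name: str
    half_life: float
    positron_rms_range: float = 0.0
    endpoint_energy: float = 0.0
    prompt_gamma: bool = False
    sigma_cs: float | None = None

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError(f"half_life must be > 0, got {self.half_life}")
        if self.positron_rms_range < 0:
            raise ValueError("positron_rms_range must be >= 0")
        if self.sigma_cs is not None and self.sigma_cs < 0:
            raise ValueError("sigma_cs must be >= 0")

    @property
    def decay_constant(self) -> float:
        """Decay constant lambda = ln(2)/t_half in 1/s."""
        return LN2 / self.half_life


@dataclass(frozen=True)
class BeamCycle:
    """Pulsed-beam time structure: ``t_p`` s ON then ``t_r`` s OFF."""

    t_p: float
    t_r: float

    def __post_init__(self) -> None:
        if self.t_p <= 0:
            raise ValueError(f"t_p must be > 0, got {self.t_p}")
        if self.t_r <= 0:
            raise ValueError(f"t_r must be > 0, got {self.t_r}")

    @property
    def T(self) -> float:
        """Full cycle period t_p + t_r in seconds."""
        return self.t_p + self.t_r


@dataclass(frozen=True)
class ProductionSpec:
    """Accelerator-side factors linking primary to secondary intensity.

    ``I_s = eta * I_0`` with ``eta = sigma_cs * rho_A * epsilon``:
    I_0 primary ions per pulse, rho_A production-target areal density
    (atoms/cm^2), epsilon transport efficiency through the separator.
    """

    I_0: float
    eta: float | None = None
    rho_A: float = 1.0
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.I_0 <= 0:
            raise ValueError("I_0 must be > 0")
        if self.eta is not None and self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.rho_A <= 0 or self.epsilon <= 0:
            raise ValueError("rho_A and epsilon must be > 0")
        if self.epsilon > 1:
            raise ValueError("epsilon must be <= 1")


@dataclass(frozen=True)
class YieldResult:
    """Expected emitter and decay counts for one run configuration."""

    N0: float
    ND: float
    Nn: float
    n: int


def decay_constant(half_life: float) -> float:
    """Return the decay constant ln(2)/half_life in 1/s.

    Raises
    ------
    ValueError
        If ``half_life`` is not strictly positive.
    """
    if half_life <= 0:
        raise ValueError(f"half_life must be > 0, got {half_life}")
    return LN2 / half_life


def secondary_intensity(eta: float, I_0: float) -> float:
    """Secondary-beam intensity I_s = eta * I_0 in ions/pulse."""
    if eta <= 0 or I_0 <= 0:
        raise ValueError("eta and I_0 must be > 0")
    return eta * I_0


def conversion_factor(sigma_cs: float, rho_A: float, epsilon: float) -> float:
    """Conversion factor eta = sigma_cs * rho_A * epsilon (dimensionless).

    The three factors must carry mutually consistent units (cross-section
    area times areal density gives a probability per primary ion).
    """
    if sigma_cs <= 0 or rho_A <= 0 or epsilon <= 0:
        raise ValueError("sigma_cs, rho_A and epsilon must all be > 0")
    return sigma_cs * rho_A * epsilon


def emitters_at_pulse_end(I_s: float, half_life: float, cycle: BeamCycle) -> float:
    """Expected emitters alive at the end of one beam-ON window.

    Ions arrive at a constant rate ``I_s / t_p`` during beam-ON and decay
    while the spill is still running:

        N0 = I_s / (lambda * t_p) * (1 - exp(-lambda * t_p))

    For ``lambda * t_p -> 0`` this tends to ``I_s`` (no decay losses).
    """
    if I_s < 0:
        raise ValueError("I_s must be >= 0")
    lam = decay_constant(half_life)
    x = lam * cycle.t_p
    # -expm1(-x)/x is the stable form of (1 - e^-x)/x, -> 1 as x -> 0
    return I_s * (-math.expm1(-x) / x)


def decays_per_cycle(I_s: float, half_life: float, cycle: BeamCycle) -> float:
    """Expected decays during the beam-OFF window of a single cycle.

    ND = N0 * (1 - exp(-lambda * t_r)).  Because only beam-OFF
    coincidences enter the analysis, ND is the model count of usable
    decays per cycle.
    """
    lam = decay_constant(half_life)
    N0 = emitters_at_pulse_end(I_s, half_life, cycle)
    return N0 * -math.expm1(-lam * cycle.t_r)


def cumulative_decays(I_s: float, half_life: float, cycle: BeamCycle, n: int) -> float:
    """Cumulative beam-OFF decays summed over the first ``n`` cycles.

    Each earlier cycle's cohort keeps contributing to later beam-OFF
    windows, attenuated by a full cycle period per cycle of age:

        N(n) = ND * sum_{j=0}^{n-1} (n - j) * exp(-lambda * j * T)

    ``N(1) == ND`` and ``N`` is non-decreasing in ``n``.
    """
    if not float(n).is_integer() or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    n = int(n)
    lam = decay_constant(half_life)
    ND = decays_per_cycle(I_s, half_life, cycle)
    j = np.arange(n)
    return float(ND * np.sum((n - j) * np.exp(-lam * j * cycle.T)))


def figure_of_merit(isotope: IsotopeSpec, cycle: BeamCycle, n: int = 1) -> float:
    """System-independent ranking quantity for candidate beam nuclides.

    Evaluates the cumulative beam-OFF decay count with every
    accelerator-dependent factor (primary intensity, target areal
    density, transport efficiency) set to unity, so the secondary
    intensity reduces to the production cross-section.  Depends only on
    the nuclide's half-life, its cross-section and the cycle structure;
    dimensionless and proportional to the usable coincidence yield.
    """
    if isotope.sigma_cs is None:
        raise ValueError(f"isotope {isotope.name} has no sigma_cs configured")
    if isotope.sigma_cs == 0:
        return 0.0
    return cumulative_decays(isotope.sigma_cs, isotope.half_life, cycle, n)


def rank_isotopes(
    isotopes: list[IsotopeSpec],
    cycle: BeamCycle | dict[str, BeamCycle],
    n: int = 1,
    mode: str = "fom",
    production: dict[str, ProductionSpec] | None = None,
    normalize_to: str = "15O",
) -> pd.DataFrame:
    """Rank nuclides by expected usable coincidence yield.

    Parameters
    ----------
    isotopes : list of IsotopeSpec
        Candidates; each needs ``sigma_cs`` (mode ``"fom"``) or an entry
        in ``production`` (mode ``"experimental"``).
    cycle : BeamCycle or mapping name -> BeamCycle
        Shared cycle structure, or one per nuclide (the experimental
        comparison uses the cycle each beam was actually run with).
    n : int
        Number of cycles accumulated.
    mode : {"fom", "experimental"}
        ``"fom"`` uses the unit-system figure of merit;
        ``"experimental"`` uses measured ``eta * I_0`` per nuclide.
    production : dict, optional
        Per-nuclide ProductionSpec, required for mode ``"experimental"``.
    normalize_to : str
        Nuclide whose entry defines relative yield 1.0; if absent the
        maximum is used and the ``normalized_to`` attribute records it.

    Returns
    -------
    pandas.DataFrame
        Columns ``isotope, half_life, value, relative``, sorted by
        descending value; ``df.attrs["normalized_to"]`` names the
        reference nuclide.
    """
    if not isotopes:
        raise ValueError("need at least one isotope")
    if mode not in ("fom", "experimental"):
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for iso in isotopes:
        cyc = cycle[iso.name] if isinstance(cycle, dict) else cycle
        if mode == "fom":
            value = figure_of_merit(iso, cyc, n)
        else:
            if production is None or iso.name not in production:
                raise ValueError(f"mode='experimental' needs production spec for {iso.name}")
            prod = production[iso.name]
            if prod.eta is None:
                raise ValueError(f"production spec for {iso.name} lacks eta")
            I_s = secondary_intensity(prod.eta, prod.I_0)
            value = cumulative_decays(I_s, iso.half_life, cyc, n)
        rows.append({"isotope": iso.name, "half_life": iso.half_life, "value": value})

    df = pd.DataFrame(rows).sort_values("value", ascending=False, ignore_index=True)
    names = set(df["isotope"])
    ref = normalize_to if normalize_to in names else df.loc[0, "isotope"]
    ref_value = float(df.loc[df["isotope"] == ref, "value"].iloc[0])
    df["relative"] = df["value"] / ref_value
    df.attrs["normalized_to"] = ref
    return df
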