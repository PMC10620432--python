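"""Monte-Carlo list-mode coincidence simulator for implanted beta+ beams.

Emulates the implantation of a pulsed positron-emitting ion beam into a
PMMA phantom viewed by two flat PET panels (one above, one below the
beam plane).  The chain is: sample ion stopping points (mean range +
straggling), turn each ion into positron emitters (the stopped primary
nuclide, optional projectile-fragment contaminants and a target-fragment
plateau), draw exponential decay times, blur annihilation positions by
the positron range, and trace back-to-back 511 keV photon pairs to the
panels with attenuation in the phantom and a lumped per-photon
detection efficiency.  Events carry 1 ms timestamps and a beam-ON flag
derived from the cycle structure; uniform beam-ON background emulates
prompt gammas and millisecond-lived fragments.

Coordinates: ``depth`` runs along the beam with origin at the phantom
entrance face (increasing downstream), ``height`` is vertical (the
panel-separation axis, 0 at the beam plane), ``width`` is lateral.
All distances in mm, times in ms in event records.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .yield_model import BeamCycle, decay_constant

__all__ = [
    "PhantomSpec",
    "ScannerSpec",
    "ActivityComponent",
    "ImplantationSpec",
    "RunConfig",
    "CoincidenceEvent",
    "ListModeParseError",
    "sample_stopping_points",
    "build_decay_schedule",
    "detect_pair",
    "detect_pairs",
    "simulate_run",
    "write_listmode",
    "read_listmode",
]

LISTMODE_COLUMNS = [
    "t_ms",
    "top_depth_mm",
    "top_width_mm",
    "bottom_depth_mm",
    "bottom_width_mm",
    "beam_on",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Homogeneous rectangular phantom, long side along the beam.

    ``size`` is (depth, height, width) of the interior in mm; ``mu_511``
    the linear attenuation coefficient at 511 keV in 1/mm (default is
    PMMA).
    """

    size: tuple[float, float, float] = (350.0, 120.0, 250.0)
    entrance_face_position: float = 0.0
    mu_511: float = 0.01141

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError("phantom dimensions must be > 0")
        if self.mu_511 < 0:
            raise ValueError("mu_511 must be >= 0")

    @property
    def depth_interval(self) -> tuple[float, float]:
        return (self.entrance_face_position, self.entrance_face_position + self.size[0])

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of (n, 3) (depth, height, width) points inside."""
        d0, d1 = self.depth_interval
        hh, hw = self.size[1] / 2, self.size[2] / 2
        p = np.atleast_2d(points)
        return (
            (p[:, 0] >= d0)
            & (p[:, 0] <= d1)
            & (np.abs(p[:, 1]) <= hh)
            & (np.abs(p[:, 2]) <= hw)
        )


@dataclass(frozen=True)
class ScannerSpec:
    """Two flat rectangular panels parallel to the beam plane.

    ``panel_size`` is (depth extent, width extent); panels sit at
    height = +/- ``panel_separation``/2, centred laterally on the beam
    axis and at ``center_depth`` along the beam.  ``per_photon_efficiency``
    lumps the energy window and crystal efficiency into one Bernoulli
    per photon; ``coincidence_resolution`` is informational (events are
    generated as true pairs).
    """

    panel_size: tuple[float, float] = (225.0, 220.0)
    panel_separation: float = 350.0
    crystal_pitch: float = 4.0
    per_photon_efficiency: float = 0.6
    coincidence_resolution: float = 4.1
    timestamp_resolution_ms: float = 1.0
    center_depth: float = 112.5

    def __post_init__(self) -> None:
        if not (0 < self.per_photon_efficiency <= 1):
            raise ValueError("per_photon_efficiency must be in (0, 1]")
        if self.panel_separation <= 0:
            raise ValueError("panel_separation must be > 0")

    @property
    def panel_depth_interval(self) -> tuple[float, float]:
        a = self.panel_size[0] / 2
        return (self.center_depth - a, self.center_depth + a)

    @property
    def panel_width_interval(self) -> tuple[float, float]:
        b = self.panel_size[1] / 2
        return (-b, b)


@dataclass(frozen=True)
class ActivityComponent:
    """One positron-emitting species contributing to the activity.

    ``spatial_kind`` selects where the emitter sits relative to the
    ion's stopping point: ``stopped_peak`` (at the stopping point, the
    primary beam nuclide), ``shifted_peak`` (displaced ``shift`` mm
    upstream, projectile fragments stopping short of the primaries) or
    ``plateau`` (uniform from the entrance face to the stopping depth,
    target fragments created along the track).  ``yield_per_ion`` is the
    expected emitters per implanted primary ion (Poisson unless
    ``deterministic``).
    """

    species: str
    half_life: float
    yield_per_ion: float
    spatial_kind: str = "stopped_peak"
    shift: float = 0.0
    positron_rms_range: float = 1.0
    deterministic: bool = False

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be > 0")
        if self.yield_per_ion < 0:
            raise ValueError("yield_per_ion must be >= 0")
        if self.spatial_kind not in ("stopped_peak", "shifted_peak", "plateau"):
            raise ValueError(f"unknown spatial_kind {self.spatial_kind!r}")


@dataclass(frozen=True)
class ImplantationSpec:
    """Stopped-ion depth distribution and lateral beam spot.

    The default depth spread reflects a separated secondary beam whose
    momentum spread (~2% FWHM) dominates over intrinsic range
    straggling: about 4 mm sigma at a ~10 cm mean range.
    """

    mean_range: float
    range_straggling_sigma: float = 4.0
    lateral_sigma: float = 5.0
    beam_axis_offset: tuple[float, float] = (0.0, 0.0)  # (height, width)

    def __post_init__(self) -> None:
        if self.range_straggling_sigma < 0 or self.lateral_sigma < 0:
            raise ValueError("sigmas must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    """Pulsed-run configuration: cycle structure, intensity, seed."""

    cycle: BeamCycle
    ions_per_pulse: int
    n_cycles: int
    rng_seed: int = 0
    beam_on_background_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.ions_per_pulse < 0:
            raise ValueError("ions_per_pulse must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def duration(self) -> float:
        """Run length in seconds (n_cycles full cycles)."""
        return self.n_cycles * self.cycle.T


@dataclass(frozen=True)
class CoincidenceEvent:
    """One detected photon pair: timestamp and panel hit coordinates."""

    t: int
    top_hit: tuple[float, float]
    bottom_hit: tuple[float, float]
    beam_on: bool


class ListModeParseError(ValueError):
    """Raised when a list-mode file cannot be parsed; names the line."""


def sample_stopping_points(
    impl: ImplantationSpec,
    n_ions: int,
    rng: np.random.Generator,
    phantom: PhantomSpec | None = None,
) -> np.ndarray:
    """Sample (depth, height, width) stopping points for ``n_ions`` ions.

    Depth follows a normal distribution (mean range, straggling sigma)
    truncated to the phantom interior; the lateral coordinates are
    normal around the beam axis.  Returns an (n_ions, 3) array.
    """
    phantom = phantom or PhantomSpec()
    d0, d1 = phantom.depth_interval
    if not (d0 < impl.mean_range < d1):
        raise ValueError(
            f"mean_range {impl.mean_range} outside phantom depth ({d0}, {d1})"
        )
    if n_ions == 0:
        return np.empty((0, 3))
    if impl.range_straggling_sigma == 0:
        depth = np.full(n_ions, impl.mean_range)
    else:
        # rejection-free truncated normal via repeated resampling of the
        # (tiny) out-of-range tail; the peak sits far from the faces
        depth = rng.normal(impl.mean_range, impl.range_straggling_sigma, n_ions)
        bad = (depth < d0) | (depth > d1)
        while bad.any():
            depth[bad] = rng.normal(
                impl.mean_range, impl.range_straggling_sigma, int(bad.sum())
            )
            bad = (depth < d0) | (depth > d1)
    oh, ow = impl.beam_axis_offset
    if impl.lateral_sigma == 0:
        height = np.full(n_ions, oh)
        width = np.full(n_ions, ow)
    else:
        height = rng.normal(oh, impl.lateral_sigma, n_ions)
        width = rng.normal(ow, impl.lateral_sigma, n_ions)
    return np.column_stack([depth, height, width])


def build_decay_schedule(
    components: list[ActivityComponent],
    stopping_points: np.ndarray,
    run: RunConfig,
    rng: np.random.Generator,
    phantom: PhantomSpec | None = None,
) -> pd.DataFrame:
    """Turn implanted ions into positron emitters and draw decay times.

    Ions are assigned to beam pulses in order (``ions_per_pulse`` per
    cycle) and arrive uniformly within their beam-ON window.  Each ion
    contributes, per component, Poisson(``yield_per_ion``) emitters born
    at the ion's arrival; each emitter decays after an Exponential(lambda)
    waiting time and its annihilation position is the component-specific
    position blurred isotropically by the positron range.

    Returns a DataFrame with columns ``depth, height, width`` (blurred
    annihilation position, mm), ``birth_time``, ``decay_time`` (s since
    run start) and ``species``; decays beyond the run end are included
    (callers filter on ``decay_time``).
    """
    if not components:
        raise ValueError("need at least one activity component")
    phantom = phantom or PhantomSpec()
    n_ions = len(stopping_points)
    cycle_idx = np.arange(n_ions) // max(run.ions_per_pulse, 1)
    arrival = cycle_idx * run.cycle.T + rng.uniform(0.0, run.cycle.t_p, n_ions)
    entrance = phantom.entrance_face_position

    frames = []
    for comp in components:
        if comp.deterministic:
            counts = np.full(n_ions, int(round(comp.yield_per_ion)))
        else:
            counts = rng.poisson(comp.yield_per_ion, n_ions)
        idx = np.repeat(np.arange(n_ions), counts)
        if idx.size == 0:
            continue
        pos = stopping_points[idx].copy()
        if comp.spatial_kind == "shifted_peak":
            pos[:, 0] -= comp.shift
        elif comp.spatial_kind == "plateau":
            pos[:, 0] = rng.uniform(entrance, stopping_points[idx, 0])
        lam = decay_constant(comp.half_life)
        birth = arrival[idx]
        decay = birth + rng.exponential(1.0 / lam, idx.size)
        if comp.positron_rms_range > 0:
            pos += rng.normal(0.0, comp.positron_rms_range, pos.shape)
        frames.append(
            pd.DataFrame(
                {
                    "depth": pos[:, 0],
                    "height": pos[:, 1],
                    "width": pos[:, 2],
                    "birth_time": birth,
                    "decay_time": decay,
                    "species": comp.species,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["depth", "height", "width", "birth_time", "decay_time", "species"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values("decay_time", ignore_index=True)


def _quantize(x: np.ndarray, origin: float, pitch: float) -> np.ndarray:
    """Snap coordinates to crystal centres on a grid starting at origin."""
    idx = np.floor((x - origin) / pitch)
    return origin + (idx + 0.5) * pitch


def _chord_length(p: np.ndarray, q: np.ndarray, phantom: PhantomSpec) -> np.ndarray:
    """Length of segment p->q inside the phantom box (vectorized AABB clip)."""
    d0, d1 = phantom.depth_interval
    lo = np.array([d0, -phantom.size[1] / 2, -phantom.size[2] / 2])
    hi = np.array([d1, phantom.size[1] / 2, phantom.size[2] / 2])
    v = q - p
    seg = np.linalg.norm(v, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (lo - p) / v
        t_hi = (hi - p) / v
    t_near = np.where(np.isnan(t_lo), -np.inf, np.minimum(t_lo, t_hi))
    t_far = np.where(np.isnan(t_hi), np.inf, np.maximum(t_lo, t_hi))
    # axes with v == 0: inside slab -> unbounded, outside -> empty
    zero = v == 0
    inside = (p >= lo) & (p <= hi)
    t_near = np.where(zero, np.where(inside, -np.inf, np.inf), t_near)
    t_far = np.where(zero, np.where(inside, np.inf, -np.inf), t_far)
    t0 = np.clip(t_near.max(axis=1), 0.0, 1.0)
    t1 = np.clip(t_far.min(axis=1), 0.0, 1.0)
    return seg * np.maximum(t1 - t0, 0.0)


def detect_pairs(
    positions: np.ndarray,
    scanner: ScannerSpec,
    rng: np.random.Generator,
    phantom: PhantomSpec | None = None,
    attenuation: bool = True,
    quantize: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trace annihilation-photon pairs from ``positions`` to the panels.

    Each annihilation emits two back-to-back photons along an isotropic
    random axis.  A pair is detected when both photons geometrically hit
    their panel, survive attenuation along their chord through the
    phantom (if ``attenuation``), and pass the per-photon efficiency.

    Returns ``(detected_mask, top_hits, bottom_hits)`` where the hit
    arrays are (n, 2) (depth, width) panel coordinates (quantized to
    crystal centres when ``quantize``); rows for undetected pairs are
    NaN.
    """
    phantom = phantom or PhantomSpec()
    p = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(p)
    top = np.full((n, 2), np.nan)
    bot = np.full((n, 2), np.nan)
    if n == 0:
        return np.zeros(0, dtype=bool), top, bot

    # isotropic unit vectors, oriented toward the top panel
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v *= np.where(v[:, 1] >= 0, 1.0, -1.0)[:, None]
    # avoid exactly-parallel rays
    v[:, 1] = np.maximum(v[:, 1], 1e-12)

    z_top = scanner.panel_separation / 2
    t_top = (z_top - p[:, 1]) / v[:, 1]
    t_bot = (p[:, 1] + z_top) / v[:, 1]
    hit_top = p + v * t_top[:, None]
    hit_bot = p - v * t_bot[:, None]

    u0, u1 = scanner.panel_depth_interval
    w0, w1 = scanner.panel_width_interval
    ok = (
        (t_top >= 0)
        & (t_bot >= 0)
        & (hit_top[:, 0] >= u0)
        & (hit_top[:, 0] <= u1)
        & (hit_top[:, 2] >= w0)
        & (hit_top[:, 2] <= w1)
        & (hit_bot[:, 0] >= u0)
        & (hit_bot[:, 0] <= u1)
        & (hit_bot[:, 2] >= w0)
        & (hit_bot[:, 2] <= w1)
    )

    if attenuation and phantom.mu_511 > 0 and ok.any():
        surv_t = np.exp(-phantom.mu_511 * _chord_length(p[ok], hit_top[ok], phantom))
        surv_b = np.exp(-phantom.mu_511 * _chord_length(p[ok], hit_bot[ok], phantom))
        keep = rng.random(int(ok.sum())) < surv_t * surv_b
        ok[np.flatnonzero(ok)[~keep]] = False

    eff = scanner.per_photon_efficiency
    if eff < 1 and ok.any():
        keep = rng.random(int(ok.sum())) < eff * eff
        ok[np.flatnonzero(ok)[~keep]] = False

    for hits, out in ((hit_top, top), (hit_bot, bot)):
        d = hits[ok, 0]
        w = hits[ok, 2]
        if quantize:
            d = _quantize(d, u0, scanner.crystal_pitch)
            w = _quantize(w, w0, scanner.crystal_pitch)
        out[ok, 0] = d
        out[ok, 1] = w
    return ok, top, bot


def detect_pair(
    position,
    scanner: ScannerSpec,
    rng: np.random.Generator,
    phantom: PhantomSpec | None = None,
    **kwargs,
) -> tuple[tuple[float, float], tuple[float, float]] | None:
    """Single-annihilation wrapper around :func:`detect_pairs`.

    Returns ``(top_hit, bottom_hit)`` panel coordinates or ``None`` if
    either photon is missed.
    """
    ok, top, bot = detect_pairs(
        np.asarray(position, dtype=float)[None, :], scanner, rng, phantom, **kwargs
    )
    if not ok[0]:
        return None
    return (float(top[0, 0]), float(top[0, 1])), (float(bot[0, 0]), float(bot[0, 1]))


def simulate_run(
    run: RunConfig,
    impl: ImplantationSpec,
    components: list[ActivityComponent],
    phantom: PhantomSpec | None = None,
    scanner: ScannerSpec | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full implantation + detection simulation of one pulsed run.

    Returns ``(events, truth)``.  ``events`` is a list-mode DataFrame
    with columns ``t_ms, top_depth_mm, top_width_mm, bottom_depth_mm,
    bottom_width_mm, beam_on`` sorted by timestamp.  ``truth`` records
    per-cycle implanted ions, the true mean annihilation depth of the
    primary (first stopped-peak) component, total decays within the run,
    and beam-OFF decay counts per cycle (all components, and primary
    only) — the ground truth used to validate reconstruction and the
    analytic yield model.
    """
    phantom = phantom or PhantomSpec()
    scanner = scanner or ScannerSpec()
    rng = np.random.default_rng(run.rng_seed)

    n_ions = run.ions_per_pulse * run.n_cycles
    points = sample_stopping_points(impl, n_ions, rng, phantom)
    schedule = build_decay_schedule(components, points, run, rng, phantom)

    T, t_p = run.cycle.T, run.cycle.t_p
    in_run = schedule[schedule["decay_time"] < run.duration].reset_index(drop=True)

    primary = next(
        (c.species for c in components if c.spatial_kind == "stopped_peak"), None
    )
    phase = in_run["decay_time"] % T
    cyc = (in_run["decay_time"] // T).astype(int)
    off_mask = phase.to_numpy() >= t_p
    off_counts = np.bincount(cyc[off_mask], minlength=run.n_cycles)
    if primary is not None:
        prim_mask = (in_run["species"] == primary).to_numpy()
        prim_off = np.bincount(cyc[off_mask & prim_mask], minlength=run.n_cycles)
        true_depth = float(in_run.loc[prim_mask, "depth"].mean()) if prim_mask.any() else np.nan
    else:
        prim_off = np.zeros(run.n_cycles, dtype=int)
        true_depth = np.nan

    pos = in_run[["depth", "height", "width"]].to_numpy()
    ok, top, bot = detect_pairs(pos, scanner, rng, phantom)
    t_ms = np.floor(in_run["decay_time"].to_numpy()[ok] * 1000).astype(np.int64)
    events = pd.DataFrame(
        {
            "t_ms": t_ms,
            "top_depth_mm": top[ok, 0],
            "top_width_mm": top[ok, 1],
            "bottom_depth_mm": bot[ok, 0],
            "bottom_width_mm": bot[ok, 1],
        }
    )

    # uniform beam-ON background (prompt gammas, ms-lived fragments)
    if run.beam_on_background_rate > 0 and run.ions_per_pulse > 0:
        n_bg = rng.poisson(
            run.beam_on_background_rate * run.ions_per_pulse, run.n_cycles
        )
        tot = int(n_bg.sum())
        if tot:
            cyc_bg = np.repeat(np.arange(run.n_cycles), n_bg)
            t_bg = cyc_bg * T + rng.uniform(0, t_p, tot)
            u0, u1 = scanner.panel_depth_interval
            w0, w1 = scanner.panel_width_interval
            cols = {}
            for prefix in ("top", "bottom"):
                cols[f"{prefix}_depth_mm"] = _quantize(
                    rng.uniform(u0, u1, tot), u0, scanner.crystal_pitch
                )
                cols[f"{prefix}_width_mm"] = _quantize(
                    rng.uniform(w0, w1, tot), w0, scanner.crystal_pitch
                )
            bg = pd.DataFrame({"t_ms": np.floor(t_bg * 1000).astype(np.int64), **cols})
            events = pd.concat([events, bg], ignore_index=True)

    events["beam_on"] = (events["t_ms"].to_numpy() / 1000.0) % T < t_p
    events = events.sort_values(
        ["t_ms", "top_depth_mm", "top_width_mm", "bottom_depth_mm", "bottom_width_mm"],
        kind="stable",
        ignore_index=True,
    )[LISTMODE_COLUMNS]

    truth = {
        "ions_per_cycle": [run.ions_per_pulse] * run.n_cycles,
        "n_ions": n_ions,
        "true_peak_depth": true_depth,
        "n_decays_in_run": int(len(in_run)),
        "beam_off_decays_per_cycle": off_counts.tolist(),
        "beam_off_primary_decays_per_cycle": prim_off.tolist(),
        "primary_species": primary,
        "seed": run.rng_seed,
    }
    return events, truth


def write_listmode(
    events: pd.DataFrame,
    path: str | Path,
    scanner: ScannerSpec | None = None,
    phantom: PhantomSpec | None = None,
    seed: int | None = None,
) -> Path:
    """Write events as a tab-delimited table plus a JSON geometry sidecar."""
    path = Path(path)
    df = events[LISTMODE_COLUMNS].copy()
    df["beam_on"] = df["beam_on"].astype(int)
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "format": "petrange-listmode-v1",
        "n_events": int(len(df)),
        "seed": seed,
        "scanner": asdict(scanner) if scanner else None,
        "phantom": asdict(phantom) if phantom else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_listmode(
    path: str | Path,
    expected_scanner: ScannerSpec | None = None,
) -> tuple[pd.DataFrame, dict | None]:
    """Read a list-mode file written by :func:`write_listmode`.

    Malformed rows raise :class:`ListModeParseError` naming the line.
    If ``expected_scanner`` is given and disagrees with the sidecar
    geometry, a warning is emitted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={
                "t_ms": np.int64,
                "top_depth_mm": float,
                "top_width_mm": float,
                "bottom_depth_mm": float,
                "bottom_width_mm": float,
                "beam_on": np.int64,
            },
        )
        if list(df.columns) != LISTMODE_COLUMNS:
            raise ValueError(f"bad header: {list(df.columns)}")
    except (ValueError, TypeError) as exc:
        line = _locate_bad_line(path)
        raise ListModeParseError(f"{path}: line {line}: {exc}") from exc
    df["beam_on"] = df["beam_on"].astype(bool)

    sidecar = None
    sc_path = path.with_suffix(path.suffix + ".json")
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())
        if expected_scanner is not None and sidecar.get("scanner") is not None:
            # JSON round-trip normalizes tuples to lists
            expected = json.loads(json.dumps(asdict(expected_scanner)))
            if sidecar["scanner"] != expected:
                warnings.warn(
                    f"{path}: sidecar scanner geometry differs from expected",
                    stacklevel=2,
                )
    return df, sidecar


def _locate_bad_line(path: Path) -> int:
    """Find the first malformed line (1-based) of a list-mode file."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != LISTMODE_COLUMNS:
            return 1
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(LISTMODE_COLUMNS):
                return lineno
            try:
                int(parts[0]), int(parts[5])
                [float(x) for x in parts[1:5]]
            except ValueError:
                return lineno
    return -1
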