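"""Synthetic retina scenes and every input the analysis pipeline consumes.

The generator emulates the three experimental readouts of a Dendra2
photoconversion study:

* hyperspectral conversion series — a field of green microglia imaged at
  ~1 scan/s, with 20 baseline scans under 488-nm excitation (bleaching
  only) followed by 405-nm conversion restricted to a rectangular region;
* two-channel (488 / 561 nm excited) day-scale time-lapse frames for
  three scenarios: healthy (turnover only), focal injury (converted cells
  migrate to and cluster at the damage locus, then disperse) and
  widespread degeneration (green-only monocytes infiltrate from vessels);
* flow-cytometry event tables (~200,000 events/sample) with the gated
  population structure: microglia (green-only or green/red double
  positive), peripheral monocytes, debris, doublets and dead cells.

All randomness flows from a single integer seed through named substreams;
with noise off, rendered signal is exactly linear in molecular pool
amounts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dendratrack import photophysics as pp
from dendratrack.photophysics import (
    DendraPool,
    FilterSpec,
    IlluminationProtocol,
    KineticRates,
    WavelengthGrid,
)

DEFAULT_N_EVENTS = 200_000
DEFAULT_N_BASELINE_SCANS = 20
DEFAULT_SCAN_PERIOD_S = 1.0


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Detection noise: Poisson shot noise, Gaussian read noise, a flat
    autofluorescence floor, and linear channel bleedthrough.

    ``shot`` is the photon count corresponding to one signal unit (larger
    means relatively less shot noise); ``enabled=False`` renders noiseless.
    """

    shot: float = 200.0
    read_sigma: float = 0.01
    af_level: float = 0.02
    green_into_red: float = 0.01
    red_into_green: float = 0.005
    enabled: bool = True

    def __post_init__(self) -> None:
        if min(self.shot, self.read_sigma, self.af_level,
               self.green_into_red, self.red_into_green) < 0:
            raise ValueError("noise parameters must be non-negative")

    def apply(self, signal: np.ndarray, rng: np.random.Generator
              ) -> np.ndarray:
        if not self.enabled:
            return signal
        counts = rng.poisson(np.maximum(signal, 0.0) * self.shot) / self.shot
        return np.maximum(counts + rng.normal(0.0, self.read_sigma,
                                              size=signal.shape), 0.0)


NOISELESS = NoiseModel(enabled=False)


# ---------------------------------------------------------------------------
# scene
# ---------------------------------------------------------------------------


@dataclass
class Cell:
    id: int
    soma_xy_um: tuple[float, float]
    morphology: str = "ramified"  # ramified | amoeboid
    pool: DendraPool = field(default_factory=lambda: DendraPool(g=1.0))
    origin: str = "resident"      # resident | infiltrating
    expression: float = 1.0       # per-cell Cx3cr1-driven expression level
    trajectory: list = field(default_factory=list)  # (time_h, (x, y))
    home_xy_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.home_xy_um is None:
            self.home_xy_um = self.soma_xy_um
        if self.origin == "infiltrating" and self.pool.r != 0:
            raise ValueError("infiltrating cells appear unconverted (r = 0)")


@dataclass
class RetinaScene:
    field_um: float
    cells: list[Cell]
    vessel_mask: np.ndarray
    injury: tuple[tuple[float, float], float] | None  # (center_xy, diameter)
    rng_seed: int


def _draw_vessels(shape: tuple[int, int], rng: np.random.Generator
                  ) -> np.ndarray:
    """Procedural branching vessel curves radiating from the disc center."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    cx, cy = w / 2.0, h / 2.0
    n_vessels = rng.integers(3, 6)
    for _ in range(n_vessels):
        angle = rng.uniform(0, 2 * np.pi)
        x, y = cx, cy
        for _ in range(int(1.2 * max(h, w))):
            angle += rng.normal(0.0, 0.08)
            x += np.cos(angle)
            y += np.sin(angle)
            if not (0 <= x < w and 0 <= y < h):
                break
            xi, yi = int(x), int(y)
            mask[max(yi - 1, 0):yi + 2, max(xi - 1, 0):xi + 2] = True
    return mask


def generate_scene(field_um: float = 1456.0, n_cells: int = 80,
                   seed: int = 0, min_dist_um: float = 80.0,
                   injury: tuple[tuple[float, float], float] | None = None,
                   mask_px: int = 182,
                   expression_cv: float = 0.15) -> RetinaScene:
    """Quasi-regular mosaic of ramified Dendra2-expressing cells.

    Soma positions are drawn by minimum-distance rejection sampling
    (microglia tile the retina in an exclusion-zone mosaic).  Fully
    deterministic per seed.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    margin = min(min_dist_um / 2.0, field_um / 20.0)
    positions: list[tuple[float, float]] = []
    max_attempts = 2000 * max(n_cells, 1)
    attempts = 0
    while len(positions) < n_cells:
        if attempts >= max_attempts:
            raise ValueError(
                f"cannot place {n_cells} cells with exclusion radius "
                f"{min_dist_um} µm in a {field_um} µm field")
        attempts += 1
        xy = tuple(rng.uniform(margin, field_um - margin, size=2))
        if all((xy[0] - p[0]) ** 2 + (xy[1] - p[1]) ** 2 >= min_dist_um ** 2
               for p in positions):
            positions.append(xy)
    cells = []
    for i, xy in enumerate(positions):
        expr = float(rng.lognormal(0.0, expression_cv))
        cells.append(Cell(id=i, soma_xy_um=xy, expression=expr,
                          pool=DendraPool(g=expr)))
    vessels = _draw_vessels((mask_px, mask_px), rng)
    return RetinaScene(field_um=field_um, cells=cells, vessel_mask=vessels,
                       injury=injury, rng_seed=seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _render_cell_maps(scene: RetinaScene, px_size_um: float,
                      soma_sigma_um: float = 5.0,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Render per-pixel g and r pool density maps for the scene.

    Somata are 2-D Gaussian blobs; ramified cells get 3–5 straight
    processes of fainter blobs, amoeboid cells a larger bare soma.
    """
    n = int(round(scene.field_um / px_size_um))
    g_map = np.zeros((n, n))
    r_map = np.zeros((n, n))
    yy, xx = np.mgrid[0:n, 0:n]
    proc_rng = rng or np.random.default_rng(
        np.random.SeedSequence([scene.rng_seed, 202]))
    for cell in scene.cells:
        cx = cell.soma_xy_um[0] / px_size_um
        cy = cell.soma_xy_um[1] / px_size_um
        sigma = (soma_sigma_um if cell.morphology == "ramified"
                 else 1.6 * soma_sigma_um) / px_size_um
        lo_y, hi_y = int(max(cy - 6 * sigma, 0)), int(min(cy + 6 * sigma + 1, n))
        lo_x, hi_x = int(max(cx - 6 * sigma, 0)), int(min(cx + 6 * sigma + 1, n))
        if lo_y >= hi_y or lo_x >= hi_x:
            continue
        sub_y = yy[lo_y:hi_y, lo_x:hi_x]
        sub_x = xx[lo_y:hi_y, lo_x:hi_x]
        blob = np.exp(-((sub_x - cx) ** 2 + (sub_y - cy) ** 2)
                      / (2 * sigma ** 2))
        if cell.morphology == "ramified":
            n_proc = int(proc_rng.integers(3, 6))
            angles = proc_rng.uniform(0, 2 * np.pi, n_proc)
            length = 25.0 / px_size_um
            psig = 2.0 / px_size_um
            for ang in angles:
                for frac in np.linspace(0.25, 1.0, 6):
                    px_ = cx + frac * length * np.cos(ang)
                    py_ = cy + frac * length * np.sin(ang)
                    blob += 0.12 * np.exp(
                        -((sub_x - px_) ** 2 + (sub_y - py_) ** 2)
                        / (2 * psig ** 2))
        g_map[lo_y:hi_y, lo_x:hi_x] += cell.pool.g * blob
        r_map[lo_y:hi_y, lo_x:hi_x] += cell.pool.r * blob
    return g_map, r_map


# ---------------------------------------------------------------------------
# hyperspectral conversion series
# ---------------------------------------------------------------------------


@dataclass
class HyperspectralStack:
    """(scan, y, x, wavelength) stack with axis metadata."""

    data: np.ndarray
    wavelength_axis: WavelengthGrid
    scan_period_s: float = DEFAULT_SCAN_PERIOD_S
    n_baseline_scans: int = DEFAULT_N_BASELINE_SCANS
    roi_px: tuple[slice, slice] | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("stack must be (scan, y, x, wavelength)")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("stack data must be finite and non-negative")


def _rect_to_px(rect_um: tuple[float, float, float, float],
                px_size_um: float, n_px: int) -> tuple[slice, slice]:
    """(x0, y0, x1, y1) µm rectangle → (row slice, col slice)."""
    x0, y0, x1, y1 = rect_um
    c0, c1 = int(np.floor(x0 / px_size_um)), int(np.ceil(x1 / px_size_um))
    r0, r1 = int(np.floor(y0 / px_size_um)), int(np.ceil(y1 / px_size_um))
    if not (0 <= c0 < c1 <= n_px and 0 <= r0 < r1 <= n_px):
        raise ValueError("ROI lies outside the imaged field")
    return slice(r0, r1), slice(c0, c1)


def simulate_conversion_series(
    scene: RetinaScene,
    roi_um: tuple[float, float, float, float],
    protocol: IlluminationProtocol,
    rates: KineticRates = KineticRates(),
    noise: NoiseModel = NoiseModel(),
    n_scans: int = 40,
    n_baseline: int = DEFAULT_N_BASELINE_SCANS,
    scan_period_s: float = DEFAULT_SCAN_PERIOD_S,
    px_size_um: float = 4.0,
    grid: WavelengthGrid | None = None,
    imaging_irradiance_w_cm2: float = 0.02,
    references: list | None = None,
) -> HyperspectralStack:
    """Render a hyperspectral stack of a photoconversion time series.

    Every scan exposes the whole field to the 488-nm imaging beam
    (bleaching only); from scan ``n_baseline`` onward the 405-nm beam
    additionally converts pixels inside ``roi_um``.  Each pixel's spectrum
    is the combined 488- and 561-nm-excited emission of its local pool,
    through the respective long-pass detection filters.

    The photokinetic system is linear in the pool, so the per-pixel state
    is a shared (inside-ROI / outside-ROI) trajectory scaled by the
    pixel's rendered protein density.
    """
    grid = grid or WavelengthGrid()
    refs = references or pp.build_reference_spectra(grid)
    n_px = int(round(scene.field_um / px_size_um))
    roi = _rect_to_px(roi_um, px_size_um, n_px)
    g_map, _ = _render_cell_maps(scene, px_size_um)
    roi_mask = np.zeros((n_px, n_px), dtype=bool)
    roi_mask[roi] = True

    I405 = pp.irradiance(protocol,
                         at_retina=protocol.transmittance < 1.0)
    # unit-pool fractional trajectories (shared by all pixels of a region)
    in_state = DendraPool(g=1.0)
    out_state = DendraPool(g=1.0)
    rng = np.random.default_rng(
        np.random.SeedSequence([scene.rng_seed, 303]))

    def spectrum_of(state: DendraPool) -> np.ndarray:
        s488 = pp.emitted_spectrum(state, pp.GREEN_EX_NM, refs)
        s561 = pp.emitted_spectrum(state, pp.RED_EX_NM, refs)
        return s488 + s561

    af = next(s for s in refs if s.name == "autofluorescence")
    af_spec = noise.af_level * (
        pp.apply_filter(af.emission_curve, pp.DEFAULT_FILTERS[pp.GREEN_EX_NM],
                        grid)
        + pp.apply_filter(af.emission_curve, pp.DEFAULT_FILTERS[pp.RED_EX_NM],
                          grid))

    data = np.empty((n_scans, n_px, n_px, len(grid)), dtype=np.float32)
    for s in range(n_scans):
        spec_in = spectrum_of(in_state)
        spec_out = spectrum_of(out_state)
        frame = (g_map * roi_mask)[..., None] * spec_in \
            + (g_map * (~roi_mask))[..., None] * spec_out \
            + af_spec
        data[s] = noise.apply(frame, rng)
        # advance pools through this scan's exposure
        for state, converting in ((in_state, s >= n_baseline),
                                  (out_state, False)):
            traj = pp._integrate(
                state, rates.k_conv if converting else rates.k_conv_488,
                rates.k_bleach_g, rates.k_bleach_r,
                imaging_irradiance_w_cm2 + (I405 if converting else 0.0),
                scan_period_s, dt_s=scan_period_s / 10.0)
            f = traj.final
            state.g, state.r, state.bleached = f.g, f.r, f.bleached
    return HyperspectralStack(data=data, wavelength_axis=grid,
                              scan_period_s=scan_period_s,
                              n_baseline_scans=n_baseline, roi_px=roi)


# ---------------------------------------------------------------------------
# longitudinal two-channel frames
# ---------------------------------------------------------------------------


@dataclass
class FrameSeries:
    """Green/red channel time-lapse with timestamps in hours."""

    times_h: np.ndarray
    green: list[np.ndarray]
    red: list[np.ndarray]
    px_size_um: float
    conversion_region_um: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if not (len(self.times_h) == len(self.green) == len(self.red)):
            raise ValueError("times and frames must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def _render_channels(scene: RetinaScene, px_size_um: float,
                     noise: NoiseModel, rng: np.random.Generator,
                     brightness_r: float = 2.0
                     ) -> tuple[np.ndarray, np.ndarray]:
    g_map, r_map = _render_cell_maps(scene, px_size_um, rng=rng)
    r_map = brightness_r * r_map
    green = g_map + noise.af_level + noise.red_into_green * r_map
    red = r_map + noise.af_level + noise.green_into_red * g_map
    return noise.apply(green, rng), noise.apply(red, rng)


def _in_rect(xy: tuple[float, float],
             rect: tuple[float, float, float, float]) -> bool:
    x, y = xy
    return rect[0] <= x <= rect[2] and rect[1] <= y <= rect[3]


def simulate_longitudinal(
    scene: RetinaScene,
    roi_um: tuple[float, float, float, float],
    protocol: IlluminationProtocol = pp.IN_VIVO_LOCAL,
    rates: KineticRates = KineticRates(),
    days: int = 7,
    scenario: str = "healthy",
    noise: NoiseModel = NoiseModel(),
    px_size_um: float = 8.0,
    migration_speed_um_h: float = 10.0,
    cluster_radius_um: float | None = None,
    disperse_after_day: int = 7,
    infiltration_per_day: int = 4,
) -> tuple[FrameSeries, RetinaScene]:
    """Day-scale two-channel series for one experimental scenario.

    Day 0: cells whose soma lies in ``roi_um`` are photoconverted.  Each
    subsequent day applies protein turnover to every cell, then the
    scenario dynamics:

    * ``healthy`` — nothing else; red decays by turnover alone.
    * ``injury`` — converted cells take drift-biased random-walk steps
      toward the injury center (default 10 µm/h), clustering within the
      damage locus by ~3 days and dispersing back after ``disperse_after_day``.
      Cell count is conserved throughout (no cell loss).
    * ``degeneration`` — from day 1, green-only (unconverted) cells
      infiltrate at vessel positions, emulating monocyte extravasation.

    The first frame (t = −1 h) is the pre-conversion baseline.  Returns the
    series and the evolved scene (ground truth for validation).
    """
    if scenario not in ("healthy", "injury", "degeneration"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "injury" and scene.injury is None:
        raise ValueError("injury scenario requires a scene with an injury "
                         "site")
    scene = dataclasses.replace(
        scene, cells=[dataclasses.replace(c, pool=dataclasses.replace(c.pool),
                                          trajectory=list(c.trajectory))
                      for c in scene.cells])
    rng = np.random.default_rng(np.random.SeedSequence([scene.rng_seed, 404]))
    render_rng = np.random.default_rng(
        np.random.SeedSequence([scene.rng_seed, 405]))

    times_h: list[float] = []
    greens: list[np.ndarray] = []
    reds: list[np.ndarray] = []

    def snapshot(t_h: float) -> None:
        g, r = _render_channels(scene, px_size_um, noise, render_rng)
        times_h.append(t_h)
        greens.append(g)
        reds.append(r)
        for c in scene.cells:
            c.trajectory.append((t_h, c.soma_xy_um))

    snapshot(-1.0)  # pre-conversion baseline

    converted_ids = set()
    for cell in scene.cells:
        if _in_rect(cell.soma_xy_um, roi_um):
            traj = pp.photoconvert(cell.pool, rates, protocol, dt_s=1.0)
            f = traj.final
            cell.pool.g, cell.pool.r, cell.pool.bleached = f.g, f.r, f.bleached
            converted_ids.add(cell.id)
    snapshot(0.0)

    if scene.injury is not None:
        (inj_x, inj_y), inj_diam = scene.injury
        locus_radius = (cluster_radius_um if cluster_radius_um is not None
                        else inj_diam / 2.0)

    for day in range(1, days + 1):
        for cell in scene.cells:
            f = pp.turnover(cell.pool, 1.0, rates).final
            cell.pool.g, cell.pool.r, cell.pool.bleached = f.g, f.r, f.bleached
        if scenario == "injury":
            step_um = migration_speed_um_h * 24.0
            for cell in scene.cells:
                if cell.id not in converted_ids:
                    continue
                if day <= disperse_after_day:
                    target = (inj_x, inj_y)
                    stop = locus_radius * 0.8
                else:
                    target = cell.home_xy_um
                    stop = 5.0
                x, y = cell.soma_xy_um
                dx, dy = target[0] - x, target[1] - y
                d = float(np.hypot(dx, dy))
                travel = min(step_um, max(d - stop, 0.0))
                if d > 0 and travel > 0:
                    jitter = rng.normal(0.0, 3.0, size=2)
                    x += travel * dx / d + jitter[0]
                    y += travel * dy / d + jitter[1]
                    cell.soma_xy_um = (float(np.clip(x, 0, scene.field_um)),
                                       float(np.clip(y, 0, scene.field_um)))
                in_locus = (np.hypot(cell.soma_xy_um[0] - inj_x,
                                     cell.soma_xy_um[1] - inj_y)
                            <= locus_radius)
                cell.morphology = ("amoeboid"
                                   if in_locus and day <= disperse_after_day
                                   else "ramified")
        elif scenario == "degeneration":
            vessel_yx = np.argwhere(scene.vessel_mask)
            scale = scene.field_um / scene.vessel_mask.shape[0]
            next_id = max((c.id for c in scene.cells), default=-1) + 1
            for _ in range(infiltration_per_day):
                yx = vessel_yx[rng.integers(len(vessel_yx))]
                pos = (float(yx[1] * scale + rng.normal(0, 5)),
                       float(yx[0] * scale + rng.normal(0, 5)))
                pos = (float(np.clip(pos[0], 0, scene.field_um)),
                       float(np.clip(pos[1], 0, scene.field_um)))
                expr = 2.0  # infiltrating monocytes appear bright green
                scene.cells.append(Cell(
                    id=next_id, soma_xy_um=pos, morphology="amoeboid",
                    pool=DendraPool(g=expr), origin="infiltrating",
                    expression=expr))
                next_id += 1
        snapshot(day * 24.0)

    series = FrameSeries(times_h=np.asarray(times_h), green=greens, red=reds,
                         px_size_um=px_size_um, conversion_region_um=roi_um)
    return series, scene


# ---------------------------------------------------------------------------
# flow cytometry events
# ---------------------------------------------------------------------------

FLOW_CHANNELS = ["fsc_a", "fsc_h", "ssc_a", "viability", "cd45", "cd11b",
                 "green", "red"]

POPULATIONS = ["gD2_microglia", "rD2_microglia", "peripheral_monocyte",
               "debris", "doublet", "dead"]

# log-normal channel medians and log-sigmas per population
_CHANNEL_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "gD2_microglia": {
        "fsc_a": (5e4, 0.20), "ssc_a": (2e4, 0.25), "viability": (200, 0.5),
        "cd45": (5e3, 0.40), "cd11b": (5e3, 0.40),
        "green": (1e4, 0.35), "red": (30, 0.4),
    },
    "rD2_microglia": {
        "fsc_a": (5e4, 0.20), "ssc_a": (2e4, 0.25), "viability": (200, 0.5),
        "cd45": (5e3, 0.40), "cd11b": (5e3, 0.40),
        # residual green: conversion never consumes all gD2
        "green": (3e3, 0.35), "red": (2e4, 0.35),
    },
    "peripheral_monocyte": {
        "fsc_a": (6e4, 0.20), "ssc_a": (3e4, 0.25), "viability": (200, 0.5),
        "cd45": (8e3, 0.40), "cd11b": (5e3, 0.40),
        "green": (300, 0.5), "red": (30, 0.4),
    },
    "debris": {
        "fsc_a": (5e3, 0.45), "ssc_a": (3e3, 0.45), "viability": (300, 0.6),
        "cd45": (100, 0.6), "cd11b": (100, 0.6),
        "green": (80, 0.6), "red": (30, 0.4),
    },
    "doublet": {
        "fsc_a": (1e5, 0.20), "ssc_a": (4e4, 0.25), "viability": (250, 0.5),
        "cd45": (6e3, 0.40), "cd11b": (6e3, 0.40),
        "green": (1.2e4, 0.40), "red": (100, 0.7),
    },
    "dead": {
        "fsc_a": (4e4, 0.30), "ssc_a": (2.5e4, 0.30), "viability": (2e4, 0.3),
        "cd45": (3e3, 0.50), "cd11b": (3e3, 0.50),
        "green": (4e3, 0.60), "red": (300, 0.8),
    },
}


@dataclass(frozen=True)
class PopulationSpec:
    """Target event-class fractions; the remainder (if fractions sum to
    < 1) is assigned to debris."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        for name, frac in self.fractions.items():
            if name not in POPULATIONS:
                raise ValueError(f"unknown population {name!r}")
            if frac < 0:
                raise ValueError(f"negative fraction for {name}")
        if sum(self.fractions.values()) > 1.0 + 1e-9:
            raise ValueError("population fractions must sum to ≤ 1")

    def full_fractions(self) -> dict[str, float]:
        out = {name: self.fractions.get(name, 0.0) for name in POPULATIONS}
        out["debris"] += max(0.0, 1.0 - sum(out.values()))
        return out

    @property
    def rd2_fraction_of_microglia(self) -> float:
        micro = (self.fractions.get("gD2_microglia", 0.0)
                 + self.fractions.get("rD2_microglia", 0.0))
        if micro == 0:
            return 0.0
        return self.fractions.get("rD2_microglia", 0.0) / micro


def _microglia_spec(rd2_fraction: float, microglia_total: float = 0.30
                    ) -> PopulationSpec:
    return PopulationSpec({
        "gD2_microglia": microglia_total * (1.0 - rd2_fraction),
        "rD2_microglia": microglia_total * rd2_fraction,
        "peripheral_monocyte": 0.02,
        "dead": 0.10,
        "doublet": 0.08,
        "debris": 0.50,
    })


#: converted retina: 16 % of gated microglia are rD2-positive
CONVERTED_SPEC = _microglia_spec(0.16)
#: unconverted control: no converted cells; red positives arise only from
#: bleedthrough/noise tails
UNCONVERTED_SPEC = _microglia_spec(0.0)
#: degenerating retina, 24/48 h after conversion: same stable rD2 fraction,
#: with an enlarged infiltrating-monocyte population
DEGENERATING_SPEC = PopulationSpec({
    "gD2_microglia": 0.30 * 0.84, "rD2_microglia": 0.30 * 0.16,
    "peripheral_monocyte": 0.06, "dead": 0.12, "doublet": 0.08,
    "debris": 0.44,
})


@dataclass
class FlowEventTable:
    """Per-event channel intensities plus simulator ground-truth labels.

    ``events`` holds the measurement channels only; ``true_population``
    is kept separately so gating can never peek at it.
    """

    events: pd.DataFrame
    true_population: pd.Series

    def __post_init__(self) -> None:
        missing = [c for c in FLOW_CHANNELS if c not in self.events.columns]
        if missing:
            raise ValueError(f"missing flow channels: {missing}")

    def __len__(self) -> int:
        return len(self.events)


def generate_flow_sample(spec: PopulationSpec = CONVERTED_SPEC,
                         n_events: int = DEFAULT_N_EVENTS,
                         noise: NoiseModel = NoiseModel(),
                         seed: int = 0) -> FlowEventTable:
    """Draw one flow-cytometry sample (one retina's worth of events).

    Populations are multinomially assigned and each channel drawn from a
    population-specific log-normal cluster.  Doublets carry fsc_a ≫ fsc_h;
    dead cells a high viability-dye signal; rD2 microglia are green/red
    double positive (residual green protein survives conversion); spectral
    bleedthrough couples the green and red channels linearly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    fracs = spec.full_fractions()
    labels = rng.choice(POPULATIONS, size=n_events,
                        p=[fracs[p] for p in POPULATIONS])
    data = {c: np.empty(n_events) for c in FLOW_CHANNELS}
    for pop in POPULATIONS:
        idx = np.flatnonzero(labels == pop)
        if len(idx) == 0:
            continue
        params = _CHANNEL_PARAMS[pop]
        for ch, (median, sigma) in params.items():
            data[ch][idx] = rng.lognormal(np.log(median), sigma, len(idx))
        ratio = 2.0 if pop == "doublet" else 1.0  # fsc_a/fsc_h area:height
        data["fsc_h"][idx] = (data["fsc_a"][idx] / ratio
                              * rng.lognormal(0.0, 0.05, len(idx)))
    # linear spectral bleedthrough between fluorescence channels
    g0, r0 = data["green"].copy(), data["red"].copy()
    bleed_rng = rng.lognormal(0.0, 0.6, n_events)
    data["red"] = r0 + noise.green_into_red * g0 * bleed_rng
    data["green"] = g0 + noise.red_into_green * r0 * bleed_rng
    events = pd.DataFrame(data)[FLOW_CHANNELS]
    return FlowEventTable(events=events,
                          true_population=pd.Series(labels,
                                                    name="true_population"))


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_stack(stack: HyperspectralStack, tiff_path, json_path) -> None:
    """Multi-page TIFF (scan-major) plus sidecar JSON metadata."""
    import json

    import tifffile

    n_scans, h, w, n_wl = stack.data.shape
    # page per scan; wavelengths unrolled along the fast axis
    tifffile.imwrite(tiff_path, stack.data.reshape(n_scans, h, w * n_wl))
    meta = {
        "wavelength_start_nm": stack.wavelength_axis.start_nm,
        "wavelength_stop_nm": stack.wavelength_axis.stop_nm,
        "wavelength_step_nm": stack.wavelength_axis.step_nm,
        "scan_period_s": stack.scan_period_s,
        "n_baseline_scans": stack.n_baseline_scans,
        "shape": list(stack.data.shape),
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def read_stack(tiff_path, json_path) -> HyperspectralStack:
    import json

    import tifffile

    with open(json_path) as fh:
        meta = json.load(fh)
    n_scans, h, w, n_wl = meta["shape"]
    data = tifffile.imread(tiff_path).reshape(n_scans, h, w, n_wl)
    grid = WavelengthGrid(meta["wavelength_start_nm"],
                          meta["wavelength_stop_nm"],
                          meta["wavelength_step_nm"])
    return HyperspectralStack(data=data, wavelength_axis=grid,
                              scan_period_s=meta["scan_period_s"],
                              n_baseline_scans=meta["n_baseline_scans"])


def write_frames(series: FrameSeries, directory) -> None:
    """Per-channel, per-timepoint TIFFs plus a times CSV."""
    from pathlib import Path

    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, t in enumerate(series.times_h):
        tifffile.imwrite(directory / f"green_{i:03d}.tif",
                         series.green[i].astype(np.float32))
        tifffile.imwrite(directory / f"red_{i:03d}.tif",
                         series.red[i].astype(np.float32))
    pd.DataFrame({"index": range(len(series.times_h)),
                  "time_h": series.times_h}).to_csv(
        directory / "times.csv", index=False)


def write_flow_sample(table: FlowEventTable, events_csv,
                      labels_csv=None) -> None:
    """Events CSV (channels only); ground-truth labels to a separate file
    so analysis inputs stay blind."""
    table.events.to_csv(events_csv, index=False)
    if labels_csv is not None:
        table.true_population.to_frame().to_csv(labels_csv, index=False)


def read_flow_sample(events_csv, labels_csv=None) -> FlowEventTable:
    events = pd.read_csv(events_csv)
    if labels_csv is not None:
        labels = pd.read_csv(labels_csv)["true_population"]
    else:
        labels = pd.Series(["unknown"] * len(events), name="true_population")
    return FlowEventTable(events=events, true_population=labels)
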