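"""Synthetic dual-reporter tissue generator with ground truth.

Forward model: every cell expresses a convertible nuclear label and a
constitutive membrane label at 1:1 stoichiometry. Photoconversion moves a
fraction ``p_conv`` of the unconverted nuclear pool into the converted pool
for cells inside the illuminated region. The converted pool is long-lived
and only diluted: at each division the two daughters partition it (mean
half/half), while the unconverted pool is reset to the steady-state
synthesis level. Frames are rendered as Gaussian nuclear blobs plus
Voronoi-boundary membrane ridges, followed by PSF blur, Poisson shot noise,
a camera offset and Gaussian read noise.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import ChannelStack

CHANNEL_ORDER = ("membrane", "nuclear_unconverted", "nuclear_converted")


# ---------------------------------------------------------------------------
# cell and scenario state
# ---------------------------------------------------------------------------


@dataclass
class CellState:
    """One cell: position, label pools, and lineage bookkeeping."""

    id: int
    position: np.ndarray  # (y, x) in micrometres
    radius_um: float
    converted_pool: float
    unconverted_pool: float
    membrane_pool: float
    division_count: int = 0
    parent: int | None = None
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64)
        if self.converted_pool < 0 or self.unconverted_pool < 0 or self.membrane_pool < 0:
            raise ValueError("pools must be non-negative")
        if self.division_count < 0:
            raise ValueError("division_count must be >= 0")


@dataclass
class StripeRegion:
    """Band ``|x - center_x| <= width/2`` (photoconversion stripe)."""

    center_x: float
    width_um: float

    def __post_init__(self) -> None:
        if self.width_um <= 0:
            raise ValueError("stripe width must be > 0")

    def contains(self, position: np.ndarray) -> bool:
        return abs(float(position[1]) - self.center_x) <= self.width_um / 2


@dataclass
class SphereRegion:
    """Disc of given radius around a (y, x) center."""

    center: tuple[float, float]
    radius_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("sphere radius must be > 0")

    def contains(self, position: np.ndarray) -> bool:
        d = np.asarray(position, dtype=float) - np.asarray(self.center, dtype=float)
        return float(np.hypot(*d)) <= self.radius_um


@dataclass
class Optics:
    """Point-spread and camera noise parameters."""

    psf_sigma_um: float = 0.5
    gain: float = 0.0  # 0 disables Poisson shot noise
    read_noise_sigma: float = 0.0
    offset: float = 0.0


@dataclass
class Scenario:
    name: str
    field_um: tuple[float, float] = (200.0, 200.0)
    pixel_size_um: float = 1.0
    n_founders: int = 3
    n_bystanders: int = 0
    frames: int = 1
    time_step_min: float = 30.0
    region: StripeRegion | SphereRegion | None = None
    p_conv: float = 0.95
    # endpoint mode: latent per-cell division classes (count, proportion)
    division_classes: tuple[tuple[int, float], ...] = ()
    # time-lapse mode: cell id -> frame at which its daughters first appear
    division_frames: dict[int, int] = field(default_factory=dict)
    founder_positions: tuple[tuple[float, float], ...] | None = None
    motion_sigma_um: float = 0.0
    drift_um: tuple[float, float] = (0.0, 0.0)
    optics: Optics = field(default_factory=Optics)
    nuclear_radius_um: float = 2.5
    min_dist_um: float = 16.0
    pool0: float = 800.0
    membrane_pool: float = 60.0
    partition_cv: float = 0.05
    decay_rate_per_min: float = 0.0
    # keep-out buffer around the conversion region when placing bystanders,
    # so membrane ridges of unlabeled neighbours never cross converted blobs
    bystander_buffer_um: float = 0.0
    # optional "guide cells": undivided cells laid out on a line, even spacing
    guide_cells: int = 0
    guide_spacing_um: float = 30.0
    guide_jitter_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_conv <= 1.0:
            raise ValueError("p_conv must be in [0, 1]")
        if self.division_classes:
            total = sum(p for _, p in self.division_classes)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("division class proportions must sum to 1")
        if self.nuclear_radius_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("sizes must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region"] = None if self.region is None else {
            "kind": type(self.region).__name__,
            **dataclasses.asdict(self.region),
        }
        return d


@dataclass
class GroundTruth:
    """Per-frame true cell states plus lineage edges; the downstream oracle."""

    cells: pd.DataFrame  # frame, id, y_um, x_um, converted_pool, unconverted_pool,
    #                      division_count, converted
    lineage: list[tuple[int, int, int]]  # (parent id, child id, frame of division)
    scenario: Scenario

    def frame_cells(self, t: int) -> pd.DataFrame:
        return self.cells[self.cells["frame"] == t].reset_index(drop=True)

    def lineage_dict(self) -> dict:
        return {
            "edges": [
                {"parent": int(p), "child": int(c), "frame": int(f)}
                for p, c, f in self.lineage
            ]
        }


# ---------------------------------------------------------------------------
# biology primitives
# ---------------------------------------------------------------------------


def apply_photoconversion(
    cells: list[CellState],
    region: StripeRegion | SphereRegion,
    p_conv: float,
) -> list[CellState]:
    """Convert a fraction of the unconverted pool for cells inside ``region``.

    The per-cell total pool (converted + unconverted) is conserved exactly;
    cells outside the region are untouched. Mutates and returns ``cells``.
    """
    if not 0.0 <= p_conv <= 1.0:
        raise ValueError("p_conv must be in [0, 1]")
    for cell in cells:
        if region.contains(cell.position):
            moved = p_conv * cell.unconverted_pool
            cell.converted_pool += moved
            cell.unconverted_pool -= moved
    return cells


def draw_partition_fraction(partition_cv: float, rng: np.random.Generator) -> float:
    """Daughter fraction f ~ N(0.5, 0.5*cv) truncated to the open unit interval."""
    if partition_cv < 0:
        raise ValueError("partition_cv must be >= 0")
    f = float(rng.normal(0.5, 0.5 * partition_cv))
    while not 0.0 < f < 1.0:
        f = float(rng.normal(0.5, 0.5 * partition_cv))
    return f


def advance_division(
    parent: CellState,
    partition_cv: float,
    rng: np.random.Generator,
    steady_state_unconverted: float = 0.0,
    id_counter: itertools.count | None = None,
    lineage: list[tuple[int, int, int]] | None = None,
    frame: int = 0,
) -> tuple[CellState, CellState]:
    """Split a parent cell into two daughters.

    The converted pool is partitioned (fractions ``f`` and ``1 - f``, exact
    conservation); the unconverted pool of each daughter is reset to the
    steady-state synthesis level; division counts increment; a lineage edge
    per daughter is appended to ``lineage`` when given.
    """
    if not parent.alive:
        raise ValueError("cannot divide a dead cell")
    f = draw_partition_fraction(partition_cv, rng)
    ids = id_counter if id_counter is not None else itertools.count(parent.id * 2 + 1)
    daughters = []
    for frac in (f, 1.0 - f):
        child = CellState(
            id=next(ids),
            position=parent.position.copy(),
            radius_um=parent.radius_um,
            converted_pool=parent.converted_pool * frac,
            unconverted_pool=steady_state_unconverted,
            membrane_pool=parent.membrane_pool,
            division_count=parent.division_count + 1,
            parent=parent.id,
        )
        daughters.append(child)
        if lineage is not None:
            lineage.append((parent.id, child.id, frame))
    parent.alive = False
    return daughters[0], daughters[1]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _stamp_gaussian(img: np.ndarray, cy: float, cx: float, sigma: float, amplitude: float) -> None:
    if amplitude <= 0:
        return
    h, w = img.shape
    r = int(np.ceil(3 * sigma))  # shared truncation keeps pool->signal proportionality exact
    y0, y1 = max(0, int(np.floor(cy)) - r), min(h, int(np.floor(cy)) + r + 1)
    x0, x1 = max(0, int(np.floor(cx)) - r), min(w, int(np.floor(cx)) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)[:, None] - cy
    xx = np.arange(x0, x1)[None, :] - cx
    img[y0:y1, x0:x1] += amplitude * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))


def nearest_cell_labels(
    positions_px: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Per-pixel index of the nearest cell center (pixel-seeded Voronoi)."""
    seeds = np.zeros(shape, dtype=bool)
    iy = np.clip(np.round(positions_px[:, 0]).astype(int), 0, shape[0] - 1)
    ix = np.clip(np.round(positions_px[:, 1]).astype(int), 0, shape[1] - 1)
    seed_img = np.full(shape, -1, dtype=np.int64)
    seed_img[iy, ix] = np.arange(len(positions_px))
    seeds[iy, ix] = True
    _, (ny, nx) = ndimage.distance_transform_edt(~seeds, return_indices=True)
    return seed_img[ny, nx]


def voronoi_ridge_mask(labels: np.ndarray) -> np.ndarray:
    """Pixels adjacent (4-neighbour) to a pixel of a different Voronoi cell."""
    ridge = np.zeros(labels.shape, dtype=bool)
    ridge[:-1, :] |= labels[:-1, :] != labels[1:, :]
    ridge[1:, :] |= labels[:-1, :] != labels[1:, :]
    ridge[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    ridge[:, 1:] |= labels[:, :-1] != labels[:, 1:]
    return ridge


def render_frame(
    cells: list[CellState],
    field_um: tuple[float, float],
    pixel_size_um: float,
    optics: Optics,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one (c, z=1, y, x) frame for the live cells.

    Nuclei are Gaussian blobs (sigma = nuclear radius, peak = pool) in the
    matching nuclear channel; membranes are ridges on the boundaries of the
    nearest-nucleus partition, scaled by the local cell's membrane pool.
    """
    h = int(round(field_um[0] / pixel_size_um))
    w = int(round(field_um[1] / pixel_size_um))
    live = [c for c in cells if c.alive]
    channels = {role: np.zeros((h, w)) for role in CHANNEL_ORDER}

    for cell in live:
        cy, cx = cell.position / pixel_size_um
        sigma = cell.radius_um / pixel_size_um
        _stamp_gaussian(channels["nuclear_unconverted"], cy, cx, sigma, cell.unconverted_pool)
        _stamp_gaussian(channels["nuclear_converted"], cy, cx, sigma, cell.converted_pool)

    if live:
        pos_px = np.array([c.position for c in live]) / pixel_size_um
        owner = nearest_cell_labels(pos_px, (h, w))
        ridge = voronoi_ridge_mask(owner)
        pools = np.array([c.membrane_pool for c in live])
        channels["membrane"][ridge] = pools[owner[ridge]]

    frame = np.stack([channels[r] for r in CHANNEL_ORDER])[:, None]  # (c, 1, y, x)

    if optics.psf_sigma_um > 0:
        sig = optics.psf_sigma_um / pixel_size_um
        for c in range(frame.shape[0]):
            frame[c, 0] = ndimage.gaussian_filter(frame[c, 0], sig)
    if optics.gain > 0:
        frame = rng.poisson(frame / optics.gain) * optics.gain
    frame = frame + optics.offset
    if optics.read_noise_sigma > 0:
        frame = frame + rng.normal(0.0, optics.read_noise_sigma, frame.shape)
    return np.clip(frame, 0.0, None)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def _place_points(
    n: int,
    field_um: tuple[float, float],
    min_dist_um: float,
    rng: np.random.Generator,
    margin_um: float,
    existing: list[np.ndarray] | None = None,
    exclude_region=None,
) -> list[np.ndarray]:
    """Rejection-sample n points with a minimum pairwise distance."""
    cell = max(min_dist_um, 1e-6)
    grid: dict[tuple[int, int], list[np.ndarray]] = {}

    def add_to_grid(p):
        grid.setdefault((int(p[0] // cell), int(p[1] // cell)), []).append(p)

    def ok(p):
        gy, gx = int(p[0] // cell), int(p[1] // cell)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for q in grid.get((gy + dy, gx + dx), ()):
                    if np.hypot(*(p - q)) < min_dist_um:
                        return False
        return True

    for p in existing or []:
        add_to_grid(np.asarray(p, dtype=float))

    points: list[np.ndarray] = []
    attempts = 0
    max_attempts = 2000 * n + 10000
    while len(points) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} points at min_dist {min_dist_um} in field {field_um}"
            )
        p = np.array(
            [
                rng.uniform(margin_um, field_um[0] - margin_um),
                rng.uniform(margin_um, field_um[1] - margin_um),
            ]
        )
        if exclude_region is not None and exclude_region.contains(p):
            continue
        if ok(p):
            points.append(p)
            add_to_grid(p)
    return points


# ---------------------------------------------------------------------------
# scenario presets and simulation
# ---------------------------------------------------------------------------

PRESETS = ("gastrulation_videoS1", "regeneration_7dpa")

# Time-lapse fixture: three photoconverted founders inside a small disc;
# founders 0 and 1 divide between the first two frames, founder 2 mid-movie.
_GASTRULATION_FOUNDERS = ((60.0, 70.0), (85.0, 105.0), (100.0, 60.0))
_GASTRULATION_DIVISION_FRAMES = {0: 1, 1: 1, 2: 4}


def scenario_preset(name: str, seed: int = 0, no_noise: bool = False, **overrides) -> Scenario:
    """Build a named scenario with optional field overrides."""
    if name == "gastrulation_videoS1":
        params = dict(
            name=name,
            field_um=(160.0, 160.0),
            pixel_size_um=1.0,
            n_founders=3,
            n_bystanders=12,
            frames=13,
            time_step_min=30.0,
            region=SphereRegion(center=(80.0, 80.0), radius_um=30.0),
            bystander_buffer_um=30.0,
            founder_positions=_GASTRULATION_FOUNDERS,
            division_frames=dict(_GASTRULATION_DIVISION_FRAMES),
            motion_sigma_um=0.5,
            optics=Optics(psf_sigma_um=0.5, gain=0.0, read_noise_sigma=0.0, offset=0.0),
            nuclear_radius_um=2.5,
            min_dist_um=12.0,
            pool0=800.0,
            partition_cv=0.05,
            seed=seed,
        )
    elif name == "regeneration_7dpa":
        params = dict(
            name=name,
            field_um=(1250.0, 1250.0),
            pixel_size_um=1.0,
            n_founders=1500,
            n_bystanders=300,
            frames=1,
            region=StripeRegion(center_x=625.0, width_um=100.0),
            division_classes=((0, 0.10), (2, 0.30), (5, 0.60)),
            optics=Optics(psf_sigma_um=0.5, gain=2.0, read_noise_sigma=2.0, offset=10.0),
            nuclear_radius_um=2.5,
            min_dist_um=20.0,
            pool0=800.0,
            partition_cv=0.05,
            seed=seed,
        )
    else:
        raise ValueError(f"unknown scenario preset {name!r}")
    params.update(overrides)
    scenario = Scenario(**params)
    if no_noise:
        scenario.optics = Optics(
            psf_sigma_um=scenario.optics.psf_sigma_um, gain=0.0, read_noise_sigma=0.0, offset=0.0
        )
    return scenario


def _simulate_endpoint(scenario: Scenario, rng: np.random.Generator):
    """Single end-frame tissue: converted cells carry latent division classes."""
    # exact class counts from proportions (largest remainder)
    n = scenario.n_founders
    raw = [(d, p * n) for d, p in scenario.division_classes]
    counts = {d: int(np.floor(c)) for d, c in raw}
    short = n - sum(counts.values())
    for d, c in sorted(raw, key=lambda t: t[1] - np.floor(t[1]), reverse=True):
        if short <= 0:
            break
        counts[d] += 1
        short -= 1

    margin = 4 * scenario.nuclear_radius_um
    cells: list[CellState] = []
    next_id = itertools.count(0)

    guide_positions: list[np.ndarray] = []
    if scenario.guide_cells > 0:
        # undivided "guide" cells on a horizontal line at equal spacing
        y0 = scenario.field_um[0] / 2
        x0 = (scenario.field_um[1] - (scenario.guide_cells - 1) * scenario.guide_spacing_um) / 2
        for i in range(scenario.guide_cells):
            jitter = rng.normal(0.0, scenario.guide_jitter_um, 2) if scenario.guide_jitter_um > 0 else np.zeros(2)
            guide_positions.append(np.array([y0, x0 + i * scenario.guide_spacing_um]) + jitter)

    n_random = n + scenario.n_bystanders
    positions = _place_points(
        n_random, scenario.field_um, scenario.min_dist_um, rng, margin, existing=guide_positions
    )

    class_list = [d for d, c in sorted(counts.items()) for _ in range(c)]
    rng.shuffle(class_list)

    for pos in guide_positions:
        cells.append(
            CellState(
                id=next(next_id),
                position=pos,
                radius_um=scenario.nuclear_radius_um,
                converted_pool=scenario.p_conv * scenario.pool0,
                unconverted_pool=(1 - scenario.p_conv) * scenario.pool0,
                membrane_pool=scenario.membrane_pool,
                division_count=0,
            )
        )

    for i, pos in enumerate(positions):
        if i < n:
            d = class_list[i]
            conv = scenario.p_conv * scenario.pool0
            for _ in range(d):
                conv *= draw_partition_fraction(scenario.partition_cv, rng)
            unconv = scenario.pool0 if d > 0 else (1 - scenario.p_conv) * scenario.pool0
            cells.append(
                CellState(
                    id=next(next_id),
                    position=pos,
                    radius_um=scenario.nuclear_radius_um,
                    converted_pool=conv,
                    unconverted_pool=unconv,
                    membrane_pool=scenario.membrane_pool,
                    division_count=d,
                )
            )
        else:
            cells.append(
                CellState(
                    id=next(next_id),
                    position=pos,
                    radius_um=scenario.nuclear_radius_um,
                    converted_pool=0.0,
                    unconverted_pool=scenario.pool0,
                    membrane_pool=scenario.membrane_pool,
                    division_count=0,
                )
            )

    rows = [
        dict(
            frame=0,
            id=c.id,
            y_um=c.position[0],
            x_um=c.position[1],
            converted_pool=c.converted_pool,
            unconverted_pool=c.unconverted_pool,
            division_count=c.division_count,
            converted=c.converted_pool > 0,
        )
        for c in cells
    ]
    frame = render_frame(cells, scenario.field_um, scenario.pixel_size_um, scenario.optics, rng)
    pixels = frame[None]  # (1, c, 1, y, x)
    truth = GroundTruth(pd.DataFrame(rows), [], scenario)
    return pixels, truth


def _simulate_timelapse(scenario: Scenario, rng: np.random.Generator):
    margin = 4 * scenario.nuclear_radius_um
    next_id = itertools.count(0)
    cells: list[CellState] = []
    lineage: list[tuple[int, int, int]] = []

    founder_pos = [np.asarray(p, dtype=float) for p in (scenario.founder_positions or ())]
    if len(founder_pos) != scenario.n_founders:
        raise ValueError("founder_positions must match n_founders for time-lapse scenarios")
    for pos in founder_pos:
        cells.append(
            CellState(
                id=next(next_id),
                position=pos.copy(),
                radius_um=scenario.nuclear_radius_um,
                converted_pool=0.0,
                unconverted_pool=scenario.pool0,
                membrane_pool=scenario.membrane_pool,
            )
        )
    exclude = scenario.region
    if scenario.bystander_buffer_um > 0 and exclude is not None:
        if isinstance(exclude, SphereRegion):
            exclude = SphereRegion(exclude.center, exclude.radius_um + scenario.bystander_buffer_um)
        elif isinstance(exclude, StripeRegion):
            exclude = StripeRegion(
                exclude.center_x, exclude.width_um + 2 * scenario.bystander_buffer_um
            )
    for pos in _place_points(
        scenario.n_bystanders,
        scenario.field_um,
        scenario.min_dist_um,
        rng,
        margin,
        existing=founder_pos,
        exclude_region=exclude,
    ):
        cells.append(
            CellState(
                id=next(next_id),
                position=pos,
                radius_um=scenario.nuclear_radius_um,
                converted_pool=0.0,
                unconverted_pool=scenario.pool0,
                membrane_pool=scenario.membrane_pool,
            )
        )

    apply_photoconversion(cells, scenario.region, scenario.p_conv)

    frames = []
    rows = []
    sep = 3.2 * scenario.nuclear_radius_um  # daughter center separation
    for t in range(scenario.frames):
        if t > 0:
            for c in cells:
                if c.alive:
                    step = rng.normal(0.0, scenario.motion_sigma_um, 2) + np.asarray(
                        scenario.drift_um
                    )
                    c.position = np.clip(
                        c.position + step,
                        margin,
                        np.asarray(scenario.field_um) - margin,
                    )
            if scenario.decay_rate_per_min > 0:
                decay = np.exp(-scenario.decay_rate_per_min * scenario.time_step_min)
                for c in cells:
                    c.converted_pool *= decay
            # divisions whose daughters first appear at this frame
            for cid, when in sorted(scenario.division_frames.items()):
                if when == t:
                    parent = next(c for c in cells if c.id == cid and c.alive)
                    d1, d2 = advance_division(
                        parent,
                        scenario.partition_cv,
                        rng,
                        steady_state_unconverted=scenario.pool0,
                        id_counter=next_id,
                        lineage=lineage,
                        frame=t,
                    )
                    theta = rng.uniform(0, 2 * np.pi)
                    offset = np.array([np.sin(theta), np.cos(theta)]) * sep / 2
                    d1.position = np.clip(
                        parent.position + offset, margin, np.asarray(scenario.field_um) - margin
                    )
                    d2.position = np.clip(
                        parent.position - offset, margin, np.asarray(scenario.field_um) - margin
                    )
                    cells.extend([d1, d2])

        for c in cells:
            if c.alive:
                rows.append(
                    dict(
                        frame=t,
                        id=c.id,
                        y_um=c.position[0],
                        x_um=c.position[1],
                        converted_pool=c.converted_pool,
                        unconverted_pool=c.unconverted_pool,
                        division_count=c.division_count,
                        converted=c.converted_pool > 0,
                    )
                )
        frames.append(
            render_frame(cells, scenario.field_um, scenario.pixel_size_um, scenario.optics, rng)
        )

    pixels = np.stack(frames)
    truth = GroundTruth(pd.DataFrame(rows), lineage, scenario)
    return pixels, truth


def simulate_tissue(scenario: Scenario) -> tuple[ChannelStack, GroundTruth]:
    """Simulate a scenario; deterministic for a given scenario + seed."""
    rng = np.random.default_rng(scenario.seed)
    if scenario.frames == 1:
        pixels, truth = _simulate_endpoint(scenario, rng)
    else:
        pixels, truth = _simulate_timelapse(scenario, rng)
    stack = ChannelStack(
        pixels,
        CHANNEL_ORDER,
        (1.0, scenario.pixel_size_um, scenario.pixel_size_um),
        scenario.time_step_min if scenario.frames > 1 else None,
    )
    return stack, truth
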