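"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate the study's recording conditions — an arena explored
by a freely moving mouse filmed at 15 frames/s, deconvolved spike trains for
simultaneously imaged neurons, footshock / social / freezing event timelines,
negative-binomial marker-gene counts per transcriptomic cluster, and 2-D
smFISH cell layouts over the eight named BLA subregions — with known ground
truth attached, so every downstream stage is testable without any download.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUBREGIONS",
    "SECTIONS",
    "SECTION_OF_SUBREGION",
    "ArenaSpec",
    "Trajectory",
    "SpikeMatrix",
    "EventTimeline",
    "SimTruth",
    "feeding_arena",
    "social_arena",
    "gen_trajectory",
    "gen_tuned_spikes",
    "gen_event_spikes",
    "gen_expression",
    "gen_fish_dataset",
    "make_tuning_truth",
    "random_profiles",
    "layout_one_per_subregion",
]

#: The eight BLA subregions, anterior to posterior, lateral (LA) then basal (BA).
SUBREGIONS = ("aLA", "pLA", "ppLA", "amBA", "alBA", "acBA", "pBA", "ppBA")

#: The four coronal sections used for smFISH.
SECTIONS = ("anterior", "anterior-middle", "posterior-middle", "posterior")

#: Simulator placement of each subregion in exactly one section (LA row on
#: top of the BA row).  The real parcellation lets subregions span sections;
#: the generator only needs named, non-overlapping tiles.
SECTION_OF_SUBREGION: Mapping[str, str] = {
    "aLA": "anterior",
    "amBA": "anterior",
    "pLA": "anterior-middle",
    "alBA": "anterior-middle",
    "ppLA": "posterior-middle",
    "acBA": "posterior-middle",
    "pBA": "posterior",
    "ppBA": "posterior",
}


class ParameterError(ValueError):
    """A generator or analysis parameter is out of its valid domain."""


class AlignmentError(ValueError):
    """Two inputs that must share a frame base do not."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of a behavioral arena and its target-centred zones.

    The *target* is the food container (feeding assay) or the centre of the
    wired cage (social assay).  ``norm_radius_cm`` is the chamber radius used
    to normalize distances to [0, 1]; ``zone_inner_cm``/``zone_outer_cm`` are
    the pro/anti zone radii (5/17 cm for food, 10/20 cm for social).
    """

    shape: str  # "circle" | "rectangle"
    center_x_cm: float = 0.0
    center_y_cm: float = 0.0
    radius_cm: float | None = None
    width_cm: float | None = None
    height_cm: float | None = None
    target_x_cm: float = 0.0
    target_y_cm: float = 0.0
    norm_radius_cm: float = 1.0
    zone_inner_cm: float = 5.0
    zone_outer_cm: float = 17.0

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "rectangle"):
            raise ParameterError(f"unknown arena shape {self.shape!r}")
        if self.shape == "circle":
            if self.radius_cm is None or self.radius_cm <= 0:
                raise ParameterError("circle arena needs radius_cm > 0")
        else:
            if (
                self.width_cm is None
                or self.height_cm is None
                or self.width_cm <= 0
                or self.height_cm <= 0
            ):
                raise ParameterError("rectangle arena needs width_cm, height_cm > 0")
        if self.norm_radius_cm <= 0:
            raise ParameterError("norm_radius_cm must be > 0")
        if not 0 < self.zone_inner_cm < self.zone_outer_cm:
            raise ParameterError("need 0 < zone_inner_cm < zone_outer_cm")
        if not self.contains(self.target_x_cm, self.target_y_cm):
            raise ParameterError("target must lie inside the arena")

    def contains(self, x, y) -> np.ndarray | bool:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.shape == "circle":
            r2 = (x - self.center_x_cm) ** 2 + (y - self.center_y_cm) ** 2
            return r2 <= self.radius_cm**2 + 1e-12
        hw, hh = self.width_cm / 2.0, self.height_cm / 2.0
        return (
            (np.abs(x - self.center_x_cm) <= hw + 1e-12)
            & (np.abs(y - self.center_y_cm) <= hh + 1e-12)
        )

    def distance_to_target(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.hypot(x - self.target_x_cm, y - self.target_y_cm)


def feeding_arena(**overrides) -> ArenaSpec:
    """Home-cage feeding arena (20 x 32.5 cm) with the food container in a
    corner; pro/anti-food radii 5/17 cm, distances normalized by 17.5 cm
    (half the cage diagonal is ~19 cm; the half long-side is used)."""
    kwargs = dict(
        shape="rectangle",
        width_cm=20.0,
        height_cm=32.5,
        target_x_cm=-8.0,
        target_y_cm=-14.0,
        norm_radius_cm=16.25,
        zone_inner_cm=5.0,
        zone_outer_cm=17.0,
    )
    kwargs.update(overrides)
    return ArenaSpec(**kwargs)


def social_arena(**overrides) -> ArenaSpec:
    """Round social arena (inner diameter 49 cm) with the wired cage at the
    centre; pro/anti-social radii 10/20 cm, distances normalized by the
    24.5 cm chamber radius."""
    kwargs = dict(
        shape="circle",
        radius_cm=24.5,
        target_x_cm=0.0,
        target_y_cm=0.0,
        norm_radius_cm=24.5,
        zone_inner_cm=10.0,
        zone_outer_cm=20.0,
    )
    kwargs.update(overrides)
    return ArenaSpec(**kwargs)


@dataclass
class Trajectory:
    """Frame-aligned 2-D position (and optional heading) of one animal."""

    x_cm: np.ndarray
    y_cm: np.ndarray
    frame_rate_hz: float = 15.0
    heading_deg: np.ndarray | None = None  # 0 = +x axis, counter-clockwise

    def __post_init__(self) -> None:
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        if self.frame_rate_hz <= 0:
            raise ParameterError("frame_rate_hz must be > 0")
        if self.x_cm.shape != self.y_cm.shape or self.x_cm.ndim != 1:
            raise ParameterError("x_cm and y_cm must be 1-D and equal length")
        if not (np.isfinite(self.x_cm).all() and np.isfinite(self.y_cm).all()):
            raise ParameterError("positions must be finite")
        if self.heading_deg is not None:
            self.heading_deg = np.asarray(self.heading_deg, dtype=float)
            if self.heading_deg.shape != self.x_cm.shape:
                raise AlignmentError("heading_deg length mismatch")

    @property
    def n_frames(self) -> int:
        return self.x_cm.size

    def to_frame(self) -> pd.DataFrame:
        d = {
            "frame_index": np.arange(self.n_frames),
            "x_cm": self.x_cm,
            "y_cm": self.y_cm,
        }
        if self.heading_deg is not None:
            d["heading_deg"] = self.heading_deg
        return pd.DataFrame(d)


@dataclass
class SpikeMatrix:
    """Nonnegative inferred spiking, neurons x frames, aligned to a Trajectory."""

    neuron_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ParameterError("counts must be 2-D (neurons x frames)")
        if len(self.neuron_ids) != self.counts.shape[0]:
            raise AlignmentError("neuron_ids length must match counts rows")
        if self.counts.size and self.counts.min() < 0:
            raise ParameterError("spike counts must be nonnegative")

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_frames(self) -> int:
        return self.counts.shape[1]


@dataclass
class EventTimeline:
    """Labelled, non-overlapping behavioral intervals in seconds."""

    events: pd.DataFrame  # columns: onset_s, offset_s, label

    VALID_LABELS = ("shock", "social", "freezing")

    def __post_init__(self) -> None:
        ev = pd.DataFrame(self.events, columns=["onset_s", "offset_s", "label"])
        if len(ev) and (ev["onset_s"] >= ev["offset_s"]).any():
            raise ParameterError("event onset_s must be < offset_s")
        for label, grp in ev.groupby("label"):
            g = grp.sort_values("onset_s")
            if (g["onset_s"].values[1:] < g["offset_s"].values[:-1]).any():
                raise ParameterError(f"overlapping {label!r} events")
        self.events = ev.sort_values("onset_s", ignore_index=True)

    def __len__(self) -> int:
        return len(self.events)

    def select(self, label: str) -> "EventTimeline":
        return EventTimeline(self.events[self.events["label"] == label])

    def check_span(self, n_frames: int, frame_rate_hz: float) -> None:
        span = n_frames / frame_rate_hz
        if len(self.events) and (
            (self.events["onset_s"] < 0).any() or (self.events["offset_s"] > span).any()
        ):
            raise ParameterError("events extend outside the recording span")

    def frame_mask(self, n_frames: int, frame_rate_hz: float, label: str | None = None) -> np.ndarray:
        """Boolean per-frame mask; intervals are half-open [onset, offset)."""
        ev = self.events if label is None else self.events[self.events["label"] == label]
        mask = np.zeros(n_frames, dtype=bool)
        for onset, offset in zip(ev["onset_s"], ev["offset_s"]):
            a = int(round(onset * frame_rate_hz))
            b = int(round(offset * frame_rate_hz))
            mask[max(a, 0) : min(b, n_frames)] = True
        return mask


@dataclass
class SimTruth:
    """Ground truth attached to a simulated dataset.

    ``neurons`` holds per-neuron tuning/responder parameters, ``cells`` the
    true transcriptomic cluster of each simulated cell.
    """

    neurons: pd.DataFrame = field(default_factory=pd.DataFrame)
    cells: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.neurons):
            for col, lo in (("baseline", 0.0), ("amplitude", 0.0)):
                if col in self.neurons and (self.neurons[col] < lo).any():
                    raise ParameterError(f"{col} must be >= {lo}")
            if "preferred_distance_norm" in self.neurons:
                d0 = self.neurons["preferred_distance_norm"].dropna()
                if ((d0 < 0) | (d0 > 1)).any():
                    raise ParameterError("preferred_distance_norm must be in [0, 1]")


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

def _reflect_circle(x: float, y: float, arena: ArenaSpec) -> tuple[float, float]:
    cx, cy, R = arena.center_x_cm, arena.center_y_cm, arena.radius_cm
    for _ in range(16):
        r = np.hypot(x - cx, y - cy)
        if r <= R:
            return x, y
        # radial reflection about the boundary circle
        scale = (2.0 * R - r) / r
        x = cx + (x - cx) * scale
        y = cy + (y - cy) * scale
    # pathological step (>> arena size): clamp to the boundary
    r = np.hypot(x - cx, y - cy)
    return cx + (x - cx) * R / r, cy + (y - cy) * R / r


def _fold(u: float, half: float) -> float:
    """Reflect a coordinate into [-half, half] (triangle-wave fold)."""
    period = 4.0 * half
    u = (u + half) % period
    if u > 2.0 * half:
        u = period - u
    return u - half


def gen_trajectory(
    arena: ArenaSpec,
    n_frames: int,
    step_sd_cm: float = 1.0,
    seed: int = 0,
    frame_rate_hz: float = 15.0,
    with_heading: bool = True,
    visit_rate_per_min: float = 2.0,
    visit_dwell_s: float = 3.0,
) -> Trajectory:
    """Reflected Gaussian random walk with intermittent target visits.

    Roaming steps are iid N(0, step_sd_cm**2) per axis, and positions
    leaving the arena are reflected back across the boundary, which keeps
    occupancy of all distance bins nonzero for long runs.  Because the
    assays being emulated are approach assays (a fasted mouse feeding at the
    container, a test mouse investigating a caged conspecific), the animal
    additionally initiates target visits at ``visit_rate_per_min``: it walks
    towards the target and dwells there for an exponential time of mean
    ``visit_dwell_s``, so near-target distance bins carry realistic
    occupancy.  Set ``visit_rate_per_min=0`` for a pure unbiased walk.
    Heading is the direction of the step into each frame.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if step_sd_cm <= 0:
        raise ParameterError("step_sd_cm must be > 0")
    if visit_rate_per_min < 0 or visit_dwell_s < 0:
        raise ParameterError("visit parameters must be >= 0")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd_cm, size=(n_frames, 2))
    u = rng.random(n_frames)
    p_visit = visit_rate_per_min / (60.0 * frame_rate_hz)
    x = np.empty(n_frames)
    y = np.empty(n_frames)
    cx, cy = arena.center_x_cm, arena.center_y_cm
    tx, ty = arena.target_x_cm, arena.target_y_cm
    circle = arena.shape == "circle"
    if not circle:
        hw, hh = arena.width_cm / 2.0, arena.height_cm / 2.0
    px, py = cx, cy  # start at the arena centre
    approach_speed = 2.0 * step_sd_cm
    dwell_left = 0  # frames left at the target; <0 means travelling there
    for i in range(n_frames):
        if dwell_left == 0 and u[i] < p_visit:
            dwell_left = -1  # start travelling towards the target
        if dwell_left < 0:
            dx, dy = tx - px, ty - py
            dist = np.hypot(dx, dy)
            if dist <= approach_speed:
                dwell_left = max(
                    1, int(round(rng.exponential(visit_dwell_s) * frame_rate_hz))
                )
                sx, sy = dx, dy
            else:
                sx = dx / dist * approach_speed + 0.25 * steps[i, 0]
                sy = dy / dist * approach_speed + 0.25 * steps[i, 1]
        elif dwell_left > 0:
            sx, sy = 0.3 * steps[i, 0], 0.3 * steps[i, 1]  # jitter at the target
            dwell_left -= 1
        else:
            sx, sy = steps[i, 0], steps[i, 1]
        if circle:
            px, py = _reflect_circle(px + sx, py + sy, arena)
        else:
            px = cx + _fold(px + sx - cx, hw)
            py = cy + _fold(py + sy - cy, hh)
        x[i], y[i] = px, py
    heading = None
    if with_heading:
        dx = np.diff(x, prepend=x[0] - steps[0, 0])
        dy = np.diff(y, prepend=y[0] - steps[0, 1])
        heading = np.degrees(np.arctan2(dy, dx))
    return Trajectory(x, y, frame_rate_hz=frame_rate_hz, heading_deg=heading)


# --------------------------------------------------------------------------
# spikes
# --------------------------------------------------------------------------

def make_tuning_truth(
    n_neurons: int,
    frac_tuned: float = 0.5,
    baseline: float = 0.2,
    amplitude: float = 0.6,
    seed: int = 0,
    d0_range: tuple[float, float] = (0.1, 0.9),
) -> SimTruth:
    """Per-neuron tuning parameters: a fraction of neurons carry a Gaussian
    bump of height ``amplitude`` (spikes/frame) at a preferred normalized
    distance drawn uniformly from ``d0_range``; the rest fire at baseline."""
    rng = np.random.default_rng(seed)
    tuned = np.zeros(n_neurons, dtype=bool)
    tuned[: int(round(frac_tuned * n_neurons))] = True
    d0 = np.where(tuned, rng.uniform(*d0_range, size=n_neurons), np.nan)
    neurons = pd.DataFrame(
        {
            "neuron_id": [f"n{i:04d}" for i in range(n_neurons)],
            "tuned": tuned,
            "preferred_distance_norm": d0,
            "amplitude": np.where(tuned, amplitude, 0.0),
            "baseline": baseline,
            "responder": False,
            "event_gain": 1.0,
        }
    )
    return SimTruth(neurons=neurons)


def gen_tuned_spikes(
    traj: Trajectory,
    arena: ArenaSpec,
    truth: SimTruth,
    seed: int = 0,
    tuning_sigma: float = 0.1,
) -> SpikeMatrix:
    """Poisson spike trains with optional Gaussian tuning to distance.

    Per-frame rate lambda(t) = baseline + amplitude * exp(-(d_norm(t) - d0)^2
    / (2 sigma^2)); counts are Poisson(lambda).
    """
    if not len(truth.neurons):
        raise ParameterError("truth has no neuron records")
    d = arena.distance_to_target(traj.x_cm, traj.y_cm)
    d_norm = np.clip(d / arena.norm_radius_cm, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    nt = truth.neurons
    base = nt["baseline"].to_numpy(float)[:, None]
    amp = nt["amplitude"].to_numpy(float)[:, None]
    d0 = np.nan_to_num(nt["preferred_distance_norm"].to_numpy(float))[:, None]
    lam = base + amp * np.exp(-((d_norm[None, :] - d0) ** 2) / (2.0 * tuning_sigma**2))
    counts = rng.poisson(lam).astype(float)
    return SpikeMatrix(list(nt["neuron_id"]), counts)


def gen_event_spikes(
    n_frames: int,
    frame_rate_hz: float,
    events: EventTimeline,
    baseline: float | Sequence[float],
    gain: float | Sequence[float],
    seed: int = 0,
    label: str | None = None,
) -> SpikeMatrix:
    """Poisson spike trains with a multiplicative rate gain inside events.

    ``baseline`` and ``gain`` may be scalars (one neuron) or equal-length
    sequences (one neuron each); rate = baseline * gain inside the event
    windows and baseline outside.
    """
    base = np.atleast_1d(np.asarray(baseline, dtype=float))
    g = np.atleast_1d(np.asarray(gain, dtype=float))
    if base.size == 1 and g.size > 1:
        base = np.full(g.size, base[0])
    if g.size == 1 and base.size > 1:
        g = np.full(base.size, g[0])
    if base.size != g.size:
        raise ParameterError("baseline and gain must have equal length")
    if (g < 0).any():
        raise ParameterError("gain must be >= 0")
    events.check_span(n_frames, frame_rate_hz)
    mask = events.frame_mask(n_frames, frame_rate_hz, label=label)
    rng = np.random.default_rng(seed)
    lam = np.where(mask[None, :], base[:, None] * g[:, None], base[:, None])
    counts = rng.poisson(lam).astype(float)
    ids = [f"n{i:04d}" for i in range(base.size)]
    return SpikeMatrix(ids, counts)


# --------------------------------------------------------------------------
# expression and smFISH
# --------------------------------------------------------------------------

def random_profiles(
    n_clusters: int,
    genes: Sequence[str] | None = None,
    n_markers_per_cluster: int = 2,
    high: float = 10.0,
    low: float = 0.1,
    seed: int = 0,
):
    """Well-separated reference cluster profiles.

    Each cluster is assigned ``n_markers_per_cluster`` (near-)exclusive
    high-mean genes over a shared low-mean floor, mimicking the handpicked
    marker panel.  Returns a :class:`blapipe.markersel.ClusterProfile`.
    """
    from .markersel import ClusterProfile

    if genes is None:
        genes = [f"g{i:02d}" for i in range(n_clusters * n_markers_per_cluster)]
    genes = list(genes)
    rng = np.random.default_rng(seed)
    agg = np.full((n_clusters, len(genes)), low)
    for c in range(n_clusters):
        for m in range(n_markers_per_cluster):
            gi = (c * n_markers_per_cluster + m) % len(genes)
            agg[c, gi] = high * (1.0 + 0.1 * rng.standard_normal())
    clusters = [f"cl{c + 1}" for c in range(n_clusters)]
    return ClusterProfile.from_aggregate(clusters, genes, agg)


def gen_expression(
    profiles,
    n_cells_per_cluster: int,
    library_scale: float = 10.0,
    dispersion: float = 10.0,
    seed: int = 0,
):
    """Negative-binomial per-cluster gene counts around the profile means.

    Per-gene mean for cluster c is ``library_scale * scaled[c, g]``; counts
    are gamma-Poisson with shape ``dispersion`` (variance m + m^2/dispersion,
    near-Poisson as dispersion grows).  Returns (ExpressionMatrix, SimTruth).
    """
    from .markersel import ExpressionMatrix

    if dispersion <= 0:
        raise ParameterError("dispersion must be > 0")
    if profiles is None or len(profiles.clusters) == 0:
        raise ParameterError("empty cluster profile")
    if n_cells_per_cluster < 0:
        raise ParameterError("n_cells_per_cluster must be >= 0")
    rng = np.random.default_rng(seed)
    means = library_scale * profiles.scaled
    rows, labels = [], []
    for ci, cl in enumerate(profiles.clusters):
        if n_cells_per_cluster == 0:
            continue
        m = np.broadcast_to(means[ci], (n_cells_per_cluster, means.shape[1]))
        lam = rng.gamma(dispersion, m / dispersion)
        rows.append(rng.poisson(lam))
        labels.extend([cl] * n_cells_per_cluster)
    counts = np.vstack(rows) if rows else np.empty((0, means.shape[1]))
    cell_ids = [f"c{i:05d}" for i in range(counts.shape[0])]
    expr = ExpressionMatrix(
        counts=counts.astype(float),
        cell_ids=cell_ids,
        gene_ids=list(profiles.genes),
        labels=pd.Series(labels, index=cell_ids, name="cluster", dtype=object),
    )
    truth = SimTruth(cells=pd.DataFrame({"cell_id": cell_ids, "cluster": labels}))
    return expr, truth


def layout_one_per_subregion(clusters: Sequence[str]) -> pd.DataFrame:
    """Subregion -> cluster mixture table placing one cluster per subregion
    (clusters are recycled if fewer than eight)."""
    clusters = list(clusters)
    mix = pd.DataFrame(0.0, index=list(SUBREGIONS), columns=clusters)
    for i, s in enumerate(SUBREGIONS):
        mix.loc[s, clusters[i % len(clusters)]] = 1.0
    return mix


# rectangular tiles per subregion, in um; LA row above BA row
_TILE_W, _TILE_H, _TILE_GAP = 1000.0, 800.0, 200.0


def _subregion_tile(subregion: str) -> tuple[float, float]:
    """(x0, y0) of the subregion's tile within its section image."""
    section = SECTION_OF_SUBREGION[subregion]
    in_la = subregion.endswith("LA")
    col = 0 if in_la else 1
    return col * (_TILE_W + _TILE_GAP), 0.0 if in_la else _TILE_H + _TILE_GAP


def gen_fish_dataset(
    profiles,
    layout: pd.DataFrame,
    n_cells: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    scale: float = 20.0,
):
    """Synthetic smFISH cell table over the eight BLA subregions.

    Cells are placed uniformly within rectangular subregion tiles across the
    four named sections; each cell draws a true cluster from its subregion's
    mixture row and a raw value vector ``scale * scaled_profile + N(0,
    noise_sd)`` clipped at zero (exactly proportional when ``noise_sd=0``).
    Returns (cell table DataFrame, SimTruth).
    """
    layout = pd.DataFrame(layout)
    row_sums = layout.to_numpy(float).sum(axis=1)
    if np.abs(row_sums - 1.0).max() > 1e-9:
        raise ParameterError("layout mixture rows must sum to 1")
    unknown = set(layout.columns) - set(profiles.clusters)
    if unknown:
        raise ParameterError(f"layout references unknown clusters {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    subs = list(layout.index)
    per = np.full(len(subs), n_cells // len(subs))
    per[: n_cells % len(subs)] += 1
    prof_row = {cl: profiles.scaled[i] for i, cl in enumerate(profiles.clusters)}
    records, values, true_cl = [], [], []
    cid = 0
    for s, n_s in zip(subs, per):
        x0, y0 = _subregion_tile(s)
        section = SECTION_OF_SUBREGION[s]
        mix = layout.loc[s].to_numpy(float)
        choices = rng.choice(len(layout.columns), size=n_s, p=mix)
        xs = rng.uniform(x0, x0 + _TILE_W, size=n_s)
        ys = rng.uniform(y0, y0 + _TILE_H, size=n_s)
        for j in range(n_s):
            cl = layout.columns[choices[j]]
            v = scale * prof_row[cl].copy()
            if noise_sd > 0:
                v = v + rng.normal(0.0, noise_sd, size=v.size)
            values.append(np.clip(v, 0.0, None))
            true_cl.append(cl)
            records.append(
                {
                    "cell_id": f"f{cid:05d}",
                    "section": section,
                    "subregion": s,
                    "x_um": xs[j],
                    "y_um": ys[j],
                }
            )
            cid += 1
    cells = pd.DataFrame(records)
    vals = (
        np.vstack(values) if values else np.empty((0, len(profiles.genes)))
    )
    for gi, g in enumerate(profiles.genes):
        cells[g] = vals[:, gi] if len(cells) else pd.Series(dtype=float)
    truth = SimTruth(
        cells=pd.DataFrame({"cell_id": cells.get("cell_id", pd.Series(dtype=object)), "cluster": true_cl})
    )
    return cells, truth
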