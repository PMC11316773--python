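"""File formats, run configuration and end-to-end orchestration.

Canonical interchange is tab-separated UTF-8 text with '.' decimals; sparse
expression may come as matrix-market triplets plus id files.  Frame indices
are 0-based and all time windows are half-open [start, end).  Percentages
serialize on the 0-100 scale; distances are cm (behavior) or um (smFISH).

``run_pipeline`` executes the demo end-to-end flow (simulate -> markers ->
spatial -> tuning -> events) and writes every result table plus a
machine-readable run manifest, so two runs with the same config and seed
produce byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import yaml

from . import __version__
from . import disttuning, eventresp, markersel, simdata, spatialmap
from .simdata import (
    AlignmentError,
    ArenaSpec,
    EventTimeline,
    ParameterError,
    SpikeMatrix,
    Trajectory,
)

__all__ = [
    "SessionBundle",
    "RunConfig",
    "read_trajectory",
    "write_trajectory",
    "read_spike_matrix",
    "write_spike_matrix",
    "read_events",
    "write_events",
    "read_fish_cells",
    "write_fish_cells",
    "read_expression",
    "write_expression",
    "read_expression_mtx",
    "load_session",
    "run_pipeline",
]

SESSION_KINDS = ("feeding", "social", "cfc", "combined")

#: Pro/anti zone radii (cm) per session kind.
ZONE_RADII = {"feeding": (5.0, 17.0), "social": (10.0, 20.0)}


class ValidationError(ValueError):
    pass


# --------------------------------------------------------------------------
# delimited readers/writers
# --------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    df = traj.to_frame()
    df.to_csv(path, sep="\t", index=False)


def read_trajectory(path, frame_rate_hz: float = 15.0) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    idx = df["frame_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(df))):
        raise ValidationError(f"{path}: frame_index must be contiguous from 0")
    heading = df["heading_deg"].to_numpy() if "heading_deg" in df else None
    return Trajectory(
        df["x_cm"].to_numpy(),
        df["y_cm"].to_numpy(),
        frame_rate_hz=frame_rate_hz,
        heading_deg=heading,
    )


def write_spike_matrix(spikes: SpikeMatrix, path) -> None:
    df = pd.DataFrame(spikes.counts, index=pd.Index(spikes.neuron_ids, name="neuron_id"))
    df.columns = [str(c) for c in range(spikes.n_frames)]
    df.to_csv(path, sep="\t")


def read_spike_matrix(path) -> SpikeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="neuron_id")
    counts = df.to_numpy(float)
    bad = np.argwhere(counts < 0)
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"{path}: negative spike value at neuron {df.index[r]!r}, frame {c}"
        )
    return SpikeMatrix([str(i) for i in df.index], counts)


def write_events(events: EventTimeline, path) -> None:
    events.events.to_csv(path, sep="\t", index=False)


def read_events(path) -> EventTimeline:
    return EventTimeline(pd.read_csv(path, sep="\t"))


def write_fish_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def read_fish_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("cell_id", "section", "subregion", "x_um", "y_um"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return df


def write_expression(expr: markersel.ExpressionMatrix, path) -> None:
    """Dense delimited matrix: header row of gene ids plus a cluster column."""
    df = pd.DataFrame(
        expr.counts, index=pd.Index(expr.cell_ids, name="cell_id"), columns=expr.gene_ids
    )
    df.insert(0, "cluster", expr.labels.values)
    df.to_csv(path, sep="\t")


def read_expression(path) -> markersel.ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="cell_id")
    if "cluster" not in df.columns:
        raise ValidationError(f"{path}: missing 'cluster' column")
    labels = df.pop("cluster").astype(str)
    return markersel.ExpressionMatrix(
        counts=df.to_numpy(float),
        cell_ids=[str(i) for i in df.index],
        gene_ids=[str(c) for c in df.columns],
        labels=labels,
    )


def read_expression_mtx(mtx_path, cells_path, genes_path) -> markersel.ExpressionMatrix:
    """Matrix-market triplets (cells x genes) plus two id files.

    The cells file is a 2-column TSV (cell_id, cluster); the genes file one
    gene id per line.
    """
    counts = np.asarray(scipy.io.mmread(mtx_path).todense(), dtype=float)
    cells = pd.read_csv(cells_path, sep="\t")
    genes = [l.strip() for l in Path(genes_path).read_text().splitlines() if l.strip()]
    return markersel.ExpressionMatrix(
        counts=counts,
        cell_ids=[str(c) for c in cells["cell_id"]],
        gene_ids=genes,
        labels=pd.Series(cells["cluster"].astype(str).values, index=[str(c) for c in cells["cell_id"]]),
    )


# --------------------------------------------------------------------------
# session bundles and config
# --------------------------------------------------------------------------

@dataclass
class SessionBundle:
    """Paths and metadata for one recorded session."""

    trajectory_path: str
    spikes_path: str
    arena: ArenaSpec
    session_kind: str = "feeding"
    events_path: str | None = None
    population: str = "pop"
    frame_rate_hz: float = 15.0

    def __post_init__(self) -> None:
        if self.session_kind not in SESSION_KINDS:
            raise ValidationError(f"unknown session kind {self.session_kind!r}")


def load_session(bundle: SessionBundle):
    """Read and align one session's trajectory, spikes and (optional) events."""
    for p in (bundle.trajectory_path, bundle.spikes_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    traj = read_trajectory(bundle.trajectory_path, bundle.frame_rate_hz)
    spikes = read_spike_matrix(bundle.spikes_path)
    if spikes.n_frames != traj.n_frames:
        raise AlignmentError(
            f"frame mismatch: spikes have {spikes.n_frames}, trajectory {traj.n_frames}"
        )
    events = None
    if bundle.events_path is not None:
        if not Path(bundle.events_path).exists():
            raise FileNotFoundError(bundle.events_path)
        events = read_events(bundle.events_path)
        events.check_span(traj.n_frames, bundle.frame_rate_hz)
    return traj, spikes, events


_ARENA_KEYS = {
    "shape",
    "center_x_cm",
    "center_y_cm",
    "radius_cm",
    "width_cm",
    "height_cm",
    "target_x_cm",
    "target_y_cm",
    "norm_radius_cm",
    "zone_inner_cm",
    "zone_outer_cm",
}

_SIM_DEFAULTS = dict(
    n_frames=3000,
    n_neurons=30,
    frac_tuned=0.5,
    baseline=0.2,
    amplitude=0.6,
    tuning_sigma=0.1,
    step_sd_cm=1.0,
    shock_onsets_s=[60.0, 100.0, 140.0],
    shock_duration_s=2.0,
    responder_gain=3.0,
    n_clusters=6,
    n_cells_per_cluster=40,
    library_scale=10.0,
    dispersion=10.0,
    n_fish_cells=400,
    fish_noise_sd=1.0,
)

_TUNING_KEYS = {"n_bins", "n_shuffles", "fdr_q", "tail", "seed"}
_SPATIAL_KEYS = {
    "neighbor_radius_um",
    "pixel_size_um",
    "smoothing_sigma_px",
    "threshold_method",
    "quantile",
    "fixed_thresholds",
}


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValidationError(f"unknown {section} key(s): {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated configuration of a full demo run (unknown keys rejected)."""

    seed: int = 0
    out_dir: str = "blapipe_out"
    tuning: disttuning.TuningConfig = field(default_factory=disttuning.TuningConfig)
    spatial: spatialmap.SpatialConfig = field(default_factory=spatialmap.SpatialConfig)
    feeding_arena: ArenaSpec = field(default_factory=simdata.feeding_arena)
    social_arena: ArenaSpec = field(default_factory=simdata.social_arena)
    sim: dict = field(default_factory=lambda: dict(_SIM_DEFAULTS))

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        _check_keys(
            "config",
            raw,
            {"seed", "out_dir", "tuning", "spatial", "feeding_arena", "social_arena", "sim"},
        )
        tuning_raw = dict(raw.get("tuning", {}))
        _check_keys("tuning", tuning_raw, _TUNING_KEYS)
        tuning_raw.setdefault("seed", int(raw.get("seed", 0)))
        spatial_raw = dict(raw.get("spatial", {}))
        _check_keys("spatial", spatial_raw, _SPATIAL_KEYS)
        sim = dict(_SIM_DEFAULTS)
        sim_raw = dict(raw.get("sim", {}))
        _check_keys("sim", sim_raw, set(_SIM_DEFAULTS))
        sim.update(sim_raw)

        def arena(key, default_factory):
            if key not in raw:
                return default_factory()
            a = dict(raw[key])
            _check_keys(key, a, _ARENA_KEYS)
            return ArenaSpec(**a)

        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "blapipe_out")),
            tuning=disttuning.TuningConfig(**tuning_raw),
            spatial=spatialmap.SpatialConfig(**spatial_raw),
            feeding_arena=arena("feeding_arena", simdata.feeding_arena),
            social_arena=arena("social_arena", simdata.social_arena),
            sim=sim,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def _sub_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> markers -> spatial -> tuning -> events on synthetic
    data, writing all result tables and a run manifest under
    ``config.out_dir``.  Returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    seed = config.seed
    written: list[str] = []

    def save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False, float_format="%.10g")
        written.append(name)

    # --- simulate -----------------------------------------------------
    truth = simdata.make_tuning_truth(
        sim["n_neurons"],
        frac_tuned=sim["frac_tuned"],
        baseline=sim["baseline"],
        amplitude=sim["amplitude"],
        seed=_sub_seed(seed, 1),
    )
    feeding_traj = simdata.gen_trajectory(
        config.feeding_arena, sim["n_frames"], sim["step_sd_cm"], seed=_sub_seed(seed, 2)
    )
    feeding_spikes = simdata.gen_tuned_spikes(
        feeding_traj,
        config.feeding_arena,
        truth,
        seed=_sub_seed(seed, 3),
        tuning_sigma=sim["tuning_sigma"],
    )
    shock_events = EventTimeline(
        pd.DataFrame(
            {
                "onset_s": sim["shock_onsets_s"],
                "offset_s": [t + sim["shock_duration_s"] for t in sim["shock_onsets_s"]],
                "label": "shock",
            }
        )
    )
    n_resp = sim["n_neurons"] // 2
    gains = np.concatenate(
        [np.full(n_resp, sim["responder_gain"]), np.ones(sim["n_neurons"] - n_resp)]
    )
    cfc_spikes = simdata.gen_event_spikes(
        sim["n_frames"],
        15.0,
        shock_events,
        baseline=sim["baseline"],
        gain=gains,
        seed=_sub_seed(seed, 4),
    )
    profiles = simdata.random_profiles(
        sim["n_clusters"], seed=_sub_seed(seed, 5)
    )
    expr, expr_truth = simdata.gen_expression(
        profiles,
        sim["n_cells_per_cluster"],
        library_scale=sim["library_scale"],
        dispersion=sim["dispersion"],
        seed=_sub_seed(seed, 6),
    )
    layout = simdata.layout_one_per_subregion(profiles.clusters)
    fish, fish_truth = simdata.gen_fish_dataset(
        profiles,
        layout,
        sim["n_fish_cells"],
        noise_sd=sim["fish_noise_sd"],
        seed=_sub_seed(seed, 7),
    )
    write_trajectory(feeding_traj, out / "feeding_trajectory.tsv")
    write_spike_matrix(feeding_spikes, out / "feeding_spikes.tsv")
    write_spike_matrix(cfc_spikes, out / "cfc_spikes.tsv")
    write_events(shock_events, out / "cfc_events.tsv")
    write_expression(expr, out / "expression.tsv")
    write_fish_cells(fish, out / "fish_cells.tsv")
    save(truth.neurons, "truth_neurons.tsv")
    save(expr_truth.cells, "truth_expression_cells.tsv")
    save(fish_truth.cells, "truth_fish_cells.tsv")
    written += [
        "feeding_trajectory.tsv",
        "feeding_spikes.tsv",
        "cfc_spikes.tsv",
        "cfc_events.tsv",
        "expression.tsv",
        "fish_cells.tsv",
    ]

    # --- markers ------------------------------------------------------
    markers = markersel.compute_auc_markers(expr)
    save(markers, "markers.tsv")
    profile = markersel.aggregate_profiles(expr, expr.gene_ids)
    save(profile.to_frame().reset_index(names="cluster"), "cluster_profiles.tsv")
    dend = markersel.cluster_dendrogram(profile)

    # --- spatial ------------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fish_pos = spatialmap.call_positive_cells(fish, config.spatial)
        fr = spatialmap.subregion_fractions(fish_pos)
        save(fr.fractions.reset_index(), "subregion_fractions.tsv")
        corr, leaf_order = spatialmap.subregion_correlation(fr)
        save(corr.reset_index(names="subregion"), "subregion_correlation.tsv")
        eigen_top4 = {}
        for section in sorted(fish_pos["section"].unique()):
            res = spatialmap.compute_eigen_images(fish_pos, config.spatial, section)
            eigen_top4[section] = res.top4_variance
    assign = spatialmap.assign_cells_to_clusters(
        fish_pos[["cell_id"] + spatialmap.gene_columns(fish_pos)], profile
    )
    save(assign.assignments, "fish_assignments.tsv")

    # --- tuning -------------------------------------------------------
    tuning_cfg = config.tuning
    result = disttuning.analyze_tuning(
        feeding_spikes, feeding_traj, config.feeding_arena, tuning_cfg
    )
    save(result.table, "feeding_tuning.tsv")
    thirds = np.array_split(np.arange(sim["n_neurons"]), 3)
    zone_labels = {
        f"pop{k + 1}": list(result.table["zone"].to_numpy()[idx])
        for k, idx in enumerate(thirds)
    }
    comp = disttuning.composition_test(zone_labels, "pop1", "pro", tuning_cfg)
    (out / "composition_test.json").write_text(json.dumps(comp.to_dict(), indent=2))
    written.append("composition_test.json")

    # --- events -------------------------------------------------------
    shock_cls = eventresp.classify_shock_responders(
        cfc_spikes, shock_events, 15.0, tuning_cfg
    )
    save(shock_cls, "shock_responders.tsv")

    manifest = {
        "blapipe_version": __version__,
        "seed": seed,
        "sim": sim,
        "tuning": {
            "n_bins": tuning_cfg.n_bins,
            "n_shuffles": tuning_cfg.n_shuffles,
            "fdr_q": tuning_cfg.fdr_q,
            "tail": tuning_cfg.tail,
        },
        "zone_radii_cm": {
            "feeding": [config.feeding_arena.zone_inner_cm, config.feeding_arena.zone_outer_cm],
            "social": [config.social_arena.zone_inner_cm, config.social_arena.zone_outer_cm],
        },
        "positive_thresholds": fish_pos.attrs.get("thresholds", {}),
        "dendrogram_leaf_order": dend.leaf_order,
        "subregion_leaf_order": list(leaf_order),
        "eigen_top4_variance_fraction": eigen_top4,
        "n_significant_feeding": int(result.table["significant"].sum()),
        "composition_verdict": comp.verdict,
        "outputs": sorted(set(written)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
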