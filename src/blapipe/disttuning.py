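"""Distance-to-target tuning analysis of deconvolved calcium activity.

The question the module answers: does a neuron's firing depend on the
animal's distance to a target (food container or social partner) beyond what
chance alignment of an autocorrelated spike train with an autocorrelated
behavior trace would produce?

Distances are normalized by the chamber radius and clipped to [0, 1], the
normalized range is split into 31 equal bins, and each neuron's statistic is
the maximum binned mean firing rate.  The null distribution comes from
rotary (circular) shuffles of the neuron's own spike train against the fixed
distance series — a shift-invariant null that preserves the train's values
and autocorrelation while breaking its alignment with behavior.  Per-neuron
permutation p-values are corrected with Benjamini-Hochberg at FDR 5%, and a
neuron's zone (pro / neutral / anti) is the zone of its peak-rate bin.

Population compositions (e.g. "is the pro-food fraction of the Lypd1
population larger than chance?") are tested by pooling the zone labels of
all recorded populations and repeatedly drawing N labels without
replacement, comparing the observed percentage with the 2.5% tails of the
resampled null.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .simdata import AlignmentError, ArenaSpec, ParameterError, SpikeMatrix, Trajectory

__all__ = [
    "TuningConfig",
    "DistanceSeries",
    "BinnedRates",
    "TuningResult",
    "CompositionResult",
    "compute_distance_series",
    "bin_firing_by_distance",
    "classify_peak_zone",
    "rotary_shuffle",
    "tuning_pvalues",
    "bh_adjust",
    "analyze_tuning",
    "composition_test",
]

ZONES = ("pro", "neutral", "anti")


@dataclass(frozen=True)
class TuningConfig:
    """Knobs of the permutation analysis (defaults follow the study design:
    31 bins, 1000 shuffles, FDR 5%, 2.5% composition-test tails)."""

    n_bins: int = 31
    n_shuffles: int = 1000
    fdr_q: float = 0.05
    tail: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")
        if self.n_shuffles < 1:
            raise ParameterError("n_shuffles must be >= 1")
        if not 0 < self.fdr_q < 1:
            raise ParameterError("fdr_q must be in (0, 1)")
        if not 0 < self.tail < 0.5:
            raise ParameterError("tail must be in (0, 0.5)")


@dataclass
class DistanceSeries:
    """Per-frame distance to the target, raw (cm) and normalized/clipped."""

    distance_cm: np.ndarray
    distance_norm: np.ndarray  # distance_cm / norm_radius, clipped to [0, 1]

    @property
    def n_frames(self) -> int:
        return self.distance_cm.size


def compute_distance_series(traj: Trajectory, arena: ArenaSpec) -> DistanceSeries:
    """Euclidean distance to the arena target per frame, normalized by the
    chamber radius and clipped to [0, 1] (rectangle corners can exceed the
    normalizer; clipping keeps the bin domain fixed)."""
    d = arena.distance_to_target(traj.x_cm, traj.y_cm)
    return DistanceSeries(d, np.clip(d / arena.norm_radius_cm, 0.0, 1.0))


@dataclass
class BinnedRates:
    """Mean firing per distance bin with frame occupancy.

    ``rates`` is neurons x bins with NaN in unoccupied bins; bin edges are
    equal width on [0, 1], left-closed/right-open (last bin right-closed).
    """

    rates: np.ndarray
    occupancy: np.ndarray
    bin_edges: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _bin_index(distance_norm: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.floor(distance_norm * n_bins).astype(int)
    return np.minimum(idx, n_bins - 1)  # d_norm == 1 falls in the last bin


def bin_firing_by_distance(
    spikes: SpikeMatrix, ds: DistanceSeries, cfg: TuningConfig | None = None
) -> BinnedRates:
    """Average firing rate (spikes/frame) per equal-width distance bin."""
    cfg = cfg or TuningConfig()
    if spikes.n_frames != ds.n_frames:
        raise AlignmentError(
            f"spikes have {spikes.n_frames} frames, distances {ds.n_frames}"
        )
    idx = _bin_index(ds.distance_norm, cfg.n_bins)
    occ = np.bincount(idx, minlength=cfg.n_bins)
    sums = np.vstack(
        [np.bincount(idx, weights=row, minlength=cfg.n_bins) for row in spikes.counts]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(occ > 0, sums / np.where(occ > 0, occ, 1), np.nan)
    edges = np.linspace(0.0, 1.0, cfg.n_bins + 1)
    return BinnedRates(rates, occ, edges)


def classify_peak_zone(peak_distance_cm: float, arena: ArenaSpec) -> str:
    """pro if the peak is at or inside the inner radius, anti if strictly
    outside the outer radius, neutral in between."""
    if peak_distance_cm <= arena.zone_inner_cm:
        return "pro"
    if peak_distance_cm > arena.zone_outer_cm:
        return "anti"
    return "neutral"


def rotary_shuffle(
    train: np.ndarray,
    offset: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Circular shift of a spike train by a random (or given) offset.

    Element i moves to (i + k) mod T with k uniform on {1, ..., T-1}; the
    spike multiset, total count and autocorrelation are preserved exactly.
    A train of length < 2 is degenerate and returned unchanged with a
    warning.
    """
    train = np.asarray(train)
    T = train.size
    if T < 2:
        warnings.warn("rotary shuffle of a length-<2 train is the identity")
        return train.copy()
    if offset is None:
        if rng is None:
            rng = np.random.default_rng()
        offset = int(rng.integers(1, T))
    return np.roll(train, offset)


def _neuron_rng(seed: int, neuron_id: str) -> np.random.Generator:
    # one stream per neuron derived from (seed, id): results do not depend on
    # neuron order or parallel chunking
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(str(neuron_id).encode())])
    )


def _null_max_rates(
    train: np.ndarray, bin_idx: np.ndarray, occ: np.ndarray
) -> np.ndarray:
    """Max binned mean rate of every circular shift of ``train``, via FFT.

    For bin b with indicator u_b, the shifted-train bin sum at offset k is
    the circular cross-correlation sum_m train(m) * u_b(m + k); computing it
    with FFTs gives the statistic for all T offsets at once.
    """
    T = train.size
    occupied = np.flatnonzero(occ > 0)
    U = np.vstack([(bin_idx == b).astype(float) for b in occupied])
    C = np.fft.irfft(
        np.conj(np.fft.rfft(train))[None, :] * np.fft.rfft(U, axis=1), n=T, axis=1
    )
    return (C / occ[occupied, None]).max(axis=0)


def tuning_pvalues(
    spikes: SpikeMatrix, ds: DistanceSeries, cfg: TuningConfig | None = None
) -> np.ndarray:
    """Per-neuron permutation p-value for distance tuning.

    Statistic: the maximum over occupied bins of the binned mean rate.  The
    null resamples the statistic over ``cfg.n_shuffles`` rotary shuffles of
    the neuron's own train against the fixed distance series, and
    p = (1 + #{null >= observed}) / (1 + n_shuffles) (add-one rule: p is
    never 0, which keeps BH applicable).  Constant trains (including
    all-zero) are shift-invariant and get p = 1.
    """
    cfg = cfg or TuningConfig()
    if spikes.n_frames != ds.n_frames:
        raise AlignmentError("spike/distance frame mismatch")
    T = spikes.n_frames
    idx = _bin_index(ds.distance_norm, cfg.n_bins)
    occ = np.bincount(idx, minlength=cfg.n_bins)
    binned = bin_firing_by_distance(spikes, ds, cfg)
    obs = np.nanmax(binned.rates, axis=1)
    p = np.ones(spikes.n_neurons)
    for i, nid in enumerate(spikes.neuron_ids):
        train = spikes.counts[i]
        if np.ptp(train) == 0:  # constant (or all-zero): every shuffle identical
            continue
        rng = _neuron_rng(cfg.seed, nid)
        offsets = rng.integers(1, T, size=cfg.n_shuffles)
        null_all = _null_max_rates(train, idx, occ)
        tol = 1e-9 * max(1.0, abs(obs[i]))  # FFT round-off guard
        exceed = int((null_all[offsets] >= obs[i] - tol).sum())
        p[i] = (1 + exceed) / (1 + cfg.n_shuffles)
    return p


def bh_adjust(pvalues: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p <= 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class TuningResult:
    """Per-neuron tuning summary plus the underlying binned rates."""

    table: pd.DataFrame  # neuron_id, peak_bin, peak_distance_cm, zone, p_value, significant
    binned: BinnedRates


def analyze_tuning(
    spikes: SpikeMatrix,
    traj: Trajectory,
    arena: ArenaSpec,
    cfg: TuningConfig | None = None,
) -> TuningResult:
    """Full per-neuron distance-tuning analysis for one session.

    Bins firing by normalized distance, finds each neuron's peak bin
    (smallest index on ties, unoccupied bins excluded), converts the bin
    centre back to cm to classify the pro/neutral/anti zone, computes
    rotary-shuffle permutation p-values and applies BH across the neurons of
    the session.
    """
    cfg = cfg or TuningConfig()
    ds = compute_distance_series(traj, arena)
    binned = bin_firing_by_distance(spikes, ds, cfg)
    rates = np.where(np.isnan(binned.rates), -np.inf, binned.rates)
    peak_bin = rates.argmax(axis=1)  # argmax takes the smallest index on ties
    peak_cm = binned.bin_centers[peak_bin] * arena.norm_radius_cm
    zone = [classify_peak_zone(c, arena) for c in peak_cm]
    p = tuning_pvalues(spikes, ds, cfg)
    sig = bh_adjust(p, cfg.fdr_q)
    table = pd.DataFrame(
        {
            "neuron_id": spikes.neuron_ids,
            "peak_bin": peak_bin,
            "peak_distance_cm": peak_cm,
            "zone": zone,
            "p_value": p,
            "significant": sig,
        }
    )
    return TuningResult(table, binned)


@dataclass
class CompositionResult:
    """Pooled-resampling test of one population's zone percentage."""

    population: str
    zone: str
    observed_pct: float
    null_pct: np.ndarray
    lower_pct: float
    upper_pct: float
    verdict: str  # above | below | ns
    n_selected: int

    def to_dict(self) -> dict:
        return {
            "population": self.population,
            "zone": self.zone,
            "observed_pct": self.observed_pct,
            "lower_pct": self.lower_pct,
            "upper_pct": self.upper_pct,
            "verdict": self.verdict,
            "n_selected": self.n_selected,
        }


def composition_test(
    zone_labels: Mapping[str, Sequence[str]],
    target_population: str,
    zone: str,
    cfg: TuningConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CompositionResult:
    """Is the target population's percentage of ``zone`` neurons beyond what
    drawing the same number of neurons from the pooled populations gives?

    The pool is the union of all populations' zone labels (the tested
    population included).  Each of ``cfg.n_shuffles`` resamples draws N
    labels without replacement (N = target population size) and records the
    zone percentage; the observed percentage is compared against the
    empirical ``tail`` / ``1 - tail`` quantiles of that null.
    """
    cfg = cfg or TuningConfig()
    if target_population not in zone_labels:
        raise ParameterError(f"unknown population {target_population!r}")
    pool = np.concatenate([np.asarray(v, dtype=object) for v in zone_labels.values()])
    target = np.asarray(zone_labels[target_population], dtype=object)
    N = target.size
    if N == 0 or N > pool.size:
        raise ParameterError("target population must be nonempty and <= pool size")
    observed = 100.0 * float((target == zone).mean())
    is_zone = (pool == zone).astype(float)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if N == pool.size:
        null = np.full(cfg.n_shuffles, 100.0 * is_zone.mean())
    else:
        # N smallest of iid uniform keys per resample = uniform subset
        keys = rng.random((cfg.n_shuffles, pool.size))
        take = np.argpartition(keys, N - 1, axis=1)[:, :N]
        null = 100.0 * is_zone[take].mean(axis=1)
    lower = float(np.quantile(null, cfg.tail))
    upper = float(np.quantile(null, 1.0 - cfg.tail))
    if observed > upper:
        verdict = "above"
    elif observed < lower:
        verdict = "below"
    else:
        verdict = "ns"
    return CompositionResult(
        target_population, zone, observed, null, lower, upper, verdict, N
    )
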