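"""Event-locked response scores and responder classification.

All three of the study's response scores share one contrast form,
(A - B) / (A + B), on averaged firing rates: the shock response score (SRC)
contrasts the 2 s from footshock onset with the 2 s before it, the freezing
score contrasts freezing with non-freezing frames, and the social response
score (SoRC) contrasts social-interaction frames (head oriented at the wired
container, distance < 10 cm) with non-social frames.  Scores of +1 / -1 mean
maximal activation / inhibition.

Footshock responders are classified against a rotary-shuffle null of the
mean SRC: pro-footshock above the top 2.5% of the null, anti-footshock below
the bottom 2.5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .disttuning import TuningConfig
from .simdata import (
    AlignmentError,
    ArenaSpec,
    EventTimeline,
    ParameterError,
    SpikeMatrix,
    Trajectory,
)

__all__ = [
    "WindowRates",
    "event_window_rates",
    "contrast_score",
    "shock_score",
    "classify_shock_responders",
    "detect_social_frames",
    "masked_score",
    "filter_min_duration",
    "ols_fit",
]


@dataclass
class WindowRates:
    """Mean spikes/frame in the 2-s windows before and from each event onset.

    ``f_before``/``f_during`` are neurons x events; events whose windows
    would be truncated by the recording edges are dropped with a warning and
    listed in ``skipped_events``.
    """

    f_before: np.ndarray
    f_during: np.ndarray
    onset_frames: np.ndarray
    window_frames: int
    skipped_events: list[int]


def event_window_rates(
    spikes: SpikeMatrix,
    events: EventTimeline,
    frame_rate_hz: float,
    window_s: float = 2.0,
    label: str | None = "shock",
) -> WindowRates:
    """Per-event mean rates over [onset - w, onset) and [onset, onset + w)."""
    w = int(round(window_s * frame_rate_hz))
    if w < 1:
        raise ParameterError("window shorter than one frame")
    ev = events.events if label is None else events.select(label).events
    onsets = np.round(ev["onset_s"].to_numpy(float) * frame_rate_hz).astype(int)
    T = spikes.n_frames
    keep, skipped = [], []
    for j, f in enumerate(onsets):
        if f - w < 0 or f + w > T:
            skipped.append(j)
        else:
            keep.append(f)
    if skipped:
        warnings.warn(f"{len(skipped)} event(s) with truncated windows skipped")
    before = np.empty((spikes.n_neurons, len(keep)))
    during = np.empty((spikes.n_neurons, len(keep)))
    for j, f in enumerate(keep):
        before[:, j] = spikes.counts[:, f - w : f].mean(axis=1)
        during[:, j] = spikes.counts[:, f : f + w].mean(axis=1)
    return WindowRates(before, during, np.asarray(keep), w, skipped)


def contrast_score(f_a, f_b):
    """(A - B) / (A + B), the shared SRC / SoRC / freezing-score form.

    Defined as 0 when both rates are 0; antisymmetric, bounded in [-1, 1]
    with the bounds attained exactly when one rate is 0 and the other
    positive.
    """
    a = np.asarray(f_a, dtype=float)
    b = np.asarray(f_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ParameterError("rates must be nonnegative")
    tot = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(tot > 0, (a - b) / np.where(tot > 0, tot, 1.0), 0.0)
    return s if s.ndim else float(s)


def shock_score(wr: WindowRates) -> np.ndarray:
    """Mean SRC per neuron: the unweighted mean of per-event contrast scores.

    NaN for neurons with zero valid events (none here unless all events were
    skipped, in which case every neuron is undefined).
    """
    if wr.f_during.shape[1] == 0:
        return np.full(wr.f_during.shape[0], np.nan)
    return contrast_score(wr.f_during, wr.f_before).mean(axis=1)


def _sliding_window_sums(train: np.ndarray, w: int) -> np.ndarray:
    """S(x) = sum of train[x : x+w] on the circularly extended train."""
    ext = np.concatenate([train, train[: w - 1]]) if w > 1 else train
    c = np.concatenate([[0.0], np.cumsum(ext)])
    return c[w:] - c[: train.size]


def classify_shock_responders(
    spikes: SpikeMatrix,
    events: EventTimeline,
    frame_rate_hz: float,
    cfg: TuningConfig | None = None,
    window_s: float = 2.0,
) -> pd.DataFrame:
    """Classify each neuron pro / anti / neutral against a rotary-shuffle
    null of the mean SRC.

    Each shuffle circularly shifts the whole train by one random offset and
    recomputes the mean SRC; a neuron is pro-footshock if its observed mean
    SRC is strictly above the ``1 - tail`` empirical quantile of the null,
    anti-footshock if strictly below the ``tail`` quantile (2.5% tails by
    default).  Constant trains are shift-invariant, hence neutral.
    """
    from .disttuning import _neuron_rng

    cfg = cfg or TuningConfig()
    wr = event_window_rates(spikes, events, frame_rate_hz, window_s)
    if wr.f_during.shape[1] == 0:
        raise ParameterError("no event with complete windows")
    obs = shock_score(wr)
    T = spikes.n_frames
    w = wr.window_frames
    rows = []
    for i, nid in enumerate(spikes.neuron_ids):
        train = spikes.counts[i]
        if np.ptp(train) == 0:
            rows.append((nid, obs[i], "neutral", np.nan, np.nan))
            continue
        S = _sliding_window_sums(train, w)
        rng = _neuron_rng(cfg.seed, nid)
        offsets = rng.integers(1, T, size=cfg.n_shuffles)
        # shifted train y(j) = train[(j - k) mod T]; window starting at frame f
        # covers original indices starting at (f - k) mod T
        null_scores = np.zeros(cfg.n_shuffles)
        for f in wr.onset_frames:
            during = S[(f - offsets) % T] / w
            before = S[(f - w - offsets) % T] / w
            null_scores += contrast_score(during, before)
        null_scores /= wr.onset_frames.size
        lo = np.quantile(null_scores, cfg.tail)
        hi = np.quantile(null_scores, 1.0 - cfg.tail)
        cls = "pro" if obs[i] > hi else ("anti" if obs[i] < lo else "neutral")
        rows.append((nid, obs[i], cls, lo, hi))
    return pd.DataFrame(
        rows, columns=["neuron_id", "score", "class", "null_lower", "null_upper"]
    )


def detect_social_frames(
    traj: Trajectory,
    arena: ArenaSpec,
    max_dist_cm: float = 10.0,
    max_angle_deg: float = 45.0,
) -> np.ndarray:
    """Frames of social engagement: head oriented towards the wired container
    (angle between heading and the cell-to-container vector <= max_angle_deg)
    while closer than ``max_dist_cm`` to the container centre."""
    if traj.heading_deg is None:
        raise ParameterError("trajectory has no heading; cannot detect social frames")
    dx = arena.target_x_cm - traj.x_cm
    dy = arena.target_y_cm - traj.y_cm
    dist = np.hypot(dx, dy)
    to_target = np.degrees(np.arctan2(dy, dx))
    dang = np.abs((traj.heading_deg - to_target + 180.0) % 360.0 - 180.0)
    return (dist < max_dist_cm) & (dang <= max_angle_deg)


def masked_score(
    spikes: SpikeMatrix, mask: np.ndarray, kind: str = "social"
) -> pd.DataFrame:
    """Contrast of mean rates inside vs outside a boolean frame mask.

    ``kind='social'`` yields the SoRC with ON (score > 0) / OFF labels;
    ``kind='freezing'`` yields the freezing score with the same labelling
    rule.  Raises if the mask or its complement is empty (the score is
    undefined then).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != spikes.n_frames:
        raise AlignmentError("mask length must equal the frame count")
    if kind not in ("social", "freezing"):
        raise ParameterError(f"unknown score kind {kind!r}")
    if not mask.any() or mask.all():
        raise ParameterError("mask and its complement must both be nonempty")
    f_in = spikes.counts[:, mask].mean(axis=1)
    f_out = spikes.counts[:, ~mask].mean(axis=1)
    score = contrast_score(f_in, f_out)
    cls = np.where(score > 0, "ON", "OFF")  # score 0 -> OFF (strictly positive = ON)
    return pd.DataFrame(
        {"neuron_id": spikes.neuron_ids, "kind": kind, "score": score, "class": cls}
    )


def filter_min_duration(events: EventTimeline, min_s: float = 2.0) -> EventTimeline:
    """Drop bouts shorter than ``min_s`` (the study's 2-s minimum freezing
    duration, enforced here on input masks/timelines)."""
    ev = events.events
    keep = (ev["offset_s"] - ev["onset_s"]) >= min_s
    return EventTimeline(ev[keep])


def ols_fit(x, y) -> dict:
    """Simple least-squares line with slope t-test (two-sided).

    Returns slope, intercept, r_squared and two_sided_p.  Constant x is a
    degenerate design and raises; constant y gives slope 0, r_squared 0,
    p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise AlignmentError("x and y must have equal length")
    if x.size < 3:
        raise ParameterError("need n >= 3 points")
    if np.ptp(x) == 0:
        raise ParameterError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        return {"slope": 0.0, "intercept": float(y[0]), "r_squared": 0.0, "two_sided_p": 1.0}
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "two_sided_p": float(res.pvalue),
    }
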