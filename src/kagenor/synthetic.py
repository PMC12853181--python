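"""Synthetic homecage NOR sessions and synthetic annotator label sets.

The session generator emulates what the automated homecage records: 2-fps keypoint
tracks plus the ground-truth per-frame exploration state, driven by a
discrete-time (per-frame) Markov state machine over five behavioural states
(nest / corridor / roam / explore-left / explore-right).  Object changes at
phase boundaries transiently boost the per-side exploration hazard

    lambda_side(t) = baseline_hazard * side_mult * boost(t) * novelty(side)

with an exponentially decaying boost (time constant ``novelty_decay_tau``)
so that exploration returns to baseline within 20-30 min of an object
change, and a multiplicative novel-side factor ``f`` (default 1.67, i.e. a
~67% higher exploration rate at the novel object) during the test phase.
Bout durations are geometric (the discrete analogue of exponential holding
times); this distributional choice is a modelling convenience, see the
methods note.

The annotator simulator draws label sets of controlled size and purity:
each simulated annotator selects ``round(ss * N)`` frames of which
``round(pef * ss * N)`` are true exploratory frames drawn uniformly without
replacement, the remainder near-miss frames from a non-exploratory pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import (
    DEFAULT_FRAME_RATE,
    CageLayout,
    ExplorationSeries,
    KeypointTrack,
    PhaseSchedule,
)

__all__ = [
    "SessionSimConfig",
    "SyntheticSession",
    "CorridorVisit",
    "simulate_session",
    "simulate_cohort",
    "simulate_annotators",
    "expected_bout_starts",
    "adjacent_pool",
]


class SimConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class SessionSimConfig:
    """Generative parameters of one synthetic homecage session.

    Durations default to the full study schedule (9 d habituation, 24 h
    sample, 24 h retention, 2 h test); analyses on a compute budget pass
    shorter phases explicitly.  ``novel_side_factor`` is the novel:familiar
    exploration-rate ratio f; its default 1.67 encodes the ~67% increase in
    novel-object exploration that corresponds to a discrimination index of
    0.25.  ``novelty_decay_tau`` = 480 s puts 3 tau at 24 min, i.e. the
    boost has decayed to baseline within 20-30 min of an object change.
    """

    frame_rate: float = DEFAULT_FRAME_RATE
    habituation_s: float = 9 * 86400.0
    sample_s: float = 86400.0
    retention_s: float = 86400.0
    test_s: float = 7200.0
    baseline_hazard: float = 0.006  # bout starts / s / side, unboosted
    novelty_boost_amplitude: float = 6.0
    novelty_decay_tau: float = 480.0
    retention_boost_scale: float = 0.25  # baseline objects return: weaker response
    novel_side_factor: float = 1.67
    side_bias: float = 1.0  # multiplier on right-side hazard
    bout_duration_mean_s: float = 2.5
    nest_position: tuple[float, float] = (60.0, 40.0)
    nest_entry_rate: float = 0.004  # entries / s while roaming
    nest_stay_mean_s: float = 240.0
    corridor_visit_rate: float = 0.004  # visits / s while roaming (both corridors)
    corridor_stay_mean_s: float = 20.0
    corridor_side_coupling: float = 0.5
    keypoint_noise_sd_px: float = 1.0
    confidence_alpha: float = 20.0  # likelihood ~ Beta(alpha, beta), peaked near 1
    confidence_beta: float = 1.0
    dropout_prob: float = 0.01  # occasional low-confidence snout frames
    novel_side: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise SimConfigError("frame_rate must be positive")
        for name in ("habituation_s", "sample_s", "retention_s", "test_s"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        for name in (
            "baseline_hazard",
            "novelty_decay_tau",
            "bout_duration_mean_s",
            "novel_side_factor",
            "side_bias",
        ):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if self.novelty_boost_amplitude < 0:
            raise SimConfigError("novelty_boost_amplitude must be non-negative")
        if not 0.0 <= self.corridor_side_coupling <= 1.0:
            raise SimConfigError("corridor_side_coupling must lie in [0, 1]")
        if self.novel_side not in ("left", "right"):
            raise SimConfigError("novel_side must be 'left' or 'right'")

    def schedule(self) -> PhaseSchedule:
        return PhaseSchedule.standard(
            habituation_s=self.habituation_s,
            sample_s=self.sample_s,
            retention_s=self.retention_s,
            test_s=self.test_s,
            novel_side=self.novel_side,
        )


@dataclass(frozen=True)
class CorridorVisit:
    side: str
    start_s: float
    end_s: float


@dataclass
class SyntheticSession:
    """One simulated session: keypoints, ground-truth labels, schedule, events."""

    keypoints: KeypointTrack
    labels: ExplorationSeries
    schedule: PhaseSchedule
    corridor_visits: list[CorridorVisit]
    nest_intervals: list[tuple[float, float]]
    states: np.ndarray  # per-frame behavioural state code
    truth_params: SessionSimConfig
    layout: CageLayout


# behavioural state codes
NEST, CORRIDOR_L, CORRIDOR_R, ROAM, EXPLORE_L, EXPLORE_R = range(6)


def hazard_profile(config: SessionSimConfig, side: str, time_s: np.ndarray) -> np.ndarray:
    """Per-side exploration-bout hazard lambda_side(t) in starts/s.

    Piecewise over phases: habituation is baseline; each object change
    (sample, retention, test onset) adds an exponentially decaying boost;
    during the test the novel side is multiplied by f.
    """
    sched = config.schedule()
    lam = np.full_like(time_s, config.baseline_hazard, dtype=float)
    side_mult = config.side_bias if side == "right" else 1.0
    lam *= side_mult
    for phase_name, scale in (
        ("sample", 1.0),
        ("retention", config.retention_boost_scale),
        ("test", 1.0),
    ):
        p = sched.phase(phase_name)
        in_phase = (time_s >= p.start_s) & (time_s < p.end_s)
        dt = time_s[in_phase] - p.start_s
        boost = 1.0 + scale * config.novelty_boost_amplitude * np.exp(-dt / config.novelty_decay_tau)
        lam[in_phase] *= boost
    test = sched.phase("test")
    if side == config.novel_side:
        in_test = (time_s >= test.start_s) & (time_s < test.end_s)
        lam[in_test] *= config.novel_side_factor
    return lam


def expected_bout_starts(
    config: SessionSimConfig, side: str, available: np.ndarray, time_s: np.ndarray
) -> tuple[float, float]:
    """Expected bout-start count and its SD given frame availability.

    The generator starts a bout on an available (roaming) frame with
    probability ``lambda_side(t) / frame_rate``; conditioning on the realised
    availability mask makes the count a Poisson-binomial whose mean is the
    hazard integral over available frames.
    """
    lam = hazard_profile(config, side, time_s)
    p = np.clip(lam / config.frame_rate, 0.0, 1.0)[np.asarray(available, dtype=bool)]
    return float(p.sum()), float(np.sqrt((p * (1.0 - p)).sum()))


def _emit_keypoints(
    states: np.ndarray,
    layout: CageLayout,
    config: SessionSimConfig,
    rng: np.random.Generator,
) -> KeypointTrack:
    """Render body-part coordinates consistent with the behavioural states.

    During exploration the snout sits on an annulus inside the object-window
    access radius with the head axis (ears-midpoint -> snout) pointing at the
    window centre; otherwise the body centre follows a reflected random walk
    kept clear of both access windows, with random heading.
    """
    n = len(states)
    margin = 8.0
    lo_x = layout.object_window_left.x + layout.object_window_left.radius + margin
    hi_x = layout.object_window_right.x - layout.object_window_right.radius - margin
    lo_y, hi_y = 10.0, layout.height_px - 10.0

    center = np.empty((n, 2))
    heading = np.empty((n, 2))  # unit vector, body axis tail->snout

    pos = np.array([layout.width_px / 2.0, layout.height_px / 2.0])
    steps = rng.normal(0.0, 6.0, size=(n, 2))
    angles = rng.uniform(0.0, 2 * np.pi, size=n)
    nest = np.asarray(config.nest_position, dtype=float)

    for i in range(n):
        s = states[i]
        if s == ROAM:
            pos = pos + steps[i]
            pos[0] = np.clip(pos[0], lo_x, hi_x)
            pos[1] = np.clip(pos[1], lo_y, hi_y)
            center[i] = pos
            heading[i] = (np.cos(angles[i]), np.sin(angles[i]))
        elif s == NEST:
            center[i] = nest + rng.normal(0.0, 2.0, size=2)
            heading[i] = (np.cos(angles[i]), np.sin(angles[i]))
            pos = center[i]
        elif s in (CORRIDOR_L, CORRIDOR_R):
            entry = layout.corridor_entry("left" if s == CORRIDOR_L else "right")
            center[i] = entry.center + rng.normal(0.0, 2.0, size=2)
            heading[i] = (np.cos(angles[i]), np.sin(angles[i]))
            pos = center[i]
        else:  # exploring
            win = layout.object_window("left" if s == EXPLORE_L else "right")
            r = rng.uniform(5.0, 0.65 * win.radius)
            phi = rng.uniform(0.0, 2 * np.pi)
            snout = win.center + r * np.array([np.cos(phi), np.sin(phi)])
            u = win.center - snout
            u = u / np.linalg.norm(u)
            center[i] = snout  # body centre placed behind below
            heading[i] = u
            pos = snout

    # assemble skeleton along the heading axis; in the nest the animal is
    # curled up, so the whole skeleton contracts around the body centre
    head_len = 6.0
    ear_span = 5.0
    spine_step = 9.0
    u = heading
    perp = np.stack([-u[:, 1], u[:, 0]], axis=1)
    scale = np.where(states == NEST, 0.2, 1.0)[:, None]

    exploring = (states == EXPLORE_L) | (states == EXPLORE_R)
    snout_xy = np.where(exploring[:, None], center, center + scale * head_len * u)
    ears_mid = snout_xy - scale * head_len * u
    coords = {
        "snout": snout_xy,
        "ear_left": ears_mid + scale * ear_span * perp,
        "ear_right": ears_mid - scale * ear_span * perp,
        "spine_1": ears_mid - scale * spine_step * u,
        "spine_2": ears_mid - scale * 2 * spine_step * u,
        "spine_3": ears_mid - scale * 3 * spine_step * u,
        "tail_base": ears_mid - scale * 4 * spine_step * u,
    }
    noise_sd = config.keypoint_noise_sd_px
    likelihoods = {}
    for part in coords:
        coords[part] = coords[part] + rng.normal(0.0, noise_sd, size=(n, 2))
        lik = rng.beta(config.confidence_alpha, config.confidence_beta, size=n)
        drop = rng.random(n) < config.dropout_prob
        lik[drop] = rng.beta(2.0, 5.0, size=int(drop.sum()))
        likelihoods[part] = lik
    return KeypointTrack.from_arrays(coords, likelihoods, frame_rate=config.frame_rate)


def simulate_session(
    config: SessionSimConfig, layout: CageLayout | None = None
) -> SyntheticSession:
    """Simulate one homecage NOR session.

    Deterministic under a fixed ``config.seed``; the single seed is expanded
    into independent substreams for the state process and the keypoint
    rendering so the two components can be varied independently.
    """
    layout = layout or CageLayout()
    sched = config.schedule()
    fps = config.frame_rate
    n = int(round(sched.total_duration_s * fps))
    time_s = np.arange(n) / fps

    ss = np.random.SeedSequence(config.seed)
    rng_states, rng_kp = (np.random.default_rng(s) for s in ss.spawn(2))

    lam_l = hazard_profile(config, "left", time_s) / fps
    lam_r = hazard_profile(config, "right", time_s) / fps
    p_nest = config.nest_entry_rate / fps
    p_corr = config.corridor_visit_rate / fps
    p_leave_nest = 1.0 / (config.nest_stay_mean_s * fps)
    p_leave_corr = 1.0 / (config.corridor_stay_mean_s * fps)
    m_frames = config.bout_duration_mean_s * fps
    p_end_bout = 1.0 / m_frames

    states = np.empty(n, dtype=np.int8)
    state = ROAM
    pending_corridor: str | None = None
    corridor_visits: list[CorridorVisit] = []
    nest_intervals: list[tuple[float, float]] = []
    visit_start = 0.0
    u = rng_states.random(n)
    u2 = rng_states.random(n)

    for i in range(n):
        t = time_s[i]
        if state in (EXPLORE_L, EXPLORE_R):
            if u[i] < p_end_bout:
                state = ROAM
        elif state == NEST:
            if u[i] < p_leave_nest:
                nest_intervals.append((visit_start, t))
                state = ROAM
        elif state in (CORRIDOR_L, CORRIDOR_R):
            if u[i] < p_leave_corr:
                side = "left" if state == CORRIDOR_L else "right"
                corridor_visits.append(CorridorVisit(side, visit_start, t))
                pending_corridor = side
                state = ROAM
        else:  # ROAM
            pl, pr = lam_l[i], lam_r[i]
            if u[i] < pl + pr:
                if pending_corridor is not None:
                    same = u2[i] < config.corridor_side_coupling
                    side = pending_corridor if same else (
                        "right" if pending_corridor == "left" else "left"
                    )
                    pending_corridor = None
                else:
                    side = "left" if u[i] < pl else "right"
                state = EXPLORE_L if side == "left" else EXPLORE_R
            elif u[i] < pl + pr + p_nest:
                state = NEST
                visit_start = t
            elif u[i] < pl + pr + p_nest + p_corr:
                state = CORRIDOR_L if u2[i] < 0.5 else CORRIDOR_R
                visit_start = t
        states[i] = state

    labels = ExplorationSeries(
        explore_left=states == EXPLORE_L,
        explore_right=states == EXPLORE_R,
        frame_rate=fps,
    )
    keypoints = _emit_keypoints(states, layout, config, rng_kp)
    return SyntheticSession(
        keypoints=keypoints,
        labels=labels,
        schedule=sched,
        corridor_visits=corridor_visits,
        nest_intervals=nest_intervals,
        states=states,
        truth_params=config,
        layout=layout,
    )


def simulate_cohort(
    config: SessionSimConfig,
    n_mice: int,
    layout: CageLayout | None = None,
    novel_sides: Sequence[str] | None = None,
) -> list[SyntheticSession]:
    """Simulate ``n_mice`` independent sessions, counterbalancing the novel
    side across mice unless ``novel_sides`` is given explicitly.

    Per-mouse seeds are derived from ``config.seed`` so the cohort is fully
    reproducible while sessions remain independent.
    """
    if n_mice < 1:
        raise SimConfigError("n_mice must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n_mice)
    sessions = []
    for i, child in enumerate(children):
        side = (
            novel_sides[i]
            if novel_sides is not None
            else ("left" if i % 2 == 0 else "right")
        )
        sub = replace(
            config, seed=int(child.generate_state(1)[0] % (2**31 - 1)), novel_side=side
        )
        sessions.append(simulate_session(sub, layout=layout))
    return sessions


def adjacent_pool(truth_frames: np.ndarray, n_frames: int, halo: int = 3) -> np.ndarray:
    """Non-exploratory frames within ``halo`` frames of a true bout.

    Real annotation false positives are near-misses at bout boundaries, so
    the default candidate pool for a simulated annotator's false frames is
    the halo around true bouts rather than arbitrary frames.
    """
    truth = np.zeros(n_frames, dtype=bool)
    truth[np.asarray(truth_frames, dtype=int)] = True
    near = np.zeros(n_frames, dtype=bool)
    for k in range(1, halo + 1):
        near[k:] |= truth[:-k]
        near[:-k] |= truth[k:]
    return np.flatnonzero(near & ~truth)


def simulate_annotators(
    truth_frames: Sequence[int] | np.ndarray,
    non_exploratory_pool: Sequence[int] | np.ndarray,
    ss: float,
    pef: float,
    n_annotators: int,
    seed: int,
) -> list[np.ndarray]:
    """Draw independent annotator label sets of controlled size and purity.

    Each annotator selects ``round(ss * |truth|)`` frames total, of which
    ``round(pef * ss * |truth|)`` are drawn uniformly without replacement
    from the true exploratory frames and the remainder uniformly from the
    non-exploratory pool.  Counts use round-half-to-even.
    """
    truth = np.unique(np.asarray(truth_frames, dtype=np.int64))
    pool = np.unique(np.asarray(non_exploratory_pool, dtype=np.int64))
    if np.intersect1d(truth, pool).size:
        raise SimConfigError("truth frames and non-exploratory pool must be disjoint")
    if ss <= 0 or pef <= 0 or pef > 1:
        raise SimConfigError("require ss > 0 and 0 < pef <= 1")
    n_truth = truth.size
    n_total = round(ss * n_truth)
    n_true = round(pef * ss * n_truth)
    if n_true > n_truth:
        raise SimConfigError(
            f"pef*ss = {pef * ss:.3f} requests {n_true} true frames but only "
            f"{n_truth} exist (cap: pef*ss <= 1)"
        )
    n_false = n_total - n_true
    if n_false > pool.size:
        raise SimConfigError(
            f"requested {n_false} false frames but pool holds {pool.size}"
        )
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_annotators):
        chosen_true = rng.choice(truth, size=n_true, replace=False)
        chosen_false = rng.choice(pool, size=n_false, replace=False)
        out.append(np.sort(np.concatenate([chosen_true, chosen_false])))
    return out
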