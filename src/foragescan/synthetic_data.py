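"""Simulator of the dynamic, non-exhaustive foraging task.

Emulates the touch-screen task the analysis assumes: displays of 60/100/140
or 180 items on a 1400 x 1050 px screen, a 20-30 % target proportion drawn
per trial, items drifting at a constant 44 px/s with pseudo-random heading
changes, and agents that collect targets one by one and may quit a patch at
will.  Agents range from uniformly random pickers to scanner-like sweepers,
spiral collectors, and the generative bias model, so every regime the
organization metrics are meant to separate can be produced on demand.

Scoring (2 points per target, -1 per distractor tap, 200-point session cap)
is tracked for task fidelity but plays no role in any metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import bias_model
from .data_io import Pick, TrialRecord

DISPLAY_W = 1400.0
DISPLAY_H = 1050.0
SPEED = 44.0            # px/s, constant item speed
SET_SIZES = (60, 100, 140, 180)
TARGET_FRACTION = (0.20, 0.30)

FEATURE_COLORS = ("green", "blue", "yellow", "red")
CONJ_CLASSES = ("green-square", "green-circle", "blue-square", "blue-circle")


@dataclass
class DisplayState:
    """Positions, classes and motion state of all items at one instant."""

    xy: np.ndarray            # (n, 2)
    heading: np.ndarray       # (n,) radians
    classes: np.ndarray       # (n,) labels
    is_target: np.ndarray     # (n,) bool
    next_change: np.ndarray   # (n,) absolute time of next heading redraw
    time: float = 0.0
    width: float = DISPLAY_W
    height: float = DISPLAY_H

    @property
    def n_items(self) -> int:
        return len(self.xy)

    @property
    def n_targets(self) -> int:
        return int(self.is_target.sum())

    def target_coords(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.is_target
        return self.xy[m].copy(), self.classes[m].copy()

    def without_item(self, idx: int) -> "DisplayState":
        keep = np.ones(self.n_items, dtype=bool)
        keep[idx] = False
        return replace(self, xy=self.xy[keep], heading=self.heading[keep],
                       classes=self.classes[keep],
                       is_target=self.is_target[keep],
                       next_change=self.next_change[keep])


def gen_display(set_size: int, condition: str,
                rng: np.random.Generator | int,
                target_fraction: float | None = None,
                n_target_classes: int = 1,
                mean_change_interval: float = 1.0) -> DisplayState:
    """Generate a fresh display.

    Items get uniform random positions within the bounds and uniform random
    headings; the target fraction is drawn uniformly in [0.20, 0.30] unless
    given.  In the feature condition items are colored squares with one
    target color; in the conjunction condition classes are color x shape
    cells with one target cell.  ``n_target_classes=2`` splits the targets
    over two class labels — a harness for exercising the class-preference
    and stickiness parameters of the choice model, which are degenerate
    when every target shares one label.
    """
    if set_size < 2:
        raise ValueError("set_size must be >= 2")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    if target_fraction is None:
        target_fraction = rng.uniform(*TARGET_FRACTION)
    n_targets = int(round(set_size * target_fraction))
    pool = FEATURE_COLORS if condition == "feature" else CONJ_CLASSES
    tgt_pool = pool[:n_target_classes]
    classes = np.empty(set_size, dtype=object)
    is_target = np.zeros(set_size, dtype=bool)
    is_target[:n_targets] = True
    classes[:n_targets] = rng.choice(tgt_pool, size=n_targets)
    classes[n_targets:] = rng.choice(pool[n_target_classes:],
                                     size=set_size - n_targets)
    xy = np.column_stack([rng.uniform(0, DISPLAY_W, set_size),
                          rng.uniform(0, DISPLAY_H, set_size)])
    heading = rng.uniform(0, 2 * math.pi, set_size)
    next_change = rng.exponential(mean_change_interval, set_size)
    return DisplayState(xy=xy, heading=heading,
                        classes=classes.astype(str), is_target=is_target,
                        next_change=next_change)


def step_motion(display: DisplayState, dt: float,
                rng: np.random.Generator | int,
                speed: float = SPEED,
                mean_change_interval: float = 1.0) -> DisplayState:
    """Advance every item by ``speed * dt`` px along its heading.

    Headings are redrawn at exponentially distributed intervals (memoryless
    pseudo-random direction changes); walls reflect both position and the
    heading component normal to the wall, so the travelled path length is
    exactly ``speed * dt`` for every item.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    xy = display.xy.copy()
    heading = display.heading.copy()
    next_change = display.next_change.copy()
    t_end = display.time + dt
    t = np.full(display.n_items, display.time)
    # advance all items segment-by-segment (segments end at a heading
    # redraw or at t_end); typically 1-3 rounds for dt of order the mean
    # change interval
    while True:
        active = t < t_end
        if not active.any():
            break
        seg_end = np.minimum(next_change, t_end)
        hop = np.where(active, speed * (seg_end - t), 0.0)
        x = xy[:, 0] + hop * np.cos(heading)
        y = xy[:, 1] + hop * np.sin(heading)
        for axis, pos, hi in ((0, x, display.width),
                              (1, y, display.height)):
            z = np.mod(pos, 2 * hi)
            flip = z > hi
            xy[:, axis] = np.where(flip, 2 * hi - z, z)
            if axis == 0:
                heading = np.where(flip, math.pi - heading, heading)
            else:
                heading = np.where(flip, -heading, heading)
        t = np.where(active, seg_end, t)
        redraw = active & (next_change <= t_end)
        if redraw.any():
            heading[redraw] = rng.uniform(0, 2 * math.pi, int(redraw.sum()))
            next_change[redraw] = next_change[redraw] + rng.exponential(
                mean_change_interval, int(redraw.sum()))
    return replace(display, xy=xy, heading=heading,
                   next_change=next_change, time=t_end)


# ---------------------------------------------------------------------------
# agents


@dataclass
class AgentPolicy:
    """How an agent picks targets and when it quits a patch.

    kind: 'uniform_random' | 'scanner_lr' | 'scanner_tb' | 'spiral'
    | 'bias_model' | 'nearest_fvf'.  Scanner agents sweep bands of
    ``band_width`` px (vertical bands left-to-right, or horizontal bands
    top-to-bottom), picking the first remaining target in lexicographic
    band order.  The spiral agent visits targets by increasing angular
    order around the target centroid.  The ``nearest_fvf`` agent is
    proximity-driven with a limited functional visual field: it takes the
    nearest remaining target within ``fvf_radius`` px of the last pick, and
    jumps to a uniformly random remaining target when none is detectable —
    so its organization degrades as the patch depletes and targets drop
    below the detection radius.  ``n_picks`` is the quit rule (stop after
    that many targets, or when targets run out if fewer remain);
    ``min_targets_left`` quits earlier once targets become scarce.
    """

    kind: str
    bias: bias_model.BiasParams | None = None
    n_picks: int | None = None
    min_targets_left: int = 0
    band_width: float = 50.0
    fvf_radius: float = 300.0
    fvf_gate: bool = False           # bias_model: restrict choices to FVF
    decision_interval: float = 0.7   # s between consecutive picks
    motion: bool = True

    def __post_init__(self) -> None:
        kinds = ("uniform_random", "scanner_lr", "scanner_tb", "spiral",
                 "bias_model", "nearest_fvf")
        if self.kind not in kinds:
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "bias_model" and self.bias is None:
            self.bias = bias_model.BiasParams()


def _pick_index(display: DisplayState, policy: AgentPolicy,
                rng: np.random.Generator,
                prev_xy, prev_class, prev_heading,
                spiral_angle: list[float], class_a: str) -> int:
    """Index (into display items) of the target the policy picks next."""
    tmask = np.flatnonzero(display.is_target)
    coords = display.xy[tmask]
    if policy.kind == "uniform_random":
        return int(tmask[rng.integers(len(tmask))])
    if policy.kind in ("scanner_lr", "scanner_tb"):
        primary = coords[:, 0] if policy.kind == "scanner_lr" else coords[:, 1]
        secondary = coords[:, 1] if policy.kind == "scanner_lr" else coords[:, 0]
        band = np.floor(primary / policy.band_width)
        j = np.lexsort((secondary, band))[0]
        return int(tmask[j])
    if policy.kind == "spiral":
        centroid = coords.mean(axis=0)
        rel = coords - centroid
        if prev_xy is None:
            # start at the innermost target and sweep outward
            j = int(np.argmin(np.linalg.norm(rel, axis=1)))
            spiral_angle[0] = math.atan2(rel[j, 1], rel[j, 0])
            return int(tmask[j])
        ang = np.arctan2(rel[:, 1], rel[:, 0])
        inc = np.mod(ang - spiral_angle[0], 2 * math.pi)
        # advance counterclockwise: nearest candidate in the forward
        # half-turn, so multi-turn layouts are swept one turn at a time
        d = np.linalg.norm(coords - prev_xy, axis=1)
        fwd = np.flatnonzero((inc > 1e-9) & (inc <= math.pi))
        j = int(fwd[np.argmin(d[fwd])]) if len(fwd) else int(np.argmin(d))
        spiral_angle[0] = ang[j]
        return int(tmask[j])
    if policy.kind == "nearest_fvf":
        if prev_xy is None:
            return int(tmask[rng.integers(len(tmask))])
        d = np.linalg.norm(coords - prev_xy, axis=1)
        near = np.flatnonzero(d <= policy.fvf_radius)
        if len(near):
            return int(tmask[near[np.argmin(d[near])]])
        return int(tmask[rng.integers(len(tmask))])
    # bias_model; with fvf_gate the choice set shrinks to the targets
    # inside the functional visual field around the last pick (all
    # targets when none is detectable), so organization degrades as the
    # patch depletes even though the per-choice weights are unchanged
    if policy.fvf_gate and prev_xy is not None:
        d = np.linalg.norm(coords - prev_xy, axis=1)
        near = np.flatnonzero(d <= policy.fvf_radius)
        if len(near):
            tmask, coords = tmask[near], coords[near]
    ctx = bias_model.ChoiceContext(
        coords, display.classes[tmask], class_a,
        prev_xy=prev_xy, prev_class=prev_class, prev_heading=prev_heading)
    probs = bias_model.selection_weights(ctx, policy.bias)
    return int(tmask[rng.choice(len(tmask), p=probs)])


def run_agent(display: DisplayState, policy: AgentPolicy,
              rng: np.random.Generator | int,
              participant_id: str = "sim", age_years: float = 25.0,
              condition: str = "feature", trial_index: int = 0,
              return_snapshots: bool = False):
    """Run one agent through one patch; returns the trial log.

    Motion steps (if enabled) and picks alternate at the policy's decision
    interval; pick-time coordinates are what gets logged, matching the
    a-posteriori scoring convention of the metrics.  With
    ``return_snapshots=True`` also returns, per pick, the remaining-target
    coordinates/classes at choice time plus the chosen local index — the
    display history the choice-model likelihood needs on a moving display.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    n_picks = policy.n_picks if policy.n_picks is not None \
        else display.n_targets
    class_a = bias_model.reference_class(display.target_coords()[1])
    prev_xy = prev_class = prev_heading = None
    spiral_angle = [-math.pi]
    picks: list[Pick] = []
    snapshots: list[tuple[np.ndarray, np.ndarray, int]] = []
    score = 0
    for k in range(n_picks):
        if display.n_targets <= policy.min_targets_left:
            break
        if policy.motion and k > 0:
            display = step_motion(display, policy.decision_interval, rng)
        idx = _pick_index(display, policy, rng, prev_xy, prev_class,
                          prev_heading, spiral_angle, class_a)
        if return_snapshots:
            tmask = np.flatnonzero(display.is_target)
            snapshots.append((display.xy[tmask].copy(),
                              display.classes[tmask].copy(),
                              int(np.searchsorted(tmask, idx))))
        x, y = display.xy[idx]
        cls = str(display.classes[idx])
        picks.append(Pick(order=len(picks) + 1, x=float(x), y=float(y),
                          t=display.time, item_class=cls, is_target=True))
        score += 2
        if prev_xy is not None:
            delta = np.array([x, y]) - prev_xy
            if np.linalg.norm(delta) > 0:
                prev_heading = math.atan2(delta[1], delta[0])
        prev_xy, prev_class = np.array([x, y]), cls
        display = display.without_item(idx)
    trial = TrialRecord(participant_id=participant_id, age_years=age_years,
                        condition=condition, set_size=display.n_items
                        + len(picks), trial_index=trial_index, picks=picks)
    if return_snapshots:
        return trial, snapshots
    return trial


# ---------------------------------------------------------------------------
# lifespan cohort generator


@dataclass
class LifespanConfig:
    """Study-shaped cohort: who forages, how biases drift with age.

    Ages span 4-25 years with ``n_per_age`` observers per integer age
    (21 by default, the study's minimum per-age cell — 462 observers in
    all); ``n_participants`` optionally subsamples the cohort.  Each
    participant gets choice-model parameters whose proximity bias grows
    with ln(age) (organization improving over development); effect sizes
    are linear coefficients on ln(age).  ``trials_per_cell`` patches are
    run per condition x set size cell; the agent collects a fraction of
    the available targets (non-exhaustive) and the display depletes as it
    does, so a scarcity-driven decline in organization emerges in the
    second half of every trial without being scripted.
    """

    ages: tuple[int, int] = (4, 25)
    n_per_age: int = 21
    n_participants: int | None = None
    set_sizes: tuple[int, ...] = SET_SIZES
    conditions: tuple[str, ...] = ("feature", "conjunction")
    trials_per_cell: int = 1
    pick_fraction: float = 0.8        # fraction of targets collected
    rho_d_intercept: float = 0.0
    rho_d_age_slope: float = 1.0      # per unit ln(age)
    rho_theta_mean: float = 0.5
    p_a: float = 0.5
    p_s: float = 0.6
    param_sd: float = 0.25            # between-participant jitter
    fvf_radius: float | None = 300.0  # None disables the detection limit
    decision_interval: float = 0.7


def gen_lifespan_dataset(config: LifespanConfig,
                         rng: np.random.Generator | int,
                         return_snapshots: bool = False):
    """Simulate a lifespan-style cohort; returns (trials, ground truth).

    The truth table holds each participant's generating parameters, for
    parameter-recovery and model-recovery tests.  With
    ``return_snapshots=True`` a third value maps each trial key
    (participant, condition, trial) to its per-pick remaining-target
    snapshots, the display history needed to evaluate the choice-model
    likelihood on the moving displays.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    ages = np.repeat(np.arange(config.ages[0], config.ages[1] + 1),
                     config.n_per_age).astype(float)
    ages = ages + rng.uniform(0, 1, len(ages))  # within-year spread
    if config.n_participants is not None and \
            config.n_participants < len(ages):
        keep = rng.choice(len(ages), config.n_participants, replace=False)
        ages = ages[np.sort(keep)]
    trials: list[TrialRecord] = []
    truth_rows = []
    snapshots: dict[tuple[str, str, int], list] = {}
    for i, age in enumerate(ages):
        pid = f"P{i:04d}"
        rho_d = max(0.0, config.rho_d_intercept
                    + config.rho_d_age_slope * math.log(age)
                    + rng.normal(0, config.param_sd))
        rho_theta = config.rho_theta_mean + rng.normal(0, config.param_sd)
        params = bias_model.BiasParams(p_a=config.p_a, p_s=config.p_s,
                                       rho_d=rho_d, rho_theta=rho_theta)
        truth_rows.append({"participant": pid, "age": age,
                           "p_a": params.p_a, "p_s": params.p_s,
                           "rho_d": rho_d, "rho_theta": rho_theta})
        t_idx = 0
        for cond in config.conditions:
            for ss in config.set_sizes:
                for _ in range(config.trials_per_cell):
                    disp = gen_display(ss, cond, rng)
                    n_picks = max(2, int(round(
                        disp.n_targets * config.pick_fraction)))
                    policy = AgentPolicy(
                        kind="bias_model", bias=params, n_picks=n_picks,
                        fvf_gate=config.fvf_radius is not None,
                        fvf_radius=config.fvf_radius or 0.0,
                        decision_interval=config.decision_interval)
                    out = run_agent(disp, policy, rng,
                                    participant_id=pid, age_years=age,
                                    condition=cond, trial_index=t_idx,
                                    return_snapshots=return_snapshots)
                    if return_snapshots:
                        tr, snaps = out
                        snapshots[(pid, cond, t_idx)] = snaps
                    else:
                        tr = out
                    trials.append(tr)
                    t_idx += 1
    truth = pd.DataFrame(truth_rows)
    if return_snapshots:
        return trials, truth, snapshots
    return trials, truth
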