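"""Sampling-without-replacement target-choice model with class and spatial biases.

At every step of a trial the forager picks one of the remaining targets.
The probability of picking target *j* is proportional to the product of
four weights:

* class preference  ``w_class = p_a``            if j is of the reference
  class A, else ``1 - p_a``;
* class stickiness  ``w_stick = p_s``            if j matches the class of
  the previous pick, else ``1 - p_s``;
* proximity         ``w_prox  = exp(-rho_d * d_j / s)`` with ``d_j`` the
  distance from the previous pick and ``s`` a fixed standardization scale
  (the display diagonal by default);
* direction         ``w_dir   = exp(|rho_theta| * cos(dtheta_j - mu))`` with
  ``dtheta_j`` the signed angle between the heading to j and the previous
  movement direction.  ``mu = 0`` when ``rho_theta >= 0`` (straight-ahead
  perseverance); a negative ``rho_theta`` routes its magnitude to a lateral
  offset ``mu`` (default -pi/2), so the *sign* encodes the side of the bias
  and only ``|rho_theta|`` measures its strength.

The first pick of a trial uses the class weight only; the second adds
stickiness and proximity (no previous heading exists yet).  With the
spatial terms at zero the model reduces exactly to the two-parameter
"bag foraging" model (class preference + stickiness).

Fitting is by maximum likelihood: p_a and p_s are optimized on the logit
scale, rho_d and rho_theta on the natural scale (keeping the neutral point
rho_d = 0 in the interior of the search space), with a small multistart and
observed-information standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess1

DEFAULT_SCALE = math.hypot(1400.0, 1050.0)  # display diagonal, px
DEFAULT_DIRECTION_OFFSET = -math.pi / 2


@dataclass
class BiasParams:
    """Choice-model parameters.

    p_a, p_s in [0, 1]; rho_d >= 0 for a proximity *bias* (a fitted value
    may fall slightly below 0 around neutrality); rho_theta signed, with
    only the magnitude measuring direction-perseverance strength.
    """

    p_a: float = 0.5
    p_s: float = 0.5
    rho_d: float = 0.0
    rho_theta: float = 0.0

    @property
    def abs_rho_theta(self) -> float:
        return abs(self.rho_theta)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_a <= 1.0 and 0.0 <= self.p_s <= 1.0):
            raise ValueError("p_a and p_s must lie in [0, 1]")


NEUTRAL = BiasParams()


@dataclass
class ChoiceContext:
    """State one choice conditions on: remaining targets plus history."""

    coords: np.ndarray                 # (m, 2) remaining target positions
    classes: np.ndarray                # (m,) class labels
    class_a: str                       # reference class for p_a
    prev_xy: np.ndarray | None = None  # previous pick position
    prev_class: str | None = None
    prev_heading: float | None = None  # previous movement direction, rad
    scale: float = DEFAULT_SCALE

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.classes = np.asarray(self.classes)
        if len(self.coords) == 0:
            raise ValueError("choice evaluated with empty remaining set")
        if self.scale <= 0:
            raise ValueError("distance scale must be positive")


def _wrap_angle(a):
    """Wrap to (-pi, pi]."""
    return np.mod(np.asarray(a) + np.pi, 2 * np.pi) - np.pi


def _log_weights(ctx: ChoiceContext, params: BiasParams,
                 direction_offset: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        la, l1a = np.log(params.p_a), np.log(1.0 - params.p_a)
        ls, l1s = np.log(params.p_s), np.log(1.0 - params.p_s)
    is_a = ctx.classes == ctx.class_a
    lw = np.where(is_a, la, l1a)
    if ctx.prev_xy is not None:
        same = ctx.classes == ctx.prev_class
        lw = lw + np.where(same, ls, l1s)
        d = np.linalg.norm(ctx.coords - ctx.prev_xy, axis=1)
        lw = lw - params.rho_d * d / ctx.scale
        if ctx.prev_heading is not None:
            head = np.arctan2(ctx.coords[:, 1] - ctx.prev_xy[1],
                              ctx.coords[:, 0] - ctx.prev_xy[0])
            dtheta = _wrap_angle(head - ctx.prev_heading)
            mu = 0.0 if params.rho_theta >= 0 else direction_offset
            lw = lw + abs(params.rho_theta) * np.cos(dtheta - mu)
    return lw


def selection_weights(ctx: ChoiceContext, params: BiasParams,
                      direction_offset: float = DEFAULT_DIRECTION_OFFSET
                      ) -> np.ndarray:
    """Probability of picking each remaining target; sums to 1.

    If every weight underflows to zero (e.g. p_a = 1 with no class-A target
    remaining) the distribution falls back to uniform over the remaining set.
    """
    lw = _log_weights(ctx, params, direction_offset)
    m = np.max(lw)
    if not np.isfinite(m):
        return np.full(len(lw), 1.0 / len(lw))
    w = np.exp(lw - m)
    return w / w.sum()


# ---------------------------------------------------------------------------
# simulation


def _display_targets(display) -> tuple[np.ndarray, np.ndarray]:
    """Accept a DisplayState-like object or a (coords, classes) pair."""
    if hasattr(display, "target_coords"):
        return display.target_coords()
    coords, classes = display
    return np.asarray(coords, dtype=float), np.asarray(classes)


def reference_class(classes) -> str:
    """Reference class A: lexicographically first target class label."""
    return str(min(np.unique(np.asarray(classes))))


def simulate_sequence(display, params: BiasParams, n_picks: int,
                      rng: np.random.Generator | int,
                      scale: float = DEFAULT_SCALE,
                      direction_offset: float = DEFAULT_DIRECTION_OFFSET,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n_picks`` targets without replacement from a static display.

    Returns ``(coords, classes)`` of the picked targets in pick order.
    Motion between choices is the simulator's job
    (:func:`foragescan.synthetic_data.run_agent`); within a choice the
    display is frozen.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    coords, classes = _display_targets(display)
    if n_picks > len(coords):
        raise ValueError(f"n_picks={n_picks} exceeds {len(coords)} targets")
    class_a = reference_class(classes)
    remaining = list(range(len(coords)))
    prev_xy = prev_heading = prev_class = None
    picked = []
    for _ in range(n_picks):
        ctx = ChoiceContext(coords[remaining], classes[remaining], class_a,
                            prev_xy=prev_xy, prev_class=prev_class,
                            prev_heading=prev_heading, scale=scale)
        probs = selection_weights(ctx, params, direction_offset)
        j = remaining[rng.choice(len(remaining), p=probs)]
        if prev_xy is not None:
            delta = coords[j] - prev_xy
            if np.linalg.norm(delta) > 0:
                prev_heading = math.atan2(delta[1], delta[0])
        prev_xy, prev_class = coords[j], classes[j]
        picked.append(j)
        remaining.remove(j)
    idx = np.array(picked, dtype=int)
    return coords[idx].copy(), classes[idx].copy()


# ---------------------------------------------------------------------------
# likelihood


@dataclass
class ChoiceData:
    """Pre-compiled per-candidate arrays for fast likelihood evaluation.

    All candidate targets of all steps of all trials are concatenated into
    flat arrays; ``offsets`` marks the start of each step's block and
    ``chosen`` indexes the selected candidate within the flat arrays.
    """

    is_a: np.ndarray        # (M,) candidate is reference class
    same: np.ndarray        # (M,) candidate class == previous pick class
    has_stick: np.ndarray   # (M,) step has a previous pick
    nd: np.ndarray          # (M,) distance / scale (0 where no previous pick)
    cos_dt: np.ndarray      # (M,) cos of signed heading difference
    sin_dt: np.ndarray      # (M,)
    has_dir: np.ndarray     # (M,) step has a previous heading
    offsets: np.ndarray     # (n_steps,) block starts
    chosen: np.ndarray      # (n_steps,) flat index of selected candidate
    n_steps: int
    class_a: str
    scale: float = DEFAULT_SCALE
    single_class: bool = False


def compile_choice_data(trials: Sequence[Sequence[ChoiceContext]],
                        chosen: Sequence[Sequence[int]]) -> ChoiceData:
    """Flatten per-step contexts + chosen indices into a ChoiceData."""
    is_a, same, has_stick, nd, cos_dt, sin_dt, has_dir = ([] for _ in range(7))
    offsets, chosen_flat = [], []
    pos = 0
    class_a = None
    scale = DEFAULT_SCALE
    for steps, sel in zip(trials, chosen):
        for ctx, j in zip(steps, sel):
            m = len(ctx.coords)
            class_a = ctx.class_a
            scale = ctx.scale
            offsets.append(pos)
            chosen_flat.append(pos + int(j))
            is_a.append(ctx.classes == ctx.class_a)
            if ctx.prev_xy is None:
                same.append(np.zeros(m, bool))
                has_stick.append(np.zeros(m, bool))
                nd.append(np.zeros(m))
            else:
                same.append(ctx.classes == ctx.prev_class)
                has_stick.append(np.ones(m, bool))
                nd.append(np.linalg.norm(ctx.coords - ctx.prev_xy, axis=1)
                          / ctx.scale)
            if ctx.prev_xy is not None and ctx.prev_heading is not None:
                head = np.arctan2(ctx.coords[:, 1] - ctx.prev_xy[1],
                                  ctx.coords[:, 0] - ctx.prev_xy[0])
                dt = _wrap_angle(head - ctx.prev_heading)
                cos_dt.append(np.cos(dt))
                sin_dt.append(np.sin(dt))
                has_dir.append(np.ones(m, bool))
            else:
                cos_dt.append(np.zeros(m))
                sin_dt.append(np.zeros(m))
                has_dir.append(np.zeros(m, bool))
            pos += m
    cat = np.concatenate
    is_a_arr = cat(is_a)
    data = ChoiceData(
        is_a=is_a_arr, same=cat(same), has_stick=cat(has_stick),
        nd=cat(nd), cos_dt=cat(cos_dt), sin_dt=cat(sin_dt),
        has_dir=cat(has_dir),
        offsets=np.asarray(offsets, dtype=int),
        chosen=np.asarray(chosen_flat, dtype=int),
        n_steps=len(offsets), class_a=str(class_a), scale=scale,
    )
    data.single_class = bool(is_a_arr.all() or (~is_a_arr).all())
    return data


def steps_from_picks(pick_coords, pick_classes, display,
                     scale: float = DEFAULT_SCALE,
                     atol: float = 1e-6,
                     ) -> tuple[list[ChoiceContext], list[int]]:
    """Reconstruct the per-step choice contexts for an observed sequence.

    ``display`` is a static display (or (coords, classes) pair) listing all
    targets; each pick is matched to a remaining target by coordinates.
    Raises ValueError if a pick cannot be found among the remaining targets
    (data inconsistency).
    """
    coords, classes = _display_targets(display)
    pick_coords = np.asarray(pick_coords, dtype=float)
    pick_classes = np.asarray(pick_classes)
    class_a = reference_class(classes)
    remaining = list(range(len(coords)))
    prev_xy = prev_heading = prev_class = None
    steps, chosen = [], []
    for xy in pick_coords:
        d = np.linalg.norm(coords[remaining] - xy, axis=1)
        j_local = int(np.argmin(d))
        if d[j_local] > atol:
            raise ValueError("pick not found among remaining targets "
                             f"(nearest at distance {d[j_local]:.3g})")
        ctx = ChoiceContext(coords[remaining], classes[remaining], class_a,
                            prev_xy=prev_xy, prev_class=prev_class,
                            prev_heading=prev_heading, scale=scale)
        steps.append(ctx)
        chosen.append(j_local)
        j = remaining[j_local]
        if prev_xy is not None:
            delta = coords[j] - prev_xy
            if np.linalg.norm(delta) > 0:
                prev_heading = math.atan2(delta[1], delta[0])
        prev_xy, prev_class = coords[j], classes[j]
        remaining.pop(j_local)
    return steps, chosen


def steps_from_snapshots(snapshots,
                         scale: float = DEFAULT_SCALE,
                         ) -> tuple[list[ChoiceContext], list[int]]:
    """Choice contexts from per-step remaining-target snapshots.

    ``snapshots`` is a sequence of ``(coords, classes, chosen_index)``
    triples, one per pick, as produced by the simulator on a moving
    display.  The reference class is taken from the first snapshot.
    """
    class_a = reference_class(snapshots[0][1])
    prev_xy = prev_heading = prev_class = None
    steps, chosen = [], []
    for coords, classes, j in snapshots:
        coords = np.asarray(coords, dtype=float)
        ctx = ChoiceContext(coords, classes, class_a, prev_xy=prev_xy,
                            prev_class=prev_class,
                            prev_heading=prev_heading, scale=scale)
        steps.append(ctx)
        chosen.append(int(j))
        if prev_xy is not None:
            delta = coords[j] - prev_xy
            if np.linalg.norm(delta) > 0:
                prev_heading = math.atan2(delta[1], delta[0])
        prev_xy, prev_class = coords[j].copy(), classes[j]
    return steps, chosen


def _loglik_arrays(data: ChoiceData, p_a, p_s, rho_d, rho_theta,
                   direction_offset: float) -> float:
    with np.errstate(divide="ignore"):
        la, l1a = np.log(p_a), np.log(1.0 - p_a)
        ls, l1s = np.log(p_s), np.log(1.0 - p_s)
    lw = np.where(data.is_a, la, l1a)
    lw = lw + np.where(data.has_stick,
                       np.where(data.same, ls, l1s), 0.0)
    lw = lw - rho_d * data.nd
    mu = 0.0 if rho_theta >= 0 else direction_offset
    lw = lw + np.where(
        data.has_dir,
        abs(rho_theta) * (data.cos_dt * math.cos(mu)
                          + data.sin_dt * math.sin(mu)),
        0.0)
    # segmented log-sum-exp over each step's candidate block
    step_max = np.maximum.reduceat(lw, data.offsets)
    expanded = np.repeat(step_max, np.diff(
        np.append(data.offsets, len(lw))))
    sums = np.add.reduceat(np.exp(lw - expanded), data.offsets)
    lse = step_max + np.log(sums)
    return float(lw[data.chosen].sum() - lse.sum())


def log_likelihood(data: ChoiceData | tuple, params: BiasParams,
                   direction_offset: float = DEFAULT_DIRECTION_OFFSET
                   ) -> float:
    """Total log-likelihood of the observed choices under ``params``.

    ``data`` is a :class:`ChoiceData` (see :func:`compile_choice_data` /
    :func:`steps_from_picks`) or a ``(steps, chosen)`` pair for one trial.
    """
    if not isinstance(data, ChoiceData):
        steps, chosen = data
        data = compile_choice_data([steps], [chosen])
    return _loglik_arrays(data, params.p_a, params.p_s,
                          params.rho_d, params.rho_theta, direction_offset)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class BiasFit:
    """ML fit of the choice model: estimates, SEs, diagnostics."""

    params: BiasParams
    se: dict[str, float]
    loglik: float
    converged: bool
    flags: list[str] = field(default_factory=list)
    n_steps: int = 0


def _logit(p):
    return math.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + math.exp(-x))


def fit_bias_grouped(snapshots, group_fn=None,
                     scale: float = DEFAULT_SCALE,
                     split_halves: bool = False,
                     fix: dict[str, float] | None = None,
                     prior_sd: dict[str, float] | None = None) -> list[dict]:
    """Fit the choice model separately per group of trials.

    ``snapshots`` maps a trial key (participant, condition, trial) to that
    trial's per-pick snapshots (see the simulator); ``group_fn`` maps a
    trial key to a grouping key (default: participant x condition).  With
    ``split_halves`` each trial's choice steps are split into first/second
    halves and fitted separately, yielding per-bin parameter estimates for
    time-course modelling.  Returns one result row (dict) per group.
    """
    if group_fn is None:
        group_fn = lambda key: (key[0], key[1])  # noqa: E731
    grouped: dict = {}
    for key, snaps in snapshots.items():
        steps, chosen = steps_from_snapshots(snaps, scale=scale)
        if split_halves:
            half = (len(steps) + 1) // 2
            parts = [("bin1", steps[:half], chosen[:half]),
                     ("bin2", steps[half:], chosen[half:])]
        else:
            parts = [("whole", steps, chosen)]
        for label, s, ch in parts:
            if not s:
                continue
            gkey = (*group_fn(key), label) if split_halves \
                else group_fn(key)
            grouped.setdefault(gkey, ([], []))
            grouped[gkey][0].append(s)
            grouped[gkey][1].append(ch)
    rows = []
    for gkey, (trials, sels) in sorted(grouped.items()):
        fit = fit_bias(compile_choice_data(trials, sels), fix=fix,
                       prior_sd=prior_sd)
        row = {"group": gkey,
               "p_a": fit.params.p_a, "p_s": fit.params.p_s,
               "rho_d": fit.params.rho_d,
               "rho_theta": fit.params.rho_theta,
               "abs_rho_theta": fit.params.abs_rho_theta,
               "loglik": fit.loglik, "converged": fit.converged,
               "n_steps": fit.n_steps, "flags": ";".join(fit.flags)}
        row.update({f"se_{k}": v for k, v in fit.se.items()})
        rows.append(row)
    return rows


_START_GRID = [
    (0.0, 0.0, 0.0, 0.0),
    (0.85, 0.85, 1.0, 0.5),
    (-0.85, -0.85, 3.0, -0.5),
]


def fit_bias(data: ChoiceData,
             fix: dict[str, float] | None = None,
             prior_sd: dict[str, float] | None = None,
             direction_offset: float = DEFAULT_DIRECTION_OFFSET) -> BiasFit:
    """Maximum-likelihood fit of the four bias parameters.

    ``fix`` pins parameters at given values (e.g. ``{"rho_d": 0.0,
    "rho_theta": 0.0}`` fits the pure bag model).  If all targets share one
    class, p_a and p_s are unidentifiable: they are pinned at 0.5 and
    flagged.  Standard errors come from the observed information (numerical
    Hessian at the optimum), delta-method-transformed to the probability
    scale for p_a and p_s.

    ``prior_sd`` switches to MAP estimation with independent zero-mean
    Gaussian priors of the given standard deviations on the named
    parameters (working scale), e.g. ``{"rho_d": 5.0, "rho_theta": 2.0}``.
    Useful for very small per-cell fits, where a handful of
    nearest-target choices can otherwise push rho_d to infinity
    (separation); with hundreds of choice steps the penalty is negligible.
    The reported log-likelihood excludes the penalty.
    """
    fix = dict(fix or {})
    flags: list[str] = []
    if data.single_class and ("p_a" not in fix or "p_s" not in fix):
        fix.setdefault("p_a", 0.5)
        fix.setdefault("p_s", 0.5)
        flags.append("class_unidentifiable")

    names = ["p_a", "p_s", "rho_d", "rho_theta"]
    free = [n for n in names if n not in fix]
    if not free:
        raise ValueError("no free parameters to fit")

    def unpack(theta):
        vals = {}
        it = iter(theta)
        for n in names:
            if n in fix:
                vals[n] = fix[n]
            elif n in ("p_a", "p_s"):
                vals[n] = _expit(next(it))
            else:
                vals[n] = float(next(it))
        return vals

    prior_sd = prior_sd or {}

    def penalty(theta):
        if not prior_sd:
            return 0.0
        pen = 0.0
        for x, n in zip(theta, free):
            if n in prior_sd:
                pen += 0.5 * (x / prior_sd[n]) ** 2
        return pen

    def nll(theta):
        v = unpack(theta)
        return -_loglik_arrays(data, v["p_a"], v["p_s"], v["rho_d"],
                               v["rho_theta"], direction_offset) \
            + penalty(theta)

    best = None
    for start in _START_GRID:
        x0 = [s for n, s in zip(names, start) if n in free]
        res = minimize(nll, np.asarray(x0, dtype=float), method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    if not best.success:
        flags.append("non_convergence")

    vals = unpack(best.x)
    # observed information on the working (logit / natural) scale
    se = {n: float("nan") for n in names}
    try:
        H = approx_hess1(best.x, nll)
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag < 0):
            raise np.linalg.LinAlgError("negative variance")
        sd = np.sqrt(diag)
        for i, n in enumerate(free):
            if n in ("p_a", "p_s"):
                p = vals[n]
                se[n] = float(sd[i] * p * (1.0 - p))  # delta method
            else:
                se[n] = float(sd[i])
    except np.linalg.LinAlgError:
        flags.append("information_singular")

    loglik = _loglik_arrays(data, vals["p_a"], vals["p_s"], vals["rho_d"],
                            vals["rho_theta"], direction_offset)
    return BiasFit(
        params=BiasParams(**vals),
        se=se,
        loglik=float(loglik),
        converged=bool(best.success),
        flags=flags,
        n_steps=data.n_steps,
    )
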