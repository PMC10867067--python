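"""Scan-path organization indicators for ordered target-pick sequences.

Four indicators quantify how spatially organized a foraging scan-path is:

* **best-r** — the larger of ``|Pearson(order, x)|`` and ``|Pearson(order, y)|``;
  close to 1 for reading/scanner-like sweeps, low for disorganized picking
  (and, by construction, blind to spiral-like organization).
* **mean ITD** — mean Euclidean distance between consecutive picks (pixels);
  lower means tighter, more organized hops.
* **PAO** — percentage above optimal: how much longer the realized path is
  than the shortest open Hamiltonian path through the same pick locations,
  ``(actual / optimal - 1) * 100``; 0 means the observed order is optimal.
* **intersection rate** — self-crossings of the scan-path polyline between
  non-adjacent segments, divided by the number of picks.

All indicators are computed a posteriori from pick-time coordinates (items
may have moved since); distances, crossings and correlations-up-to-sign make
every indicator invariant to the screen-pixel axis convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .data_io import OrgScores, Pick

#: default size above which the exact DP path solver yields to the heuristic
EXACT_THRESHOLD = 10


def _as_coords(picks) -> np.ndarray:
    """Accept an (n,2) array-like or a sequence of Pick; return float array."""
    if len(picks) and isinstance(picks[0], Pick):
        return np.array([[p.x, p.y] for p in picks], dtype=float)
    a = np.asarray(picks, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError(f"expected (n, 2) coordinates, got shape {a.shape}")
    return a


def path_length(coords) -> float:
    """Total Euclidean length of the polyline through ``coords`` in order."""
    c = _as_coords(coords)
    if len(c) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())


def best_r(picks) -> float:
    """Greater of the two |Pearson| correlations between pick order and x / y.

    Returns NaN if fewer than 3 picks, or if both coordinate axes have zero
    variance.  A single zero-variance axis simply contributes nothing: the
    defined axis alone supplies the value (Pearson is undefined on a constant
    vector, and propagating that as NaN would discard the informative axis).
    """
    c = _as_coords(picks)
    n = len(c)
    if n < 3:
        return float("nan")
    order = np.arange(1, n + 1, dtype=float)
    rs = []
    for axis in (0, 1):
        v = c[:, axis]
        if np.ptp(v) > 0:
            rs.append(abs(pearsonr(order, v).statistic))
    if not rs:
        return float("nan")
    return float(max(rs))


def mean_itd(picks) -> float:
    """Mean Euclidean distance between consecutive picks, in pixels."""
    c = _as_coords(picks)
    if len(c) < 2:
        return float("nan")
    return float(np.linalg.norm(np.diff(c, axis=0), axis=1).mean())


@dataclass
class PathSolution:
    """Shortest-open-path solution over a point set (free endpoints)."""

    order_permutation: np.ndarray
    length: float
    method: str  # 'exact_dp' | 'heuristic_2opt' | 'degenerate'


def _exact_open_path(dist: np.ndarray) -> tuple[np.ndarray, float]:
    """Held–Karp dynamic program over subsets; free start and end points.

    dp[S][j] = length of the shortest path visiting exactly the points in
    bitmask S and ending at j.  O(2^n · n^2) time — fine for n <= ~12.
    """
    n = dist.shape[0]
    full = 1 << n
    INF = math.inf
    dp = np.full((full, n), INF)
    parent = np.full((full, n), -1, dtype=int)
    for j in range(n):
        dp[1 << j, j] = 0.0
    for S in range(full):
        row = dp[S]
        for j in range(n):
            dj = row[j]
            if not np.isfinite(dj):
                continue
            for k in range(n):
                if S & (1 << k):
                    continue
                S2 = S | (1 << k)
                cand = dj + dist[j, k]
                if cand < dp[S2, k]:
                    dp[S2, k] = cand
                    parent[S2, k] = j
    end = int(np.argmin(dp[full - 1]))
    length = float(dp[full - 1, end])
    # reconstruct
    order = []
    S, j = full - 1, end
    while j != -1:
        order.append(j)
        pj = parent[S, j]
        S &= ~(1 << j)
        j = pj
    return np.array(order[::-1], dtype=int), length


def _nn_path(dist: np.ndarray, start: int) -> list[int]:
    n = dist.shape[0]
    unvisited = set(range(n))
    unvisited.remove(start)
    order = [start]
    cur = start
    while unvisited:
        nxt = min(unvisited, key=lambda k: dist[cur, k])
        unvisited.remove(nxt)
        order.append(nxt)
        cur = nxt
    return order


def _path_len(dist: np.ndarray, order: Sequence[int]) -> float:
    o = np.asarray(order)
    return float(dist[o[:-1], o[1:]].sum())


def _two_opt(dist: np.ndarray, order: list[int]) -> list[int]:
    """2-opt for an OPEN path: reversing order[i:j+1] swaps two boundary
    edges (one of which vanishes when the reversed block touches an end)."""
    n = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                a = dist[order[i - 1], order[i]] if i > 0 else 0.0
                b = dist[order[j], order[j + 1]] if j < n - 1 else 0.0
                a2 = dist[order[i - 1], order[j]] if i > 0 else 0.0
                b2 = dist[order[i], order[j + 1]] if j < n - 1 else 0.0
                if a2 + b2 < a + b - 1e-12:
                    order[i:j + 1] = order[i:j + 1][::-1]
                    improved = True
    return order


def optimal_open_path(points, mode: str = "auto",
                      exact_threshold: int = EXACT_THRESHOLD) -> PathSolution:
    """Shortest open Hamiltonian path (free endpoints) through ``points``.

    ``mode='exact'`` runs the subset dynamic program (globally optimal,
    O(2^n)); ``'heuristic'`` takes the best nearest-neighbour construction
    over all starting points and refines it with 2-opt; ``'auto'`` picks
    exact for n <= ``exact_threshold``.
    """
    c = _as_coords(points)
    n = len(c)
    if n == 0:
        raise ValueError("empty point set")
    if n == 1:
        return PathSolution(np.array([0]), 0.0, "degenerate")
    dist = squareform(pdist(c))
    if mode == "auto":
        mode = "exact" if n <= exact_threshold else "heuristic"
    if mode == "exact":
        order, length = _exact_open_path(dist)
        return PathSolution(order, length, "exact_dp")
    if mode != "heuristic":
        raise ValueError(f"unknown mode {mode!r}")
    best: list[int] | None = None
    best_len = math.inf
    for start in range(n):
        order = _two_opt(dist, _nn_path(dist, start))
        length = _path_len(dist, order)
        if length < best_len:
            best, best_len = order, length
    return PathSolution(np.array(best, dtype=int), best_len, "heuristic_2opt")


def pao(picks, exact_threshold: int = EXACT_THRESHOLD) -> float:
    """Percentage above optimal: ``(actual / optimal - 1) * 100``.

    The optimum is the shortest open Hamiltonian path through the same
    pick-time coordinates.  Because the observed order is itself a
    Hamiltonian path, a heuristic "optimum" can never legitimately exceed
    the actual length; if it does, the actual path replaces it (PAO = 0),
    which guarantees PAO >= 0.  NaN for fewer than 3 picks or when all picks
    coincide (optimal length 0).
    """
    c = _as_coords(picks)
    if len(c) < 3:
        return float("nan")
    actual = path_length(c)
    sol = optimal_open_path(c, mode="auto", exact_threshold=exact_threshold)
    optimal = min(sol.length, actual)  # clamp: observed order is a valid path
    if optimal <= 0:
        return float("nan")
    return (actual / optimal - 1.0) * 100.0


def _segments_intersect(p1, p2, q1, q2, eps: float) -> bool:
    """Inclusive segment intersection via orientation / straddle test.

    Touching counts: a shared point, or collinear overlap, is an
    intersection.  ``eps`` absorbs floating error in the cross products.
    """
    def cross2(a, b):
        return a[0] * b[1] - a[1] * b[0]

    d1 = cross2(q2 - q1, p1 - q1)
    d2 = cross2(q2 - q1, p2 - q1)
    d3 = cross2(p2 - p1, q1 - p1)
    d4 = cross2(p2 - p1, q2 - p1)
    if ((d1 > eps and d2 < -eps) or (d1 < -eps and d2 > eps)) and \
       ((d3 > eps and d4 < -eps) or (d3 < -eps and d4 > eps)):
        return True

    def on_segment(a, b, p):
        return (min(a[0], b[0]) - eps <= p[0] <= max(a[0], b[0]) + eps and
                min(a[1], b[1]) - eps <= p[1] <= max(a[1], b[1]) + eps)

    if abs(d1) <= eps and on_segment(q1, q2, p1):
        return True
    if abs(d2) <= eps and on_segment(q1, q2, p2):
        return True
    if abs(d3) <= eps and on_segment(p1, p2, q1):
        return True
    if abs(d4) <= eps and on_segment(p1, p2, q2):
        return True
    return False


def count_intersections(picks) -> int:
    """Number of crossings between non-adjacent scan-path segments.

    Segments sharing an endpoint (adjacent in the pick order) are never
    counted; each crossing pair counts once.  Collinear overlap of two
    non-adjacent segments counts as one, as does a segment passing exactly
    through another's vertex.  Returns 0 for fewer than 4 picks (no two
    non-adjacent segments exist).
    """
    c = _as_coords(picks)
    n = len(c)
    if n < 4:
        return 0
    span = max(np.ptp(c[:, 0]), np.ptp(c[:, 1]), 1.0)
    eps = 1e-9 * span
    count = 0
    for i, j in itertools.combinations(range(n - 1), 2):
        if j == i + 1:
            continue
        if _segments_intersect(c[i], c[i + 1], c[j], c[j + 1], eps):
            count += 1
    return count


def intersection_rate(picks) -> float:
    """Crossings per target collected: ``count_intersections / n_picks``."""
    c = _as_coords(picks)
    if len(c) < 4:
        return float("nan")
    return count_intersections(c) / len(c)


def score_sequence(picks, bin_label: str = "whole",
                   exact_threshold: int = EXACT_THRESHOLD) -> OrgScores:
    """Bundle the four indicators for one pick sequence.

    Accepts Pick objects (distractor picks are dropped first — the metrics
    are defined over collected targets) or bare coordinates.  Indicators
    whose preconditions fail are None with a reason code.
    """
    if len(picks) and isinstance(picks[0], Pick):
        picks = [p for p in picks if p.is_target]
    c = _as_coords(picks) if len(picks) else np.empty((0, 2))
    n = len(c)
    reasons: dict[str, str] = {}

    def guard(name, minimum, fn):
        if n < minimum:
            reasons[name] = "too_few_picks"
            return None
        v = fn(c)
        if isinstance(v, float) and math.isnan(v):
            reasons[name] = ("degenerate_geometry" if name in ("best_r", "pao")
                             else "undefined")
            return None
        return v

    return OrgScores(
        best_r=guard("best_r", 3, best_r),
        mean_itd=guard("mean_itd", 2, mean_itd),
        pao=guard("pao", 3, lambda x: pao(x, exact_threshold)),
        intersection_rate=guard("intersection_rate", 4, intersection_rate),
        n_picks=n,
        bin_label=bin_label,
        reasons=reasons,
    )
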