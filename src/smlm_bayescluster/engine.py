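"""Bayesian scoring of cluster proposals over a parameter grid.

Every labeling produced by a clusterer at one grid point is scored under a
generative model of the localization table:

* each localization is background with prior probability ``p_b`` and then
  uniform on the ROI (density 1/A);
* clustered localizations are partitioned by a Chinese-restaurant-process
  prior with concentration ``alpha``;
* each cluster has a center uniform on the ROI (density 1/A, integrated in
  closed form over the plane) and an isotropic Gaussian spread ``sigma``
  marginalized over a discrete grid with uniform weights;
* localization i is observed with total per-axis variance
  ``sigma^2 + sd_i^2``, so the per-localization precision enters the score
  even though the clusterers never see it.

The log score of a labeling with background set B, clusters 1..K of sizes
n_k and n_c clustered points is::

    sum_B log(p_b / A) + n_c log(1 - p_b)
    + K log(alpha) + sum_k log Gamma(n_k) + log Gamma(alpha) - log Gamma(alpha + n_c)
    + sum_k log m_k

with the cluster marginal likelihood (v_i = sigma^2 + sd_i^2)::

    m_k = mean_sigma (1/A) * prod_{d in x,y} (2 pi)^(-(n_k-1)/2)
          (prod_i v_i)^(-1/2) (sum_i 1/v_i)^(-1/2)
          exp(-1/2 (sum_i d_i^2/v_i - (sum_i d_i/v_i)^2 / sum_i 1/v_i))

Scores are comparable only across proposals on the same table and
parameters.  Scoring is fully deterministic, with a fixed floating-point
summation order, so sequential and parallel runs agree bit for bit.
"""

from __future__ import annotations

import os
from concurrent.futures import ProcessPoolExecutor

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .clusterers import NeighborGraph, dbscan_labels, ripley_labels, tomato_labels
from .types import BayesParams, Proposal, ScoredProposal, ValidationError

__all__ = [
    "ScoreContext",
    "score_labels",
    "make_proposal_grid",
    "run_engine",
    "select_best",
    "EngineError",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class EngineError(RuntimeError):
    """A proposal evaluation failed; the message names the grid point."""


class ScoreContext:
    """Precomputed per-table quantities for fast repeated scoring."""

    def __init__(self, table: pd.DataFrame, params: BayesParams):
        self.params = params
        x = table["x_nm"].to_numpy(dtype=np.float64)
        y = table["y_nm"].to_numpy(dtype=np.float64)
        sd = table["sd_nm"].to_numpy(dtype=np.float64)
        self.xy = np.column_stack([x, y])
        self.n = len(x)
        A = params.roi.area_nm2
        self.log_A = float(np.log(A))
        self.log_bg = float(np.log(params.p_b) - self.log_A)  # per background point
        self.log_fg = float(np.log1p(-params.p_b))  # per clustered point
        self.log_alpha = float(np.log(params.alpha))

        sig = params.sigma_grid_nm
        self.m_sigmas = len(sig)
        v = sig[:, None] ** 2 + sd[None, :] ** 2  # (m, n)
        inv_v = 1.0 / v
        # per-point summands needed for the closed-form cluster marginal
        self._fields = np.stack(
            [inv_v, np.log(v), x * inv_v, x * x * inv_v, y * inv_v, y * y * inv_v]
        )  # (6, m, n)

    def score(self, labels: np.ndarray) -> float:
        labels = np.asarray(labels)
        if labels.shape != (self.n,):
            raise ValidationError("labels length does not match table")
        n_c = int(np.count_nonzero(labels))
        n_b = self.n - n_c
        base = n_b * self.log_bg + n_c * self.log_fg
        if n_c == 0:
            return base
        K = int(labels.max())
        sizes = np.bincount(labels, minlength=K + 1)
        if np.any(sizes[1:] == 0):
            raise ValidationError("labels must be contiguous 1..K (empty label present)")
        n_k = sizes[1:].astype(np.float64)

        order = np.argsort(labels, kind="stable")
        clustered = order[n_b:]  # sorted by label, background first
        starts = np.searchsorted(labels[order], np.arange(1, K + 1)) - n_b
        sums = np.add.reduceat(self._fields[:, :, clustered], starts, axis=2)  # (6, m, K)
        A_k, G, Lx, Qx, Ly, Qy = sums

        alpha = self.params.alpha
        log_per_sigma = (
            -(n_k - 1.0) * _LOG2PI
            - G
            - np.log(A_k)
            - 0.5 * (Qx - Lx * Lx / A_k)
            - 0.5 * (Qy - Ly * Ly / A_k)
            - self.log_A
        )  # (m, K)
        log_m = logsumexp(log_per_sigma, axis=0) - np.log(self.m_sigmas)
        crp = (
            K * self.log_alpha
            + float(np.sum(gammaln(n_k)))
            + float(gammaln(alpha))
            - float(gammaln(alpha + n_c))
        )
        return float(base + crp + np.sum(log_m))


def score_labels(table: pd.DataFrame, labels: np.ndarray, params: BayesParams) -> float:
    """Log posterior score (up to a table-wide constant) of one labeling."""
    return ScoreContext(table, params).score(labels)


def make_proposal_grid(
    r_lo: float, r_hi: float, r_step: float, T_lo: int, T_hi: int, T_step: int
) -> list[tuple[float, int]]:
    """Inclusive Cartesian grid, row-major (r outer, T inner).

    The default search space is r = 5:300:5 nm by T = 5:500:5
    (6000 proposals).
    """
    if r_step <= 0 or T_step <= 0:
        raise ValidationError("grid steps must be > 0")
    if r_lo > r_hi or T_lo > T_hi:
        raise ValidationError("grid bounds must satisfy lo <= hi")
    n_r = int(np.floor((r_hi - r_lo) / r_step + 1e-9)) + 1
    n_t = int(np.floor((T_hi - T_lo) / T_step + 1e-9)) + 1
    rs = [r_lo + i * r_step for i in range(n_r)]
    ts = [int(T_lo + j * T_step) for j in range(n_t)]
    return [(r, t) for r in rs for t in ts]


def _labels_for(graph: NeighborGraph, method: str, T: int,
                cache: dict[bytes, np.ndarray]) -> np.ndarray:
    """Labeling at one grid point, deduplicating identical point subsets.

    For ripley/dbscan the labeling is a pure function of the thresholded
    point mask, so grid points whose masks coincide share one computation.
    """
    if method == "ripley":
        mask = graph.counts >= T
        key = b"r" + np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = ripley_labels(graph, T)
        return cache[key]
    if method == "dbscan":
        core = graph.counts + 1 >= T
        key = b"d" + np.packbits(core).tobytes()
        if key not in cache:
            cache[key] = dbscan_labels(graph, T)
        return cache[key]
    if method == "tomato":
        return tomato_labels(graph, float(T))
    raise ValidationError(f"unknown method {method!r}")


def _eval_r_group(args):
    """Evaluate all thresholds at one radius; used by every execution mode."""
    xy, sd, method, r, Ts, params = args
    try:
        table = pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1], "sd_nm": sd})
        ctx = ScoreContext(table, params)
        graph = NeighborGraph(xy, r)
        label_cache: dict[bytes, np.ndarray] = {}
        score_cache: dict[bytes, float] = {}
        out = []
        for T in Ts:
            labels = _labels_for(graph, method, int(T), label_cache)
            key = labels.tobytes()
            if key not in score_cache:
                score_cache[key] = ctx.score(labels)
            out.append((int(T), labels, score_cache[key]))
        return r, out
    except Exception as exc:  # noqa: BLE001 - re-raised with grid location
        raise EngineError(f"proposal evaluation failed at r={r}, method={method}: {exc}") from exc


def run_engine(
    table: pd.DataFrame,
    method: str,
    grid: list[tuple[float, int]],
    params: BayesParams,
    n_workers: int = 1,
) -> tuple[list[ScoredProposal], ScoredProposal]:
    """Cluster and score every grid point; return all proposals and the best.

    Results are bit-identical for any ``n_workers``: the grid is split into
    per-radius groups that are evaluated independently (in worker processes
    when ``n_workers > 1``) and reassembled in grid order.
    """
    if n_workers < 1:
        raise ValidationError("n_workers must be >= 1")
    if not grid:
        raise ValidationError("empty proposal grid")
    xy = np.column_stack([table["x_nm"].to_numpy(np.float64), table["y_nm"].to_numpy(np.float64)])
    sd = table["sd_nm"].to_numpy(np.float64)

    groups: dict[float, list[int]] = {}
    for r, T in grid:
        groups.setdefault(float(r), []).append(int(T))
    jobs = [(xy, sd, method, r, Ts, params) for r, Ts in groups.items()]

    if n_workers == 1:
        results = [_eval_r_group(job) for job in jobs]
    else:
        n_workers = min(n_workers, len(jobs), os.cpu_count() or 1)
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(_eval_r_group, jobs, chunksize=1))

    by_r = {r: {T: (labels, s) for T, labels, s in out} for r, out in results}
    scored = [
        ScoredProposal(Proposal(method, float(r), int(T)), *by_r[float(r)][int(T)])
        for r, T in grid
    ]
    return scored, select_best(scored)


def select_best(scored: list[ScoredProposal]) -> ScoredProposal:
    """Highest log score; ties broken by smaller r, then smaller T."""
    if not scored:
        raise ValidationError("select_best requires a non-empty list")
    best = scored[0]
    for sp in scored[1:]:
        if sp.log_score > best.log_score or (
            sp.log_score == best.log_score
            and (sp.proposal.r_nm, sp.proposal.T) < (best.proposal.r_nm, best.proposal.T)
        ):
            best = sp
    return best
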