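"""Synthetic SMLM data: ground-truth clusters, blinking emulation, grouping.

Two generators are provided.  :func:`simulate_ground_truth` produces an
idealized localization table in which every clustered localization is an
independent draw around a cluster center — one localization per "molecule".
:func:`simulate_blinking` instead places molecules and lets each switch
between a fluorescent and a dark state frame by frame, so a single molecule
typically produces bursts of localizations spread over consecutive frames,
the artifact that :func:`group_localizations` is designed to undo.

Blinking is emulated directly at the localization level: no camera image is
rendered and no PSF fitting is performed; the localization error is applied
as an isotropic Gaussian with a per-localization precision drawn from the
same gamma law used for the ground-truth generator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import make_table, validate_table
from .types import BlinkConfig, GroundTruthConfig, PlacementError, ValidationError

#: retry budget for rejection-sampled center placement
MAX_PLACEMENT_ATTEMPTS = 1_000_000


def _place_centers(
    rng: np.random.Generator,
    n: int,
    lo_x: float,
    hi_x: float,
    lo_y: float,
    hi_y: float,
    min_sep: float,
) -> np.ndarray:
    """Sequential rejection sampling of n centers with pairwise min distance."""
    if hi_x < lo_x or hi_y < lo_y:
        raise PlacementError("ROI too small for the requested margin")
    centers = np.empty((n, 2))
    placed = 0
    attempts = 0
    min_sep2 = min_sep * min_sep
    while placed < n:
        if attempts >= MAX_PLACEMENT_ATTEMPTS:
            raise PlacementError(
                f"could not place {n} centers at separation {min_sep} nm "
                f"after {attempts} attempts ({placed} placed)"
            )
        attempts += 1
        cand = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])
        if placed:
            d2 = np.sum((centers[:placed] - cand) ** 2, axis=1)
            if np.any(d2 < min_sep2):
                continue
        centers[placed] = cand
        placed += 1
    return centers


def simulate_ground_truth(config: GroundTruthConfig) -> pd.DataFrame:
    """Generate clustered localizations with known labels.

    Exactly ``n_clusters * locs_per_cluster`` clustered rows are drawn from
    isotropic 2-D normals (sd ``cluster_sd_nm``) around rejection-sampled
    centers (pairwise separation >= ``min_center_sep_nm``), plus
    ``round(f/(1-f) * n_clustered)`` uniform background rows, where *f* is
    ``background_fraction``.  Every row then receives an isotropic Gaussian
    localization error with its own precision ``sd_nm``, drawn i.i.d. from
    gamma(shape, rate), so the observed spread of a cluster is
    ``sqrt(cluster_sd_nm^2 + sd_i^2)`` per axis.  ``true_label`` is 0 for
    background and k for cluster k.
    """
    rng = np.random.default_rng(config.seed)
    roi = config.roi
    centers = _place_centers(
        rng, config.n_clusters, 0.0, roi.width_nm, 0.0, roi.height_nm,
        config.min_center_sep_nm,
    )
    n_clustered = config.n_clusters * config.locs_per_cluster
    offsets = rng.normal(0.0, config.cluster_sd_nm, size=(n_clustered, 2))
    pos = np.repeat(centers, config.locs_per_cluster, axis=0) + offsets
    labels = np.repeat(np.arange(1, config.n_clusters + 1), config.locs_per_cluster)

    f = config.background_fraction
    n_bg = int(round(f / (1.0 - f) * n_clustered))
    bg = np.column_stack(
        [rng.uniform(0.0, roi.width_nm, n_bg), rng.uniform(0.0, roi.height_nm, n_bg)]
    )
    xy = np.vstack([pos, bg])
    true_label = np.concatenate([labels, np.zeros(n_bg, dtype=np.int64)])
    sd = rng.gamma(config.precision_shape, 1.0 / config.precision_rate, size=len(xy))
    xy = xy + rng.normal(0.0, 1.0, size=xy.shape) * sd[:, None]
    return make_table(xy[:, 0], xy[:, 1], sd, true_label=true_label)


def stationary_on_fraction(p_off_to_on: float, p_on_to_off: float) -> float:
    """Stationary on-state probability of the discrete two-state chain.

    For switching rates k (per second) and frame time dt the per-frame
    switch probabilities are 1 - exp(-k dt); to first order in k dt the
    stationary fraction equals the continuous duty cycle k_on/(k_on+k_off).
    """
    if p_off_to_on == 0.0:
        return 0.0
    return p_off_to_on / (p_off_to_on + p_on_to_off)


def simulate_blinking(config: BlinkConfig) -> pd.DataFrame:
    """Generate a blinking-fluorophore localization table.

    Molecules are placed uniformly inside non-overlapping disc clusters
    (Poisson count per cluster) and as a uniform Poisson background on the
    remaining ROI area.  Each molecule follows a stationary two-state
    on/off Markov chain over frames with per-frame switching probabilities
    ``1 - exp(-k * exposure_s)``; every on-frame emits one localization at
    the molecule position plus isotropic Gaussian error.

    Returns a table with ``frame`` and ``molecule_id`` columns; molecules in
    cluster k carry ``true_label`` k, background molecules 0.
    """
    rng = np.random.default_rng(config.seed)
    roi = config.roi
    radius = config.cluster_diameter_nm / 2.0
    margin = config.min_cluster_margin_nm + radius
    centers = _place_centers(
        rng, config.n_clusters,
        margin, roi.width_nm - margin, margin, roi.height_nm - margin,
        config.cluster_diameter_nm,  # center distance >= diameter: discs disjoint
    )

    # molecules inside clusters: Poisson count, uniform in the disc
    counts = rng.poisson(config.molecules_per_cluster_mean, size=config.n_clusters)
    mol_pos = []
    mol_label = []
    for k in range(config.n_clusters):
        r = radius * np.sqrt(rng.random(counts[k]))
        theta = rng.uniform(0.0, 2.0 * np.pi, counts[k])
        mol_pos.append(centers[k] + np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
        mol_label.append(np.full(counts[k], k + 1, dtype=np.int64))

    # background molecules: Poisson on the ROI area left free by the discs
    disc_area = config.n_clusters * np.pi * radius**2
    free_area_um2 = (roi.area_nm2 - disc_area) / 1e6
    n_bg = rng.poisson(config.background_molecule_density_um2 * free_area_um2)
    placed = 0
    bg_chunks = []
    while placed < n_bg:
        cand = np.column_stack([
            rng.uniform(0.0, roi.width_nm, n_bg - placed),
            rng.uniform(0.0, roi.height_nm, n_bg - placed),
        ])
        d2 = ((cand[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        keep = cand[np.all(d2 > radius**2, axis=1)]
        bg_chunks.append(keep)
        placed += len(keep)
    if bg_chunks:
        mol_pos.append(np.vstack(bg_chunks))
        mol_label.append(np.zeros(n_bg, dtype=np.int64))
    positions = np.vstack(mol_pos) if mol_pos else np.empty((0, 2))
    labels = np.concatenate(mol_label) if mol_label else np.empty(0, dtype=np.int64)
    n_mol = len(positions)

    # two-state chain, one vectorized step per frame
    p_off_to_on = -np.expm1(-config.k_on * config.exposure_s)
    p_on_to_off = -np.expm1(-config.k_off * config.exposure_s)
    state = rng.random(n_mol) < stationary_on_fraction(p_off_to_on, p_on_to_off)
    emit_mol: list[np.ndarray] = []
    emit_frame: list[np.ndarray] = []
    for frame in range(config.n_frames):
        on = np.flatnonzero(state)
        if on.size:
            emit_mol.append(on)
            emit_frame.append(np.full(on.size, frame, dtype=np.int64))
        u = rng.random(n_mol)
        state = np.where(state, u >= p_on_to_off, u < p_off_to_on)

    if emit_mol:
        mol_idx = np.concatenate(emit_mol)
        frames = np.concatenate(emit_frame)
    else:
        mol_idx = np.empty(0, dtype=np.int64)
        frames = np.empty(0, dtype=np.int64)
    sd = rng.gamma(config.precision_shape, 1.0 / config.precision_rate, size=len(mol_idx))
    err = rng.normal(0.0, 1.0, size=(len(mol_idx), 2)) * sd[:, None]
    xy = positions[mol_idx] + err if len(mol_idx) else np.empty((0, 2))

    # frame-major order (chronological), molecules in index order within a frame
    order = np.lexsort((mol_idx, frames))
    return make_table(
        xy[order, 0], xy[order, 1], sd[order],
        frame=frames[order], molecule_id=mol_idx[order],
        true_label=labels[mol_idx[order]],
    )


def group_localizations(table: pd.DataFrame, dT: int, dX_nm: float) -> pd.DataFrame:
    """Merge repeated localizations of one blinking event into one.

    Localizations are chained in chronological order: a localization at
    frame f joins an existing chain if the chain's last member lies within
    ``dX_nm`` and at a frame in ``[f - dT - 1, f - 1]`` (at most ``dT``
    intervening dark frames).  Each chain accepts at most one localization
    per frame; when several chains qualify, the chain started earliest
    (lowest first row index) wins.  A chain is replaced by a single
    localization at the precision-weighted mean position with combined
    precision ``1/sqrt(sum 1/sd_i^2)`` and the first frame of the chain.
    """
    validate_table(table)
    if "frame" not in table.columns:
        raise ValidationError("group_localizations requires a frame column")
    if dT < 0 or dX_nm < 0:
        raise ValidationError("dT and dX_nm must be non-negative")

    x = table["x_nm"].to_numpy()
    y = table["y_nm"].to_numpy()
    sd = table["sd_nm"].to_numpy()
    fr = table["frame"].to_numpy()
    n = len(table)

    # chain state (python lists; chains are few at any instant)
    c_sum_w: list[float] = []
    c_sum_wx: list[float] = []
    c_sum_wy: list[float] = []
    c_last_x: list[float] = []
    c_last_y: list[float] = []
    c_last_frame: list[int] = []
    c_first_frame: list[int] = []
    c_first_row: list[int] = []
    active: list[int] = []  # indices into the chain arrays, sorted by first_row

    order = np.lexsort((np.arange(n), fr))
    dx2 = dX_nm * dX_nm
    max_gap = dT + 1

    prev_frame = None
    extended: set[int] = set()
    for row in order:
        f = int(fr[row])
        if f != prev_frame:
            active = [c for c in active if f - c_last_frame[c] <= max_gap]
            extended = set()
            prev_frame = f
        w = 1.0 / (sd[row] * sd[row])
        joined = -1
        for c in active:  # ascending first_row: earliest chain wins
            if c in extended or c_last_frame[c] >= f:
                continue
            ddx = c_last_x[c] - x[row]
            ddy = c_last_y[c] - y[row]
            if ddx * ddx + ddy * ddy <= dx2:
                joined = c
                break
        if joined >= 0:
            c_sum_w[joined] += w
            c_sum_wx[joined] += w * x[row]
            c_sum_wy[joined] += w * y[row]
            c_last_x[joined] = x[row]
            c_last_y[joined] = y[row]
            c_last_frame[joined] = f
            extended.add(joined)
        else:
            cid = len(c_sum_w)
            c_sum_w.append(w)
            c_sum_wx.append(w * x[row])
            c_sum_wy.append(w * y[row])
            c_last_x.append(x[row])
            c_last_y.append(y[row])
            c_last_frame.append(f)
            c_first_frame.append(f)
            c_first_row.append(row)
            active.append(cid)

    sum_w = np.array(c_sum_w)
    gx = np.array(c_sum_wx) / sum_w
    gy = np.array(c_sum_wy) / sum_w
    gsd = 1.0 / np.sqrt(sum_w)
    gframe = np.array(c_first_frame, dtype=np.int64)
    first_rows = np.array(c_first_row, dtype=np.int64)

    kwargs = {}
    if "molecule_id" in table.columns:
        kwargs["molecule_id"] = table["molecule_id"].to_numpy()[first_rows]
    if "true_label" in table.columns:
        kwargs["true_label"] = table["true_label"].to_numpy()[first_rows]
    return make_table(gx, gy, gsd, frame=gframe, **kwargs)
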