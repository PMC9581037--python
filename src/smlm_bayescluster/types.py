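"""Core value types shared across the pipeline.

Localization tables themselves are plain :class:`pandas.DataFrame` objects
with the columns ``x_nm``, ``y_nm``, ``sd_nm`` and optionally ``frame``,
``molecule_id`` and ``true_label`` (see :mod:`smlm_bayescluster.io`).  The
small frozen dataclasses here carry everything else: the region of interest,
simulation recipes, the proposal grid entries and the Bayesian prior
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROI",
    "GroundTruthConfig",
    "BlinkConfig",
    "Proposal",
    "BayesParams",
    "ScoredProposal",
    "FormatError",
    "ValidationError",
    "PlacementError",
    "StoreError",
]


class FormatError(ValueError):
    """An input file could not be interpreted as a localization table."""


class ValidationError(ValueError):
    """A table or labeling violates an invariant (e.g. non-positive sd)."""


class PlacementError(RuntimeError):
    """Cluster-center placement failed after the configured retry budget."""


class StoreError(RuntimeError):
    """HDF5 store is missing, incompatible, or flagged incomplete."""


@dataclass(frozen=True)
class ROI:
    """Rectangular field of view with origin at (0, 0), in nm."""

    width_nm: float = 3000.0
    height_nm: float = 3000.0

    def __post_init__(self) -> None:
        if not (self.width_nm > 0 and self.height_nm > 0):
            raise ValidationError("ROI dimensions must be positive")

    @property
    def area_nm2(self) -> float:
        return self.width_nm * self.height_nm

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / 1e6


@dataclass(frozen=True)
class GroundTruthConfig:
    """Recipe for clustered ground-truth localizations.

    Defaults reproduce the standard benchmark condition: ten isotropic
    Gaussian clusters (sd 50 nm) of 100 localizations each, centers at least
    100 nm apart, plus uniform background making up 50% of all localizations
    in a 3000 x 3000 nm field of view.  Localization precisions are drawn
    from a gamma law with shape 5 and rate 0.166667 1/nm (mean 30 nm).
    """

    n_clusters: int = 10
    locs_per_cluster: int = 100
    cluster_sd_nm: float = 50.0
    min_center_sep_nm: float = 100.0
    background_fraction: float = 0.5
    roi: ROI = field(default_factory=ROI)
    precision_shape: float = 5.0
    precision_rate: float = 0.166667
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValidationError("background_fraction must be in [0, 1)")
        if self.min_center_sep_nm < 0:
            raise ValidationError("min_center_sep_nm must be >= 0")
        if not (self.precision_shape > 0 and self.precision_rate > 0):
            raise ValidationError("gamma precision parameters must be > 0")


@dataclass(frozen=True)
class BlinkConfig:
    """Recipe for a blinking-fluorophore experiment at localization level.

    Molecules sit in non-overlapping disc clusters (kept away from the ROI
    border) on top of a uniform background; each molecule switches between a
    fluorescent and a dark state with rates ``k_on``/``k_off`` and emits one
    localization per frame spent on.  Defaults correspond to a dSTORM-like
    dye (duty cycle 1e-3) at the densest benchmark condition: 40 clusters of
    50 nm diameter with on average 49 molecules each.
    """

    n_clusters: int = 40
    cluster_diameter_nm: float = 50.0
    molecules_per_cluster_mean: float = 49.0
    background_molecule_density_um2: float = 346.0
    k_on: float = 0.01
    k_off: float = 10.0
    exposure_s: float = 0.01
    n_frames: int = 50_000
    min_cluster_margin_nm: float = 500.0
    roi: ROI = field(default_factory=ROI)
    precision_shape: float = 5.0
    precision_rate: float = 0.166667
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off <= 0:
            raise ValidationError("require k_on >= 0 and k_off > 0")
        if self.cluster_diameter_nm <= 0 or self.n_frames < 1:
            raise ValidationError("cluster diameter and frame count must be positive")
        if self.exposure_s <= 0:
            raise ValidationError("exposure_s must be > 0")


@dataclass(frozen=True, order=True)
class Proposal:
    """One clusterer invocation: method name plus (radius, threshold)."""

    method: str
    r_nm: float
    T: int

    def __post_init__(self) -> None:
        if self.method not in ("ripley", "dbscan", "tomato"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.r_nm <= 0 or self.T < 1:
            raise ValidationError("require r_nm > 0 and T >= 1")


def default_sigma_grid() -> np.ndarray:
    """20 log-spaced candidate cluster standard deviations, 5-300 nm."""
    return np.geomspace(5.0, 300.0, 20)


@dataclass(frozen=True)
class BayesParams:
    """Prior parameters of the Bayesian scoring model.

    p_b
        Prior probability that a localization is background (default 0.5).
    alpha
        Dirichlet-process concentration of the partition prior (default 20).
    roi
        Field of view; its area enters the uniform background and cluster
        center densities.
    sigma_grid_nm
        Discrete grid of candidate cluster standard deviations over which
        the cluster spread is marginalized with uniform weights.
    """

    p_b: float = 0.5
    alpha: float = 20.0
    roi: ROI = field(default_factory=ROI)
    sigma_grid_nm: np.ndarray = field(default_factory=default_sigma_grid)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_b < 1.0:
            raise ValidationError("p_b must be in (0, 1)")
        if self.alpha <= 0:
            raise ValidationError("alpha must be > 0")
        sig = np.asarray(self.sigma_grid_nm, dtype=float)
        if sig.size == 0 or np.any(sig <= 0):
            raise ValidationError("sigma_grid_nm must be non-empty and positive")
        object.__setattr__(self, "sigma_grid_nm", sig)


@dataclass(frozen=True)
class ScoredProposal:
    """A proposal, its labeling, and its log posterior score.

    Scores are natural-log posteriors up to an additive constant shared by
    all proposals on the same table and parameters; only differences are
    meaningful.
    """

    proposal: Proposal
    labels: np.ndarray
    log_score: float
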