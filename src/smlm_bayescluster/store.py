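"""Single-file HDF5 store for one dataset and its analysis products.

Layout::

    /localizations            table columns as 1-D datasets
    /roi                      width_nm / height_nm as attributes
    /proposals/<method>/<r>_<T>/labels     per-proposal label vector
    /proposals/<method>/scores             (r, T, log_score) per grid point
    /best                     method / r / T attributes of the winner
    /stats                    per-cluster statistics table

Round-trips are bit-identical: coordinates are stored as float64 in nm and
labels as int32.  A ``complete`` flag guards against partially written
proposal sets; readers refuse stores whose ``format_version`` does not
match.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .io import CORE_COLUMNS, OPTIONAL_COLUMNS, validate_table
from .types import ROI, Proposal, ScoredProposal, StoreError

FORMAT_VERSION = 1


def open_store(path: str | Path, mode: str = "r") -> "Store":
    """Open (or create, for mode 'w'/'a') a store at *path*."""
    return Store(path, mode)


class Store:
    """Handle to the single HDF5 file of one analysis run."""

    def __init__(self, path: str | Path, mode: str = "r"):
        path = Path(path)
        if mode == "r" and not path.exists():
            raise FileNotFoundError(path)
        self._h5 = h5py.File(path, mode)
        self.path = path
        version = self._h5.attrs.get("format_version")
        if version is None:
            if self._h5.mode == "r+":
                self._h5.attrs["format_version"] = FORMAT_VERSION
        elif int(version) != FORMAT_VERSION:
            self._h5.close()
            raise StoreError(
                f"{path}: store format version {version} != {FORMAT_VERSION}"
            )

    # -- lifecycle -----------------------------------------------------
    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- localization table -------------------------------------------
    def put_table(self, table: pd.DataFrame) -> None:
        validate_table(table)
        if "localizations" in self._h5:
            del self._h5["localizations"]
        grp = self._h5.create_group("localizations")
        for col in CORE_COLUMNS + OPTIONAL_COLUMNS:
            if col in table.columns:
                grp.create_dataset(col, data=table[col].to_numpy())

    def get_table(self) -> pd.DataFrame:
        if "localizations" not in self._h5:
            raise StoreError(f"{self.path}: no localization table stored")
        grp = self._h5["localizations"]
        data = {col: grp[col][...] for col in CORE_COLUMNS + OPTIONAL_COLUMNS if col in grp}
        return pd.DataFrame(data)

    # -- ROI -----------------------------------------------------------
    def put_roi(self, roi: ROI) -> None:
        grp = self._h5.require_group("roi")
        grp.attrs["width_nm"] = float(roi.width_nm)
        grp.attrs["height_nm"] = float(roi.height_nm)

    def get_roi(self) -> ROI:
        if "roi" not in self._h5:
            raise StoreError(f"{self.path}: no ROI stored")
        a = self._h5["roi"].attrs
        return ROI(width_nm=float(a["width_nm"]), height_nm=float(a["height_nm"]))

    # -- scored proposals ----------------------------------------------
    @staticmethod
    def _grid_key(r_nm: float, T: int) -> str:
        return f"{r_nm:g}_{T:d}"

    def put_scored_proposals(self, method: str, scored: list[ScoredProposal]) -> None:
        """Store labels and scores for one method; atomic via a complete flag."""
        root = self._h5.require_group("proposals")
        if method in root:
            del root[method]
        grp = root.create_group(method)
        grp.attrs["complete"] = False
        rows = np.empty((len(scored), 3), dtype=np.float64)
        for i, sp in enumerate(scored):
            rows[i] = (sp.proposal.r_nm, sp.proposal.T, sp.log_score)
            key = self._grid_key(sp.proposal.r_nm, sp.proposal.T)
            grp.create_dataset(
                f"{key}/labels", data=np.asarray(sp.labels, dtype=np.int32)
            )
        grp.create_dataset("scores", data=rows)
        grp.attrs["complete"] = True

    def get_scored_proposals(self, method: str) -> list[ScoredProposal]:
        try:
            grp = self._h5["proposals"][method]
        except KeyError:
            raise StoreError(f"{self.path}: no proposals stored for {method!r}")
        if not grp.attrs.get("complete", False):
            raise StoreError(
                f"{self.path}: proposal set for {method!r} is incomplete "
                "(interrupted write)"
            )
        out = []
        for r_nm, T, score in grp["scores"][...]:
            key = self._grid_key(float(r_nm), int(T))
            labels = grp[key]["labels"][...]
            out.append(
                ScoredProposal(Proposal(method, float(r_nm), int(T)), labels, float(score))
            )
        return out

    def methods(self) -> list[str]:
        if "proposals" not in self._h5:
            return []
        return sorted(self._h5["proposals"].keys())

    # -- best proposal ---------------------------------------------------
    def put_best(self, best: ScoredProposal) -> None:
        grp = self._h5.require_group("best")
        grp.attrs["method"] = best.proposal.method
        grp.attrs["r_nm"] = float(best.proposal.r_nm)
        grp.attrs["T"] = int(best.proposal.T)
        grp.attrs["log_score"] = float(best.log_score)
        if "labels" in grp:
            del grp["labels"]
        grp.create_dataset("labels", data=np.asarray(best.labels, dtype=np.int32))

    def get_best(self) -> ScoredProposal:
        if "best" not in self._h5:
            raise StoreError(f"{self.path}: no best proposal stored")
        grp = self._h5["best"]
        prop = Proposal(
            str(grp.attrs["method"]), float(grp.attrs["r_nm"]), int(grp.attrs["T"])
        )
        return ScoredProposal(prop, grp["labels"][...], float(grp.attrs["log_score"]))

    # -- statistics ------------------------------------------------------
    def put_stats(self, stats: pd.DataFrame) -> None:
        if "stats" in self._h5:
            del self._h5["stats"]
        grp = self._h5.create_group("stats")
        for col in stats.columns:
            grp.create_dataset(str(col), data=stats[col].to_numpy())

    def get_stats(self) -> pd.DataFrame:
        if "stats" not in self._h5:
            raise StoreError(f"{self.path}: no stats stored")
        grp = self._h5["stats"]
        return pd.DataFrame({col: grp[col][...] for col in grp})
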