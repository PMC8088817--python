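"""Normative atlas: spatial mean/SD of a biomarker over non-epileptic sites.

For any query coordinate the atlas returns the mean and sample SD of the
biomarker over the k closest non-epileptic sites (default k = 60, Euclidean
distance in template mm), after a single one-sided outlier pass: a neighbour
value more than ``outlier_sd`` (default 10) SDs *above* the mean of the other
k-1 neighbours is dropped and the statistics recomputed once.  A channel's z-score against the atlas is
(x - mean)/SD; when the neighbour values are degenerate (SD = 0, e.g. no
events detected anywhere in non-epileptic cortex for that detector/band) the
z-score is NA and stays NA downstream.

When a site that is itself part of the atlas is z-scored, it is left out of
its own neighbourhood (on by default) so calibration is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "NormativeAtlas",
    "ZScoredValue",
    "build_atlas",
    "zscore_value",
    "zscore_table",
    "zscore_cohort",
]


@dataclass
class ZScoredValue:
    z: float  # NaN when sigma == 0
    mu: float
    sigma: float
    n_used: int


@dataclass
class NormativeAtlas:
    """Queryable (mean, SD) map built from non-epileptic site values."""

    site_coords: np.ndarray  # n x 3, mm
    site_values: np.ndarray  # n
    k: int = 60
    outlier_sd: float = 10.0
    metric: str = "euclidean_mm"
    _tree: cKDTree = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.site_coords = np.asarray(self.site_coords, dtype=float).reshape(-1, 3)
        self.site_values = np.asarray(self.site_values, dtype=float)
        n = self.site_coords.shape[0]
        if self.site_values.shape != (n,):
            raise ValueError("one value per site required")
        if not np.all(np.isfinite(self.site_values)):
            raise ValueError("site values must be finite")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if n < self.k:
            raise ValueError(
                f"atlas needs at least k={self.k} sites, got {n} "
                f"(short by {self.k - n})"
            )
        self._tree = cKDTree(self.site_coords)

    # -- queries ------------------------------------------------------------

    def query(
        self, coord: np.ndarray, exclude_index: int | None = None
    ) -> tuple[float, float, int]:
        """(mean, SD, n_used) over the k nearest sites with one outlier pass.

        Distance ties are broken by site index (stable).  ``exclude_index``
        removes one site (leave-self-out) before the neighbour search.
        """
        coord = np.asarray(coord, dtype=float).reshape(3)
        k_query = self.k + (1 if exclude_index is not None else 0)
        k_query = min(k_query, self.site_coords.shape[0])
        dist, idx = self._tree.query(coord, k=k_query)
        idx = np.atleast_1d(idx)
        dist = np.atleast_1d(dist)
        order = np.lexsort((idx, dist))  # stable: distance then site index
        idx = idx[order]
        if exclude_index is not None:
            idx = idx[idx != exclude_index]
        idx = idx[: self.k]
        vals = self.site_values[idx]
        # One-sided outlier pass, jackknifed: each value is compared with the
        # mean + outlier_sd * SD of the OTHER k-1 neighbours.  (With the
        # candidate included, the largest achievable deviation among k values
        # is (k-1)/sqrt(k) SDs — under 8 for k = 60 — so a 10-SD rule could
        # never fire.)  Drops are decided simultaneously in a single pass.
        k = vals.size
        if k > 2:
            s, ss = vals.sum(), (vals**2).sum()
            mean_rest = (s - vals) / (k - 1)
            var_rest = (ss - vals**2 - (k - 1) * mean_rest**2) / (k - 2)
            sd_rest = np.sqrt(np.clip(var_rest, 0.0, None))
            keep = vals <= mean_rest + self.outlier_sd * sd_rest
            vals = vals[keep]
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return mu, sd, int(vals.size)

    def zscore(
        self, x: float, coord: np.ndarray, exclude_index: int | None = None
    ) -> ZScoredValue:
        mu, sd, n_used = self.query(coord, exclude_index=exclude_index)
        return zscore_value(x, mu, sd, n_used)


def build_atlas(
    coords: np.ndarray, values: np.ndarray, k: int = 60, outlier_sd: float = 10.0
) -> NormativeAtlas:
    """Build an atlas from non-epileptic site coordinates and biomarker values."""
    return NormativeAtlas(site_coords=coords, site_values=values, k=k, outlier_sd=outlier_sd)


def zscore_value(x: float, mu: float, sigma: float, n_used: int = 0) -> ZScoredValue:
    z = (x - mu) / sigma if sigma > 0 else float("nan")
    return ZScoredValue(z=z, mu=mu, sigma=sigma, n_used=n_used)


def zscore_table(
    table: pd.DataFrame,
    value_column: str,
    atlas: NormativeAtlas,
    leave_self_out: bool = True,
    coord_columns: tuple[str, str, str] = ("x_mm", "y_mm", "z_mm"),
) -> pd.Series:
    """z-score one biomarker column of a channel table against an atlas.

    When ``leave_self_out`` is set, a channel whose coordinate coincides with
    an atlas site (same point, within 1e-9 mm) is scored with that site
    excluded from its own neighbourhood.
    """
    coords = table[list(coord_columns)].to_numpy(dtype=float)
    vals = table[value_column].to_numpy(dtype=float)
    out = np.empty(len(table))
    for i in range(len(table)):
        excl = None
        if leave_self_out:
            d, j = atlas._tree.query(coords[i], k=1)
            if d < 1e-9:
                excl = int(j)
        out[i] = atlas.zscore(vals[i], coords[i], exclude_index=excl).z
    return pd.Series(out, index=table.index, name=f"z_{value_column}")


def zscore_cohort(
    channel_tables: dict[str, pd.DataFrame],
    value_column: str,
    k_values: tuple[int, ...] = (60,),
    outlier_sd: float = 10.0,
    leave_self_out: bool = True,
) -> dict[int, dict[str, pd.Series]]:
    """z-score a biomarker across a whole cohort for a sweep of k values.

    The atlas for each k pools the non-epileptic, non-artifact sites of every
    patient (all layouts live in the same template space).  Returns
    {k: {patient_id: z series}}.  k values exceeding the available site count
    are skipped.
    """
    coords, values = [], []
    for df in channel_tables.values():
        ok = df["non_epileptic"] & ~df["artifact"]
        coords.append(df.loc[ok, ["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float))
        values.append(df.loc[ok, value_column].to_numpy(dtype=float))
    coords = np.concatenate(coords)
    values = np.concatenate(values)
    out: dict[int, dict[str, pd.Series]] = {}
    for k in k_values:
        if k > len(values):
            continue
        atl = build_atlas(coords, values, k=k, outlier_sd=outlier_sd)
        out[k] = {
            pid: zscore_table(df, value_column, atl, leave_self_out=leave_self_out)
            for pid, df in channel_tables.items()
        }
    return out
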