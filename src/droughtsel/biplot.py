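"""Rank-2 SVD biplot engine for two-way genotype tables.

A two-way table (genotypes × testers, where a tester is a trait, an
index or an environment) is column-centered, optionally column-scaled,
and decomposed as X = U·S·Vᵀ.  Two singular-value partitionings are
supported:

* ``tester`` (tester-focused, column-metric preserving): testers get
  V·S, genotypes get U — tester vector lengths and angles then encode
  column standard deviations and correlations, the view used to compare
  indices and find the ideal one.
* ``symmetric``: both sides get the square root of the singular values —
  the view used for the which-won-where polygon of genotypes and
  environments.

Coordinates are data; plotting is a thin optional layer (:func:`plot_biplot`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .indices import INDEX_NAMES

__all__ = ["TwoWayError", "Biplot", "SectorMap", "two_way_table", "plot_biplot"]


class TwoWayError(ValueError):
    """Invalid two-way table (missing cells, too small, degenerate)."""


def two_way_table(data: pd.DataFrame, mode: str = "GT") -> pd.DataFrame:
    """Build a validated genotypes × testers table.

    Parameters
    ----------
    data
        ``GT`` / ``PCA`` modes: an index table (from
        :func:`droughtsel.indices.index_table`, optionally with a ``csi``
        column).  ``GGE`` mode: a long-format trial table.
    mode
        ``GT``   → testers are YP, YS and the nine indices (plus CSI when
        present), raw values;
        ``PCA``  → testers are the nine indices, standardized to mean 0 /
        sd 1;
        ``GGE``  → testers are the year×condition environments (e.g.
        ``2017N``), cell values are mean yields.
    """
    if mode in ("GT", "PCA"):
        cols = [c for c in ("yp", "ys") if mode == "GT"] + list(INDEX_NAMES)
        if mode == "GT" and "csi" in data.columns:
            cols.append("csi")
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise TwoWayError(f"index table lacks column(s): {missing}")
        table = data[cols].copy()
        table.columns = [c.upper() for c in cols]
        if mode == "PCA":
            sd = table.std(ddof=1)
            if (sd == 0).any():
                raise TwoWayError(
                    f"constant column(s) cannot be standardized: "
                    f"{list(sd.index[sd == 0])}"
                )
            table = (table - table.mean()) / sd
    elif mode == "GGE":
        required = {"genotype", "year", "condition", "yield"}
        if missing := required - set(data.columns):
            raise TwoWayError(f"trial table lacks column(s): {sorted(missing)}")
        table = (
            data.groupby(["genotype", "year", "condition"], sort=False)["yield"]
            .mean()
            .unstack(["year", "condition"])
        )
        table.columns = [f"{y}{c}" for y, c in table.columns]
        table = table[sorted(table.columns)]
    else:
        raise TwoWayError(f"unknown mode {mode!r}; expected GT, PCA or GGE")

    if table.isna().any().any():
        offenders = [
            f"{table.index[g]}/{table.columns[t]}"
            for g, t in zip(*np.where(table.isna().to_numpy()))
        ][:10]
        raise TwoWayError(f"missing cells (genotype/tester): {offenders}")
    if table.shape[0] < 3 or table.shape[1] < 2:
        raise TwoWayError(f"table too small for a biplot: shape {table.shape}")
    table.index = table.index.astype(str)
    table.index.name = "genotype"
    table.attrs["mode"] = mode
    return table


@dataclass(frozen=True)
class SectorMap:
    """Which-won-where partition of the biplot plane.

    The convex hull of genotype points is divided into sectors by the
    perpendiculars from the origin to the hull edges; each tester falls
    in exactly one sector and that sector's hull vertex wins it.
    """

    hull_vertices: list[str]            # counter-clockwise order
    boundary_angles: dict[str, float]   # vertex -> CCW sector-start angle (rad)
    tester_sector: dict[str, str]       # tester -> winning vertex (= sector id)

    @property
    def winners(self) -> dict[str, str]:
        return dict(self.tester_sector)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"tester": t, "sector": s, "winner": s}
                for t, s in self.tester_sector.items()
            ]
        )


@dataclass
class Biplot:
    """Fitted rank-2 biplot of a column-centered two-way table.

    Attributes
    ----------
    row_coords, col_coords
        Rank-2 genotype and tester coordinates (columns ``PC1``/``PC2``).
    singular_values
        All singular values of the processed matrix.
    explained
        Share of total sum of squares per axis (sums to 1 over full rank).
    """

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    singular_values: np.ndarray
    explained: np.ndarray
    centering: str
    scaling: str
    partitioning: str
    processed: pd.DataFrame = field(repr=False)
    rows_full: np.ndarray = field(repr=False)
    cols_full: np.ndarray = field(repr=False)

    @classmethod
    def fit(
        cls,
        table: pd.DataFrame,
        scaling: str = "none",
        partitioning: str = "tester",
    ) -> "Biplot":
        """Center (and optionally scale) columns, SVD, partition.

        Parameters
        ----------
        table
            Validated two-way table from :func:`two_way_table`.
        scaling
            ``none`` or ``unit-sd`` (divide centered columns by their sd).
        partitioning
            ``tester`` (singular values to the tester side) or
            ``symmetric`` (split by square root).
        """
        if partitioning not in ("tester", "symmetric"):
            raise ValueError(f"unknown partitioning {partitioning!r}")
        if scaling not in ("none", "unit-sd"):
            raise ValueError(f"unknown scaling {scaling!r}")
        X = table.to_numpy(dtype=float)
        X = X - X.mean(axis=0, keepdims=True)
        if scaling == "unit-sd":
            sd = X.std(axis=0, ddof=1)
            if (sd == 0).any():
                raise TwoWayError(
                    f"constant column(s): {list(table.columns[sd == 0])}"
                )
            X = X / sd

        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        V = Vt.T
        # resolve SVD sign ambiguity: largest-|loading| per axis positive
        for k in range(len(s)):
            j = np.argmax(np.abs(V[:, k]))
            if V[j, k] < 0:
                V[:, k] *= -1.0
                U[:, k] *= -1.0

        total = float((s**2).sum())
        explained = s**2 / total if total > 0 else np.zeros_like(s)
        if len(s) < 2 or (total > 0 and s[1] ** 2 / total < 1e-12):
            warnings.warn("table is effectively rank 1; axis-2 coordinates ~0",
                          stacklevel=2)

        if partitioning == "tester":
            rows_full = U
            cols_full = V * s
        else:
            root = np.sqrt(s)
            rows_full = U * root
            cols_full = V * root

        axes = [f"PC{k + 1}" for k in range(min(2, rows_full.shape[1]))]
        return cls(
            row_coords=pd.DataFrame(
                rows_full[:, :2], index=table.index, columns=axes
            ),
            col_coords=pd.DataFrame(
                cols_full[:, :2], index=table.columns, columns=axes
            ),
            singular_values=s,
            explained=explained,
            centering="tester-centered",
            scaling=scaling,
            partitioning=partitioning,
            processed=pd.DataFrame(X, index=table.index, columns=table.columns),
            rows_full=rows_full,
            cols_full=cols_full,
        )

    # ------------------------------------------------------------------
    def vector_angles(self) -> pd.DataFrame:
        """Pairwise cosines between rank-2 tester vectors.

        On a tester-focused model of a standardized table the cosine
        approximates the Pearson correlation between the raw columns.
        """
        if self.partitioning != "tester":
            raise ValueError("vector angles require a tester-focused model")
        C = self.col_coords.to_numpy()
        norms = np.linalg.norm(C, axis=1)
        if (norms == 0).any():
            warnings.warn(
                f"zero-length tester vector(s): "
                f"{list(self.col_coords.index[norms == 0])}",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            cos = (C @ C.T) / np.outer(norms, norms)
        np.fill_diagonal(cos, np.where(norms > 0, 1.0, np.nan))
        return pd.DataFrame(
            cos, index=self.col_coords.index, columns=self.col_coords.index
        )

    def which_won_where(self) -> SectorMap:
        """Convex-hull sectors and the winning genotype per tester.

        The winner of a tester is the hull vertex maximizing the inner
        product with the tester vector (equivalent to the perpendicular-
        sector construction).  A tester exactly on a sector boundary
        joins the counter-clockwise sector.
        """
        if self.partitioning != "symmetric":
            raise ValueError("which-won-where requires symmetric partitioning")
        R = self.row_coords.to_numpy()
        if R.shape[1] < 2:
            raise TwoWayError("rank-1 model: polygon view undefined")
        try:
            hull = ConvexHull(R)
        except QhullError as err:
            raise TwoWayError(f"degenerate genotype cloud (collinear?): {err}") from None
        order = hull.vertices  # counter-clockwise in 2D
        vertex_ids = [str(self.row_coords.index[i]) for i in order]
        vertex_pts = R[order]

        # boundary between adjacent vertices v_i, v_j: ray perpendicular to
        # the edge, i.e. where both project equally; oriented outward
        boundaries: dict[str, float] = {}
        m = len(order)
        for k in range(m):
            vi, vj = vertex_pts[k], vertex_pts[(k + 1) % m]
            d = np.array([-(vj - vi)[1], (vj - vi)[0]])
            if d @ (vi + vj) < 0:
                d = -d
            boundaries[vertex_ids[k]] = float(np.arctan2(d[1], d[0]))

        tester_sector: dict[str, str] = {}
        for t, tvec in zip(self.col_coords.index, self.col_coords.to_numpy()):
            dots = vertex_pts @ tvec
            best = dots.max()
            tied = np.where(np.isclose(dots, best, rtol=0, atol=1e-12 * max(1, abs(best))))[0]
            if len(tied) == 1:
                win = tied[0]
            else:
                # boundary tie: the counter-clockwise sector wins
                t_ang = np.arctan2(tvec[1], tvec[0])
                v_ang = np.arctan2(vertex_pts[tied, 1], vertex_pts[tied, 0])
                ccw = np.mod(v_ang - t_ang, 2 * np.pi)
                win = tied[int(np.argmin(ccw))]
            tester_sector[str(t)] = vertex_ids[win]
        return SectorMap(
            hull_vertices=vertex_ids,
            boundary_angles=boundaries,
            tester_sector=tester_sector,
        )

    def ideal_tester_ranking(self) -> pd.DataFrame:
        """Testers ordered by distance to the ideal tester.

        The ideal tester sits on the average-tester axis at the length of
        the longest tester vector; small distance means the tester is
        both representative (aligned with the average) and discriminating
        (long vector).
        """
        if self.partitioning != "tester":
            raise ValueError("ideal-tester ranking requires a tester-focused model")
        C = self.col_coords.to_numpy()
        avg = C.mean(axis=0)
        norm = np.linalg.norm(avg)
        if norm == 0:
            raise ValueError("average tester vector is zero; ideal tester undefined")
        ideal = avg / norm * np.linalg.norm(C, axis=1).max()
        dist = np.linalg.norm(C - ideal, axis=1)
        out = pd.DataFrame(
            {"tester": self.col_coords.index, "distance_to_ideal": dist}
        )
        out = out.sort_values("distance_to_ideal", kind="stable").reset_index(drop=True)
        out.attrs["ideal"] = ideal
        return out

    def pc_score_ranking(self, axes: tuple[int, ...] = (1,)) -> list[str]:
        """Genotypes sorted descending by the summed scores on *axes*.

        Axes are 1-based (PC1, PC2).  Ties break by genotype id.
        """
        for ax in axes:
            if ax < 1 or ax > self.row_coords.shape[1]:
                raise ValueError(f"invalid axis {ax}")
            if self.explained[ax - 1] < 1e-12:
                warnings.warn(f"axis {ax} explains ~0 variance; scores are noise",
                              stacklevel=2)
        score = sum(self.row_coords[f"PC{ax}"] for ax in axes)
        frame = pd.DataFrame({"genotype": score.index.astype(str), "score": score.values})
        frame = frame.sort_values(["score", "genotype"], ascending=[False, True],
                                  kind="stable")
        return frame["genotype"].tolist()

    def reconstruct(self) -> np.ndarray:
        """Full-rank product rows_full @ cols_fullᵀ (= processed matrix)."""
        return self.rows_full @ self.cols_full.T


def plot_biplot(model: Biplot, ax=None, sector_map: SectorMap | None = None):
    """Render genotype points and tester vectors (optional polygon view)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    R = model.row_coords
    C = model.col_coords
    ax.scatter(R["PC1"], R["PC2"], s=10, color="grey", zorder=2)
    for name, (x, y) in C.iterrows():
        ax.annotate(str(name), (x, y), color="tab:blue", fontsize=9)
        ax.plot([0, x], [0, y], color="tab:blue", lw=0.8)
    if sector_map is not None:
        pts = R.loc[sector_map.hull_vertices, ["PC1", "PC2"]].to_numpy()
        poly = np.vstack([pts, pts[:1]])
        ax.plot(poly[:, 0], poly[:, 1], color="black", lw=1)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel(f"PC1 ({100 * model.explained[0]:.1f}%)")
    if len(model.explained) > 1:
        ax.set_ylabel(f"PC2 ({100 * model.explained[1]:.1f}%)")
    return ax
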