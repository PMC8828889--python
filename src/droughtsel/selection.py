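"""Index selection, the CSI composite index, ranking and transgressive segregants.

The composite selection index (CSI) for genotype *i* is

    CSI_i = ½ · Σ_j (r_YP,j + r_YS,j) · index_ij

summed over the *significant* indices j — those whose Pearson correlation
with grain yield is significant under both the non-stress (YP) and the
stress (YS) condition — with the signed correlation coefficients as
weights.  Higher CSI identifies genotypes that combine yield potential
with yield under stress.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .indices import INDEX_NAMES

__all__ = [
    "NoSignificantIndexError",
    "CSIWeights",
    "SegregantReport",
    "pearson_with_p",
    "correlate_with_yield",
    "select_significant",
    "composite_index",
    "rank_by_score",
    "transgressive_segregants",
]


class NoSignificantIndexError(ValueError):
    """No index correlates significantly with yield under both conditions."""


@dataclass(frozen=True)
class CSIWeights:
    """The selected significant indices with their correlation weights."""

    weights: pd.DataFrame  # indexed by index name, columns r_yp, r_ys
    alpha: float
    scope: str = "pooled"

    def __post_init__(self) -> None:
        if len(self.weights) == 0:
            raise NoSignificantIndexError(
                "CSI is undefined: no index is significantly correlated with "
                f"yield under both conditions at alpha={self.alpha}"
            )

    @property
    def index_names(self) -> list[str]:
        return list(self.weights.index)


@dataclass(frozen=True)
class SegregantReport:
    """Transgressive segregants per environment and overall.

    ``positive[env]`` lists lines yielding strictly above the better
    parent in that environment, ``negative[env]`` strictly below the
    worse parent.  ``overall_positive[cond]`` / ``overall_negative[cond]``
    hold lines qualifying in every environment of condition ``cond``.
    """

    positive: dict[str, list[str]]
    negative: dict[str, list[str]]
    overall_positive: dict[str, list[str]] = field(default_factory=dict)
    overall_negative: dict[str, list[str]] = field(default_factory=dict)
    parent_ids: tuple[str, str] = ("", "")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for env in self.positive:
            for g in self.positive[env]:
                rows.append({"environment": env, "direction": "positive", "genotype": g})
            for g in self.negative[env]:
                rows.append({"environment": env, "direction": "negative", "genotype": g})
        for cond in self.overall_positive:
            for g in self.overall_positive[cond]:
                rows.append(
                    {"environment": f"overall_{cond}", "direction": "positive", "genotype": g}
                )
            for g in self.overall_negative.get(cond, []):
                rows.append(
                    {"environment": f"overall_{cond}", "direction": "negative", "genotype": g}
                )
        return pd.DataFrame(rows, columns=["environment", "direction", "genotype"])


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p-value from the t statistic.

    p = 2·P(T_{n−2} > |r|·√(n−2)/√(1−r²)).  Returns (nan, nan) when
    either variable has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations for a correlation test")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        return float("nan"), float("nan")
    r = float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlate_with_yield(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Correlate every index column with YP and with YS over genotypes.

    Parameters
    ----------
    table
        Index table from :func:`droughtsel.indices.index_table` (must
        contain ``yp``, ``ys`` and the index columns).
    alpha
        Significance level for the two-sided t test of r.

    Returns a DataFrame indexed by index name with columns ``r_yp``,
    ``p_yp``, ``r_ys``, ``p_ys``, ``n``, ``significant_both``; the alpha
    used is stored in ``DataFrame.attrs``.  Zero-variance index columns
    are reported as missing with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    present = [c for c in INDEX_NAMES if c in table.columns]
    complete = table.dropna(subset=["yp", "ys"])
    rows = {}
    for name in present:
        col = complete[name].dropna()
        sub = complete.loc[col.index]
        n = len(sub)
        if n < 3:
            raise ValueError(f"fewer than 3 complete genotypes for index {name!r}")
        r_yp, p_yp = pearson_with_p(sub[name].to_numpy(), sub["yp"].to_numpy())
        r_ys, p_ys = pearson_with_p(sub[name].to_numpy(), sub["ys"].to_numpy())
        if np.isnan(r_yp) or np.isnan(r_ys):
            warnings.warn(f"index {name!r} has zero variance; correlation undefined",
                          stacklevel=2)
        rows[name] = {
            "r_yp": r_yp,
            "p_yp": p_yp,
            "r_ys": r_ys,
            "p_ys": p_ys,
            "n": n,
            "significant_both": bool(p_yp < alpha and p_ys < alpha),
        }
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "index"
    report.attrs["alpha"] = alpha
    report.attrs["scope"] = table.attrs.get("scope", "pooled")
    return report


def select_significant(
    report: pd.DataFrame, require_positive: bool = False
) -> CSIWeights:
    """Pick the indices significant under both conditions as CSI weights.

    Weights keep the sign of the correlation.  With ``require_positive``
    only positively correlated indices qualify.  Raises
    :class:`NoSignificantIndexError` when nothing qualifies.
    """
    alpha = report.attrs.get("alpha", 0.05)
    keep = report["significant_both"].fillna(False)
    if require_positive:
        keep &= (report["r_yp"] > 0) & (report["r_ys"] > 0)
    selected = report.loc[keep, ["r_yp", "r_ys"]]
    # canonical publication order
    order = [n for n in INDEX_NAMES if n in selected.index]
    return CSIWeights(
        weights=selected.loc[order],
        alpha=alpha,
        scope=report.attrs.get("scope", "pooled"),
    )


def composite_index(table: pd.DataFrame, weights: CSIWeights) -> pd.Series:
    """CSI_i = ½ Σ_j (r_YP,j + r_YS,j)·index_ij for each genotype.

    Genotypes missing any weighted index get NaN.
    """
    missing = [n for n in weights.index_names if n not in table.columns]
    if missing:
        raise ValueError(f"index table lacks weighted column(s): {missing}")
    w = 0.5 * (weights.weights["r_yp"] + weights.weights["r_ys"])
    values = table[weights.index_names]
    csi = values.mul(w, axis=1).sum(axis=1, min_count=len(w))
    csi.name = "csi"
    n_missing = int(csi.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} genotype(s) missing an index value; CSI set to NaN",
                      stacklevel=2)
    return csi


def rank_by_score(scores: pd.Series, top_k: int | None = None) -> list[str]:
    """Genotypes in descending score order; ties broken by genotype id.

    ``top_k`` limits the list; asking for more than available returns
    everything with a warning.
    """
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    scores = scores.dropna()
    ordered = scores.to_frame("score").reset_index()
    ordered.columns = ["genotype", "score"]
    ordered["genotype"] = ordered["genotype"].astype(str)
    ordered = ordered.sort_values(
        ["score", "genotype"], ascending=[False, True], kind="stable"
    )
    ids = ordered["genotype"].tolist()
    if top_k is None:
        return ids
    if top_k > len(ids):
        warnings.warn(
            f"top_k={top_k} exceeds population size {len(ids)}; returning all",
            stacklevel=2,
        )
        return ids
    return ids[:top_k]


def transgressive_segregants(
    trial: pd.DataFrame,
    parent_ids: tuple[str, str],
    require_all_envs: bool = True,
    atol: float = 1e-9,
) -> SegregantReport:
    """Find lines yielding strictly outside the parental range.

    Per environment (year × condition), *positive* segregants yield above
    the better parent and *negative* below the worse parent (strict
    inequalities; equalling a parent — within the absolute tie tolerance
    ``atol``, in t ha⁻¹ — does not qualify).  When
    ``require_all_envs`` is set, the overall lists per condition contain
    the lines qualifying in every environment of that condition.
    Environments where a parent is missing are skipped with a warning.
    """
    p1, p2 = parent_ids
    cell = (
        trial.groupby(["genotype", "year", "condition"], sort=False)["yield"]
        .mean()
        .reset_index()
    )
    if "entry_type" in trial.columns:
        lines = set(
            trial.loc[trial["entry_type"] == "line", "genotype"].astype(str)
        )
    else:
        lines = set(cell["genotype"].astype(str)) - {str(p1), str(p2)}

    positive: dict[str, list[str]] = {}
    negative: dict[str, list[str]] = {}
    env_cond: dict[str, str] = {}
    for (year, cond), env_df in cell.groupby(["year", "condition"], sort=False):
        env = f"{year}{cond}"
        by_geno = env_df.set_index(env_df["genotype"].astype(str))["yield"]
        if str(p1) not in by_geno.index or str(p2) not in by_geno.index:
            warnings.warn(f"parent missing in environment {env}; skipped", stacklevel=2)
            continue
        hi = max(by_geno[str(p1)], by_geno[str(p2)])
        lo = min(by_geno[str(p1)], by_geno[str(p2)])
        line_yields = by_geno[by_geno.index.isin(lines)]
        positive[env] = sorted(line_yields.index[line_yields > hi + atol])
        negative[env] = sorted(line_yields.index[line_yields < lo - atol])
        env_cond[env] = str(cond)

    overall_pos: dict[str, list[str]] = {}
    overall_neg: dict[str, list[str]] = {}
    if require_all_envs:
        for cond in sorted(set(env_cond.values())):
            envs = [e for e, c in env_cond.items() if c == cond]
            pos_sets = [set(positive[e]) for e in envs]
            neg_sets = [set(negative[e]) for e in envs]
            overall_pos[cond] = sorted(set.intersection(*pos_sets)) if pos_sets else []
            overall_neg[cond] = sorted(set.intersection(*neg_sets)) if neg_sets else []
    return SegregantReport(
        positive=positive,
        negative=negative,
        overall_positive=overall_pos,
        overall_negative=overall_neg,
        parent_ids=(str(p1), str(p2)),
    )
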