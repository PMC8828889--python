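"""Yield-based drought tolerance and susceptibility indices.

Nine scalar indices computed from a genotype's grain yield under
non-stress (YP) and drought-stress (YS) conditions, together with the
population means Ȳ_P and Ȳ_S over all entries:

====  =======================================  ==========================
name  formula                                  reads as
====  =======================================  ==========================
SSI   (1 − YS/YP) / (1 − Ȳ_S/Ȳ_P)              stress susceptibility index
RSI   (YS/YP) / (Ȳ_S/Ȳ_P)                      relative stress index
TOL   YP − YS                                  tolerance (t ha⁻¹)
MP    (YP + YS) / 2                            mean productivity (t ha⁻¹)
YSI   YS / YP                                  yield stability index
HM    2·YP·YS / (YP + YS)                      harmonic mean (t ha⁻¹)
GMP   √(YP·YS)                                 geometric mean productivity
STI   YP·YS / Ȳ_P²                             stress tolerance index
YI    YS / Ȳ_S                                 yield index
====  =======================================  ==========================

All functions accept a "pairs" table: a :class:`pandas.DataFrame` with
columns ``genotype``, ``yp``, ``ys`` (yields in t ha⁻¹) and optionally
``entry_type`` (``line`` / ``parent`` / ``check``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "INDEX_NAMES",
    "PopulationMeans",
    "population_means",
    "index_table",
    "yield_reduction",
    "paired_yields",
]

#: Index columns in canonical (publication) order.
INDEX_NAMES = ("ssi", "rsi", "tol", "mp", "ysi", "hm", "gmp", "sti", "yi")

_PAIR_COLS = ("genotype", "yp", "ys")


@dataclass(frozen=True)
class PopulationMeans:
    """Population mean yields Ȳ_P (non-stress) and Ȳ_S (stress).

    Computed over all entries supplied (lines, parents and checks by
    default); these means are the denominators of SSI, RSI, STI and YI.
    """

    ybar_p: float
    ybar_s: float
    n_entries: int

    def __post_init__(self) -> None:
        if self.n_entries < 2:
            raise ValueError("population means need at least 2 entries")
        if not (np.isfinite(self.ybar_p) and np.isfinite(self.ybar_s)):
            raise ValueError("population means must be finite")
        if self.ybar_p <= 0:
            raise ValueError(f"non-stress mean must be positive, got {self.ybar_p}")
        if self.ybar_s < 0:
            raise ValueError(f"stress mean must be non-negative, got {self.ybar_s}")

    @property
    def stress_intensity(self) -> float:
        """1 − Ȳ_S/Ȳ_P, the population-level relative yield loss."""
        return 1.0 - self.ybar_s / self.ybar_p


def _validate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _PAIR_COLS if c not in pairs.columns]
    if missing:
        raise ValueError(f"pairs table is missing column(s): {missing}")
    if len(pairs) == 0:
        raise ValueError("pairs table is empty")
    yields = pairs[["yp", "ys"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(yields)):
        raise ValueError("pairs table contains non-finite yields")
    if (yields < 0).any():
        bad = pairs.loc[(yields < 0).any(axis=1), "genotype"].tolist()
        raise ValueError(f"negative yields for genotype(s): {bad}")
    return pairs


def population_means(
    pairs: pd.DataFrame, entry_types: list[str] | None = None
) -> PopulationMeans:
    """Arithmetic mean yields over all supplied entries.

    Parameters
    ----------
    pairs
        Paired-yield table (``genotype``, ``yp``, ``ys`` [, ``entry_type``]).
    entry_types
        Restrict the mean to these entry types (e.g. ``["line"]``).
        Default: every entry in the table, matching the convention of
        taking the total mean of lines together with the check varieties.
    """
    pairs = _validate_pairs(pairs)
    if entry_types is not None:
        if "entry_type" not in pairs.columns:
            raise ValueError("entry_types filter given but pairs has no entry_type column")
        pairs = pairs[pairs["entry_type"].isin(entry_types)]
        if len(pairs) < 2:
            raise ValueError("fewer than 2 entries left after entry-type filtering")
    return PopulationMeans(
        ybar_p=float(pairs["yp"].mean()),
        ybar_s=float(pairs["ys"].mean()),
        n_entries=int(len(pairs)),
    )


def index_table(pairs: pd.DataFrame, means: PopulationMeans | None = None) -> pd.DataFrame:
    """Compute the nine indices for every genotype in *pairs*.

    Returns a DataFrame indexed by genotype with columns ``yp``, ``ys``
    and the nine indices (see module docstring).  Genotypes with YP = 0
    get NaN for the ratio indices (YSI, SSI, RSI) with a warning; the
    degenerate case Ȳ_S = Ȳ_P (SSI denominator zero) is a hard error.

    The population means default to the means of *pairs* itself.
    """
    pairs = _validate_pairs(pairs)
    if means is None:
        means = population_means(pairs)
    if means.ybar_s <= 0:
        raise ValueError("stress population mean must be positive to compute RSI/YI")
    if means.stress_intensity == 0:
        raise ValueError(
            "SSI undefined: population means equal under stress and non-stress "
            "(1 - Ybar_S/Ybar_P = 0)"
        )

    yp = pairs["yp"].to_numpy(dtype=float)
    ys = pairs["ys"].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(yp > 0, ys / yp, np.nan)
    n_undef = int(np.sum(yp == 0))
    if n_undef:
        warnings.warn(
            f"{n_undef} genotype(s) have YP=0; YSI/SSI/RSI reported as missing",
            stacklevel=2,
        )

    sum_py = yp + ys
    with np.errstate(divide="ignore", invalid="ignore"):
        hm = np.where(sum_py > 0, 2.0 * yp * ys / sum_py, 0.0)

    table = pd.DataFrame(
        {
            "yp": yp,
            "ys": ys,
            "ssi": (1.0 - ratio) / means.stress_intensity,
            "rsi": ratio / (means.ybar_s / means.ybar_p),
            "tol": yp - ys,
            "mp": sum_py / 2.0,
            "ysi": ratio,
            "hm": hm,
            "gmp": np.sqrt(yp * ys),
            "sti": yp * ys / means.ybar_p**2,
            "yi": ys / means.ybar_s,
        },
        index=pd.Index(pairs["genotype"], name="genotype"),
    )
    table.attrs["population_means"] = means
    return table


def yield_reduction(yp, ys) -> float | np.ndarray:
    """Percent yield reduction under stress, 100·(YP − YS)/YP.

    Accepts scalars or arrays; YP must be strictly positive.
    """
    yp = np.asarray(yp, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if np.any(yp <= 0):
        raise ValueError("yield reduction undefined for YP <= 0")
    out = 100.0 * (yp - ys) / yp
    return float(out) if out.ndim == 0 else out


def paired_yields(trial: pd.DataFrame, scope: str = "pooled") -> pd.DataFrame:
    """Collapse a long-format trial table into paired (YP, YS) means.

    Parameters
    ----------
    trial
        Long-format records with columns ``genotype``, ``entry_type``,
        ``year``, ``condition`` (``N``/``D``) and ``yield``.
    scope
        A year label to use that year only, or ``"pooled"`` for the
        arithmetic mean of per-year genotype means over all years.

    Genotypes missing either condition in the scope are dropped with a
    warning.  The returned frame has columns ``genotype``, ``entry_type``,
    ``yp``, ``ys`` and carries ``scope`` in ``DataFrame.attrs``.
    """
    required = {"genotype", "year", "condition", "yield"}
    missing = required - set(trial.columns)
    if missing:
        raise ValueError(f"trial table is missing column(s): {sorted(missing)}")
    sub = trial if scope == "pooled" else trial[trial["year"].astype(str) == str(scope)]
    if len(sub) == 0:
        raise ValueError(f"no records for scope {scope!r}")

    # per-year genotype means first, then average over years: each year
    # contributes equally to the pooled value regardless of replication
    per_year = (
        sub.groupby(["genotype", "condition", "year"], sort=False)["yield"]
        .mean()
        .groupby(["genotype", "condition"], sort=False)
        .mean()
        .unstack("condition")
    )
    for cond in ("N", "D"):
        if cond not in per_year.columns:
            raise ValueError(f"scope {scope!r} has no records under condition {cond!r}")
    incomplete = per_year.index[per_year[["N", "D"]].isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} genotype(s) missing a condition in scope "
            f"{scope!r}: {list(incomplete)[:10]}",
            stacklevel=2,
        )
        per_year = per_year.drop(index=incomplete)

    pairs = pd.DataFrame(
        {
            "genotype": per_year.index,
            "yp": per_year["N"].to_numpy(),
            "ys": per_year["D"].to_numpy(),
        }
    )
    if "entry_type" in trial.columns:
        etype = trial.drop_duplicates("genotype").set_index("genotype")["entry_type"]
        pairs["entry_type"] = etype.reindex(pairs["genotype"]).to_numpy()
    pairs.attrs["scope"] = str(scope)
    return pairs
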