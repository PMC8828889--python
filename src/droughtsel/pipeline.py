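"""End-to-end screening pipeline: indices → correlations → CSI → biplots → segregants.

:func:`run_pipeline` runs every stage per scope (each trial year and the
pooled means), writes CSV outputs and a JSON summary into an output
directory, and returns the summary.  Any stage failure leaves the
completed outputs on disk together with a manifest of finished stages
before the error propagates.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .biplot import Biplot, two_way_table
from .indices import index_table, paired_yields, population_means, yield_reduction
from .io import read_trial
from .selection import (
    NoSignificantIndexError,
    composite_index,
    correlate_with_yield,
    rank_by_score,
    select_significant,
    transgressive_segregants,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("droughtsel")


@dataclass
class RunConfig:
    """Options of a full pipeline run (mirrors the CLI flags)."""

    input: str | Path
    out_dir: str | Path
    input_format: str = "long"
    scope: str = "both"               # per-year | pooled | both
    alpha: float = 0.05
    entry_types: tuple[str, ...] | None = None
    require_positive: bool = False
    gge_scaling: str = "none"         # GGE biplot column scaling
    top_k: int = 10
    parent_ids: tuple[str, str] | None = None
    require_all_envs: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.scope not in ("per-year", "pooled", "both"):
            raise ValueError(f"unknown scope {self.scope!r}")
        self.input = Path(self.input)
        if not self.input.exists():
            raise FileNotFoundError(f"input file not found: {self.input}")
        self.out_dir = Path(self.out_dir)


def _scope_stages(trial: pd.DataFrame, scope: str, config: RunConfig,
                  out: Path) -> dict:
    """Indices, correlations, CSI and GT biplots for one scope."""
    summary: dict = {"scope": scope}
    pairs = paired_yields(trial, scope=scope)
    means = population_means(pairs, entry_types=config.entry_types)
    table = index_table(pairs, means)
    table.attrs["scope"] = scope
    summary["population_means"] = {
        "ybar_p": means.ybar_p, "ybar_s": means.ybar_s, "n_entries": means.n_entries,
    }
    summary["yield_reduction_pct"] = yield_reduction(means.ybar_p, means.ybar_s)
    table.to_csv(out / f"indices_{scope}.csv")

    report = correlate_with_yield(table, alpha=config.alpha)
    report.to_csv(out / f"correlations_{scope}.csv")

    try:
        weights = select_significant(report, require_positive=config.require_positive)
    except NoSignificantIndexError as err:
        warnings.warn(f"scope {scope}: {err}", stacklevel=2)
        summary["csi"] = None
        weights = None
    if weights is not None:
        csi = composite_index(table, weights)
        ranked = rank_by_score(csi, top_k=None)
        scores = csi.loc[ranked].to_frame()
        scores["rank"] = range(1, len(scores) + 1)
        scores.to_csv(out / f"csi_{scope}.csv")
        summary["csi"] = {
            "weights": {
                name: {"r_yp": float(r.r_yp), "r_ys": float(r.r_ys)}
                for name, r in weights.weights.iterrows()
            },
            "alpha": weights.alpha,
            "top": ranked[: config.top_k],
        }
        table = table.join(csi)

    # GT biplot: tester-focused for index comparison, symmetric for
    # the which-won-where polygon
    gt = two_way_table(table, mode="GT")
    tester = Biplot.fit(gt, scaling="unit-sd", partitioning="tester")
    tester.col_coords.to_csv(out / f"gt_tester_coords_{scope}.csv")
    tester.row_coords.to_csv(out / f"gt_genotype_coords_{scope}.csv")
    tester.ideal_tester_ranking().to_csv(out / f"gt_ideal_ranking_{scope}.csv",
                                         index=False)
    symmetric = Biplot.fit(gt, scaling="unit-sd", partitioning="symmetric")
    symmetric.which_won_where().to_frame().to_csv(
        out / f"gt_sectors_{scope}.csv", index=False
    )
    summary["gt_biplot"] = {
        "explained_pc1": float(tester.explained[0]),
        "explained_pc2": float(tester.explained[1]),
        "ideal_nearest": tester.ideal_tester_ranking()["tester"].iloc[0],
    }
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write outputs + ``report.json`` to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    caught: list[str] = []
    summary: dict = {
        "version": __version__,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in asdict(config).items()},
        "scopes": {},
        "warnings": caught,
        "completed_stages": completed,
    }

    def _finish(error: str | None = None) -> None:
        if error is not None:
            summary["error"] = error
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, default=str)

    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            trial = read_trial(config.input, fmt=config.input_format)
            completed.append("read_trial")

            years = sorted(trial["year"].unique())
            scopes = []
            if config.scope in ("per-year", "both"):
                scopes += years
            if config.scope in ("pooled", "both"):
                scopes.append("pooled")
            for scope in scopes:
                summary["scopes"][str(scope)] = _scope_stages(
                    trial, str(scope), config, out
                )
                completed.append(f"scope:{scope}")

            # GGE which-won-where over year×condition environments
            if len(years) >= 1:
                gge = two_way_table(trial, mode="GGE")
                if gge.shape[1] >= 2:
                    model = Biplot.fit(gge, scaling=config.gge_scaling,
                                       partitioning="symmetric")
                    model.row_coords.to_csv(out / "gge_genotype_coords.csv")
                    model.col_coords.to_csv(out / "gge_env_coords.csv")
                    sectors = model.which_won_where()
                    sectors.to_frame().to_csv(out / "gge_sectors.csv", index=False)
                    summary["gge_biplot"] = {
                        "explained_pc1": float(model.explained[0]),
                        "explained_pc2": float(model.explained[1]),
                        "winners": sectors.winners,
                    }
                    completed.append("gge_biplot")

            if config.parent_ids is not None:
                seg = transgressive_segregants(
                    trial, config.parent_ids,
                    require_all_envs=config.require_all_envs,
                )
                seg.to_frame().to_csv(out / "segregants.csv", index=False)
                summary["segregants"] = {
                    "overall_positive": seg.overall_positive,
                    "overall_negative": seg.overall_negative,
                    "per_environment_positive": seg.positive,
                    "per_environment_negative": seg.negative,
                }
                completed.append("segregants")

        caught.extend(str(w.message) for w in wrec)
        for msg in caught:
            log.warning(msg)
    except Exception as err:  # manifest of completed stages, then re-raise
        _finish(error=f"{type(err).__name__}: {err}")
        raise
    _finish()
    return summary
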