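"""Reading and writing trial tables and configuration files.

The canonical on-disk format is a long CSV (comma separator, UTF-8, ``.``
decimal, header mandatory) with columns ``genotype``, ``entry_type``,
``year``, ``condition``, ``yield``; a wide format with one row per
genotype and columns like ``2017_N`` is also accepted.  Condition labels
are normalized to ``N``/``D`` through a configurable alias table.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["CONDITION_ALIASES", "read_trial", "write_trial", "load_config"]

#: Default condition-label aliases (matched case-insensitively).
CONDITION_ALIASES = {
    "n": "N", "normal": "N", "non-stress": "N", "nonstress": "N", "ns": "N",
    "d": "D", "s": "D", "stress": "D", "drought": "D", "drought-stress": "D",
}


def _normalize_conditions(values: pd.Series, aliases: dict[str, str]) -> pd.Series:
    mapped = values.astype(str).str.strip().str.lower().map(aliases)
    if mapped.isna().any():
        bad = values[mapped.isna()].unique().tolist()
        raise ValueError(f"unknown condition label(s): {bad}")
    return mapped


def read_trial(
    path: str | Path,
    fmt: str = "long",
    aliases: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a trial CSV; returns the long-format table.

    Duplicate (genotype, year, condition) records are averaged with a
    warning.  Non-numeric yields and unknown condition labels raise with
    the offending row (1-based, counting the header as row 1) or label.
    """
    aliases = {k.lower(): v for k, v in (aliases or CONDITION_ALIASES).items()}
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, encoding="utf-8", skipinitialspace=True)
    raw.columns = [c.strip().lower() for c in raw.columns]

    if fmt == "long":
        required = ["genotype", "year", "condition", "yield"]
        if missing := [c for c in required if c not in raw.columns]:
            raise ValueError(f"{path.name}: missing required column(s) {missing}")
        yields = pd.to_numeric(raw["yield"], errors="coerce")
        if yields.isna().any():
            row = int(yields.index[yields.isna()][0]) + 2  # header is row 1
            raise ValueError(
                f"{path.name}: non-numeric yield {raw['yield'][row - 2]!r} at row {row}"
            )
        trial = pd.DataFrame(
            {
                "genotype": raw["genotype"].str.strip(),
                "entry_type": (
                    raw["entry_type"].str.strip().str.lower()
                    if "entry_type" in raw.columns
                    else "line"
                ),
                "year": raw["year"].str.strip(),
                "condition": _normalize_conditions(raw["condition"], aliases),
                "yield": yields,
            }
        )
    elif fmt == "wide":
        if "genotype" not in raw.columns:
            raise ValueError(f"{path.name}: missing required column 'genotype'")
        id_cols = [c for c in ("genotype", "entry_type") if c in raw.columns]
        value_cols = [c for c in raw.columns if c not in id_cols]
        if not value_cols:
            raise ValueError(f"{path.name}: no year_condition columns found")
        long = raw.melt(id_vars=id_cols, value_vars=value_cols,
                        var_name="env", value_name="yield")
        parts = long["env"].str.rsplit("_", n=1, expand=True)
        if parts.isna().any().any():
            bad = long.loc[parts.isna().any(axis=1), "env"].unique().tolist()
            raise ValueError(
                f"{path.name}: column(s) {bad} not of the form <year>_<condition>"
            )
        yields = pd.to_numeric(long["yield"], errors="coerce")
        if yields.isna().any():
            i = yields.index[yields.isna()][0]
            raise ValueError(
                f"{path.name}: non-numeric yield {long['yield'][i]!r} for genotype "
                f"{long['genotype'][i]!r}, column {long['env'][i]!r}"
            )
        trial = pd.DataFrame(
            {
                "genotype": long["genotype"].str.strip(),
                "entry_type": (
                    long["entry_type"].str.strip().str.lower()
                    if "entry_type" in long.columns
                    else "line"
                ),
                "year": parts[0].str.strip(),
                "condition": _normalize_conditions(parts[1], aliases),
                "yield": yields,
            }
        )
    else:
        raise ValueError(f"unknown trial format {fmt!r}; expected 'long' or 'wide'")

    if trial["yield"].lt(0).any():
        row = int(trial.index[trial["yield"] < 0][0]) + 2
        raise ValueError(f"{path.name}: negative yield at row {row}")

    key = ["genotype", "year", "condition"]
    if trial.duplicated(key).any():
        n_dup = int(trial.duplicated(key).sum())
        warnings.warn(
            f"{path.name}: {n_dup} duplicate (genotype, year, condition) "
            "record(s) averaged",
            stacklevel=2,
        )
        trial = (
            trial.groupby(key + ["entry_type"], sort=False, as_index=False)["yield"]
            .mean()[["genotype", "entry_type", "year", "condition", "yield"]]
        )
    return trial.reset_index(drop=True)


def write_trial(trial: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format trial table as canonical CSV."""
    cols = ["genotype", "entry_type", "year", "condition", "yield"]
    trial[cols].to_csv(path, index=False, encoding="utf-8")


def load_config(path: str | Path) -> dict:
    """Load a structured key-value (YAML) run-configuration file."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of option: value")
    return cfg
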