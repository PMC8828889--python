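"""Synthetic recombinant-inbred-line (RIL) multi-environment yield trials.

Emulates the statistical structure of a biparental RIL drought-screening
trial: ``n_lines`` fully homozygous lines plus parents and check
varieties, grown for ``n_years`` under paired non-stress (N) and
drought-stress (D) regimes.  The generative model is

* additive genetics — each line inherits each of ``n_loci`` independent
  loci from either parent with probability ½; the non-stress genetic
  value g_P is the sum of inherited allele effects.  With the default
  complementary parents (each carrying the plus-allele at half the
  loci) both parents share the same g_P and transgressive segregation
  in both directions is expected;
* a stress genetic value g_S correlated with g_P at ``rho_g``,
  g_S = m + ρ·(g_P − m) + √(1−ρ²)·η with η matched to the genetic
  variance (parents and checks use fixed offsets in place of η, so
  ρ=1 forces g_S = g_P for every entry);
* year main effects, genotype×environment noise and plot error;
* multiplicative stress: the year-specific reduction factor δ_y acts on
  the genetic+year component, so the population-level percent reduction
  recovers δ_y directly from the N and D means.

Yields are truncated at zero (severe-stress years otherwise go
negative); truncation counts are reported as a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimSpec", "simulate_trial", "truth_report"]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic trial (yields in t ha⁻¹).

    Defaults emulate a 152-line rice RIL population with five checks
    (two of them the parents) over three years whose stress severities
    differ strongly (δ = 0.89, 0.58, 0.35).
    """

    n_lines: int = 152
    n_years: int = 3
    years: tuple[str, ...] = ("2017", "2018", "2019")
    n_loci: int = 20
    locus_effect: float = 0.2
    mu_p: float = 2.0
    year_effects: tuple[float, ...] = (0.3, -0.1, -0.2)
    deltas: tuple[float, ...] = (0.89, 0.58, 0.35)
    rho_g: float = 0.7
    sd_gxe: float = 0.25
    sd_error: float = 0.3
    # parents: complementary plus-alleles; fixed stress offsets make one
    # parent drought-tolerant and the other sensitive
    parent_ids: tuple[str, str] = ("P1", "P2")
    parent_stress_offsets: tuple[float, float] = (0.9, -1.4)
    # non-parent checks: (id, non-stress genetic value, stress offset)
    checks: tuple[tuple[str, float, float], ...] = (
        ("C1", 1.6, 0.3),
        ("C2", 2.1, -0.2),
        ("C3", 2.4, 0.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2 or self.n_loci < 1 or self.n_years < 1:
            raise ValueError("n_lines, n_loci and n_years must be positive")
        if len(self.years) != self.n_years:
            raise ValueError("years labels must match n_years")
        for name in ("year_effects", "deltas"):
            if len(getattr(self, name)) != self.n_years:
                raise ValueError(f"{name} must have one entry per year")
        if not all(0 <= d < 1 for d in self.deltas):
            raise ValueError("stress reductions delta must lie in [0, 1)")
        if not -1 <= self.rho_g <= 1:
            raise ValueError("rho_g must lie in [-1, 1]")
        if self.sd_gxe < 0 or self.sd_error < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.locus_effect < 0:
            raise ValueError("locus_effect must be non-negative")

    @property
    def parent_effect_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Complementary allele-effect vectors of the two parents."""
        a = self.locus_effect
        half = self.n_loci // 2
        p1 = np.zeros(self.n_loci)
        p1[:half] = a
        p2 = np.zeros(self.n_loci)
        p2[half:] = a
        return p1, p2

    @property
    def genetic_mean(self) -> float:
        """Expected line genetic value E[g_P] (also both parents' g_P)."""
        p1, p2 = self.parent_effect_vectors
        return float((p1 + p2).sum() / 2.0)

    @property
    def genetic_sd(self) -> float:
        """Segregation sd of g_P: √(Σ_l (a1_l − a2_l)²/4)."""
        p1, p2 = self.parent_effect_vectors
        return float(np.sqrt(((p1 - p2) ** 2).sum() / 4.0))


def simulate_trial(spec: SimSpec) -> pd.DataFrame:
    """Generate a long-format trial table from *spec* (seeded, reproducible).

    Returns records (``genotype``, ``entry_type``, ``year``,
    ``condition``, ``yield``) with one row per genotype × year ×
    condition.  The per-genotype truth (g_P, g_S, transgressive flags)
    and the spec ride along in ``DataFrame.attrs`` for oracle use; see
    :func:`truth_report`.
    """
    rng = np.random.default_rng(spec.seed)
    p1_eff, p2_eff = spec.parent_effect_vectors
    m = spec.genetic_mean
    v = spec.genetic_sd**2

    # line genetics: each locus from either parent with probability 1/2
    inherit = rng.random((spec.n_lines, spec.n_loci)) < 0.5
    g_p_lines = np.where(inherit, p1_eff, p2_eff).sum(axis=1)
    eta = rng.normal(0.0, np.sqrt(v), spec.n_lines)
    rho = spec.rho_g
    g_s_lines = m + rho * (g_p_lines - m) + np.sqrt(1.0 - rho**2) * eta

    ids = [f"L{i + 1}" for i in range(spec.n_lines)]
    types = ["line"] * spec.n_lines
    g_p = list(g_p_lines)
    g_s = list(g_s_lines)
    for pid, eff, off in zip(spec.parent_ids, (p1_eff, p2_eff),
                             spec.parent_stress_offsets):
        gp = float(eff.sum())
        ids.append(pid)
        types.append("parent")
        g_p.append(gp)
        g_s.append(m + rho * (gp - m) + np.sqrt(1.0 - rho**2) * off)
    for cid, gp, off in spec.checks:
        ids.append(cid)
        types.append("check")
        g_p.append(gp)
        g_s.append(m + rho * (gp - m) + np.sqrt(1.0 - rho**2) * off)
    g_p = np.asarray(g_p)
    g_s = np.asarray(g_s)
    n = len(ids)

    records = []
    n_truncated = 0
    for y, (year, ye, delta) in enumerate(
        zip(spec.years, spec.year_effects, spec.deltas)
    ):
        for cond in ("N", "D"):
            gxe = rng.normal(0.0, spec.sd_gxe, n)
            err = rng.normal(0.0, spec.sd_error, n)
            if cond == "N":
                mu = spec.mu_p + ye + g_p
            else:
                mu = (1.0 - delta) * (spec.mu_p + ye + g_s)
            raw = mu + gxe + err
            n_truncated += int((raw < 0).sum())
            y_obs = np.maximum(raw, 0.0)
            for gid, et, val in zip(ids, types, y_obs):
                records.append((gid, et, year, cond, float(val)))
    if n_truncated:
        warnings.warn(f"{n_truncated} plot yield(s) truncated at 0", stacklevel=2)

    trial = pd.DataFrame(
        records, columns=["genotype", "entry_type", "year", "condition", "yield"]
    )

    truth = pd.DataFrame({"genotype": ids, "entry_type": types, "g_p": g_p, "g_s": g_s})
    parent_rows = truth["entry_type"] == "parent"
    hi_p, lo_p = truth.loc[parent_rows, "g_p"].agg(["max", "min"])
    hi_s, lo_s = truth.loc[parent_rows, "g_s"].agg(["max", "min"])
    is_line = truth["entry_type"] == "line"
    # same tie tolerance as segregant detection: a line carrying exactly
    # half the plus-alleles matches the parents up to float summation order
    atol = 1e-9
    truth["true_positive_n"] = is_line & (truth["g_p"] > hi_p + atol)
    truth["true_negative_n"] = is_line & (truth["g_p"] < lo_p - atol)
    truth["true_positive_d"] = is_line & (truth["g_s"] > hi_s + atol)
    truth["true_negative_d"] = is_line & (truth["g_s"] < lo_s - atol)
    truth["is_true_transgressive"] = (
        truth["true_positive_n"] & truth["true_positive_d"]
    ) | (truth["true_negative_n"] & truth["true_negative_d"])

    trial.attrs["truth"] = truth
    trial.attrs["spec"] = spec
    return trial


def truth_report(trial: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype true genetic values and transgressive flags.

    Only available for tables produced by :func:`simulate_trial` in the
    same session (the truth rides in ``DataFrame.attrs``); tables read
    back from disk carry no truth.
    """
    truth = trial.attrs.get("truth")
    if truth is None:
        raise ValueError("trial table carries no embedded simulation truth")
    return truth.copy()
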