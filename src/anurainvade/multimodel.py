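"""AICc ranking, Akaike weights, model averaging, relative importance.

Because several candidate models typically score within a few AICc
points of each other, effect sizes are estimated by averaging over the
top model set (all models within 4 AICc points of the best, strict
inequality) with Akaike weights w_i = exp(-delta_i/2) normalized over
the set.  Two averaging variants are computed:

* full (shrinkage) averaging — a model not containing a factor
  contributes coefficient 0, so weakly supported factors shrink toward
  zero; this is the headline output;
* conditional averaging — weights renormalized over only the models
  containing the factor.

Unconditional standard errors follow the classical model-averaging
formula SE = sum_i w_i * sqrt(se_i^2 + (b_i - b_bar)^2), which folds
model-selection uncertainty into the interval; 95% CIs are normal
(b_bar +/- 1.96 SE).  A factor's relative importance is the summed
weight of the models that contain it: 1 means it appears in every
top model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import FACTOR_CODES, FACTORS
from .glmm import FitResult

__all__ = ["ModelTable", "AveragedEstimates", "enumerate_models", "rank_models",
           "top_set", "akaike_weights", "model_average", "relative_importance"]

MAX_CANDIDATES = 12
Z_95 = 1.959963984540054  # standard-normal 97.5% quantile


def _spec_key(spec: tuple[str, ...]) -> tuple:
    return tuple(sorted(FACTOR_CODES[f] for f in spec))


@dataclass
class ModelTable:
    """Ranked model set: one row per model, ascending AICc."""

    entries: pd.DataFrame  # spec, spec_code, aicc, delta_aicc, weight, k, loglik

    def __post_init__(self) -> None:
        w = self.entries["weight"].to_numpy()
        if len(w) and abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def specs(self) -> list[tuple[str, ...]]:
        return list(self.entries["spec"])


@dataclass
class AveragedEstimates:
    """Model-averaged coefficients with unconditional uncertainty.

    One row per coefficient (factor level): full and conditional
    averages, unconditional SE, normal 95% CI, and the factor's
    relative importance.
    """

    table: pd.DataFrame


def enumerate_models(candidates) -> list[tuple[str, ...]]:
    """All 2^m main-effect subsets of the candidate factors, null first.

    Candidates may be column names or 1-10 codes; order within a spec is
    by factor code.  Guarded at 12 candidates (4096 models).
    """
    names = []
    for f in candidates:
        names.append(FACTORS[f] if isinstance(f, (int, np.integer)) else str(f))
    if len(set(names)) != len(names):
        raise ValueError("duplicate candidate factor")
    if len(names) > MAX_CANDIDATES:
        raise ValueError(f"{len(names)} candidates exceeds guard of {MAX_CANDIDATES}")
    names = sorted(names, key=lambda f: FACTOR_CODES[f])
    specs = []
    for r in range(len(names) + 1):
        for combo in itertools.combinations(names, r):
            specs.append(tuple(combo))
    return specs


def akaike_weights(deltas) -> np.ndarray:
    """exp(-delta/2), normalized."""
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise ValueError("empty delta list")
    if np.any(d < 0) or not np.isclose(d.min(), 0.0):
        raise ValueError("deltas must be >= 0 with minimum 0")
    w = np.exp(-d / 2.0)
    return w / w.sum()


def rank_models(fits: list[FitResult]) -> ModelTable:
    """Rank fits by AICc; ties broken by smaller k then by spec code.

    All fits must share the same row set (identical n) — AICc values on
    different data are not comparable.
    """
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits on differing row counts {sorted(ns)}; AICc not comparable")
    rows = sorted(fits, key=lambda f: (f.aicc, f.k, _spec_key(f.model_spec)))
    aiccs = np.array([f.aicc for f in rows])
    deltas = aiccs - aiccs[0]
    entries = pd.DataFrame({
        "spec": [f.model_spec for f in rows],
        "spec_code": [f.spec_code for f in rows],
        "aicc": aiccs,
        "delta_aicc": deltas,
        "weight": akaike_weights(deltas),
        "k": [f.k for f in rows],
        "loglik": [f.loglik for f in rows],
    })
    return ModelTable(entries)


def top_set(table: ModelTable, delta_max: float = 4.0) -> ModelTable:
    """Models with delta AICc strictly below delta_max, weights renormalized."""
    if len(table) == 0:
        raise ValueError("empty model table")
    sub = table.entries[table.entries["delta_aicc"] < delta_max].copy()
    sub["weight"] = akaike_weights(sub["delta_aicc"].to_numpy())
    return ModelTable(sub.reset_index(drop=True))


def relative_importance(top: ModelTable, factor) -> float:
    """Summed weight of the top-set models containing the factor."""
    name = FACTORS[factor] if isinstance(factor, (int, np.integer)) else str(factor)
    mask = [name in spec for spec in top.entries["spec"]]
    return float(top.entries.loc[mask, "weight"].sum())


def model_average(top: ModelTable, fits: list[FitResult]) -> AveragedEstimates:
    """Average coefficients over the top set.

    Full averaging substitutes coefficient 0 (and SE 0) for models that
    do not contain a factor; conditional averaging renormalizes weights
    over the containing models.  CIs use the full average.
    """
    if len(top) == 0:
        raise ValueError("empty top set")
    by_spec = {_spec_key(f.model_spec): f for f in fits}
    sel = []
    for spec, w in zip(top.entries["spec"], top.entries["weight"]):
        key = _spec_key(tuple(spec))
        if key not in by_spec:
            raise KeyError(f"no fit supplied for model {spec}")
        sel.append((by_spec[key], float(w)))

    # union of coefficient labels across the set, intercept first
    labels: list[str] = []
    for f, _ in sel:
        for lbl in f.coef.index:
            if lbl not in labels:
                labels.append(lbl)

    def factor_of(lbl: str) -> str:
        return lbl.split("[")[0] if "[" in lbl else lbl

    rows = []
    for lbl in labels:
        fac = factor_of(lbl)
        betas = np.array([float(f.coef.get(lbl, 0.0)) for f, _ in sel])
        ses = np.array([float(f.se.get(lbl, 0.0)) for f, _ in sel])
        w = np.array([wi for _, wi in sel])
        present = np.array([lbl in f.coef.index for f, _ in sel])

        beta_full = float(np.sum(w * betas))
        se_full = float(np.sum(w * np.sqrt(ses ** 2 + (betas - beta_full) ** 2)))
        if present.any():
            wc = w[present] / w[present].sum()
            bc = betas[present]
            beta_cond = float(np.sum(wc * bc))
            se_cond = float(np.sum(wc * np.sqrt(ses[present] ** 2 + (bc - beta_cond) ** 2)))
            importance = (1.0 if lbl == "(Intercept)"
                          else relative_importance(top, fac))
        else:
            beta_cond, se_cond, importance = 0.0, 0.0, 0.0
        rows.append({
            "coefficient": lbl,
            "factor": fac,
            "estimate": beta_full,
            "se": se_full,
            "ci_low": beta_full - Z_95 * se_full,
            "ci_high": beta_full + Z_95 * se_full,
            "estimate_conditional": beta_cond,
            "se_conditional": se_cond,
            "importance": importance,
        })
    return AveragedEstimates(pd.DataFrame(rows))
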