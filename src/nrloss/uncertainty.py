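"""Monte Carlo propagation of N-rate and EF uncertainty to loss CVs.

Grid-level N application rates and predicted EFs are treated as normal
random variables around their point estimates; per draw, the losses
E_ij = rate_j * EF_ij and the total are recomputed and summarized.
Reported statistics are the coefficient of variation (CV = sd/mean, in
percent) of the grid-mean loss per pathway and of the total, plus
optional per-cell CVs. Draws can be truncated at zero (negative rates
or EFs are unphysical) or left untruncated to preserve normality
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathways import PATHWAYS


@dataclass
class UncertaintySpec:
    """Monte Carlo settings.

    ``cv_n_rate`` is the relative sd of grid-level application rates
    (default 0.258, the grid-level CV of the bottom-up survey this
    package's defaults emulate). EF spread comes either from the
    per-profile spread of repeated model runs ('run_spread', supplied as
    arrays) or from a fixed relative sd ('fixed_cv').
    """

    n_draws: int = 1000
    cv_n_rate: float = 0.258
    ef_sd_source: str = "run_spread"
    ef_cv: float = 0.15
    truncate_at_zero: bool = True
    seed: int = 0
    ef_sd: dict[str, "np.ndarray | float"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        if self.cv_n_rate < 0 or self.ef_cv < 0:
            raise ValueError("CVs must be >= 0")
        if self.ef_sd_source not in ("run_spread", "fixed_cv"):
            raise ValueError("ef_sd_source must be 'run_spread' or 'fixed_cv'")

    def pathway_ef_sd(self, pathway: str, ef_mean: np.ndarray) -> np.ndarray:
        if self.ef_sd_source == "fixed_cv":
            return self.ef_cv * np.abs(ef_mean)
        sd = self.ef_sd.get(pathway, 0.0)
        return np.broadcast_to(np.asarray(sd, float), ef_mean.shape)


def sample_inputs(
    inventory: pd.DataFrame,
    spec: UncertaintySpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One Monte Carlo draw of (n_rates, efs[pathway, cell])."""
    rates = inventory["n_rate"].to_numpy(float)
    rate_draw = rng.normal(rates, spec.cv_n_rate * rates)
    efs = np.stack([inventory[f"ef_{p}"].to_numpy(float) for p in PATHWAYS])
    ef_sd = np.stack([spec.pathway_ef_sd(p, efs[i]) for i, p in enumerate(PATHWAYS)])
    ef_draw = rng.normal(efs, ef_sd)
    if spec.truncate_at_zero:
        n_clipped = int((rate_draw < 0).sum() + (ef_draw < 0).sum())
        frac = n_clipped / (rate_draw.size + ef_draw.size)
        if frac > 0.5:
            warnings.warn(f"truncation removed {100 * frac:.0f}% of draws")
        rate_draw = np.maximum(rate_draw, 0.0)
        ef_draw = np.maximum(ef_draw, 0.0)
    return rate_draw, ef_draw


@dataclass
class UncertaintySummary:
    """Per-pathway and total uncertainty of the grid-mean loss."""

    table: pd.DataFrame          # mean, sd, cv_pct per pathway + total
    per_cell_cv: pd.DataFrame    # per-cell loss CV (%) per pathway + total


def propagate(inventory: pd.DataFrame, spec: UncertaintySpec) -> UncertaintySummary:
    """Recompute losses under ``spec.n_draws`` input draws and summarize.

    The headline statistic is the CV across draws of the grid-mean loss
    (per pathway and total); per-cell CV layers are returned alongside,
    since averaging over cells shrinks relative spread when cell errors
    are independent.
    """
    if inventory.empty:
        raise ValueError("inventory is empty; build it first")
    rng = np.random.default_rng(spec.seed)
    n_cells = len(inventory)
    n_path = len(PATHWAYS)
    gridmean = np.empty((spec.n_draws, n_path + 1))
    cell_sum = np.zeros((n_path + 1, n_cells))
    cell_sq = np.zeros((n_path + 1, n_cells))
    for d in range(spec.n_draws):
        rate_draw, ef_draw = sample_inputs(inventory, spec, rng)
        losses = rate_draw[None, :] * ef_draw        # (pathway, cell)
        total = losses.sum(axis=0)
        stacked = np.vstack([losses, total[None, :]])
        gridmean[d] = stacked.mean(axis=1)
        cell_sum += stacked
        cell_sq += stacked**2
    labels = list(PATHWAYS) + ["total"]
    mean = gridmean.mean(axis=0)
    sd = gridmean.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    cm = cell_sum / spec.n_draws
    cvar = np.maximum(cell_sq / spec.n_draws - cm**2, 0.0) * (
        spec.n_draws / (spec.n_draws - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ccv = np.where(cm > 0, 100.0 * np.sqrt(cvar) / cm, np.nan)
    per_cell = pd.DataFrame(ccv.T, columns=labels, index=inventory.index)
    table = pd.DataFrame({
        "mean": mean, "sd": sd, "cv_pct": cv,
        "mean_cell_cv_pct": np.nanmean(ccv, axis=1),
    }, index=labels)
    return UncertaintySummary(table=table, per_cell_cv=per_cell)
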