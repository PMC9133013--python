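"""Gridded Nr-loss inventory: per-cell EFs, per-pathway and total losses.

Per cell j and pathway i the seasonal loss is

    E_ij = N_applied_j * EF_ij            (kg N ha^-1)
    total_j = E_1j + E_2j + E_3j + E_4j + E_5j

with EFs predicted by the per-pathway models and N_applied the kriged
application rate. EFs are held as fractions internally and rendered as
percent only at reporting boundaries.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .forest import BaggedTreeRegressor
from .pathways import PATHWAYS
from .raster import Raster, write_ascii_grid

LOSS_COLUMNS = tuple(f"loss_{p}" for p in PATHWAYS)
EF_COLUMNS = tuple(f"ef_{p}" for p in PATHWAYS)


def predict_grid_efs(
    cells: pd.DataFrame,
    models: Mapping[str, BaggedTreeRegressor],
) -> pd.DataFrame:
    """Predict one EF (fraction of applied N) per cell per pathway."""
    if cells.empty:
        raise ValueError("empty grid")
    out = pd.DataFrame(index=cells.index)
    for pathway in PATHWAYS:
        model = models[pathway]
        missing = [f for f in model.feature_names_in_ if f not in cells.columns]
        if missing:
            raise KeyError(f"cells lack factors {missing} needed by the "
                           f"{pathway} model")
        out[f"ef_{pathway}"] = model.predict(cells)
    return out


def compute_losses(cells: pd.DataFrame, efs: pd.DataFrame) -> pd.DataFrame:
    """Per-pathway losses E_ij = n_rate_j * EF_ij in kg N ha^-1."""
    if (cells["n_rate"] < 0).any():
        raise ValueError("negative n_rate (flooring happens upstream)")
    out = pd.DataFrame(index=cells.index)
    for pathway in PATHWAYS:
        out[f"loss_{pathway}"] = cells["n_rate"].to_numpy(float) * efs[
            f"ef_{pathway}"].to_numpy(float)
    return out


def total_loss(losses: pd.DataFrame) -> pd.Series:
    """Elementwise sum of exactly the five pathway loss layers."""
    missing = [c for c in LOSS_COLUMNS if c not in losses.columns]
    if missing:
        raise ValueError(f"missing pathway layers {missing}")
    lengths = {len(losses[c]) for c in LOSS_COLUMNS}
    if len(lengths) != 1:
        raise ValueError("pathway layers have mismatched shapes")
    return losses[list(LOSS_COLUMNS)].sum(axis=1).rename("total_loss")


def build_inventory(
    cells: pd.DataFrame,
    models: Mapping[str, BaggedTreeRegressor],
) -> pd.DataFrame:
    """Cells joined with EF, loss and total-loss columns."""
    efs = predict_grid_efs(cells, models)
    losses = compute_losses(cells, efs)
    inv = pd.concat([cells, efs, losses], axis=1)
    inv["total_loss"] = total_loss(losses)
    inv.attrs.update(cells.attrs)
    return inv


def summarize(inventory: pd.DataFrame) -> pd.DataFrame:
    """Per-pathway and total means and ranges over active cells.

    EFs are reported in percent, losses in kg N ha^-1; the formatted
    column renders "mean (min-max)" with one decimal, the numeric
    columns stay at full precision. Means are unweighted cell means.
    """
    if inventory.empty:
        raise ValueError("empty inventory")

    def fmt(mean: float, lo: float, hi: float) -> str:
        return f"{mean:.1f} ({lo:.1f}-{hi:.1f})"

    rows = []
    for pathway in PATHWAYS:
        ef = 100.0 * inventory[f"ef_{pathway}"]
        loss = inventory[f"loss_{pathway}"]
        rows.append({
            "pathway": pathway,
            "mean_ef_pct": ef.mean(), "min_ef_pct": ef.min(), "max_ef_pct": ef.max(),
            "mean_loss": loss.mean(), "min_loss": loss.min(), "max_loss": loss.max(),
            "ef_formatted": fmt(ef.mean(), ef.min(), ef.max()),
            "loss_formatted": fmt(loss.mean(), loss.min(), loss.max()),
        })
    tot_ef = 100.0 * sum(inventory[c] for c in EF_COLUMNS)
    tot = inventory["total_loss"]
    rows.append({
        "pathway": "total",
        "mean_ef_pct": tot_ef.mean(), "min_ef_pct": tot_ef.min(),
        "max_ef_pct": tot_ef.max(),
        "mean_loss": tot.mean(), "min_loss": tot.min(), "max_loss": tot.max(),
        "ef_formatted": fmt(tot_ef.mean(), tot_ef.min(), tot_ef.max()),
        "loss_formatted": fmt(tot.mean(), tot.min(), tot.max()),
    })
    return pd.DataFrame(rows).set_index("pathway")


def cells_to_raster(inventory: pd.DataFrame, column: str, like: Raster) -> Raster:
    """Scatter a per-cell column back onto the grid (inactive cells NaN)."""
    data = np.full(like.shape, np.nan)
    data[inventory["row"].to_numpy(int), inventory["col"].to_numpy(int)] = (
        inventory[column].to_numpy(float))
    return like.copy_with(data)


def export_inventory(
    inventory: pd.DataFrame,
    like: Raster,
    outdir: str | Path,
    provenance: dict | None = None,
) -> dict:
    """Write the 12 inventory layers, the summary table and a manifest.

    Layers: five EF layers (percent), five loss layers and the total
    (kg N ha^-1), and the N application rate. Rasters are Esri ASCII
    grids; the manifest (JSON) records units, abbreviations, the active
    cell count and any provenance passed in.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layers: dict[str, dict] = {}
    for pathway in PATHWAYS:
        ef_pct = inventory[f"ef_{pathway}"] * 100.0
        r = cells_to_raster(inventory.assign(_tmp=ef_pct), "_tmp", like)
        write_ascii_grid(r, outdir / f"ef_{pathway}.asc")
        layers[f"ef_{pathway}.asc"] = {
            "quantity": f"{pathway} emission factor", "units": "% of applied N"}
        r = cells_to_raster(inventory, f"loss_{pathway}", like)
        write_ascii_grid(r, outdir / f"loss_{pathway}.asc")
        layers[f"loss_{pathway}.asc"] = {
            "quantity": f"{pathway} Nr loss", "units": "kg N ha-1 season-1"}
    write_ascii_grid(cells_to_raster(inventory, "n_rate", like), outdir / "n_rate.asc")
    layers["n_rate.asc"] = {
        "quantity": "N application rate", "units": "kg N ha-1 season-1"}
    write_ascii_grid(
        cells_to_raster(inventory, "total_loss", like), outdir / "total_loss.asc")
    layers["total_loss.asc"] = {
        "quantity": "total Nr loss (sum of 5 pathways)",
        "units": "kg N ha-1 season-1"}
    summary = summarize(inventory)
    summary.to_csv(outdir / "summary.csv")
    manifest = {
        "layers": layers,
        "n_active_cells": int(len(inventory)),
        "abbreviations": {
            "Nr": "reactive nitrogen (all N species except N2)",
            "EF": "emission factor, (E_treatment - E_control) / N applied",
            "NO": "nitric oxide", "N2O": "nitrous oxide", "NH3": "ammonia",
            "NO3_leaching": "nitrate leaching", "runoff": "dissolved Nr runoff",
        },
        "provenance": provenance or {},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
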