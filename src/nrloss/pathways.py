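"""Pathway and covariate vocabulary shared across the package.

Five reactive-nitrogen (Nr) loss pathways from fertilized wheat are
tracked: nitric-oxide (NO) and nitrous-oxide (N2O) emission, ammonia
(NH3) volatilization, nitrate (NO3-) leaching, and dissolved Nr runoff.
Ten environmental covariates describe each site: four soil physical
factors (bulk density, silt, clay, sand), four soil chemical factors
(pH, soil organic carbon, cation exchange capacity, total N) and two
growing-season weather factors (total rainfall, mean temperature).
"""

from __future__ import annotations

PATHWAYS: tuple[str, ...] = ("NO", "N2O", "NH3", "NO3_leaching", "runoff")

#: The ten candidate environmental covariates, in the canonical order used
#: for deterministic tie-breaking throughout the package.
COVARIATES: tuple[str, ...] = (
    "bulk_density",  # g cm^-3
    "silt",          # %
    "clay",          # %
    "sand",          # %
    "pH",            # unitless
    "soc",           # soil organic carbon, g kg^-1
    "cec",           # cation exchange capacity, cmol kg^-1
    "total_n",       # total soil N, g kg^-1
    "rainfall",      # growing-season total, mm
    "temperature",   # growing-season mean, deg C
)

#: Per-pathway environmental-factor ensembles retained after constrained
#: ordination of the national wheat field-experiment corpus, together with
#: the total explanatory rate (% of EF variance explained). Shipped as a
#: frozen preset so EF models can be built without re-running selection.
FACTOR_PRESETS: dict[str, tuple[str, ...]] = {
    "NO": ("total_n", "rainfall", "pH", "clay", "silt", "sand"),
    "N2O": ("pH", "bulk_density", "rainfall", "soc", "clay", "total_n"),
    "NH3": ("clay", "rainfall", "sand", "pH", "silt", "total_n", "temperature", "soc"),
    "NO3_leaching": ("rainfall", "total_n", "temperature", "cec", "pH", "sand", "clay"),
    "runoff": ("pH", "total_n", "temperature", "clay", "soc", "rainfall"),
}

#: Total explanatory rates (%) reported alongside the preset ensembles.
PRESET_EXPLANATORY_RATES: dict[str, float] = {
    "NO": 97.8,
    "N2O": 99.9,
    "NH3": 100.0,
    "NO3_leaching": 99.7,
    "runoff": 99.9,
}

#: Published national-scale EF ranges per pathway (fraction of applied N).
#: Used to bound the synthetic truth functions and as sanity anchors.
EF_RANGES: dict[str, tuple[float, float]] = {
    "NO": (0.002, 0.022),
    "N2O": (0.002, 0.015),
    "NH3": (0.031, 0.179),
    "NO3_leaching": (0.019, 0.340),
    "runoff": (0.014, 0.232),
}

#: National-scale reference mean EFs (% of applied N) per pathway for
#: wheat, used in aggregation consistency checks and reporting examples.
REFERENCE_MEAN_EF_PCT: dict[str, float] = {
    "NO": 0.5,
    "N2O": 0.4,
    "NH3": 7.2,
    "NO3_leaching": 12.2,
    "runoff": 5.8,
}

#: Reference mean seasonal losses (kg N ha^-1) per pathway.
REFERENCE_MEAN_LOSS: dict[str, float] = {
    "NO": 1.0,
    "N2O": 0.8,
    "NH3": 14.7,
    "NO3_leaching": 25.0,
    "runoff": 11.1,
}

#: The four agroecological wheat regions.
REGIONS: tuple[str, ...] = (
    "North China",
    "North China Plain",
    "South China",
    "Southwest China",
)

#: Field-experiment observation counts per pathway in the meta-corpus the
#: synthetic generator emulates (941 observations in total).
DEFAULT_N_PER_PATHWAY: dict[str, int] = {
    "NO": 121,
    "N2O": 383,
    "NH3": 185,
    "NO3_leaching": 188,
    "runoff": 64,
}


def check_pathway(pathway: str) -> str:
    if pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")
    return pathway
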