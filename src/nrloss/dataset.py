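"""Emission-factor meta-dataset assembly.

Field-experiment records are screened by four exclusion criteria
(season coverage, field vs. greenhouse/laboratory, presence of a zero-N
control, and absence of manure / controlled-release fertilizer /
inhibitors), converted to emission factors

    EF = (E_treatment - E_control) / N_applied

as a fraction of applied N, optionally completed by source-precedence
imputation, and assembled into per-pathway modeling tables restricted
to a chosen factor ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pathways import COVARIATES, check_pathway

#: Screening criteria in their fixed reporting order: (flag column,
#: value that triggers rejection, rejection reason).
SCREENING_CRITERIA: tuple[tuple[str, bool, str], ...] = (
    ("covers_full_season", False, "not full growing season"),
    ("is_greenhouse_or_lab", True, "greenhouse/laboratory"),
    ("has_zero_n_control", False, "no zero-N control"),
    ("uses_manure_crf_or_inhibitor", True, "manure/CRF/inhibitor"),
)

#: Imputation source precedence: which lookup table fills which fields.
IMPUTATION_SOURCES: dict[str, tuple[str, ...]] = {
    "climate": ("rainfall", "temperature"),
    "soil_fertility": ("soc", "total_n"),
    "soil_survey": ("silt", "clay", "sand", "bulk_density", "cec", "pH"),
}


@dataclass(frozen=True)
class ScreeningDecision:
    accepted: bool
    reason: str | None = None


def screen_observation(obs: pd.Series | dict) -> ScreeningDecision:
    """Accept or reject one observation; the reason names the first
    failing criterion in the fixed criterion order."""
    get = obs.get if hasattr(obs, "get") else obs.__getitem__
    for flag, reject_value, reason in SCREENING_CRITERIA:
        value = get(flag) if hasattr(obs, "get") else obs[flag]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return ScreeningDecision(False, "unscreenable")
        if bool(value) == reject_value:
            return ScreeningDecision(False, reason)
    return ScreeningDecision(True)


def screen_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Screen a table; returns a report with study_id, decision, reason."""
    rows = []
    for _, row in obs.iterrows():
        d = screen_observation(row)
        rows.append((row.get("study_id"), "accept" if d.accepted else "reject", d.reason))
    return pd.DataFrame(rows, columns=["study_id", "decision", "reason"])


def compute_ef(e_treatment: float, e_control: float, n_rate: float) -> float:
    """Emission factor as a fraction of applied N."""
    if n_rate <= 0:
        raise ValueError(f"n_rate must be positive, got {n_rate}")
    if e_treatment is None or e_control is None or np.isnan(e_treatment) or np.isnan(e_control):
        raise ValueError("E_treatment and E_control must both be present")
    return (e_treatment - e_control) / n_rate


def compute_efs(
    obs: pd.DataFrame,
    clip_negative: bool = False,
) -> pd.DataFrame:
    """Vectorized EF computation over an accepted-observation table.

    Negative EFs (control loss exceeding treatment loss) are retained by
    default since the estimator is signed; ``clip_negative`` floors them
    at zero. Adds ``ef`` (fraction) and ``ef_negative`` flag columns.
    """
    if (obs["n_rate"] <= 0).any():
        bad = obs.loc[obs["n_rate"] <= 0, "study_id"].tolist()
        raise ValueError(f"non-positive n_rate for studies {bad}")
    out = obs.copy()
    ef = (out["E_treatment"] - out["E_control"]) / out["n_rate"]
    out["ef_negative"] = ef < 0
    out["ef"] = ef.clip(lower=0.0) if clip_negative else ef
    return out


def impute_profile(
    profile: pd.Series | dict,
    lookups: dict[str, "pd.DataFrame | dict"],
    location: tuple[float, float] | None = None,
) -> tuple[pd.Series, list[str]]:
    """Fill missing covariates by source precedence.

    ``lookups`` maps source name ('climate', 'soil_fertility',
    'soil_survey') to either a dict of field -> value for the
    observation's location, or a callable-free DataFrame indexed however
    the caller resolved the location already. Returns the completed
    profile and the list of imputed field names.

    Raises ``KeyError`` naming the first field missing from both the
    record and its designated source.
    """
    prof = pd.Series(profile, dtype=object).copy()
    imputed: list[str] = []
    for source, fields in IMPUTATION_SOURCES.items():
        table = lookups.get(source, {})
        for f in fields:
            val = prof.get(f)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                if f not in table or table[f] is None:
                    raise KeyError(
                        f"covariate {f!r} missing from record and from "
                        f"{source!r} lookup"
                    )
                prof[f] = table[f]
                imputed.append(f)
    return prof, imputed


def assemble_pathway_dataset(
    records: pd.DataFrame,
    pathway: str,
    factors: tuple[str, ...] | list[str],
) -> pd.DataFrame:
    """Restrict an EF table to one pathway and one factor ensemble.

    Rows with any missing selected factor are dropped (the drop count is
    recorded in ``result.attrs['n_dropped']``); duplicated input rows
    stay duplicated. Raises if the result is empty.
    """
    check_pathway(pathway)
    factors = list(factors)
    unknown = set(factors) - set(COVARIATES)
    if unknown:
        raise ValueError(f"unknown covariates {sorted(unknown)}")
    sub = records.loc[records["pathway"] == pathway, factors + ["ef"]]
    complete = sub.dropna()
    if complete.empty:
        raise ValueError(f"no complete records for pathway {pathway!r}")
    complete = complete.reset_index(drop=True)
    complete.attrs["n_dropped"] = len(sub) - len(complete)
    complete.attrs["pathway"] = pathway
    complete.attrs["factors"] = tuple(factors)
    return complete
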