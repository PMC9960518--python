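"""Joint race/ethnicity x SES-quartile effects.

Rather than adding product terms to two main effects, the joint model
replaces the race and income factors by a single crossed factor with
(4 races x 4 quartiles) = 16 levels, one of which — NHW in the lowest income
quartile by default — is the reference. Each of the remaining 15 levels then
gets its own relative risk against that common reference, which is how
registry studies present combined race-and-income disparities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spatial_model import ModelSpec, PosteriorSamples

JOINT_SEP = "|"


@dataclass(frozen=True)
class JointFactor:
    """The crossed factor: its column name, level grid, and reference."""

    name: str
    race_levels: tuple[str, ...]
    ses_levels: tuple[str, ...]
    reference: str  # e.g. "NHW|Q1"

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(
            f"{r}{JOINT_SEP}{q}" for r in self.race_levels for q in self.ses_levels
        )


def encode_joint(
    data: pd.DataFrame,
    spec: ModelSpec,
    race_factor: str = "race",
    ses_factor: str = "income_quartile",
    reference: str | None = None,
) -> tuple[pd.DataFrame, ModelSpec, JointFactor]:
    """Replace the race and SES main effects by their crossed factor.

    Returns the data with a new ``race|ses`` column, a ModelSpec in which
    the joint factor stands in for the two mains (other factors, e.g. age
    and sex, and the spatial effect are retained), and the JointFactor
    descriptor. Default reference: NHW crossed with Q1 (lowest income).
    Joint levels with no observed cells are warned about but retained —
    the prior regularizes them.
    """
    for factor in (race_factor, ses_factor):
        if factor not in data.columns:
            raise ValueError(f"factor {factor!r} not in data")
    race_levels = tuple(sorted(data[race_factor].astype(str).unique()))
    ses_levels = tuple(sorted(data[ses_factor].astype(str).unique()))
    if reference is None:
        reference = f"{spec.reference_for(race_factor)}{JOINT_SEP}{spec.reference_for(ses_factor)}"

    joint = JointFactor(
        name=f"{race_factor}{JOINT_SEP}{ses_factor}",
        race_levels=race_levels,
        ses_levels=ses_levels,
        reference=reference,
    )
    if reference not in joint.levels:
        raise ValueError(f"joint reference {reference!r} not among observed levels")

    out = data.copy()
    out[joint.name] = (
        out[race_factor].astype(str) + JOINT_SEP + out[ses_factor].astype(str)
    )
    observed = set(out.loc[out["cases"] > 0, joint.name]) if "cases" in out else set(out[joint.name])
    empty = [lv for lv in joint.levels if lv not in observed]
    if empty:
        warnings.warn(
            f"joint level(s) without cases: {empty}; retained (prior regularizes)",
            stacklevel=2,
        )

    factors = tuple(
        f for f in spec.factors if f not in (race_factor, ses_factor)
    ) + (joint.name,)
    references = dict(spec.references)
    references[joint.name] = reference
    new_spec = ModelSpec(
        factors=factors,
        references=references,
        interaction=(race_factor, ses_factor),
        spatial=spec.spatial,
        unstructured=spec.unstructured,
    )
    return out, new_spec, joint


def joint_rr_table(
    samples: PosteriorSamples,
    joint: JointFactor,
    case_table: pd.DataFrame | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Race-by-SES grid of counts, within-race percentages, and RRs.

    One row per (race, ses) combination with columns ``n``, ``percent``
    (percentages sum to 100 across SES levels within each race group),
    ``rr``, ``lower``, ``upper`` and a ``referent`` flag. Counts come from
    ``case_table`` (needs the joint column and ``cases``) when given.
    """
    alpha = 1.0 - level
    beta_by_level = {}
    for j, name in enumerate(samples.colnames):
        factor, lvl = name.split(":", 1)
        if factor == joint.name:
            beta_by_level[lvl] = samples.beta[:, j]

    counts = {}
    if case_table is not None:
        counts = (
            case_table.groupby(joint.name, observed=True)["cases"].sum().to_dict()
        )

    rows = []
    for race in joint.race_levels:
        race_total = sum(
            counts.get(f"{race}{JOINT_SEP}{q}", 0) for q in joint.ses_levels
        )
        for ses in joint.ses_levels:
            lvl = f"{race}{JOINT_SEP}{ses}"
            n = counts.get(lvl, np.nan) if case_table is not None else np.nan
            pct = 100.0 * n / race_total if case_table is not None and race_total else np.nan
            if lvl == joint.reference:
                rows.append(
                    {"race": race, "ses": ses, "n": n, "percent": pct,
                     "rr": 1.0, "lower": np.nan, "upper": np.nan, "referent": True}
                )
            else:
                draws = beta_by_level.get(lvl)
                if draws is None:
                    rows.append(
                        {"race": race, "ses": ses, "n": n, "percent": pct,
                         "rr": np.nan, "lower": np.nan, "upper": np.nan,
                         "referent": False}
                    )
                else:
                    rows.append(
                        {
                            "race": race,
                            "ses": ses,
                            "n": n,
                            "percent": pct,
                            "rr": float(np.exp(draws.mean())),
                            "lower": float(np.exp(np.percentile(draws, 100 * alpha / 2))),
                            "upper": float(np.exp(np.percentile(draws, 100 * (1 - alpha / 2)))),
                            "referent": False,
                        }
                    )
    return pd.DataFrame(rows)


def joint_table_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy joint table into a race x SES display grid."""
    def fmt(row):
        if row["referent"]:
            return "Referent"
        if np.isnan(row["rr"]):
            return ""
        return f"{row['rr']:.2f} ({row['lower']:.2f}-{row['upper']:.2f})"

    disp = table.copy()
    disp["cell"] = [
        (f"{int(r['n'])} ({r['percent']:.0f}%) " if not np.isnan(r["n"]) else "") + fmt(r)
        for _, r in disp.iterrows()
    ]
    return disp.pivot(index="race", columns="ses", values="cell")
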