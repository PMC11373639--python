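"""Derived postharvest phenotypes and technical-rep averaging.

Derived traits follow the fruit-quality phenotyping conventions of blueberry
postharvest trials:

* water-loss percentage, ``WL% = (Wi - Wf) / Wi * 100``;
* pedicel scar coefficient, a weighted score in [1, 3] from counts of
  small/medium/large scars on a berry subsample;
* Δ-traits, the difference between a trait at a storage time point and its
  value at the 1-day (harvest) baseline, computed within (genotype, year)
  because the fruit of one time series comes from a single harvest.

Technical repetitions come from the same experimental unit in the field, so
they are arithmetic-averaged before any statistical modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import PhenotypeTable, TIME_POINTS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DerivedTraitSpec:
    """Definition of a baseline-difference (Δ) trait.

    ``baseline_time`` must precede every target time point in storage order.
    """

    base_trait: str
    name: str
    baseline_time: str = "1D"

    def __post_init__(self) -> None:
        if self.baseline_time not in TIME_POINTS:
            raise ValueError(f"unknown baseline time {self.baseline_time!r}")
        if self.baseline_time == TIME_POINTS[-1]:
            raise ValueError("baseline time must precede at least one later time point")


def water_loss_pct(wi, wf):
    """Water-loss percentage from initial and final sample weights (grams)."""
    wi = np.asarray(wi, dtype=float)
    wf = np.asarray(wf, dtype=float)
    if np.any(wi <= 0):
        raise ValueError("initial weight must be positive")
    if np.any(wf < 0):
        raise ValueError("final weight must be non-negative")
    out = (wi - wf) / wi * 100.0
    return float(out) if out.ndim == 0 else out


def scar_coefficient(ns, nm, nl):
    """Pedicel scar score ``(1*Ns + 2*Nm + 3*Nl) / (Ns + Nm + Nl)`` in [1, 3]."""
    ns = np.asarray(ns)
    nm = np.asarray(nm)
    nl = np.asarray(nl)
    for name, c in (("Ns", ns), ("Nm", nm), ("Nl", nl)):
        if np.any(c < 0) or np.any(np.mod(c, 1) != 0):
            raise ValueError(f"{name} must be a non-negative integer count")
    total = ns + nm + nl
    if np.any(total == 0):
        raise ValueError("at least one berry must be scored")
    out = (1 * ns + 2 * nm + 3 * nl) / total
    return float(out) if out.ndim == 0 else out


def average_reps(table: PhenotypeTable) -> PhenotypeTable:
    """Average technical reps to one record per (genotype, year, time, trait).

    Idempotent: a table that already has a single rep per key is returned
    with unchanged values (and ``rep`` set to 1).
    """
    df = (
        table.df.groupby(
            ["genotype", "year", "time_point", "trait", "is_check"],
            observed=True,
            as_index=False,
        )["value"]
        .mean()
    )
    df["rep"] = 1
    return PhenotypeTable(df, strict=False)


def delta_trait(
    table: PhenotypeTable,
    spec: DerivedTraitSpec,
    include_baseline: bool = False,
) -> PhenotypeTable:
    """Compute a Δ-trait: value at each later time point minus the baseline.

    Reps are averaged first; the result carries ``rep = 1``.  A (genotype,
    year) series lacking a baseline record is skipped with a logged warning
    rather than an error, since augmented designs routinely have holes.

    Returns a table containing only the derived rows (trait ``spec.name``);
    concatenate with the source table if an appended layout is wanted.
    """
    base = average_reps(table.filter(trait=spec.base_trait)).df
    if base.empty:
        raise ValueError(f"no records for base trait {spec.base_trait!r}")
    later = list(TIME_POINTS[TIME_POINTS.index(spec.baseline_time) + 1 :])
    later = [t for t in later if t in set(base["time_point"].astype(str))]

    wide = base.pivot_table(
        index=["genotype", "year", "is_check"],
        columns="time_point",
        values="value",
        observed=True,
    )
    has_baseline = spec.baseline_time in wide.columns and wide[spec.baseline_time].notna()
    if spec.baseline_time not in wide.columns:
        raise ValueError(f"no {spec.baseline_time} records for trait {spec.base_trait!r}")
    skipped = wide.index[~has_baseline].get_level_values("genotype").unique().tolist()
    if skipped:
        logger.warning(
            "delta trait %s: skipping %d genotype-year series without a %s baseline: %s",
            spec.name, len(skipped), spec.baseline_time, skipped[:5],
        )
    wide = wide[has_baseline]

    rows = []
    targets = later + ([spec.baseline_time] if include_baseline else [])
    for t in targets:
        if t not in wide.columns:
            continue
        diff = wide[t] - wide[spec.baseline_time]
        diff = diff.dropna()
        sub = diff.reset_index()
        sub.columns = ["genotype", "year", "is_check", "value"]
        sub["time_point"] = t
        rows.append(sub)
    if not rows:
        out = pd.DataFrame(columns=["genotype", "year", "is_check", "value", "time_point"])
    else:
        out = pd.concat(rows, ignore_index=True)
    out["trait"] = spec.name
    out["rep"] = 1
    return PhenotypeTable(out, strict=False)
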