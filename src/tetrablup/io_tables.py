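"""Delimited-text I/O for allele-dosage matrices and longitudinal phenotype tables.

Two containers are defined here and used throughout the package:

* :class:`DosageMatrix` — a genotypes × markers matrix of integer allele
  dosages (0..ploidy, NaN for missing), the raw genomic input for the
  tetrasomic relationship matrix.
* :class:`PhenotypeTable` — a tidy long-format table of repeated-measures
  phenotype records (genotype, year, postharvest time point, trait, value,
  check flag, technical-rep index).

Files are plain CSV (tab accepted via ``sep``), matching the spreadsheet
exports typical of breeding-trial supplementary data.  Missing values may be
encoded as an empty cell or ``NA``.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Ordered postharvest storage time points (1 day, 1 week, 3 weeks, 7 weeks).
TIME_POINTS: tuple[str, ...] = ("1D", "1W", "3W", "7W")

#: Logical column names of a phenotype table.
PHENO_COLUMNS: tuple[str, ...] = (
    "genotype",
    "year",
    "time_point",
    "trait",
    "value",
    "is_check",
    "rep",
)

_NA_VALUES = ["", "NA", "NaN", "nan"]


class ValidationError(ValueError):
    """Raised when an input file or table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Dosage matrix
# ---------------------------------------------------------------------------


@dataclass
class DosageMatrix:
    """Genotypes × markers integer allele dosages for a polyploid population.

    Parameters
    ----------
    genotype_ids
        Unique genotype identifiers, one per row. IDs are opaque strings.
    marker_ids
        Unique marker identifiers, one per column.
    dosages
        Float array of shape ``(len(genotype_ids), len(marker_ids))``; each
        non-missing entry is an integer in ``[0, ploidy]``, missing entries
        are ``NaN``.
    ploidy
        Even ploidy level; 4 for an autotetraploid such as highbush blueberry.
    """

    genotype_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    ploidy: int = 4

    def __post_init__(self) -> None:
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.ploidy <= 0 or self.ploidy % 2:
            raise ValidationError(f"ploidy must be a positive even integer, got {self.ploidy}")
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if n != len(self.genotype_ids) or m != len(self.marker_ids):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.genotype_ids)} genotypes x {len(self.marker_ids)} markers"
            )
        for kind, ids in (("genotype", self.genotype_ids), ("marker", self.marker_ids)):
            dup = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate {kind} IDs: {sorted(set(dup))[:5]}")
        self._check_entries()

    def _check_entries(self) -> None:
        vals = self.dosages
        finite = np.isfinite(vals)
        bad = finite & ((vals < 0) | (vals > self.ploidy) | (np.mod(vals, 1) != 0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {vals[i, j]!r} at genotype {self.genotype_ids[i]!r}, "
                f"marker {self.marker_ids[j]!r} is not an integer in [0, {self.ploidy}]"
            )

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.dosages).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.genotype_ids, columns=self.marker_ids)


def read_dosage_matrix(path: str | Path, ploidy: int = 4, sep: str = ",") -> DosageMatrix:
    """Read a genotypes × markers dosage matrix from delimited text.

    The first column holds genotype IDs and the header row holds marker IDs.
    Missing cells may be empty or ``NA``; they are kept as NaN, never imputed
    here (imputation is an explicit step of the relationship-matrix builder).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    marker_ids = [h.strip() for h in header[1:]]
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=_NA_VALUES, keep_default_na=False)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric dosage entry in {path}: {exc}") from exc
    return DosageMatrix(
        genotype_ids=[str(g) for g in df.index],
        marker_ids=marker_ids,
        dosages=values,
        ploidy=ploidy,
    )


def write_dosage_matrix(dm: DosageMatrix, path: str | Path, sep: str = ",") -> None:
    df = dm.to_dataframe()
    # integers written without a trailing ".0"; NaN becomes an empty cell
    df.to_csv(path, sep=sep, index_label="genotype", float_format="%g")


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------


class PhenotypeTable:
    """Tidy repeated-measures phenotype records.

    The underlying :class:`pandas.DataFrame` (``.df``) has the seven columns
    in :data:`PHENO_COLUMNS`; ``time_point`` is an ordered categorical with
    levels ``1D < 1W < 3W < 7W``.  Rows are kept in a canonical sort order so
    that write/read round-trips are exact.

    Parameters
    ----------
    df
        Long-format records.
    strict
        When True (the default for data read from disk), additionally require
        that every check genotype appears in more than one year whenever the
        table spans multiple years — the connectivity requirement of an
        augmented design.  Internally derived tables (e.g. Δ-traits) may relax
        this.
    """

    def __init__(self, df: pd.DataFrame, strict: bool = True) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        df = df.loc[:, list(PHENO_COLUMNS)].copy()

        bad_times = set(map(str, df["time_point"].unique())) - set(TIME_POINTS)
        if bad_times:
            raise ValidationError(
                f"unknown time point labels {sorted(bad_times)}; allowed: {list(TIME_POINTS)}"
            )
        df["genotype"] = df["genotype"].astype(str)
        df["year"] = df["year"].astype(int)
        df["time_point"] = pd.Categorical(
            df["time_point"].astype(str), categories=TIME_POINTS, ordered=True
        )
        df["trait"] = df["trait"].astype(str)
        df["value"] = df["value"].astype(float)
        df["is_check"] = _coerce_bool(df["is_check"])
        df["rep"] = df["rep"].astype(int)
        if (df["rep"] < 1).any():
            raise ValidationError("rep indices must be >= 1")

        key = ["genotype", "year", "time_point", "trait", "rep"]
        dup = df.duplicated(subset=key, keep=False)
        if dup.any():
            first = df.loc[dup, key].iloc[0].tolist()
            raise ValidationError(f"duplicate (genotype, year, time, trait, rep) key: {first}")

        flags = df.groupby("genotype", observed=True)["is_check"].nunique()
        if (flags > 1).any():
            bad = flags[flags > 1].index.tolist()[:5]
            raise ValidationError(f"inconsistent is_check flag for genotypes: {bad}")

        if strict and df["year"].nunique() > 1:
            span = df[df["is_check"]].groupby("genotype", observed=True)["year"].nunique()
            lonely = span[span < 2].index.tolist()
            if lonely:
                raise ValidationError(
                    "check genotypes must appear in more than one year when the table "
                    f"spans multiple years; offenders: {lonely[:5]}"
                )

        df = df.sort_values(key, kind="mergesort").reset_index(drop=True)
        self.df = df

    # -- convenience -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.df["genotype"].unique())

    @property
    def check_genotypes(self) -> list[str]:
        return sorted(self.df.loc[self.df["is_check"], "genotype"].unique())

    def filter(
        self,
        trait: str | None = None,
        time_points: Sequence[str] | None = None,
        genotypes: Iterable[str] | None = None,
    ) -> "PhenotypeTable":
        df = self.df
        if trait is not None:
            df = df[df["trait"] == trait]
        if time_points is not None:
            df = df[df["time_point"].isin(list(time_points))]
        if genotypes is not None:
            df = df[df["genotype"].isin(set(genotypes))]
        return PhenotypeTable(df, strict=False)


def _coerce_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "t": True, "f": False, "yes": True, "no": False,
    }
    out = s.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = s[out.isna()].unique()[:5]
        raise ValidationError(f"cannot interpret is_check values: {list(bad)}")
    return out.astype(bool)


def read_phenotypes(
    path: str | Path,
    sep: str = ",",
    column_map: Mapping[str, str] | None = None,
) -> PhenotypeTable:
    """Read a long-format phenotype table.

    ``column_map`` maps the logical column names in :data:`PHENO_COLUMNS`
    to the actual column names in the file, so arbitrary spreadsheet exports
    can be ingested without renaming by hand.
    """
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False)
    if column_map:
        unknown = set(column_map) - set(PHENO_COLUMNS)
        if unknown:
            raise ValidationError(f"column_map keys must be logical names, got {sorted(unknown)}")
        rename = {actual: logical for logical, actual in column_map.items()}
        missing = [a for a in rename if a not in df.columns]
        if missing:
            raise ValidationError(f"mapped columns not found in file: {missing}")
        df = df.rename(columns=rename)
    return PhenotypeTable(df, strict=True)


def write_phenotypes(table: PhenotypeTable, path: str | Path, sep: str = ",") -> None:
    table.df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------


def write_matrix(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a labelled matrix (e.g. G, Σt, BLUPs) as CSV with row/col headers."""
    df.to_csv(path, sep=sep, index_label="id")


def read_matrix(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=0)


def write_run_metadata(path: str | Path, **info) -> None:
    """Write a reproducibility record (seeds, tolerances, versions) as JSON."""
    meta = {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    meta.update({k: _jsonable(v) for k, v in info.items()})
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
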