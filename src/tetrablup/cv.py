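"""CV1 / CV2 genomic-prediction cross-validation schemes.

Prediction ability (PA) is the Pearson correlation between GEBVs and
phenotypic values of test genotypes.  Two schemes are implemented on top of
the longitudinal fit:

* **CV1** — test genotypes have *no* phenotypic records at any time point;
  their GEBVs come purely from genomic relationships to the training set.
  PA is reported per time point.
* **CV2(known_time)** — test genotypes keep their record at one earlier
  time point; the model predicts a later target time point.  The gain of
  CV2 over CV1 measures how much an early (e.g. at-harvest) measurement
  improves prediction of long-storage performance.

Folds are a near-equal random partition of the non-check genotypes (check
genotypes are fixed effects, hence never test individuals).  One master
seed deterministically derives the per-repeat fold seeds, so the whole
pipeline is reproducible bit for bit.  Within a repeat, PA pools the test
pairs of all folds before correlating (the per-fold alternative is
available via ``aggregate="per_fold"``).

Variance components for a CV2 fold are estimated by REML on the fully
phenotyped training genotypes only — the same fit as CV1 — and the test
genotypes' known-time records enter at the BLUP stage with components held
fixed.  This keeps component estimation free of any test-genotype data and
makes CV2 collapse to CV1 exactly when the known-time records are absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .grm import GenomicRelationship
from .io_tables import PhenotypeTable, TIME_POINTS
from .lmm import LongitudinalFit, ModelSpec, fit_longitudinal, solve_gblup
from .traits import average_reps


@dataclass
class CVResult:
    """Prediction abilities of one scheme at one target time point."""

    scheme: str
    trait: str
    target_time: str
    pa_mean: float
    pa_per_repeat: np.ndarray
    k: int
    n_repeats: int
    seed: int
    known_time: str | None = None

    def __post_init__(self) -> None:
        self.pa_per_repeat = np.asarray(self.pa_per_repeat, dtype=float)
        finite = self.pa_per_repeat[np.isfinite(self.pa_per_repeat)]
        if finite.size and not np.isclose(self.pa_mean, finite.mean()):
            raise ValueError("pa_mean must equal the mean of pa_per_repeat")


def prediction_ability(gebv, pheno) -> float:
    """Pearson correlation between GEBVs and phenotypic values."""
    g = np.asarray(gebv, dtype=float)
    y = np.asarray(pheno, dtype=float)
    if g.shape != y.shape or g.ndim != 1:
        raise ValueError("gebv and pheno must be 1-D vectors of equal length")
    if g.size < 3:
        raise ValueError("need at least 3 pairs to compute a prediction ability")
    if np.isclose(g.std(ddof=0), 0.0) or np.isclose(y.std(ddof=0), 0.0):
        raise ValueError("zero variance in GEBVs or phenotypes; correlation undefined")
    return float(stats.pearsonr(g, y)[0])


def make_folds(ids, k: int, seed: int) -> list[np.ndarray]:
    """Random near-equal partition of ``ids`` into ``k`` test folds."""
    ids = np.asarray(list(ids))
    if k > ids.size:
        raise ValueError(f"cannot split {ids.size} genotypes into {k} folds")
    if k < 2:
        raise ValueError("need at least 2 folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=int(seed))
    return [ids[test] for _, test in kf.split(ids)]


def _repeat_seeds(seed: int, n_repeats: int) -> np.ndarray:
    return np.random.SeedSequence(int(seed)).generate_state(n_repeats)


def _adjusted_values(df: pd.DataFrame, beta: pd.Series, raw: bool) -> pd.Series:
    """Per-record phenotype minus fitted time and year fixed effects."""
    v = df["value"].to_numpy(dtype=float).copy()
    if not raw:
        t_eff = df["time_point"].astype(str).map(
            lambda t: beta.get(f"time:{t}", 0.0)
        ).to_numpy(dtype=float)
        y_eff = df["year"].map(lambda y: beta.get(f"year:{y}", 0.0)).to_numpy(dtype=float)
        v = v - t_eff - y_eff
    return pd.Series(v, index=df.index)


def _pa_from_pairs(pairs: list[tuple[float, float]], label: str) -> float:
    if len(pairs) < 3:
        warnings.warn(f"{label}: fewer than 3 test pairs; PA reported as NaN")
        return float("nan")
    arr = np.asarray(pairs, dtype=float)
    if np.isclose(arr[:, 0].std(), 0.0) or np.isclose(arr[:, 1].std(), 0.0):
        warnings.warn(f"{label}: degenerate variance in test pairs; PA reported as NaN")
        return float("nan")
    return float(stats.pearsonr(arr[:, 0], arr[:, 1])[0])


def _eligible_ids(df: pd.DataFrame, grm: GenomicRelationship) -> list[str]:
    obs = set(df.loc[~df["is_check"], "genotype"])
    return [g for g in grm.genotype_ids if g in obs]


def run_cv1(
    pheno: PhenotypeTable,
    grm: GenomicRelationship,
    spec: ModelSpec,
    k: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    raw_phenotypes: bool = False,
    aggregate: str = "pool",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> dict[str, CVResult]:
    """CV1: predict genotypes with no phenotypic records at any time point.

    Per repeat and fold, all records of the test genotypes are deleted, the
    longitudinal model is refitted by REML on the remaining data, and test
    GEBVs are correlated with the (fixed-effect-adjusted, unless
    ``raw_phenotypes``) held-out phenotypes at each time point.  Returns one
    :class:`CVResult` per time point.
    """
    if aggregate not in ("pool", "per_fold"):
        raise ValueError("aggregate must be 'pool' or 'per_fold'")
    table = average_reps(pheno.filter(trait=spec.trait, time_points=spec.time_points))
    df = table.df.dropna(subset=["value"])
    eligible = _eligible_ids(df, grm)
    rep_seeds = _repeat_seeds(seed, n_repeats)

    times = [t for t in spec.time_points if t in set(df["time_point"].astype(str))]
    pa = {t: [] for t in times}
    for r in range(n_repeats):
        folds = make_folds(eligible, k, rep_seeds[r])
        theta = None
        pairs = {t: [] for t in times}
        fold_pas = {t: [] for t in times}
        for test_ids in folds:
            test_set = set(test_ids)
            train = PhenotypeTable(df[~df["genotype"].isin(test_set)], strict=False)
            fit = fit_longitudinal(train, grm, spec, tol=tol, max_iter=max_iter, theta0=theta)
            theta = fit._theta
            held = df[df["genotype"].isin(test_set)]
            adj = _adjusted_values(held, fit.beta, raw_phenotypes)
            fold_pairs = {t: [] for t in times}
            for idx, rec in held.iterrows():
                t = str(rec["time_point"])
                if t in fit.blups.columns:
                    fold_pairs[t].append((fit.blups.at[rec["genotype"], t], adj[idx]))
            for t in times:
                pairs[t].extend(fold_pairs[t])
                if aggregate == "per_fold":
                    fold_pas[t].append(_pa_from_pairs(fold_pairs[t], f"CV1 fold {t}"))
        for t in times:
            if aggregate == "pool":
                pa[t].append(_pa_from_pairs(pairs[t], f"CV1 repeat {r} time {t}"))
            else:
                vals = [x for x in fold_pas[t] if np.isfinite(x)]
                pa[t].append(float(np.mean(vals)) if vals else float("nan"))

    return {
        t: CVResult(
            scheme="CV1",
            trait=spec.trait,
            target_time=t,
            pa_mean=float(np.nanmean(pa[t])),
            pa_per_repeat=np.array(pa[t]),
            k=k,
            n_repeats=n_repeats,
            seed=seed,
        )
        for t in times
    }


def run_cv2(
    pheno: PhenotypeTable,
    grm: GenomicRelationship,
    spec: ModelSpec,
    known_time: str,
    target_time: str,
    k: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    raw_phenotypes: bool = False,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> CVResult:
    """CV2: predict a later time point knowing an earlier one.

    Test genotypes keep their records at ``known_time`` (and only it); the
    model predicts ``target_time``.  Fold partitions are identical to
    :func:`run_cv1` at the same master seed, so the two schemes are paired.
    """
    if known_time == target_time:
        raise ValueError("known_time must differ from target_time")
    order = {t: i for i, t in enumerate(TIME_POINTS)}
    if known_time not in order or target_time not in order:
        raise ValueError(f"time points must be among {list(TIME_POINTS)}")
    if order[known_time] >= order[target_time]:
        raise ValueError("known_time must be strictly earlier than target_time")

    table = average_reps(pheno.filter(trait=spec.trait, time_points=spec.time_points))
    df = table.df.dropna(subset=["value"])
    eligible = _eligible_ids(df, grm)
    checks = table.check_genotypes
    rep_seeds = _repeat_seeds(seed, n_repeats)

    pa = []
    for r in range(n_repeats):
        folds = make_folds(eligible, k, rep_seeds[r])
        theta = None
        pairs = []
        for test_ids in folds:
            test_set = set(test_ids)
            is_test = df["genotype"].isin(test_set)
            train_df = df[~is_test]
            train = PhenotypeTable(train_df, strict=False)
            fit = fit_longitudinal(train, grm, spec, tol=tol, max_iter=max_iter, theta0=theta)
            theta = fit._theta

            known = df[is_test & (df["time_point"].astype(str) == known_time)]
            aug = PhenotypeTable(pd.concat([train_df, known]), strict=False)
            sol = solve_gblup(aug, grm, spec, fit.components, check_genotypes=checks)

            held = df[is_test & (df["time_point"].astype(str) == target_time)]
            adj = _adjusted_values(held, sol.beta, raw_phenotypes)
            for idx, rec in held.iterrows():
                pairs.append((sol.blups.at[rec["genotype"], target_time], adj[idx]))
        pa.append(_pa_from_pairs(pairs, f"CV2 repeat {r}"))

    return CVResult(
        scheme="CV2",
        trait=spec.trait,
        target_time=target_time,
        pa_mean=float(np.nanmean(pa)),
        pa_per_repeat=np.array(pa),
        k=k,
        n_repeats=n_repeats,
        seed=seed,
        known_time=known_time,
    )
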