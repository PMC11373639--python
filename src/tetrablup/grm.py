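"""Tetrasomic VanRaden genomic relationship matrix from allele dosages.

For a ploidy-``m`` population with dosage matrix ``M`` (genotypes × markers)
and allele frequencies ``p_j = mean(M[:, j]) / m``, the additive relationship
matrix generalizing VanRaden's method is

    W = M - m * P            (column-centred dosages, P = 1 p')
    G = W W' / sum_j m * p_j * (1 - p_j)

The denominator is the expected dosage variance under polysomic
Hardy-Weinberg equilibrium, ``Var(d_j) = m p_j (1 - p_j)`` for a
Binomial(m, p_j) dosage; setting ``m = 2`` recovers the classical diploid
VanRaden matrix.  Monomorphic markers (and optionally markers below a minor
allele frequency threshold) are excluded; missing dosages are mean-imputed
per marker after the frequencies are computed.  A small ridge on the
diagonal keeps G invertible for mixed-model use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import DosageMatrix, read_matrix, write_matrix


@dataclass
class GenomicRelationship:
    """Symmetric genotype × genotype additive relationship matrix."""

    genotype_ids: list[str]
    values: np.ndarray
    ploidy: int
    n_markers_used: int
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genotype_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"G shape {self.values.shape} does not match {n} genotypes")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("G must be symmetric to 1e-10")
        self._index = {g: i for i, g in enumerate(self.genotype_ids)}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genotype_ids, columns=self.genotype_ids)

    def indices(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[g] for g in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"genotype {exc.args[0]!r} not in relationship matrix") from None

    def submatrix(self, ids) -> np.ndarray:
        idx = self.indices(ids)
        return self.values[np.ix_(idx, idx)]

    def cross(self, row_ids, col_ids) -> np.ndarray:
        return self.values[np.ix_(self.indices(row_ids), self.indices(col_ids))]


def allele_frequencies(dosages: DosageMatrix) -> np.ndarray:
    """Per-marker allele frequency: mean non-missing dosage divided by ploidy."""
    vals = dosages.dosages
    n_obs = np.sum(np.isfinite(vals), axis=0)
    empty = n_obs == 0
    if empty.any():
        bad = [dosages.marker_ids[j] for j in np.flatnonzero(empty)[:5]]
        raise ValueError(f"markers with no observed dosages: {bad}")
    return np.nanmean(vals, axis=0) / dosages.ploidy


def vanraden_grm(
    dosages: DosageMatrix,
    min_maf: float = 0.0,
    ridge: float = 1e-6,
) -> GenomicRelationship:
    """Build the (tetrasomic) VanRaden relationship matrix.

    Parameters
    ----------
    dosages
        Allele-dosage matrix; its ploidy sets the centring and the HWE
        variance in the denominator.
    min_maf
        Markers with minor allele frequency strictly below this are dropped.
        The default 0.0 keeps every polymorphic marker.
    ridge
        Added to the diagonal so G stays positive definite under near-perfect
        relatives; use 0 to obtain the textbook matrix exactly.
    """
    if dosages.n_genotypes < 2:
        raise ValueError("need at least 2 genotypes to build a relationship matrix")
    m = dosages.ploidy
    p = allele_frequencies(dosages)
    maf = np.minimum(p, 1.0 - p)
    variable = np.nanvar(dosages.dosages, axis=0) > 0.0
    keep = variable & (maf > (min_maf if min_maf > 0 else 0.0))
    if not keep.any():
        raise ValueError("no polymorphic markers pass the MAF filter; cannot build G")

    M = dosages.dosages[:, keep].copy()
    pk = p[keep]
    # mean imputation per marker (equivalently: missing cells contribute 0 after centring)
    col_mean = m * pk
    nan_mask = np.isnan(M)
    if nan_mask.any():
        M[nan_mask] = np.broadcast_to(col_mean, M.shape)[nan_mask]

    W = M - col_mean
    denom = float(np.sum(m * pk * (1.0 - pk)))
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    if ridge:
        G = G + ridge * np.eye(G.shape[0])
    return GenomicRelationship(
        genotype_ids=list(dosages.genotype_ids),
        values=G,
        ploidy=m,
        n_markers_used=int(keep.sum()),
        ridge=float(ridge),
    )


def write_grm(grm: GenomicRelationship, path: str | Path, sep: str = ",") -> None:
    write_matrix(grm.to_dataframe(), path, sep=sep)


def read_grm(path: str | Path, ploidy: int = 4, sep: str = ",") -> GenomicRelationship:
    df = read_matrix(path, sep=sep)
    return GenomicRelationship(
        genotype_ids=[str(g) for g in df.index],
        values=df.to_numpy(dtype=float),
        ploidy=ploidy,
        n_markers_used=0,
    )
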