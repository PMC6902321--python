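"""Pedigree and genomic relationship algebra.

* sparse A-inverse by Henderson's rules with inbreeding from the
  Meuwissen-Luo recursion;
* dense tabular A (independent O(n^2) recursion, also the workhorse for the
  partitions needed by marker imputation at small scale);
* VanRaden genomic relationship G = ZZ' / sum 2 p_j (1 - p_j) with the
  centering frequencies taken from a configurable base cohort;
* the single-step H-inverse, H^-1 = A^-1 + [[0,0],[0, Gb^-1 - A22^-1]] with
  an optional blend Gb = (1-w) G + w A22 guarding against singular G.

The counted allele is allele "1" of the simulator everywhere (frequencies,
centering, gene content).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy.sparse.linalg import splu

__all__ = [
    "RelationshipMatrix",
    "MarkerMatrix",
    "inbreeding",
    "a_inverse",
    "a_matrix_tabular",
    "a_partitions",
    "a_submatrix",
    "allele_frequencies",
    "center_markers",
    "g_matrix",
    "blend_g",
    "h_inverse",
    "h_submatrix",
]


@dataclass(frozen=True)
class RelationshipMatrix:
    """A relationship matrix plus the animal index set it refers to."""

    values: object  # dense ndarray or scipy sparse
    index: np.ndarray
    kind: str  # "A" | "Ainv" | "A22" | "G" | "Hinv"


@dataclass(frozen=True)
class MarkerMatrix:
    """Centred marker covariates ((count) - 2 p_j) for a set of animals."""

    covariates: np.ndarray  # (n, m) float64
    centering_freqs: np.ndarray  # (m,)
    base_tag: str  # "P-base" | "G-base" | other label


def _parent_arrays(pedigree) -> tuple[np.ndarray, np.ndarray]:
    sire = np.asarray(pedigree.sire, np.int64)
    dam = np.asarray(pedigree.dam, np.int64)
    n = sire.size
    order = np.arange(n)
    if np.any((sire >= 0) & (sire >= order)) or np.any((dam >= 0) & (dam >= order)):
        raise ValueError("pedigree is not chronologically ordered (parent after offspring)")
    return sire, dam


@njit(cache=False)
def _inbreeding_ml(sire, dam):  # pragma: no cover
    # Meuwissen & Luo principle: per animal, trace its gene-flow row back
    # through the ancestry; A_ii = sum_j L_ij^2 d_jj with d_jj the Mendelian
    # sampling variance of ancestor j, and F_i = A_ii - 1.
    n = sire.shape[0]
    F = np.zeros(n)
    vals = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        fi = -1.0
        vals[i] = 1.0
        for j in range(i, -1, -1):
            if vals[j] == 0.0:
                continue
            v = vals[j]
            vals[j] = 0.0
            sj, dj = sire[j], dam[j]
            if sj >= 0:
                vals[sj] += 0.5 * v
            if dj >= 0:
                vals[dj] += 0.5 * v
            fj_s = F[sj] if sj >= 0 else 0.0
            fj_d = F[dj] if dj >= 0 else 0.0
            if sj >= 0 and dj >= 0:
                djj = 0.5 - 0.25 * (fj_s + fj_d)
            elif sj >= 0 or dj >= 0:
                djj = 0.75 - 0.25 * (fj_s if sj >= 0 else fj_d)
            else:
                djj = 1.0
            fi += v * v * djj
        F[i] = fi
    return F


def inbreeding(pedigree) -> np.ndarray:
    """Inbreeding coefficient per animal (Meuwissen-Luo style recursion)."""
    sire, dam = _parent_arrays(pedigree)
    return _inbreeding_ml(sire, dam)


def a_inverse(pedigree) -> sp.csc_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding."""
    sire, dam = _parent_arrays(pedigree)
    n = sire.size
    F = _inbreeding_ml(sire, dam)
    rows, cols, vals = [], [], []

    def fcoef(p):
        return F[p] if p >= 0 else 0.0

    for i in range(n):
        s, d = int(sire[i]), int(dam[i])
        n_par = int(s >= 0) + int(d >= 0)
        if n_par == 2:
            dii = 0.5 - 0.25 * (fcoef(s) + fcoef(d))
        elif n_par == 1:
            dii = 0.75 - 0.25 * fcoef(s if s >= 0 else d)
        else:
            dii = 1.0
        ainv = 1.0 / dii
        rows.append(i); cols.append(i); vals.append(ainv)
        for p in (s, d):
            if p >= 0:
                rows.append(i); cols.append(p); vals.append(-0.5 * ainv)
                rows.append(p); cols.append(i); vals.append(-0.5 * ainv)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    rows.append(p); cols.append(q); vals.append(0.25 * ainv)
    return sp.csc_matrix((vals, (rows, cols)), shape=(n, n))


@njit(cache=False)
def _tabular_a(sire, dam):  # pragma: no cover
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        ass = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * ass
        for j in range(i):
            aij = 0.0
            if s >= 0:
                aij += 0.5 * A[j, s]
            if d >= 0:
                aij += 0.5 * A[j, d]
            A[i, j] = aij
            A[j, i] = aij
    return A


def a_matrix_tabular(pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method (O(n^2))."""
    sire, dam = _parent_arrays(pedigree)
    return _tabular_a(sire, dam)


def a_submatrix(ainv: sp.spmatrix, idx: np.ndarray) -> np.ndarray:
    """Dense A[idx, idx] recovered from sparse A^-1 by solving for unit columns."""
    idx = np.asarray(idx, np.int64)
    lu = splu(sp.csc_matrix(ainv))
    rhs = np.zeros((ainv.shape[0], idx.size))
    rhs[idx, np.arange(idx.size)] = 1.0
    cols = lu.solve(rhs)
    return cols[idx, :]


def a_partitions(pedigree, genotyped: np.ndarray):
    """Dense partitions (A11, A12, A21, A22, A22^-1) w.r.t. the genotyped set.

    Partition 1 = non-genotyped, 2 = genotyped, each in ascending pedigree
    order.  Dense tabular A underneath: intended for desk-scale pedigrees.
    """
    genotyped = np.asarray(genotyped, np.int64)
    n = np.asarray(pedigree.sire).size
    if genotyped.size == 0:
        raise ValueError("genotyped set is empty")
    if genotyped.min() < 0 or genotyped.max() >= n:
        raise ValueError("genotyped id absent from pedigree")
    mask = np.zeros(n, bool)
    mask[genotyped] = True
    ng = np.flatnonzero(~mask)
    gg = np.flatnonzero(mask)
    A = a_matrix_tabular(pedigree)
    A11 = A[np.ix_(ng, ng)]
    A12 = A[np.ix_(ng, gg)]
    A22 = A[np.ix_(gg, gg)]
    return A11, A12, A12.T.copy(), A22, np.linalg.inv(A22)


def allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Frequency of the counted allele per marker from a (n, m) 0/1/2 matrix."""
    genotypes = np.asarray(genotypes)
    if genotypes.shape[0] == 0:
        raise ValueError("empty cohort: allele frequencies undefined")
    return genotypes.mean(axis=0) / 2.0


def center_markers(genotypes: np.ndarray, freqs: np.ndarray, base_tag: str = "") -> MarkerMatrix:
    Z = np.asarray(genotypes, np.float64) - 2.0 * np.asarray(freqs)[None, :]
    return MarkerMatrix(covariates=Z, centering_freqs=np.asarray(freqs, float), base_tag=base_tag)


def g_matrix(markers: MarkerMatrix) -> np.ndarray:
    """VanRaden G = ZZ' / sum_j 2 p_j (1 - p_j) at the matrix's centering base."""
    p = markers.centering_freqs
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all centering frequencies fixed: G denominator is zero")
    Z = markers.covariates
    return (Z @ Z.T) / denom


def blend_g(G: np.ndarray, A22: np.ndarray, weight: float) -> np.ndarray:
    """Gb = (1 - w) G + w A22; w = 0 returns G unchanged."""
    if weight == 0.0:
        return G
    return (1.0 - weight) * G + weight * A22


def h_inverse(
    ainv: sp.spmatrix,
    G_b: np.ndarray,
    a22_inv: np.ndarray,
    genotyped: np.ndarray,
) -> sp.csc_matrix:
    """H^-1 = A^-1 + [[0,0],[0, Gb^-1 - A22^-1]] on the full pedigree index."""
    genotyped = np.asarray(genotyped, np.int64)
    if genotyped.size == 0:
        return sp.csc_matrix(ainv)
    try:
        g_inv = np.linalg.inv(G_b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(
            "blended G is singular; increase the A22 blend weight"
        ) from exc
    corr = g_inv - a22_inv
    ii, jj = np.meshgrid(genotyped, genotyped, indexing="ij")
    corr_sp = sp.csc_matrix(
        (corr.ravel(), (ii.ravel(), jj.ravel())), shape=ainv.shape
    )
    return (sp.csc_matrix(ainv) + corr_sp).tocsc()


def h_submatrix(
    ainv: sp.spmatrix,
    genotyped: np.ndarray,
    G_b: np.ndarray,
    rows: np.ndarray,
) -> np.ndarray:
    """Dense H[rows, rows] without forming H.

    Uses H = A + W (Gb - A22) W' with W = A[:, genotyped] A22^-1, so only
    the A columns at ``rows`` and ``genotyped`` are recovered from sparse
    A^-1.
    """
    rows = np.asarray(rows, np.int64)
    genotyped = np.asarray(genotyped, np.int64)
    if genotyped.size == 0:
        return a_submatrix(ainv, rows)
    union, inv = np.unique(np.concatenate([rows, genotyped]), return_inverse=True)
    lu = splu(sp.csc_matrix(ainv))
    rhs = np.zeros((ainv.shape[0], union.size))
    rhs[union, np.arange(union.size)] = 1.0
    Acols = lu.solve(rhs)  # (n, |union|) = A[:, union]
    r_pos = inv[: rows.size]
    g_pos = inv[rows.size:]
    A_rr = Acols[rows, :][:, r_pos]
    A_rg = Acols[rows, :][:, g_pos]
    A22 = Acols[genotyped, :][:, g_pos]
    W_r = np.linalg.solve(A22.T, A_rg.T).T  # A_rg @ A22^-1
    return A_rr + W_r @ (G_b - A22) @ W_r.T
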