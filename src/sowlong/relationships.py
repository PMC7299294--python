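"""Pedigree, genomic and single-step relationship matrices.

Builds the additive relationship matrix A (tabular method), its sparse
inverse directly from the pedigree (Meuwissen & Luo inbreeding +
Henderson rules), the VanRaden genomic matrix G, and the single-step
H-inverse that augments A-inverse with genomic information on the
genotyped subset.  SNPs are filtered for segregation in every
population and within-population MAF before G construction.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve_triangular

from .errors import ConfigurationError, NumericalError, PedigreeError

# ---------------------------------------------------------------------------
# containers


@dataclass
class RelationshipMatrix:
    """A relationship matrix with its animal-id index map.

    kind is one of {"A", "A_inverse", "G", "H_inverse", "A22"}.  The
    values are dense for A/G/A22 and sparse (CSR) for the inverses.
    """

    kind: str
    ids: np.ndarray
    values: object  # ndarray or scipy sparse

    @property
    def index_map(self) -> dict:
        return {a: i for i, a in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class SnpFilterReport:
    n_input: int
    n_removed_not_segregating: int
    n_removed_maf: int
    n_retained: int
    allele_freqs: pd.DataFrame = field(repr=False)  # population x SNP

    def __post_init__(self):
        total = self.n_removed_not_segregating + self.n_removed_maf + self.n_retained
        if total != self.n_input:
            raise ValueError("inconsistent SNP filter report totals")


# ---------------------------------------------------------------------------
# pedigree utilities


def _parent_indices(pedigree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (ids, sire_idx, dam_idx) with -1 for unknown, validated parents-first."""
    tab = pedigree.table if hasattr(pedigree, "table") else pedigree
    ids = tab["animal"].to_numpy()
    pos = {a: i for i, a in enumerate(ids)}
    if len(pos) != len(ids):
        raise PedigreeError("duplicated animal ids in pedigree")

    def resolve(col):
        out = np.full(len(ids), -1, dtype=np.int64)
        for i, p in enumerate(tab[col].to_numpy()):
            if p is None or (isinstance(p, float) and np.isnan(p)) or p == 0:
                continue
            j = pos.get(p, -1)
            if j >= 0:
                out[i] = j
        return out

    sire = resolve("sire")
    dam = resolve("dam")
    if np.any(sire >= np.arange(len(ids))) or np.any(dam >= np.arange(len(ids))):
        raise PedigreeError("pedigree not ordered parents-first (or contains a cycle)")
    return ids, sire, dam


def inbreeding_coefficients(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo path traversal.

    For each animal the diagonal a_ii = sum_j L_ij^2 d_j is accumulated over
    ancestors j, where d_j is the Mendelian-sampling variance factor; then
    F_i = a_ii - 1.  Requires a parents-first ordering.
    """
    n = len(sire)
    F = np.zeros(n)
    d = np.zeros(n)
    for i in range(n):
        s, m = sire[i], dam[i]
        if s >= 0 and m >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[m])
        elif s >= 0:
            d[i] = 0.75 - 0.25 * F[s]
        elif m >= 0:
            d[i] = 0.75 - 0.25 * F[m]
        else:
            d[i] = 1.0
        if s < 0 or m < 0:
            F[i] = 0.0
            continue
        # traverse ancestors from i downwards, accumulating path coefficients
        coeff = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = coeff.pop(j, 0.0)
            if lj == 0.0:
                continue
            aii += lj * lj * d[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p not in coeff:
                        heapq.heappush(heap, -p)
                        coeff[p] = 0.0
                    coeff[p] += 0.5 * lj
        F[i] = aii - 1.0
        # d of later animals depends on F already stored; recompute not needed
    return F


def mendelian_variance_factors(sire, dam, F=None):
    """Within-family (Mendelian sampling) variance factors d_i."""
    if F is None:
        F = inbreeding_coefficients(sire, dam)
    n = len(sire)
    d = np.ones(n)
    both = (sire >= 0) & (dam >= 0)
    one_s = (sire >= 0) & ~both
    one_d = (dam >= 0) & ~both
    d[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    d[one_s] = 0.75 - 0.25 * F[sire[one_s]]
    d[one_d] = 0.75 - 0.25 * F[dam[one_d]]
    return d, F


def build_A(pedigree) -> RelationshipMatrix:
    """Dense additive relationship matrix by the tabular method."""
    ids, sire, dam = _parent_indices(pedigree)
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        s, m = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += A[:i, s]
        if m >= 0:
            row += A[:i, m]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, m] if (s >= 0 and m >= 0) else 0.0)
    return RelationshipMatrix("A", ids, A)


def build_A_inverse(pedigree) -> RelationshipMatrix:
    """Sparse A-inverse directly from the pedigree, accounting for inbreeding."""
    ids, sire, dam = _parent_indices(pedigree)
    d, _ = mendelian_variance_factors(sire, dam)
    alpha = 1.0 / d
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(len(ids)):
        s, m = sire[i], dam[i]
        a = alpha[i]
        add(i, i, a)
        for p in (s, m):
            if p >= 0:
                add(i, p, -0.5 * a)
                add(p, i, -0.5 * a)
                add(p, p, 0.25 * a)
        if s >= 0 and m >= 0:
            add(s, m, 0.25 * a)
            add(m, s, 0.25 * a)
        elif s >= 0 or m >= 0:
            # the 0.25 contribution of the known parent is already added above;
            # nothing further for the unknown one (treated as unrelated founder)
            pass
    n = len(ids)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix("A_inverse", ids, Ainv)


def _lower_T_and_D(pedigree):
    """(I - P) lower-triangular factor and Mendelian variance diag of A = T D T'."""
    ids, sire, dam = _parent_indices(pedigree)
    d, _ = mendelian_variance_factors(sire, dam)
    n = len(ids)
    rows, cols, vals = list(range(n)), list(range(n)), [1.0] * n
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                rows.append(i)
                cols.append(p)
                vals.append(-0.5)
    ImP = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return ids, ImP, d


def build_A22(pedigree, genotyped_ids) -> RelationshipMatrix:
    """Pedigree relationships among the genotyped subset without forming full A.

    Uses the factorisation A = T D T' (Colleau's indirect method): the
    required columns are T' S with S the genotyped selector, obtained by one
    sparse triangular solve.
    """
    ids, ImP, d = _lower_T_and_D(pedigree)
    pos = {a: i for i, a in enumerate(ids)}
    try:
        g_rows = np.array([pos[a] for a in genotyped_ids])
    except KeyError as e:  # pragma: no cover
        raise PedigreeError(f"genotyped animal {e} not in pedigree") from e
    n, g = len(ids), len(g_rows)
    S = np.zeros((n, g))
    S[g_rows, np.arange(g)] = 1.0
    M = spsolve_triangular(ImP.T.tocsr(), S, lower=False)  # M = T' S
    A22 = (M * d[:, None]).T @ M
    A22 = 0.5 * (A22 + A22.T)
    return RelationshipMatrix("A22", np.asarray(genotyped_ids), A22)


# ---------------------------------------------------------------------------
# SNP filtering and G


def filter_snps(dosages, breed_labels, maf_threshold: float = 0.01, strict: bool = True):
    """Retain SNPs segregating in every population with within-population MAF >= threshold.

    Removal reasons are assigned in a fixed order: a SNP fixed (frequency 0
    or 1) in any population is counted as not segregating; among the
    remaining, a SNP below the MAF threshold in any population is counted as
    a MAF removal.

    Returns (retained_index, SnpFilterReport).
    """
    dosages = np.asarray(dosages)
    breeds = pd.Series(list(breed_labels))
    pops = sorted(breeds.unique())
    if strict and len(pops) < 3:
        raise ConfigurationError(
            f"strict SNP filtering expects three populations, found {pops}"
        )
    freqs = {}
    for p in pops:
        rows = np.where((breeds == p).to_numpy())[0]
        freqs[p] = dosages[rows].mean(axis=0) / 2.0
    fdf = pd.DataFrame(freqs).T  # population x SNP
    f = fdf.to_numpy()
    segregating = np.all((f > 0.0) & (f < 1.0), axis=0)
    maf = np.minimum(f, 1.0 - f)
    maf_ok = np.all(maf >= maf_threshold, axis=0)
    retained = segregating & maf_ok
    n_not_seg = int(np.sum(~segregating))
    n_maf = int(np.sum(segregating & ~maf_ok))
    report = SnpFilterReport(
        n_input=dosages.shape[1],
        n_removed_not_segregating=n_not_seg,
        n_removed_maf=n_maf,
        n_retained=int(retained.sum()),
        allele_freqs=fdf,
    )
    return np.where(retained)[0], report


def build_G(dosages, ids, retained=None, allele_freqs=None) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    G = M M' / (2 * sum p(1-p)) with M the dosage matrix centred at twice the
    allele frequency.  Frequencies default to the pooled mean over all
    genotyped animals.
    """
    Z = np.asarray(dosages, dtype=float)
    if retained is not None:
        Z = Z[:, retained]
    if Z.shape[0] < 2 or Z.shape[1] < 1:
        raise ConfigurationError("G needs at least two animals and one SNP")
    p = Z.mean(axis=0) / 2.0 if allele_freqs is None else np.asarray(allele_freqs, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise NumericalError("monomorphic SNP set: 2*sum p(1-p) is zero; filter first")
    M = Z - 2.0 * p
    if np.abs(M).max() == 0.0:
        raise NumericalError("all dosages equal their centring value; G is undefined")
    G = (M @ M.T) / denom
    return RelationshipMatrix("G", np.asarray(ids), G)


# ---------------------------------------------------------------------------
# single-step H inverse


def build_H_inverse(
    A_inv: RelationshipMatrix,
    A22: RelationshipMatrix,
    G: RelationshipMatrix,
    tau: float = 1.0,
    omega: float = 1.0,
    blend_weight: float = 0.05,
) -> RelationshipMatrix:
    """Single-step H-inverse: A-inverse plus the genomic correction block.

    H^-1 = A^-1 + S' (tau * Gw^-1 - omega * A22^-1) S on the genotyped
    subset, with Gw = (1-w) G + w A22 the blended genomic matrix.
    """
    if not np.array_equal(np.asarray(G.ids), np.asarray(A22.ids)):
        raise ConfigurationError("G and A22 must index the same genotyped animals")
    pos = A_inv.index_map
    try:
        g_rows = np.array([pos[a] for a in np.asarray(G.ids)])
    except KeyError as e:
        raise PedigreeError(f"genotyped animal {e} not in pedigree") from e

    if len(g_rows) == 0:
        return RelationshipMatrix("H_inverse", A_inv.ids, A_inv.values.copy())

    Gw = (1.0 - blend_weight) * np.asarray(G.values) + blend_weight * np.asarray(A22.values)
    try:
        Gw_inv = np.linalg.inv(Gw)
        A22_inv = np.linalg.inv(np.asarray(A22.values))
    except np.linalg.LinAlgError as e:
        raise NumericalError(
            "singular blended genomic matrix; raise blend_weight"
        ) from e
    block = tau * Gw_inv - omega * A22_inv
    n = A_inv.n
    corr = sp.coo_matrix(
        (
            block.ravel(),
            (np.repeat(g_rows, len(g_rows)), np.tile(g_rows, len(g_rows))),
        ),
        shape=(n, n),
    )
    Hinv = (A_inv.values + corr).tocsr()
    return RelationshipMatrix("H_inverse", A_inv.ids, Hinv)
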