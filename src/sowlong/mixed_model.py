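"""Henderson's mixed-model equations for the longevity evaluations.

The model is y = Xb + Zu + Vv + e with u ~ N(0, K x G0) for a pedigree
(A) or single-step (H) relationship K and a t x t genetic covariance G0
over trait slots, v ~ N(0, I sigma_v^2) the common-litter effect and a
diagonal residual.  In multi-breed "different" mode each record belongs
to exactly one breed slot, so the residual never couples slots and the
missing-record treatment reduces to a diagonal R.

Fixed effects are built per slot (factors one-hot with the first sorted
level dropped, covariates optionally nested within a factor, e.g. one
weaned-count slope per herd); linearly dependent columns are detected on
the Gram matrix and dropped with a log message, so confounded factor
sets (herd within country) remain solvable and reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import qr as dense_qr
from scipy.sparse.linalg import splu, cg

from .errors import ConfigurationError, ConvergenceError

log = logging.getLogger(__name__)

DIRECT_SOLVE_LIMIT = 20_000


def splu_symmetric(M):
    """Sparse LU of a symmetric system with a symmetric fill-reducing ordering."""
    return splu(
        sp.csc_matrix(M),
        permc_spec="MMD_AT_PLUS_A",
        options={"SymmetricMode": True},
    )


@dataclass
class ModelSpec:
    """Which effects enter the model for one trait."""

    trait: str
    fixed_factors: tuple = ()
    covariate_by: dict = field(default_factory=dict)  # covariate column -> nesting factor
    random_litter: bool = True
    repeatability: bool = False
    trait_mode: str = "same"
    relationship: str = "A"  # provenance tag: A for REML, H for EBV runs
    breed_fixed_effect: bool = False

    @classmethod
    def for_trait(cls, trait: str, trait_mode: str = "same", relationship: str = "A"):
        """Default per-trait effect lists used throughout the evaluation."""
        if trait in ("LGY12", "LGY15"):
            return cls(
                trait=trait,
                fixed_factors=("dam_parity", "herd", "year", "country"),
                trait_mode=trait_mode,
                relationship=relationship,
            )
        if trait == "Survival":
            # repeatability model without a permanent environmental effect
            return cls(
                trait=trait,
                fixed_factors=("parity", "dam_parity", "herd_year", "country", "season"),
                covariate_by={"n_weaned": "herd"},
                repeatability=True,
                trait_mode=trait_mode,
                relationship=relationship,
            )
        raise ConfigurationError(f"unknown trait {trait!r}")


@dataclass
class VarianceComponents:
    """(co)variance parameters for one fit; slot order matches the design."""

    slots: tuple
    G0: np.ndarray
    sigma_v2: np.ndarray | None
    sigma_e2: np.ndarray
    se: dict | None = None
    param_cov: np.ndarray | None = None
    converged: bool = True
    n_iterations: int = 0
    loglik: float = np.nan
    history: list = field(default_factory=list)

    def validate(self, need_litter: bool) -> None:
        if np.any(np.diag(np.atleast_2d(self.G0)) <= 0):
            raise ConfigurationError("genetic variances must be strictly positive")
        if np.any(self.sigma_e2 <= 0):
            raise ConfigurationError("residual variances must be strictly positive")
        if need_litter:
            if self.sigma_v2 is None or np.any(self.sigma_v2 <= 0):
                raise ConfigurationError("litter variances must be strictly positive")


@dataclass
class DesignMatrices:
    X: sp.csr_matrix
    Z: sp.csr_matrix
    V: sp.csr_matrix | None
    y: np.ndarray
    slots: tuple
    slot_of_record: np.ndarray
    x_labels: list
    dropped_labels: list
    animal_ids: np.ndarray
    litter_index: pd.MultiIndex | None  # (slot, litter_id) per V column

    @property
    def n_records(self):
        return len(self.y)


@dataclass
class EvaluationResult:
    b_hat: pd.Series
    u_hat: pd.DataFrame  # animals x slots
    v_hat: pd.Series | None  # indexed by (slot, litter)
    diagnostics: dict
    spec: ModelSpec
    variance_components: VarianceComponents
    relationship_kind: str
    design: DesignMatrices


# ---------------------------------------------------------------------------
# design construction


def _one_hot(codes: np.ndarray, n_levels: int, n_rows: int) -> sp.csr_matrix:
    return sp.csr_matrix(
        (np.ones(len(codes)), (np.arange(n_rows), codes)), shape=(n_rows, n_levels)
    )


def _drop_dependent_columns(X: sp.csr_matrix, labels: list):
    """Drop columns that are linearly dependent, detected on the Gram matrix."""
    gram = (X.T @ X).toarray()
    scale = np.sqrt(np.clip(np.diag(gram), 1e-300, None))
    gram = gram / scale[:, None] / scale[None, :]
    _, R, piv = dense_qr(gram, pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(gram.shape) * np.finfo(float).eps * 100 if len(diag) else 0.0
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    dropped = [labels[j] for j in piv[rank:]]
    if dropped:
        log.warning("dropping %d confounded fixed-effect columns: %s%s",
                    len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
    kept_labels = [labels[j] for j in keep]
    return X[:, keep].tocsr(), kept_labels, dropped


def build_design_matrices(table: pd.DataFrame, spec: ModelSpec, animal_ids) -> DesignMatrices:
    """Incidence matrices X (fixed), Z (animal x slot), V (litter x slot).

    Fixed effects are nested within trait slot; reference levels are the
    first level in sort order, deterministically.  Z columns cover every
    animal in ``animal_ids`` (slot-major), so phenotype-less animals get
    breeding values.  V columns exist only for (slot, litter) pairs with
    records.
    """
    slots = tuple(sorted(table["slot"].unique()))
    n = len(table)
    slot_of_record = np.array([slots.index(s) for s in table["slot"]])
    animal_ids = np.asarray(animal_ids)
    apos = {a: i for i, a in enumerate(animal_ids)}
    q = len(animal_ids)

    x_blocks, labels = [], []
    for si, s in enumerate(slots):
        rows = np.where(slot_of_record == si)[0]
        sub = table.iloc[rows]
        cols = [sp.csr_matrix((np.ones(len(rows)), (rows, np.zeros(len(rows), int))), shape=(n, 1))]
        lab = [f"{s}:intercept"]
        factors = list(spec.fixed_factors)
        if spec.breed_fixed_effect and "breed" in table.columns:
            factors.append("breed")
        for fct in factors:
            levels = np.sort(sub[fct].astype(str).unique())
            if len(levels) < 2:
                continue
            codes = pd.Categorical(sub[fct].astype(str), categories=levels).codes
            oh = sp.csr_matrix(
                (np.ones(len(rows)), (rows, codes)), shape=(n, len(levels))
            )[:, 1:]  # drop first sorted level
            cols.append(oh)
            lab.extend(f"{s}:{fct}={lv}" for lv in levels[1:])
        for cov, by in spec.covariate_by.items():
            x = pd.to_numeric(sub[cov], errors="coerce").fillna(0.0).to_numpy(float)
            if by is None:
                cols.append(sp.csr_matrix((x, (rows, np.zeros(len(rows), int))), shape=(n, 1)))
                lab.append(f"{s}:{cov}")
            else:
                levels = np.sort(sub[by].astype(str).unique())
                codes = pd.Categorical(sub[by].astype(str), categories=levels).codes
                cols.append(
                    sp.csr_matrix((x, (rows, codes)), shape=(n, len(levels)))
                )
                lab.extend(f"{s}:{cov}@{by}={lv}" for lv in levels)
        x_blocks.append(sp.hstack(cols, format="csr"))
        labels.extend(lab)
    X = sp.hstack(x_blocks, format="csr") if len(x_blocks) > 1 else x_blocks[0]
    X, labels, dropped = _drop_dependent_columns(X, labels)

    arow = np.array([apos[a] for a in table["animal"]])
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), slot_of_record * q + arow)),
        shape=(n, len(slots) * q),
    )

    V = litter_index = None
    if spec.random_litter and "litter_id" in table.columns:
        pairs = pd.MultiIndex.from_arrays(
            [table["slot"].to_numpy(), table["litter_id"].to_numpy()], names=["slot", "litter"]
        )
        litter_index = pairs.unique().sortlevel()[0]
        lpos = {p: i for i, p in enumerate(litter_index)}
        lrow = np.array([lpos[p] for p in pairs])
        V = sp.csr_matrix((np.ones(n), (np.arange(n), lrow)), shape=(n, len(litter_index)))

    y = pd.to_numeric(table["value"]).to_numpy(float)
    return DesignMatrices(
        X=X, Z=Z, V=V, y=y, slots=slots, slot_of_record=slot_of_record,
        x_labels=labels, dropped_labels=dropped, animal_ids=animal_ids,
        litter_index=litter_index,
    )


# ---------------------------------------------------------------------------
# MME assembly and solution


def _litter_slot_codes(dm: DesignMatrices) -> np.ndarray:
    return np.array([dm.slots.index(s) for s, _ in dm.litter_index])


def assemble_mme(dm: DesignMatrices, vc: VarianceComponents, K_inv: sp.spmatrix):
    """Sparse symmetric MME system (LHS, RHS) for given variance components.

    The animal block adds kron(G0^-1, K^-1) (Z columns are slot-major);
    the litter block adds 1/sigma_v^2 per slot on its diagonal.
    """
    vc.validate(need_litter=dm.V is not None)
    t = len(dm.slots)
    G0 = np.atleast_2d(np.asarray(vc.G0, float))
    if G0.shape != (t, t):
        raise ConfigurationError(f"G0 shape {G0.shape} does not match {t} slots")
    r_inv = 1.0 / np.asarray(vc.sigma_e2, float)[dm.slot_of_record]
    parts = [dm.X, dm.Z] + ([dm.V] if dm.V is not None else [])
    W = sp.hstack(parts, format="csr")
    WtR = W.T.tocsr().multiply(r_inv[None, :]).tocsr()
    LHS = (WtR @ W).tocsr()
    p = dm.X.shape[1]
    G0_inv = np.linalg.inv(G0)
    Gu = sp.kron(sp.csr_matrix(G0_inv), K_inv, format="csr")
    LHS = (LHS + sp.block_diag(
        [sp.csr_matrix((p, p)), Gu]
        + ([sp.diags(1.0 / np.asarray(vc.sigma_v2, float)[_litter_slot_codes(dm)])]
           if dm.V is not None else []),
        format="csr",
    )).tocsc()
    RHS = WtR @ dm.y
    return LHS, RHS


def solve_mme(LHS, RHS, method: str = "auto", tol: float = 1e-10, max_iter: int = 5000):
    """Solve the MME: sparse direct up to DIRECT_SOLVE_LIMIT equations, PCG above.

    Returns (solution, diagnostics).  Raises ConvergenceError (with the
    residual history) if PCG does not reach the tolerance.
    """
    m = LHS.shape[0]
    if method == "auto":
        method = "direct" if m <= DIRECT_SOLVE_LIMIT else "pcg"
    if method == "direct":
        lu = splu_symmetric(LHS)
        sol = lu.solve(RHS)
        res = np.linalg.norm(LHS @ sol - RHS) / max(np.linalg.norm(RHS), 1e-300)
        return sol, {"method": "direct", "iterations": 1, "relative_residual": float(res)}
    if method != "pcg":
        raise ConfigurationError(f"unknown solve method {method!r}")
    d = LHS.diagonal()
    M = sp.diags(1.0 / np.where(d > 0, d, 1.0))
    history = []

    def cb(xk):
        history.append(float(np.linalg.norm(LHS @ xk - RHS)))

    sol, info = cg(LHS, RHS, rtol=tol, maxiter=max_iter, M=M, callback=cb)
    res = np.linalg.norm(LHS @ sol - RHS) / max(np.linalg.norm(RHS), 1e-300)
    if info != 0:
        raise ConvergenceError(
            f"PCG did not converge in {max_iter} iterations (residual {res:.2e})",
            history=history,
        )
    return sol, {"method": "pcg", "iterations": len(history), "relative_residual": float(res)}


def split_solution(sol: np.ndarray, dm: DesignMatrices):
    """Partition the stacked MME solution into b, u (animals x slots) and v."""
    p = dm.X.shape[1]
    q = len(dm.animal_ids)
    t = len(dm.slots)
    b = pd.Series(sol[:p], index=dm.x_labels, name="b_hat")
    u = pd.DataFrame(
        sol[p : p + t * q].reshape(t, q).T, index=dm.animal_ids, columns=list(dm.slots)
    )
    v = None
    if dm.V is not None:
        v = pd.Series(sol[p + t * q :], index=dm.litter_index, name="v_hat")
    return b, u, v


def fit_blup(
    table: pd.DataFrame,
    spec: ModelSpec,
    vc: VarianceComponents,
    relationship,  # RelationshipMatrix with kind A_inverse or H_inverse
    method: str = "auto",
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> EvaluationResult:
    """Assemble and solve the MME for one trait / data set; EBVs for all animals."""
    dm = build_design_matrices(table, spec, relationship.ids)
    LHS, RHS = assemble_mme(dm, vc, relationship.values)
    sol, diag = solve_mme(LHS, RHS, method=method, tol=tol, max_iter=max_iter)
    b, u, v = split_solution(sol, dm)
    diag = dict(diag)
    diag["n_equations"] = LHS.shape[0]
    return EvaluationResult(
        b_hat=b, u_hat=u, v_hat=v, diagnostics=diag, spec=spec,
        variance_components=vc, relationship_kind=relationship.kind, design=dm,
    )
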