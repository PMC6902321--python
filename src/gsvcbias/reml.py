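"""Single-trait mixed-model machinery.

Model: y = X beta + Z a + e with a ~ N(0, K sigma_g^2), e ~ N(0, I sigma_e^2),
where K is the pedigree relationship A or the single-step H.  Fixed effects
are herd-year-season contemporary groups in cell-means coding (one column
per observed class, full rank without an explicit constraint).

Two computational routes are provided:

* :func:`assemble_mme` / :func:`solve_blup` build and solve the sparse mixed
  model equations over the whole pedigree (used for the in-scheme BLUP and
  GEBV evaluations);
* :func:`fit_reml` maximizes the restricted likelihood by the average
  information (AI) algorithm on the *marginal* covariance of the recorded
  animals, V = K_rr sigma_g^2 + I sigma_e^2.  Animals without records
  marginalize out of the restricted likelihood exactly, so this is the same
  REML objective as the MME route while keeping the AI trace terms dense and
  cheap at the problem sizes this package targets.  An EM step replaces any
  AI update that proposes a non-positive variance, and step-halving enforces
  a non-decreasing likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import splu

__all__ = ["MixedModelSpec", "VcEstimate", "assemble_mme", "solve_blup",
           "fit_reml", "restricted_loglik", "RemlError"]


class RemlError(RuntimeError):
    """Non-convergence or singular-system failure, carrying the iterate path."""

    def __init__(self, msg, path=None):
        super().__init__(msg)
        self.path = path or []


@dataclass
class MixedModelSpec:
    """One phenotype analysis: records, design, and relationship structure.

    ``k_inverse`` is the sparse A^-1 or H^-1 over ``n_animals``.  For REML,
    ``k_records`` (dense relationship among the record animals) may be
    supplied directly; otherwise it is recovered from ``k_inverse``.
    """

    y: np.ndarray
    X: np.ndarray  # (n, p) dense fixed-effect design, full column rank
    rec_animal: np.ndarray  # (n,) index of each record's animal
    n_animals: int
    k_inverse: sp.spmatrix | None = None
    k_records: np.ndarray | None = None
    start_values: tuple[float, float] | None = None  # (sigma_g2, sigma_e2)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.X = np.asarray(self.X, float)
        if self.y.size == 0:
            raise ValueError("empty data: no phenotype records")
        if self.X.shape[0] != self.y.size or self.rec_animal.shape[0] != self.y.size:
            raise ValueError("design rows must equal number of records")
        if np.any(self.rec_animal < 0) or np.any(self.rec_animal >= self.n_animals):
            raise ValueError("record refers to an animal outside the pedigree")

    def relationship_records(self) -> np.ndarray:
        if self.k_records is not None:
            return self.k_records
        if self.k_inverse is None:
            raise ValueError("need k_inverse or k_records")
        from .relationships import a_submatrix

        uniq, inv = np.unique(self.rec_animal, return_inverse=True)
        K = a_submatrix(self.k_inverse, uniq)
        self.k_records = K[np.ix_(inv, inv)]
        return self.k_records


@dataclass
class VcEstimate:
    """Variance components from one model fit."""

    genetic_variance: float
    residual_variance: float
    se_genetic: float = float("nan")
    se_residual: float = float("nan")
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    model: str = ""
    scenario: str = ""
    replicate: int = -1
    path: list = field(default_factory=list)

    @property
    def heritability(self) -> float:
        g, e = self.genetic_variance, self.residual_variance
        return g / (g + e)


def hys_design(labels) -> tuple[np.ndarray, np.ndarray]:
    """Cell-means incidence matrix for contemporary-group labels."""
    codes, uniq = _factorize(labels)
    X = np.zeros((codes.size, uniq.size))
    X[np.arange(codes.size), codes] = 1.0
    return X, uniq


def _factorize(labels):
    import pandas as pd

    codes, uniq = pd.factorize(pd.Series(list(map(tuple, labels)) if not np.isscalar(labels[0]) else labels))
    return np.asarray(codes), np.asarray(uniq)


def assemble_mme(spec: MixedModelSpec, vc: tuple[float, float]):
    """Sparse symmetric MME [[X'X, X'Z], [Z'X, Z'Z + K^-1 lambda]] and RHS."""
    sg2, se2 = vc
    if sg2 <= 0 or se2 <= 0:
        raise ValueError("variance components must be positive")
    if spec.k_inverse is None:
        raise ValueError("assemble_mme needs the sparse relationship inverse")
    n, q = spec.y.size, spec.n_animals
    lam = se2 / sg2
    Xs = sp.csr_matrix(spec.X)
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), spec.rec_animal)), shape=(n, q)
    )
    C = sp.bmat(
        [
            [Xs.T @ Xs, Xs.T @ Z],
            [Z.T @ Xs, Z.T @ Z + lam * sp.csc_matrix(spec.k_inverse)],
        ],
        format="csc",
    )
    rhs = np.concatenate([Xs.T @ spec.y, Z.T @ spec.y])
    return C, rhs


def solve_blup(spec: MixedModelSpec, vc: tuple[float, float]):
    """Solve the MME; returns (fixed-effect solutions, EBV over all animals)."""
    C, rhs = assemble_mme(spec, vc)
    try:
        sol = splu(C).solve(rhs)
    except RuntimeError as exc:  # pragma: no cover
        raise RemlError(f"singular mixed-model equations: {exc}") from exc
    p = spec.X.shape[1]
    return sol[:p], sol[p:]


def _loglik_pieces(y, X, K, sg2, se2):
    n = y.size
    V = sg2 * K + se2 * np.eye(n)
    c, low = cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_y = cho_solve((c, low), y)
    Vi_X = cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    cx = cho_factor(XtViX, lower=True)
    logdet_x = 2.0 * np.sum(np.log(np.diag(cx[0])))
    beta = cho_solve(cx, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    return ll, (c, low), cx, Vi_X, Py


def restricted_loglik(spec: MixedModelSpec, sg2: float, se2: float) -> float:
    """Restricted log-likelihood (up to an additive constant)."""
    K = spec.relationship_records()
    ll, *_ = _loglik_pieces(spec.y, spec.X, K, sg2, se2)
    return ll


def fit_reml(spec: MixedModelSpec, tol: float = 1e-8, max_iter: int = 200,
             verbose: bool = False) -> VcEstimate:
    """AI-REML with EM fallback for the two-variance animal model."""
    y, X = spec.y, spec.X
    n, p = y.size, X.shape[1]
    if n < 2:
        raise ValueError("need at least two records for REML")
    K = spec.relationship_records()
    vp = float(np.var(y, ddof=1))
    sg2, se2 = spec.start_values or (0.5 * vp, 0.5 * vp)
    floor = 1e-8 * vp
    path = [(sg2, se2)]
    ll_old = -np.inf
    I_n = np.eye(n)
    ai = np.eye(2)
    converged = False
    for it in range(1, max_iter + 1):
        ll, chov, chox, Vi_X, Py = _loglik_pieces(y, X, K, sg2, se2)
        # step-halving: retreat towards the previous accepted iterate
        halves = 0
        while ll < ll_old - 1e-10 and halves < 30:
            sg2 = 0.5 * (sg2 + path[-2][0])
            se2 = 0.5 * (se2 + path[-2][1])
            ll, chov, chox, Vi_X, Py = _loglik_pieces(y, X, K, sg2, se2)
            halves += 1
        ViK = cho_solve(chov, K)
        ViI = cho_solve(chov, I_n)
        BtK = Vi_X.T @ K
        tr_PK = np.trace(ViK) - np.trace(cho_solve(chox, BtK @ Vi_X))
        tr_P = np.trace(ViI) - np.trace(cho_solve(chox, Vi_X.T @ Vi_X))
        KPy = K @ Py
        yPKPy = float(Py @ KPy)
        yPPy = float(Py @ Py)
        score = np.array([-0.5 * (tr_PK - yPKPy), -0.5 * (tr_P - yPPy)])

        def project(f):
            ViF = cho_solve(chov, f)
            return ViF - Vi_X @ cho_solve(chox, Vi_X.T @ f)

        PF_g = project(KPy)
        PF_e = project(Py)
        ai = 0.5 * np.array(
            [[KPy @ PF_g, KPy @ PF_e], [Py @ PF_g, Py @ PF_e]]
        )
        try:
            delta = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            delta = np.array([np.nan, np.nan])
        new_g, new_e = sg2 + delta[0], se2 + delta[1]
        if not np.isfinite(new_g) or not np.isfinite(new_e) or new_g <= 0 or new_e <= 0:
            # EM-REML fallback (guaranteed uphill, positivity-preserving direction)
            new_g = max(sg2 + 2.0 * sg2**2 * score[0] / n, floor)
            new_e = max(se2 + 2.0 * se2**2 * score[1] / n, floor)
        rel = max(abs(new_g - sg2) / max(sg2, floor), abs(new_e - se2) / max(se2, floor))
        sg2, se2 = float(new_g), float(new_e)
        path.append((sg2, se2))
        ll_old = ll
        if verbose:
            print(f"iter {it}: sg2={sg2:.6f} se2={se2:.6f} ll={ll:.6f}")
        if rel < tol:
            converged = True
            break
    if not converged:
        raise RemlError(
            f"AI-REML did not converge in {max_iter} rounds", path=path
        )
    ll = restricted_loglik(spec, sg2, se2)
    try:
        cov = np.linalg.inv(ai)
        se_g, se_e = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_g = se_e = float("nan")
    return VcEstimate(
        genetic_variance=sg2,
        residual_variance=se2,
        se_genetic=float(se_g),
        se_residual=float(se_e),
        loglik=float(ll),
        n_iter=it,
        converged=True,
        path=path,
    )
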