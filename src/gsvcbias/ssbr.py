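"""Single-step Bayesian regression (BayesC with pi = 0).

Phenotypes of genotyped and non-genotyped animals are modelled jointly:

    y = X beta + mu_g * (genotyped indicator) + Z [M1 alpha + eps; M2 alpha] + e

where M2 holds observed centred marker covariates, M1 = A12 A22^-1 M2 the
pedigree-imputed covariates of non-genotyped animals, and eps the imputation
residual with covariance (A11 - A12 A22^-1 A21) sigma_eps^2.  The sampler
never forms that dense covariance: its inverse is the (1,1) block of A^-1,
which is sparse, so eps is updated single-site from its sparse-precision
full conditional.  Marker effects get systematic-scan single-site updates
with residual bookkeeping; the three variances get scaled-inverse-chi-square
draws.

Two genetic-variance summaries are available: the imputation-residual
variance sigma_eps^2 (total genetic variance) and the marker-based genetic
variance sigma_alpha^2 * sum_j 2 p_j (1 - p_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit
from scipy.sparse.linalg import splu

from .relationships import center_markers

__all__ = [
    "SsbrPriors",
    "SsbrModel",
    "PosteriorChain",
    "impute_markers",
    "build_ssbr_model",
    "run_gibbs",
    "marker_genetic_variance",
    "gebv",
    "monte_carlo_error",
]


@dataclass(frozen=True)
class SsbrPriors:
    """Scaled-inverse-chi-square hyperparameters (defaults as published)."""

    scale_alpha: float = 0.0002
    scale_eps: float = 2.0
    scale_e: float = 2.5
    df: float = 4.0
    pi: float = 0.0  # all markers have effects

    def __post_init__(self):
        if self.pi != 0.0:
            raise NotImplementedError("only pi = 0 (all markers in the model) is supported")


def impute_markers(M2: np.ndarray, ainv: sp.spmatrix, genotyped: np.ndarray):
    """Pedigree-based imputation M1 = A12 A22^-1 M2 for non-genotyped animals.

    Uses the block-inverse identity A12 A22^-1 = -(P11)^-1 P12 with
    P = A^-1, so only the sparse (1,1) block P11 is factorized.  Returns
    ``(M1, J1, non_genotyped_index, P11)``: J1 = A12 A22^-1 1 is the imputed
    genotyped-group covariate of the non-genotyped animals, and P11 is the
    sparse precision basis of the imputation residual,
    (A11 - A12 A22^-1 A21)^-1.
    """
    n = ainv.shape[0]
    genotyped = np.asarray(genotyped, np.int64)
    mask = np.zeros(n, bool)
    mask[genotyped] = True
    ng = np.flatnonzero(~mask)
    P = sp.csr_matrix(ainv)
    P11 = P[ng, :][:, ng].tocsc()
    if ng.size == 0:
        return np.zeros((0, M2.shape[1])), np.zeros(0), ng, P11
    P12 = P[ng, :][:, genotyped]
    rhs = -(P12 @ np.column_stack([M2, np.ones(genotyped.size)]))
    sol = np.asarray(splu(P11).solve(rhs))
    return sol[:, :-1], sol[:, -1], ng, P11


@dataclass
class SsbrModel:
    """Assembled data for the Gibbs sampler (build with build_ssbr_model)."""

    y: np.ndarray
    rec_class: np.ndarray  # HYS class code per record
    n_classes: int
    rec_m: np.ndarray  # (n_rec, m) covariate row of each record's animal
    rec_eps: np.ndarray  # index into eps vector, -1 for genotyped animals
    rec_geno: np.ndarray  # bool, record's animal genotyped
    rec_j: np.ndarray  # genotyped-group covariate per record (1 or imputed J1)
    eps_rec: np.ndarray  # (n1,) record index of each non-genotyped animal, -1 if none
    P11: sp.csc_matrix  # sparse precision basis of eps
    M1: np.ndarray
    J1: np.ndarray
    M2: np.ndarray
    non_genotyped: np.ndarray  # pedigree indices, order matching M1/eps
    genotyped: np.ndarray
    centering_freqs: np.ndarray
    use_mug: bool

    @property
    def n_markers(self) -> int:
        return self.rec_m.shape[1]

    @property
    def sum2pq(self) -> float:
        p = self.centering_freqs
        return float(np.sum(2.0 * p * (1.0 - p)))


def build_ssbr_model(
    pedigree,
    phenotypes: pd.DataFrame,
    genotyped: np.ndarray,
    genotypes2: np.ndarray,
    freqs: np.ndarray,
    ainv: sp.spmatrix,
    base_tag: str = "",
) -> SsbrModel:
    """Assemble the single-step regression from simulation-level objects.

    ``phenotypes`` needs columns animal/value/herd/year/season;
    ``genotypes2`` is the (n_genotyped, m) 0/1/2 matrix aligned with
    ``genotyped`` (pedigree indices).
    """
    genotyped = np.asarray(genotyped, np.int64)
    M2 = center_markers(genotypes2, freqs, base_tag).covariates
    M1, J1, ng, P11 = impute_markers(M2, ainv, genotyped)

    n_animals = ainv.shape[0]
    row_of = np.full(n_animals, -1, np.int64)
    row_of[ng] = np.arange(ng.size)
    grow_of = np.full(n_animals, -1, np.int64)
    grow_of[genotyped] = np.arange(genotyped.size)

    anim = phenotypes["animal"].to_numpy(np.int64)
    y = phenotypes["value"].to_numpy(float)
    codes, _ = pd.factorize(
        pd.Series(zip(phenotypes["herd"], phenotypes["year"], phenotypes["season"]))
    )
    is_geno = grow_of[anim] >= 0
    m = M2.shape[1] if M2.ndim == 2 else 0
    rec_m = np.zeros((anim.size, m))
    if m:
        if is_geno.any():
            rec_m[is_geno] = M2[grow_of[anim[is_geno]]]
        if (~is_geno).any():
            rec_m[~is_geno] = M1[row_of[anim[~is_geno]]]
    rec_eps = np.where(is_geno, -1, row_of[anim]).astype(np.int64)
    eps_rec = np.full(ng.size, -1, np.int64)
    nz = rec_eps >= 0
    eps_rec[rec_eps[nz]] = np.flatnonzero(nz)
    rec_j = np.where(is_geno, 1.0, 0.0)
    if ng.size and (~is_geno).any():
        rec_j[~is_geno] = J1[row_of[anim[~is_geno]]]
    # the group covariate is dropped when it cannot separate from the
    # contemporary-group effects (no genotyped animals at all)
    use_mug = bool(genotyped.size > 0 and np.ptp(rec_j) > 1e-12)
    return SsbrModel(
        y=y,
        rec_class=np.asarray(codes, np.int64),
        n_classes=int(codes.max()) + 1,
        rec_m=np.ascontiguousarray(rec_m, float),
        rec_eps=rec_eps,
        rec_geno=is_geno,
        rec_j=rec_j,
        eps_rec=eps_rec,
        P11=P11,
        M1=M1,
        J1=J1,
        M2=M2,
        non_genotyped=ng,
        genotyped=genotyped,
        centering_freqs=np.asarray(freqs, float),
        use_mug=use_mug,
    )


@dataclass
class PosteriorChain:
    """Sampled variance trajectories plus posterior-mean location effects."""

    var_alpha: np.ndarray  # sigma_alpha^2 per iteration (full chain)
    var_eps: np.ndarray
    var_e: np.ndarray
    burn_in: int
    seed: int
    alpha_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    eps_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mug_mean: float = 0.0
    sum2pq: float = 0.0

    def kept(self, name: str) -> np.ndarray:
        return getattr(self, "var_" + name)[self.burn_in:]

    def posterior_mean(self, name: str) -> float:
        return float(self.kept(name).mean())

    def posterior_sd(self, name: str) -> float:
        return float(self.kept(name).std(ddof=1))

    def heritability(self) -> float:
        ve, vr = self.kept("eps"), self.kept("e")
        return float((ve / (ve + vr)).mean())


@njit(cache=False)
def _gibbs_kernel(  # pragma: no cover
    y, rec_class, n_classes, mt, mjj, rec_eps, jvec, jj, use_mug,
    q_indptr, q_indices, q_data, eps_rec,
    s2a, s2eps, s2e, nu,
    sa2_init, seps2_init, se2_init,
    n_iter, burn_in, seed,
    ch_a, ch_eps, ch_e, alpha_mean, eps_mean, beta_mean,
):
    np.random.seed(seed)
    n_rec = y.shape[0]
    m = mt.shape[0]
    n1 = eps_rec.shape[0]
    beta = np.zeros(n_classes)
    alpha = np.zeros(m)
    eps = np.zeros(n1)
    mug = 0.0
    # class -> record lists
    counts = np.zeros(n_classes, np.int64)
    for i in range(n_rec):
        counts[rec_class[i]] += 1
    indptr = np.zeros(n_classes + 1, np.int64)
    for k in range(n_classes):
        indptr[k + 1] = indptr[k] + counts[k]
    fill = indptr[:-1].copy()
    class_rec = np.zeros(n_rec, np.int64)
    for i in range(n_rec):
        k = rec_class[i]
        class_rec[fill[k]] = i
        fill[k] += 1

    r = y.copy()
    se2 = se2_init
    seps2 = seps2_init
    sa2 = sa2_init
    n_kept = 0.0
    mug_sum = 0.0
    for it in range(n_iter):
        # contemporary-group effects, flat prior
        for k in range(n_classes):
            nk = indptr[k + 1] - indptr[k]
            if nk == 0:
                continue
            s = 0.0
            for t in range(indptr[k], indptr[k + 1]):
                s += r[class_rec[t]]
            old = beta[k]
            new = (s / nk + old) + np.random.normal() * np.sqrt(se2 / nk)
            d = new - old
            beta[k] = new
            for t in range(indptr[k], indptr[k + 1]):
                r[class_rec[t]] -= d
        # genotyped-group effect on the imputed J covariate, flat prior
        if use_mug and jj > 0.0:
            num = jj * mug
            for i in range(n_rec):
                num += jvec[i] * r[i]
            old = mug
            new = num / jj + np.random.normal() * np.sqrt(se2 / jj)
            d = new - old
            mug = new
            for i in range(n_rec):
                r[i] -= d * jvec[i]
        # marker effects, systematic scan
        lam_a = se2 / sa2
        for j in range(m):
            old = alpha[j]
            num = mjj[j] * old
            for i in range(n_rec):
                num += mt[j, i] * r[i]
            lhs = mjj[j] + lam_a
            mean = num / lhs
            new = mean + np.random.normal() * np.sqrt(se2 / lhs)
            d = new - old
            alpha[j] = new
            if d != 0.0:
                for i in range(n_rec):
                    r[i] -= d * mt[j, i]
        # imputation residuals, sparse-precision single site
        for a in range(n1):
            qii = 0.0
            cross = 0.0
            for t in range(q_indptr[a], q_indptr[a + 1]):
                col = q_indices[t]
                if col == a:
                    qii = q_data[t]
                else:
                    cross += q_data[t] * eps[col]
            prec = qii / seps2
            num = -cross / seps2
            rec = eps_rec[a]
            old = eps[a]
            if rec >= 0:
                prec += 1.0 / se2
                num += (r[rec] + old) / se2
            new = num / prec + np.random.normal() / np.sqrt(prec)
            eps[a] = new
            if rec >= 0:
                r[rec] -= new - old
        # variances: scaled-inverse-chi-square draws
        ssa = 0.0
        for j in range(m):
            ssa += alpha[j] * alpha[j]
        sa2 = (ssa + nu * s2a) / np.random.chisquare(nu + m)
        quad = 0.0
        for a in range(n1):
            for t in range(q_indptr[a], q_indptr[a + 1]):
                quad += eps[a] * q_data[t] * eps[q_indices[t]]
        seps2 = (quad + nu * s2eps) / np.random.chisquare(nu + n1) if n1 > 0 else (
            nu * s2eps / np.random.chisquare(nu)
        )
        sse = 0.0
        for i in range(n_rec):
            sse += r[i] * r[i]
        se2 = (sse + nu * s2e) / np.random.chisquare(nu + n_rec)
        ch_a[it] = sa2
        ch_eps[it] = seps2
        ch_e[it] = se2
        if it >= burn_in:
            n_kept += 1.0
            for j in range(m):
                alpha_mean[j] += alpha[j]
            for a in range(n1):
                eps_mean[a] += eps[a]
            for k in range(n_classes):
                beta_mean[k] += beta[k]
            mug_sum += mug
    if n_kept > 0:
        for j in range(m):
            alpha_mean[j] /= n_kept
        for a in range(n1):
            eps_mean[a] /= n_kept
        for k in range(n_classes):
            beta_mean[k] /= n_kept
        mug_sum /= n_kept
    return mug_sum


def run_gibbs(model: SsbrModel, priors: SsbrPriors, chain_config, seed: int) -> PosteriorChain:
    """Run the sampler; deterministic for a given seed."""
    n_iter, burn_in = chain_config.n_iter, chain_config.burn_in
    if burn_in >= n_iter:
        raise ValueError("burn-in must be shorter than the chain")
    mt = np.ascontiguousarray(model.rec_m.T)
    mjj = np.einsum("ji,ji->j", mt, mt)
    Q = model.P11.tocsr()
    # start the variances on the data scale: half the phenotypic variance to
    # the residual, half to each genetic route (markers on the per-effect
    # scale), so the chain does not have to climb out of the tiny prior mode
    vy = float(np.var(model.y)) if model.y.size > 1 else 1.0
    se2_init = 0.5 * vy if vy > 0 else priors.scale_e
    seps2_init = 0.5 * vy if vy > 0 else priors.scale_eps
    s2pq = model.sum2pq
    sa2_init = (0.5 * vy / s2pq) if (s2pq > 0 and vy > 0) else priors.scale_alpha
    ch_a = np.zeros(n_iter)
    ch_eps = np.zeros(n_iter)
    ch_e = np.zeros(n_iter)
    alpha_mean = np.zeros(model.n_markers)
    eps_mean = np.zeros(model.non_genotyped.size)
    beta_mean = np.zeros(model.n_classes)
    mug = _gibbs_kernel(
        model.y,
        model.rec_class,
        model.n_classes,
        mt,
        mjj,
        model.rec_eps,
        np.ascontiguousarray(model.rec_j, np.float64),
        float(model.rec_j @ model.rec_j),
        model.use_mug,
        Q.indptr.astype(np.int64),
        Q.indices.astype(np.int64),
        Q.data.astype(np.float64),
        model.eps_rec,
        priors.scale_alpha,
        priors.scale_eps,
        priors.scale_e,
        float(priors.df),
        sa2_init,
        seps2_init,
        se2_init,
        int(n_iter),
        int(burn_in),
        np.uint32(seed) & np.uint32(0x7FFFFFFF),
        ch_a,
        ch_eps,
        ch_e,
        alpha_mean,
        eps_mean,
        beta_mean,
    )
    if not (np.all(np.isfinite(ch_e)) and np.all(np.isfinite(ch_eps))):
        bad = int(np.flatnonzero(~np.isfinite(ch_e + ch_eps))[0])
        raise FloatingPointError(f"non-finite conditional variance at iteration {bad}")
    return PosteriorChain(
        var_alpha=ch_a,
        var_eps=ch_eps,
        var_e=ch_e,
        burn_in=burn_in,
        seed=seed,
        alpha_mean=alpha_mean,
        eps_mean=eps_mean,
        beta_mean=beta_mean,
        mug_mean=float(mug),
        sum2pq=model.sum2pq,
    )


def marker_genetic_variance(chain: PosteriorChain, freqs: np.ndarray) -> tuple[float, float]:
    """Posterior mean and SD of sigma_alpha^2 * sum_j 2 p_j (1 - p_j)."""
    freqs = np.asarray(freqs, float)
    kept = chain.kept("alpha")
    s2pq = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    samples = kept * s2pq
    return float(samples.mean()), float(samples.std(ddof=1))


def gebv(model: SsbrModel, chain: PosteriorChain) -> np.ndarray:
    """Posterior-mean breeding values over the pedigree: g1 = M1 a + eps, g2 = M2 a."""
    n = model.M1.shape[0] + model.M2.shape[0]
    g = np.zeros(n)
    g[model.non_genotyped] = model.M1 @ chain.alpha_mean + chain.eps_mean
    g[model.genotyped] = model.M2 @ chain.alpha_mean
    return g


def monte_carlo_error(samples: np.ndarray, batch_size: int) -> float:
    """Batch-means Monte Carlo standard error of the sample mean."""
    samples = np.asarray(samples, float)
    if batch_size >= samples.size:
        raise ValueError("batch size must be smaller than the chain segment")
    n_batch = samples.size // batch_size
    means = samples[: n_batch * batch_size].reshape(n_batch, batch_size).mean(axis=1)
    if n_batch < 2:
        raise ValueError("need at least two batches")
    return float(means.std(ddof=1) / np.sqrt(n_batch))
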