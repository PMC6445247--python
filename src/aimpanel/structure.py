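"""Population-structure inference.

* :class:`GenotypePCA` — PCA of standardized ancestral-allele dosages.
  Each locus is centred by twice its reference mean frequency and scaled
  by ``sqrt(pbar (1 - pbar))`` (the expected binomial standard deviation
  per allele copy), missing entries are mean-imputed at the centring
  step, monomorphic loci are dropped, and test individuals are projected
  with the reference means, scales and loadings only.

* :class:`AdmixtureModel` — maximum-likelihood admixture proportions.
  Each individual i carries ancestry fractions q_ik over K source
  groups with allele frequencies f_lk; the dosage likelihood is
  binomial with success probability ``mu_il = sum_k q_ik f_lk``.  Plain
  EM alternates closed-form updates of Q and F (F held fixed in
  supervised mode); the log-likelihood is non-decreasing and the trace
  is retained.  Multi-start (default 3) guards against local optima.

* :func:`cv_error` — entry-masking cross-validation over K: masked
  dosages are predicted as ``2 mu`` and scored by a root-mean-square
  binomial deviance residual; the K minimising the error is the
  supported number of ancestral clusters.

* :func:`align_cluster_labels` — greedy resolution of label switching
  between two fits of equal K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, FrequencyTable, GenotypeMatrix

__all__ = [
    "PCAResult",
    "GenotypePCA",
    "pca_fit_project",
    "AdmixtureModel",
    "AdmixtureResults",
    "admixture_em",
    "cv_error",
    "align_cluster_labels",
]

_F_EPS = 1e-6


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    """Loadings, scores and eigenvalues of a genotype PCA."""

    rs_ids: list[str]            # loci retained (monomorphic dropped)
    loadings: np.ndarray         # loci x components
    eigenvalues: np.ndarray      # non-increasing
    center: np.ndarray           # 2 * reference mean frequency per locus
    scale: np.ndarray            # sqrt(pbar (1 - pbar)) per locus
    scores_ref: pd.DataFrame
    scores_test: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        tot = self.eigenvalues.sum()
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "explained_fraction": self.eigenvalues / tot if tot > 0 else 0.0,
            },
            index=[f"PC{i+1}" for i in range(len(self.eigenvalues))],
        )


class GenotypePCA:
    """PCA of a reference panel with optional projection of test samples."""

    def __init__(self, ref: GenotypeMatrix, n_components: int = 10) -> None:
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.ref = ref
        self.n_components = n_components

    def fit(self, test: GenotypeMatrix | None = None) -> PCAResult:
        ref = self.ref
        d = ref.dosage_float()
        called = np.sum(~np.isnan(d), axis=0)
        if np.any(called == 0):
            bad = ref.rs_ids[int(np.argmin(called))]
            raise ValueError(f"locus {bad} has no non-missing reference calls")
        pbar = np.nanmean(d, axis=0) / 2.0
        keep = (pbar > 0.0) & (pbar < 1.0)
        if not np.all(keep):
            import logging

            logging.getLogger(__name__).warning(
                "dropping %d monomorphic loci from PCA", int(np.sum(~keep))
            )
        pbar = pbar[keep]
        center = 2.0 * pbar
        scale = np.sqrt(pbar * (1.0 - pbar))
        X = d[:, keep]
        X = np.where(np.isnan(X), center, X)
        X = (X - center) / scale
        n_comp = min(self.n_components, min(X.shape))
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        U, S, Vt = U[:, :n_comp], S[:n_comp], Vt[:n_comp]
        scores = U * S
        eigvals = S**2 / max(X.shape[0] - 1, 1)
        cols = [f"PC{i+1}" for i in range(n_comp)]
        res = PCAResult(
            rs_ids=[r for r, k in zip(ref.rs_ids, keep) if k],
            loadings=Vt.T,
            eigenvalues=eigvals,
            center=center,
            scale=scale,
            scores_ref=pd.DataFrame(scores, index=ref.individual_ids, columns=cols),
        )
        if test is not None:
            res.scores_test = self.project(test, res)
        return res

    def project(self, test: GenotypeMatrix, res: PCAResult) -> pd.DataFrame:
        """Project test individuals using reference means/scales/loadings."""
        index = {r: j for j, r in enumerate(test.rs_ids)}
        missing = [r for r in res.rs_ids if r not in index]
        if missing:
            raise ValueError(f"test matrix lacks PCA loci: {missing[:5]}")
        cols = [index[r] for r in res.rs_ids]
        d = test.dosage_float()[:, cols]
        d = np.where(np.isnan(d), res.center, d)
        X = (d - res.center) / res.scale
        scores = X @ res.loadings
        return pd.DataFrame(
            scores, index=test.individual_ids,
            columns=[f"PC{i+1}" for i in range(res.loadings.shape[1])],
        )


def pca_fit_project(
    ref: GenotypeMatrix, test: GenotypeMatrix | None = None, n_components: int = 10
) -> PCAResult:
    """Functional wrapper over :class:`GenotypePCA`."""
    return GenotypePCA(ref, n_components).fit(test)


# ---------------------------------------------------------------------------
# admixture EM

@dataclass
class AdmixtureResults:
    """Fitted admixture proportions Q and source frequencies F."""

    K: int
    Q: np.ndarray                  # individuals x K, rows on the simplex
    F: np.ndarray                  # loci x K, in [eps, 1-eps]
    loglik: float
    loglik_trace: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    iterations: int = 0
    converged: bool = False
    individual_ids: list[str] = field(default_factory=list)
    rs_ids: list[str] = field(default_factory=list)
    cv_error: float | None = None

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Q, index=self.individual_ids,
            columns=[f"K{k+1}" for k in range(self.K)],
        )

    def summary(self) -> pd.DataFrame:
        df = self.q_frame().round(4)
        return df


def _loglik(g: np.ndarray, obs: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    mu = np.clip(Q @ F.T, _F_EPS, 1.0 - _F_EPS)
    with np.errstate(invalid="ignore"):
        ll = np.where(obs, g * np.log(mu) + (2.0 - g) * np.log1p(-mu), 0.0)
    return float(ll.sum())


class AdmixtureModel:
    """Likelihood-based admixture model for a genotype matrix.

    ``supervised_F`` fixes the source allele frequencies to a reference
    table (K then equals its group count) and estimates only Q — the
    supervised projection used to place new individuals against known
    continental references.
    """

    def __init__(
        self,
        geno: GenotypeMatrix,
        K: int,
        supervised_F: FrequencyTable | None = None,
    ) -> None:
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > geno.n_individuals:
            raise ValueError(f"K={K} exceeds the {geno.n_individuals} individuals")
        if supervised_F is not None:
            if supervised_F.rs_ids != geno.rs_ids:
                raise ValueError("supervised_F loci do not match the genotype matrix")
            if supervised_F.n_groups != K:
                raise ValueError("K must equal the supervised frequency table's group count")
        obs = ~geno.missing_mask()
        if np.any(obs.sum(axis=1) == 0):
            bad = geno.individual_ids[int(np.argmin(obs.sum(axis=1)))]
            raise ValueError(f"individual {bad} has no non-missing genotypes")
        self.geno = geno
        self.K = K
        self.supervised_F = supervised_F

    def fit(
        self,
        seed: int = 0,
        tol: float = 1e-6,
        max_iter: int = 2000,
        n_starts: int = 3,
    ) -> AdmixtureResults:
        """Run EM from ``n_starts`` seeded initialisations, keep the best."""
        g = self.geno.geno.astype(float)
        obs = self.geno.geno != MISSING
        g = np.where(obs, g, 0.0)
        n, L = g.shape
        K = self.K

        if K == 1 and self.supervised_F is None:
            called = obs.sum(axis=0)
            with np.errstate(invalid="ignore"):
                f = (g * obs).sum(axis=0) / (2.0 * np.where(called > 0, called, np.nan))
            f = np.nan_to_num(f, nan=0.5)
            F = np.clip(f, _F_EPS, 1.0 - _F_EPS)[:, None]
            Q = np.ones((n, 1))
            ll = _loglik(g, obs, Q, F)
            return AdmixtureResults(
                K=1, Q=Q, F=F, loglik=ll, loglik_trace=np.array([ll]),
                iterations=0, converged=True,
                individual_ids=self.geno.individual_ids, rs_ids=self.geno.rs_ids,
            )

        best: AdmixtureResults | None = None
        ss = np.random.SeedSequence([int(seed) % (2**31), 7])
        for child in ss.spawn(max(1, n_starts)):
            rng = np.random.default_rng(child)
            res = self._fit_once(g, obs, rng, tol, max_iter)
            if best is None or res.loglik > best.loglik:
                best = res
        assert best is not None
        return best

    def _fit_once(self, g, obs, rng, tol, max_iter) -> AdmixtureResults:
        n, L = g.shape
        K = self.K
        supervised = self.supervised_F is not None
        Q = rng.dirichlet(np.ones(K), size=n)
        if supervised:
            F = np.clip(self.supervised_F.freq, _F_EPS, 1.0 - _F_EPS)
        else:
            called = obs.sum(axis=0)
            with np.errstate(invalid="ignore"):
                base = (g * obs).sum(axis=0) / (2.0 * np.where(called > 0, called, np.nan))
            base = np.nan_to_num(base, nan=0.5)
            F = base[:, None] + rng.uniform(-0.1, 0.1, size=(L, K))
            F = np.clip(F, _F_EPS, 1.0 - _F_EPS)

        n_obs2 = 2.0 * obs.sum(axis=1, keepdims=True)
        trace = [_loglik(g, obs, Q, F)]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            mu = np.clip(Q @ F.T, _F_EPS, 1.0 - _F_EPS)
            R = np.where(obs, g / mu, 0.0)                 # ancestral-copy weight
            S = np.where(obs, (2.0 - g) / (1.0 - mu), 0.0)  # derived-copy weight
            A = (R @ F + S @ (1.0 - F)) * Q
            Q_new = A / n_obs2
            Q_new /= Q_new.sum(axis=1, keepdims=True)
            if supervised:
                F_new = F
            else:
                num = (R.T @ Q) * F
                den = num + (S.T @ Q) * (1.0 - F)
                with np.errstate(invalid="ignore"):
                    F_new = np.where(den > 0, num / den, F)
                F_new = np.clip(F_new, _F_EPS, 1.0 - _F_EPS)
            Q, F = Q_new, F_new
            ll = _loglik(g, obs, Q, F)
            if ll < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
                raise RuntimeError(
                    f"EM log-likelihood decreased at iteration {it}: {trace[-1]} -> {ll}"
                )
            delta = ll - trace[-1]
            trace.append(ll)
            if abs(delta) < tol:
                converged = True
                break
        return AdmixtureResults(
            K=K, Q=Q, F=F, loglik=trace[-1], loglik_trace=np.array(trace),
            iterations=it, converged=converged,
            individual_ids=self.geno.individual_ids, rs_ids=self.geno.rs_ids,
        )


def admixture_em(
    geno: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    supervised_F: FrequencyTable | None = None,
    n_starts: int = 3,
) -> AdmixtureResults:
    """Functional wrapper over :class:`AdmixtureModel`."""
    return AdmixtureModel(geno, K, supervised_F).fit(
        seed=seed, tol=tol, max_iter=max_iter, n_starts=n_starts
    )


# ---------------------------------------------------------------------------
# cross-validation over K

def _deviance_rmse(g: np.ndarray, mu2: np.ndarray) -> float:
    """Root-mean-square binomial deviance residual of dosages vs predictions."""
    mu2 = np.clip(mu2, 2.0 * _F_EPS, 2.0 - 2.0 * _F_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(g > 0, g * np.log(g / mu2), 0.0)
        t2 = np.where(g < 2, (2.0 - g) * np.log((2.0 - g) / (2.0 - mu2)), 0.0)
    d2 = 2.0 * (t1 + t2)
    return float(np.sqrt(np.mean(np.maximum(d2, 0.0))))


def cv_error(
    geno: GenotypeMatrix,
    K_range: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    n_starts: int = 2,
    max_iter: int = 500,
    tol: float = 1e-5,
    max_redraws: int = 10,
) -> pd.Series:
    """Entry-masking cross-validation error for each K.

    Observed genotype entries are partitioned into ``folds`` seeded
    folds; each fold is masked in turn, the model refit on the rest, and
    the masked dosages predicted as ``2 sum_k q_ik f_lk``.  The per-fold
    error is a root-mean-square binomial deviance residual; the returned
    value per K is the mean across folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    obs_idx = np.argwhere(geno.geno != MISSING)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 13]))

    fold_of = None
    for _ in range(max_redraws):
        cand = rng.integers(0, folds, size=len(obs_idx))
        ok = True
        for f in range(folds):
            masked = obs_idx[cand == f]
            kept = np.ones(geno.geno.shape, dtype=bool) & (geno.geno != MISSING)
            kept[masked[:, 0], masked[:, 1]] = False
            if np.any(kept.sum(axis=1) == 0) or np.any(kept.sum(axis=0) == 0):
                ok = False
                break
        if ok:
            fold_of = cand
            break
    if fold_of is None:
        raise RuntimeError("could not draw a fold assignment keeping all rows/columns observed")

    errors = {K: [] for K in K_range}
    for f in range(folds):
        masked = obs_idx[fold_of == f]
        g_masked = geno.geno.copy()
        g_masked[masked[:, 0], masked[:, 1]] = MISSING
        gm = GenotypeMatrix(geno.individual_ids, geno.population_labels, geno.loci, g_masked)
        truth = geno.geno[masked[:, 0], masked[:, 1]].astype(float)
        for K in K_range:
            fit = AdmixtureModel(gm, K).fit(
                seed=int(rng.integers(2**31)), tol=tol, max_iter=max_iter, n_starts=n_starts
            )
            mu2 = 2.0 * np.einsum("ik,ik->i", fit.Q[masked[:, 0]], fit.F[masked[:, 1]])
            errors[K].append(_deviance_rmse(truth, mu2))
    return pd.Series({K: float(np.mean(v)) for K, v in errors.items()}, name="cv_error")


# ---------------------------------------------------------------------------
# label alignment

def align_cluster_labels(fit_a: AdmixtureResults, fit_b: AdmixtureResults) -> np.ndarray:
    """Permutation aligning fit_b's clusters to fit_a's.

    Greedy best-match on Q-column correlation: repeatedly pair the
    highest-correlated unmatched columns.  Returns ``perm`` such that
    ``fit_b.Q[:, perm]`` matches fit_a's column order.
    """
    if fit_a.K != fit_b.K:
        raise ValueError(f"K mismatch: {fit_a.K} vs {fit_b.K}")
    if fit_a.Q.shape[0] != fit_b.Q.shape[0]:
        raise ValueError("fits cover different individual sets")
    K = fit_a.K
    A, B = fit_a.Q, fit_b.Q

    def _sim(a: np.ndarray, b: np.ndarray) -> float:
        sa, sb = a.std(), b.std()
        if sa < 1e-12 or sb < 1e-12:
            return -float(np.mean(np.abs(a - b)))  # degenerate column: closeness
        return float(np.corrcoef(a, b)[0, 1])

    sim = np.array([[_sim(A[:, i], B[:, j]) for j in range(K)] for i in range(K)])
    perm = np.full(K, -1)
    used_a, used_b = set(), set()
    for _ in range(K):
        best, bi, bj = -np.inf, -1, -1
        for i in range(K):
            if i in used_a:
                continue
            for j in range(K):
                if j in used_b:
                    continue
                if sim[i, j] > best:
                    best, bi, bj = sim[i, j], i, j
        perm[bi] = bj
        used_a.add(bi)
        used_b.add(bj)
    return perm
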