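"""Biogeographic ancestry classification.

Two classifiers, both presented as model objects whose ``classify``
returns a :class:`ClassificationResults`:

* :class:`NaiveBayesAncestry` — frequency-based naive Bayes.  Each
  locus contributes a Hardy-Weinberg genotype likelihood from the
  reference group's (pseudocount-corrected) ancestral-allele frequency
  p': dosage 2 -> p'^2, 1 -> 2p'(1-p'), 0 -> (1-p')^2.  Log-likelihoods
  are summed over the individual's non-missing loci; posteriors combine
  a prior (uniform by default) in log space.  Likelihood ratios between
  groups are carried as log values so a ratio of 10^9 or more never
  overflows.
* :class:`MultinomialLogisticAncestry` — multinomial logistic regression
  on ancestral-allele dosages (scikit-learn solver, small ridge penalty
  so separable classes converge to a stable, deterministic solution).
  Reported probabilities are rounded to 4 decimals in ``summary``, so a
  cleanly separated class prints 1.0000.

``leave_one_out`` wraps either model in leave-one-out validation and
returns a confusion matrix with overall accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .containers import FrequencyTable, GenotypeMatrix, GroupAssignment, MISSING
from .popstats import allele_frequencies

__all__ = [
    "ClassificationResults",
    "NaiveBayesAncestry",
    "MultinomialLogisticAncestry",
    "leave_one_out",
]


@dataclass
class ClassificationResults:
    """Per-individual assignment probabilities and likelihood summaries.

    ``log_likelihood`` and ``posterior`` are individuals x groups frames;
    posteriors sum to one per row and ``assigned`` is the argmax.  The
    log likelihood-ratio of the best group against each other group is in
    ``log_lr_best`` (natural log; the ratio of best vs itself is 1, i.e.
    log 0).
    """

    groups: list[str]
    log_likelihood: pd.DataFrame
    posterior: pd.DataFrame
    assigned: pd.Series
    n_loci_used: pd.Series
    converged: bool = True

    def log_lr_best(self) -> pd.DataFrame:
        """log LR of each individual's best group vs every group."""
        best = self.log_likelihood.max(axis=1)
        return self.log_likelihood.rsub(best, axis=0)

    def likelihood_ratio(self, individual: str, group_a: str, group_b: str) -> float:
        """Natural-scale likelihood ratio of group_a vs group_b (may be inf)."""
        d = (
            self.log_likelihood.loc[individual, group_a]
            - self.log_likelihood.loc[individual, group_b]
        )
        with np.errstate(over="ignore"):
            return float(np.exp(d))

    def summary(self, decimals: int = 4) -> pd.DataFrame:
        out = self.posterior.round(decimals).copy()
        out.insert(0, "assigned", self.assigned)
        out["n_loci_used"] = self.n_loci_used
        return out

    def accuracy(self, true_labels: Sequence[str]) -> float:
        return float(np.mean(np.asarray(true_labels) == self.assigned.to_numpy()))


def _corrected_frequencies(refs: FrequencyTable, correction: str, eps: float) -> np.ndarray:
    """Zero-frequency-safe reference frequencies p'.

    ``"pseudocount"`` uses p' = (2N p + 1) / (2N + 2) per group when the
    table carries sample sizes (one artificial copy of each allele), and
    clamps to [eps, 1-eps] otherwise; ``"clamp"`` always clamps;
    ``"none"`` leaves frequencies untouched (infinite LRs possible).
    """
    p = refs.freq.copy()
    if correction == "none":
        return p
    if correction == "pseudocount" and refs.sample_sizes is not None:
        n2 = 2.0 * np.array([refs.sample_sizes[g] for g in refs.group_names])
        return (p * n2 + 1.0) / (n2 + 2.0)
    if correction in ("pseudocount", "clamp"):
        return np.clip(p, eps, 1.0 - eps)
    raise ValueError(f"unknown correction {correction!r}")


class NaiveBayesAncestry:
    """Frequency-based naive-Bayes ancestry classifier.

    Parameters
    ----------
    refs : FrequencyTable
        Reference ancestral-allele frequencies per group.
    prior : sequence of float, optional
        Per-group prior, summing to 1 (uniform by default — blind-sample
        treatment).
    correction : {"pseudocount", "clamp", "none"}
        Zero-frequency handling; see :func:`_corrected_frequencies`.
    """

    def __init__(
        self,
        refs: FrequencyTable,
        prior: Sequence[float] | None = None,
        correction: Literal["pseudocount", "clamp", "none"] = "pseudocount",
        eps: float = 1.0 / 2000.0,
    ) -> None:
        self.refs = refs
        self.groups = list(refs.group_names)
        if prior is None:
            prior = np.full(len(self.groups), 1.0 / len(self.groups))
        prior = np.asarray(prior, dtype=float)
        if prior.shape != (len(self.groups),) or not np.isclose(prior.sum(), 1.0):
            raise ValueError("prior must have one entry per group and sum to 1")
        self.prior = prior
        self._p = _corrected_frequencies(refs, correction, eps)

    @classmethod
    def from_genotypes(
        cls,
        train: GenotypeMatrix,
        groups: GroupAssignment | None = None,
        **kwargs,
    ) -> "NaiveBayesAncestry":
        """Build the classifier from labelled training genotypes."""
        return cls(allele_frequencies(train, groups), **kwargs)

    def classify(self, geno: GenotypeMatrix) -> ClassificationResults:
        """Classify each individual by summed per-locus HWE log-likelihoods."""
        ref_index = {rec.rs_id: i for i, rec in enumerate(self.refs.loci)}
        missing = [r for r in geno.rs_ids if r not in ref_index]
        if missing:
            raise KeyError(f"loci absent from reference table: {missing[:5]}")
        rows = [ref_index[r] for r in geno.rs_ids]
        p = self._p[rows]  # loci x groups
        with np.errstate(divide="ignore"):
            ll_by_dose = np.stack(
                [
                    2.0 * np.log1p(-p),              # dosage 0
                    np.log(2.0) + np.log(p) + np.log1p(-p),
                    2.0 * np.log(p),                 # dosage 2
                ]
            )  # 3 x loci x groups
        g = geno.geno
        obs = g != MISSING
        n_used = obs.sum(axis=1)
        if np.any(n_used == 0):
            bad = geno.individual_ids[int(np.argmin(n_used))]
            raise ValueError(f"individual {bad} has no non-missing genotypes")
        loglik = np.zeros((geno.n_individuals, len(self.groups)))
        for dose in (0, 1, 2):
            mask = (g == dose).astype(float)
            loglik += mask @ ll_by_dose[dose]
        logpost = loglik + np.log(self.prior)
        logpost -= logsumexp(logpost, axis=1, keepdims=True)
        post = np.exp(logpost)
        ll = pd.DataFrame(loglik, index=geno.individual_ids, columns=self.groups)
        posterior = pd.DataFrame(post, index=geno.individual_ids, columns=self.groups)
        assigned = posterior.idxmax(axis=1)
        return ClassificationResults(
            groups=self.groups,
            log_likelihood=ll,
            posterior=posterior,
            assigned=assigned,
            n_loci_used=pd.Series(n_used, index=geno.individual_ids),
        )


class MultinomialLogisticAncestry:
    """Multinomial logistic regression on ancestral-allele dosages."""

    def __init__(
        self,
        ridge: float = 1e-6,
        max_iter: int = 1000,
        tol: float = 1e-8,
    ) -> None:
        self.ridge = ridge
        self.max_iter = max_iter
        self.tol = tol
        self._clf = None
        self._train_rs: list[str] | None = None
        self._col_means: np.ndarray | None = None
        self.converged = True

    def fit(
        self, train: GenotypeMatrix, groups: GroupAssignment | None = None
    ) -> "MultinomialLogisticAncestry":
        from sklearn.linear_model import LogisticRegression

        if groups is None:
            groups = GroupAssignment.identity(train.population_labels)
        y = np.asarray(groups.groups_for(train))
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        if np.any(counts < 2):
            small = classes[counts < 2].tolist()
            raise ValueError(f"classes with fewer than 2 training individuals: {small}")
        X = train.dosage_float()
        self._col_means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        self._col_means = np.nan_to_num(self._col_means, nan=1.0)
        X = np.where(np.isnan(X), self._col_means, X)
        self._clf = LogisticRegression(
            C=1.0 / self.ridge,
            solver="lbfgs",
            max_iter=self.max_iter,
            tol=self.tol,
        )
        import warnings

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            self._clf.fit(X, y)
        self.converged = not any(w.category.__name__ == "ConvergenceWarning" for w in caught)
        self._train_rs = train.rs_ids
        return self

    def classify(self, geno: GenotypeMatrix) -> ClassificationResults:
        if self._clf is None:
            raise RuntimeError("model is not fitted")
        if geno.rs_ids != self._train_rs:
            raise ValueError("test loci do not match training loci")
        X = geno.dosage_float()
        X = np.where(np.isnan(X), self._col_means, X)
        logp = self._clf.predict_log_proba(X)
        groups = list(self._clf.classes_)
        post = pd.DataFrame(np.exp(logp), index=geno.individual_ids, columns=groups)
        ll = pd.DataFrame(logp, index=geno.individual_ids, columns=groups)
        n_used = (~geno.missing_mask()).sum(axis=1)
        return ClassificationResults(
            groups=groups,
            log_likelihood=ll,
            posterior=post,
            assigned=post.idxmax(axis=1),
            n_loci_used=pd.Series(n_used, index=geno.individual_ids),
            converged=self.converged,
        )


def leave_one_out(
    method: Literal["bayes", "logistic"] | Callable[[GenotypeMatrix, GroupAssignment], ClassificationResults],
    geno: GenotypeMatrix,
    groups: GroupAssignment | None = None,
) -> tuple[pd.DataFrame, float]:
    """Leave-one-out validation of a classifier.

    Each individual is classified by a model trained on everyone else.
    Returns (confusion matrix with true classes as rows, accuracy).
    """
    if groups is None:
        groups = GroupAssignment.identity(geno.population_labels)
    y = groups.groups_for(geno)
    classes = sorted(set(y))
    counts = {c: y.count(c) for c in classes}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 individuals: {small}")

    def _classify_one(train: GenotypeMatrix, test: GenotypeMatrix) -> str:
        if method == "bayes":
            model = NaiveBayesAncestry.from_genotypes(train, groups)
            return str(model.classify(test).assigned.iloc[0])
        if method == "logistic":
            model = MultinomialLogisticAncestry().fit(train, groups)
            return str(model.classify(test).assigned.iloc[0])
        return str(method(train, test).assigned.iloc[0])  # type: ignore[call-arg]

    conf = pd.DataFrame(0, index=classes, columns=classes)
    n = geno.n_individuals
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        train = geno.subset_individuals(rest)
        test = geno.subset_individuals([i])
        pred = _classify_one(train, test)
        conf.loc[y[i], pred] += 1
    accuracy = float(np.trace(conf.to_numpy()) / n)
    return conf, accuracy
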