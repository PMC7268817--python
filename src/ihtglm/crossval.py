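"""q-fold cross-validation over a path of sparsity levels.

For each fold and each candidate model size ``k`` a training model is
fitted on the remaining folds and scored by the summed squared deviance
residuals of the holdout samples (for the normal family this is n times
the holdout mean squared error).  The selected size ``k_hat`` minimizes
the fold-averaged holdout deviance; ties go to the smallest ``k``
(parsimony).

Every (fold, k) task is independent, so the computation is a pure map:
results are identical whatever the execution schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import Design
from .projections import SparsityConstraint
from .solver import IhtOptions, fit_iht

__all__ = ["CvResult", "assign_folds", "cv_iht"]


@dataclass
class CvResult:
    """Cross-validation summary.

    k_path : evaluated sparsity levels
    mean_deviance : per-k holdout deviance averaged across folds
    per_fold : (q, len(k_path)) deviance table (NaN for skipped folds)
    k_hat : argmin of mean_deviance (ties -> smallest k)
    seed : fold-assignment seed
    """

    k_path: np.ndarray
    mean_deviance: np.ndarray
    per_fold: np.ndarray
    k_hat: int
    seed: int


def assign_folds(n, q, seed):
    """Random fold labels in 1..q with sizes differing by at most one."""
    if q < 2:
        raise ValueError("need at least 2 folds")
    if q > n:
        raise ValueError("more folds than samples")
    labels = np.arange(n) % q + 1
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(n)]


def _holdout_deviance(state, design_all, family, y, holdout):
    eta = design_all.forward(state.b)[holdout]
    mu = family.mean(eta)
    return float(np.sum(family.deviance(y[holdout], mu)))


def cv_iht(
    y,
    genotypes,
    covariates=None,
    family=None,
    k_path=None,
    q=5,
    seed=0,
    options=None,
    constraint_for_k=None,
):
    """Select the model size by q-fold cross-validation.

    Parameters
    ----------
    k_path
        Ascending sparsity levels to evaluate.
    constraint_for_k
        Optional callable ``k -> SparsityConstraint`` (defaults to the
        plain top-k constraint); lets grouped or weighted constraints
        ride the same path.

    Returns a :class:`CvResult`.
    """
    if family is None:
        raise ValueError("a GlmFamily is required")
    k_path = np.asarray(k_path, dtype=int)
    if k_path.size == 0:
        raise ValueError("k_path must be nonempty")
    options = options or IhtOptions()
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    folds = assign_folds(n, q, seed)
    design_all = Design(genotypes, covariates, backend=options.backend)
    make = constraint_for_k or (lambda k: SparsityConstraint(k=int(k)))

    per_fold = np.full((q, k_path.size), np.nan)
    for f in range(1, q + 1):
        train = np.flatnonzero(folds != f)
        holdout = np.flatnonzero(folds == f)
        if family.name == "bernoulli" and np.unique(y[train]).size < 2:
            warnings.warn(f"fold {f}: single response class; fold skipped")
            continue
        for ik, k in enumerate(k_path):
            state = fit_iht(
                y[train],
                genotypes,
                covariates,
                family=family,
                constraint=make(int(k)),
                options=options,
                rows=train,
            )
            per_fold[f - 1, ik] = _holdout_deviance(
                state, design_all, family, y, holdout
            )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_dev = np.nanmean(per_fold, axis=0)
    if np.all(np.isnan(mean_dev)):
        raise RuntimeError("every fold was degenerate; cannot cross-validate")
    k_hat = int(k_path[int(np.nanargmin(mean_dev))])  # first argmin = smallest k
    return CvResult(
        k_path=k_path,
        mean_deviance=mean_dev,
        per_fold=per_fold,
        k_hat=k_hat,
        seed=seed,
    )
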