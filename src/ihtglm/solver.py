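"""Iterative hard thresholding for sparse GLM regression.

The solver maximizes the GLM loglikelihood subject to a hard sparsity
constraint by projected gradient ascent:

1. take a steepest-ascent step ``beta + s * grad L(beta)`` with the
   expected-information step size
   ``s = ||grad||^2 / (grad' J(beta) grad)``, ``J = X' W2 X``;
2. project the step onto the constraint set (plain top-k, doubly
   sparse, and/or prior-weighted);
3. if the loglikelihood fails to increase, halve the step at most
   ``max_backtracks`` times; after exhausting the budget the last halved
   proposal is accepted and iteration continues.

Convergence is declared when
``||b_next - b_prev||_inf / (||b_prev||_inf + 1) < tol``.

An optional debiasing pass replaces the coefficients on the current
support by the unpenalized GLM maximum-likelihood fit restricted to the
support columns (Fisher scoring / IRLS).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .families import GlmFamily, glm_weights
from .genotypes import Design
from .projections import SparsityConstraint

__all__ = [
    "IhtOptions",
    "IhtState",
    "step_size",
    "converged",
    "debias",
    "fit_iht",
    "IhtNumericalError",
]

log = logging.getLogger(__name__)


class IhtNumericalError(RuntimeError):
    """Non-finite objective that step-halving could not repair."""


@dataclass
class IhtOptions:
    """Solver controls.

    tol
        Convergence tolerance on the relative sup-norm change of the
        coefficient vector (default 1e-4).
    max_iter
        Iteration cap (default 200; fits in practice converge far
        earlier).
    max_backtracks
        Step-halvings allowed per iteration to restore ascent (default 5).
    debias
        Refit the unpenalized GLM on the support after every accepted
        iteration.
    project_covariates
        Whether non-genetic coefficients (including the intercept)
        compete in the sparsity projection (default True).
    backend
        Genotype product backend, ``"packed"`` (exact) or ``"dense"``
        (float32 BLAS cache).
    """

    tol: float = 1e-4
    max_iter: int = 200
    max_backtracks: int = 5
    debias: bool = False
    project_covariates: bool = True
    backend: str = "packed"

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class IhtState:
    """Solver state: stacked coefficients, support, objective, counters."""

    b: np.ndarray  # stacked (beta, gamma)
    p: int  # number of genetic coefficients
    loglik: float = -np.inf
    step: float = 0.0
    iters: int = 0
    backtracks: int = 0
    converged: bool = False
    trace: list = field(default_factory=list)

    @property
    def beta(self):
        return self.b[: self.p]

    @property
    def gamma(self):
        return self.b[self.p :]

    @property
    def support(self):
        return np.flatnonzero(self.b)


def step_size(grad, design, family, mu, eta, mask=None):
    """Expected-information step: ||grad||^2 / (grad' X' W2 X grad).

    With ``mask`` (a boolean active set) the gradient is restricted to
    the active coordinates before the quotient is formed, the
    normalized-IHT step: the quotient is then the exact minimizer of the
    quadratic model along the restricted gradient, and the restricted
    quadratic form needs only a support-sized product.  ``mask=None``
    uses the full gradient.

    Returns None when the (restricted) gradient vanishes; the caller
    should declare convergence rather than divide by zero.
    """
    g = grad if mask is None else np.where(mask, grad, 0.0)
    num = float(g @ g)
    if num == 0.0:
        return None
    u = design.forward(g)
    _, w2 = glm_weights(family, eta, mu)
    denom = float(np.sum(w2 * u * u))
    if denom <= 0.0 or not np.isfinite(denom):
        return None
    return num / denom


def converged(b_prev, b_next, tol):
    """Relative sup-norm test; the +1 guards against division by zero."""
    delta = np.max(np.abs(b_next - b_prev)) if b_next.size else 0.0
    return bool(delta / (np.max(np.abs(b_prev), initial=0.0) + 1.0) < tol)


def _project(b, p, constraint, project_covariates):
    if project_covariates:
        full = constraint.project_full(b, p)
        return full
    out = b.copy()
    out[:p] = constraint.project(b[:p])
    return out


def _objective(design, family, y, b):
    eta = design.forward(b)
    mu = family.mean(eta)
    return family.loglikelihood(y, mu), mu, eta


def debias(state, design, family, y, tol=1e-8, max_inner=100):
    """Refit the GLM restricted to the support columns (Fisher scoring).

    Off-support coefficients stay zero.  A singular restricted design
    falls back to the unbiased iterate with a warning instead of
    aborting.
    """
    support = state.support
    if support.size == 0 or support.size > design.n_rows:
        return state
    cols = design.columns(support)
    b_s = state.b[support].copy()
    for _ in range(max_inner):
        eta = cols @ b_s
        mu = family.mean(eta)
        w1, w2 = glm_weights(family, eta, mu)
        g = cols.T @ (w1 * (y - mu))
        H = (cols * w2[:, None]).T @ cols
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            warnings.warn("singular restricted design in debiasing; skipped")
            return state
        b_s = b_s + delta
        if np.max(np.abs(delta)) < tol * (np.max(np.abs(b_s)) + 1.0):
            break
    b = np.zeros_like(state.b)
    b[support] = b_s
    ll, _, _ = _objective(design, family, y, b)
    if not np.isfinite(ll):
        warnings.warn("non-finite loglikelihood after debiasing; skipped")
        return state
    state.b = b
    state.loglik = ll
    return state


def fit_iht(
    y,
    genotypes,
    covariates=None,
    family=None,
    constraint=None,
    options=None,
    rows=None,
):
    """Run IHT from the zero vector until convergence or ``max_iter``.

    Parameters
    ----------
    y
        Response vector (over the active rows when ``rows`` is given).
    genotypes
        A :class:`~ihtglm.genotypes.GenotypeMatrix` (or ``None`` for a
        covariate-only model).
    covariates
        Optional :class:`~ihtglm.genotypes.CovariateMatrix`.
    family
        A :class:`~ihtglm.families.GlmFamily`.
    constraint
        A :class:`~ihtglm.projections.SparsityConstraint` over the
        genetic (or, when covariates are projected, stacked) vector.
    options
        :class:`IhtOptions`.
    rows
        Optional sample indices (training subset); standardization stays
        full-data.

    Returns the final :class:`IhtState`, whose ``trace`` holds one
    ``(iter, loglik, step, backtracks, support_size)`` record per
    accepted iteration.
    """
    options = options or IhtOptions()
    if family is None:
        raise ValueError("a GlmFamily is required")
    design = Design(genotypes, covariates, rows=rows, backend=options.backend)
    y = family.check_support(np.asarray(y, dtype=float))
    if y.shape[0] != design.n_rows:
        raise ValueError("response length does not match the active rows")

    p = design.p
    b = np.zeros(design.width)
    state = IhtState(b=b, p=p)
    ll, mu, eta = _objective(design, family, y, b)
    state.loglik = ll

    if constraint is not None and constraint.max_support() == 0:
        state.converged = True
        return state

    for it in range(1, options.max_iter + 1):
        resid_w = glm_weights(family, eta, mu)[0] * (y - mu)
        grad = design.adjoint(resid_w)
        # active set for the normalized step: the current support, or on
        # the first iteration the support the projected gradient selects
        mask = b != 0
        if not mask.any():
            if constraint is not None:
                mask = _project(grad, p, constraint, options.project_covariates) != 0
            if not mask.any():
                mask = None
        s = step_size(grad, design, family, mu, eta, mask=mask)
        if s is None:
            state.converged = True
            break

        accepted = None
        n_back = 0
        while True:
            proposal = b + s * grad
            if constraint is not None:
                proposal = _project(
                    proposal, p, constraint, options.project_covariates
                )
            ll_new, mu_new, eta_new = _objective(design, family, y, proposal)
            if np.isfinite(ll_new) and ll_new >= state.loglik:
                accepted = (proposal, ll_new, mu_new, eta_new)
                break
            if n_back >= options.max_backtracks:
                break
            s *= 0.5
            n_back += 1

        if accepted is None:
            # after exhausting backtracks, accept the last halved proposal
            if not np.isfinite(ll_new):
                raise IhtNumericalError(
                    f"non-finite loglikelihood for family {family.name!r} "
                    f"after {n_back} step-halvings at iteration {it}"
                )
            accepted = (proposal, ll_new, mu_new, eta_new)

        b_prev = b
        b, ll, mu, eta = accepted
        state.b = b
        state.loglik = ll
        state.step = s
        state.iters = it
        state.backtracks += n_back

        if options.debias:
            state = debias(state, design, family, y)
            b = state.b
            ll = state.loglik
            eta = design.forward(b)
            mu = family.mean(eta)

        state.trace.append((it, state.loglik, s, n_back, int(state.support.size)))
        log.debug(
            "iter=%d loglik=%.6f step=%.3g backtracks=%d support=%d",
            it, state.loglik, s, n_back, state.support.size,
        )
        if converged(b_prev, b, options.tol):
            state.converged = True
            break

    return state
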