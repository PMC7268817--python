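"""Hard-thresholding projection operators.

Three projections drive the sparse solver:

* :func:`project_k` — keep the ``k`` largest-magnitude coefficients.
* :func:`project_group_sparse` — doubly sparse projection: keep at most
  ``j`` groups and at most ``lambda_g`` coefficients inside each kept
  group.  Groups are ranked by the retained mass ``||P_g(beta_g)||^2`` so
  the output is a Euclidean-nearest point of the constraint set; the
  degenerate single-group case reduces exactly to :func:`project_k`.
* :func:`project_weighted` — prior-weighted projection: the support is
  chosen by projecting the Hadamard product ``w ∘ beta``, but the
  surviving coefficients keep their unweighted values.

Ties are broken deterministically: equal magnitudes go to the lowest
coefficient index, equal group scores to the lowest group label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SparsityConstraint",
    "project_k",
    "project_group_sparse",
    "project_weighted",
]


def _top_indices(absb, k):
    """Indices of the k largest entries of ``absb``; ties -> lowest index.

    Entries strictly above the k-th largest value are always kept (at
    most k - 1 of them); the remaining slots are filled with the
    lowest-index entries equal to that threshold value.
    """
    n = absb.shape[0]
    if k >= n:
        return np.arange(n)
    if k == 0:
        return np.empty(0, dtype=np.intp)
    thresh = np.partition(absb, n - k)[n - k]
    above = np.flatnonzero(absb > thresh)
    need = k - above.size
    equal = np.flatnonzero(absb == thresh)[:need]
    return np.sort(np.concatenate([above, equal]))


def project_k(beta, k):
    """Zero all but the ``k`` largest-magnitude entries of ``beta``.

    Entries that are exactly zero never enter the support, so the output
    support size is ``min(k, nnz(beta))``.  Idempotent.
    """
    beta = np.asarray(beta, dtype=float)
    if k < 0:
        raise ValueError("sparsity budget k must be nonnegative")
    out = np.zeros_like(beta)
    if k == 0:
        return out
    idx = _top_indices(np.abs(beta), int(k))
    idx = idx[beta[idx] != 0.0]
    out[idx] = beta[idx]
    return out


def project_group_sparse(beta, membership, j, lambda_g):
    """Doubly sparse projection: at most ``j`` groups, ``lambda_g`` per group.

    Parameters
    ----------
    beta
        Coefficient vector.
    membership
        Integer group label per coefficient; labels partition the index
        set (nonoverlapping, exhaustive).
    j
        Number of groups to keep.
    lambda_g
        Within-group budgets: a mapping or array indexed by group label,
        or a single int applied to every group.  Each budget must be >= 1.

    The within-group projection keeps the ``lambda_g`` largest magnitudes
    in each group; groups are then ranked by their retained squared norm
    and the top ``j`` survive.  Surviving entries keep their input values.
    """
    beta = np.asarray(beta, dtype=float)
    membership = np.asarray(membership)
    if membership.shape != beta.shape:
        raise ValueError("group membership length must match beta")
    labels = np.unique(membership)
    if j > labels.size:
        raise ValueError("cannot select more groups than exist")

    def budget(lab):
        if np.isscalar(lambda_g) or isinstance(lambda_g, (int, np.integer)):
            b = int(lambda_g)
        elif isinstance(lambda_g, dict):
            b = int(lambda_g[lab])
        else:
            b = int(np.asarray(lambda_g)[lab])
        if b < 1:
            raise ValueError("within-group budget lambda_g must be >= 1")
        return b

    absb = np.abs(beta)
    kept = {}
    scores = np.empty(labels.size)
    for gi, lab in enumerate(labels):
        idx = np.flatnonzero(membership == lab)
        lam = budget(lab)
        loc = _top_indices(absb[idx], lam)
        keep = idx[loc]
        keep = keep[beta[keep] != 0.0]
        kept[lab] = keep
        scores[gi] = np.sum(beta[keep] ** 2)
    # rank groups by retained mass; ties -> lowest group label
    order = np.lexsort((labels, -scores))
    out = np.zeros_like(beta)
    for lab in labels[order[: int(j)]]:
        out[kept[lab]] = beta[kept[lab]]
    return out


def project_weighted(beta, w, projector):
    """Prior-weighted projection.

    The support ``S`` is that of ``projector(w ∘ beta)``; the output
    equals ``beta`` on ``S`` and zero elsewhere, i.e. weights steer the
    selection but never rescale the surviving coefficients.
    """
    beta = np.asarray(beta, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.shape != beta.shape:
        raise ValueError("weight vector length must match beta")
    if np.any(w <= 0):
        raise ValueError("prior weights must be positive")
    proj = projector(w * beta)
    out = np.zeros_like(beta)
    support = proj != 0.0
    out[support] = beta[support]
    return out


def maf_weights(maf):
    """MAF-based prior weights w_j = 1 / sqrt(2 p_j (1 - p_j)).

    Up-weights rare variants; appropriate for traits under strong
    negative selection.
    """
    maf = np.asarray(maf, dtype=float)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf))


@dataclass
class SparsityConstraint:
    """A sparsity pattern: overall budget, or group spec, plus prior weights.

    Exactly one of ``k`` or (``membership``, ``j``, ``lambda_g``) styles is
    active.  ``weights`` (all positive, default ones) steer support
    selection via :func:`project_weighted`.
    """

    k: int | None = None
    membership: np.ndarray | None = None
    j: int | None = None
    lambda_g: object = None
    weights: np.ndarray | None = None

    def __post_init__(self):
        grouped = self.membership is not None
        if grouped == (self.k is not None):
            raise ValueError("specify exactly one of k or a group spec")
        if grouped and (self.j is None or self.lambda_g is None):
            raise ValueError("group spec requires both j and lambda_g")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ValueError("prior weights must be positive")

    @property
    def grouped(self):
        return self.membership is not None

    def max_support(self):
        """Largest admissible support size."""
        if not self.grouped:
            return int(self.k)
        labels = np.unique(self.membership)

        def budget(lab):
            if np.isscalar(self.lambda_g) or isinstance(self.lambda_g, (int, np.integer)):
                return int(self.lambda_g)
            if isinstance(self.lambda_g, dict):
                return int(self.lambda_g[lab])
            return int(np.asarray(self.lambda_g)[lab])

        budgets = sorted((budget(lab) for lab in labels), reverse=True)
        return int(sum(budgets[: int(self.j)]))

    def base_projector(self):
        if self.grouped:
            return lambda b: project_group_sparse(
                b, self.membership, self.j, self.lambda_g
            )
        return lambda b: project_k(b, self.k)

    def project(self, beta):
        """Apply the full (possibly weighted) projection."""
        proj = self.base_projector()
        if self.weights is None:
            return proj(beta)
        return project_weighted(beta, self.weights, proj)

    def project_full(self, b, p):
        """Project a stacked (beta, gamma) vector of which ``p`` entries
        are genetic.

        A plain-k constraint lets covariate coefficients compete for the
        budget (their prior weight defaults to 1).  A grouped constraint
        defined over the SNPs only leaves trailing covariate entries
        untouched, since they belong to no group.
        """
        b = np.asarray(b, dtype=float)
        m = b.shape[0]
        if m == p:
            return self.project(b)
        if self.grouped:
            if self.membership.shape[0] == m:
                return self.project(b)
            out = b.copy()
            out[:p] = self.project(b[:p])
            return out
        w = self.weights
        if w is not None and w.shape[0] == p:
            w = np.concatenate([w, np.ones(m - p)])
        proj = lambda x: project_k(x, self.k)
        if w is None:
            return proj(b)
        return project_weighted(b, w, proj)
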