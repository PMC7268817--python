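"""Synthetic genotype/phenotype generators and the simulation-study harness.

The generators emulate two genotype regimes:

* independent SNPs — per-SNP minor-allele frequency drawn uniformly on
  (0, 0.5) (optionally floored, e.g. at 0.05 to avoid monomorphic
  columns at moderate n) and counts drawn Binomial(2, maf);
* LD blocks — SNPs partitioned into blocks of 20; each block carries a
  pool of 20 binary haplotypes built by a two-state Markov chain
  (``x_{i+1} = x_i`` with probability 0.75), the pool regenerated until
  both alleles appear at every SNP; a sample's block genotype is the sum
  of two pool draws with replacement.  Correlation between SNPs decays
  with their separation within a block and vanishes across blocks.

Responses are drawn from the requested GLM family with mean
``g(clamp(eta))`` where ``eta`` is the *standardized* genotype matrix
times the effect vector: normal with unit variance, Bernoulli and
Poisson with canonical links, negative binomial with the log link and
``r = 10`` required failures.

:func:`run_experiment` wires generators, solver and cross-validation
into the canonical simulation designs (see the design table in
``docs/methods.md``) and returns one row per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossval import cv_iht
from .families import GlmFamily, get_family
from .genotypes import GenotypeMatrix
from .projections import SparsityConstraint
from .solver import IhtOptions, fit_iht

__all__ = [
    "SimConfig",
    "simulate_genotypes_independent",
    "simulate_genotypes_ld",
    "simulate_coefficients",
    "simulate_response",
    "run_experiment",
    "EXPERIMENTS",
]

DEFAULT_EFFECTS = np.round(np.arange(0.1, 1.01, 0.1), 10)


@dataclass
class SimConfig:
    """All knobs of the data-generating procedures.

    Defaults are the canonical study conditions: 10 causal SNPs with
    effect sizes 0.1..1.0 on the standardized scale, MAF ~ Uniform(0,
    0.5), LD blocks of 20 SNPs with haplotype pools of 20 and Markov
    flip-retention probability 0.75, linear-predictor clamp [-20, 20],
    10 required failures for the negative binomial.
    """

    n: int = 1000
    p: int = 10000
    family: str = "normal"
    k_true: int = 10
    effect_sizes: np.ndarray = field(default_factory=lambda: DEFAULT_EFFECTS.copy())
    min_maf: float = 0.0
    ld: bool = False
    block_size: int = 20
    flip_prob: float = 0.75
    pool_size: int = 20
    clamp: tuple = (-20.0, 20.0)
    nb_failures: float = 10.0
    seed: int = 0

    def make_family(self) -> GlmFamily:
        return get_family(
            self.family, nb_failures=self.nb_failures, clamp_bounds=self.clamp
        )


def simulate_genotypes_independent(cfg, rng=None):
    """Independent binomial SNPs: maf_j ~ U(min_maf, 0.5), counts Bin(2, maf_j)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    maf = rng.uniform(cfg.min_maf, 0.5, size=cfg.p)
    # one uniform per genotype, inverted through the Binomial(2, maf) CDF,
    # in column chunks to bound the transient draw memory
    counts = np.empty((cfg.n, cfg.p), dtype=np.uint8)
    c0 = ((1.0 - maf) ** 2).astype(np.float32)  # P(count = 0)
    c1 = (c0 + 2.0 * maf * (1.0 - maf)).astype(np.float32)  # P(count <= 1)
    chunk = max(1, int(4e7) // max(cfg.n, 1))
    for start in range(0, cfg.p, chunk):
        stop = min(start + chunk, cfg.p)
        u = rng.random((cfg.n, stop - start), dtype=np.float32)
        block = (u >= c0[start:stop]).astype(np.uint8)
        block += u >= c1[start:stop]
        counts[:, start:stop] = block
    return GenotypeMatrix.from_counts(counts)


def _haplotype_pool(rng, pool_size, length, flip_prob, max_attempts=1000):
    """A pool of binary haplotypes from the two-state Markov chain.

    Regenerated until every SNP shows both alleles somewhere in the pool.
    """
    for _ in range(max_attempts):
        h = np.empty((pool_size, length), dtype=np.uint8)
        h[:, 0] = rng.random(pool_size) < 0.5
        stay = rng.random((pool_size, length - 1)) < flip_prob
        for i in range(1, length):
            h[:, i] = np.where(stay[:, i - 1], h[:, i - 1], 1 - h[:, i - 1])
        col_any0 = (h == 0).any(axis=0)
        col_any1 = (h == 1).any(axis=0)
        if np.all(col_any0 & col_any1):
            return h
    raise RuntimeError("haplotype pool regeneration exceeded the attempt cap")


def simulate_genotypes_ld(cfg, rng=None):
    """LD-block genotypes from per-block haplotype pools.

    A trailing partial block (p not divisible by block_size) is simply
    shorter; its pool is built at that length.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    counts = np.empty((cfg.n, cfg.p), dtype=np.uint8)
    start = 0
    while start < cfg.p:
        length = min(cfg.block_size, cfg.p - start)
        pool = _haplotype_pool(rng, cfg.pool_size, length, cfg.flip_prob)
        draws = rng.integers(0, cfg.pool_size, size=(cfg.n, 2))
        counts[:, start : start + length] = pool[draws[:, 0]] + pool[draws[:, 1]]
        start += length
    return GenotypeMatrix.from_counts(counts)


def simulate_coefficients(cfg, rng=None, grouping=None):
    """Causal positions and effect sizes.

    Default: ``k_true`` positions chosen uniformly without replacement,
    assigned ``cfg.effect_sizes`` in order.  With ``grouping = (n_groups,
    causal_per_group)`` the causal SNPs are instead placed in distinct
    blocks: ``causal_per_group[i]`` SNPs inside the i-th chosen block,
    effects drawn uniformly from {-e, +e} with e = ``effect_sizes[0]``.

    Returns ``(beta, causal_idx)`` and, for grouped layouts, the list of
    causal group labels as a third element.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    beta = np.zeros(cfg.p)
    if grouping is None:
        if cfg.k_true == 0:
            return beta, np.array([], dtype=int)
        causal = rng.choice(cfg.p, size=cfg.k_true, replace=False)
        effects = np.asarray(cfg.effect_sizes, dtype=float)
        if effects.size != cfg.k_true:
            raise ValueError("effect_sizes length must equal k_true")
        beta[causal] = effects
        return beta, np.sort(causal)
    n_groups, causal_per_group = grouping
    block = cfg.block_size
    total_groups = cfg.p // block
    if n_groups > total_groups:
        raise ValueError("grouping inconsistent with p")
    chosen = rng.choice(total_groups, size=n_groups, replace=False)
    e = float(np.asarray(cfg.effect_sizes).ravel()[0])
    causal = []
    for g, c in zip(chosen, causal_per_group):
        pos = g * block + rng.choice(block, size=int(c), replace=False)
        beta[pos] = rng.choice([-e, e], size=int(c))
        causal.extend(pos.tolist())
    return beta, np.sort(np.asarray(causal)), np.sort(chosen)


def simulate_response(cfg, genotypes, beta, rng=None, backend="packed"):
    """Draw responses with mean g(clamp(eta)), eta = X_std beta.

    Effects are on the standardized scale: the linear predictor uses the
    same implicitly standardized matrix the solver sees, so simulation
    and fitting are exactly matched.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    family = cfg.make_family()
    eta = genotypes.standardized_xv(np.asarray(beta, dtype=float), backend=backend)
    mu = family.mean(eta)
    name = family.name
    if name == "normal":
        return mu + rng.standard_normal(mu.shape)
    if name == "bernoulli":
        return (rng.random(mu.shape) < mu).astype(float)
    if name == "poisson":
        return rng.poisson(mu).astype(float)
    if name == "negative_binomial":
        r = cfg.nb_failures
        return rng.negative_binomial(r, r / (r + mu)).astype(float)
    raise ValueError(f"no sampler for family {name!r}")


# ---------------------------------------------------------------------------
# Experiment harness


def _count_tp_fp(support, causal, p):
    support = np.asarray(support)
    support = support[support < p]  # covariates never count
    causal = set(np.asarray(causal).tolist())
    tp = sum(1 for s in support if s in causal)
    return tp, support.size - tp


def _comparison_design(family, replicates, seed, options):
    """Small-problem comparison: n=1000, p=10000, CV over k=1..50, q=3."""
    rows = []
    ss = np.random.SeedSequence(seed)
    for rep, child in enumerate(ss.spawn(replicates)):
        rng = np.random.default_rng(child)
        cfg = SimConfig(n=1000, p=10000, family=family)
        G = simulate_genotypes_independent(cfg, rng)
        beta, causal = simulate_coefficients(cfg, rng)
        y = simulate_response(cfg, G, beta, rng, backend=options.backend)
        cv = cv_iht(
            y, G, family=cfg.make_family(), k_path=np.arange(1, 51), q=3,
            seed=int(child.generate_state(1)[0] % (2**31)), options=options,
        )
        state = fit_iht(
            y, G, family=cfg.make_family(),
            constraint=SparsityConstraint(k=cv.k_hat), options=options,
        )
        tp, fp = _count_tp_fp(state.support, causal, cfg.p)
        rows.append(
            dict(design="table2", family=family, replicate=rep,
                 k_hat=cv.k_hat, tp=tp, fp=fp)
        )
    return pd.DataFrame(rows)


TABLE3_EFFECTS = np.array(
    [0.5, 0.5, 0.5, 0.25, 0.25, 0.25, 0.10, 0.10, 0.05, 0.05]
)


def _reconstruction_design(family, replicates, seed, options):
    """Coefficient recovery: n=5000, p=10000, min MAF 0.05, fixed k=10."""
    rows = []
    ss = np.random.SeedSequence(seed)
    for rep, child in enumerate(ss.spawn(replicates)):
        rng = np.random.default_rng(child)
        cfg = SimConfig(
            n=5000, p=10000, family=family, min_maf=0.05,
            effect_sizes=TABLE3_EFFECTS.copy(),
        )
        G = simulate_genotypes_independent(cfg, rng)
        beta, causal = simulate_coefficients(cfg, rng)
        y = simulate_response(cfg, G, beta, rng, backend=options.backend)
        state = fit_iht(
            y, G, family=cfg.make_family(),
            constraint=SparsityConstraint(k=10), options=options,
        )
        support = set(state.support.tolist())
        for j in causal:
            if j in support:
                rows.append(
                    dict(design="table3", family=family, replicate=rep,
                         beta_true=float(beta[j]), beta_hat=float(state.b[j]))
                )
    return pd.DataFrame(rows)


def _grouped_design(family, replicates, seed, options):
    """Doubly sparse vs plain IHT on LD blocks (15 causal SNPs, 5 groups)."""
    rows = []
    ss = np.random.SeedSequence(seed)
    causal_per_group = [1, 2, 3, 4, 5]
    for rep, child in enumerate(ss.spawn(replicates)):
        rng = np.random.default_rng(child)
        cfg = SimConfig(
            n=1000, p=10000, family=family, ld=True,
            effect_sizes=np.array([0.2]), k_true=15,
        )
        G = simulate_genotypes_ld(cfg, rng)
        beta, causal, causal_groups = simulate_coefficients(
            cfg, rng, grouping=(5, causal_per_group)
        )
        y = simulate_response(cfg, G, beta, rng, backend=options.backend)
        fam = cfg.make_family()
        plain = fit_iht(
            y, G, family=fam, constraint=SparsityConstraint(k=15),
            options=options,
        )
        membership = np.arange(cfg.p) // cfg.block_size
        lam = np.ones(cfg.p // cfg.block_size, dtype=int)
        for g, c in zip(causal_groups, np.bincount(
            (np.asarray(causal) // cfg.block_size)
        )[causal_groups]):
            lam[g] = c
        grouped = fit_iht(
            y, G, family=fam,
            constraint=SparsityConstraint(membership=membership, j=5, lambda_g=lam),
            options=options,
        )
        tp_u, fp_u = _count_tp_fp(plain.support, causal, cfg.p)
        tp_g, fp_g = _count_tp_fp(grouped.support, causal, cfg.p)
        rows.append(
            dict(design="table4", family=family, replicate=rep,
                 tp_ungrouped=tp_u, fp_ungrouped=fp_u,
                 tp_grouped=tp_g, fp_grouped=fp_g)
        )
    return pd.DataFrame(rows)


def _weighted_design(family, replicates, seed, options):
    """Prior weights: w=2 on 10% of variants (incl. all causal), else 1."""
    rows = []
    ss = np.random.SeedSequence(seed)
    for rep, child in enumerate(ss.spawn(replicates)):
        rng = np.random.default_rng(child)
        cfg = SimConfig(n=1000, p=10000, family=family)
        G = simulate_genotypes_independent(cfg, rng)
        beta, causal = simulate_coefficients(cfg, rng)
        y = simulate_response(cfg, G, beta, rng, backend=options.backend)
        fam = cfg.make_family()
        w = np.ones(cfg.p)
        n_favored = cfg.p // 10
        favored = rng.choice(
            np.setdiff1d(np.arange(cfg.p), causal),
            size=n_favored - len(causal), replace=False,
        )
        w[favored] = 2.0
        w[causal] = 2.0
        unweighted = fit_iht(
            y, G, family=fam, constraint=SparsityConstraint(k=10),
            options=options,
        )
        weighted = fit_iht(
            y, G, family=fam, constraint=SparsityConstraint(k=10, weights=w),
            options=options,
        )
        tp_u, fp_u = _count_tp_fp(unweighted.support, causal, cfg.p)
        tp_w, fp_w = _count_tp_fp(weighted.support, causal, cfg.p)
        rows.append(
            dict(design="table6", family=family, replicate=rep,
                 tp_unweighted=tp_u, fp_unweighted=fp_u,
                 tp_weighted=tp_w, fp_weighted=fp_w)
        )
    return pd.DataFrame(rows)


def _model_size_design(family, replicates, seed, options):
    """Model-size recovery: n=5000, p=10000, 5-fold CV over k=1..20."""
    rows = []
    ss = np.random.SeedSequence(seed)
    for rep, child in enumerate(ss.spawn(replicates)):
        rng = np.random.default_rng(child)
        cfg = SimConfig(n=5000, p=10000, family=family)
        G = simulate_genotypes_independent(cfg, rng)
        beta, causal = simulate_coefficients(cfg, rng)
        y = simulate_response(cfg, G, beta, rng, backend=options.backend)
        cv = cv_iht(
            y, G, family=cfg.make_family(), k_path=np.arange(1, 21), q=5,
            seed=int(child.generate_state(1)[0] % (2**31)), options=options,
        )
        rows.append(
            dict(design="fig3", family=family, replicate=rep,
                 k_hat=cv.k_hat, abs_err=abs(cv.k_hat - cfg.k_true))
        )
    return pd.DataFrame(rows)


EXPERIMENTS = {
    "t2": _comparison_design,
    "t3": _reconstruction_design,
    "t4": _grouped_design,
    "t6": _weighted_design,
    "fig3": _model_size_design,
}


def run_experiment(design, family="normal", replicates=10, seed=0, options=None):
    """Run a canonical simulation design and return per-replicate rows.

    ``design`` is one of ``t2`` (comparison, CV-selected model size),
    ``t3`` (coefficient recovery at fixed k), ``t4`` (grouped vs plain
    on LD blocks), ``t6`` (weighted vs unweighted), ``fig3`` (CV
    model-size recovery).  ``replicates = 0`` returns an empty frame.
    """
    if design not in EXPERIMENTS:
        raise ValueError(f"unknown design {design!r}; choose from {sorted(EXPERIMENTS)}")
    options = options or IhtOptions(backend="dense")
    if replicates == 0:
        return pd.DataFrame(
            columns=["design", "family", "replicate"]
        )
    return EXPERIMENTS[design](family, replicates, seed, options)


def summarize(df, columns=None):
    """Mean and standard error of the replicate-level columns."""
    if df.empty:
        return pd.DataFrame(columns=["metric", "mean", "se", "n"])
    if columns is None:
        columns = [
            c for c in df.columns
            if c not in ("design", "family", "replicate")
            and np.issubdtype(df[c].dtype, np.number)
        ]
    rows = []
    for c in columns:
        vals = df[c].to_numpy(dtype=float)
        rows.append(
            dict(metric=c, mean=vals.mean(),
                 se=vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0,
                 n=len(vals))
        )
    return pd.DataFrame(rows)
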