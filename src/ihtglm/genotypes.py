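"""PLINK 2-bit genotype storage and implicitly standardized linear algebra.

Genotypes are stored SNP-major as 2-bit codes, exactly the payload layout
of a PLINK ``.bed`` file (4 samples per byte, magic ``6C 1B 01``).  The
code-to-count mapping counts the A1 (minor) allele:

====  =================
bits  minor-allele count
====  =================
00    2
10    1
11    0
01    missing
====  =================

Standardization substitutes ``(x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j))``
for the raw count, with ``p_j`` the estimated minor-allele frequency —
the binomial mean/variance, not the empirical column moments.  The
standardized matrix is never materialized: matrix-vector products fold
the centering in as a rank-one correction and the scaling as a diagonal.

Two product backends are available:

* ``"packed"`` (default) — streams over the 2-bit codes in column
  blocks, exact in float64, O(n + p) working memory beyond the codes.
* ``"dense"`` — a float32 cache of the raw counts (built once, counts
  are exact in float32) routed through BLAS; used by the large
  simulation harnesses where wall-clock matters.  Accumulation is
  single precision, so agreement with the exact path is ~1e-6 relative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "CovariateMatrix",
    "Design",
    "read_plink",
    "write_plink",
    "PlinkFormatError",
]

MISSING = 255  # sentinel for a missing count after decoding

_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.uint8)
_COUNT_TO_CODE = {2: 0, 1: 2, 0: 3, MISSING: 1}
_BED_MAGIC = b"\x6c\x1b\x01"


class PlinkFormatError(ValueError):
    """Malformed PLINK BED/BIM/FAM input."""


def _pack_counts(counts):
    """Pack an n x p count matrix (values 0/1/2/MISSING) into SNP-major codes.

    Returns a (p, ceil(n/4)) uint8 array; pad bits are zero.
    """
    counts = np.asarray(counts)
    n, p = counts.shape
    lut = np.zeros(256, dtype=np.uint8)
    lut[[2, 1, 0, MISSING]] = (0, 2, 3, 1)
    codes = lut[counts.T]
    nbytes = (n + 3) // 4
    padded = np.zeros((p, nbytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    return np.ascontiguousarray(packed)


def _unpack_block(packed_block, n):
    """Decode a (m, nbytes) block of codes into an (m, n) uint8 count matrix."""
    m = packed_block.shape[0]
    out = np.empty((m, packed_block.shape[1] * 4), dtype=np.uint8)
    out[:, 0::4] = packed_block & 3
    out[:, 1::4] = (packed_block >> 2) & 3
    out[:, 2::4] = (packed_block >> 4) & 3
    out[:, 3::4] = (packed_block >> 6) & 3
    return _CODE_TO_COUNT[out[:, :n]]


@dataclass
class GenotypeMatrix:
    """An n x p minor-allele-count matrix in packed 2-bit codes.

    Attributes
    ----------
    packed
        (p, ceil(n/4)) uint8 SNP-major code array (the BED payload).
    n, p
        Sample and SNP counts.
    maf
        Per-SNP estimated minor-allele frequency (sample frequency over
        observed genotypes, after any allele flip so that maf <= 0.5).
    snp_meta, sample_meta
        Optional BIM/FAM records as DataFrames.
    """

    packed: np.ndarray
    n: int
    p: int
    maf: np.ndarray = None
    snp_meta: pd.DataFrame = None
    sample_meta: pd.DataFrame = None
    has_missing: bool = False
    _cache: np.ndarray = field(default=None, repr=False)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_counts(cls, counts, snp_meta=None, sample_meta=None):
        """Build from a dense count matrix (0/1/2, MISSING for absent)."""
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be an n x p matrix")
        n, p = counts.shape
        counts = counts.astype(np.uint8, copy=True)
        ok = np.zeros(256, dtype=bool)
        ok[[0, 1, 2, MISSING]] = True
        if not ok[counts].all():
            raise ValueError("genotype counts must be 0, 1, 2 or missing")
        has_missing = bool((counts == MISSING).any())
        if has_missing:
            obs = counts != MISSING
            n_obs = obs.sum(axis=0)
            freq = np.where(obs, counts, 0).sum(axis=0) / (
                2.0 * np.maximum(n_obs, 1)
            )
            freq[n_obs == 0] = 0.0
        else:
            freq = counts.mean(axis=0, dtype=np.float64) / 2.0
        # flip alleles so counts are minor-allele counts
        flip = freq > 0.5
        if np.any(flip):
            cols = counts[:, flip]
            mask = cols != MISSING
            cols[mask] = 2 - cols[mask]
            counts[:, flip] = cols
            freq = freq.copy()
            freq[flip] = 1.0 - freq[flip]
        return cls(
            packed=_pack_counts(counts),
            n=n,
            p=p,
            maf=freq,
            snp_meta=snp_meta,
            sample_meta=sample_meta,
            has_missing=has_missing,
        )

    # -- basic access -------------------------------------------------------

    @property
    def scale(self):
        """Per-SNP standard deviation sqrt(2 p_j (1 - p_j)); 0 if monomorphic."""
        return np.sqrt(2.0 * self.maf * (1.0 - self.maf))

    @property
    def monomorphic(self):
        return (self.maf <= 0.0) | (self.maf >= 1.0)

    def decode(self, cols=None):
        """Dense uint8 count matrix (n x len(cols)); MISSING for absent."""
        if cols is None:
            block = self.packed
        else:
            cols = np.atleast_1d(np.asarray(cols, dtype=np.intp))
            if cols.size and (cols.min() < 0 or cols.max() >= self.p):
                raise IndexError("SNP index out of range")
            block = self.packed[cols]
        return _unpack_block(block, self.n).T

    def counts_cache(self, dtype=np.float32):
        """Dense float count matrix, built once and memoized.

        Requires imputation first (no missing codes).
        """
        if self.has_missing:
            raise ValueError("impute missing genotypes before numeric products")
        if self._cache is None or self._cache.dtype != np.dtype(dtype):
            self._cache = self.decode().astype(dtype)
        return self._cache

    # -- imputation ---------------------------------------------------------

    def impute_mode(self):
        """Replace missing genotypes by each SNP's modal observed count."""
        if not self.has_missing:
            return self
        counts = self.decode()
        miss = counts == MISSING
        bad_cols = np.flatnonzero(miss.all(axis=0))
        if bad_cols.size:
            raise ValueError(
                f"SNP(s) with all genotypes missing: {bad_cols.tolist()}"
            )
        for j in np.flatnonzero(miss.any(axis=0)):
            col = counts[:, j]
            obs = col[col != MISSING]
            tallies = np.bincount(obs, minlength=3)[:3]
            mode = int(np.argmax(tallies))  # ties -> lowest count value
            col[col == MISSING] = mode
        return GenotypeMatrix.from_counts(
            counts, snp_meta=self.snp_meta, sample_meta=self.sample_meta
        )

    # -- implicitly standardized products ------------------------------------

    def _inv_scale(self):
        if getattr(self, "_inv_scale_memo", None) is None:
            s = self.scale
            inv = np.zeros_like(s)
            ok = s > 0
            inv[ok] = 1.0 / s[ok]
            self._inv_scale_memo = inv
        return self._inv_scale_memo

    def standardized_xv(self, beta, backend="packed"):
        """X_std @ beta decoding only the support columns. Returns an n-vector."""
        if self.has_missing:
            raise ValueError("impute missing genotypes before numeric products")
        beta = np.asarray(beta, dtype=float)
        if beta.shape[0] != self.p:
            raise ValueError("beta length must equal the number of SNPs")
        support = np.flatnonzero(beta)
        if support.size == 0:
            return np.zeros(self.n)
        inv = self._inv_scale()[support]
        coef = beta[support] * inv
        if backend == "dense":
            cache = self.counts_cache()
            if support.size > self.p // 4:
                # dense direction: a full gemv beats slicing the cache
                full = np.zeros(self.p, dtype=cache.dtype)
                full[support] = coef
                raw = (cache @ full).astype(float)
            else:
                raw = cache[:, support] @ coef.astype(cache.dtype)
                raw = raw.astype(float)
        else:
            cols = self.decode(support).astype(float)
            raw = cols @ coef
        return raw - float(2.0 * self.maf[support] @ coef)

    def standardized_xtv(self, v, backend="packed", block=1024):
        """X_std' @ v over all p SNPs without forming X_std. Returns a p-vector."""
        if self.has_missing:
            raise ValueError("impute missing genotypes before numeric products")
        v = np.asarray(v, dtype=float)
        if v.shape[0] != self.n:
            raise ValueError("v length must equal the number of samples")
        if backend == "dense":
            cache = self.counts_cache()
            raw = (cache.T @ v.astype(cache.dtype)).astype(float)
        else:
            raw = np.empty(self.p)
            for start in range(0, self.p, block):
                stop = min(start + block, self.p)
                counts = _unpack_block(self.packed[start:stop], self.n)
                raw[start:stop] = counts.astype(float) @ v
        vsum = float(v.sum())
        return (raw - 2.0 * self.maf * vsum) * self._inv_scale()


@dataclass
class CovariateMatrix:
    """Non-genetic covariates Z, standardized except for the intercept.

    Constant columns (the intercept) are left untouched; every other
    column is centered and scaled to unit variance.
    """

    values: np.ndarray
    standardized: np.ndarray = None

    @classmethod
    def from_array(cls, values, standardize=True):
        values = np.array(values, dtype=float, copy=True)
        if values.ndim == 1:
            values = values[:, None]
        flags = np.zeros(values.shape[1], dtype=bool)
        if standardize:
            sd = values.std(axis=0)
            for c in range(values.shape[1]):
                if sd[c] > 0:
                    values[:, c] = (values[:, c] - values[:, c].mean()) / sd[c]
                    flags[c] = True
        return cls(values=values, standardized=flags)

    @classmethod
    def intercept_only(cls, n):
        return cls(values=np.ones((n, 1)), standardized=np.zeros(1, dtype=bool))

    @property
    def r(self):
        return self.values.shape[1]


class Design:
    """The block design (X Z) as a pair of implicit matrix operators.

    Products follow the block identities ``(X Z)(beta; gamma) = X beta +
    Z gamma`` and ``(X Z)' v = (X' v; Z' v)``.  An optional ``rows``
    index restricts samples (cross-validation folds) while keeping the
    full-data standardization; products are then computed on zero-padded
    full-length vectors so no row copy of X is ever made.
    """

    def __init__(self, genotypes, covariates=None, rows=None, backend="packed"):
        self.G = genotypes
        self.Z = covariates
        if genotypes is None and covariates is None:
            raise ValueError("need genotypes, covariates or both")
        if (
            covariates is not None
            and genotypes is not None
            and covariates.values.shape[0] != genotypes.n
        ):
            raise ValueError("covariate and genotype row counts disagree")
        self.rows = None if rows is None else np.asarray(rows, dtype=np.intp)
        self.backend = backend

    @property
    def n(self):
        return self.G.n if self.G is not None else self.Z.values.shape[0]

    @property
    def p(self):
        return 0 if self.G is None else self.G.p

    @property
    def r(self):
        return 0 if self.Z is None else self.Z.r

    @property
    def width(self):
        return self.p + self.r

    @property
    def n_rows(self):
        return self.n if self.rows is None else self.rows.shape[0]

    def split(self, b):
        """Split a stacked coefficient vector into (beta, gamma)."""
        return b[: self.p], b[self.p :]

    def forward(self, b):
        """(X Z)(beta; gamma) restricted to the active rows."""
        beta, gamma = self.split(np.asarray(b, dtype=float))
        eta = np.zeros(self.n)
        if self.G is not None:
            eta += self.G.standardized_xv(beta, backend=self.backend)
        if self.Z is not None and gamma.size:
            eta = eta + self.Z.values @ gamma
        return eta if self.rows is None else eta[self.rows]

    def adjoint(self, v):
        """(X Z)' v over the active rows; returns a (p + r)-vector."""
        v = np.asarray(v, dtype=float)
        if self.rows is None:
            w = v
        else:
            w = np.zeros(self.n)
            w[self.rows] = v
        parts = []
        if self.G is not None:
            parts.append(self.G.standardized_xtv(w, backend=self.backend))
        if self.Z is not None:
            parts.append(self.Z.values.T @ w)
        return parts[0] if len(parts) == 1 else np.concatenate(parts)

    def columns(self, idx):
        """Dense standardized columns of (X Z) on the active rows."""
        idx = np.asarray(idx, dtype=np.intp)
        snp = idx[idx < self.p]
        cov = idx[idx >= self.p] - self.p
        cols = []
        if snp.size:
            counts = self.G.decode(snp).astype(float)
            inv = self.G._inv_scale()[snp]
            cols.append((counts - 2.0 * self.G.maf[snp]) * inv)
        if cov.size:
            cols.append(self.Z.values[:, cov])
        mat = np.hstack(cols) if cols else np.empty((self.n, 0))
        # restore the caller's column order
        order = np.argsort(np.argsort(np.concatenate([snp, cov + self.p])))
        mat = mat[:, order]
        return mat if self.rows is None else mat[self.rows]


# -- PLINK and delimited-text IO ---------------------------------------------


def write_plink(prefix, genotypes, phenotype=None):
    """Write BED/BIM/FAM files (and optionally a phenotype in FAM column 6)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    G = genotypes
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(G.packed.tobytes())
    if G.snp_meta is not None:
        bim = G.snp_meta
    else:
        bim = pd.DataFrame(
            {
                "chrom": 1,
                "snp": [f"snp{j + 1}" for j in range(G.p)],
                "cm": 0,
                "pos": np.arange(1, G.p + 1),
                "a1": "A",
                "a2": "G",
            }
        )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    if G.sample_meta is not None:
        fam = G.sample_meta.copy()
    else:
        fam = pd.DataFrame(
            {
                "fid": [f"f{i + 1}" for i in range(G.n)],
                "iid": [f"i{i + 1}" for i in range(G.n)],
                "pat": 0,
                "mat": 0,
                "sex": 0,
                "pheno": -9,
            }
        )
    if phenotype is not None:
        fam["pheno"] = np.asarray(phenotype)
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix):
    """Read a BED/BIM/FAM triple into a :class:`GenotypeMatrix`.

    The BED payload is kept in its packed 2-bit form; only allele
    frequencies are estimated (decoding column blocks transiently).
    """
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f"missing PLINK file: {f}")
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
    )
    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    n, p = len(fam_df), len(bim_df)
    raw = bed.read_bytes()
    if raw[:2] != _BED_MAGIC[:2]:
        raise PlinkFormatError(f"{bed}: bad BED magic bytes")
    if raw[2:3] != _BED_MAGIC[2:]:
        raise PlinkFormatError(f"{bed}: not in SNP-major mode")
    nbytes = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != nbytes * p:
        raise PlinkFormatError(
            f"{bed}: truncated payload; expected {nbytes * p} bytes "
            f"(ceil({n}/4) * {p}), found {payload.size}"
        )
    counts = _unpack_block(payload.reshape(p, nbytes), n).T
    G = GenotypeMatrix.from_counts(counts, snp_meta=bim_df, sample_meta=fam_df)
    if np.any(G.monomorphic):
        warnings.warn(
            f"{int(G.monomorphic.sum())} monomorphic SNP(s); their "
            "standardized columns are identically zero and cannot be selected"
        )
    return G


def read_table(path):
    """Read a delimited numeric table (tab, comma or whitespace)."""
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        sep = "\t"
    elif "," in first:
        sep = ","
    else:
        sep = r"\s+"
    return pd.read_csv(path, sep=sep)


def read_phenotype(path):
    """Read a phenotype vector from a one-column (optionally headered) file."""
    df = read_table(path)
    return df.iloc[:, -1].to_numpy(dtype=float)
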