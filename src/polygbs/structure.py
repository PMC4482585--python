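"""Population structure: numeric genotype encoding, nearest-neighbor
imputation and covariance-method PCA.

Diploid calls are collapsed to a biallelic major-allele dosage coding
(0/1/2 copies of the locus's major allele), missing cells are filled by
copying from the nearest sample under the unweighted Manhattan distance
(normalized by the number of jointly observed loci), and sample scores are
obtained by eigendecomposition of the column-centered (unscaled) genotype
covariance.  A permutation test on the first-component scores quantifies
differentiation between two populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gcall


def encode(diploid_codes: pd.DataFrame) -> pd.DataFrame:
    """Samples x loci matrix of major-allele counts {0, 1, 2}, NaN missing.

    The major allele at a locus is the one with the higher call-based
    frequency (A1 on ties).  Monomorphic loci are retained with zero
    variance.  Input is the loci x samples diploid-code matrix.
    """
    codes = diploid_codes.to_numpy()
    non_missing = codes != gcall.MISSING
    a1 = (np.where(codes == gcall.HOM_A1, 2, 0) + (codes == gcall.HET)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        f1 = a1 / np.maximum(2 * non_missing.sum(axis=1), 1)
    a1_major = f1 >= 0.5
    x = codes.astype(float)
    x[~non_missing] = np.nan
    # codes already count A1 alleles; flip where A2 is major
    flip = ~a1_major
    x[flip] = 2.0 - x[flip]
    return pd.DataFrame(x.T, index=diploid_codes.columns,
                        columns=diploid_codes.index)


@dataclass
class ImputationLog:
    removed_samples: list[str]
    n_imputed: int
    n_mode_filled: int


def impute(matrix: pd.DataFrame, max_missing: float = 0.5):
    """Fill missing genotypes from the nearest sample (Manhattan distance).

    Samples with a missing fraction above ``max_missing`` are removed first.
    Each missing cell is copied from the nearest other sample (unweighted
    Manhattan distance over jointly non-missing loci, divided by their
    number) that has data at that locus; distance ties are broken by sample
    order.  A cell with no eligible donor falls back to the locus mode.
    Returns ``(complete DataFrame, ImputationLog)``.
    """
    x = matrix.to_numpy(dtype=float)
    missing_frac = np.isnan(x).mean(axis=1)
    keep = missing_frac <= max_missing
    removed = matrix.index[~keep].tolist()
    x = x[keep]
    index = matrix.index[keep]
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least two samples after screening")

    obs = ~np.isnan(x)
    # pairwise normalized Manhattan distances over shared loci
    dist = np.full((n, n), np.inf)
    for i in range(n):
        shared = obs[i] & obs
        counts = shared.sum(axis=1)
        diffs = np.nansum(np.abs(np.where(shared, x - x[i], 0.0)), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(counts > 0, diffs / counts, np.inf)
        dist[i] = d
    np.fill_diagonal(dist, np.inf)

    n_imputed = n_mode = 0
    order = np.argsort(dist, axis=1, kind="stable")  # ties -> sample order
    filled = x.copy()
    for i in range(n):
        miss = np.flatnonzero(~obs[i])
        if miss.size == 0:
            continue
        for j in miss:
            donor_val = np.nan
            for cand in order[i]:
                if np.isinf(dist[i, cand]):
                    break
                if obs[cand, j]:
                    donor_val = x[cand, j]
                    break
            if np.isnan(donor_val):
                col = x[obs[:, j], j]
                if col.size:
                    vals, cnts = np.unique(col, return_counts=True)
                    donor_val = vals[np.argmax(cnts)]
                else:
                    donor_val = 0.0
                n_mode += 1
            filled[i, j] = donor_val
            n_imputed += 1
    log = ImputationLog(removed_samples=removed, n_imputed=n_imputed,
                        n_mode_filled=n_mode)
    return pd.DataFrame(filled, index=index, columns=matrix.columns), log


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    proportions: np.ndarray       # variance share per component, sums to 1
    loadings: np.ndarray          # components x loci


def pca(matrix: pd.DataFrame) -> PCAResult:
    """Covariance-method PCA: column-center (no variance scaling), SVD.

    Each component's loading vector is oriented so that its
    largest-magnitude element is positive (sign convention for
    reproducibility).  Fails on a zero-variance matrix.
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 loci")
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; impute first")
    xc = x - x.mean(axis=0)
    if not np.any(xc):
        raise ValueError("zero-variance matrix: no polymorphism to decompose")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    var = s ** 2
    proportions = var / var.sum()
    cols = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return PCAResult(scores=pd.DataFrame(scores, index=matrix.index, columns=cols),
                     proportions=proportions, loadings=vt)


def population_separation_test(scores: pd.Series, labels,
                               n_permutations: int = 999,
                               seed: int = 0) -> float:
    """Permutation p-value for |mean PC-score difference| between two groups."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    groups = np.unique(lab)
    if len(groups) != 2:
        raise ValueError("exactly two population labels required")
    mask = lab == groups[0]
    observed = abs(s[mask].mean() - s[~mask].mean())
    rng = np.random.default_rng(seed)
    n, n_a = len(s), int(mask.sum())
    # vectorized label shuffles: first n_a slots of each random ordering
    idx = rng.random((n_permutations, n)).argsort(axis=1)[:, :n_a]
    pa = s[idx].mean(axis=1)
    pb = (s.sum() - pa * n_a) / (n - n_a)
    count = 1 + int((np.abs(pa - pb) >= observed).sum())
    return count / (n_permutations + 1)
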