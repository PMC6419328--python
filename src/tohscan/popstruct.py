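"""Population-stratification covariates from genotype PCA.

Genotypes are standardized per SNP the way EigenStrat does: with allele-B
frequency estimate ``p_j`` (half the mean dosage among called genotypes),
each entry becomes ``(x - 2 p_j) / sqrt(2 p_j (1 - p_j))`` and missing
entries are set to 0 after centering.  Monomorphic columns carry no
information and are dropped.  Individual scores are the leading left
singular vectors of the standardized matrix, with each component's sign
fixed so its largest-magnitude entry is positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MISSING, DataError, GenotypeMatrix


def standardize_genotypes(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Return the standardized matrix and the indices of retained SNPs."""
    if genotypes.n_samples == 0 or genotypes.n_snps == 0:
        raise DataError("cannot standardize an empty genotype matrix")
    g = genotypes.calls.astype(float)
    miss = genotypes.calls == MISSING
    g[miss] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=0) / 2.0
    called = (~miss).sum(axis=0)
    keep = (called > 0) & (p > 0.0) & (p < 1.0)
    p = p[keep]
    x = g[:, keep] - 2.0 * p
    x /= np.sqrt(2.0 * p * (1.0 - p))
    x[np.isnan(x)] = 0.0
    return x, np.flatnonzero(keep)


def compute_pcs(standardized: np.ndarray, k: int) -> np.ndarray:
    """Top-``k`` individual scores (left singular vectors), sign-fixed.

    Deterministic: a dense SVD plus the convention that each component's
    largest-magnitude entry is positive.
    """
    x = np.asarray(standardized, dtype=float)
    if k < 0:
        raise DataError("k must be >= 0")
    if k == 0:
        return np.empty((x.shape[0], 0))
    if k >= x.shape[0]:
        raise DataError(f"k={k} must be smaller than the number of individuals")
    u, s, _vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k]
    for j in range(k):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def covariate_matrix(
    genotypes: GenotypeMatrix, k: int = 2, exclude_snps: np.ndarray | None = None
) -> pd.DataFrame:
    """Sex plus the top-``k`` PC scores, one row per individual.

    ``exclude_snps`` (marker indices) removes markers from the PCA input —
    used by the pipeline to drop cTOH-region markers, the analogue of
    excluding atypical long-range-sharing regions before stratification PCA
    so the ancestry axes are not driven by the very homozygosity signal
    under test.
    """
    gm = genotypes
    if exclude_snps is not None and len(exclude_snps):
        keep = np.setdiff1d(np.arange(gm.n_snps), np.asarray(exclude_snps))
        gm = gm.subset(snp_idx=keep)
    x, _keep = standardize_genotypes(gm)
    scores = compute_pcs(x, k)
    out = pd.DataFrame(
        {
            "sample_id": genotypes.samples["sample_id"].to_numpy(),
            "sex": genotypes.samples["sex"].to_numpy(),
        }
    )
    for j in range(scores.shape[1]):
        out[f"PC{j + 1}"] = scores[:, j]
    return out
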