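"""Effective number of independent tests and Bonferroni thresholds.

Dense SNP panels carry heavy linkage disequilibrium, so a Bonferroni
correction over the raw marker count is far too strict.  Following the
principal-component approach, the effective number of tests on a
chromosome is the smallest number of eigenvalues of the inter-marker
correlation matrix whose sum reaches a set fraction (default 99.6%) of
the total variance; the genome-wide count is the sum over chromosomes
and the significance threshold is -log10(alpha / M_total).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class ThresholdResult:
    per_chromosome: pd.DataFrame  # chrom, n_snps, n_effective
    total_effective: int
    genomewide_mlog10: float
    suggestive_mlog10: float
    alpha: float
    variance_kept: float

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "variance_kept": self.variance_kept,
            "per_chromosome": self.per_chromosome.to_dict("records"),
            "total_effective_tests": self.total_effective,
            "genomewide_mlog10": self.genomewide_mlog10,
            "genomewide_mlog10_1dp": round(self.genomewide_mlog10, 1),
            "suggestive_mlog10": self.suggestive_mlog10,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def effective_tests(values: np.ndarray, variance_kept: float = 0.996) -> int:
    """Effective number of independent tests for one chromosome's markers.

    ``values``: (n_individuals, m_snps) dosage matrix.  Constant
    columns are dropped with a warning.  The eigenvalues of the m x m
    Pearson correlation matrix are accumulated (largest first) until
    ``variance_kept`` of the total (= m) is reached.  When m exceeds n
    the spectrum is computed from the n x n dual of the standardized
    matrix, which shares the nonzero eigenvalues.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 SNPs")
    has_nan = np.isnan(x).any()
    if has_nan:
        sd = np.nanstd(x, axis=0)
    else:
        sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant SNP columns", int((~keep).sum()))
    x = x[:, keep]
    m = x.shape[1]
    if m < 2:
        return 1 if m == 1 else 0
    if has_nan:
        corr = pd.DataFrame(x).corr(min_periods=2).to_numpy()
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        eig = np.linalg.eigvalsh(corr)
    else:
        z = (x - x.mean(axis=0)) / x.std(axis=0)
        n = x.shape[0]
        if m <= n:
            corr = (z.T @ z) / n
            eig = np.linalg.eigvalsh(corr)
        else:
            dual = (z @ z.T) / n
            eig = np.linalg.eigvalsh(dual)
    eig = np.clip(eig, 0.0, None)[::-1]
    total = m  # trace of the correlation matrix
    csum = np.cumsum(eig)
    k = int(np.searchsorted(csum, variance_kept * total) + 1)
    return min(k, m)


def effective_tests_by_chromosome(
    gm: GenotypeMatrix, variance_kept: float = 0.996
) -> pd.DataFrame:
    rows = []
    for chrom, grp in gm.snp_map.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        k = effective_tests(gm.values[:, cols], variance_kept)
        rows.append({"chrom": str(chrom), "n_snps": len(cols), "n_effective": k})
    return pd.DataFrame(rows)


def bonferroni_threshold(effective_per_chromosome, alpha: float = 0.05) -> float:
    """-log10(alpha / total effective tests)."""
    counts = np.asarray(list(effective_per_chromosome), dtype=float)
    if np.any(counts <= 0):
        raise ValueError("effective test counts must be positive")
    total = counts.sum()
    return float(-np.log10(alpha / total))


def compute_thresholds(
    gm: GenotypeMatrix,
    variance_kept: float = 0.996,
    alpha: float = 0.05,
    suggestive: float = 3.0,
) -> ThresholdResult:
    """Per-chromosome effective tests + genome-wide Bonferroni threshold.

    LD is assessed on the observed (breeder) genotypes, whose LD
    structure is the population's own.
    """
    per_chrom = effective_tests_by_chromosome(gm, variance_kept)
    thr = bonferroni_threshold(per_chrom["n_effective"], alpha)
    return ThresholdResult(
        per_chromosome=per_chrom,
        total_effective=int(per_chrom["n_effective"].sum()),
        genomewide_mlog10=thr,
        suggestive_mlog10=suggestive,
        alpha=alpha,
        variance_kept=variance_kept,
    )
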