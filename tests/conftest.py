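import numpy as np
import pandas as pd
import pytest

from divsel_gwas.genotypes import predict_average_genotypes
from divsel_gwas.simdesign import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale two-line experiment with one strong planted QTL."""
    cfg = SimConfig(
        n_chromosomes=2,
        n_snps_per_chrom=40,
        n_founder_matings=12,
        n_tested_males=24,
        n_tested_males_g0=30,
        n_selected_sires=4,
        n_dams=12,
        response_counts=(24,) * 9,
        traits=("RFI",),
        n_qtl=1,
        qtl_effects=(0.4,),
        founder_maf_range=(0.3, 0.5),
        seed=11,
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_avg(small_sim):
    return predict_average_genotypes(small_sim.breeder_genotypes, small_sim.pedigree)


def toy_pedigree(rows):
    """rows: (id, sire, dam) triples; fills the remaining columns."""
    df = pd.DataFrame(rows, columns=["id", "sire", "dam"])
    df["sex"] = "M"
    df["line"] = "HRFI"
    df["generation"] = 0
    df["role"] = "breeder"
    return df


def random_pedigree(n, rng, n_founders=8):
    """Random acyclic pedigree of n animals for oracle comparisons."""
    rows = [(f"A{i}", "0", "0") for i in range(n_founders)]
    for i in range(n_founders, n):
        s, d = rng.choice(i, size=2, replace=False)
        rows.append((f"A{i}", f"A{s}", f"A{d}"))
    return toy_pedigree(rows)


def gene_drop_kinship(ped, n_drops, rng):
    """Monte-Carlo additive relationship estimate by gene dropping.

    Founders get unique allele labels; alleles are dropped through the
    pedigree; a_ij is estimated as twice the probability that random
    alleles from i and j are identical by descent.
    """
    ids = list(ped["id"])
    idx = {i: k for k, i in enumerate(ids)}
    sire = list(ped["sire"])
    dam = list(ped["dam"])
    n = len(ids)
    alleles = np.zeros((n, 2, n_drops), dtype=np.int32)
    next_allele = 1
    for k in range(n):
        for slot, parent in enumerate((sire[k], dam[k])):
            if parent == "0" or parent not in idx:
                alleles[k, slot] = next_allele
                next_allele += 1
            else:
                p = idx[parent]
                pick = rng.integers(0, 2, size=n_drops)
                alleles[k, slot] = alleles[p, pick, np.arange(n_drops)]
    amat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ibd = np.zeros(n_drops)
            for a in range(2):
                for b in range(2):
                    ibd += alleles[i, a] == alleles[j, b]
            if i == j:
                # a_ii = 1 + F, F = P(the two alleles of i are IBD)
                amat[i, i] = 1.0 + np.mean(alleles[i, 0] == alleles[i, 1])
            else:
                amat[i, j] = amat[j, i] = 2.0 * np.mean(ibd) / 4.0
    return amat


def dense_gls_oracle(y, x, a_values, lam):
    """Brute-force GLS of y on (1, x) under V = lam*A + I with explicit inverse."""
    n = len(y)
    v = lam * a_values + np.eye(n)
    vi = np.linalg.inv(v)
    xmat = np.column_stack([np.ones(n), x])
    cov = np.linalg.inv(xmat.T @ vi @ xmat)
    bhat = cov @ xmat.T @ vi @ y
    resid = y - xmat @ bhat
    sigma2 = float(resid @ vi @ resid) / (n - 2)
    se = float(np.sqrt(sigma2 * cov[1, 1]))
    return float(bhat[1]), se
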