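"""Genotype containers, I/O, quality control and parental-average prediction.

Genotypes are stored as counted-allele dosages per (individual, SNP).
The counted allele is fixed at load (or simulation) time from the SNP
map and is never re-polarized after subsetting, so "frequency" tracks
one fixed allele across generations -- a requirement for the
allele-frequency trajectory analysis.  The chip convention of the
source design codes 0/1/2 as minor-homozygote/het/major-homozygote;
the PLINK loader exposes both orientations and records the one used.

Response animals of the design are not genotyped; each receives the
average genotype of its parents, (sire + dam)/2 per SNP, taking values
in {0, 0.5, 1, 1.5, 2}.  All full sibs therefore share identical rows.
Each predicted cell carries a certainty class: ``certain`` when the
parental pair determines the offspring genotype (0x0, 2x2, 0x2),
``half_certain`` for 1x1 matings, ``uncertain`` for 0x1 and 1x2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, normalize_pedigree

logger = logging.getLogger(__name__)

SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele_counted", "allele_other"]

AUTOSOME_EXCLUDE = {"X", "Y", "MT", "M", "0", "XY", ""}


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Observed genotypes: dosage of the counted allele in {0,1,2}, NaN missing."""

    ids: list[str]
    snp_map: pd.DataFrame
    values: np.ndarray  # float, shape (n_individuals, n_snps)

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        if self.values.shape != (len(self.ids), len(self.snp_map)):
            raise GenotypeError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.snp_map)} SNPs"
            )

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_map["snp_id"])

    def row(self, ind_id: str) -> np.ndarray:
        return self.values[self.ids.index(str(ind_id))]

    def subset(self, ids=None, snp_ids=None) -> "GenotypeMatrix":
        vals = self.values
        out_ids = self.ids
        smap = self.snp_map
        if ids is not None:
            index = {i: k for k, i in enumerate(self.ids)}
            ix = [index[str(i)] for i in ids]
            vals = vals[ix]
            out_ids = [str(i) for i in ids]
        if snp_ids is not None:
            sindex = {s: k for k, s in enumerate(self.snp_map["snp_id"])}
            jx = [sindex[s] for s in snp_ids]
            vals = vals[:, jx]
            smap = self.snp_map.iloc[jx].reset_index(drop=True)
        return type(self)(out_ids, smap, vals.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.snp_ids)

    def write_dosage_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class AverageGenotypeMatrix(GenotypeMatrix):
    """Parental-average dosages in {0, 0.5, 1, 1.5, 2} with certainty classes.

    ``certainty`` is an int8 array aligned with ``values``:
    1 = certain, 2 = half_certain, 3 = uncertain, 0 = missing.
    """

    certainty: np.ndarray = None

    CERTAIN, HALF_CERTAIN, UNCERTAIN = 1, 2, 3

    def subset(self, ids=None, snp_ids=None) -> "AverageGenotypeMatrix":
        base = GenotypeMatrix(self.ids, self.snp_map, self.values).subset(ids, snp_ids)
        cert = GenotypeMatrix(self.ids, self.snp_map, self.certainty.astype(float)).subset(
            ids, snp_ids
        )
        return AverageGenotypeMatrix(
            base.ids, base.snp_map, base.values, cert.values.astype(np.int8)
        )


# ---------------------------------------------------------------------------
# PLINK text and dosage TSV I/O


def read_map(path) -> pd.DataFrame:
    """Read a PLINK .map file (chrom, snp_id, cM, pos_bp)."""
    m = pd.read_csv(
        path, sep=r"\s+", header=None, names=["chrom", "snp_id", "cm", "pos_bp"],
        dtype={"chrom": str, "snp_id": str},
    )
    return m


def read_plink(ped_path, map_path, orientation: str = "minor_zero") -> GenotypeMatrix:
    """Read PLINK text .ped/.map into a GenotypeMatrix.

    orientation="minor_zero" follows the design's chip coding (dosage 0 =
    homozygote for the minor allele, i.e. the counted allele is the major
    one); "major_zero" counts the minor allele instead.  The counted
    allele per SNP is recorded in the returned map and kept fixed.
    """
    if orientation not in ("minor_zero", "major_zero"):
        raise GenotypeError(f"unknown orientation {orientation!r}")
    snp_map = read_map(map_path)
    m = len(snp_map)
    ids, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeError(
                    f"ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}"
                )
            ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype="U2").reshape(len(ids), m, 2)
    counted = np.empty(m, dtype="U2")
    other = np.empty(m, dtype="U2")
    vals = np.full((len(ids), m), np.nan)
    for j in range(m):
        col = alleles[:, j, :]
        obs = col[(col != "0")]
        uniq, counts = np.unique(obs, return_counts=True)
        if uniq.size == 0:
            counted[j], other[j] = "0", "0"
            continue
        order = np.argsort(counts)  # ascending: minor first
        minor = uniq[order[0]]
        major = uniq[order[-1]] if uniq.size > 1 else minor
        # minor_zero: dosage counts the major allele so minor-homozygote = 0
        counted[j], other[j] = (major, minor) if orientation == "minor_zero" else (minor, major)
        miss = (col == "0").any(axis=1)
        vals[:, j] = (col == counted[j]).sum(axis=1)
        vals[miss, j] = np.nan
    snp_map = snp_map.assign(allele_counted=counted, allele_other=other)[
        ["snp_id", "chrom", "pos_bp", "allele_counted", "allele_other"]
    ]
    return GenotypeMatrix(ids, snp_map, vals)


def write_plink(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PLINK text .ped/.map (alleles from the SNP map)."""
    smap = gm.snp_map
    with open(map_path, "w") as fh:
        for _, r in smap.iterrows():
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{int(r.pos_bp)}\n")
    counted = smap["allele_counted"].to_numpy(dtype="U2")
    other = smap["allele_other"].to_numpy(dtype="U2")
    with open(ped_path, "w") as fh:
        for k, ind in enumerate(gm.ids):
            row = gm.values[k]
            fields = [ind, ind, "0", "0", "0", "-9"]
            for j, d in enumerate(row):
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [other[j], other[j]]
                elif d == 1:
                    fields += [counted[j], other[j]]
                else:
                    fields += [counted[j], counted[j]]
            fh.write(" ".join(fields) + "\n")


def read_dosage_tsv(path, snp_map: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if snp_map is None:
        snp_map = pd.DataFrame(
            {
                "snp_id": df.columns,
                "chrom": "1",
                "pos_bp": np.arange(1, df.shape[1] + 1),
                "allele_counted": "A",
                "allele_other": "B",
            }
        )
    return GenotypeMatrix(list(df.index.astype(str)), snp_map, df.to_numpy(float))


# ---------------------------------------------------------------------------
# Quality control


@dataclass
class QcReport:
    """Accounting of QC removals, with thresholds used."""

    removed_snps: pd.DataFrame  # columns snp_id, reason
    removed_individuals: pd.DataFrame  # columns id, reason
    thresholds: dict
    orientation_note: str = "counted allele fixed at load time"
    n_before: tuple[int, int] = (0, 0)
    n_after: tuple[int, int] = (0, 0)

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "orientation_note": self.orientation_note,
            "n_individuals_before": self.n_before[0],
            "n_snps_before": self.n_before[1],
            "n_individuals_after": self.n_after[0],
            "n_snps_after": self.n_after[1],
            "removed_individuals": self.removed_individuals.to_dict("records"),
            "removed_snps_by_reason": self.removed_snps["reason"]
            .value_counts()
            .to_dict(),
            "removed_snps": self.removed_snps.to_dict("records"),
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Enumerates the conditional distribution of the heterozygote count
    given the allele counts (Levene/Haldane distribution) and sums the
    probabilities of all outcomes no more probable than the observed
    one (Wigginton-style, no mid-p).
    """
    n_het, n_hom1, n_hom2 = int(n_het), int(n_hom1), int(n_hom2)
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # log-probability recurrence over het counts of the same parity as `rare`
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.zeros(len(hets))
    for k in range(1, len(hets)):
        h = hets[k]
        hr_prev = (rare - hets[k - 1]) // 2  # rare homozygotes at previous het count
        hc_prev = n - hets[k - 1] - hr_prev
        # P(h) / P(h-2) = 4 * hr_prev * hc_prev / (h * (h - 1))
        logp[k] = logp[k - 1] + np.log(4.0 * hr_prev * hc_prev) - np.log(h * (h - 1.0))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = np.searchsorted(hets, n_het)
    return float(min(1.0, p[p <= p[obs] * (1 + 1e-12)].sum()))


def _call_rates(values: np.ndarray):
    obs = ~np.isnan(values)
    return obs.mean(axis=1), obs.mean(axis=0)  # per-individual CR, per-SNP CF


def qc_filter(
    gm: GenotypeMatrix,
    cf_min: float = 0.95,
    maf_min: float = 0.01,
    cr_min: float = 0.90,
    hwe_p: float = 1e-10,
) -> tuple[GenotypeMatrix, QcReport]:
    """Marker and individual quality control.

    Filter order: unmapped / non-autosomal SNPs, individual call rate,
    SNP call frequency, minor allele frequency, then the exact
    Hardy-Weinberg test on the retained individuals.  MAF is
    orientation-free (min of the counted-allele frequency and its
    complement).
    """
    if len(gm.ids) == 0 or len(gm.snp_map) == 0:
        raise GenotypeError("empty genotype matrix")
    vals = gm.values.copy()
    smap = gm.snp_map.reset_index(drop=True)
    removed_snps: list[tuple[str, str]] = []
    removed_inds: list[tuple[str, str]] = []

    chroms = smap["chrom"].astype(str).str.upper()
    bad_map = chroms.isin(AUTOSOME_EXCLUDE) | smap["pos_bp"].isna()
    for s in smap.loc[bad_map, "snp_id"]:
        removed_snps.append((s, "unmapped_or_sex"))
    keep_snp = ~bad_map.to_numpy()
    vals = vals[:, keep_snp]
    smap = smap[keep_snp].reset_index(drop=True)
    if smap.empty:
        raise GenotypeError("all SNPs removed (unmapped_or_sex)")

    cr, _ = _call_rates(vals)
    keep_ind = cr >= cr_min
    for i in np.flatnonzero(~keep_ind):
        removed_inds.append((gm.ids[i], "call_rate"))
    ids = [gm.ids[i] for i in np.flatnonzero(keep_ind)]
    vals = vals[keep_ind]
    if not ids:
        raise GenotypeError("all individuals removed (call_rate)")

    _, cf = _call_rates(vals)
    drop = cf < cf_min
    for j in np.flatnonzero(drop):
        removed_snps.append((smap["snp_id"].iloc[j], "call_frequency"))
    vals = vals[:, ~drop]
    smap = smap[~drop].reset_index(drop=True)
    if smap.empty:
        raise GenotypeError("all SNPs removed (call_frequency)")

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(vals, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    drop = ~(maf >= maf_min)
    for j in np.flatnonzero(drop):
        removed_snps.append((smap["snp_id"].iloc[j], "maf"))
    vals = vals[:, ~drop]
    smap = smap[~drop].reset_index(drop=True)
    if smap.empty:
        raise GenotypeError("all SNPs removed (maf)")

    drop_idx = []
    for j in range(vals.shape[1]):
        col = vals[:, j]
        col = col[~np.isnan(col)]
        n_het = int((col == 1).sum())
        n0 = int((col == 0).sum())
        n2 = int((col == 2).sum())
        if hwe_exact_pvalue(n_het, n0, n2) < hwe_p:
            drop_idx.append(j)
            removed_snps.append((smap["snp_id"].iloc[j], "hwe"))
    if drop_idx:
        keep = np.setdiff1d(np.arange(vals.shape[1]), drop_idx)
        vals = vals[:, keep]
        smap = smap.iloc[keep].reset_index(drop=True)
    if smap.empty:
        raise GenotypeError("all SNPs removed (hwe)")

    report = QcReport(
        removed_snps=pd.DataFrame(removed_snps, columns=["snp_id", "reason"]),
        removed_individuals=pd.DataFrame(removed_inds, columns=["id", "reason"]),
        thresholds={"cf_min": cf_min, "maf_min": maf_min, "cr_min": cr_min, "hwe_p": hwe_p},
        n_before=(len(gm.ids), len(gm.snp_map)),
        n_after=(len(ids), len(smap)),
    )
    logger.info(
        "QC: %d/%d individuals, %d/%d SNPs retained (%s)",
        len(ids), len(gm.ids), len(smap), len(gm.snp_map),
        report.removed_snps["reason"].value_counts().to_dict(),
    )
    return GenotypeMatrix(ids, smap, vals), report


# ---------------------------------------------------------------------------
# Parental-average genotypes


def predict_average_genotypes(
    breeders: GenotypeMatrix, ped: pd.DataFrame
) -> AverageGenotypeMatrix:
    """Average parental genotype (sire + dam)/2 for each response animal.

    Response animals whose sire or dam is absent from the breeder
    genotype matrix are excluded (and logged); per-SNP missing parental
    genotypes give missing cells.  All full sibs share identical rows.
    """
    ped = normalize_pedigree(ped)
    resp = ped[ped["role"] == "response"]
    index = {i: k for k, i in enumerate(breeders.ids)}
    kept_ids, sire_ix, dam_ix, skipped = [], [], [], []
    for _, r in resp.iterrows():
        if r.sire == UNKNOWN or r.dam == UNKNOWN or r.sire not in index or r.dam not in index:
            skipped.append(r.id)
            continue
        kept_ids.append(r.id)
        sire_ix.append(index[r.sire])
        dam_ix.append(index[r.dam])
    if skipped:
        logger.info("excluded %d response animals with ungenotyped parents", len(skipped))
    gs = breeders.values[sire_ix]
    gd = breeders.values[dam_ix]
    vals = (gs + gd) / 2.0
    cert = np.zeros(vals.shape, dtype=np.int8)
    ok = ~np.isnan(vals)
    both_hom = ok & (gs != 1) & (gd != 1)
    both_het = ok & (gs == 1) & (gd == 1)
    cert[both_hom] = AverageGenotypeMatrix.CERTAIN
    cert[both_het] = AverageGenotypeMatrix.HALF_CERTAIN
    cert[ok & ~both_hom & ~both_het] = AverageGenotypeMatrix.UNCERTAIN
    return AverageGenotypeMatrix(kept_ids, breeders.snp_map.copy(), vals, cert)


def certainty_summary(avg: AverageGenotypeMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Certain-genotype proportions per SNP and per individual.

    A half_certain cell (1x1 mating) counts for one half, following the
    rule that half of the predicted class-1 genotypes from such matings
    are correct in expectation.
    """
    if len(avg.ids) == 0:
        raise GenotypeError("empty average genotype matrix")
    c = avg.certainty
    certain = (c == avg.CERTAIN) + 0.5 * (c == avg.HALF_CERTAIN)
    nonmiss = c != 0
    with np.errstate(invalid="ignore"):
        per_snp = pd.DataFrame(
            {
                "snp_id": avg.snp_ids,
                "certain_count": certain.sum(axis=0),
                "n": nonmiss.sum(axis=0),
                "proportion_certain": certain.sum(axis=0) / nonmiss.sum(axis=0),
            }
        )
        per_ind = pd.DataFrame(
            {
                "id": avg.ids,
                "certain_count": certain.sum(axis=1),
                "n": nonmiss.sum(axis=1),
                "proportion_certain": certain.sum(axis=1) / nonmiss.sum(axis=1),
            }
        )
    return per_snp, per_ind


def allele_frequencies(gm: GenotypeMatrix, subset=None) -> pd.Series:
    """Counted-allele frequency per SNP: mean dosage / 2 over non-missing cells."""
    vals = gm.values
    if subset is not None:
        subset = [str(s) for s in subset]
        if not subset:
            raise GenotypeError("empty subset")
        index = {i: k for k, i in enumerate(gm.ids)}
        vals = vals[[index[s] for s in subset]]
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(vals, axis=0) / 2.0
    n_empty = int(np.isnan(freq).sum())
    if n_empty:
        logger.warning("%d SNPs have no non-missing calls in the subset", n_empty)
    return pd.Series(freq, index=gm.snp_ids, name="freq")


# ---------------------------------------------------------------------------
# IBS / MDS


def ibs_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise identity-by-state similarity: mean over SNPs of (2 - |gi - gj|)/2."""
    v = gm.values
    if np.isnan(v).any():
        n = len(gm.ids)
        sim = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = np.abs(v[i] - v[j])
                d = d[~np.isnan(d)]
                if d.size == 0:
                    raise GenotypeError(f"no shared calls between {gm.ids[i]} and {gm.ids[j]}")
                sim[i, j] = sim[j, i] = float(np.mean((2.0 - d) / 2.0))
        return sim
    n, m = v.shape
    # |gi - gj| summed over SNPs via dosage-class indicator cross products
    ind = np.stack([(v == k).astype(float) for k in (0, 1, 2)])
    absdiff = np.zeros((n, n))
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            absdiff += abs(a - b) * ind[a] @ ind[b].T
    return (2.0 * m - absdiff) / (2.0 * m)


def classical_mds(dist: np.ndarray, n_axes: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (metric) MDS: double-centering + eigen-decomposition.

    Returns (coordinates, eigenvalues) for the top ``n_axes`` positive
    eigenvalues; each axis is sign-fixed so its largest-magnitude
    loading is positive.
    """
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist ** 2) @ j
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > 1e-10
    rank = int(pos.sum())
    if n_axes > rank:
        logger.warning("n_axes=%d exceeds rank %d; truncating", n_axes, rank)
        n_axes = rank
    coords = v[:, :n_axes] * np.sqrt(w[:n_axes])
    for k in range(n_axes):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] = -coords[:, k]
    return coords, w[:n_axes]


def ibs_mds(gm: GenotypeMatrix, n_axes: int = 2) -> pd.DataFrame:
    """Classical MDS on the 1 - IBS distance matrix."""
    if len(gm.ids) < 3:
        raise GenotypeError("MDS needs at least 3 individuals")
    dist = 1.0 - ibs_matrix(gm)
    coords, _ = classical_mds(dist, n_axes)
    return pd.DataFrame(
        coords, index=gm.ids, columns=[f"axis{k + 1}" for k in range(coords.shape[1])]
    )
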