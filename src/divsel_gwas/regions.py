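"""QTL windows, cross-trait QTL regions and SNP-QTL tagging.

The genome is cut into 1-Mb bins (0-based half-open, bin index =
floor(position / 1 Mb)).  Per trait and analysis, bins holding at least
one marker at or above the genome-wide threshold are retained and runs
of adjacent retained bins are merged into QTL-windows.  Within an
analysis, windows of all traits are then fused whenever they touch or
overlap, yielding non-overlapping QTL-regions; for each trait present
in a region, the most significant member marker (ties broken by
smallest position, then marker id) tags the association as a SNP-QTL
with its allelic substitution effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MB = 1_000_000


@dataclass
class QTLWindow:
    trait: str
    analysis: str
    chrom: str
    start_mb: int
    end_mb: int  # half-open [start_mb, end_mb)
    top_snp: str
    top_pos_bp: int
    top_mlog10p: float
    top_beta: float
    n_significant: int


@dataclass
class SnpQtl:
    trait: str
    analysis: str
    region_id: str
    snp_id: str
    chrom: str
    pos_bp: int
    beta: float
    mlog10p: float


@dataclass
class QTLRegion:
    region_id: str
    analysis: str
    chrom: str
    start_mb: int
    end_mb: int
    windows: list[QTLWindow] = field(default_factory=list)
    snp_qtls: list[SnpQtl] = field(default_factory=list)

    @property
    def traits(self) -> list[str]:
        return sorted({w.trait for w in self.windows})


def make_windows(
    assoc: pd.DataFrame,
    threshold: float,
    trait: str = "",
    analysis: str = "",
    bridge_gap: int = 0,
) -> list[QTLWindow]:
    """1-Mb QTL-windows from one trait's association scan.

    ``assoc`` needs columns snp_id, chrom, pos_bp, neg_log10_p, beta.
    Retained bins whose indices differ by at most ``bridge_gap`` + 1
    on the same chromosome are merged (default: touching bins only).
    """
    sig = assoc[assoc["neg_log10_p"] >= threshold].copy()
    if sig.empty:
        return []
    sig["bin"] = (sig["pos_bp"] // MB).astype(int)
    windows: list[QTLWindow] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        bins = np.sort(grp["bin"].unique())
        run_start = bins[0]
        prev = bins[0]
        runs = []
        for b in bins[1:]:
            if b - prev <= 1 + bridge_gap:
                prev = b
            else:
                runs.append((run_start, prev))
                run_start = prev = b
        runs.append((run_start, prev))
        for lo, hi in runs:
            members = grp[(grp["bin"] >= lo) & (grp["bin"] <= hi)]
            top = _top_marker(members)
            windows.append(
                QTLWindow(
                    trait=trait, analysis=analysis, chrom=str(chrom),
                    start_mb=int(lo), end_mb=int(hi) + 1,
                    top_snp=str(top.snp_id), top_pos_bp=int(top.pos_bp),
                    top_mlog10p=float(top.neg_log10_p), top_beta=float(top.beta),
                    n_significant=len(members),
                )
            )
    return windows


def _top_marker(members: pd.DataFrame) -> pd.Series:
    best = members.sort_values(
        ["neg_log10_p", "pos_bp", "snp_id"], ascending=[False, True, True]
    )
    return best.iloc[0]


def fuse_regions(windows: list[QTLWindow], analysis: str = "") -> list[QTLRegion]:
    """Fuse adjacent/overlapping windows across traits into QTL-regions."""
    if not windows:
        return []
    regions: list[QTLRegion] = []
    by_chrom: dict[str, list[QTLWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    counter = 0
    for chrom in sorted(by_chrom, key=_chrom_key):
        ws = sorted(by_chrom[chrom], key=lambda w: (w.start_mb, w.end_mb))
        cur = [ws[0]]
        cur_end = ws[0].end_mb
        groups = []
        for w in ws[1:]:
            if w.start_mb <= cur_end:  # touching ([a,b) then [b,c)) or overlapping
                cur.append(w)
                cur_end = max(cur_end, w.end_mb)
            else:
                groups.append(cur)
                cur = [w]
                cur_end = w.end_mb
        groups.append(cur)
        for grp in groups:
            counter += 1
            region = QTLRegion(
                region_id=f"R{counter:03d}",
                analysis=analysis or grp[0].analysis,
                chrom=chrom,
                start_mb=min(w.start_mb for w in grp),
                end_mb=max(w.end_mb for w in grp),
                windows=list(grp),
            )
            for trait in region.traits:
                tws = [w for w in grp if w.trait == trait]
                top = sorted(
                    tws, key=lambda w: (-w.top_mlog10p, w.top_pos_bp, w.top_snp)
                )[0]
                region.snp_qtls.append(
                    SnpQtl(
                        trait=trait, analysis=region.analysis,
                        region_id=region.region_id, snp_id=top.top_snp,
                        chrom=chrom, pos_bp=top.top_pos_bp,
                        beta=top.top_beta, mlog10p=top.top_mlog10p,
                    )
                )
            regions.append(region)
    return regions


def _chrom_key(c: str):
    return (0, int(c)) if str(c).isdigit() else (1, str(c))


def regions_table(regions: list[QTLRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            {
                "region_id": r.region_id, "analysis": r.analysis, "chrom": r.chrom,
                "start_mb": r.start_mb, "end_mb": r.end_mb,
                "size_mb": r.end_mb - r.start_mb,
                "traits": ",".join(r.traits),
                "snp_qtls": ",".join(f"{s.trait}:{s.snp_id}" for s in r.snp_qtls),
            }
        )
    return pd.DataFrame(
        rows, columns=["region_id", "analysis", "chrom", "start_mb", "end_mb",
                       "size_mb", "traits", "snp_qtls"],
    )


def snp_qtl_table(regions: list[QTLRegion]) -> pd.DataFrame:
    rows = [
        {
            "trait": s.trait, "analysis": s.analysis, "region_id": s.region_id,
            "snp_id": s.snp_id, "chrom": s.chrom, "pos_bp": s.pos_bp,
            "beta": s.beta, "mlog10p": s.mlog10p,
        }
        for r in regions
        for s in r.snp_qtls
    ]
    return pd.DataFrame(
        rows, columns=["trait", "analysis", "region_id", "snp_id", "chrom",
                       "pos_bp", "beta", "mlog10p"],
    )


def write_regions_bed(regions: list[QTLRegion], path) -> None:
    """BED export (chrom, chromStart, chromEnd in bp, name)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_mb * MB}\t{r.end_mb * MB}\t{r.region_id}\n")


def cross_analysis_compare(
    regions_by_analysis: dict[str, list[QTLRegion]],
    assoc_by_analysis: dict[str, dict[str, pd.DataFrame]],
    genomewide: float = 4.5,
    suggestive: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match QTL-regions across analyses and look SNP-QTL p-values up.

    ``assoc_by_analysis`` maps analysis -> trait -> scan DataFrame.
    Returns (region overlap table, SNP-QTL lookup table) where the
    lookup reports each SNP-QTL's -log10 p in every analysis with
    significant (>= genome-wide) / suggestive (>= suggestive) flags.
    """
    analyses = list(regions_by_analysis)
    overlap_rows = []
    for an, regs in regions_by_analysis.items():
        for r in regs:
            row = {"analysis": an, "region_id": r.region_id, "chrom": r.chrom,
                   "start_mb": r.start_mb, "end_mb": r.end_mb}
            for other in analyses:
                if other == an:
                    continue
                hits = [
                    o.region_id
                    for o in regions_by_analysis[other]
                    if o.chrom == r.chrom and o.start_mb < r.end_mb and r.start_mb < o.end_mb
                ]
                row[f"overlap_{other}"] = ",".join(hits)
            overlap_rows.append(row)
    overlap = pd.DataFrame(overlap_rows)

    lookup_rows = []
    for an, regs in regions_by_analysis.items():
        for s in (s for r in regs for s in r.snp_qtls):
            row = {
                "trait": s.trait, "discovery_analysis": an, "region_id": s.region_id,
                "snp_id": s.snp_id, "chrom": s.chrom, "pos_bp": s.pos_bp, "beta": s.beta,
            }
            for other in analyses:
                scan = assoc_by_analysis.get(other, {}).get(s.trait)
                val = np.nan
                if scan is not None:
                    hit = scan.loc[scan["snp_id"] == s.snp_id, "neg_log10_p"]
                    if len(hit):
                        val = float(hit.iloc[0])
                row[f"mlog10p_{other}"] = val
                row[f"significant_{other}"] = bool(np.isfinite(val) and val >= genomewide)
                row[f"suggestive_{other}"] = bool(np.isfinite(val) and val >= suggestive)
            lookup_rows.append(row)
    return overlap, pd.DataFrame(lookup_rows)
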