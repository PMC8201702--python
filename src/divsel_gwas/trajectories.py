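"""Allele-frequency trajectories of SNP-QTL versus drift baselines.

For each tagged marker and line, allele frequencies are computed on
cumulative response-animal cohorts: f_1 uses generation-1 animals
only, f_2 generations 1-2, ..., f_9 all nine generations (frequencies
come from the parental-average genotypes, the only genotypes response
animals have).  A straight line of frequency on generation number is
fitted per line; its slope (frequency change per generation) is tested
against zero with a Wald test.  Comparing the two lines' slopes yields
four evolution categories -- no_change, co_selected (both significant,
same sign), opposite (both significant, different signs), and
one_line_only -- and an evolution score n_generations * (|significant
slope HRFI| + |significant slope LRFI|) approximating the total
frequency change attributable to the experiment.

The neutral reference is idealized Wright-Fisher drift (panmixia, no
selection, population size N): after t generations the frequency SD is
sqrt(p0 (1 - p0) (1 - (1 - 1/(2N))^t)), with a companion binomial
resampling simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import AverageGenotypeMatrix, GenotypeMatrix
from .pedigree import normalize_pedigree

logger = logging.getLogger(__name__)

LINES = ("HRFI", "LRFI")


class TrajectoryError(ValueError):
    pass


@dataclass
class TrajectoryFit:
    snp_id: str
    line: str
    frequencies: np.ndarray  # cumulative f_1..f_T
    slope: float
    slope_se: float
    wald_p: float

    @property
    def significant(self) -> bool:
        return self.wald_p < 0.05


@dataclass
class EvolutionRecord:
    snp_id: str
    category: str  # no_change | co_selected | opposite | one_line_only
    changed_line: str | None  # set for one_line_only
    evolution_score: float
    slope_hrfi: float
    slope_lrfi: float
    p_hrfi: float
    p_lrfi: float
    g1_line_freq_difference: float = np.nan


def _cohorts(ped: pd.DataFrame, line: str) -> dict[int, list[str]]:
    ped = normalize_pedigree(ped)
    resp = ped[(ped["role"] == "response") & (ped["line"] == line)]
    return {
        int(g): list(grp["id"]) for g, grp in resp.groupby("generation", sort=True)
    }


def cumulative_frequencies(
    avg: AverageGenotypeMatrix | GenotypeMatrix,
    ped: pd.DataFrame,
    line: str,
    snp_ids=None,
) -> pd.DataFrame:
    """Cumulative allele frequencies per generation for one line.

    Returns a DataFrame indexed by snp_id with one column per
    generation g holding the frequency over response animals of
    generations 1..g.  Raises if any generation 1..max has no
    response animals with predicted genotypes.
    """
    cohorts = _cohorts(ped, line)
    if not cohorts:
        raise TrajectoryError(f"no response animals in line {line}")
    gens = sorted(cohorts)
    missing = [g for g in range(1, max(gens) + 1) if g not in cohorts]
    if missing:
        raise TrajectoryError(f"line {line} has no response animals in generations {missing}")
    index = {i: k for k, i in enumerate(avg.ids)}
    cols = None
    if snp_ids is not None:
        sindex = {s: k for k, s in enumerate(avg.snp_ids)}
        cols = [sindex[s] for s in snp_ids]
    sums = None
    counts = None
    out = {}
    for g in gens:
        rows = [index[i] for i in cohorts[g] if i in index]
        if not rows:
            raise TrajectoryError(f"no predicted genotypes for line {line} generation {g}")
        vals = avg.values[rows]
        if cols is not None:
            vals = vals[:, cols]
        s = np.nansum(vals, axis=0)
        c = np.sum(~np.isnan(vals), axis=0)
        sums = s if sums is None else sums + s
        counts = c if counts is None else counts + c
        with np.errstate(invalid="ignore", divide="ignore"):
            out[g] = sums / counts / 2.0
    idx = list(snp_ids) if snp_ids is not None else avg.snp_ids
    return pd.DataFrame(out, index=idx)


def slope_test(frequencies, generations=None) -> tuple[float, float, float]:
    """Least-squares slope of frequency on generation with a Wald test.

    Returns (slope, se, p).  p uses a t reference with n-2 df; a zero
    residual variance (exact line) is guarded to a tiny epsilon so the
    p-value degenerates to ~0 for a nonzero slope.  A constant series
    returns slope 0, p 1.
    """
    f = np.asarray(frequencies, dtype=float)
    ok = np.isfinite(f)
    g = np.arange(1, len(f) + 1, dtype=float) if generations is None else np.asarray(generations, float)
    f, g = f[ok], g[ok]
    if len(f) < 3:
        raise TrajectoryError("need at least 3 points for the slope test")
    if np.ptp(f) == 0:
        return 0.0, 0.0, 1.0
    n = len(f)
    gc = g - g.mean()
    sxx = float(np.sum(gc * gc))
    slope = float(np.sum(gc * (f - f.mean())) / sxx)
    resid = f - f.mean() - slope * gc
    s2 = float(np.sum(resid * resid) / (n - 2))
    se = float(np.sqrt(max(s2, 1e-300) / sxx))
    tstat = slope / se
    p = float(2 * stats.t.sf(abs(tstat), df=n - 2))
    return slope, se, p


def fit_trajectory(
    avg: AverageGenotypeMatrix | GenotypeMatrix,
    ped: pd.DataFrame,
    snp_id: str,
    line: str,
) -> TrajectoryFit:
    freqs = cumulative_frequencies(avg, ped, line, snp_ids=[snp_id]).iloc[0].to_numpy()
    slope, se, p = slope_test(freqs)
    return TrajectoryFit(snp_id=snp_id, line=line, frequencies=freqs,
                         slope=slope, slope_se=se, wald_p=p)


def classify_evolution(
    fit_hrfi: TrajectoryFit, fit_lrfi: TrajectoryFit, n_generations: int = 9
) -> EvolutionRecord:
    """Four-way classification of a marker's frequency evolution.

    The evolution score counts only significant slopes (non-significant
    slopes contribute 0), scaled by the number of generations.
    """
    if fit_hrfi.snp_id != fit_lrfi.snp_id:
        raise TrajectoryError("line fits are for different markers")
    sig_h, sig_l = fit_hrfi.significant, fit_lrfi.significant
    if not sig_h and not sig_l:
        category, changed = "no_change", None
    elif sig_h and sig_l:
        same = np.sign(fit_hrfi.slope) == np.sign(fit_lrfi.slope)
        category, changed = ("co_selected" if same else "opposite"), None
    else:
        category = "one_line_only"
        changed = "HRFI" if sig_h else "LRFI"
    score = n_generations * (
        (abs(fit_hrfi.slope) if sig_h else 0.0) + (abs(fit_lrfi.slope) if sig_l else 0.0)
    )
    return EvolutionRecord(
        snp_id=fit_hrfi.snp_id, category=category, changed_line=changed,
        evolution_score=float(score),
        slope_hrfi=fit_hrfi.slope, slope_lrfi=fit_lrfi.slope,
        p_hrfi=fit_hrfi.wald_p, p_lrfi=fit_lrfi.wald_p,
    )


def g1_line_difference(
    avg: AverageGenotypeMatrix | GenotypeMatrix, ped: pd.DataFrame, snp_id: str
) -> float:
    """|freq_HRFI - freq_LRFI| among generation-1 response animals."""
    vals = {}
    for line in LINES:
        cohorts = _cohorts(ped, line)
        if 1 not in cohorts:
            raise TrajectoryError(f"no generation-1 response animals in line {line}")
        index = {i: k for k, i in enumerate(avg.ids)}
        rows = [index[i] for i in cohorts[1] if i in index]
        j = avg.snp_ids.index(snp_id)
        vals[line] = float(np.nanmean(avg.values[rows, j]) / 2.0)
    return abs(vals["HRFI"] - vals["LRFI"])


def evolution_records(
    avg: AverageGenotypeMatrix | GenotypeMatrix,
    ped: pd.DataFrame,
    snp_ids,
    n_generations: int = 9,
) -> list[EvolutionRecord]:
    """Trajectory fits + classification for a set of tagged markers."""
    records = []
    freq_by_line = {
        line: cumulative_frequencies(avg, ped, line, snp_ids=snp_ids) for line in LINES
    }
    for snp in snp_ids:
        fits = {}
        for line in LINES:
            f = freq_by_line[line].loc[snp].to_numpy()
            slope, se, p = slope_test(f)
            fits[line] = TrajectoryFit(snp, line, f, slope, se, p)
        rec = classify_evolution(fits["HRFI"], fits["LRFI"], n_generations)
        rec.g1_line_freq_difference = g1_line_difference(avg, ped, snp)
        records.append(rec)
    return records


def records_table(records: list[EvolutionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp_id": r.snp_id, "category": r.category,
                "changed_line": r.changed_line or "",
                "evolution_score": r.evolution_score,
                "slope_HRFI": r.slope_hrfi, "slope_LRFI": r.slope_lrfi,
                "p_HRFI": r.p_hrfi, "p_LRFI": r.p_lrfi,
                "g1_line_freq_difference": r.g1_line_freq_difference,
            }
            for r in records
        ],
        columns=["snp_id", "category", "changed_line", "evolution_score",
                 "slope_HRFI", "slope_LRFI", "p_HRFI", "p_LRFI",
                 "g1_line_freq_difference"],
    )


def trait_evolution_summary(
    records_by_trait: dict[str, list[EvolutionRecord]],
    line_differences_sigma_g: dict[str, float],
) -> tuple[pd.DataFrame, float]:
    """Per-trait mean evolution score and its correlation with the
    realized genetic line differences (in sigma_g units).

    Traits with no tagged marker are omitted (logged).  The Pearson
    correlation is NaN (with a warning) when either side has zero
    variance or fewer than 3 traits are summarised.
    """
    rows = []
    for trait, recs in records_by_trait.items():
        if not recs:
            logger.info("trait %s has no SNP-QTL; omitted from the evolution summary", trait)
            continue
        rows.append(
            {
                "trait": trait,
                "n_snp_qtl": len(recs),
                "mean_evolution_score": float(np.mean([r.evolution_score for r in recs])),
                "line_difference_sigma_g": float(line_differences_sigma_g.get(trait, np.nan)),
            }
        )
    summary = pd.DataFrame(rows, columns=["trait", "n_snp_qtl", "mean_evolution_score",
                                          "line_difference_sigma_g"])
    usable = summary.dropna(subset=["line_difference_sigma_g"])
    corr = np.nan
    if len(usable) >= 3:
        x = usable["mean_evolution_score"].to_numpy()
        y = usable["line_difference_sigma_g"].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("evolution-score correlation undefined (zero variance)")
        else:
            corr = float(stats.pearsonr(x, y)[0])
    elif len(usable) == 2:
        x = usable["mean_evolution_score"].to_numpy()
        y = usable["line_difference_sigma_g"].to_numpy()
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            corr = float(np.sign(np.corrcoef(x, y)[0, 1]))
    else:
        logger.warning("fewer than 2 traits with SNP-QTL; correlation undefined")
    return summary, corr


# ---------------------------------------------------------------------------
# Wright-Fisher drift baselines


def drift_sd(p0: float, n_e: int, t: int) -> float:
    """Closed-form SD of the allele frequency after t generations of drift."""
    if not (0 < p0 < 1):
        raise TrajectoryError(f"p0={p0} must be in (0, 1)")
    if n_e < 1 or t < 0:
        raise TrajectoryError("need n_e >= 1 and t >= 0")
    return float(np.sqrt(p0 * (1 - p0) * (1 - (1 - 1 / (2 * n_e)) ** t)))


def wright_fisher_frequencies(
    p0: float, n_e: int, t: int, n_replicates: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Binomial-resampling Wright-Fisher simulation of final frequencies."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.full(n_replicates, p0)
    for _ in range(t):
        p = rng.binomial(2 * n_e, p) / (2 * n_e)
    return p


def drift_sd_mc(
    p0: float, n_e: int, t: int, n_replicates: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo companion of :func:`drift_sd`."""
    return float(np.std(wright_fisher_frequencies(p0, n_e, t, n_replicates, seed)))
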