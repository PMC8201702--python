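"""Forward-in-time simulator of a two-line divergent selection experiment.

The simulated design mirrors a closed divergent selection scheme on a
residual-feed-intake-like trait: lines are founded from a set of F0
matings; in every generation each line tests a batch of boars on the
selected trait and keeps the most extreme ones (high in the HRFI line,
low in the LRFI line) as sires, while dams are chosen at random; each
generation also produces "response" animals -- phenotyped sibs that are
never genotyped in the analysis pipeline (their true genotypes are kept
for validation only).

Genetics: biallelic SNPs on autosomes; founder allele frequencies drawn
independently per SNP from a configurable range (no ancestral LD --
linkage disequilibrium accrues from the pedigree bottleneck);
recombination with Poisson crossover counts (Haldane, no interference).
Phenotypes combine planted QTL effects, a pedigree-correlated polygenic
value and an independent residual; non-selected traits are tied to the
selected trait through a single-factor genetic correlation structure.
Phenotypic variance is 1 per trait, so effects are in phenotypic SD
units.

Polygenic values follow the standard recursive rule: the parent
average plus a Mendelian-sampling deviation with variance
0.5 * sigma_g^2 * (1 - (F_sire + F_dam)/2); inbreeding coefficients are
tracked on the fly from parental coancestry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import traits as trait_defaults
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

LINES = ("HRFI", "LRFI")


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Configuration of the breeding-scheme simulator.

    Defaults follow the design of the source experiment: lines founded
    from 30 F0 matings (116 G0 males tested), 6 selected sires and 40
    random dams per line per generation, 96 tested males per line per
    generation, 9 generations, response cohorts of 96/line/generation
    in G1-G5 and 175/line/generation in G6-G9.  The genome is a
    desk-scale stand-in (a few autosomes, ~1 SNP/Mb); scale it up or
    down freely -- the breeding structure, not the marker count, drives
    the population genetics.
    """

    n_chromosomes: int = 5
    chrom_length_mb: float = 100.0
    n_snps_per_chrom: int = 100
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    n_founder_matings: int = 30
    n_tested_males: int = 96
    n_tested_males_g0: int = 116
    n_selected_sires: int = 6
    n_dams: int = 40
    n_generations: int = 9
    response_counts: tuple[int, ...] = (96, 96, 96, 96, 96, 175, 175, 175, 175)
    n_qtl: int = 0
    qtl_effects: tuple[float, ...] | None = None
    traits: tuple[str, ...] = trait_defaults.TRAIT_NAMES
    selected_trait: str = trait_defaults.SELECTED_TRAIT
    h2_by_trait: dict[str, float] = field(
        default_factory=lambda: dict(trait_defaults.H2_BY_TRAIT)
    )
    genetic_corr_to_selected: dict[str, float] = field(
        default_factory=lambda: dict(trait_defaults.DEFAULT_CORR_TO_SELECTED)
    )
    recomb_rate_cm_per_mb: float = 1.0
    selection: bool = True  # False: sires drawn at random (drift-only scheme)
    sex_effect: float = 0.25
    cg_effect_sd: float = 0.30
    cg_size: int = 45
    seed: int = 0

    def validate(self) -> None:
        if self.n_selected_sires > min(self.n_tested_males, self.n_tested_males_g0):
            raise ConfigError(
                f"cannot select {self.n_selected_sires} sires from "
                f"{min(self.n_tested_males, self.n_tested_males_g0)} tested males"
            )
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"founder_maf_range {self.founder_maf_range} not within (0, 0.5]")
        if len(self.response_counts) != self.n_generations:
            raise ConfigError(
                f"response_counts has {len(self.response_counts)} entries for "
                f"{self.n_generations} generations"
            )
        if self.selected_trait not in self.traits:
            raise ConfigError(f"selected trait {self.selected_trait!r} not in traits")
        for t in self.traits:
            h2 = self.h2_by_trait.get(t)
            if h2 is None or not (0 <= h2 <= 1):
                raise ConfigError(f"h2 for trait {t!r} missing or outside [0, 1]")
            r = self._corr(t)
            if abs(r) > 1:
                raise ConfigError(
                    f"genetic correlation matrix not positive semi-definite: "
                    f"|corr({t}, {self.selected_trait})| = {abs(r)} > 1"
                )
        if self.n_qtl > 0 and (
            self.qtl_effects is None or len(self.qtl_effects) != self.n_qtl
        ):
            raise ConfigError("qtl_effects must provide one effect per planted QTL")
        if self.n_dams < 1 or self.n_founder_matings < 1 or self.n_generations < 1:
            raise ConfigError("counts must be positive")

    def _corr(self, t: str) -> float:
        if t == self.selected_trait:
            return 1.0
        return float(self.genetic_corr_to_selected.get(t, 0.0))


@dataclass
class SimOutput:
    """Everything the downstream pipeline (and its validation) needs."""

    pedigree: pd.DataFrame
    breeder_genotypes: GenotypeMatrix
    snp_map: pd.DataFrame
    phenotypes: pd.DataFrame
    true_qtl: pd.DataFrame  # snp_id, trait, effect, founder_freq
    response_genotypes: GenotypeMatrix  # truth, withheld from the pipeline
    breeder_phenotypes: pd.DataFrame  # selected-trait phenotype of breeders
    founder_freq: pd.Series
    config: SimConfig


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _build_genome(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        top = int(config.chrom_length_mb * 1e6)
        pos = np.array([], dtype=np.int64)
        while len(pos) < config.n_snps_per_chrom:
            extra = rng.integers(1, top, size=2 * config.n_snps_per_chrom)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=config.n_snps_per_chrom, replace=False))
        for k, p in enumerate(pos):
            rows.append((f"c{c}s{k + 1}", str(c), int(p), "A", "B"))
    return pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos_bp", "allele_counted", "allele_other"]
    )


class _Meiosis:
    """Gamete formation with per-chromosome Poisson crossovers (Haldane)."""

    def __init__(self, snp_map: pd.DataFrame, length_mb: float, rate_cm_per_mb: float):
        self.slices: list[tuple[slice, np.ndarray]] = []
        start = 0
        for _, grp in snp_map.groupby("chrom", sort=False):
            sl = slice(start, start + len(grp))
            self.slices.append((sl, grp["pos_bp"].to_numpy(float)))
            start += len(grp)
        self.len_bp = length_mb * 1e6
        self.mean_xo = length_mb * rate_cm_per_mb / 100.0

    def gamete(self, haps: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(haps.shape[1], dtype=np.int8)
        for sl, pos in self.slices:
            k = rng.poisson(self.mean_xo)
            start = rng.integers(2)
            if k == 0:
                out[sl] = haps[start, sl]
                continue
            xo = np.sort(rng.uniform(0, self.len_bp, size=k))
            src = (start + np.searchsorted(xo, pos)) % 2
            seg = haps[:, sl]
            out[sl] = seg[src, np.arange(len(pos))]
        return out


def simulate_experiment(config: SimConfig) -> SimOutput:
    """Run the two-line breeding scheme G0 -> G{n_generations}."""
    config.validate()
    seed = config.seed
    genome = _build_genome(config, _rng(seed, 0))
    m = len(genome)
    meiosis = _Meiosis(genome, config.chrom_length_mb, config.recomb_rate_cm_per_mb)

    traits = list(config.traits)
    n_t = len(traits)
    sel = traits.index(config.selected_trait)
    h2 = np.array([config.h2_by_trait[t] for t in traits])
    corr = np.array([config._corr(t) for t in traits])

    rng_f = _rng(seed, 1)
    founder_freq = rng_f.uniform(*config.founder_maf_range, size=m)

    # planted QTL (on the selected trait)
    if config.n_qtl > 0:
        qtl_idx = np.sort(rng_f.choice(m, size=config.n_qtl, replace=False))
        qtl_eff = np.asarray(config.qtl_effects, dtype=float)
    else:
        qtl_idx = np.array([], dtype=int)
        qtl_eff = np.array([])
    var_qtl = float(
        np.sum(2 * founder_freq[qtl_idx] * (1 - founder_freq[qtl_idx]) * qtl_eff ** 2)
    )
    sigma_g2 = h2.copy()
    sigma_g2[sel] = h2[sel] - var_qtl
    if sigma_g2[sel] < -1e-9:
        raise ConfigError(
            f"planted QTL variance {var_qtl:.3f} exceeds h2={h2[sel]} of the selected trait"
        )
    sigma_g2[sel] = max(sigma_g2[sel], 0.0)
    sigma_g = np.sqrt(sigma_g2)
    corr_mat = np.outer(corr, corr)
    np.fill_diagonal(corr_mat, 1.0)
    cov_g = corr_mat * np.outer(sigma_g, sigma_g)
    chol_g = np.linalg.cholesky(cov_g + 1e-12 * np.eye(n_t))
    resid_sd = np.sqrt(1.0 - h2)

    def qtl_value(dosage: np.ndarray) -> float:
        if qtl_idx.size == 0:
            return 0.0
        return float(np.dot(dosage[qtl_idx] - 2 * founder_freq[qtl_idx], qtl_eff))

    # ---- founders (F0): parents of the founding matings, unrelated
    n_f = config.n_founder_matings
    haps: dict[str, np.ndarray] = {}
    bv: dict[str, np.ndarray] = {}
    ped_rows: list[tuple] = []
    f0_sires = [f"F0_M{k + 1:03d}" for k in range(n_f)]
    f0_dams = [f"F0_F{k + 1:03d}" for k in range(n_f)]
    for ids, sex in ((f0_sires, "M"), (f0_dams, "F")):
        for i in ids:
            haps[i] = (rng_f.random((2, m)) < founder_freq).astype(np.int8)
            bv[i] = chol_g @ rng_f.standard_normal(n_t)
            ped_rows.append((i, "0", "0", sex, "F0", -1, "breeder"))

    # kinship bookkeeping: k_ii = 0.5 (1 + F_i); offspring F = k(sire, dam)
    kin_ids = f0_sires + f0_dams
    kin_index = {i: k for k, i in enumerate(kin_ids)}
    kin = 0.5 * np.eye(2 * n_f)

    def child_kinship(pairs: list[tuple[str, str]]) -> np.ndarray:
        """Kinship matrix of a set of offspring given parental kinship."""
        si = np.array([kin_index[s] for s, _ in pairs])
        di = np.array([kin_index[d] for _, d in pairs])
        knew = 0.25 * (
            kin[np.ix_(si, si)] + kin[np.ix_(si, di)]
            + kin[np.ix_(di, si)] + kin[np.ix_(di, di)]
        )
        np.fill_diagonal(knew, 0.5 * (1.0 + kin[si, di]))
        return knew

    def make_offspring(ident, sire, dam, rng) -> None:
        haps[ident] = np.stack([meiosis.gamete(haps[sire], rng), meiosis.gamete(haps[dam], rng)])
        f_par = 0.5 * ((2 * kin[kin_index[sire], kin_index[sire]] - 1)
                       + (2 * kin[kin_index[dam], kin_index[dam]] - 1))
        mend = np.sqrt(max(0.5 * (1 - f_par), 0.0)) * (chol_g @ rng.standard_normal(n_t))
        bv[ident] = 0.5 * (bv[sire] + bv[dam]) + mend

    def selected_phenotype(ident, rng) -> float:
        dosage = haps[ident].sum(axis=0)
        return qtl_value(dosage) + bv[ident][sel] + resid_sd[sel] * rng.standard_normal()

    # ---- G0 cohort: line foundation from the F0 matings
    rng0 = _rng(seed, 2)
    matings0 = list(zip(f0_sires, f0_dams))
    male_tmp = [f"tmpM{k}" for k in range(config.n_tested_males_g0)]
    female_tmp = [f"tmpF{k}" for k in range(2 * config.n_dams)]
    parents_of: dict[str, tuple[str, str]] = {}
    for k, ident in enumerate(male_tmp + female_tmp):
        s, d = matings0[k % n_f]
        parents_of[ident] = (s, d)
        make_offspring(ident, s, d, rng0)
    pheno0 = {i: selected_phenotype(i, rng0) for i in male_tmp + female_tmp}
    if config.selection:
        ranked = sorted(male_tmp, key=lambda i: pheno0[i])
    else:
        ranked = list(male_tmp)
        rng0.shuffle(ranked)
    chosen_sires = {"HRFI": ranked[-config.n_selected_sires:], "LRFI": ranked[: config.n_selected_sires]}
    females = list(female_tmp)
    rng0.shuffle(females)
    chosen_dams = {"HRFI": females[: config.n_dams], "LRFI": females[config.n_dams: 2 * config.n_dams]}

    breeders: dict[str, dict[str, list[str]]] = {ln: {} for ln in LINES}
    breeder_pheno_rows: list[tuple] = []
    renamed: dict[str, str] = {}
    for ln in LINES:
        seq = 0
        for tmp, sex in [(i, "M") for i in chosen_sires[ln]] + [(i, "F") for i in chosen_dams[ln]]:
            seq += 1
            ident = f"{ln}_G0_{seq:04d}"
            renamed[tmp] = ident
            haps[ident] = haps.pop(tmp)
            bv[ident] = bv.pop(tmp)
            s, d = parents_of[tmp]
            ped_rows.append((ident, s, d, sex, ln, 0, "breeder"))
            breeder_pheno_rows.append((ident, ln, 0, pheno0[tmp]))
        breeders[ln] = {
            "sires": [renamed[i] for i in chosen_sires[ln]],
            "dams": [renamed[i] for i in chosen_dams[ln]],
        }
    # drop unselected G0 candidates
    for tmp in male_tmp + female_tmp:
        haps.pop(tmp, None)
        bv.pop(tmp, None)

    new_ids = [renamed[i] for ln in LINES for i in chosen_sires[ln] + chosen_dams[ln]]
    pairs = []
    for ln in LINES:
        for i in chosen_sires[ln] + chosen_dams[ln]:
            pairs.append(parents_of[i])
    kin_new = child_kinship(pairs)
    kin, kin_ids = kin_new, new_ids
    kin_index = {i: k for k, i in enumerate(kin_ids)}

    # ---- generations 1 .. n
    response_ids: list[str] = []
    pheno_rows: list[dict] = []
    for g in range(1, config.n_generations + 1):
        all_new_breeders: list[str] = []
        all_new_pairs: list[tuple[str, str]] = []
        next_breeders: dict[str, dict[str, list[str]]] = {}
        for ln_i, ln in enumerate(LINES):
            rng = _rng(seed, 3, g, ln_i)
            sires = breeders[ln]["sires"]
            dams = list(breeders[ln]["dams"])
            rng.shuffle(dams)
            sire_of = {d: sires[k % len(sires)] for k, d in enumerate(dams)}
            last = g == config.n_generations
            n_lit = len(dams)
            seq = 0

            def spawn(sex_label):
                nonlocal seq
                seq += 1
                return f"{ln}_G{g}_{seq:04d}", sex_label

            # candidate males / females (not needed in the final generation)
            males, females_c = [], []
            if not last:
                for k in range(config.n_tested_males):
                    ident, sex = spawn("M")
                    d = dams[k % n_lit]
                    make_offspring(ident, sire_of[d], d, rng)
                    males.append((ident, sire_of[d], d))
                for k in range(2 * config.n_dams):
                    ident, sex = spawn("F")
                    d = dams[k % n_lit]
                    make_offspring(ident, sire_of[d], d, rng)
                    females_c.append((ident, sire_of[d], d))
            # response animals; contemporary groups (~cg_size animals born the
            # same week, tested together) span both lines, as in a design
            # where the lines share the testing unit
            n_resp = config.response_counts[g - 1]
            cg_effects: dict[str, np.ndarray] = {}
            per_line_batch = max(1, config.cg_size // 2)
            for k in range(n_resp):
                ident, _ = spawn("R")
                d = dams[k % n_lit]
                s = sire_of[d]
                make_offspring(ident, s, d, rng)
                sex = "F" if k % 2 == 0 else "C"  # females and castrated males
                cg_num = k // per_line_batch
                cg = f"G{g}_B{cg_num}"
                if cg not in cg_effects:
                    cg_effects[cg] = config.cg_effect_sd * _rng(
                        config.seed, 5, g, cg_num
                    ).standard_normal(n_t)
                dosage = haps[ident].sum(axis=0)
                y = (
                    bv[ident]
                    + resid_sd * rng.standard_normal(n_t)
                    + cg_effects[cg]
                    + (config.sex_effect if sex == "F" else 0.0)
                )
                y[sel] += qtl_value(dosage)
                pen = int(rng.choice([10, 12, 14]))
                row = {
                    "id": ident, "line": ln, "generation": g, "sex": sex,
                    "contemporary_group": cg, "pen_size": pen,
                    "slaughter_age": float(np.round(rng.normal(170, 5), 1)),
                }
                y += 0.02 * (pen - 12)
                for t_i, t in enumerate(traits):
                    row[t] = float(y[t_i])
                pheno_rows.append(row)
                ped_rows.append((ident, s, d, sex, ln, g, "response"))
                response_ids.append(ident)
            # selection for the next generation
            if not last:
                phen = {i: selected_phenotype(i, rng) for i, _, _ in males + females_c}
                if config.selection:
                    order = sorted(males, key=lambda rec: phen[rec[0]])
                else:
                    order = list(males)
                    rng.shuffle(order)
                chosen = order[-config.n_selected_sires:] if ln == "HRFI" else order[: config.n_selected_sires]
                rng.shuffle(females_c)
                chosen_d = females_c[: config.n_dams]
                next_breeders[ln] = {
                    "sires": [i for i, _, _ in chosen],
                    "dams": [i for i, _, _ in chosen_d],
                }
                for i, s, d in chosen + chosen_d:
                    sex = "M" if (i, s, d) in chosen else "F"
                    ped_rows.append((i, s, d, sex, ln, g, "breeder"))
                    all_new_breeders.append(i)
                    all_new_pairs.append((s, d))
                for i, _, _ in chosen + chosen_d:
                    breeder_pheno_rows.append((i, ln, g, phen[i]))
                # drop unselected candidates
                keep = {i for i, _, _ in chosen + chosen_d}
                for i, _, _ in males + females_c:
                    if i not in keep:
                        haps.pop(i, None)
                        bv.pop(i, None)
        if all_new_breeders:
            kin = child_kinship(all_new_pairs)
            kin_ids = all_new_breeders
            kin_index = {i: k for k, i in enumerate(kin_ids)}
            breeders = next_breeders

    pedigree = pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "sex", "line", "generation", "role"])
    breeder_ids = list(pedigree.loc[pedigree["role"] == "breeder", "id"])
    bg = GenotypeMatrix(
        breeder_ids, genome.copy(),
        np.stack([haps[i].sum(axis=0) for i in breeder_ids]).astype(float),
    )
    rg = GenotypeMatrix(
        response_ids, genome.copy(),
        np.stack([haps[i].sum(axis=0) for i in response_ids]).astype(float),
    )
    true_qtl = pd.DataFrame(
        {
            "snp_id": genome["snp_id"].to_numpy()[qtl_idx],
            "trait": config.selected_trait,
            "effect": qtl_eff,
            "founder_freq": founder_freq[qtl_idx],
        }
    )
    return SimOutput(
        pedigree=pedigree,
        breeder_genotypes=bg,
        snp_map=genome,
        phenotypes=pd.DataFrame(pheno_rows),
        true_qtl=true_qtl,
        response_genotypes=rg,
        breeder_phenotypes=pd.DataFrame(
            breeder_pheno_rows, columns=["id", "line", "generation", config.selected_trait]
        ),
        founder_freq=pd.Series(founder_freq, index=genome["snp_id"], name="founder_freq"),
        config=config,
    )


def inject_missingness(
    gm: GenotypeMatrix, snp_miss_rate: float, ind_miss_rate: float, seed: int
) -> GenotypeMatrix:
    """Independent Bernoulli masking of genotype calls.

    ``snp_miss_rate`` masks calls uniformly at random across the whole
    matrix (per-call missingness); ``ind_miss_rate`` additionally masks
    whole random cells per individual at the given rate.  The input is
    left untouched.
    """
    for r in (snp_miss_rate, ind_miss_rate):
        if not (0 <= r < 1):
            raise ConfigError(f"missingness rate {r} outside [0, 1)")
    rng = np.random.default_rng(seed)
    vals = gm.values.copy()
    if snp_miss_rate > 0:
        vals[rng.random(vals.shape) < snp_miss_rate] = np.nan
    if ind_miss_rate > 0:
        vals[rng.random(vals.shape) < ind_miss_rate] = np.nan
    return GenotypeMatrix(list(gm.ids), gm.snp_map.copy(), vals)


def scaled_config(**overrides) -> SimConfig:
    """Convenience: paper-structure config with keyword overrides."""
    return replace(SimConfig(), **overrides)
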