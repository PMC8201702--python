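"""Derived feed-efficiency traits and fixed-effect pre-adjustment.

Residual feed intake (RFI) is the part of daily feed intake not
explained by production (growth, lean deposition) and maintenance
(metabolic body weight) requirements.  The design's operational
definitions:

* average metabolic body weight over the test, AMBW =
  (BW1^1.6 - BW0^1.6) / (1.6 * (BW1 - BW0)), the time-average of
  BW^0.6 under linear growth between BW0 and BW1;
* lean meat content, LMC(%) = 25.08 - 1.23*backfat% + 0.87*loin% +
  0.73*ham%;
* RFI = DFI - 1.48*ADG + 23.2*LMC - 99.1*AMBW, with the published
  coefficients taken as fixed constants (signs as published; a flag
  selects the conventional all-minus regression form, and the
  coefficients can be re-estimated from data for synthetic tables).

Before association, phenotypes are pre-adjusted by per-trait ordinary
least squares on the stated fixed effects and covariates; the
residuals become the working phenotypes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


def ambw(bw0, bw1):
    """Average metabolic body weight (kg^0.75-scale) over the test period."""
    bw0 = np.asarray(bw0, dtype=float)
    bw1 = np.asarray(bw1, dtype=float)
    if np.any(bw0 <= 0) or np.any(bw1 <= bw0):
        raise ValueError("requires BW1 > BW0 > 0")
    out = (bw1 ** 1.6 - bw0 ** 1.6) / (1.6 * (bw1 - bw0))
    return out if out.ndim else float(out)


def lmc(backfat_pct, loin_pct, ham_pct):
    """Lean meat content (%) from carcass component percentages."""
    out = (
        25.08
        - 1.23 * np.asarray(backfat_pct, dtype=float)
        + 0.87 * np.asarray(loin_pct, dtype=float)
        + 0.73 * np.asarray(ham_pct, dtype=float)
    )
    return out if out.ndim else float(out)


def rfi(dfi, adg, lmc_value, ambw_value, conventional_signs: bool = False):
    """Residual feed intake from its published fixed-coefficient equation.

    With ``conventional_signs=True`` all predicted-intake terms are
    subtracted (DFI - 1.48*ADG - 23.2*LMC - 99.1*AMBW), the usual
    residual-from-regression form.
    """
    dfi = np.asarray(dfi, dtype=float)
    adg = np.asarray(adg, dtype=float)
    lmc_value = np.asarray(lmc_value, dtype=float)
    ambw_value = np.asarray(ambw_value, dtype=float)
    s = -1.0 if conventional_signs else 1.0
    out = dfi - 1.48 * adg + s * 23.2 * lmc_value - 99.1 * ambw_value
    return out if out.ndim else float(out)


def estimate_rfi_coefficients(table: pd.DataFrame) -> dict:
    """Re-estimate the RFI regression on a supplied table.

    Multiple regression of DFI on ADG, LMC and AMBW; returns the
    coefficients and the residual (an RFI in the conventional sense).
    Column names: DFI, ADG, LMC, AMBW.
    """
    x = sm.add_constant(table[["ADG", "LMC", "AMBW"]])
    fit = sm.OLS(table["DFI"], x, missing="drop").fit()
    return {
        "intercept": float(fit.params["const"]),
        "ADG": float(fit.params["ADG"]),
        "LMC": float(fit.params["LMC"]),
        "AMBW": float(fit.params["AMBW"]),
        "residuals": table["DFI"] - fit.predict(x),
    }


def adjust_phenotypes(
    phenos: pd.DataFrame,
    model_spec: dict[str, dict],
    id_col: str = "id",
) -> pd.DataFrame:
    """Per-trait OLS pre-adjustment for fixed effects and covariates.

    ``model_spec`` maps trait -> {"fixed": [categorical columns],
    "covariates": [numeric columns]}.  Rows with a missing trait value
    or missing model column are dropped per trait (and logged);
    aliased (collinear) dummy columns are dropped with a warning
    rather than failing.  Returns a DataFrame indexed by animal id
    with one residual column per trait (NaN where not fitted).
    """
    out = pd.DataFrame(index=phenos[id_col].astype(str))
    out.index.name = id_col
    for trait, spec in model_spec.items():
        if trait not in phenos.columns:
            raise KeyError(f"trait column {trait!r} not in phenotype table")
        fixed = list(spec.get("fixed", []))
        covs = list(spec.get("covariates", []))
        for c in fixed + covs:
            if c not in phenos.columns:
                raise KeyError(f"model column {c!r} not in phenotype table")
        cols = [id_col, trait] + fixed + covs
        sub = phenos[cols].dropna()
        n_drop = len(phenos) - len(sub)
        if n_drop:
            logger.info("%s: dropped %d rows with missing values", trait, n_drop)
        parts = [pd.Series(1.0, index=sub.index, name="const")]
        for c in fixed:
            d = pd.get_dummies(sub[c].astype(str), prefix=c, drop_first=True, dtype=float)
            parts.append(d)
        for c in covs:
            parts.append(sub[c].astype(float))
        design = pd.concat(parts, axis=1)
        rank = np.linalg.matrix_rank(design.to_numpy())
        if rank < design.shape[1]:
            logger.warning(
                "%s: design is rank-deficient (%d < %d); aliased levels dropped",
                trait, rank, design.shape[1],
            )
            keep = _independent_columns(design.to_numpy())
            design = design.iloc[:, keep]
        fit = sm.OLS(sub[trait].astype(float), design).fit()
        res = pd.Series(fit.resid.to_numpy(), index=sub[id_col].astype(str), name=trait)
        out[trait] = res
    return out


def _independent_columns(x: np.ndarray) -> list[int]:
    keep: list[int] = []
    for j in range(x.shape[1]):
        cand = keep + [j]
        if np.linalg.matrix_rank(x[:, cand]) == len(cand):
            keep.append(j)
    return keep
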