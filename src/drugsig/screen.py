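"""Per-probe two-way fixed-effects ANOVA screen for drug-responsive transcripts.

Each probe is tested with a balanced two-way ANOVA with a treatment
factor (every drug plus the vehicle groups as levels; the naive group
is excluded) and a time factor, including their interaction.  On the
full study design of 20 treatment levels × 4 time-points the degrees
of freedom are 19 (drug), 3 (time) and 57 (interaction).  P values from
the drug main effect are corrected with Bonferroni and
Benjamini-Hochberg, and the total number of true positives is estimated
over a grid of FDR thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .synthetic import NAIVE_LABEL


@dataclass
class ScreenResult:
    """Per-probe F statistics, P values and multiplicity-adjusted P values."""

    table: pd.DataFrame  # probe × [F_drug, p_drug, F_time, p_time, F_int, p_int, p_bonf, p_bh]
    df_drug: int
    df_time: int
    df_interaction: int
    df_residual: int

    def significant(self, column: str = "p_bonf", alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table[column] <= alpha]

    def write(self, path) -> None:
        self.table.rename_axis("probe_id").to_csv(path, sep="\t")


def _check_balanced(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
    drugs = pd.Categorical(design["drug"])
    times = pd.Categorical(design["time_h"])
    counts = pd.crosstab(drugs, times)
    if counts.shape[0] < 2 or counts.shape[1] < 1:
        raise ValueError("need >= 2 treatment levels")
    n = counts.to_numpy()
    if (n != n[0, 0]).any():
        raise ValueError(
            "unbalanced design: replicate counts per drug × time cell differ "
            f"(min {n.min()}, max {n.max()}); rebalance or subset the samples"
        )
    if n[0, 0] < 2:
        raise ValueError("need >= 2 replicates per drug × time cell")
    return drugs.codes, times.codes, int(n[0, 0])


def twoway_anova(em: ExpressionMatrix, exclude: tuple[str, ...] = (NAIVE_LABEL,)) -> ScreenResult:
    """Balanced two-way ANOVA (treatment × time) for every probe at once.

    Sums of squares follow the standard fixed-effects decomposition
    (equivalent to type I/II/III in a balanced design).  The treatment
    factor includes vehicle groups as levels; groups named in
    ``exclude`` (the naive arm by default) are dropped first.
    """
    keep = ~em.samples["drug"].isin(exclude)
    design = em.samples.loc[keep]
    Y = em.values.loc[:, keep.index[keep]].to_numpy(dtype=float)
    drug_codes, time_codes, r = _check_balanced(design)
    a, b = int(drug_codes.max()) + 1, int(time_codes.max()) + 1
    n_tot = Y.shape[1]

    grand = Y.mean(axis=1, keepdims=True)
    # cell / marginal means via index accumulation
    cell = np.zeros((Y.shape[0], a, b))
    np.add.at(cell.transpose(1, 2, 0), (drug_codes, time_codes), Y.T)
    cell /= r
    drug_mean = cell.mean(axis=2)
    time_mean = cell.mean(axis=1)

    ss_drug = r * b * ((drug_mean - grand) ** 2).sum(axis=1)
    ss_time = r * a * ((time_mean - grand) ** 2).sum(axis=1)
    ss_cells = r * ((cell - grand[:, :, None]) ** 2).sum(axis=(1, 2))
    ss_int = ss_cells - ss_drug - ss_time
    fitted = cell[:, drug_codes, time_codes]
    ss_err = ((Y - fitted) ** 2).sum(axis=1)

    df_drug, df_time = a - 1, b - 1
    df_int = df_drug * df_time
    df_err = n_tot - a * b
    ms_err = ss_err / df_err

    with np.errstate(divide="ignore", invalid="ignore"):
        F_drug = (ss_drug / df_drug) / ms_err
        F_time = (ss_time / df_time) / ms_err
        F_int = (ss_int / df_int) / ms_err
    p_drug = stats.f.sf(F_drug, df_drug, df_err)
    p_time = stats.f.sf(F_time, df_time, df_err)
    p_int = stats.f.sf(F_int, df_int, df_err)

    table = pd.DataFrame(
        {
            "F_drug": F_drug, "p_drug": p_drug,
            "F_time": F_time, "p_time": p_time,
            "F_int": F_int, "p_int": p_int,
        },
        index=em.values.index,
    )
    table["p_bonf"] = adjust_pvalues(table["p_drug"].to_numpy(), "bonferroni")
    table["p_bh"] = adjust_pvalues(table["p_drug"].to_numpy(), "bh")
    return ScreenResult(
        table=table,
        df_drug=df_drug,
        df_time=df_time,
        df_interaction=df_int,
        df_residual=df_err,
    )


def anova_sums_of_squares(em: ExpressionMatrix, exclude=(NAIVE_LABEL,)) -> pd.DataFrame:
    """Per-probe SS decomposition (drug, time, interaction, residual, total)."""
    keep = ~em.samples["drug"].isin(exclude)
    design = em.samples.loc[keep]
    Y = em.values.loc[:, keep.index[keep]].to_numpy(dtype=float)
    drug_codes, time_codes, r = _check_balanced(design)
    a, b = int(drug_codes.max()) + 1, int(time_codes.max()) + 1
    grand = Y.mean(axis=1, keepdims=True)
    cell = np.zeros((Y.shape[0], a, b))
    np.add.at(cell.transpose(1, 2, 0), (drug_codes, time_codes), Y.T)
    cell /= r
    ss_drug = r * b * ((cell.mean(axis=2) - grand) ** 2).sum(axis=1)
    ss_time = r * a * ((cell.mean(axis=1) - grand) ** 2).sum(axis=1)
    ss_cells = r * ((cell - grand[:, :, None]) ** 2).sum(axis=(1, 2))
    fitted = cell[:, drug_codes, time_codes]
    ss_err = ((Y - fitted) ** 2).sum(axis=1)
    ss_tot = ((Y - grand) ** 2).sum(axis=1)
    return pd.DataFrame(
        {
            "ss_drug": ss_drug,
            "ss_time": ss_time,
            "ss_interaction": ss_cells - ss_drug - ss_time,
            "ss_residual": ss_err,
            "ss_total": ss_tot,
        },
        index=em.values.index,
    )


def adjust_pvalues(pvals, method: str) -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` or ``bh`` (step-up FDR)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}; use 'bonferroni' or 'bh'")
    return multipletests(p, method=key)[1]


def estimate_true_positives(pvals, fdr_grid=None) -> pd.DataFrame:
    """Estimated number of true positives across a range of FDR cutoffs.

    At FDR level q the BH procedure declares R(q) discoveries, of which
    an expected fraction q are false; TP(q) = R(q) * (1 - q) is reported
    as the estimated count of genuinely regulated transcripts.  The
    returned frame carries the grid plus a ``plateau`` attribute (the
    maximum of TP(q) over the grid), summarising the estimated total.
    """
    if fdr_grid is None:
        fdr_grid = np.round(np.arange(0.01, 0.51, 0.01), 4)
    q = np.asarray(fdr_grid, dtype=float)
    if q.size == 0:
        raise ValueError("fdr_grid is empty")
    if np.any((q <= 0) | (q >= 1)) or np.any(np.diff(q) <= 0):
        raise ValueError("fdr_grid must be increasing within (0, 1)")
    p_bh = adjust_pvalues(pvals, "bh")
    R = np.array([(p_bh <= qi).sum() for qi in q])
    tp = R * (1.0 - q)
    out = pd.DataFrame({"fdr": q, "discoveries": R, "true_positives": tp})
    out.attrs["plateau"] = float(tp.max())
    return out
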