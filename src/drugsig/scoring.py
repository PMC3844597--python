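"""Fold changes versus vehicle and the genes2mind gene-selection score.

For every (probe, drug, time-point) the module computes the log2 fold
change against the drug's matched vehicle group and a two-sample
Student's t-test P value.  The genes2mind score combines, per probe i
and drug/time cell (i, j):

    score = 10 * (-log2 p_ij) * log2(f_ij + 1) * (foldmean_i / foldsd_i)

where p_ij is the t-test P value, f_ij = 2^|log2fc| - 1 is the magnitude
of the fold change (symmetric in direction, so swapping drug and vehicle
labels only flips the score's sign), and foldmean/foldsd are the mean
and (n-1) standard
deviation of the signed log2 fold changes across the time-course — a
consistency ratio whose sign carries the direction of regulation.
Consistently down-regulated transcripts therefore receive negative
scores of symmetric magnitude; ranking uses the absolute score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .synthetic import NAIVE_LABEL

#: sentinel for scores that are undefined because foldsd == 0
UNDEFINED_SCORE = np.nan


@dataclass
class FoldChangeTable:
    """Long-format per (probe, drug, time) fold changes and t-test P values.

    ``per_cell`` columns: log2fc, fold (= 2**log2fc), t_p.
    ``per_drug`` columns: foldmean, foldsd (signed log2fc summaries over
    the time-course), indexed by (probe_id, drug).
    """

    per_cell: pd.DataFrame  # index (probe_id, drug, time_h)
    per_drug: pd.DataFrame  # index (probe_id, drug)

    @property
    def drugs(self) -> list:
        return list(self.per_cell.index.get_level_values("drug").unique())

    @property
    def time_points(self) -> list:
        return sorted(self.per_cell.index.get_level_values("time_h").unique())

    @property
    def probes(self) -> pd.Index:
        return self.per_cell.index.get_level_values("probe_id").unique()

    def write(self, path) -> None:
        self.per_cell.join(self.per_drug, on=["probe_id", "drug"]).to_csv(path, sep="\t")


def _resolve_vehicle_map(em: ExpressionMatrix, vehicle_policy, vehicle_map):
    vehicles = sorted(em.samples.loc[em.samples["is_vehicle"], "drug"].unique())
    if not vehicles:
        raise ValueError("no vehicle samples in the experiment")
    drugs = [
        d
        for d in em.samples["drug"].unique()
        if d not in vehicles and d != NAIVE_LABEL
    ]
    if vehicle_policy == "always_saline":
        if "saline" not in vehicles:
            raise ValueError("'always_saline' policy but no 'saline' vehicle present")
        return {d: "saline" for d in drugs}, drugs
    if vehicle_policy == "matched":
        if vehicle_map is None:
            if len(vehicles) == 1:
                return {d: vehicles[0] for d in drugs}, drugs
            raise ValueError(
                "matched vehicle policy with several vehicles requires vehicle_map"
            )
        missing = [d for d in drugs if d not in vehicle_map]
        if missing:
            raise ValueError(f"vehicle_map missing drugs: {missing}")
        return {d: vehicle_map[d] for d in drugs}, drugs
    raise ValueError(f"unknown vehicle_policy {vehicle_policy!r}")


def fold_changes(
    em: ExpressionMatrix,
    vehicle_policy: str = "matched",
    vehicle_map: dict[str, str] | None = None,
) -> FoldChangeTable:
    """Per-time log2 fold changes and equal-variance t-tests vs vehicle.

    Expects a normalized log2-scale matrix.  ``vehicle_policy`` is
    ``"matched"`` (each drug compared with its own control solvent, via
    ``vehicle_map``) or ``"always_saline"``.
    """
    vmap, drugs = _resolve_vehicle_map(em, vehicle_policy, vehicle_map)
    times = sorted(em.samples.loc[em.samples["drug"].isin(drugs), "time_h"].unique())
    probes = em.values.index.rename("probe_id")

    sample_groups = {
        key: list(idx) for key, idx in em.samples.groupby(["drug", "time_h"]).groups.items()
    }
    cell_rows = []
    cell_index = []
    for d in drugs:
        veh = vmap[d]
        for t in times:
            cols_d = sample_groups.get((d, t), [])
            cols_v = sample_groups.get((veh, t), [])
            if len(cols_v) == 0:
                raise ValueError(f"no vehicle {veh!r} samples at time {t}")
            if len(cols_d) < 2 or len(cols_v) < 2:
                raise ValueError(
                    f"need >= 2 replicates for {d!r} and {veh!r} at time {t}"
                )
            X = em.values[cols_d].to_numpy(dtype=float)
            V = em.values[cols_v].to_numpy(dtype=float)
            log2fc = X.mean(axis=1) - V.mean(axis=1)
            t_p = stats.ttest_ind(X, V, axis=1, equal_var=True).pvalue
            t_p = np.where(np.isfinite(t_p), t_p, 1.0)  # zero-variance cells
            cell_rows.append(np.column_stack([log2fc, np.exp2(log2fc), t_p]))
            cell_index.append((d, t))

    per_cell = pd.concat(
        {
            key: pd.DataFrame(
                block, index=probes, columns=["log2fc", "fold", "t_p"]
            )
            for key, block in zip(cell_index, cell_rows)
        },
        names=["drug", "time_h"],
    )
    per_cell = per_cell.reorder_levels(["probe_id", "drug", "time_h"]).sort_index()

    g = per_cell["log2fc"].groupby(level=["probe_id", "drug"])
    per_drug = pd.DataFrame({"foldmean": g.mean(), "foldsd": g.std(ddof=1)})
    return FoldChangeTable(per_cell=per_cell, per_drug=per_drug)


@dataclass
class G2MScoreTable:
    """genes2mind scores at cell, drug and probe granularity."""

    per_cell: pd.DataFrame  # index (probe_id, drug, time_h), column score
    per_drug: pd.Series  # index (probe_id, drug): signed score of max |score| time
    global_score: pd.Series  # index probe_id: signed score of max |score| drug

    def write(self, path) -> None:
        out = self.per_cell.copy()
        out["drug_score"] = self.per_drug.reindex(
            out.index.droplevel("time_h")
        ).to_numpy()
        out["global_score"] = self.global_score.reindex(
            out.index.get_level_values("probe_id")
        ).to_numpy()
        out.to_csv(path, sep="\t")


def _signed_absmax(s: pd.Series, level) -> pd.Series:
    order = s.abs().groupby(level=level)
    idx = order.idxmax()
    return pd.Series(s.loc[idx].to_numpy(), index=idx.index)


def g2m(fct: FoldChangeTable) -> G2MScoreTable:
    """Evaluate the genes2mind score on a complete fold-change table.

    Probes with foldsd = 0 for a drug (identical log2fc at every
    time-point, typically an all-zero profile) get an undefined score
    (NaN sentinel) for that drug and are excluded from ranking.
    """
    cells = fct.per_cell
    summ = fct.per_drug.reindex(cells.index.droplevel("time_h"))
    foldmean = summ["foldmean"].to_numpy()
    foldsd = summ["foldsd"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        consistency = foldmean / foldsd
    n_undef = int((foldsd == 0).sum())
    if n_undef:
        warnings.warn(
            f"{n_undef} (probe, drug) cells have zero fold-change spread; "
            "their scores are undefined and excluded from ranking"
        )
        consistency = np.where(foldsd == 0, UNDEFINED_SCORE, consistency)

    t_p = cells["t_p"].to_numpy()
    # fold-magnitude term, symmetric in direction: 2^|log2fc| - 1 so that
    # swapping drug and vehicle labels leaves |score| unchanged
    magnitude = np.exp2(np.abs(cells["log2fc"].to_numpy())) - 1.0
    score = 10.0 * (-np.log2(np.clip(t_p, 1e-300, 1.0))) * np.log2(magnitude + 1.0) * consistency

    per_cell = pd.DataFrame({"score": score}, index=cells.index)
    valid = per_cell["score"].dropna()
    per_drug = _signed_absmax(valid, ["probe_id", "drug"])
    global_score = _signed_absmax(per_drug, "probe_id")
    return G2MScoreTable(per_cell=per_cell, per_drug=per_drug, global_score=global_score)


def select_transcripts(scores: G2MScoreTable, mode: str, value) -> pd.Index:
    """Rank probes by |global score| and select the top k or all above a threshold.

    Ties are broken by probe id (lexicographic) for a deterministic order.
    """
    s = scores.global_score.dropna()
    order = pd.DataFrame(
        {"mag": s.abs().to_numpy(), "probe_id": s.index.to_numpy()}
    ).sort_values(["mag", "probe_id"], ascending=[False, True])
    ranked = pd.Index(order["probe_id"])
    if mode == "top_k":
        k = int(value)
        if k > len(ranked):
            raise ValueError(f"top_k={k} exceeds the {len(ranked)} scored probes")
        return ranked[:k]
    if mode == "threshold":
        keep = order["mag"] > float(value)
        return pd.Index(order.loc[keep, "probe_id"])
    raise ValueError(f"unknown mode {mode!r}; use 'top_k' or 'threshold'")


def per_drug_counts(scores: G2MScoreTable, threshold: float = 10.0) -> pd.Series:
    """Number of probes per drug with |drug-level score| above ``threshold``."""
    s = scores.per_drug.dropna()
    flags = s.abs() > threshold
    return flags.groupby(level="drug").sum().astype(int).sort_index()


def drug_response_summary(fct: FoldChangeTable) -> pd.DataFrame:
    """Probe × drug matrix of signed log2fc at the time of maximum |log2fc|.

    The per-drug scalar summary of each transcript's response, used both
    for component correlation in drug space and as the expression matrix
    E of the mechanism-inference model.
    """
    s = fct.per_cell["log2fc"]
    idx = s.abs().groupby(level=["probe_id", "drug"]).idxmax()
    flat = pd.Series(s.loc[idx].to_numpy(), index=idx.index)
    return flat.unstack("drug")
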