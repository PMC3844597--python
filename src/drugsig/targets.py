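"""Model-based inference of a drug's pharmacological mechanisms.

Transcriptional effects are modeled bilinearly: the response E[t, d] of
transcript t to drug d is the sum over pharmacological mechanisms m of
A[m, t] * B[d, m], where B holds the drug's engagement of each
mechanism (derived from binding constants) and A the sensitivity of the
transcript to activation of that mechanism.  Given expression responses
of a training drug panel and its binding matrix, A is estimated by
least squares; the model is then reduced to the most sensitive
transcripts per mechanism, and a query drug's mechanism-activation
vector is obtained by regressing its expression signature onto the
reduced sensitivities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def ki_to_binding(ki_table: pd.DataFrame, pki_floor: float = 5.0) -> pd.DataFrame:
    """Turn a drug × mechanism Ki table (nM) into engagement strengths.

    B = max(0, pKi - floor) with pKi = -log10(Ki in molar); the default
    floor of 5 treats affinities weaker than Ki = 10 µM as no
    engagement.  Missing entries mean no measurable affinity (B = 0).
    Smaller Ki (tighter binding) always gives larger B.
    """
    ki = ki_table.astype(float)
    if (ki <= 0).any().any():
        raise ValueError("Ki values must be positive (nM)")
    pki = 9.0 - np.log10(ki)  # Ki in nM -> molar
    B = (pki - pki_floor).clip(lower=0.0).fillna(0.0)
    return B


def fit_sensitivity(
    E: pd.DataFrame, B: pd.DataFrame, ridge: float = 0.0
) -> pd.DataFrame:
    """Least-squares estimate of mechanism × transcript sensitivities A.

    ``E`` is transcripts × drugs (per-drug response summaries), ``B``
    drugs × mechanisms.  Solves min_A ||E - A^T-product|| per transcript;
    when B is rank-deficient the minimum-norm solution is returned.  An
    optional ridge penalty stabilises ill-conditioned binding panels.
    """
    if list(E.columns) != list(B.index):
        if set(E.columns) != set(B.index):
            raise ValueError("E columns and B rows name different drugs")
        B = B.loc[E.columns]
    Bm = B.to_numpy(dtype=float)
    if not Bm.any():
        raise ValueError("binding matrix is all zero")
    Et = E.to_numpy(dtype=float).T  # drugs × transcripts
    if ridge > 0:
        m = Bm.shape[1]
        G = Bm.T @ Bm + ridge * np.eye(m)
        A = np.linalg.solve(G, Bm.T @ Et)
    else:
        A, *_ = np.linalg.lstsq(Bm, Et, rcond=None)
    return pd.DataFrame(A, index=B.columns, columns=E.index)


def reduce_sensitive(A: pd.DataFrame, top_k: int = 50) -> tuple[pd.Index, pd.DataFrame]:
    """Union over mechanisms of the ``top_k`` most sensitive transcripts.

    Sensitivity is |A|; ties break by transcript id for determinism.
    Returns the selected transcript index (sorted) and the reduced A'.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if top_k > A.shape[1]:
        raise ValueError(f"top_k={top_k} exceeds {A.shape[1]} transcripts")
    chosen: set = set()
    for mech in A.index:
        row = A.loc[mech]
        order = (
            pd.DataFrame({"mag": row.abs(), "id": row.index})
            .sort_values(["mag", "id"], ascending=[False, True])
        )
        chosen.update(order["id"].iloc[:top_k])
    idx = pd.Index(sorted(chosen, key=str), name=A.columns.name)
    return idx, A.loc[:, idx]


@dataclass
class ActivationVector:
    """Predicted per-mechanism activation of a query drug plus fit residual."""

    activation: pd.Series
    residual_norm: float

    def top_mechanism(self) -> str:
        return self.activation.idxmax()

    def write(self, path) -> None:
        out = self.activation.rename("activation").rename_axis("mechanism").to_frame()
        out.to_csv(path, sep="\t")


def predict_mechanisms(e_query: pd.Series, A_reduced: pd.DataFrame) -> ActivationVector:
    """Regress a query drug's signature onto the reduced sensitivities.

    Solves min_b ||E' - A'^T b||² over mechanism activations b (signed,
    unconstrained; minimum-norm under rank deficiency).  Scaling the
    query signature by c scales the activations by c.
    """
    if A_reduced.shape[1] == 0:
        raise ValueError("reduced transcript set is empty")
    e = e_query.reindex(A_reduced.columns)
    if e.isna().any():
        missing = list(e.index[e.isna()][:5])
        raise ValueError(f"query signature missing transcripts: {missing}")
    M = A_reduced.to_numpy(dtype=float).T  # transcripts × mechanisms
    b, *_ = np.linalg.lstsq(M, e.to_numpy(dtype=float), rcond=None)
    resid = float(np.linalg.norm(e.to_numpy() - M @ b))
    return ActivationVector(
        activation=pd.Series(b, index=A_reduced.index), residual_norm=resid
    )


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    return float(u @ v / (nu * nv))


def loo_validate(E: pd.DataFrame, B: pd.DataFrame, top_k: int = 50) -> pd.DataFrame:
    """Leave-one-drug-out validation of the mechanism-inference model.

    For each drug: refit A without it, reduce to the most sensitive
    transcripts, predict its activation vector from its own signature,
    and report the cosine similarity to its true binding row plus the
    rank of its strongest true mechanism among the predictions (1 is
    best).  Drugs whose true mechanisms are all unengaged by the
    remaining panel are flagged unpredictable (rank NaN).
    """
    if E.shape[1] < 3:
        raise ValueError("need >= 3 drugs for leave-one-out validation")
    if list(E.columns) != list(B.index):
        B = B.loc[E.columns]
    rows = []
    for drug in E.columns:
        train = [d for d in E.columns if d != drug]
        B_train = B.loc[train]
        true_row = B.loc[drug]
        engaged = B_train.to_numpy().any(axis=0)
        true_mechs = true_row[true_row > 0].index
        predictable = any(
            engaged[B_train.columns.get_loc(m)] for m in true_mechs
        ) if len(true_mechs) else False
        if not predictable:
            rows.append((drug, float("nan"), float("nan"), False))
            continue
        A = fit_sensitivity(E[train], B_train)
        _, A_red = reduce_sensitive(A, top_k=min(top_k, A.shape[1]))
        pred = predict_mechanisms(E[drug], A_red)
        cos = _cosine(pred.activation.to_numpy(), true_row.to_numpy())
        top_true = true_row.idxmax()
        order = pred.activation.sort_values(ascending=False).index
        rank = int(list(order).index(top_true)) + 1
        rows.append((drug, cos, rank, True))
    return pd.DataFrame(
        rows, columns=["drug", "cosine", "rank_of_truth", "predictable"]
    ).set_index("drug")
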