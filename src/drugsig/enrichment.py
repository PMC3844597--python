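"""Over-representation analysis of transcript lists against annotation sets.

Generic over user-supplied collections (cell-type markers, transcription
factor binding site targets, GO-style terms, any GMT file).  Each set is
tested with a one-sided Fisher's exact test on the 2×2 selected/set
table against a background universe; sets must overlap the selection by
at least ``min_overlap`` transcripts (default 3) and pass P < alpha.
Scalar per-transcript annotations (e.g. mRNA half-life in hours) are
compared between the selection and the background with a two-sided
rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .screen import adjust_pvalues


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they live in.

    Members outside the universe are dropped with a warning; empty sets
    are rejected.
    """

    sets: dict[str, set] = field(default_factory=dict)
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty background universe")
        cleaned = {}
        n_dropped = 0
        for name, members in self.sets.items():
            members = set(members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            inside = members & self.universe
            n_dropped += len(members) - len(inside)
            cleaned[name] = inside
        if n_dropped:
            warnings.warn(f"dropped {n_dropped} set members outside the universe")
        self.sets = cleaned


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Parse a GMT file (set name, description, members, tab-delimited).

    If ``universe`` is None, the union of all set members is used.
    """
    sets = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=set(universe))


def overrepresentation_pvalue(k: int, n: int, K: int, N: int) -> float:
    """One-sided Fisher / hypergeometric upper-tail P(X >= k).

    X counts members of a size-K set in a size-n draw from a size-N
    universe.  This is the P value behind :func:`set_enrichment`.
    """
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def set_enrichment(
    selected,
    collection: GeneSetCollection,
    min_overlap: int = 3,
    alpha: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """One-sided Fisher over-representation of ``selected`` in each set.

    Returns one row per set with overlap k >= ``min_overlap`` and
    P < ``alpha``, sorted by P: columns set, k, n, K, N, fold, p
    (and p_bh when ``bh``).  fold = (k/n) / (K/N).
    """
    selected = set(selected)
    outside = selected - collection.universe
    if outside:
        warnings.warn(f"dropped {len(outside)} selected ids outside the universe")
        selected &= collection.universe
    if not selected:
        raise ValueError("empty selection after restriction to the universe")

    N = len(collection.universe)
    n = len(selected)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(selected & members)
        if k < min_overlap:
            continue
        fold = (k / n) / (K / N)
        p = overrepresentation_pvalue(k, n, K, N)
        rows.append((name, k, n, K, N, fold, p))
    out = pd.DataFrame(rows, columns=["set", "k", "n", "K", "N", "fold", "p"])
    if bh and len(out):
        out["p_bh"] = adjust_pvalues(out["p"].to_numpy(), "bh")
    out = out[out["p"] < alpha]
    return out.sort_values(["p", "set"]).reset_index(drop=True)


@dataclass
class ScalarComparison:
    median_selected: float
    median_background: float
    p_value: float
    n_selected: int
    n_background: int


def compare_scalar_annotation(
    selected, scalar_table: pd.Series, min_annotated: int = 5
) -> ScalarComparison:
    """Compare a scalar annotation between selected transcripts and background.

    ``scalar_table`` maps transcript id -> value for the whole annotated
    background (e.g. mRNA half-lives).  Medians are reported for the
    selection and for the full background; the two-sided Mann-Whitney
    rank-sum P compares the selection against its complement (NaN if the
    complement is smaller than ``min_annotated``).
    """
    scalar_table = pd.Series(scalar_table).dropna()
    sel_vals = scalar_table.loc[scalar_table.index.intersection(pd.Index(set(selected)))]
    if len(sel_vals) < min_annotated:
        raise ValueError(
            f"only {len(sel_vals)} selected transcripts annotated (< {min_annotated})"
        )
    rest = scalar_table.drop(sel_vals.index)
    if len(rest) >= min_annotated:
        p = float(stats.mannwhitneyu(sel_vals, rest, alternative="two-sided").pvalue)
    else:
        p = float("nan")
    return ScalarComparison(
        median_selected=float(sel_vals.median()),
        median_background=float(scalar_table.median()),
        p_value=p,
        n_selected=int(len(sel_vals)),
        n_background=int(len(scalar_table)),
    )
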