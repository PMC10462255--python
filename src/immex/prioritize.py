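"""Geometric-mean rank integration of the three evidence streams.

Each candidate pathway carries three pieces of evidence:

* bulk activation z-score in the discovery cohort (higher is better),
* anti-correlation of its score with T cell-inflamed expression in a
  validation cohort (more negative is better),
* the single-cell low-vs-high infiltration contrast p-value (smaller
  is better; an effect-size mode ranks by the contrast estimate,
  larger is better).

Each stream is converted to a relative rank in (0, 1] — average-tie
rank position divided by the number of pathways, so the best pathway
gets 1/N and the worst 1 — and the three ranks are combined by their
geometric mean.  A pathway is nominated when its combined rank is
below 0.6 and the maximum pairwise difference among its three ranks
is below 0.3 (both strict inequalities, as printed), i.e. the streams
must both agree and rank it highly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

COMBINED_THRESHOLD = 0.6
MAXDIFF_THRESHOLD = 0.3

Direction = Literal["high", "low"]


@dataclass
class PriorityRecord:
    pathway: str
    rank_bulk_activation: float
    rank_anticorrelation: float
    rank_sc: float
    combined: float
    max_diff: float
    passes: bool

    @property
    def ranks(self) -> tuple[float, float, float]:
        return (self.rank_bulk_activation, self.rank_anticorrelation,
                self.rank_sc)


def relative_rank(values: Mapping[str, float] | pd.Series,
                  best: Direction) -> pd.Series:
    """Relative rank in (0, 1]: rank position / N, average ties.

    ``best="high"`` ranks the largest value first (rank 1/N);
    ``best="low"`` ranks the smallest first.
    """
    s = pd.Series(values, dtype=float)
    if len(s) == 0:
        raise ValueError("no values to rank")
    arr = s.to_numpy()
    if not np.isfinite(arr).all():
        bad = list(s.index[~np.isfinite(arr)])
        raise ValueError(f"non-finite values for: {bad}")
    if best == "high":
        arr = -arr
    elif best != "low":
        raise ValueError("best must be 'high' or 'low'")
    ranks = rankdata(arr, method="average") / len(arr)
    return pd.Series(ranks, index=s.index, name="relative_rank")


def combined_rank(r1: float, r2: float, r3: float) -> float:
    """Geometric mean of three relative ranks."""
    ranks = np.array([r1, r2, r3], dtype=float)
    if (ranks <= 0).any() or (ranks > 1).any():
        raise ValueError("ranks must lie in (0, 1]")
    return float(np.exp(np.log(ranks).mean()))


def prioritize(bulk_z: Mapping[str, float] | pd.Series,
               anticorr: Mapping[str, float] | pd.Series,
               sc_values: Mapping[str, float] | pd.Series,
               sc_mode: Literal["pvalue", "effect"] = "pvalue",
               combined_lt: float = COMBINED_THRESHOLD,
               maxdiff_lt: float = MAXDIFF_THRESHOLD,
               impute_missing: bool = False) -> list[PriorityRecord]:
    """Integrate the three streams into sorted :class:`PriorityRecord`s.

    ``bulk_z`` ranks high-to-low, ``anticorr`` (correlation
    coefficients) low-to-high (most negative first), and ``sc_values``
    small-to-large for ``sc_mode="pvalue"`` or large-to-small for
    ``sc_mode="effect"``.  Streams must cover the same pathway set;
    with ``impute_missing=True`` a pathway absent from a stream gets
    that stream's worst rank (1.0) instead of raising.  Output is
    sorted by combined rank ascending, ties broken by pathway name.
    """
    streams = {
        "bulk": (pd.Series(bulk_z, dtype=float), "high"),
        "anticorr": (pd.Series(anticorr, dtype=float), "low"),
        "sc": (pd.Series(sc_values, dtype=float),
               "low" if sc_mode == "pvalue" else "high"),
    }
    universe = sorted(set().union(*(set(s.index) for s, _ in streams.values())))
    common = set(universe)
    for s, _ in streams.values():
        common &= set(s.index)
    if not common:
        raise ValueError("no pathway is present in all three streams")
    if len(common) < len(universe) and not impute_missing:
        missing = sorted(set(universe) - common)
        raise ValueError(
            f"pathways missing from some stream: {missing}; "
            "pass impute_missing=True to assign worst rank"
        )

    ranks = {}
    for key, (s, direction) in streams.items():
        r = relative_rank(s, best=direction)
        ranks[key] = r.reindex(universe).fillna(1.0)

    records = []
    for name in universe:
        r1 = float(ranks["bulk"][name])
        r2 = float(ranks["anticorr"][name])
        r3 = float(ranks["sc"][name])
        comb = combined_rank(r1, r2, r3)
        trio = (r1, r2, r3)
        max_diff = float(max(trio) - min(trio))
        records.append(PriorityRecord(
            pathway=name, rank_bulk_activation=r1, rank_anticorrelation=r2,
            rank_sc=r3, combined=comb, max_diff=max_diff,
            passes=bool(comb < combined_lt and max_diff < maxdiff_lt),
        ))
    records.sort(key=lambda rec: (rec.combined, rec.pathway))
    return records


def records_to_frame(records: Sequence[PriorityRecord]) -> pd.DataFrame:
    """Tabulate :class:`PriorityRecord`s for TSV output."""
    return pd.DataFrame([{
        "pathway": r.pathway,
        "rank_bulk_activation": r.rank_bulk_activation,
        "rank_anticorrelation": r.rank_anticorrelation,
        "rank_sc": r.rank_sc,
        "combined": r.combined,
        "max_diff": r.max_diff,
        "passes": r.passes,
    } for r in records])
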