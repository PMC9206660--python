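"""Additive decomposition of dual-peptide editing effects.

A dual-fusion screen measures control-normalised editing for every
(N-terminal, C-terminal) peptide pair. Under the additive hypothesis the
observed value for pair (i, j) is baseline + a_i + b_j with
position-specific effects; the model is fit by least squares to the median
across replicates, with the control peptide's effect anchored at 0 in each
position to fix the shift ambiguity. Pearson correlation between
predicted and observed per-pair medians quantifies how additive the screen
really is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DualObservation", "AdditiveFit", "fit_additive", "predict_pair", "additivity_r"]

VALUE_COL = "normalized_edited_fraction"


@dataclass(frozen=True)
class DualObservation:
    """One replicate measurement of one ordered peptide pair."""

    n_term_id: str
    c_term_id: str
    replicate: str
    normalized_edited_fraction: float


@dataclass
class AdditiveFit:
    """Least-squares additive fit of a dual-peptide grid."""

    baseline: float
    n_effects: dict[str, float]
    c_effects: dict[str, float]
    pair_table: pd.DataFrame  # n_term_id, c_term_id, observed_median, predicted
    pearson_r: float


def _as_frame(obs: Union[pd.DataFrame, Iterable[DualObservation]]) -> pd.DataFrame:
    if isinstance(obs, pd.DataFrame):
        df = obs.copy()
    else:
        df = pd.DataFrame([o.__dict__ for o in obs])
    required = {"n_term_id", "c_term_id", VALUE_COL}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dual observations missing columns: {sorted(missing)}")
    return df


def _check_connected(pairs: pd.DataFrame) -> None:
    """All peptides must be linked through shared pairs for identifiability."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        parent[find(x)] = find(y)

    for row in pairs.itertuples(index=False):
        union(f"N:{row.n_term_id}", f"C:{row.c_term_id}")
    roots = {find(x) for x in parent}
    if len(roots) > 1:
        raise ValueError(
            f"dual design is disconnected ({len(roots)} components); effects unidentifiable"
        )


def fit_additive(
    obs: Union[pd.DataFrame, Iterable[DualObservation]],
    control_n: str = "CTRL",
    control_c: str = "CTRL",
) -> AdditiveFit:
    """Fit observed ≈ baseline + a(n_term) + b(c_term) by least squares.

    The observed quantity per pair is the median across replicates. Effects
    are anchored so the control peptide (or, if absent, the alphabetically
    first peptide) has effect 0 in each position; predictions are invariant
    to this choice.
    """
    df = _as_frame(obs)
    medians = (
        df.groupby(["n_term_id", "c_term_id"], as_index=False)[VALUE_COL]
        .median()
        .rename(columns={VALUE_COL: "observed_median"})
    )
    _check_connected(medians)

    n_ids = sorted(medians["n_term_id"].unique())
    c_ids = sorted(medians["c_term_id"].unique())
    anchor_n = control_n if control_n in n_ids else n_ids[0]
    anchor_c = control_c if control_c in c_ids else c_ids[0]
    n_free = [i for i in n_ids if i != anchor_n]
    c_free = [j for j in c_ids if j != anchor_c]

    npairs = len(medians)
    X = np.zeros((npairs, 1 + len(n_free) + len(c_free)))
    X[:, 0] = 1.0
    n_col = {pid: 1 + k for k, pid in enumerate(n_free)}
    c_col = {pid: 1 + len(n_free) + k for k, pid in enumerate(c_free)}
    for r, row in enumerate(medians.itertuples(index=False)):
        if row.n_term_id in n_col:
            X[r, n_col[row.n_term_id]] = 1.0
        if row.c_term_id in c_col:
            X[r, c_col[row.c_term_id]] = 1.0
    yv = medians["observed_median"].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, yv, rcond=None)

    baseline = float(coef[0])
    n_effects = {anchor_n: 0.0, **{pid: float(coef[n_col[pid]]) for pid in n_free}}
    c_effects = {anchor_c: 0.0, **{pid: float(coef[c_col[pid]]) for pid in c_free}}
    predicted = X @ coef
    pair_table = medians.assign(predicted=predicted)
    r = _pearson(predicted, yv)
    return AdditiveFit(baseline, n_effects, c_effects, pair_table, r)


def predict_pair(fit: AdditiveFit, n_id: str, c_id: str) -> float:
    """Predicted normalised editing for a pair: baseline + a(n) + b(c)."""
    if n_id not in fit.n_effects or c_id not in fit.c_effects:
        raise ValueError(f"unknown peptide id: {n_id!r} or {c_id!r}")
    return fit.baseline + fit.n_effects[n_id] + fit.c_effects[c_id]


def additivity_r(
    fit: AdditiveFit,
    obs: Optional[Union[pd.DataFrame, Iterable[DualObservation]]] = None,
) -> float:
    """Pearson r between predicted and observed per-pair medians.

    Computed over pairs, not replicates. Returns NaN when either vector has
    zero variance (the correlation is undefined there).
    """
    if obs is None:
        table = fit.pair_table
        predicted = table["predicted"].to_numpy(dtype=float)
        observed = table["observed_median"].to_numpy(dtype=float)
    else:
        df = _as_frame(obs)
        medians = df.groupby(["n_term_id", "c_term_id"], as_index=False)[VALUE_COL].median()
        predicted = np.array(
            [predict_pair(fit, r.n_term_id, r.c_term_id) for r in medians.itertuples(index=False)]
        )
        observed = medians[VALUE_COL].to_numpy(dtype=float)
    if len(observed) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    return _pearson(predicted, observed)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
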