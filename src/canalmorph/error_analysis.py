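"""Measurement repeatability: technical error of measurement and rm-ANOVA.

The classical technical error of measurement (TEM) is defined for two
measurement sessions: sqrt(Σ_s d_s² / 2n) over the n subjects' session
differences. With five sessions the statistic is computed for every one of
the 10 unordered session pairs and averaged. Relative TEM expresses the
result as a percentage of the grand mean of all values.

TEM assumes each session re-measures the same homologous quantity. That
holds for the inter-canal angles but not for lumen diameters, which are
taken at different loci along the canal; requesting a lumen TEM therefore
emits a warning unless forced.

A one-way repeated-measures ANOVA (subjects = specimens, within factor =
measurement session) tests for a systematic session effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.anova import AnovaRM

from .exceptions import (
    CanalmorphError,
    DegenerateVarianceError,
    InsufficientDataError,
)
from .measurements_io import ANGLE_VARIABLES, SpecimenRecord


@dataclass(frozen=True)
class ReplicateMatrix:
    """Complete n specimens x k sessions matrix of one variable's replicates."""

    variable_id: str
    specimen_ids: tuple[str, ...]
    values: np.ndarray  # shape (n, k)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise CanalmorphError("replicate matrix must be 2-D (specimens x sessions)")
        if values.shape[0] != len(self.specimen_ids):
            raise CanalmorphError(
                f"{values.shape[0]} rows but {len(self.specimen_ids)} specimen ids"
            )
        if not np.all(np.isfinite(values)):
            raise CanalmorphError("replicate matrix has missing or non-finite cells")

    @property
    def n_specimens(self) -> int:
        return self.values.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TEMResult:
    variable_id: str
    abs_tem: float  # measurement units
    rel_tem: float  # percent of the grand mean
    n_pairs: int  # k(k-1)/2 session pairs averaged
    grand_mean: float


@dataclass(frozen=True)
class RmAnovaResult:
    variable_id: str
    f_stat: float
    df_between: int  # sessions factor, k-1
    df_error: int  # (n-1)(k-1)
    p_value: float


def replicate_matrix(
    records: Sequence[SpecimenRecord], variable_id: str
) -> ReplicateMatrix:
    """Assemble the specimens-by-sessions matrix for one panel variable."""
    rows, ids = [], []
    for rec in records:
        if variable_id in rec.panels:
            ids.append(rec.specimen_id)
            rows.append(rec.panels[variable_id].values)
    if not rows:
        raise CanalmorphError(f"no specimen carries a {variable_id} panel")
    return ReplicateMatrix(
        variable_id=variable_id, specimen_ids=tuple(ids), values=np.array(rows)
    )


def tem_pair(col_i: Sequence[float], col_j: Sequence[float]) -> float:
    """Two-session TEM: sqrt(Σ_s (x_si - x_sj)² / 2n) over n specimens."""
    a = np.asarray(col_i, dtype=float)
    b = np.asarray(col_j, dtype=float)
    if a.shape != b.shape:
        raise CanalmorphError(f"session columns differ in shape: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise CanalmorphError("need at least one specimen")
    return float(np.sqrt(np.sum((a - b) ** 2) / (2.0 * a.size)))


def tem_averaged(m: ReplicateMatrix, force: bool = False) -> TEMResult:
    """TEM averaged over all unordered session pairs, pooled across specimens.

    The absolute TEM is the mean of :func:`tem_pair` over the k(k-1)/2
    session pairs; the relative TEM divides it by the grand mean of all
    n·k values (as a percent).
    """
    if m.variable_id not in ANGLE_VARIABLES and not force:
        warnings.warn(
            f"{m.variable_id}: lumen diameters are measured at different loci, "
            "not homologous points; TEM is not meaningful (pass force=True to "
            "compute it anyway)",
            stacklevel=2,
        )
    k = m.n_sessions
    if k < 2:
        raise InsufficientDataError(f"need >= 2 sessions, got {k}")
    pairs = list(combinations(range(k), 2))
    abs_tem = float(
        np.mean([tem_pair(m.values[:, i], m.values[:, j]) for i, j in pairs])
    )
    grand_mean = float(m.values.mean())
    return TEMResult(
        variable_id=m.variable_id,
        abs_tem=abs_tem,
        rel_tem=100.0 * abs_tem / grand_mean,
        n_pairs=len(pairs),
        grand_mean=grand_mean,
    )


def rm_anova(m: ReplicateMatrix) -> RmAnovaResult:
    """One-way within-subject ANOVA: session as the within factor.

    F = MS_session / MS_error with (k-1, (n-1)(k-1)) degrees of freedom;
    no sphericity correction is applied.
    """
    n, k = m.n_specimens, m.n_sessions
    if n < 2 or k < 2:
        raise InsufficientDataError(
            f"need >= 2 specimens and >= 2 sessions, got {n} x {k}"
        )
    # error SS after removing subject and session effects
    resid = (
        m.values
        - m.values.mean(axis=1, keepdims=True)
        - m.values.mean(axis=0, keepdims=True)
        + m.values.mean()
    )
    if np.sum(resid**2) <= 0.0:
        raise DegenerateVarianceError(
            f"{m.variable_id}: zero error variance; F is undefined"
        )
    long = pd.DataFrame(
        {
            "specimen": np.repeat(m.specimen_ids, k),
            "session": np.tile(np.arange(k), n),
            "value": m.values.ravel(),
        }
    )
    fitted = AnovaRM(
        long, depvar="value", subject="specimen", within=["session"]
    ).fit()
    row = fitted.anova_table.loc["session"]
    return RmAnovaResult(
        variable_id=m.variable_id,
        f_stat=float(row["F Value"]),
        df_between=int(row["Num DF"]),
        df_error=int(row["Den DF"]),
        p_value=float(row["Pr > F"]),
    )
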