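"""Replicate averaging, log2(x+1) transformation and per-probe z-scaling.

Replicate means are taken on raw intensities first and logged afterwards;
clustering operates on row-scaled log profiles, while co-expression
correlations later use replicate-level log values (Pearson r is invariant
to per-row scaling, so rows are never scaled for the network stage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from knoxnet.expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

#: canonical condition order for the drought time-course design
CONDITION_ORDER = ("watered", "drought", "rewatered")


@dataclass
class ProfileMatrix:
    """Probes x (condition, day) profile grid on the log2 scale.

    ``scaled`` records whether rows have been z-scaled (mean 0, sd 1).
    """

    probe_ids: list[str]
    conditions: list[tuple[str, float]]
    values: np.ndarray
    logged: bool = True
    scaled: bool = False
    dropped_constant: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.conditions)):
            raise ValueError("value grid does not match probe/condition lists")
        if self.scaled:
            m = self.values.mean(axis=1)
            s = self.values.std(axis=1, ddof=1)
            if self.values.shape[1] > 1 and (
                np.abs(m).max(initial=0.0) > 1e-9
                or np.abs(s - 1).max(initial=0.0) > 1e-6
            ):
                raise ValueError("scaled profile rows must have mean 0, sd 1")

    @property
    def condition_labels(self) -> list[str]:
        return [f"{c}_{day:g}d" for c, day in self.conditions]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.probe_ids, columns=self.condition_labels
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# logged={self.logged} scaled={self.scaled}\n")
            df = self.to_frame()
            df.index.name = "probe_id"
            df.to_csv(fh, sep="\t", float_format="%.10g")


def log_transform(values: np.ndarray) -> np.ndarray:
    """Elementwise log2(x + 1); input must be non-negative."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size and finite.min() < 0:
        raise ValueError("log_transform requires non-negative intensities")
    return np.log2(values + 1.0)


def _condition_sort_key(
    cond_day: tuple[str, float], order: tuple[str, ...]
) -> tuple[int, str, float]:
    cond, day = cond_day
    rank = order.index(cond) if cond in order else len(order)
    return (rank, "" if cond in order else cond, day)


def average_replicates(
    matrix: ExpressionMatrix,
    condition_order: tuple[str, ...] = CONDITION_ORDER,
    log: bool = True,
) -> ProfileMatrix:
    """Mean over replicates per (condition, day) group, then log2(x+1).

    Means are computed on raw intensities; the log is applied to the means
    (not the other way round).  Columns are ordered by condition rank
    (watered, drought, rewatered by default) then ascending day.
    """
    groups: dict[tuple[str, float], list[int]] = {}
    for j, s in enumerate(matrix.samples):
        groups.setdefault((s.condition, s.day), []).append(j)
    ordered = sorted(
        groups, key=lambda cd: _condition_sort_key(cd, condition_order)
    )
    means = np.column_stack(
        [np.nanmean(matrix.values[:, groups[cd]], axis=1) for cd in ordered]
    )
    return ProfileMatrix(
        probe_ids=list(matrix.probe_ids),
        conditions=ordered,
        values=log_transform(means) if log else means,
        logged=log,
        scaled=False,
    )


def scale_rows(profile: ProfileMatrix, ddof: int = 1) -> ProfileMatrix:
    """Z-scale each row to mean 0, sd 1 (sample sd, n-1 by default).

    Constant rows carry no temporal shape and are dropped with a warning;
    their ids are recorded on the returned profile.
    """
    if len(profile.conditions) < 2:
        raise ValueError("scaling requires at least 2 conditions")
    sd = profile.values.std(axis=1, ddof=ddof)
    constant = sd == 0
    dropped = [p for p, c in zip(profile.probe_ids, constant) if c]
    if dropped:
        logger.warning(
            "dropping %d constant profile(s) before scaling: %s",
            len(dropped),
            dropped[:10],
        )
    keep = ~constant
    values = profile.values[keep]
    scaled = (values - values.mean(axis=1, keepdims=True)) / values.std(
        axis=1, ddof=ddof, keepdims=True
    )
    return ProfileMatrix(
        probe_ids=[p for p, k in zip(profile.probe_ids, keep) if k],
        conditions=list(profile.conditions),
        values=scaled,
        logged=profile.logged,
        scaled=True,
        dropped_constant=dropped,
    )
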