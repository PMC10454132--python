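"""Expression matrix, sample design and probe-annotation I/O.

TSV dialect: tab-separated, first column ``probe_id``, header row of sample
ids; ``.`` or an empty cell denotes a missing value.  The sample design
table has columns ``sample_id``, ``condition``, ``day``, ``replicate`` and
optionally ``tissue``.  The annotation table has columns ``probe_id``,
``gene_id``, ``gene_name`` and ``modules`` (comma-joined tags).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKENS = {".", "", "NA", "NaN", "nan"}


@dataclass(frozen=True)
class SampleDesign:
    """One microarray sample: condition label, day of sampling, replicate."""

    sample_id: str
    condition: str
    day: float
    replicate: int
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"negative day for sample {self.sample_id!r}")
        if self.replicate < 1:
            raise ValueError(
                f"replicate index must be >= 1 for sample {self.sample_id!r}"
            )


@dataclass
class ExpressionMatrix:
    """Probes x samples intensity table with its sample design.

    Intensities are non-negative summarized array values (not logged).
    ``values`` rows follow ``probe_ids``; columns follow ``samples``.
    """

    probe_ids: list[str]
    samples: list[SampleDesign]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.samples)):
            raise ValueError(
                f"value grid {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.samples)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dupes = sorted(
                {p for p in self.probe_ids if self.probe_ids.count(p) > 1}
            )
            raise ValueError(f"duplicate probe ids: {dupes}")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids in design")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            i, j = np.argwhere(
                np.isfinite(self.values) & (self.values < 0)
            )[0]
            raise ValueError(
                f"negative intensity at probe {self.probe_ids[i]!r}, "
                f"sample {self.samples[j].sample_id!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.probe_ids, columns=self.sample_ids
        )

    def subset(self, probes: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset preserving this matrix's probe order."""
        wanted = set(probes)
        missing = wanted - set(self.probe_ids)
        if missing:
            raise KeyError(f"probes not in matrix: {sorted(missing)}")
        keep = [i for i, p in enumerate(self.probe_ids) if p in wanted]
        return ExpressionMatrix(
            probe_ids=[self.probe_ids[i] for i in keep],
            samples=list(self.samples),
            values=self.values[keep, :],
        )


@dataclass(frozen=True)
class ModuleAnnotation:
    """Probe-to-gene mapping with functional module tags (TF, CK, GA, ABA,
    oxidative_stress, proline_metabolism, TALE, ...)."""

    probe_id: str
    gene_id: str = ""
    gene_name: str = ""
    modules: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.probe_id:
            raise ValueError("probe_id must be non-empty")
        object.__setattr__(self, "modules", frozenset(self.modules))


def read_design(design_path: str | Path) -> list[SampleDesign]:
    """Read a sample-design TSV (sample_id, condition, day, replicate[, tissue])."""
    df = pd.read_csv(design_path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "day", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    designs = []
    for row in df.itertuples(index=False):
        designs.append(
            SampleDesign(
                sample_id=row.sample_id,
                condition=row.condition,
                day=float(row.day),
                replicate=int(row.replicate),
                tissue=getattr(row, "tissue", "") or "",
            )
        )
    _check_replicate_indices(designs)
    return designs


def _check_replicate_indices(designs: Iterable[SampleDesign]) -> None:
    seen: dict[tuple[str, float], set[int]] = {}
    for d in designs:
        key = (d.condition, d.day)
        reps = seen.setdefault(key, set())
        if d.replicate in reps:
            raise ValueError(
                f"duplicate replicate {d.replicate} in group {key}"
            )
        reps.add(d.replicate)


def read_expression(
    matrix_path: str | Path, design_path: str | Path
) -> ExpressionMatrix:
    """Read an intensity matrix and its sample design.

    Every matrix column must appear in the design; sample order follows the
    matrix header.  Negative or non-numeric cells are hard errors; missing
    cells (``.`` or empty) become NaN and are resolved downstream.
    """
    designs = {d.sample_id: d for d in read_design(design_path)}
    df = pd.read_csv(
        matrix_path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    missing_cols = [c for c in df.columns if c not in designs]
    if missing_cols:
        raise ValueError(
            f"matrix column(s) absent from design: {missing_cols}"
        )
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, (probe, cell) in enumerate(df[col].items()):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} at probe {probe!r}, "
                    f"sample {col!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"negative value {v} at probe {probe!r}, sample {col!r}"
                )
            values[i, j] = v
    return ExpressionMatrix(
        probe_ids=[str(p) for p in df.index],
        samples=[designs[c] for c in df.columns],
        values=values,
    )


def write_expression(
    matrix: ExpressionMatrix,
    matrix_path: str | Path,
    design_path: str | Path | None = None,
) -> None:
    """Write matrix (and optionally design) in the package TSV dialect."""
    df = matrix.to_frame()
    df.index.name = "probe_id"
    df.to_csv(matrix_path, sep="\t", na_rep=".", float_format="%.17g")
    if design_path is not None:
        pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in matrix.samples],
                "condition": [s.condition for s in matrix.samples],
                "day": [s.day for s in matrix.samples],
                "replicate": [s.replicate for s in matrix.samples],
                "tissue": [s.tissue for s in matrix.samples],
            }
        ).to_csv(design_path, sep="\t", index=False)


def read_annotation(annot_path: str | Path) -> list[ModuleAnnotation]:
    """Read a probe annotation TSV with comma-joined module tags."""
    df = pd.read_csv(annot_path, sep="\t", dtype=str, keep_default_na=False)
    required = {"probe_id", "modules"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    annots = []
    for row in df.itertuples(index=False):
        tags = frozenset(
            t.strip() for t in row.modules.split(",") if t.strip()
        )
        annots.append(
            ModuleAnnotation(
                probe_id=row.probe_id,
                gene_id=getattr(row, "gene_id", "") or "",
                gene_name=getattr(row, "gene_name", "") or "",
                modules=tags,
            )
        )
    return annots


def write_annotation(
    annots: Sequence[ModuleAnnotation], annot_path: str | Path
) -> None:
    pd.DataFrame(
        {
            "probe_id": [a.probe_id for a in annots],
            "gene_id": [a.gene_id for a in annots],
            "gene_name": [a.gene_name for a in annots],
            "modules": [",".join(sorted(a.modules)) for a in annots],
        }
    ).to_csv(annot_path, sep="\t", index=False)


def select_probes(
    matrix: ExpressionMatrix,
    annot: Sequence[ModuleAnnotation],
    wanted_modules: Iterable[str],
) -> ExpressionMatrix:
    """Restrict the matrix to probes annotated with any wanted module tag.

    This builds the analysis sub-database: probes whose module tags
    intersect ``wanted_modules``, in original matrix order.  Selecting zero
    probes is a hard error -- an empty analysis is never intended.
    """
    wanted = set(wanted_modules)
    if not wanted:
        raise ValueError("wanted_modules must be non-empty")
    tagged = {a.probe_id for a in annot if a.modules & wanted}
    selected = [p for p in matrix.probe_ids if p in tagged]
    if not selected:
        raise ValueError(
            f"no probes selected for modules {sorted(wanted)}"
        )
    logger.info(
        "selected %d of %d probes for modules %s",
        len(selected),
        matrix.n_probes,
        sorted(wanted),
    )
    return matrix.subset(selected)


def drop_incomplete_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop probes with any missing value (complete-case analysis)."""
    complete = np.isfinite(matrix.values).all(axis=1)
    if complete.all():
        return matrix
    dropped = [p for p, ok in zip(matrix.probe_ids, complete) if not ok]
    logger.warning(
        "dropping %d probe(s) with missing values: %s",
        len(dropped),
        dropped[:10],
    )
    keep = [p for p, ok in zip(matrix.probe_ids, complete) if ok]
    if not keep:
        raise ValueError("all probes have missing values")
    return matrix.subset(keep)
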