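"""Validated containers and tab-separated on-disk dialects.

Every artifact the pipeline touches lives in one of four plain-text formats:

* expression TSV — genes as rows, samples as columns, first column ``gene_id``,
  header row of sample ids, decimal-point numerics;
* GMT — one gene set per line: ``name<TAB>description<TAB>member...``;
* annotation TSV — columns ``sample_id``, ``arm``, ``batch``, ``replicate``
  (extra columns are carried through untouched);
* survival TSV — columns ``patient_id``, ``time``, ``event``, ``endpoint``
  and optionally ``group`` (extra columns carried through).

Readers are strict: anything outside the documented dialect is rejected with
an error that names the offending row/column, never silently coerced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "SampleAnnotation",
    "GeneSetCollection",
    "SurvivalTable",
    "ENDPOINTS",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_annotation",
    "read_survival",
    "write_survival",
]

ENDPOINTS = ("OS", "RFS", "DMFS")

SCALES = ("raw_intensity", "log2")


class FormatError(ValueError):
    """A file or container violated the documented dialect or an invariant."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise FormatError(f"duplicate {kind} id(s): {', '.join(map(str, dups))}")


@dataclass
class ExpressionMatrix:
    """Genes × samples numeric matrix with an explicit scale flag.

    ``scale`` is ``"raw_intensity"`` (non-negative bead-style intensities) or
    ``"log2"``.  All values must be finite; ids must be unique on both axes.
    """

    frame: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise FormatError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not isinstance(self.frame, pd.DataFrame):
            raise FormatError("expression values must be a pandas DataFrame")
        self.frame = self.frame.astype(float)
        _check_unique(self.frame.index, "gene")
        _check_unique(self.frame.columns, "sample")
        vals = self.frame.to_numpy()
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise FormatError(
                f"non-finite expression value at gene {self.frame.index[bad[0]]!r}, "
                f"sample {self.frame.columns[bad[1]]!r}"
            )
        if self.scale == "raw_intensity" and (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative raw intensity at gene {self.frame.index[bad[0]]!r}, "
                f"sample {self.frame.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "ExpressionMatrix":
        """Same ids, new values (and optionally a new scale flag)."""
        new = pd.DataFrame(values, index=self.frame.index, columns=self.frame.columns)
        return ExpressionMatrix(new, scale=scale if scale is not None else self.scale)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = [g for g in gene_ids]
        missing = [g for g in wanted if g not in self.frame.index]
        if missing:
            raise FormatError(f"gene id(s) not in matrix: {', '.join(missing[:10])}")
        return ExpressionMatrix(self.frame.loc[wanted], scale=self.scale)


@dataclass
class SampleAnnotation:
    """Per-sample treatment arm, batch, and replicate labels.

    Extra columns in the source file are preserved as opaque metadata.
    """

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "arm", "batch", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise FormatError(f"annotation missing column(s): {', '.join(missing)}")
        _check_unique(self.frame["sample_id"], "sample")
        try:
            self.frame["replicate"] = self.frame["replicate"].astype(int)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"replicate column is not integer: {exc}") from exc
        self.frame = self.frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def arms(self) -> list[str]:
        return sorted(self.frame["arm"].unique())

    def arm_of(self) -> pd.Series:
        return pd.Series(self.frame["arm"].to_numpy(), index=self.frame["sample_id"])

    def batch_of(self) -> pd.Series:
        return pd.Series(self.frame["batch"].to_numpy(), index=self.frame["sample_id"])

    def samples_in_arm(self, arm: str) -> list[str]:
        return list(self.frame.loc[self.frame["arm"] == arm, "sample_id"])

    def check_pairing(self, matrix: ExpressionMatrix) -> None:
        """Require exact (set-equality) agreement with a matrix's samples."""
        mine = set(self.sample_ids)
        theirs = set(matrix.sample_ids)
        if mine != theirs:
            only_ann = sorted(mine - theirs)
            only_mat = sorted(theirs - mine)
            raise FormatError(
                "annotation/matrix sample mismatch; "
                f"annotation-only: {only_ann}; matrix-only: {only_mat}"
            )


@dataclass
class GeneSetCollection:
    """Ordered, named gene sets with GMT semantics."""

    sets: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([name for name, _, _ in self.sets], "gene set")
        cleaned = []
        for name, desc, members in self.sets:
            deduped = tuple(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(f"gene set {name!r}: dropped duplicate members", stacklevel=2)
            if not deduped:
                raise FormatError(f"gene set {name!r} is empty")
            cleaned.append((name, desc, deduped))
        self.sets = cleaned

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.sets]

    def members(self, name: str) -> tuple[str, ...]:
        for n, _, m in self.sets:
            if n == name:
                return m
        raise KeyError(name)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class SurvivalTable:
    """Per-patient time-to-event records for one or more endpoints.

    ``time`` is a positive real in arbitrary units; ``event`` is 1 for an
    observed event and 0 for right-censoring; ``endpoint`` is one of
    OS (overall), RFS (relapse-free) or DMFS (distant-metastasis-free)
    survival.  An optional ``group`` column carries an expression-derived
    stratum label.
    """

    frame: pd.DataFrame

    REQUIRED = ("patient_id", "time", "event", "endpoint")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise FormatError(f"survival table missing column(s): {', '.join(missing)}")
        self.frame = self.frame.reset_index(drop=True)
        try:
            self.frame["time"] = self.frame["time"].astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"time column is not numeric: {exc}") from exc
        bad = np.flatnonzero(~(self.frame["time"].to_numpy() > 0))
        if bad.size:
            raise FormatError(f"time must be > 0; violated at row(s) {list(bad + 1)}")
        ev = pd.to_numeric(self.frame["event"], errors="coerce")
        bad = np.flatnonzero(~ev.isin([0, 1]).to_numpy())
        if bad.size:
            raise FormatError(f"event must be 0 or 1; violated at row(s) {list(bad + 1)}")
        self.frame["event"] = ev.astype(int)
        bad = np.flatnonzero(~self.frame["endpoint"].isin(ENDPOINTS).to_numpy())
        if bad.size:
            raise FormatError(
                f"endpoint must be one of {ENDPOINTS}; violated at row(s) {list(bad + 1)}"
            )

    @property
    def times(self) -> np.ndarray:
        return self.frame["time"].to_numpy()

    @property
    def events(self) -> np.ndarray:
        return self.frame["event"].to_numpy()

    def for_endpoint(self, endpoint: str) -> "SurvivalTable":
        if endpoint not in ENDPOINTS:
            raise FormatError(f"unknown endpoint {endpoint!r}")
        return SurvivalTable(self.frame.loc[self.frame["endpoint"] == endpoint].copy())

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a genes × samples expression TSV.

    The first column holds gene ids, the header row sample ids.  Duplicate
    ids and non-numeric cells are rejected with located errors.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = sorted(set(raw.index[raw.index.duplicated()]))
        raise FormatError(f"{path}: duplicate gene id(s): {', '.join(dups)}")
    if raw.columns.has_duplicates:
        dups = sorted(set(raw.columns[raw.columns.duplicated()]))
        raise FormatError(f"{path}: duplicate sample id(s): {', '.join(dups)}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() & raw.notna().to_numpy())
    if bad.size:
        g, s = bad[0]
        raise FormatError(
            f"{path}: non-numeric cell {raw.iat[g, s]!r} at gene "
            f"{raw.index[g]!r} (row {g + 2}), sample {raw.columns[s]!r} (column {s + 2})"
        )
    if numeric.isna().to_numpy().any():
        g, s = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: empty cell at gene {raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    return ExpressionMatrix(numeric, scale=scale)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.frame.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    path = Path(path)
    sets: list[tuple[str, str, tuple[str, ...]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no members")
            sets.append((name, desc, tuple(members)))
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, desc, members in collection:
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_annotation(path: str | Path) -> SampleAnnotation:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "arm": str, "batch": str})
    return SampleAnnotation(frame)


def write_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    annotation.frame.to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> SurvivalTable:
    frame = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "endpoint": str})
    return SurvivalTable(frame)


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
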