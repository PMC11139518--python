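"""Experimental design and count-table I/O for multi-condition time courses.

The supported design observes C biological conditions at T time points with
R replicates per (condition, time) cell.  The first time point in time order
is the reference ``t0``: every temporal contrast compares a later time
against it.  Samples are annotated either through an explicit sample sheet
(CSV with columns ``sample_id, condition, time, replicate``) or through the
column-naming convention ``{condition}_{time}_r{replicate}``, e.g.
``A_t3_r2``.

Two contrast families are enumerated from a design:

* temporal ("horizontal"): ``ti vs t0`` within each condition — C x (T-1)
  contrasts;
* condition ("vertical"): each unordered condition pair at each time —
  T x C(C-1)/2 contrasts.

The per-(condition, time) specificity analyses built on the vertical family
are counted separately (C x T analysis units).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "SampleInfo",
    "ExperimentalDesign",
    "CountMatrix",
    "ContrastSpec",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "enumerate_temporal_contrasts",
    "enumerate_condition_contrasts",
    "count_analysis_units",
]


class DesignError(ValueError):
    """Raised when a design, sample sheet or count table is invalid."""


_SAMPLE_NAME_RE = re.compile(r"^(?P<condition>.+)_(?P<time>[^_]+)_r(?P<replicate>\d+)$")
_NUMERIC_TIME_RE = re.compile(r"^[A-Za-z]*(\d+(?:\.\d+)?)$")


@dataclass(frozen=True)
class SampleInfo:
    """One sample: its identifier and (condition, time, replicate) triple."""

    sample_id: str
    condition: str
    time: str
    replicate: int

    @property
    def cell(self) -> tuple[str, str]:
        return (self.condition, self.time)


def _time_sort_key(label: str):
    m = _NUMERIC_TIME_RE.match(label)
    return float(m.group(1)) if m else None


def order_times(labels: Sequence[str], declared_order: Sequence[str] | None = None) -> tuple[str, ...]:
    """Order time labels: numerically when all labels carry a numeric part
    (``t0``, ``t1``, ``4h`` ...), otherwise by declared/appearance order."""
    unique = list(dict.fromkeys(labels))
    keys = [_time_sort_key(t) for t in unique]
    if all(k is not None for k in keys):
        return tuple(sorted(unique, key=_time_sort_key))
    if declared_order is not None:
        missing = [t for t in unique if t not in declared_order]
        if missing:
            raise DesignError(f"time labels missing from declared order: {missing}")
        return tuple(t for t in declared_order if t in unique)
    return tuple(unique)


@dataclass
class ExperimentalDesign:
    """Validated sample layout with a distinguished reference time.

    ``times[0]`` is the reference t0.  Conditions and times keep a stable
    order so contrast enumeration is deterministic.
    """

    samples: tuple[SampleInfo, ...]
    conditions: tuple[str, ...]
    times: tuple[str, ...]

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        self.conditions = tuple(self.conditions)
        self.times = tuple(self.times)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DesignError(f"duplicate sample ids: {dup}")
        triples = [(s.condition, s.time, s.replicate) for s in self.samples]
        if len(set(triples)) != len(triples):
            dup = sorted({t for t in triples if triples.count(t) > 1})
            raise DesignError(f"duplicate (condition, time, replicate) triples: {dup}")
        for s in self.samples:
            if s.condition not in self.conditions:
                raise DesignError(f"sample {s.sample_id!r}: unknown condition {s.condition!r}")
            if s.time not in self.times:
                raise DesignError(f"sample {s.sample_id!r}: unknown time {s.time!r}")
            if s.replicate < 1:
                raise DesignError(f"sample {s.sample_id!r}: replicate must be >= 1")
        if not self.times:
            raise DesignError("design has no time points")

    # -- basic geometry ---------------------------------------------------
    @property
    def t0(self) -> str:
        return self.times[0]

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples)

    def cells(self) -> list[tuple[str, str]]:
        """All (condition, time) cells in (condition-order, time-order)."""
        return [(c, t) for c in self.conditions for t in self.times]

    def sample_indices(self, condition: str, time: str) -> list[int]:
        return [i for i, s in enumerate(self.samples)
                if s.condition == condition and s.time == time]

    @property
    def replicate_counts(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {cell: 0 for cell in self.cells()}
        for s in self.samples:
            counts[s.cell] += 1
        return counts

    def validate_for_de(self) -> None:
        """DE contrasts need within-cell variance: >= 2 replicates per cell."""
        thin = [cell for cell, n in self.replicate_counts.items() if n < 2]
        if thin:
            raise DesignError(
                f"cells with fewer than 2 replicates cannot be used in DE contrasts: {thin}"
            )

    # -- construction ------------------------------------------------------
    @classmethod
    def from_sample_table(cls, table: pd.DataFrame) -> "ExperimentalDesign":
        required = {"sample_id", "condition", "time", "replicate"}
        missing = required - set(table.columns)
        if missing:
            raise DesignError(f"sample sheet missing columns: {sorted(missing)}")
        samples = tuple(
            SampleInfo(str(r.sample_id), str(r.condition), str(r.time), int(r.replicate))
            for r in table.itertuples()
        )
        conditions = tuple(dict.fromkeys(s.condition for s in samples))
        times = order_times([s.time for s in samples],
                            declared_order=list(dict.fromkeys(s.time for s in samples)))
        return cls(samples, conditions, times)

    @classmethod
    def from_sample_names(cls, names: Sequence[str]) -> "ExperimentalDesign":
        """Parse the ``{condition}_{time}_r{replicate}`` naming convention."""
        samples = []
        for name in names:
            m = _SAMPLE_NAME_RE.match(name)
            if m is None:
                raise DesignError(
                    f"sample column {name!r} does not follow the "
                    "'{{condition}}_{{time}}_r{{replicate}}' convention"
                )
            samples.append(SampleInfo(name, m["condition"], m["time"], int(m["replicate"])))
        conditions = tuple(dict.fromkeys(s.condition for s in samples))
        times = order_times([s.time for s in samples])
        return cls(tuple(samples), conditions, times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "time": [s.time for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )


@dataclass
class CountMatrix:
    """Raw counts: G genes x S samples, non-negative integers."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        self.sample_ids = tuple(self.sample_ids)
        self.counts = np.asarray(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise DesignError(f"duplicate gene ids: {dup}")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DesignError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac = np.mod(self.counts, 1)
            bad = np.argwhere(frac != 0)
            if bad.size:
                g, s = bad[0]
                raise DesignError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}: {self.counts[g, s]}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise DesignError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}: {self.counts[g, s]}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.gene_ids),
                            columns=list(self.sample_ids))


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group contrast over (condition, time) cells.

    ``temporal``: condition_a at ``time`` vs the same condition at t0.
    ``condition``: condition_a vs condition_b at ``time`` (pair in canonical
    lexicographic order so each unordered pair appears once).
    """

    kind: Literal["temporal", "condition"]
    condition_a: str
    condition_b: str | None
    time: str
    t0: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "temporal":
            if self.condition_b is not None:
                raise DesignError("temporal contrast must not set condition_b")
            if self.t0 is not None and self.time == self.t0:
                raise DesignError("temporal contrast time must differ from t0")
        elif self.kind == "condition":
            if self.condition_b is None or self.condition_a == self.condition_b:
                raise DesignError("condition contrast needs two distinct conditions")
            if self.condition_b < self.condition_a:
                a, b = self.condition_a, self.condition_b
                object.__setattr__(self, "condition_a", b)
                object.__setattr__(self, "condition_b", a)
        else:
            raise DesignError(f"unknown contrast kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "temporal":
            return f"{self.condition_a}:{self.time}_vs_{self.t0}"
        return f"{self.time}:{self.condition_a}_vs_{self.condition_b}"

    def cells(self) -> tuple[tuple[str, str], tuple[str, str]]:
        """The (numerator, denominator) cells of the contrast."""
        if self.kind == "temporal":
            return (self.condition_a, self.time), (self.condition_a, self.t0)
        return (self.condition_a, self.time), (self.condition_b, self.time)


def enumerate_temporal_contrasts(design: ExperimentalDesign) -> list[ContrastSpec]:
    """One ti-vs-t0 contrast per condition per non-reference time.

    Ordered by (condition order, time order); length C x (T-1).
    """
    if design.n_times < 2:
        raise DesignError("no non-reference time: temporal contrasts need T >= 2")
    return [
        ContrastSpec("temporal", c, None, t, t0=design.t0)
        for c in design.conditions
        for t in design.times[1:]
    ]


def enumerate_condition_contrasts(design: ExperimentalDesign) -> list[ContrastSpec]:
    """Each unordered condition pair once per time; length T x C(C-1)/2."""
    if design.n_conditions < 2:
        raise DesignError("no condition pair: condition contrasts need C >= 2")
    out = []
    for t in design.times:
        for i, a in enumerate(design.conditions):
            for b in design.conditions[i + 1:]:
                lo, hi = sorted((a, b))
                out.append(ContrastSpec("condition", lo, hi, t))
    return out


def count_analysis_units(design: ExperimentalDesign,
                         family: Literal["temporal", "condition"]) -> int:
    """Number of DE analysis units in a contrast family.

    temporal: C x (T-1), one per condition per non-reference time.
    condition: C x T, one per-(condition, time) specificity analysis.  Note
    the underlying pairwise contrasts number T x C(C-1)/2 — use
    ``len(enumerate_condition_contrasts(design))`` for that count.
    """
    if family == "temporal":
        return design.n_conditions * (design.n_times - 1)
    if family == "condition":
        return design.n_conditions * design.n_times
    raise DesignError(f"unknown analysis family {family!r}")


# -- file I/O --------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_sample_sheet(path: str | Path) -> ExperimentalDesign:
    table = pd.read_csv(Path(path), sep=_sep_for(Path(path)))
    return ExperimentalDesign.from_sample_table(table)


def read_counts(
    path: str | Path,
    sample_sheet: str | Path | None = None,
) -> tuple[CountMatrix, ExperimentalDesign]:
    """Read a count table (first column gene id, one column per sample).

    With ``sample_sheet`` the design comes from the sheet and every count
    column must be listed there; without it every column name must follow
    the ``{condition}_{time}_r{replicate}`` convention.  Row and column
    order of the file are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    gene_ids = [str(g) for g in table.index]
    sample_ids = [str(c) for c in table.columns]
    for col in table.columns:
        if not pd.api.types.is_numeric_dtype(table[col]):
            bad = table.index[pd.to_numeric(table[col], errors="coerce").isna()][0]
            raise DesignError(
                f"non-integer count at gene {bad!r}, sample {col!r}: "
                f"{table.loc[bad, col]!r}"
            )
    cm = CountMatrix(gene_ids, sample_ids, table.to_numpy())

    if sample_sheet is not None:
        design = read_sample_sheet(sample_sheet)
        known = set(design.sample_ids)
        unknown = [s for s in sample_ids if s not in known]
        if unknown:
            raise DesignError(
                f"count columns absent from the sample sheet: {unknown}"
            )
        extra = [s for s in design.sample_ids if s not in set(sample_ids)]
        if extra:
            raise DesignError(f"sample sheet rows without a count column: {extra}")
        # re-order design samples to the count-file column order
        by_id = {s.sample_id: s for s in design.samples}
        design = ExperimentalDesign(
            tuple(by_id[s] for s in sample_ids), design.conditions, design.times
        )
    else:
        design = ExperimentalDesign.from_sample_names(sample_ids)
    return cm, design


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write counts as delimited text; inverse of :func:`read_counts`."""
    path = Path(path)
    cm.to_frame().rename_axis("gene_id").to_csv(path, sep=_sep_for(path))
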