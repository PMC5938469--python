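"""Resource-use and resource-availability matrices.

Species are characterized by the resources they use (foraging strata, nest
locations, diet items); habitat types by the resources they make available,
scored on an equivalent grid. Sharing one schema across the two matrix kinds
is what makes community and landscape functional diversity commensurable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Block",
    "Kind",
    "Category",
    "ResourceSchema",
    "ResourceMatrix",
    "ValidationError",
    "default_schema",
    "read_resource_matrix",
    "write_resource_matrix",
    "split_by_provenance",
]

PROVENANCES = ("native", "exotic")


class ValidationError(ValueError):
    """A resource matrix violated its schema."""


class Block(str, Enum):
    FORAGING_STRATA = "foraging_strata"
    NEST_LOCATION = "nest_location"
    DIET = "diet"


class Kind(str, Enum):
    BINARY = "binary"
    ORDINAL = "ordinal"


@dataclass(frozen=True)
class Category:
    name: str
    block: Block
    kind: Kind

    @property
    def max_level(self) -> int:
        return 1 if self.kind is Kind.BINARY else 3


@dataclass(frozen=True)
class ResourceSchema:
    """Ordered list of resource categories with their coding."""

    categories: tuple[Category, ...]

    def __post_init__(self):
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate category names in schema")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.categories]

    @property
    def max_levels(self) -> np.ndarray:
        return np.array([c.max_level for c in self.categories], dtype=int)

    def __len__(self) -> int:
        return len(self.categories)


def default_schema() -> ResourceSchema:
    """6 binary foraging strata + 7 binary nest locations + 25 ordinal (0-3) diet items."""
    cats = (
        [Category(f"strata_{i + 1}", Block.FORAGING_STRATA, Kind.BINARY) for i in range(6)]
        + [Category(f"nest_{i + 1}", Block.NEST_LOCATION, Kind.BINARY) for i in range(7)]
        + [Category(f"diet_{i + 1}", Block.DIET, Kind.ORDINAL) for i in range(25)]
    )
    return ResourceSchema(tuple(cats))


def schema_from_yaml(path: str | Path) -> ResourceSchema:
    """Sidecar schema: a mapping ``name -> {block, kind}`` in file order."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    cats = tuple(
        Category(name, Block(entry["block"]), Kind(entry["kind"]))
        for name, entry in mapping.items()
    )
    return ResourceSchema(cats)


@dataclass
class ResourceMatrix:
    """Components (species or habitats) x resource categories, with provenance labels."""

    schema: ResourceSchema
    component_ids: list[str]
    provenance: dict[str, str]
    values: np.ndarray  # integer grid, shape (n_components, n_categories)
    component_kind: str  # "species" | "habitat"
    low_count_warning: bool = field(default=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.validate()

    def validate(self) -> None:
        n, p = self.values.shape if self.values.ndim == 2 else (0, 0)
        if n == 0:
            raise ValidationError("no components")
        if p != len(self.schema):
            raise ValidationError(
                f"{p} value columns but schema has {len(self.schema)} categories"
            )
        if len(self.component_ids) != n:
            raise ValidationError("component_ids length mismatch")
        if len(set(self.component_ids)) != n:
            dupes = {i for i in self.component_ids if self.component_ids.count(i) > 1}
            raise ValidationError(f"duplicate component id(s): {sorted(dupes)}")
        for cid in self.component_ids:
            prov = self.provenance.get(cid)
            if prov not in PROVENANCES:
                raise ValidationError(f"unknown provenance label {prov!r} for {cid!r}")
        if not np.issubdtype(self.values.dtype, np.integer):
            flt = np.asarray(self.values, dtype=float)
            if np.isnan(flt).any():
                i, j = np.argwhere(np.isnan(flt))[0]
                raise ValidationError(
                    f"missing value at row {self.component_ids[i]!r}, "
                    f"column {self.schema.names[j]!r}"
                )
            if not np.all(flt == np.round(flt)):
                raise ValidationError("non-integer resource values")
            self.values = flt.astype(int)
        maxes = self.schema.max_levels
        bad = (self.values < 0) | (self.values > maxes[None, :])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"value {self.values[i, j]} > max_level {maxes[j]} at row "
                f"{self.component_ids[i]!r}, column {self.schema.names[j]!r}"
                if self.values[i, j] > maxes[j]
                else f"negative value at row {self.component_ids[i]!r}, "
                f"column {self.schema.names[j]!r}"
            )

    @property
    def n_components(self) -> int:
        return len(self.component_ids)

    def provenance_counts(self) -> dict[str, int]:
        out = {p: 0 for p in PROVENANCES}
        for cid in self.component_ids:
            out[self.provenance[cid]] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.schema.names)
        df.insert(0, "provenance", [self.provenance[c] for c in self.component_ids])
        df.insert(0, "id", self.component_ids)
        return df

    def subset(self, ids: Sequence[str]) -> "ResourceMatrix":
        idx = {c: i for i, c in enumerate(self.component_ids)}
        missing = [c for c in ids if c not in idx]
        if missing:
            raise KeyError(f"unknown component id(s): {missing}")
        rows = [idx[c] for c in ids]
        return ResourceMatrix(
            schema=self.schema,
            component_ids=list(ids),
            provenance={c: self.provenance[c] for c in ids},
            values=self.values[rows],
            component_kind=self.component_kind,
        )


def read_resource_matrix(
    path: str | Path | io.TextIOBase,
    component_kind: str,
    schema: ResourceSchema | None = None,
) -> ResourceMatrix:
    """Read a resource matrix CSV: columns ``id, provenance, <category...>``.

    Category kinds come from *schema* (default: the 38-category schema) and are
    matched against the header by name when the header names are known to the
    schema, otherwise positionally.
    """
    df = pd.read_csv(path, dtype={0: str, 1: str})
    if df.shape[0] == 0:
        raise ValidationError("no components")
    if df.shape[1] < 3:
        raise ValidationError("expected columns: id, provenance, categories...")
    schema = schema or default_schema()
    value_cols = list(df.columns[2:])
    if set(value_cols) == set(schema.names):
        df = df[[df.columns[0], df.columns[1], *schema.names]]
    elif len(value_cols) != len(schema):
        raise ValidationError(
            f"{len(value_cols)} category columns but schema has {len(schema)}"
        )
    ids = df.iloc[:, 0].astype(str).tolist()
    prov = dict(zip(ids, df.iloc[:, 1].astype(str).str.strip().str.lower()))
    values = df.iloc[:, 2:].to_numpy()
    return ResourceMatrix(
        schema=schema,
        component_ids=ids,
        provenance=prov,
        values=values,
        component_kind=component_kind,
    )


def write_resource_matrix(m: ResourceMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, index=False)


def split_by_provenance(m: ResourceMatrix) -> tuple[ResourceMatrix, ResourceMatrix]:
    """Partition into (native, exotic) matrices, preserving row order.

    A group with fewer than 2 components gets ``low_count_warning=True``
    (functional diversity over it is undefined downstream). An empty group is
    returned as a zero-row matrix bypassing the no-components validation.
    """
    out = []
    for label in PROVENANCES:
        ids = [c for c in m.component_ids if m.provenance[c] == label]
        if ids:
            sub = m.subset(ids)
            sub.low_count_warning = len(ids) < 2
        else:
            sub = object.__new__(ResourceMatrix)
            sub.schema = m.schema
            sub.component_ids = []
            sub.provenance = {}
            sub.values = np.zeros((0, len(m.schema)), dtype=int)
            sub.component_kind = m.component_kind
            sub.low_count_warning = True
        out.append(sub)
    return tuple(out)
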