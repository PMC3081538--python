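"""Labeled feature tables of per-protein predictor outputs.

The central container is :class:`FeatureTable`: one row per protein, one
column per prediction tool, values in ``[0, 1]`` (binary hit/no-hit tools use
``{0, 1}``, scoring tools like MitoProt II use the full range) with an explicit
missingness mask for tools that return no call for a protein.  Mitochondrial
proteins carry label 1 (the positive class), non-mitochondrial label 0 — fixed
everywhere so that "sensitivity" always means recall of mitochondrial proteins.

Files are plain TSV: ``id<TAB>label<TAB><tool1>...<toolN>``, UTF-8, '.'
decimal separator, missing cells written as the missing token (default
``NA``).  Floats are serialized with ``repr`` (shortest round-trip form), so
writing a table twice produces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Default token used for cells where a tool produced no call.
MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class ToolSubset:
    """A non-empty subset of predictor columns encoded as a bitmask.

    Bit ``i`` set means tool ``i`` (column order of the owning table) is
    included.  The empty subset is invalid: a combined predictor needs at
    least one source of evidence.
    """

    mask: int

    def __post_init__(self) -> None:
        if not isinstance(self.mask, (int, np.integer)) or self.mask <= 0:
            raise ValueError(f"subset mask must be a positive integer, got {self.mask!r}")
        object.__setattr__(self, "mask", int(self.mask))

    @property
    def size(self) -> int:
        """Number of tools in the subset (popcount of the mask)."""
        return self.mask.bit_count()

    @property
    def indices(self) -> tuple[int, ...]:
        """Included tool indices, ascending."""
        return tuple(i for i in range(self.mask.bit_length()) if self.mask >> i & 1)

    @classmethod
    def from_indices(cls, indices: Sequence[int]) -> "ToolSubset":
        mask = 0
        for i in indices:
            if i < 0:
                raise ValueError(f"negative tool index {i}")
            mask |= 1 << i
        return cls(mask)

    @classmethod
    def from_names(cls, names: Sequence[str], tool_names: Sequence[str]) -> "ToolSubset":
        order = {name: i for i, name in enumerate(tool_names)}
        try:
            return cls.from_indices([order[n] for n in names])
        except KeyError as exc:
            raise ValueError(f"unknown tool name {exc.args[0]!r}; known: {list(tool_names)}") from None

    def contains(self, index: int) -> bool:
        return bool(self.mask >> index & 1)

    def tool_names(self, all_names: Sequence[str]) -> tuple[str, ...]:
        if self.mask >= 1 << len(all_names):
            raise ValueError(f"mask {self.mask} references tools beyond the {len(all_names)} available")
        return tuple(all_names[i] for i in self.indices)


@dataclass
class FeatureTable:
    """Per-protein predictor outputs with class labels and a missingness mask.

    Invariants (enforced by :meth:`validate`): unique protein ids, label in
    {0, 1}, ``values`` of shape ``(n_proteins, n_tools)``, every non-missing
    value in ``[0, 1]``.
    """

    protein_ids: list[str]
    labels: np.ndarray            # shape (n,), int8, values in {0, 1}
    tool_names: list[str]
    values: np.ndarray            # shape (n, m), float64; entries under the mask are undefined
    missing_mask: np.ndarray = field(default=None)  # shape (n, m), bool

    def __post_init__(self) -> None:
        self.protein_ids = list(self.protein_ids)
        self.tool_names = list(self.tool_names)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (proteins x tools)")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    # -- basic geometry -------------------------------------------------

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_tools(self) -> int:
        return len(self.tool_names)

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.labels == 0))

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def validate(self) -> None:
        n, m = len(self.protein_ids), len(self.tool_names)
        if m < 1:
            raise ValueError("a feature table needs at least one tool column")
        if len(set(self.protein_ids)) != n:
            seen: set[str] = set()
            for pid in self.protein_ids:
                if pid in seen:
                    raise ValueError(f"duplicate protein id {pid!r}")
                seen.add(pid)
        if self.labels.shape != (n,):
            raise ValueError(f"labels shape {self.labels.shape} != ({n},)")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (non-mitochondrial) or 1 (mitochondrial)")
        if self.values.shape != (n, m):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {m})")
        if self.missing_mask.shape != (n, m):
            raise ValueError(f"missing_mask shape {self.missing_mask.shape} != ({n}, {m})")
        observed = self.values[~self.missing_mask]
        if observed.size and (np.isnan(observed).any() or (observed < 0).any() or (observed > 1).any()):
            bad = np.argwhere(~self.missing_mask & ~((self.values >= 0) & (self.values <= 1)))
            r, c = bad[0]
            raise ValueError(
                f"value {self.values[r, c]!r} out of [0, 1] at row {r} "
                f"(protein {self.protein_ids[r]!r}), column {self.tool_names[c]!r}"
            )

    def require_evaluable(self) -> None:
        """Check the table can back a train/test evaluation (≥2 per class)."""
        if self.n_positive < 2 or self.n_negative < 2:
            raise ValueError(
                f"evaluation needs at least 2 proteins per class; "
                f"got {self.n_positive} positive / {self.n_negative} negative"
            )

    # -- slicing --------------------------------------------------------

    def restrict(self, subset: ToolSubset) -> "FeatureTable":
        """Return the table restricted to the subset's tool columns."""
        idx = list(subset.indices)
        if subset.mask >= 1 << self.n_tools:
            raise ValueError(f"subset mask {subset.mask} out of range for {self.n_tools} tools")
        return FeatureTable(
            protein_ids=self.protein_ids,
            labels=self.labels,
            tool_names=[self.tool_names[i] for i in idx],
            values=self.values[:, idx],
            missing_mask=self.missing_mask[:, idx],
        )

    def take_rows(self, indices: np.ndarray) -> "FeatureTable":
        indices = np.asarray(indices, dtype=np.intp)
        return FeatureTable(
            protein_ids=[self.protein_ids[i] for i in indices],
            labels=self.labels[indices],
            tool_names=self.tool_names,
            values=self.values[indices],
            missing_mask=self.missing_mask[indices],
        )

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.protein_ids == other.protein_ids
            and self.tool_names == other.tool_names
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.array_equal(
                np.where(self.missing_mask, 0.0, self.values),
                np.where(other.missing_mask, 0.0, other.values),
            )
        )


def impute_missing(table: FeatureTable, fill_value: float = 0.0) -> FeatureTable:
    """Replace missing cells by ``fill_value`` (default 0, the no-evidence point).

    Non-missing cells are untouched; the result has an all-false mask.
    """
    if not 0.0 <= fill_value <= 1.0:
        raise ValueError(f"fill_value must lie in [0, 1], got {fill_value}")
    values = np.where(table.missing_mask, fill_value, table.values)
    return FeatureTable(
        protein_ids=table.protein_ids,
        labels=table.labels,
        tool_names=table.tool_names,
        values=values,
        missing_mask=np.zeros_like(table.missing_mask),
    )


def read_feature_table(path, missing_token: str = MISSING_TOKEN) -> FeatureTable:
    """Read a TSV feature table.

    Expected header: ``id<TAB>label<TAB><tool1>...<toolN>``.  Labels must be
    the literal tokens ``0``/``1``; values must parse as decimals in [0, 1]
    or equal ``missing_token``.  Malformed input raises ``ValueError`` with
    the offending row/column — nothing is silently coerced.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "id" or header[1] != "label":
        raise ValueError(f"{path}: header must start with 'id<TAB>label' followed by tool names")
    tool_names = header[2:]
    if len(set(tool_names)) != len(tool_names):
        raise ValueError(f"{path}: duplicate tool names in header")

    ids: list[str] = []
    seen: set[str] = set()
    labels: list[int] = []
    n_tools = len(tool_names)
    rows = np.zeros((len(lines) - 1, n_tools), dtype=np.float64)
    mask = np.zeros((len(lines) - 1, n_tools), dtype=bool)
    for r, line in enumerate(lines[1:], start=1):
        parts = line.split("\t")
        if len(parts) != 2 + n_tools:
            raise ValueError(f"{path}: line {r + 1} has {len(parts)} fields, expected {2 + n_tools}")
        pid, label = parts[0], parts[1]
        if pid in seen:
            raise ValueError(f"{path}: duplicate protein id {pid!r} at line {r + 1}")
        seen.add(pid)
        ids.append(pid)
        if label not in ("0", "1"):
            raise ValueError(f"{path}: non-binary label {label!r} at line {r + 1}")
        labels.append(int(label))
        for c, cell in enumerate(parts[2:]):
            if cell == missing_token:
                mask[r - 1, c] = True
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: unparseable value {cell!r} at line {r + 1}, column {tool_names[c]!r}"
                ) from None
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"{path}: value {cell} outside [0, 1] at line {r + 1}, column {tool_names[c]!r}"
                )
            rows[r - 1, c] = v
    return FeatureTable(
        protein_ids=ids,
        labels=np.asarray(labels, dtype=np.int8),
        tool_names=tool_names,
        values=rows,
        missing_mask=mask,
    )


def _format_value(v: float) -> str:
    # repr gives the shortest string that round-trips the float exactly
    if v == int(v):
        return str(int(v))
    return repr(float(v))


def write_feature_table(table: FeatureTable, path, missing_token: str = MISSING_TOKEN) -> None:
    """Write a table as TSV readable by :func:`read_feature_table`.

    Column order is preserved; missing cells are serialized as the missing
    token; re-reading reproduces the table exactly.
    """
    table.validate()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(["id", "label", *table.tool_names]) + "\n")
        for r in range(table.n_proteins):
            cells = [table.protein_ids[r], str(int(table.labels[r]))]
            for c in range(table.n_tools):
                if table.missing_mask[r, c]:
                    cells.append(missing_token)
                else:
                    cells.append(_format_value(table.values[r, c]))
            fh.write("\t".join(cells) + "\n")
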