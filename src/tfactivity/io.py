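"""Reading and writing the pipeline's tabular formats.

All tables are delimited text (tab by default).  An expression table has a
``gene`` column followed by one column per sampling time, headers being bare
minute labels (``0``, ``2.5`` ... ``80``).  A regulon table has columns
``tf``, ``gene`` and an optional ``sign`` column with values ``+``, ``-`` or
``?``.  Values written by :func:`write_table` are deterministic: fixed column
order, rows sorted by primary key, and floats rendered with 17 significant
digits so that a rerun is byte-identical and a read-back recovers the stored
float64 exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

#: Tokens accepted as explicitly-missing cells in input tables.
NA_TOKENS = {"", "NA", "NaN", "nan"}

#: Sign codes used in regulon tables.
_SIGN_CODES = {"+": 1, "-": -1, "−": -1, "?": None, "": None}


class TableFormatError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass(frozen=True)
class ExpressionTimeCourse:
    """A genes x timepoints matrix of log2 expression ratios.

    Values are log2 ratios to the pre-treatment (minute-0) sample; missing
    cells are NaN.  Gene identifiers are unique, timepoints strictly
    ascending, in minutes.
    """

    gene_ids: tuple[str, ...]
    timepoints_min: tuple[float, ...]
    values: np.ndarray  # shape (n_genes, n_timepoints), float64, NaN = missing
    condition_label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dups = sorted({g for g in self.gene_ids if g in seen or seen.add(g)})
            raise TableFormatError(f"duplicate gene ids: {', '.join(dups)}")
        tps = np.asarray(self.timepoints_min, dtype=float)
        if tps.size and (np.any(np.diff(tps) <= 0) or np.any(tps < 0)):
            raise TableFormatError(
                f"timepoints must be non-negative and strictly ascending, got {list(tps)}"
            )
        if values.shape != (len(self.gene_ids), len(self.timepoints_min)):
            raise TableFormatError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.timepoints_min)} timepoints"
            )
        with np.errstate(invalid="ignore"):
            if np.any(np.isinf(values)):
                raise TableFormatError("expression values must be finite or missing (NaN)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints_min)

    @property
    def has_baseline(self) -> bool:
        """True when a minute-0 (pre-treatment) column is present."""
        return bool(self.timepoints_min) and self.timepoints_min[0] == 0.0

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in expression matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.timepoints_min)
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionTimeCourse":
        idx = [self.gene_index(g) for g in gene_ids]
        return ExpressionTimeCourse(
            tuple(gene_ids), self.timepoints_min, self.values[idx], self.condition_label
        )


@dataclass(frozen=True)
class RegulonNetwork:
    """TF -> target-gene edges with optional regulatory sign.

    ``edges`` maps ``(tf_id, gene_id)`` to +1 (activation), -1 (repression)
    or ``None`` (unknown).  Duplicate rows are collapsed upstream; duplicate
    rows with conflicting signs collapse to unknown.
    """

    edges: Mapping[tuple[str, str], int | None]

    @property
    def tf_ids(self) -> tuple[str, ...]:
        return tuple(sorted({tf for tf, _ in self.edges}))

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(sorted({g for _, g in self.edges}))

    def targets(self, tf_id: str) -> tuple[str, ...]:
        return tuple(sorted(g for tf, g in self.edges if tf == tf_id))

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class CategoryMap:
    """Gene -> functional category, one category per gene.

    Genes absent from the map fall into ``"unclassified"``.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = sorted(g for g, c in self.mapping.items() if not str(c).strip())
        if bad:
            raise TableFormatError(f"empty category name for genes: {', '.join(bad)}")

    def category(self, gene_id: str) -> str:
        return self.mapping.get(gene_id, "unclassified")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.mapping.values()) | {"unclassified"}))


def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    return [ln for ln in text.splitlines() if ln and not ln.startswith("#")]


def _split(line: str, delimiter: str) -> list[str]:
    return [c.strip() for c in line.split(delimiter)]


def read_expression_table(
    path: str | Path, condition_label: str = "", delimiter: str = "\t"
) -> ExpressionTimeCourse:
    """Read a genes x minutes expression table.

    The first column holds gene ids; remaining headers must parse as minutes.
    Columns are reordered to ascending time, rows sorted by gene id, so the
    in-memory object does not depend on file ordering.  Empty cells and
    ``NA`` are recorded as missing, never as zero.
    """
    lines = _read_lines(path)
    if not lines:
        raise TableFormatError(f"{path}: empty expression table")
    header = _split(lines[0], delimiter)
    if len(header) < 2:
        raise TableFormatError(f"{path}: expression table needs >=1 timepoint column")
    try:
        minutes = [float(h) for h in header[1:]]
    except ValueError as exc:
        raise TableFormatError(f"{path}: timepoint header not parseable as minutes: {exc}")

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for i, line in enumerate(lines[1:], start=2):
        cells = _split(line, delimiter)
        if len(cells) != len(header):
            raise TableFormatError(f"{path}, line {i}: expected {len(header)} columns, got {len(cells)}")
        gene_ids.append(cells[0])
        row: list[float] = []
        for j, cell in enumerate(cells[1:], start=2):
            if cell in NA_TOKENS:
                row.append(math.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise TableFormatError(
                    f"{path}, line {i}, column {j} ({header[j - 1]} min): "
                    f"non-numeric cell {cell!r}"
                ) from None
        rows.append(row)

    dups = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
    if dups:
        raise TableFormatError(f"{path}: duplicate gene ids: {', '.join(dups)}")

    values = np.asarray(rows, dtype=float)
    time_order = np.argsort(minutes, kind="stable")
    gene_order = np.argsort(gene_ids, kind="stable")
    return ExpressionTimeCourse(
        gene_ids=tuple(gene_ids[i] for i in gene_order),
        timepoints_min=tuple(minutes[i] for i in time_order),
        values=values[np.ix_(gene_order, time_order)],
        condition_label=condition_label,
    )


def read_regulon_table(path: str | Path, delimiter: str = "\t") -> RegulonNetwork:
    """Read a TF -> gene edge table with an optional sign column.

    Duplicate (tf, gene) rows are deduplicated; duplicates with conflicting
    signs keep sign ``unknown`` and emit a warning.  An edgeless file is a
    hard error.
    """
    lines = _read_lines(path)
    if not lines:
        raise TableFormatError(f"{path}: empty regulon table")
    header = [h.lower() for h in _split(lines[0], delimiter)]
    if header[:2] != ["tf", "gene"]:
        raise TableFormatError(f"{path}: regulon header must start with 'tf', 'gene', got {header}")
    has_sign = len(header) > 2 and header[2] == "sign"

    edges: dict[tuple[str, str], int | None] = {}
    conflicts: set[tuple[str, str]] = set()
    for i, line in enumerate(lines[1:], start=2):
        cells = _split(line, delimiter)
        if len(cells) < 2:
            raise TableFormatError(f"{path}, line {i}: need at least tf and gene columns")
        tf, gene = cells[0], cells[1]
        raw_sign = cells[2] if has_sign and len(cells) > 2 else ""
        if raw_sign not in _SIGN_CODES:
            raise TableFormatError(f"{path}, line {i}: unknown sign {raw_sign!r}")
        sign = _SIGN_CODES[raw_sign]
        key = (tf, gene)
        if key in edges and edges[key] != sign and key not in conflicts:
            conflicts.add(key)
            edges[key] = None
            warnings.warn(
                f"conflicting signs for edge {tf}->{gene}; keeping sign 'unknown'",
                stacklevel=2,
            )
        elif key not in edges:
            edges[key] = sign
    if not edges:
        raise TableFormatError(f"{path}: regulon table has no edges")
    return RegulonNetwork(edges=edges)


def read_category_table(path: str | Path, delimiter: str = "\t") -> CategoryMap:
    """Read a two-column gene -> category table (header ``gene``, ``category``)."""
    lines = _read_lines(path)
    if not lines:
        raise TableFormatError(f"{path}: empty category table")
    mapping: dict[str, str] = {}
    for i, line in enumerate(lines[1:], start=2):
        cells = _split(line, delimiter)
        if len(cells) < 2:
            raise TableFormatError(f"{path}, line {i}: need gene and category columns")
        mapping[cells[0]] = cells[1]
    return CategoryMap(mapping=mapping)


def _format_cell(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return format(value, ".17g")
    if isinstance(value, (np.floating,)):
        return _format_cell(float(value))
    if isinstance(value, (np.integer,)):
        return str(int(value))
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def config_hash(config: object) -> str:
    """Stable short hash of a configuration object (dict/dataclass/str)."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    digest = hashlib.sha256(repr(sorted(config.items()) if isinstance(config, dict) else config).encode())
    return digest.hexdigest()[:12]


def write_table(
    records: Iterable,
    path: str | Path,
    seed: int | None = None,
    config: object | None = None,
) -> Path:
    """Write records (dataclass instances or dicts) to a deterministic TSV.

    Column order follows the record's field order; rows are sorted by the
    first field (primary key); floats use 17 significant digits so a rerun
    is byte-identical and values round-trip exactly.  A leading comment line
    records tool version, seed and config hash.
    """
    records = list(records)
    columns: list[str]
    dict_rows: list[dict[str, object]] = []
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            dict_rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, dict):
            dict_rows.append(dict(rec))
        else:
            raise TypeError(f"write_table cannot serialize {type(rec).__name__}")
    if dict_rows:
        columns = list(dict_rows[0].keys())
    else:
        columns = []
    key = lambda row: tuple(str(row[c]) for c in columns[:1])  # noqa: E731
    dict_rows.sort(key=key)

    meta = f"# tfactivity {__version__}"
    if seed is not None:
        meta += f" seed={seed}"
    if config is not None:
        meta += f" config_hash={config_hash(config)}"

    out = Path(path)
    try:
        with out.open("w") as fh:
            fh.write(meta + "\n")
            fh.write("\t".join(columns) + "\n")
            for row in dict_rows:
                fh.write("\t".join(_format_cell(row[c]) for c in columns) + "\n")
    except OSError as exc:
        raise TableFormatError(f"cannot write table to {out}: {exc}") from exc
    return out


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table` (comment line skipped)."""
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        na_values=sorted(NA_TOKENS - {""}),
        float_precision="round_trip",
    )
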