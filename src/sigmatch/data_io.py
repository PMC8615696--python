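"""Readers and writers for the tab-delimited formats the screen touches.

Three formats are handled: GCT expression matrices (1.2 and 1.3 text
dialects), GMT gene-set libraries, and plain TSV score/metadata tables.
Gene and sample identifiers are opaque, case-sensitive strings; no
symbol/probe mapping is attempted. All readers validate eagerly and fail
with the offending line number where one exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
TREATMENT = "treatment"
_CLASSES = frozenset({CONTROL, TREATMENT})


class FormatError(ValueError):
    """The file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """The file parses but violates a data invariant."""


class SchemaError(ValueError):
    """A required column is missing from a table."""


@dataclass
class ExpressionExperiment:
    """A genes x samples matrix with control/treatment labels.

    ``values`` holds log-scale expression or z-scores (unitless); rows
    follow ``gene_ids`` and columns follow ``sample_ids``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_class: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        g, s = self.values.shape
        if g != len(self.gene_ids):
            raise ValidationError(
                f"matrix has {g} rows but {len(self.gene_ids)} gene ids"
            )
        if s != len(self.sample_ids):
            raise ValidationError(
                f"matrix has {s} columns but {len(self.sample_ids)} sample ids"
            )
        if len(self.sample_class) != s:
            raise ValidationError("one class label required per sample")
        if len(set(self.gene_ids)) != g:
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicated gene ids: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != s:
            raise ValidationError("duplicated sample ids")
        bad = set(self.sample_class) - _CLASSES
        if bad:
            raise ValidationError(f"unknown sample classes: {sorted(bad)}")
        if CONTROL not in self.sample_class or TREATMENT not in self.sample_class:
            raise ValidationError("need at least 1 control and 1 treatment sample")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def class_mask(self, label: str) -> np.ndarray:
        return np.array([c == label for c in self.sample_class])


@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]


@dataclass
class GeneSetLibrary:
    """An ordered collection of named gene sets (GMT contents)."""

    entries: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicated set names: {sorted(_duplicates(names))[:5]}")
        for e in self.entries:
            if not e.members:
                raise ValidationError(f"gene set {e.name!r} is empty")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def as_dict(self) -> dict[str, set[str]]:
        return {e.name: set(e.members) for e in self.entries}

    def names(self) -> list[str]:
        return [e.name for e in self.entries]


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


# ---------------------------------------------------------------------------
# GCT


def read_gct(path: str | Path, class_path: str | Path) -> ExpressionExperiment:
    """Read a GCT 1.2/1.3 matrix plus a sample-class sidecar TSV.

    The sidecar has columns ``sample_id`` and ``class`` (control/treatment);
    classes are never inferred from sample names. For GCT 1.3 only gene ids
    and values are retained; row/column annotations are parsed and dropped.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file (line 1)")
    version = lines[0].strip()
    if version == "#1.2":
        n_meta_rows, n_row_annot = 0, 0
    elif version == "#1.3":
        n_row_annot = None  # read from the dimension line
    else:
        raise FormatError(f"{path}: line 1: unknown GCT version {version!r}")
    if len(lines) < 3:
        raise FormatError(f"{path}: line 2: truncated GCT")
    dims = lines[1].split("\t")
    try:
        dims = [int(x) for x in dims]
    except ValueError as exc:
        raise FormatError(f"{path}: line 2: non-integer dimensions") from exc
    if version == "#1.2":
        if len(dims) != 2:
            raise FormatError(f"{path}: line 2: GCT 1.2 needs 2 dimensions")
        n_rows, n_cols = dims
    else:
        if len(dims) != 4:
            raise FormatError(f"{path}: line 2: GCT 1.3 needs 4 dimensions")
        n_rows, n_cols, n_row_annot, n_meta_rows = dims

    header = lines[2].rstrip("\n").split("\t")
    n_lead = 2 if version == "#1.2" else 1 + n_row_annot
    if len(header) != n_lead + n_cols:
        raise FormatError(
            f"{path}: line 3: header has {len(header)} fields, "
            f"expected {n_lead + n_cols}"
        )
    sample_ids = header[n_lead:]

    body_start = 3 + (n_meta_rows if version == "#1.3" else 0)
    body = [ln for ln in lines[body_start:] if ln.strip() != ""]
    if len(body) != n_rows:
        raise FormatError(
            f"{path}: line 2: declared {n_rows} data rows but found {len(body)}"
        )
    gene_ids: list[str] = []
    values = np.empty((n_rows, n_cols))
    for i, ln in enumerate(body):
        fields = ln.split("\t")
        lineno = body_start + i + 1
        if len(fields) != n_lead + n_cols:
            raise FormatError(
                f"{path}: line {lineno}: {len(fields)} fields, expected {n_lead + n_cols}"
            )
        gene_ids.append(fields[0])
        try:
            values[i] = [float(x) for x in fields[n_lead:]]
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric value") from exc

    classes = read_sample_classes(class_path)
    missing = [s for s in sample_ids if s not in classes]
    if missing:
        raise ValidationError(f"samples without a class label: {missing[:5]}")
    sample_class = [classes[s] for s in sample_ids]
    return ExpressionExperiment(gene_ids, sample_ids, values, sample_class)


def write_gct(experiment: ExpressionExperiment, path: str | Path) -> None:
    """Write a GCT 1.2 text file (values at 10 significant digits)."""
    experiment.validate()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{experiment.n_genes}\t{len(experiment.sample_ids)}\n")
        fh.write("Name\tDescription\t" + "\t".join(experiment.sample_ids) + "\n")
        for gid, row in zip(experiment.gene_ids, experiment.values):
            vals = "\t".join(f"{v:.10g}" for v in row)
            fh.write(f"{gid}\tna\t{vals}\n")


def read_sample_classes(path: str | Path) -> dict[str, str]:
    """Read a (sample_id, class) TSV; classes must be control/treatment."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "class"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicated sample ids")
    bad = set(df["class"]) - _CLASSES
    if bad:
        raise ValidationError(f"{path}: unknown classes {sorted(bad)}")
    return dict(zip(df["sample_id"], df["class"]))


def write_sample_classes(classes: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\n")
        for sid, cls in classes.items():
            fh.write(f"{sid}\t{cls}\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a GMT library: name, description, then members; members deduplicated."""
    path = Path(path)
    entries: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    seen.add(g)
                    members.append(g)
            entries.append(GeneSet(name, desc, members))
    return GeneSetLibrary(entries)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in library:
            fh.write("\t".join([e.name, e.description or "na", *e.members]) + "\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_score_table(
    path: str | Path,
    id_column: str,
    score_column: str,
    bounds: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Read a compound->score TSV; optionally enforce score bounds.

    ``bounds=(-1.0, 1.0)`` is the blood-brain-barrier probability contract.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (id_column, score_column):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    ids = df[id_column].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].tolist()
        raise ValidationError(f"{path}: duplicated ids: {dupes[:5]}")
    scores = df[score_column].astype(float)
    if not np.all(np.isfinite(scores)):
        raise ValidationError(f"{path}: non-finite scores")
    if bounds is not None:
        lo, hi = bounds
        out = scores[(scores < lo) | (scores > hi)]
        if len(out):
            raise ValidationError(
                f"{path}: scores outside [{lo}, {hi}]: {out.tolist()[:5]}"
            )
    return dict(zip(ids, scores))


METADATA_COLUMNS = ["signature_id", "drug_id", "cell_line", "dose", "time"]


def read_metadata_table(path: str | Path) -> pd.DataFrame:
    """Read the signature-metadata TSV (signature_id, drug_id, cell_line, dose, time)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df["signature_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicated signature ids")
    return df[METADATA_COLUMNS].copy()


def write_metadata_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=METADATA_COLUMNS)
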