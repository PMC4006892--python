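"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
expression TSV
    Columns ``probe_id``, ``gene_symbol``, then one column per sample; the
    header row carries sample names. Lines starting with ``#`` are
    provenance comments and are skipped on read.
groups TSV
    Two columns ``sample_id``, ``group``.
GMT
    Standard tab-separated gene sets: name, description, member genes.
qPCR TSV
    Columns ``sample_id``, ``group``, ``target``, ``ct``.

Writers optionally prepend a provenance block (``#``-prefixed lines carrying
the tool version and a config hash); ``write(read(x)) == x`` holds for all
formats.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, GeneSet
from .errors import InputError


def _check_nonempty(path: Path) -> Path:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file does not exist: {path}")
    if path.stat().st_size == 0:
        raise InputError(f"input file is empty: {path}")
    return path


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def read_expression(expression_path, groups_path) -> ExpressionMatrix:
    """Load an expression TSV plus its sample->group table."""
    path = _check_nonempty(expression_path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str, "gene_symbol": str})
    for col in ("probe_id", "gene_symbol"):
        if col not in df.columns:
            raise InputError(f"{path}: expression TSV lacks required column {col!r}")
    if df.empty:
        raise InputError(f"{path}: expression TSV contains no probe rows")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].head(3).tolist()
        raise InputError(f"{path}: duplicate probe ids {dup}")
    df = df.set_index("probe_id")
    df.index.name = None
    genes = df.pop("gene_symbol").rename("gene")
    bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise InputError(f"{path}: non-numeric sample column(s) {list(bad)}")
    groups = read_groups(groups_path)
    return ExpressionMatrix(values=df.astype(float), genes=genes, groups=groups)


def write_expression(matrix: ExpressionMatrix, expression_path, groups_path=None,
                     provenance: dict | None = None) -> None:
    out = matrix.values.copy()
    out.insert(0, "gene_symbol", matrix.genes)
    out.index.name = "probe_id"
    with open(expression_path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        out.to_csv(fh, sep="\t")
    if groups_path is not None:
        write_groups(matrix.groups, groups_path, provenance=provenance)


def read_groups(path) -> pd.Series:
    path = _check_nonempty(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise InputError(f"{path}: groups TSV lacks required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise InputError(f"{path}: duplicate sample ids in groups TSV")
    groups = df.set_index("sample_id")["group"]
    groups.index.name = None
    return groups


def write_groups(groups: pd.Series, path, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        groups.rename("group").rename_axis("sample_id").to_csv(fh, sep="\t")


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: name <tab> description <tab> member genes."""
    path = _check_nonempty(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member, "
                    f"got {len(fields)} field(s)"
                )
            name, description, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                raise InputError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in seen:
                raise InputError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, members=tuple(members), description=description))
    if not sets:
        raise InputError(f"{path}: GMT file defines no gene sets")
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for gs in sets:
            writer.writerow([gs.name, gs.description, *gs.members])


def read_qpcr(path) -> pd.DataFrame:
    path = _check_nonempty(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sample_id", "group", "target", "ct"):
        if col not in df.columns:
            raise InputError(f"{path}: qPCR TSV lacks required column {col!r}")
    if df.empty:
        raise InputError(f"{path}: qPCR TSV contains no rows")
    if df["ct"].isna().any():
        raise InputError(f"{path}: qPCR TSV contains missing Ct values")
    return df


def write_qpcr(table: pd.DataFrame, path, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        table.to_csv(fh, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, provenance: dict | None = None, index: bool = True) -> None:
    """Write any result table as TSV with an optional provenance block."""
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep="\t", index=index)
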