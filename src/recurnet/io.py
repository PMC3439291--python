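"""Readers and writers for the pipeline's plain-text formats.

Expression: TSV, genes in rows, first column the gene ID, header row of sample
IDs.  Groups: two-column TSV sample -> group.  Clinical: CSV with a header.
Gene sets: standard GMT (term, description, tab-separated members).  All
writers are deterministic so identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .synthetic import AnnotationCollection, ClinicalTable, LabeledExpressionMatrix


class InputFormatError(ValueError):
    """A malformed input file; the message names file, line, and violation."""


# ---------------------------------------------------------------- expression

def write_expression(expr: LabeledExpressionMatrix, path: Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def write_groups(expr: LabeledExpressionMatrix, path: Path) -> None:
    expr.group.rename("group").to_csv(path, sep="\t", index_label="sample_id")


def read_expression(
    expression_path: Path, groups_path: Path
) -> LabeledExpressionMatrix:
    expression_path, groups_path = Path(expression_path), Path(groups_path)
    try:
        values = pd.read_csv(expression_path, sep="\t", index_col=0)
    except Exception as err:
        raise InputFormatError(f"{expression_path}: cannot parse as TSV: {err}") from err
    bad = values.columns[~values.apply(
        lambda c: pd.to_numeric(c, errors="coerce").notna().all()
    )]
    if len(bad):
        col = bad[0]
        coerced = pd.to_numeric(values[col], errors="coerce")
        row = coerced.index[coerced.isna()][0]
        line = values.index.get_loc(row) + 2  # header is line 1
        raise InputFormatError(
            f"{expression_path}: non-numeric value in column {col!r} at line {line}"
        )
    values = values.astype(float)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)
    if "group" not in groups.columns:
        raise InputFormatError(f"{groups_path}: missing 'group' column")
    group = groups["group"].astype(str)
    missing = set(values.columns) - set(group.index)
    if missing:
        raise InputFormatError(
            f"{groups_path}: samples without a group label: {sorted(missing)[:5]}"
        )
    return LabeledExpressionMatrix(
        values=values, group=group.reindex(values.columns)
    )


# ------------------------------------------------------------------ clinical

def write_clinical(clinical: ClinicalTable, path: Path) -> None:
    clinical.data.to_csv(path, index_label="patient_id", float_format="%.10g")


def read_clinical(path: Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    for col in ("time_months", "event", "group"):
        if col not in df.columns:
            raise InputFormatError(f"{path}: missing required column {col!r}")
    if (pd.to_numeric(df["time_months"], errors="coerce") <= 0).any():
        raise InputFormatError(f"{path}: time_months must be positive")
    if not df["event"].isin([0, 1]).all():
        raise InputFormatError(f"{path}: event must be 0/1")
    return df


# ----------------------------------------------------------------------- GMT

def write_gmt(annotations: AnnotationCollection, path: Path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(annotations.terms):
            name, members = annotations.terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")


def read_gmt(path: Path, universe=None) -> AnnotationCollection:
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    genes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputFormatError(
                    f"{path}: line {lineno}: GMT rows need term, description, "
                    "and at least one member"
                )
            term_id, name, *members = parts
            if term_id in terms:
                raise InputFormatError(f"{path}: line {lineno}: duplicate term {term_id!r}")
            terms[term_id] = (name, frozenset(members))
            genes.update(members)
    uni = frozenset(universe) if universe is not None else frozenset(genes)
    return AnnotationCollection(terms=terms, universe=uni)


# ----------------------------------------------------------------- edge lists

def write_edges(edges: pd.DataFrame, group: str, path: Path) -> None:
    out = edges.copy()
    out["group"] = group
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edges(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"gene_a", "gene_b", "r", "p"}
    if not needed.issubset(df.columns):
        raise InputFormatError(f"{path}: edge list needs columns {sorted(needed)}")
    return df


# ------------------------------------------------------------------ manifest

def file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: list[Path], out_path: Path) -> dict[str, str]:
    manifest = {p.name: file_sha256(p) for p in sorted(paths, key=lambda p: p.name)}
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
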