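"""Readers and writers for the standard formats around the analysis.

Edge lists (2+ column TSV, or SIF), gene sets (one-per-line lists, GMT),
GWAS Catalog association exports (the EBI/NHGRI tab-separated download),
and JSON/TSV result reports.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .connectivity import ConnectivityResult
from .errors import (
    EmptySetError,
    InputError,
    ParameterError,
    SchemaError,
    SetNotFoundError,
)
from .types import GeneSet, GwasCatalogFilter, Interactome, normalize_symbol

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

# Official column headers of a GWAS Catalog associations export.
_GWAS_TRAIT = "DISEASE/TRAIT"
_GWAS_P = "P-VALUE"
_GWAS_MAPPED = "MAPPED_GENE"
_GWAS_REPORTED = "REPORTED GENE(S)"

# Multi-gene delimiters used by the Catalog. MAPPED_GENE joins the flanking
# genes of intergenic hits with " - " and interaction hits with " x ";
# REPORTED GENE(S) is comma-separated.
_MAPPED_SPLIT = re.compile(r"\s+-\s+|;\s*|\s+x\s+")
_REPORTED_SPLIT = re.compile(r",\s*|;\s*")

# Placeholder tokens that are not gene symbols.
_PLACEHOLDERS = {"NR", "INTERGENIC", "NONE", "NA", "-"}


# ---------------------------------------------------------------------------
# interactomes


def _looks_like_header(fields: list[str]) -> bool:
    headerish = {"SOURCE", "TARGET", "NODE1", "NODE2", "GENE1", "GENE2",
                 "PROTEIN1", "PROTEIN2", "FROM", "TO"}
    return len(fields) >= 2 and all(
        f.strip().upper() in headerish for f in fields[:2]
    )


def read_edge_list(
    path: PathLike,
    dialect: str = "tsv",
    name: Optional[str] = None,
) -> Interactome:
    """Read an undirected interactome from a TSV edge list or a SIF file.

    TSV: two or more tab-separated columns (source, target; extras
    ignored); a header line is auto-detected and skipped. SIF:
    ``node relation node [node ...]`` per line, whitespace-separated.
    Self-loops are dropped, duplicate/reversed edges collapse.
    """
    if dialect not in ("tsv", "sif"):
        raise ParameterError(f"unknown edge-list dialect {dialect!r}")
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputError(f"cannot read edge list {path}: {exc}") from exc

    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    for lineno, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            # "# node: X" comments carry isolated nodes through round trips
            if line.startswith("# node:"):
                isolated.append(line.split(":", 1)[1])
            continue
        if dialect == "tsv":
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputError(
                    f"{path}:{lineno + 1}: expected >= 2 tab-separated columns"
                )
            if lineno == 0 and _looks_like_header(fields):
                continue
            edges.append((fields[0], fields[1]))
        else:  # sif: source relation target [target...]
            fields = line.split()
            if len(fields) < 3:
                raise InputError(
                    f"{path}:{lineno + 1}: SIF line needs source, relation, target"
                )
            src = fields[0]
            for tgt in fields[2:]:
                edges.append((src, tgt))
    return Interactome.from_edges(
        edges, nodes=isolated, name=name or path.stem, provenance=str(path)
    )


def write_edge_list(interactome: Interactome, path: PathLike) -> None:
    """Write a 2-column TSV edge list (with header) that round-trips.

    Isolated nodes are preserved as ``# node: X`` comment lines, which
    other tools skip but :func:`read_edge_list` understands.
    """
    path = Path(path)
    lines = ["source\ttarget"]
    lines += [f"{u}\t{v}" for u, v in sorted(interactome.edges)]
    connected = {n for e in interactome.edges for n in e}
    lines += [f"# node: {n}" for n in sorted(interactome.nodes - connected)]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene sets


def read_gene_set(
    path: PathLike,
    format: str = "list",
    set_name: Optional[str] = None,
) -> GeneSet:
    """Read a gene set from a one-per-line list or a GMT record.

    ``list``: one symbol per line, ``#`` comments allowed. ``gmt``:
    ``name<TAB>description<TAB>gene...`` per line; ``set_name`` selects the
    record.
    """
    if format not in ("list", "gmt"):
        raise ParameterError(f"unknown gene-set format {format!r}")
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputError(f"cannot read gene set {path}: {exc}") from exc

    if format == "list":
        symbols = [
            line.strip()
            for line in text.splitlines()
            if line.strip() and not line.lstrip().startswith("#")
        ]
        gs = GeneSet.from_symbols(set_name or path.stem, symbols, source="list")
        if not gs.members:
            raise EmptySetError(f"gene list {path} is empty")
        return gs

    for line in text.splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            continue
        rec_name = fields[0].strip()
        if set_name is None or rec_name == set_name:
            gs = GeneSet.from_symbols(rec_name, fields[2:], source="gmt")
            if not gs.members:
                raise EmptySetError(f"GMT record {rec_name!r} in {path} is empty")
            return gs
    raise SetNotFoundError(f"gene set {set_name!r} not found in {path}")


def write_gene_set(gene_set: GeneSet, path: PathLike) -> None:
    """Write a one-per-line gene list."""
    Path(path).write_text("\n".join(sorted(gene_set.members)) + "\n")


# ---------------------------------------------------------------------------
# GWAS Catalog


def _split_genes(value: str, pattern: re.Pattern) -> list[str]:
    out = []
    for token in pattern.split(value):
        sym = normalize_symbol(token)
        if sym and sym not in _PLACEHOLDERS:
            out.append(sym)
    return out


def read_gwas_catalog(
    path: PathLike,
    filter: GwasCatalogFilter = GwasCatalogFilter(),
    set_name: str = "gwas_catalog",
) -> GeneSet:
    """Assemble a gene list from a GWAS Catalog associations export.

    Keeps rows whose DISEASE/TRAIT contains ``filter.trait_substring``
    (case-insensitive) and whose P-VALUE is <= ``filter.p_threshold``; then
    extracts genes from MAPPED_GENE and/or REPORTED GENE(S) per
    ``filter.gene_field_policy``, splitting the Catalog's multi-gene
    delimiters and dropping placeholders ("NR", "intergenic", empty).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read GWAS Catalog file {path}: {exc}") from exc

    required = [_GWAS_TRAIT, _GWAS_P]
    if filter.gene_field_policy in ("mapped", "union"):
        required.append(_GWAS_MAPPED)
    if filter.gene_field_policy in ("reported", "union"):
        required.append(_GWAS_REPORTED)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing column(s): {', '.join(missing)}")

    trait_ok = df[_GWAS_TRAIT].str.contains(
        re.escape(filter.trait_substring), case=False, na=False
    )
    pvals = pd.to_numeric(df[_GWAS_P], errors="coerce")
    keep = df[trait_ok & (pvals <= filter.p_threshold)]

    genes: set[str] = set()
    for _, row in keep.iterrows():
        if filter.gene_field_policy in ("mapped", "union"):
            genes.update(_split_genes(row[_GWAS_MAPPED], _MAPPED_SPLIT))
        if filter.gene_field_policy in ("reported", "union"):
            genes.update(_split_genes(row[_GWAS_REPORTED], _REPORTED_SPLIT))

    if not genes:
        raise EmptySetError(
            f"no genes pass trait={filter.trait_substring!r}, "
            f"p<={filter.p_threshold} in {path}"
        )
    return GeneSet(set_name, frozenset(genes), source="gwas_catalog")


# ---------------------------------------------------------------------------
# reports


def write_report(
    result: ConnectivityResult, path: PathLike, format: str = "json"
) -> None:
    """Write an analysis report; the JSON form round-trips via read_report.

    TSV writes one ``key<TAB>value`` row per scalar field, with list fields
    comma-joined — convenient for shell pipelines, not for re-reading.
    """
    if format not in ("json", "tsv"):
        raise ParameterError(f"unknown report format {format!r}")
    path = Path(path)
    d = result.to_dict()
    try:
        if format == "json":
            path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
        else:
            rows = []
            for key in sorted(d):
                value = d[key]
                if isinstance(value, dict):
                    value = ";".join(
                        f"{k}={'|'.join(v)}" for k, v in sorted(value.items())
                    )
                elif isinstance(value, list):
                    value = ",".join(map(str, value))
                rows.append(f"{key}\t{value}")
            path.write_text("\n".join(rows) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: PathLike) -> ConnectivityResult:
    """Re-read a JSON report written by :func:`write_report`."""
    try:
        d = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"cannot read report {path}: {exc}") from exc
    return ConnectivityResult.from_dict(d)
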