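"""Reading and writing expression tables, gene universes, and concordance reports.

File dialect for expression tables: UTF-8, tab-separated, one header line,
``.`` decimal separator, two columns (``gene_id``, ``value``).  Gene universes
may be a plain one-identifier-per-line list, BED (identifier from the *name*
column), or GFF3 (identifier from the ``ID``/``gene_id`` attribute of features
typed ``gene``).  Reports are emitted as sorted-key JSON plus two TSV tables
with fixed numeric formatting (6 significant digits), so identical inputs
always produce byte-identical artifacts.

Gene identifiers are opaque, case-sensitive strings; no symbol-to-accession
mapping is attempted.  A gene absent from a table is treated as measured at
zero when detection calls are made downstream.
"""

from __future__ import annotations

import json
import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator, Mapping

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .concordance import ConcordanceReport

__all__ = [
    "ParseError",
    "ValidationError",
    "PLATFORM_TAGS",
    "GeneUniverse",
    "ExpressionTable",
    "read_expression_table",
    "write_expression_table",
    "read_gene_universe",
    "write_report",
    "fmt6",
    "round6",
]

PLATFORM_TAGS = ("short_read", "long_read", "qpcr", "other")


class ParseError(ValueError):
    """A file could not be parsed (malformed row, wrong column count...)."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (duplicates, negatives...)."""


def fmt6(x: float) -> str:
    """Render a real with 6 significant digits (the report TSV contract)."""
    return format(float(x), ".6g")


def round6(x: float) -> float:
    """Round a real to 6 significant digits for deterministic JSON output."""
    return float(fmt6(x))


@dataclass(frozen=True)
class GeneUniverse:
    """The declared reference gene set against which coverage is computed.

    For the chromosome-18 benchmark this is the set of 275 protein-coding
    genes on the chromosome; any detection call is evaluated relative to it.
    """

    genes: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValidationError("gene universe is empty")
        seen = set()
        for g in self.genes:
            if not g:
                raise ValidationError("gene universe contains an empty identifier")
            if g in seen:
                raise ValidationError(f"duplicate gene identifier in universe: {g!r}")
            seen.add(g)

    @property
    def size(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in set(self.genes)


@dataclass(frozen=True)
class ExpressionTable:
    """One platform x sample x batch worth of gene-level measurements.

    Values are kept in the platform's native unit (e.g. RPKM for short-read
    sequencing, a normalized read count for long-read, a qPCR-derived
    abundance score); no cross-platform normalization is performed, because
    the concordance analysis applies one cutoff ladder per platform in that
    platform's own unit.
    """

    platform: str
    sample: str
    batch: str
    unit: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.platform not in PLATFORM_TAGS:
            raise ValidationError(
                f"unknown platform tag {self.platform!r}; expected one of {PLATFORM_TAGS}"
            )
        for g, v in self.values.items():
            if not g:
                raise ValidationError("empty gene identifier in expression table")
            if not math.isfinite(v):
                raise ValidationError(f"non-finite value for gene {g!r}: {v!r}")
            if v < 0:
                raise ValidationError(f"negative value for gene {g!r}: {v!r}")

    @property
    def provenance(self) -> tuple[str, str, str]:
        """(platform, sample, batch) identity of this measurement campaign."""
        return (self.platform, self.sample, self.batch)

    def __len__(self) -> int:
        return len(self.values)


def read_expression_table(
    path: str | os.PathLike[str],
    platform: str,
    sample: str,
    batch: str,
    unit: str,
) -> ExpressionTable:
    """Read a two-column (gene_id, value) TSV into an :class:`ExpressionTable`.

    Raises :class:`ParseError` naming the offending line for malformed rows,
    and :class:`ValidationError` for duplicate identifiers or negative values.
    """
    path = Path(path)
    values: dict[str, float] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: missing header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            gene, raw = parts
            if not gene:
                raise ParseError(f"{path}: line {lineno}: empty gene identifier")
            try:
                value = float(raw)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric value {raw!r}"
                ) from None
            if not math.isfinite(value):
                raise ValidationError(
                    f"{path}: line {lineno}: non-finite value {raw!r}"
                )
            if value < 0:
                raise ValidationError(
                    f"{path}: line {lineno}: negative value {value} for gene {gene!r}"
                )
            if gene in values:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate gene identifier {gene!r}"
                )
            values[gene] = value
    return ExpressionTable(platform=platform, sample=sample, batch=batch, unit=unit, values=values)


def write_expression_table(table: ExpressionTable, path: str | os.PathLike[str]) -> None:
    """Write a table in the canonical TSV dialect (shortest round-trip floats)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tvalue\n")
        for gene, value in table.values.items():
            fh.write(f"{gene}\t{value!r}\n")


def _universe_from_list(path: Path) -> list[str]:
    genes: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            g = line.strip()
            if g:
                genes.append(g)
    return genes


def _universe_from_bed(path: Path) -> list[str]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty gene universe file") from None
    if df.shape[1] < 4:
        raise ParseError(
            f"{path}: BED universe needs >= 4 columns (name in column 4), got {df.shape[1]}"
        )
    return [g for g in df.iloc[:, 3].tolist() if isinstance(g, str) and g]


def _universe_from_gff3(path: Path) -> list[str]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[str] = []
    for feat in db.features_of_type("gene", order_by="start"):
        attrs = feat.attributes
        if "gene_id" in attrs:
            genes.append(attrs["gene_id"][0])
        elif feat.id:
            genes.append(feat.id)
    return genes


def read_gene_universe(
    path: str | os.PathLike[str],
    fmt: str | None = None,
    label: str | None = None,
) -> GeneUniverse:
    """Read a gene universe from a plain list, BED, or GFF3 file.

    The format is auto-detected from the extension (``.bed`` / ``.gff``,
    ``.gff3`` / anything else = list) and can be forced with ``fmt``.
    Identifiers are deduplicated preserving first-seen order.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".bed": "bed", ".gff": "gff3", ".gff3": "gff3"}.get(suffix, "list")
    if fmt == "list":
        raw = _universe_from_list(path)
    elif fmt == "bed":
        raw = _universe_from_bed(path)
    elif fmt == "gff3":
        raw = _universe_from_gff3(path)
    else:
        raise ValueError(f"unknown universe format {fmt!r}")
    genes: list[str] = []
    seen: set[str] = set()
    for g in raw:
        if g not in seen:
            seen.add(g)
            genes.append(g)
    if not genes:
        raise ValidationError(f"{path}: empty gene universe file")
    return GeneUniverse(genes=tuple(genes), label=label if label is not None else path.stem)


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_report(report: "ConcordanceReport", outdir: str | os.PathLike[str]) -> list[Path]:
    """Write a concordance report to ``outdir`` as JSON + two TSV tables.

    Emits ``report.json`` (machine readable, sorted keys, floats rounded to 6
    significant digits), ``gene_tiers.tsv`` (per cutoff and gene, the number
    of platforms detecting it) and ``cutoff_summary.tsv`` (one row per
    cutoff).  Files are written atomically (temp file + rename) so a failed
    run leaves no partial artifacts, and identical reports produce identical
    bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    json_path = outdir / "report.json"
    tiers_path = outdir / "gene_tiers.tsv"
    summary_path = outdir / "cutoff_summary.tsv"

    payload = report.to_dict()
    json_text = json.dumps(payload, sort_keys=True, indent=2) + "\n"

    tier_lines = ["cutoff\tgene_id\tn_platforms"]
    for res in report.results:
        for gene in sorted(res.tiers):
            tier_lines.append(f"{fmt6(res.cutoff)}\t{gene}\t{res.tiers[gene]}")
    tiers_text = "\n".join(tier_lines) + "\n"

    k = len(report.labels)
    header = [
        "cutoff",
        "union_size",
        "common_all",
        "coverage",
        "min_tanimoto",
        *(f"tier{i}" for i in range(1, k + 1)),
        "n_undetected",
    ]
    summary_lines = ["\t".join(header)]
    for res in report.results:
        values = [t.value for t in res.tanimoto]
        min_t = fmt6(min(values)) if values else "NA"
        row = [
            fmt6(res.cutoff),
            str(res.venn.union_size),
            str(res.venn.common_all),
            fmt6(res.coverage),
            min_t,
            *(str(res.tier_counts.get(i, 0)) for i in range(1, k + 1)),
            str(len(res.undetected)),
        ]
        summary_lines.append("\t".join(row))
    summary_text = "\n".join(summary_lines) + "\n"

    _atomic_write(json_path, json_text)
    _atomic_write(tiers_path, tiers_text)
    _atomic_write(summary_path, summary_text)
    return [json_path, tiers_path, summary_path]
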