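"""Readers, writers and per-sample composition statistics for methylation data.

The on-disk dialects handled here are the ones methylation extractors and
annotation pipelines actually emit:

* cytosine reports — 7-column TSV (chromosome, 1-based position, strand,
  methylated read count, unmethylated read count, context CG/CHG/CHH,
  trinucleotide), one file per sample;
* sample metadata — TSV with sample_id, cultivar, experiment, chilling_hours,
  stage;
* gene models — GFF3; TE and QTL tracks — BED6+1 with the TE class or QTL
  trait label in column 7.

Internally every interval is 0-based half-open.  Cytosine positions are
1-based on disk and converted exactly once, at this boundary; feature
identifiers are printed 1-based (``chr_4_31092165``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

#: Cytosine sequence contexts in plants (H = A, C or T).
CONTEXTS = ("CG", "CHG", "CHH")

#: Canonical dormancy-stage order (used for class indexing and tie-breaks).
STAGES = ("paradormancy", "endodormancy", "ecodormancy")

REPORT_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "n_meth",
    "n_unmeth",
    "context",
    "trinucleotide",
]

META_COLUMNS = ["sample_id", "cultivar", "experiment", "chilling_hours", "stage"]


class ReportFormatError(ValueError):
    """A cytosine report (or metadata/annotation file) failed validation."""


@dataclass(frozen=True)
class CytosineRecord:
    """One strand-resolved cytosine observation in one sample."""

    chrom: str
    pos: int  # 1-based
    strand: str
    n_meth: int
    n_unmeth: int
    context: str
    trinucleotide: str

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


def _empty_report() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype="int64"),
            "strand": pd.Series(dtype=str),
            "n_meth": pd.Series(dtype="int64"),
            "n_unmeth": pd.Series(dtype="int64"),
            "context": pd.Series(dtype=str),
            "trinucleotide": pd.Series(dtype=str),
        }
    )


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Read and validate a Bismark-dialect cytosine report.

    Returns a DataFrame with columns ``chrom, pos, strand, n_meth, n_unmeth,
    context, trinucleotide`` in input order.  An empty file yields an empty
    frame.  Malformed lines raise :class:`ReportFormatError` naming the file
    and 1-based line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=REPORT_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "trinucleotide": str,
            },
            comment=None,
        )
    except pd.errors.EmptyDataError:
        return _empty_report()
    except (ValueError, pd.errors.ParserError) as exc:
        raise ReportFormatError(f"{path}: malformed cytosine report ({exc})") from exc

    for col in ("pos", "n_meth", "n_unmeth"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        numeric_bad = coerced.isna()
        if numeric_bad.any():
            line = int(numeric_bad.idxmax()) + 1
            raise ReportFormatError(
                f"{path}, line {line}: non-integer value in column '{col}'"
            )
        if (coerced % 1 != 0).any():
            line = int((coerced % 1 != 0).idxmax()) + 1
            raise ReportFormatError(
                f"{path}, line {line}: non-integer value in column '{col}'"
            )
        df[col] = coerced.astype("int64")

    checks = [
        (df["pos"] < 1, "position must be >= 1"),
        (df["n_meth"] < 0, "negative methylated count"),
        (df["n_unmeth"] < 0, "negative unmethylated count"),
        (~df["strand"].isin(["+", "-"]), "strand must be '+' or '-'"),
        (~df["context"].isin(CONTEXTS), "unknown context token"),
    ]
    for bad, msg in checks:
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ReportFormatError(f"{path}, line {line}: {msg}")
    return df


def write_cytosine_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write a cytosine report; exact inverse of :func:`read_cytosine_report`."""
    report.to_csv(path, sep="\t", header=False, index=False, columns=REPORT_COLUMNS)


def iter_records(report: pd.DataFrame) -> Iterator[CytosineRecord]:
    """Yield :class:`CytosineRecord` objects from a report frame, in order."""
    for row in report.itertuples(index=False):
        yield CytosineRecord(*row)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table (TSV with a header row).

    Validates unique sample ids, non-negative chilling hours and stage labels
    from the closed set {paradormancy, endodormancy, ecodormancy}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cultivar": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ReportFormatError(f"{path}: missing metadata columns {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ReportFormatError(f"{path}: duplicate sample_id '{dup}'")
    bad_stage = ~meta["stage"].isin(STAGES)
    if bad_stage.any():
        raise ReportFormatError(
            f"{path}: unknown stage label "
            f"'{meta.loc[bad_stage, 'stage'].iloc[0]}' (expected one of {STAGES})"
        )
    if (meta["chilling_hours"] < 0).any():
        raise ReportFormatError(f"{path}: negative chilling_hours")
    return meta


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, columns=META_COLUMNS)


# ---------------------------------------------------------------------------
# methylation-context composition
# ---------------------------------------------------------------------------


@dataclass
class ContextComposition:
    """Per-context absolute methylation and relative methylated-cytosine share.

    ``absolute_level[ctx]`` is the read-level ratio sum(n_meth)/sum(coverage)
    over cytosines of that context; it is ``nan`` (and listed in
    ``undefined_absolute``) when the context has zero total coverage.
    ``relative_share[ctx]`` is the fraction of *called-methylated* cytosines
    belonging to that context; shares are ``nan`` (``undefined_relative`` True)
    when no cytosine is called methylated.
    """

    absolute_level: dict[str, float]
    relative_share: dict[str, float]
    undefined_absolute: set[str] = field(default_factory=set)
    undefined_relative: bool = False


def context_composition(
    report: pd.DataFrame,
    *,
    min_coverage: int = 4,
    min_level: float = 0.1,
) -> ContextComposition:
    """Compute per-context composition statistics for one sample.

    A cytosine counts as *methylated* for the relative shares when it has
    ``n_meth >= 1``, coverage ``>= min_coverage`` and methylation level
    ``>= min_level`` — a conventional callable-cytosine rule; both thresholds
    are exposed because extraction pipelines differ on this call.
    """
    if len(report) == 0:
        raise ValueError("context_composition requires a non-empty report")
    cov = report["n_meth"] + report["n_unmeth"]
    absolute: dict[str, float] = {}
    undefined: set[str] = set()
    for ctx in CONTEXTS:
        mask = report["context"] == ctx
        total = int(cov[mask].sum())
        if total == 0:
            absolute[ctx] = math.nan
            undefined.add(ctx)
        else:
            absolute[ctx] = float(report.loc[mask, "n_meth"].sum()) / total

    called = (
        (report["n_meth"] >= 1)
        & (cov >= min_coverage)
        & (report["n_meth"] / cov.where(cov > 0, 1) >= min_level)
    )
    n_called = int(called.sum())
    if n_called == 0:
        shares = {ctx: math.nan for ctx in CONTEXTS}
        return ContextComposition(absolute, shares, undefined, undefined_relative=True)
    counts = report.loc[called, "context"].value_counts()
    shares = {ctx: float(counts.get(ctx, 0)) / n_called for ctx in CONTEXTS}
    return ContextComposition(absolute, shares, undefined, undefined_relative=False)


def composition_table(
    reports: Mapping[str, pd.DataFrame],
    *,
    min_coverage: int = 4,
    min_level: float = 0.1,
) -> pd.DataFrame:
    """Composition statistics for many samples as one tidy table."""
    rows = []
    for sample_id, report in reports.items():
        comp = context_composition(
            report, min_coverage=min_coverage, min_level=min_level
        )
        row: dict[str, object] = {"sample_id": sample_id}
        for ctx in CONTEXTS:
            row[f"abs_{ctx}"] = comp.absolute_level[ctx]
            row[f"rel_{ctx}"] = comp.relative_share[ctx]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation tracks
# ---------------------------------------------------------------------------


@dataclass
class AnnotationBundle:
    """Typed genomic interval tracks, all 0-based half-open.

    ``genes``/``exons``: chrom, start, end, strand, gene_id;
    ``te``: chrom, start, end, name, strand, te_class;
    ``qtl``: chrom, start, end, name, strand, trait.
    ``chrom_lengths`` may be absent (None) when not derivable from the inputs.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    te: pd.DataFrame
    qtl: pd.DataFrame
    chrom_lengths: dict[str, int] | None = None


def read_gff3_genes(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read gene and exon intervals from a GFF3 file (via pyranges).

    pyranges converts GFF3's 1-based inclusive coordinates to 0-based
    half-open on read, which matches the internal convention.
    """
    import pyranges as pr

    df = pr.read_gff3(str(path)).df
    if df.empty:
        raise ReportFormatError(f"{path}: no GFF3 records")
    df = df.rename(
        columns={"Chromosome": "chrom", "Start": "start", "End": "end", "Strand": "strand"}
    )
    if (df["end"] <= df["start"]).any():
        raise ReportFormatError(f"{path}: interval with end <= start")
    genes = df[df["Feature"] == "gene"][["chrom", "start", "end", "strand", "ID"]]
    genes = genes.rename(columns={"ID": "gene_id"})
    genes = genes.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    if "Parent" in df.columns:
        exons = df[df["Feature"] == "exon"][["chrom", "start", "end", "strand", "Parent"]]
        exons = exons.rename(columns={"Parent": "gene_id"})
        exons = exons.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    else:
        exons = genes.iloc[0:0].copy()
    for df_ in (genes, exons):
        df_["chrom"] = df_["chrom"].astype(str)
        df_["strand"] = df_["strand"].astype(str)
        df_["gene_id"] = df_["gene_id"].astype(str)
        df_[["start", "end"]] = df_[["start", "end"]].astype("int64")
    return genes, exons


def read_bed_track(path: str | Path, label_column: str) -> pd.DataFrame:
    """Read a BED6+1 track whose 7th column carries a label.

    Used for TE tracks (label = RepeatMasker-style class, e.g. ``LTR/Copia``)
    and QTL tracks (label = trait in {CR, HR, FD, MD}).  BED is 0-based
    half-open already; overlapping intervals are retained, never merged.
    """
    names = ["chrom", "start", "end", "name", "score", "strand", label_column]
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=names,
            dtype={"chrom": str, "name": str, "strand": str, label_column: str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names)
    df["start"] = df["start"].astype("int64")
    df["end"] = df["end"].astype("int64")
    if (df["end"] <= df["start"]).any():
        line = int((df["end"] <= df["start"]).idxmax()) + 1
        raise ReportFormatError(f"{path}, line {line}: interval with end <= start")
    return df[["chrom", "start", "end", "name", "strand", label_column]]


def read_annotation(
    gff3_path: str | Path,
    te_bed_path: str | Path,
    qtl_bed_path: str | Path,
    *,
    chrom_lengths: Mapping[str, int] | None = None,
) -> AnnotationBundle:
    """Load gene models (GFF3), TE track and QTL track into one bundle."""
    genes, exons = read_gff3_genes(gff3_path)
    te = read_bed_track(te_bed_path, "te_class")
    qtl = read_bed_track(qtl_bed_path, "trait")
    return AnnotationBundle(
        genes=genes,
        exons=exons,
        te=te,
        qtl=qtl,
        chrom_lengths=dict(chrom_lengths) if chrom_lengths is not None else None,
    )


def write_bed_track(df: pd.DataFrame, path: str | Path, label_column: str | None = None) -> None:
    """Write a BED6(+1) track, 0-based half-open, deterministic row order."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    out = df.copy()
    if "score" not in out.columns:
        out["score"] = 0
    if "name" not in out.columns:
        out["name"] = "."
    if label_column is not None:
        cols = cols + [label_column]
    out = out.sort_values(["chrom", "start", "end"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False, columns=cols)
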