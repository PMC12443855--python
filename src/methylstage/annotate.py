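"""Genomic-context placement and downstream summaries of selected features.

Selected cytosines (1-bp intervals) and regions (first-to-last cytosine
spans) are placed into mutually exclusive genomic contexts with the
precedence TE > promoter > gene body > downstream > intergenic; the promoter
is the 2 kb window upstream of the TSS and the downstream context the 2 kb
window past the TTS, both strand-aware.  A parallel gene-relative context
(ignoring the TE layer) supports the TE class x context cross-tabulation.
Overlap everywhere means >= 1 shared bp.

All coordinates in this module are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .methio import AnnotationBundle

PROMOTER_BP = 2_000
DOWNSTREAM_BP = 2_000

#: mutually exclusive primary contexts, highest precedence first
DEFAULT_PRECEDENCE = ("TE", "promoter", "gene", "downstream", "intergenic")


def derive_promoters(
    genes: pd.DataFrame, chrom_lengths: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """2 kb windows upstream of each TSS, strand-aware, clipped at bounds."""
    rows = []
    for g in genes.itertuples(index=False):
        if g.strand == "+":
            start, end = g.start - PROMOTER_BP, g.start
        elif g.strand == "-":
            start, end = g.end, g.end + PROMOTER_BP
        else:
            raise ValueError(f"gene {g.gene_id}: unknown strand {g.strand!r}")
        start = max(start, 0)
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[g.chrom])
        if end > start:
            rows.append((g.chrom, start, end, g.strand, g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])


def derive_downstream(
    genes: pd.DataFrame, chrom_lengths: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """2 kb windows past each TTS (the 3' mirror of :func:`derive_promoters`)."""
    rows = []
    for g in genes.itertuples(index=False):
        if g.strand == "+":
            start, end = g.end, g.end + DOWNSTREAM_BP
        elif g.strand == "-":
            start, end = g.start - DOWNSTREAM_BP, g.start
        else:
            raise ValueError(f"gene {g.gene_id}: unknown strand {g.strand!r}")
        start = max(start, 0)
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[g.chrom])
        if end > start:
            rows.append((g.chrom, start, end, g.strand, g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])


def infer_introns(genes: pd.DataFrame, exons: pd.DataFrame) -> pd.DataFrame:
    """Introns as each gene span minus its exons (for GFF3s without them)."""
    rows = []
    for g in genes.itertuples(index=False):
        ex = exons[exons["gene_id"] == g.gene_id].sort_values("start")
        pos = g.start
        for e in ex.itertuples(index=False):
            if e.start > pos:
                rows.append((g.chrom, pos, e.start, g.strand, g.gene_id))
            pos = max(pos, e.end)
        if pos < g.end and len(ex) > 0:
            rows.append((g.chrom, pos, g.end, g.strand, g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])


def _build_trees(df: pd.DataFrame, label_col: str | None = None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in df.itertuples(index=False):
        data = getattr(row, label_col) if label_col else None
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, data)
    return trees


@dataclass
class ContextAssignment:
    feature_id: str
    primary_context: str
    te_overlap: bool
    te_class: str | None
    gene_relative_context: str


def assign_context(
    features: pd.DataFrame,
    annotation: AnnotationBundle,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> pd.DataFrame:
    """Assign each feature its primary and gene-relative genomic context.

    ``features`` needs columns feature_id, chrom, start, end.  Overlap is
    >= 1 bp.  ``primary_context`` follows ``precedence``; the gene-relative
    context applies the same order with the TE layer removed.  ``te_class``
    is the class of the TE with the largest overlap (ties to the first TE by
    coordinate).  Features on a chromosome absent from every track raise.
    """
    chrom_lengths = annotation.chrom_lengths
    promoters = derive_promoters(annotation.genes, chrom_lengths)
    downstream = derive_downstream(annotation.genes, chrom_lengths)
    trees = {
        "TE": _build_trees(annotation.te, "te_class"),
        "promoter": _build_trees(promoters),
        "gene": _build_trees(annotation.genes),
        "downstream": _build_trees(downstream),
    }
    known_chroms = set(chrom_lengths or [])
    for t in trees.values():
        known_chroms |= set(t)

    rows = []
    for f in features.itertuples(index=False):
        if f.chrom not in known_chroms:
            raise ValueError(f"feature {f.feature_id}: unknown chromosome {f.chrom!r}")
        hits = {
            kind: sorted(
                trees[kind].get(f.chrom, IntervalTree()).overlap(f.start, f.end),
                key=lambda iv: (iv.begin, iv.end),
            )
            for kind in trees
        }
        te_hits = hits["TE"]
        te_overlap = len(te_hits) > 0
        te_class = None
        if te_overlap:
            best = max(
                te_hits,
                key=lambda iv: (min(iv.end, f.end) - max(iv.begin, f.start), -iv.begin, -iv.end),
            )
            te_class = best.data
        primary = "intergenic"
        for kind in precedence:
            if kind == "intergenic":
                break
            if hits.get(kind):
                primary = kind
                break
        gene_relative = "intergenic"
        for kind in precedence:
            if kind in ("TE", "intergenic"):
                continue
            if hits.get(kind):
                gene_relative = kind
                break
        rows.append(
            {
                "feature_id": f.feature_id,
                "primary_context": primary,
                "te_overlap": te_overlap,
                "te_class": te_class,
                "gene_relative_context": gene_relative,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "primary_context",
            "te_overlap",
            "te_class",
            "gene_relative_context",
        ],
    )


def te_context_crosstab(assignments: pd.DataFrame) -> pd.DataFrame:
    """Contingency counts of TE-overlapping features by (te_class, context)."""
    sub = assignments[assignments["te_overlap"]]
    if len(sub) == 0:
        return pd.DataFrame()
    return pd.crosstab(sub["te_class"], sub["gene_relative_context"])


def compare_feature_sets(sets: Mapping[str, pd.DataFrame]) -> dict:
    """Set comparisons across named feature sets.

    Each set is a coordinate frame (feature_id, chrom, start, end, kind).
    Returns identifier-based pairwise shared counts and exclusive
    intersection-region counts (Venn cells), plus positional colocalization
    counts of cytosines contained in regions, reported separately because a
    cytosine id can never literally equal a region id.
    """
    if len(sets) < 2:
        raise ValueError("compare_feature_sets needs at least two named sets")
    ids: dict[str, set[str]] = {}
    for name, df in sets.items():
        if df["feature_id"].duplicated().any():
            dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise ValueError(f"set '{name}': duplicate feature id '{dup}'")
        ids[name] = set(df["feature_id"])

    names = list(sets)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pairwise[(a, b)] = len(ids[a] & ids[b])

    all_ids = set().union(*ids.values())
    exclusive: dict[frozenset, int] = {}
    for fid in all_ids:
        member = frozenset(n for n in names if fid in ids[n])
        exclusive[member] = exclusive.get(member, 0) + 1

    coloc = {}
    for a in names:
        dfa = sets[a]
        cyt = dfa[dfa["kind"] == "cytosine"] if "kind" in dfa.columns else dfa.iloc[0:0]
        if len(cyt) == 0:
            continue
        for b in names:
            dfb = sets[b]
            reg = dfb[dfb["kind"] == "region"] if "kind" in dfb.columns else dfb.iloc[0:0]
            if len(reg) == 0:
                continue
            trees = _build_trees(reg.rename(columns={"feature_id": "name"}), "name")
            n = 0
            for c in cyt.itertuples(index=False):
                if trees.get(c.chrom, IntervalTree()).overlap(c.start, c.end):
                    n += 1
            coloc[(a, b)] = n
    return {"pairwise_shared": pairwise, "exclusive": exclusive, "cytosines_in_regions": coloc}


def density_windows(
    features: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Per-window feature counts by kind, tiling each chromosome from 0.

    A feature is counted in the window containing its start (regions crossing
    a boundary are not double-counted).  Features past the chromosome end
    raise.
    """
    kinds = sorted(features["kind"].unique()) if len(features) else []
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_win = max(1, -(-length // window))
        sub = features[features["chrom"] == chrom]
        if len(sub) and (sub["start"] >= length).any():
            bad = sub.loc[sub["start"] >= length, "feature_id"].iloc[0]
            raise ValueError(f"feature {bad} lies beyond the end of {chrom}")
        win_idx = (sub["start"] // window).astype(int) if len(sub) else pd.Series(dtype=int)
        for w in range(n_win):
            row = {
                "chrom": chrom,
                "window": w,
                "start": w * window,
                "end": min((w + 1) * window, length),
            }
            for kind in kinds:
                row[f"n_{kind}"] = int(((win_idx == w) & (sub["kind"] == kind)).sum())
            rows.append(row)
    return pd.DataFrame(rows)


def qtl_colocalization(features: pd.DataFrame, qtl: pd.DataFrame) -> pd.DataFrame:
    """Per-trait lists of features overlapping (>= 1 bp) any QTL interval.

    A feature may hit several traits and is reported under each.
    """
    rows = []
    for trait, sub in qtl.groupby("trait", sort=True):
        trees = _build_trees(sub)
        hit_ids = [
            f.feature_id
            for f in features.itertuples(index=False)
            if trees.get(f.chrom, IntervalTree()).overlap(f.start, f.end)
        ]
        rows.append({"trait": trait, "n_features": len(hit_ids), "feature_ids": sorted(hit_ids)})
    return pd.DataFrame(rows, columns=["trait", "n_features", "feature_ids"])


def te_genome_fraction(te: pd.DataFrame, chrom_lengths: Mapping[str, int]) -> float:
    """Union-merged TE bases divided by total genome bases."""
    total = sum(chrom_lengths.values())
    covered = 0
    for chrom, sub in te.groupby("chrom"):
        ivs = sub[["start", "end"]].sort_values(["start", "end"]).to_numpy()
        cur_s, cur_e = None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
    return covered / total if total else 0.0


def write_bed(features: pd.DataFrame, path: str | Path) -> None:
    """Write features as BED6 (0-based half-open, name = feature id)."""
    out = features.copy()
    out["name"] = out["feature_id"]
    out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    out = out.sort_values(["chrom", "start", "end", "name"], kind="mergesort")
    out.to_csv(
        path,
        sep="\t",
        header=False,
        index=False,
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )


def read_feature_bed(path: str | Path) -> pd.DataFrame:
    """Read a feature BED written by :func:`write_bed`."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    df = df.rename(columns={"name": "feature_id"})
    df["kind"] = np.where(df["end"] - df["start"] == 1, "cytosine", "region")
    return df[["feature_id", "chrom", "start", "end", "kind", "score", "strand"]]
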