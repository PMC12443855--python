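"""Coverage/presence filtering, region clustering and methylation matrices.

The feature pipeline mirrors a standard WGBS classification preprocessing:

1. keep cytosines with >= ``min_coverage`` reads in *every* sample (strict
   completeness; no imputation);
2. optionally cluster retained cytosines into regions: a region is a run of
   cytosines in which no two consecutive members are more than ``gap_max`` bp
   apart and which contains at least ``min_cytosines`` members — region widths
   therefore vary rather than being fixed-size bins;
3. summarise each feature per sample as a methylation level in [0, 1]
   (cytosine: n_meth / coverage; region: mean of member-cytosine levels).

Feature identifiers are printed with 1-based coordinates: ``chr_4_31092165``
for a cytosine, ``chr_3_9331371_9331488`` for a region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RegionCluster:
    """A cluster of >= min_cytosines retained cytosines with bounded gaps."""

    chrom: str
    positions: tuple[int, ...]  # sorted, 1-based

    @property
    def first(self) -> int:
        return self.positions[0]

    @property
    def last(self) -> int:
        return self.positions[-1]

    @property
    def n_cytosines(self) -> int:
        return len(self.positions)


@dataclass
class MethylationMatrix:
    """Samples x features methylation levels plus coordinates and labels.

    ``values``: DataFrame, index = sample ids, columns = feature ids, complete
    (the presence filter guarantees no missing cells), all entries in [0, 1].
    ``coords``: one row per feature (feature_id, chrom, start, end, kind,
    n_cytosines) with 0-based half-open start/end.
    ``labels``: one row per sample (stage, cultivar), same index as values.
    """

    values: pd.DataFrame
    coords: pd.DataFrame
    labels: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, feature_ids: Sequence[str]) -> "MethylationMatrix":
        ids = list(feature_ids)
        coords = self.coords.set_index("feature_id").loc[ids].reset_index()
        return MethylationMatrix(
            values=self.values[ids].copy(), coords=coords, labels=self.labels
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        ids = list(sample_ids)
        return MethylationMatrix(
            values=self.values.loc[ids].copy(),
            coords=self.coords,
            labels=self.labels.loc[ids].copy(),
        )


def methylation_level(n_meth, n_unmeth):
    """Methylation level n_meth / (n_meth + n_unmeth); errors on zero coverage."""
    n_meth = np.asarray(n_meth, dtype=float)
    n_unmeth = np.asarray(n_unmeth, dtype=float)
    cov = n_meth + n_unmeth
    if np.any(cov < 1):
        raise ValueError("methylation level undefined at zero coverage")
    out = n_meth / cov
    return float(out) if out.ndim == 0 else out


def filter_cytosines(
    reports: Mapping[str, pd.DataFrame],
    *,
    min_coverage: int = 4,
    context: str | None = "CG",
) -> pd.DataFrame:
    """Coverage/presence filter across all samples.

    A (chrom, pos) coordinate is retained iff it appears with coverage
    >= ``min_coverage`` in *every* sample.  ``context`` restricts the filter
    to one sequence context (default CpG; pass None to admit all contexts).
    Returns a DataFrame (chrom, pos) sorted by coordinate.
    """
    if len(reports) == 0:
        raise ValueError("filter_cytosines requires at least one sample")
    retained: pd.DataFrame | None = None
    for sample_id, report in reports.items():
        df = report
        if context is not None:
            df = df[df["context"] == context]
        cov = df["n_meth"] + df["n_unmeth"]
        coords = df.loc[cov >= min_coverage, ["chrom", "pos"]]
        coords = coords.drop_duplicates()
        if retained is None:
            retained = coords
        else:
            retained = retained.merge(coords, on=["chrom", "pos"], how="inner")
    assert retained is not None
    return retained.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def cluster_regions(
    coords: pd.DataFrame,
    *,
    gap_max: int = 100,
    min_cytosines: int = 4,
) -> list[RegionCluster]:
    """Greedy gap-based clustering of retained cytosines into regions.

    Per chromosome, a cluster is extended while the next retained cytosine is
    <= ``gap_max`` bp from the previous member and closed otherwise; clusters
    with fewer than ``min_cytosines`` members are dropped.  Clusters are
    disjoint and returned in coordinate order.
    """
    clusters: list[RegionCluster] = []
    if len(coords) == 0:
        return clusters
    coords = coords.sort_values(["chrom", "pos"], kind="mergesort")
    for chrom, sub in coords.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > gap_max)
        start = 0
        for b in list(breaks) + [len(pos) - 1]:
            members = pos[start : b + 1]
            if len(members) >= min_cytosines:
                clusters.append(RegionCluster(str(chrom), tuple(int(p) for p in members)))
            start = b + 1
    return clusters


def format_feature_id(chrom: str, first: int, last: int | None = None, kind: str = "cytosine") -> str:
    """Feature identifier with 1-based coordinates.

    cytosine -> ``<chrom>_<pos>``; region -> ``<chrom>_<first>_<last>``.
    """
    if kind == "cytosine":
        return f"{chrom}_{first}"
    if kind == "region":
        if last is None:
            raise ValueError("region feature id requires first and last")
        return f"{chrom}_{first}_{last}"
    raise ValueError(f"unknown feature kind: {kind}")


def parse_feature_id(feature_id: str) -> tuple[str, int, int | None, str]:
    """Inverse of :func:`format_feature_id` -> (chrom, first, last, kind).

    Chromosome names may themselves contain underscores and digits
    (``chr_4``), so the id grammar is disambiguated by counting trailing
    all-digit tokens T: T >= 3 parses as a region (the last two tokens are
    first/last), otherwise the last token is a cytosine position.  Under the
    ``chr_<n>`` naming used throughout this package the parse is exact; a
    chromosome name that *ends* in a bare number yet does not follow the
    ``<prefix>_<n>`` shape (e.g. ``chr4``) would make region ids ambiguous.
    """
    tokens = feature_id.split("_")
    trailing = 0
    for tok in reversed(tokens):
        if tok.isdigit():
            trailing += 1
        else:
            break
    if trailing >= 3 and len(tokens) >= 3:
        chrom = "_".join(tokens[:-2])
        return chrom, int(tokens[-2]), int(tokens[-1]), "region"
    if trailing >= 1 and len(tokens) >= 2:
        chrom = "_".join(tokens[:-1])
        return chrom, int(tokens[-1]), None, "cytosine"
    raise ValueError(f"unparseable feature id: {feature_id}")


def _level_lookup(report: pd.DataFrame) -> pd.DataFrame:
    cov = report["n_meth"] + report["n_unmeth"]
    out = report[["chrom", "pos"]].copy()
    out["cov"] = cov
    out["level"] = report["n_meth"] / cov.where(cov > 0)
    return out


def build_matrix(
    reports: Mapping[str, pd.DataFrame],
    meta: pd.DataFrame,
    features: pd.DataFrame | Sequence[RegionCluster],
    *,
    kind: str = "cytosine",
    coverage_weighted: bool = False,
) -> MethylationMatrix:
    """Assemble the samples x features methylation matrix.

    ``features`` is the output of :func:`filter_cytosines` (kind="cytosine")
    or :func:`cluster_regions` (kind="region").  Region values are the
    unweighted mean of member-cytosine levels per sample, or a
    coverage-weighted mean when ``coverage_weighted`` is set.
    Every sample in ``reports`` must have a labels row in ``meta``.
    """
    meta_idx = meta.set_index("sample_id")
    missing = [s for s in reports if s not in meta_idx.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")

    if kind == "cytosine":
        coords = features  # DataFrame chrom,pos
        feature_ids = [
            format_feature_id(c, int(p)) for c, p in zip(coords["chrom"], coords["pos"])
        ]
        coord_df = pd.DataFrame(
            {
                "feature_id": feature_ids,
                "chrom": coords["chrom"].to_numpy(),
                "start": coords["pos"].to_numpy() - 1,
                "end": coords["pos"].to_numpy(),
                "kind": "cytosine",
                "n_cytosines": 1,
            }
        )
        key = pd.MultiIndex.from_arrays([coords["chrom"], coords["pos"]])
        rows = {}
        for sample_id, report in reports.items():
            lv = _level_lookup(report).set_index(["chrom", "pos"])
            sub = lv.loc[key]
            if sub["level"].isna().any():
                bad = sub.index[sub["level"].isna()][0]
                raise ValueError(
                    f"sample {sample_id}: retained cytosine {bad} has zero coverage"
                )
            rows[sample_id] = sub["level"].to_numpy()
        values = pd.DataFrame.from_dict(rows, orient="index", columns=feature_ids)
    elif kind == "region":
        clusters = list(features)
        feature_ids = [
            format_feature_id(cl.chrom, cl.first, cl.last, kind="region") for cl in clusters
        ]
        coord_df = pd.DataFrame(
            {
                "feature_id": feature_ids,
                "chrom": [cl.chrom for cl in clusters],
                "start": [cl.first - 1 for cl in clusters],
                "end": [cl.last for cl in clusters],
                "kind": "region",
                "n_cytosines": [cl.n_cytosines for cl in clusters],
            }
        )
        rows = {}
        for sample_id, report in reports.items():
            lv = _level_lookup(report).set_index(["chrom", "pos"])
            vals = np.empty(len(clusters))
            for j, cl in enumerate(clusters):
                key = pd.MultiIndex.from_arrays(
                    [[cl.chrom] * cl.n_cytosines, list(cl.positions)]
                )
                sub = lv.loc[key]
                if sub["level"].isna().any():
                    raise ValueError(
                        f"sample {sample_id}: region {feature_ids[j]} has a zero-coverage member"
                    )
                if coverage_weighted:
                    w = sub["cov"].to_numpy(dtype=float)
                    vals[j] = float(np.average(sub["level"].to_numpy(), weights=w))
                else:
                    vals[j] = float(sub["level"].mean())
            rows[sample_id] = vals
        values = pd.DataFrame.from_dict(rows, orient="index", columns=feature_ids)
    else:
        raise ValueError(f"unknown feature kind: {kind}")

    values.index.name = "sample_id"
    labels = meta_idx.loc[values.index, ["stage", "cultivar"]]
    return MethylationMatrix(values=values, coords=coord_df, labels=labels)


def write_matrix(matrix: MethylationMatrix, prefix: str | Path) -> dict[str, Path]:
    """Persist a matrix as TSV plus a sidecar BED of feature coordinates."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": prefix.with_suffix(".tsv"),
        "bed": prefix.with_suffix(".bed"),
        "labels": Path(str(prefix) + ".labels.tsv"),
    }
    matrix.values.to_csv(paths["values"], sep="\t")
    bed = matrix.coords.copy()
    bed["name"] = bed["feature_id"]
    bed["score"] = 0
    bed["strand"] = "."
    bed = bed.sort_values(["chrom", "start", "end"], kind="mergesort")
    bed.to_csv(
        paths["bed"],
        sep="\t",
        header=False,
        index=False,
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    matrix.labels.to_csv(paths["labels"], sep="\t")
    return paths


def read_matrix(prefix: str | Path) -> MethylationMatrix:
    """Load a matrix written by :func:`write_matrix`."""
    prefix = Path(prefix)
    values = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col=0)
    labels = pd.read_csv(Path(str(prefix) + ".labels.tsv"), sep="\t", index_col=0)
    rows = []
    for fid in values.columns:
        chrom, first, last, kind = parse_feature_id(fid)
        if kind == "cytosine":
            rows.append((fid, chrom, first - 1, first, kind, 1))
        else:
            rows.append((fid, chrom, first - 1, last, kind, -1))
    coords = pd.DataFrame(
        rows, columns=["feature_id", "chrom", "start", "end", "kind", "n_cytosines"]
    )
    return MethylationMatrix(values=values, coords=coords, labels=labels)
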