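"""Synthetic multi-sample methylomes with planted dormancy-stage signal.

This module emulates the *structure* of a multi-cultivar bud-dormancy WGBS
study so that every downstream stage (filtering, region clustering, consensus
selection, cross-validation, annotation) is testable without any download:

* 8 chromosomes with gene models, a TE track (LTR/Ty3, LTR/Copia, ...) and
  one QTL interval per trait (CR, HR, FD, MD) on chromosome 4;
* 71 samples by default (9 paradormancy / 36 endodormancy / 26 ecodormancy)
  spread over 4 cultivars;
* per-cytosine read counts: coverage ~ NegativeBinomial (the usual WGBS
  overdispersion model), methylated reads ~ Binomial(coverage, p) with
  logit(p) = logit(base level of the context)
             + stage_effect  * coef(locus, stage)      at informative loci
             + cultivar_effect * sign(locus)           at confounder loci of
                                                        the sample's cultivar.

Stage-informative loci and cultivar-confounder loci are disjoint sets of
CG-context cytosines; the confounder effect is larger by default so that the
*raw* data clusters by cultivar while only the planted loci separate stages —
the property the selection step is supposed to recover.

All distributional choices are stand-ins: no published noise model exists for
these data, so defaults were picked once as field-typical values (see
docs/methods.md) and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .methio import (
    CONTEXTS,
    STAGES,
    AnnotationBundle,
    write_bed_track,
    write_cytosine_report,
    write_sample_metadata,
)

DEFAULT_CHROM_LENGTHS: tuple[tuple[str, int], ...] = (
    ("chr_1", 1_000_000),
    ("chr_2", 900_000),
    ("chr_3", 800_000),
    ("chr_4", 700_000),
    ("chr_5", 600_000),
    ("chr_6", 500_000),
    ("chr_7", 400_000),
    ("chr_8", 300_000),
)

QTL_TRAITS = ("CR", "HR", "FD", "MD")

TE_CLASSES = ("LTR/Ty3", "LTR/Copia", "LINE/L1", "DNA/MULE", "Unknown")
TE_CLASS_PROBS = (0.35, 0.30, 0.10, 0.10, 0.15)

_MIN_CHROM_LENGTH = 8_000  # shortest chromosome able to hold one gene + flanks


class SynthConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class SynthConfig:
    """Generator settings; defaults are the package's reference study design."""

    seed: int = 0
    chrom_lengths: tuple[tuple[str, int], ...] = DEFAULT_CHROM_LENGTHS
    n_cytosines: int = 5_000
    class_counts: dict[str, int] = field(
        default_factory=lambda: {
            "paradormancy": 9,
            "endodormancy": 36,
            "ecodormancy": 26,
        }
    )
    n_cultivars: int = 4
    frac_informative: float = 0.01
    stage_effect: float = 0.6  # logit-scale shift per unit stage coefficient
    cultivar_effect: float = 3.5  # logit-scale; dominates the raw signal
    frac_confounder: float = 0.05
    coverage_mean: float = 20.0
    coverage_dispersion: float = 20.0  # negative-binomial size (var/mean = 2 at 20x)
    base_level_by_context: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.5, "CHG": 0.3, "CHH": 0.1}
    )
    context_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)
    te_fraction: float = 0.5
    informative_annotation_enrichment: float = 3.0
    # cytosines arrive in clumps (CpG-dense patches) so that region clustering
    # has something to find; the remainder are scattered singletons
    frac_clustered: float = 0.7
    clump_size_mean: float = 6.0
    clump_span: int = 150

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise SynthConfigError("chrom_lengths must be non-empty")
        if any(c < 1 for c in self.class_counts.values()):
            raise SynthConfigError("class_counts values must be >= 1")
        if not set(self.class_counts) <= set(STAGES):
            raise SynthConfigError(f"stages must be a subset of {STAGES}")
        if not (0 < self.frac_informative < 1 and 0 <= self.frac_confounder < 1):
            raise SynthConfigError("informative/confounder fractions out of range")
        if self.frac_informative + self.frac_confounder >= 1:
            raise SynthConfigError("frac_informative + frac_confounder must be < 1")
        if abs(sum(self.context_mix) - 1.0) > 1e-9:
            raise SynthConfigError("context_mix must sum to 1")
        if self.coverage_mean <= 0:
            raise SynthConfigError("coverage_mean must be positive")
        if self.coverage_dispersion <= 0:
            raise SynthConfigError("coverage_dispersion must be positive")
        for ctx in CONTEXTS:
            lvl = self.base_level_by_context.get(ctx)
            if lvl is None or not (0 < lvl < 1):
                raise SynthConfigError(f"base level for {ctx} must be in (0,1)")
        for eff in (self.stage_effect, self.cultivar_effect):
            if not np.isfinite(eff):
                raise SynthConfigError("effects must be finite")
        if self.n_cultivars < 1:
            raise SynthConfigError("n_cultivars must be >= 1")
        if not (0 < self.te_fraction < 1):
            raise SynthConfigError("te_fraction must be in (0,1)")


@dataclass
class TruthTable:
    """Planted ground truth: which loci carry which signal.

    ``informative``: chrom, pos (1-based), context, plus one ``coef_<stage>``
    column per stage holding the per-stage effect coefficient in {-1, 0, +1}.
    ``confounder``: chrom, pos, context, cultivar, sign.  The two locus sets
    are disjoint by construction.
    """

    informative: pd.DataFrame
    confounder: pd.DataFrame

    @property
    def informative_ids(self) -> set[tuple[str, int]]:
        return set(zip(self.informative["chrom"], self.informative["pos"]))

    @property
    def confounder_ids(self) -> set[tuple[str, int]]:
        return set(zip(self.confounder["chrom"], self.confounder["pos"]))


@dataclass
class SimulatedDataset:
    """In-memory result of :func:`simulate_methylomes`."""

    reports: dict[str, pd.DataFrame]
    meta: pd.DataFrame
    truth: TruthTable


# ---------------------------------------------------------------------------
# annotation simulation
# ---------------------------------------------------------------------------


def simulate_genome_annotation(config: SynthConfig) -> AnnotationBundle:
    """Generate non-overlapping gene models, a TE track and QTL intervals.

    Deterministic given ``config.seed``.  TEs are laid down by an alternating
    gap/element walk whose expected covered fraction equals
    ``config.te_fraction``; QTLs (one per trait) land on chromosome 4 when at
    least four chromosomes exist, else on the last chromosome.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    for chrom, length in config.chrom_lengths:
        if length < _MIN_CHROM_LENGTH:
            raise SynthConfigError(
                f"{chrom}: length {length} bp cannot hold a gene with 2 kb flanks "
                f"(need >= {_MIN_CHROM_LENGTH})"
            )

    gene_rows, exon_rows = [], []
    gid = 0
    for chrom, length in config.chrom_lengths:
        pos = int(rng.integers(2_000, 4_000))
        while True:
            glen = int(rng.integers(1_000, 5_001))
            if pos + glen + 2_000 > length:
                break
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"gene_{gid}"
            gene_rows.append((chrom, pos, pos + glen, strand, gene_id))
            n_exons = int(rng.integers(1, 4))
            bounds = np.sort(rng.choice(np.arange(1, glen), size=2 * n_exons, replace=False))
            for k in range(n_exons):
                exon_rows.append(
                    (chrom, pos + int(bounds[2 * k]), pos + int(bounds[2 * k + 1]), strand, gene_id)
                )
            # intergenic gap before the next gene (>= 2 kb keeps genes apart)
            pos = pos + glen + int(rng.integers(2_000, 12_000))

    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand", "gene_id"])
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "strand", "gene_id"])
    exons = exons[exons["end"] > exons["start"]].reset_index(drop=True)

    te_rows = []
    tid = 0
    f = config.te_fraction
    mean_len = 2_750.0  # TE length ~ U(500, 5000)
    mean_gap = mean_len * (1.0 - f) / f
    for chrom, length in config.chrom_lengths:
        pos = int(rng.uniform(0, 2 * mean_gap))
        while True:
            tlen = int(rng.integers(500, 5_001))
            if pos + tlen > length:
                break
            tid += 1
            te_class = str(rng.choice(TE_CLASSES, p=TE_CLASS_PROBS))
            te_rows.append((chrom, pos, pos + tlen, f"te_{tid}", "+", te_class))
            pos = pos + tlen + int(rng.uniform(0, 2 * mean_gap))
    te = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "name", "strand", "te_class"])

    chroms = [c for c, _ in config.chrom_lengths]
    qtl_chrom = chroms[3] if len(chroms) >= 4 else chroms[-1]
    qtl_len_total = dict(config.chrom_lengths)[qtl_chrom]
    qtl_rows = []
    for i, trait in enumerate(QTL_TRAITS):
        span = int(qtl_len_total * 0.08)
        lo = int(rng.uniform(0.4 * qtl_len_total, 0.9 * qtl_len_total - span))
        qtl_rows.append((qtl_chrom, lo, lo + span, f"qtl_{trait.lower()}", "+", trait))
    qtl = pd.DataFrame(qtl_rows, columns=["chrom", "start", "end", "name", "strand", "trait"])

    return AnnotationBundle(
        genes=genes,
        exons=exons,
        te=te,
        qtl=qtl,
        chrom_lengths=dict(config.chrom_lengths),
    )


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------


def _clustered_positions(rng: np.random.Generator, length: int, n: int, config: SynthConfig) -> np.ndarray:
    """Draw ~n distinct 1-based positions, most of them in CpG-dense clumps."""
    positions: list[int] = []
    while len(positions) < n:
        anchor = int(rng.integers(1, max(2, length - config.clump_span)))
        if rng.random() < config.frac_clustered:
            k = 4 + rng.poisson(max(config.clump_size_mean - 4.0, 0.0))
            offs = rng.integers(0, config.clump_span, size=int(k))
            positions.extend(int(anchor + o) for o in np.unique(offs))
        else:
            positions.append(anchor)
    uniq = np.unique(np.asarray(positions, dtype=np.int64))
    uniq = uniq[uniq <= length]
    if len(uniq) > n:
        keep = np.sort(rng.choice(len(uniq), size=n, replace=False))
        uniq = uniq[keep]
    return uniq


def _interval_membership(pos: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask: 1-based positions falling in any 0-based half-open interval."""
    mask = np.zeros(len(pos), dtype=bool)
    for s, e in zip(intervals["start"], intervals["end"]):
        mask |= (pos > s) & (pos <= e)
    return mask


def _make_trinucleotide(rng: np.random.Generator, context: str) -> str:
    h = "ACT"
    n = "ACGT"
    if context == "CG":
        return "CG" + n[rng.integers(0, 4)]
    if context == "CHG":
        return "C" + h[rng.integers(0, 3)] + "G"
    return "C" + h[rng.integers(0, 3)] + h[rng.integers(0, 3)]


def simulate_methylomes(
    config: SynthConfig, annotation: AnnotationBundle
) -> SimulatedDataset:
    """Simulate per-sample cytosine reports plus metadata and ground truth.

    See the module docstring for the sampling model.  Informative and
    confounder loci are planted on CG-context cytosines (the default feature
    pipeline is CpG-based); informative loci are drawn with sampling weight
    ``1 + informative_annotation_enrichment`` inside TE or QTL intervals.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 202])

    # --- cytosine map ------------------------------------------------------
    total_len = sum(l for _, l in config.chrom_lengths)
    chrom_arr, pos_arr = [], []
    remaining = config.n_cytosines
    for i, (chrom, length) in enumerate(config.chrom_lengths):
        if i == len(config.chrom_lengths) - 1:
            n_here = remaining
        else:
            n_here = int(round(config.n_cytosines * length / total_len))
            n_here = min(n_here, remaining)
        remaining -= n_here
        p = _clustered_positions(rng, length, n_here, config)
        chrom_arr.extend([chrom] * len(p))
        pos_arr.extend(p.tolist())
    chroms = np.asarray(chrom_arr)
    positions = np.asarray(pos_arr, dtype=np.int64)
    n_cyt = len(positions)

    contexts = rng.choice(CONTEXTS, size=n_cyt, p=np.asarray(config.context_mix))
    trinucs = np.asarray([_make_trinucleotide(rng, c) for c in contexts])

    # --- planted loci ------------------------------------------------------
    cg_idx = np.flatnonzero(contexts == "CG")
    n_inf = int(round(config.frac_informative * n_cyt))
    n_conf = int(round(config.frac_confounder * n_cyt))
    if n_inf + n_conf > len(cg_idx):
        raise SynthConfigError(
            f"not enough CG cytosines ({len(cg_idx)}) to plant "
            f"{n_inf} informative + {n_conf} confounder loci"
        )

    anno_mask = np.zeros(n_cyt, dtype=bool)
    for chrom, _ in config.chrom_lengths:
        sel = chroms == chrom
        if not sel.any():
            continue
        sub_pos = positions[sel]
        m = _interval_membership(sub_pos, annotation.te[annotation.te["chrom"] == chrom])
        m |= _interval_membership(sub_pos, annotation.qtl[annotation.qtl["chrom"] == chrom])
        anno_mask[np.flatnonzero(sel)] = m

    weights = 1.0 + config.informative_annotation_enrichment * anno_mask[cg_idx]
    weights = weights / weights.sum()
    inf_idx = np.sort(rng.choice(cg_idx, size=n_inf, replace=False, p=weights))
    rest = np.setdiff1d(cg_idx, inf_idx)
    conf_idx = np.sort(rng.choice(rest, size=n_conf, replace=False))

    stages = [s for s in STAGES if s in config.class_counts]
    coefs = np.zeros((n_inf, len(stages)))
    for i in range(n_inf):
        coefs[i] = rng.permutation([-1.0, 0.0, 1.0])[: len(stages)]
        if np.all(coefs[i] == coefs[i][0]):  # degenerate for < 3 stages
            coefs[i] = np.asarray([-1.0, 1.0])[: len(stages)]
    conf_cultivar = rng.integers(0, config.n_cultivars, size=n_conf)
    conf_sign = rng.choice([-1.0, 1.0], size=n_conf)

    truth_inf = pd.DataFrame(
        {
            "chrom": chroms[inf_idx],
            "pos": positions[inf_idx],
            "context": contexts[inf_idx],
        }
    )
    for j, stage in enumerate(stages):
        truth_inf[f"coef_{stage}"] = coefs[:, j]
    truth_conf = pd.DataFrame(
        {
            "chrom": chroms[conf_idx],
            "pos": positions[conf_idx],
            "context": contexts[conf_idx],
            "cultivar": [f"cv{int(c) + 1}" for c in conf_cultivar],
            "sign": conf_sign,
        }
    )
    truth = TruthTable(informative=truth_inf, confounder=truth_conf)

    # --- samples -----------------------------------------------------------
    ch_ranges = {
        "paradormancy": (0.0, 200.0),
        "endodormancy": (200.0, 900.0),
        "ecodormancy": (900.0, 1500.0),
    }
    sample_rows = []
    k = 0
    for stage in stages:
        for _ in range(config.class_counts[stage]):
            k += 1
            cultivar = k % config.n_cultivars  # stages span cultivars
            lo, hi = ch_ranges[stage]
            sample_rows.append(
                {
                    "sample_id": f"S{k:02d}",
                    "cultivar": f"cv{cultivar + 1}",
                    "experiment": f"exp{cultivar % 3 + 1}",
                    "chilling_hours": round(float(rng.uniform(lo, hi)), 1),
                    "stage": stage,
                }
            )
    meta = pd.DataFrame(sample_rows, columns=["sample_id", "cultivar", "experiment", "chilling_hours", "stage"])
    n_samples = len(meta)

    # --- methylation model -------------------------------------------------
    base = np.asarray([config.base_level_by_context[c] for c in contexts])
    logit_base = logit(base)
    stage_index = {s: j for j, s in enumerate(stages)}

    logits = np.tile(logit_base, (n_samples, 1))
    for si, row in enumerate(meta.itertuples(index=False)):
        j = stage_index[row.stage]
        logits[si, inf_idx] += config.stage_effect * coefs[:, j]
        mine = truth_conf["cultivar"].to_numpy() == row.cultivar
        logits[si, conf_idx[mine]] += config.cultivar_effect * conf_sign[mine]
    p = expit(logits)

    size = config.coverage_dispersion
    nb_p = size / (size + config.coverage_mean)
    coverage = rng.negative_binomial(size, nb_p, size=(n_samples, n_cyt))
    n_meth = rng.binomial(coverage, p)
    n_unmeth = coverage - n_meth

    reports: dict[str, pd.DataFrame] = {}
    for si, sample_id in enumerate(meta["sample_id"]):
        reports[sample_id] = pd.DataFrame(
            {
                "chrom": chroms,
                "pos": positions,
                "strand": "+",
                "n_meth": n_meth[si],
                "n_unmeth": n_unmeth[si],
                "context": contexts,
                "trinucleotide": trinucs,
            }
        )
    return SimulatedDataset(reports=reports, meta=meta, truth=truth)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_gff3(annotation: AnnotationBundle, path: str | Path) -> None:
    """Write genes and exons as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes.itertuples(index=False):
            fh.write(
                f"{g.chrom}\tmethylstage\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            exons = annotation.exons[annotation.exons["gene_id"] == g.gene_id]
            for e in exons.itertuples(index=False):
                fh.write(
                    f"{e.chrom}\tmethylstage\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\tParent={g.gene_id}\n"
                )


def write_annotation(annotation: AnnotationBundle, outdir: str | Path) -> dict[str, Path]:
    """Write genes.gff3, te.bed, qtl.bed (and chrom_lengths.tsv) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": outdir / "genes.gff3",
        "te": outdir / "te.bed",
        "qtl": outdir / "qtl.bed",
        "chrom_lengths": outdir / "chrom_lengths.tsv",
    }
    write_gff3(annotation, paths["gff3"])
    write_bed_track(annotation.te, paths["te"], "te_class")
    write_bed_track(annotation.qtl, paths["qtl"], "trait")
    if annotation.chrom_lengths:
        pd.DataFrame(
            sorted(annotation.chrom_lengths.items()), columns=["chrom", "length"]
        ).to_csv(paths["chrom_lengths"], sep="\t", index=False)
    return paths


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write per-sample cytosine reports, metadata and the truth tables."""
    outdir = Path(outdir)
    reports_dir = outdir / "reports"
    reports_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {"reports_dir": reports_dir}
    for sample_id, report in dataset.reports.items():
        write_cytosine_report(report, reports_dir / f"{sample_id}.CX_report.txt")
    paths["meta"] = outdir / "meta.tsv"
    write_sample_metadata(dataset.meta, paths["meta"])
    paths["truth_informative"] = outdir / "truth_informative.tsv"
    paths["truth_confounder"] = outdir / "truth_confounder.tsv"
    dataset.truth.informative.to_csv(paths["truth_informative"], sep="\t", index=False)
    dataset.truth.confounder.to_csv(paths["truth_confounder"], sep="\t", index=False)
    return paths
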