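"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methylstage import features, synthgen


@pytest.fixture(scope="session")
def small_config() -> synthgen.SynthConfig:
    return synthgen.SynthConfig(seed=11, n_cytosines=800)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return synthgen.simulate_genome_annotation(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_annotation):
    return synthgen.simulate_methylomes(small_config, small_annotation)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    retained = features.filter_cytosines(small_dataset.reports)
    return features.build_matrix(
        small_dataset.reports, small_dataset.meta, retained, kind="cytosine"
    )


def random_reports(rng: np.random.Generator, n_samples: int, n_cytosines: int):
    """Random toy cytosine reports sharing a common coordinate map."""
    chroms = rng.choice(["chr_1", "chr_2"], size=n_cytosines)
    pos = {}
    for c in ("chr_1", "chr_2"):
        idx = np.flatnonzero(chroms == c)
        pos_c = np.sort(rng.choice(np.arange(1, 10_000), size=len(idx), replace=False))
        for i, p in zip(idx, pos_c):
            pos[i] = p
    positions = np.array([pos[i] for i in range(n_cytosines)])
    contexts = rng.choice(["CG", "CHG", "CHH"], size=n_cytosines)
    reports = {}
    for s in range(n_samples):
        cov = rng.integers(0, 12, size=n_cytosines)
        meth = rng.binomial(cov, 0.4)
        reports[f"S{s}"] = pd.DataFrame(
            {
                "chrom": chroms,
                "pos": positions,
                "strand": "+",
                "n_meth": meth,
                "n_unmeth": cov - meth,
                "context": contexts,
                "trinucleotide": "CGA",
            }
        )
    return reports
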