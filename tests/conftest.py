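import numpy as np
import pandas as pd
import pytest

from edmr.io import CPG_COLUMNS


def make_cpgs(positions, chrom="chr1", strand="+", diffs=None, pvals=None, qvals=None,
              coverage=50):
    """Build a minimal per-CpG frame from positions (single chromosome)."""
    n = len(positions)
    df = pd.DataFrame({
        "chrom": chrom,
        "pos": np.asarray(positions, dtype="int64"),
        "strand": strand,
        "coverage": coverage,
        "meth_diff": np.zeros(n) if diffs is None else np.asarray(diffs, dtype=float),
        "pvalue": np.full(n, 0.5) if pvals is None else np.asarray(pvals, dtype=float),
        "qvalue": np.full(n, 0.5) if qvals is None else np.asarray(qvals, dtype=float),
    })
    return df[CPG_COLUMNS].sort_values(["chrom", "pos"]).reset_index(drop=True)


def make_dmrs(rows):
    """DMR frame from (chrom, start, end, cpg_count, dmc_count, mean_diff, p, q) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cpg_count", "dmc_count",
                                     "mean_diff", "p_combined", "q_value"])
    df["direction"] = np.where(df["mean_diff"] > 0, "hyper", "hypo")
    return df[["chrom", "start", "end", "cpg_count", "dmc_count", "mean_diff",
               "direction", "p_combined", "q_value"]]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_synthetic():
    """Small synthetic dataset shared by I/O, CLI and module tests."""
    from edmr.synthetic import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(seed=3, n_cpgs=20_000, n_dmrs=8, chroms=("chr1", "chr2"))
    cpgs, truth = generate_dataset(cfg)
    return cfg, cpgs, truth
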