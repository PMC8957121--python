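import numpy as np
import pandas as pd
import pytest

from gbmseesaw import SimConfig, fixture_tiny, simulate_study


@pytest.fixture
def tiny_study():
    """Hand-enumerable micro-study (5 genes, 12 CpG sites, 2+2 samples)."""
    return fixture_tiny()


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic study, shared across tests."""
    return simulate_study(SimConfig(seed=0))


def make_genes(rows):
    """Gene table from (gene_id, chrom, start, end, strand) tuples."""
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    ).set_index("gene_id")
    df["length"] = df["end"] - df["start"] + 1
    return df


def make_cpgs(rows):
    """CpG table from (chrom, pos, strand, meth, unmeth) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "meth_count", "unmeth_count"]
    )


def random_instance(rng, n_genes=20, n_cpgs=200, n_samples=2, max_pos=10_000):
    """A random small quantification instance for oracle comparisons."""
    genes = []
    for i in range(n_genes):
        chrom = f"c{rng.integers(1, 4)}"
        start = int(rng.integers(1, max_pos))
        end = start + int(rng.integers(0, 2000))
        genes.append((f"g{i}", chrom, start, end, "+" if rng.random() < 0.5 else "-"))
    cpgs = {}
    for s in range(n_samples):
        rows = []
        for _ in range(n_cpgs):
            chrom = f"c{rng.integers(1, 4)}"
            pos = int(rng.integers(1, max_pos + 2000))
            meth = int(rng.integers(0, 20))
            unmeth = int(rng.integers(0, 20))
            rows.append((chrom, pos, "+", meth, unmeth))
        cpgs[f"s{s}"] = make_cpgs(rows)
    return make_genes(genes), cpgs


def brute_force_gene_sums(cpgs, genes):
    """Quadratic scan of every CpG against every gene interval."""
    out = {}
    for sample, table in cpgs.items():
        for gene_id, g in genes.iterrows():
            m = c = 0
            for row in table.itertuples():
                if row.chrom == g["chrom"] and g["start"] <= row.pos <= g["end"]:
                    m += row.meth_count
                    c += row.meth_count + row.unmeth_count
            out[(gene_id, sample)] = (m, c)
    return out
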