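"""Synthetic studies with planted, recoverable parameters.

The generator emulates the statistical structure the analysis assumes in
real invertebrate methylome/transcriptome studies:

* bimodal gene-level methylation: each gene draws a baseline methylation
  probability from a low (Beta, mean 1%) or high (Beta, mean 60%)
  mixture component; the truth label ``true_class`` records which side
  of the 2.5% class cutoff the drawn probability falls on, the mixture
  component is kept separately;
* per-CpG bisulfite counts: CpG sites placed uniformly inside genes
  (plus ~10% intergenic sites), Poisson coverage, binomial methylated
  counts at the gene's probability, logit-shifted in condition 2 by the
  gene's planted methylation change;
* expression coupled to methylation at baseline: mean log2 RPKM is
  linear in log2 percent methylation, and negative-binomial dispersion
  is lower for the high class, so expression level rises and
  between-replicate variability falls with methylation;
* tunable change-change coupling: planted methylation changes (logit
  scale) and expression changes (log2 scale) share a latent Gaussian
  with loading sqrt(|rho|), so their correlation converges to
  ``delta_coupling_rho``; class-level seesaw shifts add class means to
  both;
* MBD capture and mdRAD read counts whose expectations increase with
  the methylation probability.

All randomness derives from one seed through named substreams (one per
variable), so enlarging the study extends, rather than reshuffles,
earlier draws of each variable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .types import ContrastSpec, GbmError

_SIGMOID = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic study; defaults define the study conditions.

    Methylation probabilities are per gene; condition-2 shifts act on the
    logit scale so probabilities stay inside (0, 1). Expression changes
    are on the log2 scale. ``delta_gbm_sd`` / ``delta_expr_sd`` are the
    gene-level spreads of the planted changes around their class means.
    """

    n_genes: int = 2000
    n_contigs: int = 20
    gene_length_median: float = 2000.0
    gene_length_log_sd: float = 0.6
    cpgs_per_kb: float = 20.0
    prop_high: float = 0.4
    low_meth_mean: float = 0.01
    low_meth_conc: float = 50.0
    high_meth_mean: float = 0.60
    high_meth_conc: float = 10.0
    coverage_per_cpg: float = 30.0
    n_samples_per_condition: int = 3
    condition1: str = "control"
    condition2: str = "treated"
    class_cutoff_pct: float = 2.5
    expr_intercept: float = 3.0
    expr_slope_vs_gbm: float = 0.35
    expr_dispersion_low: float = 0.4
    expr_dispersion_high: float = 0.1
    delta_coupling_rho: float = 0.0
    seesaw_delta_gbm_high: float = 0.0
    seesaw_delta_gbm_low: float = 0.0
    seesaw_delta_expr_high: float = 0.0
    seesaw_delta_expr_low: float = 0.0
    delta_gbm_sd: float = 1.0
    delta_expr_sd: float = 1.5
    library_size: float = 5e6
    mdrad_library_size: float = 2e6
    mbd_library_size: float = 2e6
    n_mbd_pairs: int = 3
    n_mdrad_per_condition: int = 3
    intergenic_cpg_frac: float = 0.1
    gap_median: float = 3000.0
    gap_log_sd: float = 0.5
    contig_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prop_high", "low_meth_mean", "high_meth_mean"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise GbmError(f"{name} must be in [0, 1], got {v}")
        for name in ("low_meth_conc", "high_meth_conc"):
            if getattr(self, name) <= 0:
                raise GbmError(f"{name} must be > 0")
        if abs(self.delta_coupling_rho) > 1:
            raise GbmError("|delta_coupling_rho| must be <= 1")
        if self.n_genes < 1 or self.n_contigs < 1:
            raise GbmError("n_genes and n_contigs must be >= 1")
        if self.n_samples_per_condition < 1:
            raise GbmError("n_samples_per_condition must be >= 1")


@dataclass
class SimulatedStudy:
    """In-memory bundle of everything one synthetic study produces."""

    config: SimConfig
    genes: pd.DataFrame
    contig_lengths: dict[str, int]
    cpg_reports: dict[str, pd.DataFrame]
    counts: dict[str, pd.DataFrame]
    mbd_pairs: list[tuple[str, str]]
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame
    contrast: ContrastSpec = field(init=False)

    def __post_init__(self) -> None:
        self.contrast = ContrastSpec(
            self.config.condition1, self.config.condition2, assay="rnaseq"
        )


def _rng(seed: int, name: str) -> np.random.Generator:
    """A named, seed-derived stream: stable under adding other streams."""
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _beta_params(mean: float, conc: float) -> tuple[float, float]:
    return mean * conc, (1.0 - mean) * conc


def _place_genes(cfg: SimConfig) -> tuple[pd.DataFrame, dict[str, int], list[tuple[str, int, int]]]:
    """Lay genes head-to-tail with lognormal gaps; returns genes, contig
    lengths, and the intergenic gap intervals."""
    rng_len = _rng(cfg.seed, "gene_length")
    rng_gap = _rng(cfg.seed, "gene_gap")
    lengths = np.maximum(
        rng_len.lognormal(np.log(cfg.gene_length_median), cfg.gene_length_log_sd, cfg.n_genes),
        200,
    ).astype(np.int64)
    gaps = np.maximum(
        rng_gap.lognormal(np.log(cfg.gap_median), cfg.gap_log_sd, cfg.n_genes), 1500
    ).astype(np.int64)
    per_contig = int(np.ceil(cfg.n_genes / cfg.n_contigs))
    rows, gap_intervals = [], []
    contig_lengths: dict[str, int] = {}
    strands = _rng(cfg.seed, "gene_strand").choice(["+", "-"], size=cfg.n_genes)
    g = 0
    for c in range(cfg.n_contigs):
        chrom = f"contig{c + 1}"
        cursor = 0  # last occupied coordinate
        for _ in range(per_contig):
            if g >= cfg.n_genes:
                break
            start = cursor + gaps[g]
            end = start + lengths[g] - 1
            gap_intervals.append((chrom, cursor + 1, start - 1))
            rows.append((f"gene{g + 1:05d}", chrom, int(start), int(end), strands[g]))
            cursor = end
            g += 1
        contig_lengths[chrom] = int(cursor + 2000)
        if cfg.contig_length is not None and contig_lengths[chrom] > cfg.contig_length:
            raise GbmError(
                f"gene placement exceeds contig_length={cfg.contig_length} on "
                f"{chrom}; use fewer genes, more contigs, or longer contigs"
            )
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    ).set_index("gene_id")
    genes["length"] = genes["end"] - genes["start"] + 1
    return genes, contig_lengths, gap_intervals


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Negative binomial with mean/dispersion parameterisation (var = m + a m^2)."""
    n = 1.0 / np.maximum(alpha, 1e-12)
    p = n / (n + np.maximum(mean, 1e-12))
    return rng.negative_binomial(n, p)


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate one complete synthetic study from a single seed.

    Returns cytosine reports per WGBS sample, gene models, RNA-seq /
    MBD / mdRAD count matrices, a sample sheet, and the truth table used
    by parameter-recovery tests.
    """
    cfg = config
    genes, contig_lengths, gap_intervals = _place_genes(cfg)
    n = cfg.n_genes

    component = _rng(cfg.seed, "class").random(n) < cfg.prop_high
    a_lo, b_lo = _beta_params(cfg.low_meth_mean, cfg.low_meth_conc)
    a_hi, b_hi = _beta_params(cfg.high_meth_mean, cfg.high_meth_conc)
    # one stream per mixture component keeps early genes' draws stable
    # when n_genes grows
    p_base = np.where(
        component,
        _rng(cfg.seed, "baseline_meth_high").beta(a_hi, b_hi, n),
        _rng(cfg.seed, "baseline_meth_low").beta(a_lo, b_lo, n),
    )
    p_base = np.clip(p_base, 1e-6, 1 - 1e-6)
    # class at baseline drives class-dependent effects (shifts, dispersion)
    base_class = p_base >= cfg.class_cutoff_pct / 100.0

    # planted condition-2 shifts sharing a latent Gaussian (loading sqrt|rho|)
    rho = cfg.delta_coupling_rho
    z = _rng(cfg.seed, "delta_latent").standard_normal(n)
    e_m = _rng(cfg.seed, "delta_meth_noise").standard_normal(n)
    e_x = _rng(cfg.seed, "delta_expr_noise").standard_normal(n)
    root = np.sqrt(abs(rho))
    resid = np.sqrt(1.0 - abs(rho))
    dm_mean = np.where(base_class, cfg.seesaw_delta_gbm_high, cfg.seesaw_delta_gbm_low)
    dx_mean = np.where(base_class, cfg.seesaw_delta_expr_high, cfg.seesaw_delta_expr_low)
    delta_meth = dm_mean + cfg.delta_gbm_sd * (root * z + resid * e_m)
    delta_expr = dx_mean + cfg.delta_expr_sd * (np.sign(rho) * root * z + resid * e_x)

    # the class label the analysis estimates: the cutoff applied to the
    # gene's average methylation probability across the two conditions
    # (mean percent methylation averages all samples from both groups)
    p_cond2_gene = _SIGMOID(_logit(p_base) + delta_meth)
    true_class = (p_base + p_cond2_gene) / 2.0 >= cfg.class_cutoff_pct / 100.0

    # CpG layout: sites uniform inside genes plus intergenic sites in gaps
    rng_ncpg = _rng(cfg.seed, "cpg_count")
    n_cpg = rng_ncpg.poisson(genes["length"].to_numpy() / 1000.0 * cfg.cpgs_per_kb)
    rng_pos = _rng(cfg.seed, "cpg_pos")
    chroms, positions, gene_of = [], [], []
    starts = genes["start"].to_numpy()
    lengths = genes["length"].to_numpy()
    gene_chroms = genes["chrom"].to_numpy()
    for i in range(n):
        if n_cpg[i] == 0:
            continue
        offs = np.unique(rng_pos.integers(0, lengths[i], size=n_cpg[i]))
        positions.append(starts[i] + offs)
        chroms.append(np.repeat(gene_chroms[i], offs.size))
        gene_of.append(np.full(offs.size, i, dtype=np.int64))
    n_genic = int(sum(p.size for p in positions))
    n_inter = int(round(n_genic * cfg.intergenic_cpg_frac / max(1 - cfg.intergenic_cpg_frac, 1e-9)))
    rng_ipos = _rng(cfg.seed, "intergenic_pos")
    gap_arr = [(c, s, e) for c, s, e in gap_intervals if e - s > 100]
    if n_inter and gap_arr:
        gap_lens = np.array([e - s + 1 for _, s, e in gap_arr], dtype=float)
        alloc = rng_ipos.multinomial(n_inter, gap_lens / gap_lens.sum())
        for (chrom, s, e), k in zip(gap_arr, alloc):
            if k == 0:
                continue
            offs = np.unique(rng_ipos.integers(s, e + 1, size=k))
            positions.append(offs)
            chroms.append(np.repeat(chrom, offs.size))
            gene_of.append(np.full(offs.size, -1, dtype=np.int64))
    pos_all = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    chrom_all = np.concatenate(chroms) if chroms else np.empty(0, dtype=object)
    gene_all = np.concatenate(gene_of) if gene_of else np.empty(0, dtype=np.int64)
    strand_all = _rng(cfg.seed, "cpg_strand").choice(["+", "-"], size=pos_all.size)

    n_inter_real = int((gene_all < 0).sum())
    p_inter = np.clip(
        _rng(cfg.seed, "intergenic_meth").beta(a_lo, b_lo, n_inter_real), 1e-6, 1 - 1e-6
    )

    # per-site methylation probability per condition
    base_site = np.where(gene_all >= 0, p_base[np.maximum(gene_all, 0)], np.nan)
    base_site[gene_all < 0] = p_inter
    logit_site = _logit(base_site)
    shift_site = np.where(gene_all >= 0, delta_meth[np.maximum(gene_all, 0)], 0.0)
    p_cond = {
        cfg.condition1: base_site,
        cfg.condition2: _SIGMOID(logit_site + shift_site),
    }

    nsc = cfg.n_samples_per_condition
    cpg_reports: dict[str, pd.DataFrame] = {}
    sheet_rows = []
    for cond_i, cond in enumerate((cfg.condition1, cfg.condition2)):
        for rep in range(1, nsc + 1):
            sample = f"wgbs_{cond}_{rep}"
            r = _rng(cfg.seed, f"wgbs:{cond}:{rep}")
            cov = r.poisson(cfg.coverage_per_cpg, pos_all.size)
            meth = r.binomial(cov, p_cond[cond])
            df = pd.DataFrame(
                {
                    "chrom": chrom_all,
                    "pos": pos_all,
                    "strand": strand_all,
                    "meth_count": meth,
                    "unmeth_count": cov - meth,
                }
            ).sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
            cpg_reports[sample] = df
            sheet_rows.append((sample, cond, "wgbs", "none", cond_i == 0, ""))

    # RNA-seq: mean log2 RPKM linear in log2 percent methylation
    log2_gbm_true = np.log2(100.0 * p_base)
    log2_rpkm = cfg.expr_intercept + cfg.expr_slope_vs_gbm * log2_gbm_true
    alpha = np.where(base_class, cfg.expr_dispersion_high, cfg.expr_dispersion_low)
    len_kb = lengths / 1000.0
    mu_base = 2.0**log2_rpkm * len_kb * cfg.library_size / 1e6
    mu_cond = {
        cfg.condition1: mu_base,
        cfg.condition2: mu_base * 2.0**delta_expr,
    }
    rna = {}
    for cond_i, cond in enumerate((cfg.condition1, cfg.condition2)):
        for rep in range(1, nsc + 1):
            sample = f"rna_{cond}_{rep}"
            r = _rng(cfg.seed, f"rna:{cond}:{rep}")
            rna[sample] = _nb_draw(r, mu_cond[cond], alpha)
            sheet_rows.append((sample, cond, "rnaseq", "none", cond_i == 0, ""))
    rna_counts = pd.DataFrame(rna, index=genes.index)

    truth = pd.DataFrame(
        {
            "true_class": np.where(true_class, "high", "low"),
            "mixture_component": np.where(component, "high", "low"),
            "true_baseline_meth": p_base,
            "true_delta_meth": delta_meth,
            "true_log2_expr": log2_rpkm,
            "true_delta_log2_expr": delta_expr,
        },
        index=genes.index,
    )

    # mdRAD: read density proportional to methylation probability
    mdrad = {}
    for cond_i, cond in enumerate((cfg.condition1, cfg.condition2)):
        p_gene = p_base if cond_i == 0 else _SIGMOID(_logit(p_base) + delta_meth)
        w = (0.05 + p_gene) * len_kb
        mu = w / w.sum() * cfg.mdrad_library_size
        for rep in range(1, cfg.n_mdrad_per_condition + 1):
            sample = f"mdrad_{cond}_{rep}"
            r = _rng(cfg.seed, f"mdrad:{cond}:{rep}")
            mdrad[sample] = r.poisson(mu)
            sheet_rows.append((sample, cond, "mdrad", "none", cond_i == 0, ""))
    mdrad_counts = pd.DataFrame(mdrad, index=genes.index)

    mbd_counts, mbd_pairs, mbd_sheet_rows = simulate_mbd_counts(truth, genes, cfg)
    sheet_rows.extend(mbd_sheet_rows)

    sheet = pd.DataFrame(
        sheet_rows,
        columns=["sample_id", "condition", "assay", "fraction", "is_control", "pair_id"],
    ).set_index("sample_id")

    return SimulatedStudy(
        config=cfg,
        genes=genes,
        contig_lengths=contig_lengths,
        cpg_reports=cpg_reports,
        counts={"rnaseq": rna_counts, "mdrad": mdrad_counts, "mbd": mbd_counts},
        mbd_pairs=mbd_pairs,
        sample_sheet=sheet,
        truth=truth,
    )


def simulate_mbd_counts(
    truth: pd.DataFrame, genes: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, list[tuple[str, str]], list[tuple]]:
    """Captured/unbound MBD count pairs from true methylation probabilities.

    The captured fraction's expected reads grow with gene length times
    methylation probability; the unbound fraction's shrink with it, so
    the expected MBD-score rises monotonically with true methylation.
    """
    cfg = config
    p = truth["true_baseline_meth"].to_numpy()
    len_kb = genes.loc[truth.index, "length"].to_numpy() / 1000.0
    w_cap = (0.05 + p) * len_kb
    w_unb = (1.05 - p) * len_kb
    mu_cap = w_cap / w_cap.sum() * cfg.mbd_library_size
    mu_unb = w_unb / w_unb.sum() * cfg.mbd_library_size
    cols, pairs, sheet_rows = {}, [], []
    for k in range(1, cfg.n_mbd_pairs + 1):
        cap, unb = f"mbd_cap_{k}", f"mbd_unb_{k}"
        r = _rng(cfg.seed, f"mbd:{k}")
        cols[cap] = r.poisson(mu_cap)
        cols[unb] = r.poisson(mu_unb)
        pairs.append((cap, unb))
        sheet_rows.append((cap, cfg.condition1, "mbd", "captured", True, f"pair{k}"))
        sheet_rows.append((unb, cfg.condition1, "mbd", "unbound", True, f"pair{k}"))
    return pd.DataFrame(cols, index=truth.index), pairs, sheet_rows


def fixture_tiny() -> SimulatedStudy:
    """A hand-enumerable micro-study used as the brute-force anchor.

    Five genes on two contigs (one, ``g_nil``, contains no CpG), at most
    twenty CpG sites, two WGBS and two RNA-seq samples per condition.
    Every intermediate value is small enough to verify by hand.
    """
    cfg = SimConfig(n_genes=5, n_contigs=2, n_samples_per_condition=2, seed=0)
    genes = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
            "start": [1000, 5000, 9000, 2000, 6000],
            "end": [1999, 6499, 9999, 3999, 6999],
            "strand": ["+", "-", "+", "+", "-"],
        },
        index=pd.Index(["g1", "g2", "g3", "g4", "g_nil"], name="gene_id"),
    )
    genes["length"] = genes["end"] - genes["start"] + 1
    contig_lengths = {"chr1": 12000, "chr2": 9000}

    # (chrom, pos, strand) for every CpG site; g_nil gets none, two sites
    # are intergenic so window/off-gene logic is exercised
    sites = [
        ("chr1", 1100, "+"), ("chr1", 1500, "-"), ("chr1", 1900, "+"),
        ("chr1", 5200, "+"), ("chr1", 6000, "-"),
        ("chr1", 9100, "+"), ("chr1", 9500, "+"), ("chr1", 9900, "-"),
        ("chr2", 2500, "+"), ("chr2", 3500, "-"),
        ("chr1", 4200, "+"),   # intergenic, upstream of g2 (- strand: no)
        ("chr2", 1500, "-"),   # intergenic, in g4's promoter window
    ]

    def report(meths, covs):
        return pd.DataFrame(
            {
                "chrom": [s[0] for s in sites],
                "pos": [s[1] for s in sites],
                "strand": [s[2] for s in sites],
                "meth_count": meths,
                "unmeth_count": [c - m for m, c in zip(meths, covs)],
            }
        ).sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)

    covs = [10] * 12
    cpg_reports = {
        # g1 sites: (3,10),(1,10),(0,10) -> pooled 4/30
        "wgbs_control_1": report([3, 1, 0, 6, 8, 0, 0, 0, 5, 5, 1, 2], covs),
        "wgbs_control_2": report([1, 1, 0, 7, 7, 0, 1, 0, 5, 5, 0, 1], covs),
        "wgbs_treated_1": report([2, 0, 0, 9, 9, 0, 0, 1, 8, 6, 1, 1], covs),
        "wgbs_treated_2": report([0, 2, 0, 8, 9, 1, 0, 0, 7, 7, 0, 2], covs),
    }
    rna_counts = pd.DataFrame(
        {
            "rna_control_1": [10, 100, 20, 50, 5],
            "rna_control_2": [12, 110, 18, 55, 4],
            "rna_treated_1": [11, 210, 21, 28, 5],
            "rna_treated_2": [9, 190, 19, 26, 6],
        },
        index=genes.index,
    )
    sheet = pd.DataFrame(
        [
            ("wgbs_control_1", "control", "wgbs", "none", True, ""),
            ("wgbs_control_2", "control", "wgbs", "none", True, ""),
            ("wgbs_treated_1", "treated", "wgbs", "none", False, ""),
            ("wgbs_treated_2", "treated", "wgbs", "none", False, ""),
            ("rna_control_1", "control", "rnaseq", "none", True, ""),
            ("rna_control_2", "control", "rnaseq", "none", True, ""),
            ("rna_treated_1", "treated", "rnaseq", "none", False, ""),
            ("rna_treated_2", "treated", "rnaseq", "none", False, ""),
        ],
        columns=["sample_id", "condition", "assay", "fraction", "is_control", "pair_id"],
    ).set_index("sample_id")
    truth = pd.DataFrame(
        {
            "true_class": ["low", "high", "low", "high", "low"],
            "mixture_component": ["low", "high", "low", "high", "low"],
            "true_baseline_meth": [0.01, 0.7, 0.01, 0.5, 0.01],
            "true_delta_meth": [0.0, 0.0, 0.0, 0.0, 0.0],
            "true_log2_expr": [1.0, 4.0, 1.0, 3.0, 0.5],
            "true_delta_log2_expr": [0.0, 1.0, 0.0, -1.0, 0.0],
        },
        index=genes.index,
    )
    return SimulatedStudy(
        config=cfg,
        genes=genes,
        contig_lengths=contig_lengths,
        cpg_reports=cpg_reports,
        counts={"rnaseq": rna_counts},
        mbd_pairs=[],
        sample_sheet=sheet,
        truth=truth,
    )


def config_as_dict(cfg: SimConfig) -> dict:
    """Plain-dict view of a config (for serialisation alongside outputs)."""
    return asdict(cfg)
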