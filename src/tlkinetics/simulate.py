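"""Synthetic nucleotide-recoding RNA-seq data with known kinetics.

Generates read-level mutation tables, count matrices and ground-truth
kinetic parameters with exactly the statistical structure the inference
model assumes: two (or more) conditions with replicate libraries, each
replicate contributing one s4U-labeled library and one unlabeled
control; per-gene fraction-new theta fixed by a ground-truth
degradation rate and the labeling time (theta = 1 - exp(-k_deg * t));
per-read T-to-C counts drawn from the two-component Poisson mixture on
log-scale rates with gene-level variation around global means;
steady-state read depth proportional to k_syn / k_deg up to a
log-normal library-size factor; and optional SNP sites that elevate
mutation rates in labeled and control libraries alike.

Reads are abstract records that carry their retained tc count directly
(the inference consumes nothing else); base-by-base sequence simulation
is deliberately out of scope. For exercising the mutation filters,
:func:`read_records_with_artifacts` decorates the simulated reads with
per-event qualities/offsets plus filterable artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .calling import MutationEvent, ReadRecord

__all__ = ["SimConfig", "GroundTruth", "SimulatedExperiment",
           "simulate_gene_reads", "simulate_experiment",
           "read_records_with_artifacts", "write_fixture_bundle"]


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults emulate the source experimental design: two genotypes,
    three replicates each, a 2-hour s4U label, new-RNA log mutation
    rate around -1 and background around -3 with modest gene-to-gene
    spread, degradation rates log-normal around a ~3.5 h half-life, and
    ~10% library-depth variation.
    """

    n_genes: int = 100
    conditions: tuple = ("WT", "KO")
    replicates_per_condition: int = 3
    reads_per_gene: int = 300
    labeling_time_t: float = 2.0
    lambda_n_global: float | dict = -1.0
    lambda_o_global: float = -3.0
    sigma_n: float | dict = 0.15
    sigma_o: float = 0.15
    kdeg_truth: np.ndarray | float | None = None   # (n_genes, n_conditions)
    ksyn_truth: np.ndarray | float | None = None
    kdeg_log_mean: float = float(np.log(0.2))      # per hour
    kdeg_log_sd: float = 0.5
    expression_log_sd: float = 0.7                 # spread of relative N
    library_size_sd: float = 0.1
    depth_mode: str = "exact"                      # "exact" | "poisson"
    snp_fraction: float = 0.01
    snp_het_prob: float = 0.5
    snp_cover_prob: float = 0.3
    n_t_sites_per_read: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0:
            raise ValueError("n_genes must be nonnegative")
        if self.replicates_per_condition < 1:
            raise ValueError("need at least one replicate per condition")
        if self.labeling_time_t <= 0:
            raise ValueError("labeling time must be positive")
        if np.any(np.asarray(self.reads_per_gene) < 0):
            raise ValueError("reads_per_gene must be nonnegative")
        if self.sigma_o < 0 or np.any(np.asarray(
                list(self.sigma_n.values()) if isinstance(self.sigma_n, dict)
                else self.sigma_n) < 0):
            raise ValueError("gene-level standard deviations must be >= 0")
        if not 0 <= self.snp_fraction <= 1:
            raise ValueError("snp_fraction must lie in [0, 1]")
        if self.depth_mode not in ("exact", "poisson"):
            raise ValueError("depth_mode must be 'exact' or 'poisson'")

    def lambda_n_for(self, condition):
        if isinstance(self.lambda_n_global, dict):
            return float(self.lambda_n_global[condition])
        return float(self.lambda_n_global)

    def sigma_n_for(self, condition):
        if isinstance(self.sigma_n, dict):
            return float(self.sigma_n[condition])
        return float(self.sigma_n)


@dataclass
class GroundTruth:
    """True parameter values behind a simulated experiment.

    ``params``: one row per (gene, condition) with theta, kdeg, ksyn,
    lambda_n, lambda_o (theta = 1 - exp(-kdeg*t) exactly).
    ``snp_sites``: injected (gene_id, ref_pos) SNP sites.
    ``samples``: per-library metadata incl. the s4U indicator (0 for
    every control library) and library-size factor.
    """

    params: pd.DataFrame
    snp_sites: pd.DataFrame
    samples: pd.DataFrame
    globals: dict = field(default_factory=dict)


@dataclass
class SimulatedExperiment:
    reads: pd.DataFrame        # per-read mutation table
    counts: pd.DataFrame       # gene x sample matrix
    truth: GroundTruth
    site_counts: pd.DataFrame  # per-site control mutation evidence
    config: SimConfig


def simulate_gene_reads(theta, lambda_n, lambda_o, n_reads, labeled, rng):
    """Draw per-read tc counts from the labeled/background mixture.

    Each read independently comes from the new component
    Poisson(exp(lambda_n)) with probability ``labeled * theta`` and from
    the background Poisson(exp(lambda_o)) otherwise.
    """
    if not 0 <= theta <= 1:
        raise ValueError("theta must lie in [0, 1]")
    if n_reads < 0:
        raise ValueError("n_reads must be nonnegative")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) \
        else rng
    w = theta if labeled else 0.0
    is_new = rng.random(n_reads) < w
    tc = np.where(is_new,
                  rng.poisson(np.exp(lambda_n), n_reads),
                  rng.poisson(np.exp(lambda_o), n_reads))
    return tc.astype(np.int64)


def _gene_ids(n):
    width = max(4, len(str(max(n - 1, 0))))
    return [f"gene_{i:0{width}d}" for i in range(n)]


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Generate a full labeled+control experiment from the config.

    Per condition and replicate, one labeled library (s4u=1) and one
    unlabeled control (s4u=0) are emitted. Expected read depth per gene
    follows steady-state expression N = k_syn / k_deg (relative, scaled
    to ``reads_per_gene`` on average) times a log-normal library factor.
    Everything is reproducible from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    G, J = cfg.n_genes, len(cfg.conditions)
    t = cfg.labeling_time_t
    genes = _gene_ids(G)

    # gene-level log-rates around the global means
    lam_o = cfg.lambda_o_global + cfg.sigma_o * rng.standard_normal(G)
    lam_n = np.empty((G, J))
    for j, cond in enumerate(cfg.conditions):
        lam_n[:, j] = (cfg.lambda_n_for(cond)
                       + cfg.sigma_n_for(cond) * rng.standard_normal(G))

    # kinetic truth
    if cfg.kdeg_truth is None:
        base = np.exp(cfg.kdeg_log_mean
                      + cfg.kdeg_log_sd * rng.standard_normal(G))
        kdeg = np.tile(base[:, None], (1, J))
    else:
        kdeg = np.broadcast_to(np.asarray(cfg.kdeg_truth, dtype=float),
                               (G, J)).copy()
    if np.any(kdeg < 0):
        raise ValueError("kdeg_truth must be nonnegative")
    if cfg.ksyn_truth is None:
        rel_n = np.exp(cfg.expression_log_sd * rng.standard_normal(G))
        # synthesis set so reference-condition expression equals rel_n;
        # ksyn carried across conditions (a pure-stability perturbation
        # changes N, not ksyn)
        ksyn = np.tile((rel_n * kdeg[:, 0])[:, None], (1, J))
    else:
        ksyn = np.broadcast_to(np.asarray(cfg.ksyn_truth, dtype=float),
                               (G, J)).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        n_level = np.where(kdeg > 0, ksyn / np.maximum(kdeg, 1e-300), 0.0)
    theta = -np.expm1(-kdeg * t)

    # libraries
    sample_rows = []
    for j, cond in enumerate(cfg.conditions):
        for r in range(cfg.replicates_per_condition):
            for s4u in (1, 0):
                tag = "s4U" if s4u else "ctl"
                sample_rows.append({
                    "sample_id": f"{cond}_rep{r + 1}_{tag}",
                    "condition": cond, "replicate": r + 1, "s4u": s4u,
                    "lib_factor": float(np.exp(
                        cfg.library_size_sd * rng.standard_normal())),
                })
    samples = pd.DataFrame(sample_rows)

    # expected depth per gene: relative expression, mean-normalized
    mean_n = n_level.mean() if G else 1.0
    weight = n_level / mean_n if mean_n > 0 else np.ones_like(n_level)
    reads_per_gene = np.broadcast_to(
        np.asarray(cfg.reads_per_gene), (G,)).astype(float)

    read_rows = []
    counts = np.zeros((G, len(samples)), dtype=np.int64)
    for ci, sample in enumerate(samples.itertuples(index=False)):
        j = list(cfg.conditions).index(sample.condition)
        lam_expect = reads_per_gene * weight[:, j] * sample.lib_factor
        if cfg.depth_mode == "exact":
            n_reads = np.maximum(np.rint(lam_expect), 0).astype(np.int64)
        else:
            n_reads = rng.poisson(lam_expect).astype(np.int64)
        counts[:, ci] = n_reads
        for g in range(G):
            tc = simulate_gene_reads(theta[g, j], lam_n[g, j], lam_o[g],
                                     int(n_reads[g]), sample.s4u, rng)
            for k, c in enumerate(tc):
                read_rows.append((
                    sample.sample_id, sample.condition, sample.replicate,
                    sample.s4u, genes[g],
                    f"{sample.sample_id}:{genes[g]}:{k}", int(c),
                    cfg.n_t_sites_per_read, ""))

    reads = pd.DataFrame(read_rows, columns=[
        "sample_id", "condition", "replicate", "s4u", "gene_id", "read_id",
        "tc", "n_t_sites", "events"])
    count_df = pd.DataFrame(counts, index=genes,
                            columns=samples["sample_id"])
    count_df.index.name = "gene_id"

    # SNP sites and site-level control evidence
    snp_flags = rng.random((G, cfg.n_t_sites_per_read)) < cfg.snp_fraction
    n_ctrl_reads = counts[:, samples["s4u"].to_numpy() == 0].sum(axis=1)
    site_rows = []
    for g in range(G):
        per_site_err = np.exp(lam_o[g]) / cfg.n_t_sites_per_read
        for p in range(cfg.n_t_sites_per_read):
            cov = int(rng.binomial(int(n_ctrl_reads[g]), cfg.snp_cover_prob))
            if cov == 0:
                continue
            rate = cfg.snp_het_prob if snp_flags[g, p] else per_site_err
            mut = int(rng.binomial(cov, rate))
            site_rows.append((genes[g], p, mut, cov, bool(snp_flags[g, p])))
    site_counts = pd.DataFrame(
        site_rows, columns=["gene_id", "ref_pos", "mutations", "coverage",
                            "is_snp"])
    snp_sites = site_counts.loc[site_counts["is_snp"],
                                ["gene_id", "ref_pos"]].reset_index(drop=True)

    params = pd.DataFrame({
        "gene_id": np.repeat(genes, J),
        "condition": list(cfg.conditions) * G,
        "theta": theta.ravel(),
        "kdeg": kdeg.ravel(),
        "ksyn": ksyn.ravel(),
        "lambda_n": lam_n.ravel(),
        "lambda_o": np.repeat(lam_o, J),
    })
    truth = GroundTruth(
        params=params, snp_sites=snp_sites, samples=samples,
        globals={"lambda_o_global": cfg.lambda_o_global,
                 "lambda_n_global": {c: cfg.lambda_n_for(c)
                                     for c in cfg.conditions},
                 "labeling_time_t": t})
    return SimulatedExperiment(reads=reads, counts=count_df, truth=truth,
                               site_counts=site_counts, config=cfg)


def read_records_with_artifacts(dataset: SimulatedExperiment,
                                read_length: int = 100,
                                artifact_rate: float = 0.15,
                                end_event_rate: float = 0.1,
                                snp_event_prob: float = 0.15,
                                seed: int = 0):
    """Decorate simulated reads with events, including filterable junk.

    Every true tc event gets quality >= 40 and internal offsets (so it
    survives the filters). With the given per-read rates, extra events
    are added that each fail exactly one filter: low base quality
    (< 40), end proximity (offset < 3), or location at an injected SNP
    site. Running the mutation filters with the generator's SNP mask
    must therefore recover each read's true tc exactly.

    Returns (records, mask_sites) where mask_sites is the set of
    (gene_id, ref_pos) SNP positions to mask.
    """
    rng = np.random.default_rng(seed)
    snp_lookup = {}
    for row in dataset.truth.snp_sites.itertuples(index=False):
        snp_lookup.setdefault(row.gene_id, []).append(int(row.ref_pos))
    records = []
    interior = np.arange(3, read_length - 3)
    for r in dataset.reads.itertuples(index=False):
        events = []
        for _ in range(int(r.tc)):
            off5 = int(rng.choice(interior))
            events.append(MutationEvent(
                ref_pos=int(rng.integers(1000, 2000)),
                base_quality=int(rng.integers(40, 42)),
                offset_from_5p=off5, offset_from_3p=read_length - 1 - off5))
        if rng.random() < artifact_rate:   # low-quality event
            off5 = int(rng.choice(interior))
            events.append(MutationEvent(
                ref_pos=int(rng.integers(1000, 2000)),
                base_quality=int(rng.integers(2, 40)),
                offset_from_5p=off5, offset_from_3p=read_length - 1 - off5))
        if rng.random() < end_event_rate:  # read-end event
            off5 = int(rng.integers(0, 3)) if rng.random() < 0.5 \
                else read_length - 1 - int(rng.integers(0, 3))
            events.append(MutationEvent(
                ref_pos=int(rng.integers(1000, 2000)),
                base_quality=41,
                offset_from_5p=off5, offset_from_3p=read_length - 1 - off5))
        sites = snp_lookup.get(r.gene_id)
        if sites and rng.random() < snp_event_prob:  # SNP-site event
            off5 = int(rng.choice(interior))
            events.append(MutationEvent(
                ref_pos=int(rng.choice(sites)), base_quality=41,
                offset_from_5p=off5, offset_from_3p=read_length - 1 - off5))
        records.append(ReadRecord(
            sample_id=r.sample_id, gene_id=r.gene_id, read_id=r.read_id,
            mate_flags=(99, 147), events=events, n_t_sites=r.n_t_sites))
    mask_sites = {(g, p) for g, ps in snp_lookup.items() for p in ps}
    return records, mask_sites


def planted_destabilization_config(n_genes: int = 200,
                                   n_destabilized: int = 20,
                                   kdeg_ratio: float = 2.0,
                                   reads_per_gene: int = 300,
                                   replicates_per_condition: int = 3,
                                   sigma_n: float = 0.0,
                                   sigma_o: float = 0.0,
                                   seed: int = 0,
                                   **overrides):
    """Config for a planted-signal study: some genes destabilized in KO.

    Baseline degradation rates are drawn log-normal around 0.35/h
    (half-lives of roughly 1.4-3 h, where a 2-h label is maximally
    informative); ``n_destabilized`` randomly chosen genes get
    ``kdeg_ratio``-fold faster degradation in the second condition with
    synthesis unchanged, so their expression drops by the same factor
    at steady state. Mutation rates sit exactly at the global values by
    default (no gene-level spread) so the planted kinetic change is the
    only per-gene difference between conditions. Returns
    (config, planted_gene_ids).
    """
    rng = np.random.default_rng(seed)
    base = np.exp(np.log(0.35) + 0.25 * rng.standard_normal(n_genes))
    kdeg = np.stack([base, base.copy()], axis=1)
    planted_idx = rng.choice(n_genes, size=n_destabilized, replace=False)
    kdeg[planted_idx, 1] *= kdeg_ratio
    # synthesis identical across conditions (and uniform across genes, so
    # every gene sees the nominal read depth): expression responds to kdeg
    ksyn = np.tile(base[:, None], (1, 2))
    overrides.setdefault("depth_mode", "poisson")  # counts carry shot noise
    cfg = SimConfig(n_genes=n_genes, reads_per_gene=reads_per_gene,
                    replicates_per_condition=replicates_per_condition,
                    kdeg_truth=kdeg, ksyn_truth=ksyn,
                    sigma_n=sigma_n, sigma_o=sigma_o,
                    seed=seed + 1, **overrides)
    genes = _gene_ids(n_genes)
    planted = sorted(genes[i] for i in planted_idx)
    return cfg, planted


def write_fixture_bundle(dataset: SimulatedExperiment, out_dir):
    """Write a simulated experiment as a TSV bundle (+ config snapshot).

    Files: reads.tsv (per-read table), counts.tsv (gene x sample),
    truth.tsv, samples.tsv, sites.tsv (control site evidence),
    snp_sites.tsv, config.yaml. Round-trips losslessly through
    :mod:`tlkinetics.io`.
    """
    from . import io as tio
    return tio.write_bundle(dataset, out_dir)
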