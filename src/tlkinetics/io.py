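"""TSV/YAML input-output for all pipeline tables.

Flat tab-separated files throughout: the per-read mutation table, the
gene-by-sample count matrix, ground-truth and posterior-summary tables,
and a YAML config snapshot. Readers and writers round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

READ_COLUMNS = ["sample_id", "condition", "replicate", "s4u", "gene_id",
                "read_id", "tc", "n_t_sites", "events"]


def _to_path(p):
    return Path(p)


# -- per-read mutation table -------------------------------------------------

def write_mutation_table(reads: pd.DataFrame, path):
    out = reads.copy()
    for col in READ_COLUMNS:
        if col not in out.columns:
            out[col] = "" if col == "events" else 0
    out[READ_COLUMNS].to_csv(path, sep="\t", index=False)
    return _to_path(path)


def read_mutation_table(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"events": "string"},
                    keep_default_na=False)
    for col in ("s4u", "tc"):
        t[col] = t[col].astype(np.int64)
    if "replicate" in t.columns and len(t):
        t["replicate"] = t["replicate"].astype(np.int64)
    return t


# -- count matrix ------------------------------------------------------------

def write_count_matrix(counts: pd.DataFrame, path):
    counts.to_csv(path, sep="\t", index_label="gene_id")
    return _to_path(path)


def read_count_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# -- generic tidy tables -----------------------------------------------------

def write_table(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)
    return _to_path(path)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- config ------------------------------------------------------------------

def write_config(cfg, path):
    """Serialize a (dataclass or dict) config as YAML."""
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        data = dataclasses.asdict(cfg)
    else:
        data = dict(cfg)
    clean = {}
    for k, v in data.items():
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        clean[k] = v
    with open(path, "w") as fh:
        yaml.safe_dump(clean, fh, sort_keys=True)
    return _to_path(path)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


# -- simulated bundle --------------------------------------------------------

def write_bundle(dataset, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": write_mutation_table(dataset.reads, out / "reads.tsv"),
        "counts": write_count_matrix(dataset.counts, out / "counts.tsv"),
        "truth": write_table(dataset.truth.params, out / "truth.tsv"),
        "samples": write_table(dataset.truth.samples, out / "samples.tsv"),
        "sites": write_table(dataset.site_counts, out / "sites.tsv"),
        "snp_sites": write_table(dataset.truth.snp_sites,
                                 out / "snp_sites.tsv"),
        "config": write_config(dataset.config, out / "config.yaml"),
    }
    return paths


def read_bundle(in_dir) -> dict:
    d = Path(in_dir)
    return {
        "reads": read_mutation_table(d / "reads.tsv"),
        "counts": read_count_matrix(d / "counts.tsv"),
        "truth": read_table(d / "truth.tsv"),
        "samples": read_table(d / "samples.tsv"),
        "sites": read_table(d / "sites.tsv"),
        "snp_sites": read_table(d / "snp_sites.tsv"),
        "config": read_config(d / "config.yaml"),
    }


# -- posterior archives ------------------------------------------------------

def write_posterior(results, out_dir) -> dict:
    """Flat posterior archive: draw-level TSV + summary TSV + settings."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    post = results.posterior
    chains, draws = post["theta"].shape[:2]
    idx = pd.MultiIndex.from_product(
        [range(chains), range(draws)], names=["chain", "draw"])
    cols = {}
    for g, grp in enumerate(results.groups):
        for s, gene in enumerate(results.genes):
            cols[f"theta[{grp},{gene}]"] = post["theta"][:, :, g, s].ravel()
    for j, cond in enumerate(results.conditions):
        cols[f"lambda_n_bar[{cond}]"] = post["lambda_n_bar"][:, :, j].ravel()
        cols[f"sigma_n[{cond}]"] = post["sigma_n"][:, :, j].ravel()
    cols["lambda_o_bar"] = post["lambda_o_bar"].ravel()
    cols["sigma_o"] = post["sigma_o"].ravel()
    draws_df = pd.DataFrame(cols, index=idx).reset_index()
    draws_df.to_csv(out / "posterior_draws.tsv", sep="\t", index=False)
    summary = results.summary()
    summary.to_csv(out / "posterior_summary.tsv", sep="\t", index=False)
    with open(out / "sampler_settings.json", "w") as fh:
        json.dump(results.settings, fh, indent=2)
    return {"draws": out / "posterior_draws.tsv",
            "summary": out / "posterior_summary.tsv",
            "settings": out / "sampler_settings.json"}
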