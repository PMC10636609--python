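"""End-to-end orchestration: simulate → call → fit → decompose → report.

Stages communicate through the TSV schemas in :mod:`tlkinetics.io`; a
run manifest (JSON) records the config snapshot, input checksums,
per-stage read/gene attrition and seeds so a run is auditable and
reproducible byte-for-byte given the same seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io as tio
from .decompose import StabilityDecomposition
from .model import PoissonMixtureKinetics, PriorSpec


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Filter and interval defaults follow the protocol the model was
    built for: phred >= 40, 3-nt end exclusion, SNP alpha 0.05, a
    2-hour label, 80% classification interval and a 95% interval for
    stability calls.
    """

    reads_path: str = ""
    counts_path: str = ""
    out_dir: str = "tlkinetics_out"
    reference: str = "WT"
    treatment: str = "KO"
    labeling_time_t: float = 2.0
    min_quality: int = 40
    end_exclusion_nt: int = 3
    snp_alpha: float = 0.05
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    classify_interval: float = 0.8
    call_ci: float = 0.95
    normalization: str = "upperquartile"
    share_theta: bool = True
    priors: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **overrides):
        data = tio.read_config(path)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})


def _checksum(path):
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    timestamp: str = ""

    def write(self, path):
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
        return Path(path)


def run_all(config: RunConfig) -> dict:
    """Execute fit + decomposition + report on a called mutation table.

    Inputs: ``reads_path`` (MutationCountTable TSV; tc already filtered)
    and ``counts_path`` (gene-by-sample matrix). Writes per-gene results,
    the scatter-ready table, posterior archives and the run manifest
    under ``out_dir``. Idempotent given (config, inputs, seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))
    for name, p in (("reads", config.reads_path),
                    ("counts", config.counts_path)):
        manifest.input_checksums[name] = _checksum(p)

    reads = tio.read_mutation_table(config.reads_path)
    counts = tio.read_count_matrix(config.counts_path)
    manifest.stage_counts["input_reads"] = int(len(reads))
    manifest.stage_counts["input_genes"] = int(counts.shape[0])

    priors = PriorSpec(**config.priors) if config.priors else PriorSpec()
    model = PoissonMixtureKinetics(reads, priors=priors,
                                   share_theta=config.share_theta)
    manifest.stage_counts["genes_fitted"] = len(model.genes)
    manifest.stage_counts["genes_skipped_zero_coverage"] = \
        len(model.skipped_genes)
    if model.skipped_genes:
        manifest.warnings.append(
            f"{len(model.skipped_genes)} genes lacked reads in some sample "
            "and were excluded")

    results = model.fit(chains=config.chains, warmup=config.warmup,
                        draws=config.draws, seed=config.seed)
    if not results.converged:
        manifest.warnings.append(
            f"convergence flag: max R-hat {results.max_rhat():.3f} "
            ">= 1.05")
    results.save(out / "posterior")

    sample_conditions = dict(
        reads.drop_duplicates("sample_id")
             .set_index("sample_id")["condition"])
    decomp = StabilityDecomposition(
        results, counts, sample_conditions,
        reference=config.reference, treatment=config.treatment,
        labeling_time=config.labeling_time_t)
    dres = decomp.fit(interval=config.classify_interval,
                      call_ci=config.call_ci)
    tio.write_table(dres.table, out / "results.tsv")
    tio.write_table(dres.scatter_table(), out / "scatter.tsv")
    manifest.stage_counts["genes_decomposed"] = int(len(dres.table))
    manifest.stage_counts["destabilized_calls"] = \
        int(len(dres.called("destabilized")))
    manifest.stage_counts["stabilized_calls"] = \
        int(len(dres.called("stabilized")))
    manifest.write(out / "manifest.json")
    (out / "report.txt").write_text(dres.summary() + "\n")
    return {"results": out / "results.tsv", "scatter": out / "scatter.tsv",
            "manifest": out / "manifest.json", "decomposition": dres,
            "fit": results}


def report_from_results(results_path, out_path=None) -> str:
    """Per-class counts, called genes and the scatter table from a results TSV."""
    t = pd.read_table(results_path)
    lines = [f"genes: {len(t)}"]
    if len(t) == 0:
        lines.append("no genes in results")
    else:
        for cls, n in t["class"].value_counts().items():
            lines.append(f"class {cls}: {n}")
        called = t[t.get("called", "").astype(str) == "destabilized"]
        lines.append(f"destabilized calls: {len(called)}")
        if len(called):
            ranked = called.sort_values("l2fc_kdeg_median", ascending=False)
            lines.append("called genes: " + ", ".join(ranked["gene_id"]))
        defined = t[t["class"] != "undefined"]
        if out_path is not None:
            scatter = defined[["gene_id", "l2fc_n", "fracdeg_median",
                               "class"]].rename(columns={
                                   "l2fc_n": "expression_l2fc",
                                   "fracdeg_median":
                                       "degradation_contribution"})
            tio.write_table(scatter, out_path)
            lines.append(f"scatter rows: {len(scatter)}")
        if len(defined) == 0:
            lines.append("warning: no gene has a defined frac_deg")
    return "\n".join(lines)
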