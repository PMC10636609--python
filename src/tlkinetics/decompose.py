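"""Degradation/synthesis decomposition of expression changes.

Under first-order turnover, steady-state expression is
``N = k_syn / k_deg``, the fraction of transcripts made during a label
of length t is ``theta = 1 - exp(-k_deg * t)``, and on log2 scale a
change in expression splits exactly into synthesis and degradation
parts: ``L2FC_N = L2FC_ksyn - L2FC_kdeg``. The ``frac_deg`` statistic

    frac_deg = ((|L2FC_kdeg| - |L2FC_ksyn|) / |L2FC_N| + 1) / 2

lies in [0, 1] by the reverse triangle inequality and reads as the
share of a gene's expression change attributable to stability (1 =
pure degradation change, 0 = pure synthesis change). Genes are called
stability- or synthesis-driven when the 80% equal-tailed credible
interval of frac_deg clears 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import KineticsResults, summarize_posterior

__all__ = [
    "NormFactors", "upper_quartile_factors", "theta_to_kdeg", "compute_ksyn",
    "l2fc_decompose", "frac_deg", "classify_gene", "call_stability_changes",
    "StabilityDecomposition", "DecompositionResults",
]

UNDEFINED_EPS = 1e-6
THETA_CLIP = 1.0 - 1e-9

STABILITY = "stability_driven"
SYNTHESIS = "synthesis_driven"
AMBIGUOUS = "ambiguous"
UNDEFINED = "undefined"


# ---------------------------------------------------------------------------
# normalization

@dataclass
class NormFactors:
    """Per-sample scale factors from upper-quartile normalization."""

    table: pd.DataFrame  # sample_id, lib_size, upper_quartile, factor

    @property
    def factors(self) -> pd.Series:
        return self.table.set_index("sample_id")["factor"]

    def effective_lib_sizes(self) -> pd.Series:
        t = self.table.set_index("sample_id")
        return t["lib_size"] * t["factor"]


def upper_quartile_factors(counts: pd.DataFrame) -> NormFactors:
    """Upper-quartile normalization factors for a gene-by-sample matrix.

    Per sample: the 75th percentile of counts over expressed genes
    (count > 0), divided by library size; factors are rescaled so their
    geometric mean is 1. A depth-rescaled sample therefore gets the
    same factor, and identical samples get factor 1.
    """
    if counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    rows = []
    for s in counts.columns:
        col = counts[s].to_numpy(dtype=float)
        lib = col.sum()
        pos = col[col > 0]
        if lib == 0 or pos.size == 0:
            raise ValueError(f"sample {s!r} has all-zero counts")
        uq = np.percentile(pos, 75)
        rows.append({"sample_id": s, "lib_size": lib, "upper_quartile": uq,
                     "factor": uq / lib})
    t = pd.DataFrame(rows)
    t["factor"] /= np.exp(np.mean(np.log(t["factor"])))
    return NormFactors(t)


def normalized_counts(counts: pd.DataFrame,
                      norm: NormFactors | None = None) -> pd.DataFrame:
    """Counts per million of effective (factor-scaled) library size."""
    norm = norm or upper_quartile_factors(counts)
    eff = norm.effective_lib_sizes()[counts.columns]
    return counts / eff.to_numpy() * 1e6


# ---------------------------------------------------------------------------
# kinetic transforms

def theta_to_kdeg(theta, t: float):
    """Degradation rate (per hour) from fraction-new under exponential decay.

    ``k_deg = -ln(1 - theta) / t``; applied element-wise to posterior
    draws to propagate uncertainty. theta == 1 is clipped to 1 - 1e-9
    with a warning (infinite rate otherwise).
    """
    if t <= 0:
        raise ValueError("labeling time must be positive")
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0) or np.any(th > 1):
        raise ValueError("theta must lie in [0, 1]")
    if np.any(th == 1.0):
        import warnings
        warnings.warn("theta == 1 clipped to 1 - 1e-9", stacklevel=2)
        th = np.minimum(th, THETA_CLIP)
    out = -np.log1p(-th) / t
    return float(out) if np.isscalar(theta) else out


def kdeg_to_theta(kdeg, t: float):
    """Inverse of :func:`theta_to_kdeg`: ``theta = 1 - exp(-k_deg * t)``."""
    kd = np.asarray(kdeg, dtype=float)
    if np.any(kd < 0):
        raise ValueError("k_deg must be nonnegative")
    out = -np.expm1(-kd * t)
    return float(out) if np.isscalar(kdeg) else out


def compute_ksyn(n_level, kdeg_draws):
    """Synthesis rate draws ``k_syn = N * k_deg`` (draw-wise product)."""
    if np.any(np.asarray(n_level) < 0):
        raise ValueError("normalized expression must be nonnegative")
    return np.asarray(n_level) * np.asarray(kdeg_draws)


# ---------------------------------------------------------------------------
# fold-change decomposition

def l2fc_decompose(kdeg_a, kdeg_b, n_a, n_b, pseudocount: float = 0.5):
    """Per-gene log2 fold changes between reference (a) and perturbed (b).

    ``kdeg_a``/``kdeg_b`` are draw arrays (paired draw-wise); ``n_a``/
    ``n_b`` are scalar normalized expression levels. Returns
    ``(l2fc_n, l2fc_kdeg_draws, l2fc_ksyn_draws)`` with the identity
    ``L2FC_N = L2FC_ksyn - L2FC_kdeg`` holding exactly on every draw
    (ksyn fold change is constructed from it).
    """
    l2fc_kdeg = np.log2(np.asarray(kdeg_b) / np.asarray(kdeg_a))
    l2fc_n = float(np.log2((n_b + pseudocount) / (n_a + pseudocount)))
    l2fc_ksyn = l2fc_n + l2fc_kdeg
    return l2fc_n, l2fc_kdeg, l2fc_ksyn


def frac_deg(l2fc_kdeg, l2fc_ksyn, l2fc_n):
    """Fraction of an expression change attributable to degradation.

    Draws where ``|L2FC_N| <= 1e-6`` are undefined and returned as NaN.
    """
    kd = np.asarray(l2fc_kdeg, dtype=float)
    ks = np.asarray(l2fc_ksyn, dtype=float)
    n = np.asarray(l2fc_n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = ((np.abs(kd) - np.abs(ks)) / np.abs(n) + 1.0) / 2.0
    # the reverse triangle inequality bounds the value in [0, 1] exactly;
    # clip the float residue
    out = np.clip(out, 0.0, 1.0)
    out = np.where(np.abs(n) <= UNDEFINED_EPS, np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def classify_gene(frac_deg_draws, interval: float = 0.8) -> str:
    """Stability/synthesis call from the credible interval of frac_deg.

    Equal-tailed interval at ``interval`` mass: entirely above 0.5 →
    stability_driven; entirely below → synthesis_driven; straddling →
    ambiguous; no defined draws → undefined.
    """
    d = np.asarray(frac_deg_draws, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < 2:
        return UNDEFINED
    _, lo, hi = summarize_posterior(d, interval)
    if lo > 0.5:
        return STABILITY
    if hi < 0.5:
        return SYNTHESIS
    return AMBIGUOUS


def call_stability_changes(results: pd.DataFrame,
                           direction: str = "destabilized") -> pd.DataFrame:
    """Genes with a confident degradation-rate change of the given sign.

    A gene is called ``destabilized`` when its L2FC_kdeg credible
    interval (columns ``call_ci_low``/``call_ci_high``; mass set when
    the decomposition was fitted, default 95%) lies entirely above zero
    AND its class is stability_driven; ``stabilized`` is the mirror
    image. Returns the called rows ranked by median L2FC_kdeg, largest
    change first.
    """
    if direction not in ("destabilized", "stabilized"):
        raise ValueError("direction must be 'destabilized' or 'stabilized'")
    lo, hi = results["call_ci_low"], results["call_ci_high"]
    if direction == "destabilized":
        mask = (lo > 0) & (results["class"] == STABILITY)
    else:
        mask = (hi < 0) & (results["class"] == STABILITY)
    called = results[mask].copy()
    return called.sort_values("l2fc_kdeg_median",
                              ascending=(direction == "stabilized"))


# ---------------------------------------------------------------------------
# model-style front end

class StabilityDecomposition:
    """Decompose condition-level expression changes into kinetic parts.

    Parameters
    ----------
    results : KineticsResults
        Fitted fraction-new posteriors (theta shared per condition).
    counts : DataFrame
        Gene-by-sample count matrix covering both conditions.
    sample_conditions : mapping
        sample_id -> condition label, used to average normalized counts
        per condition.
    reference, treatment : str
        Condition labels; fold changes are treatment over reference.
    labeling_time : float
        s4U labeling time in hours (default 2).
    """

    def __init__(self, results: KineticsResults, counts: pd.DataFrame,
                 sample_conditions, reference: str, treatment: str,
                 labeling_time: float = 2.0, pseudocount: float = 0.5):
        for cond in (reference, treatment):
            if cond not in results.groups:
                raise ValueError(f"condition {cond!r} absent from fit")
        self.results = results
        self.counts = counts
        self.sample_conditions = dict(sample_conditions)
        self.reference = reference
        self.treatment = treatment
        self.labeling_time = labeling_time
        self.pseudocount = pseudocount

    def _condition_expression(self):
        norm = upper_quartile_factors(self.counts)
        cpm = normalized_counts(self.counts, norm)
        by_cond = {}
        for cond in (self.reference, self.treatment):
            cols = [s for s in self.counts.columns
                    if self.sample_conditions.get(s) == cond]
            if not cols:
                raise ValueError(f"no samples for condition {cond!r}")
            by_cond[cond] = cpm[cols].mean(axis=1)
        return norm, by_cond

    def fit(self, interval: float = 0.8, call_ci: float = 0.95
            ) -> "DecompositionResults":
        res = self.results
        t = self.labeling_time
        norm, expr = self._condition_expression()
        th_a = np.clip(res.theta_draws(self.reference), 0.0, THETA_CLIP)
        th_b = np.clip(res.theta_draws(self.treatment), 0.0, THETA_CLIP)
        kdeg_a = theta_to_kdeg(th_a, t)
        kdeg_b = theta_to_kdeg(th_b, t)
        genes = res.genes
        n_a = expr[self.reference].reindex(genes)
        n_b = expr[self.treatment].reindex(genes)

        rows = []
        fd_draws = {}
        for i, gene in enumerate(genes):
            if np.isnan(n_a.iloc[i]) or np.isnan(n_b.iloc[i]):
                continue  # gene absent from the count matrix
            l2fc_n, l2fc_kd, l2fc_ks = l2fc_decompose(
                kdeg_a[:, i], kdeg_b[:, i],
                float(n_a.iloc[i]), float(n_b.iloc[i]),
                pseudocount=self.pseudocount)
            fd = frac_deg(l2fc_kd, l2fc_ks, l2fc_n)
            fd_draws[gene] = fd
            kd_med, kd_lo, kd_hi = summarize_posterior(l2fc_kd, call_ci)
            ks_med = float(np.median(l2fc_ks))
            if np.all(np.isnan(fd)):
                fd_med = fd_lo = fd_hi = np.nan
                cls = UNDEFINED
            else:
                fd_med, fd_lo, fd_hi = summarize_posterior(
                    fd[~np.isnan(fd)], interval)
                cls = classify_gene(fd, interval)
            rows.append({
                "gene_id": gene,
                "n_ref": float(n_a.iloc[i]), "n_treat": float(n_b.iloc[i]),
                "l2fc_n": l2fc_n,
                "l2fc_kdeg_median": float(kd_med),
                "call_ci_low": float(kd_lo), "call_ci_high": float(kd_hi),
                "l2fc_ksyn_median": ks_med,
                "fracdeg_median": float(fd_med),
                "fracdeg_ci_low": float(fd_lo),
                "fracdeg_ci_high": float(fd_hi),
                "class": cls,
            })
        table = pd.DataFrame(rows)
        destab = call_stability_changes(table, "destabilized")
        stab = call_stability_changes(table, "stabilized")
        table["called"] = np.where(
            table["gene_id"].isin(destab["gene_id"]), "destabilized",
            np.where(table["gene_id"].isin(stab["gene_id"]),
                     "stabilized", ""))
        return DecompositionResults(self, table, fd_draws, norm,
                                    interval, call_ci)


class DecompositionResults:
    """Per-gene decomposition table with convenience views."""

    def __init__(self, model, table, fracdeg_draws, norm_factors,
                 interval, call_ci):
        self.model = model
        self.table = table
        self.fracdeg_draws = fracdeg_draws
        self.norm_factors = norm_factors
        self.interval = interval
        self.call_ci = call_ci

    def called(self, direction: str = "destabilized") -> pd.DataFrame:
        return call_stability_changes(self.table, direction)

    def class_counts(self) -> pd.Series:
        return self.table["class"].value_counts()

    def scatter_table(self) -> pd.DataFrame:
        """Expression fold change vs degradation contribution, per gene.

        One row per gene with defined frac_deg; ready for plotting.
        """
        t = self.table[self.table["class"] != UNDEFINED]
        return t[["gene_id", "l2fc_n", "fracdeg_median", "class"]].rename(
            columns={"l2fc_n": "expression_l2fc",
                     "fracdeg_median": "degradation_contribution"})

    def plot_scatter(self, ax=None):
        """Scatter of expression L2FC vs frac_deg, colored by class."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        st = self.scatter_table()
        colors = {STABILITY: "#c0392b", SYNTHESIS: "#2980b9",
                  AMBIGUOUS: "#95a5a6"}
        for cls, grp in st.groupby("class"):
            ax.scatter(grp["expression_l2fc"],
                       grp["degradation_contribution"],
                       s=12, alpha=0.7, label=cls,
                       color=colors.get(cls, "black"))
        ax.axhline(0.5, ls="--", lw=0.8, color="gray")
        ax.set_xlabel("expression log2 fold change")
        ax.set_ylabel("fraction of change from degradation")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def summary(self) -> str:
        """Human-readable run summary."""
        counts = self.class_counts()
        destab = self.called("destabilized")
        stab = self.called("stabilized")
        lines = [
            "Stability/synthesis decomposition",
            f"  reference: {self.model.reference}  "
            f"treatment: {self.model.treatment}",
            f"  genes analyzed: {len(self.table)}",
            "  classes: " + ", ".join(
                f"{k}={int(v)}" for k, v in counts.items()),
            f"  destabilized calls ({int(self.call_ci*100)}% CI): {len(destab)}",
            f"  stabilized calls: {len(stab)}",
        ]
        if len(destab):
            top = ", ".join(destab["gene_id"].head(10))
            lines.append(f"  top destabilized: {top}")
        return "\n".join(lines)
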