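"""Hierarchical Bayesian model of fraction-new RNA from mutation counts.

The entry point is :class:`PoissonMixtureKinetics`, a model object built
from a mutation-count table (one row per read: sample, condition, s4U
indicator, gene, tc). ``fit()`` runs MCMC and returns a
:class:`KineticsResults` carrying posterior draws, convergence
diagnostics and posterior-median point estimates with equal-tailed
credible intervals.

The model: per-read tc counts follow a two-component Poisson mixture
(new RNA vs background; see :mod:`tlkinetics.likelihood`) whose
log-rates vary by gene around global means through a non-centered
hierarchy, and whose mixing weight theta[j,s] — the fraction of gene
s's transcripts made during the labeling window in condition j — gets a
Uniform(0,1) prior by default. Unlabeled control libraries pin down the
background rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import arviz as az
import numpy as np
import pandas as pd

from ._mcmc import MixtureData, MixtureSampler

__all__ = ["PriorSpec", "PoissonMixtureKinetics", "KineticsResults",
           "summarize_posterior"]

RHAT_LIMIT = 1.05


@dataclass
class PriorSpec:
    """Hyperparameters of the hierarchical mixture priors.

    Defaults are weakly informative on the log-rate scale:
    ``Normal(-3, 1.5)`` for the global background log-rate (a background
    error rate of e^-3 ≈ 0.05 mutations/read), ``Normal(-1, 1.5)`` for
    the global new-RNA log-rate per condition (e^-1 ≈ 0.37), half-Cauchy
    scale 1.5 for both gene-level standard deviations, ``Normal(0, 1.5)``
    for the non-centered gene z-scores, and ``Beta(1, 1)`` (uniform) for
    the fraction-new theta.
    """

    lambda_o_mean: float = -3.0
    lambda_o_sd: float = 1.5
    lambda_n_mean: float = -1.0
    lambda_n_sd: float = 1.5
    sigma_scale: float = 1.5
    z_sd: float = 1.5
    theta_a: float = 1.0
    theta_b: float = 1.0

    def __post_init__(self):
        if self.lambda_o_sd <= 0 or self.lambda_n_sd <= 0:
            raise ValueError("prior standard deviations must be positive")
        if self.sigma_scale <= 0 or self.z_sd <= 0:
            raise ValueError("scale hyperparameters must be positive")
        if self.theta_a <= 0 or self.theta_b <= 0:
            raise ValueError("Beta hyperparameters must be positive")


REQUIRED_COLUMNS = ("sample_id", "condition", "s4u", "gene_id", "tc")


class PoissonMixtureKinetics:
    """Two-component Poisson mixture over per-read T-to-C counts.

    Parameters
    ----------
    table : DataFrame
        Mutation-count table with columns ``sample_id``, ``condition``,
        ``s4u`` (0/1 indicator), ``gene_id``, ``tc``. Reads with tc=0
        are observations and must be present as rows.
    priors : PriorSpec, optional
    share_theta : bool
        If True (default) replicate labeled libraries within a condition
        share one theta per gene; if False every labeled sample gets its
        own theta (the new-RNA rate hierarchy stays per-condition).

    Genes lacking at least one read in every sample are excluded before
    fitting (the mixture is only well informed on genes observed
    throughout) and listed in ``skipped_genes``.
    """

    def __init__(self, table: pd.DataFrame, priors: PriorSpec | None = None,
                 share_theta: bool = True):
        missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"mutation-count table lacks columns {missing}")
        if len(table) and not set(np.unique(table["s4u"])) <= {0, 1}:
            raise ValueError("s4u column must be a 0/1 indicator")
        self.priors = priors or PriorSpec()
        self.share_theta = share_theta
        self.table = table
        if not (table["s4u"] == 1).any():
            warnings.warn(
                "no labeled (s4u=1) reads: theta is unidentified and its "
                "posterior will reproduce the prior", stacklevel=2)
        if not (table["s4u"] == 0).any():
            warnings.warn(
                "no unlabeled control reads: the background mutation rate "
                "is only weakly identified", stacklevel=2)
        self._prepare()

    @classmethod
    def from_tsv(cls, path, **kwargs):
        from .io import read_mutation_table
        return cls(read_mutation_table(path), **kwargs)

    def _prepare(self):
        t = self.table
        samples = sorted(t["sample_id"].unique())
        per_gene_samples = t.groupby("gene_id")["sample_id"].nunique()
        keep = set(per_gene_samples[per_gene_samples == len(samples)].index)
        self.skipped_genes = sorted(set(t["gene_id"]) - keep)
        t = t[t["gene_id"].isin(keep)]
        if t.empty:
            raise ValueError("no gene has at least one read in every sample")
        genes = sorted(keep)
        conditions = sorted(t["condition"].unique())
        gidx = {g: i for i, g in enumerate(genes)}
        cidx = {c: i for i, c in enumerate(conditions)}

        lab = t[t["s4u"] == 1]
        ctrl = t[t["s4u"] == 0]
        kmax = int(t["tc"].max())

        if self.share_theta:
            groups = list(conditions)
            group_key = lab["condition"].map(cidx).to_numpy()
            cond_of_group = np.arange(len(conditions))
        else:
            groups = sorted(lab["sample_id"].unique())
            smap = {s: i for i, s in enumerate(groups)}
            group_key = lab["sample_id"].map(smap).to_numpy()
            cond_of_group = np.array([
                cidx[lab.loc[lab["sample_id"] == s, "condition"].iloc[0]]
                for s in groups
            ])

        H = np.zeros((len(groups), len(genes), kmax + 1), dtype=np.int64)
        np.add.at(H, (group_key, lab["gene_id"].map(gidx).to_numpy(),
                      lab["tc"].to_numpy()), 1)
        C = np.zeros((len(genes), kmax + 1), dtype=np.int64)
        if len(ctrl):
            np.add.at(C, (ctrl["gene_id"].map(gidx).to_numpy(),
                          ctrl["tc"].to_numpy()), 1)

        self._data = MixtureData(
            labeled_hist=H, control_hist=C, cond_of_group=cond_of_group,
            genes=genes, conditions=conditions, groups=groups,
        )

    @property
    def genes(self):
        return self._data.genes

    @property
    def conditions(self):
        return self._data.conditions

    def fit(self, chains: int = 4, warmup: int = 1000, draws: int = 1000,
            seed: int = 0) -> "KineticsResults":
        """Sample the posterior by adaptive Metropolis-within-Gibbs.

        Identical (seed, chains, warmup, draws) yield identical draws.
        """
        if chains < 1 or warmup < 0 or draws < 1:
            raise ValueError("need chains >= 1, warmup >= 0, draws >= 1")
        child_seeds = np.random.SeedSequence(seed).spawn(chains)
        chain_draws = []
        for cs in child_seeds:
            sampler = MixtureSampler(self._data, self.priors, cs)
            chain_draws.append(sampler.run(warmup, draws))
        posterior = {
            k: np.stack([c[k] for c in chain_draws], axis=0)
            for k in chain_draws[0]
        }
        settings = {"chains": chains, "warmup": warmup, "draws": draws,
                    "seed": seed, "share_theta": self.share_theta,
                    "priors": asdict(self.priors)}
        return KineticsResults(self, posterior, settings)


def _equal_tailed(draws, mass, axis=0):
    lo = (1.0 - mass) / 2.0
    return (np.quantile(draws, lo, axis=axis),
            np.quantile(draws, 1.0 - lo, axis=axis))


def summarize_posterior(draws_2d, interval=0.8):
    """Median and equal-tailed interval of an array of posterior draws.

    ``draws_2d`` has draws on the first axis; remaining axes are
    parameter dimensions.
    """
    if not 0 < interval < 1:
        raise ValueError("interval mass must lie in (0, 1)")
    lo, hi = _equal_tailed(draws_2d, interval, axis=0)
    return np.median(draws_2d, axis=0), lo, hi


class KineticsResults:
    """Posterior draws and summaries from :meth:`PoissonMixtureKinetics.fit`.

    Attributes
    ----------
    posterior : dict of arrays
        Keyed by parameter; shape ``(chains, draws, ...)``. ``theta``
        is ``(chains, draws, n_groups, n_genes)``; ``lambda_n``/
        ``lambda_o`` carry the non-centered identities applied draw-wise.
    settings : dict
        Sampler configuration echo (chains, warmup, draws, seed, priors).
    """

    def __init__(self, model, posterior, settings):
        self.model = model
        self.posterior = posterior
        self.settings = settings
        self._diagnostics = None

    # -- basic accessors ---------------------------------------------------

    @property
    def genes(self):
        return self.model.genes

    @property
    def conditions(self):
        return self.model.conditions

    @property
    def groups(self):
        return self.model._data.groups

    def flat(self, name):
        """Draws for ``name`` with chains flattened onto the first axis."""
        d = self.posterior[name]
        return d.reshape(-1, *d.shape[2:])

    def theta_draws(self, condition):
        """(total draws, n_genes) theta draws for one condition/group."""
        g = list(self.groups).index(condition)
        return self.flat("theta")[:, g, :]

    # -- diagnostics -------------------------------------------------------

    def diagnostics(self):
        """Split-R̂ and bulk ESS per parameter block (via ArviZ)."""
        if self._diagnostics is None:
            idata = az.from_dict(posterior={
                "theta": self.posterior["theta"],
                "lambda_n_bar": self.posterior["lambda_n_bar"],
                "lambda_o_bar": self.posterior["lambda_o_bar"][..., None],
                "sigma_n": self.posterior["sigma_n"],
                "sigma_o": self.posterior["sigma_o"][..., None],
            })
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = az.rhat(idata)
                ess = az.ess(idata)
            self._diagnostics = {"rhat": rhat, "ess": ess}
        return self._diagnostics

    def max_rhat(self):
        d = self.diagnostics()["rhat"]
        return float(max(np.nanmax(d[v].values) for v in d.data_vars))

    @property
    def converged(self):
        return self.max_rhat() < RHAT_LIMIT

    # -- summaries ---------------------------------------------------------

    def summary(self, interval: float = 0.8) -> pd.DataFrame:
        """Posterior summary table: median, equal-tailed CI, R̂, ESS.

        One row per scalar parameter; theta / gene-level rates are rows
        per (group, gene).
        """
        diag = self.diagnostics()
        rows = []

        def block(name, values, labels, rhat=None, ess=None):
            med, lo, hi = summarize_posterior(values, interval)
            med, lo, hi = np.atleast_1d(med), np.atleast_1d(lo), np.atleast_1d(hi)
            for i, lab in enumerate(labels):
                rows.append({
                    "parameter": f"{name}[{lab}]" if lab else name,
                    "median": med[i], "ci_low": lo[i], "ci_high": hi[i],
                    "rhat": rhat[i] if rhat is not None else np.nan,
                    "ess": ess[i] if ess is not None else np.nan,
                })

        rh = diag["rhat"]
        es = diag["ess"]
        block("lambda_o_bar", self.flat("lambda_o_bar")[:, None], [""],
              rh["lambda_o_bar"].values.ravel(), es["lambda_o_bar"].values.ravel())
        block("sigma_o", self.flat("sigma_o")[:, None], [""],
              rh["sigma_o"].values.ravel(), es["sigma_o"].values.ravel())
        block("lambda_n_bar", self.flat("lambda_n_bar"), self.conditions,
              rh["lambda_n_bar"].values.ravel(), es["lambda_n_bar"].values.ravel())
        block("sigma_n", self.flat("sigma_n"), self.conditions,
              rh["sigma_n"].values.ravel(), es["sigma_n"].values.ravel())
        th = self.flat("theta")
        th_rhat = rh["theta"].values
        th_ess = es["theta"].values
        for g, grp in enumerate(self.groups):
            block("theta", th[:, g, :],
                  [f"{grp},{gene}" for gene in self.genes],
                  th_rhat[g], th_ess[g])
        return pd.DataFrame(rows)

    def estimates(self, interval: float = 0.8) -> pd.DataFrame:
        """Per (group, gene) fraction-new summary (tidy frame)."""
        th = self.flat("theta")
        med, lo, hi = summarize_posterior(th, interval)
        frames = []
        for g, grp in enumerate(self.groups):
            frames.append(pd.DataFrame({
                "condition": grp, "gene_id": self.genes,
                "theta_median": med[g], "theta_ci_low": lo[g],
                "theta_ci_high": hi[g],
            }))
        return pd.concat(frames, ignore_index=True)

    # -- persistence -------------------------------------------------------

    def save(self, out_dir):
        from .io import write_posterior
        return write_posterior(self, out_dir)
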