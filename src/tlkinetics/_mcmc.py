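"""Adaptive Metropolis-within-Gibbs sampler for the hierarchical mixture.

The model (one shared background rate hierarchy, one new-RNA rate
hierarchy per condition, non-centered):

    lbar_o        ~ Normal(mu_o, sd_o)            global background log-rate
    lbar_n[j]     ~ Normal(mu_n, sd_n)            global new-RNA log-rate, condition j
    sigma_o       ~ HalfCauchy(scale_o)
    sigma_n[j]    ~ HalfCauchy(scale_n)
    z_o[s]        ~ Normal(0, zsd)
    z_n[j,s]      ~ Normal(0, zsd)
    lambda_o[s]   = lbar_o + sigma_o * z_o[s]
    lambda_n[j,s] = lbar_n[j] + sigma_n[j] * z_n[j,s]
    theta[g,s]    ~ Beta(a0, b0)                  g: theta group (condition or sample)

    labeled read:  tc ~ theta*Pois(e^lambda_n) + (1-theta)*Pois(e^lambda_o)
    control read:  tc ~ Pois(e^lambda_o)

Per-read counts are collapsed to histograms over tc — the mixture
likelihood depends on a read only through its tc value, so histograms
are sufficient and make each sweep O(genes * conditions * max_tc).

Sweep structure (a partially collapsed Gibbs scheme; the ordering
matters for correctness):

1. every lambda-hierarchy parameter is updated by random-walk
   Metropolis against the *mixture-marginal* likelihood (component
   assignments integrated out),
2. latent per-read component assignments are imputed from the current
   (theta, lambda) state,
3. theta is drawn exactly from its conjugate Beta conditional given the
   assignments.

Because the assignments are discarded and re-imputed after every
lambda update, each step leaves the marginal posterior over
(theta, lambda) invariant. Proposal scales adapt during warmup toward
a 0.44 acceptance rate and are frozen afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logsumexp

_TARGET_ACC = 0.44


@dataclass
class MixtureData:
    """Sufficient statistics of a mutation-count table.

    labeled_hist : (n_groups, n_genes, K+1) read counts by tc value
    control_hist : (n_genes, K+1) pooled control read counts by tc value
    cond_of_group : (n_groups,) condition index of each theta group
    """

    labeled_hist: np.ndarray
    control_hist: np.ndarray
    cond_of_group: np.ndarray
    genes: list = field(default_factory=list)
    conditions: list = field(default_factory=list)
    groups: list = field(default_factory=list)

    @property
    def n_genes(self):
        return self.labeled_hist.shape[1]

    @property
    def n_conditions(self):
        return len(self.conditions)

    @property
    def n_groups(self):
        return self.labeled_hist.shape[0]

    @property
    def kmax(self):
        return self.labeled_hist.shape[2] - 1


class _State:
    __slots__ = (
        "lbar_o", "sigma_o", "lbar_n", "sigma_n", "z_o", "z_n", "theta"
    )

    def __init__(self, lbar_o, sigma_o, lbar_n, sigma_n, z_o, z_n, theta):
        self.lbar_o = lbar_o
        self.sigma_o = sigma_o
        self.lbar_n = lbar_n
        self.sigma_n = sigma_n
        self.z_o = z_o
        self.z_n = z_n
        self.theta = theta


def _half_cauchy_logpdf(x, scale):
    # support (0, inf); normalizing constant irrelevant for MH
    return np.where(x > 0, -np.log1p((x / scale) ** 2), -np.inf)


class MixtureSampler:
    """One MCMC chain over the hierarchical mixture posterior."""

    def __init__(self, data: MixtureData, priors, seed):
        self.data = data
        self.priors = priors
        self.rng = np.random.default_rng(seed)
        k = np.arange(data.kmax + 1, dtype=float)
        self._k = k
        self._lgk = gammaln(k + 1.0)
        # per-group condition index for broadcasting lambda_n
        self._cog = data.cond_of_group
        self._init_state()
        self._init_steps()

    # -- likelihood pieces -------------------------------------------------

    def _pois_logpmf(self, log_rate):
        """log Pois(k; e^log_rate) for k=0..K; log_rate broadcasts to (..., 1).

        The rate exponent is capped at e^30: beyond that the likelihood
        is effectively -inf for any observable count, and the cap keeps
        wild warmup proposals from overflowing.
        """
        lr = np.asarray(log_rate)[..., None]
        return self._k * lr - np.exp(np.minimum(lr, 30.0)) - self._lgk

    def _labeled_loglik(self, theta, lam_n_gs, lam_o_s):
        """(n_groups, n_genes) mixture log-likelihood of labeled histograms.

        lam_n_gs: (n_groups, n_genes) new-RNA log-rate per theta group;
        lam_o_s: (n_genes,) background log-rate.
        """
        ln_new = self._pois_logpmf(lam_n_gs)            # (G, S, K+1)
        ln_old = self._pois_logpmf(lam_o_s)[None, :, :]  # (1, S, K+1)
        th = np.clip(theta, 1e-12, 1 - 1e-12)[..., None]
        per_k = logsumexp(
            np.stack([np.log(th) + ln_new,
                      np.log1p(-th) + np.broadcast_to(ln_old, ln_new.shape)],
                     axis=0),
            axis=0,
        )
        return np.sum(self.data.labeled_hist * per_k, axis=2)

    def _control_loglik(self, lam_o_s):
        """(n_genes,) Poisson log-likelihood of pooled control histograms."""
        per_k = self._pois_logpmf(lam_o_s)
        return np.sum(self.data.control_hist * per_k, axis=1)

    def _lam_n(self, st):
        """(n_groups, n_genes) lambda_n broadcast to theta groups."""
        lam = st.lbar_n[:, None] + st.sigma_n[:, None] * st.z_n  # (J, S)
        return lam[self._cog]

    def _lam_o(self, st):
        return st.lbar_o + st.sigma_o * st.z_o

    # -- initialization ----------------------------------------------------

    def _init_state(self):
        d, p = self.data, self.priors
        J, G, S = d.n_conditions, d.n_groups, d.n_genes
        lbar_o = p.lambda_o_mean
        lbar_n = np.full(J, p.lambda_n_mean)
        sigma_o = 0.3
        sigma_n = np.full(J, 0.3)
        z_o = np.zeros(S)
        z_n = np.zeros((J, S))
        # moment-matched theta start
        n_lab = d.labeled_hist.sum(axis=2)
        mean_tc = np.where(
            n_lab > 0, (d.labeled_hist * self._k).sum(axis=2) / np.maximum(n_lab, 1), 0.0
        )
        rn, ro = np.exp(p.lambda_n_mean), np.exp(p.lambda_o_mean)
        theta = np.clip((mean_tc - ro) / (rn - ro), 0.05, 0.95)
        self.state = _State(lbar_o, sigma_o, lbar_n, sigma_n, z_o, z_n, theta)

    def _init_steps(self):
        d = self.data
        self._step_z_o = np.full(d.n_genes, 0.5)
        self._step_z_n = np.full((d.n_conditions, d.n_genes), 0.5)
        self._step_lbar_o = 0.05
        self._step_lbar_n = np.full(d.n_conditions, 0.05)
        self._step_lsig_o = 0.2
        self._step_lsig_n = np.full(d.n_conditions, 0.2)
        self._step_tr_o = 0.1
        self._step_tr_n = np.full(d.n_conditions, 0.1)
        self._step_sc_o = 0.2
        self._step_sc_n = np.full(d.n_conditions, 0.2)
        self._step_ridge = np.full((d.n_conditions, d.n_genes), 0.3)
        self._step_gridge = np.full(d.n_conditions, 0.05)

    # -- Metropolis updates ------------------------------------------------

    @staticmethod
    def _adapt(step, acc, it):
        gamma = (it + 1.0) ** -0.6
        return step * np.exp(gamma * (acc - _TARGET_ACC))

    def _update_z_n(self, it, adapt):
        st, d, p = self.state, self.data, self.priors
        prop = st.z_n + self._step_z_n * self.rng.standard_normal(st.z_n.shape)
        lam_o = self._lam_o(st)

        def loglik(z_n):
            lam = (st.lbar_n[:, None] + st.sigma_n[:, None] * z_n)[self._cog]
            ll_g = self._labeled_loglik(st.theta, lam, lam_o)  # (G, S)
            # fold groups back onto conditions
            out = np.zeros((d.n_conditions, d.n_genes))
            np.add.at(out, self._cog, ll_g)
            return out

        lp_cur = loglik(st.z_n) - 0.5 * (st.z_n / p.z_sd) ** 2
        lp_new = loglik(prop) - 0.5 * (prop / p.z_sd) ** 2
        acc = np.log(self.rng.uniform(size=st.z_n.shape)) < lp_new - lp_cur
        st.z_n = np.where(acc, prop, st.z_n)
        if adapt:
            self._step_z_n = self._adapt(self._step_z_n, acc.astype(float), it)

    def _update_z_o(self, it, adapt):
        st, p = self.state, self.priors
        prop = st.z_o + self._step_z_o * self.rng.standard_normal(st.z_o.shape)
        lam_n = self._lam_n(st)

        def loglik(z_o):
            lam_o = st.lbar_o + st.sigma_o * z_o
            return (self._control_loglik(lam_o)
                    + self._labeled_loglik(st.theta, lam_n, lam_o).sum(axis=0))

        lp_cur = loglik(st.z_o) - 0.5 * (st.z_o / p.z_sd) ** 2
        lp_new = loglik(prop) - 0.5 * (prop / p.z_sd) ** 2
        acc = np.log(self.rng.uniform(size=st.z_o.shape)) < lp_new - lp_cur
        st.z_o = np.where(acc, prop, st.z_o)
        if adapt:
            self._step_z_o = self._adapt(self._step_z_o, acc.astype(float), it)

    def _total_loglik(self, st, lbar_o=None, sigma_o=None, lbar_n=None,
                      sigma_n=None):
        lbar_o = st.lbar_o if lbar_o is None else lbar_o
        sigma_o = st.sigma_o if sigma_o is None else sigma_o
        lbar_n = st.lbar_n if lbar_n is None else lbar_n
        sigma_n = st.sigma_n if sigma_n is None else sigma_n
        lam_o = lbar_o + sigma_o * st.z_o
        lam_n = (lbar_n[:, None] + sigma_n[:, None] * st.z_n)[self._cog]
        return (self._control_loglik(lam_o).sum()
                + self._labeled_loglik(st.theta, lam_n, lam_o).sum())

    def _update_globals(self, it, adapt):
        st, p, rng = self.state, self.priors, self.rng
        cur_ll = self._total_loglik(st)  # tracked across accepts within the sweep

        # lbar_o
        prop = st.lbar_o + self._step_lbar_o * rng.standard_normal()
        new_ll = self._total_loglik(st, lbar_o=prop)
        lp_cur = cur_ll - 0.5 * ((st.lbar_o - p.lambda_o_mean) / p.lambda_o_sd) ** 2
        lp_new = new_ll - 0.5 * ((prop - p.lambda_o_mean) / p.lambda_o_sd) ** 2
        a = np.log(rng.uniform()) < lp_new - lp_cur
        if a:
            st.lbar_o, cur_ll = prop, new_ll
        if adapt:
            self._step_lbar_o = self._adapt(self._step_lbar_o, float(a), it)

        # sigma_o on the log scale (Jacobian = +log sigma)
        lprop = np.log(st.sigma_o) + self._step_lsig_o * rng.standard_normal()
        sprop = np.exp(lprop)
        new_ll = self._total_loglik(st, sigma_o=sprop)
        lp_cur = (cur_ll + _half_cauchy_logpdf(st.sigma_o, p.sigma_scale)
                  + np.log(st.sigma_o))
        lp_new = new_ll + _half_cauchy_logpdf(sprop, p.sigma_scale) + lprop
        a = np.log(rng.uniform()) < lp_new - lp_cur
        if a:
            st.sigma_o, cur_ll = sprop, new_ll
        if adapt:
            self._step_lsig_o = self._adapt(self._step_lsig_o, float(a), it)

        # per-condition lbar_n, sigma_n
        for j in range(self.data.n_conditions):
            prop_vec = st.lbar_n.copy()
            prop_vec[j] += self._step_lbar_n[j] * rng.standard_normal()
            new_ll = self._total_loglik(st, lbar_n=prop_vec)
            lp_cur = cur_ll - 0.5 * ((st.lbar_n[j] - p.lambda_n_mean) / p.lambda_n_sd) ** 2
            lp_new = new_ll - 0.5 * ((prop_vec[j] - p.lambda_n_mean) / p.lambda_n_sd) ** 2
            a = np.log(rng.uniform()) < lp_new - lp_cur
            if a:
                st.lbar_n, cur_ll = prop_vec, new_ll
            if adapt:
                self._step_lbar_n[j] = self._adapt(self._step_lbar_n[j], float(a), it)

            sprop_vec = st.sigma_n.copy()
            lprop = np.log(st.sigma_n[j]) + self._step_lsig_n[j] * rng.standard_normal()
            sprop_vec[j] = np.exp(lprop)
            new_ll = self._total_loglik(st, sigma_n=sprop_vec)
            lp_cur = (cur_ll + _half_cauchy_logpdf(st.sigma_n[j], p.sigma_scale)
                      + np.log(st.sigma_n[j]))
            lp_new = new_ll + _half_cauchy_logpdf(sprop_vec[j], p.sigma_scale) + lprop
            a = np.log(rng.uniform()) < lp_new - lp_cur
            if a:
                st.sigma_n, cur_ll = sprop_vec, new_ll
            if adapt:
                self._step_lsig_n[j] = self._adapt(self._step_lsig_n[j], float(a), it)

    def _interweave_moves(self, it, adapt):
        """Likelihood-invariant hierarchy moves (centered-parametrization
        interweaving).

        Translation: (lbar + d, z - d/sigma) keeps every lambda fixed, so
        acceptance depends on priors alone; scale: (sigma*c, z/c) likewise
        (Jacobian c^(1-S)). These decorrelate the global mean/scale from
        the gene-level z's, which otherwise pin them in place when the
        data are informative.
        """
        st, p, rng = self.state, self.priors, self.rng
        S = self.data.n_genes

        def z_logprior(z):
            return -0.5 * np.sum((z / p.z_sd) ** 2)

        # background hierarchy
        d = self._step_tr_o * rng.standard_normal()
        z_new = st.z_o - d / st.sigma_o
        lp = (z_logprior(z_new) - z_logprior(st.z_o)
              - 0.5 * ((st.lbar_o + d - p.lambda_o_mean) / p.lambda_o_sd) ** 2
              + 0.5 * ((st.lbar_o - p.lambda_o_mean) / p.lambda_o_sd) ** 2)
        a = np.log(rng.uniform()) < lp
        if a:
            st.lbar_o += d
            st.z_o = z_new
        if adapt:
            self._step_tr_o = self._adapt(self._step_tr_o, float(a), it)

        c = np.exp(self._step_sc_o * rng.standard_normal())
        s_new, z_new = st.sigma_o * c, st.z_o / c
        lp = (z_logprior(z_new) - z_logprior(st.z_o)
              + _half_cauchy_logpdf(s_new, p.sigma_scale)
              - _half_cauchy_logpdf(st.sigma_o, p.sigma_scale)
              + (1 - S) * np.log(c))  # Jacobian of (sigma, z) -> (sigma*c, z/c)
        a = np.log(rng.uniform()) < lp
        if a:
            st.sigma_o, st.z_o = s_new, z_new
        if adapt:
            self._step_sc_o = self._adapt(self._step_sc_o, float(a), it)

        # per-condition new-RNA hierarchy
        for j in range(self.data.n_conditions):
            d = self._step_tr_n[j] * rng.standard_normal()
            z_new = st.z_n[j] - d / st.sigma_n[j]
            lp = (z_logprior(z_new) - z_logprior(st.z_n[j])
                  - 0.5 * ((st.lbar_n[j] + d - p.lambda_n_mean)
                           / p.lambda_n_sd) ** 2
                  + 0.5 * ((st.lbar_n[j] - p.lambda_n_mean)
                           / p.lambda_n_sd) ** 2)
            a = np.log(rng.uniform()) < lp
            if a:
                st.lbar_n[j] += d
                st.z_n[j] = z_new
            if adapt:
                self._step_tr_n[j] = self._adapt(self._step_tr_n[j], float(a), it)

            c = np.exp(self._step_sc_n[j] * rng.standard_normal())
            s_new, z_new = st.sigma_n[j] * c, st.z_n[j] / c
            lp = (z_logprior(z_new) - z_logprior(st.z_n[j])
                  + _half_cauchy_logpdf(s_new, p.sigma_scale)
                  - _half_cauchy_logpdf(st.sigma_n[j], p.sigma_scale)
                  + (1 - S) * np.log(c))
            a = np.log(rng.uniform()) < lp
            if a:
                st.sigma_n[j] = s_new
                st.z_n[j] = z_new
            if adapt:
                self._step_sc_n[j] = self._adapt(self._step_sc_n[j], float(a), it)

    def _ridge_move(self, it, adapt):
        """Joint (z_n, theta) proposal along the mean-preserving ridge.

        theta and lambda_n trade off through the labeled mean
        theta*exp(lambda_n); proposing lambda_n -> lambda_n + sigma*eps
        with theta -> theta*exp(-sigma*eps) moves along that ridge so the
        pair can travel where axis-aligned updates crawl. Deterministic
        map given eps; Jacobian d(theta')/d(theta) = exp(-sigma*eps) per
        theta group in the condition.
        """
        st, d, p, rng = self.state, self.data, self.priors, self.rng
        J, S = d.n_conditions, d.n_genes
        eps = self._step_ridge * rng.standard_normal((J, S))
        z_new = st.z_n + eps
        log_factor = -(st.sigma_n[:, None] * eps)          # (J, S)
        theta_new = st.theta * np.exp(
            np.minimum(log_factor[self._cog], 50.0))  # (G, S); >=1 rejected

        lam_o = self._lam_o(st)
        lam_cur = (st.lbar_n[:, None] + st.sigma_n[:, None] * st.z_n)[self._cog]
        lam_new = (st.lbar_n[:, None] + st.sigma_n[:, None] * z_new)[self._cog]
        ll_cur_g = self._labeled_loglik(st.theta, lam_cur, lam_o)
        ll_new_g = self._labeled_loglik(np.minimum(theta_new, 1 - 1e-12),
                                        lam_new, lam_o)
        ll_cur = np.zeros((J, S))
        ll_new = np.zeros((J, S))
        bad = np.zeros((J, S), dtype=bool)
        np.add.at(ll_cur, self._cog, ll_cur_g)
        np.add.at(ll_new, self._cog, ll_new_g)
        np.logical_or.at(bad, self._cog, theta_new >= 1.0)
        n_groups = np.bincount(self._cog, minlength=J).astype(float)

        lp = (ll_new - ll_cur
              - 0.5 * ((z_new / p.z_sd) ** 2 - (st.z_n / p.z_sd) ** 2)
              + n_groups[:, None] * log_factor)
        if p.theta_a != 1.0 or p.theta_b != 1.0:
            th_c = np.clip(st.theta, 1e-12, 1 - 1e-12)
            th_n = np.clip(theta_new, 1e-12, 1 - 1e-12)
            dbeta = ((p.theta_a - 1) * (np.log(th_n) - np.log(th_c))
                     + (p.theta_b - 1) * (np.log1p(-th_n) - np.log1p(-th_c)))
            fold = np.zeros((J, S))
            np.add.at(fold, self._cog, dbeta)
            lp = lp + fold
        acc = (np.log(rng.uniform(size=(J, S))) < lp) & ~bad
        st.z_n = np.where(acc, z_new, st.z_n)
        acc_g = acc[self._cog]
        st.theta = np.where(acc_g, theta_new, st.theta)
        if adapt:
            self._step_ridge = self._adapt(self._step_ridge, acc.astype(float), it)

    def _global_ridge_move(self, it, adapt):
        """Condition-level ridge: lbar_n + d with every theta scaled e^-d.

        Keeps each gene's labeled mean roughly fixed, letting the global
        new-RNA rate and the whole fraction-new vector trade off; without
        it the chain can wedge slightly off the rate scale and stay there.
        Jacobian: e^(-d) per theta in the condition.
        """
        st, d_, p, rng = self.state, self.data, self.priors, self.rng
        lam_o = self._lam_o(st)
        for j in range(d_.n_conditions):
            delta = self._step_gridge[j] * rng.standard_normal()
            groups_j = np.flatnonzero(self._cog == j)
            theta_new = st.theta.copy()
            theta_new[groups_j] = st.theta[groups_j] * np.exp(-delta)
            if np.any(theta_new[groups_j] >= 1.0):
                if adapt:
                    self._step_gridge[j] = self._adapt(
                        self._step_gridge[j], 0.0, it)
                continue
            lbar_new = st.lbar_n.copy()
            lbar_new[j] += delta
            lam_cur = self._lam_n(st)
            lam_new = (lbar_new[:, None] + st.sigma_n[:, None] * st.z_n)[self._cog]
            ll_cur = self._labeled_loglik(st.theta, lam_cur, lam_o)[groups_j].sum()
            ll_new = self._labeled_loglik(theta_new, lam_new, lam_o)[groups_j].sum()
            lp = (ll_new - ll_cur
                  - 0.5 * ((lbar_new[j] - p.lambda_n_mean) / p.lambda_n_sd) ** 2
                  + 0.5 * ((st.lbar_n[j] - p.lambda_n_mean) / p.lambda_n_sd) ** 2
                  - delta * len(groups_j) * d_.n_genes)
            if p.theta_a != 1.0 or p.theta_b != 1.0:
                th_c = np.clip(st.theta[groups_j], 1e-12, 1 - 1e-12)
                th_n = np.clip(theta_new[groups_j], 1e-12, 1 - 1e-12)
                lp += float(
                    (p.theta_a - 1) * (np.log(th_n) - np.log(th_c)).sum()
                    + (p.theta_b - 1) * (np.log1p(-th_n) - np.log1p(-th_c)).sum())
            a = np.log(rng.uniform()) < lp
            if a:
                st.lbar_n = lbar_new
                st.theta = theta_new
            if adapt:
                self._step_gridge[j] = self._adapt(
                    self._step_gridge[j], float(a), it)

    def _update_theta(self):
        """Impute read assignments, then conjugate Beta draw for theta."""
        st, d, p = self.state, self.data, self.priors
        lam_n = self._lam_n(st)
        lam_o = self._lam_o(st)
        ln_new = self._pois_logpmf(lam_n)
        ln_old = np.broadcast_to(self._pois_logpmf(lam_o)[None], ln_new.shape)
        th = np.clip(st.theta, 1e-12, 1 - 1e-12)[..., None]
        log_w_new = np.log(th) + ln_new
        log_w_old = np.log1p(-th) + ln_old
        p_new = expit(log_w_new - log_w_old)
        n_new = self.rng.binomial(d.labeled_hist, p_new)
        a = n_new.sum(axis=2)
        b = d.labeled_hist.sum(axis=2) - a
        st.theta = self.rng.beta(p.theta_a + a, p.theta_b + b)

    # -- driver ------------------------------------------------------------

    def sweep(self, it, adapt):
        self._update_z_n(it, adapt)
        self._update_z_o(it, adapt)
        self._update_globals(it, adapt)
        self._interweave_moves(it, adapt)
        self._global_ridge_move(it, adapt)
        # theta and the (theta, lambda_n) ridge are the slowest directions;
        # cycling them a few times per sweep costs little and buys ESS
        for _ in range(3):
            self._update_theta()
            self._ridge_move(it, adapt)

    def run(self, warmup, draws):
        d = self.data
        out = {
            "theta": np.empty((draws, d.n_groups, d.n_genes)),
            "z_n": np.empty((draws, d.n_conditions, d.n_genes)),
            "z_o": np.empty((draws, d.n_genes)),
            "lambda_n_bar": np.empty((draws, d.n_conditions)),
            "lambda_o_bar": np.empty(draws),
            "sigma_n": np.empty((draws, d.n_conditions)),
            "sigma_o": np.empty(draws),
        }
        for it in range(warmup):
            self.sweep(it, adapt=True)
        for it in range(draws):
            self.sweep(warmup + it, adapt=False)
            st = self.state
            out["theta"][it] = st.theta
            out["z_n"][it] = st.z_n
            out["z_o"][it] = st.z_o
            out["lambda_n_bar"][it] = st.lbar_n
            out["lambda_o_bar"][it] = st.lbar_o
            out["sigma_n"][it] = st.sigma_n
            out["sigma_o"][it] = st.sigma_o
        # derived, non-centered identities applied draw-wise
        out["lambda_o"] = out["lambda_o_bar"][:, None] + out["sigma_o"][:, None] * out["z_o"]
        out["lambda_n"] = (out["lambda_n_bar"][:, :, None]
                           + out["sigma_n"][:, :, None] * out["z_n"])
        return out
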