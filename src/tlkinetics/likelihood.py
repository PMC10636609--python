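"""Two-component Poisson mixture likelihood for per-read T-to-C counts.

A read from a labeled (s4U-treated) library carries ``tc`` retained
T-to-C mutations drawn either from the "new RNA" component (recoding
chemistry, log-rate ``lambda_n``) with probability ``theta`` — the
fraction of transcripts synthesized during the labeling window — or
from the background component (RT/sequencing error, log-rate
``lambda_o``). Unlabeled control libraries (indicator 0) collapse to the
background Poisson alone. Both rates are parametrized on the log scale:
a log-rate ``lam`` means a Poisson rate of ``exp(lam)``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "poisson_log_pmf",
    "mixture_log_pmf",
    "dataset_log_likelihood",
    "grid_map_theta",
]


def poisson_log_pmf(tc, log_rate):
    """Poisson log-pmf with the rate given on the log scale.

    ``log P(tc) = tc*log_rate - exp(log_rate) - log(tc!)``
    """
    tc = np.asarray(tc)
    return tc * log_rate - np.exp(log_rate) - gammaln(tc + 1.0)


def _check_counts(tc):
    tc = np.asarray(tc)
    if tc.size and (np.any(tc < 0) or not np.issubdtype(tc.dtype, np.integer)):
        if np.any(tc < 0) or np.any(tc != np.floor(tc)):
            raise ValueError("tc counts must be nonnegative integers")
    return tc


def mixture_log_pmf(tc, theta, lambda_n, lambda_o, labeled=1):
    """Log-pmf of the labeled/background Poisson mixture.

    ``log[ I*theta*Pois(tc; e^lambda_n) + (1 - I*theta)*Pois(tc; e^lambda_o) ]``

    computed via log-sum-exp. ``labeled`` is the s4U indicator I; with
    I=0 (or theta=0) the expression is exactly the background Poisson
    log-pmf, and with I=1, theta=1 exactly the new-component log-pmf —
    the vanishing component is dropped rather than evaluated at
    ``log(0)``.

    Parameters broadcast; ``tc`` must hold nonnegative integers and
    ``theta`` must lie in [0, 1].
    """
    tc = _check_counts(tc)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta must lie in [0, 1]")
    w = np.asarray(labeled, dtype=float) * theta  # effective new-component weight
    ln_new = poisson_log_pmf(tc, lambda_n)
    ln_old = poisson_log_pmf(tc, lambda_o)
    w, ln_new, ln_old = np.broadcast_arrays(w, ln_new, ln_old)
    with np.errstate(divide="ignore"):
        stacked = np.stack(
            [np.log(w) + ln_new, np.log1p(-w) + ln_old], axis=0
        )
    out = logsumexp(stacked, axis=0)
    # drop the vanishing component at the boundaries
    out = np.where(w == 0.0, ln_old, out)
    out = np.where(w == 1.0, ln_new, out)
    if out.ndim == 0:
        return float(out)
    return out


def dataset_log_likelihood(table, params, theta_col="theta"):
    """Joint log-likelihood of a mutation-count table under given parameters.

    ``table`` is a MutationCountTable DataFrame (columns ``gene_id``,
    ``condition``, ``s4u``, ``tc``); ``params`` is a DataFrame indexed
    (or keyed) by (condition, gene_id) with columns ``theta``,
    ``lambda_n``, ``lambda_o``. Reads are independent, so the result is
    the sum of ``mixture_log_pmf`` over rows and is additive over
    disjoint subsets.

    Raises ``KeyError`` naming the gene if a (condition, gene) observed
    in the table has no parameters.
    """
    if len(table) == 0:
        return 0.0
    p = params
    if p.index.nlevels < 2:
        p = params.set_index(["condition", "gene_id"])
    total = 0.0
    for (cond, gene), grp in table.groupby(["condition", "gene_id"], sort=False):
        try:
            row = p.loc[(cond, gene)]
        except KeyError:
            raise KeyError(
                f"no model parameters for gene {gene!r} in condition {cond!r}"
            ) from None
        ll = mixture_log_pmf(
            grp["tc"].to_numpy(),
            float(row[theta_col]),
            float(row["lambda_n"]),
            float(row["lambda_o"]),
            grp["s4u"].to_numpy(),
        )
        total += float(np.sum(ll))
    return total


def grid_map_theta(tc_counts, lambda_n, lambda_o, step=0.001):
    """Brute-force maximum-likelihood fraction-new at fixed mutation rates.

    Maximizes the per-gene mixture likelihood of labeled read counts
    over a theta grid of the given step. Intended as an independent
    check on the sampler, not as an estimator in its own right (it
    ignores the hierarchy and the rate uncertainty).
    """
    tc = _check_counts(np.asarray(tc_counts))
    grid = np.arange(0.0, 1.0 + step / 2, step)
    ln_new = poisson_log_pmf(tc, lambda_n)[None, :]
    ln_old = poisson_log_pmf(tc, lambda_o)[None, :]
    with np.errstate(divide="ignore"):
        lw = np.log(grid)[:, None]
        lw1 = np.log1p(-grid)[:, None]
    per_read = logsumexp(
        np.stack([lw + ln_new, lw1 + ln_old], axis=0), axis=0
    )
    per_read[0] = ln_old[0]
    per_read[-1] = ln_new[0]
    ll = per_read.sum(axis=1)
    return float(grid[int(np.argmax(ll))])
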