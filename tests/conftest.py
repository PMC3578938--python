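"""Shared statistical helpers for the test suite."""

import numpy as np
import pytest
from scipy import stats


def poisson_gof_pvalue(samples, mu):
    """Chi-square goodness-of-fit p-value of integer samples vs Poisson(mu).

    Bins are pooled from the tails inward so every expected count is >= 5.
    """
    samples = np.asarray(samples)
    n = samples.size
    hi = int(max(samples.max(), mu + 6 * np.sqrt(mu)))
    ks = np.arange(hi + 1)
    probs = stats.poisson.pmf(ks, mu)
    probs[-1] += stats.poisson.sf(hi, mu)
    obs = np.bincount(samples, minlength=hi + 1).astype(float)
    # pool sparse bins from the left and right tails
    exp = probs * n
    lo_edge = 0
    while exp[: lo_edge + 1].sum() < 5:
        lo_edge += 1
    hi_edge = hi
    while exp[hi_edge:].sum() < 5:
        hi_edge -= 1
    obs_b = [obs[: lo_edge + 1].sum()]
    exp_b = [exp[: lo_edge + 1].sum()]
    for k in range(lo_edge + 1, hi_edge):
        obs_b.append(obs[k])
        exp_b.append(exp[k])
    obs_b.append(obs[hi_edge:].sum())
    exp_b.append(exp[hi_edge:].sum())
    obs_b, exp_b = np.asarray(obs_b), np.asarray(exp_b)
    exp_b *= obs_b.sum() / exp_b.sum()
    stat, p = stats.chisquare(obs_b, exp_b)
    return p


def overdispersion_pvalue(samples):
    """One-sided test of variance > mean against the Poisson null.

    Under Poisson the index of dispersion statistic (n-1)*s^2/xbar is
    approximately chi-square with n-1 degrees of freedom.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    stat = (n - 1) * samples.var(ddof=1) / samples.mean()
    return stats.chi2.sf(stat, n - 1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
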