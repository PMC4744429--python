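"""MCMC diagnostics shared by both stages: DIC and the Gelman-Rubin PSRF."""

from __future__ import annotations

import numpy as np

__all__ = ["dic", "gelman_rubin"]


def dic(deviance_draws, deviance_at_mean: float) -> tuple[float, float, float]:
    """Deviance information criterion from posterior deviance draws.

    Dbar is the posterior mean deviance, pD = Dbar - D(theta_bar) the
    effective number of parameters, and DIC = Dbar + pD. Smaller is better.
    Requires at least 100 draws for a stable Dbar.
    """
    d = np.asarray(deviance_draws, dtype=float)
    if d.size < 100:
        raise ValueError("need at least 100 deviance draws for DIC")
    dbar = float(d.mean())
    pd_ = dbar - float(deviance_at_mean)
    return dbar + pd_, pd_, dbar


def gelman_rubin(chains) -> float | np.ndarray:
    """Potential scale reduction factor from >= 2 equal-length chains.

    ``chains`` has shape (m, n) for a scalar parameter or (m, n, k) for k
    parameters. PSRF = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-
    chain variance and B/n the variance of the chain means. Zero within-
    chain variance with distinct chains yields +inf (a flagged failure);
    identical constant chains yield 1.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim == 2:
        c = c[:, :, None]
        squeeze = True
    else:
        squeeze = False
    m, n = c.shape[0], c.shape[1]
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains of length >= 10")
    means = c.mean(axis=1)  # (m, k)
    W = c.var(axis=1, ddof=1).mean(axis=0)  # (k,)
    Bn = means.var(axis=0, ddof=1)  # B/n
    with np.errstate(divide="ignore", invalid="ignore"):
        vhat = (n - 1) / n * W + Bn
        psrf = np.sqrt(vhat / W)
    psrf = np.where((W == 0) & (Bn > 0), np.inf, psrf)
    psrf = np.where((W == 0) & (Bn == 0), 1.0, psrf)
    return float(psrf[0]) if squeeze else psrf
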