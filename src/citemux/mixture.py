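"""One-dimensional two-component Gaussian mixtures.

Both hashtag (HTO) demultiplexing and surface-protein positivity calling rest
on the same primitive: fit a 2-component Gaussian mixture to a bimodal
1-D distribution and report, per observation, the posterior probability of
belonging to the higher-mean ("positive") component.

Fitting uses EM with a deterministic quantile-split initialization (lower and
upper thirds of the sorted values) plus two seeded random restarts; the fit
with the best lower bound is kept, so results are reproducible and invariant
to observation order.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture


class DegenerateFitError(RuntimeError):
    """Raised when the values cannot support a two-component fit."""


@dataclass
class MixtureFit:
    """Fitted 1-D two-component Gaussian mixture.

    ``means``, ``variances`` and ``weights`` are ordered (low, high) by
    component mean; ``posterior_positive`` is the per-observation posterior
    of the high-mean component, in the original observation order.
    """

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    posterior_positive: np.ndarray
    converged: bool


def fit_two_component(values: np.ndarray, seed: int = 0,
                      min_observations: int = 50,
                      max_iter: int = 500) -> MixtureFit:
    """Fit a two-component Gaussian mixture to 1-D ``values``.

    Parameters
    ----------
    values
        1-D array of observations (e.g. one tag's normalized counts across
        droplets, or one protein's CLR values across cells).
    seed
        Seed for the random restarts; the quantile-split initialization is
        deterministic regardless.
    min_observations
        Minimum number of observations required for a meaningful fit.

    Raises
    ------
    DegenerateFitError
        If the values are (near-)constant, or EM fails to converge.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < min_observations:
        raise DegenerateFitError(
            f"need at least {min_observations} observations, got {x.size}")
    if np.ptp(x) == 0 or np.std(x) < 1e-12:
        raise DegenerateFitError(
            "values are constant; two-component fit is degenerate — "
            "inspect the input distribution")

    # order-invariant: fit on sorted values, map posteriors back at the end
    order = np.argsort(x, kind="stable")
    xs = x[order].reshape(-1, 1)

    lo, hi = np.quantile(x, [1 / 3, 2 / 3])
    inits: list[dict] = [dict(means_init=np.array([[lo], [hi]]),
                              random_state=int(seed % (2**31)))]
    inits += [dict(random_state=int((seed + r) % (2**31)), init_params="random")
              for r in (1, 2)]

    best: GaussianMixture | None = None
    for kw in inits:
        gm = GaussianMixture(n_components=2, covariance_type="full",
                             reg_covar=1e-6, max_iter=max_iter, n_init=1, **kw)
        try:
            gm.fit(xs)
        except ValueError:
            continue
        if best is None or gm.lower_bound_ > best.lower_bound_:
            best = gm
    if best is None or not best.converged_:
        raise DegenerateFitError(
            "EM did not converge; inspect the input distribution")

    means = best.means_.ravel()
    variances = best.covariances_.reshape(-1)
    weights = best.weights_.ravel()
    if means[0] == means[1]:
        raise DegenerateFitError("components collapsed to identical means")
    comp_order = np.argsort(means)
    post_sorted = best.predict_proba(xs)[:, comp_order[1]]
    posterior = np.empty_like(post_sorted)
    posterior[order] = post_sorted
    return MixtureFit(means=means[comp_order], variances=variances[comp_order],
                      weights=weights[comp_order],
                      posterior_positive=posterior, converged=True)
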