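"""Brute-force dense-grid posterior oracles used to validate the sampler.

These evaluate flat-prior posteriors directly from the likelihood formulas
(independently of the package's vectorised evaluation pipeline) on fine
grids, for problems small enough to enumerate.
"""

import numpy as np
from scipy.special import erf


def grid_posterior_cdf_1d(case, n_grid=20001):
    """Flat-prior posterior CDF of f1 for a two-source, one-signature case."""
    meas = case.measurements[0]
    model = case.model
    S = model.source_means()[:, 0]
    g = np.linspace(0.0, 1.0, n_grid)
    mu = g * S[0] + (1 - g) * S[1]
    if model.sources[0].mode == "point":
        sd = model.source_sigmas()[:, 0]
        sigma = np.sqrt(meas.sigma_x[0] ** 2 + g**2 * sd[0] ** 2
                        + (1 - g) ** 2 * sd[1] ** 2)
        w = np.exp(-((meas.x[0] - mu) ** 2) / (2 * sigma**2)) / sigma
    else:
        hr = model.source_half_ranges()[:, 0]
        delta = g * hr[0] + (1 - g) * hr[1]
        z = (meas.x[0] - mu) / (meas.sigma_x[0] * np.sqrt(2))
        d = delta / (meas.sigma_x[0] * np.sqrt(2))
        w = erf(z + d) - erf(z - d)
    w = w / w.sum()
    return g, np.cumsum(w)


def grid_marginal_cdfs_2d(case, n_grid=801):
    """Flat-Dirichlet posterior marginal CDFs of (f1, f2, f3) for a
    three-source, two-signature range-mode case, by triangle enumeration."""
    meas = case.measurements[0]
    S = case.model.source_means()
    HR = case.model.source_half_ranges()
    g = np.linspace(0.0, 1.0, n_grid)
    F1, F2 = np.meshgrid(g, g, indexing="ij")
    inside = (F1 + F2) <= 1.0
    F3 = 1.0 - F1 - F2
    W = np.ones_like(F1)
    for i in range(2):
        MU = F1 * S[0, i] + F2 * S[1, i] + F3 * S[2, i]
        D = F1 * HR[0, i] + F2 * HR[1, i] + F3 * HR[2, i]
        z = (meas.x[i] - MU) / (meas.sigma_x[i] * np.sqrt(2))
        d = D / (meas.sigma_x[i] * np.sqrt(2))
        W = W * (erf(z + d) - erf(z - d))
    W[~inside] = 0.0
    cdfs = {}
    for name, marg in (("f1", W.sum(axis=1)), ("f2", W.sum(axis=0))):
        marg = marg / marg.sum()
        cdfs[name] = np.cumsum(marg)
    # f3 marginal: histogram the triangle onto the same grid
    w3 = np.zeros_like(g)
    idx = np.clip(np.round(F3[inside] * (n_grid - 1)).astype(int), 0, n_grid - 1)
    np.add.at(w3, idx, W[inside])
    cdfs["f3"] = np.cumsum(w3 / w3.sum())
    return g, cdfs


def ks_distance(samples, grid, grid_cdf):
    """Kolmogorov-Smirnov distance between an empirical sample and a grid CDF."""
    vals = np.sort(np.asarray(samples, dtype=float))
    emp = np.arange(1, vals.size + 1) / vals.size
    ref = np.interp(vals, grid, grid_cdf)
    return float(np.max(np.abs(emp - ref)))
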