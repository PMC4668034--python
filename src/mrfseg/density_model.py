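"""Gaussian-mixture label densities and unary potentials.

Per channel, the local-entropy values of a slice are modelled as a univariate
three-component Gaussian mixture: a low-entropy "background" component, a
high-entropy "in focus" component, and an intermediate "out of focus"
component.  For two-channel data the three segmentation labels get bivariate
densities built as products of the per-channel pieces:

    pi_T(r, g) = f_R,if(r) * m_G(g)      (in-focus tumour in red)
    pi_C(r, g) = m_R(r)    * f_G,if(g)   (in-focus CAF in green)
    pi_B(r, g) = m_R(r)    * m_G(g)      (neither in focus)

where f_c,if is the in-focus component of channel c and m_c is the
weight-renormalized mixture of the remaining ("out of focus" + "background")
components.  Unary MRF potentials are the negative log of these densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .entropy_filter import EntropyStack

_LOG_2PI = np.log(2.0 * np.pi)

VARIANCE_FLOOR = 1e-6  # bits^2; keeps components proper densities
DEFAULT_EPS = 1e-12    # density floor in the unary potentials


@dataclass(frozen=True)
class Mixture1D:
    """A fitted univariate 3-component Gaussian mixture, sorted by mean."""

    weights: tuple[float, float, float]
    means: tuple[float, float, float]
    variances: tuple[float, float, float]
    loglik: float

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(w <= 0 for w in self.weights):
            raise ValueError("mixture weights must be positive")
        if any(v < VARIANCE_FLOOR * (1 - 1e-12) for v in self.variances):
            raise ValueError("variance below floor")

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        out = np.zeros_like(x)
        for w, m, v in zip(self.weights, self.means, self.variances):
            out += w * np.exp(-0.5 * (x - m) ** 2 / v) / np.sqrt(2.0 * np.pi * v)
        return out

    def component_pdf(self, k: int, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        m, v = self.means[k], self.variances[k]
        return np.exp(-0.5 * (x - m) ** 2 / v) / np.sqrt(2.0 * np.pi * v)

    def to_dict(self) -> dict:
        return {"weights": list(self.weights), "means": list(self.means),
                "variances": list(self.variances), "loglik": self.loglik}

    @classmethod
    def from_dict(cls, d: dict) -> "Mixture1D":
        return cls(tuple(d["weights"]), tuple(d["means"]),
                   tuple(d["variances"]), float(d["loglik"]))


@dataclass(frozen=True)
class ChannelRoles:
    """Component indices by role; means satisfy bg <= oof <= if."""

    bg_idx: int
    oof_idx: int
    if_idx: int


def assign_roles(mix: Mixture1D) -> ChannelRoles:
    """Assign background / out-of-focus / in-focus roles by increasing mean."""
    order = np.argsort(mix.means, kind="stable")
    return ChannelRoles(bg_idx=int(order[0]), oof_idx=int(order[1]),
                        if_idx=int(order[2]))


#: histogram resolution used for fitting; bin width is (data range)/1024,
#: ~0.006 bits for full-range entropy data — far below any component width
#: of interest, and it makes the EM cost independent of image size.
FIT_BINS = 1024


def _em_init(values: np.ndarray, n_init: int, seed: int):
    """Quantile-based means plus seeded jitter; equal weights; pooled variance.

    The first restart sits at the evenly spaced quantiles (1/6, 1/2, 5/6);
    the others draw random quantile levels so that restarts cover the data
    range even when the distribution is heavily skewed (a single fixed
    quantile triple can leave a far-out mode unseeded on every restart).
    """
    rng = np.random.default_rng(seed)
    std = values.std()
    levels = np.sort(rng.uniform(0.01, 0.99, size=(n_init, 3)), axis=1)
    levels[0] = (1 / 6, 1 / 2, 5 / 6)
    means = (np.quantile(values, levels.ravel()).reshape(n_init, 3)
             + rng.normal(0.0, 0.05 * std, size=(n_init, 3)))
    variances = np.full((n_init, 3), max(values.var(), VARIANCE_FLOOR))
    weights = np.full((n_init, 3), 1.0 / 3.0)
    return means, variances, weights


def _bin_values(values: np.ndarray, bins: int):
    """Histogram a data vector; returns (bin centres, counts)."""
    counts, edges = np.histogram(values, bins=bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return centres[keep], counts[keep].astype(np.float64)


def _em_batch(x_rows: np.ndarray, c_rows: np.ndarray, means: np.ndarray,
              variances: np.ndarray, weights: np.ndarray,
              tol: float = 1e-8, max_iter: int = 500):
    """Run many independent weighted univariate 3-component EMs in lock-step.

    ``x_rows``/``c_rows`` are (R, n): support points and their counts, one
    row per EM problem (rows repeat when restarts share data; unused tail
    positions carry count 0).  A row freezes once its log-likelihood
    improvement drops below ``tol``; all rows share the iteration loop,
    which keeps the whole batch inside vectorised numpy.
    Returns updated (means, variances, weights, loglik).
    """
    R, n = x_rows.shape
    x = x_rows[:, :, None]                        # (R, n, 1)
    c = c_rows[:, :, None]
    n_total = c_rows.sum(axis=1)                  # (R,)
    loglik = np.full(R, -np.inf)
    frozen = np.zeros(R, dtype=bool)

    for _ in range(max_iter):
        m = means[:, None, :]                     # (R, 1, 3)
        v = variances[:, None, :]
        w = weights[:, None, :]
        # linear-space E-step; the pooled-variance init keeps at least one
        # broad component so the mixture density g rarely underflows —
        # guarded anyway.
        g = (w / np.sqrt(2.0 * np.pi * v)) * np.exp(-0.5 * (x - m) ** 2 / v)
        norm = g.sum(axis=2)                      # (R, n)
        bad = norm <= 0.0
        if bad.any():
            # fully underflowed support points: prior responsibilities
            g[bad] = np.broadcast_to(weights[:, None, :], g.shape)[bad]
            norm[bad] = 1.0
        ll = (c_rows * np.log(norm)).sum(axis=1)
        resp = (g / norm[:, :, None]) * c         # weighted responsibilities

        nk = np.maximum(resp.sum(axis=1), 1e-300)  # (R, 3)
        new_means = (resp * x).sum(axis=1) / nk
        sq = (resp * x * x).sum(axis=1) / nk
        new_vars = np.maximum(sq - new_means**2, VARIANCE_FLOOR)
        new_weights = nk / n_total[:, None]

        keep = frozen[:, None]
        means = np.where(keep, means, new_means)
        variances = np.where(keep, variances, new_vars)
        weights = np.where(keep, weights, new_weights)
        improved = ll - loglik
        loglik = np.where(frozen, loglik, ll)
        frozen |= improved < tol
        if frozen.all():
            break
    return means, variances, weights, loglik


def _em_restarts(values: np.ndarray, n_init: int, seed: int,
                 tol: float = 1e-8, max_iter: int = 500,
                 bins: int = FIT_BINS):
    """Best-of-restarts EM on one data vector (histogram-weighted).

    Returns (weights, means, variances, loglik), each with a leading
    restart axis.
    """
    means, variances, weights = _em_init(values, n_init, seed)
    centres, counts = _bin_values(values, bins)
    x_rows = np.broadcast_to(centres, (n_init, centres.size))
    c_rows = np.broadcast_to(counts, (n_init, counts.size))
    means, variances, weights, loglik = _em_batch(x_rows, c_rows, means,
                                                  variances, weights, tol,
                                                  max_iter)
    return weights, means, variances, loglik


def fit_mixture3(values: np.ndarray, n_init: int = 10, seed: int = 0) -> Mixture1D:
    """Fit a 3-component univariate Gaussian mixture by best-of-``n_init`` EM.

    EM stops when the log-likelihood improvement falls below 1e-8 or after
    500 iterations; the restart with the highest log-likelihood wins.
    Deterministic given ``seed``.  Raises on degenerate (constant) input.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 100:
        raise ValueError(f"need >= 100 values to fit, got {values.size}")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values")
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: all values identical, slice unfittable")
    w, m, v, ll = _em_restarts(values, n_init, seed)
    best = int(np.argmax(ll))
    # zero-weight collapse: a component that lost all responsibility
    if w[best].min() <= 0:
        raise ValueError("mixture fit collapsed a component to zero weight")
    order = np.argsort(m[best], kind="stable")
    return Mixture1D(tuple(w[best][order]), tuple(m[best][order]),
                     tuple(v[best][order]), float(ll[best]))


def fit_mixtures_per_slice(entropy: EntropyStack, channel: int,
                           n_init: int = 10, seed: int = 0) -> list:
    """Fit one mixture per slice for a channel; failed slices yield None.

    All slices of the channel share one lock-step EM batch (slice z uses
    seed ``seed + z``, identical to fitting the slices one at a time), which
    keeps a whole stack's fitting inside a single vectorised loop.
    """
    nz = entropy.shape[0]
    fittable, supports, inits = [], [], []
    for z in range(nz):
        vals = entropy.values[z, :, :, channel].ravel()
        if vals.size < 100 or not np.isfinite(vals).all() or np.ptp(vals) == 0:
            continue
        fittable.append(z)
        supports.append(_bin_values(vals, FIT_BINS))
        inits.append(_em_init(vals, n_init, seed + z))
    fits: list = [None] * nz
    if not fittable:
        return fits
    # pad per-slice histogram supports to a common width with zero counts
    width = max(c.size for c, _ in supports)
    x_rows = np.zeros((len(fittable) * n_init, width))
    c_rows = np.zeros_like(x_rows)
    for s, (centres, counts) in enumerate(supports):
        sl = slice(s * n_init, (s + 1) * n_init)
        x_rows[sl, :centres.size] = centres
        x_rows[sl, centres.size:] = centres[0]
        c_rows[sl, :counts.size] = counts
    means = np.concatenate([i[0] for i in inits])
    variances = np.concatenate([i[1] for i in inits])
    weights = np.concatenate([i[2] for i in inits])
    means, variances, weights, loglik = _em_batch(x_rows, c_rows, means,
                                                  variances, weights)
    for s, z in enumerate(fittable):
        sl = slice(s * n_init, (s + 1) * n_init)
        w, m, v, ll = weights[sl], means[sl], variances[sl], loglik[sl]
        valid = (w.min(axis=1) > 0)
        if not valid.any():
            continue
        ll = np.where(valid, ll, -np.inf)
        best = int(np.argmax(ll))
        order = np.argsort(m[best], kind="stable")
        fits[z] = Mixture1D(tuple(w[best][order]), tuple(m[best][order]),
                            tuple(v[best][order]), float(ll[best]))
    return fits


def fit_mixture_pooled(entropy: EntropyStack, channel: int,
                       n_init: int = 10, seed: int = 0) -> Mixture1D:
    """Fit a single mixture to all slices of a channel jointly (optional mode)."""
    return fit_mixture3(entropy.values[..., channel].ravel(), n_init=n_init,
                        seed=seed)


def select_reference_image(fits: list) -> int:
    """Pick the slice whose fit has the greatest sum of paired mean distances.

    Score is \\|mu1-mu2\\| + \\|mu1-mu3\\| + \\|mu2-mu3\\|; a well-separated fit marks a
    slice where all three populations are represented.  Ties go to the lowest
    slice index; entries of ``fits`` that are None (failed slices) are skipped.
    """
    best_idx, best_score = None, -np.inf
    for i, fit in enumerate(fits):
        if fit is None:
            continue
        m1, m2, m3 = fit.means
        score = abs(m1 - m2) + abs(m1 - m3) + abs(m2 - m3)
        if score > best_score:
            best_idx, best_score = i, score
    if best_idx is None:
        raise ValueError("no successful mixture fit in the stack")
    return best_idx


@dataclass
class LabelDensitySet:
    """Densities pi_l over the observation space, one per segmentation label.

    ``densities[l]`` maps an (..., nc) observation array to density values;
    label order is (background, tumour, CAF) for two channels and
    (background, foreground, intermediate) for one channel.
    """

    densities: tuple[Callable, Callable, Callable]
    eps: float
    n_channels: int

    def evaluate(self, obs: np.ndarray) -> np.ndarray:
        """Evaluate all three densities; returns (..., 3)."""
        obs = np.asarray(obs, dtype=np.float64)
        if obs.shape[-1] != self.n_channels:
            raise ValueError("observation channel count mismatch")
        return np.stack([d(obs) for d in self.densities], axis=-1)


def _role_mixture(mix: Mixture1D, roles: ChannelRoles):
    """Renormalized background + out-of-focus mixture m_c of one channel."""
    w_bg = mix.weights[roles.bg_idx]
    w_oof = mix.weights[roles.oof_idx]
    total = w_bg + w_oof
    if total < 1e-6:
        raise ValueError("background + out-of-focus weight below 1e-6")

    def m(x: np.ndarray) -> np.ndarray:
        return (w_bg * mix.component_pdf(roles.bg_idx, x)
                + w_oof * mix.component_pdf(roles.oof_idx, x)) / total

    return m


def build_label_densities(red_mix: Mixture1D, green_mix: Mixture1D,
                          eps: float = DEFAULT_EPS) -> LabelDensitySet:
    """Build the three bivariate label densities from the two channel fits."""
    red_roles = assign_roles(red_mix)
    green_roles = assign_roles(green_mix)
    m_r = _role_mixture(red_mix, red_roles)
    m_g = _role_mixture(green_mix, green_roles)
    f_r_if = lambda x: red_mix.component_pdf(red_roles.if_idx, x)
    f_g_if = lambda x: green_mix.component_pdf(green_roles.if_idx, x)

    def pi_t(obs):
        return f_r_if(obs[..., 0]) * m_g(obs[..., 1])

    def pi_c(obs):
        return m_r(obs[..., 0]) * f_g_if(obs[..., 1])

    def pi_b(obs):
        return m_r(obs[..., 0]) * m_g(obs[..., 1])

    return LabelDensitySet((pi_b, pi_t, pi_c), eps=eps, n_channels=2)


def build_label_densities_1ch(mix: Mixture1D,
                              eps: float = DEFAULT_EPS) -> LabelDensitySet:
    """Single-channel label densities: one Gaussian component per label.

    Label order: background (lowest-mean component), foreground (highest
    mean, the textured structure), intermediate (middle, out-of-focus
    halo).
    """
    roles = assign_roles(mix)

    def make(idx):
        return lambda obs: mix.component_pdf(idx, obs[..., 0])

    return LabelDensitySet((make(roles.bg_idx), make(roles.if_idx),
                            make(roles.oof_idx)), eps=eps, n_channels=1)


@dataclass
class UnaryField:
    """Unary potentials u[z, y, x, label] = -log max(pi_l(z_i), eps)."""

    u: np.ndarray

    def __post_init__(self) -> None:
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError("unary field must have axes (z, y, x, label=3)")
        if not np.isfinite(self.u).all():
            raise ValueError("unary potentials must be finite")

    @property
    def shape(self):
        return self.u.shape


def unary_potentials(entropy: EntropyStack,
                     densities: LabelDensitySet) -> UnaryField:
    """Evaluate u_{i;l} = -log(max(pi_l(z_i), eps)) for every voxel and label."""
    obs = entropy.values
    if obs.shape[-1] != densities.n_channels:
        raise ValueError("entropy stack channel count does not match densities")
    pi = densities.evaluate(obs)
    return UnaryField(-np.log(np.maximum(pi, densities.eps)))
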