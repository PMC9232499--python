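"""Independent brute-force oracles used to cross-check the fitted models.

These deliberately avoid the estimators under test: the likelihood surfaces
are maximized by dense grid evaluation (coarse scan + local refinement at
0.001 rad in the location and 0.01 in the concentration), and geometric
quantities are computed from first principles.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0


def _vm_loglik_grid(thetas: np.ndarray, mus: np.ndarray, kappas: np.ndarray) -> np.ndarray:
    """logL matrix (len(kappas), len(mus)) of the von Mises family."""
    # sum_n cos(theta_n - mu) = C cos(mu) + S sin(mu)
    C, S = np.cos(thetas).sum(), np.sin(thetas).sum()
    n = len(thetas)
    proj = C * np.cos(mus) + S * np.sin(mus)  # (m,)
    norm = n * (np.log(2 * np.pi) + np.log(i0(kappas)))  # (k,)
    return kappas[:, None] * proj[None, :] - norm[:, None]


def _bimodal_loglik_grid(thetas, mus, kappas) -> np.ndarray:
    """logL matrix of the antipodal equal-weight von Mises mixture."""
    cosd = np.cos(thetas[None, :] - mus[:, None])  # (m, n)
    n = len(thetas)
    out = np.empty((len(kappas), len(mus)))
    norm = n * (np.log(2 * np.pi) + np.log(i0(kappas)))
    for i, k in enumerate(kappas):
        x = k * cosd
        ax = np.abs(x)
        logcosh = ax + np.log1p(np.exp(-2 * ax)) - np.log(2)
        out[i] = logcosh.sum(axis=1) - norm[i]
    return out


def grid_max_loglik(
    thetas: np.ndarray,
    family: str,
    kappa_max: float = 20.0,
    mu_step: float = 0.001,
    kappa_step: float = 0.01,
) -> float:
    """Maximum log-likelihood of a family by coarse-to-fine grid search.

    ``family`` is ``"flock"`` (von Mises), ``"stream"`` (antipodal mixture)
    or ``"swarm"`` (closed form, no search).
    """
    thetas = np.asarray(thetas, float)
    if family == "swarm":
        return -len(thetas) * np.log(2 * np.pi)
    period = 2 * np.pi if family == "flock" else np.pi
    grid_fn = _vm_loglik_grid if family == "flock" else _bimodal_loglik_grid

    mus = np.arange(0.0, period, 0.02)
    kappas = np.arange(0.0, kappa_max + 1e-12, 0.1)
    L = grid_fn(thetas, mus, kappas)
    ik, im = np.unravel_index(np.argmax(L), L.shape)
    mu_c, ka_c = mus[im], kappas[ik]

    mus_f = np.arange(mu_c - 0.04, mu_c + 0.04 + 1e-12, mu_step)
    kappas_f = np.arange(max(ka_c - 0.2, 0.0), min(ka_c + 0.2, kappa_max) + 1e-12, kappa_step)
    Lf = grid_fn(thetas, mus_f, kappas_f)
    return float(max(L.max(), Lf.max()))


def max_chord_angle_deg(points_xy: np.ndarray) -> float:
    """All-pairs longest-chord orientation in [0, 180) degrees (brute force)."""
    pts = np.asarray(points_xy, float)
    iu, ju = np.triu_indices(len(pts), 1)
    d = pts[ju] - pts[iu]
    dist2 = d[:, 0] ** 2 + d[:, 1] ** 2
    dmax = dist2.max()
    ties = dist2 >= dmax * (1 - 1e-9)
    ang = np.degrees(np.arctan2(d[ties, 1], d[ties, 0])) % 180.0
    return float(ang.min())


def random_heading_sample(rng: np.random.Generator, n: int) -> np.ndarray:
    """A heading sample from a randomly chosen generating law (for oracles)."""
    kind = rng.integers(0, 3)
    if kind == 0:
        th = rng.uniform(0, 2 * np.pi, n)
    elif kind == 1:
        th = rng.vonmises(rng.uniform(0, 2 * np.pi), rng.uniform(0.5, 3.0), n)
    else:
        mu = rng.uniform(0, np.pi)
        kap = rng.uniform(0.5, 3.0)
        lane = rng.integers(0, 2, n)
        th = mu + np.pi * lane + rng.vonmises(0.0, kap, n)
    return np.mod(th, 2 * np.pi)
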