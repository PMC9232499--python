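"""Likelihood classification of collective-motion patterns.

A zone's heading sample (angle velocities pooled over frames) is fit with
three candidate circular distributions:

* **swarm** — uniform on the circle: every direction equally probable; no
  free parameters.
* **flock** — unimodal von Mises ``f(theta; mu, kappa)``: one preferred
  direction; 2 free parameters.
* **stream** — equal-weight antipodal von Mises mixture
  ``(f(theta; mu, kappa) + f(theta; mu + pi, kappa)) / 2``: two equal but
  opposite directions sharing one concentration; 2 free parameters
  (axis ``mu`` mod pi, and ``kappa``).

Models are compared by Akaike weights ``AW_i = exp(-Delta_i/2) /
sum_j exp(-Delta_j/2)`` with ``Delta_i = AIC_i - min AIC``; the zone label
is the family with the largest weight.  Both directional families carry the
same parameter count, so the stream/flock decision is purely
likelihood-driven while the swarm/directional decision trades likelihood
against the 2-parameter penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import i0e, i1e

__all__ = [
    "HeadingSample",
    "DistributionModel",
    "PatternFit",
    "KDEstimate",
    "KAPPA_MAX",
    "FAMILIES",
    "loglik_uniform",
    "fit_unimodal",
    "fit_bimodal",
    "akaike_weights",
    "classify_pattern",
    "circular_kde",
    "angle_histogram",
    "vonmises_logpdf",
    "bimodal_logpdf",
]

#: Upper clip for the fitted concentration; keeps likelihoods finite for
#: degenerate (delta-like) samples.
KAPPA_MAX = 500.0

#: Pattern labels in tie-break (parsimony-first) order.
FAMILIES = ("swarm", "stream", "flock")

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class HeadingSample:
    """A set of per-step headings (radians in [0, 2pi)) from one zone."""

    thetas: np.ndarray
    zone_id: str = ""

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=float).ravel()
        if self.thetas.size < 1:
            raise ValueError("heading sample must contain at least one angle")
        if not np.all(np.isfinite(self.thetas)):
            raise ValueError("headings must be finite")
        if np.any(self.thetas < 0) or np.any(self.thetas >= 2 * np.pi):
            raise ValueError("headings must lie in [0, 2pi)")

    @property
    def n(self) -> int:
        return self.thetas.size


@dataclass
class DistributionModel:
    """One fitted candidate family with its maximized log-likelihood."""

    family: str  # 'swarm' | 'flock' | 'stream'
    log_likelihood: float
    k_free: int
    mu: float | None = None  # mean direction (flock) or axis mod pi (stream)
    kappa: float | None = None
    kappa_clipped: bool = False


@dataclass
class PatternFit:
    """Model-comparison result for one zone."""

    zone_id: str
    n: int
    fits: dict[str, DistributionModel] = field(default_factory=dict)
    aic: dict[str, float] = field(default_factory=dict)
    delta_aic: dict[str, float] = field(default_factory=dict)
    akaike_weights: dict[str, float] = field(default_factory=dict)
    label: str | None = None
    insufficient_sample: bool = False

    def to_dict(self) -> dict:
        """JSON-ready summary (per zone: N, logL, AIC, AW, label, mu, kappa)."""
        return {
            "zone_id": self.zone_id,
            "n": self.n,
            "label": self.label,
            "insufficient_sample": self.insufficient_sample,
            "log_likelihood": {
                k: f.log_likelihood for k, f in self.fits.items()
            },
            "aic": dict(self.aic),
            "akaike_weights": dict(self.akaike_weights),
            "mu": {k: f.mu for k, f in self.fits.items()},
            "kappa": {k: f.kappa for k, f in self.fits.items()},
        }


@dataclass
class KDEstimate:
    """Circular kernel density estimate on a uniform grid over [0, 2pi)."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth_kappa: float


# ---------------------------------------------------------------------------
# von Mises building blocks (numerically stable for kappa up to KAPPA_MAX)
# ---------------------------------------------------------------------------

def _log_i0(kappa: float | np.ndarray):
    """log I0(kappa) via the exponentially scaled Bessel function."""
    return np.log(i0e(kappa)) + kappa


def vonmises_logpdf(theta: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    return kappa * np.cos(theta - mu) - LOG_2PI - _log_i0(kappa)


def _logcosh(x: np.ndarray) -> np.ndarray:
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)


def bimodal_logpdf(theta: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    # (f_vM(mu) + f_vM(mu+pi))/2 = cosh(kappa cos(theta-mu)) / (2 pi I0(kappa))
    return _logcosh(kappa * np.cos(theta - mu)) - LOG_2PI - _log_i0(kappa)


def _solve_kappa(rbar: float, kappa_max: float) -> tuple[float, bool]:
    """Invert the Bessel ratio A(kappa) = I1/I0 = rbar; clip at kappa_max."""
    if rbar <= 1e-12:  # antipodally balanced up to roundoff
        return 0.0, False

    def f(k: float) -> float:
        return i1e(k) / i0e(k) - rbar

    if f(kappa_max) <= 0.0:
        return kappa_max, True
    return float(brentq(f, 1e-12, kappa_max, xtol=1e-12, rtol=1e-14)), False


# ---------------------------------------------------------------------------
# family fits
# ---------------------------------------------------------------------------

def loglik_uniform(sample: HeadingSample) -> DistributionModel:
    """Swarm model: uniform density 1/(2pi); logL = -N ln(2pi) exactly."""
    return DistributionModel(
        family="swarm",
        log_likelihood=-sample.n * LOG_2PI,
        k_free=0,
    )


def fit_unimodal(
    sample: HeadingSample, kappa_max: float = KAPPA_MAX
) -> DistributionModel:
    """Flock model: maximum-likelihood von Mises fit.

    ``mu_hat`` is the direction of the mean resultant vector and
    ``kappa_hat`` solves ``I1(kappa)/I0(kappa) = Rbar`` (clipped to
    ``kappa_max`` for near-degenerate samples, e.g. all headings identical).
    An antipodally balanced sample has ``Rbar = 0``, giving ``kappa_hat = 0``
    and a log-likelihood equal to the uniform model's.
    """
    if sample.n < 2:
        raise ValueError("unimodal fit requires at least 2 headings")
    th = sample.thetas
    C = float(np.cos(th).sum())
    S = float(np.sin(th).sum())
    rbar = float(np.hypot(C, S) / sample.n)
    mu = float(np.mod(np.arctan2(S, C), 2 * np.pi))
    kappa, clipped = _solve_kappa(rbar, kappa_max)
    ll = float(vonmises_logpdf(th, mu, kappa).sum())
    return DistributionModel(
        family="flock",
        log_likelihood=ll,
        k_free=2,
        mu=mu,
        kappa=kappa,
        kappa_clipped=clipped,
    )


def fit_bimodal(
    sample: HeadingSample, kappa_max: float = KAPPA_MAX
) -> DistributionModel:
    """Stream model: antipodal equal-weight von Mises mixture MLE.

    The axis is initialized from the doubled-angle mean direction
    ``mu0 = arg(sum exp(2 i theta)) / 2`` and ``(mu, kappa)`` are then
    refined by bounded quasi-Newton maximization of the mixture
    log-likelihood, multi-started over concentrations so the global optimum
    is found on both diffuse and highly concentrated samples.  The reported
    ``mu`` is the axis, reduced mod pi.
    """
    if sample.n < 2:
        raise ValueError("bimodal fit requires at least 2 headings")
    th = sample.thetas
    n = sample.n
    c2 = float(np.cos(2 * th).sum())
    s2 = float(np.sin(2 * th).sum())
    mu0 = 0.5 * np.arctan2(s2, c2)

    def nll(p: np.ndarray) -> float:
        mu, kappa = p
        return -float(bimodal_logpdf(th, mu, kappa).sum())

    best: tuple[float, float, float] | None = None  # (nll, mu, kappa)
    # moment-style initial kappa from the doubled-angle resultant, plus a
    # ladder of starts; the profile in kappa can have a boundary optimum
    r2 = np.hypot(c2, s2) / n
    starts = {0.25, 1.0, 4.0, 16.0, 64.0, 256.0, max(2.0 * r2, 1e-3)}
    for k0 in starts:
        res = minimize(
            nll,
            x0=np.array([mu0, min(k0, kappa_max)]),
            method="L-BFGS-B",
            bounds=[(mu0 - np.pi / 2, mu0 + np.pi / 2), (0.0, kappa_max)],
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best[0]:
            best = (float(res.fun), float(res.x[0]), float(res.x[1]))
    # explicit boundary candidates
    for mu_c, k_c in ((mu0, 0.0), (mu0, kappa_max)):
        v = nll(np.array([mu_c, k_c]))
        if v < best[0]:
            best = (v, mu_c, k_c)
    ll, mu, kappa = -best[0], best[1], best[2]
    clipped = kappa >= kappa_max - 1e-9
    return DistributionModel(
        family="stream",
        log_likelihood=float(ll),
        k_free=2,
        mu=float(np.mod(mu, np.pi)),
        kappa=float(kappa),
        kappa_clipped=clipped,
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def akaike_weights(
    fits: dict[str, DistributionModel],
    n: int | None = None,
    zone_id: str = "",
    use_aicc: bool = False,
) -> PatternFit:
    """Compare fitted families by Akaike weights and label the pattern.

    ``AIC = 2 k - 2 logL`` (or the small-sample corrected AICc when
    ``use_aicc``); weights are ``exp(-Delta/2)`` normalized to 1.  Exact
    weight ties are broken toward the simpler explanation, in the order
    swarm > stream > flock.
    """
    if set(fits) != set(FAMILIES):
        raise ValueError(f"expected fits for {FAMILIES}, got {sorted(fits)}")
    for fam, f in fits.items():
        if not np.isfinite(f.log_likelihood):
            raise ValueError(f"{fam}: non-finite log-likelihood")
    if n is None:
        n = 0
    aic = {}
    for fam, f in fits.items():
        a = 2.0 * f.k_free - 2.0 * f.log_likelihood
        if use_aicc and n > f.k_free + 1:
            a += 2.0 * f.k_free * (f.k_free + 1) / (n - f.k_free - 1)
        aic[fam] = a
    amin = min(aic.values())
    delta = {fam: aic[fam] - amin for fam in FAMILIES}
    w = np.array([np.exp(-delta[fam] / 2.0) for fam in FAMILIES])
    w /= w.sum()
    weights = {fam: float(wi) for fam, wi in zip(FAMILIES, w)}
    label = FAMILIES[0]
    for fam in FAMILIES[1:]:
        if weights[fam] > weights[label]:
            label = fam
    return PatternFit(
        zone_id=zone_id,
        n=n,
        fits=dict(fits),
        aic=aic,
        delta_aic=delta,
        akaike_weights=weights,
        label=label,
    )


def classify_pattern(
    sample: HeadingSample,
    min_n: int = 30,
    kappa_max: float = KAPPA_MAX,
    use_aicc: bool = False,
) -> PatternFit:
    """Fit all three families to a zone's headings and label the zone.

    Samples smaller than ``min_n`` produce an "insufficient sample" result
    with a null label (no exception): with a handful of headings the Akaike
    comparison is meaningless.
    """
    if sample.n < min_n:
        return PatternFit(
            zone_id=sample.zone_id,
            n=sample.n,
            label=None,
            insufficient_sample=True,
        )
    fits = {
        "swarm": loglik_uniform(sample),
        "stream": fit_bimodal(sample, kappa_max),
        "flock": fit_unimodal(sample, kappa_max),
    }
    out = akaike_weights(fits, n=sample.n, zone_id=sample.zone_id, use_aicc=use_aicc)
    return out


# ---------------------------------------------------------------------------
# reporting helpers
# ---------------------------------------------------------------------------

def circular_kde(
    sample: HeadingSample,
    bandwidth_kappa: float = 8.0,
    n_grid: int = 360,
) -> KDEstimate:
    """Non-parametric circular density: mean of von Mises kernels.

    ``density(theta) = (1/N) sum_n f_vM(theta; theta_n, bandwidth_kappa)``.
    The kernel concentration plays the role of an (inverse) bandwidth; as it
    tends to 0 the estimate flattens to the uniform density 1/(2pi).  Used
    for display alongside the fitted families, never for classification.
    """
    if not bandwidth_kappa > 0:
        raise ValueError("bandwidth_kappa must be > 0")
    grid = np.linspace(0.0, 2 * np.pi, n_grid, endpoint=False)
    diff = grid[:, None] - sample.thetas[None, :]
    log_kernel = (
        bandwidth_kappa * np.cos(diff) - LOG_2PI - _log_i0(bandwidth_kappa)
    )
    density = np.exp(log_kernel).mean(axis=1)
    return KDEstimate(grid=grid, density=density, bandwidth_kappa=bandwidth_kappa)


def angle_histogram(
    sample: HeadingSample, n_bins: int = 24
) -> tuple[np.ndarray, np.ndarray]:
    """Rose-plot counts over equal-width bins of [0, 2pi).

    Returns ``(counts, bin_edges)`` with ``counts.sum() == N``; an angle just
    below 2pi lands in the last bin.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    edges = np.linspace(0.0, 2 * np.pi, n_bins + 1)
    counts, _ = np.histogram(sample.thetas, bins=edges)
    return counts, edges
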