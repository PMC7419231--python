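"""Divergence dating from Ks distributions and ancestor placement.

Synonymous substitution rates (Ks) between syntelog pairs are modal
around divergence events, so a Gaussian mixture fitted to ln(Ks) — after
discarding values <= 0.001, which are dominated by allelic noise —
separates the divergence signals.  The number of components is chosen by
the Bayesian information criterion (BIC = p ln n - 2 loglik with
p = 3k - 1 free parameters, minimized) and the fit is checked with a
chi-square goodness-of-fit test on binned counts.  A component mean
converts to an age under a strict molecular clock, T = Ks / (2 r), with
r the synonymous substitution rate per site per year; no default rate is
assumed.

Independently, the median genome and its three per-leaf DCJ distances
yield a rooted ultrametric tree: the root sits on the median-to-outgroup
edge at the offset x solving d_out - x = x + mean(d_in1, d_in2), which
equalizes root-to-leaf depths in DCJ units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
import numpy as np
from scipy import stats

from .median_solver import MedianResult

__all__ = [
    "KsSample",
    "KsMixtureFit",
    "AncestorPlacement",
    "fit_lnks_mixture",
    "chi2_goodness",
    "peak_to_time",
    "place_ancestor",
]

KS_FILTER = 0.001


@dataclass
class KsSample:
    """Per-pair Ks values for one genome (or subgenome) comparison."""

    values: np.ndarray
    pair_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def lnks(self, min_ks: float = KS_FILTER) -> tuple[np.ndarray, int]:
        """ln of retained Ks values (> min_ks) and the count discarded."""
        finite = self.values[np.isfinite(self.values)]
        keep = finite[finite > min_ks]
        return np.log(keep), self.values.size - keep.size


@dataclass
class KsMixtureFit:
    """Gaussian mixture on ln(Ks): parameters, likelihood and BIC trace."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float
    bic: float
    bic_trace: list[float]
    chosen_by: str = "bic"
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "means": list(map(float, self.means)),
            "sds": list(map(float, self.sds)),
            "weights": list(map(float, self.weights)),
            "loglik": self.loglik,
            "bic": self.bic,
            "bic_trace": self.bic_trace,
            "chosen_by": self.chosen_by,
            "n": self.n,
        }


def _em_1d(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    jitter: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """One EM run for a k-component 1-D Gaussian mixture.

    Quantile-based means (optionally jittered), pooled initial sd,
    uniform weights.  The log-likelihood is asserted non-decreasing.
    """
    n = x.size
    means = np.quantile(x, (np.arange(k) + 0.5) / k)
    sd0 = max(x.std(), 1e-3)
    if jitter:
        means = means + jitter * sd0 * rng.standard_normal(k)
    sds = np.full(k, sd0)
    weights = np.full(k, 1.0 / k)
    prev = -np.inf
    for _ in range(max_iter):
        # E-step in log space
        logp = (
            np.log(weights)[None, :]
            - 0.5 * math.log(2 * math.pi)
            - np.log(sds)[None, :]
            - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        loglik = float(lse.sum())
        assert loglik >= prev - 1e-7 * max(1.0, abs(prev)), "EM log-likelihood decreased"
        resp = np.exp(logp - lse[:, None])
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, 1e-12))
        if loglik - prev < tol * max(1.0, abs(loglik)):
            prev = loglik
            break
        prev = loglik
    return means, sds, weights, prev


def fit_lnks_mixture(
    sample: KsSample,
    k_max: int = 4,
    seed: int = 0,
    min_values: int = 50,
    restarts: int = 3,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> KsMixtureFit:
    """Fit 1..k_max Gaussian components to ln(Ks) and select k by BIC.

    Deterministic for a fixed seed: the first restart uses exact
    quantile initialization, later restarts jitter it with seed-derived
    noise; the best-likelihood run per k wins, and the k minimizing BIC
    (smallest k on ties) is returned.  In one dimension the quantile
    start is already near the optimum, so a few restarts and a modest
    iteration cap suffice; over-parameterized k never fully converges
    (components trade vanishing mass indefinitely) and is cut off by
    the cap, which only depresses a log-likelihood that BIC penalizes
    away regardless.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    x, dropped = sample.lnks()
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "Ks filter: discarded %d values <= %.3g", dropped, KS_FILTER
        )
    if x.size < min_values:
        raise ValueError(
            f"need at least {min_values} Ks values after filtering, got {x.size}"
        )
    n = x.size
    fits = []
    for k in range(1, k_max + 1):
        if k == 1:
            mu, sd = float(x.mean()), float(max(x.std(), 1e-6))
            loglik = float(stats.norm.logpdf(x, mu, sd).sum())
            best = (np.array([mu]), np.array([sd]), np.array([1.0]), loglik)
        else:
            best = None
            for r in range(restarts):
                rng = np.random.default_rng((seed, k, r))
                res = _em_1d(x, k, rng, jitter=0.0 if r == 0 else 0.3, tol=tol, max_iter=max_iter)
                if best is None or res[3] > best[3]:
                    best = res
        p = 3 * k - 1
        bic = p * math.log(n) - 2 * best[3]
        fits.append((k, best, bic))
    best_k, best_fit, best_bic = min(fits, key=lambda f: (f[2], f[0]))
    means, sds, weights, loglik = best_fit
    order = np.argsort(means)
    return KsMixtureFit(
        k=best_k,
        means=np.asarray(means)[order],
        sds=np.asarray(sds)[order],
        weights=np.asarray(weights)[order],
        loglik=loglik,
        bic=best_bic,
        bic_trace=[f[2] for f in fits],
        n=n,
    )


def _mixture_cdf(fit: KsMixtureFit, edges: np.ndarray) -> np.ndarray:
    return sum(
        w * stats.norm.cdf(edges, mu, sd)
        for w, mu, sd in zip(fit.weights, fit.means, fit.sds)
    )


def chi2_goodness(
    fit: KsMixtureFit, sample: KsSample, n_bins: int = 30
) -> tuple[float, int, float]:
    """Chi-square observed-vs-expected check of a fitted ln(Ks) mixture.

    Bins with expected count < 5 are merged with their neighbour;
    degrees of freedom = bins - 1 - (3k - 1).
    """
    x, _ = sample.lnks()
    if x.size == 0:
        raise ValueError("empty sample after Ks filtering")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    obs, _ = np.histogram(x, bins=edges)
    cdf = _mixture_cdf(fit, edges)
    cdf[0], cdf[-1] = 0.0, 1.0  # open tails absorb mass outside the range
    exp = np.diff(cdf) * x.size
    # merge low-expectation bins left to right
    mo: list[float] = []
    me: list[float] = []
    co = ce = 0.0
    for o, e in zip(obs, exp):
        co += o
        ce += e
        if ce >= 5:
            mo.append(co)
            me.append(ce)
            co = ce = 0.0
    if co or ce:
        if me:
            mo[-1] += co
            me[-1] += ce
        else:
            mo.append(co)
            me.append(ce)
    if len(mo) < 3:
        raise ValueError("fewer than 3 bins with adequate expected counts")
    stat = float(sum((o - e) ** 2 / e for o, e in zip(mo, me)))
    dof = len(mo) - 1 - (3 * fit.k - 1)
    if dof < 1:
        raise ValueError("non-positive degrees of freedom; use more bins")
    p = float(stats.chi2.sf(stat, dof))
    return stat, dof, p


def peak_to_time(fit: KsMixtureFit, clock_rate: float | None) -> list[float]:
    """Component ages in Ma under a strict clock: T = Ks / (2 r).

    ``clock_rate`` is the synonymous substitution rate per site per
    year; it must be supplied explicitly — published rates differ by
    lineage and calibration, so there is no defensible default.
    """
    if clock_rate is None or clock_rate <= 0:
        raise ValueError(
            "a positive clock_rate (substitutions/site/year) must be supplied "
            "explicitly; no default is assumed"
        )
    return [float(math.exp(mu) / (2.0 * clock_rate) / 1e6) for mu in fit.means]


@dataclass
class AncestorPlacement:
    """Ultrametric root placement on the median-to-outgroup edge."""

    per_leaf_distances: dict[str, int]
    outgroup: str
    root_offset: float
    leaf_depths: dict[str, float]
    newick: str


def place_ancestor(result: MedianResult, outgroup_leaf: str) -> AncestorPlacement:
    """Root the three-leaf star at the clock-consistent point.

    With per-leaf DCJ distances (d_in1, d_in2, d_out), the root lies on
    the median-outgroup edge at x = (d_out - mean(d_in1, d_in2)) / 2, so
    that the outgroup depth d_out - x equals the ingroup depth
    x + mean(d_in); the two ingroup branch lengths are equalized to
    their mean.  Offsets outside [0, d_out] are clamped with a warning
    (non-clock-like data).
    """
    labels = list(result.leaf_labels)
    if outgroup_leaf not in labels:
        raise ValueError(f"outgroup {outgroup_leaf!r} not among leaves {labels}")
    dist = dict(zip(labels, result.per_leaf))
    d_out = dist[outgroup_leaf]
    ingroup = sorted(l for l in labels if l != outgroup_leaf)
    mean_in = (dist[ingroup[0]] + dist[ingroup[1]]) / 2.0
    x = (d_out - mean_in) / 2.0
    if not 0.0 <= x <= d_out:
        warnings.warn(
            f"clock-consistent root offset {x:.3g} lies outside [0, {d_out}]; "
            "clamping (distances are not clock-like)",
            stacklevel=2,
        )
        x = min(max(x, 0.0), float(d_out))
    depth = d_out - x
    newick = (
        f"(({ingroup[0]}:{mean_in:g},{ingroup[1]}:{mean_in:g})median:{x:g},"
        f"{outgroup_leaf}:{depth:g})root;"
    )
    return AncestorPlacement(
        per_leaf_distances=dist,
        outgroup=outgroup_leaf,
        root_offset=x,
        leaf_depths={l: depth for l in labels},
        newick=newick,
    )
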