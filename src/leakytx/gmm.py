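"""Two-component Gaussian-mixture classification of log2(TPM) values.

The model: detected protein-coding transcripts in a homogeneous cell
population fall into two classes — an actively transcribed, higher-expressed
class and a leakily transcribed, lower-expressed class — whose log2(TPM)
values form a two-component Gaussian mixture (a dominant right peak with a
low "left shoulder").  Fitting the mixture by expectation maximization
yields, for each detected gene, the posterior probability P(active) of
belonging to the higher-mean component.  Genes are called ``active`` when
P(active) > 0.67, ``leaky`` when P(active) < 0.33 and ``undetermined``
in between.

Datasets whose log2(TPM) distribution is unimodal (no left shoulder) or
needs a third component are not classifiable under the two-class model and
are excluded; :func:`assess_eligibility` automates that decision with BIC
model selection over k = 1, 2, 3 plus a component-separation check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .io import ExpressionDataset, GeneUniverse, coding_log2_values

__all__ = [
    "GmmFit",
    "PosteriorCall",
    "GmmDatasetResult",
    "EmError",
    "fit_two_component_gmm",
    "posterior_active",
    "classify_by_posterior",
    "assess_eligibility",
    "gmm_classify_dataset",
]

_LOG_2PI = math.log(2.0 * math.pi)
_VAR_FLOOR = 1e-6

#: Default posterior thresholds: active above, leaky below, undetermined between.
P_ACTIVE_UPPER = 0.67
P_ACTIVE_LOWER = 0.33


class EmError(RuntimeError):
    """EM failed in every restart (non-convergence or variance collapse).

    Carries the log-likelihood trace of the last attempted restart in
    ``trace`` for diagnosis.
    """

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


class _Collapse(RuntimeError):
    """Internal: a component's variance fell below the floor."""


@dataclass
class GmmFit:
    """Parameters of a fitted two-component univariate Gaussian mixture.

    Components are identified by their means: ``active`` is always the
    higher-mean component.  ``loglik_trace`` records the EM objective of the
    winning restart and is non-decreasing by construction.
    """

    mu_leaky: float
    mu_active: float
    sigma_leaky: float
    sigma_active: float
    w_leaky: float
    w_active: float
    loglik_trace: list[float]
    converged: bool
    n_points: int
    eligibility: str | None = None

    def __post_init__(self) -> None:
        if abs(self.w_leaky + self.w_active - 1.0) > 1e-12:
            raise ValueError("mixing weights must sum to 1")
        if not self.mu_active > self.mu_leaky:
            raise ValueError("active component must have the higher mean")
        if min(self.sigma_leaky, self.sigma_active) <= 0:
            raise ValueError("component s.d.s must be positive")


@dataclass(frozen=True)
class PosteriorCall:
    """Per-gene posterior classification within one dataset."""

    gene_id: str
    log2_tpm: float
    p_active: float
    p_leaky: float
    label: str  # active | leaky | undetermined

    def __post_init__(self) -> None:
        if abs(self.p_active + self.p_leaky - 1.0) > 1e-12:
            raise ValueError("p_active + p_leaky must equal 1")


@dataclass
class GmmDatasetResult:
    """Eligibility verdict plus (for eligible datasets) fit and calls."""

    dataset_id: str
    eligibility: str  # two_component | three_component | unimodal
    fit: GmmFit | None
    calls: list[PosteriorCall]

    @property
    def call_map(self) -> dict[str, PosteriorCall]:
        return {c.gene_id: c for c in self.calls}

    @property
    def eligible(self) -> bool:
        return self.eligibility == "two_component"


def _log_weighted_density(
    x: np.ndarray, w: np.ndarray, mu: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """(n, k) matrix of log w_k + log N(x_i; mu_k, sigma_k)."""
    z = (x[:, None] - mu[None, :]) / sigma[None, :]
    return np.log(w)[None, :] - np.log(sigma)[None, :] - 0.5 * _LOG_2PI - 0.5 * z * z


def _check_values(values: Sequence[float] | np.ndarray, min_n: int = 50) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if x.std() <= 0:
        raise ValueError("values have zero spread; nothing to fit")
    return x


def _init_params(
    x: np.ndarray, k: int, rng: np.random.Generator, perturb: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quantile-split initialization: k equal-size blocks of the sorted data."""
    xs = np.sort(x)
    blocks = np.array_split(xs, k)
    sd_all = x.std()
    mu = np.array([b.mean() for b in blocks])
    sigma = np.array([max(b.std(), 0.05 * sd_all) for b in blocks])
    w = np.array([len(b) / x.size for b in blocks])
    if perturb:
        mu = mu + rng.normal(0.0, 0.25 * sd_all, size=k)
        sigma = sigma * rng.uniform(0.8, 1.25, size=k)
        w = np.clip(w + rng.uniform(-0.1, 0.1, size=k), 0.05, None)
        w = w / w.sum()
    return w, mu, sigma


def _run_em(
    x: np.ndarray,
    w: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    """Plain EM for a univariate Gaussian mixture with free weights/means/variances.

    Responsibilities are computed in log space (log-sum-exp); the iteration
    stops when the relative log-likelihood gain per step falls below ``tol``.
    Raises :class:`_Collapse` if any component variance drops below the floor.
    """
    n = x.size
    trace: list[float] = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        log_wd = _log_weighted_density(x, w, mu, sigma)
        top = log_wd.max(axis=1)
        resp = np.exp(log_wd - top[:, None])
        denom = resp.sum(axis=1)
        ll = float((top + np.log(denom)).sum())
        trace.append(ll)
        if ll - prev < tol * (abs(ll) + 1.0) and len(trace) > 1:
            converged = True
            break
        prev = ll
        resp /= denom[:, None]
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            raise _Collapse("a component lost all responsibility")
        w = nk / n
        mu = resp.T @ x / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        if np.any(var < _VAR_FLOOR):
            raise _Collapse("component variance collapsed below floor")
        sigma = np.sqrt(var)
    return w, mu, sigma, trace, converged


def _fit_k_component(
    x: np.ndarray,
    k: int,
    seed: int,
    tol: float,
    max_iter: int,
    n_restarts: int,
    require_convergence: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    """Best-of-restarts EM fit for a k-component mixture.

    Restart 0 uses the deterministic quantile-split initialization; later
    restarts perturb it with the seeded generator.  Returns the restart with
    the highest final log-likelihood; with ``require_convergence`` only
    converged restarts are candidates.  Raises :class:`EmError` if every
    restart fails.
    """
    if k == 1:
        mu = np.array([x.mean()])
        sigma = np.array([x.std()])
        if sigma[0] <= 0:
            raise EmError("zero variance for single-component fit")
        w = np.array([1.0])
        lw = _log_weighted_density(x, w, mu, sigma)
        ll = float(logsumexp(lw, axis=1).sum())
        return w, mu, sigma, [ll], True

    rng = np.random.default_rng(seed)
    best = None
    last_trace: list[float] = []
    failures: list[str] = []
    for restart in range(n_restarts):
        w0, mu0, sigma0 = _init_params(x, k, rng, perturb=restart > 0)
        try:
            w, mu, sigma, trace, converged = _run_em(x, w0, mu0, sigma0, tol, max_iter)
        except _Collapse as exc:
            failures.append(str(exc))
            continue
        last_trace = trace
        if require_convergence and not converged:
            failures.append(f"restart {restart}: no convergence in {max_iter} iterations")
            continue
        if best is None or trace[-1] > best[3][-1]:
            best = (w, mu, sigma, trace, converged)
    if best is None:
        raise EmError(
            f"EM failed in all {n_restarts} restarts for k={k}: "
            + "; ".join(failures),
            trace=last_trace,
        )
    return best


def fit_two_component_gmm(
    values: Sequence[float] | np.ndarray,
    seed: int,
    tol: float = 1e-8,
    max_iter: int = 2000,
    n_restarts: int = 5,
) -> GmmFit:
    """Fit the two-component Gaussian mixture to log2(TPM) values by EM.

    Parameters
    ----------
    values
        log2(TPM) of detected coding genes (at least 50 finite values with
        positive spread).
    seed
        Seeds the restart perturbations; the first restart is deterministic.
    tol
        Relative log-likelihood gain below which EM is declared converged.
    max_iter, n_restarts
        Iteration cap per restart and number of restarts; the best converged
        restart by final log-likelihood wins.

    Returns a :class:`GmmFit` with components ordered so that ``active`` is
    the higher-mean component.  The eligibility field is left unset; use
    :func:`assess_eligibility` for the k-selection verdict.
    """
    x = _check_values(values)
    w, mu, sigma, trace, converged = _fit_k_component(
        x, 2, seed, tol, max_iter, n_restarts
    )
    order = np.argsort(mu)
    lo, hi = order[0], order[1]
    return GmmFit(
        mu_leaky=float(mu[lo]),
        mu_active=float(mu[hi]),
        sigma_leaky=float(sigma[lo]),
        sigma_active=float(sigma[hi]),
        w_leaky=float(w[lo]),
        w_active=float(w[hi]),
        loglik_trace=[float(v) for v in trace],
        converged=converged,
        n_points=int(x.size),
    )


def posterior_active(fit: GmmFit, x: float | np.ndarray) -> float | np.ndarray:
    """P(active | x): posterior probability of the higher-mean component.

    Computed in log space for numerical stability:
    ``w_a N(x; mu_a, s_a) / [w_l N(x; mu_l, s_l) + w_a N(x; mu_a, s_a)]``.
    """
    xv = np.asarray(x, dtype=float)
    za = (xv - fit.mu_active) / fit.sigma_active
    zl = (xv - fit.mu_leaky) / fit.sigma_leaky
    log_a = math.log(fit.w_active) - math.log(fit.sigma_active) - 0.5 * za * za
    log_l = math.log(fit.w_leaky) - math.log(fit.sigma_leaky) - 0.5 * zl * zl
    p = np.exp(log_a - np.logaddexp(log_a, log_l))
    return float(p) if np.isscalar(x) or xv.ndim == 0 else p


def classify_by_posterior(
    p_active: float,
    lower: float = P_ACTIVE_LOWER,
    upper: float = P_ACTIVE_UPPER,
) -> str:
    """Label a gene from its P(active): strict thresholds, boundary -> undetermined."""
    if not 0.0 <= p_active <= 1.0:
        raise ValueError(f"p_active must lie in [0, 1], got {p_active}")
    if not lower <= upper:
        raise ValueError("lower threshold must not exceed upper threshold")
    if p_active > upper:
        return "active"
    if p_active < lower:
        return "leaky"
    return "undetermined"


def assess_eligibility(
    values: Sequence[float] | np.ndarray,
    seed: int,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 3,
    delta_bic: float = 10.0,
    separation_factor: float = 1.0,
) -> str:
    """Decide whether a dataset's log2(TPM) distribution supports the 2-class model.

    Fits k = 1, 2, 3 component mixtures and selects k by BIC
    (``BIC = p ln n − 2 logL`` with p = 3k − 1 free parameters):

    * k = 1 wins                         -> ``unimodal``
    * k = 3 wins by more than ``delta_bic`` over k = 2 -> ``three_component``
    * otherwise ``two_component``, unless the 2-component fit's means are
      closer than ``separation_factor`` times the larger component s.d.
      (no discernible left shoulder)     -> ``unimodal``

    Model-selection fits use a looser tolerance and iteration cap than the
    final classification fit, and the best final log-likelihood is accepted
    even without formal convergence: the BIC decision operates on margins of
    tens to hundreds of units, far above the truncation error.
    """
    x = _check_values(values)
    n = x.size

    def bic(ll: float, k: int) -> float:
        return (3 * k - 1) * math.log(n) - 2.0 * ll

    fits: dict[int, tuple] = {}
    bics: dict[int, float] = {}
    for k in (1, 2, 3):
        try:
            fit = _fit_k_component(
                x, k, seed + k, tol, max_iter, n_restarts,
                require_convergence=False,
            )
        except EmError:
            bics[k] = math.inf
            continue
        fits[k] = fit
        bics[k] = bic(fit[3][-1], k)
    if all(math.isinf(b) for b in bics.values()):
        raise EmError("mixture fitting failed for every k in {1, 2, 3}")

    best_k = min(bics, key=lambda k: bics[k])
    if best_k == 1:
        return "unimodal"
    if best_k == 3 and bics[2] - bics[3] > delta_bic:
        return "three_component"
    if 2 not in fits:
        return "unimodal"
    _, mu, sigma, _, _ = fits[2]
    if abs(mu[1] - mu[0]) < separation_factor * float(sigma.max()):
        return "unimodal"
    return "two_component"


def gmm_classify_dataset(
    ds: ExpressionDataset,
    universe: GeneUniverse,
    seed: int,
    lower: float = P_ACTIVE_LOWER,
    upper: float = P_ACTIVE_UPPER,
    eligibility: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    n_restarts: int = 5,
) -> GmmDatasetResult:
    """Classify every detected coding gene of a dataset by GMM posterior.

    Genes with TPM = 0 are never classified (they are "not detected").
    If the dataset is not eligible for the two-class model (unimodal or
    three-component distribution) the verdict is returned with no calls.
    ``eligibility`` can inject a precomputed or manually curated verdict,
    bypassing :func:`assess_eligibility`.
    """
    pairs = coding_log2_values(ds, universe)
    x = np.array([v for _, v in pairs], dtype=float)
    verdict = eligibility or assess_eligibility(x, seed, tol=tol, max_iter=max_iter)
    if verdict != "two_component":
        return GmmDatasetResult(ds.dataset_id, verdict, None, [])
    fit = fit_two_component_gmm(
        x, seed, tol=tol, max_iter=max_iter, n_restarts=n_restarts
    )
    fit.eligibility = verdict
    p = posterior_active(fit, x)
    calls = [
        PosteriorCall(
            gene_id=gene,
            log2_tpm=float(val),
            p_active=float(pa),
            p_leaky=float(1.0 - pa),
            label=classify_by_posterior(float(pa), lower=lower, upper=upper),
        )
        for (gene, val), pa in zip(pairs, p)
    ]
    return GmmDatasetResult(ds.dataset_id, verdict, fit, calls)
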