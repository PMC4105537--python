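"""Differential-expression measures and empirical-null mixture calling.

The per-tissue DE measure d is the difference of normalized mean expression
between the two states.  A two-component normal mixture is fitted to the
d-vector by EM; the component with the smaller variance plays the empirical
null (mean and variance estimated, not assumed), and genes are called by
ranking on the posterior null probability until the running mean — the
estimated false discovery rate of the called set — exceeds the target.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError, ValidationError
from .exprio import SampleSheet
from .normalization import NormalizedExpression

_SQRT2PI = np.sqrt(2.0 * np.pi)


def de_measure(norm: NormalizedExpression, sheet: SampleSheet, tissue: str) -> pd.Series:
    """Per-gene mean normalized value over POST libraries minus PRE, one tissue."""
    for state in ("PRE", "POST"):
        if not (sheet.mask(tissue=tissue, state=state)).any():
            raise ValidationError(f"tissue {tissue!r} has no libraries in state {state}")
    post = sheet.mask(tissue=tissue, state="POST")
    pre = sheet.mask(tissue=tissue, state="PRE")
    d = norm.values[:, post].mean(axis=1) - norm.values[:, pre].mean(axis=1)
    return pd.Series(d, index=norm.gene_ids, name=tissue)


@dataclass
class MixtureFit:
    """Two-component normal mixture with the small-variance component as null."""

    pi0: float
    pi1: float
    mu0: float
    sigma0: float
    mu1: float
    sigma1: float
    loglik: float
    n_iter: int
    converged: bool
    posterior_null: np.ndarray

    @property
    def no_de_signal(self) -> bool:
        """True when the two components are essentially indistinct."""
        return self.sigma1 / max(self.sigma0, 1e-300) < 2.0 or min(self.pi0, self.pi1) < 0.02

    def posterior_null_at(self, x: np.ndarray) -> np.ndarray:
        f0 = self.pi0 * _norm_pdf(x, self.mu0, self.sigma0)
        f1 = self.pi1 * _norm_pdf(x, self.mu1, self.sigma1)
        return f0 / (f0 + f1)


def _norm_pdf(x, mu, sigma):
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return np.exp(-0.5 * z * z) / (sigma * _SQRT2PI)


def _em_once(x: np.ndarray, mu, sigma, pi, tol, max_iter, sigma_floor):
    n = x.size
    ll_prev = -np.inf
    ll = -np.inf
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        f = np.column_stack([pi[k] * _norm_pdf(x, mu[k], sigma[k]) for k in (0, 1)])
        tot = f.sum(axis=1)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.log(tot).sum())
        resp = f / tot[:, None]
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        pi = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(np.maximum(var, sigma_floor**2))
        if ll - ll_prev < tol * max(1.0, abs(ll)) and it > 1:
            converged = True
            break
        ll_prev = ll
    return mu, sigma, pi, ll, it, converged


def fit_mixture(
    d: np.ndarray | pd.Series,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_starts: int = 10,
    seed: int = 0,
) -> MixtureFit:
    """Maximum-likelihood two-component fit, best of ``n_starts`` EM restarts."""
    x = np.asarray(d, dtype=float).ravel()
    if x.size < 50:
        raise ValidationError(f"need >= 50 observations, got {x.size}")
    sd = float(np.std(x))
    if sd < 1e-14:
        raise DegenerateInputError("all DE measures are identical")
    rng = np.random.default_rng(seed)
    sigma_floor = max(1e-8, 1e-3 * sd)

    # The two-component likelihood is unbounded (a component can collapse onto
    # a few points), so restarts that end with a vanishing proportion or a
    # floored scale are treated as spurious and only win if nothing else does.
    best = None
    best_spurious = None
    for s in range(n_starts):
        if s == 0:
            # deterministic start: narrow null around the median, wide non-null
            mu = np.array([float(np.median(x))] * 2)
            sigma = np.array([0.25 * sd, 2.0 * sd])
            pi = np.array([0.9, 0.1])
        else:
            mu = rng.choice(x, size=2, replace=False).astype(float)
            sigma = sd * rng.uniform(0.1, 2.0, size=2)
            pi = np.array([0.5, 0.5])
        out = _em_once(x, mu, sigma, pi, tol, max_iter, sigma_floor)
        mu_f, sigma_f, pi_f = out[0], out[1], out[2]
        spurious = float(pi_f.min()) < 0.02 or float(sigma_f.min()) <= 2.0 * sigma_floor
        if spurious:
            if best_spurious is None or out[3] > best_spurious[3]:
                best_spurious = out
        elif best is None or out[3] > best[3]:
            best = out
    if best is None:
        best = best_spurious
    mu, sigma, pi, ll, it, converged = best
    if not converged:
        warnings.warn("mixture EM did not converge; best fit returned", RuntimeWarning)

    null = int(np.argmin(sigma))  # small-variance component is the null
    alt = 1 - null
    fit = MixtureFit(
        pi0=float(pi[null]),
        pi1=float(pi[alt]),
        mu0=float(mu[null]),
        sigma0=float(sigma[null]),
        mu1=float(mu[alt]),
        sigma1=float(sigma[alt]),
        loglik=ll,
        n_iter=it,
        converged=converged,
        posterior_null=np.empty(0),
    )
    fit.posterior_null = fit.posterior_null_at(x)
    return fit


def call_de(fit: MixtureFit, d: pd.Series, fdr_target: float = 0.01) -> pd.DataFrame:
    """Call DE genes at an estimated FDR below ``fdr_target``.

    Genes are ranked by posterior null probability; the called set is the
    largest prefix whose mean posterior (the mixture-model FDR estimate)
    stays at or below the target.  Fold change uses the signed convention
    2^d for d >= 0 and -2^(-d) for d < 0.
    """
    if not 0.0 < fdr_target < 1.0:
        raise ParameterError(f"fdr_target must be in (0, 1), got {fdr_target}")
    d = pd.Series(np.asarray(d, dtype=float), index=d.index if hasattr(d, "index") else None)
    post = fit.posterior_null_at(d.to_numpy())
    order = np.argsort(post, kind="stable")
    cum_mean = np.cumsum(post[order]) / np.arange(1, post.size + 1)
    ok = np.where(cum_mean <= fdr_target)[0]
    n_called = int(ok[-1]) + 1 if ok.size else 0
    is_de = np.zeros(post.size, dtype=bool)
    is_de[order[:n_called]] = True

    dv = d.to_numpy()
    fold = np.where(dv >= 0, np.exp2(dv), -np.exp2(-dv))
    return pd.DataFrame(
        {
            "gene": d.index,
            "d": dv,
            "fold_change": fold,
            "posterior_null": post,
            "is_de": is_de,
            "direction": np.where(dv > 0, "up", "down"),
        }
    ).set_index("gene")


def de_table(
    norm: NormalizedExpression,
    sheet: SampleSheet,
    fdr_target: float = 0.01,
    seed: int = 0,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-tissue DE calls for every tissue, concatenated into one table.

    With ``pooled=True`` a single mixture is fitted to all tissues' measures
    jointly and reused for each tissue's calls.
    """
    tissues = sheet.tissues
    measures = {t: de_measure(norm, sheet, t) for t in tissues}
    pooled_fit = None
    if pooled:
        pooled_fit = fit_mixture(np.concatenate([m.to_numpy() for m in measures.values()]), seed=seed)
    frames = []
    for t in tissues:
        fit = pooled_fit if pooled else fit_mixture(measures[t], seed=seed)
        calls = call_de(fit, measures[t], fdr_target=fdr_target)
        calls.insert(0, "tissue", t)
        frames.append(calls.reset_index())
    return pd.concat(frames, ignore_index=True)
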