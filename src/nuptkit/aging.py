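"""Relative ages of NUPTs and univariate age-distribution modeling.

A NUPT's relative age is K, the JC69-corrected number of substitutions per
site estimated from its plastid-vs-nuclear alignment.  Whether NUPTs arise
continuously (exponential age decay) or episodically (a Gaussian age burst)
is decided by fitting four univariate models to the K distribution —
exponential (EXP), single Gaussian (GAUSS1), two-component Gaussian mixture
(GAUSS2), and exponential+Gaussian mixture (EXPGAUSS) — and selecting the
lowest-BIC model over replicated EM starts.

The modeling surface follows the statsmodels idiom: ``NuptAgeModel`` holds
the data, ``fit``/``select`` return results objects with ``summary()``.

Model densities
---------------
EXP:       f(k) = lam * exp(-lam*k),              k >= 0
GAUSS1:    f(k) = N(k; mu, sigma^2)                (untruncated)
GAUSS2:    f(k) = w*N(k; mu1, s1^2) + (1-w)*N(k; mu2, s2^2)
EXPGAUSS:  f(k) = w*Exp(k; lam) + (1-w)*N(k; mu, sigma^2)

BIC = nu*ln(n) - 2*lnL with nu = 1, 2, 5, 4 respectively; lower is better.
Gaussian components are left untruncated even though K >= 0, mirroring the
Ks-plot mixture methodology; the probability mass each Gaussian places below
zero is reported as a diagnostic.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, StatisticsError

P_SATURATION = 0.75  # JC69 expected p-distance as K -> infinity
SIGMA_MIN = 1e-4  # floor preventing likelihood spikes on repeated values
EM_TOL = 1e-8  # relative log-likelihood change declaring convergence
EM_MAX_ITER = 1000

MODEL_KINDS = ("EXP", "GAUSS1", "GAUSS2", "EXPGAUSS")
N_FREE_PARAMS = {"EXP": 1, "GAUSS1": 2, "GAUSS2": 5, "EXPGAUSS": 4}


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def p_distance(hit) -> float:
    """Observed substitutions per site of one alignment hit: mismatch/length.

    Gap columns are absent from the numerator but counted in the denominator
    (the only definition computable from 12-column tabular output), making
    this at most a gap-fraction underestimate.
    """
    if hit.length < 1:
        raise InputError(f"alignment length must be >= 1, got {hit.length}")
    if hit.mismatch > hit.length:
        raise InputError(
            f"mismatch ({hit.mismatch}) exceeds alignment length ({hit.length})"
        )
    return hit.mismatch / hit.length


def jc69(p):
    """Jukes–Cantor (1969) multiple-hit correction K = -(3/4) ln(1 - (4/3)p).

    Accepts a scalar or array of p-distances in [0, 0.75); K >= p always,
    with K(0) = 0 and divergence as p approaches the 0.75 saturation point.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr >= P_SATURATION):
        raise InputError("p-distance outside [0, 0.75): JC69 is saturated")
    k = -0.75 * np.log1p(-(4.0 / 3.0) * p_arr)
    return float(k) if np.isscalar(p) or p_arr.ndim == 0 else k


def jc69_inverse(k):
    """Expected p-distance for a given K: p = (3/4)(1 - exp(-4K/3))."""
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 0):
        raise InputError("K must be non-negative")
    p = 0.75 * -np.expm1(-(4.0 / 3.0) * k_arr)
    return float(p) if np.isscalar(k) or k_arr.ndim == 0 else p


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class AgeModelFit:
    """One fitted univariate model of the K distribution."""

    model_kind: str
    params: dict[str, float]
    loglik: float
    n: int
    n_free_params: int
    bic: float
    seed: int | None
    converged: bool
    n_iter: int
    loglik_trajectory: list[float] = field(default_factory=list, repr=False)

    @property
    def n_components(self) -> int:
        return 2 if self.model_kind in ("GAUSS2", "EXPGAUSS") else 1

    def component_densities(self, k: np.ndarray) -> np.ndarray:
        """Weighted component densities, shape (n, n_components)."""
        k = np.asarray(k, dtype=float)
        p = self.params
        if self.model_kind == "EXP":
            return (p["lam"] * np.exp(-p["lam"] * k))[:, None]
        if self.model_kind == "GAUSS1":
            return stats.norm.pdf(k, p["mu"], p["sigma"])[:, None]
        if self.model_kind == "GAUSS2":
            return np.column_stack([
                p["w"] * stats.norm.pdf(k, p["mu1"], p["sigma1"]),
                (1.0 - p["w"]) * stats.norm.pdf(k, p["mu2"], p["sigma2"]),
            ])
        return np.column_stack([
            p["w"] * p["lam"] * np.exp(-p["lam"] * k),
            (1.0 - p["w"]) * stats.norm.pdf(k, p["mu"], p["sigma"]),
        ])

    def density(self, k: np.ndarray) -> np.ndarray:
        return self.component_densities(np.asarray(k, dtype=float)).sum(axis=1)

    def gaussian_negative_mass(self) -> float:
        """Diagnostic: probability mass the Gaussian component(s) place at
        K < 0 (the models are untruncated)."""
        p = self.params
        if self.model_kind == "GAUSS1":
            return float(stats.norm.cdf(0.0, p["mu"], p["sigma"]))
        if self.model_kind == "GAUSS2":
            return float(
                p["w"] * stats.norm.cdf(0.0, p["mu1"], p["sigma1"])
                + (1 - p["w"]) * stats.norm.cdf(0.0, p["mu2"], p["sigma2"])
            )
        if self.model_kind == "EXPGAUSS":
            return float((1 - p["w"]) * stats.norm.cdf(0.0, p["mu"], p["sigma"]))
        return 0.0


@dataclass
class MixtureAssignment:
    """Posterior component memberships for each NUPT under a 2-component fit."""

    posteriors: np.ndarray  # (n, 2), rows sum to 1
    labels: np.ndarray  # argmax component index per NUPT
    component_names: tuple[str, str]


def _bic(loglik: float, nu: int, n: int) -> float:
    return nu * np.log(n) - 2.0 * loglik


def _check_ages(ages) -> np.ndarray:
    k = np.asarray(ages, dtype=float)
    if k.ndim != 1:
        raise InputError("ages must be a 1-d array of K values")
    if not np.isfinite(k).all():
        raise InputError("non-finite ages")
    if np.any(k < 0):
        raise InputError("ages (K) must be non-negative")
    if len(k) < 10:
        raise StatisticsError(f"need at least 10 ages to fit, got {len(k)}")
    return k


def _em(k: np.ndarray, dens_fn, mstep_fn, params: dict) -> tuple[dict, list[float], bool, int]:
    """Generic two-component EM loop.

    dens_fn(params) -> (n, 2) weighted component densities;
    mstep_fn(resp) -> new params.  Log-likelihood is guarded to be
    non-decreasing (EM's defining property); a decrease beyond numerical
    noise indicates an implementation fault and raises.
    """
    trajectory: list[float] = []
    converged = False
    it = 0
    for it in range(1, EM_MAX_ITER + 1):
        dens = dens_fn(params)
        tot = dens.sum(axis=1)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.log(tot).sum())
        if trajectory:
            prev = trajectory[-1]
            if ll < prev - 1e-9 * max(1.0, abs(prev)):
                raise StatisticsError(
                    f"EM log-likelihood decreased ({prev:.10g} -> {ll:.10g})"
                )
            if abs(ll - prev) <= EM_TOL * max(1.0, abs(prev)):
                trajectory.append(ll)
                converged = True
                break
        trajectory.append(ll)
        resp = dens / tot[:, None]
        params = mstep_fn(resp)
    return params, trajectory, converged, it


def fit_model(ages, model_kind: str, seed: int | None = None) -> AgeModelFit:
    """Fit one of the four age-distribution models by maximum likelihood.

    EXP and GAUSS1 are closed-form; GAUSS2 and EXPGAUSS run EM from a
    seeded random start (w ~ U(0.2, 0.8), Gaussian means at random data
    quantiles in [0.1, 0.9], sigma = sd/2, lam = 1/mean).
    """
    k = _check_ages(ages)
    n = len(k)
    if model_kind not in MODEL_KINDS:
        raise InputError(f"unknown model kind {model_kind!r}")
    rng = np.random.default_rng(seed)

    if model_kind == "EXP":
        mean = k.mean()
        if mean <= 0:
            raise StatisticsError("all ages are zero: exponential rate undefined")
        lam = 1.0 / mean
        ll = float(n * np.log(lam) - lam * k.sum())
        return AgeModelFit("EXP", {"lam": lam}, ll, n, 1, _bic(ll, 1, n), seed,
                           True, 0, [ll])

    if model_kind == "GAUSS1":
        mu = float(k.mean())
        sigma = max(float(k.std()), SIGMA_MIN)  # biased ML sd, floored
        ll = float(stats.norm.logpdf(k, mu, sigma).sum())
        return AgeModelFit("GAUSS1", {"mu": mu, "sigma": sigma}, ll, n, 2,
                           _bic(ll, 2, n), seed, True, 0, [ll])

    sd = max(float(k.std()), SIGMA_MIN)
    mean = max(float(k.mean()), 1e-12)

    if model_kind == "GAUSS2":
        q1, q2 = rng.uniform(0.1, 0.9, size=2)
        params = {
            "w": float(rng.uniform(0.2, 0.8)),
            "mu1": float(np.quantile(k, min(q1, q2))),
            "mu2": float(np.quantile(k, max(q1, q2))),
            "sigma1": sd / 2, "sigma2": sd / 2,
        }

        def dens(p):
            return np.column_stack([
                p["w"] * stats.norm.pdf(k, p["mu1"], p["sigma1"]),
                (1 - p["w"]) * stats.norm.pdf(k, p["mu2"], p["sigma2"]),
            ])

        def mstep(r):
            n1 = max(r[:, 0].sum(), 1e-12)
            n2 = max(r[:, 1].sum(), 1e-12)
            mu1 = float((r[:, 0] * k).sum() / n1)
            mu2 = float((r[:, 1] * k).sum() / n2)
            s1 = float(np.sqrt((r[:, 0] * (k - mu1) ** 2).sum() / n1))
            s2 = float(np.sqrt((r[:, 1] * (k - mu2) ** 2).sum() / n2))
            return {"w": float(r[:, 0].mean()), "mu1": mu1, "mu2": mu2,
                    "sigma1": max(s1, SIGMA_MIN), "sigma2": max(s2, SIGMA_MIN)}

        params, traj, conv, n_iter = _em(k, dens, mstep, params)
        nu = 5
    else:  # EXPGAUSS
        params = {
            "w": float(rng.uniform(0.2, 0.8)),  # exponential weight
            "lam": 1.0 / mean,
            "mu": float(np.quantile(k, rng.uniform(0.1, 0.9))),
            "sigma": sd / 2,
        }

        def dens(p):
            return np.column_stack([
                p["w"] * p["lam"] * np.exp(-p["lam"] * k),
                (1 - p["w"]) * stats.norm.pdf(k, p["mu"], p["sigma"]),
            ])

        def mstep(r):
            n1 = max(r[:, 0].sum(), 1e-12)
            n2 = max(r[:, 1].sum(), 1e-12)
            lam = n1 / max((r[:, 0] * k).sum(), 1e-300)
            mu = float((r[:, 1] * k).sum() / n2)
            sig = float(np.sqrt((r[:, 1] * (k - mu) ** 2).sum() / n2))
            return {"w": float(r[:, 0].mean()), "lam": float(lam),
                    "mu": mu, "sigma": max(sig, SIGMA_MIN)}

        params, traj, conv, n_iter = _em(k, dens, mstep, params)
        nu = 4

    ll = traj[-1]
    return AgeModelFit(model_kind, params, ll, n, nu, _bic(ll, nu, n), seed,
                       conv, n_iter, traj)


def assign_components(ages, fit: AgeModelFit) -> MixtureAssignment:
    """Posterior probability of each mixture component for every NUPT."""
    if fit.n_components < 2:
        raise StatisticsError(
            f"{fit.model_kind} has a single component; posteriors are trivial"
        )
    k = np.asarray(ages, dtype=float)
    dens = fit.component_densities(k)
    tot = np.maximum(dens.sum(axis=1), 1e-300)
    post = dens / tot[:, None]
    names = (("exponential", "gaussian") if fit.model_kind == "EXPGAUSS"
             else ("gaussian1", "gaussian2"))
    return MixtureAssignment(post, post.argmax(axis=1), names)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def _simpler_first(kind: str) -> tuple[int, str]:
    return (N_FREE_PARAMS[kind], kind)


@dataclass
class ModelSelection:
    """Replicated BIC-based selection among the four age models."""

    best_per_replicate: list[str]
    modal_best: str
    tally: dict[str, int]
    fits: list[AgeModelFit]  # all replicate x model fits
    best_fit: AgeModelFit  # lowest-BIC fit of the modal kind

    def summary(self) -> pd.DataFrame:
        rows = [
            {"replicate": f.seed, "model": f.model_kind, "loglik": f.loglik,
             "bic": f.bic, "converged": f.converged, "n_iter": f.n_iter,
             **{f"param_{p}": v for p, v in f.params.items()}}
            for f in self.fits
        ]
        return pd.DataFrame(rows)


def select_model(ages, n_replicates: int = 15, seed: int = 0) -> ModelSelection:
    """Fit all four models in each of ``n_replicates`` replicates (distinct
    seeds drive the EM starts) and report the lowest-BIC model per replicate
    and the modal best across replicates; BIC ties break toward fewer free
    parameters."""
    k = _check_ages(ages)
    fits: list[AgeModelFit] = []
    best_per_rep: list[str] = []
    for rep in range(n_replicates):
        rep_seed = seed + rep
        rep_fits = [fit_model(k, kind, seed=rep_seed) for kind in MODEL_KINDS]
        fits.extend(rep_fits)
        best = min(rep_fits, key=lambda f: (round(f.bic, 9), _simpler_first(f.model_kind)))
        best_per_rep.append(best.model_kind)
    tally = Counter(best_per_rep)
    top = max(tally.values())
    modal = min((kind for kind, c in tally.items() if c == top),
                key=_simpler_first)
    best_fit = min((f for f in fits if f.model_kind == modal), key=lambda f: f.bic)
    return ModelSelection(best_per_rep, modal, dict(tally), fits, best_fit)


# ---------------------------------------------------------------------------
# statsmodels-style surface
# ---------------------------------------------------------------------------

class NuptAgeModel:
    """Univariate model of a NUPT age (K) distribution.

    Parameters
    ----------
    ages : array-like of non-negative K values.

    Examples
    --------
    >>> model = NuptAgeModel.from_nupts(catalog)      # doctest: +SKIP
    >>> res = model.select(n_replicates=15, seed=1)   # doctest: +SKIP
    >>> print(res.summary())                          # doctest: +SKIP
    """

    def __init__(self, ages):
        self.ages = _check_ages(ages)

    @classmethod
    def from_nupts(cls, nupts) -> "NuptAgeModel":
        return cls([r.K for r in nupts])

    def fit(self, model_kind: str = "EXPGAUSS", seed: int | None = None) -> "AgeModelResults":
        return AgeModelResults(self, fit_model(self.ages, model_kind, seed=seed))

    def select(self, n_replicates: int = 15, seed: int = 0) -> "ModelSelectionResults":
        return ModelSelectionResults(self, select_model(self.ages, n_replicates, seed))


class AgeModelResults:
    """Results wrapper for a single fitted age model."""

    def __init__(self, model: NuptAgeModel, fit: AgeModelFit):
        self.model = model
        self.fit = fit

    @property
    def params(self) -> dict[str, float]:
        return self.fit.params

    @property
    def bic(self) -> float:
        return self.fit.bic

    def component_posteriors(self) -> MixtureAssignment:
        return assign_components(self.model.ages, self.fit)

    def summary(self) -> str:
        f = self.fit
        lines = [
            f"NUPT age model: {f.model_kind}",
            f"  n = {f.n}, free parameters = {f.n_free_params}",
            f"  log-likelihood = {f.loglik:.4f}, BIC = {f.bic:.4f}",
            f"  converged = {f.converged} after {f.n_iter} EM iterations",
        ]
        for p, v in f.params.items():
            lines.append(f"  {p:>8} = {v:.6g}")
        neg = f.gaussian_negative_mass()
        if f.model_kind != "EXP":
            lines.append(f"  Gaussian mass below K=0 (diagnostic): {neg:.3e}")
        return "\n".join(lines)


class ModelSelectionResults:
    """Results wrapper for replicated BIC model selection."""

    def __init__(self, model: NuptAgeModel, selection: ModelSelection):
        self.model = model
        self.selection = selection

    @property
    def modal_best(self) -> str:
        return self.selection.modal_best

    @property
    def best_fit(self) -> AgeModelFit:
        return self.selection.best_fit

    def component_posteriors(self) -> MixtureAssignment:
        return assign_components(self.model.ages, self.selection.best_fit)

    def replicate_table(self) -> pd.DataFrame:
        return self.selection.summary()

    def summary(self) -> str:
        sel = self.selection
        lines = ["BIC model selection over replicated EM starts"]
        for kind in MODEL_KINDS:
            lines.append(f"  {kind:>8}: best in {sel.tally.get(kind, 0)} replicates")
        lines.append(f"  modal best model: {sel.modal_best}")
        lines.append(AgeModelResults(self.model, sel.best_fit).summary())
        return "\n".join(lines)
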