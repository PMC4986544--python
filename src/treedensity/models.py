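"""Negative-binomial regression, all-subsets ranking and model averaging.

Tree density at a plot is a count (stems per hectare), modelled with a
log-link negative-binomial GLM: ``E[y] = mu = exp(x' beta)``,
``Var[y] = mu + mu**2 / theta``.  For a given region, every subset of the
indicator covariates (plus the intercept-only model) is fitted and ranked by
the small-sample Akaike criterion

    AICc = -2 loglik + 2k + 2k(k + 1) / (n - k - 1),

where k counts the regression coefficients plus the dispersion.  Akaike
weights ``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)`` define a confidence
set — the smallest prefix of the ranking with cumulative weight >= 0.95 —
over which coefficients are averaged in the full (zero-substitution) sense: a
term absent from a member model contributes a zero coefficient.  The averaged
covariance combines within-model covariance and between-model spread, so the
downstream variance of predicted totals reflects model-selection uncertainty
as well as sampling noise.

Regions with fewer than 50 plots do not receive their own model; ecoregions
inherit the spatially coincident biome model, and data-poor biomes inherit a
configured ecological analog.  Provenance of every substitution is recorded.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cluster import cut_and_select, hclust_variables

__all__ = [
    "NBFit",
    "ModelSet",
    "AveragedModel",
    "fit_nb",
    "aicc",
    "dredge",
    "akaike_weights",
    "confidence_set",
    "average_models",
    "fit_region_models",
]

log = logging.getLogger(__name__)


@dataclass
class NBFit:
    """One maximum-likelihood NB2 fit.

    ``beta`` holds the coefficients (intercept first, order matching
    ``terms``); ``cov_beta`` their estimated covariance; ``theta`` the NB
    dispersion; ``k_params`` counts the beta terms plus one for theta.
    """

    terms: tuple[str, ...]
    beta: np.ndarray
    cov_beta: np.ndarray
    theta: float
    loglik: float
    n_obs: int
    converged: bool

    @property
    def k_params(self) -> int:
        return len(self.beta) + 1

    @property
    def aicc(self) -> float:
        return aicc(self)


def _round_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    rounded = np.rint(y)  # half-to-even
    if np.any(rounded != y):
        log.warning("non-integer densities rounded half-to-even for NB fitting")
    return rounded


def fit_nb(y: np.ndarray, X: np.ndarray, terms: tuple[str, ...] | None = None) -> NBFit:
    """Fit a log-link NB2 regression by maximum likelihood.

    ``X`` must include the intercept column first and be full rank.  The
    returned ``loglik`` is the NB log-likelihood at the optimum; a
    non-converged optimisation is returned flagged rather than raised, so
    the dredge can exclude and log it.
    """
    y = _round_counts(y)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if terms is None:
        terms = ("const",) + tuple(f"x{i}" for i in range(1, p))
    if n < p + 3:
        raise ValueError(f"need n >= k_params + 2 = {p + 3}, got n = {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200, method="bfgs")
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:  # noqa: BLE001 - optimizer blow-ups become flagged fits
            res = None
            converged = False
        if res is not None and converged:
            # polish with Newton for sharp ML identities (e.g. intercept-only
            # fitted mean == sample mean to machine precision)
            try:
                res = model.fit(start_params=res.params, disp=0, maxiter=100, method="newton")
                converged = bool(res.mle_retvals.get("converged", converged))
            except Exception:  # noqa: BLE001
                pass
    if res is None:
        return NBFit(terms, np.full(p, np.nan), np.full((p, p), np.nan),
                     np.nan, -np.inf, n, converged=False)
    alpha = float(res.params[-1])
    theta = 1.0 / alpha if alpha > 0 else np.inf
    cov = np.asarray(res.cov_params())[:p, :p]
    cov = (cov + cov.T) / 2.0
    return NBFit(
        terms=terms,
        beta=np.asarray(res.params[:p], dtype=float),
        cov_beta=cov,
        theta=theta,
        loglik=float(res.llf),
        n_obs=n,
        converged=converged,
    )


def aicc(fit: NBFit) -> float:
    """Small-sample corrected AIC; undefined when n <= k + 1."""
    k, n = fit.k_params, fit.n_obs
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n = {n}, k = {k}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelSet:
    """AICc-ranked candidate fits with Akaike weights."""

    fits: list[NBFit]
    delta: np.ndarray
    weights: np.ndarray
    dropped: list[tuple[str, ...]] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Dredge table: terms, k, loglik, AICc, delta, weight."""
        return pd.DataFrame(
            {
                "terms": ["+".join(f.terms[1:]) or "(intercept)" for f in self.fits],
                "k": [f.k_params for f in self.fits],
                "loglik": [f.loglik for f in self.fits],
                "aicc": [f.aicc for f in self.fits],
                "delta": self.delta,
                "weight": self.weights,
            }
        )


def akaike_weights(aicc_values: np.ndarray) -> np.ndarray:
    """``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)``."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def dredge(
    y: np.ndarray,
    X_terms: pd.DataFrame,
    p_max: int = 12,
) -> ModelSet:
    """Fit and rank every covariate subset of the global model.

    All ``2**p`` submodels (including intercept-only) are fitted; each
    includes the intercept.  Ranking is by AICc ascending with ties broken by
    the lexicographic order of the term-name tuple.  Non-converged fits are
    excluded from the ranking and recorded in ``dropped``.
    """
    names = list(X_terms.columns)
    p = len(names)
    if p > p_max:
        raise ValueError(
            f"{p} candidate terms would require {2**p} fits; raise p_max (= {p_max}) "
            "explicitly or reduce the indicator set"
        )
    y = np.asarray(y, dtype=float)
    n = len(y)
    intercept = np.ones((n, 1))
    fits: list[NBFit] = []
    dropped: list[tuple[str, ...]] = []
    for r in range(p + 1):
        for subset in itertools.combinations(names, r):
            X = np.hstack([intercept, X_terms[list(subset)].to_numpy()]) if subset else intercept
            fit = fit_nb(y, X, terms=("const",) + subset)
            if fit.converged:
                fits.append(fit)
            else:
                dropped.append(subset)
    if dropped:
        log.info("dredge: %d non-converged subset(s) excluded: %s", len(dropped), dropped)
    if not fits:
        raise RuntimeError("no candidate model converged")
    fits.sort(key=lambda f: (f.aicc, f.terms[1:]))
    a = np.array([f.aicc for f in fits])
    return ModelSet(fits=fits, delta=a - a.min(), weights=akaike_weights(a), dropped=dropped)


def confidence_set(model_set: ModelSet, cum: float = 0.95) -> tuple[list[NBFit], np.ndarray]:
    """Smallest prefix of the ranking with cumulative Akaike weight >= cum.

    Returns the member fits and their weights renormalised over the set.
    """
    cw = np.cumsum(model_set.weights)
    n_keep = int(np.searchsorted(cw, cum - 1e-12) + 1)
    n_keep = min(n_keep, len(model_set.fits))
    fits = model_set.fits[:n_keep]
    w = model_set.weights[:n_keep]
    return fits, w / w.sum()


@dataclass
class AveragedModel:
    """Weighted average of a confidence set of NB fits.

    ``terms`` is the union of member-model terms (intercept first); members
    missing a term contribute a zero coefficient there.  ``cov`` combines the
    weighted within-model covariances with the between-model coefficient
    spread.  ``provenance`` is ``"own"`` for a region's own fit or
    ``"substituted-from:<region>"`` for an inherited model.
    """

    region_id: int | str | None
    terms: tuple[str, ...]
    beta: np.ndarray
    cov: np.ndarray
    theta: float
    provenance: str = "own"
    n_obs: int = 0
    indicator_set: tuple[str, ...] = ()

    @property
    def substituted(self) -> bool:
        return self.provenance.startswith("substituted-from:")

    def predict_density(self, covariates: pd.DataFrame) -> np.ndarray:
        """Expected trees/ha at rows of a covariate table."""
        eta = np.full(len(covariates), self.beta[0], dtype=float)
        for b, t in zip(self.beta[1:], self.terms[1:]):
            eta += b * covariates[t].to_numpy(dtype=float)
        return np.exp(eta)

    def to_json(self) -> dict:
        return {
            "region_id": self.region_id,
            "terms": list(self.terms),
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "theta": self.theta,
            "provenance": self.provenance,
            "n_obs": self.n_obs,
            "indicator_set": list(self.indicator_set),
        }

    @classmethod
    def from_json(cls, d: dict) -> "AveragedModel":
        return cls(
            region_id=d["region_id"],
            terms=tuple(d["terms"]),
            beta=np.asarray(d["beta"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            theta=float(d["theta"]),
            provenance=d.get("provenance", "own"),
            n_obs=int(d.get("n_obs", 0)),
            indicator_set=tuple(d.get("indicator_set", ())),
        )


def average_models(
    fits: list[NBFit],
    weights: np.ndarray,
    region_id: int | str | None = None,
) -> AveragedModel:
    """Full (zero-substitution) model averaging over a confidence set.

    ``beta_bar_t = sum_i w_i beta_{i,t}`` with absent terms entering as 0;
    ``cov = sum_i w_i [Cov_i + (beta_i - beta_bar)(beta_i - beta_bar)']`` on
    the zero-padded union term basis; ``theta_bar = sum_i w_i theta_i``.
    """
    if not fits:
        raise ValueError("empty confidence set")
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    union: list[str] = ["const"]
    for f in fits:
        for t in f.terms:
            if t not in union:
                union.append(t)
    idx = {t: i for i, t in enumerate(union)}
    m = len(union)
    betas = np.zeros((len(fits), m))
    covs = np.zeros((len(fits), m, m))
    for i, f in enumerate(fits):
        pos = [idx[t] for t in f.terms]
        betas[i, pos] = f.beta
        covs[i][np.ix_(pos, pos)] = f.cov_beta
    beta_bar = weights @ betas
    dev = betas - beta_bar
    cov = np.einsum("i,ijk->jk", weights, covs) + np.einsum("i,ij,ik->jk", weights, dev, dev)
    theta_bar = float(weights @ np.array([f.theta for f in fits]))
    return AveragedModel(
        region_id=region_id,
        terms=tuple(union),
        beta=beta_bar,
        cov=(cov + cov.T) / 2.0,
        theta=theta_bar,
        n_obs=fits[0].n_obs,
    )


def _fit_one_region(
    plots: pd.DataFrame,
    covariates: list[str],
    region_id,
    k_clusters: int | str,
    cum: float,
    p_max: int,
    indicator_override: tuple[str, ...] | None = None,
) -> AveragedModel:
    y = plots["trees_per_ha"].to_numpy()
    if indicator_override is not None:
        indicators = list(indicator_override)
    else:
        tree = hclust_variables(plots[covariates])
        indicators = list(cut_and_select(tree, k=k_clusters).indicators)
    mset = dredge(y, plots[indicators], p_max=p_max)
    fits, w = confidence_set(mset, cum=cum)
    model = average_models(fits, w, region_id=region_id)
    model.n_obs = len(plots)
    model.indicator_set = tuple(indicators)
    return model


def fit_region_models(
    plots: pd.DataFrame,
    covariates: list[str],
    level: str = "biome",
    min_n: int = 50,
    substitutions: dict | None = None,
    cum: float = 0.95,
    k_clusters: int | str = "auto",
    p_max: int = 12,
    min_plots_per_var: int = 5,
    biome_models: dict | None = None,
) -> dict:
    """Fit an averaged NB model for every region at the given level.

    A region with at least ``min_n`` plots gets its own clustered, dredged
    and averaged model.  An ecoregion below ``min_n`` inherits the spatially
    coincident biome model; an ecoregion with enough plots for fitting but
    too few for stable variable clustering (fewer than ``min_plots_per_var``
    per candidate covariate) reuses its biome's indicator set.  A biome below
    ``min_n`` inherits the analog named in ``substitutions``
    (``{biome_id: analog_biome_id}``); a data-poor biome with no configured
    analog is an error.  Provenance of every substitution is recorded on the
    model.
    """
    substitutions = substitutions or {}
    key = "biome_id" if level == "biome" else "ecoregion_id"
    groups = {rid: g for rid, g in plots.groupby(key)}
    models: dict = {}
    if level == "biome":
        poor = []
        for rid, g in sorted(groups.items()):
            if len(g) >= min_n:
                models[rid] = _fit_one_region(g, covariates, rid, k_clusters, cum, p_max)
                log.info("biome %s: own model on %d plots, indicators %s",
                         rid, len(g), models[rid].indicator_set)
            else:
                poor.append(rid)
        for rid in poor:
            analog = substitutions.get(rid)
            if analog is None or analog not in models:
                raise ValueError(
                    f"biome {rid} has {len(groups[rid])} < {min_n} plots and no fitted analog "
                    f"in substitutions ({substitutions})"
                )
            donor = models[analog]
            models[rid] = AveragedModel(
                region_id=rid, terms=donor.terms, beta=donor.beta.copy(),
                cov=donor.cov.copy(), theta=donor.theta,
                provenance=f"substituted-from:{analog}",
                n_obs=len(groups[rid]), indicator_set=donor.indicator_set,
            )
            log.info("biome %s: substituted from analog biome %s", rid, analog)
        return models

    if level != "ecoregion":
        raise ValueError(f"level must be 'biome' or 'ecoregion', got {level!r}")
    if biome_models is None:
        biome_models = fit_region_models(
            plots, covariates, level="biome", min_n=min_n, substitutions=substitutions,
            cum=cum, k_clusters=k_clusters, p_max=p_max,
        )
    for rid, g in sorted(groups.items()):
        parent = int(g["biome_id"].iloc[0])
        if len(g) >= min_n:
            override = None
            if len(g) < min_plots_per_var * len(covariates) and parent in biome_models:
                override = biome_models[parent].indicator_set
            models[rid] = _fit_one_region(g, covariates, rid, k_clusters, cum, p_max,
                                          indicator_override=override)
        else:
            if parent not in biome_models:
                raise ValueError(f"ecoregion {rid} below {min_n} plots and biome {parent} has no model")
            donor = biome_models[parent]
            models[rid] = AveragedModel(
                region_id=rid, terms=donor.terms, beta=donor.beta.copy(),
                cov=donor.cov.copy(), theta=donor.theta,
                provenance=f"substituted-from:biome:{parent}",
                n_obs=len(g), indicator_set=donor.indicator_set,
            )
    return models
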