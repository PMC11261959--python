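"""Maximum-likelihood fitting of the DoC model families.

Fitting minimizes the raw-data -2 log-likelihood with a quasi-Newton search
(L-BFGS-B) on the unconstrained scale of :class:`~mixdoc.transforms.
Parameterization`.  Multiple starts perturb a method-of-moments initial
point; the best local optimum wins, with ties broken toward the smallest
start index so results are reproducible.  The public surface is the
scikit-learn style :class:`MixDoC` estimator; :func:`fit` and
:func:`fit_model_set` are the function equivalents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .data import TwinDataset, as_twin_dataset
from .likelihood import LikelihoodEvaluator, MixtureWeights, aic, minus2_loglik
from .model_core import (
    CholeskyParams,
    Direction,
    DoCParams,
    FAMILIES,
    ModelSpec,
    count_free_parameters,
    model_df,
)
from .simulate import direction_intercepts
from .transforms import Parameterization

__all__ = ["FitResult", "fit", "fit_model_set", "MixDoC"]

logger = logging.getLogger(__name__)

_BIG = 1e12


@dataclass(frozen=True)
class FitResult:
    """Point estimates and fit diagnostics of one fitted model."""

    spec: ModelSpec
    params: object  # DoCParams or CholeskyParams
    weights: MixtureWeights | None
    minus2ll: float
    k: int
    df: int
    aic: float
    converged: bool
    n_starts_used: int
    best_start: int
    n_iter: int
    start_minus2lls: tuple

    def to_dict(self) -> dict:
        p = self.params
        if isinstance(p, CholeskyParams):
            est = {
                "l_a": np.asarray(p.l_a).tolist(),
                "l_c": np.asarray(p.l_c).tolist(),
                "l_e": np.asarray(p.l_e).tolist(),
                "mu": np.asarray(p.mu).tolist(),
            }
        else:
            est = {f: getattr(p, f) for f in p.__dataclass_fields__}
        out = {
            "family": self.spec.family,
            "confound_ra_free": self.spec.confound_ra_free,
            "estimates": est,
            "minus2ll": self.minus2ll,
            "k": self.k,
            "df": self.df,
            "aic": self.aic,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "best_start": self.best_start,
        }
        if self.weights is not None:
            out["weights"] = {
                "MZ": list(self.weights.omega_mz),
                "DZ": list(self.weights.omega_dz),
            }
        return out


# ---------------------------------------------------------------------------
# method-of-moments initial values


def _clip_var(v: float, floor: float) -> float:
    return max(float(v), floor)


def _univariate_ace(data: TwinDataset, col: int):
    """Moment estimates (a2, c2, e2) for one trait from cross-twin covariances."""
    vals = np.concatenate([data.values[:, col], data.values[:, col + 2]])
    var = np.nanvar(vals)
    covs = {}
    for zyg in ("MZ", "DZ"):
        Y = data.by_zygosity(zyg)
        Y = Y[np.isfinite(Y).all(axis=1)]
        covs[zyg] = np.cov(Y[:, col], Y[:, col + 2])[0, 1] if len(Y) > 1 else 0.3 * var
    a2 = 2.0 * (covs["MZ"] - covs["DZ"])
    c2 = 2.0 * covs["DZ"] - covs["MZ"]
    floor = 0.05 * max(var, 1e-6)
    a2, c2 = _clip_var(a2, floor), _clip_var(c2, floor)
    e2 = _clip_var(var - a2 - c2, floor)
    return a2, c2, e2


def _cluster_means(data: TwinDataset, rng: np.random.Generator):
    """Provisional 2-means split of pair averages -> two (mu_x, mu_y) centers."""
    avg = np.column_stack([
        np.nanmean(data.values[:, [0, 2]], axis=1),
        np.nanmean(data.values[:, [1, 3]], axis=1),
    ])
    avg = avg[np.isfinite(avg).all(axis=1)]
    if len(avg) < 4:
        m = avg.mean(axis=0) if len(avg) else np.zeros(2)
        return m, m
    km = KMeans(n_clusters=2, n_init=3, random_state=int(rng.integers(2**31)))
    km.fit(avg)
    centers = km.cluster_centers_
    order = np.lexsort((centers[:, 1], centers[:, 0]))
    return centers[order[0]], centers[order[1]]


def _mom_doc_params(data: TwinDataset, spec: ModelSpec, rng, swap_clusters=False):
    ax2, cx2, ex2 = _univariate_ace(data, 0)
    ay2, cy2, ey2 = _univariate_ace(data, 1)
    vals = data.values[np.isfinite(data.values).all(axis=1)]
    xs = np.concatenate([vals[:, 0], vals[:, 2]])
    ys = np.concatenate([vals[:, 1], vals[:, 3]])
    cxy = np.cov(xs, ys)[0, 1] if len(xs) > 1 else 0.0
    b_xy0 = float(np.clip(cxy / max(np.var(xs), 1e-6), -0.8, 0.8))
    b_yx0 = float(np.clip(cxy / max(np.var(ys), 1e-6), -0.8, 0.8))
    mx, my = float(np.mean(xs)), float(np.mean(ys))
    if spec.is_mixture:
        m1, m2 = _cluster_means(data, rng)
        if swap_clusters:
            m1, m2 = m2, m1
    else:
        m1 = m2 = np.array([mx, my])
    # deflate pre-causal variances a little: causal paths add variance on top
    shrink = 0.8
    kw = dict(
        a_x=np.sqrt(shrink * ax2), c_x=np.sqrt(shrink * cx2), e_x=np.sqrt(shrink * ex2),
        a_y=np.sqrt(shrink * ay2), c_y=np.sqrt(shrink * cy2), e_y=np.sqrt(shrink * ey2),
    )
    if spec.family in ("mix4", "mix2", "doc_xy", "doc_bidir"):
        kw["b_xy"] = b_xy0 if spec.family != "doc_bidir" else 0.5 * b_xy0
    if spec.family in ("mix4", "mix2", "doc_yx", "doc_bidir"):
        kw["b_yx"] = b_yx0 if spec.family != "doc_bidir" else 0.5 * b_yx0
    d_xy = Direction.XY if spec.family != "doc_bidir" else Direction.BOTH
    nu1 = direction_intercepts(m1[0], m1[1], d_xy, kw.get("b_xy", 0.0), kw.get("b_yx", 0.0))
    nu2 = direction_intercepts(m2[0], m2[1], Direction.YX, kw.get("b_xy", 0.0), kw.get("b_yx", 0.0))
    kw.update(nu_x_xy=nu1[0], nu_y_xy=nu1[1], nu_x_yx=nu2[0], nu_y_yx=nu2[1])
    if spec.confound_ra_free:
        kw["r_a"] = 0.0
    return DoCParams(**kw)


def _nearest_spd(M: np.ndarray, floor: float) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    return (V * np.maximum(w, floor)) @ V.T


def _mom_cholesky(data: TwinDataset):
    vals = data.values[np.isfinite(data.values).all(axis=1)]
    within = 0.5 * (np.cov(vals[:, :2].T) + np.cov(vals[:, 2:].T))
    cross = {}
    for zyg in ("MZ", "DZ"):
        Y = data.by_zygosity(zyg)
        Y = Y[np.isfinite(Y).all(axis=1)]
        C = np.cov(Y.T)[:2, 2:] if len(Y) > 1 else 0.3 * within
        cross[zyg] = 0.5 * (C + C.T)
    floor = 0.02 * float(np.trace(within)) / 2.0
    A = _nearest_spd(2.0 * (cross["MZ"] - cross["DZ"]), floor)
    C = _nearest_spd(2.0 * cross["DZ"] - cross["MZ"], floor)
    E = _nearest_spd(within - A - C, floor)
    mu = np.array([
        np.mean(np.concatenate([vals[:, 0], vals[:, 2]])),
        np.mean(np.concatenate([vals[:, 1], vals[:, 3]])),
    ])
    return CholeskyParams(
        l_a=np.linalg.cholesky(A), l_c=np.linalg.cholesky(C),
        l_e=np.linalg.cholesky(E), mu=mu,
    )


def _initial_weights(spec: ModelSpec) -> MixtureWeights | None:
    if not spec.is_mixture:
        return None
    if spec.family == "mix2":
        return MixtureWeights.concordant_only()
    return MixtureWeights.equal()


def _start_points(data, spec, parameterization, n_starts, rng):
    """Unconstrained start vectors: MoM, cluster-swapped MoM, perturbations."""
    starts = []
    base = parameterization.to_unconstrained(
        _mom_cholesky(data) if spec.family == "cholesky" else _mom_doc_params(data, spec, rng),
        _initial_weights(spec),
    )
    starts.append(base)
    if spec.is_mixture and n_starts > 1:
        starts.append(
            parameterization.to_unconstrained(
                _mom_doc_params(data, spec, rng, swap_clusters=True),
                _initial_weights(spec),
            )
        )
    while len(starts) < n_starts:
        starts.append(base + rng.normal(0.0, 0.25, size=base.shape))
    return starts[:n_starts]


# ---------------------------------------------------------------------------
# fitting


def _make_nll(data, spec, parameterization, missing):
    if missing == "marginalize":
        def nll(z):
            try:
                params, weights = parameterization.from_unconstrained(z)
                val = minus2_loglik(data, spec, params, weights, missing=missing)
            except (np.linalg.LinAlgError, ValueError, FloatingPointError):
                return _BIG
            if not np.isfinite(val):
                return _BIG
            return val

        return nll

    evaluator = LikelihoodEvaluator(data, spec)

    def nll(z):
        try:
            params, weights = parameterization.from_unconstrained(z)
            val = evaluator.minus2ll(params, weights)
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            return _BIG
        if not np.isfinite(val):
            return _BIG
        return val

    return nll


def fit(
    data,
    spec: ModelSpec | str,
    n_starts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    missing: str = "complete",
) -> FitResult:
    """Fit one model family by multi-start maximum likelihood.

    Deterministic given (data, seed).  Raises if no start reaches a finite
    optimum, reporting the per-start status.
    """
    if isinstance(spec, str):
        spec = ModelSpec(family=spec)
    spec.validate()
    data = as_twin_dataset(data)
    if len(data) == 0:
        raise ValueError("cannot fit an empty dataset")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if missing == "complete":
        keep = np.isfinite(data.values).all(axis=1)
        data = TwinDataset(data.values[keep], data.zygosity[keep])
        if len(data) == 0:
            raise ValueError("no complete pairs left after complete-case filtering")
    parameterization = Parameterization(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    starts = _start_points(data, spec, parameterization, n_starts, rng)
    nll = _make_nll(data, spec, parameterization, missing)

    best = None
    statuses = []
    for idx, z0 in enumerate(starts):
        res = minimize(
            nll, z0, method="L-BFGS-B",
            options=dict(maxiter=max_iter, maxfun=20 * max_iter, ftol=1e-10, gtol=1e-5),
        )
        statuses.append((idx, float(res.fun), bool(res.success), res.message))
        if res.fun < _BIG and (best is None or res.fun < best[1].fun - 1e-9):
            best = (idx, res)
    if best is None:
        lines = "; ".join(f"start {i}: f={f:.3g} ok={s} ({m})" for i, f, s, m in statuses)
        raise RuntimeError(f"no start converged to a finite optimum: {lines}")
    idx, res = best
    params, weights = parameterization.from_unconstrained(res.x)
    k = count_free_parameters(spec)
    m2ll = float(res.fun)
    degrees = model_df(spec, data.n_datapoints())
    if weights is not None:
        small = [w for w in (*weights.omega_mz, *weights.omega_dz) if 0 < w < 1e-4]
        if small:
            logger.warning("degenerate mixture component(s) with weight < 1e-4: %s", small)
    return FitResult(
        spec=spec, params=params, weights=weights,
        minus2ll=m2ll, k=k, df=degrees, aic=aic(m2ll, k),
        converged=bool(res.success), n_starts_used=len(starts), best_start=idx,
        n_iter=int(res.nit), start_minus2lls=tuple(round(f, 6) for _, f, _, _ in statuses),
    )


def fit_model_set(
    data,
    n_starts: int = 4,
    seed: int = 0,
    max_iter: int = 500,
    families=FAMILIES,
) -> tuple[pd.DataFrame, dict]:
    """Fit the six-family comparison set and tabulate df / -2LL / AIC.

    Per-family failures are flagged in the table (NaN fit statistics) rather
    than aborting the whole set.
    """
    data = as_twin_dataset(data)
    rows, results = [], {}
    for family in families:
        spec = ModelSpec(family=family)
        try:
            fr = fit(data, spec, n_starts=n_starts, seed=seed, max_iter=max_iter)
            rows.append(
                dict(family=family, k=fr.k, df=fr.df, minus2ll=fr.minus2ll,
                     aic=fr.aic, converged=fr.converged, error="")
            )
            results[family] = fr
        except Exception as err:  # noqa: BLE001 - flagged, never fatal for the set
            logger.warning("fit of %s failed: %s", family, err)
            rows.append(
                dict(family=family, k=count_free_parameters(spec), df=np.nan,
                     minus2ll=np.nan, aic=np.nan, converged=False, error=str(err))
            )
    return pd.DataFrame(rows), results


# ---------------------------------------------------------------------------
# scikit-learn estimator


class MixDoC(BaseEstimator):
    """Direction-of-causation twin model with optional causal-direction mixture.

    Parameters
    ----------
    family : str
        ``mix4`` (4 causal-direction classes per zygosity), ``mix2``
        (concordant classes only), ``doc_xy``/``doc_yx`` (single-class
        unidirectional), ``doc_bidir`` (reciprocal causation) or
        ``cholesky`` (saturated bivariate ACE).
    confound_ra_free : bool
        Free the additive-genetic cross-trait correlation (the extended
        variant); ignored/invalid for ``cholesky``.
    proportions_by_zygosity : bool
        Estimate separate mixing proportions for MZ and DZ pairs.
    n_starts, max_iter : int
        Multi-start budget and per-start iteration cap.
    missing : str
        ``complete`` drops pairs with missing values, ``marginalize``
        integrates the pair density over its missing entries.
    random_state : int or None
        Seed for start-point perturbations (an int makes fits reproducible).

    After ``fit``, estimates live in ``params_`` and ``weights_``, and fit
    statistics in ``minus2ll_``, ``k_``, ``df_``, ``aic_``, ``converged_``.
    """

    def __init__(
        self,
        family: str = "mix4",
        *,
        confound_ra_free: bool = False,
        proportions_by_zygosity: bool = True,
        n_starts: int = 10,
        max_iter: int = 500,
        missing: str = "complete",
        random_state: int | None = 0,
    ):
        self.family = family
        self.confound_ra_free = confound_ra_free
        self.proportions_by_zygosity = proportions_by_zygosity
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.missing = missing
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            family=self.family,
            confound_ra_free=self.confound_ra_free,
            proportions_by_zygosity=self.proportions_by_zygosity,
        )

    def _seed(self) -> int:
        if self.random_state is None:
            return int(np.random.default_rng().integers(2**31))
        return int(self.random_state)

    def fit(self, X, y=None):
        data = as_twin_dataset(X, y)
        self.result_ = fit(
            data, self._spec(), n_starts=self.n_starts, seed=self._seed(),
            max_iter=self.max_iter, missing=self.missing,
        )
        self.params_ = self.result_.params
        self.weights_ = self.result_.weights
        self.minus2ll_ = self.result_.minus2ll
        self.k_ = self.result_.k
        self.df_ = self.result_.df
        self.aic_ = self.result_.aic
        self.converged_ = self.result_.converged
        self.n_iter_ = self.result_.n_iter
        return self

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise AttributeError("this MixDoC instance is not fitted yet; call fit first")

    def score_samples(self, X, y=None) -> np.ndarray:
        """Per-pair mixture log density under the fitted model."""
        from .classification import _pair_log_mixture

        self._check_fitted()
        data = as_twin_dataset(X, y)
        return _pair_log_mixture(data, self.result_)[0]

    def score(self, X, y=None) -> float:
        """Mean per-pair log-likelihood (sklearn convention: higher is better)."""
        return float(np.mean(self.score_samples(X, y)))

    def predict_proba(self, X, y=None) -> np.ndarray:
        """Posterior causal-class membership probabilities (pairs x classes)."""
        from .classification import posterior_probabilities

        self._check_fitted()
        data = as_twin_dataset(X, y)
        return posterior_probabilities(data, self.result_).p

    def predict(self, X, y=None) -> np.ndarray:
        """Hard causal-class assignment by maximum posterior probability."""
        from .classification import assign_classes, posterior_probabilities

        self._check_fitted()
        data = as_twin_dataset(X, y)
        return assign_classes(posterior_probabilities(data, self.result_))
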