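"""Raw-data (FIML) mixture likelihood over twin pairs.

Each pair contributes log f(y) = log sum_c omega_c Phi_c(y; mu_c, sigma_c),
where the per-class moments come from :mod:`mixdoc.model_core` and the sum
runs over the causal-direction classes of the family (a single term for the
non-mixture families).  MZ and DZ pairs use their own zygosity's moments and
mixing proportions.  The class sum is evaluated with log-sum-exp so small
densities never underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .data import TwinDataset, ZYGOSITIES
from .model_core import ModelSpec, PairModel, family_moments

__all__ = [
    "MixtureWeights",
    "pair_log_density",
    "mvn_logpdf",
    "minus2_loglik",
    "aic",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MixtureWeights:
    """Per-zygosity mixing proportions over the four causal-direction classes.

    Order: (concordant X→Y, concordant Y→X, discordant, discordant).  Twin
    order within a pair is arbitrary, so the two discordant proportions are
    constrained equal; a 2-class model simply fixes them to zero.
    """

    omega_mz: tuple
    omega_dz: tuple

    def __post_init__(self):
        for name in ("omega_mz", "omega_dz"):
            w = np.asarray(getattr(self, name), dtype=float)
            if w.shape != (4,):
                raise ValueError(f"{name} must have 4 entries")
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} must be a probability vector, got {w}")
            if abs(w[2] - w[3]) > 1e-10:
                raise ValueError("discordant-class proportions must be equal")
            object.__setattr__(self, name, tuple(w))

    def omega(self, zygosity: str) -> np.ndarray:
        return np.asarray(self.omega_mz if zygosity == "MZ" else self.omega_dz)

    @classmethod
    def equal(cls) -> "MixtureWeights":
        q = (0.25, 0.25, 0.25, 0.25)
        return cls(q, q)

    @classmethod
    def concordant_only(cls, p_xy_mz: float = 0.5, p_xy_dz: float = 0.5) -> "MixtureWeights":
        return cls((p_xy_mz, 1 - p_xy_mz, 0.0, 0.0), (p_xy_dz, 1 - p_xy_dz, 0.0, 0.0))


def mvn_logpdf(Y: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Gaussian log density of the rows of ``Y`` (any dimension d)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    d = Y.shape[1]
    L = np.linalg.cholesky(sigma)
    z = solve_triangular(L, (Y - mu).T, lower=True, check_finite=False)
    quad = np.einsum("ij,ij->j", z, z)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (d * _LOG_2PI + logdet + quad)


def pair_log_density(y4: np.ndarray, model: PairModel) -> float:
    """Exact 4-variate Gaussian log density of one pair vector."""
    y4 = np.asarray(y4, dtype=float)
    if y4.shape != (4,):
        raise ValueError("y4 must be a length-4 vector (x1, y1, x2, y2)")
    if not np.isfinite(y4).all():
        raise ValueError("pair vector contains non-finite values")
    return float(mvn_logpdf(y4[None, :], model.mu, model.sigma)[0])


def _class_log_matrix(Y, models, context):
    """(C, n) matrix of per-class log densities; names the class on failure."""
    out = np.empty((len(models), Y.shape[0]))
    for c, m in enumerate(models):
        try:
            out[c] = mvn_logpdf(Y, m.mu, m.sigma)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"class {c} ({context}): {err}") from err
    return out


def _marginal_logpdf(Y, model):
    """Per-row Gaussian log density marginalized to each row's observed entries."""
    n = Y.shape[0]
    out = np.zeros(n)
    obs = np.isfinite(Y)
    for pattern in np.unique(obs, axis=0):
        rows = np.nonzero((obs == pattern).all(axis=1))[0]
        idx = np.nonzero(pattern)[0]
        if idx.size == 0:
            continue  # fully missing pair contributes nothing
        sub = Y[np.ix_(rows, idx)]
        out[rows] = mvn_logpdf(sub, model.mu[idx], model.sigma[np.ix_(idx, idx)])
    return out


def minus2_loglik(
    data: TwinDataset,
    spec: ModelSpec,
    params,
    weights: MixtureWeights | None = None,
    missing: str = "complete",
) -> float:
    """-2 log-likelihood of a twin dataset under one model family.

    ``missing="complete"`` (default) drops pairs with any missing value;
    ``missing="marginalize"`` integrates each pair's density over its missing
    entries instead.  Weights are ignored for the single-class families.
    """
    spec.validate()
    if missing not in ("complete", "marginalize"):
        raise ValueError("missing must be 'complete' or 'marginalize'")
    if spec.is_mixture and weights is None:
        raise ValueError(f"family {spec.family} requires mixing weights")
    total = 0.0
    for zyg in ZYGOSITIES:
        Y = data.by_zygosity(zyg)
        if Y.shape[0] == 0:
            continue
        if np.isinf(Y).any():
            raise ValueError("trait values must be finite (NaN marks missing)")
        if missing == "complete":
            Y = Y[np.isfinite(Y).all(axis=1)]
            if Y.shape[0] == 0:
                continue
        models = family_moments(params, spec, zyg)
        if not spec.is_mixture:
            if missing == "marginalize" and not np.isfinite(Y).all():
                lp = _marginal_logpdf(Y, models[0])
            else:
                lp = _class_log_matrix(Y, models, zyg)[0]
            total += lp.sum()
            continue
        w = weights.omega(zyg)
        active = np.nonzero(w > 0)[0]
        if spec.family == "mix2" and (w[2] > 0 or w[3] > 0):
            raise ValueError("mix2 requires zero discordant proportions")
        if missing == "marginalize" and not np.isfinite(Y).all():
            logs = np.vstack([_marginal_logpdf(Y, models[c]) for c in active])
        else:
            logs = _class_log_matrix(Y, [models[c] for c in active], zyg)
        total += logsumexp(logs + np.log(w[active])[:, None], axis=0).sum()
    return -2.0 * total


def aic(minus2ll: float, k: int) -> float:
    """Akaike information criterion, -2LL + 2k."""
    if k < 0:
        raise ValueError("parameter count must be non-negative")
    return float(minus2ll) + 2.0 * k


# ---------------------------------------------------------------------------
# optimizer hot path


class LikelihoodEvaluator:
    """-2LL evaluator bound to one dataset and family.

    Functionally identical to :func:`minus2_loglik` on complete data (the
    test suite asserts agreement) but restructured for the optimizer's inner
    loop: per-zygosity data are extracted once, class covariances are built
    with closed-form reduced-form algebra and factored with batched 4x4
    Cholesky decompositions.
    """

    def __init__(self, data: TwinDataset, spec: ModelSpec):
        from .model_core import TWIN_A_CORR, Direction, family_class_labels

        spec.validate()
        self.spec = spec
        self._Y = {}
        for zyg in ZYGOSITIES:
            Y = data.by_zygosity(zyg)
            Y = Y[np.isfinite(Y).all(axis=1)]
            if Y.shape[0]:
                self._Y[zyg] = np.ascontiguousarray(Y)
        self._gamma = TWIN_A_CORR
        if spec.family == "cholesky":
            self._labels = None
        else:
            labels = family_class_labels(spec.family)
            # per class and twin: 0 = X->Y, 1 = Y->X, 2 = reciprocal
            code = {Direction.XY: 0, Direction.YX: 1, Direction.BOTH: 2}
            self._labels = [(code[l.twin1], code[l.twin2]) for l in labels]

    # -- moment assembly ----------------------------------------------------

    def _doc_reduced(self, p):
        """(C,4,4) reduced-form transforms T=(I-B)^{-1} and (C,4) intercepts."""
        t_dir = np.empty((3, 2, 2))
        t_dir[0] = [[1.0, 0.0], [p.b_xy, 1.0]]  # X->Y: nilpotent, (I-B)^{-1}=I+B
        t_dir[1] = [[1.0, p.b_yx], [0.0, 1.0]]
        det = 1.0 - p.b_xy * p.b_yx
        if abs(det) < 1e-12:
            raise np.linalg.LinAlgError("reciprocal effects make (I - B) singular")
        t_dir[2] = np.array([[1.0, p.b_yx], [p.b_xy, 1.0]]) / det
        nu_dir = np.array(
            [[p.nu_x_xy, p.nu_y_xy], [p.nu_x_yx, p.nu_y_yx], [p.nu_x_xy, p.nu_y_xy]]
        )
        C = len(self._labels)
        Ts = np.zeros((C, 4, 4))
        nus = np.empty((C, 4))
        for c, (d1, d2) in enumerate(self._labels):
            Ts[c, :2, :2] = t_dir[d1]
            Ts[c, 2:, 2:] = t_dir[d2]
            nus[c, :2] = t_dir[d1] @ nu_dir[d1]
            nus[c, 2:] = t_dir[d2] @ nu_dir[d2]
        return Ts, nus

    def _psi(self, p, gamma):
        vx = p.a_x**2 + p.c_x**2 + p.e_x**2
        vy = p.a_y**2 + p.c_y**2 + p.e_y**2
        w_within = p.r_a * p.a_x * p.a_y + p.r_c * p.c_x * p.c_y + p.r_e * p.e_x * p.e_y
        ct_x = gamma * p.a_x**2 + p.c_x**2
        ct_y = gamma * p.a_y**2 + p.c_y**2
        w_cross = gamma * p.r_a * p.a_x * p.a_y + p.r_c * p.c_x * p.c_y
        return np.array(
            [
                [vx, w_within, ct_x, w_cross],
                [w_within, vy, w_cross, ct_y],
                [ct_x, w_cross, vx, w_within],
                [w_cross, ct_y, w_within, vy],
            ]
        )

    def class_moments(self, params):
        """{zygosity: (mus (C,4), sigmas (C,4,4))} for the bound family."""
        out = {}
        if self.spec.family == "cholesky":
            A = params.l_a @ params.l_a.T
            Cm = params.l_c @ params.l_c.T
            E = params.l_e @ params.l_e.T
            within = A + Cm + E
            mu = np.tile(np.asarray(params.mu, float), 2)[None, :]
            for zyg in self._Y:
                cross = self._gamma[zyg] * A + Cm
                out[zyg] = (mu, np.block([[within, cross], [cross, within]])[None])
            return out
        Ts, nus = self._doc_reduced(params)
        for zyg in self._Y:
            psi = self._psi(params, self._gamma[zyg])
            sigmas = Ts @ psi @ Ts.transpose(0, 2, 1)
            out[zyg] = (nus, sigmas)
        return out

    # -- evaluation ---------------------------------------------------------

    def minus2ll(self, params, weights: MixtureWeights | None = None) -> float:
        moments = self.class_moments(params)
        total = 0.0
        for zyg, Y in self._Y.items():
            mus, sigmas = moments[zyg]
            L = np.linalg.cholesky(sigmas)  # batched; raises on non-PD
            diag = L[:, range(4), range(4)]
            logdet = 2.0 * np.log(diag).sum(axis=1)
            Linv = np.linalg.inv(L)
            dev = Y[None, :, :] - mus[:, None, :]
            z = dev @ Linv.transpose(0, 2, 1)  # batched BLAS matmul
            lp = -0.5 * (4.0 * _LOG_2PI + logdet[:, None] + (z * z).sum(axis=2))
            if self.spec.is_mixture:
                w = weights.omega(zyg)[: lp.shape[0]]
                active = w > 0
                lp = lp[active] + np.log(w[active])[:, None]
                top = lp.max(axis=0)
                total += (top + np.log(np.exp(lp - top).sum(axis=0))).sum()
            else:
                total += lp[0].sum()
        return -2.0 * total
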