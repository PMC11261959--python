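"""Bijective reparameterization onto an unconstrained optimization scale.

Loadings (non-negative, E strictly positive) travel on the log scale,
correlations through atanh, mixing proportions through a multinomial logit
that bakes in both the simplex constraint and the equality of the two
discordant classes.  Everything else (causal effects, intercepts) is
unconstrained already.  The maps round-trip to machine precision, which the
optimizer relies on for reporting estimates back on the natural scale.
"""

from __future__ import annotations

import numpy as np

from .likelihood import MixtureWeights
from .model_core import CholeskyParams, DoCParams, ModelSpec, count_free_parameters

__all__ = ["Parameterization"]

_PATHS = ("a_x", "c_x", "e_x", "a_y", "c_y", "e_y")

_FAMILY_STRUCTURAL = {
    # (causal fields, intercept fields)
    "mix4": (("b_xy", "b_yx"), ("nu_x_xy", "nu_y_xy", "nu_x_yx", "nu_y_yx")),
    "mix2": (("b_xy", "b_yx"), ("nu_x_xy", "nu_y_xy", "nu_x_yx", "nu_y_yx")),
    "doc_xy": (("b_xy",), ("nu_x_xy", "nu_y_xy")),
    "doc_yx": (("b_yx",), ("nu_x_yx", "nu_y_yx")),
    "doc_bidir": (("b_xy", "b_yx"), ("nu_x_xy", "nu_y_xy")),
}

_CHOL_FIELDS = (
    ("l_a", 0, 0, "pos"), ("l_a", 1, 0, "free"), ("l_a", 1, 1, "pos"),
    ("l_c", 0, 0, "pos"), ("l_c", 1, 0, "free"), ("l_c", 1, 1, "pos"),
    ("l_e", 0, 0, "pos"), ("l_e", 1, 0, "free"), ("l_e", 1, 1, "pos"),
)


def _to_log(value: float, name: str) -> float:
    if value <= 0:
        raise ValueError(f"{name}={value} out of domain: must be > 0 on the optimization scale")
    return float(np.log(value))


def _to_atanh(value: float, name: str) -> float:
    if not -1.0 < value < 1.0:
        raise ValueError(f"{name}={value} out of domain: must lie strictly inside (-1, 1)")
    return float(np.arctanh(value))


class Parameterization:
    """Packs/unpacks one family's free parameters to a flat unconstrained vector."""

    def __init__(self, spec: ModelSpec):
        spec.validate()
        self.spec = spec
        names: list[str] = []
        if spec.family == "cholesky":
            names += [f"{f}[{i}{j}]" for f, i, j, _ in _CHOL_FIELDS]
            names += ["mu_x", "mu_y"]
        else:
            causal, intercepts = _FAMILY_STRUCTURAL[spec.family]
            names += list(_PATHS) + list(causal) + list(intercepts)
            if spec.confound_ra_free:
                names.append("r_a")
            if spec.is_mixture:
                groups = ("MZ", "DZ") if spec.proportions_by_zygosity else ("pooled",)
                n_logit = 2 if spec.family == "mix4" else 1
                for g in groups:
                    names += [f"logit{j + 1}_{g}" for j in range(n_logit)]
        self.names = tuple(names)
        assert len(names) == count_free_parameters(spec)

    @property
    def n_params(self) -> int:
        return len(self.names)

    # -- forward ------------------------------------------------------------

    def to_unconstrained(self, params, weights: MixtureWeights | None = None) -> np.ndarray:
        spec = self.spec
        z: list[float] = []
        if spec.family == "cholesky":
            if not isinstance(params, CholeskyParams):
                raise TypeError("cholesky family expects CholeskyParams")
            params.validate()
            for field, i, j, kind in _CHOL_FIELDS:
                v = float(np.asarray(getattr(params, field))[i, j])
                z.append(_to_log(v, f"{field}[{i}{j}]") if kind == "pos" else v)
            z += [float(params.mu[0]), float(params.mu[1])]
            return np.array(z)
        if not isinstance(params, DoCParams):
            raise TypeError(f"family {spec.family} expects DoCParams")
        params.validate()
        for name in _PATHS:
            z.append(_to_log(getattr(params, name), name))
        causal, intercepts = _FAMILY_STRUCTURAL[spec.family]
        z += [float(getattr(params, n)) for n in causal]
        z += [float(getattr(params, n)) for n in intercepts]
        if spec.confound_ra_free:
            z.append(_to_atanh(params.r_a, "r_a"))
        if spec.is_mixture:
            if weights is None:
                raise ValueError("mixture families need MixtureWeights")
            groups = ("MZ", "DZ") if spec.proportions_by_zygosity else ("MZ",)
            for g in groups:
                z += list(self._weights_to_logits(weights.omega(g)))
        return np.array(z)

    def _weights_to_logits(self, w: np.ndarray) -> tuple:
        if self.spec.family == "mix4":
            if w[0] <= 0 or w[1] <= 0 or w[2] <= 0:
                raise ValueError(
                    f"mix4 proportions must be strictly positive on the logit scale, got {w}"
                )
            return (float(np.log(w[0] / w[2])), float(np.log(w[1] / w[2])))
        # mix2: only the two concordant classes
        if w[0] <= 0 or w[1] <= 0:
            raise ValueError(f"mix2 concordant proportions must be positive, got {w}")
        return (float(np.log(w[0] / w[1])),)

    # -- inverse ------------------------------------------------------------

    def from_unconstrained(self, z: np.ndarray):
        spec = self.spec
        z = np.asarray(z, dtype=float)
        if z.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters, got {z.shape}")
        if spec.family == "cholesky":
            mats = {"l_a": np.zeros((2, 2)), "l_c": np.zeros((2, 2)), "l_e": np.zeros((2, 2))}
            for val, (field, i, j, kind) in zip(z[:9], _CHOL_FIELDS):
                mats[field][i, j] = np.exp(val) if kind == "pos" else val
            return CholeskyParams(mu=np.array(z[9:11]), **mats), None
        pos = 0
        kw = {}
        for name in _PATHS:
            kw[name] = float(np.exp(z[pos])); pos += 1
        causal, intercepts = _FAMILY_STRUCTURAL[spec.family]
        for name in causal + intercepts:
            kw[name] = float(z[pos]); pos += 1
        if spec.confound_ra_free:
            kw["r_a"] = float(np.tanh(z[pos])); pos += 1
        params = DoCParams(**kw)
        weights = None
        if spec.is_mixture:
            n_logit = 2 if spec.family == "mix4" else 1
            omegas = []
            groups = 2 if spec.proportions_by_zygosity else 1
            for _ in range(groups):
                omegas.append(self._logits_to_weights(z[pos : pos + n_logit]))
                pos += n_logit
            if groups == 1:
                omegas.append(omegas[0])
            weights = MixtureWeights(tuple(omegas[0]), tuple(omegas[1]))
        assert pos == self.n_params
        return params, weights

    def _logits_to_weights(self, logits: np.ndarray) -> np.ndarray:
        if self.spec.family == "mix4":
            l1, l2 = logits
            m = max(l1, l2, 0.0)
            e1, e2, e3 = np.exp(l1 - m), np.exp(l2 - m), np.exp(-m)
            denom = e1 + e2 + 2.0 * e3
            return np.array([e1, e2, e3, e3]) / denom
        p = 1.0 / (1.0 + np.exp(-logits[0]))
        return np.array([p, 1.0 - p, 0.0, 0.0])
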