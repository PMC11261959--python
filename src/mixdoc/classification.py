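"""Posterior class membership and the relative-entropy classification index.

For a fitted mixture, each twin pair's posterior probability of belonging to
causal-direction class c is Bayes' rule over the class densities,

    p_ic = omega_c Phi_c(y_i) / sum_k omega_k Phi_k(y_i),

evaluated in log space.  Classification quality is summarized by the
relative entropy index

    Ent = 1 - sum_i sum_c (-p_ic ln p_ic) / (N ln C),

which is 0 when every posterior is uniform (classification no better than
the prior) and 1 when every posterior is degenerate (perfect assignment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import TwinDataset, as_twin_dataset
from .likelihood import MixtureWeights, _class_log_matrix
from .model_core import CLASS_NAMES, ModelSpec, family_moments

__all__ = [
    "PosteriorMatrix",
    "posterior_probabilities",
    "posterior_probabilities_at",
    "relative_entropy",
    "assign_classes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PosteriorMatrix:
    """Pairs x classes posterior probabilities with zygosity bookkeeping."""

    p: np.ndarray
    zygosity: np.ndarray
    class_names: tuple

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2:
            raise ValueError("posterior matrix must be 2-D (pairs x classes)")
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise ValueError("posterior probabilities must lie in [0, 1]")
        if p.shape[0] and np.abs(p.sum(axis=1) - 1.0).max() > 1e-10:
            raise ValueError("posterior rows must sum to 1")
        object.__setattr__(self, "p", p)

    @property
    def n_classes(self) -> int:
        return self.p.shape[1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.p, columns=list(self.class_names))
        df.insert(0, "zygosity", self.zygosity)
        return df


def _pair_log_mixture(data: TwinDataset, fit):
    """(per-pair log mixture density, per-pair-per-class joint log terms)."""
    spec: ModelSpec = fit.spec
    n = len(data)
    n_classes = len(family_moments(fit.params, spec, "MZ"))
    joint = np.full((n, n_classes), -np.inf)
    for zyg in ("MZ", "DZ"):
        idx = np.nonzero(data.zygosity == zyg)[0]
        if idx.size == 0:
            continue
        Y = data.values[idx]
        models = family_moments(fit.params, spec, zyg)
        logs = _class_log_matrix(Y, models, zyg).T  # (n_z, C)
        if spec.is_mixture:
            w = fit.weights.omega(zyg)[:n_classes]
            with np.errstate(divide="ignore"):
                logs = logs + np.log(w)
        joint[idx] = logs
    return logsumexp(joint, axis=1), joint


def posterior_probabilities(data, fit) -> PosteriorMatrix:
    """Posterior causal-class probabilities for every pair under a fitted mixture."""
    data = as_twin_dataset(data)
    spec: ModelSpec = fit.spec
    if not spec.is_mixture:
        raise ValueError(
            f"family {spec.family!r} has a single class; posterior classification "
            "needs a mixture family (mix4 or mix2)"
        )
    log_mix, joint = _pair_log_mixture(data, fit)
    with np.errstate(invalid="ignore"):
        p = np.exp(joint - log_mix[:, None])
    p = np.where(np.isfinite(p), p, 0.0)
    p /= p.sum(axis=1, keepdims=True)
    names = CLASS_NAMES[: p.shape[1]]
    return PosteriorMatrix(p=p, zygosity=data.zygosity, class_names=names)


def posterior_probabilities_at(data, spec: ModelSpec, params, weights: MixtureWeights) -> PosteriorMatrix:
    """Posteriors evaluated at supplied (e.g. generating) parameter values."""
    from types import SimpleNamespace

    shim = SimpleNamespace(spec=spec, params=params, weights=weights)
    return posterior_probabilities(data, shim)


def relative_entropy(post, by_zygosity: bool = False):
    """Relative entropy index in [0, 1] of a posterior matrix.

    By default all pairs are pooled (the sampling unit is the pair, and the
    classes align across the two zygosity groups); ``by_zygosity=True``
    returns the index computed separately within MZ and DZ pairs.
    """
    if isinstance(post, PosteriorMatrix):
        p, zyg = post.p, post.zygosity
    else:
        p = np.asarray(post, dtype=float)
        zyg = None
        if by_zygosity:
            raise ValueError("by_zygosity needs a PosteriorMatrix with zygosity labels")
    if p.ndim != 2 or p.shape[1] < 2:
        raise ValueError("need an (N, C) posterior matrix with C >= 2 classes")
    if p.shape[0] == 0:
        raise ValueError("cannot compute entropy of an empty posterior matrix")
    if by_zygosity:
        return {
            z: relative_entropy(p[zyg == z]) for z in ("MZ", "DZ") if (zyg == z).any()
        }
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)  # 0 ln 0 = 0
    total_shannon = -plogp.sum()
    n, c = p.shape
    return float(1.0 - total_shannon / (n * np.log(c)))


def assign_classes(post) -> np.ndarray:
    """Hard class labels (0-based indices) by maximum posterior probability.

    Ties go to the lowest class index and are logged.
    """
    p = post.p if isinstance(post, PosteriorMatrix) else np.asarray(post, dtype=float)
    labels = p.argmax(axis=1)  # argmax already prefers the lowest index on ties
    ties = (p == p.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.warning(
            "%d pair(s) had tied posterior probabilities; assigned to the lowest class index",
            int(ties.sum()),
        )
    return labels
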