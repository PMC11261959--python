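"""Seeded twin-pair data generators.

Two independent sampling routes produce the same distribution and
cross-validate each other:

* :func:`simulate_dataset` draws each pair directly from its class's
  expected 4-variate Gaussian (moment route);
* :func:`structural_simulate` draws the latent A/C/E variables with their
  cross-twin and cross-trait correlations, applies the loadings, and solves
  the causal system for the phenotypes (latent route).

All randomness descends from one root seed through fixed-offset
``SeedSequence`` children (per zygosity and class), so editing one piece of
a scenario never reshuffles the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import TwinDataset, ZYGOSITIES
from .likelihood import MixtureWeights
from .model_core import (
    TWIN_A_CORR,
    ClassLabel,
    Direction,
    DoCParams,
    causal_matrix,
    expected_pair_moments,
    family_class_labels,
    structural_intercepts,
)

__all__ = [
    "ScenarioConfig",
    "simulate_dataset",
    "structural_simulate",
    "make_params",
    "direction_intercepts",
]

GENERATING_FAMILIES = ("mix4", "mix2", "doc_xy", "doc_yx", "doc_bidir")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation condition: sample sizes, class weights and parameters.

    ``fixed_quota=True`` reproduces exact-proportion designs (e.g. exactly a
    quarter of the pairs in each class) instead of a multinomial draw.
    """

    n_mz: int
    n_dz: int
    params: DoCParams
    weights: MixtureWeights = field(default_factory=MixtureWeights.equal)
    family: str = "mix4"
    seed: int = 0
    fixed_quota: bool = False

    def validate(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be non-negative")
        if self.family not in GENERATING_FAMILIES:
            raise ValueError(
                f"generating family must be one of {GENERATING_FAMILIES}, got {self.family!r}"
            )
        self.params.validate()

    def replace(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


def _class_counts(n: int, omega: np.ndarray, fixed: bool, rng: np.random.Generator):
    if fixed:
        # largest-remainder apportionment of n among the classes
        raw = n * omega
        counts = np.floor(raw).astype(int)
        short = n - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
        return counts
    return rng.multinomial(n, omega)


def _active_classes(cfg: ScenarioConfig):
    labels = family_class_labels(cfg.family)
    if cfg.family in ("mix4", "mix2"):
        return labels
    return labels  # single-class families: one label, weight handling below


def _per_class_counts(cfg: ScenarioConfig, zyg: str, rng):
    labels = _active_classes(cfg)
    n = cfg.n_mz if zyg == "MZ" else cfg.n_dz
    if len(labels) == 1:
        return labels, np.array([n])
    omega = cfg.weights.omega(zyg)[: len(labels)]
    omega = omega / omega.sum()
    return labels, _class_counts(n, omega, cfg.fixed_quota, rng)


def _streams(cfg: ScenarioConfig, seed):
    root = cfg.seed if seed is None else seed
    if root < 0:
        raise ValueError("seed must be non-negative")
    return root


def _assemble(parts_values, parts_zyg, root):
    if not parts_values:
        return TwinDataset.empty()
    values = np.vstack(parts_values)
    zyg = np.concatenate(parts_zyg)
    perm = np.random.default_rng(np.random.SeedSequence([root, 999])).permutation(len(zyg))
    return TwinDataset(values[perm], zyg[perm])


def simulate_dataset(cfg: ScenarioConfig, seed: int | None = None) -> TwinDataset:
    """Moment-route sampler: pairs drawn from their class's expected Gaussian."""
    cfg.validate()
    root = _streams(cfg, seed)
    values, zygs = [], []
    for zi, zyg in enumerate(ZYGOSITIES):
        count_rng = np.random.default_rng(np.random.SeedSequence([root, zi, 900]))
        labels, counts = _per_class_counts(cfg, zyg, count_rng)
        for ci, (label, n_c) in enumerate(zip(labels, counts)):
            if n_c == 0:
                continue
            pm = expected_pair_moments(cfg.params, label, zyg)
            rng = np.random.default_rng(np.random.SeedSequence([root, zi, ci]))
            L = np.linalg.cholesky(pm.sigma)
            draws = pm.mu + rng.standard_normal((int(n_c), 4)) @ L.T
            values.append(draws)
            zygs.append(np.full(int(n_c), zyg, dtype=object))
    return _assemble(values, zygs, root)


def _chol2(r: float) -> np.ndarray:
    return np.array([[1.0, 0.0], [r, np.sqrt(max(0.0, 1.0 - r * r))]])


def _latent_pairs(n: int, twin_r: float, trait_r: float, rng) -> np.ndarray:
    """(n, 4) latent scores (x1, y1, x2, y2) with the given correlations.

    Twin sharing is realized as sqrt(gamma)*common + sqrt(1-gamma)*unique so
    the perfectly shared MZ case needs no degenerate Cholesky.
    """
    Lt = _chol2(trait_r).T
    common = rng.standard_normal((n, 2)) @ Lt
    u1 = rng.standard_normal((n, 2)) @ Lt
    u2 = rng.standard_normal((n, 2)) @ Lt
    s, q = np.sqrt(twin_r), np.sqrt(1.0 - twin_r)
    return np.hstack([s * common + q * u1, s * common + q * u2])


def structural_simulate(cfg: ScenarioConfig, seed: int | None = None) -> TwinDataset:
    """Latent-route sampler: explicit A/C/E draws solved through (I-B)^{-1}."""
    cfg.validate()
    p = cfg.params
    root = _streams(cfg, seed)
    values, zygs = [], []
    for zi, zyg in enumerate(ZYGOSITIES):
        count_rng = np.random.default_rng(np.random.SeedSequence([root, zi, 900]))
        labels, counts = _per_class_counts(cfg, zyg, count_rng)
        gamma = TWIN_A_CORR[zyg]
        for ci, (label, n_c) in enumerate(zip(labels, counts)):
            n_c = int(n_c)
            if n_c == 0:
                continue
            rng = np.random.default_rng(np.random.SeedSequence([root, zi, ci]))
            A = _latent_pairs(n_c, gamma, p.r_a, rng)
            C = _latent_pairs(n_c, 1.0, p.r_c, rng)
            E = _latent_pairs(n_c, 0.0, p.r_e, rng)
            loads = np.array([p.a_x, p.a_y, p.a_x, p.a_y]), np.array(
                [p.c_x, p.c_y, p.c_x, p.c_y]
            ), np.array([p.e_x, p.e_y, p.e_x, p.e_y])
            u = A * loads[0] + C * loads[1] + E * loads[2]
            B = causal_matrix(label, p.b_xy, p.b_yx)
            T = np.linalg.inv(np.eye(4) - B)
            nu = structural_intercepts(p, label)
            values.append((nu + u) @ T.T)
            zygs.append(np.full(n_c, zyg, dtype=object))
    return _assemble(values, zygs, root)


# ---------------------------------------------------------------------------
# scenario construction helpers


def direction_intercepts(mu_x: float, mu_y: float, direction: Direction,
                         b_xy: float, b_yx: float) -> tuple:
    """Structural intercepts giving the requested *phenotypic* class means.

    The observed class means are (I-B)^{-1} nu within a twin, so
    nu = (I-B) mu inverts the causal propagation.
    """
    if direction == Direction.XY:
        return (mu_x, mu_y - b_xy * mu_x)
    if direction == Direction.YX:
        return (mu_x - b_yx * mu_y, mu_y)
    return (mu_x - b_yx * mu_y, mu_y - b_xy * mu_x)  # reciprocal


def make_params(
    var_x: tuple = (0.7, 0.1, 0.2),
    var_y: tuple = (0.2, 0.5, 0.3),
    b_xy: float = 0.5,
    b_yx: float = 0.5,
    mean_diff_x: float = 0.0,
    mean_diff_y: float = 0.0,
    base_mean: tuple = (1.0, 1.0),
    r_a: float = 0.0,
    r_c: float = 0.0,
    r_e: float = 0.0,
) -> DoCParams:
    """Build generating parameters from interpretable quantities.

    ``var_x``/``var_y`` are the pre-causal (A, C, E) variance components of
    each trait; loadings are their square roots.  Class means follow the
    structural reading: every class shares the base trait intercepts
    ``base_mean``, the X→Y class is offset by ``-mean_diff/2`` and the Y→X
    class by ``+mean_diff/2`` on each trait, and the *observed* class means
    are the intercepts propagated through the causal paths, ``(I-B)^{-1}
    nu``.  With a nonzero base mean the causal direction itself displaces
    the downstream trait's mean (by b times the upstream intercept), which
    is what lets the mixture separate classes even when ``mean_diff`` is
    small.
    """
    ax2, cx2, ex2 = var_x
    ay2, cy2, ey2 = var_y
    return DoCParams(
        a_x=np.sqrt(ax2), c_x=np.sqrt(cx2), e_x=np.sqrt(ex2),
        a_y=np.sqrt(ay2), c_y=np.sqrt(cy2), e_y=np.sqrt(ey2),
        b_xy=b_xy, b_yx=b_yx,
        nu_x_xy=base_mean[0] - mean_diff_x / 2.0,
        nu_y_xy=base_mean[1] - mean_diff_y / 2.0,
        nu_x_yx=base_mean[0] + mean_diff_x / 2.0,
        nu_y_yx=base_mean[1] + mean_diff_y / 2.0,
        r_a=r_a, r_c=r_c, r_e=r_e,
    )
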