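"""Path-model expectations for bivariate direction-of-causation (DoC) twin models.

The classical twin design measures two traits, X and Y, on monozygotic (MZ)
and dizygotic (DZ) twin pairs.  Each trait is decomposed into additive
genetic (A), shared environmental (C) and unique environmental (E) latent
components with loadings a, c, e; A correlates 1 across MZ co-twins and 0.5
across DZ co-twins, C correlates 1, and E is uncorrelated across twins.
A causal regression between the phenotypes (X→Y with coefficient b_xy,
Y→X with b_yx, or both) carries the cross-trait covariance; optional latent
cross-trait correlations r_a, r_c, r_e model background confounding.

Everything here is exact moment algebra in the reduced form

    p = (I - B)^{-1} (nu + u),      Cov(u) = Psi,

with the pair phenotype vector ordered ``(x1, y1, x2, y2)``.  B holds the
causal regressions, nu the structural intercepts (which may differ by
causal-direction class) and Psi the pre-causal ACE covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "Direction",
    "ClassLabel",
    "MIXTURE_LABELS",
    "BIDIRECTIONAL_LABEL",
    "CLASS_NAMES",
    "DoCParams",
    "CholeskyParams",
    "PairModel",
    "ModelSpec",
    "FAMILIES",
    "MIXTURE_FAMILIES",
    "TWIN_A_CORR",
    "causal_matrix",
    "psi_matrix",
    "structural_intercepts",
    "expected_pair_moments",
    "cholesky_ace_moments",
    "family_class_labels",
    "family_moments",
    "count_free_parameters",
    "model_df",
]

#: additive-genetic cross-twin correlation by zygosity
TWIN_A_CORR = {"MZ": 1.0, "DZ": 0.5}

_PD_TOL = 1e-10


class Direction(str, Enum):
    """Causal direction operating within one twin."""

    XY = "xy"  # X causes Y
    YX = "yx"  # Y causes X
    BOTH = "both"  # reciprocal causation (single-class bidirectional family)


@dataclass(frozen=True)
class ClassLabel:
    """Causal-direction assignment of the two members of a twin pair."""

    twin1: Direction
    twin2: Direction

    def swapped(self) -> "ClassLabel":
        return ClassLabel(self.twin2, self.twin1)


#: canonical class order: concordant X→Y, concordant Y→X, the two discordant
MIXTURE_LABELS = (
    ClassLabel(Direction.XY, Direction.XY),
    ClassLabel(Direction.YX, Direction.YX),
    ClassLabel(Direction.XY, Direction.YX),
    ClassLabel(Direction.YX, Direction.XY),
)
BIDIRECTIONAL_LABEL = ClassLabel(Direction.BOTH, Direction.BOTH)

CLASS_NAMES = ("conc_xy", "conc_yx", "disc_xy_yx", "disc_yx_xy")

FAMILIES = ("mix4", "mix2", "doc_xy", "doc_yx", "doc_bidir", "cholesky")
MIXTURE_FAMILIES = ("mix4", "mix2")


@dataclass(frozen=True)
class DoCParams:
    """Structural parameters of one DoC model variant.

    Loadings are on the trait standard-deviation scale and constrained
    non-negative (they are sign-indeterminate); the unique-environment
    loadings must be strictly positive wherever a proper class density is
    required (enforced by the positive-definiteness checks downstream).
    The four ``nu`` fields are structural intercepts per causal direction:
    a twin whose direction is X→Y receives ``(nu_x_xy, nu_y_xy)``, one whose
    direction is Y→X receives ``(nu_x_yx, nu_y_yx)``.  The bidirectional
    family stores its single intercept pair in the ``_xy`` slots.
    """

    a_x: float
    c_x: float
    e_x: float
    a_y: float
    c_y: float
    e_y: float
    b_xy: float = 0.0
    b_yx: float = 0.0
    nu_x_xy: float = 0.0
    nu_y_xy: float = 0.0
    nu_x_yx: float = 0.0
    nu_y_yx: float = 0.0
    r_a: float = 0.0
    r_c: float = 0.0
    r_e: float = 0.0

    def validate(self) -> None:
        for name in ("a_x", "c_x", "e_x", "a_y", "c_y", "e_y"):
            if getattr(self, name) < 0:
                raise ValueError(f"loading {name} must be >= 0 (sign convention)")
        # e_x = e_y = 0 is allowed for structural simulation of deterministic
        # twins; the moment builders reject it via the positive-definiteness
        # check wherever a proper density is required
        for name in ("r_a", "r_c", "r_e"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation {name}={r} outside [-1, 1]")
        for name in ("b_xy", "b_yx", "nu_x_xy", "nu_y_xy", "nu_x_yx", "nu_y_yx"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def replace(self, **kw) -> "DoCParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class CholeskyParams:
    """Bivariate Cholesky ACE parameters: three 2x2 lower factors + trait means."""

    l_a: np.ndarray
    l_c: np.ndarray
    l_e: np.ndarray
    mu: np.ndarray  # (mu_x, mu_y)

    def validate(self) -> None:
        for name in ("l_a", "l_c", "l_e"):
            L = np.asarray(getattr(self, name), dtype=float)
            if L.shape != (2, 2) or L[0, 1] != 0:
                raise ValueError(f"{name} must be 2x2 lower triangular")
        if np.asarray(self.l_e).diagonal().min() <= 0:
            raise ValueError("diagonal of the E factor must be > 0")
        if np.asarray(self.mu, dtype=float).shape != (2,):
            raise ValueError("mu must have length 2")


@dataclass(frozen=True)
class PairModel:
    """Expected mean (length 4) and covariance (4x4) of one pair vector."""

    mu: np.ndarray
    sigma: np.ndarray


@dataclass(frozen=True)
class ModelSpec:
    """Which model family to entertain, and its constraint switches."""

    family: str
    confound_ra_free: bool = False
    proportions_by_zygosity: bool = True

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.family == "cholesky" and self.confound_ra_free:
            raise ValueError("cholesky already estimates r_a; confound_ra_free is redundant")

    @property
    def is_mixture(self) -> bool:
        return self.family in MIXTURE_FAMILIES


# ---------------------------------------------------------------------------
# structural matrices


def causal_matrix(label: ClassLabel, b_xy: float, b_yx: float) -> np.ndarray:
    """4x4 causal-regression matrix B for a pair, ordering (x1, y1, x2, y2).

    Each twin occupies a 2x2 diagonal block; a unidirectional class puts a
    single regression in each block, the bidirectional label puts both.
    """
    B = np.zeros((4, 4))
    for t, direction in enumerate((label.twin1, label.twin2)):
        o = 2 * t
        if direction in (Direction.XY, Direction.BOTH):
            B[o + 1, o] = b_xy  # y <- x
        if direction in (Direction.YX, Direction.BOTH):
            B[o, o + 1] = b_yx  # x <- y
        if direction == Direction.BOTH and abs(1.0 - b_xy * b_yx) < 1e-12:
            raise ValueError(
                f"reciprocal effects b_xy*b_yx = {b_xy * b_yx} make (I - B) singular"
            )
    return B


def psi_matrix(params: DoCParams, zygosity: str) -> np.ndarray:
    """Pre-causal 4x4 residual covariance Psi built from the ACE components.

    Each component contributes D K D where D holds its loadings and K is the
    Kronecker product of the cross-twin correlation matrix (1 or gamma off
    the diagonal) with the cross-trait correlation matrix (r on the off
    diagonal).  Cross-twin correlations: A = 1 (MZ) / 0.5 (DZ), C = 1, E = 0.
    """
    gamma = TWIN_A_CORR[zygosity]
    psi = np.zeros((4, 4))
    for load_x, load_y, twin_r, trait_r in (
        (params.a_x, params.a_y, gamma, params.r_a),
        (params.c_x, params.c_y, 1.0, params.r_c),
        (params.e_x, params.e_y, 0.0, params.r_e),
    ):
        twin = np.array([[1.0, twin_r], [twin_r, 1.0]])
        trait = np.array([[1.0, trait_r], [trait_r, 1.0]])
        D = np.diag([load_x, load_y, load_x, load_y])
        psi += D @ np.kron(twin, trait) @ D
    return psi


def structural_intercepts(params: DoCParams, label: ClassLabel) -> np.ndarray:
    """Length-4 intercept vector nu for a class label."""
    nu = np.empty(4)
    for t, direction in enumerate((label.twin1, label.twin2)):
        if direction == Direction.YX:
            pair = (params.nu_x_yx, params.nu_y_yx)
        else:  # XY and BOTH share the _xy slots
            pair = (params.nu_x_xy, params.nu_y_xy)
        nu[2 * t : 2 * t + 2] = pair
    return nu


def _check_pd(sigma: np.ndarray, context: str) -> None:
    if np.linalg.eigvalsh(sigma)[0] <= _PD_TOL:
        raise np.linalg.LinAlgError(
            f"expected covariance for {context} is not positive definite"
        )


def expected_pair_moments(
    params: DoCParams, label: ClassLabel, zygosity: str
) -> PairModel:
    """Expected pair mean and covariance under one causal-direction class.

    sigma = (I-B)^{-1} Psi (I-B)^{-T}, mu = (I-B)^{-1} nu.
    Raises on zygosity typos and on non-positive-definite results, naming
    the offending class.
    """
    if zygosity not in TWIN_A_CORR:
        raise ValueError(f"unknown zygosity {zygosity!r}")
    B = causal_matrix(label, params.b_xy, params.b_yx)
    T = np.linalg.inv(np.eye(4) - B)
    sigma = T @ psi_matrix(params, zygosity) @ T.T
    sigma = 0.5 * (sigma + sigma.T)
    _check_pd(sigma, f"class ({label.twin1.value},{label.twin2.value}) {zygosity}")
    mu = T @ structural_intercepts(params, label)
    return PairModel(mu=mu, sigma=sigma)


def cholesky_ace_moments(chol: CholeskyParams, zygosity: str) -> PairModel:
    """Expected pair moments under the saturated bivariate Cholesky ACE model.

    Within-twin block is the sum of the three factor outer products; the
    cross-twin block scales the A part by the zygosity correlation and keeps
    C in full (E never crosses twins).
    """
    if zygosity not in TWIN_A_CORR:
        raise ValueError(f"unknown zygosity {zygosity!r}")
    chol.validate()
    gamma = TWIN_A_CORR[zygosity]
    A = np.asarray(chol.l_a, float) @ np.asarray(chol.l_a, float).T
    C = np.asarray(chol.l_c, float) @ np.asarray(chol.l_c, float).T
    E = np.asarray(chol.l_e, float) @ np.asarray(chol.l_e, float).T
    within = A + C + E
    cross = gamma * A + C
    sigma = np.block([[within, cross], [cross, within]])
    _check_pd(sigma, f"cholesky {zygosity}")
    mu = np.tile(np.asarray(chol.mu, float), 2)
    return PairModel(mu=mu, sigma=sigma)


# ---------------------------------------------------------------------------
# family plumbing


def family_class_labels(family: str) -> tuple[ClassLabel, ...]:
    if family == "mix4":
        return MIXTURE_LABELS
    if family == "mix2":
        return MIXTURE_LABELS[:2]
    if family == "doc_xy":
        return (MIXTURE_LABELS[0],)
    if family == "doc_yx":
        return (MIXTURE_LABELS[1],)
    if family == "doc_bidir":
        return (BIDIRECTIONAL_LABEL,)
    if family == "cholesky":
        raise ValueError("cholesky has no causal-direction classes")
    raise ValueError(f"unknown family {family!r}")


def family_moments(params, spec: ModelSpec, zygosity: str) -> list[PairModel]:
    """Per-class PairModels for one zygosity under any family."""
    spec.validate()
    if spec.family == "cholesky":
        return [cholesky_ace_moments(params, zygosity)]
    return [
        expected_pair_moments(params, label, zygosity)
        for label in family_class_labels(spec.family)
    ]


def count_free_parameters(spec: ModelSpec) -> int:
    """Number of freely estimated parameters of a model family.

    Structural block: 6 loadings, the active causal effects, and the
    direction-specific trait intercepts.  Mixtures add mixing proportions:
    after the simplex constraint and the equality of the two discordant
    classes, mix4 has 2 free proportions per zygosity group and mix2 has 1.
    """
    spec.validate()
    groups = 2 if spec.proportions_by_zygosity else 1
    if spec.family == "mix4":
        k = 6 + 2 + 4 + 2 * groups
    elif spec.family == "mix2":
        k = 6 + 2 + 4 + 1 * groups
    elif spec.family in ("doc_xy", "doc_yx"):
        k = 6 + 1 + 2
    elif spec.family == "doc_bidir":
        k = 6 + 2 + 2
    else:  # cholesky
        k = 9 + 2
    if spec.confound_ra_free:
        k += 1
    return k


def model_df(spec: ModelSpec, n_datapoints: int) -> int:
    """Raw-data degrees of freedom: observed data points minus parameters."""
    k = count_free_parameters(spec)
    df = int(n_datapoints) - k
    if df <= 0:
        raise ValueError(
            f"model {spec.family} with {k} parameters is over-parameterized "
            f"for {n_datapoints} data points"
        )
    return df
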