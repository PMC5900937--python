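"""Synthetic patient cohorts with controlled marginal prevalences and latent
factor structure.

Items are generated by a latent-probit (Gaussian copula) mechanism: a latent
multivariate normal vector z ~ N(0, ΛΦΛᵀ + Ψ) is drawn per patient and item j
is recorded present iff z_j exceeds the upper-tail normal quantile of its
target prevalence. Under this mechanism the tetrachoric correlation between
any two items *is* the corresponding entry of ΛΦΛᵀ + Ψ, so the factor-analysis
stage's dichotomized-bivariate-normal assumption holds exactly in simulation
and parameter recovery can be tested against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .transactions import STUDY_ITEMS, TransactionMatrix

__all__ = [
    "GeneratorConfig",
    "study_default_config",
    "STUDY_PREVALENCES",
    "generate",
    "ground_truth_tetrachoric",
    "worked_fixture",
]

#: Marginal prevalences of the 9 screening items in the study population
#: (counts out of 92 140 patients).
STUDY_PREVALENCES: dict[str, float] = {
    "BP": 75_564 / 92_140,
    "BMI": 56_573 / 92_140,
    "WC": 11_348 / 92_140,
    "LDL": 70_680 / 92_140,
    "A1c": 72_594 / 92_140,
    "smoking": 74_124 / 92_140,
    "alcohol": 54_260 / 92_140,
    "diet": 3_320 / 92_140,
    "exercise": 14_131 / 92_140,
}

# One-factor-per-item loading blocks for the 3 clinical categories. Strong
# within-category loadings and moderately correlated factors give the same
# qualitative structure as the study population: a dominant laboratory pair
# and clearly separated vitals / laboratory / lifestyle groupings.
_STUDY_LOADINGS = np.array(
    [
        # vitals  laboratory  lifestyle
        [0.75, 0.00, 0.00],  # BP
        [0.80, 0.00, 0.00],  # BMI
        [0.65, 0.00, 0.00],  # WC
        [0.00, 0.85, 0.00],  # LDL
        [0.00, 0.85, 0.00],  # A1c
        [0.00, 0.00, 0.70],  # smoking
        [0.00, 0.00, 0.75],  # alcohol
        [0.00, 0.00, 0.60],  # diet
        [0.00, 0.00, 0.65],  # exercise
    ]
)

_STUDY_PHI = np.array(
    [
        [1.00, 0.40, 0.35],
        [0.40, 1.00, 0.35],
        [0.35, 0.35, 1.00],
    ]
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the latent-probit cohort generator.

    ``loadings`` (m x k) and ``factor_correlations`` (k x k) define the
    common part of the latent correlation matrix; uniquenesses are implied,
    Ψ = I − diag(ΛΦΛᵀ), so the latent scale has unit variance per item.
    """

    n: int
    items: tuple[str, ...]
    prevalences: np.ndarray  # (m,)
    loadings: np.ndarray  # (m, k)
    factor_correlations: np.ndarray  # (k, k)
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.prevalences, dtype=float)
        lam = np.asarray(self.loadings, dtype=float)
        phi = np.asarray(self.factor_correlations, dtype=float)
        if p.shape != (len(self.items),):
            raise ValueError("one prevalence per item required")
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("prevalences must lie strictly in (0, 1)")
        if lam.shape[0] != len(self.items):
            raise ValueError("one loading row per item required")
        if phi.shape != (lam.shape[1], lam.shape[1]):
            raise ValueError("factor_correlations shape mismatch")
        if not np.allclose(phi, phi.T) or not np.allclose(np.diag(phi), 1.0):
            raise ValueError("factor_correlations must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(phi)[0] <= 0:
            raise ValueError("factor_correlations must be positive definite")
        common = np.einsum("if,fg,jg->ij", lam, phi, lam)
        if np.any(np.diag(common) >= 1):
            raise ValueError("communalities implied by the loadings reach 1")
        object.__setattr__(self, "prevalences", p)
        object.__setattr__(self, "loadings", lam)
        object.__setattr__(self, "factor_correlations", phi)

    @property
    def uniquenesses(self) -> np.ndarray:
        common = self.loadings @ self.factor_correlations @ self.loadings.T
        return 1.0 - np.diag(common)

    @property
    def thresholds(self) -> np.ndarray:
        """Upper-tail standard-normal quantile per item: P(Z > t_j) = p_j."""
        return stats.norm.isf(self.prevalences)


def study_default_config(n: int = 92_140, seed: int = 0) -> GeneratorConfig:
    """The study-emulating configuration: 9 items, 3 correlated factors."""
    return GeneratorConfig(
        n=n,
        items=STUDY_ITEMS,
        prevalences=np.array([STUDY_PREVALENCES[i] for i in STUDY_ITEMS]),
        loadings=_STUDY_LOADINGS.copy(),
        factor_correlations=_STUDY_PHI.copy(),
        seed=seed,
    )


def ground_truth_tetrachoric(config: GeneratorConfig) -> np.ndarray:
    """Population latent correlation matrix ΛΦΛᵀ + Ψ (unit diagonal)."""
    r = config.loadings @ config.factor_correlations @ config.loadings.T
    np.fill_diagonal(r, 1.0)
    return r


def generate(config: GeneratorConfig) -> TransactionMatrix:
    """Draw a cohort; identical config (including seed) gives identical data."""
    sigma = ground_truth_tetrachoric(config)
    if np.linalg.eigvalsh(sigma)[0] <= 0:
        raise ValueError("latent correlation matrix is not positive definite")
    rng = np.random.default_rng(config.seed)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((config.n, len(config.items))) @ chol.T
    values = (z > config.thresholds).astype(np.uint8)
    ids = tuple(f"P{i + 1}" for i in range(config.n))
    return TransactionMatrix(ids, tuple(config.items), values)


def worked_fixture() -> TransactionMatrix:
    """Deterministic 10-patient, 3-item fixture with hand-checkable metrics.

    Rows 1-7 contain {a, b}; row 8 contains {a, b, c}; row 9 only {b};
    row 10 only {c}. Hence support(a)=0.8, support(b)=0.9, support(c)=0.2,
    support({a,b})=0.8 and confidence(a→b)=1.
    """
    rows = [[1, 1, 0]] * 7 + [[1, 1, 1], [0, 1, 0], [0, 0, 1]]
    return TransactionMatrix.from_arrays(np.array(rows), ("a", "b", "c"))
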