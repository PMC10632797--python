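"""Linear decomposition of the ion-hopping free-energy barrier.

The barrier for the interlayer hop decomposes into an ion–water term
(proportional to the change in hydration number ΔN_water), a carbonyl
term (proportional to the change in carbonyl coordination ΔN_carbonyl)
and an ion–membrane constant:

    ΔG = a·ΔN_water + b·ΔN_carbonyl + c.

Fitting this model across pore configurations separates the two
coordination effects: for K⁺ the carbonyl coefficient is negative
(carbonyl substitution assists the hop), for Na⁺ it is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateDesignError

__all__ = [
    "DecompositionSample",
    "DecompositionFit",
    "fit_decomposition",
    "predict_barrier",
    "read_samples",
    "write_samples",
]


@dataclass(frozen=True)
class DecompositionSample:
    dn_water: float
    dn_carbonyl: float
    dg: float  # kcal/mol

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.dn_water, self.dn_carbonyl, self.dg])):
            raise DegenerateDesignError("sample values must be finite")


@dataclass(frozen=True)
class DecompositionFit:
    """OLS fit of ΔG on (ΔN_water, ΔN_carbonyl, 1)."""

    water_coefficient: float  # a, kcal/mol per unit ΔN_water
    carbonyl_coefficient: float  # b, kcal/mol per unit ΔN_carbonyl
    membrane_constant: float  # c, kcal/mol
    stderr_water: float
    stderr_carbonyl: float
    stderr_constant: float
    residual_std: float
    n_samples: int

    def as_dict(self) -> dict:
        return {
            "water_coefficient": self.water_coefficient,
            "carbonyl_coefficient": self.carbonyl_coefficient,
            "membrane_constant": self.membrane_constant,
            "stderr": {
                "water": self.stderr_water,
                "carbonyl": self.stderr_carbonyl,
                "constant": self.stderr_constant,
            },
            "residual_std": self.residual_std,
            "n_samples": self.n_samples,
        }


def fit_decomposition(samples: list[DecompositionSample]) -> DecompositionFit:
    """Ordinary least squares fit of the barrier decomposition.

    Requires at least 4 samples and a full-rank design (the two ΔN
    regressors and the intercept must not be collinear).
    """
    if len(samples) < 4:
        raise DegenerateDesignError(
            f"need at least 4 samples, got {len(samples)}"
        )
    x = np.array([[s.dn_water, s.dn_carbonyl] for s in samples])
    y = np.array([s.dg for s in samples])
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateDesignError("rank-deficient design matrix")
    res = sm.OLS(y, design).fit()
    c, a, b = res.params
    se_c, se_a, se_b = res.bse
    dof = max(len(samples) - 3, 1)
    return DecompositionFit(
        water_coefficient=float(a),
        carbonyl_coefficient=float(b),
        membrane_constant=float(c),
        stderr_water=float(se_a),
        stderr_carbonyl=float(se_b),
        stderr_constant=float(se_c),
        residual_std=float(np.sqrt(res.ssr / dof)),
        n_samples=len(samples),
    )


def predict_barrier(fit: DecompositionFit, dn_water: float, dn_carbonyl: float) -> float:
    """ΔG (kcal/mol) predicted by the fitted decomposition."""
    return (
        fit.water_coefficient * dn_water
        + fit.carbonyl_coefficient * dn_carbonyl
        + fit.membrane_constant
    )


def read_samples(path: str | Path) -> list[DecompositionSample]:
    """Read `dN_water,dN_carbonyl,dG_kcal_mol` CSV."""
    df = pd.read_csv(path)
    return [
        DecompositionSample(r.dN_water, r.dN_carbonyl, r.dG_kcal_mol)
        for r in df.itertuples()
    ]


def write_samples(samples: list[DecompositionSample], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "dN_water": [s.dn_water for s in samples],
            "dN_carbonyl": [s.dn_carbonyl for s in samples],
            "dG_kcal_mol": [s.dg for s in samples],
        }
    ).to_csv(path, index=False)
    return path
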