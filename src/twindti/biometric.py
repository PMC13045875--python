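"""Univariate ACE/ADE biometric variance decomposition from twin correlations.

The classical twin design partitions the standardized variance of a trait
into additive genetic (A), shared-environment (C) or dominance genetic (D),
and unique-environment (E) components.  Monozygotic (MZ) co-twins share all
genetic variance; dizygotic (DZ) co-twins share half of the additive and a
quarter of the dominance variance, and (by assumption) all of the shared
environment.  The model-implied within-pair correlations are therefore

    ACE:  r_MZ = A + C          r_DZ = A/2 + C
    ADE:  r_MZ = A + D          r_DZ = A/2 + D/4

C and D are confounded in a design with twins reared together, so only one
of the two fully parameterized models can be fitted at a time.  The
conventional choice is driven by the observed correlations: when
``r_DZ < r_MZ / 2`` the DZ correlation is too low for any non-negative C and
an ADE model is indicated, otherwise ACE.

Fitting maximizes the normal-theory likelihood of the two observed 2x2
within-pair correlation matrices given the model-implied matrices, with
group weights ``n - 1`` and non-negativity constraints on the components
(E is floored at 0.001 since it absorbs measurement error and cannot
vanish).  Because the fully parameterized models are exactly identified,
an interior maximum reproduces the observed correlations exactly and
coincides with the closed-form Falconer (method-of-moments) estimates,
which this module also exposes as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "VarianceComponents",
    "FitInput",
    "select_model",
    "expected_twin_correlations",
    "falconer_components",
    "fit_components_ml",
    "broad_sense_G",
]

E_FLOOR = 0.001


@dataclass(frozen=True)
class VarianceComponents:
    """Standardized variance components for one region/metric.

    ``G`` is the heritability reported for the fit: narrow-sense (A) under
    ACE, broad-sense (A + D) under ADE.  ``constrained`` flags a solution
    on the non-negativity boundary (for the ML fit) or a closed-form
    solution with a negative component (for Falconer estimates).
    """

    model: str
    A: float
    C: float
    D: float
    E: float
    region: str | None = None
    metric: str | None = None
    constrained: bool = False

    @property
    def G(self) -> float:
        return self.A if self.model == "ACE" else self.A + self.D

    @property
    def total(self) -> float:
        return self.A + self.C + self.D + self.E


@dataclass(frozen=True)
class FitInput:
    """Observed twin correlations and pair counts for one region/metric."""

    r_mz: float
    n_mz: int
    r_dz: float
    n_dz: int

    def validate(self) -> None:
        for r, n, lab in ((self.r_mz, self.n_mz, "MZ"), (self.r_dz, self.n_dz, "DZ")):
            if not math.isfinite(r) or abs(r) > 1:
                raise ValueError(f"{lab} correlation {r} outside [-1, 1]")
            if abs(r) == 1.0:
                raise ValueError(f"{lab} correlation of +/-1 is degenerate")
            if n < 4:
                raise ValueError(f"{lab} group has {n} pairs; need >= 4")


def select_model(r_mz: float, r_dz: float) -> str:
    """Choose ACE or ADE from the observed correlation pattern.

    ADE iff ``r_dz < r_mz / 2`` (DZ resemblance below the pure-additive
    expectation); ties resolve to ACE.
    """
    if not (math.isfinite(r_mz) and math.isfinite(r_dz)):
        raise ValueError("correlations must be finite")
    return "ADE" if r_dz < r_mz / 2 else "ACE"


def expected_twin_correlations(components: VarianceComponents) -> tuple[float, float]:
    """Model-implied (r_MZ, r_DZ) under the component values."""
    if components.model == "ACE":
        return components.A + components.C, components.A / 2 + components.C
    return components.A + components.D, components.A / 2 + components.D / 4


def falconer_components(r_mz: float, r_dz: float, model: str | None = None) -> VarianceComponents:
    """Closed-form method-of-moments components from two twin correlations.

    ACE:  A = 2(r_MZ - r_DZ),  C = 2 r_DZ - r_MZ,  E = 1 - r_MZ
    ADE:  A = 4 r_DZ - r_MZ,   D = 2 r_MZ - 4 r_DZ, E = 1 - r_MZ

    No constraints are applied: a component may come out negative, in which
    case the result is flagged ``constrained=True`` and the ML fit will pin
    it at zero.
    """
    if model is None:
        model = select_model(r_mz, r_dz)
    if model == "ACE":
        A = 2.0 * (r_mz - r_dz)
        C = 2.0 * r_dz - r_mz
        D = 0.0
    elif model == "ADE":
        A = 4.0 * r_dz - r_mz
        D = 2.0 * r_mz - 4.0 * r_dz
        C = 0.0
    else:
        raise ValueError(f"unknown model {model!r}")
    E = 1.0 - r_mz
    flagged = min(A, C, D, E) < 0
    return VarianceComponents(model=model, A=A, C=C, D=D, E=E, constrained=flagged)


def _neg_log_likelihood(x: np.ndarray, model: str, data: FitInput) -> float:
    """-2/2 * sum of group Wishart log-likelihood terms (constants dropped).

    For a 2x2 correlation matrix with model off-diagonal rho and observed
    off-diagonal r, the per-group contribution is
    ``(n-1) * [log(1 - rho^2) + 2 (1 - rho r) / (1 - rho^2)] / 2``.
    """
    a, x2 = x
    if model == "ACE":
        rho_mz = a + x2
        rho_dz = 0.5 * a + x2
    else:
        rho_mz = a + x2
        rho_dz = 0.5 * a + 0.25 * x2
    total = 0.0
    for rho, r, n in (
        (rho_mz, data.r_mz, data.n_mz),
        (rho_dz, data.r_dz, data.n_dz),
    ):
        one_m = 1.0 - rho * rho
        if one_m <= 1e-12:
            return 1e12
        total += (n - 1) * 0.5 * (math.log(one_m) + 2.0 * (1.0 - rho * r) / one_m)
    return total


def fit_components_ml(
    data: FitInput,
    model: str | None = None,
    *,
    region: str | None = None,
    metric: str | None = None,
) -> VarianceComponents:
    """Constrained maximum-likelihood fit of the fully parameterized model.

    Maximizes the normal-theory likelihood of the MZ and DZ 2x2 correlation
    matrices over (A, C) or (A, D), subject to non-negativity and
    ``A + C + D + E = 1`` with ``E >= 0.001``.  Five deterministic starting
    points are used (one of them the feasibility-clipped Falconer point);
    the best converged likelihood wins, ties resolving to the smallest A.

    When the unconstrained optimum is interior, the fit reproduces the
    observed correlations exactly and equals :func:`falconer_components`.
    """
    data.validate()
    if model is None:
        model = select_model(data.r_mz, data.r_dz)
    if model not in ("ACE", "ADE"):
        raise ValueError(f"unknown model {model!r}")

    upper = 1.0 - E_FLOOR
    moments = falconer_components(data.r_mz, data.r_dz, model)
    m2 = moments.C if model == "ACE" else moments.D
    clipped = np.clip([moments.A, m2], 0.0, upper)
    if clipped.sum() > upper:
        clipped *= upper / clipped.sum()
    starts = [
        clipped,
        np.array([0.3, 0.3]),
        np.array([0.6, 0.1]),
        np.array([0.1, 0.6]),
        np.array([0.02, 0.02]),
    ]

    best: tuple[float, float, np.ndarray] | None = None
    constraint = {"type": "ineq", "fun": lambda x: upper - x[0] - x[1]}
    for x0 in starts:
        res = minimize(
            _neg_log_likelihood,
            x0,
            args=(model, data),
            method="SLSQP",
            bounds=[(0.0, upper), (0.0, upper)],
            constraints=[constraint],
            options={"ftol": 1e-14, "maxiter": 500},
        )
        if not res.success and not math.isfinite(res.fun):
            continue
        key = (res.fun, res.x[0])
        if best is None or key < (best[0], best[1]):
            best = (res.fun, res.x[0], res.x)
    if best is None:
        raise RuntimeError(
            f"ML fit failed to converge for r_mz={data.r_mz}, r_dz={data.r_dz}, model={model}"
        )

    a, x2 = best[2]
    # snap hairline boundary touches so downstream flags are meaningful
    a = 0.0 if a < 1e-9 else float(a)
    x2 = 0.0 if x2 < 1e-9 else float(x2)
    E = 1.0 - a - x2
    on_boundary = a == 0.0 or x2 == 0.0 or E <= E_FLOOR + 1e-9
    if model == "ACE":
        comp = VarianceComponents(
            model="ACE", A=a, C=x2, D=0.0, E=E, region=region, metric=metric, constrained=on_boundary
        )
    else:
        comp = VarianceComponents(
            model="ADE", A=a, C=0.0, D=x2, E=E, region=region, metric=metric, constrained=on_boundary
        )
    return comp


def broad_sense_G(components: VarianceComponents) -> float:
    """Heritability summary: A under ACE, A + D (broad sense) under ADE."""
    g = components.G
    if not 0.0 <= g <= 1.0 + 1e-9:
        raise ValueError(f"heritability {g} outside [0, 1]")
    return min(g, 1.0)
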