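"""Per-child growth-curve registration.

A child's growth trajectory is modelled as a warped copy of the population
mean curve ``f``:

    H(x) = f(alpha * x + beta) + gamma

* ``alpha`` (tempo, dimensionless, > 0) stretches or compresses the age
  axis: a child racing through puberty has alpha < 1, a flat grower
  alpha >= 1.
* ``beta`` (phase, years) shifts the curve along the age axis: positive
  for early developers, negative for late ones.
* ``gamma`` (amplitude, cm) shifts the curve vertically: smaller for
  shorter children.

``gamma`` is anchored first from the predicted adult height,
``gamma = H_final - f(18)``, which pins the curve at adulthood.  With
``gamma`` frozen, (alpha, beta) are found by bounded nonlinear least
squares over the anchor equations — the current measurement(s) plus the
adult anchor.  With a single current measurement this is the classic
two-equation system in two unknowns; measurement error makes it
inconsistent, hence the least-squares treatment, and extra historical
measurements simply add residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .reference import MeanGrowthCurve

__all__ = [
    "AnchorSet",
    "PersonalCurve",
    "gamma_from_adult_height",
    "fit_personal_curve",
    "predict_stage_height",
]

ALPHA_BOUNDS = (0.5, 1.5)
BETA_BOUNDS = (-4.0, 4.0)


@dataclass(frozen=True)
class AnchorSet:
    """Observed (age, height) pairs plus the adult-height anchor."""

    observations: tuple  # of (age_years, height_cm)
    adult_height: float
    adult_age: float = 18.0

    def __post_init__(self) -> None:
        obs = tuple((float(a), float(h)) for a, h in self.observations)
        object.__setattr__(self, "observations", obs)
        if len(obs) < 1:
            raise ValueError("need at least one observation")
        for age, height in obs:
            if age >= self.adult_age:
                raise ValueError("observation ages must precede adult_age")
            if height <= 0:
                raise ValueError("heights must be positive")
        if self.adult_height <= 0:
            raise ValueError("adult_height must be positive")


def gamma_from_adult_height(adult_height: float, base: MeanGrowthCurve,
                            adult_age: float = 18.0) -> float:
    """Amplitude shift pinning the curve at adulthood: H_final - f(18)."""
    return float(adult_height) - base.predict(adult_age)


def _curve_eval(coef, t, age_min, age_max):
    """Evaluate the base polynomial with adult-plateau clamping both ways.

    Used only inside the objective: below-domain ages are clamped so the
    residual stays defined while a separate penalty term pushes the solver
    back; above-domain ages hit the adult plateau like ``predict``.
    """
    return np.polyval(coef, np.clip(t, age_min, age_max))


class PersonalCurve(BaseEstimator, RegressorMixin):
    """Three-parameter registration of the mean curve to one child.

    Parameters
    ----------
    base : MeanGrowthCurve
        Fitted population mean curve ``f``.
    adult_age : float, default 18.0
        Age at which growth is considered complete; the adult anchor and
        ``gamma`` both refer to ``f(adult_age)``.
    alpha_bounds, beta_bounds : tuple
        Box constraints for the tempo and phase parameters.
    joint_refit : bool, default False
        After the two-stage fit, re-optimise (alpha, beta, gamma) jointly.
    penalty_scale : float, default 10.0
        Weight (cm per year) of the smooth quadratic penalty applied when
        a transformed age falls below the base-curve domain during the
        search; keeps the objective continuous instead of failing hard.

    Fitted attributes: ``alpha_``, ``beta_``, ``gamma_``, ``objective_``
    (sum of squared anchor residuals including penalties, cm^2) and
    ``n_anchors_``.
    """

    def __init__(self, base: MeanGrowthCurve | None = None,
                 adult_age: float = 18.0,
                 alpha_bounds: tuple = ALPHA_BOUNDS,
                 beta_bounds: tuple = BETA_BOUNDS,
                 joint_refit: bool = False,
                 penalty_scale: float = 10.0):
        self.base = base
        self.adult_age = adult_age
        self.alpha_bounds = alpha_bounds
        self.beta_bounds = beta_bounds
        self.joint_refit = joint_refit
        self.penalty_scale = penalty_scale

    # -- objective --------------------------------------------------------
    def _residuals(self, params, ages, heights, gamma):
        base = self.base
        coef = base.coefficients_
        if len(params) == 3:
            alpha, beta, gamma = params
        else:
            alpha, beta = params
        t = alpha * ages + beta
        resid = _curve_eval(coef, t, base.age_min_, base.age_max_) + gamma - heights
        penalty = self.penalty_scale * np.maximum(0.0, base.age_min_ - t)
        return np.concatenate([resid, penalty])

    def objective(self, alpha, beta, anchors: AnchorSet) -> float:
        """Sum of squared anchor residuals (plus domain penalty) at (alpha, beta).

        ``gamma`` is the adult-height anchor value; exposed so independent
        searches can score candidate parameters on the exact same surface
        the solver minimises.
        """
        check_is_fitted(self.base, "coefficients_")
        ages, heights = self._anchor_arrays(anchors)
        gamma = gamma_from_adult_height(anchors.adult_height, self.base,
                                        anchors.adult_age)
        r = self._residuals((alpha, beta), ages, heights, gamma)
        return float(r @ r)

    def _anchor_arrays(self, anchors: AnchorSet):
        obs = list(anchors.observations) + [(anchors.adult_age,
                                             anchors.adult_height)]
        arr = np.asarray(obs, dtype=float)
        return arr[:, 0], arr[:, 1]

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None, adult_height: float | None = None,
            adult_age: float | None = None) -> "PersonalCurve":
        """Fit (alpha, beta, gamma) to observations plus the adult anchor.

        ``X`` is either an :class:`AnchorSet` or an array of observation
        ages with heights in ``y`` and ``adult_height`` given explicitly.
        """
        if self.base is None:
            raise ValueError("PersonalCurve requires a fitted base curve")
        check_is_fitted(self.base, "coefficients_")
        if isinstance(X, AnchorSet):
            anchors = X
        else:
            if adult_height is None:
                raise ValueError("adult_height is required")
            ages = np.asarray(X, dtype=float).ravel()
            heights = np.asarray(y, dtype=float).ravel()
            anchors = AnchorSet(observations=tuple(zip(ages, heights)),
                                adult_height=float(adult_height),
                                adult_age=self.adult_age if adult_age is None
                                else float(adult_age))
        gamma = gamma_from_adult_height(anchors.adult_height, self.base,
                                        anchors.adult_age)
        ages, heights = self._anchor_arrays(anchors)

        lb = (self.alpha_bounds[0], self.beta_bounds[0])
        ub = (self.alpha_bounds[1], self.beta_bounds[1])

        def solve(x0):
            return least_squares(self._residuals, x0, bounds=(lb, ub),
                                 args=(ages, heights, gamma), method="trf",
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12)

        # (1, 0) = the population-average child, plus a coarse deterministic
        # multistart: the surface can be locally flat when an observation
        # sits on the adult plateau
        starts = [(1.0, 0.0)]
        starts += [(a0, b0)
                   for a0 in np.linspace(lb[0] + 1e-3, ub[0] - 1e-3, 3)
                   for b0 in np.linspace(lb[1] + 1e-3, ub[1] - 1e-3, 3)]
        result = None
        for x0 in starts:
            cand = solve(x0)
            if result is None or cand.cost < result.cost - 1e-15:
                result = cand
        if not result.success and not np.isfinite(result.cost):
            raise RuntimeError(
                f"personal-curve solver failed (final residual {result.cost})")
        alpha, beta = result.x

        if self.joint_refit:
            lb3 = (*lb, gamma - 20.0)
            ub3 = (*ub, gamma + 20.0)
            joint = least_squares(self._residuals, (alpha, beta, gamma),
                                  bounds=(lb3, ub3),
                                  args=(ages, heights, gamma), method="trf",
                                  xtol=1e-12, ftol=1e-12, gtol=1e-12)
            if joint.success and joint.cost <= result.cost:
                alpha, beta, gamma = joint.x
                result = joint

        self.alpha_ = float(alpha)
        self.beta_ = float(beta)
        self.gamma_ = float(gamma)
        self.objective_ = float(2.0 * result.cost)  # least_squares cost = 1/2 SSE
        self.n_anchors_ = ages.size
        self.anchors_ = anchors
        return self

    def predict(self, ages):
        """Stage height ``f(alpha*x + beta) + gamma`` at target ages.

        Transformed ages above the base domain hit the adult plateau;
        below the domain an error is raised (no infant extrapolation).
        """
        check_is_fitted(self, "alpha_")
        arr = np.asarray(ages, dtype=float)
        scalar = arr.ndim == 0
        t = self.alpha_ * np.atleast_1d(arr).ravel() + self.beta_
        base = self.base
        if np.any(t < base.age_min_):
            raise ValueError("transformed age below the base-curve domain")
        out = np.polyval(base.coefficients_,
                         np.minimum(t, base.age_max_)) + self.gamma_
        return float(out[0]) if scalar else out

    def __call__(self, age: float) -> float:
        return self.predict(age)


def fit_personal_curve(anchors: AnchorSet, base: MeanGrowthCurve,
                       **kwargs) -> PersonalCurve:
    """Fit a :class:`PersonalCurve` to an anchor set against ``base``."""
    return PersonalCurve(base=base, adult_age=anchors.adult_age,
                         **kwargs).fit(anchors)


def predict_stage_height(curve: PersonalCurve, target_age: float) -> float:
    """Evaluate a fitted personal curve at a target age (cm)."""
    return curve.predict(target_age)
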