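"""TOPALS estimation of single-age mortality rates from grouped counts.

TOPALS (tool for projecting age-specific rates using linear splines)
represents small-area log-mortality as a smooth national reference
schedule plus a linear-spline offset,

    log m(x) = log m*(x) + sum_k alpha_k B_k(x),

where the B_k are hat functions anchored at a small set of knot ages.
The offsets are estimated by maximising a penalised Poisson likelihood
for grouped death counts, with a squared-first-difference penalty that
keeps neighbouring offsets close and stabilises the fit when deaths are
sparse.  Fitting uses penalised iteratively reweighted least squares
(Fisher scoring with step halving).

Because a linear spline anchored at the last knot can drift at the
oldest ages, a post-fit correction blends the fitted schedule back into
a level-shifted copy of the reference above a start age (default 90).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_KNOTS",
    "SplineBasis",
    "MortalityInput",
    "ReferenceSchedule",
    "TopalsFit",
    "build_spline_basis",
    "fit_topals",
    "correct_old_age",
    "spread_deaths",
    "parse_age_group",
]

#: Knot ages for the linear-spline offset.  This follows the reference
#: TOPALS convention: dense knots at the infant/child ages where the
#: log-mortality curve bends sharply, sparse knots over adulthood.
DEFAULT_KNOTS = (0.0, 1.0, 10.0, 20.0, 40.0, 70.0, 100.0)


def parse_age_group(label: str, age_max: int) -> tuple[int, int]:
    """Parse a 5-year age-group label such as ``"20-24"`` or ``"90+"``.

    Returns the closed integer range ``(lo, hi)`` of single ages the
    group covers; the open-ended group runs to ``age_max``.
    """
    label = str(label).strip()
    if label.endswith("+"):
        return int(label[:-1]), age_max
    lo, hi = label.split("-")
    return int(lo), int(hi)


@dataclass(frozen=True)
class SplineBasis:
    """Linear B-spline (hat function) basis evaluated on a set of ages."""

    knots: np.ndarray
    ages: np.ndarray
    B: np.ndarray  # shape (n_ages, n_knots); rows sum to 1 in-span


def build_spline_basis(ages, knots=DEFAULT_KNOTS) -> SplineBasis:
    """Evaluate the hat-function basis at ``ages``.

    Each basis column k is the piecewise-linear function that is 1 at
    knot k, 0 at every other knot.  Rows therefore sum to one and have
    at most two non-zero entries.

    Raises
    ------
    ValueError
        If the knots are not strictly increasing or any age lies
        outside the knot span.
    """
    knots = np.asarray(knots, dtype=float)
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if knots.ndim != 1 or knots.size < 2:
        raise ValueError("need at least two knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing (no duplicates)")
    if ages.size and (ages.min() < knots[0] or ages.max() > knots[-1]):
        raise ValueError(
            f"ages must lie within the knot span [{knots[0]}, {knots[-1]}]"
        )
    eye = np.eye(knots.size)
    B = np.column_stack([np.interp(ages, knots, eye[k]) for k in range(knots.size)])
    return SplineBasis(knots=knots, ages=ages, B=B)


@dataclass
class MortalityInput:
    """Grouped deaths and person-years of exposure for one area and sex.

    ``exposure`` is population times the number of pooled calendar
    years.  Deaths may be non-integral (e.g. expected counts in
    simulation studies); they must be non-negative.
    """

    area_id: str
    sex: str
    age_groups: list[str]
    deaths: np.ndarray
    exposure: np.ndarray

    def __post_init__(self):
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        if len(self.age_groups) != self.deaths.size or self.deaths.size != self.exposure.size:
            raise ValueError("age_groups, deaths and exposure must have equal length")
        if np.any(self.deaths < 0):
            raise ValueError("deaths must be non-negative")
        if np.any(self.exposure <= 0):
            raise ValueError("every age group needs positive exposure")

    def bounds(self, age_max: int) -> list[tuple[int, int]]:
        b = [parse_age_group(g, age_max) for g in self.age_groups]
        for (lo0, hi0), (lo1, hi1) in zip(b, b[1:]):
            if lo1 != hi0 + 1:
                raise ValueError("age groups must be contiguous and non-overlapping")
        return b


@dataclass(frozen=True)
class ReferenceSchedule:
    """National log-mortality by single year of age, used as the TOPALS standard."""

    sex: str
    ages: np.ndarray
    log_mx: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=int))
        object.__setattr__(self, "log_mx", np.asarray(self.log_mx, dtype=float))
        if self.ages.size != self.log_mx.size:
            raise ValueError("ages and log_mx must have equal length")
        if not np.all(np.isfinite(self.log_mx)):
            raise ValueError("reference log-rates must be finite at every age")
        if not np.array_equal(self.ages, np.arange(self.ages[0], self.ages[-1] + 1)):
            raise ValueError("reference schedule must cover consecutive single ages")

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])


@dataclass
class TopalsFit:
    """Result of a penalised TOPALS fit for one area and sex."""

    area_id: str
    sex: str
    knots: np.ndarray
    alpha: np.ndarray
    log_m: np.ndarray  # fitted log-rates at the reference ages
    ages: np.ndarray
    lam: float
    converged: bool
    iterations: int
    gradient_norm: float = field(default=np.nan)

    @property
    def mx(self) -> np.ndarray:
        """Fitted single-age mortality rates (always strictly positive)."""
        return np.exp(self.log_m)


def _expand_exposure(data: MortalityInput, ref: ReferenceSchedule):
    """Split grouped exposure uniformly across single ages.

    Returns (E_x, group_index, group_starts) aligned with ``ref.ages``.
    Single-age populations are not observable in the grouped inputs, so
    a uniform within-band split is used throughout.
    """
    bounds = data.bounds(ref.age_max)
    if bounds[0][0] != int(ref.ages[0]) or bounds[-1][1] != ref.age_max:
        raise ValueError("age groups must cover the full reference age range")
    n_ages = ref.ages.size
    E_x = np.empty(n_ages)
    group_index = np.empty(n_ages, dtype=int)
    starts = []
    pos = 0
    for g, (lo, hi) in enumerate(bounds):
        width = hi - lo + 1
        starts.append(pos)
        E_x[pos:pos + width] = data.exposure[g] / width
        group_index[pos:pos + width] = g
        pos += width
    return E_x, group_index, np.asarray(starts)


def _penalised_loglik(alpha, D, E_x, log_mstar, B, starts, pen):
    mu_x = E_x * np.exp(log_mstar + B @ alpha)
    mu_g = np.add.reduceat(mu_x, starts)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(D > 0, D * np.log(mu_g), 0.0)
    return float(term.sum() - mu_g.sum() - alpha @ pen @ alpha)


def fit_topals(
    data: MortalityInput,
    ref: ReferenceSchedule,
    basis: SplineBasis | None = None,
    lam: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> TopalsFit:
    """Fit spline offsets to a reference schedule by penalised IRLS.

    Maximises

        sum_g [ D_g log mu_g(alpha) - mu_g(alpha) ]
            - lam * sum_k (alpha_{k+1} - alpha_k)^2

    where ``mu_g = sum_{x in g} E_x exp(log m*(x) + (B alpha)_x)`` and the
    grouped exposure is split uniformly over the single ages of each
    band.  Fisher scoring with step halving; convergence is declared
    when the gradient 2-norm falls below ``tol``.

    Ages beyond the last knot carry the last knot's offset (constant
    extrapolation), so a reference running to age 110 can be fitted
    with knots ending at 100.

    A fit that fails to converge within ``max_iter`` is returned with
    ``converged=False`` and a warning — never silently.
    """
    if lam < 0:
        raise ValueError("penalty weight lam must be non-negative")
    E_x, _, starts = _expand_exposure(data, ref)
    if basis is None:
        basis = build_spline_basis(
            np.clip(ref.ages.astype(float), DEFAULT_KNOTS[0], DEFAULT_KNOTS[-1])
        )
    knots = basis.knots
    B = basis.B
    if B.shape[0] != ref.ages.size:
        raise ValueError("basis must be evaluated at the reference ages")
    K = knots.size
    Dmat = np.diff(np.eye(K), axis=0)
    pen = lam * (Dmat.T @ Dmat)

    D = data.deaths
    log_mstar = ref.log_mx
    alpha = np.zeros(K)
    ll = _penalised_loglik(alpha, D, E_x, log_mstar, B, starts, pen)

    converged = False
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        mu_x = E_x * np.exp(log_mstar + B @ alpha)
        mu_g = np.add.reduceat(mu_x, starts)
        V = np.add.reduceat(mu_x[:, None] * B, starts, axis=0)  # d mu_g / d alpha
        grad = V.T @ (D / mu_g - 1.0) - 2.0 * (pen @ alpha)
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm <= tol:
            converged = True
            break
        info = V.T @ (V / mu_g[:, None]) + 2.0 * pen  # Fisher information
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step halving: the penalised log-likelihood must not decrease
        new_ll = None
        for _ in range(50):
            cand = alpha + step
            new_ll = _penalised_loglik(cand, D, E_x, log_mstar, B, starts, pen)
            if new_ll >= ll - 1e-12 * max(1.0, abs(ll)):
                break
            step = step / 2.0
        alpha = alpha + step
        ll = new_ll
    else:
        it = max_iter

    if not converged:
        # re-check the gradient at the final iterate
        mu_x = E_x * np.exp(log_mstar + B @ alpha)
        mu_g = np.add.reduceat(mu_x, starts)
        V = np.add.reduceat(mu_x[:, None] * B, starts, axis=0)
        grad = V.T @ (D / mu_g - 1.0) - 2.0 * (pen @ alpha)
        grad_norm = float(np.linalg.norm(grad))
        converged = grad_norm <= tol
        if not converged:
            warnings.warn(
                f"TOPALS fit for area={data.area_id} sex={data.sex} did not reach "
                f"gradient norm {tol:g} within {max_iter} iterations "
                f"(final norm {grad_norm:.3e})",
                RuntimeWarning,
                stacklevel=2,
            )

    return TopalsFit(
        area_id=data.area_id,
        sex=data.sex,
        knots=knots,
        alpha=alpha,
        log_m=log_mstar + B @ alpha,
        ages=ref.ages.copy(),
        lam=lam,
        converged=converged,
        iterations=it,
        gradient_norm=grad_norm,
    )


def correct_old_age(
    fit: TopalsFit, ref: ReferenceSchedule, start_age: int = 90
) -> np.ndarray:
    """Blend the fitted schedule into an anchored reference above ``start_age``.

    The anchor is the reference schedule shifted by the fitted offset at
    ``start_age``, so the corrected schedule keeps the area's level at
    90 but adopts the reference *shape* towards the oldest ages, where a
    linear-spline tail can over- or under-state mortality.  The blend
    weight rises linearly from 0 at ``start_age`` to 1 at the last age;
    ages below ``start_age`` are untouched.

    Returns the corrected single-age rates m(x) over the full reference
    age range.
    """
    age_max = ref.age_max
    if start_age >= age_max:
        raise ValueError("start_age must be below the maximum age of the schedule")
    ages = ref.ages
    if start_age < ages[0]:
        raise ValueError("start_age below the schedule's first age")
    log_m = fit.log_m.copy()
    i0 = int(np.searchsorted(ages, start_age))
    offset = fit.log_m[i0] - ref.log_mx[i0]
    w = (ages[i0:] - start_age) / (age_max - start_age)
    anchor = ref.log_mx[i0:] + offset
    log_m[i0:] = w * anchor + (1.0 - w) * log_m[i0:]
    return np.exp(log_m)


def spread_deaths(data: MortalityInput, mx: np.ndarray, ref: ReferenceSchedule) -> np.ndarray:
    """Distribute grouped deaths over single ages, proportional to fitted
    expected deaths (uniform exposure split times the fitted rate).

    Needed by the mortality-variance propagation, which works at single
    ages while counts are only observed per 5-year band.
    """
    E_x, group_index, starts = _expand_exposure(data, ref)
    expected = E_x * np.asarray(mx, dtype=float)
    totals = np.add.reduceat(expected, starts)
    share = expected / totals[group_index]
    return data.deaths[group_index] * share
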