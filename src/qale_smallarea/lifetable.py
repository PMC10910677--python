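"""Single-age period life tables.

Standard columns by exact age x: mx (central death rate), ax (mean
person-years lived in the interval by those dying in it), qx (death
probability), lx (survivors from a radix), dx (deaths), Lx (person-years
lived in the interval), Tx (person-years above x) and ex (remaining life
expectancy).  The table is closed with an open interval at the last age,
where q = 1 and L = l / m.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_life_table", "life_expectancy"]


def build_life_table(
    mx, radix: float = 100_000.0, age_start: int = 0
) -> pd.DataFrame:
    """Build a complete (single-age) period life table from a rate schedule.

    Parameters
    ----------
    mx
        Central death rates by single year of age, the last entry being
        the open interval.  All rates must be non-negative and the final
        rate strictly positive (it closes the table via L = l/m).
    radix
        Survivors at the first age (l0); conventionally 100 000.
    age_start
        Age of the first entry, usually 0.

    Notes
    -----
    Separation factors: ax = 0.5 for all closed intervals except infancy,
    where the rule a0 = 0.07 + 1.7 m0 (capped at 0.5) reflects the
    concentration of infant deaths early in the first year of life.  The
    open interval uses a = 1/m.  qx = mx / (1 + (1-ax) mx) for closed
    intervals, capped at 1.
    """
    mx = np.asarray(mx, dtype=float)
    if mx.ndim != 1 or mx.size < 2:
        raise ValueError("mx must be a 1-d schedule with at least two ages")
    if np.any(mx < 0) or not np.all(np.isfinite(mx)):
        raise ValueError("death rates must be finite and non-negative")
    if mx[-1] <= 0:
        raise ValueError("the final (open-interval) rate must be strictly positive")

    n = mx.size
    ages = np.arange(age_start, age_start + n)

    ax = np.full(n, 0.5)
    if age_start == 0:
        ax[0] = min(0.5, 0.07 + 1.7 * mx[0])
    ax[-1] = 1.0 / mx[-1]

    qx = np.minimum(mx / (1.0 + (1.0 - ax) * mx), 1.0)
    qx[-1] = 1.0

    lx = np.empty(n)
    lx[0] = radix
    lx[1:] = radix * np.cumprod(1.0 - qx[:-1])
    dx = lx * qx

    Lx = lx - (1.0 - ax) * dx
    Lx[-1] = lx[-1] / mx[-1]

    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)

    return pd.DataFrame(
        {
            "age": ages,
            "mx": mx,
            "ax": ax,
            "qx": qx,
            "lx": lx,
            "dx": dx,
            "Lx": Lx,
            "Tx": Tx,
            "ex": ex,
        }
    )


def life_expectancy(lt: pd.DataFrame, age: int = 0) -> float:
    """Remaining life expectancy ex at an exact age of the table."""
    row = lt.loc[lt["age"] == age, "ex"]
    if row.empty:
        raise ValueError(f"age {age} is outside the life table")
    return float(row.iloc[0])
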