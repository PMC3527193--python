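"""Quantile-quantile series of observed vs expected -log10 P-values.

Under the global null every P-value is uniform on (0, 1), so the ordered
observed P-values should track the uniform order-statistic quantiles; the
Q-Q plot draws observed against expected on the -log10 scale, where an
excess of small P-values lifts the right-hand tail off the identity line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import EmptyInputError, OptionError
from .layout import TransformPolicy, neglog10_array


@dataclass(frozen=True)
class QqSeries:
    """Paired expected/observed -log10 P quantiles, ascending in expected."""

    expected: np.ndarray
    observed: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if len(self.expected) != len(self.observed):
            raise ValueError("expected and observed must have equal length")
        if self.n != len(self.expected):
            raise ValueError("n must equal the number of pairs")


def expected_quantiles(
    n: int, convention: Literal["midpoint", "rank"] = "midpoint"
) -> np.ndarray:
    """Uniform-null expected P quantiles for ranks 1..n, ascending.

    ``midpoint`` uses (i - 0.5)/n, which is symmetric in the ranks and
    keeps the largest expected -log10 value at -log10(0.5/n); ``rank``
    uses the alternative i/(n + 1) convention.
    """
    i = np.arange(1, n + 1, dtype=float)
    if convention == "midpoint":
        return (i - 0.5) / n
    if convention == "rank":
        return i / (n + 1)
    raise OptionError(f"unknown quantile convention {convention!r}")


def qq_series(
    pvalues,
    policy: TransformPolicy = TransformPolicy(),
    convention: Literal["midpoint", "rank"] = "midpoint",
) -> QqSeries:
    """Build the Q-Q series for one trait's P-values.

    Missing values are excluded; zero P-values follow ``policy`` (clamped
    to the ceiling or dropped). With sorted P-values p(1) <= ... <= p(N),
    pair i is (-log10(q_i), -log10(p(i))) with q_i the expected quantile;
    pairs are returned in ascending expected order, so both arrays ascend.
    """
    p = np.asarray(pvalues, dtype=float)
    y, keep = neglog10_array(p, policy)
    y = y[keep]
    if y.size == 0:
        raise EmptyInputError("no non-missing P-values for the Q-Q series")
    n = int(y.size)
    observed = np.sort(y)  # ascending -log10 == descending p, stable ties
    expected = -np.log10(expected_quantiles(n, convention))[::-1]
    return QqSeries(expected=expected, observed=observed, n=n)


__all__ = ["QqSeries", "expected_quantiles", "qq_series"]
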