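"""Five-parameter logistic (5PL) dose/dilution-response curve.

The curve is evaluated in log-log coordinates: the abscissa is log2
relative concentration (one unit per 1:1 dilution step), the ordinate is
log10 net fluorescence.  The asymmetric (five-parameter) form is used
because immunoassay dilution curves are typically not symmetric about
their inflection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LN2 = math.log(2.0)


@dataclass(frozen=True)
class FivePL:
    """5PL parameters.

    Attributes
    ----------
    A : float
        Lower (high-dilution) asymptote, log10 AU.
    D : float
        Upper (low-dilution) asymptote, log10 AU.
    C : float
        Inflection position on the log2-concentration axis.
    B : float
        Hill slope (> 0).
    G : float
        Asymmetry constant (> 0); G = 1 recovers the symmetric 4PL.
    """

    A: float
    D: float
    C: float
    B: float = 1.0
    G: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.A, self.D, self.C, self.B, self.G)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite 5PL parameters: {vals}")
        if self.B <= 0:
            raise ValueError(f"Hill slope B must be > 0, got {self.B}")
        if self.G <= 0:
            raise ValueError(f"asymmetry G must be > 0, got {self.G}")
        if self.A == self.D:
            raise ValueError("asymptotes A and D must differ")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.D, self.C, self.B, self.G], float)

    @classmethod
    def from_array(cls, v: np.ndarray) -> "FivePL":
        return cls(A=float(v[0]), D=float(v[1]), C=float(v[2]),
                   B=float(v[3]), G=float(v[4]))


def eval_5pl(x, params: FivePL):
    """Evaluate the 5PL response at log2 concentration ``x``.

        y(x) = D + (A - D) / (1 + 2**(B*(x - C)))**G

    computed in log space so that extreme ``x`` never overflow:
    y -> A as x -> -inf and y -> D as x -> +inf.  Monotone increasing in
    ``x`` when D > A (signal rises with concentration).

    Parameters
    ----------
    x : array_like
        log2 relative concentration.
    params : FivePL

    Returns
    -------
    ndarray or float
        log10 net intensity.
    """
    x = np.asarray(x, dtype=float)
    t = LN2 * params.B * (x - params.C)
    # (1 + e^t)^-G  ==  exp(-G * log(1 + e^t))
    y = params.D + (params.A - params.D) * np.exp(-params.G * np.logaddexp(0.0, t))
    return y if y.ndim else float(y)


def response_band(params: FivePL, lo: float = 0.25, hi: float = 0.75) -> tuple[float, float]:
    """Ordinate interval covering [lo, hi] of the asymptote-to-asymptote range.

    Used to delimit the "linear portion" of the logistic for the
    y-intercept readout.
    """
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError(f"band fractions must satisfy 0 <= lo < hi <= 1, got {(lo, hi)}")
    y0, y1 = sorted((params.A, params.D))
    span = y1 - y0
    return y0 + lo * span, y0 + hi * span
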