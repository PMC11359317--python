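"""Independent brute-force evaluations of the printed 2x2 formulas.

Deliberately written with the plain math module (no numpy/scipy) so the
package's vectorized/scipy-backed implementations are checked against a
separate code path.
"""

import math

# exact standard-normal quantile for 97.5%, from Abramowitz-style inverse
# erf via bisection (independent of scipy)


def _norm_ppf(p: float) -> float:
    lo, hi = -10.0, 10.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if 0.5 * (1.0 + math.erf(mid / math.sqrt(2.0))) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def ror_oracle(a, b, c, d, alpha=0.05):
    est = (a * d) / (b * c)
    z = _norm_ppf(1.0 - alpha / 2.0)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return est, math.exp(math.log(est) - z * se), math.exp(math.log(est) + z * se)


def prr_oracle(a, b, c, d):
    return (a / (a + b)) / (c / (c + d))


def chi2_oracle(a, b, c, d, yates=False):
    n = a + b + c + d
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    return n * diff * diff / ((a + b) * (c + d) * (a + c) * (b + d))
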