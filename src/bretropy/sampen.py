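"""Sample Entropy (SampEn) of a univariate series.

SampEn(m, r, N) is the negative logarithm of the conditional probability that
two subsequences that match within tolerance r for m consecutive points also
match for m + 1 points (Chebyshev distance, self-matches excluded):

    SampEn = -ln(A / B)

where B counts matching template pairs of length m and A those of length
m + 1.  Lower values mean a more regular, predictable series.  Templates of
length k are taken at starting indices 0 .. N-k-1 (N-k templates), the
convention of the widely used reference implementations, so B and A count
pairs over nested index ranges.

An optional small-sample correction multiplies the ratio by N/(N-2) inside
the logarithm; it is on by default here because the target application is
short (~70-sample) biosensor kinetic traces.

The matching tolerance is r = r_factor * sample standard deviation (ddof=1)
of the analyzed segment, the field-standard choice r = 0.2*SD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np


class DegenerateInputError(ValueError):
    """Series cannot be analyzed (zero variance => tolerance r = 0)."""


class SeriesTooShortError(ValueError):
    """Series shorter than the m + 2 samples template matching requires."""


@dataclass(frozen=True)
class SampEnParams:
    """SampEn parameters: embedding dimension m, tolerance factor, correction.

    ``m=1`` suits short kinetic epochs (more template pairs per trace);
    ``r_factor=0.2`` is the conventional 0.2*SD matching threshold.
    """

    m: int = 1
    r_factor: float = 0.2
    apply_small_sample_correction: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be > 0")


def match_counts(series: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Count template pair matches of length m (B) and m+1 (A).

    A pair (i, j), i < j, matches at length k when the Chebyshev distance
    between the k-length templates starting at i and j is <= r.  Templates
    run over starting indices 0 .. N-k-1.  Always A <= B.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < m + 2:
        raise SeriesTooShortError(f"need at least m + 2 = {m + 2} samples, got {n}")
    if r <= 0:
        raise DegenerateInputError("matching tolerance r must be > 0")

    def _pairs(k: int) -> int:
        # templates x[i:i+k] for i in 0..n-k-1, vectorized over all pairs
        nt = n - k
        tpl = np.lib.stride_tricks.sliding_window_view(x, k)[:nt]
        # Chebyshev distance matrix via broadcasting: nt is ~70-200 here
        d = np.abs(tpl[:, None, :] - tpl[None, :, :]).max(axis=2)
        return int(np.sum(np.triu(d <= r, k=1)))

    b = _pairs(m)
    a = _pairs(m + 1)
    return b, a


def sample_entropy(
    series: np.ndarray,
    params: SampEnParams = SampEnParams(),
    r_absolute: float | None = None,
) -> float:
    """SampEn of a series; NaN (with a warning) when no (m+1)-matches exist.

    The tolerance is ``params.r_factor`` times the series' sample standard
    deviation unless ``r_absolute`` overrides it.  A zero-variance series
    raises :class:`DegenerateInputError` (the relative tolerance collapses).
    With the small-sample correction on, the value is
    ``-ln((A/B) * N/(N-2))``; with it off, the standard ``-ln(A/B)``.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < params.m + 2:
        raise SeriesTooShortError(f"need at least m + 2 = {params.m + 2} samples, got {n}")
    if r_absolute is not None:
        r = float(r_absolute)
        if r <= 0:
            raise DegenerateInputError("absolute tolerance must be > 0")
    else:
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            raise DegenerateInputError("zero-variance series: r = r_factor * SD collapses to 0")
        r = params.r_factor * sd

    b, a = match_counts(x, params.m, r)
    if b == 0 or a == 0:
        warnings.warn(
            f"SampEn undefined: no template matches (B={b}, A={a}); returning NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.nan
    ratio = a / b
    if params.apply_small_sample_correction:
        ratio *= n / (n - 2)
    return -math.log(ratio)
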