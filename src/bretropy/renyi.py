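"""Rényi entropy spectrum of a trace's value distribution.

The distribution of a trace's BRET-ratio values is estimated by Gaussian
kernel density estimation with the robust Silverman rule-of-thumb bandwidth

    h = 0.9 * min(s, IQR/1.34) * N**(-1/5),

evaluated on an even grid spanning the data range and normalized to sum to
one, giving a discrete probability vector p.  On p the Rényi entropy of
order alpha is

    H_alpha = 1/(1-alpha) * ln(sum_i p_i**alpha),

with the limits H_1 = -sum p ln p (Shannon), H_0 = ln(#support points with
mass) (Hartley) and H_inf = -ln(max p) (min-entropy).  Negative orders
amplify the rarest states and so probe low-probability signaling events;
they are computed stably in log space (log-sum-exp of alpha*ln p).

Every order is reported raw (nats) and normalized by the Hartley entropy
H_0 = ln(n), which bounds the normalized value in (0, 1] for alpha >= 1 and
makes spectra comparable across equal-length traces.  The standard report
grid is the integers -10..10 plus infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .sampen import DegenerateInputError, SampEnParams, sample_entropy

#: standard report grid: integer orders -10..10 plus infinity
ALPHA_GRID: tuple[float, ...] = tuple(float(a) for a in range(-10, 11)) + (math.inf,)


@dataclass(frozen=True)
class KdeParams:
    """KDE discretization settings.

    ``n_support=None`` uses one evaluation point per sample (keeps the
    Hartley normalizer ln N comparable across equal-length traces);
    ``support_extent`` widens the grid by 3 bandwidths on each side when set
    to ``"extended"``.
    """

    n_support: int | None = None
    bandwidth_rule: str = "silverman"
    support_extent: str = "data_range"

    def __post_init__(self) -> None:
        if self.n_support is not None and self.n_support < 2:
            raise ValueError("n_support must be >= 2")
        if self.bandwidth_rule != "silverman":
            raise ValueError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
        if self.support_extent not in ("data_range", "extended"):
            raise ValueError(f"unknown support_extent {self.support_extent!r}")


@dataclass(frozen=True)
class ProbabilityDistribution:
    """Discrete distribution: ordered support points + probabilities."""

    support: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "support", np.asarray(self.support, dtype=float))
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if len(self.support) != len(self.p):
            raise ValueError("support and p must have equal length")
        if np.any(self.p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(float(self.p.sum()) - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {self.p.sum()}, not 1")

    def __len__(self) -> int:
        return len(self.p)


def silverman_bandwidth(series: np.ndarray) -> float:
    """Robust Silverman rule: 0.9 * min(s, IQR/1.34) * N^(-1/5).

    Falls back to the sample SD when the IQR is zero (tight clusters), so a
    positive-variance series always gets a positive bandwidth.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    s = float(np.std(x, ddof=1))
    if s == 0.0:
        raise DegenerateInputError("zero-variance series has no KDE bandwidth")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(s, iqr / 1.34) if iqr > 0 else s
    return 0.9 * spread * n ** (-0.2)


def estimate_pdf(series: np.ndarray, params: KdeParams = KdeParams()) -> ProbabilityDistribution:
    """Gaussian-KDE probability vector of a series' values.

    The density sum_j exp(-(x - x_j)^2 / 2h^2) is evaluated at ``n_support``
    evenly spaced points spanning [min, max] of the data (``data_range``
    mode) and divided by its total, so all probabilities are strictly
    positive and sum to one.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise ValueError(f"need at least 10 samples for a KDE, got {len(x)}")
    h = silverman_bandwidth(x)
    n_support = params.n_support if params.n_support is not None else len(x)
    lo, hi = float(x.min()), float(x.max())
    if params.support_extent == "extended":
        lo, hi = lo - 3.0 * h, hi + 3.0 * h
    support = np.linspace(lo, hi, n_support)
    # log-space kernel sum keeps tiny tail masses finite and positive
    z = -((support[:, None] - x[None, :]) ** 2) / (2.0 * h * h)
    log_density = logsumexp(z, axis=1)
    log_p = log_density - logsumexp(log_density)
    return ProbabilityDistribution(support=support, p=np.exp(log_p))


def renyi_entropy(
    dist: ProbabilityDistribution | np.ndarray,
    alpha: float,
    p_threshold: float = 0.0,
    base: float = math.e,
) -> float:
    """Rényi entropy of order ``alpha`` in units of log ``base`` (default nats).

    Handles the special orders: alpha=0 -> Hartley ln(#{p_i > p_threshold});
    alpha=1 -> Shannon; alpha=inf -> min-entropy -ln(max p).  Negative orders
    require every probability to be positive (they diverge otherwise, which
    cannot happen for KDE output but can for user-supplied vectors).
    """
    p = dist.p if isinstance(dist, ProbabilityDistribution) else np.asarray(dist, dtype=float)
    if alpha < 0 and np.any(p <= 0):
        raise ValueError("Rényi entropy of negative order diverges when any p_i = 0")
    scale = 1.0 / math.log(base)
    if math.isinf(alpha):
        return -math.log(float(p.max())) * scale
    if alpha == 0:
        n_eff = int(np.sum(p > p_threshold))
        return math.log(n_eff) * scale
    if alpha == 1:
        pos = p[p > 0]
        return float(-(pos * np.log(pos)).sum()) * scale
    logp = np.log(p[p > 0]) if alpha > 0 else np.log(p)
    return float(logsumexp(alpha * logp)) / (1.0 - alpha) * scale


@dataclass(frozen=True)
class EntropySpectrum:
    """Per-trace entropy report: SampEn + raw and normalized Rényi values."""

    experiment_id: str
    well_id: str
    condition: str
    alpha_grid: tuple[float, ...]
    h_raw: np.ndarray
    h0: float
    h_norm: np.ndarray
    sampen: float
    tau: int = 1

    def value_at(self, alpha: float, normalized: bool = True) -> float:
        idx = self.alpha_grid.index(alpha)
        return float(self.h_norm[idx] if normalized else self.h_raw[idx])

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "well_id": self.well_id,
            "condition": self.condition,
            "tau": self.tau,
            "sampen": self.sampen,
            "H0": self.h0,
            "alpha": ["inf" if math.isinf(a) else a for a in self.alpha_grid],
            "H_raw": [float(v) for v in self.h_raw],
            "H_norm": [float(v) for v in self.h_norm],
        }


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping means of ``tau`` consecutive samples (length floor(N/tau)).

    The temporal coarse-graining stage of multiscale entropy; ``tau=1`` is
    the identity.
    """
    x = np.asarray(series, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if len(x) < 10 * tau:
        raise ValueError(f"series of length {len(x)} too short for scale tau={tau}")
    n = (len(x) // tau) * tau
    return x[:n].reshape(-1, tau).mean(axis=1)


def renyi_spectrum(
    series: np.ndarray,
    kde: KdeParams = KdeParams(),
    sampen_params: SampEnParams = SampEnParams(),
    alpha_grid: tuple[float, ...] = ALPHA_GRID,
    experiment_id: str = "",
    well_id: str = "",
    condition: str = "",
    tau: int = 1,
) -> EntropySpectrum:
    """Full entropy report for one series (already segmented/coarse-grained).

    H_raw is evaluated on the KDE distribution at every grid order, H0 is the
    Hartley entropy ln(n_support), H_norm = H_raw / H0, and SampEn is
    computed on the same series.
    """
    dist = estimate_pdf(series, kde)
    h_raw = np.array([renyi_entropy(dist, a) for a in alpha_grid])
    h0 = math.log(len(dist))
    sampen = sample_entropy(series, sampen_params)
    return EntropySpectrum(
        experiment_id=experiment_id,
        well_id=well_id,
        condition=condition,
        alpha_grid=tuple(alpha_grid),
        h_raw=h_raw,
        h0=h0,
        h_norm=h_raw / h0,
        sampen=sampen,
        tau=tau,
    )
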