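"""Automatic histogram thresholding: Isodata, Otsu, fuzzy entropy, and their fusion.

Each channel of the quantized Lab image is thresholded three ways and the
three results are averaged into one operating threshold — the fusion
smooths the highest and lowest of the individual estimates.  Successive
re-thresholding of the resulting partitions yields multi-level threshold
lists, which is how the classifier grows the number of classes on demand.

All thresholders share the same convention: a threshold ``t`` assigns a
pixel with level ``v`` to the lower region iff ``v <= t``, so a valid
threshold always lies in ``[min occupied level, max occupied level)``.
Plateau ties are broken to the smallest candidate level for determinism.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateHistogramError,
    EmptyHistogramError,
    ThresholdCountError,
)

__all__ = [
    "GreyHistogram",
    "ThresholdDiagnostics",
    "ChannelThresholds",
    "MultilevelThresholds",
    "isodata_threshold",
    "otsu_threshold",
    "fuzzy_threshold",
    "combined_threshold",
    "successive_thresholds",
]


@dataclass(frozen=True)
class GreyHistogram:
    """Discrete grey-level histogram: counts ``h(i)`` for levels ``0 .. L-1``."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 2:
            raise ConfigurationError("histogram needs >= 2 levels")
        if (counts < 0).any():
            raise ConfigurationError("histogram counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_values(cls, values: np.ndarray, n_levels: int) -> "GreyHistogram":
        values = np.asarray(values).ravel()
        if values.size and (values.min() < 0 or values.max() >= n_levels):
            raise ConfigurationError("values outside [0, n_levels)")
        return cls(np.bincount(values.astype(np.int64), minlength=n_levels))

    @property
    def n_levels(self) -> int:
        return self.counts.size

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        if self.total == 0:
            raise EmptyHistogramError("histogram is empty")
        return self.counts / self.total

    def occupied(self) -> np.ndarray:
        return np.flatnonzero(self.counts)

    def _require_splittable(self) -> None:
        occ = self.occupied()
        if occ.size == 0:
            raise EmptyHistogramError("histogram is empty")
        if occ.size == 1:
            raise DegenerateHistogramError(
                f"all mass at level {occ[0]}; no threshold exists"
            )


@dataclass
class ThresholdDiagnostics:
    """Per-candidate curves behind a threshold decision.

    Arrays are indexed by candidate threshold level ``t``; entries are NaN
    where the candidate is invalid (one side of the split empty).
    """

    levels: np.ndarray
    w: np.ndarray
    mu: np.ndarray
    mu_total: float
    mu1: np.ndarray
    mu2: np.ndarray
    between_class_variance: np.ndarray | None = None
    fuzziness: np.ndarray | None = None

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            header = ["t", "w", "mu", "mu1", "mu2"]
            cols = [self.levels, self.w, self.mu, self.mu1, self.mu2]
            if self.between_class_variance is not None:
                header.append("between_class_variance")
                cols.append(self.between_class_variance)
            if self.fuzziness is not None:
                header.append("fuzziness")
                cols.append(self.fuzziness)
            writer.writerow(header)
            for row in zip(*cols):
                writer.writerow([f"{v:.9g}" for v in row])


@dataclass(frozen=True)
class ChannelThresholds:
    """The three method thresholds for one histogram and their fused average."""

    isodata: int
    otsu: int
    fuzzy: int
    channel: str | None = None

    @property
    def fused(self) -> int:
        # integer bin index; floor of the average
        return (self.isodata + self.otsu + self.fuzzy) // 3


@dataclass(frozen=True)
class MultilevelThresholds:
    """Strictly increasing fused thresholds for one channel, with provenance."""

    thresholds: tuple[int, ...]
    steps: tuple[ChannelThresholds, ...] = field(default=())
    channel: str | None = None

    def __post_init__(self):
        t = tuple(int(v) for v in self.thresholds)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ConfigurationError(f"thresholds not strictly increasing: {t}")
        object.__setattr__(self, "thresholds", t)

    @property
    def n_partitions(self) -> int:
        return len(self.thresholds) + 1


def _moments(hist: GreyHistogram):
    """Cumulative moments and conditional class means for every candidate t.

    Returns (w, mu, mu_total, mu1, mu2) where w(t) is the zeroth and mu(t)
    the first cumulative moment of the probability histogram up to level t,
    and mu1(t), mu2(t) are the means of the two regions split at t
    (NaN where a region is empty).
    """
    p = hist.probabilities
    levels = np.arange(hist.n_levels)
    w = np.cumsum(p)
    mu = np.cumsum(levels * p)
    mu_total = float(mu[-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        mu1 = np.where(w > 0, mu / w, np.nan)
        mu2 = np.where(w < 1, (mu_total - mu) / (1.0 - w), np.nan)
    return w, mu, mu_total, mu1, mu2


def _valid_candidates(w: np.ndarray) -> np.ndarray:
    # both regions non-empty: 0 < w(t) < 1 (up to float rounding of cumsum)
    return (w > 1e-12) & (w < 1.0 - 1e-12)


def isodata_threshold(hist: GreyHistogram) -> tuple[int, ThresholdDiagnostics]:
    """Iterative midpoint threshold.

    Starting from the floor of the histogram mean, the threshold is moved
    to the integer part of the midpoint of the two class means until it
    stops changing; the result is a fixpoint of
    ``t -> floor((mu1(t) + mu2(t)) / 2)``.
    """
    hist._require_splittable()
    w, mu, mu_total, mu1, mu2 = _moments(hist)
    diag = ThresholdDiagnostics(np.arange(hist.n_levels), w, mu, mu_total, mu1, mu2)

    t = int(np.floor(mu_total))
    occ = hist.occupied()
    # keep the split two-sided; the mean always lies in [min, max)
    t = int(np.clip(t, occ[0], occ[-1] - 1))
    seen = set()
    while t not in seen:
        seen.add(t)
        t_next = int((mu1[t] + mu2[t]) // 2)
        if t_next == t:
            break
        t = t_next
    return t, diag


def otsu_threshold(hist: GreyHistogram) -> tuple[int, ThresholdDiagnostics]:
    """Threshold maximizing the between-class variance of the histogram.

    ``sigma_B^2(t) = [mu_T w(t) - mu(t)]^2 / (w(t) (1 - w(t)))`` over
    candidates with both classes non-empty; ties go to the smallest level.
    """
    hist._require_splittable()
    w, mu, mu_total, mu1, mu2 = _moments(hist)
    valid = _valid_candidates(w)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = np.where(valid, (mu_total * w - mu) ** 2 / (w * (1.0 - w)), np.nan)
    diag = ThresholdDiagnostics(
        np.arange(hist.n_levels), w, mu, mu_total, mu1, mu2, between_class_variance=sigma_b
    )
    t = int(np.nanargmax(np.where(valid, sigma_b, -np.inf)))
    return t, diag


def _shannon(m: np.ndarray) -> np.ndarray:
    """Shannon binary entropy S(m) = -m ln m - (1-m) ln(1-m), with 0 ln 0 = 0."""
    m = np.clip(m, 0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = -np.where(m > 0, m * np.log(m), 0.0) - np.where(
            m < 1, (1.0 - m) * np.log(1.0 - m), 0.0
        )
    return s


def fuzzy_threshold(
    hist: GreyHistogram, membership_normalization: str = "range"
) -> tuple[int, ThresholdDiagnostics]:
    """Threshold minimizing the entropy-based measure of image fuzziness.

    For a candidate t, each level i gets a membership
    ``1 / (1 + |i - mu1(t)| / C)`` below the split and
    ``1 / (1 + |i - mu2(t)| / C)`` above; the fuzziness is the
    histogram-weighted mean of the Shannon function of the memberships,
    normalized by ln 2 so it lies in [0, 1].  The returned threshold is
    the argmin, ties to the smallest level.

    ``membership_normalization`` sets the constant C:

    - ``"range"`` (default): C = span of occupied levels, the classical
      fuzzy-entropy formulation; memberships stay in [1/2, 1] and the
      measure is invariant to rescaling the grey axis;
    - ``"none"``: C = 1, a variant sometimes printed without the
      normalizer.  Distances then dominate the membership, which biases
      the argmin toward extreme thresholds on wide histograms.
    """
    if membership_normalization not in ("range", "none"):
        raise ConfigurationError(
            f"unknown membership normalization: {membership_normalization!r}"
        )
    hist._require_splittable()
    w, mu, mu_total, mu1, mu2 = _moments(hist)
    valid = _valid_candidates(w)
    levels = np.arange(hist.n_levels)
    occ = hist.occupied()
    span = float(occ[-1] - occ[0]) if membership_normalization == "range" else 1.0

    cand = np.flatnonzero(valid)
    # membership matrix over (candidate t, level i); L <= a few hundred
    below = levels[None, :] <= cand[:, None]
    centre = np.where(below, mu1[cand][:, None], mu2[cand][:, None])
    membership = 1.0 / (1.0 + np.abs(levels[None, :] - centre) / span)
    entropy = (_shannon(membership) @ hist.counts) / (hist.total * np.log(2.0))

    fuzziness = np.full(hist.n_levels, np.nan)
    fuzziness[cand] = entropy
    diag = ThresholdDiagnostics(
        levels, w, mu, mu_total, mu1, mu2, fuzziness=fuzziness
    )
    t = int(cand[np.argmin(entropy)])
    return t, diag


def combined_threshold(hist: GreyHistogram, channel: str | None = None) -> ChannelThresholds:
    """Fuse the Isodata, Otsu and fuzzy thresholds by averaging.

    The fused threshold is the integer part of ``(t_I + t_O + t_F) / 3``;
    the component thresholds are retained in the result.
    """
    t_iso, _ = isodata_threshold(hist)
    t_otsu, _ = otsu_threshold(hist)
    t_fuzzy, _ = fuzzy_threshold(hist)
    return ChannelThresholds(isodata=t_iso, otsu=t_otsu, fuzzy=t_fuzzy, channel=channel)


def _partition_spread(counts: np.ndarray) -> float:
    """Population-weighted within-partition variance (sum of squared deviations)."""
    n = counts.sum()
    if n == 0:
        return 0.0
    levels = np.arange(counts.size, dtype=float)
    mean = (levels * counts).sum() / n
    return float(((levels - mean) ** 2 * counts).sum())


def successive_thresholds(
    values: np.ndarray,
    m: int,
    n_levels: int | None = None,
    channel: str | None = None,
) -> MultilevelThresholds:
    """Place ``m`` ordered thresholds by repeated partition splitting.

    The first threshold comes from the full histogram.  Each subsequent
    threshold re-thresholds the sub-histogram of one existing partition —
    the one with the largest population-weighted within-partition
    variance, mirroring the variance logic of the cluster-merging stage.
    Degenerate partitions are skipped; if no partition can be split before
    ``m`` thresholds are placed, :class:`ThresholdCountError` is raised
    with the partial result attached.
    """
    if m < 1:
        raise ConfigurationError(f"threshold count must be >= 1, got {m}")
    values = np.asarray(values).ravel()
    if n_levels is None:
        n_levels = int(values.max()) + 1 if values.size else 2
    hist = GreyHistogram.from_values(values, max(n_levels, 2))

    thresholds: list[int] = []
    steps: list[ChannelThresholds] = []
    while len(thresholds) < m:
        # partitions delimited by the current thresholds: (lo, hi] level spans
        bounds = [-1] + thresholds + [hist.n_levels - 1]
        spans = list(zip(bounds[:-1], bounds[1:]))
        order = sorted(
            range(len(spans)),
            key=lambda i: -_partition_spread(hist.counts[spans[i][0] + 1 : spans[i][1] + 1]),
        )
        placed = False
        for idx in order:
            lo, hi = spans[idx]
            sub = np.zeros_like(hist.counts)
            sub[lo + 1 : hi + 1] = hist.counts[lo + 1 : hi + 1]
            try:
                step = combined_threshold(GreyHistogram(sub), channel=channel)
            except (DegenerateHistogramError, EmptyHistogramError):
                continue
            thresholds.append(step.fused)
            thresholds.sort()
            steps.append(step)
            placed = True
            break
        if not placed:
            raise ThresholdCountError(
                f"could only place {len(thresholds)} of {m} thresholds",
                partial=MultilevelThresholds(tuple(thresholds), tuple(steps), channel),
            )
    return MultilevelThresholds(tuple(thresholds), tuple(steps), channel)
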