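"""Pixel coding, labelling, and variance-driven cluster merging.

The classifier is unsupervised with a dynamic number of classes.  Each
Lab channel is partitioned by its fused thresholds; the per-channel
partition codes are packed into a single class label.  Classes whose
within-class spectral spread exceeds their mutual separation are merged,
and if no merge happens at all the number of thresholds is increased and
the whole clustering restarts — the class count emerges from the data.

For the four-class frost-damage survey (green oat GO, dried oat DO,
half-dried oat HD, shady ground SG) the merge criterion can additionally
be relaxed to force fusion down to a target class count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .colour import quantize_channels
from .errors import (
    CannotSplitError,
    ConfigurationError,
    CorruptInputError,
)
from .thresholding import MultilevelThresholds, ThresholdCountError, successive_thresholds

__all__ = [
    "ClassStats",
    "ROLES",
    "encode_pixels",
    "label_pixels",
    "class_statistics",
    "between_class_separation",
    "merge_step",
    "merge_until_stable",
    "classify",
    "semantic_mapping",
    "damage_report",
]

logger = logging.getLogger(__name__)

#: The four semantic classes of the frost-damage survey.
ROLES = ("GO", "DO", "HD", "SG")


@dataclass(frozen=True)
class ClassStats:
    """Population, spectral mean and within-class spread of one class.

    ``sigma`` is, in the default ``as_printed`` form, the mean Euclidean
    distance of member pixels to the class mean scaled by 1/d (d = 3
    channels); in the ``squared`` form it is the mean squared deviation
    per channel, which is dimensionally commensurate with the
    between-class separation of :func:`between_class_separation`.
    """

    label: int
    n: int
    mean: tuple[float, float, float]
    sigma: float


def encode_pixels(
    quantized: np.ndarray, thresholds: list[MultilevelThresholds]
) -> np.ndarray:
    """Code each pixel channel against its ordered thresholds.

    A value ``v`` gets code ``c`` = number of thresholds strictly below
    ``v``: the lower interval is ``v <= t_1`` (code 0), then
    ``t_1 < v <= t_2`` (code 1), ..., ``v > t_M`` (code M).
    """
    quantized = np.asarray(quantized)
    if quantized.shape[-1] != len(thresholds):
        raise ConfigurationError("one threshold list per channel required")
    counts = {len(t.thresholds) for t in thresholds}
    if len(counts) != 1:
        raise ConfigurationError(f"threshold count differs across channels: {counts}")
    coded = np.empty(quantized.shape, dtype=np.int64)
    for c, thr in enumerate(thresholds):
        coded[..., c] = np.searchsorted(
            np.asarray(thr.thresholds), quantized[..., c], side="left"
        )
    return coded


def label_pixels(coded: np.ndarray, n_partitions: int) -> np.ndarray:
    """Pack per-channel codes into one label: ``n^2 c_L + n c_a + c_b``.

    With ``n`` partitions per channel and 3 channels this is a bijection
    between code triplets and ``{0 .. n^3 - 1}``.
    """
    coded = np.asarray(coded)
    if coded.min() < 0 or coded.max() >= n_partitions:
        raise CorruptInputError("pixel code outside [0, n_partitions)")
    n = n_partitions
    return n * n * coded[..., 0] + n * coded[..., 1] + coded[..., 2]


def class_statistics(
    lab: np.ndarray, labels: np.ndarray, variance_form: str = "as_printed"
) -> list[ClassStats]:
    """Per-class population, spectral mean, and within-class spread.

    The mean is the centroid of member pixels in Lab.  The spread is
    ``(1 / (d N_k)) * sum_k ||pixel - mean||`` in the ``as_printed`` form
    (a 1/d-scaled mean distance) or the mean squared deviation per
    channel in the ``squared`` form.  Empty classes are excluded.
    """
    if variance_form not in ("as_printed", "squared"):
        raise ConfigurationError(f"unknown variance form: {variance_form!r}")
    pixels = np.asarray(lab, dtype=float).reshape(-1, 3)
    flat = np.asarray(labels).ravel()
    if flat.size != pixels.shape[0]:
        raise CorruptInputError("label map and Lab image sizes differ")
    occupied, inverse, counts = np.unique(flat, return_inverse=True, return_counts=True)
    d = 3
    sums = np.zeros((occupied.size, d))
    np.add.at(sums, inverse, pixels)
    means = sums / counts[:, None]
    dev = pixels - means[inverse]
    sq = (dev**2).sum(axis=1)
    if variance_form == "as_printed":
        per_class = np.bincount(inverse, weights=np.sqrt(sq), minlength=occupied.size)
    else:
        per_class = np.bincount(inverse, weights=sq, minlength=occupied.size)
    sigma = per_class / (d * counts)
    return [
        ClassStats(int(k), int(n), tuple(mu), float(s))
        for k, n, mu, s in zip(occupied, counts, means, sigma)
    ]


def between_class_separation(a: ClassStats, b: ClassStats) -> float:
    """Mean squared distance between two class means: ``(1/d) ||mu_k - mu_h||^2``."""
    diff = np.asarray(a.mean) - np.asarray(b.mean)
    return float((diff**2).sum() / 3.0)


def _separation_matrix(stats: list[ClassStats]) -> np.ndarray:
    means = np.array([s.mean for s in stats])
    diff = means[:, None, :] - means[None, :, :]
    return (diff**2).sum(axis=-1) / 3.0


def _best_pair(stats: list[ClassStats], require_overlap: bool):
    """Pair with the largest merge-criterion violation ``max(s_k, s_h) - s_kh``.

    With ``require_overlap`` only pairs actually satisfying the merge
    criterion (``s_k >= s_kh`` or ``s_h >= s_kh``) qualify; without it the
    criterion is relaxed and the least-separated pair is returned (used to
    force fusion down to a target class count).
    """
    sep = _separation_matrix(stats)
    sigmas = np.array([s.sigma for s in stats])
    best, best_score = None, -np.inf
    for i in range(len(stats)):
        for j in range(i + 1, len(stats)):
            score = max(sigmas[i], sigmas[j]) - sep[i, j]
            if require_overlap and score < 0:
                continue
            if score > best_score:
                best, best_score = (i, j), score
    return best, best_score


def _merge_pair(labels: np.ndarray, stats: list[ClassStats], i: int, j: int) -> np.ndarray:
    # the fused class keeps the label of the smaller-variance member
    keep, drop = (i, j) if stats[i].sigma <= stats[j].sigma else (j, i)
    out = labels.copy()
    out[out == stats[drop].label] = stats[keep].label
    logger.debug(
        "merge: %d <- %d (sigma_k=%.4g, sigma_h=%.4g, sigma_kh=%.4g)",
        stats[keep].label,
        stats[drop].label,
        stats[i].sigma,
        stats[j].sigma,
        between_class_separation(stats[i], stats[j]),
    )
    return out


def merge_step(
    labels: np.ndarray, lab: np.ndarray, variance_form: str = "as_printed"
) -> tuple[np.ndarray, bool]:
    """Perform at most one merge of spectrally overlapping classes.

    Classes ``k`` and ``h`` are merge candidates when the within-class
    spread of either reaches their between-class separation
    (``sigma_k >= sigma_kh`` or ``sigma_h >= sigma_kh``); the pair with
    the greatest violation is merged first, keeping the label of the
    smaller-variance member.  Returns the (possibly new) label map and a
    flag telling whether a merge occurred.
    """
    stats = class_statistics(lab, labels, variance_form)
    if len(stats) < 2:
        return labels, False
    pair, _ = _best_pair(stats, require_overlap=True)
    if pair is None:
        return labels, False
    return _merge_pair(labels, stats, *pair), True


def merge_until_stable(
    labels: np.ndarray, lab: np.ndarray, variance_form: str = "as_printed"
) -> tuple[np.ndarray, bool]:
    """Merge repeatedly until every between-class separation exceeds both
    within-class spreads.  Returns the stable map and whether any merge
    occurred; terminates in at most (initial class count - 1) merges."""
    any_merge = False
    while True:
        labels, merged = merge_step(labels, lab, variance_form)
        if not merged:
            return labels, any_merge
        any_merge = True


def _apply_population_floor(
    labels: np.ndarray, lab: np.ndarray, min_population: int, variance_form: str
) -> np.ndarray:
    """Merge classes below the population floor into their nearest neighbour.

    Nearest is by between-class separation; the smallest class goes
    first.  With the default floor of 1 this is a no-op.
    """
    while True:
        stats = class_statistics(lab, labels, variance_form)
        small = [s for s in stats if s.n < min_population]
        if not small or len(stats) < 2:
            return labels
        sep = _separation_matrix(stats)
        i = stats.index(min(small, key=lambda s: s.n))
        j = min((j for j in range(len(stats)) if j != i), key=lambda j: sep[i, j])
        labels = _merge_pair(labels, stats, i, j)


def classify(
    lab: np.ndarray,
    target_classes: int | None = None,
    variance_form: str = "as_printed",
    l_levels: int = 101,
    ab_levels: int = 221,
    max_thresholds: int = 6,
    min_population: int = 1,
) -> tuple[np.ndarray, list[ClassStats]]:
    """Full unsupervised pipeline: threshold, code, label, merge.

    Starting with one threshold per channel, the image is coded and
    labelled, then overlapping classes are merged until stable.

    Without a target class count the number of classes is dynamic: if no
    merge happens at all the partition is judged too coarse, the
    per-channel threshold count is increased by one and clustering
    restarts, until a fusion occurs.  Should the probe exhaust
    ``max_thresholds`` without any fusion ever occurring — every probed
    partition already being properly separated — the coarsest stable
    partition (one threshold per channel) is kept: finer thresholds only
    subdivide classes that the merge criterion then declines to reunite.

    With ``target_classes`` K, the survey workflow applies: one
    threshold per channel already yields up to 8 classes, so the
    coarsest partition whose stable class count reaches K is used and
    the merge criterion is then relaxed, fusing the pair with the
    greatest overlap (largest ``max(sigma_k, sigma_h) - sigma_kh``)
    until exactly K classes remain.  The threshold count is increased
    only when the stable partition has fewer than K classes; if even
    ``max_thresholds`` cannot produce K, the class count cannot be
    reached (the method only merges) and an error is raised.

    ``min_population`` sets an optional floor below which classes are
    folded into their nearest neighbour before the merge loop (default
    1: no filtering).
    """
    lab = np.asarray(lab, dtype=float)
    quantized = quantize_channels(lab, l_levels=l_levels, ab_levels=ab_levels)
    channel_names = ("L", "a", "b")
    n_channel_levels = (l_levels, ab_levels, ab_levels)

    if target_classes is not None and target_classes < 1:
        raise ConfigurationError("target class count must be >= 1")

    labels = None
    coarsest = None
    m = 1
    while True:
        try:
            thresholds = [
                successive_thresholds(
                    quantized[..., c], m, n_levels=n_channel_levels[c], channel=channel_names[c]
                )
                for c in range(3)
            ]
        except ThresholdCountError:
            # no channel partition can be split further
            labels = coarsest if coarsest is not None else labels
            break
        for thr in thresholds:
            logger.debug("channel %s thresholds (M=%d): %s", thr.channel, m, thr.thresholds)
        coded = encode_pixels(quantized, thresholds)
        labels = label_pixels(coded, n_partitions=m + 1)
        if min_population > 1:
            labels = _apply_population_floor(labels, lab, min_population, variance_form)
        labels, any_merge = merge_until_stable(labels, lab, variance_form)
        if target_classes is not None:
            # survey workflow: coarsest partition reaching the target count
            if len(np.unique(labels)) >= target_classes:
                break
        elif any_merge:
            break
        elif coarsest is None:
            coarsest = labels
        m += 1
        if m > max_thresholds:
            if target_classes is None:
                labels = coarsest
            break
    if labels is None:
        # image so uniform that even one threshold cannot be placed
        labels = np.zeros(lab.shape[:-1], dtype=np.int64)

    if target_classes is not None:
        stats = class_statistics(lab, labels, variance_form)
        if target_classes > len(stats):
            raise CannotSplitError(
                f"{len(stats)} classes remain but {target_classes} requested; "
                "the method only merges"
            )
        while len(stats) > target_classes:
            pair, _ = _best_pair(stats, require_overlap=False)
            labels = _merge_pair(labels, stats, *pair)
            stats = class_statistics(lab, labels, variance_form)
    return labels, class_statistics(lab, labels, variance_form)


def semantic_mapping(stats: list[ClassStats]) -> dict[int, str]:
    """Assign the four survey roles GO/DO/HD/SG to four classes by their means.

    SG (shady ground) is the class with the lowest lightness; among the
    rest GO (green oat) has the most negative a* (greenest), DO (dried
    oat) the most positive b* of the remaining two (yellowest), and HD
    (half-dried) is the remainder.  The heuristic is a convenience — the
    mapping is returned with the statistics so a user can override it.
    Ties are resolved by class label, with a warning.
    """
    if len(stats) != 4:
        raise ConfigurationError(f"semantic mapping needs exactly 4 classes, got {len(stats)}")

    def pick(pool: list[ClassStats], key) -> ClassStats:
        ordered = sorted(pool, key=lambda s: (key(s), s.label))
        if len(ordered) > 1 and key(ordered[0]) == key(ordered[1]):
            warnings.warn("tie in semantic mapping; resolved by class label", stacklevel=3)
        return ordered[0]

    pool = list(stats)
    sg = pick(pool, lambda s: s.mean[0])
    pool.remove(sg)
    go = pick(pool, lambda s: s.mean[1])
    pool.remove(go)
    do = pick(pool, lambda s: -s.mean[2])
    pool.remove(do)
    (hd,) = pool
    return {go.label: "GO", do.label: "DO", hd.label: "HD", sg.label: "SG"}


def damage_report(
    labels: np.ndarray,
    roles: dict[int, str],
    area_per_pixel: float = 1.0,
    hd_usable_fraction: float = 0.5,
) -> dict:
    """Per-role coverage and the usable (harvestable) area.

    Healthy green oat counts fully; half-dried oat contributes the
    fraction ``hd_usable_fraction`` of its area (experts place the usable
    share of that class at 40-60%, hence the 0.5 default); dried oat and
    shady ground contribute nothing.
    """
    if not 0.0 <= hd_usable_fraction <= 1.0:
        raise ConfigurationError("hd_usable_fraction must lie in [0, 1]")
    flat = np.asarray(labels).ravel()
    present = np.unique(flat)
    unknown = [int(k) for k in present if int(k) not in roles]
    if unknown:
        raise CorruptInputError(f"labels without a role: {unknown}")
    total = flat.size
    role_pixels = {role: 0 for role in ROLES}
    for k in present:
        role_pixels[roles[int(k)]] += int((flat == k).sum())
    fractions = {role: n / total for role, n in role_pixels.items()}
    areas = {role: n * area_per_pixel for role, n in role_pixels.items()}
    usable = areas["GO"] + hd_usable_fraction * areas["HD"]
    return {
        "pixels": role_pixels,
        "fractions": fractions,
        "areas": areas,
        "total_area": total * area_per_pixel,
        "hd_usable_fraction": hd_usable_fraction,
        "usable_area": usable,
    }
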