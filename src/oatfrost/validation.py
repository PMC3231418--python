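"""Accuracy assessment for thematic maps: sampling design and fuzzy error matrices.

Reference data are homogeneous polygons drawn by an expert rather than
single pixels, so that positional error does not masquerade as thematic
error.  Sample units are cross-tabulated into a square error matrix of
classified class (rows) versus reference class (columns).  In the fuzzy
variant each off-diagonal cell holds a pair *(acceptable; unacceptable)*:
a unit whose classified map overlaps its reference class on at least 50%
of its surface is only *acceptably* wrong, not an outright error.
Collapsing the pairs by addition recovers the ordinary deterministic
matrix.

Derived measures follow remote-sensing convention: overall accuracy
(diagonal over grand total), classifier's (user's) accuracy per row with
its complement the commission error, and expert's (producer's) accuracy
per column with its complement the omission error.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from skimage.draw import polygon as draw_polygon

from .errors import (
    ConfigurationError,
    CorruptInputError,
    GeometryError,
    UndefinedAccuracyError,
)

__all__ = [
    "chi_square_coefficient",
    "sample_size",
    "allocate_samples",
    "PolygonSample",
    "overlap_fraction",
    "score_polygon",
    "PolygonScore",
    "build_error_matrix",
    "FuzzyErrorMatrix",
    "accuracy_report",
]


def chi_square_coefficient(b: float, k: int) -> float:
    """Chi-square quantile with 1 degree of freedom at probability ``1 - b/k``.

    This is the coefficient B of the multinomial sample-size formula; the
    division of the accuracy ``b`` by the class count ``k`` is the
    Bonferroni-style correction for simultaneous class-wise intervals.
    """
    if not 0.0 < b < 1.0:
        raise ConfigurationError(f"accuracy b must lie in (0, 1), got {b}")
    if k < 1:
        raise ConfigurationError(f"class count must be >= 1, got {k}")
    return float(chi2.ppf(1.0 - b / k, df=1))


def sample_size(
    fractions,
    b: float = 0.05,
    coefficient: float | None = None,
    class_index: int | None = None,
) -> int:
    """Required number of sample units, ``n_s = ceil(B * Pi (1 - Pi) / b^2)``.

    ``fractions`` are the per-class image-surface fractions Pi_k.  Unless
    ``class_index`` picks a specific class, the fraction maximizing
    ``Pi (1 - Pi)`` (the worst case) is used.  ``coefficient`` overrides
    the computed chi-square quantile B, e.g. to match a printed table.
    """
    pis = np.asarray(fractions, dtype=float)
    if pis.ndim == 0:
        pis = pis[None]
    if ((pis < 0) | (pis > 1)).any():
        raise ConfigurationError("class fractions must lie in [0, 1]")
    if pis.sum() > 1.0 + 1e-9:
        raise ConfigurationError("class fractions sum to more than 1")
    if not 0.0 < b < 1.0:
        raise ConfigurationError(f"accuracy b must lie in (0, 1), got {b}")
    k = pis.size
    if class_index is not None:
        pi = float(pis[class_index])
    else:
        pi = float(pis[np.argmax(pis * (1.0 - pis))])
    if pi in (0.0, 1.0):
        warnings.warn(f"class fraction {pi} gives a degenerate sample size of 0", stacklevel=2)
        return 0
    big_b = coefficient if coefficient is not None else chi_square_coefficient(b, k)
    return math.ceil(big_b * pi * (1.0 - pi) / b**2)


def allocate_samples(n_samples: int, fractions) -> list[int]:
    """Apportion ``n_samples`` to classes by largest remainder.

    Counts are the floors of ``n_samples * fraction`` with the leftover
    units given to the classes with the largest fractional remainders
    (ties to the earlier class); the counts always sum to ``n_samples``.
    """
    fr = np.asarray(fractions, dtype=float)
    if (fr < 0).any():
        raise ConfigurationError("fractions must be non-negative")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must sum to 1, got {fr.sum()}")
    quotas = n_samples * fr
    counts = np.floor(quotas).astype(int)
    remainder = n_samples - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts.tolist()


@dataclass
class PolygonSample:
    """A homogeneous reference region with a single expert-assigned class.

    Vertices are (x, y) pixel coordinates (x = column, y = row), at least
    three of them; the rasterized pixel set is boundary-inclusive.
    """

    polygon_id: str
    label: str
    vertices: list[tuple[float, float]]
    _pixels: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise GeometryError(
                f"polygon {self.polygon_id!r} needs >= 3 vertices, got {len(self.vertices)}"
            )

    def pixels(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the rasterized polygon within ``shape``."""
        if self._pixels is None:
            xs = np.array([v[0] for v in self.vertices], dtype=float)
            ys = np.array([v[1] for v in self.vertices], dtype=float)
            if xs.min() < 0 or ys.min() < 0 or xs.max() >= shape[1] or ys.max() >= shape[0]:
                raise GeometryError(f"polygon {self.polygon_id!r} falls outside the map")
            rr, cc = draw_polygon(ys, xs, shape=shape)
            if rr.size == 0:
                raise GeometryError(f"polygon {self.polygon_id!r} rasterizes to no pixels")
            self._pixels = (rr, cc)
        return self._pixels

    @property
    def n_pixels(self) -> int:
        if self._pixels is None:
            raise GeometryError("polygon not yet rasterized; call pixels(shape) first")
        return int(self._pixels[0].size)


def _role_counts(poly: PolygonSample, role_map: np.ndarray, classes) -> dict[str, int]:
    rr, cc = poly.pixels(np.asarray(role_map).shape)
    values = np.asarray(role_map)[rr, cc]
    if values.min() < 0 or values.max() >= len(classes):
        raise CorruptInputError("role map contains values outside the class list")
    counts = np.bincount(values, minlength=len(classes))
    return {cls: int(n) for cls, n in zip(classes, counts)}


def overlap_fraction(poly: PolygonSample, role_map: np.ndarray, role: str, classes) -> float:
    """Fraction of the polygon's pixels carrying ``role`` on the classified map."""
    counts = _role_counts(poly, role_map, classes)
    if role not in counts:
        raise ConfigurationError(f"unknown role {role!r}")
    return counts[role] / sum(counts.values())


@dataclass(frozen=True)
class PolygonScore:
    """Outcome of comparing one reference polygon with the classified map."""

    polygon_id: str
    outcome: str  # absolutely_correct | acceptable | error
    row: str  # classified class (matrix row)
    column: str  # reference class (matrix column)
    overlap: float
    n_pixels: int


def score_polygon(poly: PolygonSample, role_map: np.ndarray, classes) -> PolygonScore:
    """Score one sample unit under the fuzzy rules.

    With ``f`` the overlap between the polygon and its reference class on
    the classified map: ``f = 1`` is absolutely correct (diagonal cell);
    ``0.5 <= f < 1`` is acceptable, tallied in the left counter of the
    cell whose row is the majority *non-reference* classified class;
    ``f < 0.5`` is an error, tallied in the right counter of the cell
    whose row is the majority classified class.
    """
    if poly.label not in classes:
        raise ConfigurationError(f"polygon {poly.polygon_id!r} has unknown class {poly.label!r}")
    counts = _role_counts(poly, role_map, classes)
    total = sum(counts.values())
    f = counts[poly.label] / total
    if f == 1.0:
        return PolygonScore(poly.polygon_id, "absolutely_correct", poly.label, poly.label, f, total)
    others = {cls: n for cls, n in counts.items() if cls != poly.label}
    majority_other = max(others, key=lambda cls: (others[cls], -classes.index(cls)))
    if f >= 0.5:
        return PolygonScore(poly.polygon_id, "acceptable", majority_other, poly.label, f, total)
    # an outright error: row = the class the unit was mostly classified as
    majority = max(counts, key=lambda cls: (counts[cls], -classes.index(cls)))
    if majority == poly.label:
        majority = majority_other  # plurality ties the reference below 50%; keep off-diagonal
    return PolygonScore(poly.polygon_id, "error", majority, poly.label, f, total)


@dataclass
class FuzzyErrorMatrix:
    """Square accounting of sample units: classified (rows) x reference (columns).

    ``correct[i]`` is the diagonal count of class ``i``;
    ``acceptable[i, j]`` / ``unacceptable[i, j]`` are the left and right
    counters of off-diagonal cell (row i, column j).  The deterministic
    matrix is the same structure with each off-diagonal pair collapsed by
    addition.
    """

    classes: tuple[str, ...]
    correct: np.ndarray
    acceptable: np.ndarray
    unacceptable: np.ndarray

    def __post_init__(self):
        k = len(self.classes)
        self.correct = np.asarray(self.correct, dtype=np.int64)
        self.acceptable = np.asarray(self.acceptable, dtype=np.int64)
        self.unacceptable = np.asarray(self.unacceptable, dtype=np.int64)
        if self.correct.shape != (k,) or self.acceptable.shape != (k, k):
            raise ConfigurationError("matrix shapes inconsistent with class list")
        if self.unacceptable.shape != (k, k):
            raise ConfigurationError("matrix shapes inconsistent with class list")
        for arr in (self.correct, self.acceptable, self.unacceptable):
            if (arr < 0).any():
                raise ConfigurationError("matrix counts must be non-negative")
        if np.diagonal(self.acceptable).any() or np.diagonal(self.unacceptable).any():
            raise ConfigurationError("off-diagonal pair counters must be zero on the diagonal")

    @classmethod
    def empty(cls, classes) -> "FuzzyErrorMatrix":
        k = len(classes)
        return cls(tuple(classes), np.zeros(k, int), np.zeros((k, k), int), np.zeros((k, k), int))

    # -- structure ---------------------------------------------------------
    def deterministic(self) -> np.ndarray:
        """Collapsed K x K count matrix (pairs summed, diagonal on the diagonal)."""
        out = self.acceptable + self.unacceptable
        out[np.diag_indices_from(out)] = self.correct
        return out

    def row_totals(self) -> np.ndarray:
        return self.deterministic().sum(axis=1)

    def column_totals(self) -> np.ndarray:
        return self.deterministic().sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.deterministic().sum())

    def _index(self, cls: str) -> int:
        try:
            return self.classes.index(cls)
        except ValueError:
            raise ConfigurationError(f"unknown class {cls!r}") from None

    def add(self, score: PolygonScore, weight: int = 1) -> None:
        i, j = self._index(score.row), self._index(score.column)
        if score.outcome == "absolutely_correct":
            self.correct[i] += weight
        elif score.outcome == "acceptable":
            self.acceptable[i, j] += weight
        elif score.outcome == "error":
            self.unacceptable[i, j] += weight
        else:
            raise ConfigurationError(f"unknown outcome {score.outcome!r}")

    # -- accuracy measures -------------------------------------------------
    def overall_accuracy(self, mode: str = "deterministic") -> float:
        """Diagonal (plus acceptable counts in fuzzy mode) over the grand total."""
        total = self.grand_total
        if total == 0:
            raise UndefinedAccuracyError("empty matrix")
        good = self.correct.sum()
        if _check_mode(mode) == "fuzzy":
            good = good + self.acceptable.sum()
        return float(good / total)

    def classifier_accuracy(self, cls: str, mode: str = "deterministic") -> float:
        """User's accuracy: correct units over all units classified into ``cls``.

        Fuzzy mode also credits the row's acceptable counts.  The
        complement is the commission error.
        """
        i = self._index(cls)
        row_total = self.row_totals()[i]
        if row_total == 0:
            raise UndefinedAccuracyError(f"no units classified as {cls!r}")
        good = self.correct[i]
        if _check_mode(mode) == "fuzzy":
            good = good + self.acceptable[i].sum()
        return float(good / row_total)

    def expert_accuracy(self, cls: str, mode: str = "deterministic") -> float:
        """Producer's accuracy: correct units over all reference units of ``cls``.

        Fuzzy mode also credits the column's acceptable counts.  The
        complement is the omission error.
        """
        j = self._index(cls)
        col_total = self.column_totals()[j]
        if col_total == 0:
            raise UndefinedAccuracyError(f"no reference units of {cls!r}")
        good = self.correct[j]
        if _check_mode(mode) == "fuzzy":
            good = good + self.acceptable[:, j].sum()
        return float(good / col_total)

    def commission_error(self, cls: str, mode: str = "deterministic") -> float:
        return 1.0 - self.classifier_accuracy(cls, mode)

    def omission_error(self, cls: str, mode: str = "deterministic") -> float:
        return 1.0 - self.expert_accuracy(cls, mode)

    # -- serialisation -----------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the matrix with off-diagonal cells in ``acceptable;unacceptable`` style."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["classified\\reference", *self.classes, "row_total"])
            for i, cls in enumerate(self.classes):
                cells = [
                    str(int(self.correct[i]))
                    if i == j
                    else f"{int(self.acceptable[i, j])};{int(self.unacceptable[i, j])}"
                    for j in range(len(self.classes))
                ]
                writer.writerow([cls, *cells, int(self.row_totals()[i])])
            writer.writerow(["column_total", *map(int, self.column_totals()), self.grand_total])

    @classmethod
    def from_csv(cls, path) -> "FuzzyErrorMatrix":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        classes = tuple(rows[0][1:-1])
        matrix = cls.empty(classes)
        for i, row in enumerate(rows[1 : 1 + len(classes)]):
            for j, cell in enumerate(row[1 : 1 + len(classes)]):
                if i == j:
                    matrix.correct[i] = int(cell)
                else:
                    acc, unacc = cell.split(";")
                    matrix.acceptable[i, j] = int(acc)
                    matrix.unacceptable[i, j] = int(unacc)
        return matrix


def _check_mode(mode: str) -> str:
    if mode not in ("deterministic", "fuzzy"):
        raise ConfigurationError(f"unknown accuracy mode {mode!r}")
    return mode


def build_error_matrix(
    polygons,
    role_map: np.ndarray,
    classes,
    weighting: str = "pixel",
) -> FuzzyErrorMatrix:
    """Accumulate polygon scores into a fuzzy error matrix.

    With ``weighting='pixel'`` (default) each sample unit contributes its
    pixel count, so the grand total is the sampled surface; with
    ``'unit'`` each polygon counts once and the grand total is the number
    of polygons.
    """
    if weighting not in ("pixel", "unit"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    matrix = FuzzyErrorMatrix.empty(classes)
    for poly in polygons:
        score = score_polygon(poly, role_map, classes)
        matrix.add(score, weight=score.n_pixels if weighting == "pixel" else 1)
    return matrix


def accuracy_report(matrix: FuzzyErrorMatrix) -> dict:
    """All accuracy measures as exact ratios plus nearest-integer percents."""

    def pct(x: float) -> int:
        return round(100.0 * x)

    report: dict = {"classes": list(matrix.classes), "grand_total": matrix.grand_total}
    for mode in ("deterministic", "fuzzy"):
        overall = matrix.overall_accuracy(mode)
        section = {"overall_accuracy": overall, "overall_accuracy_pct": pct(overall), "classes": {}}
        for cls in matrix.classes:
            ca = matrix.classifier_accuracy(cls, mode)
            ea = matrix.expert_accuracy(cls, mode)
            section["classes"][cls] = {
                "classifier_accuracy": ca,
                "classifier_accuracy_pct": pct(ca),
                "commission_error_pct": 100 - pct(ca),
                "expert_accuracy": ea,
                "expert_accuracy_pct": pct(ea),
                "omission_error_pct": 100 - pct(ea),
            }
        report[mode] = section
    return report
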