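"""DOMAIN climate envelopes and the climate-matching statistic.

The DOMAIN algorithm scores a location by its range-normalized mean
absolute (Gower) distance to the *nearest* climatic training point of a
species.  Here a species' envelope is built from the distinct raster
cells holding its occurrences (at least six), and a species-region
climate match is the fraction of the region's cells whose DOMAIN
similarity reaches a percentile threshold of the envelope itself.

Threshold convention: the envelope's threshold at percentile ``q`` is
the (100-q)th percentile of the leave-one-out maximum similarities
among the training points, so q=90 demands that a cell be at least as
similar to the envelope as 90% of the envelope's own points are to each
other.  Higher scores mean better climatic match.

Cells with a perfect similarity (1 within 1e-9) are excluded from both
numerator and denominator of the score: occurrence databases contain
introduced populations, and their own cells would otherwise inflate the
match of exactly the successful introductions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .rasters import RasterStack

logger = logging.getLogger(__name__)

MIN_OCCURRENCES = 6
PERFECT_TOL = 1e-9

__all__ = [
    "ClimateEnvelope", "ClimateMatchScore", "MIN_OCCURRENCES",
    "extract_cell_climate", "gower_distance", "build_envelope",
    "domain_similarity", "climate_match_score",
    "InsufficientOccurrencesError", "DegenerateEnvelopeError",
]


class InsufficientOccurrencesError(ValueError):
    """Fewer than six distinct occurrence cells for a species."""


class DegenerateEnvelopeError(ValueError):
    """All training ranges are zero: no variable discriminates."""


@dataclass
class ClimateEnvelope:
    """A species' climatic envelope.

    training: (n, v) array of climate vectors, one per occurrence cell.
    ranges: per-variable max - min over training.
    threshold_similarity: similarity a cell must reach to count as a match.
    """

    species_id: str
    training: np.ndarray
    ranges: np.ndarray
    threshold_similarity: float
    percentile_q: int

    def __post_init__(self) -> None:
        self.training = np.asarray(self.training, dtype=float)
        self.ranges = np.asarray(self.ranges, dtype=float)
        if self.training.shape[0] < MIN_OCCURRENCES:
            raise InsufficientOccurrencesError(
                f"{self.species_id}: {self.training.shape[0]} training cells "
                f"(need >= {MIN_OCCURRENCES})"
            )
        if np.any(self.ranges < 0):
            raise ValueError("negative variable range")
        if not 0.0 <= self.threshold_similarity <= 1.0:
            raise ValueError("threshold_similarity outside [0, 1]")


@dataclass
class ClimateMatchScore:
    """Climate match of one species-jurisdiction pair."""

    score: float  # NaN when every cell was excluded as perfect
    n_cells_scored: int
    n_cells_perfect_excluded: int
    species_id: str = ""
    jurisdiction_id: str = ""

    @property
    def defined(self) -> bool:
        return not np.isnan(self.score)


def extract_cell_climate(
    stack: RasterStack, lons, lats, return_cells: bool = False
):
    """Climate vectors of the distinct raster cells hit by a set of points.

    Duplicate points in one cell collapse to a single vector; points
    outside the grid extent are dropped with a warning; cells with any
    NODATA variable are dropped and counted in the log.

    Returns an (n_cells, n_vars) array (plus the (row, col) cell ids
    when ``return_cells``).  Raises ValueError when no cell survives.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if lons.shape != lats.shape:
        raise ValueError("lon/lat length mismatch")
    grid = stack.grid
    cells: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    n_outside = 0
    for lon, lat in zip(lons, lats):
        cell = grid.cell_of(lon, lat)
        if cell is None:
            n_outside += 1
            continue
        if cell not in seen:
            seen.add(cell)
            cells.append(cell)
    if n_outside:
        logger.warning("%d point(s) outside raster extent dropped", n_outside)
    cube = stack.as_array()  # (v, rows, cols)
    vectors, kept_cells = [], []
    n_nodata = 0
    for row, col in cells:
        vec = cube[:, row, col]
        if np.any(np.isnan(vec)):
            n_nodata += 1
            continue
        vectors.append(vec)
        kept_cells.append((row, col))
    if n_nodata:
        logger.warning("%d cell(s) with missing climate dropped", n_nodata)
    if not vectors:
        raise ValueError("no occupied raster cell with complete climate data")
    out = np.vstack(vectors)
    return (out, kept_cells) if return_cells else out


def gower_distance(x, y, ranges) -> float:
    """Range-normalized mean absolute distance between two climate vectors.

    Variables with zero range are dropped from the mean (they cannot
    discriminate); when every range is zero the envelope is degenerate.
    The distance can exceed 1 when y lies outside the training ranges.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranges = np.asarray(ranges, dtype=float)
    if x.shape != y.shape or x.shape != ranges.shape:
        raise ValueError("vector/range length mismatch")
    active = ranges > 0
    if not np.any(active):
        raise DegenerateEnvelopeError("all variable ranges are zero")
    return float(np.mean(np.abs(x[active] - y[active]) / ranges[active]))


def _similarity_matrix(cells: np.ndarray, training: np.ndarray,
                       ranges: np.ndarray) -> np.ndarray:
    """(n_cells, n_training) DOMAIN similarities, vectorized."""
    active = ranges > 0
    if not np.any(active):
        raise DegenerateEnvelopeError("all variable ranges are zero")
    diff = np.abs(cells[:, None, active] - training[None, :, active])
    dist = diff / ranges[active]
    return np.clip(1.0 - dist.mean(axis=2), 0.0, None)


def build_envelope(training, percentile_q: int = 90,
                   species_id: str = "") -> ClimateEnvelope:
    """Build a species' envelope and its percentile similarity threshold.

    The threshold is the (100-q)th percentile (linear interpolation
    between order statistics) of each training point's maximum
    similarity to the other training points (leave-one-out).
    """
    training = np.asarray(training, dtype=float)
    if training.ndim != 2:
        raise ValueError("training must be a 2-D (points x variables) array")
    if training.shape[0] < MIN_OCCURRENCES:
        raise InsufficientOccurrencesError(
            f"{species_id or 'species'}: {training.shape[0]} training cells "
            f"(need >= {MIN_OCCURRENCES})"
        )
    if percentile_q not in (50, 80, 90, 95):
        raise ValueError("percentile_q must be one of 50, 80, 90, 95")
    ranges = training.max(axis=0) - training.min(axis=0)
    sim = _similarity_matrix(training, training, ranges)
    np.fill_diagonal(sim, -np.inf)  # leave-one-out
    loo_max = sim.max(axis=1)
    threshold = float(np.percentile(loo_max, 100 - percentile_q))
    return ClimateEnvelope(
        species_id=species_id, training=training, ranges=ranges,
        threshold_similarity=float(np.clip(threshold, 0.0, 1.0)),
        percentile_q=percentile_q,
    )


def domain_similarity(cell, env: ClimateEnvelope) -> float:
    """DOMAIN similarity of one cell to an envelope: max over training
    points of 1 - Gower distance, clipped below at 0."""
    cell = np.asarray(cell, dtype=float)
    sims = _similarity_matrix(cell[None, :], env.training, env.ranges)
    return float(sims[0].max())


def climate_match_score(env: ClimateEnvelope, region_cells,
                        species_id: str = "",
                        jurisdiction_id: str = "") -> ClimateMatchScore:
    """Fraction of a region's cells whose similarity reaches the
    envelope threshold, after excluding perfect-similarity cells."""
    region_cells = np.asarray(region_cells, dtype=float)
    if region_cells.ndim != 2 or region_cells.shape[0] == 0:
        raise ValueError("region_cells must be a nonempty 2-D array")
    sims = _similarity_matrix(region_cells, env.training, env.ranges).max(axis=1)
    perfect = sims >= 1.0 - PERFECT_TOL
    scored = sims[~perfect]
    n_excluded = int(perfect.sum())
    if scored.size == 0:
        warnings.warn(
            f"all {n_excluded} region cells perfectly match the envelope of "
            f"{species_id or env.species_id}; score undefined",
            stacklevel=2,
        )
        return ClimateMatchScore(np.nan, 0, n_excluded,
                                 species_id or env.species_id, jurisdiction_id)
    score = float(np.mean(scored >= env.threshold_similarity))
    return ClimateMatchScore(score, int(scored.size), n_excluded,
                             species_id or env.species_id, jurisdiction_id)
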