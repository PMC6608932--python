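"""Flowering-phenotype normalization and allele-phenotype association.

Full-bloom days are recorded as days after January 1st inside a per-year
population flowering window. To compare years, each individual's bloom day
is mapped to its day rank within the window divided by the window length
(first window day -> 1/length, last -> 1); the per-individual statistic is
the median of these normalized values over available years.

Association between a dichotomous variable (presence/absence of a parental
allele) and a continuous flowering phenotype uses the two-sided Wilcoxon
rank-sum test with midranks for ties; p-values at or below 0.05 are called
significant. The exact null distribution of the rank-sum statistic W (sum of
the carrier group's ranks) is obtained by enumerating all C(n_a+n_b, n_a)
group assignments when feasible; otherwise a normal approximation with
tie-corrected variance and continuity correction is used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import combinations
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .io_formats import FloweringPeriod, PhenotypeRow

logger = logging.getLogger(__name__)

ALPHA = 0.05
EXACT_LIMIT_NO_TIES = 20
EXACT_LIMIT_TIES = 12

PHENOTYPE_SCALES = ("days", "median", "accumulated_temperature", "global_radiation")


def default_flowering_periods() -> list[FloweringPeriod]:
    """The bundled per-year flowering windows of the study population."""
    text = (resources.files("amphase.data") / "flowering_periods.tsv").read_text()
    periods = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        year, start, end = (int(t) for t in line.split("\t"))
        periods.append(FloweringPeriod(year, start, end))
    return periods


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_flowering_day(row: PhenotypeRow, period: FloweringPeriod) -> float:
    """Normalized bloom day in (0, 1]: (day rank within window) / (window length).

    A bloom day outside the window is clamped to the nearer bound and logged
    (the population window should contain every individual's bloom day; an
    outside value is treated as a data-entry slip, not rejected).
    """
    if row.year != period.year:
        raise ValueError(f"year mismatch: row {row.year} vs period {period.year}")
    day = row.bloom_day
    if day < period.start_day or day > period.end_day:
        clamped = min(max(day, period.start_day), period.end_day)
        logger.warning(
            "bloom day %d of %s outside %d window [%d, %d]; clamped to %d",
            day, row.individual_id, row.year, period.start_day, period.end_day, clamped,
        )
        day = clamped
    return (day - period.start_day + 1) / period.length


def median_flowering(values: Sequence[float]) -> float:
    """Median of the per-year normalized values (mean of the central pair for
    even counts). Empty input raises; callers exclude such individuals."""
    if not values:
        raise ValueError("median of no values is undefined")
    return float(median(values))


def median_phenotypes(
    rows: Sequence[PhenotypeRow], periods: Sequence[FloweringPeriod]
) -> dict[str, float]:
    """Per-individual median normalized flowering value across available years.

    Individuals with no usable year are excluded (and logged)."""
    by_year = {p.year: p for p in periods}
    per_ind: dict[str, list[float]] = {}
    for row in rows:
        period = by_year.get(row.year)
        if period is None:
            logger.info("no flowering window for year %d; row skipped", row.year)
            continue
        per_ind.setdefault(row.individual_id, []).append(
            normalize_flowering_day(row, period)
        )
    return {ind: median_flowering(vals) for ind, vals in per_ind.items() if vals}


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _exact_null(pooled_ranks: tuple[float, ...], n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Null pmf of W (sum of ``n_a`` of the pooled midranks) by enumeration
    of all C(n, n_a) assignments. Cached: under a permutation null the pooled
    ranks are identical across replicates."""
    ranks = np.asarray(pooled_ranks)
    idx = np.fromiter(
        (i for comb in combinations(range(len(ranks)), n_a) for i in comb),
        dtype=np.intp,
    ).reshape(-1, n_a)
    sums = ranks[idx].sum(axis=1)
    sums = np.round(sums, 10)
    values, counts = np.unique(sums, return_counts=True)
    return values, counts / counts.sum()


def _exact_p(w: float, values: np.ndarray, probs: np.ndarray, mean: float) -> float:
    """Two-sided exact p: P(|W - E[W]| >= |w - E[W]|) under the null."""
    d = abs(w - mean) - 1e-9
    return float(probs[np.abs(values - mean) >= d].sum())


def wilcoxon_rank_sum(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: str = "auto",
    randomized: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the sum of group A's midranks over the pooled sample. ``mode``:

    * ``exact`` — enumerate the null distribution of W over all
      C(n_a+n_b, n_a) group assignments;
    * ``approx`` — normal approximation with tie-corrected variance and
      continuity correction;
    * ``auto`` — exact when feasible (combined n <= 20 without ties,
      <= 12 with ties), else approx.

    ``randomized=True`` (exact mode) returns the randomized p-value
    ``P(|T| > t) + U * P(|T| = t)``, which is exactly Uniform(0,1) under the
    null; used for calibration checks of discrete tests.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks for ties
    w = float(ranks[: a.size].sum())
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    has_ties = np.unique(pooled).size < n

    if mode == "auto":
        limit = EXACT_LIMIT_TIES if has_ties else EXACT_LIMIT_NO_TIES
        mode = "exact" if n <= limit else "approx"
    if mode == "exact":
        values, probs = _exact_null(tuple(np.round(ranks, 10)), n_a)
        mean = n_a * (n + 1) / 2
        p = _exact_p(w, values, probs, mean)
        if randomized:
            rng = rng or np.random.default_rng()
            d = abs(w - mean)
            p_gt = float(probs[np.abs(values - mean) > d + 1e-9].sum())
            p_eq = p - p_gt
            p = p_gt + float(rng.uniform()) * p_eq
        return w, min(float(p), 1.0)
    if mode != "approx":
        raise ValueError(f"unknown mode {mode!r}")

    mean = n_a * (n + 1) / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n_a * n_b / 12 * (n + 1 - tie_term)
    if var <= 0:
        return w, 1.0
    z = (abs(w - mean) - 0.5) / math.sqrt(var)  # continuity correction
    p = 2 * norm.sf(max(z, 0.0))
    return w, min(float(p), 1.0)


# ---------------------------------------------------------------------------
# Allele-phenotype association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    gene_id: str
    allele: str
    carriers: int
    non_carriers: int
    carrier_median: float | None
    non_carrier_median: float | None
    statistic: float | None
    p_value: float | None
    significant: bool
    phenotype_scale: str
    determined: bool = True


def associate_allele(
    carrier_sets: Mapping[str, Iterable[str]],
    phenotypes: Mapping[str, float],
    gene_id: str = "",
    scale: str = "median",
    mode: str = "auto",
    alpha: float = ALPHA,
    bh_correct: bool = False,
) -> list[AssociationResult]:
    """Rank-sum association of each allele's presence with the phenotype.

    ``carrier_sets`` maps allele label -> ids of individuals carrying it
    (under any consistent origin assignment, when ambiguous). Only
    individuals with a phenotype are analyzed. An allele carried by fewer
    than two, or by all but one or fewer, phenotyped individuals yields a
    not-determined result (mirroring an "n.d." entry). ``bh_correct``
    applies a Benjamini-Hochberg adjustment across the gene's alleles.
    """
    if scale not in PHENOTYPE_SCALES:
        raise ValueError(f"unknown phenotype scale {scale!r}")
    results = []
    for allele in sorted(carrier_sets):
        carrier_ids = {i for i in carrier_sets[allele] if i in phenotypes}
        other_ids = [i for i in phenotypes if i not in carrier_ids]
        xs = [phenotypes[i] for i in sorted(carrier_ids)]
        ys = [phenotypes[i] for i in sorted(other_ids)]
        if len(xs) < 2 or len(ys) < 2:
            results.append(
                AssociationResult(
                    gene_id, allele, len(xs), len(ys),
                    median_flowering(xs) if xs else None,
                    median_flowering(ys) if ys else None,
                    None, None, False, scale, determined=False,
                )
            )
            continue
        w, p = wilcoxon_rank_sum(xs, ys, mode=mode)
        results.append(
            AssociationResult(
                gene_id, allele, len(xs), len(ys),
                median_flowering(xs), median_flowering(ys),
                w, p, p <= alpha, scale,
            )
        )
    if bh_correct:
        _apply_bh(results, alpha)
    return results


def _apply_bh(results: list[AssociationResult], alpha: float) -> None:
    tested = [r for r in results if r.determined and r.p_value is not None]
    m = len(tested)
    if m == 0:
        return
    order = sorted(range(m), key=lambda i: tested[i].p_value)
    adj = [0.0] * m
    prev = 1.0
    for rank_pos in range(m - 1, -1, -1):
        i = order[rank_pos]
        val = min(prev, tested[i].p_value * m / (rank_pos + 1))
        adj[i] = val
        prev = val
    for r, q in zip(tested, adj):
        r.p_value = q
        r.significant = q <= alpha


# ---------------------------------------------------------------------------
# Flowering classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FloweringClass:
    individual_id: str
    flowering_class: int   # 1 (very early) .. 6 (very late)
    merged_class: int      # 1..3 (pairs 1+2, 3+4, 5+6 merged)


def classify_flowering(medians: Mapping[str, float]) -> list[FloweringClass]:
    """Sextile assignment of per-individual medians into six flowering
    classes (1 = very early .. 6 = very late) plus the merged 3-class view.

    Ties at a sextile boundary go to the lower class for the individual that
    sorts earlier by (median, id) — a documented deterministic tie-break.
    """
    if len(medians) < 6:
        raise ValueError("at least six individuals required for sextiles")
    ordered = sorted(medians.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(ordered)
    out = []
    for pos, (ind, _) in enumerate(ordered):
        cls = min(6, pos * 6 // n + 1)
        out.append(FloweringClass(ind, cls, (cls + 1) // 2))
    return out
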