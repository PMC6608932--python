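"""STS-marker segregation coding and expected-vs-observed concordance.

STS (sequence-tagged site) markers genotype the whole mapping population by
PCR product size on a capillary analyzer. Product sizes are clustered into
allele classes (the instrument can be off by 1-2 bp, so a size tolerance is
applied when clustering instrument data; sizes predicted from phased
sequences are exact). The two-parent genotype configuration is then coded in
the standard outcrossing notation:

==========  ====================================================
``abxcd``   four alleles, both parents heterozygous
``efxeg``   three alleles, both parents heterozygous (one shared)
``hkxhk``   two alleles, both parents heterozygous
``lmxll``   two alleles, mother heterozygous only
``nnxnp``   two alleles, father heterozygous only
==========  ====================================================

A segregation pattern expected from phased allele sequences can then be
compared with the pattern observed from marker genotyping of the full
population.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

SEGREGATION_CODES = ("abxcd", "efxeg", "hkxhk", "lmxll", "nnxnp", "uninformative")


@dataclass
class SizeGenotype:
    """PCR product sizes (bp, up to two) of one individual at one marker."""

    individual_id: str
    marker_id: str
    product_sizes: tuple[int, ...] = ()
    failed: bool = False

    def __post_init__(self) -> None:
        if self.failed and self.product_sizes:
            raise ValueError("failed genotype cannot carry sizes")
        if any(s <= 0 for s in self.product_sizes):
            raise ValueError("product sizes must be positive")
        if len(self.product_sizes) > 2:
            raise ValueError("at most two product sizes per diploid genotype")

    @property
    def is_het(self) -> bool:
        return len(set(self.product_sizes)) == 2


def cluster_product_sizes(
    sizes: Iterable[int], tolerance_bp: int = 0
) -> list[list[int]]:
    """Single-linkage clustering of product sizes: sizes within
    ``tolerance_bp`` of a cluster member merge into that cluster. Returns
    clusters sorted by their smallest member (the cluster label)."""
    if tolerance_bp < 0:
        raise ValueError("tolerance must be >= 0")
    ordered = sorted(sizes)
    clusters: list[list[int]] = []
    for s in ordered:
        if clusters and s - clusters[-1][-1] <= tolerance_bp:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    return clusters


def _cluster_label(size: int, clusters: list[list[int]]) -> int | None:
    for i, c in enumerate(clusters):
        if size in c:
            return i
    return None


def code_segregation(
    mother: SizeGenotype, father: SizeGenotype, tolerance_bp: int = 0
) -> str:
    """Segregation code from the parental size genotypes.

    Clusters the union of parental sizes at ``tolerance_bp``, then codes by
    heterozygosity and allele-cluster count: both het with 4/3/2 clusters ->
    abxcd/efxeg/hkxhk; mother-only het -> lmxll; father-only het -> nnxnp;
    both homozygous -> uninformative.
    """
    if mother.failed or father.failed:
        raise ValueError("cannot code segregation from a failed genotype")
    clusters = cluster_product_sizes(
        list(mother.product_sizes) + list(father.product_sizes), tolerance_bp
    )
    m_alleles = {_cluster_label(s, clusters) for s in mother.product_sizes}
    f_alleles = {_cluster_label(s, clusters) for s in father.product_sizes}
    m_het = len(m_alleles) == 2
    f_het = len(f_alleles) == 2
    n = len(clusters)
    if m_het and f_het:
        if n >= 4:
            return "abxcd"
        if n == 3:
            return "efxeg"
        return "hkxhk"
    if m_het:
        return "lmxll"
    if f_het:
        return "nnxnp"
    return "uninformative"


@dataclass
class MarkerRow:
    """One row of a marker comparison table (a marker may have several)."""

    gene: str
    marker_id: str
    expected_code: str | None   # None when the marker was not designed from
    observed_code: str | None   # phased sequences / genotyping failed
    expected_mother: tuple[int, ...] = ()
    expected_father: tuple[int, ...] = ()
    observed_mother: tuple[int, ...] = ()
    observed_father: tuple[int, ...] = ()


@dataclass
class ConcordanceReport:
    n_markers: int
    n_matching: int
    detail: dict[str, dict] = field(default_factory=dict)
    legend_undefined_codes: list[str] = field(default_factory=list)


def compare_expected_observed(
    rows: Sequence[MarkerRow], excluded_markers: Sequence[str] = ()
) -> ConcordanceReport:
    """Concordance of expected (phasing-derived) vs observed segregation.

    Markers in ``excluded_markers`` are removed before counting. A marker
    with multiple rows counts as matching if any row's expected code equals
    that row's observed code. Expected codes outside the standard legend
    (e.g. a parent-homozygous-by-clustering rendering) are reported as
    legend-undefined but still compared verbatim.
    """
    undefined = sorted(
        {
            r.expected_code
            for r in rows
            if r.expected_code and r.expected_code not in SEGREGATION_CODES
        }
    )
    per_marker: dict[str, dict] = {}
    for r in rows:
        if r.marker_id in excluded_markers:
            continue
        entry = per_marker.setdefault(
            r.marker_id, {"gene": r.gene, "rows": [], "match": False}
        )
        row_match = (
            r.expected_code is not None
            and r.observed_code is not None
            and r.expected_code == r.observed_code
        )
        entry["rows"].append(
            {"expected": r.expected_code, "observed": r.observed_code, "match": row_match}
        )
        entry["match"] = entry["match"] or row_match
    n_match = sum(1 for e in per_marker.values() if e["match"])
    return ConcordanceReport(
        n_markers=len(per_marker),
        n_matching=n_match,
        detail=per_marker,
        legend_undefined_codes=undefined,
    )


def marker_allele_counts(
    genotypes: Sequence[SizeGenotype],
    mother: SizeGenotype,
    father: SizeGenotype,
    tolerance_bp: int = 2,
) -> tuple[dict[int, list[str]], list[tuple[str, int]]]:
    """Assign each offspring product size to a parental allele cluster.

    Returns (cluster label -> carrier individual ids, unassigned sizes).
    Cluster labels are the smallest parental size of the cluster. Carrier
    lists feed the association module.
    """
    clusters = cluster_product_sizes(
        list(mother.product_sizes) + list(father.product_sizes), tolerance_bp
    )
    carriers: dict[int, list[str]] = {c[0]: [] for c in clusters}
    unassigned: list[tuple[str, int]] = []
    for g in genotypes:
        if g.failed:
            continue
        for size in set(g.product_sizes):
            hit = None
            for c in clusters:
                if any(abs(size - member) <= tolerance_bp for member in c):
                    hit = c[0]
                    break
            if hit is None:
                unassigned.append((g.individual_id, size))
                logger.info(
                    "size %d of %s matches no parental allele at tolerance %d",
                    size, g.individual_id, tolerance_bp,
                )
            elif g.individual_id not in carriers[hit]:
                carriers[hit].append(g.individual_id)
    return carriers, unassigned


# ---------------------------------------------------------------------------
# Bundled marker comparison table
# ---------------------------------------------------------------------------

def _parse_sizes(token: str) -> tuple[int, ...]:
    token = token.strip()
    if token in ("", "N/A", "x", "X", "/"):
        return ()
    return tuple(
        int(t) for t in token.split("/") if t.strip().lower() not in ("x", "")
    )


def read_marker_table(path: str | Path | None = None) -> list[MarkerRow]:
    """Read a marker comparison table (TSV: gene, marker, expected mother and
    father sizes, expected code, observed sizes, observed code). Without a
    path, the bundled grapevine flowering-time marker table is used."""
    if path is None:
        source = resources.files("amphase.data") / "marker_segregation.tsv"
        text = source.read_text()
    else:
        text = Path(path).read_text()
    rows: list[MarkerRow] = []
    reader = csv.reader(text.splitlines(), delimiter="\t")
    for i, row in enumerate(reader):
        if i == 0 or not row or not row[0].strip():
            continue
        gene, marker, em, ef, ec, om, of_, oc = (c.strip() for c in row[:8])
        rows.append(
            MarkerRow(
                gene=gene,
                marker_id=marker,
                expected_code=ec if ec not in ("", "N/A") else None,
                observed_code=oc if oc not in ("", "N/A") else None,
                expected_mother=_parse_sizes(em),
                expected_father=_parse_sizes(ef),
                observed_mother=_parse_sizes(om),
                observed_father=_parse_sizes(of_),
            )
        )
    return rows

MARKERS_NOT_FROM_PHASED_SEQUENCES = ("GAVBInd_019", "GAVBInd_020")
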