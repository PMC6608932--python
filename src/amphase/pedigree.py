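"""Family logic for a two-parent F1 (pseudo-testcross) population.

Aside from recombination, a parent and an offspring must share one haplotype
per chromosome, hence one identical-by-descent allele per gene. This module
assigns parental origin labels (E1/E2 maternal, L1/L2 paternal) to phased
offspring haplotypes by sequence comparison, checks the resulting labels for
Mendelian consistency, and detects allele dropout — the amplification
failure of one allele that makes a heterozygous locus look homozygous. For a
dropout the missing allele's parental origin can be deduced from Mendelian
impossibility, but its sequence remains unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import edlib

from .io_formats import GenomicInterval, VariantRecord
from .phasing import PhasedAlleleSequences

logger = logging.getLogger(__name__)

MATERNAL_LABELS = ("E1", "E2")
PATERNAL_LABELS = ("L1", "L2")


@dataclass(frozen=True)
class FamilyMap:
    mother_id: str
    father_id: str
    offspring_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = (self.mother_id, self.father_id, *self.offspring_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("family ids must be distinct")
        if not self.offspring_ids:
            raise ValueError("at least one offspring required")


@dataclass
class ParentalAlleleSet:
    """The four phased parental allele sequences of one gene."""

    gene_id: str
    e1: str
    e2: str
    l1: str
    l2: str
    interval: GenomicInterval

    def allele(self, label: str) -> str:
        return {"E1": self.e1, "E2": self.e2, "L1": self.l1, "L2": self.l2}[label]


@dataclass
class OriginAssignment:
    """Parental origin of one offspring's two haplotypes at one gene.

    Labels are sets: singletons when the parental alleles pin the origin,
    pairs when the two candidate alleles of a parent are identical. ``status``
    is ``assigned`` (both singleton), ``ambiguous``, ``violation`` (some
    haplotype matches no parental allele within tolerance), or
    ``dropout_suspected``.
    """

    individual_id: str
    gene_id: str
    maternal_label: frozenset[str]
    paternal_label: frozenset[str]
    mismatch_counts: dict[str, int] = field(default_factory=dict)
    status: str = "assigned"
    breakpoint_diagnostic: int | None = None


def _edit_distance(a: str, b: str) -> int:
    if a == b:
        return 0
    return edlib.align(a, b)["editDistance"]


def assign_parental_origin(
    offspring: PhasedAlleleSequences,
    parents: ParentalAlleleSet,
    max_mismatch: int = 0,
) -> OriginAssignment:
    """Label the offspring's haplotypes with their parental origin.

    Each offspring haplotype is compared (edit distance) against all four
    parental alleles; the pairing of one haplotype to a maternal and the
    other to a paternal allele minimizing total mismatches wins. A winning
    comparison above ``max_mismatch`` makes the assignment a violation
    (possible recombinant or error), with a single-breakpoint diagnostic.
    Equal-best candidates within one parent (identical parental alleles)
    yield an ambiguous label set.
    """
    if (offspring.interval.sequence_id, offspring.interval.start, offspring.interval.end) != (
        parents.interval.sequence_id, parents.interval.start, parents.interval.end
    ):
        raise ValueError(
            f"interval mismatch: offspring {offspring.interval} vs parents {parents.interval}"
        )
    haps = (offspring.allele_a, offspring.allele_b)
    dist = {
        (h_i, label): _edit_distance(hap, parents.allele(label))
        for h_i, hap in enumerate(haps)
        for label in MATERNAL_LABELS + PATERNAL_LABELS
    }
    # orientation: which offspring haplotype is maternal
    best = None
    for m_hap in (0, 1):
        p_hap = 1 - m_hap
        m_cost = min(dist[(m_hap, m)] for m in MATERNAL_LABELS)
        p_cost = min(dist[(p_hap, p)] for p in PATERNAL_LABELS)
        total = m_cost + p_cost
        if best is None or total < best[0]:
            best = (total, m_hap, m_cost, p_cost)
    _, m_hap, m_cost, p_cost = best
    p_hap = 1 - m_hap
    m_set = frozenset(m for m in MATERNAL_LABELS if dist[(m_hap, m)] == m_cost)
    p_set = frozenset(p for p in PATERNAL_LABELS if dist[(p_hap, p)] == p_cost)

    counts = {f"hap{h}:{lab}": d for (h, lab), d in dist.items()}
    if m_cost > max_mismatch or p_cost > max_mismatch:
        return OriginAssignment(
            offspring.individual_id, parents.gene_id, m_set, p_set,
            counts, status="violation",
            breakpoint_diagnostic=_best_breakpoint(
                haps[m_hap if m_cost > p_cost else p_hap], parents
            ),
        )
    status = "assigned" if len(m_set) == 1 and len(p_set) == 1 else "ambiguous"
    return OriginAssignment(
        offspring.individual_id, parents.gene_id, m_set, p_set, counts, status
    )


def _best_breakpoint(hap: str, parents: ParentalAlleleSet) -> int | None:
    """Prefix/suffix split minimizing mismatches against any pair of parental
    alleles; a cheap diagnostic for a single recombination breakpoint."""
    alleles = [parents.e1, parents.e2, parents.l1, parents.l2]
    n = len(hap)
    best_cost, best_k = None, None
    step = max(1, n // 64)  # coarse scan keeps this O(n/step * 16)
    for k in range(0, n + 1, step):
        pre, suf = hap[:k], hap[k:]
        cost = min(_edit_distance(pre, a[:k]) for a in alleles) + min(
            _edit_distance(suf, a[k:]) for a in alleles
        )
        if best_cost is None or cost < best_cost:
            best_cost, best_k = cost, k
    return best_k


@dataclass
class MendelianReport:
    violations: list[OriginAssignment]
    label_counts: dict[str, dict[str, int]]  # gene -> label -> count

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def check_mendelian(assignments: Sequence[OriginAssignment]) -> MendelianReport:
    """Flag assignments whose two labels do not comprise one maternal and one
    paternal allele, and tabulate label counts per gene."""
    violations = []
    counts: dict[str, dict[str, int]] = {}
    for a in assignments:
        gene_counts = counts.setdefault(a.gene_id, {})
        for lab in sorted(a.maternal_label | a.paternal_label):
            gene_counts[lab] = gene_counts.get(lab, 0) + 1
        both_maternal = a.paternal_label and a.paternal_label <= set(MATERNAL_LABELS)
        both_paternal = a.maternal_label and a.maternal_label <= set(PATERNAL_LABELS)
        if a.status == "violation" or both_maternal or both_paternal:
            violations.append(a)
    return MendelianReport(violations, counts)


@dataclass
class DropoutFlag:
    individual_id: str
    gene_id: str
    missing_parent: str          # "maternal" | "paternal" | "unknown"
    observed_matches: tuple[str, ...]
    n_informative_sites: int
    n_het_sites_observed: int


def detect_allele_dropout(
    offspring_records: Sequence[VariantRecord],
    sample: str,
    parent_genotypes: dict[str, Sequence[int]],
    gene_id: str = "",
    min_impossible_sites: int = 2,
    max_het_fraction: float = 0.1,
) -> list[DropoutFlag]:
    """Flag a gene when the offspring looks homozygous yet Mendelian-impossible.

    ``parent_genotypes`` maps each parental allele label (E1,E2,L1,L2) to its
    allele-index vector over ``offspring_records`` (the phased parental
    alleles, e.g. from a :class:`ParentalAlleleSet`'s underlying variant
    calls). A dropout is flagged when (i) the offspring is
    called homozygous at nearly all informative sites (het fraction at most
    ``max_het_fraction``) and (ii) no maternal-paternal allele pair is
    consistent with the calls at fewer than ``min_impossible_sites`` sites.
    The observed single haplotype is then matched against the parental
    alleles: if it matches only one parent's allele(s), the OTHER parent's
    contribution is the missing one. The missing allele's sequence is not
    reconstructed (it was never sampled).
    """
    gene = gene_id
    calls: list[tuple[int, tuple[int, int]]] = []
    for i, rec in enumerate(offspring_records):
        g = rec.genotypes.get(sample)
        if g is None or g.allele_indices is None:
            continue
        calls.append((i, tuple(sorted(g.allele_indices))))
    if not calls:
        return []

    # informative sites: some parental allele pair would differ there
    informative = [
        (i, gt) for i, gt in calls
        if len({parent_genotypes[lab][i] for lab in parent_genotypes}) > 1
    ]
    if len(informative) < min_impossible_sites:
        return []
    n_het = sum(1 for _, gt in informative if gt[0] != gt[1])
    if n_het > max_het_fraction * len(informative):
        return []

    # best consistent (maternal, paternal) pair
    def mismatches(m: str, p: str) -> int:
        bad = 0
        for i, gt in informative:
            expected = tuple(sorted((parent_genotypes[m][i], parent_genotypes[p][i])))
            if expected != gt:
                bad += 1
        return bad

    best_pair = min(
        mismatches(m, p) for m in MATERNAL_LABELS for p in PATERNAL_LABELS
    )
    if best_pair < min_impossible_sites:
        return []

    # which single parental allele does the observed (hom) sequence match?
    def single_mismatches(lab: str) -> int:
        bad = 0
        for i, gt in informative:
            if gt[0] == gt[1] and gt[0] != parent_genotypes[lab][i]:
                bad += 1
        return bad

    scores = {lab: single_mismatches(lab) for lab in parent_genotypes}
    best_score = min(scores.values())
    matches = tuple(sorted(lab for lab, s in scores.items() if s == best_score))
    matched_parents = {lab[0] for lab in matches}  # {"E"}, {"L"} or both
    if matched_parents == {"E"}:
        missing = "paternal"
    elif matched_parents == {"L"}:
        missing = "maternal"
    else:
        missing = "unknown"
    return [
        DropoutFlag(
            individual_id=sample,
            gene_id=gene,
            missing_parent=missing,
            observed_matches=matches,
            n_informative_sites=len(informative),
            n_het_sites_observed=n_het,
        )
    ]
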