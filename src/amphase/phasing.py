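"""Read-based diploid haplotype assembly under the minimum error correction
(MEC) criterion, phaseable-interval determination, and per-allele sequence
reconstruction.

The phasing problem: an amplicon-sequenced diploid individual yields
fragments (read pairs) that each observe the alleles of one of the two
haplotypes at the heterozygous sites they cover. MEC asks for the haplotype
pair minimizing the number of fragment calls that must be corrected
(flipped) so every fragment is consistent with one of the two haplotypes.
Since each site is heterozygous, the second haplotype is the sitewise
complement of the first, so a solution is a single binary vector per
connected component of the fragment graph.

Two solvers are provided: :func:`phase_exact` (exhaustive enumeration of
``2^(k-1)`` candidate haplotypes per component; the oracle for small
components) and :func:`phase_heuristic` (seeded greedy flip search with
restarts, capped at a configurable iteration budget, default 600).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    Fragment,
    GenomicInterval,
    VariantRecord,
)

logger = logging.getLogger(__name__)

MAX_EXACT_SITES = 20


@dataclass(frozen=True)
class HetSite:
    """One heterozygous site of an individual, referenced by fragments.

    ``index`` is the site's position in the global (all-variants) ordering
    that fragment files are indexed against; ``alleles`` is the individual's
    genotype allele pair (ascending); binary haplotype coding maps 0 to
    ``alleles[0]`` and 1 to ``alleles[1]``.
    """

    index: int
    position: int
    alleles: tuple[int, int]

    def __post_init__(self) -> None:
        if self.alleles[0] >= self.alleles[1]:
            raise ValueError("allele pair must be ascending (heterozygous)")


@dataclass
class FragmentMatrix:
    """Sparse fragment-by-site allele matrix in binary haplotype coding.

    ``calls[f, s]`` is 0/1 (the fragment observed ``sites[s].alleles[calls]``)
    or -1 where the fragment does not cover the site. Every retained fragment
    covers at least two sites.
    """

    sites: list[HetSite]
    calls: np.ndarray          # (F, k) int8, -1 = not covered
    quals: np.ndarray          # (F, k) int16
    fragment_ids: list[str]
    n_conflicting_calls: int = 0
    n_discarded_calls: int = 0

    @property
    def n_fragments(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def components(self) -> list[list[int]]:
        """Connected components of sites linked by shared fragments,
        ordered by leftmost site."""
        parent = list(range(self.n_sites))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for f in range(self.n_fragments):
            cols = np.flatnonzero(self.calls[f] >= 0)
            for c in cols[1:]:
                ra, rb = find(int(cols[0])), find(int(c))
                if ra != rb:
                    parent[rb] = ra
        groups: dict[int, list[int]] = {}
        for s in range(self.n_sites):
            groups.setdefault(find(s), []).append(s)
        return sorted(groups.values(), key=lambda g: g[0])


@dataclass
class PhaseBlock:
    """A phased set of sites: two haplotypes, MEC score, fragment assignment.

    Haplotypes are tuples of actual variant allele indices (not binary
    coding); the two differ at every site. ``status`` is ``phased`` for
    multi-site blocks and ``unphased`` for singleton sites no fragment pair
    links.
    """

    site_columns: list[int]            # column indices into the matrix
    sites: list[HetSite]
    haplotypes: tuple[tuple[int, ...], tuple[int, ...]]
    mec_score: int
    fragment_assignment: dict[str, int] = field(default_factory=dict)
    status: str = "phased"

    def __post_init__(self) -> None:
        h0, h1 = self.haplotypes
        if len(h0) != len(self.sites) or len(h1) != len(self.sites):
            raise ValueError("haplotype length must match block sites")
        if any(a == b for a, b in zip(h0, h1)):
            raise ValueError("haplotypes must differ at every (het) site")


@dataclass
class PhasedAlleleSequences:
    """Reconstructed allele sequences of one individual over one interval."""

    individual_id: str
    gene_id: str
    interval: GenomicInterval
    allele_a: str
    allele_b: str
    phasing_status: str  # phased | homozygous | failed

    def __post_init__(self) -> None:
        if self.phasing_status == "homozygous" and self.allele_a != self.allele_b:
            raise ValueError("homozygous status requires identical alleles")


# ---------------------------------------------------------------------------
# Variant filtering and fragment extraction
# ---------------------------------------------------------------------------

def filter_variants(
    records: Sequence[VariantRecord],
    sample: str,
    min_dp: int = 20,
    min_gq: int = 20,
) -> list[VariantRecord]:
    """Drop sites where the sample's depth or genotype quality is below the
    thresholds (strictly below 20 by default); order preserved. Sites with
    missing DP/GQ are dropped as unassessable."""
    kept = []
    for rec in records:
        g = rec.genotypes.get(sample)
        if g is None:
            raise KeyError(f"sample {sample!r} absent from record at {rec.position}")
        if g.depth is None or g.genotype_quality is None:
            continue
        if g.depth >= min_dp and g.genotype_quality >= min_gq:
            kept.append(rec)
    return kept


def het_sites_for_sample(
    records: Sequence[VariantRecord], sample: str
) -> list[HetSite]:
    """The sample's heterozygous sites, as binary-codable :class:`HetSite`s.

    ``index`` is the record's position in ``records`` (the global site
    ordering fragments are indexed against)."""
    sites = []
    for i, rec in enumerate(records):
        g = rec.genotypes.get(sample)
        if g is None or not g.is_het:
            continue
        a, b = sorted(g.allele_indices)
        sites.append(HetSite(index=i, position=rec.position, alleles=(a, b)))
    return sites


def extract_informative_fragments(
    observations: Iterable[Fragment], sites: Sequence[HetSite]
) -> FragmentMatrix:
    """Build the fragment matrix from per-read allele observations.

    Observations sharing a ``fragment_id`` (read-pair mates) are merged into
    one fragment by unioning their calls; conflicting duplicate calls at one
    site are dropped and counted. Calls at non-heterozygous sites or calls
    observing neither of the site's two genotype alleles are discarded (a
    diploid individual cannot carry a third allele; such calls signal error
    or contamination). Fragments left with fewer than two heterozygous-site
    calls are not informative and are dropped.
    """
    col_of = {s.index: c for c, s in enumerate(sites)}
    merged: dict[str, dict[int, tuple[int, int]]] = {}
    order: list[str] = []
    n_conflict = 0
    for obs in observations:
        if obs.fragment_id not in merged:
            merged[obs.fragment_id] = {}
            order.append(obs.fragment_id)
        tgt = merged[obs.fragment_id]
        for site, allele in obs.calls.items():
            q = obs.quals.get(site, 40)
            if site in tgt:
                if tgt[site] is not None and tgt[site][0] != allele:
                    n_conflict += 1
                    tgt[site] = None  # poisoned: mates disagree
            else:
                tgt[site] = (allele, q)

    rows, quals, ids = [], [], []
    n_discarded = 0
    for frag_id in order:
        row = np.full(len(sites), -1, dtype=np.int8)
        qrow = np.zeros(len(sites), dtype=np.int16)
        for site, val in merged[frag_id].items():
            if val is None:
                continue
            allele, q = val
            c = col_of.get(site)
            if c is None:
                continue  # not a het site for this individual
            pair = sites[c].alleles
            if allele == pair[0]:
                row[c] = 0
            elif allele == pair[1]:
                row[c] = 1
            else:
                n_discarded += 1
                continue
            qrow[c] = q
        if np.count_nonzero(row >= 0) >= 2:
            rows.append(row)
            quals.append(qrow)
            ids.append(frag_id)

    calls = np.array(rows, dtype=np.int8).reshape(len(rows), len(sites))
    qmat = np.array(quals, dtype=np.int16).reshape(len(rows), len(sites))
    return FragmentMatrix(
        sites=list(sites), calls=calls, quals=qmat, fragment_ids=ids,
        n_conflicting_calls=n_conflict, n_discarded_calls=n_discarded,
    )


# ---------------------------------------------------------------------------
# MEC scoring and solvers
# ---------------------------------------------------------------------------

def _binary_haplotype(matrix: FragmentMatrix, haplotype: Sequence[int]) -> np.ndarray:
    """Translate an allele-index haplotype into binary site coding."""
    h = np.empty(matrix.n_sites, dtype=np.int8)
    for c, (site, a) in enumerate(zip(matrix.sites, haplotype)):
        if a == site.alleles[0]:
            h[c] = 0
        elif a == site.alleles[1]:
            h[c] = 1
        else:
            raise ValueError(
                f"allele {a} not one of site alleles {site.alleles}"
            )
    return h


def _mec_binary(calls: np.ndarray, h: np.ndarray) -> int:
    """MEC of binary haplotype ``h`` (and its complement) on ``calls``."""
    covered = calls >= 0
    mism = ((calls != h) & covered).sum(axis=1)
    cov = covered.sum(axis=1)
    return int(np.minimum(mism, cov - mism).sum())


def mec_score(matrix: FragmentMatrix, haplotype: Sequence[int]) -> int:
    """Minimum error correction score of a full-length haplotype.

    ``score = sum over fragments of min(mismatches vs h, mismatches vs the
    sitewise complement of h)``; the complement takes the other heterozygous
    allele at each site.
    """
    if len(haplotype) != matrix.n_sites:
        raise ValueError(
            f"haplotype length {len(haplotype)} != {matrix.n_sites} sites"
        )
    return _mec_binary(matrix.calls, _binary_haplotype(matrix, haplotype))


def _component_matrix(matrix: FragmentMatrix, comp: list[int]) -> tuple[np.ndarray, np.ndarray]:
    sub = matrix.calls[:, comp]
    keep = (sub >= 0).sum(axis=1) >= 1
    return sub[keep], np.asarray(keep).nonzero()[0]


def _enumerate_component(sub: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """Exact MEC over all 2^(k-1) binary haplotypes with site 0 fixed to 0.

    Ties broken by lexicographically smallest binary haplotype. Vectorized:
    per-fragment mismatch counts against all candidates via matrix products.
    """
    n_cand = 1 << max(k - 1, 0)
    # candidates: column 0 fixed to 0, remaining k-1 columns a binary counter
    cand = np.zeros((n_cand, k), dtype=np.int8)
    if k > 1:
        bits = (np.arange(n_cand)[:, None] >> np.arange(k - 2, -1, -1)[None, :]) & 1
        cand[:, 1:] = bits.astype(np.int8)
    covered = (sub >= 0)
    X = np.where(covered, sub, 0).astype(np.int32)          # (F, k)
    M = covered.astype(np.int32)                            # (F, k)
    C = cand.astype(np.int32)                               # (n_cand, k)
    # mismatches(f, c) = sum_s M * (X xor C) = X@(1-C)^T + (M-X)@C^T
    mism = X @ (1 - C).T + (M - X) @ C.T                    # (F, n_cand)
    cov = M.sum(axis=1, keepdims=True)
    scores = np.minimum(mism, cov - mism).sum(axis=0)       # (n_cand,)
    best = int(scores.argmin())  # argmin returns first minimum = lexicographic
    return cand[best], int(scores[best])


def _assign_fragments(
    matrix: FragmentMatrix, comp: list[int], h: np.ndarray
) -> dict[str, int]:
    sub = matrix.calls[:, comp]
    covered = sub >= 0
    mism = ((sub != h) & covered).sum(axis=1)
    cov = covered.sum(axis=1)
    out = {}
    for f in range(matrix.n_fragments):
        if cov[f] == 0:
            continue
        out[matrix.fragment_ids[f]] = 0 if mism[f] <= cov[f] - mism[f] else 1
    return out


def _block_from_binary(
    matrix: FragmentMatrix, comp: list[int], h: np.ndarray, score: int
) -> PhaseBlock:
    sites = [matrix.sites[c] for c in comp]
    h0 = tuple(s.alleles[int(b)] for s, b in zip(sites, h))
    h1 = tuple(s.alleles[1 - int(b)] for s, b in zip(sites, h))
    status = "phased" if len(comp) > 1 else "unphased"
    return PhaseBlock(
        site_columns=list(comp),
        sites=sites,
        haplotypes=(h0, h1),
        mec_score=score,
        fragment_assignment=_assign_fragments(matrix, comp, h),
        status=status,
    )


def phase_exact(matrix: FragmentMatrix) -> list[PhaseBlock]:
    """Exhaustive MEC phasing, component by component.

    Enumerates all ``2^(k-1)`` haplotypes per connected component (first site
    fixed to binary 0 to break the global-swap symmetry); components larger
    than ``MAX_EXACT_SITES`` raise, directing to :func:`phase_heuristic`.
    Ties are broken by the lexicographically smallest binary haplotype.
    """
    blocks = []
    for comp in matrix.components():
        k = len(comp)
        if k > MAX_EXACT_SITES:
            raise ValueError(
                f"component of {k} sites exceeds exact-solver limit "
                f"{MAX_EXACT_SITES}; use phase_heuristic"
            )
        if k == 1:
            blocks.append(_block_from_binary(matrix, comp, np.zeros(1, np.int8), 0))
            continue
        sub, _ = _component_matrix(matrix, comp)
        h, score = _enumerate_component(sub, k)
        blocks.append(_block_from_binary(matrix, comp, h, score))
    return blocks


def _greedy_component(
    sub: np.ndarray, k: int, rng: np.random.Generator, max_iterations: int
) -> tuple[np.ndarray, int]:
    """Greedy single-site flip search with random restarts.

    One iteration = one sweep proposing a flip at each site and accepting the
    best strictly improving one; a sweep with no improvement is a plateau and
    triggers a restart from a fresh random haplotype. MEC never increases
    between accepted moves. Deterministic given the generator state.
    """
    best_h = None
    best_score = None
    h = np.zeros(k, dtype=np.int8)  # first start: all-zeros (reference-like)
    it = 0
    while it < max_iterations:
        score = _mec_binary(sub, h)
        improved = True
        while improved and it < max_iterations:
            it += 1
            improved = False
            flip_scores = np.empty(k, dtype=np.int64)
            for s in range(k):
                h[s] ^= 1
                flip_scores[s] = _mec_binary(sub, h)
                h[s] ^= 1
            s_best = int(flip_scores.argmin())
            if flip_scores[s_best] < score:
                h[s_best] ^= 1
                score = int(flip_scores[s_best])
                improved = True
        if best_score is None or score < best_score:
            best_score = score
            best_h = h.copy()
            if best_score == 0:
                break
        # restart
        h = rng.integers(0, 2, size=k, dtype=np.int8)
    # canonicalize: fix first site to 0, then prefer lexicographically
    # smaller of {h, complement} for deterministic output
    if best_h[0] == 1:
        best_h ^= 1
    return best_h, int(best_score)


def phase_heuristic(
    matrix: FragmentMatrix, max_iterations: int = 600, seed: int = 0
) -> list[PhaseBlock]:
    """Iterative MEC phasing: greedy flip refinement with seeded restarts.

    ``max_iterations`` caps the number of refinement sweeps per component
    (default 600). Output is deterministic given ``seed``. A matrix with no
    fragments yields one unphased singleton block per site.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for comp in matrix.components():
        k = len(comp)
        if k == 1:
            blocks.append(_block_from_binary(matrix, comp, np.zeros(1, np.int8), 0))
            continue
        sub, _ = _component_matrix(matrix, comp)
        h, score = _greedy_component(sub, k, rng, max_iterations)
        blocks.append(_block_from_binary(matrix, comp, h, score))
    return blocks


# ---------------------------------------------------------------------------
# Phaseable intervals and allele sequence reconstruction
# ---------------------------------------------------------------------------

def define_phased_intervals(
    blocks: Sequence[PhaseBlock],
    amplicon: GenomicInterval,
    all_het_sites: Sequence[HetSite],
    barrier_positions: Sequence[int] = (),
) -> list[tuple[GenomicInterval, PhaseBlock | None]]:
    """Attach to each block the interval over which its phasing is valid.

    The interval extends from just after the nearest heterozygous site NOT in
    the block on the left (or the amplicon start) to just before the nearest
    such site on the right (or the amplicon end). ``barrier_positions`` are
    additional positions the interval may not cross — typically variant sites
    whose genotype was filtered out (unassessable), where phasing cannot be
    claimed. With no heterozygous sites at all, the whole amplicon is a
    single homozygous interval (block None).
    """
    if not all_het_sites:
        if barrier_positions:
            # largest barrier-free stretch of the amplicon
            cuts = sorted(p for p in barrier_positions if amplicon.contains(p))
            bounds = [amplicon.start - 1] + cuts + [amplicon.end + 1]
            best = max(
                ((bounds[i] + 1, bounds[i + 1] - 1) for i in range(len(bounds) - 1)),
                key=lambda se: se[1] - se[0],
            )
            if best[0] <= best[1]:
                return [(GenomicInterval(amplicon.sequence_id, *best), None)]
        return [(amplicon, None)]
    positions = sorted(
        set(s.position for s in all_het_sites) | set(barrier_positions)
    )
    out: list[tuple[GenomicInterval, PhaseBlock | None]] = []
    for block in blocks:
        members = {s.position for s in block.sites}
        lo = min(members)
        hi = max(members)
        left = [p for p in positions if p < lo and p not in members]
        right = [p for p in positions if p > hi and p not in members]
        start = max(amplicon.start, (left[-1] + 1) if left else amplicon.start)
        end = min(amplicon.end, (right[0] - 1) if right else amplicon.end)
        out.append((GenomicInterval(amplicon.sequence_id, start, end), block))
    return out


def build_allele_sequences(
    reference: str,
    interval: GenomicInterval,
    block: PhaseBlock | None,
    hom_alt_variants: Sequence[tuple[VariantRecord, int]] = (),
    het_variants: Sequence[VariantRecord] = (),
    individual_id: str = "",
    gene_id: str = "",
) -> PhasedAlleleSequences:
    """Substitute phased and homozygous-alternative alleles into the reference.

    ``reference`` is the full reference sequence whose coordinate 1 is its
    first base; only ``interval`` is reconstructed. ``het_variants[i]`` is the
    variant record behind ``block.sites[i]`` (same order). ``hom_alt_variants``
    are (record, allele_index) pairs applied to both strings. Variants are
    applied right-to-left so indel length changes cannot shift the coordinates
    of variants still to be applied. Overlapping variants are an error.
    """
    if block is not None and len(het_variants) != len(block.sites):
        raise ValueError("het_variants must parallel block.sites")

    edits_a: list[tuple[int, str, str]] = []  # (pos, ref, replacement)
    edits_b: list[tuple[int, str, str]] = []
    if block is not None:
        for site, rec, a0, a1 in zip(
            block.sites, het_variants, block.haplotypes[0], block.haplotypes[1]
        ):
            if not interval.contains(rec.position):
                raise ValueError(f"variant at {rec.position} outside interval")
            edits_a.append((rec.position, rec.ref_allele, rec.allele(a0)))
            edits_b.append((rec.position, rec.ref_allele, rec.allele(a1)))
    for rec, idx in hom_alt_variants:
        if not interval.contains(rec.position):
            raise ValueError(f"variant at {rec.position} outside interval")
        edits_a.append((rec.position, rec.ref_allele, rec.allele(idx)))
        edits_b.append((rec.position, rec.ref_allele, rec.allele(idx)))

    _check_overlaps(edits_a)
    base = reference[interval.start - 1 : interval.end]
    seq_a = _apply_edits(base, interval.start, edits_a)
    seq_b = _apply_edits(base, interval.start, edits_b)
    status = "phased"
    if block is None or all(a == b for a, b in zip(*block.haplotypes)) or seq_a == seq_b:
        status = "homozygous" if seq_a == seq_b else "phased"
    return PhasedAlleleSequences(
        individual_id=individual_id,
        gene_id=gene_id or interval.sequence_id,
        interval=interval,
        allele_a=seq_a,
        allele_b=seq_b,
        phasing_status=status,
    )


def _check_overlaps(edits: list[tuple[int, str, str]]) -> None:
    spans = sorted((pos, pos + len(ref) - 1) for pos, ref, _ in edits)
    bad = [
        (spans[i], spans[i + 1])
        for i in range(len(spans) - 1)
        if spans[i][1] >= spans[i + 1][0]
    ]
    if bad:
        raise ValueError(f"overlapping variants at positions {bad}")


def _apply_edits(base: str, offset: int, edits: list[tuple[int, str, str]]) -> str:
    """Apply edits right-to-left; coordinates are reference positions."""
    seq = base
    for pos, ref, rep in sorted(edits, reverse=True):
        i = pos - offset
        if seq[i : i + len(ref)] != ref:
            raise ValueError(
                f"reference mismatch at {pos}: expected {ref!r}, "
                f"found {seq[i:i + len(ref)]!r}"
            )
        seq = seq[:i] + rep + seq[i + len(ref):]
    return seq
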