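"""MEC phasing: filtering, fragment extraction, solvers, intervals,
allele-sequence reconstruction."""

import numpy as np
import pytest

from amphase import phasing
from amphase.evaluation import random_fragment_matrix
from amphase.io_formats import (
    Fragment,
    GenomicInterval,
    SampleGenotype,
    VariantRecord,
)


def _record(pos, ref, alt, sample="s1", gt=(0, 1), dp=100, gq=99, chrom="amp1"):
    rec = VariantRecord(
        site=GenomicInterval(chrom, pos, pos + len(ref) - 1),
        ref_allele=ref,
        alt_alleles=[alt] if isinstance(alt, str) else list(alt),
    )
    rec.genotypes[sample] = SampleGenotype(sample, gt, dp, gq)
    return rec


def _matrix(frag_calls, n_sites):
    sites = [phasing.HetSite(i, (i + 1) * 100, (0, 1)) for i in range(n_sites)]
    frags = [Fragment(f"f{i}", dict(c)) for i, c in enumerate(frag_calls)]
    return phasing.extract_informative_fragments(frags, sites)


# ---------------------------------------------------------------------------
# Variant filtering
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dp, gq, kept",
    [(19, 80, False), (80, 19, False), (20, 20, True), (100, 99, True)],
)
def test_filter_variants_threshold_strictly_below_20(dp, gq, kept):
    recs = [_record(10, "A", "G", dp=dp, gq=gq)]
    out = phasing.filter_variants(recs, "s1")
    assert (len(out) == 1) == kept


def test_filter_variants_empty_and_order():
    assert phasing.filter_variants([], "s1") == []
    recs = [_record(p, "A", "G") for p in (30, 10, 20)]
    assert [r.position for r in phasing.filter_variants(recs, "s1")] == [30, 10, 20]


# ---------------------------------------------------------------------------
# Fragment extraction
# ---------------------------------------------------------------------------

def test_single_site_read_not_informative():
    m = _matrix([{0: 1}], 3)
    assert m.n_fragments == 0


def test_mates_merge_into_one_fragment():
    """Mate 1 covers site 0, mate 2 covers site 2: one fragment links them."""
    sites = [phasing.HetSite(i, (i + 1) * 100, (0, 1)) for i in range(3)]
    obs = [Fragment("pair1", {0: 0}), Fragment("pair1", {2: 1})]
    m = phasing.extract_informative_fragments(obs, sites)
    assert m.n_fragments == 1
    assert list(m.calls[0]) == [0, -1, 1]


def test_conflicting_mate_calls_dropped_and_counted():
    sites = [phasing.HetSite(i, (i + 1) * 100, (0, 1)) for i in range(3)]
    obs = [Fragment("p", {0: 0, 1: 1}), Fragment("p", {1: 0, 2: 1})]
    m = phasing.extract_informative_fragments(obs, sites)
    assert m.n_conflicting_calls == 1
    assert list(m.calls[0]) == [0, -1, 1]


def test_simple_two_site_fragment():
    m = _matrix([{0: 0, 1: 1}], 2)
    assert m.n_fragments == 1
    assert list(m.calls[0]) == [0, 1]


def test_third_allele_call_discarded():
    """A call observing neither genotype allele cannot be haplotype evidence."""
    sites = [phasing.HetSite(0, 100, (0, 1)), phasing.HetSite(1, 200, (0, 2))]
    obs = [Fragment("f", {0: 0, 1: 1})]  # allele 1 not in site 1's pair
    m = phasing.extract_informative_fragments(obs, sites)
    assert m.n_fragments == 0
    assert m.n_discarded_calls == 1


# ---------------------------------------------------------------------------
# MEC score
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "frag_calls, hap, expected",
    [
        ([{0: 0, 1: 0}, {0: 1, 1: 1}], (0, 0), 0),   # complement absorbs frag 2
        ([{0: 0, 1: 0}, {0: 0, 1: 0}, {0: 0, 1: 1}], (0, 0), 1),
        ([{0: 0, 1: 1}], (0, 0), 1),
    ],
)
def test_mec_score_examples(frag_calls, hap, expected):
    assert phasing.mec_score(_matrix(frag_calls, 2), hap) == expected


def test_mec_score_length_mismatch():
    with pytest.raises(ValueError):
        phasing.mec_score(_matrix([{0: 0, 1: 0}], 2), (0,))


def test_mec_global_swap_invariance():
    """Swapping the two haplotypes leaves the MEC score unchanged."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        m = random_fragment_matrix(rng, 6, 20, error=0.2)
        h = tuple(int(x) for x in rng.integers(0, 2, size=6))
        h_swapped = tuple(1 - x for x in h)
        assert phasing.mec_score(m, h) == phasing.mec_score(m, h_swapped)


# ---------------------------------------------------------------------------
# Exact solver
# ---------------------------------------------------------------------------

def test_phase_exact_error_free_recovers_truth():
    truth = (0, 1, 1, 0)
    frags = []
    for s in range(3):
        frags.append({s: truth[s], s + 1: truth[s + 1]})
        frags.append({s: 1 - truth[s], s + 1: 1 - truth[s + 1]})
    (block,) = phasing.phase_exact(_matrix(frags, 4))
    assert block.mec_score == 0
    assert block.haplotypes[0] in (truth, tuple(1 - t for t in truth))


def test_phase_exact_disconnected_components():
    m = _matrix([{0: 0, 1: 1}, {2: 0, 3: 0}], 4)
    blocks = phasing.phase_exact(m)
    assert len(blocks) == 2
    assert [len(b.sites) for b in blocks] == [2, 2]


def test_phase_exact_single_flipped_call():
    """Three sites, consistent fragments plus one flipped call: MEC 1 and the
    truth haplotype (verified by enumeration over the 4 candidates)."""
    truth = (0, 0, 0)
    frags = [{0: 0, 1: 0}, {1: 0, 2: 0}, {0: 0, 1: 0, 2: 0}, {0: 0, 1: 1}]
    m = _matrix(frags, 3)
    # independent oracle: enumerate all 4 sym-reduced haplotypes
    best = min(
        ((h, phasing.mec_score(m, (0,) + h)) for h in [(0, 0), (0, 1), (1, 0), (1, 1)]),
        key=lambda t: t[1],
    )
    (block,) = phasing.phase_exact(m)
    assert block.mec_score == best[1] == 1
    assert block.haplotypes[0] == truth


def test_phase_exact_component_too_large():
    frags = [{i: 0, i + 1: 0} for i in range(24)]
    with pytest.raises(ValueError, match="phase_heuristic"):
        phasing.phase_exact(_matrix(frags, 25))


# ---------------------------------------------------------------------------
# Heuristic solver
# ---------------------------------------------------------------------------

def test_phase_heuristic_matches_exact_on_small_instances():
    rng = np.random.default_rng(17)
    for i in range(40):
        m = random_fragment_matrix(rng, int(rng.integers(2, 13)), 30, error=0.1)
        if m.n_fragments == 0:
            continue
        exact = sum(b.mec_score for b in phasing.phase_exact(m))
        heur = sum(b.mec_score for b in phasing.phase_heuristic(m, seed=i))
        assert heur == exact


def test_phase_heuristic_no_fragments_gives_unphased_singletons():
    m = _matrix([], 3)
    blocks = phasing.phase_heuristic(m, seed=0)
    assert len(blocks) == 3
    assert all(b.status == "unphased" for b in blocks)


def test_phase_heuristic_deterministic_given_seed():
    rng = np.random.default_rng(3)
    m = random_fragment_matrix(rng, 10, 40, error=0.15)
    b1 = phasing.phase_heuristic(m, seed=42)
    b2 = phasing.phase_heuristic(m, seed=42)
    assert [b.haplotypes for b in b1] == [b.haplotypes for b in b2]
    assert [b.mec_score for b in b1] == [b.mec_score for b in b2]


def test_adding_consistent_fragment_never_increases_mec():
    """A fragment agreeing with the current optimum cannot raise minimal MEC."""
    rng = np.random.default_rng(9)
    for _ in range(20):
        k = int(rng.integers(3, 8))
        m = random_fragment_matrix(rng, k, 15, error=0.2)
        if m.n_fragments == 0:
            continue
        before_blocks = phasing.phase_exact(m)
        before = sum(b.mec_score for b in before_blocks)
        # build a fragment consistent with the first multi-site block
        block = max(before_blocks, key=lambda b: len(b.sites))
        if len(block.sites) < 2:
            continue
        calls = {c: int(a) for c, a in zip(block.site_columns, block.haplotypes[0])}
        frags = [
            Fragment(fid, {c: int(a) for c, a in zip(range(k), row) if a >= 0})
            for fid, row in zip(m.fragment_ids, m.calls)
        ] + [Fragment("extra", calls)]
        m2 = phasing.extract_informative_fragments(frags, m.sites)
        after = sum(b.mec_score for b in phasing.phase_exact(m2))
        assert after <= before


# ---------------------------------------------------------------------------
# Phased intervals
# ---------------------------------------------------------------------------

def _block_at(columns, sites):
    return phasing.PhaseBlock(
        site_columns=columns,
        sites=[sites[c] for c in columns],
        haplotypes=(
            tuple(0 for _ in columns),
            tuple(1 for _ in columns),
        ),
        mec_score=0,
    )


def test_interval_spans_amplicon_when_all_sites_phased():
    amp = GenomicInterval("g", 1000, 3000)
    sites = [phasing.HetSite(0, 1200, (0, 1)), phasing.HetSite(1, 1800, (0, 1))]
    block = _block_at([0, 1], sites)
    ((iv, b),) = phasing.define_phased_intervals([block], amp, sites)
    assert (iv.start, iv.end, iv.length) == (1000, 3000, 2001)


def test_interval_stops_before_unphased_het_site():
    amp = GenomicInterval("g", 1000, 3000)
    sites = [
        phasing.HetSite(0, 1200, (0, 1)),
        phasing.HetSite(1, 1800, (0, 1)),
        phasing.HetSite(2, 2500, (0, 1)),
    ]
    block = _block_at([0, 1], sites)
    ((iv, _),) = phasing.define_phased_intervals([block], amp, sites)
    assert (iv.start, iv.end) == (1000, 2499)


def test_interval_whole_amplicon_homozygous():
    amp = GenomicInterval("g", 1000, 3000)
    ((iv, b),) = phasing.define_phased_intervals([], amp, [])
    assert (iv.start, iv.end) == (1000, 3000)
    assert b is None


def test_interval_respects_barrier_positions():
    amp = GenomicInterval("g", 1000, 3000)
    sites = [phasing.HetSite(0, 1200, (0, 1)), phasing.HetSite(1, 1800, (0, 1))]
    block = _block_at([0, 1], sites)
    ((iv, _),) = phasing.define_phased_intervals([block], amp, sites, [1100, 2600])
    assert (iv.start, iv.end) == (1101, 2599)


# ---------------------------------------------------------------------------
# Allele sequence reconstruction
# ---------------------------------------------------------------------------

def test_build_sequences_het_snp():
    ref = "ACGTACGT"
    iv = GenomicInterval("g", 1, 8)
    sites = [phasing.HetSite(0, 3, (0, 1))]
    block = phasing.PhaseBlock([0], sites, ((1,), (0,)), 0)
    rec = _record(3, "G", "T")
    out = phasing.build_allele_sequences(ref, iv, block, [], [rec])
    assert out.allele_a == "ACTTACGT"
    assert out.allele_b == "ACGTACGT"
    assert out.phasing_status == "phased"


def test_build_sequences_hom_alt_applied_to_both():
    ref = "ACGTACGT"
    iv = GenomicInterval("g", 1, 8)
    rec = _record(1, "A", "G", gt=(1, 1))
    out = phasing.build_allele_sequences(ref, iv, None, [(rec, 1)], [])
    assert out.allele_a == out.allele_b == "GCGTACGT"
    assert out.phasing_status == "homozygous"


def test_build_sequences_het_deletion_two_method_agreement():
    """Right-to-left application agrees with an independent left-to-right
    rebuild that tracks the cumulative indel offset."""
    ref = "ACGTACGTACGT"
    iv = GenomicInterval("g", 1, 12)
    sites = [phasing.HetSite(0, 4, (0, 1)), phasing.HetSite(1, 10, (0, 1))]
    block = phasing.PhaseBlock([0, 1], sites, ((0, 1), (1, 0)), 0)
    recs = [_record(4, "TA", "T"), _record(10, "C", "A")]
    out = phasing.build_allele_sequences(ref, iv, block, [], recs)

    def rebuild(hap):
        seq = ref
        offset = 0
        for rec, a in sorted(zip(recs, hap), key=lambda t: t[0].position):
            if a == 0:
                continue
            i = rec.position - 1 + offset
            seq = seq[:i] + rec.allele(a) + seq[i + len(rec.ref_allele):]
            offset += len(rec.allele(a)) - len(rec.ref_allele)
        return seq

    assert out.allele_a == rebuild((0, 1))
    assert out.allele_b == rebuild((1, 0))
    assert len(out.allele_b) == len(ref) - 1  # deletion shortens allele B


def test_build_sequences_overlapping_variants_error():
    ref = "ACGTACGT"
    iv = GenomicInterval("g", 1, 8)
    recs = [(_record(3, "GT", "G", gt=(1, 1)), 1), (_record(4, "T", "C", gt=(1, 1)), 1)]
    with pytest.raises(ValueError, match="overlap"):
        phasing.build_allele_sequences(ref, iv, None, recs, [])
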