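"""Truth-based evaluation of the pipeline on simulated families.

These helpers quantify the properties the package is designed around:
haplotype recovery against simulated truth, agreement of the heuristic MEC
solver with exhaustive enumeration, allele-dropout detection rates, and the
power / type-I error of the allele-phenotype rank-sum association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import association as assoc
from . import pedigree, phasing, pipeline, simulate

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Phasing recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    n_cases: int               # individual x amplicon cases assessed
    n_labels_correct: int      # cases where both transmitted labels recovered
    n_sites: int               # phased het sites compared
    n_sites_correct: int       # sites agreeing with truth (up to hap swap)

    @property
    def label_rate(self) -> float:
        return self.n_labels_correct / self.n_cases if self.n_cases else float("nan")

    @property
    def site_rate(self) -> float:
        return self.n_sites_correct / self.n_sites if self.n_sites else float("nan")


def _site_accuracy(
    sp: pipeline.SamplePhasing, truth: simulate.TruthSet, amp_id: str, ind: str
) -> tuple[int, int]:
    """Phased-site agreement with the transmitted haplotype pair, up to the
    global haplotype swap."""
    amp = truth.amplicons[amp_id]
    tr = amp.offspring[ind]
    blocks = sp.blocks
    n = correct = 0
    for block in blocks:
        if len(block.sites) < 2:
            continue
        cols = [s.index for s in block.sites]
        # map global record index -> variant index within amplicon
        amp_offset = 0
        for other_id, other in truth.amplicons.items():
            if other_id == amp_id:
                break
            amp_offset += len(other.variants)
        vidx = [c - amp_offset for c in cols]
        t0 = np.array([tr.maternal_vec[v] for v in vidx])
        t1 = np.array([tr.paternal_vec[v] for v in vidx])
        h0 = np.array(block.haplotypes[0])
        h1 = np.array(block.haplotypes[1])
        direct = int((h0 == t0).sum() + (h1 == t1).sum())
        swapped = int((h0 == t1).sum() + (h1 == t0).sum())
        correct += max(direct, swapped)
        n += 2 * len(cols)
    return correct, n


def evaluate_recovery(
    config: simulate.SimConfig, max_mismatch: int = 0, n_amplicons: int = 1
) -> RecoveryResult:
    """Simulate a family, phase every sequenced offspring, and score label
    and site recovery against truth."""
    reference = simulate.default_reference(config, n_amplicons)
    truth = simulate.simulate_family(config, reference)
    fragments, records = simulate.simulate_fragments(truth, config)
    n_cases = n_ok = n_sites = n_sites_ok = 0
    for amp_id, amp in truth.amplicons.items():
        for ind in truth.sequenced_ids:
            sp = pipeline.phase_sample(
                records, ind, fragments[ind], amp_id, amp.reference,
                seed=config.seed,
            )
            cs, ns = _site_accuracy(sp, truth, amp_id, ind)
            n_sites += ns
            n_sites_ok += cs
            parents = pipeline.truth_parental_alleles(truth, amp_id, sp.interval)
            origin = pedigree.assign_parental_origin(
                sp.sequences, parents, max_mismatch
            )
            tr = amp.offspring[ind]
            ok = (
                origin.status in ("assigned", "ambiguous")
                and tr.maternal_label in origin.maternal_label
                and tr.paternal_label in origin.paternal_label
            )
            n_cases += 1
            n_ok += ok
    return RecoveryResult(n_cases, n_ok, n_sites, n_sites_ok)


# ---------------------------------------------------------------------------
# MEC heuristic vs exact oracle
# ---------------------------------------------------------------------------

def random_fragment_matrix(
    rng: np.random.Generator,
    n_sites: int,
    n_fragments: int,
    error: float = 0.1,
) -> phasing.FragmentMatrix:
    """A random phasing instance: fragments sampled from a random truth
    haplotype over contiguous spans, with per-call flip errors."""
    sites = [
        phasing.HetSite(index=i, position=(i + 1) * 10, alleles=(0, 1))
        for i in range(n_sites)
    ]
    truth = rng.integers(0, 2, size=n_sites, dtype=np.int8)
    frags = []
    for f in range(n_fragments):
        span = int(rng.integers(2, min(n_sites, 6) + 1))
        start = int(rng.integers(0, n_sites - span + 1))
        hap = int(rng.integers(0, 2))
        calls = {}
        for s in range(start, start + span):
            a = int(truth[s]) if hap == 0 else 1 - int(truth[s])
            if rng.uniform() < error:
                a = 1 - a
            calls[s] = a
        frags.append(phasing.Fragment(f"r{f}", calls))
    return phasing.extract_informative_fragments(frags, sites)


def mec_oracle_agreement(
    n_instances: int = 500,
    seed: int = 0,
    max_sites: int = 12,
    max_fragments: int = 60,
    error: float = 0.1,
    max_iterations: int = 600,
) -> tuple[int, int]:
    """(n_agreeing, n_instances): how often the greedy solver's MEC equals
    the exhaustive optimum on random small instances."""
    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_instances):
        k = int(rng.integers(2, max_sites + 1))
        f = int(rng.integers(5, max_fragments + 1))
        matrix = random_fragment_matrix(rng, k, f, error)
        if matrix.n_fragments == 0:
            agree += 1
            continue
        exact = phasing.phase_exact(matrix)
        heur = phasing.phase_heuristic(matrix, max_iterations=max_iterations, seed=i)
        if sum(b.mec_score for b in exact) == sum(b.mec_score for b in heur):
            agree += 1
    return agree, n_instances


# ---------------------------------------------------------------------------
# Dropout detection
# ---------------------------------------------------------------------------

@dataclass
class DropoutEvaluation:
    n_injected: int
    n_detected: int
    n_clean: int
    n_false_flags: int

    @property
    def recall(self) -> float:
        return self.n_detected / self.n_injected if self.n_injected else float("nan")

    @property
    def false_flag_rate(self) -> float:
        return self.n_false_flags / self.n_clean if self.n_clean else 0.0


def evaluate_dropout_detection(
    config: simulate.SimConfig, n_amplicons: int = 1
) -> DropoutEvaluation:
    """Inject dropouts per the config and measure flag recall / false flags.

    Detection sees only the filtered variant calls of each offspring plus the
    (truth) parental allele vectors — exactly the evidence a real study has
    after phasing the parents.
    """
    reference = simulate.default_reference(config, n_amplicons)
    truth = simulate.simulate_family(config, reference)
    _, records = simulate.simulate_fragments(truth, config)
    injected = {(ind, amp) for ind, amp, _ in truth.dropouts}
    n_detected = n_false = n_clean = 0
    for amp_id, amp in truth.amplicons.items():
        amp_records = [r for r in records if r.site.sequence_id == amp_id]
        variant_index = {id(rec): j for j, rec in enumerate(amp_records)}
        for ind in truth.sequenced_ids:
            filtered = phasing.filter_variants(amp_records, ind)
            parent_vecs = {
                lab: [
                    int(amp.parental_haps[lab][variant_index[id(r)]])
                    for r in filtered
                ]
                for lab in simulate.PARENT_LABELS
            }
            flags = pedigree.detect_allele_dropout(
                filtered, ind, parent_vecs, gene_id=amp_id
            )
            if (ind, amp_id) in injected:
                n_detected += bool(flags)
            else:
                n_clean += 1
                n_false += bool(flags)
    return DropoutEvaluation(len(injected), n_detected, n_clean, n_false)


# ---------------------------------------------------------------------------
# Association power and type-I error
# ---------------------------------------------------------------------------

def _one_association_p(
    seed: int,
    effect_days: float,
    n_offspring: int,
    target_label: str = "E1",
    noise_sd: float = 3.0,
) -> float:
    """Simulate one family's transmissions and phenotypes on a short amplicon
    and test the target allele's carriers against non-carriers (median
    normalized flowering value, rank-sum, normal approximation)."""
    effects = (
        (simulate.EffectAllele("amp1", target_label, effect_days),)
        if effect_days != 0.0
        else ()
    )
    cfg = simulate.SimConfig(
        seed=seed,
        n_offspring=n_offspring,
        n_sequenced=min(35, n_offspring),
        amplicon_length=300,
        variant_density=1.0,
        effect_alleles=effects,
        phenotype_noise_sd=noise_sd,
    )
    truth = simulate.simulate_family(cfg)
    rows = simulate.simulate_phenotypes(truth, cfg)
    medians = assoc.median_phenotypes(rows, assoc.default_flowering_periods())
    carriers = set(simulate.carriers_of(truth, "amp1", target_label))
    xs = [medians[i] for i in sorted(medians) if i in carriers]
    ys = [medians[i] for i in sorted(medians) if i not in carriers]
    if len(xs) < 2 or len(ys) < 2:
        return 1.0
    _, p = assoc.wilcoxon_rank_sum(xs, ys, mode="approx")
    return p


def association_power(
    n_replicates: int = 100,
    seed: int = 0,
    effect_days: float = -5.0,
    n_offspring: int = 151,
    alpha: float = 0.05,
) -> float:
    """Fraction of simulation replicates in which an effect allele is called
    significant."""
    hits = sum(
        _one_association_p(seed * 1_000_003 % (2**31) + r, effect_days, n_offspring) <= alpha
        for r in range(n_replicates)
    )
    return hits / n_replicates


def association_type_i_error(
    n_replicates: int = 1000,
    seed: int = 0,
    n_offspring: int = 151,
    alpha: float = 0.05,
) -> float:
    """Fraction of null replicates (no allele effect) called significant."""
    hits = sum(
        _one_association_p(seed * 1_000_003 % (2**31) + 500_000 + r, 0.0, n_offspring)
        <= alpha
        for r in range(n_replicates)
    )
    return hits / n_replicates
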