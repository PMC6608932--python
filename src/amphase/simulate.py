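"""Synthetic pseudo-testcross families with known truth.

Emulates the study design this package is built around: two heterozygous
parents (an early-flowering mother contributing alleles E1/E2 and a
late-flowering father contributing L1/L2) crossed to produce an F1
population, a subset of which is amplicon-sequenced at high depth with
paired short reads. Defaults follow the study's stated parameters: 151
offspring of which 35 are sequenced, amplicons up to 8 kb, 1.3 variants per
100 bp (the study observed 1.02-1.63), 2x250 bp read pairs with ~500 bp
inserts, mean depth 286 with SD 276 truncated at 20, and a small
per-amplicon meiotic recombination probability.

Three independent RNG streams (haplotypes, fragments, phenotypes) are
derived from the master seed so each stage can be re-run with stable
results.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    FloweringPeriod,
    Fragment,
    GenomicInterval,
    PhenotypeRow,
    SampleGenotype,
    VariantRecord,
)

logger = logging.getLogger(__name__)

PARENT_LABELS = ("E1", "E2", "L1", "L2")
MOTHER_ID = "mother"
FATHER_ID = "father"

_BASES = "ACGT"


@dataclass(frozen=True)
class EffectAllele:
    """An additive phenotype effect tied to one parental allele of one amplicon."""

    amplicon: str
    label: str          # one of E1, E2, L1, L2
    effect_days: float


@dataclass
class SimConfig:
    seed: int = 0
    n_offspring: int = 151
    n_sequenced: int = 35
    amplicon_length: int = 8000
    variant_density: float = 1.3        # variants per 100 bp
    read_length: int = 250
    insert_mean: float = 500.0
    insert_sd: float = 60.0
    depth_mean: float = 286.0
    depth_sd: float = 276.0
    depth_min: float = 20.0
    error_rate: float = 0.002
    recomb_prob: float = 0.01
    dropout_prob: float = 0.05
    effect_alleles: tuple[EffectAllele, ...] = ()
    phenotype_noise_sd: float = 3.0     # days, on the latent scale

    def __post_init__(self) -> None:
        for name in ("error_rate", "recomb_prob", "dropout_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_offspring", "n_sequenced", "amplicon_length", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sequenced > self.n_offspring:
            raise ValueError("n_sequenced cannot exceed n_offspring")

    def stream(self, purpose: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, purpose])


@dataclass
class SimVariant:
    """A biallelic variant placed on an amplicon (VCF-style anchor coding)."""

    position: int       # 1-based on the amplicon
    ref: str
    alt: str

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class OffspringTruth:
    maternal_label: str                 # E1 | E2 (label before any recombination)
    paternal_label: str                 # L1 | L2
    maternal_vec: np.ndarray            # transmitted allele indices per variant
    paternal_vec: np.ndarray
    breakpoint: tuple[str, int] | None  # (side, position) if recombinant


@dataclass
class AmpliconTruth:
    amplicon_id: str
    reference: str
    variants: list[SimVariant]
    parental_haps: dict[str, np.ndarray]        # label -> 0/1 allele vector
    offspring: dict[str, OffspringTruth]


@dataclass
class TruthSet:
    config: SimConfig
    amplicons: dict[str, AmpliconTruth]
    offspring_ids: list[str]
    sequenced_ids: list[str]
    dropouts: list[tuple[str, str, str]]        # (individual, amplicon, side)
    genetic_scores: dict[str, float]

    @property
    def individuals(self) -> list[str]:
        """Sequenced individuals, parents first."""
        return [MOTHER_ID, FATHER_ID] + self.sequenced_ids


def default_reference(config: SimConfig, n_amplicons: int = 1) -> dict[str, str]:
    """Random reference amplicons of the configured length."""
    rng = config.stream(0)
    return {
        f"amp{i + 1}": "".join(
            rng.choice(list(_BASES), size=config.amplicon_length)
        )
        for i in range(n_amplicons)
    }


# ---------------------------------------------------------------------------
# Family / haplotype simulation
# ---------------------------------------------------------------------------

def _place_variants(
    seq: str, density: float, rng: np.random.Generator
) -> list[SimVariant]:
    """Poisson-placed variants (90% SNP, 10% indel of <= 6 bp), spaced so
    anchors can never collide; resampled up to 100 times otherwise."""
    length = len(seq)
    n = rng.poisson(length * density / 100.0)
    n = min(n, max(0, (length - 10) // 8))  # physical upper bound at min gap 8
    if n == 0:
        return []
    # sample distinct positions in a range compressed by 7 bp per variant,
    # then fan out by 7*i: guarantees inter-variant gaps >= 8 so anchors
    # (ref span + <=6 bp deletion) can never collide
    hi = (length - 8) - 7 * (n - 1)
    if hi <= 2:
        raise RuntimeError(f"could not place {n} variants without anchor collisions")
    base = np.sort(rng.choice(np.arange(2, hi), size=n, replace=False))
    positions = base + 7 * np.arange(n)
    variants = []
    for pos in positions.tolist():
        ref_base = seq[pos - 1]
        if rng.uniform() < 0.9:  # SNP
            alt = _BASES[(_BASES.index(ref_base) + rng.integers(1, 4)) % 4]
            variants.append(SimVariant(pos, ref_base, alt))
        else:
            ilen = int(rng.integers(1, 7))
            if rng.uniform() < 0.5:  # insertion
                ins = "".join(rng.choice(list(_BASES), size=ilen))
                variants.append(SimVariant(pos, ref_base, ref_base + ins))
            else:  # deletion
                variants.append(
                    SimVariant(pos, seq[pos - 1 : pos + ilen], ref_base)
                )
    return variants


def simulate_family(
    config: SimConfig, reference: Mapping[str, str] | None = None
) -> TruthSet:
    """Create parental haplotypes and the F1 transmissions, with truth.

    Each of the four parental haplotypes independently carries the alternate
    allele of each placed variant with probability 1/2 (sites where all four
    end up identical to the reference are dropped). Offspring draw one
    maternal and one paternal haplotype uniformly; with probability
    ``recomb_prob`` a uniform breakpoint swaps the transmitted haplotype of
    one parent side beyond it. Deterministic given ``config.seed``.
    """
    if reference is None:
        reference = default_reference(config)
    for amp_id, seq in reference.items():
        if len(seq) < 200:
            raise ValueError(f"reference {amp_id} shorter than 200 bp")
    rng = config.stream(1)
    offspring_ids = [f"F1_{i + 1:03d}" for i in range(config.n_offspring)]

    amplicons: dict[str, AmpliconTruth] = {}
    dropouts: list[tuple[str, str, str]] = []
    for amp_id, seq in reference.items():
        variants = _place_variants(seq, config.variant_density, rng)
        k = len(variants)
        haps = {}
        carry = rng.integers(0, 2, size=(4, k)).astype(np.int8)
        # drop sites hom-ref across all four haplotypes (not a variant)
        keep = carry.any(axis=0)
        variants = [v for v, kf in zip(variants, keep) if kf]
        carry = carry[:, keep]
        for row, label in enumerate(PARENT_LABELS):
            haps[label] = carry[row].copy()
        amplicons[amp_id] = AmpliconTruth(amp_id, seq, variants, haps, {})

    # one transmitted label pair per offspring: the amplicon set models
    # tightly linked genes within one QTL region, so absent recombination
    # every gene of an individual shares the same parental labels
    for ind in offspring_ids:
        m_label = PARENT_LABELS[rng.integers(0, 2)]
        p_label = PARENT_LABELS[2 + rng.integers(0, 2)]
        for amp_id, seq in reference.items():
            amp = amplicons[amp_id]
            haps = amp.parental_haps
            variants = amp.variants
            m_vec = haps[m_label].copy()
            p_vec = haps[p_label].copy()
            breakpoint = None
            if rng.uniform() < config.recomb_prob:
                side = "maternal" if rng.uniform() < 0.5 else "paternal"
                bp = int(rng.integers(1, len(seq) + 1))
                after = np.array([v.position > bp for v in variants], dtype=bool)
                if side == "maternal":
                    other = haps["E1" if m_label == "E2" else "E2"]
                    m_vec[after] = other[after]
                else:
                    other = haps["L1" if p_label == "L2" else "L2"]
                    p_vec[after] = other[after]
                breakpoint = (side, bp)
            amp.offspring[ind] = OffspringTruth(
                m_label, p_label, m_vec, p_vec, breakpoint
            )

    scores = _genetic_scores(amplicons, offspring_ids, config.effect_alleles)
    sequenced = _select_sequenced(offspring_ids, scores, config.n_sequenced)

    for amp_id in amplicons:
        for ind in sequenced:
            if rng.uniform() < config.dropout_prob:
                side = "maternal" if rng.uniform() < 0.5 else "paternal"
                dropouts.append((ind, amp_id, side))

    return TruthSet(config, amplicons, offspring_ids, sequenced, dropouts, scores)


def _genetic_scores(
    amplicons: dict[str, AmpliconTruth],
    offspring_ids: Sequence[str],
    effects: Sequence[EffectAllele],
) -> dict[str, float]:
    scores = {ind: 0.0 for ind in offspring_ids}
    for eff in effects:
        amp = amplicons.get(eff.amplicon)
        if amp is None:
            raise ValueError(f"effect allele references unknown amplicon {eff.amplicon}")
        if eff.label not in PARENT_LABELS:
            raise ValueError(f"unknown parental label {eff.label}")
        for ind in offspring_ids:
            tr = amp.offspring[ind]
            if eff.label in (tr.maternal_label, tr.paternal_label):
                scores[ind] += eff.effect_days
    return scores


def _select_sequenced(
    offspring_ids: Sequence[str], scores: dict[str, float], n_sequenced: int
) -> list[str]:
    """Early, intermediate and late thirds by latent genetic score
    (deterministic; ties broken by id)."""
    ordered = sorted(offspring_ids, key=lambda i: (scores[i], i))
    n = len(ordered)
    k = n_sequenced
    lo = k // 3
    hi = k // 3
    mid = k - lo - hi
    early = ordered[:lo]
    late = ordered[-hi:] if hi else []
    centre_start = max(lo, (n - mid) // 2)
    middle = ordered[centre_start : centre_start + mid]
    chosen = list(dict.fromkeys(early + middle + late))
    # top up in score order if the strata overlapped
    for ind in ordered:
        if len(chosen) >= k:
            break
        if ind not in chosen:
            chosen.append(ind)
    return sorted(chosen, key=offspring_ids.index)


def carriers_of(truth: TruthSet, amplicon: str, label: str, sequenced_only: bool = False) -> list[str]:
    """Offspring carrying the given parental allele label at an amplicon."""
    amp = truth.amplicons[amplicon]
    ids = truth.sequenced_ids if sequenced_only else truth.offspring_ids
    return [
        ind for ind in ids
        if label in (amp.offspring[ind].maternal_label, amp.offspring[ind].paternal_label)
    ]


# ---------------------------------------------------------------------------
# Fragment / read-evidence simulation
# ---------------------------------------------------------------------------

def _individual_hap_vectors(
    truth: TruthSet, amp: AmpliconTruth, individual: str
) -> tuple[np.ndarray, np.ndarray]:
    if individual == MOTHER_ID:
        return amp.parental_haps["E1"], amp.parental_haps["E2"]
    if individual == FATHER_ID:
        return amp.parental_haps["L1"], amp.parental_haps["L2"]
    tr = amp.offspring[individual]
    return tr.maternal_vec, tr.paternal_vec


def simulate_fragments(
    truth: TruthSet, config: SimConfig | None = None
) -> tuple[dict[str, list[Fragment]], list[VariantRecord]]:
    """Sample paired-read fragments and build per-sample variant records.

    Per individual and amplicon the target depth is drawn from
    Normal(depth_mean, depth_sd) truncated at ``depth_min``; read pairs are
    placed uniformly and each reports the allele of one of the individual's
    two haplotypes (chosen per fragment) at every variant position covered by
    either mate, miscalled to the other allele with ``error_rate``. An
    injected dropout removes one haplotype's sampling weight entirely, so the
    locus appears homozygous. Variant records carry DP = number of covering
    fragments and a phred-scaled genotype quality from a binomial likelihood
    ratio. Fragment site indices refer to the concatenated per-amplicon
    variant ordering used by :func:`variant_site_order`.
    """
    config = config or truth.config
    rng = config.stream(2)
    dropouts = {(ind, amp): side for ind, amp, side in truth.dropouts}

    fragments: dict[str, list[Fragment]] = {ind: [] for ind in truth.individuals}
    # per-individual, per-global-site allele counts
    site_offset: dict[str, int] = {}
    total_sites = 0
    for amp_id, amp in truth.amplicons.items():
        site_offset[amp_id] = total_sites
        total_sites += len(amp.variants)
    counts = {
        ind: np.zeros((total_sites, 2), dtype=np.int64) for ind in truth.individuals
    }

    for amp_id, amp in truth.amplicons.items():
        length = len(amp.reference)
        positions = np.array([v.position for v in amp.variants])
        offset = site_offset[amp_id]
        for ind in truth.individuals:
            hap0, hap1 = _individual_hap_vectors(truth, amp, ind)
            depth = max(config.depth_min, rng.normal(config.depth_mean, config.depth_sd))
            # fragment starts are confined to [1, length - insert + 1], so the
            # interior per-base coverage is n * covered / (length - insert + 1)
            covered_per_frag = min(config.insert_mean, 2 * config.read_length)
            span = max(1.0, length - config.insert_mean + 1)
            n_frag = max(1, int(round(depth * span / covered_per_frag)))
            inserts = np.clip(
                rng.normal(config.insert_mean, config.insert_sd, size=n_frag),
                config.read_length, length,
            ).astype(int)
            starts = rng.integers(1, np.maximum(2, length - inserts + 2))
            side = dropouts.get((ind, amp_id))
            if side == "maternal":
                hap_choice = np.ones(n_frag, dtype=np.int8)   # only paternal sampled
            elif side == "paternal":
                hap_choice = np.zeros(n_frag, dtype=np.int8)
            else:
                hap_choice = rng.integers(0, 2, size=n_frag).astype(np.int8)
            errs = rng.uniform(size=(n_frag, 8))  # error draws reused per call slot

            haps = (hap0, hap1)
            for f in range(n_frag):
                s, ins = int(starts[f]), int(inserts[f])
                lo1, hi1 = s, s + config.read_length - 1
                lo2, hi2 = s + ins - config.read_length, s + ins - 1
                i1 = np.searchsorted(positions, [lo1, hi1 + 1])
                i2 = np.searchsorted(positions, [max(lo2, hi1 + 1), hi2 + 1])
                covered = np.r_[np.arange(*i1), np.arange(*i2)]
                if covered.size == 0:
                    continue
                vec = haps[hap_choice[f]]
                calls = {}
                for slot, c in enumerate(covered.tolist()):
                    allele = int(vec[c])
                    e = errs[f, slot % 8]
                    if e < config.error_rate:
                        allele = 1 - allele
                    calls[offset + c] = allele
                    counts[ind][offset + c, allele] += 1
                fragments[ind].append(
                    Fragment(f"{ind}|{amp_id}|f{f}", calls)
                )

    records = _build_variant_records(truth, counts, config)
    return fragments, records


def variant_site_order(truth: TruthSet) -> list[tuple[str, SimVariant]]:
    """The concatenated (amplicon, variant) ordering fragment indices use."""
    order = []
    for amp_id, amp in truth.amplicons.items():
        order.extend((amp_id, v) for v in amp.variants)
    return order


def _genotype_call(
    n0: int, n1: int, error_rate: float
) -> tuple[tuple[int, int] | None, int]:
    """Diploid genotype and GQ from biallelic counts via likelihood ratio."""
    dp = n0 + n1
    if dp == 0:
        return None, 0
    e = min(max(error_rate, 1e-3), 0.25)
    ll = {
        (0, 0): n0 * math.log(1 - e) + n1 * math.log(e),
        (0, 1): dp * math.log(0.5),
        (1, 1): n1 * math.log(1 - e) + n0 * math.log(e),
    }
    ordered = sorted(ll.items(), key=lambda kv: -kv[1])
    best, second = ordered[0], ordered[1]
    gq = min(99, int(round(10 / math.log(10) * (best[1] - second[1]))))
    return best[0], gq


def _build_variant_records(
    truth: TruthSet, counts: dict[str, np.ndarray], config: SimConfig
) -> list[VariantRecord]:
    records = []
    for amp_id, amp in truth.amplicons.items():
        offset = 0
        for other_id in truth.amplicons:
            if other_id == amp_id:
                break
            offset += len(truth.amplicons[other_id].variants)
        for j, v in enumerate(amp.variants):
            rec = VariantRecord(
                site=GenomicInterval(amp_id, v.position, v.position + len(v.ref) - 1),
                ref_allele=v.ref,
                alt_alleles=[v.alt],
            )
            for ind in truth.individuals:
                n0, n1 = counts[ind][offset + j]
                gt, gq = _genotype_call(int(n0), int(n1), config.error_rate)
                rec.genotypes[ind] = SampleGenotype(
                    ind, gt, int(n0 + n1), gq
                )
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    truth: TruthSet,
    config: SimConfig | None = None,
    periods: Sequence[FloweringPeriod] | None = None,
) -> list[PhenotypeRow]:
    """Flowering phenotypes from an additive latent score, mapped into each
    year's flowering window.

    Latent score: sum of carried allele effects plus Normal(0, noise_sd).
    Per year, the score's rank position scaled to [0, 1] is blended 50/50
    with per-individual uniform jitter and mapped to
    ``start_day + round((length - 1) * x)``, clamped to the window. In the
    degenerate case where every latent score is identical (no effects, no
    noise) all individuals share the window's start day. Deterministic
    given the seed.
    """
    config = config or truth.config
    if periods is None:
        from .association import default_flowering_periods

        periods = default_flowering_periods()
    if not periods:
        raise ValueError("at least one flowering period required")
    rng = config.stream(3)
    ids = truth.offspring_ids
    latent = np.array(
        [truth.genetic_scores[i] for i in ids]
    ) + rng.normal(0.0, config.phenotype_noise_sd, size=len(ids))

    rows: list[PhenotypeRow] = []
    degenerate = np.ptp(latent) < 1e-12
    ranks = np.argsort(np.argsort(latent, kind="stable"), kind="stable")
    r01 = ranks / max(len(ids) - 1, 1)
    for period in periods:
        jitter = rng.uniform(size=len(ids))
        if degenerate:
            x = np.zeros(len(ids))
        else:
            x = 0.5 * r01 + 0.5 * jitter
        days = period.start_day + np.round((period.length - 1) * x).astype(int)
        days = np.clip(days, period.start_day, period.end_day)
        rows.extend(
            PhenotypeRow(ind, period.year, int(day)) for ind, day in zip(ids, days)
        )
    return rows
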