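"""The synthetic family generator: transmissions, fragments, phenotypes."""

import numpy as np
import pytest

from amphase import simulate
from amphase.association import default_flowering_periods
from amphase.io_formats import FloweringPeriod


def _cfg(**kw):
    base = dict(
        seed=1, n_offspring=20, n_sequenced=10, amplicon_length=1200,
        depth_mean=100, depth_sd=10, recomb_prob=0.0, dropout_prob=0.0,
    )
    base.update(kw)
    return simulate.SimConfig(**base)


def test_config_validation():
    with pytest.raises(ValueError):
        simulate.SimConfig(error_rate=1.5)
    with pytest.raises(ValueError):
        simulate.SimConfig(n_sequenced=200, n_offspring=151)


def test_simulate_family_deterministic():
    t1 = simulate.simulate_family(_cfg())
    t2 = simulate.simulate_family(_cfg())
    amp1, amp2 = t1.amplicons["amp1"], t2.amplicons["amp1"]
    assert [ (v.position, v.ref, v.alt) for v in amp1.variants ] == [
        (v.position, v.ref, v.alt) for v in amp2.variants
    ]
    for lab in simulate.PARENT_LABELS:
        assert np.array_equal(amp1.parental_haps[lab], amp2.parental_haps[lab])
    assert t1.sequenced_ids == t2.sequenced_ids
    for ind in t1.offspring_ids:
        assert amp1.offspring[ind].maternal_label == amp2.offspring[ind].maternal_label


def test_offspring_copy_parental_haplotypes_without_recombination():
    truth = simulate.simulate_family(_cfg())
    amp = truth.amplicons["amp1"]
    for tr in amp.offspring.values():
        assert np.array_equal(tr.maternal_vec, amp.parental_haps[tr.maternal_label])
        assert np.array_equal(tr.paternal_vec, amp.parental_haps[tr.paternal_label])
        assert tr.maternal_label in ("E1", "E2")
        assert tr.paternal_label in ("L1", "L2")
        assert tr.breakpoint is None


def test_transmission_labels_shared_across_linked_amplicons():
    cfg = _cfg()
    ref = simulate.default_reference(cfg, n_amplicons=3)
    truth = simulate.simulate_family(cfg, ref)
    for ind in truth.offspring_ids:
        labels = {
            (a.offspring[ind].maternal_label, a.offspring[ind].paternal_label)
            for a in truth.amplicons.values()
        }
        assert len(labels) == 1


def test_recombinant_fraction_binomial():
    """10,000 offspring at recomb_prob 0.01: recombinant fraction within 3
    binomial SDs of 0.01."""
    cfg = _cfg(n_offspring=10_000, n_sequenced=10, amplicon_length=600,
               variant_density=0.8, recomb_prob=0.01)
    truth = simulate.simulate_family(cfg)
    amp = truth.amplicons["amp1"]
    n_rec = sum(tr.breakpoint is not None for tr in amp.offspring.values())
    sd = (10_000 * 0.01 * 0.99) ** 0.5
    assert abs(n_rec - 100) <= 3 * sd


def test_fragments_error_free_consistent_with_one_haplotype(small_family):
    cfg, truth, fragments, records = small_family
    amp = truth.amplicons["amp1"]
    for ind in truth.sequenced_ids[:4]:
        tr = amp.offspring[ind]
        for frag in fragments[ind][:200]:
            calls = np.array(sorted(frag.calls.items()))
            sites, alleles = calls[:, 0], calls[:, 1]
            m = np.array([tr.maternal_vec[s] for s in sites])
            p = np.array([tr.paternal_vec[s] for s in sites])
            assert np.array_equal(alleles, m) or np.array_equal(alleles, p)


def test_dropout_makes_locus_look_homozygous():
    cfg = _cfg(dropout_prob=1.0, error_rate=0.0, n_sequenced=4)
    truth = simulate.simulate_family(cfg)
    fragments, records = simulate.simulate_fragments(truth, cfg)
    amp = truth.amplicons["amp1"]
    sides = {ind: side for ind, a, side in truth.dropouts if a == "amp1"}
    for ind in truth.sequenced_ids:
        tr = amp.offspring[ind]
        surviving = tr.paternal_vec if sides[ind] == "maternal" else tr.maternal_vec
        for frag in fragments[ind][:100]:
            for s, a in frag.calls.items():
                assert a == surviving[s]
        # genotypes appear homozygous everywhere
        for j, rec in enumerate(records):
            g = rec.genotypes[ind]
            if g.allele_indices is not None:
                assert g.allele_indices[0] == g.allele_indices[1] == surviving[j]


def test_mean_depth_across_amplicons_near_target():
    """Observed mean per-site depth over 50 amplicons within 15% of the
    configured mean."""
    cfg = _cfg(n_offspring=2, n_sequenced=1, amplicon_length=1600,
               depth_mean=80, depth_sd=10, variant_density=1.0)
    ref = simulate.default_reference(cfg, n_amplicons=50)
    truth = simulate.simulate_family(cfg, ref)
    _, records = simulate.simulate_fragments(truth, cfg)
    ind = truth.sequenced_ids[0]
    # interior sites only: coverage tapers mechanically at amplicon edges
    depths = [
        rec.genotypes[ind].depth
        for rec in records
        if cfg.insert_mean < rec.position < cfg.amplicon_length - cfg.insert_mean
    ]
    assert depths, "no interior sites sampled"
    mean = float(np.mean(depths))
    assert abs(mean - cfg.depth_mean) <= 0.15 * cfg.depth_mean


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def test_phenotypes_degenerate_all_share_one_day():
    cfg = _cfg(phenotype_noise_sd=0.0)
    truth = simulate.simulate_family(cfg)
    rows = simulate.simulate_phenotypes(truth, cfg)
    per_year = {}
    for r in rows:
        per_year.setdefault(r.year, set()).add(r.bloom_day)
    assert all(len(days) == 1 for days in per_year.values())


def test_phenotypes_effect_allele_carriers_flower_earlier():
    cfg = _cfg(
        n_offspring=151, n_sequenced=35,
        effect_alleles=(simulate.EffectAllele("amp1", "E1", -5.0),),
        phenotype_noise_sd=0.1,
    )
    truth = simulate.simulate_family(cfg)
    rows = simulate.simulate_phenotypes(truth, cfg)
    carriers = set(simulate.carriers_of(truth, "amp1", "E1"))
    by_year = {}
    for r in rows:
        by_year.setdefault(r.year, []).append(r)
    for year, yr_rows in by_year.items():
        c = [r.bloom_day for r in yr_rows if r.individual_id in carriers]
        n = [r.bloom_day for r in yr_rows if r.individual_id not in carriers]
        assert np.mean(c) < np.mean(n), year


def test_phenotypes_within_period_windows():
    cfg = _cfg(phenotype_noise_sd=8.0)
    truth = simulate.simulate_family(cfg)
    periods = default_flowering_periods()
    rows = simulate.simulate_phenotypes(truth, cfg, periods)
    windows = {p.year: p for p in periods}
    for r in rows:
        w = windows[r.year]
        assert w.start_day <= r.bloom_day <= w.end_day


def test_phenotypes_require_period():
    cfg = _cfg()
    truth = simulate.simulate_family(cfg)
    with pytest.raises(ValueError):
        simulate.simulate_phenotypes(truth, cfg, periods=[])


def test_sequenced_selection_spans_score_range():
    cfg = _cfg(
        n_offspring=60, n_sequenced=12,
        effect_alleles=(simulate.EffectAllele("amp1", "E1", -5.0),),
    )
    truth = simulate.simulate_family(cfg)
    scores = [truth.genetic_scores[i] for i in truth.sequenced_ids]
    all_scores = sorted(truth.genetic_scores.values())
    assert min(scores) == all_scores[0]
    assert max(scores) == all_scores[-1]
    assert len(truth.sequenced_ids) == 12
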