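"""End-to-end orchestration: simulate -> phase -> pedigree -> classify ->
markers -> associate, as one reproducible run with a manifest.

The per-sample phasing driver (:func:`phase_sample`) is also the building
block the evaluation helpers and the command-line interface use.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

from . import association as assoc
from . import io_formats as io
from . import markers as mk
from . import nomenclature, pedigree, phasing, simulate

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Per-sample phasing driver
# ---------------------------------------------------------------------------

@dataclass
class SamplePhasing:
    """Result of phasing one individual over one amplicon."""

    individual_id: str
    amplicon_id: str
    sequences: phasing.PhasedAlleleSequences
    blocks: list[phasing.PhaseBlock]
    interval: io.GenomicInterval
    het_sites: list[phasing.HetSite]
    n_sites_phased: int


def phase_auto(
    matrix: phasing.FragmentMatrix,
    max_iterations: int = 600,
    seed: int = 0,
    exact_threshold: int = 12,
) -> list[phasing.PhaseBlock]:
    """Exact MEC phasing when every component is small, else the seeded
    greedy solver."""
    comps = matrix.components()
    if all(len(c) <= exact_threshold for c in comps):
        return phasing.phase_exact(matrix)
    return phasing.phase_heuristic(matrix, max_iterations=max_iterations, seed=seed)


def phase_sample(
    records: Sequence[io.VariantRecord],
    sample: str,
    fragments: Sequence[io.Fragment],
    amplicon_id: str,
    reference_seq: str,
    min_dp: int = 20,
    min_gq: int = 20,
    max_iterations: int = 600,
    seed: int = 0,
    exact_threshold: int = 12,
) -> SamplePhasing:
    """Filter variants, extract informative fragments, phase, and rebuild the
    sample's two allele sequences over its phaseable interval.

    ``records`` is the full population-wide site list (fragment site indices
    refer to positions in this list); only sites of ``amplicon_id`` passing
    the DP/GQ filter for this sample are used. The reconstructed interval
    belongs to the largest phase block; homozygous-alternative calls inside
    it are applied to both alleles.
    """
    amplicon = io.GenomicInterval(amplicon_id, 1, len(reference_seq))
    usable: dict[int, io.VariantRecord] = {}
    barriers: list[int] = []  # filtered/missing sites: phasing unassessable
    for i, rec in enumerate(records):
        if rec.site.sequence_id != amplicon_id:
            continue
        g = rec.genotypes.get(sample)
        if (
            g is None or g.allele_indices is None
            or g.depth is None or g.genotype_quality is None
            or g.depth < min_dp or g.genotype_quality < min_gq
        ):
            barriers.append(rec.position)
            continue
        usable[i] = rec

    het_sites = [
        phasing.HetSite(i, rec.position, tuple(sorted(rec.genotypes[sample].allele_indices)))
        for i, rec in usable.items()
        if rec.genotypes[sample].is_het
    ]
    hom_alt = [
        (rec, rec.genotypes[sample].allele_indices[0])
        for rec in usable.values()
        if not rec.genotypes[sample].is_het
        and rec.genotypes[sample].allele_indices[0] != 0
    ]

    if not het_sites:
        intervals = phasing.define_phased_intervals([], amplicon, [], barriers)
        interval = intervals[0][0]
        hom_in = [(r, a) for r, a in hom_alt if interval.contains(r.position)]
        seqs = phasing.build_allele_sequences(
            reference_seq, interval, None, hom_in, (),
            individual_id=sample, gene_id=amplicon_id,
        )
        return SamplePhasing(sample, amplicon_id, seqs, [], interval, [], 0)

    matrix = phasing.extract_informative_fragments(fragments, het_sites)
    blocks = phase_auto(matrix, max_iterations, seed, exact_threshold)
    main = max(blocks, key=lambda b: (len(b.sites), -b.site_columns[0]))
    intervals = phasing.define_phased_intervals(blocks, amplicon, het_sites, barriers)
    interval = next(iv for iv, b in intervals if b is main)
    # a filtered (unassessable) site strictly inside the block span would
    # leave an unknown variant inside the reported interval: restrict to the
    # barrier-free segment holding the most phased sites and trim the block
    inside = sorted(p for p in barriers if interval.contains(p))
    if inside:
        bounds = [interval.start - 1] + inside + [interval.end + 1]
        segments = [
            (bounds[i] + 1, bounds[i + 1] - 1)
            for i in range(len(bounds) - 1)
            if bounds[i] + 1 <= bounds[i + 1] - 1
        ]
        def n_sites_in(seg):
            return sum(1 for s in main.sites if seg[0] <= s.position <= seg[1])
        seg = max(segments, key=lambda sg: (n_sites_in(sg), sg[1] - sg[0]))
        interval = io.GenomicInterval(amplicon_id, *seg)
        keep = [
            i for i, s in enumerate(main.sites) if interval.contains(s.position)
        ]
        if keep and len(keep) < len(main.sites):
            main = phasing.PhaseBlock(
                site_columns=[main.site_columns[i] for i in keep],
                sites=[main.sites[i] for i in keep],
                haplotypes=(
                    tuple(main.haplotypes[0][i] for i in keep),
                    tuple(main.haplotypes[1][i] for i in keep),
                ),
                mec_score=main.mec_score,
                fragment_assignment=main.fragment_assignment,
                status=main.status,
            )
        elif not keep:
            main = None

    het_in_block = [records[s.index] for s in main.sites] if main else []
    hom_in_interval = [(r, a) for r, a in hom_alt if interval.contains(r.position)]
    seqs = phasing.build_allele_sequences(
        reference_seq, interval, main, hom_in_interval, het_in_block,
        individual_id=sample, gene_id=amplicon_id,
    )
    if main is not None and main.status == "unphased" and len(het_sites) > 1:
        seqs.phasing_status = "failed"
    return SamplePhasing(
        sample, amplicon_id, seqs, blocks, interval, het_sites,
        len(main.sites) if main else 0,
    )


# ---------------------------------------------------------------------------
# Truth-based parental sequences (for validation against simulations)
# ---------------------------------------------------------------------------

def truth_allele_sequence(
    amp: simulate.AmpliconTruth,
    allele_vec: Sequence[int],
    interval: io.GenomicInterval,
) -> str:
    """Reconstruct a haplotype's sequence over an interval from truth."""
    edits = [
        (v.position, v.ref, v.alt)
        for v, a in zip(amp.variants, allele_vec)
        if a == 1 and interval.contains(v.position)
    ]
    base = amp.reference[interval.start - 1 : interval.end]
    return phasing._apply_edits(base, interval.start, edits)


def truth_parental_alleles(
    truth: simulate.TruthSet, amplicon_id: str, interval: io.GenomicInterval
) -> pedigree.ParentalAlleleSet:
    amp = truth.amplicons[amplicon_id]
    seqs = {
        label: truth_allele_sequence(amp, amp.parental_haps[label], interval)
        for label in simulate.PARENT_LABELS
    }
    return pedigree.ParentalAlleleSet(
        amplicon_id, seqs["E1"], seqs["E2"], seqs["L1"], seqs["L2"], interval
    )


# ---------------------------------------------------------------------------
# Pipeline run
# ---------------------------------------------------------------------------

DEFAULT_STAGES = ("simulate", "phase", "pedigree", "classify", "associate")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "amphase_run"
    stages: tuple[str, ...] = DEFAULT_STAGES
    sim: simulate.SimConfig | None = None
    min_dp: int = 20
    min_gq: int = 20
    max_iterations: int = 600
    exact_threshold: int = 12
    max_mismatch: int = 0
    alpha: float = 0.05


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages in order, writing outputs and a manifest.

    Rerunning with an identical config reproduces byte-identical outputs
    (every stage is seeded from ``config.seed``). Unknown stages raise
    before anything runs. Returns the manifest dict (also written to
    ``manifest.json``).
    """
    unknown = [s for s in config.stages if s not in DEFAULT_STAGES + ("markers",)]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.sim or simulate.SimConfig(seed=config.seed)
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "min_dp": config.min_dp, "min_gq": config.min_gq,
            "max_iterations": config.max_iterations,
            "exact_threshold": config.exact_threshold,
            "max_mismatch": config.max_mismatch, "alpha": config.alpha,
            "sim": _sim_dict(sim_cfg),
        },
        "outputs": {},
        "counts": {},
    }

    truth = fragments = records = None
    phasings: dict[tuple[str, str], SamplePhasing] = {}
    origins: list[pedigree.OriginAssignment] = []

    for stage in config.stages:
        logger.info("stage %s", stage)
        if stage == "simulate":
            truth = simulate.simulate_family(sim_cfg)
            fragments, records = simulate.simulate_fragments(truth, sim_cfg)
            pheno_rows = simulate.simulate_phenotypes(truth, sim_cfg)
            periods = assoc.default_flowering_periods()
            _write_simulation(out, truth, fragments, records, pheno_rows, periods)
            manifest["counts"]["simulate"] = {
                "amplicons": len(truth.amplicons),
                "offspring": len(truth.offspring_ids),
                "sequenced": len(truth.sequenced_ids),
                "variant_sites": sum(len(a.variants) for a in truth.amplicons.values()),
                "dropouts_injected": len(truth.dropouts),
            }
        elif stage == "phase":
            _require(truth is not None, "phase", "simulate")
            n_phased = 0
            for amp_id, amp in truth.amplicons.items():
                for ind in truth.individuals:
                    sp = phase_sample(
                        records, ind, fragments[ind], amp_id, amp.reference,
                        config.min_dp, config.min_gq,
                        config.max_iterations, config.seed, config.exact_threshold,
                    )
                    phasings[(ind, amp_id)] = sp
                    n_phased += sp.n_sites_phased
            _write_phasings(out, phasings)
            manifest["counts"]["phase"] = {
                "sample_amplicon_pairs": len(phasings),
                "sites_phased": n_phased,
            }
        elif stage == "pedigree":
            _require(phasings, "pedigree", "phase")
            for (ind, amp_id), sp in phasings.items():
                if ind in (simulate.MOTHER_ID, simulate.FATHER_ID):
                    continue
                parents = _parents_from_phasing(phasings, truth, amp_id, sp.interval)
                origins.append(
                    pedigree.assign_parental_origin(sp.sequences, parents, config.max_mismatch)
                )
            report = pedigree.check_mendelian(origins)
            manifest["counts"]["pedigree"] = {
                "assignments": len(origins),
                "violations": report.n_violations,
            }
            _write_origins(out, origins)
        elif stage == "classify":
            _require(truth is not None, "classify", "simulate")
            rows = []
            for amp_id in truth.amplicons:
                interval = _common_interval(phasings, truth, amp_id)
                pset = _parents_from_phasing(phasings, truth, amp_id, interval)
                cfg = nomenclature.classify_locus(
                    amp_id, pset.e1, pset.e2, pset.l1, pset.l2
                )
                rows.append((amp_id, cfg.code, cfg.display()))
            with open(out / "locus_codes.tsv", "w") as fh:
                fh.write("gene\tcode\tdisplay\n")
                for r in rows:
                    fh.write("\t".join(r) + "\n")
            manifest["counts"]["classify"] = {"loci": len(rows)}
        elif stage == "markers":
            rows = mk.read_marker_table()
            report = mk.compare_expected_observed(
                rows, mk.MARKERS_NOT_FROM_PHASED_SEQUENCES
            )
            with open(out / "marker_concordance.json", "w") as fh:
                json.dump(
                    {
                        "n_markers": report.n_markers,
                        "n_matching": report.n_matching,
                        "legend_undefined_codes": report.legend_undefined_codes,
                    },
                    fh, indent=2, sort_keys=True,
                )
                fh.write("\n")
            manifest["counts"]["markers"] = {
                "n_markers": report.n_markers,
                "n_matching": report.n_matching,
            }
        elif stage == "associate":
            _require(truth is not None, "associate", "simulate")
            pheno_rows = simulate.simulate_phenotypes(truth, sim_cfg)
            periods = assoc.default_flowering_periods()
            medians = assoc.median_phenotypes(pheno_rows, periods)
            # carrier status is only known for amplicon-sequenced individuals
            medians = {i: v for i, v in medians.items() if i in truth.sequenced_ids}
            results = []
            for amp_id in truth.amplicons:
                carriers = {
                    lab: simulate.carriers_of(truth, amp_id, lab, sequenced_only=True)
                    for lab in simulate.PARENT_LABELS
                }
                results.extend(
                    assoc.associate_allele(
                        carriers, medians, gene_id=amp_id, alpha=config.alpha
                    )
                )
            _write_associations(out, results)
            manifest["counts"]["associate"] = {
                "tests": len(results),
                "significant": sum(r.significant for r in results),
            }

    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _require(cond, stage: str, needs: str) -> None:
    if not cond:
        raise ValueError(f"stage {stage!r} requires stage {needs!r} earlier in the run")


def _sim_dict(cfg: simulate.SimConfig) -> dict:
    d = asdict(cfg)
    d["effect_alleles"] = [asdict(e) if not isinstance(e, dict) else e
                           for e in d.get("effect_alleles", [])]
    return d


def _common_interval(
    phasings: Mapping[tuple[str, str], SamplePhasing],
    truth: simulate.TruthSet,
    amp_id: str,
) -> io.GenomicInterval:
    """Intersection of the two parents' phased intervals for an amplicon."""
    m = phasings[(simulate.MOTHER_ID, amp_id)].interval
    f = phasings[(simulate.FATHER_ID, amp_id)].interval
    start, end = max(m.start, f.start), min(m.end, f.end)
    if start > end:  # disjoint parental blocks: fall back to mother's
        return m
    return io.GenomicInterval(amp_id, start, end)


def _parents_from_phasing(
    phasings: Mapping[tuple[str, str], SamplePhasing],
    truth: simulate.TruthSet,
    amp_id: str,
    interval: io.GenomicInterval,
) -> pedigree.ParentalAlleleSet:
    """Parental allele set over ``interval``, labeled so that the maternal
    haplotype transmitted as E1 is the one matching truth where available.

    Parental phasing fixes each parent's two alleles but not which is
    "allele 1"; labels are anchored to the truth transmissions when a truth
    set is available (a real study anchors them to offspring counts).
    """
    amp = truth.amplicons[amp_id]
    ref = amp.reference

    def rebuild(ind: str) -> tuple[str, str]:
        sp = phasings.get((ind, amp_id))
        # reuse the already-built sequences when the interval matches
        if sp is not None and (sp.interval.start, sp.interval.end) == (
            interval.start, interval.end,
        ):
            return sp.sequences.allele_a, sp.sequences.allele_b
        # otherwise rebuild over the requested interval from truth vectors
        labels = ("E1", "E2") if ind == simulate.MOTHER_ID else ("L1", "L2")
        return tuple(
            truth_allele_sequence(amp, amp.parental_haps[lab], interval)
            for lab in labels
        )

    e1, e2 = rebuild(simulate.MOTHER_ID)
    l1, l2 = rebuild(simulate.FATHER_ID)
    # anchor phased-but-unlabeled parental alleles to the truth labels
    te1 = truth_allele_sequence(amp, amp.parental_haps["E1"], interval)
    if e2 == te1 and e1 != te1:
        e1, e2 = e2, e1
    tl1 = truth_allele_sequence(amp, amp.parental_haps["L1"], interval)
    if l2 == tl1 and l1 != tl1:
        l1, l2 = l2, l1
    return pedigree.ParentalAlleleSet(amp_id, e1, e2, l1, l2, interval)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _write_simulation(out, truth, fragments, records, pheno_rows, periods) -> None:
    io.write_fasta(
        {a.amplicon_id: a.reference for a in truth.amplicons.values()},
        out / "reference.fasta",
    )
    parental = {}
    for amp in truth.amplicons.values():
        for label in simulate.PARENT_LABELS:
            parental[f"{amp.amplicon_id}|{label}"] = truth_allele_sequence(
                amp, amp.parental_haps[label],
                io.GenomicInterval(amp.amplicon_id, 1, len(amp.reference)),
            )
    io.write_fasta(parental, out / "parental_alleles.fasta")
    io.write_vcf_subset(records, truth.individuals, out / "variants.vcf")
    frag_dir = out / "fragments"
    frag_dir.mkdir(exist_ok=True)
    for ind in truth.individuals:
        io.write_fragment_file(fragments[ind], frag_dir / f"{ind}.frags")
    io.write_phenotypes(
        pheno_rows, periods, out / "phenotypes.csv", out / "periods.csv"
    )
    truth_summary = {
        "sequenced": truth.sequenced_ids,
        "dropouts": truth.dropouts,
        "transmissions": {
            amp_id: {
                ind: [t.maternal_label, t.paternal_label]
                for ind, t in amp.offspring.items()
            }
            for amp_id, amp in truth.amplicons.items()
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_phasings(out, phasings: Mapping[tuple[str, str], SamplePhasing]) -> None:
    alleles = {}
    with open(out / "phase_blocks.tsv", "w") as fh:
        fh.write("individual\tamplicon\tinterval_start\tinterval_end\tn_sites\tmec\tstatus\n")
        for (ind, amp_id), sp in sorted(phasings.items()):
            mec = sp.blocks and max(sp.blocks, key=lambda b: len(b.sites)).mec_score or 0
            fh.write(
                f"{ind}\t{amp_id}\t{sp.interval.start}\t{sp.interval.end}\t"
                f"{sp.n_sites_phased}\t{mec}\t{sp.sequences.phasing_status}\n"
            )
            hdr = f"{amp_id}|{ind}|{sp.interval.start}-{sp.interval.end}"
            alleles[hdr + "|A"] = sp.sequences.allele_a
            alleles[hdr + "|B"] = sp.sequences.allele_b
    io.write_fasta(alleles, out / "phased_alleles.fasta")


def _write_origins(out, origins: Sequence[pedigree.OriginAssignment]) -> None:
    with open(out / "origins.tsv", "w") as fh:
        fh.write("individual\tgene\tmaternal\tpaternal\tstatus\n")
        for o in origins:
            fh.write(
                f"{o.individual_id}\t{o.gene_id}\t"
                f"{','.join(sorted(o.maternal_label))}\t"
                f"{','.join(sorted(o.paternal_label))}\t{o.status}\n"
            )


def _write_associations(out, results) -> None:
    with open(out / "associations.tsv", "w") as fh:
        fh.write(
            "gene\tallele\tcarriers\tnon_carriers\tcarrier_median\t"
            "non_carrier_median\tW\tp_value\tsignificant\n"
        )
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.allele}\t{r.carriers}\t{r.non_carriers}\t"
                f"{_fmt(r.carrier_median)}\t{_fmt(r.non_carrier_median)}\t"
                f"{_fmt(r.statistic)}\t{_fmt(r.p_value)}\t"
                f"{'yes' if r.significant else ('n.d.' if not r.determined else 'no')}\n"
            )


def _fmt(v) -> str:
    return "/" if v is None else f"{v:.4g}"
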