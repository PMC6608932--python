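"""Readers and writers for every external representation the pipeline touches.

Conventions fixed here and used everywhere else in the package:

* All genomic coordinates are 1-based and inclusive (VCF convention); there
  are no half-open intervals anywhere.
* Multi-allelic variant sites are kept intact; allele indices run 0..k with
  0 = reference.
* Missing genotypes and missing phenotype cells are carried as explicit
  missing values (``None``), never imputed.

The fragment file is a bespoke whitespace-delimited text format (one line
per fragment: ``fragment_id site:allele:qual site:allele:qual ...``) rather
than SAM/BAM ingestion; fragments reference heterozygous sites by their
index in a declared site ordering.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

MISSING = None
_DNA = set("ACGT")


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive interval on a named sequence."""

    sequence_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.sequence_id:
            raise ValueError("sequence_id must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.sequence_id}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class SampleGenotype:
    """One sample's call at a site: allele indices plus DP and GQ.

    ``allele_indices`` is a pair of ints (0 = ref, k = k-th alt) or ``None``
    when the genotype is missing. ``depth``/``genotype_quality`` are ``None``
    when the VCF carried a non-numeric value (flagged at parse time).
    """

    sample_id: str
    allele_indices: tuple[int, int] | None
    depth: int | None
    genotype_quality: int | None

    @property
    def is_het(self) -> bool:
        return (
            self.allele_indices is not None
            and self.allele_indices[0] != self.allele_indices[1]
        )

    @property
    def is_missing(self) -> bool:
        return self.allele_indices is None


@dataclass
class VariantRecord:
    """A called variant site with per-sample genotypes."""

    site: GenomicInterval
    ref_allele: str
    alt_alleles: list[str]
    genotypes: dict[str, SampleGenotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref_allele or not set(self.ref_allele) <= _DNA:
            raise ValueError(f"bad ref allele {self.ref_allele!r}")
        if not self.alt_alleles:
            raise ValueError("alt_alleles must be non-empty")
        for alt in self.alt_alleles:
            if alt == self.ref_allele:
                raise ValueError(f"alt equals ref at {self.position}")

    @property
    def position(self) -> int:
        return self.site.start

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and all(
            len(a) == 1 for a in self.alt_alleles
        )

    def allele(self, index: int) -> str:
        """Sequence of allele ``index`` (0 = ref)."""
        if index == 0:
            return self.ref_allele
        return self.alt_alleles[index - 1]

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)


@dataclass(frozen=True)
class PhenotypeRow:
    """Full-bloom day (days after January 1st) for one individual in one year."""

    individual_id: str
    year: int
    bloom_day: int

    def __post_init__(self) -> None:
        if not (1 <= self.bloom_day <= 366):
            raise ValueError(f"bloom_day {self.bloom_day} out of range")


@dataclass(frozen=True)
class FloweringPeriod:
    """The population-wide flowering window of one year (days after Jan 1st)."""

    year: int
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise ValueError("start_day must be <= end_day")

    @property
    def length(self) -> int:
        """Inclusive length in days (e.g. 2012: 153..169 -> 17)."""
        return self.end_day - self.start_day + 1


@dataclass
class Fragment:
    """Observed alleles of one sequencing fragment (read pair) at het sites.

    ``calls`` maps site index (into a declared site ordering) to the observed
    allele index; ``quals`` carries a per-call phred quality.
    """

    fragment_id: str
    calls: dict[int, int]
    quals: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.quals:
            self.quals = {i: 40 for i in self.calls}

    @property
    def sites(self) -> list[int]:
        return sorted(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered mapping of id -> uppercased sequence.

    IDs are the first whitespace-delimited token of the header. Duplicate IDs
    and malformed records raise :class:`FormatError` naming the line.
    """
    sequences: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    sequences[current] = "".join(chunks)
                current = line[1:].split()[0] if line[1:].split() else ""
                if not current:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                if current in sequences:
                    raise FormatError(
                        f"{path}: duplicate sequence ID {current!r} at line {lineno}"
                    )
                chunks = []
            else:
                if current is None:
                    raise FormatError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                chunks.append(line.upper())
    if current is not None:
        sequences[current] = "".join(chunks)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    """Write sequences in deterministic (insertion) order, wrapped at ``width``."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF subset (GT/DP/GQ)
# ---------------------------------------------------------------------------

def _parse_gt(token: str, n_alleles: int, pos: int) -> tuple[int, int] | None:
    gt = token.replace("|", "/")
    if gt in (".", "./.", ".|."):
        return None
    parts = gt.split("/")
    if len(parts) != 2 or any(p == "." for p in parts):
        return None
    a, b = (int(p) for p in parts)
    if not (0 <= a < n_alleles and 0 <= b < n_alleles):
        raise FormatError(f"allele index out of range in GT {token!r} at pos {pos}")
    return (a, b)


def _parse_int_field(token: str) -> int | None:
    try:
        return int(token)
    except (TypeError, ValueError):
        return None


def read_vcf_subset(path: str | Path, samples: Sequence[str]) -> list[VariantRecord]:
    """Read a VCF v4.x subset keeping GT, DP and GQ for the given samples.

    Positions stay 1-based as in the file; multi-allelic sites are preserved,
    not split. Non-numeric DP/GQ values are treated as missing and flagged
    with a warning. A header-only file yields an empty list.
    """
    records: list[VariantRecord] = []
    sample_cols: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header = line.lstrip("#").split("\t")
                for s in samples:
                    try:
                        sample_cols[s] = header.index(s)
                    except ValueError:
                        raise FormatError(
                            f"{path}: sample {s!r} not in VCF header"
                        ) from None
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(f"{path}: truncated VCF data line {lineno}")
            if not sample_cols:
                raise FormatError(f"{path}: data line before #CHROM header")
            chrom, pos_s, _id, ref, alt = fields[:5]
            pos = int(pos_s)
            alts = alt.split(",")
            fmt = fields[8].split(":")
            try:
                gt_i = fmt.index("GT")
            except ValueError:
                raise FormatError(f"{path}: FORMAT lacks GT at line {lineno}") from None
            dp_i = fmt.index("DP") if "DP" in fmt else None
            gq_i = fmt.index("GQ") if "GQ" in fmt else None
            rec = VariantRecord(
                site=GenomicInterval(chrom, pos, pos + len(ref) - 1),
                ref_allele=ref.upper(),
                alt_alleles=[a.upper() for a in alts],
            )
            for sample, col in sample_cols.items():
                toks = fields[col].split(":")
                gt = _parse_gt(toks[gt_i], rec.n_alleles, pos)
                dp = _parse_int_field(toks[dp_i]) if dp_i is not None and dp_i < len(toks) else None
                gq = _parse_int_field(toks[gq_i]) if gq_i is not None and gq_i < len(toks) else None
                if dp is None and dp_i is not None:
                    logger.warning("non-numeric/absent DP for %s at %s:%d", sample, chrom, pos)
                if gq is None and gq_i is not None:
                    logger.warning("non-numeric/absent GQ for %s at %s:%d", sample, chrom, pos)
                rec.genotypes[sample] = SampleGenotype(sample, gt, dp, gq)
            records.append(rec)
    return records


def write_vcf_subset(
    records: Iterable[VariantRecord], samples: Sequence[str], path: str | Path
) -> None:
    """Write records as a minimal VCF with GT:DP:GQ, byte-deterministic."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in records:
            cols = [
                rec.site.sequence_id,
                str(rec.position),
                ".",
                rec.ref_allele,
                ",".join(rec.alt_alleles),
                ".",
                "PASS",
                ".",
                "GT:DP:GQ",
            ]
            for s in samples:
                g = rec.genotypes.get(s)
                if g is None or g.allele_indices is None:
                    gt = "./."
                else:
                    gt = f"{g.allele_indices[0]}/{g.allele_indices[1]}"
                dp = "." if g is None or g.depth is None else str(g.depth)
                gq = "." if g is None or g.genotype_quality is None else str(g.genotype_quality)
                cols.append(f"{gt}:{dp}:{gq}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Fragment file
# ---------------------------------------------------------------------------

def write_fragment_file(
    fragments: Sequence[Fragment], path: str | Path, n_sites: int | None = None
) -> None:
    """Write fragments, one line each: id then site:allele:qual triples.

    If ``n_sites`` is given, site indices are bounds-checked against it.
    """
    with open(path, "w") as fh:
        for frag in fragments:
            triples = []
            for site in frag.sites:
                if n_sites is not None and not (0 <= site < n_sites):
                    raise FormatError(
                        f"fragment {frag.fragment_id}: site index {site} out of "
                        f"range for {n_sites} declared sites"
                    )
                triples.append(f"{site}:{frag.calls[site]}:{frag.quals[site]}")
            fh.write(" ".join([frag.fragment_id] + triples) + "\n")


def read_fragment_file(path: str | Path, n_sites: int | None = None) -> list[Fragment]:
    """Read a fragment file written by :func:`write_fragment_file`."""
    fragments: list[Fragment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            toks = line.split()
            frag_id, triples = toks[0], toks[1:]
            calls: dict[int, int] = {}
            quals: dict[int, int] = {}
            for t in triples:
                try:
                    site_s, allele_s, qual_s = t.split(":")
                    site, allele, qual = int(site_s), int(allele_s), int(qual_s)
                except ValueError:
                    raise FormatError(
                        f"{path}: malformed triple {t!r} at line {lineno}"
                    ) from None
                if n_sites is not None and not (0 <= site < n_sites):
                    raise FormatError(
                        f"{path}: site index {site} out of range for "
                        f"{n_sites} declared sites (line {lineno})"
                    )
                calls[site] = allele
                quals[site] = qual
            fragments.append(Fragment(frag_id, calls, quals))
    return fragments


# ---------------------------------------------------------------------------
# Phenotypes and flowering periods
# ---------------------------------------------------------------------------

def read_phenotypes(
    phenotype_path: str | Path, periods_path: str | Path
) -> tuple[list[PhenotypeRow], list[FloweringPeriod]]:
    """Read the bloom-day table and the per-year flowering windows.

    Phenotype CSV columns: individual_id, year, bloom_day. Period CSV columns:
    year, start_day, end_day (extra columns ignored). Rows with an empty bloom
    day are skipped with a log message (missing data, never imputed). A bloom
    day outside its year's window is kept but logged as a warning; clamping is
    the association module's responsibility.
    """
    periods: list[FloweringPeriod] = []
    with open(periods_path, newline="") as fh:
        for row in _data_rows(fh):
            periods.append(
                FloweringPeriod(int(row[0]), int(row[1]), int(row[2]))
            )
    by_year = {p.year: p for p in periods}

    rows: list[PhenotypeRow] = []
    with open(phenotype_path, newline="") as fh:
        for row in _data_rows(fh):
            ind, year_s, day_s = row[0], row[1], row[2] if len(row) > 2 else ""
            if day_s.strip() in ("", ".", "NA", "/"):
                logger.info("missing bloom day for %s in %s; skipped", ind, year_s)
                continue
            pr = PhenotypeRow(ind, int(year_s), int(day_s))
            period = by_year.get(pr.year)
            if period is not None and not (
                period.start_day <= pr.bloom_day <= period.end_day
            ):
                logger.warning(
                    "bloom day %d for %s outside %d window [%d, %d]",
                    pr.bloom_day, ind, pr.year, period.start_day, period.end_day,
                )
            rows.append(pr)
    return rows, periods


def _data_rows(fh) -> Iterable[list[str]]:
    """Yield non-empty, non-header rows of a comma/tab-delimited file."""
    sample = fh.read(4096)
    fh.seek(0)
    delim = "\t" if "\t" in sample.split("\n", 1)[0] else ","
    reader = csv.reader(fh, delimiter=delim)
    for i, row in enumerate(reader):
        if not row or not any(c.strip() for c in row):
            continue
        if i == 0 and not _looks_numeric(row[1] if len(row) > 1 else ""):
            continue  # header row
        yield [c.strip() for c in row]


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_phenotypes(
    rows: Sequence[PhenotypeRow], periods: Sequence[FloweringPeriod],
    phenotype_path: str | Path, periods_path: str | Path,
) -> None:
    with open(phenotype_path, "w") as fh:
        fh.write("individual_id,year,bloom_day\n")
        for r in rows:
            fh.write(f"{r.individual_id},{r.year},{r.bloom_day}\n")
    with open(periods_path, "w") as fh:
        fh.write("year,start_day,end_day\n")
        for p in periods:
            fh.write(f"{p.year},{p.start_day},{p.end_day}\n")
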