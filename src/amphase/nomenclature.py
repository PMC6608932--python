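"""Allele-identity nomenclature for a pseudo-testcross locus.

The four parental alleles of a gene — E1, E2 from the early-flowering
maternal line, L1, L2 from the late-flowering paternal line — can be
pairwise identical in 15 ways (the set partitions of four labeled items).
The nomenclature collapses these into 14 codes: the two single-cross-pair
partitions (E1=L2 alone, E2=L1 alone) share the code ``N``.

Codes:

=============  ==================================================
``E1E2xL1L2``  all four alleles distinct
``E0xL1L2``    E1 = E2 only
``E1E2xL0``    L1 = L2 only
``E0xL0``      E1 = E2 and L1 = L2 (maternal != paternal)
``N1``         E1 = L1 only
``N2``         E2 = L2 only
``N1N2``       E1 = L1 and E2 = L2
``N``          exactly one cross identity: E1 = L2, or E2 = L1
``NN``         both cross identities: E1 = L2 and E2 = L1
``Na``         E1 = E2 = L1 (L2 distinct)
``Nb``         E1 = E2 = L2 (L1 distinct)
``Nc``         E1 = L1 = L2 (E2 distinct)
``Nd``         E2 = L1 = L2 (E1 distinct)
``N0``         all four alleles identical
=============  ==================================================

``N0`` is this package's canonical symbol for the all-identical situation,
which the nomenclature describes but assigns no printed symbol.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

LABELS = ("E1", "E2", "L1", "L2")

ALL_CODES = (
    "E1E2xL1L2", "E0xL1L2", "E1E2xL0", "E0xL0",
    "N1", "N2", "N1N2", "N", "NN",
    "Na", "Nb", "Nc", "Nd", "N0",
)


@dataclass(frozen=True)
class AlleleConfiguration:
    """The identity pattern of a gene's four parental alleles."""

    gene_id: str
    code: str
    identity_partition: tuple[frozenset[str], ...]

    def display(self) -> str:
        """Human rendering in the maternal-x-paternal style, e.g. ``E0 x L1L2``."""
        if self.code in ("E1E2xL1L2", "E0xL1L2", "E1E2xL0", "E0xL0"):
            m, p = self.code.split("x")
            return f"{m} x {p}"
        return self.code


def _partition_of(seqs: dict[str, str]) -> tuple[frozenset[str], ...]:
    groups: dict[str, set[str]] = {}
    for label in LABELS:
        groups.setdefault(seqs[label], set()).add(label)
    # deterministic order: by earliest member label
    ordered = sorted(groups.values(), key=lambda g: min(LABELS.index(x) for x in g))
    return tuple(frozenset(g) for g in ordered)


def code_for_partition(partition: tuple[frozenset[str], ...]) -> str:
    """Map an identity partition of {E1,E2,L1,L2} to its nomenclature code."""
    same = {
        frozenset(pair): any(frozenset(pair) <= g for g in partition)
        for pair in combinations(LABELS, 2)
    }
    eq = lambda a, b: same[frozenset((a, b))]  # noqa: E731
    sizes = sorted(len(g) for g in partition)

    if sizes == [1, 1, 1, 1]:
        return "E1E2xL1L2"
    if sizes == [4]:
        return "N0"
    if sizes == [1, 3]:
        if eq("E1", "E2") and eq("E2", "L1"):
            return "Na"
        if eq("E1", "E2") and eq("E2", "L2"):
            return "Nb"
        if eq("E1", "L1") and eq("L1", "L2"):
            return "Nc"
        return "Nd"  # E2 = L1 = L2
    if sizes == [2, 2]:
        if eq("E1", "E2"):  # then L1 = L2
            return "E0xL0"
        if eq("E1", "L1"):  # then E2 = L2
            return "N1N2"
        return "NN"         # E1 = L2 and E2 = L1
    # sizes == [1, 1, 2]: a single identical pair
    if eq("E1", "E2"):
        return "E0xL1L2"
    if eq("L1", "L2"):
        return "E1E2xL0"
    if eq("E1", "L1"):
        return "N1"
    if eq("E2", "L2"):
        return "N2"
    return "N"  # E1 = L2 or E2 = L1


def classify_locus(
    gene_id: str,
    e1: str, e2: str, l1: str, l2: str,
    tolerance: int = 0,
) -> AlleleConfiguration:
    """Classify a locus from its four parental allele sequences.

    Identity is exact string equality after uppercasing (``tolerance`` > 0
    instead treats sequences within that edit distance as alike; default 0,
    since the nomenclature is defined on sequence identity).
    """
    raw = {"E1": e1, "E2": e2, "L1": l1, "L2": l2}
    for label, seq in raw.items():
        if not seq:
            raise ValueError(f"missing sequence for {label}")
    seqs = {k: v.upper() for k, v in raw.items()}
    if tolerance > 0:
        seqs = _merge_within_tolerance(seqs, tolerance)
    partition = _partition_of(seqs)
    return AlleleConfiguration(gene_id, code_for_partition(partition), partition)


def _merge_within_tolerance(seqs: dict[str, str], tol: int) -> dict[str, str]:
    import edlib

    reps = dict(seqs)
    for a, b in combinations(LABELS, 2):
        if reps[a] != reps[b]:
            d = edlib.align(seqs[a], seqs[b])["editDistance"]
            if 0 <= d <= tol:
                canon = reps[a]
                reps = {k: canon if v == reps[b] else v for k, v in reps.items()}
    return reps


def enumerate_cases() -> list[str]:
    """Classify one representative of each of the 15 set partitions of
    {E1,E2,L1,L2}; returns the distinct codes (exactly 14)."""
    codes = []
    for assignment in _all_partition_assignments():
        seqs = {label: "ACGT"[group] * 4 for label, group in assignment.items()}
        cfg = classify_locus("case", seqs["E1"], seqs["E2"], seqs["L1"], seqs["L2"])
        codes.append(cfg.code)
    seen: list[str] = []
    for c in codes:
        if c not in seen:
            seen.append(c)
    return seen


def _all_partition_assignments() -> list[dict[str, int]]:
    """All 15 set partitions of the four labels, as label -> group index."""
    out = []
    seen = set()
    for a in range(1):
        for b in range(2):
            for c in range(3):
                for d in range(4):
                    groups = (a, b, c, d)
                    # normalize to restricted growth string
                    if _is_rgs(groups) and groups not in seen:
                        seen.add(groups)
                        out.append(dict(zip(LABELS, groups)))
    return out


def _is_rgs(t: tuple[int, ...]) -> bool:
    mx = -1
    for v in t:
        if v > mx + 1:
            return False
        mx = max(mx, v)
    return True


def label_offspring_combination(
    origin_maternal: frozenset[str] | set[str],
    origin_paternal: frozenset[str] | set[str],
    config: AlleleConfiguration,
    individual_id: str = "",
    status: str = "assigned",
) -> set[str] | None:
    """Combination label(s) for one offspring: maternal label joined with
    paternal label, e.g. ``E1L2``. Ambiguous origins (label sets with more
    than one member) yield every compatible combination. A violation-status
    origin yields ``None`` (no label)."""
    if status == "violation":
        return None
    combos = set()
    for m in sorted(origin_maternal):
        for p in sorted(origin_paternal):
            combos.add(f"{m}{p}")
    return combos
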