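"""Codon counting, synonymous families, usage frequencies and RSCU.

The genetic code defaults to NCBI translation table 2 (vertebrate
mitochondrial), in which AGA/AGG join TAA/TAG as stops, ATA codes Met and
TGA codes Trp — leaving 60 sense codons. Synonymous families are derived
from the code table, never hardcoded, with one conventional refinement:
serine splits into Ser1 (the TCN four-codon box) and Ser2 (the AGY pair),
because the two sets are decoded by different tRNAs and are conventionally
reported as separate families. Leucine remains a single six-codon family
(TTR + CTN).

RSCU (relative synonymous codon usage) for codon ``c`` in a family of size
``k`` with family total ``n`` is ``count(c) * k / n`` — the observed count
relative to the count expected under uniform usage within the family.
Outputs use the RNA alphabet (CUA, not CTA) as is conventional for codon
usage reports; internal storage is DNA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from mitochar.errors import ComputeError

VERTEBRATE_MITO = 2  # NCBI translation table id

_AA3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}


def _code(code_id: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code_id]


def synonymous_families(code_id: int = VERTEBRATE_MITO) -> dict[str, list[str]]:
    """Synonymous codon families of a genetic code.

    Returns family label → sorted codon list (DNA alphabet). Families are
    amino-acid groups from the code table; serine is split into ``Ser1``
    (TCN box) and ``Ser2`` (AGY) when both sets are present. Stop codons
    form no family.
    """
    table = _code(code_id)
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    families: dict[str, list[str]] = {}
    for aa, codons in by_aa.items():
        label = _AA3.get(aa, aa)
        if aa == "S":
            tcn = sorted(c for c in codons if c.startswith("TC"))
            agy = sorted(c for c in codons if not c.startswith("TC"))
            if tcn and agy:
                families["Ser1"] = tcn
                families["Ser2"] = agy
                continue
        families[label] = sorted(codons)
    return families


def family_of_codon(code_id: int = VERTEBRATE_MITO) -> dict[str, str]:
    """Codon → family label map (sense codons only)."""
    return {
        codon: label
        for label, codons in synonymous_families(code_id).items()
        for codon in codons
    }


def dna_to_rna(codon: str) -> str:
    return codon.replace("T", "U")


@dataclass
class CodonUsage:
    """Codon counts over a set of coding sequences, plus code metadata."""

    genetic_code: int
    counts: dict[str, int] = field(default_factory=dict)
    total_codons: int = 0
    ambiguous: int = 0  # codons skipped for containing N/gaps
    internal_stops: int = 0  # internal stop codons encountered (warned, skipped)

    @property
    def family_size(self) -> dict[str, int]:
        """Family label → number of synonymous codons, from the code table."""
        return {k: len(v) for k, v in synonymous_families(self.genetic_code).items()}


def codon_counts(
    cds_list: list[str], code_id: int = VERTEBRATE_MITO
) -> CodonUsage:
    """Count in-frame codons over a list of sense-strand CDSs.

    Reading frame starts at position 1 of each CDS. Trailing partial codons
    (incomplete stops) are dropped; a complete terminal stop codon is
    excluded from counting; start codons are included. Codons containing N
    or gap characters are tallied separately as ambiguous. An internal stop
    codon triggers a warning with its position (annotations are sometimes
    imperfect) and is excluded from the counts.
    """
    table = _code(code_id)
    stops = set(table.stop_codons)
    usage = CodonUsage(genetic_code=code_id)
    for idx, cds in enumerate(cds_list):
        s = cds.upper().replace("U", "T")
        if len(s) < 6:
            raise ComputeError(f"CDS #{idx} is {len(s)} bp (< 6): degenerate")
        n_full = len(s) // 3
        codons = [s[3 * i : 3 * i + 3] for i in range(n_full)]
        if len(s) % 3 == 0 and codons and codons[-1] in stops:
            codons = codons[:-1]  # complete terminal stop: excluded
        for j, codon in enumerate(codons):
            if set(codon) - set("ACGT"):
                usage.ambiguous += 1
                continue
            if codon in stops:
                warnings.warn(
                    f"internal stop codon {codon} at codon {j + 1} of CDS #{idx}",
                    stacklevel=2,
                )
                usage.internal_stops += 1
                continue
            usage.counts[codon] = usage.counts.get(codon, 0) + 1
            usage.total_codons += 1
    return usage


def rscu(usage: CodonUsage) -> dict[str, float]:
    """RSCU per sense codon.

    Families with zero total are omitted (RSCU undefined there). Within any
    family with nonzero total, the RSCU values sum to the family size and
    average to 1.
    """
    families = synonymous_families(usage.genetic_code)
    out: dict[str, float] = {}
    for label, codons in families.items():
        n = sum(usage.counts.get(c, 0) for c in codons)
        if n == 0:
            continue
        k = len(codons)
        for c in codons:
            out[c] = usage.counts.get(c, 0) * k / n
    return out


def codon_frequencies(usage: CodonUsage) -> dict[str, float]:
    """Per-codon usage as a percentage of all counted codons."""
    if usage.total_codons == 0:
        raise ComputeError("no codons counted; frequencies undefined")
    return {
        c: 100.0 * n / usage.total_codons for c, n in sorted(usage.counts.items())
    }


def top_codons(usage: CodonUsage, k: int = 3) -> list[tuple[str, str, float]]:
    """The ``k`` most frequent codons as (RNA codon, family, percent).

    Sorted by descending frequency; ties break alphabetically on the codon.
    """
    freqs = codon_frequencies(usage)
    fam = family_of_codon(usage.genetic_code)
    ranked = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(dna_to_rna(c), fam.get(c, "?"), p) for c, p in ranked[:k]]


def usage_table_tsv(usage: CodonUsage, ndigits: int = 2) -> str:
    """Codon usage / RSCU table as TSV (RNA codons, as is conventional)."""
    fam = family_of_codon(usage.genetic_code)
    values = rscu(usage)
    freqs = codon_frequencies(usage) if usage.total_codons else {}
    lines = ["codon\tamino_acid\tcount\trscu\tpercent"]
    for codon in sorted(fam, key=lambda c: (fam[c], c)):
        count = usage.counts.get(codon, 0)
        r = values.get(codon)
        f = freqs.get(codon, 0.0)
        r_str = "" if r is None else f"{round(r, ndigits)}"
        lines.append(
            f"{dna_to_rna(codon)}\t{fam[codon]}\t{count}\t{r_str}\t{round(f, ndigits)}"
        )
    return "\n".join(lines) + "\n"


def assert_valid_rscu(values: dict[str, float], code_id: int = VERTEBRATE_MITO) -> None:
    """Raise if the RSCU family-sum identity is violated (debug helper)."""
    families = synonymous_families(code_id)
    for label, codons in families.items():
        present = [values[c] for c in codons if c in values]
        if present and not math.isclose(sum(present), len(codons), rel_tol=1e-9):
            raise AssertionError(f"family {label}: RSCU sum {sum(present)} != {len(codons)}")
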