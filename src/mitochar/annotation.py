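"""Derived gene-table statistics for an annotated circular mitogenome.

Reproduces the columns a mitogenome characterisation table reports per
feature — length, start/stop codon, intergenic nucleotides (IGN) — and the
genome-wide overlap/IGN summary.

Spacer convention
-----------------
The spacer attributed to a feature is the signed gap to the NEXT feature in
annotation order: ``next.start - current.end - 1``, with the final feature
wrapping to the first across the circular origin. Negative values are
overlaps. With this convention the telescoping identity

    sum(length_i + spacer_i) == genome length

holds exactly on every circular annotation.

IGN summary convention
----------------------
Overlaps are all spacers < 0. IGN regions are spacers > 0, by default
EXCLUDING the spacer whose downstream feature is the control region
(D-LOOP): the flank of the control region is conventionally treated as part
of the region's neighbourhood rather than as an intergenic spacer. Pass
``count_dloop_flank=True`` to include it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from mitochar.errors import ComputeError
from mitochar.model import AnnotatedMitogenome, MitoFeature, feature_sequence

#: Complete stop codons of the vertebrate mitochondrial code that terminate
#: mitochondrial PCGs (AGA/AGG are code-table stops but are not used as
#: genomic terminators; anything outside this set yields token ``other``).
COMPLETE_STOPS = ("TAA", "TAG")

#: Feature names treated as the control region for the IGN exclusion rule.
CONTROL_REGION_NAMES = ("D-LOOP", "CONTROL REGION", "CR")


def feature_length(feature: MitoFeature, genome_length: int) -> int:
    """Length in bp of a feature on a circle of ``genome_length``.

    ``end - start + 1`` for ordinary features; origin-spanning features
    (start > end) use ``(L - start + 1) + end``.
    """
    return feature.length(genome_length)


def spacer_to_next(genome: AnnotatedMitogenome, index: int) -> int:
    """Signed intergenic gap between feature ``index`` and the next feature.

    Computed in annotation order; the "next" of the last feature is the
    first feature, reached across the circular origin. Negative values
    indicate an overlap. A single-feature genome returns ``L - length``
    (the self-wrap gap).
    """
    feats = genome.features
    if not feats:
        raise ComputeError("no features")
    cur = feats[index]
    if len(feats) == 1:
        return genome.length - cur.length(genome.length)
    nxt = feats[(index + 1) % len(feats)]
    next_start = nxt.start
    if (index + 1) == len(feats):
        next_start += genome.length  # wrap across the origin
    cur_end = cur.end if not cur.wraps_origin else cur.end + genome.length
    return next_start - cur_end - 1


def classify_codons(cds: str) -> tuple[str, str]:
    """Start and stop codon tokens of a sense-strand CDS.

    The start codon is the first three nucleotides. The stop token depends
    on ``len(cds) mod 3``:

    * 0 — the final triplet, expected in ``{TAA, TAG}``; anything else is
      reported as ``other`` with a warning (never an exception).
    * 2 — an incomplete stop completed by polyadenylation; token ``TA-``
      when the trailing dinucleotide is ``TA``, else ``other``.
    * 1 — token ``T--`` when the trailing nucleotide is ``T``, else
      ``other``.
    """
    cds = cds.upper()
    if len(cds) < 6:
        raise ComputeError(f"degenerate CDS of {len(cds)} bp (< 6)")
    start = cds[:3]
    rem = len(cds) % 3
    if rem == 0:
        tail = cds[-3:]
        if tail in COMPLETE_STOPS:
            stop = tail
        else:
            warnings.warn(
                f"unexpected complete stop codon {tail!r}; reporting 'other'",
                stacklevel=2,
            )
            stop = "other"
    elif rem == 2:
        stop = "TA-" if cds[-2:] == "TA" else "other"
        if stop == "other":
            warnings.warn(
                f"trailing dinucleotide {cds[-2:]!r} is not an incomplete stop",
                stacklevel=2,
            )
    else:
        stop = "T--" if cds[-1] == "T" else "other"
        if stop == "other":
            warnings.warn(
                f"trailing nucleotide {cds[-1]!r} is not an incomplete stop",
                stacklevel=2,
            )
    return start, stop


@dataclass(frozen=True)
class GeneTableRow:
    """One row of the characterisation table."""

    name: str
    cls: str
    start: int
    end: int
    length: int
    start_codon: str  # empty when no sequence or not a PCG
    stop_codon: str  # token in {TAA, TAG, TA-, T--, other} or empty
    spacer_to_next: int
    strand: str
    anticodon: str | None = None


@dataclass(frozen=True)
class SpacerSummary:
    """Genome-wide overlap / intergenic-nucleotide summary."""

    n_overlaps: int
    overlap_min: int  # bp, positive magnitudes; 0 when no overlaps
    overlap_max: int
    n_ign: int
    ign_total: int
    ign_min: int
    ign_max: int


def gene_table(genome: AnnotatedMitogenome) -> list[GeneTableRow]:
    """Characterisation-table rows, one per feature in annotation order.

    Codon columns are filled for PCGs when the genome carries a sequence,
    otherwise left empty.
    """
    rows: list[GeneTableRow] = []
    for i, f in enumerate(genome.features):
        start_codon = stop_codon = ""
        if f.cls == "PCG" and genome.has_sequence:
            start_codon, stop_codon = classify_codons(feature_sequence(genome, f))
        rows.append(
            GeneTableRow(
                name=f.name,
                cls=f.cls,
                start=f.start,
                end=f.end,
                length=f.length(genome.length),
                start_codon=start_codon,
                stop_codon=stop_codon,
                spacer_to_next=spacer_to_next(genome, i),
                strand=f.strand,
                anticodon=f.anticodon,
            )
        )
    return rows


def spacer_summary(
    genome: AnnotatedMitogenome, *, count_dloop_flank: bool = False
) -> SpacerSummary:
    """Count gene overlaps and intergenic (IGN) regions around the circle.

    Overlaps are negative spacers (reported as positive magnitudes);
    IGN regions are positive spacers, excluding — unless
    ``count_dloop_flank`` — any spacer whose downstream feature is the
    control region.
    """
    feats = genome.features
    overlaps: list[int] = []
    igns: list[int] = []
    n = len(feats)
    for i in range(n):
        sp = spacer_to_next(genome, i)
        if sp < 0:
            overlaps.append(-sp)
        elif sp > 0:
            downstream = feats[(i + 1) % n]
            if (
                not count_dloop_flank
                and downstream.name.upper() in CONTROL_REGION_NAMES
            ):
                continue
            igns.append(sp)
    return SpacerSummary(
        n_overlaps=len(overlaps),
        overlap_min=min(overlaps) if overlaps else 0,
        overlap_max=max(overlaps) if overlaps else 0,
        n_ign=len(igns),
        ign_total=sum(igns),
        ign_min=min(igns) if igns else 0,
        ign_max=max(igns) if igns else 0,
    )


def gene_table_tsv(rows: list[GeneTableRow]) -> str:
    """Render gene-table rows as TSV with the standard column order."""
    header = "name\tcls\tfrom\tto\tlength\tstart_codon\tstop_codon\tanticodon\tign\tstrand"
    lines = [header]
    for r in rows:
        lines.append(
            f"{r.name}\t{r.cls}\t{r.start}\t{r.end}\t{r.length}\t"
            f"{r.start_codon}\t{r.stop_codon}\t{r.anticodon or ''}\t"
            f"{r.spacer_to_next}\t{r.strand}"
        )
    return "\n".join(lines) + "\n"
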