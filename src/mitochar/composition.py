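"""Base composition and strand-skew statistics.

Skews measure strand asymmetry of base composition:

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed on whichever strand is read, so reverse-complementing a sequence
negates both skews exactly. Ambiguity codes (N) are excluded from both the
numerators and denominators.

Two computation paths are exposed: :func:`base_composition` works from raw
counts of an actual sequence, while :func:`skew_from_percentages` applies
the formulae to already-published percentage tables (an auditing aid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from mitochar.errors import ComputeError
from mitochar.model import AnnotatedMitogenome, feature_sequence


@dataclass(frozen=True)
class CompositionSummary:
    """Base counts, percentages and skews for one sequence partition."""

    partition: str
    n: int  # unambiguous bases counted
    count_a: int
    count_c: int
    count_g: int
    count_t: int
    a_pct: float
    c_pct: float
    g_pct: float
    t_pct: float
    at_pct: float
    gc_pct: float
    at_skew: float
    gc_skew: float

    def rounded(self, ndigits: int = 2) -> "CompositionSummary":
        """Copy with percentage and skew fields rounded for reporting."""
        return CompositionSummary(
            partition=self.partition,
            n=self.n,
            count_a=self.count_a,
            count_c=self.count_c,
            count_g=self.count_g,
            count_t=self.count_t,
            a_pct=round(self.a_pct, ndigits),
            c_pct=round(self.c_pct, ndigits),
            g_pct=round(self.g_pct, ndigits),
            t_pct=round(self.t_pct, ndigits),
            at_pct=round(self.at_pct, ndigits),
            gc_pct=round(self.gc_pct, ndigits),
            at_skew=round(self.at_skew, ndigits),
            gc_skew=round(self.gc_skew, ndigits),
        )


def base_composition(seq: str, partition: str = "") -> CompositionSummary:
    """Composition summary of a nucleotide string.

    Counts are over {A, C, G, T}; N and other ambiguity codes are excluded
    entirely. Skews are computed from the raw counts, never from rounded
    percentages.
    """
    if not seq:
        raise ComputeError("empty sequence has no composition")
    s = seq.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    n = a + c + g + t
    if n == 0:
        raise ComputeError("sequence contains no unambiguous A/C/G/T bases")
    if a + t == 0 or g + c == 0:
        raise ComputeError("skew undefined: A+T or G+C count is zero")
    return CompositionSummary(
        partition=partition,
        n=n,
        count_a=a,
        count_c=c,
        count_g=g,
        count_t=t,
        a_pct=100.0 * a / n,
        c_pct=100.0 * c / n,
        g_pct=100.0 * g / n,
        t_pct=100.0 * t / n,
        at_pct=100.0 * (a + t) / n,
        gc_pct=100.0 * (g + c) / n,
        at_skew=(a - t) / (a + t),
        gc_skew=(g - c) / (g + c),
    )


def skew_from_percentages(
    a: float, t: float, c: float, g: float, ndigits: int | None = 2
) -> tuple[float, float]:
    """AT- and GC-skew from published percentage values.

    Applies the skew formulae directly to the given percentages — the
    auditing path for checking printed composition tables. Rounds to
    ``ndigits`` (default 2, typical table precision); pass ``None`` for
    full precision.
    """
    if min(a, t, c, g) < 0:
        raise ComputeError("percentages must be non-negative")
    if a + t == 0:
        raise ComputeError("AT-skew undefined: A + T == 0")
    if g + c == 0:
        raise ComputeError("GC-skew undefined: G + C == 0")
    at = (a - t) / (a + t)
    gc = (g - c) / (g + c)
    if ndigits is not None:
        at, gc = round(at, ndigits), round(gc, ndigits)
    return at, gc


def partition_composition(
    genome: AnnotatedMitogenome, ndigits: int | None = None
) -> list[CompositionSummary]:
    """Composition table over the standard mitogenome partitions.

    One row per protein-coding gene on its SENSE strand (an L-strand gene
    is read on its own coding strand, which flips its skews relative to the
    heavy strand), then concatenated partitions in annotation order:
    ``rRNAs``, ``tRNAs``, ``D-LOOP``, ``PCGs`` (sense strands), and
    ``Total`` (the heavy strand of the whole circle). Partitions with no
    members are omitted with a warning.
    """
    if not genome.has_sequence:
        raise ComputeError("genome carries no sequence; composition unavailable")
    rows: list[CompositionSummary] = []
    pcg_parts: list[str] = []
    rrna_parts: list[str] = []
    trna_parts: list[str] = []
    dloop_parts: list[str] = []
    for f in genome.features:
        sense = feature_sequence(genome, f)
        if f.cls == "PCG":
            rows.append(base_composition(sense, f.name))
            pcg_parts.append(sense)
        elif f.cls == "rRNA":
            rrna_parts.append(sense)
        elif f.cls == "tRNA":
            trna_parts.append(sense)
        elif f.name.upper() in ("D-LOOP", "CONTROL REGION", "CR"):
            dloop_parts.append(sense)
    for label, parts in (
        ("rRNAs", rrna_parts),
        ("tRNAs", trna_parts),
        ("D-LOOP", dloop_parts),
        ("PCGs", pcg_parts),
    ):
        if parts:
            rows.append(base_composition("".join(parts), label))
        else:
            warnings.warn(f"partition {label!r} has no members; row omitted", stacklevel=2)
    rows.append(base_composition(genome.seq, "Total"))
    if ndigits is not None:
        rows = [r.rounded(ndigits) for r in rows]
    return rows


def composition_tsv(rows: list[CompositionSummary], ndigits: int = 2) -> str:
    """Render composition rows as TSV in the conventional column order."""
    header = "partition\tsize_bp\tT%\tC%\tA%\tG%\tA+T%\tC+G%\tAT-skew\tGC-skew"
    lines = [header]
    for r in rows:
        rr = r.rounded(ndigits)
        lines.append(
            f"{rr.partition}\t{rr.n}\t{rr.t_pct}\t{rr.c_pct}\t{rr.a_pct}\t{rr.g_pct}\t"
            f"{rr.at_pct}\t{rr.gc_pct}\t{rr.at_skew:.{ndigits}f}\t{rr.gc_skew:.{ndigits}f}"
        )
    return "\n".join(lines) + "\n"
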