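"""Ka/Ks estimation by the Nei–Gojobori (1986) pathway-counting method.

For each codon, every possible single-nucleotide mutation is classified as
synonymous or nonsynonymous under the genetic code; mutations that would
create a stop codon are excluded from the site denominator. Summing the
per-position synonymous fractions gives the synonymous site count S of the
codon, with N = 3 − S, so S + N = 3 × (number of codons) exactly.

For a codon pair differing at d positions, the d! orderings in which the
single-nucleotide changes could have occurred are enumerated; pathways
passing through a stop codon are excluded and the synonymous/nonsynonymous
step classification is averaged over the remaining pathways with equal
weights. Proportions pS = Sd/S and pN = Nd/N (sites averaged over the two
sequences) are corrected for multiple hits with the Jukes–Cantor formula

    d = -(3/4) * ln(1 - 4p/3)

which is undefined for p >= 3/4 (saturation).

Aggregation over an alignment uses the ratio of mean distances — mean
pairwise Ka over mean pairwise Ks — which avoids the division blow-ups a
mean of per-pair ratios suffers when some pairwise Ks is near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations

from Bio.Data import CodonTable

from mitochar.errors import ComputeError, FormatError

_BASES = "ACGT"


def _stops(code_id: int) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[code_id].stop_codons)


def _aa(code_id: int) -> dict[str, str]:
    return CodonTable.unambiguous_dna_by_id[code_id].forward_table


# Per-codon site counts and per-codon-pair difference counts are pure
# functions of the genetic code; memoise them process-wide.
_SITES_CACHE: dict[tuple[int, str], tuple[float, float]] = {}
_DIFF_CACHE: dict[tuple[int, str, str], tuple[float, float] | None] = {}


def ng86_sites(codon: str, code_id: int = 2) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    At each of the three positions, the fraction of possible point
    mutations that are synonymous is computed over the mutations that do
    not create a stop codon; the synonymous site count is the sum of the
    three fractions and the nonsynonymous count is its complement to 3.
    """
    codon = codon.upper().replace("U", "T")
    key = (code_id, codon)
    if key in _SITES_CACHE:
        return _SITES_CACHE[key]
    if len(codon) != 3 or set(codon) - set(_BASES):
        raise ComputeError(f"not an unambiguous codon: {codon!r}")
    stops = _stops(code_id)
    if codon in stops:
        raise ComputeError(f"stop codon {codon!r} has no site decomposition")
    aa = _aa(code_id)
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in stops:
                continue
            n_valid += 1
            if aa[mutant] == aa[codon]:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    result = (syn, 3.0 - syn)
    _SITES_CACHE[key] = result
    return result


def _pathway_diffs(a: str, b: str, code_id: int) -> tuple[float, float] | None:
    """Mean (synonymous, nonsynonymous) differences between two sense codons.

    Averages the step classification over all orderings of the single-site
    changes, excluding pathways that pass through a stop codon. Returns
    ``None`` when every pathway is blocked.
    """
    key = (code_id, a, b) if a <= b else (code_id, b, a)
    if key in _DIFF_CACHE:
        return _DIFF_CACHE[key]
    stops = _stops(code_id)
    aa = _aa(code_id)
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        result: tuple[float, float] | None = (0.0, 0.0)
    else:
        syn_total = 0.0
        non_total = 0.0
        n_paths = 0
        for order in permutations(diff_pos):
            cur = a
            path_syn = 0
            path_non = 0
            blocked = False
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if nxt in stops:
                    blocked = True
                    break
                if aa[nxt] == aa[cur]:
                    path_syn += 1
                else:
                    path_non += 1
                cur = nxt
            if not blocked:
                syn_total += path_syn
                non_total += path_non
                n_paths += 1
        result = None if n_paths == 0 else (syn_total / n_paths, non_total / n_paths)
    _DIFF_CACHE[key] = result
    return result


def jukes_cantor(p: float) -> float | None:
    """Jukes–Cantor multiple-hit correction; ``None`` when saturated (p >= 3/4)."""
    if p < 0:
        raise ComputeError(f"proportion must be >= 0, got {p}")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    """Nei–Gojobori pairwise (or aggregated) Ka/Ks estimate.

    ``ratio`` is ``None`` when undefined (Ks = 0 or a saturated correction);
    infinities are never reported.
    """

    S: float  # synonymous sites (averaged over the two sequences)
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    n_codons: int  # codon pairs compared
    n_skipped: int = 0  # codon pairs skipped (gaps, ambiguity, stops, blocked)

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def ng86_pairwise(seq_a: str, seq_b: str, code_id: int = 2) -> KaKsResult:
    """Pairwise Ka/Ks between two equal-length, in-frame coding sequences.

    Codon pairs containing gaps or ambiguity codes in either sequence are
    skipped, as are pairs involving a stop codon (e.g. an untrimmed
    terminal stop) and pairs whose every mutational pathway is blocked by
    stops. The result is symmetric in its two arguments.
    """
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise FormatError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise FormatError(f"length {len(a)} is not a multiple of 3")
    stops = _stops(code_id)
    s_sites_a = s_sites_b = 0.0
    sd = nd = 0.0
    n_codons = 0
    n_skipped = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if (set(ca) | set(cb)) - set(_BASES):
            n_skipped += 1
            continue
        if ca in stops or cb in stops:
            n_skipped += 1
            continue
        diffs = _pathway_diffs(ca, cb, code_id)
        if diffs is None:
            n_skipped += 1
            continue
        sa, _ = ng86_sites(ca, code_id)
        sb, _ = ng86_sites(cb, code_id)
        s_sites_a += sa
        s_sites_b += sb
        sd += diffs[0]
        nd += diffs[1]
        n_codons += 1
    if n_codons == 0:
        raise ComputeError("no comparable codons between the two sequences")
    S = (s_sites_a + s_sites_b) / 2.0
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(
        S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
        ratio=ratio, n_codons=n_codons, n_skipped=n_skipped,
    )


@dataclass
class CodonAlignment:
    """A per-gene codon alignment: equal-length sense-strand rows."""

    gene: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise FormatError("taxa and rows differ in number")
        if len({len(r) for r in self.rows}) > 1:
            raise FormatError(f"{self.gene}: alignment rows differ in length")
        if self.rows and len(self.rows[0]) % 3:
            raise FormatError(f"{self.gene}: alignment length not a multiple of 3")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0


@dataclass
class GeneKaKs:
    """Aggregated Ka/Ks over all sequence pairs of one gene alignment."""

    gene: str
    n_taxa: int
    n_pairs: int
    n_undefined_pairs: int  # pairs excluded for saturated corrections
    ka: float
    ks: float
    ratio: float | None
    pairs: list[tuple[str, str, KaKsResult]] = field(repr=False, default_factory=list)


def gene_kaks(alignment: CodonAlignment, code_id: int = 2) -> GeneKaKs:
    """Aggregate Ka/Ks for one gene across all unordered taxon pairs.

    Aggregate Ka (Ks) is the mean pairwise Ka (Ks) over pairs whose
    Jukes–Cantor corrections are defined; the aggregate ratio is
    mean-Ka / mean-Ks, ``None`` when mean Ks is zero (e.g. an alignment of
    identical sequences).
    """
    if alignment.n_taxa < 2:
        raise ComputeError(f"{alignment.gene}: need >= 2 taxa")
    pairs: list[tuple[str, str, KaKsResult]] = []
    kas: list[float] = []
    kss: list[float] = []
    n_undef = 0
    for (ta, ra), (tb, rb) in combinations(zip(alignment.taxa, alignment.rows), 2):
        res = ng86_pairwise(ra, rb, code_id)
        pairs.append((ta, tb, res))
        if res.Ka is None or res.Ks is None:
            n_undef += 1
            continue
        kas.append(res.Ka)
        kss.append(res.Ks)
    if not kas:
        raise ComputeError(f"{alignment.gene}: every pair saturated; no aggregate")
    ka = sum(kas) / len(kas)
    ks = sum(kss) / len(kss)
    ratio = ka / ks if ks > 0 else None
    return GeneKaKs(
        gene=alignment.gene,
        n_taxa=alignment.n_taxa,
        n_pairs=len(pairs),
        n_undefined_pairs=n_undef,
        ka=ka,
        ks=ks,
        ratio=ratio,
        pairs=pairs,
    )


def read_codon_alignment(fasta_path, gene: str | None = None) -> CodonAlignment:
    """Read a codon alignment from FASTA; the gene name defaults to the
    file stem."""
    from pathlib import Path

    from Bio import SeqIO

    path = Path(fasta_path)
    taxa: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not taxa:
        raise FormatError(f"{path}: no sequences")
    return CodonAlignment(gene=gene or path.stem, taxa=taxa, rows=rows)


def kaks_table_tsv(results: list[GeneKaKs], ndigits: int = 4) -> str:
    """Per-gene Ka/Ks table, sorted by ratio descending, undefined last."""
    defined = [r for r in results if r.ratio is not None]
    undefined = [r for r in results if r.ratio is None]
    ordered = sorted(defined, key=lambda r: -r.ratio) + undefined
    lines = ["gene\tn_taxa\tn_pairs\tka\tks\tka_ks"]
    for r in ordered:
        ratio = "NA" if r.ratio is None else f"{round(r.ratio, ndigits)}"
        lines.append(
            f"{r.gene}\t{r.n_taxa}\t{r.n_pairs}\t"
            f"{round(r.ka, ndigits)}\t{round(r.ks, ndigits)}\t{ratio}"
        )
    return "\n".join(lines) + "\n"
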