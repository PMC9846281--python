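"""Domain types and I/O for annotated circular mitochondrial genomes.

Coordinates are 1-based and inclusive on both ends, the GenBank convention.
A feature wrapping across the circular origin is stored with ``start > end``;
its length is ``(L - start + 1) + end`` for a genome of length ``L``.

Strands are labelled H (heavy, the published reference strand) and L
(light); they map to GenBank ``+`` / ``-``. Sequence-returning operations
always orient to the feature's sense (coding) strand.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO

from mitochar.errors import CoordinateError, FormatError

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "noncoding")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Normalisation of common mitochondrial gene-name synonyms to the canonical
#: spelling used throughout this package. User-extensible: pass ``extra``
#: mappings to the readers. Unknown names pass through unchanged.
GENE_NAME_SYNONYMS: dict[str, str] = {
    "COI": "COX1",
    "COII": "COX2",
    "COIII": "COX3",
    "COXI": "COX1",
    "COXII": "COX2",
    "COXIII": "COX3",
    "CO1": "COX1",
    "CO2": "COX2",
    "CO3": "COX3",
    "MT-CO1": "COX1",
    "MT-CO2": "COX2",
    "MT-CO3": "COX3",
    "CYTB": "CYTB",
    "COB": "CYTB",
    "CYB": "CYTB",
    "MT-CYB": "CYTB",
    "ATPASE6": "ATP6",
    "ATPASE8": "ATP8",
    "ATP SYNTHASE F0 SUBUNIT 6": "ATP6",
    "ATP SYNTHASE F0 SUBUNIT 8": "ATP8",
    "NAD1": "ND1",
    "NAD2": "ND2",
    "NAD3": "ND3",
    "NAD4": "ND4",
    "NAD4L": "ND4L",
    "NAD5": "ND5",
    "NAD6": "ND6",
    "RRNS": "12S-rRNA",
    "RRNL": "16S-rRNA",
    "12S RIBOSOMAL RNA": "12S-rRNA",
    "16S RIBOSOMAL RNA": "16S-rRNA",
    "S-RRNA": "12S-rRNA",
    "L-RRNA": "16S-rRNA",
    "D-LOOP": "D-LOOP",
    "CONTROL REGION": "D-LOOP",
}


def normalize_gene_name(name: str, extra: dict[str, str] | None = None) -> str:
    """Map a gene-name synonym to its canonical spelling.

    Lookup is case-insensitive; unknown names are returned unchanged
    (whitespace-stripped).
    """
    key = name.strip().upper()
    if extra:
        extra_upper = {k.upper(): v for k, v in extra.items()}
        if key in extra_upper:
            return extra_upper[key]
    return GENE_NAME_SYNONYMS.get(key, name.strip())


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MitoFeature:
    """One annotated gene or region on the circular genome.

    Parameters
    ----------
    name : str
        Feature identifier, e.g. ``"ND1"``, ``"tRNA-Ile"``, ``"D-LOOP"``.
    cls : str
        One of ``PCG``, ``tRNA``, ``rRNA``, ``noncoding``.
    start, end : int
        1-based inclusive coordinates. ``start > end`` marks a feature
        spanning the circular origin.
    strand : str
        ``"H"`` or ``"L"``.
    anticodon : str or None
        Three-letter anticodon (tRNA features only).
    """

    name: str
    cls: str
    start: int
    end: int
    strand: str
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.cls not in FEATURE_CLASSES:
            raise FormatError(
                f"unknown feature class {self.cls!r} for {self.name!r}; "
                f"expected one of {FEATURE_CLASSES}"
            )
        if self.strand not in ("H", "L"):
            raise FormatError(
                f"strand must be 'H' or 'L', got {self.strand!r} for {self.name!r}"
            )
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"coordinates must be >= 1, got {self.start}..{self.end} "
                f"for {self.name!r}"
            )

    @property
    def wraps_origin(self) -> bool:
        """True when the feature spans the circular origin (start > end)."""
        return self.start > self.end

    def length(self, genome_length: int) -> int:
        """Feature length in bp on a circle of ``genome_length``."""
        if self.end > genome_length or self.start > genome_length:
            raise CoordinateError(
                f"{self.name!r} at {self.start}..{self.end} exceeds genome "
                f"length {genome_length}"
            )
        if self.wraps_origin:
            return (genome_length - self.start + 1) + self.end
        return self.end - self.start + 1


@dataclass
class AnnotatedMitogenome:
    """A circular mitogenome: heavy-strand sequence plus ordered features.

    The feature list order is the annotation order and is preserved exactly
    as read — intergenic-spacer arithmetic depends on it. ``seq`` may be
    ``None`` when only a feature table was supplied; coordinate-based
    operations remain available but sequence operations raise.
    """

    length: int
    features: list[MitoFeature] = field(default_factory=list)
    seq: str | None = None
    circular: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.seq is not None:
            self.seq = self.seq.upper()
            if len(self.seq) != self.length:
                raise FormatError(
                    f"declared length {self.length} != sequence length {len(self.seq)}"
                )
            bad = set(self.seq) - set("ACGTN")
            if bad:
                raise FormatError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
        if self.length < 1:
            raise FormatError("genome length must be >= 1")
        for f in self.features:
            if f.start > self.length or f.end > self.length:
                raise CoordinateError(
                    f"feature {f.name!r} at {f.start}..{f.end} exceeds genome "
                    f"length {self.length}"
                )

    @property
    def has_sequence(self) -> bool:
        return self.seq is not None

    def features_of_class(self, cls: str) -> list[MitoFeature]:
        return [f for f in self.features if f.cls == cls]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in FEATURE_CLASSES}
        for f in self.features:
            counts[f.cls] += 1
        return counts


def feature_sequence(genome: AnnotatedMitogenome, feature: MitoFeature) -> str:
    """Sense-strand sequence of ``feature``.

    H-strand features return ``seq[start..end]`` directly; L-strand features
    return the reverse complement of that range. Ranges wrapping the origin
    concatenate tail + head before orienting.
    """
    if genome.seq is None:
        raise FormatError("genome carries no sequence; sequence operations unavailable")
    if feature.start > genome.length or feature.end > genome.length:
        raise CoordinateError(
            f"feature {feature.name!r} at {feature.start}..{feature.end} exceeds "
            f"genome length {genome.length}"
        )
    if feature.wraps_origin:
        raw = genome.seq[feature.start - 1 :] + genome.seq[: feature.end]
    else:
        raw = genome.seq[feature.start - 1 : feature.end]
    return reverse_complement(raw) if feature.strand == "L" else raw


# ---------------------------------------------------------------------------
# Feature-table TSV I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ("name", "cls", "from", "to", "strand", "anticodon")


def read_feature_table(
    table_path,
    fasta_path=None,
    *,
    name_synonyms: dict[str, str] | None = None,
) -> AnnotatedMitogenome:
    """Read a plain-TSV feature table, optionally with a FASTA sequence.

    The TSV must have a header line ``name cls from to strand anticodon``
    (anticodon column optional). Without a FASTA the genome length is taken
    as the maximum ``to`` coordinate and only coordinate-based operations
    are permitted.
    """
    with open(table_path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{table_path}: empty feature table (missing header)")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    for col in _TABLE_COLUMNS[:5]:
        if col not in header:
            raise FormatError(f"{table_path}: missing required column {col!r}")
    idx = {col: header.index(col) for col in header}

    seq = None
    if fasta_path is not None:
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
        if len(records) != 1:
            raise FormatError(
                f"{fasta_path}: expected exactly one sequence, found {len(records)}"
            )
        seq = str(records[0].seq).upper()

    features: list[MitoFeature] = []
    seen: set[str] = set()
    for ln_no, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")

        def cell(col: str) -> str:
            i = idx.get(col)
            return parts[i].strip() if i is not None and i < len(parts) else ""

        name = normalize_gene_name(cell("name"), name_synonyms)
        cls = cell("cls")
        try:
            start = int(cell("from").replace(",", ""))
            end = int(cell("to").replace(",", ""))
        except ValueError as exc:
            raise FormatError(
                f"{table_path}:{ln_no}: non-integer coordinate in {line!r}"
            ) from exc
        anticodon = cell("anticodon") or None
        if name in seen:
            warnings.warn(f"duplicate feature name {name!r} (line {ln_no})", stacklevel=2)
        seen.add(name)
        features.append(
            MitoFeature(name=name, cls=cls, start=start, end=end,
                        strand=cell("strand"), anticodon=anticodon)
        )

    if seq is not None:
        length = len(seq)
    elif features:
        length = max(max(f.start, f.end) for f in features)
    else:
        raise FormatError(f"{table_path}: no features and no sequence — length unknown")
    return AnnotatedMitogenome(length=length, features=features, seq=seq)


def write_feature_table(genome: AnnotatedMitogenome, table_path, fasta_path=None) -> None:
    """Write the feature table as TSV (and optionally the sequence as FASTA)."""
    with open(table_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for f in genome.features:
            fh.write(
                f"{f.name}\t{f.cls}\t{f.start}\t{f.end}\t{f.strand}\t{f.anticodon or ''}\n"
            )
    if fasta_path is not None:
        if genome.seq is None:
            raise FormatError("genome carries no sequence to write")
        with open(fasta_path, "w", encoding="utf-8") as fh:
            fh.write(f">{genome.name or 'mitogenome'}\n")
            for i in range(0, len(genome.seq), 70):
                fh.write(genome.seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# GenBank flat-file reading
# ---------------------------------------------------------------------------

_GENBANK_CLS_BY_KEY = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "noncoding",
    "misc_feature": "noncoding",
}


def _genbank_feature_name(feat) -> str:
    for qual in ("gene", "product", "note"):
        if qual in feat.qualifiers:
            return str(feat.qualifiers[qual][0])
    return feat.type


def read_genbank(
    path, *, name_synonyms: dict[str, str] | None = None
) -> AnnotatedMitogenome:
    """Read an annotated mitogenome from a GenBank flat file.

    Features are kept in file order. ``complement`` locations map to strand
    L; compound (join) locations across the origin are stored with
    ``start > end``. ``gene`` features are used only as a fallback when no
    typed feature (CDS/tRNA/rRNA) covers the same locus.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: not a readable GenBank record ({exc})") from exc
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise FormatError(f"{path}: GenBank record carries no usable sequence")
    length = len(seq)

    features: list[MitoFeature] = []
    for feat in record.features:
        if feat.type not in _GENBANK_CLS_BY_KEY:
            continue
        cls = _GENBANK_CLS_BY_KEY[feat.type]
        name = normalize_gene_name(_genbank_feature_name(feat), name_synonyms)
        parts = feat.location.parts
        # Biopython locations are 0-based half-open; convert to 1-based inclusive.
        starts = [int(p.start) + 1 for p in parts]
        ends = [int(p.end) for p in parts]
        if len(parts) == 1:
            start, end = starts[0], ends[0]
        else:
            # join across the origin: the part touching the genome end comes
            # first on the sense strand; store as a wrap (start > end).
            start = starts[0]
            end = ends[-1]
            if not (ends[0] == length or starts[-1] == 1 or start > end):
                raise FormatError(
                    f"{path}: compound location for {name!r} is not an "
                    f"origin-spanning join"
                )
        if end > length or start > length:
            raise CoordinateError(
                f"{path}: feature {name!r} at {start}..{end} exceeds sequence "
                f"length {length}"
            )
        strand = "L" if feat.location.strand == -1 else "H"
        anticodon = None
        if cls == "tRNA" and "anticodon" in feat.qualifiers:
            qual = str(feat.qualifiers["anticodon"][0])
            m = re.search(r"seq\s*:\s*([ACGTUacgtu]{3})", qual)
            token = m.group(1) if m else qual.strip("() ")
            if len(token) == 3:
                anticodon = token.upper().replace("U", "T")
        features.append(
            MitoFeature(name=name, cls=cls, start=start, end=end,
                        strand=strand, anticodon=anticodon)
        )
    return AnnotatedMitogenome(
        length=length, features=features, seq=seq, name=record.id or ""
    )


def bundled_gene_table() -> AnnotatedMitogenome:
    """The packaged Rectoris luxiensis gene table (coordinates only).

    Transcribed from the published annotation of GenBank record OP132373:
    39 features — 13 protein-coding genes, 22 tRNAs, 2 rRNAs, a 32-bp
    non-coding region and the control region — on a 16,592 bp circle.
    No sequence is bundled, so only coordinate arithmetic is available.
    """
    from importlib.resources import files

    path = files("mitochar.data").joinpath("rectoris_luxiensis_genes.tsv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicated tRNA-Leu/tRNA-Ser names
        genome = read_feature_table(io_path(path))
    genome.name = "Rectoris_luxiensis_OP132373"
    return genome


def io_path(resource) -> str:
    """Materialise an importlib.resources path object to a filesystem path."""
    return str(resource)
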