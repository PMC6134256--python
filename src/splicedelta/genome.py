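"""Transcript models, splice sites, and the signed offset coordinate system.

A splice site is the exon/intron junction itself, represented as a genomic
*cut point*: the junction lies between base ``boundary - 1`` and base
``boundary`` (0-based). Offsets around a site are signed, 1-based and have no
zero, following the field's convention: for a donor (5' splice site) the last
exonic base is -1 and the first intronic base is +1; for an acceptor
(3' splice site) the last intronic base is -1 and the first exonic base is +1.
The analysis region around a site defaults to -10..+20 for donors and
-20..+10 for acceptors (exonic/intronic spans of 10/20).

All sequence is handled on the transcription strand: minus-strand windows and
core dinucleotides are reverse-complemented so scorer matrices (which are
strand-specific) always see donor/acceptor motifs in their canonical
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TranscriptModel",
    "SpliceSite",
    "RegionPosition",
    "RegionConfig",
    "TranscriptParseError",
    "ReferenceBoundsError",
    "fetch_seq",
    "reverse_complement",
    "load_transcript_models",
    "extract_splice_sites",
    "relative_position",
    "nearest_site",
    "window_offsets",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

CANONICAL_DONOR_CORES = ("GT",)
CANONICAL_ACCEPTOR_CORES = ("AG",)


class TranscriptParseError(ValueError):
    """Raised when a transcript annotation violates the model invariants."""


class ReferenceBoundsError(IndexError):
    """Raised when a requested interval falls outside the reference."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_seq(ref, chrom: str, start: int, end: int) -> str:
    """Fetch ``[start, end)`` (0-based) from a reference.

    Accepts a plain mapping of chromosome name to sequence string, a
    :class:`pyfaidx.Fasta`, or any object with a samtools-style
    ``fetch(chrom, start, end)`` method.
    """
    if start < 0:
        raise ReferenceBoundsError(f"negative start {start} on {chrom}")
    if hasattr(ref, "fetch"):  # pysam.FastaFile
        seq = ref.fetch(chrom, start, end)
    else:
        try:
            record = ref[chrom]
        except KeyError as exc:
            raise ReferenceBoundsError(f"unknown chromosome {chrom!r}") from exc
        chunk = record[start:end]
        seq = chunk if isinstance(chunk, str) else chunk.seq  # pyfaidx FastaRecord
    seq = str(seq).upper()
    if len(seq) != end - start:
        raise ReferenceBoundsError(
            f"interval {chrom}:{start}-{end} extends past the end of the reference"
        )
    return seq


def _chrom_length(ref, chrom: str) -> int | None:
    try:
        record = ref[chrom]
    except (KeyError, TypeError, NotImplementedError):
        return None
    try:
        return len(record)
    except TypeError:
        return None


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered run of exons on one strand.

    ``exons`` are 0-based half-open genomic intervals listed in transcription
    order: ascending genomic coordinates on ``+``, descending on ``-``.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise TranscriptParseError(f"{self.id}: strand must be '+' or '-'")
        if not self.exons:
            raise TranscriptParseError(f"{self.id}: transcript has no exons")
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        object.__setattr__(self, "exons", exons)
        for start, end in exons:
            if end - start < 1 or start < 0:
                raise TranscriptParseError(f"{self.id}: invalid exon interval ({start}, {end})")
        genomic = sorted(exons)
        for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise TranscriptParseError(f"{self.id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if exons != tuple(expected):
            raise TranscriptParseError(
                f"{self.id}: exons not in transcription order for strand {self.strand}"
            )

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass(frozen=True)
class SpliceSite:
    """A donor or acceptor exon/intron junction on a transcript."""

    transcript_id: str
    chrom: str
    strand: str
    kind: str  # "donor" | "acceptor"
    boundary: int  # genomic cut point: junction between boundary-1 and boundary
    intron_index: int
    core_dinucleotide: str = ""

    def __post_init__(self):
        if self.kind not in ("donor", "acceptor"):
            raise ValueError(f"unknown site kind {self.kind!r}")

    @property
    def canonical(self) -> bool:
        cores = CANONICAL_DONOR_CORES if self.kind == "donor" else CANONICAL_ACCEPTOR_CORES
        return self.core_dinucleotide in cores

    def offset_to_genomic(self, offset: int) -> int:
        """Genomic 0-based position of a signed 1-based offset (no zero)."""
        if offset == 0:
            raise ValueError("offset 0 is not used")
        if self.strand == "+":
            return self.boundary + offset - 1 if offset > 0 else self.boundary + offset
        return self.boundary - offset if offset > 0 else self.boundary - offset - 1

    def genomic_to_offset(self, pos: int) -> int:
        """Signed offset of a genomic position relative to the cut point."""
        if self.strand == "+":
            return pos - self.boundary + 1 if pos >= self.boundary else pos - self.boundary
        return self.boundary - pos if pos < self.boundary else self.boundary - pos - 1

    def side_of(self, offset: int) -> str:
        if self.kind == "donor":
            return "intronic" if offset > 0 else "exonic"
        return "exonic" if offset > 0 else "intronic"

    @property
    def core_offsets(self) -> tuple[int, int]:
        """Offsets holding the near-invariant core dinucleotide (GT / AG)."""
        return (1, 2) if self.kind == "donor" else (-2, -1)


@dataclass(frozen=True)
class RegionPosition:
    """A variant position expressed in a splice site's local coordinates."""

    site_kind: str
    offset: int
    side: str

    def __post_init__(self):
        if self.offset == 0:
            raise ValueError("offset 0 is not used")

    @property
    def invariant_core(self) -> bool:
        return self.side == "intronic" and abs(self.offset) <= 2


@dataclass(frozen=True)
class RegionConfig:
    """Spans (in nt) of the analysis region flanking each site kind."""

    donor_exonic_span: int = 10
    donor_intronic_span: int = 20
    acceptor_intronic_span: int = 20
    acceptor_exonic_span: int = 10

    def __post_init__(self):
        for name in (
            "donor_exonic_span",
            "donor_intronic_span",
            "acceptor_intronic_span",
            "acceptor_exonic_span",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def bounds(self, kind: str) -> tuple[int, int]:
        """(min_offset, max_offset) of the region for a site kind."""
        if kind == "donor":
            return -self.donor_exonic_span, self.donor_intronic_span
        return -self.acceptor_intronic_span, self.acceptor_exonic_span


def window_offsets(low: int, high: int) -> tuple[int, ...]:
    """Contiguous signed offsets ``low..high`` skipping the unused 0."""
    if low >= high:
        raise ValueError("window low must be < high")
    return tuple(o for o in range(low, high + 1) if o != 0)


# ---------------------------------------------------------------------------
# annotation parsing


def load_transcript_models(path: str, format: str = "gff3") -> list[TranscriptModel]:
    """Load transcripts from a GFF3 (exon features grouped by Parent) or BED12 file.

    Exon order in the file is irrelevant; models are rebuilt in transcription
    order and validated against the :class:`TranscriptModel` invariants.
    """
    if format == "gff3":
        return _load_gff3(path)
    if format == "bed12":
        return _load_bed12(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _load_gff3(path: str) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent") or [exon.id or "transcript"]
        for parent in parents:
            entry = grouped.setdefault(parent, {"chrom": exon.seqid, "strand": exon.strand, "exons": []})
            if entry["chrom"] != exon.seqid or entry["strand"] != exon.strand:
                raise TranscriptParseError(f"{parent}: exons on mixed chromosomes/strands")
            entry["exons"].append((exon.start - 1, exon.end))  # GFF3 is 1-based inclusive
    return [_assemble(tid, **entry) for tid, entry in grouped.items()]


def _load_bed12(path: str) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise TranscriptParseError(f"{path}:{lineno}: BED12 requires 12 columns")
            chrom, start, _end, name, _score, strand = fields[:6]
            start = int(start)
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != len(starts) or len(sizes) != int(fields[9]):
                raise TranscriptParseError(f"{path}:{lineno}: inconsistent block columns")
            exons = [(start + off, start + off + size) for off, size in zip(starts, sizes)]
            models.append(_assemble(name, chrom, strand, exons))
    return models


def _assemble(tid: str, chrom: str, strand: str, exons: Iterable[tuple[int, int]]) -> TranscriptModel:
    ordered = sorted(exons)
    if strand == "-":
        ordered = ordered[::-1]
    return TranscriptModel(id=tid, chrom=chrom, strand=strand, exons=tuple(ordered))


# ---------------------------------------------------------------------------
# splice-site extraction and coordinate mapping


def extract_splice_sites(t: TranscriptModel, ref) -> list[SpliceSite]:
    """One donor per intron 5' end and one acceptor per intron 3' end.

    Core dinucleotides are read strand-aware from the reference; non-canonical
    cores (GC/AT donors, AC acceptors) are returned, not dropped — whether a
    site is canonical is exposed via :attr:`SpliceSite.canonical`.
    """
    length = _chrom_length(ref, t.chrom)
    if length is not None:
        for start, end in t.exons:
            if end > length:
                raise ReferenceBoundsError(f"{t.id}: exon ({start}, {end}) beyond reference end {length}")
    sites: list[SpliceSite] = []
    for i in range(t.n_introns):
        up_exon = t.exons[i]
        down_exon = t.exons[i + 1]
        if t.strand == "+":
            donor_boundary, acceptor_boundary = up_exon[1], down_exon[0]
        else:
            donor_boundary, acceptor_boundary = up_exon[0], down_exon[1]
        for kind, boundary in (("donor", donor_boundary), ("acceptor", acceptor_boundary)):
            site = SpliceSite(t.id, t.chrom, t.strand, kind, boundary, i)
            core = _read_core(site, ref)
            sites.append(
                SpliceSite(t.id, t.chrom, t.strand, kind, boundary, i, core_dinucleotide=core)
            )
    return sites


def _read_core(site: SpliceSite, ref) -> str:
    bases = []
    for off in site.core_offsets:
        g = site.offset_to_genomic(off)
        base = fetch_seq(ref, site.chrom, g, g + 1)
        bases.append(base if site.strand == "+" else base.translate(_COMPLEMENT))
    return "".join(bases)


def relative_position(
    site: SpliceSite, genomic_pos: int, config: RegionConfig | None = None
) -> RegionPosition | None:
    """Map a genomic position into the site's signed offset system.

    Returns ``None`` when the position falls outside the configured analysis
    region (out-of-region is an expected result, not an error).
    """
    config = config or RegionConfig()
    offset = site.genomic_to_offset(genomic_pos)
    lo, hi = config.bounds(site.kind)
    if not lo <= offset <= hi:
        return None
    return RegionPosition(site.kind, offset, site.side_of(offset))


def nearest_site(
    variant_pos: int,
    sites: Sequence[SpliceSite],
    config: RegionConfig | None = None,
) -> list[tuple[SpliceSite, RegionPosition]]:
    """All sites whose analysis region contains the position.

    Short exons can put one position within reach of both their acceptor and
    donor; every such hit is returned rather than arbitrating between them.
    """
    config = config or RegionConfig()
    hits = []
    for site in sites:
        pos = relative_position(site, variant_pos, config)
        if pos is not None:
            hits.append((site, pos))
    return hits
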