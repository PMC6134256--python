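"""Variant parsing, normalization, and boundary-anchored window construction.

Scoring a variant means comparing a scorer's window read from the wild-type
reference against the same window read from the mutated sequence. For
substitutions the two windows differ at exactly the substituted base. For
insertions and deletions the mutated side of the junction is re-read so the
scorer still sees a full-length window: the splice boundary itself never
moves, while sequence content shifts on whichever side (exon or intron)
carries the indel.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

from .genome import (
    ReferenceBoundsError,
    SpliceSite,
    fetch_seq,
    reverse_complement,
)

__all__ = [
    "Variant",
    "SitePairWindows",
    "VariantValidationError",
    "parse_variants",
    "normalize_variant",
    "apply_variant",
    "build_site_windows",
    "variant_flanks",
]

_VALID = frozenset("ACGT")


class VariantValidationError(ValueError):
    """Raised for records that violate the variant model contract."""


@dataclass(frozen=True)
class Variant:
    """A normalized sequence variant (0-based, ACGT alleles only)."""

    chrom: str
    pos: int  # 0-based position of the first ref base (or insertion point)
    ref: str
    alt: str
    id: str = ""
    transcript_id: str = ""

    def __post_init__(self):
        if self.ref == self.alt:
            raise VariantValidationError(f"{self._label()}: ref equals alt")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _VALID:
                raise VariantValidationError(
                    f"{self._label()}: alleles must be ACGT only (ambiguity codes rejected)"
                )
        if self.pos < 0:
            raise VariantValidationError(f"{self._label()}: negative position")

    def _label(self) -> str:
        return self.id or f"{self.chrom}:{self.pos + 1}{self.ref}>{self.alt}"

    @property
    def vclass(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if self.ref and not self.alt:
            return "deletion"
        if self.alt and not self.ref:
            return "insertion"
        if len(self.ref) > len(self.alt):
            return "deletion"
        if len(self.alt) > len(self.ref):
            return "insertion"
        return "delins"

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def end(self) -> int:
        """0-based end (exclusive) of the reference allele."""
        return self.pos + len(self.ref)


# ---------------------------------------------------------------------------
# parsing


def parse_variants(path: str, format: str = "vcf", ref=None) -> list[Variant]:
    """Parse a minimal VCF (CHROM/POS/REF/ALT, one ALT per row) or TSV.

    TSV columns: ``chrom, pos_1based, ref, alt, transcript_id`` (tab-separated,
    with header). When ``ref`` is given every record's REF allele is checked
    against the reference and mismatches raise :class:`VariantValidationError`.
    """
    if format == "vcf":
        variants = _parse_vcf(path)
    elif format == "tsv":
        variants = _parse_tsv(path)
    else:
        raise ValueError(f"unknown variant format {format!r}")
    if ref is not None:
        bad = []
        for v in variants:
            if v.ref and fetch_seq(ref, v.chrom, v.pos, v.end) != v.ref:
                bad.append(v._label())
        if bad:
            raise VariantValidationError(
                "REF allele does not match the reference for: " + ", ".join(bad)
            )
    return variants


def _parse_vcf(path: str) -> list[Variant]:
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                raise VariantValidationError(
                    f"{rec.chrom}:{rec.pos}: multi-allelic rows must be pre-split "
                    "into one ALT per row"
                )
            variants.append(
                Variant(
                    chrom=rec.chrom,
                    pos=rec.start,
                    ref=rec.ref.upper(),
                    alt=alts[0].upper(),
                    id=rec.id or "",
                )
            )
    return variants


def _parse_tsv(path: str) -> list[Variant]:
    required = {"chrom", "pos_1based", "ref", "alt"}
    variants = []
    with open(path, newline="") as fh:
        rows = [line for line in fh if not line.startswith("#")]
        reader = csv.DictReader(rows, delimiter="\t")
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise VariantValidationError(f"{path}: missing TSV columns {sorted(missing)}")
        for row in reader:
            variants.append(
                Variant(
                    chrom=row["chrom"],
                    pos=int(row["pos_1based"]) - 1,
                    ref=row["ref"].upper().replace("-", ""),
                    alt=row["alt"].upper().replace("-", ""),
                    id=row.get("variant_id", "") or "",
                    transcript_id=row.get("transcript_id", "") or "",
                )
            )
    return variants


# ---------------------------------------------------------------------------
# normalization


def normalize_variant(v: Variant, ref) -> Variant:
    """Trim shared prefix/suffix and left-align pure indels.

    Left alignment shifts an insertion/deletion leftwards while the flanking
    reference base equals the last allele base (the standard VCF-style
    normalization within homopolymer/repeat context). Idempotent.
    """
    r, a, pos = v.ref, v.alt, v.pos
    # trim common suffix, then prefix
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    while r and a and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos += 1
    # left-align pure indels
    if (not r) != (not a):
        seq = r or a
        while pos > 0:
            prev = fetch_seq(ref, v.chrom, pos - 1, pos)
            if seq[-1] != prev:
                break
            seq = prev + seq[:-1]
            pos -= 1
        if r:
            r = seq
        else:
            a = seq
    if r == a:
        raise VariantValidationError(f"{v._label()}: no-op variant after trimming")
    return replace(v, pos=pos, ref=r, alt=a)


# ---------------------------------------------------------------------------
# applying variants around a splice boundary


def apply_variant(ref, v: Variant, span: tuple[int, int], chrom: str | None = None) -> str:
    """Mutated sequence over a genomic ``span``, re-read at full span length.

    The span is re-read from its left edge after the edit: content downstream
    of an indel shifts into (or out of) the span so the returned string always
    has the span's length. A variant that does not intersect the span returns
    wild-type content unchanged.
    """
    chrom = chrom or v.chrom
    start, end = span
    if v.chrom != chrom or v.end <= start or v.pos >= end:
        return fetch_seq(ref, chrom, start, end)
    pad = len(v.ref) + len(v.alt) + 4
    ext_start = min(start, v.pos)
    ext = fetch_seq(ref, chrom, ext_start, end + pad)
    i = v.pos - ext_start
    edited = ext[:i] + v.alt + ext[i + len(v.ref) :]
    offset = start - ext_start
    out = edited[offset : offset + (end - start)]
    if len(out) < end - start:
        raise ReferenceBoundsError(
            f"span {chrom}:{start}-{end} exceeds the reference after applying {v._label()}"
        )
    return out


def variant_flanks(ref, site: SpliceSite, v: Variant, flank: int) -> tuple[str, str, str, str]:
    """(wt_up, wt_down, var_up, var_down) transcription-strand flanks at the cut.

    ``up`` runs toward the cut (offsets ..-2,-1) and ``down`` away from it
    (+1,+2..), each of length ``flank``. The cut point is held fixed: an edit
    upstream of the junction changes only the up flank, an edit downstream
    only the down flank. Edits spanning the junction are applied with the alt
    allele anchored on the genomic-left side (deterministic convention).
    """
    b = site.boundary
    pad = len(v.ref) + len(v.alt) + 4
    left = fetch_seq(ref, site.chrom, b - flank - pad, b)
    right = fetch_seq(ref, site.chrom, b, b + flank + pad)
    cut = len(left)
    combined = left + right
    origin = b - cut
    same_chrom = v.chrom == site.chrom
    if same_chrom and v.pos >= origin and v.end <= origin + len(combined):
        i = v.pos - origin
        edited = combined[:i] + v.alt + combined[i + len(v.ref) :]
        if v.end <= b:  # entirely upstream of the cut: cut index shifts with the edit
            new_cut = cut + len(v.alt) - len(v.ref)
        elif v.pos >= b:  # entirely downstream: cut index fixed
            new_cut = cut
        else:  # spans the junction: alt assigned to the left side
            n_ref_left = b - v.pos
            new_cut = cut - n_ref_left + len(v.alt)
    else:
        edited, new_cut = combined, cut
    wt_left, wt_right = combined[cut - flank : cut], combined[cut : cut + flank]
    var_left = edited[max(0, new_cut - flank) : new_cut]
    var_right = edited[new_cut : new_cut + flank]
    if len(var_left) < flank or len(var_right) < flank:
        raise ReferenceBoundsError(
            f"window around {site.chrom}:{b} exceeds the reference after applying {v._label()}"
        )
    if site.strand == "+":
        return wt_left, wt_right, var_left, var_right
    return (
        reverse_complement(wt_right),
        reverse_complement(wt_left),
        reverse_complement(var_right),
        reverse_complement(var_left),
    )


@dataclass(frozen=True)
class SitePairWindows:
    """Matched wild-type / variant scorer windows anchored at one splice site."""

    site: SpliceSite
    window_spec: tuple[int, ...]
    wt_seq: str
    var_seq: str

    @property
    def changed(self) -> bool:
        return self.wt_seq != self.var_seq


def build_site_windows(
    site: SpliceSite, v: Variant, ref, window_spec: tuple[int, ...]
) -> SitePairWindows:
    """Read the wild-type and variant windows for one scorer at one site.

    ``window_spec`` is a contiguous run of signed offsets (no zero) anchored
    at the site boundary, e.g. ``(-3,..,-1, +1,..,+6)`` for a donor 9-mer.
    """
    offsets = tuple(window_spec)
    if 0 in offsets or offsets != tuple(sorted(offsets)):
        raise ValueError("window_spec must be sorted signed offsets without 0")
    neg = [o for o in offsets if o < 0]
    posi = [o for o in offsets if o > 0]
    flank = max(len(v.ref), len(v.alt)) + max(abs(offsets[0]), offsets[-1]) + 2
    wt_up, wt_down, var_up, var_down = variant_flanks(ref, site, v, flank)

    def read(up: str, down: str) -> str:
        parts = [up[len(up) + o] for o in neg] + [down[o - 1] for o in posi]
        return "".join(parts)

    return SitePairWindows(site, offsets, read(wt_up, wt_down), read(var_up, var_down))
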