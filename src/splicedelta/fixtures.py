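"""Deterministic synthetic references, transcripts, and labeled benchmarks.

The generator plants scorer-consensus donor and acceptor windows at every
exon/intron junction of toy multi-exon genes, so every site scores exactly
100 by consensus value. Its matrix set additionally carries two *flat*
(uninformative) window columns per site kind: a substitution there moves the
consensus value by exactly 0%, giving analytic ground-truth negatives, while
substitutions in the near-invariant core or at a high-information consensus
position are guaranteed positives. Labels in the generated benchmark play
the role of unequivocal in vitro RNA outcomes; none of this simulates real
splicing biology — it provides exact, seed-reproducible ground truth for the
scoring and benchmarking machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import BenchmarkRecord
from .genome import SpliceSite, TranscriptModel, extract_splice_sites, reverse_complement
from .maxent import TrainingSet
from .pwm import BASES, MatrixLibrary, PWMatrix, default_library
from .variants import Variant

__all__ = [
    "FixtureSpec",
    "FixtureError",
    "fixture_matrix_library",
    "generate_reference",
    "generate_benchmark_variants",
    "generate_training_kmers",
    "write_fasta",
    "write_gff3",
    "write_benchmark_tsv",
    "load_benchmark_tsv",
    "FLAT_DONOR_OFFSETS",
    "FLAT_ACCEPTOR_OFFSETS",
]

#: window offsets planted with flat (0.25 each) frequency columns
FLAT_DONOR_OFFSETS = (-3, 6)
FLAT_ACCEPTOR_OFFSETS = (-14, -4)

#: high-information non-core offsets used for consensus-weakening positives
WEAKEN_DONOR_OFFSET = 5
WEAKEN_ACCEPTOR_OFFSET = -3

#: in-region offsets outside every scorer window, used as negatives
OUTSIDE_DONOR_OFFSETS = (8, 9, 10)
OUTSIDE_ACCEPTOR_OFFSETS = (-16, -17, -18)


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study; the seed pins every byte."""

    seed: int = 1
    n_genes: int = 2
    exons_per_gene: int = 3
    exon_length: tuple[int, int] = (60, 100)
    intron_length: tuple[int, int] = (40, 70)
    flank: int = 50
    n_positive: int = 20
    n_negative: int = 20
    positive_classes: tuple[str, ...] = ("core_disruption", "consensus_weakening")
    negative_classes: tuple[str, ...] = ("low_information_position", "outside_windows")

    def __post_init__(self):
        if self.n_genes < 1 or self.exons_per_gene < 2:
            raise FixtureError("need at least one gene with two exons")
        if self.n_positive < 1 or self.n_negative < 1:
            raise FixtureError("variant counts must be >= 1")
        if self.exon_length[0] < 20:
            raise FixtureError("exons must be at least 20 nt to hold scorer windows")
        if self.intron_length[0] < 25:
            raise FixtureError(
                "introns must be at least 25 nt so donor and acceptor windows do not collide"
            )


def fixture_matrix_library() -> MatrixLibrary:
    """Bundled GT/AG matrices with flat columns planted for negative slots."""
    base = default_library()
    lib = MatrixLibrary()
    for name, flats in (("donor_GT", FLAT_DONOR_OFFSETS), ("acceptor_AG", FLAT_ACCEPTOR_OFFSETS)):
        src = base[name]
        freqs = np.array(src.freqs)
        for off in flats:
            freqs[src.offset_index(off)] = 0.25
        lib.add(
            PWMatrix(
                name=f"fixture_{name}",
                site_kind=src.site_kind,
                window_spec=src.window_spec,
                freqs=freqs,
                core_positions=src.core_positions,
            )
        )
    return lib


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_dna(rng: np.random.Generator, n: int) -> list[str]:
    return [BASES[i] for i in rng.integers(0, 4, size=n)]


def generate_reference(
    spec: FixtureSpec, library: MatrixLibrary | None = None
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """One chromosome per gene with consensus splice sites planted.

    Genes alternate between the plus and minus strand (minus-strand
    chromosomes are stored reverse-complemented, exercising strand-aware
    window logic downstream). Deterministic per seed.
    """
    library = library or fixture_matrix_library()
    donor = library.for_kind("donor")[0]
    acceptor = library.for_kind("acceptor")[0]
    donor_cons, acceptor_cons = donor.consensus, acceptor.consensus
    rng = _rng(spec.seed)
    ref: dict[str, str] = {}
    models: list[TranscriptModel] = []
    for g in range(spec.n_genes):
        strand = "+" if g % 2 == 0 else "-"
        exon_lens = rng.integers(spec.exon_length[0], spec.exon_length[1] + 1, spec.exons_per_gene)
        intron_lens = rng.integers(
            spec.intron_length[0], spec.intron_length[1] + 1, spec.exons_per_gene - 1
        )
        pieces: list[int] = [spec.flank]
        for i, el in enumerate(exon_lens):
            pieces.append(int(el))
            if i < len(intron_lens):
                pieces.append(int(intron_lens[i]))
        pieces.append(spec.flank)
        total = sum(pieces)
        seq = _random_dna(rng, total)
        # exon coordinates in transcription-strand space
        tx_exons = []
        cursor = spec.flank
        for i, el in enumerate(exon_lens):
            tx_exons.append((cursor, cursor + int(el)))
            cursor += int(el)
            if i < len(intron_lens):
                cursor += int(intron_lens[i])
        # plant consensus windows at every junction
        for (s1, e1), (s2, _) in zip(tx_exons, tx_exons[1:]):
            for k, off in enumerate(donor.window_spec):  # donor window around e1
                pos = e1 + off - 1 if off > 0 else e1 + off
                seq[pos] = donor_cons[k]
            for k, off in enumerate(acceptor.window_spec):  # acceptor window around s2
                pos = s2 + off - 1 if off > 0 else s2 + off
                seq[pos] = acceptor_cons[k]
        tx_seq = "".join(seq)
        chrom = f"chr{g + 1}"
        if strand == "+":
            ref[chrom] = tx_seq
            exons = tuple(tx_exons)
        else:
            ref[chrom] = reverse_complement(tx_seq)
            exons = tuple((total - e, total - s) for s, e in tx_exons)
        models.append(TranscriptModel(id=f"tx{g + 1}", chrom=chrom, strand=strand, exons=exons))
    return ref, models


# ---------------------------------------------------------------------------
# labeled benchmark variants


def _mutate_at_offset(
    site: SpliceSite, ref: dict[str, str], offset: int, new_base: str
) -> tuple[int, str, str] | None:
    """(genomic 0-based pos, ref base, alt base) or None if base unchanged."""
    g = site.offset_to_genomic(offset)
    wt_tx = ref[site.chrom][g]
    if site.strand == "-":
        wt_tx = reverse_complement(wt_tx)
    if wt_tx == new_base:
        return None
    ref_allele, alt_allele = wt_tx, new_base
    if site.strand == "-":
        ref_allele, alt_allele = reverse_complement(ref_allele), reverse_complement(alt_allele)
    return g, ref_allele, alt_allele


def _argmin_base(matrix: PWMatrix, offset: int) -> str:
    return BASES[int(matrix.freqs[matrix.offset_index(offset)].argmin())]


def generate_benchmark_variants(
    ref: dict[str, str],
    models: list[TranscriptModel],
    spec: FixtureSpec,
    library: MatrixLibrary | None = None,
) -> tuple[list[Variant], list[BenchmarkRecord]]:
    """Labeled SNVs with construction-guaranteed outcomes.

    Positives disrupt the near-invariant core or weaken a high-information
    consensus position; negatives hit the planted flat columns (delta exactly
    0) or sit inside the analysis region but outside every scorer window.
    Raises :class:`FixtureError` when the requested counts exceed the
    available slots.
    """
    library = library or fixture_matrix_library()
    donor_m = library.for_kind("donor")[0]
    acceptor_m = library.for_kind("acceptor")[0]
    sites = [s for m in models for s in extract_splice_sites(m, ref)]
    rng = _rng(spec.seed + 1)

    def matrix_for(site: SpliceSite) -> PWMatrix:
        return donor_m if site.kind == "donor" else acceptor_m

    pos_slots: list[tuple[SpliceSite, int, str]] = []
    for site in sites:
        if "core_disruption" in spec.positive_classes:
            for off in site.core_offsets:
                pos_slots.append((site, off, "core_disruption"))
        if "consensus_weakening" in spec.positive_classes:
            off = WEAKEN_DONOR_OFFSET if site.kind == "donor" else WEAKEN_ACCEPTOR_OFFSET
            pos_slots.append((site, off, "consensus_weakening"))
    neg_slots: list[tuple[SpliceSite, int, str]] = []
    for site in sites:
        if "low_information_position" in spec.negative_classes:
            flats = FLAT_DONOR_OFFSETS if site.kind == "donor" else FLAT_ACCEPTOR_OFFSETS
            for off in flats:
                neg_slots.append((site, off, "low_information_position"))
        if "outside_windows" in spec.negative_classes:
            outs = OUTSIDE_DONOR_OFFSETS if site.kind == "donor" else OUTSIDE_ACCEPTOR_OFFSETS
            for off in outs:
                neg_slots.append((site, off, "outside_windows"))
    if len(pos_slots) < spec.n_positive or len(neg_slots) < spec.n_negative:
        raise FixtureError(
            f"requested {spec.n_positive}+{spec.n_negative} variants but only "
            f"{len(pos_slots)}+{len(neg_slots)} slots exist; add genes or exons"
        )

    variants: list[Variant] = []
    records: list[BenchmarkRecord] = []
    counter = 0

    def emit(site: SpliceSite, offset: int, vclass: str, label: bool) -> bool:
        nonlocal counter
        matrix = matrix_for(site)
        if vclass in ("core_disruption", "consensus_weakening"):
            new_base = _argmin_base(matrix, offset)
        elif vclass == "low_information_position":
            g = site.offset_to_genomic(offset)
            wt_tx = ref[site.chrom][g]
            if site.strand == "-":
                wt_tx = reverse_complement(wt_tx)
            choices = [b for b in BASES if b != wt_tx]
            new_base = choices[int(rng.integers(0, len(choices)))]
        else:  # outside_windows
            g = site.offset_to_genomic(offset)
            wt_tx = ref[site.chrom][g]
            if site.strand == "-":
                wt_tx = reverse_complement(wt_tx)
            choices = [b for b in BASES if b != wt_tx]
            new_base = choices[int(rng.integers(0, len(choices)))]
        hit = _mutate_at_offset(site, ref, offset, new_base)
        if hit is None:
            return False
        g, ref_allele, alt_allele = hit
        counter += 1
        vid = f"var{counter:03d}"
        variants.append(
            Variant(
                chrom=site.chrom,
                pos=g,
                ref=ref_allele,
                alt=alt_allele,
                id=vid,
                transcript_id=site.transcript_id,
            )
        )
        side = site.side_of(offset)
        records.append(
            BenchmarkRecord(
                variant_id=vid,
                site_kind=site.kind,
                offset=offset,
                label=label,
                invariant_core=(side == "intronic" and abs(offset) <= 2),
            )
        )
        return True

    emitted = 0
    for site, off, vclass in pos_slots:
        if emitted >= spec.n_positive:
            break
        emitted += emit(site, off, vclass, True)
    if emitted < spec.n_positive:
        raise FixtureError("could not realize the requested number of positive variants")
    emitted = 0
    for site, off, vclass in neg_slots:
        if emitted >= spec.n_negative:
            break
        emitted += emit(site, off, vclass, False)
    if emitted < spec.n_negative:
        raise FixtureError("could not realize the requested number of negative variants")
    return variants, records


def generate_training_kmers(
    matrix: PWMatrix, n: int, seed: int, decoy: str = "uniform"
) -> TrainingSet:
    """Signal k-mers sampled from the matrix product distribution; uniform decoys."""
    if n < 1:
        raise FixtureError("n must be >= 1")
    rng = _rng(seed)
    L = len(matrix)
    cum = matrix.freqs.cumsum(axis=1)
    u = rng.random((n, L))
    signal_idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    signal = ["".join(BASES[i] for i in row) for row in signal_idx]
    if decoy == "uniform":
        decoy_idx = rng.integers(0, 4, size=(n, L))
    else:
        raise FixtureError(f"unknown decoy scheme {decoy!r}")
    decoys = ["".join(BASES[i] for i in row) for row in decoy_idx]
    return TrainingSet(tuple(signal), tuple(decoys), matrix.window_spec)


# ---------------------------------------------------------------------------
# file output (plain-text standard formats)


def write_fasta(ref: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in ref:
            fh.write(f">{chrom}\n")
            seq = ref[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models: list[TranscriptModel], path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seed is not None:
            fh.write(f"# fixture-seed={seed}\n")
        for m in models:
            start = min(s for s, _ in m.exons) + 1
            end = max(e for _, e in m.exons)
            fh.write(
                f"{m.chrom}\tsplicedelta\ttranscript\t{start}\t{end}\t.\t{m.strand}\t.\tID={m.id}\n"
            )
            for s, e in sorted(m.exons):
                fh.write(
                    f"{m.chrom}\tsplicedelta\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\tParent={m.id}\n"
                )


_BENCH_COLUMNS = (
    "variant_id",
    "chrom",
    "pos_1based",
    "ref",
    "alt",
    "transcript_id",
    "site_kind",
    "offset",
    "label",
)


def write_benchmark_tsv(
    variants: list[Variant],
    records: list[BenchmarkRecord],
    path,
    seed: int | None = None,
) -> None:
    by_id = {v.id: v for v in variants}
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# fixture-seed={seed}\n")
        fh.write("\t".join(_BENCH_COLUMNS) + "\n")
        for rec in records:
            v = by_id[rec.variant_id]
            label = "splice_altering" if rec.label else "not_altering"
            fh.write(
                "\t".join(
                    [v.id, v.chrom, str(v.pos + 1), v.ref, v.alt, v.transcript_id,
                     rec.site_kind, str(rec.offset), label]
                )
                + "\n"
            )


def load_benchmark_tsv(path) -> tuple[list[Variant], list[BenchmarkRecord]]:
    import csv

    variants, records = [], []
    with open(path) as fh:
        rows = [line for line in fh if not line.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    missing = set(_BENCH_COLUMNS) - set(reader.fieldnames or [])
    if missing:
        raise FixtureError(f"{path}: missing benchmark columns {sorted(missing)}")
    for row in reader:
        offset = int(row["offset"])
        side_intronic = (row["site_kind"] == "donor") == (offset > 0)
        variants.append(
            Variant(
                chrom=row["chrom"],
                pos=int(row["pos_1based"]) - 1,
                ref=row["ref"],
                alt=row["alt"],
                id=row["variant_id"],
                transcript_id=row["transcript_id"],
            )
        )
        records.append(
            BenchmarkRecord(
                variant_id=row["variant_id"],
                site_kind=row["site_kind"],
                offset=offset,
                label=row["label"] == "splice_altering",
                invariant_core=side_intronic and abs(offset) <= 2,
            )
        )
    return variants, records
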