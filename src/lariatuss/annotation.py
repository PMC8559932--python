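"""Gene models, splice sites, and strand-aware sequence windows.

All coordinates are internally 0-based half-open; GTF I/O converts from and
to the 1-based closed convention at the file boundary.  A splice-site
*boundary* is the position of the first intronic base for a donor (5'SS) and
of the last intronic base for an acceptor (3'SS), both in internal
coordinates on the genomic (+) axis.  On the minus strand the donor of an
intron therefore sits at the genomic *right* edge of the intron.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

DONOR = "donor"
ACCEPTOR = "acceptor"

_COMPLEMENT = str.maketrans("ACGTNRYSWKMacgtnryswkm", "TGCANYRSWMKtgcanyrswmk")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware for common codes)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Malformed or internally inconsistent annotation input."""


class BoundaryError(ValueError):
    """A requested sequence window falls outside the chromosome."""


def get_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end) as an upper-case string.

    ``genome`` may be a plain mapping of chromosome name to sequence string,
    or a ``pyfaidx.Fasta`` handle (anything whose ``__getitem__`` supports
    slicing and yields objects with ``.seq`` or plain strings).
    """
    chunk = genome[chrom][start:end]
    seq = chunk.seq if hasattr(chunk, "seq") else str(chunk)
    return seq.upper()


def chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


@dataclass(frozen=True, order=True)
class SpliceSite:
    """One donor (5'SS) or acceptor (3'SS).

    Identity — and therefore deduplication across transcripts and genes —
    is (chrom, strand, boundary, kind).
    """

    chrom: str
    strand: str
    boundary: int
    kind: str  # DONOR or ACCEPTOR

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")
        if self.kind not in (DONOR, ACCEPTOR):
            raise AnnotationError(f"invalid site kind {self.kind!r}")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.strand}:{self.boundary}:{self.kind}"

    @classmethod
    def from_id(cls, site_id: str) -> "SpliceSite":
        chrom, strand, boundary, kind = site_id.rsplit(":", 3)
        return cls(chrom, strand, int(boundary), kind)


def intron_sites(chrom: str, strand: str, intron: tuple[int, int]) -> tuple[SpliceSite, SpliceSite]:
    """(donor, acceptor) of a genomic intron interval [s, e)."""
    s, e = intron
    if strand == "+":
        return (SpliceSite(chrom, strand, s, DONOR), SpliceSite(chrom, strand, e - 1, ACCEPTOR))
    return (SpliceSite(chrom, strand, e - 1, DONOR), SpliceSite(chrom, strand, s, ACCEPTOR))


@dataclass
class GeneModel:
    """A gene: a set of transcripts, each an ordered list of exon intervals.

    Exons are (start, end) 0-based half-open genomic intervals, sorted in
    genomic order and non-overlapping within a transcript.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def validate(self, chrom_len: int | None = None) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not self.transcripts:
            raise AnnotationError(f"{self.gene_id}: no transcripts")
        for tx, exons in self.transcripts.items():
            if not exons:
                raise AnnotationError(f"{self.gene_id}/{tx}: no exons")
            prev_end = None
            for s, e in exons:
                if e <= s:
                    raise AnnotationError(f"{self.gene_id}/{tx}: exon end <= start ({s}, {e})")
                if s < 0:
                    raise AnnotationError(f"{self.gene_id}/{tx}: negative coordinate")
                if chrom_len is not None and e > chrom_len:
                    raise AnnotationError(
                        f"{self.gene_id}/{tx}: exon ({s}, {e}) exceeds {self.chrom} length {chrom_len}"
                    )
                if prev_end is not None and s <= prev_end:
                    raise AnnotationError(f"{self.gene_id}/{tx}: exons overlap or unsorted")
                prev_end = e
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 - e1 < 1:
                    raise AnnotationError(f"{self.gene_id}/{tx}: intron of length < 1")

    def introns(self, tx_id: str) -> list[tuple[int, int]]:
        exons = self.transcripts[tx_id]
        return [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])]

    def all_introns(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for tx in self.transcripts:
            out.update(self.introns(tx))
        return out

    def span(self) -> tuple[int, int]:
        starts = [ex[0] for exons in self.transcripts.values() for ex in exons]
        ends = [ex[1] for exons in self.transcripts.values() for ex in exons]
        return min(starts), max(ends)


def _dedupe_transcripts(gene: GeneModel) -> None:
    seen: dict[tuple, str] = {}
    drop = []
    for tx, exons in gene.transcripts.items():
        key = tuple(exons)
        if key in seen:
            warnings.warn(
                f"{gene.gene_id}: transcript {tx} duplicates {seen[key]} (identical exon chain); collapsed"
            )
            drop.append(tx)
        else:
            seen[key] = tx
    for tx in drop:
        del gene.transcripts[tx]


def load_annotation(gtf_source, genome=None) -> list[GeneModel]:
    """Parse a GTF/GFF file of exon features into GeneModel objects.

    Exon features must carry ``gene_id`` and ``transcript_id`` attributes.
    If ``genome`` is given, exon coordinates are validated against
    chromosome lengths.
    """
    try:
        db = gffutils.create_db(
            str(gtf_source),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises several parser error types
        raise AnnotationError(f"failed to parse {gtf_source}: {exc}") from exc

    genes: dict[str, GeneModel] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        try:
            gene_id = feat.attributes["gene_id"][0]
            tx_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks {exc} attribute"
            ) from exc
        gene = genes.setdefault(gene_id, GeneModel(gene_id, feat.seqid, feat.strand))
        if feat.seqid != gene.chrom or feat.strand != gene.strand:
            raise AnnotationError(f"{gene_id}: exons on multiple chromosomes/strands")
        # GTF is 1-based closed; internal is 0-based half-open.
        gene.transcripts.setdefault(tx_id, []).append((feat.start - 1, feat.end))

    for gene in genes.values():
        for exons in gene.transcripts.values():
            exons.sort()
        chrom_len = chrom_length(genome, gene.chrom) if genome is not None else None
        gene.validate(chrom_len)
        _dedupe_transcripts(gene)
    return sorted(genes.values(), key=lambda g: (g.chrom, g.span(), g.gene_id))


def write_gtf(models: Iterable[GeneModel], path) -> None:
    """Write exon features (1-based closed) for each transcript."""
    lines = []
    for gene in models:
        for tx_id in sorted(gene.transcripts):
            for s, e in gene.transcripts[tx_id]:
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx_id}";'
                lines.append(
                    "\t".join(
                        [gene.chrom, "lariatuss", "exon", str(s + 1), str(e), ".", gene.strand, ".", attrs]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def enumerate_splice_sites(models: Iterable[GeneModel]) -> list[SpliceSite]:
    """Every distinct (chrom, strand, boundary, kind) over all introns.

    Each intron contributes exactly one donor and one acceptor; sites shared
    between transcripts (or genes) appear once.
    """
    sites: set[SpliceSite] = set()
    for gene in models:
        for intron in gene.all_introns():
            d, a = intron_sites(gene.chrom, gene.strand, intron)
            sites.add(d)
            sites.add(a)
    return sorted(sites)


def site_gene_index(models: Iterable[GeneModel]) -> dict[SpliceSite, set[str]]:
    idx: dict[SpliceSite, set[str]] = {}
    for gene in models:
        for intron in gene.all_introns():
            for site in intron_sites(gene.chrom, gene.strand, intron):
                idx.setdefault(site, set()).add(gene.gene_id)
    return idx


def fetch_window(genome, site: SpliceSite, exonic_len: int, intronic_len: int) -> str:
    """Sense-strand sequence around a splice site.

    For a donor the window reads (exonic_len exon bases)(intronic_len intron
    bases) in transcription order; for an acceptor (intronic_len intron
    bases)(exonic_len exon bases).  Minus-strand windows are
    reverse-complemented.  A window that would run off the chromosome raises
    BoundaryError — never a silent truncation.
    """
    b = site.boundary
    if site.kind == DONOR:
        if site.strand == "+":
            start, end = b - exonic_len, b + intronic_len
            rc = False
        else:
            start, end = b - intronic_len + 1, b + exonic_len + 1
            rc = True
    else:
        if site.strand == "+":
            start, end = b - intronic_len + 1, b + exonic_len + 1
            rc = False
        else:
            start, end = b - exonic_len, b + intronic_len
            rc = True
    if start < 0 or end > chrom_length(genome, site.chrom):
        raise BoundaryError(
            f"window [{start}, {end}) for {site.site_id} exceeds {site.chrom} bounds"
        )
    seq = get_seq(genome, site.chrom, start, end)
    return revcomp(seq) if rc else seq


def site_dinucleotide(genome, site: SpliceSite) -> str:
    """First two intronic bases of a donor / last two of an acceptor (sense)."""
    if site.kind == DONOR:
        return fetch_window(genome, site, 0, 2)
    return fetch_window(genome, site, 0, 2)[:2]


def is_canonical(genome, site: SpliceSite) -> bool:
    """GT at donors, AG at acceptors.  Non-canonical sites are kept, only flagged."""
    dinuc = site_dinucleotide(genome, site)
    return dinuc == ("GT" if site.kind == DONOR else "AG")


def write_sites_bed(models: Iterable[GeneModel], path) -> None:
    """BED6 export of deduplicated splice sites (name = gene_id|kind)."""
    idx = site_gene_index(models)
    lines = []
    for site in sorted(idx):
        genes = ",".join(sorted(idx[site]))
        lines.append(
            "\t".join(
                [site.chrom, str(site.boundary), str(site.boundary + 1), f"{genes}|{site.kind}", "0", site.strand]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
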