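"""Exact-match placement and annotation of collapsed small-RNA tags.

Tags are located on both strands of the genome by exact match (the reads
are error-free by the time they reach this stage; there is no mismatch or
indel model). Each tag is then categorised against an mRNA sequence screen
and a known-miRNA catalog, and its multi-mapping multiplicity across
annotated miRNA regions is recorded for downstream abundance correction.

All genomic intervals here are 1-based closed (GFF3 convention); BED output
converts to 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from urllib.parse import unquote

from Bio import SeqIO
from Bio.Seq import Seq
from pyfaidx import Fasta

from .qc import CleanTag

_SEED_LEN = 12  # k-mer seed for the placement index; also the minimum tag length

_EBOX = re.compile(r"(?=CA[ACGTN]{2}TG)")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Placement:
    """One exact genomic occurrence of a tag.

    For strand ``-`` the genome's forward-strand window
    ``[start, start+len-1]`` reverse-complements to the tag sequence.
    """

    tag_seq: str
    chrom: str
    start: int  # 1-based
    strand: str

    @property
    def end(self) -> int:
        return self.start + len(self.tag_seq) - 1


@dataclass(frozen=True)
class MirnaAnnotation:
    mirna_id: str
    chrom: str
    strand: str
    precursor_interval: tuple[int, int]
    mature_interval: tuple[int, int]
    mature_seq: str


@dataclass(frozen=True)
class TagAnnotation:
    """Category and multiplicity of one tag.

    ``multiplicity_m`` counts the tag's genomic placements that fall in an
    annotated mature-miRNA region (the M of the RPM formula); it is 0 for
    tags outside any miRNA region.
    """

    tag_seq: str
    category: str  # mRNA | known_miRNA | unannotated | unmapped
    matched_mirna_ids: tuple[str, ...]
    multiplicity_m: int


@dataclass(frozen=True)
class AnnotatedTag:
    tag: CleanTag
    annotation: TagAnnotation
    placements: tuple[Placement, ...]


class ReferenceSet:
    """Genome + mRNA screen + known-miRNA catalog.

    Parameters
    ----------
    genome : dict
        Chromosome name -> forward-strand sequence (ACGT).
    mrna_seqs : iterable of str
        Transcript sequences used as a substring screen for degraded-mRNA
        tags.
    annotations : iterable of MirnaAnnotation
        Known-miRNA precursor/mature catalog; ids must be unique.
    """

    def __init__(self, genome, mrna_seqs=(), annotations=()):
        self.genome: dict[str, str] = dict(genome)
        self.mrna_seqs: tuple[str, ...] = tuple(mrna_seqs)
        self.annotations: tuple[MirnaAnnotation, ...] = tuple(annotations)
        ids = [a.mirna_id for a in self.annotations]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate miRNA ids in annotation")
        for a in self.annotations:
            if a.chrom not in self.genome:
                raise ValueError(f"annotation on unknown chromosome {a.chrom!r}")
            if a.precursor_interval[1] > len(self.genome[a.chrom]):
                raise ValueError(f"annotation {a.mirna_id} outside chromosome bounds")
        self._index = self._build_index()

    @classmethod
    def from_files(cls, genome_fasta, mrna_fasta=None, gff3=None) -> "ReferenceSet":
        fa = Fasta(str(genome_fasta))
        genome = {name: str(fa[name][:]).upper() for name in fa.keys()}
        fa.close()
        mrna = (
            [str(r.seq).upper() for r in SeqIO.parse(str(mrna_fasta), "fasta")]
            if mrna_fasta
            else []
        )
        annotations = read_mirna_gff3(gff3, genome) if gff3 else []
        return cls(genome, mrna, annotations)

    # -- placement ---------------------------------------------------------

    def _build_index(self) -> dict[str, list[tuple[str, int]]]:
        index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - _SEED_LEN + 1):
                index.setdefault(seq[i : i + _SEED_LEN], []).append((chrom, i))
        return index

    def _occurrences(self, query: str) -> list[tuple[str, int]]:
        """All 0-based forward-strand occurrences of query, via seed-and-verify."""
        hits = []
        for chrom, i in self._index.get(query[:_SEED_LEN], ()):
            if self.genome[chrom][i : i + len(query)] == query:
                hits.append((chrom, i))
        return hits

    def place_tag(self, tag_seq: str) -> list[Placement]:
        """Every exact occurrence of the tag on either strand.

        Sorted by (chrom, start, strand); an empty list means unmapped.
        Tags shorter than the seed length (12 nt) are rejected.
        """
        if "N" in tag_seq:
            raise ValueError("tag contains ambiguous base")
        if len(tag_seq) < _SEED_LEN:
            raise ValueError(f"tag shorter than minimum seed length {_SEED_LEN}")
        hits = [
            Placement(tag_seq, chrom, i + 1, "+")
            for chrom, i in self._occurrences(tag_seq)
        ]
        rc = revcomp(tag_seq)
        hits += [
            Placement(tag_seq, chrom, i + 1, "-") for chrom, i in self._occurrences(rc)
        ]
        if tag_seq == rc:  # palindromic tag: both strands give the same window once
            hits = list(dict.fromkeys(hits))
        return sorted(hits, key=lambda p: (p.chrom, p.start, p.strand))

    # -- annotation --------------------------------------------------------

    def _mature_overlaps(self, placement: Placement, min_frac: float) -> list[str]:
        ids = []
        need = min_frac * len(placement.tag_seq)
        for a in self.annotations:
            if a.chrom != placement.chrom or a.strand != placement.strand:
                continue
            lo = max(placement.start, a.mature_interval[0])
            hi = min(placement.end, a.mature_interval[1])
            if hi - lo + 1 >= need:
                ids.append(a.mirna_id)
        return ids

    def annotate_tag(
        self, tag_seq: str, placements: list[Placement], min_frac: float = 0.9
    ) -> TagAnnotation:
        """Categorise a tag given its genomic placements.

        Order of precedence: mRNA substring match (excluded downstream),
        then known miRNA (a placement with >= ``min_frac`` of the tag inside
        a mature interval on the same strand), then unannotated (mapped but
        outside the catalog), then unmapped.
        """
        if any(tag_seq in m for m in self.mrna_seqs):
            return TagAnnotation(tag_seq, "mRNA", (), 0)
        matched: list[str] = []
        multiplicity = 0
        for p in placements:
            ids = self._mature_overlaps(p, min_frac)
            if ids:
                multiplicity += 1
                matched.extend(i for i in ids if i not in matched)
        if matched:
            return TagAnnotation(tag_seq, "known_miRNA", tuple(matched), multiplicity)
        if placements:
            return TagAnnotation(tag_seq, "unannotated", (), 0)
        return TagAnnotation(tag_seq, "unmapped", (), 0)

    def annotate_library(
        self, tags: list[CleanTag], min_frac: float = 0.9
    ) -> list[AnnotatedTag]:
        out = []
        for tag in tags:
            placements = tuple(self.place_tag(tag.insert_seq))
            ann = self.annotate_tag(tag.insert_seq, list(placements), min_frac)
            out.append(AnnotatedTag(tag, ann, placements))
        return out


def scan_ebox(seq: str) -> list[int]:
    """1-based start positions of the c-Myc E-box motif CANNTG.

    Overlapping matches are all reported; only the forward strand is
    scanned because the motif's fixed positions are reverse-complement
    symmetric (CANNTG rc-> CANNTG). Ambiguous bases match the two wildcard
    positions but never the fixed ones.
    """
    return [m.start() + 1 for m in _EBOX.finditer(seq.upper())]


# -- GFF3 / BED / TSV interchange -----------------------------------------
#
# The miRNA catalog dialect mirrors miRBase: a precursor feature of type
# miRNA_primary_transcript with an ID attribute, and a child feature of
# type miRNA with Parent pointing at it. Coordinates 1-based closed.


def read_mirna_gff3(path, genome: dict[str, str]) -> list[MirnaAnnotation]:
    precursors: dict[str, tuple[str, str, int, int]] = {}
    matures: list[tuple[str, str, str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = cols
            attr = {
                k: unquote(v)
                for k, _, v in (a.partition("=") for a in attrs.split(";") if a)
            }
            if ftype == "miRNA_primary_transcript":
                precursors[attr["ID"]] = (chrom, strand, int(start), int(end))
            elif ftype == "miRNA":
                matures.append((attr["Parent"], chrom, strand, int(start), int(end)))
    annotations = []
    for parent, chrom, strand, start, end in matures:
        if parent not in precursors:
            raise ValueError(f"mature feature with unknown Parent {parent!r}")
        pchrom, pstrand, pstart, pend = precursors[parent]
        window = genome[chrom][start - 1 : end]
        mature_seq = window if strand == "+" else revcomp(window)
        annotations.append(
            MirnaAnnotation(parent, chrom, strand, (pstart, pend), (start, end), mature_seq)
        )
    return annotations


def write_mirna_gff3(annotations, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            ps, pe = a.precursor_interval
            ms, me = a.mature_interval
            fh.write(
                f"{a.chrom}\tmirnome\tmiRNA_primary_transcript\t{ps}\t{pe}\t.\t"
                f"{a.strand}\t.\tID={a.mirna_id}\n"
            )
            fh.write(
                f"{a.chrom}\tmirnome\tmiRNA\t{ms}\t{me}\t.\t{a.strand}\t.\t"
                f"ID={a.mirna_id}_mature;Parent={a.mirna_id}\n"
            )


def write_placements_bed(annotated: list[AnnotatedTag], path) -> None:
    """BED6 (0-based half-open), name = tag sequence, score = read count."""
    with open(path, "w") as fh:
        for at in annotated:
            for p in at.placements:
                fh.write(
                    f"{p.chrom}\t{p.start - 1}\t{p.end}\t{p.tag_seq}\t"
                    f"{at.tag.count}\t{p.strand}\n"
                )


def write_annotations_tsv(annotated: list[AnnotatedTag], path) -> None:
    with open(path, "w") as fh:
        fh.write("tag_seq\tcount\tcategory\tmatched_mirna_ids\tmultiplicity_m\tplacements\n")
        for at in annotated:
            placements = ";".join(
                f"{p.chrom}:{p.start}-{p.end}:{p.strand}" for p in at.placements
            )
            fh.write(
                f"{at.tag.insert_seq}\t{at.tag.count}\t{at.annotation.category}\t"
                f"{','.join(at.annotation.matched_mirna_ids)}\t"
                f"{at.annotation.multiplicity_m}\t{placements}\n"
            )


def read_annotations_tsv(path) -> list[AnnotatedTag]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            seq, count, category, ids, mult, placements = line.rstrip("\n").split("\t")
            plist = []
            if placements:
                for token in placements.split(";"):
                    loc, strand = token.rsplit(":", 1)
                    chrom, span = loc.rsplit(":", 1)
                    start, _ = span.split("-")
                    plist.append(Placement(seq, chrom, int(start), strand))
            out.append(
                AnnotatedTag(
                    CleanTag(seq, int(count)),
                    TagAnnotation(
                        seq,
                        category,
                        tuple(i for i in ids.split(",") if i),
                        int(mult),
                    ),
                    tuple(plist),
                )
            )
    return out
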