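"""Degenerate IUPAC motif scanning of gene regulatory regions.

Promoters (default 3000 bp upstream of the annotated gene start, clipped at
contig edges) and introns (gaps between consecutive exons of a chosen
transcript) are extracted strand-aware from FASTA + GFF3 and scanned for
exact matches of degenerate nucleotide words such as the KNOX/BLH binding
sites KGACM, TGAYTGA and TGATKKGA.  Matching is exact over the IUPAC
expansion set; ``N`` in the subject sequence never matches.  Coordinates
are 0-based half-open internally and 1-based inclusive at GFF3 boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class IUPACMotif:
    """A degenerate nucleotide word, e.g. KGACM (K = G/T, M = A/C)."""

    name: str
    pattern: str
    expansion_size: int

    def expand(self) -> list[str]:
        """All concrete words the degenerate pattern denotes."""
        return ["".join(w) for w in product(*(IUPAC[s] for s in self.pattern))]

    def regex(self, reverse_complement: bool = False) -> re.Pattern:
        pat = self.pattern
        if reverse_complement:
            pat = str(Seq(pat).reverse_complement())
        return re.compile(
            "".join(f"[{IUPAC[s]}]" if len(IUPAC[s]) > 1 else IUPAC[s] for s in pat)
        )

    def __len__(self) -> int:
        return len(self.pattern)


def compile_motif(name: str, pattern: str) -> IUPACMotif:
    """Validate an IUPAC pattern and precompute its expansion size."""
    pattern = pattern.upper()
    if not pattern:
        raise ValueError("motif pattern must be non-empty")
    for sym in pattern:
        if sym not in IUPAC:
            raise ValueError(f"illegal IUPAC symbol {sym!r} in motif {name!r}")
    size = 1
    for sym in pattern:
        size *= len(IUPAC[sym])
    return IUPACMotif(name=name, pattern=pattern, expansion_size=size)


@dataclass(frozen=True)
class GenomicRegion:
    """A promoter or intron interval.

    ``start``/``end`` are 0-based half-open on the forward genome strand;
    ``sequence`` is oriented with the transcript (reverse-complemented for
    minus-strand genes).  ``ordinal`` is the 1-based intron number in
    transcript orientation, 0 for the promoter.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    kind: str  # promoter | intron
    ordinal: int
    sequence: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match interval")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence inside a region's oriented sequence."""

    motif: str
    region: GenomicRegion
    offset: int
    strand_within_region: str
    matched: str

    def forward_coords(self) -> tuple[int, int]:
        """0-based half-open interval on the forward genome strand."""
        if self.region.strand == "+":
            s = self.region.start + self.offset
        else:
            s = self.region.end - self.offset - len(self.matched)
        return s, s + len(self.matched)


def _load_genome(genome: str | Path | dict) -> dict[str, str]:
    if isinstance(genome, dict):
        return {k: str(v).upper() for k, v in genome.items()}
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(genome), "fasta")
    }


def _parse_gff3(path: str | Path) -> list[dict]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            feats.append(
                {
                    "seq_id": f[0],
                    "type": f[2],
                    "start": int(f[3]),  # 1-based inclusive
                    "end": int(f[4]),
                    "strand": f[6],
                    "id": attrs.get("ID", ""),
                    "parent": attrs.get("Parent", ""),
                }
            )
    return feats


def _find_gene(feats: list[dict], gene_id: str) -> dict:
    for f in feats:
        if f["type"] == "gene" and f["id"] == gene_id:
            return f
    raise KeyError(f"gene {gene_id!r} not found in annotation")


def _choose_transcript(
    feats: list[dict], gene_id: str, transcript_id: str | None
) -> tuple[dict, list[dict]]:
    mrnas = [f for f in feats if f["type"] == "mRNA" and f["parent"] == gene_id]
    if transcript_id is not None:
        mrnas = [m for m in mrnas if m["id"] == transcript_id]
    if not mrnas:
        raise KeyError(
            f"no transcript for gene {gene_id!r}"
            + (f" with id {transcript_id!r}" if transcript_id else "")
        )
    # primary = longest genomic span, ties by id (stable choice)
    mrna = sorted(mrnas, key=lambda m: (-(m["end"] - m["start"]), m["id"]))[0]
    exons = sorted(
        (f for f in feats if f["type"] == "exon" and f["parent"] == mrna["id"]),
        key=lambda e: e["start"],
    )
    if not exons:
        raise KeyError(f"transcript {mrna['id']!r} has no exons")
    return mrna, exons


def extract_promoter(
    genome: str | Path | dict,
    annotation: str | Path,
    gene_id: str,
    length: int = 3000,
) -> GenomicRegion:
    """The ``length`` bp immediately upstream of the annotated gene start.

    For plus-strand genes this is the forward interval ending at the gene
    start; for minus-strand genes the interval beyond the gene end,
    reverse-complemented into transcript orientation.  Clipped at contig
    boundaries.
    """
    seqs = _load_genome(genome)
    gene = _find_gene(_parse_gff3(annotation), gene_id)
    contig = seqs[gene["seq_id"]]
    if gene["strand"] == "+":
        end = gene["start"] - 1  # 0-based gene start
        start = max(0, end - length)
        seq = contig[start:end]
    else:
        start = gene["end"]  # 0-based position after gene end
        end = min(len(contig), start + length)
        seq = str(Seq(contig[start:end]).reverse_complement())
    if end - start < length:
        import logging

        logging.getLogger(__name__).warning(
            "promoter of %s clipped to %d bp at contig edge",
            gene_id, end - start,
        )
    if end - start == 0:
        raise ValueError(f"gene {gene_id!r} has no upstream sequence")
    return GenomicRegion(
        seq_id=gene["seq_id"], start=start, end=end,
        strand=gene["strand"], kind="promoter", ordinal=0, sequence=seq,
    )


def extract_introns(
    genome: str | Path | dict,
    annotation: str | Path,
    gene_id: str,
    transcript_id: str | None = None,
) -> list[GenomicRegion]:
    """Introns of the chosen transcript, numbered 5'->3' in transcript order.

    The transcript defaults to the longest mRNA of the gene.  A
    single-exon transcript yields an empty list.
    """
    seqs = _load_genome(genome)
    feats = _parse_gff3(annotation)
    gene = _find_gene(feats, gene_id)
    _, exons = _choose_transcript(feats, gene_id, transcript_id)
    contig = seqs[gene["seq_id"]]
    gaps = []  # forward 0-based half-open
    for left, right in zip(exons, exons[1:]):
        s, e = left["end"], right["start"] - 1
        if e > s:
            gaps.append((s, e))
    if gene["strand"] == "-":
        gaps = gaps[::-1]
    regions = []
    for ordinal, (s, e) in enumerate(gaps, start=1):
        seq = contig[s:e]
        if gene["strand"] == "-":
            seq = str(Seq(seq).reverse_complement())
        regions.append(
            GenomicRegion(
                seq_id=gene["seq_id"], start=s, end=e,
                strand=gene["strand"], kind="intron", ordinal=ordinal,
                sequence=seq,
            )
        )
    return regions


def scan_region(
    region: GenomicRegion,
    motifs: list[IUPACMotif],
    strands: str = "both",
) -> list[MotifHit]:
    """All exact degenerate matches in a region's oriented sequence.

    Overlapping occurrences are each reported.  With ``strands="both"``
    the reverse strand is scanned by matching the reverse complement of
    each motif against the oriented sequence; a palindromic site therefore
    yields two hits at distinct (offset, strand) pairs.  Hits are ordered
    by (offset, strand, motif name).
    """
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    seq = region.sequence.upper()
    hits = []
    for motif in motifs:
        hits.extend(_strand_hits(motif, seq, region, "+"))
        if strands == "both":
            hits.extend(_strand_hits(motif, seq, region, "-"))
    return sorted(
        hits, key=lambda h: (h.offset, h.strand_within_region, h.motif)
    )


def _strand_hits(motif, seq, region, strand):
    """All (possibly overlapping) matches via a capturing lookahead."""
    pat = motif.regex(reverse_complement=(strand == "-"))
    look = re.compile(f"(?=({pat.pattern}))")
    return [
        MotifHit(motif.name, region, m.start(), strand, m.group(1))
        for m in look.finditer(seq)
    ]


@dataclass
class GeneScanSummary:
    """Per-gene motif counts partitioned by region kind and intron ordinal."""

    gene_id: str
    hits: list[MotifHit]

    @property
    def total(self) -> int:
        return len(self.hits)

    @property
    def promoter_count(self) -> int:
        return sum(1 for h in self.hits if h.region.kind == "promoter")

    @property
    def intron_count(self) -> int:
        return sum(1 for h in self.hits if h.region.kind == "intron")

    def count_by_motif(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for h in self.hits:
            out[h.motif] = out.get(h.motif, 0) + 1
        return out

    def count_by_region(self) -> dict[tuple[str, int], int]:
        out: dict[tuple[str, int], int] = {}
        for h in self.hits:
            key = (h.region.kind, h.region.ordinal)
            out[key] = out.get(key, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.hits:
            fs, fe = h.forward_coords()
            rows.append(
                {
                    "gene_id": self.gene_id,
                    "motif": h.motif,
                    "region_kind": h.region.kind,
                    "ordinal": h.region.ordinal,
                    "offset": h.offset,
                    "strand": h.strand_within_region,
                    "matched": h.matched,
                    "fwd_start": fs,
                    "fwd_end": fe,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "motif", "region_kind", "ordinal", "offset",
                "strand", "matched", "fwd_start", "fwd_end",
            ],
        )

    def write_bed(self, path: str | Path) -> None:
        """BED6 (0-based half-open forward coords, name = motif)."""
        with open(path, "w") as fh:
            for h in self.hits:
                fs, fe = h.forward_coords()
                genome_strand = (
                    "+" if h.region.strand == h.strand_within_region else "-"
                )
                fh.write(
                    f"{h.region.seq_id}\t{fs}\t{fe}\t{h.motif}\t0\t"
                    f"{genome_strand}\n"
                )


def scan_gene(
    genome: str | Path | dict,
    annotation: str | Path,
    gene_id: str,
    motifs: list[IUPACMotif],
    length: int = 3000,
    strands: str = "both",
    transcript_id: str | None = None,
) -> GeneScanSummary:
    """Scan a gene's promoter and all introns for the given motifs."""
    regions = [extract_promoter(genome, annotation, gene_id, length)]
    regions.extend(extract_introns(genome, annotation, gene_id, transcript_id))
    hits: list[MotifHit] = []
    for region in regions:
        hits.extend(scan_region(region, motifs, strands))
    return GeneScanSummary(gene_id=gene_id, hits=hits)


#: the three KNOX/BLH binding-site consensus words used by default
DEFAULT_MOTIFS = [
    ("KNOX/BLH_bs1", "KGACM"),
    ("KNOX/BLH_bs2", "TGAYTGA"),
    ("KNOX/BLH_bs3", "TGATKKGA"),
]


def default_motifs() -> list[IUPACMotif]:
    return [compile_motif(n, p) for n, p in DEFAULT_MOTIFS]
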