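"""Barcode → insertion-locus association from LEAP-Seq-style read pairs.

Each pair couples a cassette mate (carrying the barcode) with a genomic
mate (the flanking sequence immediately adjacent to the cassette
junction).  Flanks are placed on the genome by a k-mer seed-and-extend
aligner: exact k-mer seeds vote for a (chromosome, strand, start)
diagonal, candidates with enough seed support are verified by ungapped
comparison, and loci within the mismatch budget are ranked by score
(matches − mismatches).  Per barcode, the modal locus over its mapped
pairs (±3 bp positional slop) is called the insertion site when it has
enough supporting pairs and a large enough majority.

Coordinate convention: an insertion's ``pos`` is the 1-based genomic
coordinate of the flank's first base — the first genomic base adjacent to
the cassette junction.  ``strand`` is the genomic strand the flank reads
along: ``+`` flanks run rightward from ``pos``, ``-`` flanks leftward
(the read is the reverse complement of the genomic segment ending at
``pos``).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from coldscreen.barcodes import CassetteSpec, extract_barcode, iter_fastq

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into a name → uppercase-sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass(frozen=True)
class FlankRecord:
    barcode: str
    flank: str
    source_sample: str = ""


@dataclass(frozen=True)
class Candidate:
    chrom: str
    pos: int  # 1-based coordinate of the flank's first base
    strand: str
    score: int
    mismatches: int


@dataclass(frozen=True)
class MappedInsertion:
    barcode: str
    chrom: str | None
    pos: int | None
    strand: str | None
    support: int
    status: str  # unique | ambiguous | unmapped | conflicting
    n_records: int = 0
    n_mapped: int = 0


@dataclass
class MapParams:
    # k=17 with min_seed_hits=2 guarantees an on-diagonal seed pair for
    # 60 bp flanks carrying up to two substitutions (longest clean
    # segment >= 20 bases) while staying specific on genomes far larger
    # than those simulated here.
    k: int = 17
    min_seed_hits: int = 2
    max_mismatch_frac: float = 0.1
    min_support: int = 2
    min_agree_frac: float = 0.8
    pos_slop: int = 3


class KmerIndex:
    """Exact k-mer → genomic occurrence index over both strands.

    A ``+`` occurrence at position p means the k-mer equals the genome
    segment starting at p; a ``-`` occurrence at position p means it
    equals the reverse complement of the segment *ending* at p, i.e. p is
    where the k-mer's first base sits when read on the minus strand.
    With that convention a seed at flank offset i implies a flank start
    of ``p - i`` (+) or ``p + i`` (−).
    """

    def __init__(self, genome: Mapping[str, str], k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self.chrom_lens = {name: len(seq) for name, seq in self.genome.items()}
        self.occurrences: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
        self.skipped_kmers = 0
        for chrom, seq in self.genome.items():
            if len(seq) < k:
                logger.warning("chromosome %s shorter than k=%d; not indexed", chrom, k)
                continue
            rc = revcomp(seq)
            L = len(seq)
            for j in range(L - k + 1):
                kmer = seq[j : j + k]
                if "N" in kmer:
                    self.skipped_kmers += 1
                else:
                    self.occurrences[kmer].append((chrom, j + 1, "+"))
                # rc[j:j+k] reads the minus strand; its first base sits at
                # genomic coordinate L - j.
                rkmer = rc[j : j + k]
                if "N" not in rkmer:
                    self.occurrences[rkmer].append((chrom, L - j, "-"))

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        return self.occurrences.get(kmer, [])


def build_kmer_index(genome: Mapping[str, str] | str | Path, k: int = 17) -> KmerIndex:
    """Build the seed index from a genome mapping or FASTA path."""
    if not isinstance(genome, Mapping):
        genome = read_fasta(genome)
    return KmerIndex(genome, k)


def _window(index: KmerIndex, chrom: str, start: int, length: int, strand: str) -> str | None:
    """Genomic sequence a flank at (chrom, start, strand) should equal;
    None if it runs off the chromosome."""
    seq = index.genome[chrom]
    if strand == "+":
        if start < 1 or start + length - 1 > len(seq):
            return None
        return seq[start - 1 : start - 1 + length]
    if start - length + 1 < 1 or start > len(seq):
        return None
    return revcomp(seq[start - length : start])


def map_flank(flank: str, index: KmerIndex, params: MapParams | None = None) -> list[Candidate]:
    """Candidate insertion loci for one flank, best first.

    Seeds every k-mer of the flank, votes on (chrom, strand, start)
    diagonals, verifies candidates with >= ``min_seed_hits`` votes by
    ungapped comparison, and returns loci whose mismatch count is within
    ``max_mismatch_frac`` of the flank length, ranked by score then
    coordinate.
    """
    params = params or MapParams()
    k = index.k
    flank = flank.upper()
    L = len(flank)
    if L < k:
        return []
    votes: Counter = Counter()
    for i in range(L - k + 1):
        for chrom, p, strand in index.lookup(flank[i : i + k]):
            start = p - i if strand == "+" else p + i
            votes[(chrom, strand, start)] += 1
    max_mm = int(params.max_mismatch_frac * L)
    out = []
    for (chrom, strand, start), n in votes.items():
        if n < params.min_seed_hits:
            continue
        ref = _window(index, chrom, start, L, strand)
        if ref is None:
            continue
        mm = sum(a != b for a, b in zip(flank, ref))
        if mm <= max_mm:
            out.append(Candidate(chrom, start, strand, score=L - 2 * mm, mismatches=mm))
    out.sort(key=lambda c: (-c.score, c.chrom, c.pos, c.strand))
    return out


def associate_pairs(
    cassette_fastq: str | Path,
    flank_fastq: str | Path,
    spec: CassetteSpec,
    source_sample: str = "",
) -> tuple[list[FlankRecord], dict]:
    """Pair barcode mates with genomic mates.

    Mates are taken in lockstep order (R1 = cassette mate, R2 = genomic
    mate).  The barcode is extracted from the cassette mate; any
    detectable cassette remnant at the start of the genomic mate (a
    near-exact downstream-anchor prefix) is stripped.  Pairs failing
    barcode extraction are dropped and tallied.  A mate-count mismatch
    raises.
    """
    records: list[FlankRecord] = []
    dropped: Counter = Counter()
    it1, it2 = iter_fastq(cassette_fastq), iter_fastq(flank_fastq)
    n = 0
    down = spec.downstream_anchor
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            break
        if (r1 is None) != (r2 is None):
            raise ValueError(
                f"mate-count mismatch between {cassette_fastq} and {flank_fastq} "
                f"after {n} pairs"
            )
        n += 1
        barcode, reason = extract_barcode(r1[1], spec)
        if barcode is None:
            dropped[reason] += 1
            continue
        flank = r2[1].upper()
        # strip a cassette remnant: downstream anchor within the first few bases
        head = flank[: len(down) + 4]
        cut = head.find(down)
        if cut != -1:
            flank = flank[cut + len(down) :]
        records.append(FlankRecord(barcode=barcode, flank=flank, source_sample=source_sample))
    tally = {"pairs": n, "kept": len(records), "dropped": dict(dropped)}
    return records, tally


def _best_unique(cands: list[Candidate]) -> Candidate | None:
    """Top candidate when it strictly beats the runner-up (else None)."""
    if not cands:
        return None
    if len(cands) > 1 and cands[1].score == cands[0].score:
        return None
    return cands[0]


def call_insertions(
    records: Iterable[FlankRecord],
    index: KmerIndex,
    params: MapParams | None = None,
) -> list[MappedInsertion]:
    """Call one insertion locus per barcode by modal-locus voting.

    Each record's flank is mapped (distinct flank sequences are mapped
    once and cached); records with a unique best locus vote.  Loci on the
    same chromosome and strand within ``pos_slop`` bp are pooled.  The
    modal locus wins when it has >= ``min_support`` votes and >=
    ``min_agree_frac`` of the mapped records; a tied mode is
    ``ambiguous``; no mapped records is ``unmapped``; anything else is
    ``conflicting``.
    """
    params = params or MapParams()
    by_barcode: dict[str, list[FlankRecord]] = defaultdict(list)
    for rec in records:
        by_barcode[rec.barcode].append(rec)

    cache: dict[str, Candidate | None] = {}

    def best_for(flank: str) -> Candidate | None:
        if flank not in cache:
            cache[flank] = _best_unique(map_flank(flank, index, params))
        return cache[flank]

    out: list[MappedInsertion] = []
    for barcode in sorted(by_barcode):
        recs = by_barcode[barcode]
        loci = Counter()
        for rec in recs:
            best = best_for(rec.flank)
            if best is not None:
                loci[(best.chrom, best.pos, best.strand)] += 1
        n_mapped = sum(loci.values())
        if n_mapped == 0:
            out.append(MappedInsertion(barcode, None, None, None, 0, "unmapped", len(recs), 0))
            continue
        # pool loci within pos_slop of each exact mode, same chrom/strand
        clusters: list[tuple[tuple[str, int, str], int]] = []
        for (chrom, pos, strand), cnt in sorted(
            loci.items(), key=lambda kv: (-kv[1], kv[0])
        ):
            placed = False
            for ci, ((cchrom, cpos, cstrand), ccnt) in enumerate(clusters):
                if chrom == cchrom and strand == cstrand and abs(pos - cpos) <= params.pos_slop:
                    clusters[ci] = ((cchrom, cpos, cstrand), ccnt + cnt)
                    placed = True
                    break
            if not placed:
                clusters.append(((chrom, pos, strand), cnt))
        clusters.sort(key=lambda kv: (-kv[1], kv[0]))
        (chrom, pos, strand), support = clusters[0]
        if len(clusters) > 1 and clusters[1][1] == support:
            out.append(
                MappedInsertion(barcode, None, None, None, support, "ambiguous", len(recs), n_mapped)
            )
        elif support >= params.min_support and support >= params.min_agree_frac * n_mapped:
            out.append(
                MappedInsertion(barcode, chrom, pos, strand, support, "unique", len(recs), n_mapped)
            )
        else:
            out.append(
                MappedInsertion(barcode, chrom, pos, strand, support, "conflicting", len(recs), n_mapped)
            )
    return out


def insertions_to_frame(calls: Sequence[MappedInsertion]) -> pd.DataFrame:
    rows = [
        {
            "barcode": c.barcode,
            "chrom": c.chrom if c.chrom is not None else "",
            "pos": c.pos if c.pos is not None else "",
            "strand": c.strand if c.strand is not None else "",
            "support": c.support,
            "status": c.status,
            "n_records": c.n_records,
            "n_mapped": c.n_mapped,
        }
        for c in calls
    ]
    cols = ["barcode", "chrom", "pos", "strand", "support", "status", "n_records", "n_mapped"]
    return pd.DataFrame(rows, columns=cols)


def write_insertions(calls: Sequence[MappedInsertion], path: str | Path) -> None:
    insertions_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_bed6(calls: Sequence[MappedInsertion], path: str | Path) -> None:
    """Unique calls as BED6; 1-based inclusive pos becomes 0-based
    half-open [pos-1, pos)."""
    with open(path, "w") as fh:
        fh.write("# BED6; insertion pos converted from 1-based inclusive to 0-based half-open\n")
        for c in calls:
            if c.status != "unique":
                continue
            fh.write(f"{c.chrom}\t{c.pos - 1}\t{c.pos}\t{c.barcode}\t{c.support}\t{c.strand}\n")
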