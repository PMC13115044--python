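"""Rule-based annotation of cassette insertion sites.

An insertion position is classified into exactly one of six categories:
``five_prime_UTR``, ``exon``, ``intron``, ``three_prime_UTR``,
``potential_promoter`` (within 1 kb upstream of a transcription start
site, strand-aware) or ``intergenic``.  Overlaps are resolved by a fixed
priority: a genic sub-feature beats a promoter window, which beats
intergenic; among several genic (or promoter) candidates the gene whose
TSS is nearest wins, ties broken by lexicographic gene id.  Only the
position matters — the insertion's strand does not enter the rule.

Gene models carry one representative transcript per gene (the longest
mRNA; ties broken by lexicographically smallest mRNA id).  Introns are
the gaps between consecutive exons.  UTR intervals may be absent, in
which case the UTR categories are simply unreachable for that gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

CATEGORIES = (
    "five_prime_UTR",
    "exon",
    "intron",
    "three_prime_UTR",
    "potential_promoter",
    "intergenic",
)

Interval = tuple[int, int]  # 1-based inclusive


def _in_any(pos: int, intervals: Iterable[Interval]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


@dataclass(frozen=True)
class GeneModel:
    """One gene with its representative transcript structure.

    All intervals are 1-based inclusive genomic coordinates; ``exons``
    are sorted by start and include any UTR portions, as in a standard
    GFF3 exon annotation.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[Interval, ...]
    five_utrs: tuple[Interval, ...] = ()
    three_utrs: tuple[Interval, ...] = ()
    mrna_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start: span start on +, span end on -."""
        return self.start if self.strand == "+" else self.end

    @property
    def introns(self) -> tuple[Interval, ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)

    def promoter_window(self, window: int = 1000) -> Interval:
        """Strand-aware window of ``window`` bp immediately upstream of
        the TSS: [TSS-w, TSS-1] on +, [TSS+1, TSS+w] on -.  May extend
        below 1; callers clip."""
        if self.strand == "+":
            return (self.tss - window, self.tss - 1)
        return (self.tss + 1, self.tss + window)

    def subfeature(self, pos: int) -> str | None:
        """Category of ``pos`` inside this gene's span, else None."""
        if not (self.start <= pos <= self.end):
            return None
        if _in_any(pos, self.five_utrs):
            return "five_prime_UTR"
        if _in_any(pos, self.three_utrs):
            return "three_prime_UTR"
        if _in_any(pos, self.exons):
            return "exon"
        return "intron"


@dataclass(frozen=True)
class AnnotationCall:
    category: str
    gene_id: str | None = None
    distance_to_tss: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category}")
        if (self.gene_id is None) != (self.category == "intergenic"):
            raise ValueError("gene_id is None iff intergenic")


class GeneModelSet:
    """Indexed collection of gene models for fast positional lookup."""

    def __init__(self, genes: Sequence[GeneModel], promoter_window: int = 1000):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
        self.promoter_window_bp = promoter_window
        self._chroms = {g.chrom for g in self.genes.values()}
        self._span_trees: dict[str, IntervalTree] = {}
        self._prom_trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            # IntervalTree is half-open; store [start, end+1).
            self._span_trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end + 1, g.gene_id
            )
            ps, pe = g.promoter_window(promoter_window)
            ps = max(1, ps)
            if ps <= pe:
                self._prom_trees.setdefault(g.chrom, IntervalTree()).addi(
                    ps, pe + 1, g.gene_id
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneModelSet) and self.genes == other.genes

    def chroms(self) -> set[str]:
        return self._chroms

    def genes_overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._span_trees.get(chrom)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in tree[pos]]

    def promoters_overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._prom_trees.get(chrom)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in tree[pos]]


def _nearest_tss(candidates: Sequence[GeneModel], pos: int) -> GeneModel:
    return min(candidates, key=lambda g: (abs(g.tss - pos), g.gene_id))


def classify_insertion(
    chrom: str,
    pos: int,
    models: GeneModelSet,
    promoter_window: int = 1000,
    missing_chrom: str = "warn",
) -> AnnotationCall:
    """Classify one genomic position.

    Priority: genic sub-feature > potential promoter > intergenic.  A
    position exactly ``promoter_window`` bp upstream of a TSS is still a
    promoter call ("within 1 kb" read inclusively); one base further is
    intergenic.  An unknown chromosome yields intergenic with a warning,
    or raises if ``missing_chrom='error'``.
    """
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    if chrom not in models.chroms():
        if missing_chrom == "error":
            raise KeyError(f"chromosome {chrom!r} absent from gene models")
        logger.warning("chromosome %r absent from gene models; calling intergenic", chrom)
        return AnnotationCall("intergenic")

    genic = models.genes_overlapping(chrom, pos)
    if genic:
        gene = _nearest_tss(genic, pos)
        return AnnotationCall(gene.subfeature(pos), gene.gene_id)

    if promoter_window == models.promoter_window_bp:
        promo = models.promoters_overlapping(chrom, pos)
    else:  # non-default window: fall back to a scan
        promo = []
        for g in models.genes.values():
            if g.chrom != chrom:
                continue
            ps, pe = g.promoter_window(promoter_window)
            if max(1, ps) <= pos <= pe:
                promo.append(g)
    if promo:
        gene = _nearest_tss(promo, pos)
        dist = gene.tss - pos if gene.strand == "+" else pos - gene.tss
        return AnnotationCall("potential_promoter", gene.gene_id, dist)

    return AnnotationCall("intergenic")


def annotate_all(
    insertions: pd.DataFrame,
    models: GeneModelSet,
    promoter_window: int = 1000,
) -> tuple[pd.DataFrame, dict]:
    """Annotate a table of unique insertion calls.

    ``insertions`` needs columns ``barcode, chrom, pos`` (``strand`` is
    carried through if present).  Returns the annotated table plus a
    summary with per-category tallies and the distinct-gene count over
    non-intergenic calls.
    """
    rows = []
    for rec in insertions.itertuples(index=False):
        call = classify_insertion(rec.chrom, int(rec.pos), models, promoter_window)
        row = {
            "barcode": rec.barcode,
            "chrom": rec.chrom,
            "pos": int(rec.pos),
            "strand": getattr(rec, "strand", "."),
            "category": call.category,
            "gene_id": call.gene_id if call.gene_id is not None else "",
            "distance_to_tss": call.distance_to_tss if call.distance_to_tss is not None else "",
        }
        rows.append(row)
    cols = ["barcode", "chrom", "pos", "strand", "category", "gene_id", "distance_to_tss"]
    table = pd.DataFrame(rows, columns=cols)
    tallies = {cat: 0 for cat in CATEGORIES}
    if len(table):
        tallies.update(table["category"].value_counts().to_dict())
    genes = sorted(set(table.loc[table["category"] != "intergenic", "gene_id"])) if len(table) else []
    summary = {"tallies": tallies, "n_insertions": len(table), "n_genes": len(genes), "genes": genes}
    return table, summary


# ---------------------------------------------------------------------------
# GFF3 I/O


def load_gff3(path: str | Path) -> GeneModelSet:
    """Load gene models from GFF3 (gene/mRNA/exon, UTR features optional).

    One representative transcript per gene: the longest mRNA, ties broken
    by lexicographically smallest mRNA id.  Raises on an exon lying
    outside its mRNA's span, naming the offending feature.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            logger.warning("gene %s has no mRNA; skipped", gene.id)
            continue
        rep = min(mrnas, key=lambda m: (-(m.end - m.start + 1), m.id))
        exons, five_utrs, three_utrs = [], [], []
        for child in db.children(rep, order_by="start"):
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                if child.start < rep.start or child.end > rep.end:
                    raise ValueError(
                        f"exon {child.id or iv} outside span of mRNA {rep.id}"
                    )
                exons.append(iv)
            elif child.featuretype == "five_prime_UTR":
                five_utrs.append(iv)
            elif child.featuretype == "three_prime_UTR":
                three_utrs.append(iv)
        if not five_utrs and not three_utrs:
            logger.info("gene %s has no UTR features; UTR categories unreachable", gene.id)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=rep.start,
                end=rep.end,
                exons=tuple(exons),
                five_utrs=tuple(five_utrs),
                three_utrs=tuple(three_utrs),
                mrna_id=rep.id,
            )
        )
    return GeneModelSet(genes)


def write_gff3(models: GeneModelSet | Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive), one mRNA per gene."""
    genes = sorted(models, key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            mrna_id = g.mrna_id or f"{g.gene_id}.t1"
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tcoldscreen\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tcoldscreen\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for kind, ivs in (
                ("exon", g.exons),
                ("five_prime_UTR", g.five_utrs),
                ("three_prime_UTR", g.three_utrs),
            ):
                for i, (s, e) in enumerate(sorted(ivs), 1):
                    fh.write(
                        f"{g.chrom}\tcoldscreen\t{kind}\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={mrna_id}.{kind}.{i};Parent={mrna_id}\n"
                    )


def load_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list, one id per line; blank lines and
    ``#`` comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out
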