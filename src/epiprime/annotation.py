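"""Gene models, genomic annotation categories and nearest-gene assignment.

Every peak is reduced to its integer midpoint and classified with precedence
promoter > exon > intron > intergenic. Intergenic peaks are associated with
the nearest TSS on the same chromosome when the midpoint-to-TSS distance is
below a cutoff (default 50 kb); peaks falling inside a gene (promoter, exon or
intron) are assigned to the host gene regardless of TSS distance.
"""
from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "annotate_region",
    "assign_nearest_gene",
    "read_gene_table",
    "write_gene_table",
]

logger = logging.getLogger(__name__)

UNASSIGNED = None


@dataclass(frozen=True)
class GeneModel:
    """A gene with one transcript model.

    ``span`` runs from transcript start to end; ``tss`` is span.start on the
    + strand and span.end - 1 on the - strand. Exons are non-overlapping and
    sorted.
    """

    gene_id: str
    chrom: str
    strand: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    def promoter(self, upstream: int, downstream: int) -> GenomicInterval:
        """Strand-aware promoter window around the TSS (half-open)."""
        if self.strand == "+":
            start, end = self.tss - upstream, self.tss + downstream
        else:
            start, end = self.tss - downstream + 1, self.tss + upstream + 1
        return GenomicInterval(self.chrom, max(0, start), end)


class GenomeAnnotation:
    """Indexed gene set with a promoter window convention.

    promoter_window = (upstream_bp, downstream_bp) relative to the TSS,
    strand-aware; defaults to (-1000, +500).
    """

    def __init__(
        self,
        genes: list[GeneModel],
        promoter_window: tuple[int, int] = (1000, 500),
    ):
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id))
        self.promoter_window = promoter_window
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        # sorted TSS index per chromosome for nearest-TSS queries
        self._tss_index: dict[str, tuple[list[int], list[GeneModel]]] = {}
        for chrom, gs in self._by_chrom.items():
            order = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self._tss_index[chrom] = ([g.tss for g in order], order)
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def chrom_genes(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])


def _host_category(pos: int, gene: GeneModel, window: tuple[int, int]) -> str | None:
    """Category of position ``pos`` relative to one gene, or None."""
    prom = gene.promoter(*window)
    if prom.start <= pos < prom.end:
        return "promoter"
    if gene.span.start <= pos < gene.span.end:
        for ex in gene.exons:
            if ex.start <= pos < ex.end:
                return "exon"
        return "intron"
    return None


_PRECEDENCE = {"promoter": 0, "exon": 1, "intron": 2}


def annotate_region(iv: GenomicInterval, ann: GenomeAnnotation) -> str:
    """Classify a region by its midpoint: promoter, exon, intron or intergenic."""
    cat, _ = _annotate_with_host(iv, ann)
    return cat


def _annotate_with_host(
    iv: GenomicInterval, ann: GenomeAnnotation
) -> tuple[str, GeneModel | None]:
    pos = iv.midpoint
    genes = ann.chrom_genes(iv.chrom)
    if not genes and iv.chrom not in ann._by_chrom:
        logger.warning("chromosome %s absent from annotation; intergenic", iv.chrom)
    best: tuple[int, str, GeneModel] | None = None
    for g in genes:
        # promoter windows extend beyond the span; use a generous guard
        up, down = ann.promoter_window
        pad = max(up, down) + 1
        if pos < g.span.start - pad or pos >= g.span.end + pad:
            continue
        cat = _host_category(pos, g, ann.promoter_window)
        if cat is None:
            continue
        key = (_PRECEDENCE[cat], g.gene_id)
        if best is None or key < (best[0], best[2].gene_id):
            best = (_PRECEDENCE[cat], cat, g)
    if best is None:
        return "intergenic", None
    return best[1], best[2]


def assign_nearest_gene(
    iv: GenomicInterval,
    ann: GenomeAnnotation,
    max_tss_dist: int = 50_000,
) -> str | None:
    """Assign a region to a gene by the containment-then-proximity rule.

    Regions whose midpoint lies in a gene's promoter, exon or intron are
    assigned to that host gene. Intergenic regions are assigned to the gene
    with the nearest TSS on the same chromosome when |midpoint - TSS| is
    strictly below ``max_tss_dist``, else left unassigned (None). Distance and
    host ties break on the lexicographically smallest gene_id.
    """
    if max_tss_dist <= 0:
        raise ValueError("max_tss_dist must be positive")
    cat, host = _annotate_with_host(iv, ann)
    if host is not None:
        return host.gene_id
    if iv.chrom not in ann._tss_index:
        return UNASSIGNED
    tss_list, genes = ann._tss_index[iv.chrom]
    pos = iv.midpoint
    i = bisect_left(tss_list, pos)
    best_id, best_d = None, None
    for j in range(max(0, i - 2), min(len(genes), i + 2)):
        d = abs(pos - tss_list[j])
        gid = genes[j].gene_id
        if best_d is None or d < best_d or (d == best_d and gid < best_id):
            best_id, best_d = gid, d
    if best_d is not None and best_d < max_tss_dist:
        return best_id
    return UNASSIGNED


def read_gene_table(path) -> list[GeneModel]:
    """Read a refFlat-style gene table.

    Tab-separated columns: gene_id, chrom, strand, txStart, txEnd,
    exonStarts (comma list), exonEnds (comma list). '#' lines skipped.
    """
    genes = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gid, chrom, strand, s, e, exs, exe = line.split("\t")[:7]
            starts = [int(x) for x in exs.rstrip(",").split(",") if x]
            ends = [int(x) for x in exe.rstrip(",").split(",") if x]
            exons = tuple(
                GenomicInterval(chrom, a, b) for a, b in zip(starts, ends)
            )
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    span=GenomicInterval(chrom, int(s), int(e)),
                    exons=exons,
                )
            )
    return genes


def write_gene_table(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tchrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\n")
        for g in genes:
            exs = ",".join(str(e.start) for e in g.exons)
            exe = ",".join(str(e.end) for e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.span.start}\t{g.span.end}\t{exs}\t{exe}\n"
            )


def assign_peaks_to_genes(
    peaks: PeakSet, ann: GenomeAnnotation, max_tss_dist: int = 50_000
) -> dict[str, str | None]:
    """Vector form of :func:`assign_nearest_gene` keyed by region id."""
    return {
        rid: assign_nearest_gene(iv, ann, max_tss_dist)
        for rid, iv in zip(peaks.region_ids(), peaks)
    }
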