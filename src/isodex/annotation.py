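"""Gene models: isoform structures reduced to disjoint exon regions.

Isoforms of one gene share exons, so an observed exon-level count mixes the
contributions of every isoform that includes that exon.  The counting unit
used throughout the package is the *exon region*: a maximal segment of the
gene's exonic union that is not split by any isoform's exon boundary.  Each
gene then carries a binary inclusion matrix ``s`` (isoforms x regions) saying
which regions belong to which isoform; the observed region count is the sum
of latent per-isoform counts over the isoforms with ``s == 1``.

All coordinates are 0-based half-open internally; dialect conversion happens
only at the parse boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True)
class ExonRegion:
    """A disjoint exonic segment of one gene, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(
                f"empty or inverted region [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """One gene: its isoforms, its disjoint exon regions and inclusion matrix.

    Attributes
    ----------
    transcripts
        List of ``(transcript_id, [(exon_start, exon_end), ...])`` pairs with
        exons sorted and non-overlapping, 0-based half-open.
    regions
        Disjoint exon regions sorted by start.
    s
        Binary inclusion matrix of shape ``(T, I)``; ``s[t, i] == 1`` iff
        region ``i`` lies entirely within the exonic span of transcript ``t``.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[tuple[str, list[tuple[int, int]]]]
    regions: list[ExonRegion] = field(default_factory=list)
    s: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=np.int8))

    @property
    def n_isoforms(self) -> int:
        return len(self.transcripts)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def transcript_ids(self) -> list[str]:
        return [tid for tid, _ in self.transcripts]

    @property
    def region_lengths(self) -> np.ndarray:
        return np.array([r.length for r in self.regions], dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneModel):
            return NotImplemented
        return (
            self.gene_id == other.gene_id
            and self.chrom == other.chrom
            and self.strand == other.strand
            and self.transcripts == other.transcripts
            and self.regions == other.regions
            and np.array_equal(self.s, other.s)
        )


def build_exon_regions(
    transcripts: list[tuple[str, list[tuple[int, int]]]],
) -> tuple[list[ExonRegion], np.ndarray]:
    """Split the exonic union at every isoform boundary.

    The returned regions are the disjoint segments obtained by cutting the
    union of all exons at every exon start/end of every transcript; the
    inclusion matrix ``s`` marks segment ``i`` for transcript ``t`` iff the
    segment is contained in one of ``t``'s exons.  Concatenating a
    transcript's included segments reconstructs its exonic footprint exactly.
    """
    if not transcripts:
        raise AnnotationError("cannot build exon regions from zero transcripts")
    for tid, exons in transcripts:
        if not exons:
            raise AnnotationError(f"transcript {tid!r} has no exons")

    boundaries: set[int] = set()
    for _, exons in transcripts:
        for start, end in exons:
            if end <= start:
                raise AnnotationError(f"empty exon [{start}, {end})")
            boundaries.add(start)
            boundaries.add(end)
    cuts = sorted(boundaries)

    # candidate segments between consecutive cuts, kept if exonic in >=1 isoform
    regions: list[ExonRegion] = []
    rows: list[list[int]] = [[] for _ in transcripts]
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        included = [
            any(start <= lo and hi <= end for start, end in exons)
            for _, exons in transcripts
        ]
        if any(included):
            regions.append(ExonRegion(lo, hi))
            for row, inc in zip(rows, included):
                row.append(int(inc))
    s = np.array(rows, dtype=np.int8).reshape(len(transcripts), len(regions))
    return regions, s


def _finalize(gene: GeneModel) -> GeneModel:
    gene.regions, gene.s = build_exon_regions(gene.transcripts)
    return gene


def _parse_refflat(path: str) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 11 refFlat columns, "
                    f"got {len(fields)}")
            gene_id, tx_id, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            try:
                n_exons = int(fields[8])
                starts = [int(v) for v in fields[9].rstrip(",").split(",") if v]
                ends = [int(v) for v in fields[10].rstrip(",").split(",") if v]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(starts) != n_exons or len(ends) != n_exons:
                raise AnnotationError(
                    f"{path}:{lineno}: exonCount={n_exons} does not match "
                    f"{len(starts)} starts / {len(ends)} ends")
            if n_exons == 0:
                warnings.warn(
                    f"{path}:{lineno}: transcript {tx_id} has zero exons; skipped")
                continue
            exons = sorted(zip(starts, ends))
            key = (gene_id, chrom, strand)
            gm = genes.get(key)
            if gm is None:
                gm = genes[key] = GeneModel(gene_id, chrom, strand, [])
            gm.transcripts.append((tx_id, [(s, e) for s, e in exons]))
    return [_finalize(g) for g in genes.values()]


def _parse_gtf(path: str) -> list[GeneModel]:
    # gffutils handles attribute parsing and feature grouping; exon lines are
    # 1-based inclusive and converted here to 0-based half-open.
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    per_tx: dict[tuple[str, str, str, str], list[tuple[int, int]]] = {}
    order: list[tuple[str, str, str, str]] = []
    n_exons = 0
    for exon in db.features_of_type("exon", order_by=("seqid", "start")):
        n_exons += 1
        try:
            gene_id = exon.attributes["gene_id"][0]
            tx_id = exon.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"{path}: exon at {exon.seqid}:{exon.start} lacks {exc}") from exc
        key = (gene_id, tx_id, exon.seqid, exon.strand or ".")
        if key not in per_tx:
            per_tx[key] = []
            order.append(key)
        per_tx[key].append((exon.start - 1, exon.end))
    if n_exons == 0:
        raise AnnotationError(f"{path}: no exon features found")

    genes: dict[tuple[str, str, str], GeneModel] = {}
    for gene_id, tx_id, chrom, strand in order:
        exons = sorted(per_tx[(gene_id, tx_id, chrom, strand)])
        gkey = (gene_id, chrom, strand)
        gm = genes.get(gkey)
        if gm is None:
            gm = genes[gkey] = GeneModel(gene_id, chrom, strand, [])
        gm.transcripts.append((tx_id, exons))
    return [_finalize(g) for g in genes.values()]


def parse_annotation(path: str, dialect: str = "refFlat") -> list[GeneModel]:
    """Parse a refFlat or GTF annotation into :class:`GeneModel` objects.

    Transcripts are grouped by gene id; every gene model carries the disjoint
    exon regions and inclusion matrix from :func:`build_exon_regions`.
    """
    import os

    if not os.path.exists(path):
        raise AnnotationError(f"annotation file not found: {path}")
    if os.path.getsize(path) == 0:
        raise AnnotationError(f"annotation file is empty: {path}")
    if dialect == "refFlat":
        models = _parse_refflat(path)
    elif dialect == "GTF":
        models = _parse_gtf(path)
    else:
        raise AnnotationError(f"unknown annotation dialect: {dialect!r}")
    if not models:
        raise AnnotationError(f"no gene models parsed from {path}")
    return models


# -- tabular gene-model dump -------------------------------------------------

_TABLE_COLUMNS = [
    "gene_id", "chrom", "strand", "region_index", "start", "end",
    "transcript_ids", "inclusion",
]


def write_gene_models(models: list[GeneModel], path: str) -> None:
    """Write the tab-separated gene-model dump (one row per exon region).

    ``inclusion`` is the region's s-column as a bitstring ordered like
    ``transcript_ids``.  Transcript exon lists are recoverable because
    regions included by a transcript, merged where they touch, are exactly
    its exons (introns separate distinct exons).
    """
    rows = []
    for gm in models:
        tids = ",".join(gm.transcript_ids)
        for i, region in enumerate(gm.regions):
            rows.append((
                gm.gene_id, gm.chrom, gm.strand, i, region.start, region.end,
                tids, "".join(str(int(v)) for v in gm.s[:, i]),
            ))
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str) -> list[GeneModel]:
    """Read the dump written by :func:`write_gene_models`."""
    df = pd.read_csv(path, sep="\t", dtype={"inclusion": str})
    models = []
    for (gene_id, chrom, strand), grp in df.groupby(
            ["gene_id", "chrom", "strand"], sort=False):
        grp = grp.sort_values("region_index")
        tids = grp["transcript_ids"].iloc[0].split(",")
        transcripts = []
        for t, tid in enumerate(tids):
            segs = [
                (int(r.start), int(r.end))
                for r in grp.itertuples()
                if r.inclusion[t] == "1"
            ]
            exons: list[tuple[int, int]] = []
            for start, end in segs:
                if exons and exons[-1][1] == start:
                    exons[-1] = (exons[-1][0], end)
                else:
                    exons.append((start, end))
            transcripts.append((tid, exons))
        models.append(_finalize(GeneModel(gene_id, chrom, str(strand), transcripts)))
    return models
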