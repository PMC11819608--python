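"""Exon-region counting: aligned reads -> count tensor y and weight tensor x.

Reads are assigned by the midpoint of their aligned reference span
(CIGAR-aware): a read contributes to the unique exon region containing that
base, or is discarded as unassigned.  This rule is deterministic, never
double-counts a boundary-spanning read, and is exact on the simulator's
non-junction reads.  Secondary alignments and unmapped records are skipped;
counting is unstranded.

The weight convention is x[g][i][j] = L_i * N_j / 1e9 with N_j the number of
mapped reads in sample j, which puts the abundance parameter beta on the
FPKM scale (reads per kilobase per million mapped reads).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneModel

logger = logging.getLogger(__name__)


def _open_sam(path: str) -> pysam.AlignmentFile:
    mode = "rb" if path.endswith(".bam") else "r"
    return pysam.AlignmentFile(path, mode, check_sq=False)


def compute_library_sizes(paths: list[str]) -> np.ndarray:
    """Number of mapped primary records per alignment file."""
    sizes = []
    for path in paths:
        n = 0
        with _open_sam(path) as fh:
            for rec in fh:
                if not rec.is_unmapped and not rec.is_secondary:
                    n += 1
        if n == 0:
            raise ValueError(f"{path}: no mapped reads")
        sizes.append(n)
    return np.array(sizes, dtype=np.int64)


def count_exon_reads(
    path: str,
    models: list[GeneModel],
) -> tuple[dict[str, np.ndarray], int]:
    """Count one sample's reads into each gene's exon regions.

    Returns ``({gene_id: (I,) counts}, n_unassigned)`` where unassigned
    reads are mapped reads whose span midpoint falls in no region (including
    reads on chromosomes absent from the models, which are logged).
    """
    by_chrom: dict[str, list[tuple[int, int, str, int]]] = {}
    for g, gm in enumerate(models):
        for i, region in enumerate(gm.regions):
            by_chrom.setdefault(gm.chrom, []).append(
                (region.start, region.end, gm.gene_id, i))
    index = {}
    for chrom, entries in by_chrom.items():
        entries.sort()
        index[chrom] = (
            np.array([e[0] for e in entries]),
            np.array([e[1] for e in entries]),
            entries,
        )

    counts = {gm.gene_id: np.zeros(gm.n_regions, dtype=np.int64)
              for gm in models}
    unassigned = 0
    missing_chroms: set[str] = set()
    with _open_sam(path) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            chrom = rec.reference_name
            if chrom not in index:
                missing_chroms.add(chrom)
                unassigned += 1
                continue
            mid = (rec.reference_start + rec.reference_end) // 2
            starts, ends, entries = index[chrom]
            k = int(np.searchsorted(starts, mid, side="right")) - 1
            # regions are disjoint within a gene and genes rarely overlap, so
            # only a short backward scan can contain the midpoint
            hit = False
            for back in range(k, max(k - 50, -1), -1):
                if mid < ends[back]:
                    _, _, gid, i = entries[back]
                    counts[gid][i] += 1
                    hit = True
                    break
            if not hit:
                unassigned += 1
    if missing_chroms:
        logger.warning("%s: reads on chromosomes absent from the models "
                       "counted as unassigned: %s", path, sorted(missing_chroms))
    return counts, unassigned


def compute_weights(
    models: list[GeneModel],
    libsizes: np.ndarray,
) -> dict[str, np.ndarray]:
    """Length-by-library-size weights: x[i, j] = L_i * N_j / 1e9 per gene."""
    libsizes = np.asarray(libsizes, dtype=float)
    if np.any(libsizes <= 0):
        raise ValueError("library sizes must be positive")
    out = {}
    for gm in models:
        L = gm.region_lengths
        if np.any(L <= 0):
            raise ValueError(f"{gm.gene_id}: non-positive region length")
        out[gm.gene_id] = L[:, None] * libsizes[None, :] / 1e9
    return out


def write_count_table(counts: dict[str, np.ndarray], path: str,
                      sample_names: list[str] | None = None) -> None:
    """Dump a per-gene (region x sample) matrix dict as TSV."""
    rows = []
    for gid in counts:
        mat = np.atleast_2d(counts[gid])
        for i in range(mat.shape[0]):
            rows.append([gid, i, *mat[i].tolist()])
    n_samples = len(rows[0]) - 2
    names = sample_names or [f"sample{j + 1:02d}" for j in range(n_samples)]
    pd.DataFrame(rows, columns=["gene_id", "region_index", *names]).to_csv(
        path, sep="\t", index=False)


def read_count_table(path: str) -> tuple[dict[str, np.ndarray], list[str]]:
    """Read a TSV written by :func:`write_count_table`."""
    df = pd.read_csv(path, sep="\t")
    names = [c for c in df.columns if c not in ("gene_id", "region_index")]
    out = {}
    for gid, grp in df.groupby("gene_id", sort=False):
        grp = grp.sort_values("region_index")
        out[gid] = grp[names].to_numpy()
    return out, names
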