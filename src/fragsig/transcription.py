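"""Nascent-transcription quantification and gene classification.

Nascent-RNA (Bru-seq-style) read counts in fine bins are summarised per
gene as an RPM-normalised, gene-length-scaled density: gene-body reads
x 1e6 / library size / gene length in kb.  Counting is gene-body
(intron-inclusive), the correct choice for nascent RNA.  Genes are then
classified into genome-wide expression quartiles (q1 lowest, containing
the silent genes; q4 highest; "highly transcribed" = q3 and q4) and into
size classes — small (<250 kb), medium (250-300 kb) and large (>300 kb),
with large genes split into four length-quartile subgroups L1 (largest)
to L4.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_genomics import BinnedTrack, GeneRecord

logger = logging.getLogger(__name__)

QUARTILES = ("q1", "q2", "q3", "q4")
LARGE_SUBGROUPS = ("L1", "L2", "L3", "L4")


def _gene_body_count(track: BinnedTrack, gene: GeneRecord) -> float:
    """Reads falling in the gene body; partial bins contribute their
    covered fraction (bin counts are treated as uniform across the bin)."""
    bs = track.bin_size
    v = track.values[gene.chrom]
    b0 = gene.start // bs
    b1 = (gene.end - 1) // bs
    total = 0.0
    for b in range(b0, b1 + 1):
        x = v[b]
        if np.isnan(x):
            continue
        seg = min(gene.end, (b + 1) * bs) - max(gene.start, b * bs)
        total += x * seg / bs
    return total


def quantify_expression(
    read_counts: BinnedTrack | Mapping[str, BinnedTrack],
    library_size: float,
    genes: Sequence[GeneRecord],
    condition: str = "control",
    silence_floor: float = 0.5,
) -> pd.DataFrame:
    """Per-gene RPM-normalised read density over the gene body.

    ``read_counts`` is a fine-binned (1 kb) count track, or a mapping
    ``{'+': track, '-': track}`` for strand-aware counting (a stranded
    gene is counted on its own strand; unstranded genes sum both).
    Density = (gene-body count x 1e6 / library_size) / (length in kb),
    so it is linear in counts and inversely linear in library size.
    Genes with density below ``silence_floor`` are flagged not expressed.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    stranded = isinstance(read_counts, Mapping)
    some_track = next(iter(read_counts.values())) if stranded else read_counts
    rows = []
    for g in genes:
        if g.chrom not in some_track.genome or g.end > some_track.genome[g.chrom]:
            raise ValueError(f"gene {g.gene_id} outside the genome")
        if stranded:
            if g.strand in read_counts:
                count = _gene_body_count(read_counts[g.strand], g)
            else:
                count = sum(_gene_body_count(t, g) for t in read_counts.values())
        else:
            count = _gene_body_count(read_counts, g)
        density = (count * 1e6 / library_size) / (g.length / 1000)
        rows.append(
            {
                "gene_id": g.gene_id,
                "length": g.length,
                "density": density,
                "condition": condition,
                "expressed": density >= silence_floor,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "length", "density", "condition", "expressed"])


def classify_quartiles(
    records: pd.DataFrame, restrict_expressed: bool = False
) -> pd.DataFrame:
    """Attach genome-wide expression-quartile labels to expression records.

    Quartile cut points come from the density distribution over all
    annotated genes (or, with ``restrict_expressed``, over expressed
    genes only, leaving the rest in q1).  Assignment is rank-based with
    stable tie handling so exact-zero densities land in q1; labels are
    therefore invariant under any strictly monotone transform of the
    densities.  Adds ``quartile`` and ``highly_transcribed`` (q3 or q4).
    """
    if len(records) < 4:
        raise ValueError("quartile classification needs >= 4 genes")
    out = records.copy()
    dens = out["density"].to_numpy()
    quart = np.array(["q1"] * len(out), dtype="<U2")
    pool = np.flatnonzero(out["expressed"].to_numpy()) if restrict_expressed else np.arange(len(out))
    if len(pool):
        vals = dens[pool]
        if np.all(vals == vals[0]):
            logger.warning("all densities identical: every gene labeled q1")
        else:
            order = np.argsort(vals, kind="stable")
            n = len(pool)
            bounds = [round(n * k / 4) for k in range(5)]
            for qi, q in enumerate(QUARTILES):
                quart[pool[order[bounds[qi] : bounds[qi + 1]]]] = q
    out["quartile"] = quart
    out["highly_transcribed"] = out["quartile"].isin(("q3", "q4"))
    return out


def classify_sizes(
    genes: Sequence[GeneRecord],
    large_cutoff: int = 300_000,
    small_cutoff: int = 250_000,
) -> pd.DataFrame:
    """Size classes: small < 250 kb <= medium <= 300 kb < large.

    Large genes (>300 kb, the class enriched at fragile sites) are
    additionally split into four length-quartile subgroups, L1 holding
    the largest quarter down to L4.
    """
    lengths = np.array([g.length for g in genes])
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    size_class = np.where(
        lengths > large_cutoff, "large", np.where(lengths < small_cutoff, "small", "medium")
    )
    sub = np.array([""] * len(genes), dtype="<U2")
    large_idx = np.flatnonzero(size_class == "large")
    if len(large_idx):
        order = np.argsort(-lengths[large_idx], kind="stable")  # largest first
        n = len(large_idx)
        bounds = [round(n * k / 4) for k in range(5)]
        for gi, grp in enumerate(LARGE_SUBGROUPS):
            sub[large_idx[order[bounds[gi] : bounds[gi + 1]]]] = grp
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "length": lengths,
            "size_class": size_class,
            "large_subgroup": sub,
            "is_large": size_class == "large",
        }
    )
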