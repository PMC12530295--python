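"""Gene selection and degenerate-site extraction for dating loci.

To date splits free of purifying selection, only sites where synonymous
change is possible are used: for each included protein-coding gene the
reference strain's coding sequence is walked codon by codon and the
alignment columns at 4-fold and 2-fold degenerate positions are
concatenated, in genomic order, into one alignment per locus.

Degeneracy of a codon position is the number of nucleotides at that
position (including the observed one) that leave the encoded amino acid
unchanged under the standard genetic code.  Stop codons and reference
codons containing N or gaps are skipped entirely; 3-fold degenerate
positions (the isoleucine family) belong to neither extracted class.

Genes are excluded when they contain introns, overlap another gene, or
have low-quality sequence (N/gap in any strain) over at least 50% of
their alignment columns.  Degeneracy is classified on a designated
reference strain; columns where another strain's codon implies a
different degeneracy class are kept but flagged in the provenance table
so the disagreement stays auditable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .seqs import MISSING, StrainGenome, decode, reverse_complement

_BASES = "ACGT"

#: codon string -> translated symbol, with '*' for stops
TRANSLATION: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    TRANSLATION[_stop] = "*"

#: codon string -> (degeneracy at position 1, 2, 3)
DEGENERACY: dict[str, tuple[int, int, int]] = {}
for _codon in map("".join, itertools.product(_BASES, repeat=3)):
    degs = []
    for _p in range(3):
        aa = TRANSLATION[_codon]
        degs.append(
            sum(
                TRANSLATION[_codon[:_p] + b + _codon[_p + 1:]] == aa
                for b in _BASES
            )
        )
    DEGENERACY[_codon] = tuple(degs)

# vectorised lookups over the codon index 16*b1 + 4*b2 + b3 (A=0..T=3)
_DEG_LUT = np.zeros((3, 64), dtype=np.int8)
_STOP_LUT = np.zeros(64, dtype=bool)
for _codon, _degs in DEGENERACY.items():
    _idx = 16 * _BASES.index(_codon[0]) + 4 * _BASES.index(_codon[1]) + _BASES.index(_codon[2])
    _DEG_LUT[:, _idx] = _degs
    _STOP_LUT[_idx] = TRANSLATION[_codon] == "*"


def classify_codon_degeneracy(codon: str, position: int) -> int | None:
    """Degeneracy (1-4) of ``position`` (1-based) in ``codon``; None when
    the codon contains a base outside ACGT."""
    if position not in (1, 2, 3):
        raise ValueError("position must be 1, 2 or 3")
    codon = codon.upper()
    if codon not in DEGENERACY:
        return None
    return DEGENERACY[codon][position - 1]


@dataclass
class GeneAnnotation:
    """A gene interval (0-based half-open) with the exclusion flags."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    has_intron: bool = False
    overlaps_other_gene: bool = False
    low_quality_fraction: float = 0.0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def select_genes(
    annotations: list[GeneAnnotation],
    genomes: list[StrainGenome] | None = None,
) -> tuple[list[GeneAnnotation], dict[str, int]]:
    """Apply the gene exclusion rules; returns (included, tally).

    With ``genomes`` supplied, ``low_quality_fraction`` is recomputed as
    the fraction of the gene's columns that are N/gap in any strain.
    Exclusion reasons are tallied by the first matching rule, in order:
    intron, overlap, low quality (>= 50%, inclusive).
    """
    included: list[GeneAnnotation] = []
    tally = {"intron": 0, "overlap": 0, "low_quality": 0}
    for gene in annotations:
        if genomes is not None:
            bad = np.zeros(gene.length, dtype=bool)
            for g in genomes:
                bad |= g.sequences[gene.chrom][gene.start:gene.end] == MISSING
            gene.low_quality_fraction = float(bad.mean())
        if gene.has_intron:
            tally["intron"] += 1
        elif gene.overlaps_other_gene:
            tally["overlap"] += 1
        elif gene.low_quality_fraction >= 0.5:
            tally["low_quality"] += 1
        else:
            included.append(gene)
    return included, tally


@dataclass
class DegenerateAlignment:
    """Concatenated degenerate-site columns with per-site provenance.

    ``data`` rows are in coding orientation (minus-strand genes are
    reverse-complemented before the codon walk).  ``provenance`` columns:
    gene, chrom, pos (0-based genomic), codon_index, codon_pos (1-3),
    degeneracy, discordant (a strain's own codon implies a different
    degeneracy class at this position).
    """

    ids: list[str]
    data: np.ndarray
    provenance: pd.DataFrame
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def to_alignment(self):
        from .phylo import Alignment

        return Alignment(list(self.ids), self.data)


def _coding_array(genome: StrainGenome, gene: GeneAnnotation) -> np.ndarray:
    seg = genome.sequences[gene.chrom][gene.start:gene.end]
    return reverse_complement(seg) if gene.strand == "-" else seg.copy()


def extract_degenerate_alignment(
    genomes: list[StrainGenome],
    genes: list[GeneAnnotation],
    classes: set[int] = frozenset({2, 4}),
    reference: str | None = None,
) -> DegenerateAlignment:
    """Extract and concatenate degenerate-site columns across genes.

    ``reference`` names the strain whose codons define degeneracy
    (default: the first genome).  Genes whose length is not a multiple
    of three are skipped and listed in ``skipped``.
    """
    if not genomes:
        raise ValueError("no genomes supplied")
    ids = [g.strain for g in genomes]
    reference = reference or ids[0]
    if reference not in ids:
        raise ValueError(f"reference strain {reference!r} not among genomes")
    ref_genome = genomes[ids.index(reference)]
    classes = set(classes)

    columns: list[np.ndarray] = []
    prov_rows: list[pd.DataFrame] = []
    skipped: list[tuple[str, str]] = []

    for gene in sorted(genes, key=lambda g: (g.chrom, g.start)):
        if gene.length % 3 != 0:
            skipped.append((gene.gene_id, "length_not_multiple_of_3"))
            continue
        n_codons = gene.length // 3
        ref_cod = _coding_array(ref_genome, gene).reshape(n_codons, 3)
        valid = (ref_cod <= 3).all(axis=1)
        cidx = (16 * ref_cod[:, 0].astype(np.int32)
                + 4 * ref_cod[:, 1].astype(np.int32)
                + ref_cod[:, 2].astype(np.int32))
        cidx[~valid] = 0
        keep_codon = valid & ~_STOP_LUT[cidx]

        strain_cod = np.stack([_coding_array(g, gene) for g in genomes]).reshape(
            len(genomes), n_codons, 3
        )
        s_valid = (strain_cod <= 3).all(axis=2)
        s_idx = (16 * strain_cod[:, :, 0].astype(np.int32)
                 + 4 * strain_cod[:, :, 1].astype(np.int32)
                 + strain_cod[:, :, 2].astype(np.int32))
        s_idx[~s_valid] = 0

        # coding-offset -> genomic position map
        offsets = np.arange(gene.length)
        genomic = gene.start + offsets if gene.strand == "+" else gene.end - 1 - offsets

        for pos in range(3):
            deg = _DEG_LUT[pos][cidx]
            sel = keep_codon & np.isin(deg, list(classes))
            if not sel.any():
                continue
            codon_ids = np.flatnonzero(sel)
            off = codon_ids * 3 + pos
            cols = strain_cod[:, codon_ids, pos]
            s_deg = _DEG_LUT[pos][s_idx[:, codon_ids]]
            discord = (s_valid[:, codon_ids] & (s_deg != deg[codon_ids])).any(axis=0)
            columns.append(cols)
            prov_rows.append(
                pd.DataFrame(
                    {
                        "gene": gene.gene_id,
                        "chrom": gene.chrom,
                        "pos": genomic[off],
                        "codon_index": codon_ids,
                        "codon_pos": pos + 1,
                        "degeneracy": deg[codon_ids],
                        "discordant": discord,
                    }
                )
            )

    if columns:
        data = np.concatenate(columns, axis=1).astype(np.uint8)
        prov = pd.concat(prov_rows, ignore_index=True)
        # restore codon order within each gene (columns were emitted per
        # codon position); sort by gene order then codon then position
        gene_order = {g.gene_id: i for i, g in
                      enumerate(sorted(genes, key=lambda g: (g.chrom, g.start)))}
        prov["_g"] = prov["gene"].map(gene_order)
        order = prov.sort_values(["_g", "codon_index", "codon_pos"],
                                 kind="stable").index.to_numpy()
        prov = prov.loc[order].drop(columns="_g").reset_index(drop=True)
        data = data[:, order]
    else:
        data = np.zeros((len(genomes), 0), dtype=np.uint8)
        prov = pd.DataFrame(
            columns=["gene", "chrom", "pos", "codon_index",
                     "codon_pos", "degeneracy", "discordant"]
        )
    return DegenerateAlignment(ids, data, prov, skipped)


def degenerate_fasta_records(daln: DegenerateAlignment) -> list[tuple[str, str]]:
    """(id, sequence) pairs for FASTA output of the extracted sites."""
    return [(sid, decode(row)) for sid, row in zip(daln.ids, daln.data)]
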