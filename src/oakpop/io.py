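"""File formats: FASTA genomes/alignments, VCF variant profiles, BED
tracts, TSV tables, Newick trees, YAML configs."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon import GeneAnnotation
from .dating import GenerationModel
from .paint import PaintingProfile
from .phylo import Alignment, DistanceMatrix
from .qc import VariantProfile
from .seqs import StrainGenome, decode, encode
from .simulate import (
    AdmixtureSpec,
    ContaminationSpec,
    HetSpec,
    SimulationConfig,
)

# ---------------------------------------------------------------------------
# FASTA


def write_genome_fasta(genome: StrainGenome, path) -> None:
    records = [
        SeqRecord(Seq(decode(seq)), id=chrom, description="")
        for chrom, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path, strain: str | None = None) -> StrainGenome:
    path = Path(path)
    strain = strain or path.stem
    sequences = {
        rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return StrainGenome(strain, sequences)


def write_alignment_fasta(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(decode(row)), id=sid, description="")
        for sid, row in zip(aln.ids, aln.data)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_fasta(path) -> Alignment:
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(encode(str(rec.seq)))
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    return Alignment(ids, np.vstack(rows))


# ---------------------------------------------------------------------------
# VCF


def write_profile_vcf(profile: VariantProfile, path) -> None:
    """Plain-text VCF of the variant records; consensus call as REF, the
    secondary allele as ALT, with GT:AD:DP genotype fields.  Genome-wide
    summaries (callable length, mean depth) ride in header lines."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##oakpop_callable_length={profile.callable_length()}\n")
        fh.write(f"##oakpop_genome_length={profile.genome_length}\n")
        fh.write(f"##oakpop_mean_depth={profile.mean_depth:.4f}\n")
        for chrom, seq in profile.sequences.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{profile.strain}\n"
        )
        for rec in profile.records.itertuples(index=False):
            gt = "0/1" if rec.genotype == "het" else "0/0"
            depth = int(rec.depth)
            alt_depth = int(rec.alt_depth)
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.base}\t{rec.alt}\t{int(rec.qual)}"
                f"\t.\t.\tGT:AD:DP\t{gt}:{depth - alt_depth},{alt_depth}:{depth}\n"
            )


def read_profile_vcf(path) -> VariantProfile:
    """Read a profile written by :func:`write_profile_vcf`.

    Per-site qualities are not represented in VCF, so the returned
    profile carries an all-callable quality track of the recorded
    callable length; it supports the QC statistics but not re-masking.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strain = vcf.samples[0]
    callable_length = None
    mean_depth = 0.0
    contigs: dict[str, int] = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##oakpop_callable_length="):
            callable_length = int(line.split("=", 1)[1])
        elif line.startswith("##oakpop_mean_depth="):
            mean_depth = float(line.split("=", 1)[1])
        elif line.startswith("##contig="):
            body = line[len("##contig=<"):].rstrip(">")
            fields = dict(kv.split("=") for kv in body.split(","))
            contigs[fields["ID"]] = int(fields["length"])
    rows = []
    for v in vcf:
        ad = v.format("AD")
        dp = int(v.format("DP")[0][0])
        alt_depth = int(ad[0][1]) if ad is not None and ad.shape[1] > 1 else 0
        gts = v.genotypes[0]
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "genotype": "het" if gts[0] != gts[1] else "hom",
                "base": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
                "qual": int(v.QUAL) if v.QUAL is not None else 0,
                "depth": dp,
                "alt_depth": alt_depth,
            }
        )
    records = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "genotype", "base", "alt", "qual", "depth", "alt_depth"],
    )
    if callable_length is None:
        callable_length = sum(contigs.values())
    # synthesise a quality track reproducing the recorded callable length
    quals = {}
    sequences = {}
    remaining = callable_length
    for chrom, length in contigs.items():
        q = np.zeros(length, dtype=np.uint8)
        n_call = min(length, remaining)
        q[:n_call] = 60
        remaining -= n_call
        quals[chrom] = q
        sequences[chrom] = np.zeros(length, dtype=np.uint8)
    return VariantProfile(strain, sequences, quals, records, mean_depth)


# ---------------------------------------------------------------------------
# tables


def write_clades_tsv(truth_clades: dict[str, str], path) -> None:
    pd.DataFrame(
        {"strain": list(truth_clades), "clade": list(truth_clades.values())}
    ).to_csv(path, sep="\t", index=False)


def read_clades_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["strain"], df["clade"]))


def write_genes_tsv(genes: list[GeneAnnotation], path) -> None:
    pd.DataFrame([dataclasses.asdict(g) for g in genes]).to_csv(
        path, sep="\t", index=False
    )


def read_genes_tsv(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [GeneAnnotation(**row) for row in df.to_dict("records")]


def write_tracts_bed(tracts: dict[str, list[tuple[str, int, int, str]]], path) -> None:
    """Truth tracts as BED: chrom, start, end, recipient|donor_clade."""
    with open(path, "w") as fh:
        for strain, ivals in tracts.items():
            for chrom, start, end, donor in ivals:
                fh.write(f"{chrom}\t{start}\t{end}\t{strain}|{donor}\n")


def write_painting_bed(profile: PaintingProfile, path) -> None:
    with open(path, "w") as fh:
        for w in profile.windows:
            label = w.best_clade if w.status == "assigned" else w.status
            score = "" if w.min_prop_diff != w.min_prop_diff else f"{w.min_prop_diff:.6f}"
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{label}\t{score}\n")


def write_composition_tsv(profiles: list[PaintingProfile], path) -> None:
    clades = sorted({c for p in profiles for c in p.composition})
    rows = []
    for p in profiles:
        row = {"strain": p.strain, "primary_clade": p.primary_clade or "",
               "admixed": p.admixed,
               "diverged_fraction": p.diverged_fraction,
               "low_coverage_fraction": p.low_coverage_fraction}
        for c in clades:
            row[c] = p.composition.get(c, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_phylip(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for sid, row in zip(dm.ids, dm.values):
            fh.write(sid[:10].ljust(10) + " ".join(f"{x:.8f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# config YAML


def config_to_yaml(config: SimulationConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["admixture_specs"] = [dataclasses.asdict(s) for s in config.admixture_specs]
    data["het_specs"] = [dataclasses.asdict(s) for s in config.het_specs]
    data["contamination_specs"] = [
        dataclasses.asdict(s) for s in config.contamination_specs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "generation_model" in data and isinstance(data["generation_model"], dict):
        data["generation_model"] = GenerationModel(**data["generation_model"])
    data["admixture_specs"] = [
        AdmixtureSpec(
            s["recipient"], s["donor_clade"],
            [tuple(t) for t in s["tracts"]],
        )
        for s in data.get("admixture_specs", [])
    ]
    data["het_specs"] = [HetSpec(**s) for s in data.get("het_specs", [])]
    data["contamination_specs"] = [
        ContaminationSpec(**s) for s in data.get("contamination_specs", [])
    ]
    data["extra_strains"] = [tuple(x) for x in data.get("extra_strains", [])]
    return SimulationConfig(**data)


def write_newick(tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick"))
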