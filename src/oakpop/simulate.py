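"""Synthetic yeast cohorts with known clade structure and ground truth.

The generator emulates the data a consensus-calling pipeline produces
for a structured population of clonal, homozygous wild yeast: per-strain
chromosome sequences descended from a shared ancestor along an
ultrametric clade tree, mosaic (admixed) genomes built from explicit
donor tracts, heterozygous and contaminated strains with matching
read-support profiles, and intron-free protein-coding genes for
degenerate-site extraction.  Every injected feature is recorded in a
machine-readable truth map.

Branch lengths are converted from years to expected substitutions per
site as ``years * generations_per_year * mu``; mutations are placed
independently and uniformly per site per branch (Jukes--Cantor-like),
with a configurable transition fraction so that transition/transversion
asymmetry is available to TN93 estimation.  Two clades that split T
years ago therefore show an expected pairwise divergence of
``2 * T * g * mu``.  There is no recombination apart from explicit
admixture tracts, no indels, and no selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon import GeneAnnotation
from .dating import GenerationModel, generations_per_year
from .qc import VariantProfile
from .seqs import StrainGenome, decode

#: saturation guard: expected divergences beyond this are rejected
MAX_EXPECTED_DIVERGENCE = 0.75


@dataclass
class AdmixtureSpec:
    recipient: str
    donor_clade: str
    tracts: list[tuple[str, int, int]]  # (chrom, start, end) 0-based half-open


@dataclass
class HetSpec:
    strain: str
    rate: float  # heterozygous sites per callable bp


@dataclass
class ContaminationSpec:
    strain: str
    contaminant_clade: str
    fraction: float  # mixing fraction of contaminant reads, in (0, 0.5]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``split_times_years`` encodes an ultrametric clade history as merge
    events: each key is ``"X|Y"`` where X and Y are '+'-joined groups of
    clade names that have already been formed (single clades to begin
    with), and the value is the time of their split in years.  Splits are
    applied in increasing time order and must end in a single group
    containing every clade.
    """

    seed: int = 0
    clades: list[str] = field(default_factory=lambda: ["cladeA", "cladeB"])
    strains_per_clade: int = 3
    chromosome_lengths: list[int] = field(default_factory=lambda: [200_000])
    split_times_years: dict[str, float] = field(
        default_factory=lambda: {"cladeA|cladeB": 10_000.0}
    )
    within_clade_time_years: float = 1_500.0
    mu: float = 1.67e-10
    generation_model: GenerationModel = field(default_factory=GenerationModel)
    transition_fraction: float = 0.7
    gene_density_per_10kb: float = 1.0
    gene_length_codons: int = 400
    n_intron_genes: int = 0
    n_overlap_genes: int = 0
    extra_strains: list[tuple[str, str]] = field(default_factory=list)
    admixture_specs: list[AdmixtureSpec] = field(default_factory=list)
    het_specs: list[HetSpec] = field(default_factory=list)
    contamination_specs: list[ContaminationSpec] = field(default_factory=list)
    mean_depth: float = 50.0
    depth_overrides: dict[str, float] = field(default_factory=dict)
    base_error_rate: float = 0.002
    low_quality_rate: float = 0.005
    make_profiles: bool = True

    def validate(self) -> None:
        if len(set(self.clades)) != len(self.clades) or not self.clades:
            raise ValueError("clades must be non-empty and unique")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("all chromosome lengths must be > 0")
        if self.strains_per_clade < 1:
            raise ValueError("strains_per_clade must be >= 1")
        if not 0 < self.transition_fraction < 1:
            raise ValueError("transition_fraction must be in (0, 1)")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        for spec in self.contamination_specs:
            if not 0 < spec.fraction <= 0.5:
                raise ValueError("contamination fraction must be in (0, 0.5]")
        for spec in self.het_specs:
            if spec.rate < 0:
                raise ValueError("heterozygosity rate must be >= 0")
        merges = parse_split_times(self.split_times_years, self.clades)
        root_time = merges[-1][2] if merges else self.within_clade_time_years
        g = generations_per_year(self.generation_model)
        if 2 * root_time * g * self.mu > MAX_EXPECTED_DIVERGENCE:
            raise ValueError(
                "expected divergence exceeds the saturation limit "
                f"({MAX_EXPECTED_DIVERGENCE}); reduce split times or mu"
            )
        if len(self.clades) > 1:
            min_split = min(t for _, _, t in merges)
            if min_split <= self.within_clade_time_years:
                raise ValueError(
                    "every split time must exceed within_clade_time_years"
                )
        lengths = dict(self.chromosome_names_lengths())
        for spec in self.admixture_specs:
            if spec.donor_clade not in self.clades:
                raise ValueError(f"unknown donor clade {spec.donor_clade!r}")
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for chrom, start, end in spec.tracts:
                if chrom not in lengths:
                    raise ValueError(f"unknown chromosome {chrom!r}")
                if not 0 <= start < end <= lengths[chrom]:
                    raise ValueError(f"tract [{start}, {end}) out of bounds on {chrom}")
                by_chrom.setdefault(chrom, []).append((start, end))
            for ivals in by_chrom.values():
                ivals.sort()
                for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                    if s2 < e1:
                        raise ValueError("admixture tracts overlap")

    def chromosome_names_lengths(self) -> list[tuple[str, int]]:
        return [
            (f"chr{i + 1:02d}", length)
            for i, length in enumerate(self.chromosome_lengths)
        ]

    @property
    def n_clades(self) -> int:
        return len(self.clades)


def parse_split_times(
    split_times_years: dict[str, float], clades: list[str]
) -> list[tuple[frozenset, frozenset, float]]:
    """Resolve the merge encoding into (left_group, right_group, time)
    triples ordered by time; validates that the merges form a tree over
    exactly the configured clades."""
    if len(clades) == 1:
        if split_times_years:
            raise ValueError("split times given for a single-clade cohort")
        return []
    groups = {frozenset([c]) for c in clades}
    merges = []
    for name, t in sorted(split_times_years.items(), key=lambda kv: (kv[1], kv[0])):
        try:
            left_s, right_s = name.split("|")
        except ValueError:
            raise ValueError(f"split name {name!r} must be 'X|Y'") from None
        left = frozenset(left_s.split("+"))
        right = frozenset(right_s.split("+"))
        if left not in groups or right not in groups:
            raise ValueError(f"split {name!r} does not merge two existing groups")
        groups.remove(left)
        groups.remove(right)
        groups.add(left | right)
        merges.append((left, right, float(t)))
    if groups != {frozenset(clades)}:
        raise ValueError("split times do not resolve to a single rooted history")
    times = [t for _, _, t in merges]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("merge times must be non-decreasing")
    return merges


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    genomes: list[StrainGenome]
    truth_clades: dict[str, str]
    truth_tracts: dict[str, list[tuple[str, int, int, str]]]
    truth_split_times: dict[str, float]
    variant_profiles: dict[str, VariantProfile]
    annotations: list[GeneAnnotation]
    ancestral: StrainGenome | None = None

    def genome(self, strain: str) -> StrainGenome:
        for g in self.genomes:
            if g.strain == strain:
                return g
        raise KeyError(strain)

    def strains_in_clade(self, clade: str) -> list[str]:
        return [s for s, c in self.truth_clades.items() if c == clade]

    @property
    def strains(self) -> list[str]:
        return [g.strain for g in self.genomes]


def _mutate(seq: np.ndarray, expected_subs_per_site: float, rng, ti_frac: float) -> np.ndarray:
    """One branch of evolution: per-site substitution probability p, with
    a transition chosen with probability ``ti_frac``."""
    out = seq.copy()
    p = expected_subs_per_site
    if p <= 0:
        return out
    idx = np.flatnonzero(rng.random(seq.size) < p)
    if idx.size:
        u = rng.random(idx.size)
        b = out[idx]
        tv_split = ti_frac + (1 - ti_frac) / 2
        out[idx] = np.where(u < ti_frac, b ^ 2, np.where(u < tv_split, b ^ 1, b ^ 3))
    return out


def _place_genes(config: SimulationConfig, rng) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    glen = 3 * config.gene_length_codons
    for chrom, length in config.chromosome_names_lengths():
        n_genes = int(round(config.gene_density_per_10kb * length / 10_000))
        if n_genes == 0:
            continue
        slot = length // n_genes
        if slot <= glen + 2:
            n_genes = max(length // (glen + 3), 0)
            if n_genes == 0:
                continue
            slot = length // n_genes
        for i in range(n_genes):
            lo = i * slot
            start = int(lo + rng.integers(0, slot - glen))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneAnnotation(f"{chrom}_g{i + 1:03d}", chrom, start, start + glen, strand)
            )
    for g in genes[: config.n_intron_genes]:
        g.has_intron = True
    # overlapping genes: add a shifted copy over an existing clean gene
    clean = [g for g in genes if not g.has_intron]
    for j in range(min(config.n_overlap_genes, len(clean))):
        host = clean[j]
        shift = host.length // 2
        twin = GeneAnnotation(
            host.gene_id + "ov", host.chrom, host.start + shift,
            host.end + shift, host.strand,
            overlaps_other_gene=True,
        )
        host.overlaps_other_gene = True
        genes.append(twin)
    return genes


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a cohort under the configured study conditions.

    Deterministic given ``config.seed``: identical configurations yield
    byte-identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    g_per_year = generations_per_year(config.generation_model)
    rate = g_per_year * config.mu  # expected substitutions / site / year
    chrom_spec = config.chromosome_names_lengths()
    total_len = sum(l for _, l in chrom_spec)

    root = rng.integers(0, 4, size=total_len, dtype=np.uint8)
    merges = parse_split_times(config.split_times_years, config.clades)

    # walk the merge tree top-down to produce one ancestor per clade at
    # height within_clade_time_years
    t_w = config.within_clade_time_years
    if merges:
        root_time = merges[-1][2]
        group_seqs: dict[frozenset, tuple[np.ndarray, float]] = {
            frozenset(config.clades): (root, root_time)
        }
        for left, right, t in reversed(merges):
            parent_seq, parent_time = group_seqs.pop(left | right)
            # the parent group's sequence sits at the split time t; evolve
            # down from the enclosing split first
            at_split = _mutate(parent_seq, (parent_time - t) * rate, rng,
                               config.transition_fraction)
            group_seqs[left] = (at_split, t)
            group_seqs[right] = (
                _mutate(at_split, 0.0, rng, config.transition_fraction), t
            )
        clade_anc = {}
        for group, (seq, t) in sorted(group_seqs.items(), key=lambda kv: sorted(kv[0])):
            (clade,) = group
            clade_anc[clade] = _mutate(seq, (t - t_w) * rate, rng,
                                       config.transition_fraction)
    else:
        (clade,) = config.clades
        clade_anc = {clade: _mutate(root, 0.0, rng, config.transition_fraction)}

    # strains: per-clade independent branches of length t_w
    strain_names: list[str] = []
    truth_clades: dict[str, str] = {}
    for clade in config.clades:
        for i in range(config.strains_per_clade):
            strain_names.append(f"{clade}_s{i + 1:02d}")
            truth_clades[strain_names[-1]] = clade
    for name, clade in config.extra_strains:
        if clade not in config.clades:
            raise ValueError(f"extra strain {name!r} has unknown clade {clade!r}")
        strain_names.append(name)
        truth_clades[name] = clade

    def split_chroms(flat: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        offset = 0
        for chrom, length in chrom_spec:
            out[chrom] = flat[offset: offset + length].copy()
            offset += length
        return out

    genomes = []
    for name in strain_names:
        flat = _mutate(clade_anc[truth_clades[name]], t_w * rate, rng,
                       config.transition_fraction)
        genomes.append(StrainGenome(name, split_chroms(flat)))

    annotations = _place_genes(config, rng)

    cohort = SyntheticCohort(
        config=config,
        genomes=genomes,
        truth_clades=truth_clades,
        truth_tracts={},
        truth_split_times=dict(config.split_times_years),
        variant_profiles={},
        annotations=annotations,
        ancestral=StrainGenome("__ancestor__", split_chroms(root)),
    )

    if config.admixture_specs:
        inject_admixture_tracts(cohort, config.admixture_specs, rng=rng)

    if config.make_profiles:
        het = {s.strain: s.rate for s in config.het_specs}
        cont = {s.strain: s for s in config.contamination_specs}
        for genome in cohort.genomes:
            spec = cont.get(genome.strain)
            contaminant = None
            if spec is not None:
                donor_strains = [
                    s for s in cohort.strains_in_clade(spec.contaminant_clade)
                    if s != genome.strain
                ]
                if not donor_strains:
                    raise ValueError(
                        f"no contaminant strains in clade {spec.contaminant_clade!r}"
                    )
                contaminant = cohort.genome(
                    donor_strains[rng.integers(0, len(donor_strains))]
                )
            cohort.variant_profiles[genome.strain] = synthesize_variant_profile(
                genome,
                cohort.ancestral,
                het_rate=het.get(genome.strain, 0.0),
                contamination_fraction=spec.fraction if spec else 0.0,
                contaminant=contaminant,
                mean_depth=config.depth_overrides.get(genome.strain, config.mean_depth),
                base_error_rate=config.base_error_rate,
                low_quality_rate=config.low_quality_rate,
                rng=rng,
            )
    return cohort


def inject_admixture_tracts(
    cohort: SyntheticCohort,
    specs: list[AdmixtureSpec],
    rng=None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Overwrite recipient sequence with a donor-clade strain's sequence
    over each tract; exact bp coordinates land in ``truth_tracts``."""
    if rng is None:
        rng = np.random.default_rng(seed)
    for spec in specs:
        recipient = cohort.genome(spec.recipient)
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in spec.tracts:
            for s, e in seen.get(chrom, []):
                if start < e and s < end:
                    raise ValueError("overlapping admixture tracts")
            seen.setdefault(chrom, []).append((start, end))
        donors = [
            s for s in cohort.strains_in_clade(spec.donor_clade) if s != spec.recipient
        ]
        if not donors:
            raise ValueError(f"no donor strains in clade {spec.donor_clade!r}")
        donor = cohort.genome(donors[rng.integers(0, len(donors))])
        for chrom, start, end in spec.tracts:
            recipient.sequences[chrom][start:end] = donor.sequences[chrom][start:end]
            cohort.truth_tracts.setdefault(spec.recipient, []).append(
                (chrom, start, end, spec.donor_clade)
            )
    return cohort


def synthesize_variant_profile(
    genome: StrainGenome,
    reference: StrainGenome,
    *,
    het_rate: float = 0.0,
    contamination_fraction: float = 0.0,
    contaminant: StrainGenome | None = None,
    mean_depth: float = 50.0,
    base_error_rate: float = 0.002,
    low_quality_rate: float = 0.005,
    quality_threshold: int = 40,
    seed: int | None = None,
    rng=None,
) -> VariantProfile:
    """Read-support profile consistent with the genome and the injected
    heterozygosity/contamination.

    Records cover three site classes: homozygous differences from the
    mapping reference (secondary reads = sequencing error), heterozygous
    sites placed at ``het_rate`` over callable positions with allele
    balance near 0.5, and -- when a contaminant genome is supplied --
    sites where the contaminant differs from the strain, with secondary
    reads at the mixing fraction.
    """
    if het_rate < 0:
        raise ValueError("het_rate must be >= 0")
    if not 0 <= contamination_fraction <= 0.5:
        raise ValueError("contamination_fraction must be in [0, 0.5]")
    if contamination_fraction > 0 and contaminant is None:
        raise ValueError("a contaminant genome is required when fraction > 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    quals: dict[str, np.ndarray] = {}
    frames: list[pd.DataFrame] = []
    depths_drawn: list[np.ndarray] = []

    for chrom, seq in genome.sequences.items():
        L = len(seq)
        qual = np.full(L, 60, dtype=np.uint8)
        low = rng.random(L) < low_quality_rate
        n_low = int(low.sum())
        if n_low:
            qual[low] = rng.integers(2, 40, size=n_low, dtype=np.uint8)
        quals[chrom] = qual
        callable_mask = (qual >= quality_threshold) & (seq <= 3)

        het_mask = np.zeros(L, dtype=bool)
        if het_rate > 0:
            het_mask = callable_mask & (rng.random(L) < het_rate)

        cont_mask = np.zeros(L, dtype=bool)
        if contamination_fraction > 0:
            cseq = contaminant.sequences[chrom]
            cont_mask = (seq <= 3) & (cseq <= 3) & (seq != cseq) & ~het_mask

        ref = reference.sequences[chrom]
        hom_mask = (seq <= 3) & (ref <= 3) & (seq != ref) & ~het_mask & ~cont_mask

        rows = []
        for mask, gtype in ((het_mask, "het"), (cont_mask, "cont"), (hom_mask, "hom")):
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            depth = np.maximum(rng.poisson(mean_depth, size=idx.size), 1)
            if gtype == "het":
                alt_depth = rng.binomial(depth, 0.5)
                alt = (seq[idx] + 1 + rng.integers(0, 3, size=idx.size)) % 4
                genotype = "het"
            elif gtype == "cont":
                alt_depth = rng.binomial(depth, contamination_fraction)
                alt = contaminant.sequences[chrom][idx]
                genotype = "hom"
            else:
                alt_depth = rng.binomial(depth, base_error_rate)
                alt = (seq[idx] + 1 + rng.integers(0, 3, size=idx.size)) % 4
                genotype = "hom"
            depths_drawn.append(depth)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": idx + 1,
                        "genotype": genotype,
                        "base": [decode(np.array([b], dtype=np.uint8)) for b in seq[idx]],
                        "alt": [decode(np.array([b], dtype=np.uint8)) for b in alt.astype(np.uint8)],
                        "qual": qual[idx],
                        "depth": depth,
                        "alt_depth": alt_depth,
                    }
                )
            )
        if rows:
            frames.append(pd.concat(rows, ignore_index=True))

    if frames:
        records = (
            pd.concat(frames, ignore_index=True)
            .sort_values(["chrom", "pos"], kind="stable")
            .reset_index(drop=True)
        )
    else:
        records = pd.DataFrame(
            columns=["chrom", "pos", "genotype", "base", "alt", "qual", "depth", "alt_depth"]
        ).astype({"pos": int, "qual": int, "depth": float, "alt_depth": float})

    realized_depth = (
        float(np.concatenate(depths_drawn).mean()) if depths_drawn else float(mean_depth)
    )
    return VariantProfile(
        strain=genome.strain,
        sequences={c: s.copy() for c, s in genome.sequences.items()},
        quals=quals,
        records=records,
        mean_depth=realized_depth,
    )


# ---------------------------------------------------------------------------
# presets


def paperlike_config(seed: int = 0) -> SimulationConfig:
    """Default study conditions: six clades on an ultrametric history with
    shallow (6.1 kya) and deep (19.8 and 40 kya) splits, three strains
    per clade, and extra strains exercising admixture, heterozygosity,
    and contamination.

    Within-clade coalescence of 1,500 years puts within-clade 30 kb
    window divergence well below the 0.003 painting threshold while
    between-clade windows mostly exceed it.
    """
    clades = [
        "AsiaA",
        "EuropeanOak",
        "NorthAmericanA",
        "NorthAmericanB",
        "Taiwanese",
        "WineEuropean",
    ]
    splits = {
        "EuropeanOak|WineEuropean": 6_100.0,
        "NorthAmericanA|NorthAmericanB": 9_000.0,
        "EuropeanOak+WineEuropean|NorthAmericanA+NorthAmericanB": 11_600.0,
        "AsiaA|EuropeanOak+NorthAmericanA+NorthAmericanB+WineEuropean": 19_800.0,
        "AsiaA+EuropeanOak+NorthAmericanA+NorthAmericanB+WineEuropean|Taiwanese": 40_000.0,
    }
    return SimulationConfig(
        seed=seed,
        clades=clades,
        strains_per_clade=3,
        chromosome_lengths=[240_000] * 4,
        split_times_years=splits,
        within_clade_time_years=1_500.0,
        gene_density_per_10kb=1.5,
        gene_length_codons=400,
        extra_strains=[
            ("mosaic_EU1", "EuropeanOak"),
            ("het_WE1", "WineEuropean"),
            ("contam_NA1", "NorthAmericanA"),
        ],
        admixture_specs=[
            AdmixtureSpec(
                "mosaic_EU1",
                "NorthAmericanA",
                [("chr01", 45_000, 135_000), ("chr03", 100_000, 190_000)],
            ),
            AdmixtureSpec("mosaic_EU1", "WineEuropean", [("chr02", 60_000, 150_000)]),
        ],
        het_specs=[HetSpec("het_WE1", 0.002)],
        contamination_specs=[ContaminationSpec("contam_NA1", "AsiaA", 0.10)],
    )


def mosaic_config(seed: int = 0) -> SimulationConfig:
    """Three deep clades and two mosaic query strains carrying 18 donor
    tracts of 90 kb at off-window coordinates, for tract-recovery checks.

    The shallowest split (15 kya) puts donor/recipient divergence near
    0.0073, comfortably above twice the painting threshold.
    """
    chrom_lengths = [300_000] * 6
    chroms = [f"chr{i + 1:02d}" for i in range(len(chrom_lengths))]
    tracts1 = [(c, 47_000, 137_000) for c in chroms]
    tracts1 += [(c, 190_000, 280_000) for c in chroms]
    tracts2a = [(c, 190_000, 280_000) for c in chroms[:3]]
    tracts2b = [(c, 190_000, 280_000) for c in chroms[3:]]
    return SimulationConfig(
        seed=seed,
        clades=["cladeA", "cladeB", "cladeC"],
        strains_per_clade=3,
        chromosome_lengths=chrom_lengths,
        split_times_years={
            "cladeA|cladeB": 15_000.0,
            "cladeA+cladeB|cladeC": 25_000.0,
        },
        within_clade_time_years=1_500.0,
        extra_strains=[("mosaic1", "cladeA"), ("mosaic2", "cladeA")],
        admixture_specs=[
            AdmixtureSpec("mosaic1", "cladeB", tracts1),
            AdmixtureSpec("mosaic2", "cladeB", tracts2a),
            AdmixtureSpec("mosaic2", "cladeC", tracts2b),
        ],
        make_profiles=False,
    )


def dating_config(seed: int = 0, n_loci: int = 16, locus_length: int = 60_000,
                  split_years: float = 12_000.0) -> SimulationConfig:
    """Two clades plus an outgroup clade, one chromosome per dating locus,
    gene-dense so each locus yields several thousand degenerate sites."""
    return SimulationConfig(
        seed=seed,
        clades=["cladeA", "cladeB", "outgroup"],
        strains_per_clade=3,
        chromosome_lengths=[locus_length] * n_loci,
        split_times_years={
            "cladeA|cladeB": split_years,
            "cladeA+cladeB|outgroup": 30_000.0,
        },
        within_clade_time_years=1_500.0,
        gene_density_per_10kb=2.0,
        gene_length_codons=400,
        make_profiles=False,
    )
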