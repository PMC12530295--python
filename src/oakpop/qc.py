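"""Strain-level quality control for consensus genomes.

Implements the filters applied to diploid consensus sequences before
population analysis: quality masking (bases under a phred threshold
become N), genome-wide heterozygosity (heterozygous point substitutions
per high-quality base), a read-support contamination check, mean-depth
and duplicate filtering.  All thresholds are strict inequalities:
heterozygosity must be *over* 0.001, contamination *over* 1%, and depth
*below* 30x, for a strain to be removed.

The contamination statistic operationalises a visual allele-balance
check: among callable variant sites, the fraction whose consensus is
homozygous yet whose secondary allele is supported by an intermediate
fraction of reads (default band 0.10--0.35) -- too high for sequencing
error, too low for a diploid heterozygote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqs import MISSING, StrainGenome


@dataclass
class VariantProfile:
    """Per-site consensus calls with read support for one strain.

    ``sequences``/``quals`` hold the full consensus and its per-site
    phred qualities per chromosome.  ``records`` lists the variant-like
    sites (heterozygous calls, sites differing from the mapping
    reference, sites with secondary-allele reads) with columns
    ``chrom, pos`` (1-based), ``genotype`` ("hom"/"het"), ``base``,
    ``alt``, ``qual``, ``depth``, ``alt_depth``.
    """

    strain: str
    sequences: dict[str, np.ndarray]
    quals: dict[str, np.ndarray]
    records: pd.DataFrame
    mean_depth: float

    REQUIRED_COLUMNS = ("chrom", "pos", "genotype", "qual", "depth", "alt_depth")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")

    @property
    def genome_length(self) -> int:
        return sum(len(q) for q in self.quals.values())

    def callable_length(self, quality_threshold: int = 40) -> int:
        """Number of bases with phred quality >= the threshold."""
        return int(sum((q >= quality_threshold).sum() for q in self.quals.values()))


@dataclass
class QCConfig:
    quality_threshold: int = 40
    het_threshold: float = 0.001
    contamination_fraction_threshold: float = 0.01
    min_mean_depth: float = 30.0
    # secondary-allele read fraction consistent with neither homozygous
    # noise nor a diploid 0.5 heterozygote
    contamination_band: tuple[float, float] = (0.10, 0.35)

    def __post_init__(self):
        for name in ("quality_threshold", "het_threshold",
                     "contamination_fraction_threshold", "min_mean_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class QCReport:
    strain: str
    heterozygosity: float
    contamination_fraction: float
    mean_depth: float
    has_metadata: bool = True
    decisions: list[tuple[str, bool]] = field(default_factory=list)
    overall: str = "keep"
    reason: str | None = None


def mask_low_quality(profile: VariantProfile, quality_threshold: int = 40) -> StrainGenome:
    """Consensus genome with every base below the phred threshold set to N."""
    if quality_threshold <= 0:
        raise ValueError("quality_threshold must be > 0")
    masked = {}
    for chrom, seq in profile.sequences.items():
        out = seq.copy()
        out[profile.quals[chrom] < quality_threshold] = MISSING
        masked[chrom] = out
    return StrainGenome(profile.strain, masked)


def estimate_heterozygosity(profile: VariantProfile, quality_threshold: int = 40) -> float:
    """Heterozygous point substitutions per high-quality base."""
    callable_length = profile.callable_length(quality_threshold)
    if callable_length == 0:
        raise ValueError("callable_length is zero: heterozygosity undefined")
    recs = profile.records
    n_het = int(((recs["genotype"] == "het") & (recs["qual"] >= quality_threshold)).sum())
    return n_het / callable_length


def detect_contamination(profile: VariantProfile, cfg: QCConfig | None = None) -> tuple[bool, float]:
    """Flag a strain whose homozygous calls show intermediate secondary-
    allele read support at a frequency over the threshold.

    Returns ``(flag, fraction)`` where ``fraction`` is computed over
    callable variant sites and the flag applies the strict "over"
    comparison.
    """
    cfg = cfg or QCConfig()
    recs = profile.records
    if recs["depth"].isna().all() and len(recs):
        raise ValueError("variant records carry no read-depth information")
    callable_recs = recs[(recs["qual"] >= cfg.quality_threshold) & (recs["depth"] > 0)]
    if len(callable_recs) == 0:
        return False, 0.0
    frac = callable_recs["alt_depth"] / callable_recs["depth"]
    lo, hi = cfg.contamination_band
    in_band = (callable_recs["genotype"] == "hom") & (frac >= lo) & (frac <= hi)
    fraction = float(in_band.sum() / len(callable_recs))
    return fraction > cfg.contamination_fraction_threshold, fraction


def qc_report(profile: VariantProfile, cfg: QCConfig | None = None,
              has_metadata: bool = True) -> QCReport:
    """Evaluate the per-strain statistics feeding :func:`filter_cohort`."""
    cfg = cfg or QCConfig()
    het = estimate_heterozygosity(profile, cfg.quality_threshold)
    _, contamination = detect_contamination(profile, cfg)
    report = QCReport(
        strain=profile.strain,
        heterozygosity=het,
        contamination_fraction=contamination,
        mean_depth=profile.mean_depth,
        has_metadata=has_metadata,
    )
    _apply_rules(report, cfg, duplicate=False)
    return report


_RULES = ("duplicate", "missing_metadata", "low_depth", "contamination", "heterozygosity")


def _apply_rules(report: QCReport, cfg: QCConfig, duplicate: bool) -> None:
    checks = {
        "duplicate": not duplicate,
        "missing_metadata": report.has_metadata,
        "low_depth": not report.mean_depth < cfg.min_mean_depth,
        "contamination": not report.contamination_fraction
        > cfg.contamination_fraction_threshold,
        "heterozygosity": not report.heterozygosity > cfg.het_threshold,
    }
    report.decisions = [(rule, checks[rule]) for rule in _RULES]
    failures = [rule for rule in _RULES if not checks[rule]]
    report.overall = "keep" if not failures else "remove"
    report.reason = failures[0] if failures else None


def filter_cohort(
    reports: list[QCReport],
    cfg: QCConfig | None = None,
    duplicates: dict[str, str] | None = None,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Apply the removal rules in order (duplicate, missing metadata, low
    depth, contamination, heterozygosity); each removed strain carries
    its first triggering reason.  Output order follows input order, and
    the kept set does not depend on report order."""
    cfg = cfg or QCConfig()
    duplicates = duplicates or {}
    seen = set()
    for r in reports:
        if r.strain in seen:
            raise ValueError(f"duplicate report for strain {r.strain}")
        seen.add(r.strain)
    kept: list[str] = []
    removed: list[tuple[str, str]] = []
    for r in reports:
        _apply_rules(r, cfg, duplicate=r.strain in duplicates)
        if r.overall == "keep":
            kept.append(r.strain)
        else:
            removed.append((r.strain, r.reason))
    return kept, removed


def reports_to_frame(reports: list[QCReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "strain": r.strain,
                "heterozygosity": r.heterozygosity,
                "contamination_fraction": r.contamination_fraction,
                "mean_depth": r.mean_depth,
                "overall": r.overall,
                "reason": r.reason or "",
            }
        )
    return pd.DataFrame(rows)
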