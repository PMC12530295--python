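"""In-silico chromosome painting against a clade-labelled backbone panel.

Each non-overlapping 30 kb window of a query genome is compared to every
backbone strain by the proportion of differing sites (pairwise
deletion).  The window is painted with the clade of the most similar
backbone strain; windows diverged from every backbone sequence (minimum
proportion over the 0.003 threshold) are "white" (diverged), and
windows with too few comparable sites are "black" (low coverage).
Per-strain composition is summarised over assigned windows only --
diverged windows are excluded so that ancestral polymorphism does not
masquerade as ancestry -- and a strain is flagged admixed when no
single clade reaches the primary-ancestry threshold (default 90%).

Coordinates are 0-based half-open throughout.  The trailing partial
window of a chromosome is kept as its own window when it is at least
half the window size, otherwise it is merged into the previous window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqs import MISSING, StrainGenome


@dataclass
class PaintingConfig:
    window_size: int = 30_000
    divergence_threshold: float = 0.003
    min_callable_fraction: float = 0.3
    primary_ancestry_threshold: float = 0.90
    min_trailing_fraction: float = 0.5

    def __post_init__(self):
        if self.window_size <= 0:
            raise ValueError("window_size must be > 0")
        for name in ("divergence_threshold", "min_callable_fraction",
                     "primary_ancestry_threshold", "min_trailing_fraction"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class BackbonePanel:
    """Clade-labelled reference genomes (typically 3 strains per clade)."""

    clades: dict[str, list[StrainGenome]]

    def __post_init__(self):
        for clade, strains in self.clades.items():
            if not strains:
                raise ValueError(f"clade {clade!r} has no strains")

    @property
    def clade_names(self) -> list[str]:
        return sorted(self.clades)

    def strains(self) -> list[tuple[str, StrainGenome]]:
        out = []
        for clade in self.clade_names:
            for g in self.clades[clade]:
                out.append((clade, g))
        return out

    def strain_ids(self) -> list[str]:
        return [g.strain for _, g in self.strains()]

    def clade_of(self, strain: str) -> str:
        for clade, g in self.strains():
            if g.strain == strain:
                return clade
        raise KeyError(strain)

    def without(self, strain: str) -> "BackbonePanel":
        clades = {}
        for clade, strains in self.clades.items():
            kept = [g for g in strains if g.strain != strain]
            if kept:
                clades[clade] = kept
        return BackbonePanel(clades)

    def chromosomes(self) -> set[str]:
        _, g0 = self.strains()[0]
        return set(g0.sequences)


def panel_from_cohort(cohort, n_per_clade: int = 3, clades=None,
                      exclude=()) -> BackbonePanel:
    """Backbone panel from a simulated cohort: the first ``n_per_clade``
    strains of each clade (extra strains and ``exclude`` skipped)."""
    wanted = clades if clades is not None else sorted(set(cohort.truth_clades.values()))
    panel: dict[str, list[StrainGenome]] = {}
    for clade in wanted:
        members = [
            s for s in cohort.strains_in_clade(clade)
            if s not in exclude and s.startswith(f"{clade}_s")
        ]
        panel[clade] = [cohort.genome(s) for s in members[:n_per_clade]]
    return BackbonePanel(panel)


@dataclass
class WindowCall:
    chrom: str
    start: int
    end: int
    status: str  # assigned | diverged | low_coverage
    best_clade: str | None = None
    best_strain: str | None = None
    min_prop_diff: float = math.nan
    clade_divergences: dict[str, float] = field(default_factory=dict)
    tie: bool = False


@dataclass
class PaintingProfile:
    strain: str
    windows: list[WindowCall]
    composition: dict[str, float]
    diverged_fraction: float
    low_coverage_fraction: float
    primary_clade: str | None
    admixed: bool

    @property
    def n_assigned(self) -> int:
        return sum(1 for w in self.windows if w.status == "assigned")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "status": [w.status for w in self.windows],
                "clade": [w.best_clade or "" for w in self.windows],
                "strain": [w.best_strain or "" for w in self.windows],
                "min_prop_diff": [w.min_prop_diff for w in self.windows],
                "tie": [w.tie for w in self.windows],
            }
        )


def tile_windows(length: int, window_size: int,
                 min_trailing_fraction: float = 0.5) -> list[tuple[int, int]]:
    """Non-overlapping windows covering [0, length) exactly.  A trailing
    remainder shorter than ``min_trailing_fraction * window_size`` is
    merged into the previous window."""
    if length <= 0:
        raise ValueError("length must be > 0")
    n_full, rem = divmod(length, window_size)
    starts = [i * window_size for i in range(n_full)]
    if rem:
        if rem >= min_trailing_fraction * window_size or n_full == 0:
            starts.append(n_full * window_size)
    bounds = starts + [length]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def window_divergence(query: np.ndarray, backbone: np.ndarray,
                      start: int, end: int) -> tuple[float, int]:
    """p-distance restricted to [start, end); inf with zero compared sites."""
    from .phylo import p_distance

    return p_distance(query[start:end], backbone[start:end])


def paint_genome(query: StrainGenome, panel: BackbonePanel,
                 cfg: PaintingConfig | None = None) -> PaintingProfile:
    """Paint every window of ``query`` with the clade of its most similar
    backbone strain (see module docstring for the white/black rules)."""
    cfg = cfg or PaintingConfig()
    labelled = panel.strains()
    panel_chroms = panel.chromosomes()
    calls: list[WindowCall] = []

    for chrom, qseq in query.sequences.items():
        if chrom not in panel_chroms:
            raise ValueError(f"chromosome {chrom!r} absent from the panel")
        wins = tile_windows(len(qseq), cfg.window_size, cfg.min_trailing_fraction)
        starts = np.array([w[0] for w in wins])
        wlens = np.array([e - s for s, e in wins], dtype=float)
        q_valid = qseq != MISSING

        n_strains = len(labelled)
        ncomp = np.empty((n_strains, len(wins)), dtype=np.int64)
        nmism = np.empty_like(ncomp)
        for si, (_, genome) in enumerate(labelled):
            b = genome.sequences[chrom]
            valid = q_valid & (b != MISSING)
            mism = valid & (qseq != b)
            ncomp[si] = np.add.reduceat(valid.astype(np.int64), starts)
            nmism[si] = np.add.reduceat(mism.astype(np.int64), starts)

        eligible = ncomp / wlens[None, :] >= cfg.min_callable_fraction
        with np.errstate(divide="ignore", invalid="ignore"):
            props = np.where(ncomp > 0, nmism / np.maximum(ncomp, 1), np.inf)
        props = np.where(eligible, props, np.inf)

        for wi, (ws, we) in enumerate(wins):
            if not eligible[:, wi].any():
                calls.append(WindowCall(chrom, ws, we, "low_coverage"))
                continue
            col = props[:, wi]
            minprop = float(col.min())
            best_idx = np.flatnonzero(col == minprop)
            best_clades = sorted({labelled[i][0] for i in best_idx})
            tie = len(best_clades) > 1
            best_clade = best_clades[0]
            best_strain = min(
                labelled[i][1].strain for i in best_idx if labelled[i][0] == best_clade
            )
            clade_div: dict[str, float] = {}
            for si, (clade, _) in enumerate(labelled):
                if math.isfinite(col[si]):
                    clade_div[clade] = min(clade_div.get(clade, math.inf), float(col[si]))
            if minprop > cfg.divergence_threshold:
                calls.append(
                    WindowCall(chrom, ws, we, "diverged",
                               min_prop_diff=minprop, clade_divergences=clade_div)
                )
            else:
                calls.append(
                    WindowCall(chrom, ws, we, "assigned", best_clade, best_strain,
                               minprop, clade_div, tie)
                )

    n_windows = len(calls)
    assigned = [w for w in calls if w.status == "assigned"]
    composition: dict[str, float] = {}
    for w in assigned:
        composition[w.best_clade] = composition.get(w.best_clade, 0) + 1
    composition = {c: n / len(assigned) for c, n in composition.items()} if assigned else {}
    primary = min(
        (c for c in composition if composition[c] == max(composition.values())),
        default=None,
    )
    profile = PaintingProfile(
        strain=query.strain,
        windows=calls,
        composition=composition,
        diverged_fraction=sum(w.status == "diverged" for w in calls) / n_windows,
        low_coverage_fraction=sum(w.status == "low_coverage" for w in calls) / n_windows,
        primary_clade=primary,
        admixed=False,
    )
    profile.admixed = classify_admixture(profile, cfg) if assigned else False
    return profile


def classify_admixture(profile: PaintingProfile,
                       cfg: PaintingConfig | None = None) -> bool:
    """Admixed iff the largest single-clade composition is strictly below
    the primary-ancestry threshold (default 90%)."""
    cfg = cfg or PaintingConfig()
    if not profile.composition:
        raise ValueError("no assigned windows: admixture undefined")
    return max(profile.composition.values()) < cfg.primary_ancestry_threshold


def assigned_tracts(profile: PaintingProfile) -> list[tuple[str, int, int, str]]:
    """Merge runs of consecutive same-clade assigned windows into tracts
    (chrom, start, end, clade)."""
    tracts: list[tuple[str, int, int, str]] = []
    cur = None
    for w in profile.windows:
        if w.status != "assigned":
            cur = None
            continue
        if cur is not None and cur[0] == w.chrom and cur[2] == w.start and cur[3] == w.best_clade:
            cur = (cur[0], cur[1], w.end, cur[3])
            tracts[-1] = cur
        else:
            cur = (w.chrom, w.start, w.end, w.best_clade)
            tracts.append(cur)
    return tracts


def tract_recovery(
    profile: PaintingProfile,
    truth_tracts: list[tuple[str, int, int, str]],
    window_size: int = 30_000,
) -> tuple[int, int]:
    """How many truth tracts are recovered by the painting.

    A tract (chrom, start, end, donor) counts as recovered when exactly
    one run of consecutive donor-clade windows overlaps it and both run
    boundaries lie within one window of the true boundaries.  Returns
    (n_recovered, n_total).
    """
    runs = assigned_tracts(profile)
    recovered = 0
    for chrom, start, end, donor in truth_tracts:
        hits = [
            r for r in runs
            if r[0] == chrom and r[3] == donor and r[1] < end and start < r[2]
        ]
        if len(hits) == 1:
            _, rs, re, _ = hits[0]
            if abs(rs - start) <= window_size and abs(re - end) <= window_size:
                recovered += 1
    return recovered, len(truth_tracts)


@dataclass
class CalibrationResult:
    within: np.ndarray
    between: np.ndarray
    suggested_threshold: float
    fraction_within_below: float  # at the configured divergence threshold
    fraction_between_above: float
    warning: str | None = None


def _pair_window_divergences(a: StrainGenome, b: StrainGenome,
                             cfg: PaintingConfig) -> np.ndarray:
    vals = []
    for chrom, sa in a.sequences.items():
        sb = b.sequences[chrom]
        wins = tile_windows(len(sa), cfg.window_size, cfg.min_trailing_fraction)
        starts = np.array([w[0] for w in wins])
        wlens = np.array([e - s for s, e in wins], dtype=float)
        valid = (sa != MISSING) & (sb != MISSING)
        mism = valid & (sa != sb)
        nc = np.add.reduceat(valid.astype(np.int64), starts)
        nm = np.add.reduceat(mism.astype(np.int64), starts)
        ok = nc / wlens >= cfg.min_callable_fraction
        vals.append(nm[ok] / nc[ok])
    return np.concatenate(vals) if vals else np.array([])


def calibrate_threshold(panel: BackbonePanel,
                        cfg: PaintingConfig | None = None) -> CalibrationResult:
    """Window-divergence distributions justifying the white threshold.

    The suggested threshold is the smallest observed divergence value x
    such that at least 90% of within-clade windows fall strictly below
    x, floored at the window resolution (one mismatch per window).
    """
    cfg = cfg or PaintingConfig()
    within, between = [], []
    for ci, clade_a in enumerate(panel.clade_names):
        strains_a = panel.clades[clade_a]
        for i in range(len(strains_a)):
            for j in range(i + 1, len(strains_a)):
                within.append(_pair_window_divergences(strains_a[i], strains_a[j], cfg))
        for clade_b in panel.clade_names[ci + 1:]:
            for ga in strains_a:
                for gb in panel.clades[clade_b]:
                    between.append(_pair_window_divergences(ga, gb, cfg))
    within_arr = np.concatenate(within) if within else np.array([])
    between_arr = np.concatenate(between) if between else np.array([])

    resolution = 1.0 / cfg.window_size
    warning = None
    if within_arr.size == 0:
        warning = "no within-clade pairs: every clade has a single strain"
        suggested = resolution
    else:
        w = np.sort(within_arr)
        k = math.ceil(0.9 * w.size)
        uniq = np.unique(w)
        counts_below = np.searchsorted(w, uniq, side="left")
        hits = np.flatnonzero(counts_below >= k)
        suggested = float(uniq[hits[0]]) if hits.size else float(w[-1] + resolution)
        suggested = max(suggested, resolution)

    return CalibrationResult(
        within=within_arr,
        between=between_arr,
        suggested_threshold=suggested,
        fraction_within_below=float((within_arr < cfg.divergence_threshold).mean())
        if within_arr.size else math.nan,
        fraction_between_above=float((between_arr > cfg.divergence_threshold).mean())
        if between_arr.size else math.nan,
        warning=warning,
    )


def validate_backbone(panel: BackbonePanel, cfg: PaintingConfig | None = None
                      ) -> tuple[BackbonePanel, list[tuple[str, str]]]:
    """Hold-out self-painting QC of the panel: each backbone strain is
    painted against the panel minus itself and removed when its own-clade
    composition is below 50% or any other clade exceeds 10%."""
    cfg = cfg or PaintingConfig()
    removals: list[tuple[str, str]] = []
    for clade, genome in panel.strains():
        reduced = panel.without(genome.strain)
        if clade not in reduced.clades:
            continue  # held-out strain is its clade's only member
        profile = paint_genome(genome, reduced, cfg)
        own = profile.composition.get(clade, 0.0)
        worst_other = max(
            (f for c, f in profile.composition.items() if c != clade), default=0.0
        )
        if own < 0.5:
            removals.append((genome.strain, "primary_assignment_below_50pct"))
        elif worst_other > 0.1:
            removals.append((genome.strain, "secondary_assignment_above_10pct"))
    kept = panel
    for strain, _ in removals:
        kept = kept.without(strain)
    return kept, removals
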