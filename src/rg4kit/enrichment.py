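"""CLIP-site / RG4 enrichment statistics.

Observed binding sites are extended by a flank (default 25 nt), intersected
with the accepted RG4 catalog, and compared against random background sites
of the observed mean length via a two-sided Fisher exact test. Densities are
reported per Mb of (merged) site sequence, and the fraction of catalog RG4s
covered by sites is computed per region.

Background sites are drawn region-stratified: the null for the 3'UTR
contrast lives in 3'UTR sequence space, and so on, which isolates RG4
enrichment from region-composition effects. Overlaps are same-strand only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .intervals import SiteSet, merge_intervals, overlaps_any
from .qgrs import RG4Catalog
from .transcripts import REGIONS, Transcript

#: Relative tolerance for hypergeometric probability ties in the two-sided sum.
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class EnrichConfig:
    flank: int = 25
    n_background: int = 10000
    seed: int = 0
    min_overlap: int = 1

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class EnrichmentResult:
    """2x2 contingency outcome for one region (or 'all').

    a/b: observed sites with/without an RG4 overlap; c/d: background sites
    with/without. Odds ratio uses the Haldane-Anscombe 0.5 correction when
    any cell is zero (flagged)."""

    region: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    neg_log10_p: float
    density_obs: float
    density_bg: float
    haldane_corrected: bool = False


def read_sites(path) -> SiteSet:
    """Validated BED6 ingest (0-based half-open, strand required)."""
    return SiteSet.from_bed(path)


def extend_sites(sites: SiteSet, flank: int, bounds: dict[str, int]) -> SiteSet:
    return sites.extended(flank, bounds)


def sample_background(
    transcripts: list[Transcript],
    n: int,
    site_length: int,
    seed: int,
    region: str | None = None,
) -> SiteSet:
    """n intervals of exactly ``site_length`` placed uniformly at random over
    valid start positions of the sampling space (one region, or whole
    transcripts when region is None)."""
    if site_length < 1:
        raise ValueError("site_length must be >= 1")
    segments = []  # (transcript_id, segment_start, n_valid_starts)
    for t in transcripts:
        lo, hi = (0, t.length) if region is None else t.region_bounds(region)
        n_valid = hi - lo - site_length + 1
        if n_valid > 0:
            segments.append((t.transcript_id, lo, n_valid))
    if not segments:
        raise ValueError(
            f"site_length {site_length} exceeds every sequence in the "
            f"{'whole-transcript' if region is None else region} sampling space"
        )
    weights = np.array([s[2] for s in segments], dtype=float)
    rng = np.random.default_rng(seed)
    seg_idx = rng.choice(len(segments), size=n, p=weights / weights.sum())
    offsets = rng.integers(0, weights[seg_idx].astype(int))
    tids = np.array([s[0] for s in segments])
    los = np.array([s[1] for s in segments])
    starts = los[seg_idx] + offsets
    return SiteSet(
        pd.DataFrame(
            {
                "chrom": tids[seg_idx],
                "start": starts,
                "end": starts + site_length,
                "name": [f"bg_{k}" for k in range(n)],
                "score": 0.0,
                "strand": "+",
            }
        )
    )


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    tables (at fixed margins) no more likely than the observed one."""
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n1, n2, k = a + b, c + d, a + c
    m = n1 + n2
    if n1 == 0 or n2 == 0 or k == 0 or k == m:
        return 1.0
    support = np.arange(max(0, k - n2), min(n1, k) + 1)
    pmf = hypergeom.pmf(support, m, k, n1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def _odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a2 * d2) / (b2 * c2), True
    return (a * d) / (b * c), False


def _catalog_interval_index(
    catalog: RG4Catalog,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-transcript sorted (starts, ends) arrays of accepted hits."""
    hits = catalog.hits
    tid = hits["transcript_id"].to_numpy()
    starts = hits["start"].to_numpy()
    ends = hits["end"].to_numpy()
    order = np.lexsort((starts, tid))
    tid, starts, ends = tid[order], starts[order], ends[order]
    index = {}
    uniq, first = np.unique(tid, return_index=True)
    bounds = np.append(first, len(tid))
    for k, t in enumerate(uniq):
        index[t] = (starts[bounds[k] : bounds[k + 1]], ends[bounds[k] : bounds[k + 1]])
    return index


def _sites_overlap_catalog(
    sites: SiteSet, catalog_index: dict, min_overlap: int
) -> np.ndarray:
    """Boolean per site (sense-strand sites only can overlap sense hits)."""
    flags = np.zeros(len(sites), dtype=bool)
    df = sites.df
    sense = df["strand"] == "+"
    for tid, grp in df[sense].groupby("chrom", sort=False):
        if tid not in catalog_index:
            continue
        rs, re = catalog_index[tid]
        flags[grp.index] = overlaps_any(
            grp["start"].to_numpy(), grp["end"].to_numpy(), rs, re, min_overlap
        )
    return flags


def _assign_site_regions(sites: SiteSet, by_id: dict[str, Transcript]) -> pd.Series:
    """Region of each site's start position (vectorised)."""
    chrom = sites.df["chrom"]
    unknown = set(chrom.unique()) - set(by_id)
    if unknown:
        raise ValueError(f"sites on unknown transcripts: {sorted(unknown)}")
    utr5 = chrom.map({k: t.utr5_end for k, t in by_id.items()}).to_numpy()
    cds = chrom.map({k: t.cds_end for k, t in by_id.items()}).to_numpy()
    start = sites.df["start"].to_numpy()
    labels = np.select([start < utr5, start < cds], ["5UTR", "CDS"], default="3UTR")
    return pd.Series(labels, index=sites.df.index)


def rg4_density(
    sites: SiteSet,
    catalog: RG4Catalog,
    min_overlap: int = 1,
    _index: dict | None = None,
) -> float:
    """Accepted RG4s overlapping the site set, per Mb of merged site length."""
    index = _catalog_interval_index(catalog) if _index is None else _index
    df = sites.df
    sense = df["strand"].to_numpy() == "+"
    chrom = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    order = np.lexsort((starts, chrom))
    chrom, starts, ends, sense = (
        chrom[order], starts[order], ends[order], sense[order],
    )
    total = 0
    n_rg4 = 0
    uniq, first = np.unique(chrom, return_index=True)
    bounds_ix = np.append(first, len(chrom))
    for k, tid in enumerate(uniq):
        sl = slice(bounds_ix[k], bounds_ix[k + 1])
        ms, me = merge_intervals(starts[sl], ends[sl])
        total += int((me - ms).sum())
        if tid in index and sense[sl].any():
            s_ms, s_me = merge_intervals(starts[sl][sense[sl]], ends[sl][sense[sl]])
            rs, re = index[tid]
            n_rg4 += int(overlaps_any(rs, re, s_ms, s_me, min_overlap).sum())
    if total <= 0:
        raise ValueError("site set covers no sequence")
    return n_rg4 / total * 1e6


def fraction_rg4_bound(
    catalog: RG4Catalog,
    sites: SiteSet,
    transcripts: list[Transcript],
    config: EnrichConfig = EnrichConfig(),
    extend: bool = True,
) -> dict[str, float]:
    """Per region: accepted RG4s overlapped (>= min_overlap nt) by any
    (extended) site, over all accepted RG4s in the region."""
    bounds = {t.transcript_id: t.length for t in transcripts}
    use = sites.extended(config.flank, bounds) if extend else sites
    df = use.df[use.df["strand"] == "+"]
    site_index = {}
    for tid, grp in df.groupby("chrom", sort=False):
        site_index[tid] = merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
    bound = np.zeros(len(catalog.hits), dtype=bool)
    for tid, grp in catalog.hits.groupby("transcript_id", sort=False):
        if tid not in site_index:
            continue
        ms, me = site_index[tid]
        bound[grp.index] = overlaps_any(
            grp["start"].to_numpy(), grp["end"].to_numpy(), ms, me, config.min_overlap
        )
    out = {}
    for region in REGIONS:
        mask = (catalog.hits["region"] == region).to_numpy()
        if mask.sum() == 0:
            continue
        out[region] = float(bound[mask].sum() / mask.sum())
    return out


def fisher_enrichment(
    obs_sites: SiteSet,
    bg_sites: SiteSet,
    catalog: RG4Catalog,
    transcripts: list[Transcript],
    config: EnrichConfig = EnrichConfig(),
) -> dict[str, EnrichmentResult]:
    """Per-region (plus pooled 'all') Fisher exact enrichment of RG4 overlap
    in observed vs background sites. Both site sets are extended by the
    flank before intersection."""
    if len(obs_sites) == 0:
        raise ValueError("empty observed site set")
    by_id = {t.transcript_id: t for t in transcripts}
    bounds = {t.transcript_id: t.length for t in transcripts}
    obs_regions = _assign_site_regions(obs_sites, by_id)
    bg_regions = _assign_site_regions(bg_sites, by_id)
    obs_ext = obs_sites.extended(config.flank, bounds)
    bg_ext = bg_sites.extended(config.flank, bounds)
    index = _catalog_interval_index(catalog)
    obs_flag = _sites_overlap_catalog(obs_ext, index, config.min_overlap)
    bg_flag = _sites_overlap_catalog(bg_ext, index, config.min_overlap)

    results = {}
    for region in (*REGIONS, "all"):
        if region == "all":
            om = np.ones(len(obs_flag), dtype=bool)
            bm = np.ones(len(bg_flag), dtype=bool)
        else:
            om = (obs_regions == region).to_numpy()
            bm = (bg_regions == region).to_numpy()
        if om.sum() == 0 or bm.sum() == 0:
            continue
        a = int(obs_flag[om].sum())
        b = int(om.sum() - a)
        c = int(bg_flag[bm].sum())
        d = int(bm.sum() - c)
        p = fisher_exact_two_sided(a, b, c, d)
        odds, corrected = _odds_ratio(a, b, c, d)
        obs_sub = SiteSet(obs_ext.df[om])
        bg_sub = SiteSet(bg_ext.df[bm])
        results[region] = EnrichmentResult(
            region=region,
            a=a,
            b=b,
            c=c,
            d=d,
            odds_ratio=odds,
            p_value=p,
            neg_log10_p=-math.log10(p) if p > 0 else math.inf,
            density_obs=rg4_density(obs_sub, catalog, config.min_overlap, _index=index),
            density_bg=rg4_density(bg_sub, catalog, config.min_overlap, _index=index),
            haldane_corrected=corrected,
        )
    return results


def enrichment_experiment(
    obs_sites: SiteSet,
    catalog: RG4Catalog,
    transcripts: list[Transcript],
    config: EnrichConfig = EnrichConfig(),
) -> tuple[dict[str, EnrichmentResult], dict[str, SiteSet]]:
    """Region-stratified enrichment of one site set against sampled background.

    For each region, observed sites starting in that region are contrasted
    with ``n_background`` random sites drawn from that region's sequence
    space; a pooled 'all' contrast uses whole-transcript background. The
    background site length is the rounded mean length of the observed
    (unextended) sites. Returns (results, background site sets for audit).
    """
    if len(obs_sites) == 0:
        raise ValueError("empty observed site set")
    by_id = {t.transcript_id: t for t in transcripts}
    site_length = max(int(round(obs_sites.mean_length)), 1)
    obs_regions = _assign_site_regions(obs_sites, by_id)
    results: dict[str, EnrichmentResult] = {}
    backgrounds: dict[str, SiteSet] = {}
    for i, region in enumerate(REGIONS):
        mask = (obs_regions == region).to_numpy()
        if mask.sum() == 0:
            continue
        region_obs = SiteSet(obs_sites.df[mask])
        try:
            bg = sample_background(
                transcripts, config.n_background, site_length,
                seed=config.seed + i + 1, region=region,
            )
        except ValueError:
            continue
        backgrounds[region] = bg
        res = fisher_enrichment(region_obs, bg, catalog, transcripts, config)
        results[region] = res["all"]
        results[region].region = region
    bg_all = sample_background(
        transcripts, config.n_background, site_length, seed=config.seed
    )
    backgrounds["all"] = bg_all
    results["all"] = fisher_enrichment(obs_sites, bg_all, catalog, transcripts, config)[
        "all"
    ]
    return results, backgrounds


def intersect_target_sets(
    ids_a: list[str], ids_b: list[str]
) -> tuple[list[str], dict[str, int]]:
    """Sorted intersection of two (deduplicated, case-sensitive) identifier
    lists, with |A|, |B|, |A & B| counts."""
    sa, sb = set(ids_a), set(ids_b)
    shared = sorted(sa & sb)
    return shared, {"n_a": len(sa), "n_b": len(sb), "n_shared": len(shared)}


def results_to_frame(results: dict[str, EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for region, r in results.items():
        rows.append(
            {
                "region": region,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "neg_log10_p": r.neg_log10_p,
                "density_obs_per_mb": r.density_obs,
                "density_bg_per_mb": r.density_bg,
                "haldane_corrected": r.haldane_corrected,
            }
        )
    return pd.DataFrame(rows)
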