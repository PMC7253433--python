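"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators: transcriptomes with planted G4 motifs at controlled
per-region rates, CLIP-like binding sites preferentially placed on planted
motifs, paired label-free intensity matrices with planted fold differences
and intensity-dependent (MNAR) dropout, and closed-form assay fixtures.

All generators are deterministic under their explicit seed; no global RNG
state is used. Background transcript sequence is rejection-cleaned so that
planted motifs are the only subsequences matching the planted quadruplex
specification, making truth tables exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .intervals import SiteSet
from .qgrs import RG4Params, enumerate_qgrs
from .transcripts import REGIONS, Transcript

_BASES = np.array(list("ACGT"))
_NON_G = np.array(list("ACT"))

#: spacing between planted motifs so no cross-motif candidate fits a 30 nt window
_MOTIF_GAP = 30


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedMotifSpec:
    """Exact quadruplex to plant: four G-runs of ``g_run`` (>= 2) guanines
    separated by three loops of the given lengths (loop bases are random
    non-G)."""

    g_run: int = 3
    loop_lengths: tuple[int, int, int] = (2, 2, 2)

    def __post_init__(self) -> None:
        if self.g_run < 2:
            raise ConfigError("planted G-run length must be >= 2")
        if any(not 0 <= l <= 36 for l in self.loop_lengths):
            raise ConfigError("planted loop lengths must be in [0, 36]")

    @property
    def length(self) -> int:
        return 4 * self.g_run + sum(self.loop_lengths)


@dataclass(frozen=True)
class SimTranscriptomeConfig:
    n_transcripts: int = 100
    # per-region (mean, sd) lengths in nt; CDS is rounded to a multiple of 3
    region_lengths: dict = field(
        default_factory=lambda: {
            "5UTR": (200.0, 50.0),
            "CDS": (1200.0, 300.0),
            "3UTR": (800.0, 200.0),
        }
    )
    gc_content: float = 0.45
    # expected planted motifs per kb, per region
    g4_rate_per_region: dict = field(
        default_factory=lambda: {"5UTR": 1.5, "CDS": 0.5, "3UTR": 1.0}
    )
    planted_motif_spec: PlantedMotifSpec = field(default_factory=PlantedMotifSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ConfigError("n_transcripts must be >= 1")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ConfigError("gc_content must be in [0, 1]")
        if set(self.region_lengths) != set(REGIONS):
            raise ConfigError(f"region_lengths must cover {REGIONS}")
        if set(self.g4_rate_per_region) != set(REGIONS):
            raise ConfigError(f"g4_rate_per_region must cover {REGIONS}")
        if any(r < 0 for r in self.g4_rate_per_region.values()):
            raise ConfigError("planting rates must be >= 0")


@dataclass(frozen=True)
class SimClipConfig:
    n_sites: int = 500
    site_length_mean: float = 40.0
    site_length_sd: float = 8.0
    g4_enrichment_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.site_length_mean < 1:
            raise ConfigError("site_length_mean must be >= 1")
        if self.g4_enrichment_factor < 0:
            raise ConfigError("g4_enrichment_factor must be >= 0")


@dataclass(frozen=True)
class SimLfqConfig:
    n_proteins: int = 1000
    n_pairs: int = 4          # four biological replicates per condition
    frac_differential: float = 0.1
    true_log2_effect: float = 1.5   # positive = WT-preferring
    baseline_mean: float = 25.0     # log2 intensity
    baseline_sd: float = 2.0
    noise_sd: float = 0.25          # per-measurement replicate noise, log2
    pair_effect_sd: float = 0.25    # shared within a replicate pair, log2
    mnar_midpoint: float = 21.5     # log2 intensity of 50% dropout
    mnar_slope: float = 1.0         # logistic steepness (>= 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ConfigError("paired test undefined for n_pairs < 2")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ConfigError("frac_differential must be in [0, 1]")
        if self.mnar_slope < 0:
            raise ConfigError("mnar_slope must be >= 0")


def _random_bases(rng, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return _BASES[rng.choice(4, size=n, p=p)]


def _motif_array(spec: PlantedMotifSpec, rng) -> np.ndarray:
    parts = []
    for i in range(4):
        parts.append(np.full(spec.g_run, "G"))
        if i < 3:
            parts.append(rng.choice(_NON_G, size=spec.loop_lengths[i]))
    return np.concatenate(parts) if parts else np.array([], dtype=str)


def _place_motifs(rng, region_len: int, n_motifs: int, motif_len: int) -> list[int]:
    """Non-overlapping starts with >= _MOTIF_GAP nt between motifs, uniform."""
    if n_motifs == 0:
        return []
    slack = region_len - n_motifs * motif_len - (n_motifs - 1) * _MOTIF_GAP
    if slack < 0:
        raise ConfigError(
            f"region of {region_len} nt too short to host {n_motifs} planted "
            f"motif(s) of {motif_len} nt with {_MOTIF_GAP} nt spacing"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=n_motifs))
    return [int(c + i * (motif_len + _MOTIF_GAP)) for i, c in enumerate(cuts)]


def _clean_background(
    seq: np.ndarray,
    planted: list[tuple[int, int]],
    spec: PlantedMotifSpec,
    gc: float,
    rng,
    max_rounds: int = 200,
) -> np.ndarray:
    """Resample background positions until no quadruplex matching the planted
    spec exists outside the planted spans."""
    params = RG4Params(
        min_g_run=spec.g_run, max_qgrs_length=30, loop_min=0, loop_max=36,
        score_threshold=-np.inf,
    )
    planted_cover = np.zeros(len(seq), dtype=bool)
    for s, e in planted:
        planted_cover[s:e] = True
    for _ in range(max_rounds):
        bad = set()
        for cand in enumerate_qgrs("".join(seq), params):
            inside = any(s <= cand.start and cand.end <= e for s, e in planted)
            if inside:
                continue
            for pos in range(cand.start, cand.end):
                if not planted_cover[pos] and seq[pos] == "G":
                    bad.add(pos)
        if not bad:
            return seq
        idx = np.fromiter(bad, dtype=int)
        seq[idx] = _random_bases(rng, len(idx), gc)
    raise RuntimeError("background cleanup did not converge")


def simulate_transcriptome(
    config: SimTranscriptomeConfig,
) -> tuple[list[Transcript], pd.DataFrame]:
    """Generate transcripts plus an exact truth table of planted motifs.

    Returns (transcripts, truth) where truth has columns transcript_id,
    region, start, end (transcript coordinates), g_run and loop lengths.
    """
    rng = np.random.default_rng(config.seed)
    spec = config.planted_motif_spec
    motif_len = spec.length
    transcripts = []
    truth_rows = []
    for i in range(config.n_transcripts):
        tid = f"tx{i:04d}"
        region_arrays = {}
        region_offsets = {}
        offset = 0
        planted_all: list[tuple[int, int]] = []
        for region in REGIONS:
            mean, sd = config.region_lengths[region]
            length = max(int(round(rng.normal(mean, sd))), 30)
            if region == "CDS":
                length = max(3 * round(length / 3), 90)
            rate = config.g4_rate_per_region[region]
            n_motifs = int(rng.poisson(rate * length / 1000.0)) if rate > 0 else 0
            capacity = (length + _MOTIF_GAP) // (motif_len + _MOTIF_GAP)
            if n_motifs > 0 and capacity == 0:
                raise ConfigError(
                    f"{tid} {region}: region length {length} nt cannot host a "
                    f"{motif_len} nt planted motif"
                )
            # cap overdrawn Poisson counts at spacing capacity (rare at sane rates)
            n_motifs = min(n_motifs, capacity)
            seq = _random_bases(rng, length, config.gc_content)
            starts = _place_motifs(rng, length, n_motifs, motif_len)
            for s in starts:
                seq[s : s + motif_len] = _motif_array(spec, rng)
                planted_all.append((offset + s, offset + s + motif_len))
                truth_rows.append(
                    {
                        "transcript_id": tid,
                        "region": region,
                        "start": offset + s,
                        "end": offset + s + motif_len,
                        "g_run": spec.g_run,
                        "l1": spec.loop_lengths[0],
                        "l2": spec.loop_lengths[1],
                        "l3": spec.loop_lengths[2],
                    }
                )
            region_arrays[region] = seq
            region_offsets[region] = offset
            offset += length
        full = np.concatenate([region_arrays[r] for r in REGIONS])
        full = _clean_background(full, planted_all, spec, config.gc_content, rng)
        utr5_end = len(region_arrays["5UTR"])
        cds_end = utr5_end + len(region_arrays["CDS"])
        transcripts.append(Transcript(tid, "".join(full), utr5_end, cds_end))
    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "region", "start", "end", "g_run", "l1", "l2", "l3"],
    )
    return transcripts, truth


def simulate_clip_sites(
    transcripts: list[Transcript], truth: pd.DataFrame, config: SimClipConfig
) -> SiteSet:
    """Place binding sites with a tunable preference for planted G4s.

    A candidate site (length from the configured normal, anchored uniformly)
    is accepted with probability proportional to ``g4_enrichment_factor`` if
    it overlaps a planted motif and 1 otherwise, so factor 1 is uniform
    placement and factor 0 yields no overlapping site.
    """
    known = {t.transcript_id for t in transcripts}
    unknown = set(truth["transcript_id"]) - known
    if unknown:
        raise ValueError(f"truth table refers to absent transcripts: {sorted(unknown)}")
    lengths = np.array([t.length for t in transcripts])
    total_positions = int(lengths.sum())
    if config.n_sites > total_positions:
        raise ValueError(
            f"n_sites {config.n_sites} exceeds the {total_positions} available positions"
        )
    planted = {
        tid: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for tid, grp in truth.sort_values("start").groupby("transcript_id")
    }
    tx_ids = np.array([t.transcript_id for t in transcripts])
    rng = np.random.default_rng(config.seed)
    w_over = config.g4_enrichment_factor
    w_max = max(1.0, w_over)
    p_tx = lengths / lengths.sum()

    kept_tid: list[np.ndarray] = []
    kept_start: list[np.ndarray] = []
    kept_end: list[np.ndarray] = []
    n_kept = 0
    attempts = 0
    max_attempts = max(10000, config.n_sites * 1000)
    while n_kept < config.n_sites:
        batch = max(2 * (config.n_sites - n_kept), 256)
        attempts += batch
        if attempts > max_attempts:
            raise RuntimeError(
                "site placement rejected too often; check g4_enrichment_factor"
            )
        ti = rng.choice(len(transcripts), size=batch, p=p_tx)
        tlen = lengths[ti]
        anchor = np.floor(rng.random(batch) * tlen).astype(int)
        slen = np.maximum(
            np.rint(
                rng.normal(config.site_length_mean, config.site_length_sd, size=batch)
            ).astype(int),
            1,
        )
        start = np.maximum(anchor - slen // 2, 0)
        end = np.minimum(start + slen, tlen)
        ok = end > start
        overlaps = np.zeros(batch, dtype=bool)
        for k in np.unique(ti):
            ps, pe = planted.get(tx_ids[k], (None, None))
            if ps is None or len(ps) == 0:
                continue
            sel = ti == k
            # planted intervals are disjoint and sorted by start
            hi = np.searchsorted(ps, end[sel], side="left")
            lo = np.searchsorted(pe, start[sel], side="right")
            overlaps[sel] = hi > lo
        weight = np.where(overlaps, w_over, 1.0)
        accept = ok & (rng.random(batch) < weight / w_max)
        kept_tid.append(tx_ids[ti[accept]])
        kept_start.append(start[accept])
        kept_end.append(end[accept])
        n_kept += int(accept.sum())
    tid = np.concatenate(kept_tid)[: config.n_sites]
    start = np.concatenate(kept_start)[: config.n_sites]
    end = np.concatenate(kept_end)[: config.n_sites]
    return SiteSet(
        pd.DataFrame(
            {
                "chrom": tid,
                "start": start,
                "end": end,
                "name": [f"site_{k}" for k in range(config.n_sites)],
                "score": 0.0,
                "strand": "+",
            }
        )
    )


def simulate_lfq(config: SimLfqConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired WT/7dG label-free intensity matrix with planted effects.

    Per protein and replicate pair, the true log2 intensity is baseline +
    pair effect + condition effect (WT side, for differential proteins) +
    noise. The observed table is on the raw intensity scale with entries
    deleted by the logistic MNAR rule p_missing = expit(-slope*(x - midpoint))
    evaluated on the true log2 intensity. Returns (raw table, truth frame
    with per-protein labels 'WT-preferring'/'7dG-preferring'/'null').
    """
    rng = np.random.default_rng(config.seed)
    p, n = config.n_proteins, config.n_pairs
    n_diff = int(round(config.frac_differential * p))
    effect = np.zeros(p)
    effect[:n_diff] = config.true_log2_effect
    # shuffle so differential proteins are not a prefix block
    perm = rng.permutation(p)
    effect = effect[perm]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=p)
    pair_eff = rng.normal(0.0, config.pair_effect_sd, size=(p, n))
    wt = (
        baseline[:, None]
        + pair_eff
        + effect[:, None]
        + rng.normal(0.0, config.noise_sd, size=(p, n))
    )
    dg = baseline[:, None] + pair_eff + rng.normal(0.0, config.noise_sd, size=(p, n))
    true_log2 = np.concatenate([wt, dg], axis=1)

    p_missing = expit(-config.mnar_slope * (true_log2 - config.mnar_midpoint))
    missing = rng.random(size=true_log2.shape) < p_missing
    raw = np.power(2.0, true_log2)
    raw[missing] = 0.0  # missing values are zeros on the raw intensity scale

    if config.mnar_slope > 0 and missing.any() and (~missing).any():
        assert true_log2[missing].mean() < true_log2[~missing].mean(), (
            "MNAR direction violated: missing entries should be low-intensity"
        )

    ids = [f"P{i:05d}" for i in range(p)]
    cols = [f"WT_{j + 1}" for j in range(n)] + [f"7dG_{j + 1}" for j in range(n)]
    table = pd.DataFrame(raw, columns=cols)
    table.insert(0, "protein_id", ids)
    table.insert(1, "contaminant_flag", "")
    table.insert(2, "reverse_flag", "")

    label = np.where(
        effect > 0, "WT-preferring", np.where(effect < 0, "7dG-preferring", "null")
    )
    truth = pd.DataFrame(
        {"protein_id": ids, "label": label, "true_log2_effect": effect}
    )
    return table, truth


@dataclass
class AssayFixtures:
    """Assay fixture tables plus the construction parameters (ground truth)."""

    ddct_table: pd.DataFrame
    rip_table: pd.DataFrame
    polysome_table: pd.DataFrame
    colony_table: pd.DataFrame
    truth: dict


def simulate_assays(seed: int = 0) -> AssayFixtures:
    """Fixtures built by inverting the assay formulas, including fixed anchor
    rows (fold 1.0, TE 0.30, PE 40%) plus randomised rows."""
    rng = np.random.default_rng(seed)

    # --- ddCt: per gene, Ct values constructed so 2^(-ddCt) equals the truth
    folds = {"anchor_fold1": 1.0}
    for i in range(4):
        folds[f"gene{i}"] = float(2.0 ** rng.uniform(-2, 2))
    ddct_rows = []
    for gene, fold in folds.items():
        ref_shift = float(rng.uniform(-0.5, 0.5))
        ddct_rows.append(
            {
                "gene": gene,
                "ct_target_control": 24.0,
                "ct_ref_control": 20.0,
                "ct_target_treated": 24.0 + ref_shift - np.log2(fold),
                "ct_ref_treated": 20.0 + ref_shift,
            }
        )

    # --- RIP: enrichment relative to a flat reference gene
    rip_truth = {"HPRT": 1.0, "anchor_fold1": 1.0}
    for i in range(3):
        rip_truth[f"gene{i}"] = float(2.0 ** rng.uniform(0, 4))
    rip_rows = []
    for gene, enr in rip_truth.items():
        shift = float(rng.uniform(-1, 1))
        rip_rows.append(
            {
                "gene": gene,
                "ct_input": 20.0 + shift,
                "ct_igg": 28.0 + shift,
                "ct_ip": 28.0 + shift - np.log2(enr),
            }
        )

    # --- polysome TE
    te_truth = {"anchor_te030": 0.30}
    for i in range(3):
        te_truth[f"gene{i}"] = float(rng.uniform(0.05, 0.9))
    poly_rows = []
    for gene, te in te_truth.items():
        total = float(rng.uniform(50, 200))
        hp = te * total
        np_amt = float(rng.uniform(0.2, 0.8)) * (total - hp)
        poly_rows.append(
            {
                "gene": gene,
                "np_amount": np_amt,
                "lp_amount": total - hp - np_amt,
                "hp_amount": hp,
            }
        )

    # --- clonogenic: integer colonies so PE is exact
    plated = 500
    colony_truth = {"anchor_pe40": 40.0}
    colony_rows = [{"condition": "anchor_pe40", "colonies": 200, "plated": plated}]
    for i in range(3):
        colonies = int(rng.integers(10, 450))
        colony_truth[f"cond{i}"] = colonies / plated * 100.0
        colony_rows.append(
            {"condition": f"cond{i}", "colonies": colonies, "plated": plated}
        )

    return AssayFixtures(
        ddct_table=pd.DataFrame(ddct_rows),
        rip_table=pd.DataFrame(rip_rows),
        polysome_table=pd.DataFrame(poly_rows),
        colony_table=pd.DataFrame(colony_rows),
        truth={
            "ddct_fold": folds,
            "rip_enrichment": rip_truth,
            "polysome_te": te_truth,
            "plating_efficiency_pct": colony_truth,
        },
    )
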