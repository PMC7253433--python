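"""QGRS-style RNA G-quadruplex (RG4) prediction and G-scoring.

A quadruplex-forming G-rich sequence (QGRS) is a window of at most
``max_qgrs_length`` nucleotides containing four equal-length runs of g >= 2
guanines (the tetrad number) separated by three loops of bounded length.
Candidates are scored with a G-score that rewards more tetrads and shorter,
more even loops; hits are accepted above a score threshold and resolved
greedily so that accepted hits never overlap.

Only the sense strand is scanned: RG4s are a property of the transcript
sequence itself, and a C-rich sequence yields no hits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transcripts import REGIONS, Transcript

#: Identity of the scoring function, recorded in catalog metadata.
SCORER_ID = "surrogate-linear-v1"

_VALID = set("ACGTN")


@dataclass(frozen=True)
class RG4Params:
    """Scanner parameters.

    min_g_run
        Minimum G-run (tetrad) length, >= 2.
    max_qgrs_length
        Maximum candidate span in nt.
    loop_min, loop_max
        Allowed loop lengths in nt (loops may be empty).
    score_threshold
        Minimum G-score for an accepted hit.
    """

    min_g_run: int = 2
    max_qgrs_length: int = 30
    loop_min: int = 0
    loop_max: int = 36
    score_threshold: float = 19.0

    def __post_init__(self) -> None:
        if self.min_g_run < 2:
            raise ValueError("min_g_run must be >= 2")
        if self.loop_min > self.loop_max or self.loop_min < 0:
            raise ValueError("need 0 <= loop_min <= loop_max")
        if self.max_qgrs_length < 4 * self.min_g_run + 3 * self.loop_min:
            raise ValueError("max_qgrs_length too small for four runs plus loops")


@dataclass(frozen=True)
class RG4Hit:
    """A predicted quadruplex: four G-runs of length ``g_run_length`` with
    three loops, in 0-based half-open transcript coordinates."""

    transcript_id: str
    start: int
    end: int
    g_run_length: int
    loop_lengths: tuple[int, int, int]
    score: float = float("nan")
    region: str | None = None

    def __post_init__(self) -> None:
        g, loops = self.g_run_length, self.loop_lengths
        if self.end - self.start != 4 * g + sum(loops):
            raise ValueError("span inconsistent with runs and loops")


def normalize_sequence(sequence: str) -> str:
    """Uppercase, map U->T, and validate the alphabet (IUPAC N allowed)."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"illegal sequence characters: {sorted(bad)}")
    return seq


def find_g_runs(sequence: str, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of G of length >= min_run, as (start, length), left to right.

    N never counts as G.
    """
    seq = normalize_sequence(sequence)
    runs = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= min_run:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def _g_prefix_positions(seq: str, g: int) -> list[int]:
    """Positions i such that seq[i:i+g] is all G (sub-runs included)."""
    n = len(seq)
    run_ahead = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        run_ahead[i] = run_ahead[i + 1] + 1 if seq[i] == "G" else 0
    return [i for i in range(n) if run_ahead[i] >= g]


def gscore(candidate: RG4Hit, params: RG4Params) -> float:
    """G-score of a candidate.

    The score is linear in the tetrad number and the loop geometry:
    ``20*(g-2) + 0.5*(max_qgrs_length - 4g - sum(loops)) - (max(loop) - min(loop))``.
    It is strictly increasing in g at fixed loops, non-increasing in total
    loop length at fixed g, and maximal for even loops at fixed total length.
    """
    return _score(candidate.g_run_length, candidate.loop_lengths, params)


def _score(g: int, loops: tuple[int, int, int], params: RG4Params) -> float:
    return (
        20.0 * (g - 2)
        + 0.5 * (params.max_qgrs_length - 4 * g - sum(loops))
        - (max(loops) - min(loops))
    )


def enumerate_qgrs(
    sequence: str, params: RG4Params = RG4Params(), transcript_id: str = ""
) -> list[RG4Hit]:
    """All QGRS candidates in a sequence, one per (start, end) span.

    For each span the maximal-g decomposition is emitted; among equal-g
    decompositions of the same span the highest-scoring one is kept (ties
    broken by lexicographically smallest loop lengths).
    """
    seq = normalize_sequence(sequence)
    best: dict[tuple[int, int], tuple[int, float, tuple[int, int, int]]] = {}
    g_cap = (params.max_qgrs_length - 3 * params.loop_min) // 4
    for g in range(params.min_g_run, g_cap + 1):
        positions = _g_prefix_positions(seq, g)
        if len(positions) < 4:
            continue
        pos = np.asarray(positions)
        for i1 in positions:
            window_end = i1 + params.max_qgrs_length
            # runs 2..4 must start within the window
            local = pos[(pos >= i1 + g + params.loop_min) & (pos + g <= window_end)]
            for i2 in local:
                l1 = i2 - (i1 + g)
                if l1 < params.loop_min:
                    continue
                if l1 > params.loop_max:
                    break
                for i3 in local[local >= i2 + g + params.loop_min]:
                    l2 = i3 - (i2 + g)
                    if l2 > params.loop_max:
                        break
                    for i4 in local[local >= i3 + g + params.loop_min]:
                        l3 = i4 - (i3 + g)
                        if l3 > params.loop_max:
                            break
                        if i4 + g > window_end:
                            break
                        span = (int(i1), int(i4 + g))
                        loops = (int(l1), int(l2), int(l3))
                        sc = _score(g, loops, params)
                        prev = best.get(span)
                        if (
                            prev is None
                            or g > prev[0]
                            or (g == prev[0] and (sc, [-x for x in loops]) > (prev[1], [-x for x in prev[2]]))
                        ):
                            best[span] = (g, sc, loops)
    hits = [
        RG4Hit(transcript_id, s, e, g, loops, score=sc)
        for (s, e), (g, sc, loops) in sorted(best.items())
    ]
    return hits


def select_hits(candidates: list[RG4Hit], params: RG4Params) -> list[RG4Hit]:
    """Threshold then greedy overlap resolution.

    Candidates scoring below the threshold are dropped; remaining candidates
    are kept highest-score first, discarding any candidate sharing >= 1 nt
    with an already accepted one. Ties break by smaller start, then shorter
    span.
    """
    passing = [c for c in candidates if c.score >= params.score_threshold]
    passing.sort(key=lambda c: (-c.score, c.start, c.end - c.start))
    accepted: list[RG4Hit] = []
    for cand in passing:
        if all(cand.end <= a.start or cand.start >= a.end for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda c: c.start)
    return accepted


@dataclass
class RG4Catalog:
    """Accepted hits for a transcriptome plus per-region totals."""

    hits: pd.DataFrame
    region_summary: pd.DataFrame
    params: RG4Params
    metadata: dict = field(default_factory=dict)

    def hits_for(self, transcript_id: str) -> pd.DataFrame:
        return self.hits[self.hits["transcript_id"] == transcript_id]


_HIT_COLUMNS = [
    "transcript_id",
    "start",
    "end",
    "g_run",
    "l1",
    "l2",
    "l3",
    "score",
    "region",
]


def predict_catalog(
    transcripts: list[Transcript], params: RG4Params = RG4Params()
) -> RG4Catalog:
    """Run enumerate -> score -> select per transcript (sense strand only)
    and assign each accepted hit to a region by its start position."""
    rows = []
    region_len = {r: 0 for r in REGIONS}
    for t in transcripts:
        for region in REGIONS:
            lo, hi = t.region_bounds(region)
            region_len[region] += hi - lo
        accepted = select_hits(
            enumerate_qgrs(t.sequence, params, transcript_id=t.transcript_id), params
        )
        for h in accepted:
            rows.append(
                {
                    "transcript_id": t.transcript_id,
                    "start": h.start,
                    "end": h.end,
                    "g_run": h.g_run_length,
                    "l1": h.loop_lengths[0],
                    "l2": h.loop_lengths[1],
                    "l3": h.loop_lengths[2],
                    "score": h.score,
                    "region": t.region_of(h.start),
                }
            )
    hits = pd.DataFrame(rows, columns=_HIT_COLUMNS)
    summary = pd.DataFrame(
        {
            "region": list(REGIONS),
            "n_hits": [int((hits["region"] == r).sum()) for r in REGIONS],
            "total_length_nt": [region_len[r] for r in REGIONS],
        }
    )
    return RG4Catalog(
        hits=hits,
        region_summary=summary,
        params=params,
        metadata={"scorer": SCORER_ID},
    )


def write_catalog_bed(catalog: RG4Catalog, path) -> None:
    """BED6 + extra columns (g, l1, l2, l3, region); strand is '+' (sense)."""
    with open(path, "w") as fh:
        for _, row in catalog.hits.iterrows():
            name = f"RG4_g{row.g_run}"
            fh.write(
                f"{row.transcript_id}\t{row.start}\t{row.end}\t{name}\t"
                f"{row.score:g}\t+\t{row.g_run}\t{row.l1}\t{row.l2}\t{row.l3}\t{row.region}\n"
            )


def brute_force_qgrs(sequence: str, params: RG4Params = RG4Params()) -> list[RG4Hit]:
    """Exhaustive reference enumeration over all (run-position, g) tuples.

    Used as an independent oracle in tests; quadratic-to-quartic in sequence
    length, so only suitable for short sequences.
    """
    seq = normalize_sequence(sequence)
    n = len(seq)
    best: dict[tuple[int, int], tuple[int, float, tuple[int, int, int]]] = {}
    g_cap = (params.max_qgrs_length - 3 * params.loop_min) // 4
    for g in range(params.min_g_run, g_cap + 1):
        all_g = [i for i in range(n - g + 1) if set(seq[i : i + g]) == {"G"}]
        for i1, i2, i3, i4 in itertools.combinations(all_g, 4):
            if i4 + g - i1 > params.max_qgrs_length:
                continue
            loops = (i2 - i1 - g, i3 - i2 - g, i4 - i3 - g)
            if any(l < params.loop_min or l > params.loop_max for l in loops):
                continue
            span = (i1, i4 + g)
            sc = _score(g, loops, params)
            prev = best.get(span)
            if (
                prev is None
                or g > prev[0]
                or (g == prev[0] and (sc, [-x for x in loops]) > (prev[1], [-x for x in prev[2]]))
            ):
                best[span] = (g, sc, loops)
    return [
        RG4Hit("", s, e, g, loops, score=sc)
        for (s, e), (g, sc, loops) in sorted(best.items())
    ]
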