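"""Strand-aware interval sets (CLIP sites, background sites) in BED6 form.

All coordinates are 0-based half-open, transcript-relative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class SiteSet:
    """A collection of strand-aware intervals backed by a BED6-shaped frame."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _BED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"SiteSet frame missing columns: {missing}")
        self.df = self.df[_BED_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def mean_length(self) -> float:
        return float(self.lengths.mean())

    @classmethod
    def from_bed(cls, path) -> "SiteSet":
        """Parse and validate a BED6 file; malformed lines are reported with
        their 1-based line number."""
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise ValueError(
                        f"{path}:{lineno}: expected 6 tab-separated BED fields, "
                        f"got {len(fields)}"
                    )
                chrom, start_s, end_s, name, score_s, strand = fields[:6]
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer start/end"
                    ) from None
                if start < 0 or start >= end:
                    raise ValueError(
                        f"{path}:{lineno}: invalid interval [{start}, {end})"
                    )
                try:
                    score = float(score_s) if score_s != "." else 0.0
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric score {score_s!r}"
                    ) from None
                if strand not in {"+", "-"}:
                    raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
                rows.append((chrom, start, end, name, score, strand))
        return cls(pd.DataFrame(rows, columns=_BED_COLUMNS))

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.df.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t"
                    f"{row.score:g}\t{row.strand}\n"
                )

    def extended(self, flank: int, bounds: dict[str, int]) -> "SiteSet":
        """Grow every site by ``flank`` nt on both ends, clipped to
        [0, sequence length); strand preserved."""
        if flank < 0:
            raise ValueError("flank must be >= 0")
        df = self.df.copy()
        limits = df["chrom"].map(bounds)
        if limits.isna().any():
            unknown = sorted(df.loc[limits.isna(), "chrom"].unique())
            raise ValueError(f"no sequence bounds for: {unknown}")
        df["start"] = np.maximum(df["start"] - flank, 0)
        df["end"] = np.minimum(df["end"] + flank, limits.astype(int))
        return SiteSet(df)

    def merged_length(self) -> int:
        """Total nt covered, counting overlapping same-chrom/strand sites once."""
        total = 0
        for (_, _), grp in self.df.groupby(["chrom", "strand"], sort=False):
            total += _merged_span(grp["start"].to_numpy(), grp["end"].to_numpy())
        return total


def _merged_span(starts: np.ndarray, ends: np.ndarray) -> int:
    order = np.argsort(starts, kind="stable")
    total, cur_s, cur_e = 0, None, None
    for s, e in zip(starts[order], ends[order]):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return int(total)


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping intervals into disjoint sorted intervals."""
    if len(starts) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    order = np.argsort(starts, kind="stable")
    ms, me = [], []
    for s, e in zip(np.asarray(starts)[order], np.asarray(ends)[order]):
        if not me or s > me[-1]:
            ms.append(int(s))
            me.append(int(e))
        else:
            me[-1] = max(me[-1], int(e))
    return np.asarray(ms), np.asarray(me)


def overlaps_any(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    ref_starts: np.ndarray,
    ref_ends: np.ndarray,
    min_overlap: int = 1,
) -> np.ndarray:
    """Boolean per query: does it share >= min_overlap nt with any reference
    interval? Reference intervals must be disjoint and sorted by start."""
    q_starts = np.asarray(q_starts)
    q_ends = np.asarray(q_ends)
    if len(ref_starts) == 0:
        return np.zeros(len(q_starts), dtype=bool)
    if min_overlap == 1:
        # exact for unit overlap: ref with start < q_end and end > q_start
        hi = np.searchsorted(ref_starts, q_ends - 1, side="right")
        lo = np.searchsorted(ref_ends, q_starts + 1, side="left")
        return hi > lo
    out = np.zeros(len(q_starts), dtype=bool)
    hi = np.searchsorted(ref_starts, q_ends - min_overlap, side="right")
    lo = np.searchsorted(ref_ends, q_starts + min_overlap, side="left")
    for i, (a, b) in enumerate(zip(lo, hi)):
        for j in range(a, b):
            ov = min(q_ends[i], ref_ends[j]) - max(q_starts[i], ref_starts[j])
            if ov >= min_overlap:
                out[i] = True
                break
    return out
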