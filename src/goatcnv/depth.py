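"""Sliding-window read-depth tracks, depth summaries, and CNV ratios.

The copy-number pipeline works on fixed sliding windows (default 200 bp
windows every 100 bp).  A sample's *one-fold depth* — the mean window read
count across the whole genome — is taken as the depth of the baseline
diploid copy state, and the CNV ratio of a window is its count divided by
that one-fold depth: a ratio fluctuating around 1 means two copies, around
2 means four.

Coordinates are 0-based half-open internally; the per-base depth TSV input
is 1-based as is conventional for such tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
import yaml

__all__ = [
    "WindowDepthTrack",
    "DepthSummary",
    "CnvRatioProfile",
    "n_windows",
    "window_starts",
    "read_fai",
    "compute_window_depths",
    "summarize_depth",
    "cnv_ratio",
    "moving_average",
    "write_track_tsv",
    "read_track_tsv",
    "write_summary_yaml",
    "write_bedgraph",
    "read_bedgraph_profile",
]

#: Minimum number of windows a sequence needs before its mean/SD are
#: considered usable for CNV calling (one full scanning frame).
MIN_USABLE_WINDOWS = 7


def n_windows(seq_len: int, window_size: int = 200, step: int = 100) -> int:
    """Number of full windows tiling a sequence of length ``seq_len``.

    Trailing bases shorter than one window are dropped, so for
    L >= window_size the count is floor((L - window_size)/step) + 1.
    """
    if seq_len < window_size:
        return 0
    return (seq_len - window_size) // step + 1


def window_starts(seq_len: int, window_size: int = 200, step: int = 100) -> np.ndarray:
    """0-based start coordinates of the windows tiling a sequence."""
    return np.arange(n_windows(seq_len, window_size, step), dtype=np.int64) * step


@dataclass
class WindowDepthTrack:
    """Per-sample read counts in fixed sliding windows over every sequence.

    ``counts[seq][i]`` is the count for the window ``[i*step, i*step +
    window_size)``.  Counts are stored as floats because the per-base-depth
    path yields window means rather than integer read tallies.
    """

    sample_id: str
    window_size: int = 200
    step: int = 100
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    sequence_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_size % self.step != 0:
            raise ValueError("window_size must be a multiple of step")
        for seq, arr in self.counts.items():
            arr = np.asarray(arr, dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"negative window count on {seq}")
            self.counts[seq] = arr

    @property
    def sequences(self) -> list[str]:
        return list(self.counts)

    @property
    def total_windows(self) -> int:
        return int(sum(len(a) for a in self.counts.values()))

    def starts(self, seq: str) -> np.ndarray:
        return np.arange(len(self.counts[seq]), dtype=np.int64) * self.step

    def same_grid(self, other: "WindowDepthTrack") -> bool:
        return (
            self.window_size == other.window_size
            and self.step == other.step
            and self.sequences == other.sequences
            and all(len(self.counts[s]) == len(other.counts[s]) for s in self.counts)
        )


@dataclass
class DepthSummary:
    """Per-sequence depth statistics and the genome-wide one-fold depth.

    ``per_sequence`` maps sequence name to (mean, population SD, n_windows).
    ``genome_onefold_depth`` is the unweighted mean window count over all
    windows genome-wide: the baseline diploid depth.
    """

    sample_id: str
    per_sequence: dict[str, tuple[float, float, int]]
    genome_onefold_depth: float

    def usable(self, seq: str) -> bool:
        """Whether a sequence has enough windows to support calling."""
        return self.per_sequence[seq][2] >= MIN_USABLE_WINDOWS

    def mean(self, seq: str) -> float:
        return self.per_sequence[seq][0]

    def sd(self, seq: str) -> float:
        return self.per_sequence[seq][1]


@dataclass
class CnvRatioProfile:
    """Per-window CNV ratios: window count / genome one-fold depth."""

    sample_id: str
    window_size: int
    step: int
    ratios: dict[str, np.ndarray]

    @property
    def sequences(self) -> list[str]:
        return list(self.ratios)

    def starts(self, seq: str) -> np.ndarray:
        return np.arange(len(self.ratios[seq]), dtype=np.int64) * self.step


def read_fai(path: str | Path) -> dict[str, int]:
    """Read a ``.fai``-style name/length table (first two columns)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.split("\t")
            lengths[parts[0]] = int(parts[1])
    return lengths


def _windows_for_position(pos: np.ndarray, window_size: int, step: int, nw: int):
    """Yield window indices containing each 0-based position.

    A position ``p`` lies in windows ``i`` with ``i*step <= p < i*step +
    window_size``; since window_size is a multiple of step an interior
    position falls in exactly window_size/step windows.
    """
    for k in range(window_size // step):
        idx = pos // step - k
        ok = (idx >= 0) & (idx < nw) & (idx * step + window_size > pos)
        yield idx[ok]


def compute_window_depths(
    source: str | Path,
    reference_index: Mapping[str, int] | str | Path,
    window_size: int = 200,
    step: int = 100,
    min_mapq: int = 0,
    sample_id: str | None = None,
    assign: str = "leftmost",
) -> WindowDepthTrack:
    """Count aligned reads (or average per-base depth) per sliding window.

    ``source`` is either a SAM/BAM file — each passing read is assigned to
    every window containing its assignment base (``leftmost`` aligned base
    by default, optionally ``midpoint``); unmapped, secondary,
    supplementary and duplicate-flagged reads and reads below ``min_mapq``
    are excluded — or a per-base depth TSV
    (``sequence<TAB>position(1-based)<TAB>depth``), in which case the window
    value is the mean per-base depth over the window (absent positions count
    as depth 0).

    Raises ``ValueError`` for a sequence present in the input but absent
    from the reference index; an empty input produces an all-zero track
    with a warning.
    """
    if assign not in ("leftmost", "midpoint"):
        raise ValueError(f"unknown assignment convention: {assign!r}")
    if isinstance(reference_index, (str, Path)):
        reference_index = read_fai(reference_index)
    lengths = dict(reference_index)

    track = WindowDepthTrack(
        sample_id=sample_id or Path(str(source)).stem,
        window_size=window_size,
        step=step,
        counts={
            seq: np.zeros(n_windows(L, window_size, step), dtype=float)
            for seq, L in lengths.items()
        },
        sequence_lengths=lengths,
    )

    src = str(source)
    if src.endswith((".sam", ".bam", ".cram")):
        _count_reads(src, track, lengths, min_mapq, assign)
    else:
        _average_per_base(src, track, lengths)
    if all(not a.any() for a in track.counts.values()):
        warnings.warn(f"no depth signal in {src}: all-zero track", stacklevel=2)
    return track


def _count_reads(path, track, lengths, min_mapq, assign):
    positions: dict[str, list[int]] = {seq: [] for seq in lengths}
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as af:
        for read in af.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.mapping_quality < min_mapq
            ):
                continue
            seq = read.reference_name
            if seq not in lengths:
                raise ValueError(f"sequence {seq!r} not in reference index")
            if assign == "leftmost":
                pos = read.reference_start
            else:
                pos = (read.reference_start + read.reference_end - 1) // 2
            positions[seq].append(pos)
    for seq, pos_list in positions.items():
        if not pos_list:
            continue
        arr = track.counts[seq]
        pos = np.asarray(pos_list, dtype=np.int64)
        for idx in _windows_for_position(pos, track.window_size, track.step, len(arr)):
            np.add.at(arr, idx, 1.0)


def _average_per_base(path, track, lengths):
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["sequence", "position", "depth"],
        dtype={"sequence": str, "position": np.int64, "depth": float},
    )
    unknown = set(df["sequence"]) - set(lengths)
    if unknown:
        raise ValueError(f"sequence {sorted(unknown)[0]!r} not in reference index")
    for seq, sub in df.groupby("sequence", sort=False):
        L = lengths[seq]
        depth = np.zeros(L, dtype=float)
        pos0 = sub["position"].to_numpy() - 1  # TSV is 1-based
        if np.any((pos0 < 0) | (pos0 >= L)):
            raise ValueError(f"per-base position outside {seq!r} (length {L})")
        depth[pos0] = sub["depth"].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(depth)])
        starts = window_starts(L, track.window_size, track.step)
        track.counts[seq] = (
            csum[starts + track.window_size] - csum[starts]
        ) / track.window_size


def summarize_depth(track: WindowDepthTrack) -> DepthSummary:
    """Per-sequence mean/SD of window counts plus the genome one-fold depth.

    The SD is the population SD.  Sequences with fewer than seven windows
    (one scanning frame) are flagged with a warning; they still contribute
    to the genome-wide mean.
    """
    if track.total_windows == 0:
        raise ValueError("empty track: no windows")
    per_seq: dict[str, tuple[float, float, int]] = {}
    total = 0.0
    nw_total = 0
    for seq, arr in track.counts.items():
        nw = len(arr)
        if nw == 0:
            per_seq[seq] = (0.0, 0.0, 0)
            continue
        per_seq[seq] = (float(arr.mean()), float(arr.std()), nw)
        if nw < MIN_USABLE_WINDOWS:
            warnings.warn(
                f"sequence {seq!r} has {nw} < {MIN_USABLE_WINDOWS} windows: "
                "unusable for CNV calling",
                stacklevel=2,
            )
        total += float(arr.sum())
        nw_total += nw
    return DepthSummary(
        sample_id=track.sample_id,
        per_sequence=per_seq,
        genome_onefold_depth=total / nw_total,
    )


def cnv_ratio(track: WindowDepthTrack, summary: DepthSummary) -> CnvRatioProfile:
    """Elementwise window count / one-fold depth."""
    if summary.sample_id != track.sample_id:
        raise ValueError("summary was computed from a different sample")
    if summary.genome_onefold_depth == 0:
        raise ValueError("genome one-fold depth is zero; ratios undefined")
    return CnvRatioProfile(
        sample_id=track.sample_id,
        window_size=track.window_size,
        step=track.step,
        ratios={
            seq: arr / summary.genome_onefold_depth for seq, arr in track.counts.items()
        },
    )


def moving_average(profile: CnvRatioProfile, span_windows: int) -> CnvRatioProfile:
    """Centered moving average of the ratio profile (trend line).

    ``span_windows`` must be odd; at the ends the span is truncated to the
    available windows, so a constant profile is unchanged.
    """
    if span_windows < 1 or span_windows % 2 == 0:
        raise ValueError("span must be odd and >= 1")
    half = span_windows // 2
    smoothed = {}
    for seq, arr in profile.ratios.items():
        nw = len(arr)
        if span_windows > nw:
            raise ValueError(
                f"span {span_windows} exceeds window count {nw} on {seq!r}"
            )
        if span_windows == 1:
            smoothed[seq] = arr.copy()
            continue
        csum = np.concatenate([[0.0], np.cumsum(arr)])
        idx = np.arange(nw)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, nw)
        smoothed[seq] = (csum[hi] - csum[lo]) / (hi - lo)
    return CnvRatioProfile(
        sample_id=profile.sample_id,
        window_size=profile.window_size,
        step=profile.step,
        ratios=smoothed,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_track_tsv(track: WindowDepthTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sample_id={track.sample_id}\n")
        fh.write(f"#window_size={track.window_size}\n")
        fh.write(f"#step={track.step}\n")
        for seq, L in track.sequence_lengths.items():
            fh.write(f"#sequence_length={seq}:{L}\n")
        fh.write("sequence\tstart\tend\tcount\n")
        for seq, arr in track.counts.items():
            starts = track.starts(seq)
            for s, c in zip(starts, arr):
                fh.write(f"{seq}\t{s}\t{s + track.window_size}\t{c:g}\n")


def read_track_tsv(path: str | Path) -> WindowDepthTrack:
    meta: dict[str, str] = {}
    seq_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            if key == "sequence_length":
                name, _, L = value.partition(":")
                seq_lengths[name] = int(L)
            else:
                meta[key] = value
    df = pd.read_csv(path, sep="\t", comment="#")
    counts = {
        seq: sub["count"].to_numpy(dtype=float)
        for seq, sub in df.groupby("sequence", sort=False)
    }
    return WindowDepthTrack(
        sample_id=meta.get("sample_id", Path(str(path)).stem),
        window_size=int(meta.get("window_size", 200)),
        step=int(meta.get("step", 100)),
        counts=counts,
        sequence_lengths=seq_lengths,
    )


def write_summary_yaml(summary: DepthSummary, path: str | Path) -> None:
    data = {
        "sample_id": summary.sample_id,
        "genome_onefold_depth": summary.genome_onefold_depth,
        "sequences": {
            seq: {"mean": m, "sd": sd, "n_windows": nw}
            for seq, (m, sd, nw) in summary.per_sequence.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_bedgraph(profile: CnvRatioProfile, path: str | Path) -> None:
    """Serialize a ratio profile as bedGraph (one row per window)."""
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{profile.sample_id} CNV ratio"\n'
        )
        for seq, arr in profile.ratios.items():
            starts = profile.starts(seq)
            for s, r in zip(starts, arr):
                fh.write(f"{seq}\t{s}\t{s + profile.window_size}\t{r:.6g}\n")


def read_bedgraph_profile(
    path: str | Path,
    sample_id: str | None = None,
    window_size: int = 200,
    step: int = 100,
) -> CnvRatioProfile:
    with open(path) as fh:
        lines = [
            ln for ln in fh
            if ln.strip() and not ln.startswith(("track", "#", "browser"))
        ]
    from io import StringIO

    rows = pd.read_csv(
        StringIO("".join(lines)),
        sep="\t",
        header=None,
        names=["sequence", "start", "end", "ratio"],
    )
    ratios = {
        seq: sub["ratio"].to_numpy(dtype=float)
        for seq, sub in rows.groupby("sequence", sort=False)
    }
    return CnvRatioProfile(
        sample_id=sample_id or Path(str(path)).stem,
        window_size=window_size,
        step=step,
        ratios=ratios,
    )
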