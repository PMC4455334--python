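"""CNV gain/loss region calling from window tracks.

The detection rule is a k-of-frame scan over the sliding windows: a window
qualifies (elevated for gains, depleted-with-a-normal-neighbour for
losses), a frame of ``frame`` consecutive windows fires when at least ``k``
of its windows qualify (five of seven by default), and a called region is
the union of qualifying windows covered by any firing frame, with
overlapping or adjacent firing frames merged and the region trimmed to its
outermost qualifying window.

Gains are judged against the window's own chromosome — count above the
per-chromosome mean + 2 SD — while losses are judged against each sample's
genome-wide one-fold depth (< 0.1×) together with a cross-sample rescue
condition: at least one other individual must look normal (> 0.5× its own
one-fold depth) in the same window, which protects against systematically
unmappable sequence being called as deleted in everybody.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .depth import DepthSummary, WindowDepthTrack

__all__ = [
    "CnvRegion",
    "detect_gain_regions",
    "detect_loss_regions",
    "merge_regions",
    "aggregate_region_counts",
    "write_regions_tsv",
    "write_regions_bed",
    "read_regions_tsv",
]


@dataclass
class CnvRegion:
    """One called gain or loss interval for one sample (0-based half-open)."""

    sample_id: str
    sequence: str
    start: int
    end: int
    type: str  # "gain" | "loss"
    n_supporting_windows: int
    mean_ratio: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _scan_k_of_frame(mask: np.ndarray, k: int, frame: int) -> list[tuple[int, int, int]]:
    """k-of-frame scan over a boolean qualifying mask.

    Returns ``(first, last, n_support)`` window-index triples: for each
    merged run of firing frames, the first and last qualifying window and
    the number of qualifying windows in the run.
    """
    nw = len(mask)
    if nw < frame:
        return []
    hits = np.convolve(mask.astype(np.int64), np.ones(frame, dtype=np.int64), "valid")
    firing = np.flatnonzero(hits >= k)
    if firing.size == 0:
        return []
    out = []
    run_start = int(firing[0])
    run_end = run_start + frame  # exclusive window index
    for f in firing[1:]:
        if f <= run_end:  # overlapping or adjacent frame spans merge
            run_end = int(f) + frame
        else:
            out.append(_trim_run(mask, run_start, run_end))
            run_start = int(f)
            run_end = run_start + frame
    out.append(_trim_run(mask, run_start, run_end))
    return out


def _trim_run(mask, lo, hi):
    idx = np.flatnonzero(mask[lo:hi]) + lo
    return int(idx[0]), int(idx[-1]), int(len(idx))


def _regions_from_mask(
    mask: np.ndarray,
    counts: np.ndarray,
    onefold: float,
    sample_id: str,
    seq: str,
    region_type: str,
    k: int,
    frame: int,
    window_size: int,
    step: int,
) -> list[CnvRegion]:
    regions = []
    for first, last, n_sup in _scan_k_of_frame(mask, k, frame):
        support = np.flatnonzero(mask[first : last + 1]) + first
        regions.append(
            CnvRegion(
                sample_id=sample_id,
                sequence=seq,
                start=first * step,
                end=last * step + window_size,
                type=region_type,
                n_supporting_windows=n_sup,
                mean_ratio=float(counts[support].mean() / onefold),
            )
        )
    return regions


def detect_gain_regions(
    track: WindowDepthTrack,
    summary: DepthSummary,
    k: int = 5,
    frame: int = 7,
    sd_mult: float = 2.0,
) -> list[CnvRegion]:
    """Call gain regions: >= k of ``frame`` sequential windows elevated.

    A window is elevated when its count exceeds the per-chromosome mean +
    ``sd_mult`` × SD (population SD).  On a degenerate chromosome with
    SD = 0 the threshold reduces to the mean and any window strictly above
    it qualifies.  Sequences with fewer than ``frame`` windows are skipped
    with a warning.
    """
    if summary.sample_id != track.sample_id:
        raise ValueError("summary was computed from a different sample")
    regions: list[CnvRegion] = []
    for seq, counts in track.counts.items():
        if len(counts) < frame:
            warnings.warn(
                f"sequence {seq!r} has fewer than {frame} windows; skipped",
                stacklevel=2,
            )
            continue
        mean, sd, _ = summary.per_sequence[seq]
        mask = counts > mean + sd_mult * sd
        regions.extend(
            _regions_from_mask(
                mask, counts, summary.genome_onefold_depth, track.sample_id,
                seq, "gain", k, frame, track.window_size, track.step,
            )
        )
    return regions


def detect_loss_regions(
    tracks: Mapping[str, WindowDepthTrack],
    summaries: Mapping[str, DepthSummary],
    k: int = 5,
    frame: int = 7,
    low: float = 0.1,
    normal: float = 0.5,
) -> dict[str, list[CnvRegion]]:
    """Call loss regions per sample with the cross-sample normality rescue.

    Window w is a loss window for sample s iff count_s(w) < ``low`` × that
    sample's one-fold depth AND at least one other sample t has
    count_t(w) > ``normal`` × its own one-fold depth.  The same k-of-frame
    scan and merging as for gains then applies.  Both comparisons are
    strict, so a window at exactly 0.1× is not a loss window.
    """
    samples = list(tracks)
    if len(samples) < 2:
        raise ValueError(
            "loss calling needs >= 2 samples (cross-sample condition undefined)"
        )
    ref = tracks[samples[0]]
    for s in samples[1:]:
        if not ref.same_grid(tracks[s]):
            raise ValueError(f"track {s!r} is not on the same window grid")

    results: dict[str, list[CnvRegion]] = {s: [] for s in samples}
    for seq in ref.sequences:
        nw = len(ref.counts[seq])
        if nw < frame:
            warnings.warn(
                f"sequence {seq!r} has fewer than {frame} windows; skipped",
                stacklevel=2,
            )
            continue
        counts = np.stack([tracks[s].counts[seq] for s in samples])
        onefold = np.array([summaries[s].genome_onefold_depth for s in samples])
        low_mask = counts < low * onefold[:, None]
        normal_mask = counts > normal * onefold[:, None]
        n_normal = normal_mask.sum(axis=0)
        for i, s in enumerate(samples):
            other_normal = (n_normal - normal_mask[i]) > 0
            mask = low_mask[i] & other_normal
            results[s].extend(
                _regions_from_mask(
                    mask, counts[i], onefold[i], s, seq, "loss",
                    k, frame, ref.window_size, ref.step,
                )
            )
    return results


def merge_regions(
    regions: Sequence[CnvRegion], max_gap: int | None = None, step: int = 100
) -> list[CnvRegion]:
    """Merge same-type regions of one sample separated by <= max_gap bp.

    Default ``max_gap`` is the window step.  Supporting-window counts are
    summed; the mean ratio is combined weighted by support.  Mixing samples
    is an error.
    """
    if not regions:
        return []
    if len({r.sample_id for r in regions}) > 1:
        raise ValueError("merge_regions operates on a single sample")
    if max_gap is None:
        max_gap = step
    merged: list[CnvRegion] = []
    key = lambda r: (r.sequence, r.type, r.start, r.end)
    for r in sorted(regions, key=key):
        if (
            merged
            and merged[-1].sequence == r.sequence
            and merged[-1].type == r.type
            and r.start - merged[-1].end <= max_gap
        ):
            prev = merged[-1]
            n = prev.n_supporting_windows + r.n_supporting_windows
            merged[-1] = CnvRegion(
                sample_id=prev.sample_id,
                sequence=prev.sequence,
                start=prev.start,
                end=max(prev.end, r.end),
                type=prev.type,
                n_supporting_windows=n,
                mean_ratio=(
                    prev.mean_ratio * prev.n_supporting_windows
                    + r.mean_ratio * r.n_supporting_windows
                )
                / n,
            )
        else:
            merged.append(r)
    return merged


def aggregate_region_counts(
    regions: Sequence[CnvRegion],
    sequence_lengths: Mapping[str, int],
    bin_size: int = 1_000_000,
    min_region_size: int = 800,
) -> pd.DataFrame:
    """Count regions longer than ``min_region_size`` into 1-Mb bins.

    A region is assigned to the non-overlapping bin containing its start;
    the > filter is strict, so an 800-bp region is excluded.  Returns a
    table with one row per bin per sequence (zeros included).
    """
    rows = []
    index: dict[tuple[str, int], int] = {}
    for seq, L in sequence_lengths.items():
        nbins = max(1, -(-L // bin_size))
        for b in range(nbins):
            index[(seq, b)] = len(rows)
            rows.append(
                {
                    "sequence": seq,
                    "bin_start": b * bin_size,
                    "bin_end": min((b + 1) * bin_size, L),
                    "count": 0,
                }
            )
    for r in regions:
        if r.length <= min_region_size:
            continue
        key = (r.sequence, r.start // bin_size)
        if key not in index:
            raise ValueError(f"region start {r.start} outside {r.sequence!r}")
        rows[index[key]]["count"] += 1
    return pd.DataFrame(rows, columns=["sequence", "bin_start", "bin_end", "count"])


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_REGION_COLS = [
    "sample_id", "sequence", "start", "end", "type",
    "n_supporting_windows", "mean_ratio",
]


def write_regions_tsv(regions: Sequence[CnvRegion], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in regions], columns=_REGION_COLS).to_csv(
        path, sep="\t", index=False
    )


def read_regions_tsv(path: str | Path) -> list[CnvRegion]:
    df = pd.read_csv(path, sep="\t")
    return [CnvRegion(**{c: row[c] for c in _REGION_COLS}) for _, row in df.iterrows()]


def write_regions_bed(regions: Sequence[CnvRegion], path: str | Path) -> None:
    """BED output: name = sample|type, score = mean ratio × 100 (capped)."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.sequence, r.start)):
            score = min(1000, int(round(r.mean_ratio * 100)))
            fh.write(
                f"{r.sequence}\t{r.start}\t{r.end}\t"
                f"{r.sample_id}|{r.type}\t{score}\t.\n"
            )
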