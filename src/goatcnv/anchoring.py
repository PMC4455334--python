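"""Reference-guided scaffold anchoring and pseudo-chromosome construction.

Whole-genome alignment hits (LASTZ-style, ingested as PAF or an 8-column
table) link scaffolds to chromosome loci of a related reference.  Hits are
clustered into chains within 100-kb windows, isolated short ("orphan")
hits are discarded, and a scaffold is placed only when its longest chain is
more than twice the second longest — strictly more, so a 2.0× tie stays
ambiguous.  Placed scaffolds are ordered, oriented (reverse-complemented on
the minus strand) and joined with N gaps into pseudo-chromosomes, described
exactly by AGP v2.1.

The Y-chromosome variant merges hits under looser, repeat-aware rules
(gaps under 1 kb always merge; 1–5-kb gaps merge only when the intervening
sequence is more than half repeat) and orders scaffolds by the contig
order of a related Y assembly, after dropping low-coverage (<60%) protein
evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sim import reverse_complement

__all__ = [
    "AlignmentHit",
    "AlignmentHitChain",
    "AnchorPlacement",
    "read_hits",
    "filter_short_scaffolds",
    "cluster_hits",
    "select_placement",
    "place_all",
    "build_pseudochromosomes",
    "assemble_from_agp",
    "filter_protein_hits",
    "cluster_hits_y",
    "order_on_reference_y",
    "write_agp",
    "write_placements_tsv",
]


@dataclass
class AlignmentHit:
    query: str
    qstart: int
    qend: int
    strand: str
    target: str
    tstart: int
    tend: int
    length: int

    def __post_init__(self) -> None:
        if self.qstart >= self.qend or self.tstart >= self.tend or self.length <= 0:
            raise ValueError("malformed hit: start >= end or non-positive length")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class AlignmentHitChain:
    """A cluster of collinear hits linking one scaffold to one locus."""

    query: str
    target: str
    tstart: int
    tend: int
    total_length: int
    strand: str
    members: list[AlignmentHit] = field(default_factory=list)


@dataclass
class AnchorPlacement:
    query: str
    target: str | None
    position: int | None
    orientation: str | None
    status: str  # "placed" | "ambiguous" | "unplaced"
    chain: AlignmentHitChain | None = None


def read_hits(path: str | Path) -> list[AlignmentHit]:
    """Read alignment hits from PAF or the 8-column tabular format.

    PAF rows carry >= 12 columns with the strand in column 5 and the
    alignment block length in column 11; the tabular format is
    query, qstart, qend, strand, target, tstart, tend, match_length.
    Malformed rows (start >= end) are rejected with a warning.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                if len(parts) >= 12 and parts[4] in "+-":  # PAF
                    hit = AlignmentHit(
                        query=parts[0], qstart=int(parts[2]), qend=int(parts[3]),
                        strand=parts[4], target=parts[5],
                        tstart=int(parts[7]), tend=int(parts[8]),
                        length=int(parts[10]),
                    )
                elif len(parts) >= 8 and parts[3] in "+-":
                    hit = AlignmentHit(
                        query=parts[0], qstart=int(parts[1]), qend=int(parts[2]),
                        strand=parts[3], target=parts[4],
                        tstart=int(parts[5]), tend=int(parts[6]),
                        length=int(parts[7]),
                    )
                else:
                    raise ValueError("unrecognized hit row")
            except (ValueError, IndexError) as exc:
                warnings.warn(f"{path}:{lineno}: skipping hit row ({exc})", stacklevel=2)
                continue
            hits.append(hit)
    return hits


def filter_short_scaffolds(
    scaffold_lengths: Mapping[str, int], min_len: int = 2_000
) -> dict[str, int]:
    """Keep scaffolds strictly longer than ``min_len`` (default 2 kb)."""
    return {n: L for n, L in scaffold_lengths.items() if L > min_len}


def _chain_from_members(members: list[AlignmentHit]) -> AlignmentHitChain:
    members = sorted(members, key=lambda h: h.tstart)
    plus = sum(h.length for h in members if h.strand == "+")
    minus = sum(h.length for h in members if h.strand == "-")
    return AlignmentHitChain(
        query=members[0].query,
        target=members[0].target,
        tstart=members[0].tstart,
        tend=max(h.tend for h in members),
        total_length=sum(h.length for h in members),
        strand="+" if plus >= minus else "-",
        members=members,
    )


def cluster_hits(
    hits: Iterable[AlignmentHit],
    window: int = 100_000,
    orphan_min: int = 500,
) -> list[AlignmentHitChain]:
    """Single-linkage chaining of hits within 100-kb windows.

    Per (query, target) pair, successive hits (sorted by target start)
    join one chain while the gap between their target starts is at most
    ``window``.  A chain made of a single hit shorter than ``orphan_min``
    is an orphan and is discarded.
    """
    groups: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault((h.query, h.target), []).append(h)
    chains = []
    for members in groups.values():
        members.sort(key=lambda h: h.tstart)
        cur = [members[0]]
        for h in members[1:]:
            if h.tstart - cur[-1].tstart <= window:
                cur.append(h)
            else:
                chains.append(cur)
                cur = [h]
        chains.append(cur)
    out = []
    for members in chains:
        if len(members) == 1 and members[0].length < orphan_min:
            continue  # orphan
        out.append(_chain_from_members(members))
    out.sort(key=lambda c: (c.query, c.target, c.tstart))
    return out


def select_placement(
    query: str, chains: Sequence[AlignmentHitChain], ratio: float = 2.0
) -> AnchorPlacement:
    """Pick the best chain under the longest > ratio × second rule.

    Chains are ranked by total aligned length (sum of member hit lengths).
    A single chain wins outright; otherwise the longest must be strictly
    more than ``ratio`` times the second or the scaffold stays ambiguous.
    """
    chains = sorted(chains, key=lambda c: c.total_length, reverse=True)
    if not chains:
        return AnchorPlacement(query, None, None, None, "unplaced")
    best = chains[0]
    if len(chains) > 1 and best.total_length <= ratio * chains[1].total_length:
        return AnchorPlacement(query, None, None, None, "ambiguous")
    return AnchorPlacement(
        query, best.target, best.tstart, best.strand, "placed", chain=best
    )


def place_all(
    chains: Iterable[AlignmentHitChain], ratio: float = 2.0
) -> list[AnchorPlacement]:
    by_query: dict[str, list[AlignmentHitChain]] = {}
    for c in chains:
        by_query.setdefault(c.query, []).append(c)
    return [select_placement(q, cs, ratio) for q, cs in sorted(by_query.items())]


# ---------------------------------------------------------------------------
# pseudo-chromosome construction / AGP
# ---------------------------------------------------------------------------

def _build_object(
    name: str,
    ordered: Sequence[AnchorPlacement],
    scaffolds: Mapping[str, str],
    gap_n: int,
    part_rows: list,
) -> str:
    pieces = []
    pos = 0
    part = 1
    for i, p in enumerate(ordered):
        seq = scaffolds[p.query]
        if p.orientation == "-":
            seq = reverse_complement(seq)
        if i > 0 and gap_n > 0:
            part_rows.append(
                (name, pos + 1, pos + gap_n, part, "U", gap_n,
                 "scaffold", "yes", "align_genus")
            )
            pieces.append("N" * gap_n)
            pos += gap_n
            part += 1
        part_rows.append(
            (name, pos + 1, pos + len(seq), part, "W", p.query,
             1, len(seq), p.orientation)
        )
        pieces.append(seq)
        pos += len(seq)
        part += 1
    return "".join(pieces)


def build_pseudochromosomes(
    placements: Sequence[AnchorPlacement],
    scaffolds: Mapping[str, str],
    gap_n: int = 100,
    object_suffix: str = "",
):
    """Concatenate placed scaffolds per chromosome into pseudo-chromosomes.

    Scaffolds are ordered by placement position (ties by name), minus-strand
    scaffolds reverse-complemented, and neighbours separated by ``gap_n``
    N's recorded as AGP "U" gaps (size not experimentally determined).

    Returns ``(sequences, agp_rows, unplaced)`` where ``agp_rows`` is the
    list of AGP v2.1 tuples describing the sequences exactly.
    """
    placed = [p for p in placements if p.status == "placed"]
    seen: set[str] = set()
    for p in placed:
        if p.query in seen:
            raise ValueError(f"duplicate placement of scaffold {p.query!r}")
        seen.add(p.query)
        if p.query not in scaffolds:
            raise ValueError(f"no sequence for placed scaffold {p.query!r}")
    by_target: dict[str, list[AnchorPlacement]] = {}
    for p in placed:
        by_target.setdefault(p.target, []).append(p)

    sequences: dict[str, str] = {}
    agp_rows: list = []
    for target in sorted(by_target):
        ordered = sorted(by_target[target], key=lambda p: (p.position, p.query))
        sequences[target + object_suffix] = _build_object(
            target + object_suffix, ordered, scaffolds, gap_n, agp_rows
        )
    unplaced = [p.query for p in placements if p.status != "placed"]
    return sequences, agp_rows, unplaced


def write_agp(agp_rows: Sequence[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for row in agp_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def assemble_from_agp(
    agp: str | Path | Sequence[tuple], scaffolds: Mapping[str, str]
) -> dict[str, str]:
    """Independently rebuild object sequences from AGP + component FASTA."""
    if isinstance(agp, (str, Path)):
        rows = []
        with open(agp) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                rows.append(line.rstrip("\n").split("\t"))
    else:
        rows = [[str(x) for x in r] for r in agp]
    objects: dict[str, list[str]] = {}
    for r in rows:
        obj, comp_type = r[0], r[4]
        if comp_type in ("N", "U"):
            objects.setdefault(obj, []).append("N" * int(r[5]))
        else:
            comp, beg, end, orient = r[5], int(r[6]), int(r[7]), r[8]
            seg = scaffolds[comp][beg - 1 : end]
            if orient == "-":
                seg = reverse_complement(seg)
            objects.setdefault(obj, []).append(seg)
    return {obj: "".join(parts) for obj, parts in objects.items()}


# ---------------------------------------------------------------------------
# Y-chromosome pipeline
# ---------------------------------------------------------------------------

def filter_protein_hits(
    hits: pd.DataFrame, min_coverage: float = 0.60
) -> pd.DataFrame:
    """Drop protein hits covering less than 60% of the protein length.

    ``hits`` needs a ``coverage`` column with values in [0, 1]; the filter
    keeps coverage >= ``min_coverage`` (0.59 is dropped, 0.60 kept).
    """
    cov = hits["coverage"].to_numpy(dtype=float)
    if np.any((cov < 0) | (cov > 1)):
        raise ValueError("coverage must be within [0, 1]")
    return hits[cov >= min_coverage].reset_index(drop=True)


def _repeat_coverage(
    repeats: Sequence[tuple[int, int]], start: int, end: int
) -> float:
    """Fraction of [start, end) covered by (merged) repeat intervals."""
    if end <= start:
        return 0.0
    covered = 0
    last = start
    for rs, re in sorted(repeats):
        lo, hi = max(rs, last), min(re, end)
        if hi > lo:
            covered += hi - lo
            last = hi
        if rs >= end:
            break
    return covered / (end - start)


def cluster_hits_y(
    hits: Iterable[AlignmentHit],
    repeats: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    near: int = 1_000,
    far: int = 5_000,
    repeat_frac: float = 0.5,
) -> list[AlignmentHitChain]:
    """Repeat-aware hit merging for the Y-chromosome pipeline.

    Successive hits on the same (query, target) merge when the gap between
    them (previous end to next start) is under ``near``; a gap in
    [``near``, ``far``) merges only when strictly more than ``repeat_frac``
    of the gap interval is repeat sequence.  Without a repeat track, those
    intermediate merges are declined with a warning.
    """
    groups: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault((h.query, h.target), []).append(h)
    chains = []
    warned = False
    for (query, target), members in groups.items():
        members.sort(key=lambda h: h.tstart)
        cur = [members[0]]
        for h in members[1:]:
            gap = h.tstart - cur[-1].tend
            if gap < near:
                cur.append(h)
                continue
            if gap < far:
                if repeats is None or target not in repeats:
                    if not warned:
                        warnings.warn(
                            "no repeat track: declining 1-5 kb gap merges",
                            stacklevel=2,
                        )
                        warned = True
                elif _repeat_coverage(repeats[target], cur[-1].tend, h.tstart) > repeat_frac:
                    cur.append(h)
                    continue
            chains.append(cur)
            cur = [h]
        chains.append(cur)
    return sorted(
        (_chain_from_members(m) for m in chains),
        key=lambda c: (c.query, c.target, c.tstart),
    )


def order_on_reference_y(
    chains: Iterable[AlignmentHitChain],
    reference_order: Sequence[str] | Sequence[tuple[str, int]],
    ratio: float = 2.0,
) -> list[AnchorPlacement]:
    """Order scaffold placements by the contig order of a reference Y.

    Each query's best chain is chosen with the longest > 2× second rule;
    placements are then sorted by (reference contig rank, offset).  Queries
    whose best chain is ambiguous stay unplaced in the ordering.
    """
    if reference_order and isinstance(reference_order[0], (tuple, list)):
        order = {name: i for i, (name, _off) in enumerate(reference_order)}
    else:
        order = {name: i for i, name in enumerate(reference_order)}
    placements = place_all(chains, ratio)
    placed = [p for p in placements if p.status == "placed"]
    unknown = {p.target for p in placed} - set(order)
    if unknown:
        raise ValueError(f"placed on contig(s) absent from reference order: {sorted(unknown)}")
    placed.sort(key=lambda p: (order[p.target], p.position, p.query))
    others = [p for p in placements if p.status != "placed"]
    return placed + others


def build_y_pseudochromosome(
    ordered_placements: Sequence[AnchorPlacement],
    scaffolds: Mapping[str, str],
    object_name: str = "chrY",
    gap_n: int = 100,
):
    """Concatenate Y-ordered placements into a single pseudo-chromosome."""
    placed = [p for p in ordered_placements if p.status == "placed"]
    agp_rows: list = []
    seq = _build_object(object_name, placed, scaffolds, gap_n, agp_rows)
    unplaced = [p.query for p in ordered_placements if p.status != "placed"]
    return {object_name: seq}, agp_rows, unplaced


def write_placements_tsv(
    placements: Sequence[AnchorPlacement], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("query\ttarget\tposition\torientation\tstatus\n")
        for p in placements:
            fh.write(
                f"{p.query}\t{p.target or '.'}\t"
                f"{p.position if p.position is not None else '.'}\t"
                f"{p.orientation or '.'}\t{p.status}\n"
            )
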