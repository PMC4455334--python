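"""Candidate gene-copy gains and losses in the domestic cohort.

A gene's copy state in each sample is summarized by its *gene ratio*: the
median CNV ratio of the windows overlapping its span.  A gene is a
candidate deletion in domestic goats when it maps to a called CNV region
and its ratio is below 0.2 in every domestic sample while staying at or
above 0.5 in every wild sample; candidate duplications mirror the rule
(ratio at or above a high threshold in all domestic samples, below it in
all wild samples).  An external presence/absence table — e.g. tabulated
protein-search results against the counterpart assembly — can corroborate
deletion calls.

ΔΔCt copy-number estimation from qPCR Ct tables lives here too: ΔCt is the
target-minus-reference mean Ct per sample (normalized to a single-copy
gene), ΔΔCt subtracts a calibrator sample, and the relative copy number is
calibrator_copies × 2^(−ΔΔCt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import CnvRegion
from .depth import CnvRatioProfile

__all__ = [
    "GeneModel",
    "CandidateGeneCall",
    "QpcrEstimate",
    "read_gff3_genes",
    "read_bed_genes",
    "read_labels",
    "gene_ratio",
    "classify_candidates",
    "attach_external_presence",
    "estimate_copy_number_qpcr",
    "write_candidate_tsv",
]


@dataclass
class GeneModel:
    """A gene span (0-based half-open) on a reference sequence."""

    gene_id: str
    sequence: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id!r}: start must be < end")


@dataclass
class CandidateGeneCall:
    gene_id: str
    verdict: str  # "deleted_in_domestic" | "duplicated_in_domestic" | "none"
    gene_ratios: dict[str, float]
    evidence: dict[str, object] = field(
        default_factory=lambda: {"ratio_rule": False, "external_presence": None}
    )


@dataclass
class QpcrEstimate:
    sample: str
    gene: str
    mean_delta_ct: float
    relative_copy_number: float


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Gene features (type ``gene``) from a GFF3; coordinates to 0-based."""
    genes = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("Name") or f"{parts[0]}:{parts[3]}"
            if gid in seen:
                raise ValueError(f"duplicate gene_id {gid!r}")
            seen.add(gid)
            genes.append(
                GeneModel(
                    gene_id=gid,
                    sequence=parts[0],
                    start=int(parts[3]) - 1,
                    end=int(parts[4]),
                    strand=parts[6],
                )
            )
    return genes


def read_bed_genes(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            genes.append(
                GeneModel(
                    gene_id=parts[3].strip() if len(parts) > 3 else f"{parts[0]}:{parts[1]}",
                    sequence=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    strand=parts[5].strip() if len(parts) > 5 else "+",
                )
            )
    return genes


def read_labels(path: str | Path) -> dict[str, str]:
    """Cohort labels: ``sample<TAB>wild|domestic``."""
    labels = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sample, label = line.split()[:2]
            if label not in ("wild", "domestic"):
                raise ValueError(f"unknown cohort label {label!r} for {sample!r}")
            labels[sample] = label
    return labels


def gene_ratio(
    gene: GeneModel, profile: CnvRatioProfile, statistic: str = "median"
) -> float:
    """Aggregate CNV ratio of the windows overlapping a gene span.

    Median by default (robust to breakpoint windows), mean optionally.  A
    gene shorter than one window uses its single covering window, with a
    warning.
    """
    if gene.sequence not in profile.ratios:
        raise ValueError(f"gene {gene.gene_id!r} on missing sequence {gene.sequence!r}")
    arr = profile.ratios[gene.sequence]
    w, step = profile.window_size, profile.step
    lo = max(0, (gene.start - w) // step + 1)
    hi = min(len(arr) - 1, (gene.end - 1) // step)
    if hi < lo:
        raise ValueError(
            f"gene {gene.gene_id!r} overlaps no window "
            f"(span [{gene.start}, {gene.end}) beyond windowed portion)"
        )
    if gene.end - gene.start < w:
        warnings.warn(
            f"gene {gene.gene_id!r} shorter than one window; "
            "using its covering window(s)",
            stacklevel=2,
        )
    vals = arr[lo : hi + 1]
    if statistic == "median":
        return float(np.median(vals))
    if statistic == "mean":
        return float(np.mean(vals))
    raise ValueError(f"unknown statistic {statistic!r}")


def _overlaps_any(gene: GeneModel, regions: Sequence[CnvRegion]) -> bool:
    return any(
        r.sequence == gene.sequence and r.start < gene.end and gene.start < r.end
        for r in regions
    )


def classify_candidates(
    genes: Sequence[GeneModel],
    profiles: Mapping[str, CnvRatioProfile],
    cohort_labels: Mapping[str, str],
    del_low: float = 0.2,
    del_wild_min: float = 0.5,
    dup_high: float = 1.5,
    dup_wild_max: float = 1.5,
    require_cnv_overlap: bool = True,
    regions: Sequence[CnvRegion] | None = None,
    statistic: str = "median",
) -> list[CandidateGeneCall]:
    """Classify candidate deleted/duplicated genes in the domestic cohort.

    deleted_in_domestic: gene overlaps a called CNV region (when
    ``require_cnv_overlap``), gene ratio < ``del_low`` in ALL domestic
    samples and >= ``del_wild_min`` in ALL wild samples.

    duplicated_in_domestic: gene ratio >= ``dup_high`` in ALL domestic
    samples and < ``dup_wild_max`` in ALL wild samples.  The numeric
    duplication thresholds are this package's mirror of the published
    deletion rule ("single copy in one species, multi-copies in the
    other") and are fully configurable.
    """
    wild = [s for s, l in cohort_labels.items() if l == "wild"]
    domestic = [s for s, l in cohort_labels.items() if l == "domestic"]
    if not wild or not domestic:
        raise ValueError("both cohorts need at least one sample")
    missing = set(wild + domestic) - set(profiles)
    if missing:
        raise ValueError(f"no ratio profile for sample(s) {sorted(missing)}")
    if require_cnv_overlap and regions is None:
        raise ValueError("require_cnv_overlap=True needs the called regions")

    calls = []
    for gene in genes:
        ratios = {s: gene_ratio(gene, profiles[s], statistic) for s in wild + domestic}
        dom = [ratios[s] for s in domestic]
        wld = [ratios[s] for s in wild]
        verdict = "none"
        if (
            all(r < del_low for r in dom)
            and all(r >= del_wild_min for r in wld)
            and (not require_cnv_overlap or _overlaps_any(gene, regions))
        ):
            verdict = "deleted_in_domestic"
        elif all(r >= dup_high for r in dom) and all(r < dup_wild_max for r in wld):
            verdict = "duplicated_in_domestic"
        calls.append(
            CandidateGeneCall(
                gene_id=gene.gene_id,
                verdict=verdict,
                gene_ratios=ratios,
                evidence={"ratio_rule": verdict != "none", "external_presence": None},
            )
        )
    return calls


def attach_external_presence(
    calls: Sequence[CandidateGeneCall],
    evidence: Mapping[str, str],
    require_external: bool = False,
) -> list[CandidateGeneCall]:
    """Attach a present/absent-in-counterpart-assembly evidence table.

    Verdicts are unchanged unless ``require_external`` is set, in which
    case deletion verdicts lacking an "absent" entry are downgraded to
    none.  Table entries for unknown genes are skipped with a warning.
    """
    by_id = {c.gene_id: c for c in calls}
    unknown = set(evidence) - set(by_id)
    for gid in sorted(unknown):
        warnings.warn(f"evidence for unknown gene {gid!r} skipped", stacklevel=2)
    out = []
    for c in calls:
        status = evidence.get(c.gene_id)
        if status is not None and status not in ("present", "absent"):
            raise ValueError(f"evidence for {c.gene_id!r} must be present/absent")
        verdict = c.verdict
        if (
            require_external
            and verdict == "deleted_in_domestic"
            and status != "absent"
        ):
            verdict = "none"
        out.append(
            CandidateGeneCall(
                gene_id=c.gene_id,
                verdict=verdict,
                gene_ratios=dict(c.gene_ratios),
                evidence={**c.evidence, "external_presence": status},
            )
        )
    return out


def estimate_copy_number_qpcr(
    ct_table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
    calibrator_copies: float = 2.0,
) -> list[QpcrEstimate]:
    """ΔΔCt relative copy number from a Ct table.

    ΔCt_s = mean Ct(target, s) − mean Ct(reference gene, s);
    ΔΔCt_s = ΔCt_s − ΔCt_calibrator;
    relative copy number = calibrator_copies × 2^(−ΔΔCt).

    The calibrator is assumed to carry ``calibrator_copies`` copies of each
    target (2 = diploid single-copy locus).  Errors if the normalization
    gene is missing for any sample.
    """
    required = {"sample", "gene", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    means = ct_table.groupby(["sample", "gene"])["ct"].mean()
    samples = ct_table["sample"].unique()
    for s in samples:
        if (s, reference_gene) not in means.index:
            raise ValueError(f"reference gene {reference_gene!r} missing for {s!r}")
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")

    targets = [g for g in ct_table["gene"].unique() if g != reference_gene]
    delta_ct = {
        (s, g): means[(s, g)] - means[(s, reference_gene)]
        for s in samples
        for g in targets
        if (s, g) in means.index
    }
    estimates = []
    for g in targets:
        cal_key = (calibrator_sample, g)
        if cal_key not in delta_ct:
            raise ValueError(f"calibrator has no Ct for gene {g!r}")
        for s in samples:
            if (s, g) not in delta_ct:
                continue
            ddct = delta_ct[(s, g)] - delta_ct[cal_key]
            estimates.append(
                QpcrEstimate(
                    sample=s,
                    gene=g,
                    mean_delta_ct=float(delta_ct[(s, g)]),
                    relative_copy_number=float(calibrator_copies * 2.0 ** (-ddct)),
                )
            )
    return estimates


def write_candidate_tsv(
    calls: Sequence[CandidateGeneCall], path: str | Path
) -> None:
    samples = sorted({s for c in calls for s in c.gene_ratios})
    with open(path, "w") as fh:
        header = ["gene_id", "verdict", "external_presence"] + [
            f"ratio_{s}" for s in samples
        ]
        fh.write("\t".join(header) + "\n")
        for c in calls:
            row = [c.gene_id, c.verdict, str(c.evidence.get("external_presence"))]
            row += [f"{c.gene_ratios.get(s, float('nan')):.4g}" for s in samples]
            fh.write("\t".join(row) + "\n")
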