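"""Pedigree rare-allele retention scan over a diversity panel.

Given a diversity panel, a focal high-protein cultivar, its low-protein
recurrent parent and a set of descendant cultivars bred with continued
selection for the trait, the scan proceeds in four steps:

1. ``rare_allele_scan`` — SNPs where the focal line is homozygous for an
   allele that is rare in the panel (frequency <= ``max_panel_frequency``).
2. ``contrast_filter``  — keep SNPs whose focal allele is absent from the
   recurrent parent (and optionally from additional low-protein lines).
3. ``retention_filter`` — keep SNPs whose focal allele survives in at least
   ``min_ratio`` of the informative descendants (retention ratio
   ρ = carriers / informative; a carrier is homozygous for the focal
   allele).
4. ``build_blocks``     — assemble surviving SNPs into physical genomic
   blocks (single-linkage along each chromosome with a bp gap threshold),
   then ``annotate_blocks`` against anchor-marker and known-region tables.

Coordinates are 1-based inclusive base pairs throughout; BED export
converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import PanelGenotypes

__all__ = [
    "RetentionBlock",
    "rare_allele_scan",
    "contrast_filter",
    "retention_filter",
    "build_blocks",
    "annotate_blocks",
    "RetentionScanner",
]


@dataclass
class RetentionBlock:
    """A physical interval of retained rare-allele SNPs."""

    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    snp_ids: list[str]
    mean_ratio: float
    anchors: list[str] = field(default_factory=list)
    annotations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("block start after end")

    @property
    def novel(self) -> bool:
        return not self.anchors and not self.annotations

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _focal_allele_frequency(
    panel: PanelGenotypes, focal: str, exclude_lines: tuple[str, ...] = ()
) -> tuple[np.ndarray, np.ndarray]:
    """Panel frequency of the focal line's homozygous allele per SNP.

    Returns (frequency, focal_is_alt).  SNPs where the focal call is
    heterozygous or missing get frequency NaN.  ``exclude_lines`` are left
    out of the frequency denominator (the focal line itself always counts).
    """
    fc = panel.line_calls(focal)
    drop = set(exclude_lines) - {focal}
    rows = np.array([i for i, ln in enumerate(panel.lines) if ln not in drop])
    calls = panel.calls[rows]
    called = calls != -1
    alt = np.where(called, calls, 0).sum(axis=0, dtype=float)
    n_alleles = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_f = alt / n_alleles
    freq = np.where(fc == 2, alt_f, np.where(fc == 0, 1.0 - alt_f, np.nan))
    return freq, fc == 2


def rare_allele_scan(
    panel: PanelGenotypes,
    focal: str,
    max_panel_frequency: float = 0.02,
    exclude_lines: tuple[str, ...] = (),
) -> pd.DataFrame:
    """SNPs where the focal line's homozygous allele is rare in the panel.

    Frequencies are computed over non-missing allele calls with
    heterozygotes counted as half; heterozygous or missing focal calls are
    skipped (only homozygous focal loci are considered).  ``exclude_lines``
    (typically the focal line's own descendants) do not count toward the
    panel frequency — retention within the family is the signal under test,
    not evidence that the allele is common in the background germplasm.
    """
    if focal not in panel.lines:
        raise ValueError(f"focal line {focal!r} not in panel")
    if max_panel_frequency < 0:
        raise ValueError("max_panel_frequency must be non-negative")
    freq, is_alt = _focal_allele_frequency(panel, focal, tuple(exclude_lines))
    keep = ~np.isnan(freq) & (freq <= max_panel_frequency) & (freq > 0)
    out = panel.snps.loc[keep, ["snp", "chrom", "bp"]].copy()
    out["focal_allele"] = np.where(
        is_alt[keep], panel.snps.loc[keep, "alt"], panel.snps.loc[keep, "ref"]
    )
    out["focal_is_alt"] = is_alt[keep]
    out["panel_frequency"] = freq[keep]
    return out.reset_index(drop=True)


def _carries(call: int, focal_is_alt: bool) -> str:
    if call == -1:
        return "missing"
    if call == 1:
        return "het"
    if (call == 2) == focal_is_alt:
        return "carrier"
    return "non-carrier"


def contrast_filter(
    candidates: pd.DataFrame,
    panel: PanelGenotypes,
    recurrent_parent: str,
    low_lines: list[str] | None = None,
    low_lines_as_filter: bool = True,
) -> pd.DataFrame:
    """Keep candidate SNPs whose focal allele contrasts with the recurrent
    parent (recurrent parent homozygous for the other allele).

    ``low_lines`` are additional low-protein comparators; with
    ``low_lines_as_filter`` they must all lack the focal allele, otherwise
    their carrier status is only annotated.  A missing comparator genotype
    is non-informative: the SNP is kept and flagged.
    """
    low_lines = low_lines or []
    for name in [recurrent_parent, *low_lines]:
        if name not in panel.lines:
            raise ValueError(f"comparator line {name!r} not in panel")
    if candidates.empty:
        out = candidates.copy()
        out["comparator_missing"] = pd.Series(dtype=bool)
        return out

    snp_pos = {s: j for j, s in enumerate(panel.snps["snp"])}
    cols = np.array([snp_pos[s] for s in candidates["snp"]])
    is_alt = candidates["focal_is_alt"].to_numpy()

    def status(line: str) -> np.ndarray:
        calls = panel.line_calls(line)[cols]
        return np.array([_carries(c, a) for c, a in zip(calls, is_alt)])

    rp = status(recurrent_parent)
    keep = rp == "non-carrier"
    flagged = rp == "missing"
    keep |= flagged  # missing comparator: keep with flag
    low_status = {ln: status(ln) for ln in low_lines}
    if low_lines_as_filter:
        for ln, st in low_status.items():
            lacks = (st == "non-carrier") | (st == "missing")
            flagged |= keep & (st == "missing")
            keep &= lacks
    out = candidates.loc[keep].copy()
    out["comparator_missing"] = flagged[keep]
    for ln, st in low_status.items():
        out[f"status_{ln}"] = st[keep]
    return out.reset_index(drop=True)


def retention_filter(
    filtered: pd.DataFrame,
    panel: PanelGenotypes,
    derivatives: list[str],
    min_ratio: float = 0.66,
    min_informative: int = 4,
    hets_as_carriers: bool = False,
) -> pd.DataFrame:
    """Retention records: SNPs whose focal allele survives the derivatives.

    ρ = carriers / informative derivatives, where a carrier is homozygous
    for the focal allele (``hets_as_carriers`` relaxes this) and informative
    excludes missing and — unless hets count — heterozygous calls.  Keeps
    SNPs with ρ >= min_ratio and informative count >= min_informative.
    """
    if not (0.0 < min_ratio <= 1.0):
        raise ValueError("min_ratio must lie in (0, 1]")
    for d in derivatives:
        if d not in panel.lines:
            raise ValueError(f"derivative {d!r} not in panel")
    if filtered.empty:
        out = filtered.copy()
        out["retention_ratio"] = pd.Series(dtype=float)
        out["n_carriers"] = pd.Series(dtype=int)
        out["n_informative"] = pd.Series(dtype=int)
        return out

    snp_pos = {s: j for j, s in enumerate(panel.snps["snp"])}
    cols = np.array([snp_pos[s] for s in filtered["snp"]])
    is_alt = filtered["focal_is_alt"].to_numpy()
    carriers = np.zeros(len(filtered))
    informative = np.zeros(len(filtered))
    status_cols = {}
    for d in derivatives:
        calls = panel.line_calls(d)[cols]
        st = np.array([_carries(c, a) for c, a in zip(calls, is_alt)])
        status_cols[d] = st
        if hets_as_carriers:
            carriers += (st == "carrier") | (st == "het")
            informative += st != "missing"
        else:
            carriers += st == "carrier"
            informative += (st == "carrier") | (st == "non-carrier")

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(informative > 0, carriers / informative, np.nan)
    keep = (informative >= min_informative) & ~np.isnan(ratio) & (ratio >= min_ratio)
    out = filtered.loc[keep].copy()
    out["retention_ratio"] = ratio[keep]
    out["n_carriers"] = carriers[keep].astype(int)
    out["n_informative"] = informative[keep].astype(int)
    for d in derivatives:
        out[f"carrier_{d}"] = status_cols[d][keep]
    return out.reset_index(drop=True)


def build_blocks(
    records: pd.DataFrame,
    max_gap_bp: int = 500_000,
    min_snps: int = 2,
) -> tuple[list[RetentionBlock], list[RetentionBlock]]:
    """Single-linkage clustering of retained SNPs into physical blocks.

    Consecutive SNPs on a chromosome at most ``max_gap_bp`` apart join one
    block; clusters with fewer than ``min_snps`` members are returned
    separately as singletons.  Returns ``(blocks, singletons)``.
    """
    blocks: list[RetentionBlock] = []
    singles: list[RetentionBlock] = []
    if records.empty:
        return blocks, singles
    for chrom, grp in records.groupby("chrom", sort=False):
        grp = grp.sort_values("bp", kind="mergesort")
        bp = grp["bp"].to_numpy()
        breaks = np.flatnonzero(np.diff(bp) > max_gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(bp)]])
        for s, e in zip(starts, ends):
            cluster = grp.iloc[s:e]
            block = RetentionBlock(
                chrom=str(chrom),
                start_bp=int(cluster["bp"].min()),
                end_bp=int(cluster["bp"].max()),
                snp_ids=list(cluster["snp"]),
                mean_ratio=float(cluster["retention_ratio"].mean()),
            )
            (blocks if len(cluster) >= min_snps else singles).append(block)
    return blocks, singles


def annotate_blocks(
    blocks: list[RetentionBlock],
    anchors: pd.DataFrame | None = None,
    known_regions: pd.DataFrame | None = None,
    link_distance_bp: int = 1_000_000,
) -> list[RetentionBlock]:
    """Attach anchor markers and known regions to each block.

    Both tables carry columns ``name``, ``chrom``, ``bp`` (and optionally
    ``type``); an entry is linked when its position lies inside the block or
    within ``link_distance_bp`` of its edge.  Blocks with no link are novel.
    """
    def within(table: pd.DataFrame, block: RetentionBlock) -> list[str]:
        if table is None or table.empty:
            return []
        m = (
            (table["chrom"] == block.chrom)
            & (table["bp"] >= block.start_bp - link_distance_bp)
            & (table["bp"] <= block.end_bp + link_distance_bp)
        )
        return list(table.loc[m, "name"])

    out = []
    for b in blocks:
        out.append(
            RetentionBlock(
                chrom=b.chrom,
                start_bp=b.start_bp,
                end_bp=b.end_bp,
                snp_ids=list(b.snp_ids),
                mean_ratio=b.mean_ratio,
                anchors=within(anchors, b),
                annotations=within(known_regions, b),
            )
        )
    return out


def blocks_to_frame(blocks: list[RetentionBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "start_bp": b.start_bp,
                "end_bp": b.end_bp,
                "span_bp": b.span_bp,
                "n_snps": len(b.snp_ids),
                "mean_ratio": b.mean_ratio,
                "anchors": ";".join(b.anchors),
                "annotations": ";".join(b.annotations),
                "novel": b.novel,
            }
            for b in blocks
        ],
        columns=[
            "chrom", "start_bp", "end_bp", "span_bp", "n_snps",
            "mean_ratio", "anchors", "annotations", "novel",
        ],
    )


def blocks_to_bed(blocks: list[RetentionBlock]) -> pd.DataFrame:
    """BED representation (0-based half-open) of the blocks."""
    return pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "start": b.start_bp - 1,
                "end": b.end_bp,
                "name": f"{b.chrom}:{b.start_bp}-{b.end_bp}",
                "score": int(round(1000 * b.mean_ratio)),
            }
            for b in blocks
        ],
        columns=["chrom", "start", "end", "name", "score"],
    )


class RetentionScanner(BaseEstimator):
    """End-to-end rare-allele retention scan as one estimator.

    ``fit(panel)`` runs the rare-allele screen, the recurrent-parent/low-line
    contrast, the derivative retention filter and block building; fitted
    attributes are ``candidates_``, ``contrasted_``, ``records_``,
    ``blocks_`` and ``singletons_``.
    """

    def __init__(
        self,
        focal: str = "focal",
        recurrent_parent: str = "recurrent",
        derivatives: tuple[str, ...] = (),
        low_lines: tuple[str, ...] = (),
        max_panel_frequency: float = 0.02,
        min_ratio: float = 0.66,
        min_informative: int = 4,
        max_gap_bp: int = 500_000,
        min_snps: int = 2,
        hets_as_carriers: bool = False,
        low_lines_as_filter: bool = True,
        link_distance_bp: int = 1_000_000,
    ):
        self.focal = focal
        self.recurrent_parent = recurrent_parent
        self.derivatives = derivatives
        self.low_lines = low_lines
        self.max_panel_frequency = max_panel_frequency
        self.min_ratio = min_ratio
        self.min_informative = min_informative
        self.max_gap_bp = max_gap_bp
        self.min_snps = min_snps
        self.hets_as_carriers = hets_as_carriers
        self.low_lines_as_filter = low_lines_as_filter
        self.link_distance_bp = link_distance_bp

    def fit(
        self,
        panel: PanelGenotypes,
        anchors: pd.DataFrame | None = None,
        known_regions: pd.DataFrame | None = None,
    ) -> "RetentionScanner":
        self.candidates_ = rare_allele_scan(
            panel, self.focal, self.max_panel_frequency,
            exclude_lines=tuple(self.derivatives),
        )
        self.contrasted_ = contrast_filter(
            self.candidates_, panel, self.recurrent_parent,
            low_lines=list(self.low_lines),
            low_lines_as_filter=self.low_lines_as_filter,
        )
        self.records_ = retention_filter(
            self.contrasted_, panel, list(self.derivatives),
            min_ratio=self.min_ratio, min_informative=self.min_informative,
            hets_as_carriers=self.hets_as_carriers,
        )
        blocks, singles = build_blocks(
            self.records_, max_gap_bp=self.max_gap_bp, min_snps=self.min_snps
        )
        self.blocks_ = annotate_blocks(
            blocks, anchors, known_regions, self.link_distance_bp
        )
        self.singletons_ = annotate_blocks(
            singles, anchors, known_regions, self.link_distance_bp
        )
        return self
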