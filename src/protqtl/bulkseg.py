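"""Bulked-segregant analysis (BSA) across RIL populations.

Lines from the phenotypic extremes of each population form a high and a low
bulk; per marker, the frequency of the high-parent allele is estimated in
each bulk (lines pooled in silico: homozygotes contribute a full allele
count, heterozygotes half).  Markers are classified per population as

* ``positive``       — allele-frequency contrast Δf = f_high - f_low at
  least ``delta_threshold`` and a two-proportion exact test p <= alpha;
* ``fixed_high``     — both bulks essentially fixed for the high-parent
  allele (consistent with a locus already selected to fixation);
* ``fixed_low``      — the mirror case;
* ``uninformative``  — anything else.

Positive calls are merged across populations into loci; a locus's support
counts positives plus fixations for the high allele, reflecting that
fixation is consistent with the locus mattering for the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.base import BaseEstimator

from .containers import PhenotypeRecords, RILGenotypes
from .genmap import GeneticMap

__all__ = [
    "BulkPair",
    "make_bulks",
    "classify_markers",
    "cross_population_summary",
    "BulkSegregantAnalyzer",
]

CLASSES = ("positive", "fixed_high", "fixed_low", "uninformative")


@dataclass
class BulkPair:
    """High/low phenotype bulks of one population."""

    population: str
    high_bulk: list[str]
    low_bulk: list[str]
    high_mean: float
    low_mean: float

    def __post_init__(self) -> None:
        if set(self.high_bulk) & set(self.low_bulk):
            raise ValueError("bulks overlap")
        if not self.high_mean > self.low_mean:
            raise ValueError("high bulk mean must exceed low bulk mean")


def make_bulks(
    phenotypes: PhenotypeRecords,
    tail_fraction: float = 0.1,
    min_bulk: int = 8,
    population: str = "pop",
    trait: str = "protein",
) -> BulkPair:
    """Rank line means and take the top/bottom ``tail_fraction`` as bulks.

    Boundary ties are broken by line-name order (deterministic).
    """
    if not (0.0 < tail_fraction <= 0.5):
        raise ValueError("tail_fraction must lie in (0, 0.5]")
    means = phenotypes.line_means(trait)
    n_tail = int(len(means) * tail_fraction)
    if n_tail < min_bulk:
        raise ValueError(
            f"tail of {n_tail} lines is smaller than min_bulk={min_bulk}"
        )
    order = means.reset_index().sort_values(
        [trait, "line"], ascending=[False, True], kind="mergesort"
    )
    high = list(order["line"].iloc[:n_tail])
    low_order = means.reset_index().sort_values(
        [trait, "line"], ascending=[True, True], kind="mergesort"
    )
    low = list(low_order["line"].iloc[:n_tail])
    return BulkPair(
        population=population,
        high_bulk=high,
        low_bulk=low,
        high_mean=float(means.loc[high].mean()),
        low_mean=float(means.loc[low].mean()),
    )


def _bulk_allele_freq(
    genotypes: RILGenotypes, bulk: list[str], high_code: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker frequency of the high-parent allele in a bulk and the
    number of informative lines behind it (hets count 0.5 to each allele)."""
    index = {line: i for i, line in enumerate(genotypes.lines)}
    missing = [b for b in bulk if b not in index]
    if missing:
        raise ValueError(f"bulk lines absent from genotypes: {missing[:5]}")
    codes = genotypes.codes[[index[b] for b in bulk]]
    called = codes != -1
    n_inf = called.sum(axis=0).astype(float)
    high = (codes == high_code).sum(axis=0) + 0.5 * (codes == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_inf > 0, high / n_inf, np.nan)
    return f, n_inf


def classify_markers(
    bulks: BulkPair,
    genotypes: RILGenotypes,
    delta_threshold: float = 0.4,
    alpha: float = 0.05,
    fixed_threshold: float = 0.95,
    high_parent: str = "B",
) -> pd.DataFrame:
    """Classify every marker for one population's bulk pair.

    Returns a frame with one row per marker: frequencies, Δf, the exact-test
    p-value and the class.  Markers monomorphic across the whole population
    are flagged ``segregating = False`` and classified uninformative.
    """
    if high_parent not in ("A", "B"):
        raise ValueError("high_parent must be 'A' or 'B'")
    high_code = 2 if high_parent == "B" else 0
    f_high, n_high = _bulk_allele_freq(genotypes, bulks.high_bulk, high_code)
    f_low, n_low = _bulk_allele_freq(genotypes, bulks.low_bulk, high_code)

    called = genotypes.codes != -1
    first = np.where(called.any(axis=0), genotypes.codes[called.argmax(axis=0),
                                                         np.arange(genotypes.codes.shape[1])], -1)
    segregating = np.array([
        bool(np.any((genotypes.codes[:, j] != -1) & (genotypes.codes[:, j] != first[j])))
        for j in range(genotypes.codes.shape[1])
    ])

    delta = f_high - f_low
    n_markers = genotypes.codes.shape[1]
    pvals = np.ones(n_markers)
    calls = np.full(n_markers, "uninformative", dtype=object)
    for j in range(n_markers):
        if np.isnan(f_high[j]) or np.isnan(f_low[j]):
            continue
        # allele counts on the 2N scale for the exact test
        table = np.array(
            [
                [round(2 * f_high[j] * n_high[j]), round(2 * (1 - f_high[j]) * n_high[j])],
                [round(2 * f_low[j] * n_low[j]), round(2 * (1 - f_low[j]) * n_low[j])],
            ]
        )
        pvals[j] = fisher_exact(table, alternative="two-sided")[1]
        if delta[j] >= delta_threshold - 1e-9 and pvals[j] <= alpha:
            calls[j] = "positive"
        elif f_high[j] >= fixed_threshold and f_low[j] >= fixed_threshold:
            calls[j] = "fixed_high"
        elif f_high[j] <= 1 - fixed_threshold and f_low[j] <= 1 - fixed_threshold:
            calls[j] = "fixed_low"

    out = genotypes.gmap.table[["marker", "chrom", "cm"]].copy()
    out["population"] = bulks.population
    out["f_high"] = f_high
    out["f_low"] = f_low
    out["n_high"] = n_high
    out["n_low"] = n_low
    out["delta_f"] = delta
    out["p_value"] = pvals
    out["segregating"] = segregating
    out["call"] = calls
    return out


def cross_population_summary(
    calls: dict[str, pd.DataFrame],
    gmap: GeneticMap,
    merge_window_cm: float = 10.0,
    exclude_from_discovery: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Merge positive calls across populations into loci.

    Positive calls from discovery populations within ``merge_window_cm`` of
    each other (single-linkage along each chromosome) form one locus.
    Populations in ``exclude_from_discovery`` (e.g. a high x high cross) do
    not seed loci but their allele status at each locus is reported.  The
    support count per locus is the number of populations that are positive
    or fixed for the high allele there.
    """
    if not calls:
        raise ValueError("need at least one population")
    discovery = [p for p in calls if p not in exclude_from_discovery]
    pos_rows = []
    for pop in discovery:
        df = calls[pop]
        pos_rows.append(df[df["call"] == "positive"][["marker", "chrom", "cm", "delta_f"]])
    positives = (
        pd.concat(pos_rows, ignore_index=True)
        if pos_rows
        else pd.DataFrame(columns=["marker", "chrom", "cm", "delta_f"])
    )
    records = []
    if len(positives):
        for chrom, grp in positives.groupby("chrom", sort=False):
            grp = grp.sort_values("cm", kind="mergesort")
            cm = grp["cm"].to_numpy(dtype=float)
            breaks = np.flatnonzero(np.diff(cm) > merge_window_cm)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks + 1, [len(cm)]])
            for s, e in zip(starts, ends):
                cluster = grp.iloc[s:e]
                rep = cluster.loc[cluster["delta_f"].abs().idxmax()]
                records.append(
                    {
                        "chrom": chrom,
                        "cm_start": float(cluster["cm"].min()),
                        "cm_end": float(cluster["cm"].max()),
                        "representative_marker": rep["marker"],
                        "cm": float(rep["cm"]),
                    }
                )
    loci = pd.DataFrame(
        records, columns=["chrom", "cm_start", "cm_end", "representative_marker", "cm"]
    )

    pops = list(calls)
    statuses = {pop: [] for pop in pops}
    support = []
    for _, locus in loci.iterrows():
        n_support = 0
        for pop in pops:
            df = calls[pop]
            inside = df[
                (df["chrom"] == locus["chrom"])
                & (df["cm"] >= locus["cm_start"] - merge_window_cm)
                & (df["cm"] <= locus["cm_end"] + merge_window_cm)
            ]
            if (inside["call"] == "positive").any():
                status = "positive"
            elif (inside["call"] == "fixed_high").any():
                status = "fixed_high"
            elif len(inside) and not inside["segregating"].any():
                status = "not_segregating"
            else:
                status = "negative"
            statuses[pop].append(status)
            if status in ("positive", "fixed_high"):
                n_support += 1
        support.append(n_support)
    for pop in pops:
        loci[f"status_{pop}"] = statuses[pop]
    loci["support"] = support
    loci["n_populations"] = len(pops)
    return loci


class BulkSegregantAnalyzer(BaseEstimator):
    """Bulk construction plus marker classification for one population.

    ``fit(genotypes, phenotypes)`` builds the bulks from the phenotype tails
    and classifies every marker; fitted attributes are ``bulks_`` and
    ``calls_``.
    """

    def __init__(
        self,
        tail_fraction: float = 0.1,
        min_bulk: int = 8,
        delta_threshold: float = 0.4,
        alpha: float = 0.05,
        fixed_threshold: float = 0.95,
        high_parent: str = "B",
        population: str = "pop",
    ):
        self.tail_fraction = tail_fraction
        self.min_bulk = min_bulk
        self.delta_threshold = delta_threshold
        self.alpha = alpha
        self.fixed_threshold = fixed_threshold
        self.high_parent = high_parent
        self.population = population

    def fit(self, genotypes: RILGenotypes, phenotypes: PhenotypeRecords):
        self.bulks_ = make_bulks(
            phenotypes, tail_fraction=self.tail_fraction,
            min_bulk=self.min_bulk, population=self.population,
        )
        self.calls_ = classify_markers(
            self.bulks_, genotypes,
            delta_threshold=self.delta_threshold, alpha=self.alpha,
            fixed_threshold=self.fixed_threshold, high_parent=self.high_parent,
        )
        return self
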