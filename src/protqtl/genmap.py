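"""Genetic maps: ordered markers with cM positions, optional physical anchors.

A :class:`GeneticMap` is a thin, validated wrapper around a pandas DataFrame
with one row per marker (columns ``marker``, ``chrom``, ``cm`` and optionally
``bp`` and ``marker_class``).  Marker classes follow the common soybean
platforms: microsatellites (SSR), array presence/absence markers (DArT) and
sequencing-detected SNP-type markers (DArTseq), plus plain SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MARKER_CLASSES = ("SSR", "DArT", "DArTseq", "SNP")


@dataclass
class GeneticMap:
    """Ordered genome-wide marker map on the centimorgan scale.

    Parameters
    ----------
    table:
        DataFrame with columns ``marker`` (unique names), ``chrom``, ``cm``
        (non-negative, non-decreasing within a chromosome) and optionally
        ``bp`` (physical anchor) and ``marker_class``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chrom", "cm"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker name: {dup!r}")
        if len(t) == 0:
            raise ValueError("map has no markers")
        if (t["cm"] < 0).any():
            bad = t.loc[t["cm"] < 0, "marker"].iloc[0]
            raise ValueError(f"negative cM position at marker {bad!r}")
        if "marker_class" in t.columns:
            bad = set(t["marker_class"].dropna()) - set(MARKER_CLASSES)
            if bad:
                raise ValueError(f"unknown marker class(es): {sorted(bad)}")
        codes = pd.factorize(t["chrom"])[0]
        if np.any(np.diff(codes) < 0):
            raise ValueError("markers of one chromosome must be contiguous in the table")
        for chrom, grp in t.groupby("chrom", sort=False):
            cm = grp["cm"].to_numpy()
            if np.any(np.diff(cm) < 0):
                i = int(np.argmax(np.diff(cm) < 0)) + 1
                raise ValueError(
                    f"cM positions decrease on {chrom} at marker "
                    f"{grp['marker'].iloc[i]!r}"
                )
        self.table = t.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_names(self) -> list[str]:
        return list(self.table["marker"])

    def chrom_table(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def positions(self, chrom) -> np.ndarray:
        return self.chrom_table(chrom)["cm"].to_numpy(dtype=float)

    def chrom_length(self, chrom) -> float:
        pos = self.positions(chrom)
        return float(pos[-1] - pos[0])

    def total_length(self) -> float:
        return float(sum(self.chrom_length(c) for c in self.chromosomes))

    def marker_index(self) -> dict:
        """marker name -> integer column index into genotype matrices."""
        return {m: i for i, m in enumerate(self.table["marker"])}

    def nearest_marker(self, chrom, cm: float) -> str:
        grp = self.chrom_table(chrom)
        if grp.empty:
            raise ValueError(f"no markers on chromosome {chrom!r}")
        i = (grp["cm"] - cm).abs().to_numpy().argmin()
        return grp["marker"].iloc[int(i)]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneticMap):
            return NotImplemented
        return self.table.equals(other.table)


def haldane_r(d_cm) -> np.ndarray | float:
    """Recombination fraction for a map distance (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_recombination(r) -> np.ndarray | float:
    """Per-meiosis recombination fraction r mapped to the selfed-RIL
    recombination fraction R = 2r / (1 + 2r) (Haldane & Waddington)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


# ---------------------------------------------------------------------------
# Map factories

# Per-chromosome (marker count, mean inter-marker spacing in cM) for a
# 20-chromosome soybean SSR/DArT/DArTseq consensus-style map skeleton of the
# density typical for an F5-derived RIL mapping population (~630 markers,
# ~3300 cM with DArT-era map inflation).
_SOY_SKELETON = {
    "Gm01": (28, 7.0), "Gm02": (32, 6.3), "Gm03": (23, 3.7), "Gm04": (24, 6.8),
    "Gm05": (20, 7.0), "Gm06": (23, 10.2), "Gm07": (39, 4.8), "Gm08": (21, 9.1),
    "Gm09": (49, 4.6), "Gm10": (24, 7.5), "Gm11": (26, 6.3), "Gm12": (26, 5.7),
    "Gm13": (41, 5.1), "Gm14": (23, 5.6), "Gm15": (48, 3.2), "Gm16": (48, 2.9),
    "Gm17": (24, 7.9), "Gm18": (39, 4.7), "Gm19": (37, 6.2), "Gm20": (35, 3.6),
}


def soybean_skeleton_map(bp_per_cm: float = 400_000.0) -> GeneticMap:
    """Evenly spaced 20-chromosome soybean map skeleton.

    Marker counts and mean spacings per chromosome mimic a published-scale
    SSR/DArT/DArTseq soybean RIL map; markers are laid out at the mean
    spacing with physical anchors at ``bp_per_cm`` bases per centimorgan.
    """
    rows = []
    for chrom, (n, avg) in _SOY_SKELETON.items():
        cm = np.arange(n) * avg
        for i, pos in enumerate(cm):
            rows.append(
                {
                    "marker": f"{chrom}_M{i + 1:03d}",
                    "chrom": chrom,
                    "cm": float(pos),
                    "bp": int(round(pos * bp_per_cm)) + 1,
                    "marker_class": "SSR" if i % 3 == 0 else ("DArT" if i % 3 == 1 else "DArTseq"),
                }
            )
    return GeneticMap(pd.DataFrame(rows))


def uniform_map(
    n_chrom: int = 20,
    n_markers: int = 13,
    length_cm: float = 120.0,
    bp_per_cm: float = 400_000.0,
    chrom_prefix: str = "Gm",
) -> GeneticMap:
    """Uniformly spaced map: ``n_chrom`` chromosomes, ``n_markers`` markers
    each, spanning ``length_cm`` cM.  The workhorse for simulation studies."""
    if n_markers < 1 or n_chrom < 1:
        raise ValueError("need at least one chromosome and one marker")
    rows = []
    for c in range(1, n_chrom + 1):
        chrom = f"{chrom_prefix}{c:02d}"
        cm = np.linspace(0.0, length_cm, n_markers)
        for i, pos in enumerate(cm):
            rows.append(
                {
                    "marker": f"{chrom}_M{i + 1:03d}",
                    "chrom": chrom,
                    "cm": float(pos),
                    "bp": int(round(pos * bp_per_cm)) + 1,
                    "marker_class": "SNP",
                }
            )
    return GeneticMap(pd.DataFrame(rows))
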