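"""In-memory containers for genotype and phenotype data.

Integer genotype codes are used throughout:

* RIL coding (biparental, by parental origin):
  ``0`` = A (parent-1 homozygote), ``1`` = H (heterozygote),
  ``2`` = B (parent-2 homozygote), ``-1`` = missing.
* Panel coding (biallelic diversity-panel SNPs):
  ``0`` = hom-ref, ``1`` = het, ``2`` = hom-alt, ``-1`` = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap

RIL_CODE_TO_CHAR = {0: "A", 1: "H", 2: "B", -1: "NA"}
RIL_CHAR_TO_CODE = {"A": 0, "H": 1, "B": 2, "NA": -1, "-": -1, "": -1}

MISSING = -1


@dataclass
class RILGenotypes:
    """Recombinant-inbred-line genotypes coded by parental origin.

    ``codes`` is an ``(n_lines, n_markers)`` int8 matrix aligned with
    ``gmap.table`` column order.  ``generation`` is the derived generation
    (e.g. 5 for an F5-derived RIL population).
    """

    codes: np.ndarray = field(repr=False)
    lines: list[str]
    gmap: GeneticMap = field(repr=False)
    generation: int = 5
    parents: tuple[str, str] = ("P1", "P2")
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        if self.codes.shape != (len(self.lines), self.gmap.n_markers):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.lines)} lines x {self.gmap.n_markers} markers"
            )
        bad = ~np.isin(self.codes, (-1, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid RIL genotype code {self.codes[i, j]} for line "
                f"{self.lines[i]!r} at marker {self.gmap.marker_names[j]!r}"
            )
        if not (2 <= self.generation):
            raise ValueError("derived generation must be >= 2")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return (self.codes == MISSING).mean(axis=0)

    def heterozygosity(self) -> np.ndarray:
        """Per-marker heterozygote fraction among non-missing calls."""
        called = self.codes != MISSING
        with np.errstate(invalid="ignore"):
            return (self.codes == 1).sum(axis=0) / called.sum(axis=0)

    def expected_heterozygosity(self) -> float:
        """Residual heterozygosity of an F_k-derived RIL: (1/2)^(k-1)."""
        return 0.5 ** (self.generation - 1)

    def dosage(self) -> np.ndarray:
        """Additive dosage: A -> -1, H -> 0, B -> +1, missing -> 0."""
        x = self.codes.astype(float) - 1.0
        x[self.codes == MISSING] = 0.0
        return x

    def marker_dosage(self, marker: str) -> np.ndarray:
        j = self.gmap.marker_index()[marker]
        return self.dosage()[:, j]

    def to_frame(self) -> pd.DataFrame:
        chars = np.vectorize(RIL_CODE_TO_CHAR.get)(self.codes)
        return pd.DataFrame(chars, index=pd.Index(self.lines, name="line"),
                            columns=self.gmap.marker_names)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RILGenotypes):
            return NotImplemented
        return (
            self.lines == other.lines
            and self.generation == other.generation
            and self.gmap == other.gmap
            and np.array_equal(self.codes, other.codes)
        )


@dataclass
class PanelGenotypes:
    """Diversity-panel genotypes at biallelic SNPs with physical positions.

    ``snps`` has one row per SNP with columns ``snp`` (unique id), ``chrom``,
    ``bp`` (1-based, strictly increasing within chromosome), ``ref``, ``alt``.
    ``calls`` is ``(n_lines, n_snps)`` int8 in panel coding.
    """

    calls: np.ndarray = field(repr=False)
    lines: list[str]
    snps: pd.DataFrame = field(repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        required = {"snp", "chrom", "bp", "ref", "alt"}
        missing_cols = required - set(self.snps.columns)
        if missing_cols:
            raise ValueError(f"snps table missing columns: {sorted(missing_cols)}")
        if self.calls.shape != (len(self.lines), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.snps)} SNPs"
            )
        if self.snps["snp"].duplicated().any():
            dup = self.snps.loc[self.snps["snp"].duplicated(), "snp"].iloc[0]
            raise ValueError(f"duplicate SNP id: {dup!r}")
        if not np.isin(self.calls, (-1, 0, 1, 2)).all():
            raise ValueError("invalid panel genotype code (allowed: -1,0,1,2)")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                i = int(np.argmax(np.diff(bp) <= 0)) + 1
                raise ValueError(
                    f"physical positions not strictly increasing on {chrom} "
                    f"at SNP {grp['snp'].iloc[i]!r}"
                )
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def line_index(self, name: str) -> int:
        try:
            return self.lines.index(name)
        except ValueError:
            raise KeyError(f"line {name!r} not in panel") from None

    def line_calls(self, name: str) -> np.ndarray:
        return self.calls[self.line_index(name)]

    def alt_frequency(self) -> np.ndarray:
        """Per-SNP alt-allele frequency over non-missing calls (hets = 0.5)."""
        called = self.calls != MISSING
        alt = np.where(called, self.calls, 0).sum(axis=0, dtype=float)
        n_alleles = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return alt / n_alleles

    def with_lines(self, calls: np.ndarray, names: list[str]) -> "PanelGenotypes":
        """A new panel with extra lines appended (same SNP table)."""
        overlap = set(names) & set(self.lines)
        if overlap:
            raise ValueError(f"line names already in panel: {sorted(overlap)}")
        return PanelGenotypes(
            calls=np.vstack([self.calls, np.asarray(calls, dtype=np.int8)]),
            lines=list(self.lines) + list(names),
            snps=self.snps.copy(),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, PanelGenotypes):
            return NotImplemented
        return (
            self.lines == other.lines
            and np.array_equal(self.calls, other.calls)
            and self.snps.reset_index(drop=True).equals(other.snps.reset_index(drop=True))
        )


@dataclass
class PhenotypeRecords:
    """Line x trial phenotype table (protein %, oil %, yield kg/ha)."""

    table: pd.DataFrame = field(repr=False)
    aggregation: str = "arithmetic_mean"
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        required = {"line", "trial", "protein"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        prot = self.table["protein"]
        if ((prot < 0) | (prot > 100)).any():
            bad = self.table.loc[(prot < 0) | (prot > 100)].iloc[0]
            raise ValueError(
                f"protein out of [0,100] for line {bad['line']!r} trial {bad['trial']!r}"
            )
        if "oil" in self.table.columns:
            oil = self.table["oil"].dropna()
            if ((oil < 0) | (oil > 100)).any():
                raise ValueError("oil out of [0,100]")
        self.table = self.table.reset_index(drop=True)

    @property
    def lines(self) -> list[str]:
        return list(dict.fromkeys(self.table["line"]))

    def line_means(self, trait: str = "protein") -> pd.Series:
        """Per-line arithmetic mean over trials (equals least-square means
        in a balanced trial design)."""
        return self.table.groupby("line", sort=False)[trait].mean()

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhenotypeRecords):
            return NotImplemented
        return self.aggregation == other.aggregation and self.table.equals(other.table)
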