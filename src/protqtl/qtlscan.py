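"""Genome scans for quantitative trait loci in RIL populations.

The scan regresses line means on the expected additive dosage of a putative
locus on a centimorgan grid (Haley-Knott-style regression) and reports the
likelihood-ratio-type test statistic

    TS(position) = n * ln(RSS0 / RSS1),

where RSS0/RSS1 are the residual sums of squares of the null and the
locus-augmented model.  Genome-wide significance comes from a permutation
threshold (empirical quantile of the per-permutation maximum TS).  Two modes
are provided: simple interval mapping (SIM) and simplified composite
interval mapping (sCIM) with fixed background-marker cofactors that are
excluded within a window around the test position.  An anchored re-scan
tests for additive and epistatic effects conditional on a declared QTL.

Genotype probabilities use the fully-inbred two-state Markov chain for
selfed RILs: the per-meiosis recombination fraction r (Haldane) maps to the
line-level R = 2r/(1+2r), and heterozygous calls are treated as missing for
conditioning (the standard "riself" convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import PhenotypeRecords, RILGenotypes
from .genmap import GeneticMap, haldane_r, ril_recombination

__all__ = [
    "GenotypeProbabilities",
    "ScanResult",
    "AnchoredScanResult",
    "genotype_probabilities",
    "scan",
    "permutation_threshold",
    "variance_explained",
    "anchored_scan",
    "QTLScanner",
    "AnchoredScanner",
]


# ---------------------------------------------------------------------------
# Genotype probabilities on a cM grid


@dataclass
class GenotypeProbabilities:
    """Conditional genotype probabilities and additive dosages on a grid.

    ``probs`` is ``(n_lines, n_points, 3)`` over states (A, H, B);
    ``dosage`` is the expected additive dosage P(B) - P(A) in [-1, 1].
    """

    grid: pd.DataFrame = field(repr=False)  # columns: chrom, cm
    probs: np.ndarray = field(repr=False)
    dosage: np.ndarray = field(repr=False)
    lines: list[str]
    gmap: GeneticMap = field(repr=False)

    @property
    def n_points(self) -> int:
        return len(self.grid)

    def chrom_slice(self, chrom) -> np.ndarray:
        return (self.grid["chrom"] == chrom).to_numpy()

    def point_index(self, chrom, cm: float) -> int:
        m = (self.grid["chrom"] == chrom) & (np.abs(self.grid["cm"] - cm) < 1e-9)
        idx = np.flatnonzero(m.to_numpy())
        if len(idx) == 0:
            raise KeyError(f"no grid point at {chrom}:{cm} cM")
        return int(idx[0])


def _chrom_grid(positions: np.ndarray, step_cm: float) -> np.ndarray:
    lo, hi = positions[0], positions[-1]
    g = np.arange(lo, hi + 0.5 * step_cm, step_cm)
    return np.unique(np.concatenate([g, positions]))


def genotype_probabilities(
    genotypes: RILGenotypes,
    gmap: GeneticMap | None = None,
    step_cm: float = 1.0,
) -> GenotypeProbabilities:
    """Conditional genotype probabilities at grid points given the nearest
    informative flanking markers under the selfed-RIL transition model.

    Missing and heterozygous flanking calls are marginalized toward the next
    informative marker.  A grid point coincident with an observed marker is
    a point mass on the observed state.  Fully uninformative lines fall back
    to the RIL prior ((1-h)/2, h, (1-h)/2) with h the residual
    heterozygosity of the derived generation.
    """
    if step_cm <= 0:
        raise ValueError("step_cm must be positive")
    if gmap is None:
        gmap = genotypes.gmap
    elif gmap is not genotypes.gmap and not (gmap == genotypes.gmap):
        raise ValueError("map does not match the genotypes' map")

    h = genotypes.expected_heterozygosity()
    n = genotypes.n_lines
    grids, chrom_of = [], []
    col = 0
    blocks = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        m = len(pos)
        if m == 0:
            warnings.warn(f"chromosome {chrom!r} has no markers; skipped")
            continue
        g = _chrom_grid(pos, step_cm)
        grids.append(g)
        chrom_of.extend([chrom] * len(g))
        blocks.append((chrom, col, m, g))
        col += m

    n_points = sum(len(g) for g in grids)
    probs = np.empty((n, n_points, 3))
    dosage = np.empty((n, n_points))

    offset = 0
    for chrom, col, m, g in blocks:
        pos = gmap.positions(chrom)
        codes = genotypes.codes[:, col:col + m]
        gp = slice(offset, offset + len(g))
        for i in range(n):
            row = codes[i]
            informative = (row == 0) | (row == 2)
            if not informative.any():
                pA = pB = 0.5 * (1.0 - h)
                probs[i, gp] = (pA, h, pB)
                dosage[i, gp] = 0.0
            else:
                opos = pos[informative]
                # B-allele indicator of the observed state: 0 for A, 1 for B
                sB = (row[informative] == 2).astype(float)
                idx = np.searchsorted(opos, g)
                wA = np.ones(len(g))
                wB = np.ones(len(g))
                has_left = idx > 0
                li = np.clip(idx - 1, 0, None)
                Rl = ril_recombination(haldane_r(g - opos[li]))
                same_B = np.where(sB[li] == 1.0, 1.0 - Rl, Rl)
                wB = np.where(has_left, same_B, wB)
                wA = np.where(has_left, 1.0 - same_B, wA)
                has_right = idx < len(opos)
                ri = np.clip(idx, None, len(opos) - 1)
                Rr = ril_recombination(haldane_r(opos[ri] - g))
                same_B = np.where(sB[ri] == 1.0, 1.0 - Rr, Rr)
                wB = np.where(has_right, wB * same_B, wB)
                wA = np.where(has_right, wA * (1.0 - same_B), wA)
                z = wA + wB
                pB = wB / z
                probs[i, gp, 0] = 1.0 - pB
                probs[i, gp, 1] = 0.0
                probs[i, gp, 2] = pB
                dosage[i, gp] = 2.0 * pB - 1.0
            # point masses at observed (non-missing) markers on the grid
            obs = row != -1
            if obs.any():
                gidx = offset + np.searchsorted(g, pos[obs])
                states = row[obs]
                probs[i, gidx] = 0.0
                probs[i, gidx, states] = 1.0
                dosage[i, gidx] = states.astype(float) - 1.0
        offset += len(g)

    grid = pd.DataFrame({"chrom": chrom_of, "cm": np.concatenate(grids)})
    return GenotypeProbabilities(
        grid=grid, probs=probs, dosage=dosage, lines=list(genotypes.lines), gmap=gmap
    )


# ---------------------------------------------------------------------------
# Scan results


@dataclass
class ScanResult:
    """Test-statistic profile over a cM grid with threshold and peaks."""

    grid: pd.DataFrame = field(repr=False)
    statistic: np.ndarray = field(repr=False)
    mode: str = "SIM"
    threshold: float | None = None
    peaks: pd.DataFrame | None = field(default=None, repr=False)
    n_permutations: int = 0
    alpha: float | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.grid.copy()
        out["ts"] = self.statistic
        if self.threshold is not None:
            out["significant"] = self.statistic >= self.threshold
        return out


def _as_line_means(phenotypes) -> pd.Series:
    if isinstance(phenotypes, PhenotypeRecords):
        return phenotypes.line_means()
    if isinstance(phenotypes, pd.Series):
        return phenotypes
    raise TypeError("phenotypes must be PhenotypeRecords or a Series of line means")


def _align(genotypes: RILGenotypes, phenotypes) -> tuple[np.ndarray, np.ndarray]:
    """Row indices into the genotype matrix and the aligned phenotype values."""
    means = _as_line_means(phenotypes)
    index = {line: i for i, line in enumerate(genotypes.lines)}
    missing = [ln for ln in means.index if ln not in index]
    if missing:
        raise ValueError(f"phenotyped lines absent from genotypes: {missing[:5]}")
    rows = np.array([index[ln] for ln in means.index])
    return rows, means.to_numpy(dtype=float)


def _sim_statistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """TS = -n ln(1 - r^2) per column of X (equivalent to n ln(RSS0/RSS1))."""
    n = len(y)
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0:
        return np.zeros(X.shape[1])
    Xc = X - X.mean(axis=0)
    xnorm = np.linalg.norm(Xc, axis=0)
    ok = xnorm > 0
    r = np.zeros(X.shape[1])
    r[ok] = (Xc[:, ok].T @ yc) / (xnorm[ok] * ynorm)
    r2 = np.clip(r**2, 0.0, 1.0 - 1e-12)
    return -n * np.log1p(-r2)


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def _auto_cofactors(
    genotypes: RILGenotypes, rows: np.ndarray, y: np.ndarray, spacing_cm: float = 30.0
) -> list[str]:
    """One marker per ~spacing_cm bin, chosen by strongest marginal
    association with the phenotype."""
    gmap = genotypes.gmap
    dosage = genotypes.dosage()[rows]
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    chosen: list[str] = []
    for chrom in gmap.chromosomes:
        grp = gmap.chrom_table(chrom)
        pos = grp["cm"].to_numpy()
        bins = np.floor((pos - pos[0]) / spacing_cm).astype(int)
        for b in np.unique(bins):
            members = grp.index[bins == b]
            best, best_r = None, -1.0
            for j in members:
                x = dosage[:, j]
                xc = x - x.mean()
                xn = np.linalg.norm(xc)
                if xn == 0 or ynorm == 0:
                    continue
                r = abs(xc @ yc) / (xn * ynorm)
                if r > best_r:
                    best, best_r = j, r
            if best is not None:
                chosen.append(gmap.marker_names[best])
    return chosen


def _drop_collinear(C: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep: list[int] = []
    for j in range(C.shape[1]):
        trial = C[:, keep + [j]]
        cols = np.column_stack([np.ones(len(C)), trial])
        if np.linalg.matrix_rank(cols) == cols.shape[1]:
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear cofactor {names[j]!r}")
    return C[:, keep], [names[j] for j in keep]


def scan(
    genotypes: RILGenotypes,
    phenotypes,
    mode: str = "SIM",
    cofactors="auto",
    step_cm: float = 1.0,
    window_cm: float = 20.0,
    threshold: float | None = None,
    gp: GenotypeProbabilities | None = None,
) -> ScanResult:
    """Genome scan of line means against expected locus dosage.

    ``mode='SIM'`` is plain interval mapping; ``mode='sCIM'`` adds fixed
    marker cofactors (``cofactors='auto'`` selects one per ~30 cM by marginal
    association; a list of marker names fixes them; None/empty means no
    cofactors, in which case sCIM equals SIM point by point).  If
    ``threshold`` is given, peaks above it are reported.
    """
    mode_u = mode.upper()
    if mode_u not in ("SIM", "SCIM"):
        raise ValueError(f"unknown scan mode {mode!r}")
    rows, y = _align(genotypes, phenotypes)
    if gp is None:
        gp = genotype_probabilities(genotypes, step_cm=step_cm)
    X = gp.dosage[rows]
    n = len(y)

    if np.ptp(y) == 0:
        warnings.warn("constant phenotype: all test statistics are zero")
        ts = np.zeros(gp.n_points)
        return ScanResult(grid=gp.grid, statistic=ts, mode=mode, threshold=threshold)

    cof_names: list[str] = []
    if mode_u == "SCIM" and cofactors:
        if cofactors == "auto":
            cof_names = _auto_cofactors(genotypes, rows, y)
        else:
            cof_names = list(cofactors)
        midx = genotypes.gmap.marker_index()
        C = genotypes.dosage()[rows][:, [midx[m] for m in cof_names]]
        C, cof_names = _drop_collinear(C, cof_names)

    if not cof_names:
        ts = _sim_statistic(X, y)
    else:
        mtab = genotypes.gmap.table.set_index("marker")
        cof_chrom = mtab.loc[cof_names, "chrom"].to_numpy()
        cof_cm = mtab.loc[cof_names, "cm"].to_numpy(dtype=float)
        midx = genotypes.gmap.marker_index()
        C = genotypes.dosage()[rows][:, [midx[m] for m in cof_names]]
        grid_chrom = gp.grid["chrom"].to_numpy()
        grid_cm = gp.grid["cm"].to_numpy()
        ones = np.ones((n, 1))
        ts = np.zeros(gp.n_points)
        for k in range(gp.n_points):
            active = ~((cof_chrom == grid_chrom[k]) & (np.abs(cof_cm - grid_cm[k]) <= window_cm))
            base = np.column_stack([ones, C[:, active]]) if active.any() else ones
            rss0 = _rss(base, y)
            rss1 = _rss(np.column_stack([base, X[:, k]]), y)
            if rss1 <= 0:
                rss1 = 1e-300
            ts[k] = max(n * np.log(rss0 / rss1), 0.0)

    result = ScanResult(grid=gp.grid, statistic=ts, mode=mode, threshold=threshold)
    if threshold is not None:
        result.peaks = find_peaks(result, genotypes, phenotypes, gp=gp)
    return result


# ---------------------------------------------------------------------------
# Peaks


def find_peaks(
    result: ScanResult,
    genotypes: RILGenotypes,
    phenotypes,
    gp: GenotypeProbabilities | None = None,
    shoulder_dip: float = 0.25,
) -> pd.DataFrame:
    """Declared peaks: local maxima with TS >= threshold, one per chromosome
    unless the profile dips below the threshold between maxima; shoulder
    peaks are kept when separated from an accepted peak by a dip of at least
    ``shoulder_dip`` of the lower peak's TS."""
    if result.threshold is None:
        raise ValueError("find_peaks needs a threshold on the scan result")
    rows, y = _align(genotypes, phenotypes)
    if gp is None:
        gp = genotype_probabilities(genotypes)
    ts = result.statistic
    thr = result.threshold
    grid = result.grid
    records = []
    for chrom in grid["chrom"].unique():
        m = (grid["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(m)
        t = ts[idx]
        cand = [
            k for k in range(len(t))
            if t[k] >= thr
            and (k == 0 or t[k] >= t[k - 1])
            and (k == len(t) - 1 or t[k] > t[k + 1])
        ]
        cand.sort(key=lambda k: -t[k])
        accepted: list[int] = []
        for k in cand:
            ok = True
            for a in accepted:
                lo, hi = min(k, a), max(k, a)
                valley = t[lo:hi + 1].min()
                lower = min(t[k], t[a])
                if not (valley < thr or valley <= (1.0 - shoulder_dip) * lower):
                    ok = False
                    break
            if ok:
                accepted.append(k)
        for k in sorted(accepted):
            g = idx[k]
            cm = float(grid["cm"].iloc[g])
            x = gp.dosage[rows, g]
            r2 = _r_squared(x, y)
            records.append(
                {
                    "chrom": chrom,
                    "cm": cm,
                    "nearest_marker": genotypes.gmap.nearest_marker(chrom, cm),
                    "ts": float(ts[g]),
                    "r2": r2,
                }
            )
    return pd.DataFrame(records, columns=["chrom", "cm", "nearest_marker", "ts", "r2"])


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.linalg.norm(xc) * np.linalg.norm(yc)
    if den == 0:
        return 0.0
    return float((xc @ yc / den) ** 2)


def variance_explained(
    genotypes: RILGenotypes,
    phenotypes,
    position: tuple[str, float],
    gp: GenotypeProbabilities | None = None,
) -> float:
    """R^2 of line means regressed on the expected dosage at ``position``
    (chrom, cM); equals the squared Pearson correlation."""
    rows, y = _align(genotypes, phenotypes)
    chrom, cm = position
    if gp is not None:
        x = gp.dosage[rows, gp.point_index(chrom, cm)]
    else:
        x = _dosage_at(genotypes, chrom, cm)[rows]
    return _r_squared(x, y)


def _dosage_at(genotypes: RILGenotypes, chrom, cm: float) -> np.ndarray:
    """Expected dosage of every line at a single position."""
    gmap = genotypes.gmap
    grp = gmap.chrom_table(chrom)
    if grp.empty:
        raise ValueError(f"no markers on chromosome {chrom!r}")
    pos = grp["cm"].to_numpy(dtype=float)
    cols = grp.index.to_numpy()
    codes = genotypes.codes[:, cols]
    out = np.zeros(genotypes.n_lines)
    exact = np.flatnonzero(np.abs(pos - cm) < 1e-9)
    for i in range(genotypes.n_lines):
        row = codes[i]
        if exact.size and row[exact[0]] != -1:
            out[i] = float(row[exact[0]]) - 1.0
            continue
        informative = (row == 0) | (row == 2)
        if not informative.any():
            out[i] = 0.0
            continue
        opos = pos[informative]
        sB = (row[informative] == 2).astype(float)
        k = np.searchsorted(opos, cm)
        wA = wB = 1.0
        if k > 0:
            R = float(ril_recombination(haldane_r(cm - opos[k - 1])))
            same = 1.0 - R if sB[k - 1] == 1.0 else R
            wB *= same
            wA *= 1.0 - same
        if k < len(opos):
            R = float(ril_recombination(haldane_r(opos[k] - cm)))
            same = 1.0 - R if sB[k] == 1.0 else R
            wB *= same
            wA *= 1.0 - same
        out[i] = (wB - wA) / (wA + wB)
    return out


# ---------------------------------------------------------------------------
# Permutation threshold


def permutation_threshold(
    genotypes: RILGenotypes,
    phenotypes,
    mode: str = "SIM",
    n_permutations: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
    step_cm: float = 1.0,
    cofactors=None,
    window_cm: float = 20.0,
    gp: GenotypeProbabilities | None = None,
    return_null: bool = False,
):
    """Genome-wide critical value from phenotype permutations.

    Line means are permuted against genotype rows; the genome-wide maximum
    TS is recorded per permutation and the empirical (1 - alpha) quantile is
    returned as the k-th order statistic with k = max(1, ceil((1-alpha) n)).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    rows, y = _align(genotypes, phenotypes)
    if len(y) < 20:
        warnings.warn("fewer than 20 lines: permutation threshold is unstable")
    if gp is None:
        gp = genotype_probabilities(genotypes, step_cm=step_cm)
    rng = np.random.default_rng(seed)
    X = gp.dosage[rows]
    n = len(y)

    if mode.upper() == "SIM" and not cofactors:
        Xc = X - X.mean(axis=0)
        xnorm = np.linalg.norm(Xc, axis=0)
        ok = xnorm > 0
        Xn = np.zeros_like(Xc)
        Xn[:, ok] = Xc[:, ok] / xnorm[ok]
        null_max = np.empty(n_permutations)
        batch = 500
        for s in range(0, n_permutations, batch):
            b = min(batch, n_permutations - s)
            Y = np.empty((n, b))
            for j in range(b):
                Y[:, j] = y[rng.permutation(n)]
            Yc = Y - Y.mean(axis=0)
            ynorm = np.linalg.norm(Yc, axis=0)
            ynorm[ynorm == 0] = 1.0
            r2max = np.max((Xn.T @ (Yc / ynorm)) ** 2, axis=0)
            null_max[s:s + b] = -n * np.log1p(-np.clip(r2max, 0, 1 - 1e-12))
    else:
        null_max = np.empty(n_permutations)
        means = _as_line_means(phenotypes)
        for j in range(n_permutations):
            yp = pd.Series(y[rng.permutation(n)], index=means.index)
            res = scan(
                genotypes, yp, mode=mode, cofactors=cofactors,
                step_cm=step_cm, window_cm=window_cm, gp=gp,
            )
            null_max[j] = res.statistic.max()

    k = max(1, int(np.ceil((1.0 - alpha) * n_permutations)))
    threshold = float(np.sort(null_max)[k - 1])
    if return_null:
        return threshold, null_max
    return threshold


# ---------------------------------------------------------------------------
# Anchored re-scan for additive and epistatic effects


@dataclass
class AnchoredScanResult:
    grid: pd.DataFrame = field(repr=False)
    additive_ts: np.ndarray = field(repr=False)
    interaction_ts: np.ndarray = field(repr=False)
    anchor: tuple[str, float] = ("", 0.0)
    excluded: np.ndarray = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        out = self.grid.copy()
        out["additive_ts"] = self.additive_ts
        out["interaction_ts"] = self.interaction_ts
        out["excluded"] = self.excluded
        return out


def anchored_scan(
    genotypes: RILGenotypes,
    phenotypes,
    anchor: tuple[str, float],
    step_cm: float = 1.0,
    window_cm: float = 20.0,
    gp: GenotypeProbabilities | None = None,
) -> AnchoredScanResult:
    """Re-scan the genome with a declared QTL held in the model.

    At each grid point the model mean + anchor dosage + test dosage +
    anchor x test product is fitted; the TS for the added additive term and
    for the interaction term are reported separately.  Points within
    ``window_cm`` of the anchor on its own chromosome are excluded
    (statistics set to 0 and flagged)."""
    rows, y = _align(genotypes, phenotypes)
    if gp is None:
        gp = genotype_probabilities(genotypes, step_cm=step_cm)
    a = _dosage_at(genotypes, anchor[0], anchor[1])[rows]
    if a.std() == 0:
        raise ValueError("anchor dosage is constant")
    X = gp.dosage[rows]
    n = len(y)
    grid_chrom = gp.grid["chrom"].to_numpy()
    grid_cm = gp.grid["cm"].to_numpy()
    excluded = (grid_chrom == anchor[0]) & (np.abs(grid_cm - anchor[1]) <= window_cm)

    ones = np.ones(n)
    base = np.column_stack([ones, a])
    rss0 = _rss(base, y)
    add_ts = np.zeros(gp.n_points)
    int_ts = np.zeros(gp.n_points)
    for k in np.flatnonzero(~excluded):
        x = X[:, k]
        m1 = np.column_stack([base, x])
        rss1 = max(_rss(m1, y), 1e-300)
        m2 = np.column_stack([m1, a * x])
        rss2 = max(_rss(m2, y), 1e-300)
        add_ts[k] = max(n * np.log(rss0 / rss1), 0.0)
        int_ts[k] = max(n * np.log(rss1 / rss2), 0.0)
    return AnchoredScanResult(
        grid=gp.grid, additive_ts=add_ts, interaction_ts=int_ts,
        anchor=anchor, excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Estimators


class QTLScanner(BaseEstimator):
    """Genome-scan estimator (SIM or sCIM) with a permutation threshold.

    Parameters follow scikit-learn conventions; fitted attributes carry a
    trailing underscore.  ``fit(genotypes, phenotypes)`` computes the TS
    profile, a permutation threshold when ``n_permutations > 0``, and the
    declared peaks with their variance explained.
    """

    def __init__(
        self,
        mode: str = "SIM",
        step_cm: float = 1.0,
        cofactors="auto",
        window_cm: float = 20.0,
        n_permutations: int = 0,
        alpha: float = 0.05,
        random_state: int | None = None,
    ):
        self.mode = mode
        self.step_cm = step_cm
        self.cofactors = cofactors
        self.window_cm = window_cm
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, genotypes: RILGenotypes, phenotypes) -> "QTLScanner":
        gp = genotype_probabilities(genotypes, step_cm=self.step_cm)
        threshold = None
        if self.n_permutations:
            threshold = permutation_threshold(
                genotypes, phenotypes, mode=self.mode,
                n_permutations=self.n_permutations, alpha=self.alpha,
                seed=self.random_state, step_cm=self.step_cm,
                cofactors=self.cofactors if self.mode.upper() == "SCIM" else None,
                window_cm=self.window_cm, gp=gp,
            )
        result = scan(
            genotypes, phenotypes, mode=self.mode, cofactors=self.cofactors,
            step_cm=self.step_cm, window_cm=self.window_cm,
            threshold=threshold, gp=gp,
        )
        result.n_permutations = self.n_permutations
        result.alpha = self.alpha if self.n_permutations else None
        self.genotype_probabilities_ = gp
        self.result_ = result
        self.threshold_ = threshold
        self.peaks_ = result.peaks
        return self

    def predict(self, positions: list[tuple[str, float]]) -> np.ndarray:
        """Test statistic at the requested (chrom, cM) grid positions."""
        gp = self.genotype_probabilities_
        return np.array(
            [self.result_.statistic[gp.point_index(c, p)] for c, p in positions]
        )


class AnchoredScanner(BaseEstimator):
    """Anchored additive/epistatic re-scan around a declared QTL."""

    def __init__(
        self,
        anchor: tuple[str, float] | None = None,
        step_cm: float = 1.0,
        window_cm: float = 20.0,
    ):
        self.anchor = anchor
        self.step_cm = step_cm
        self.window_cm = window_cm

    def fit(self, genotypes: RILGenotypes, phenotypes) -> "AnchoredScanner":
        if self.anchor is None:
            raise ValueError("anchor position is required")
        self.result_ = anchored_scan(
            genotypes, phenotypes, anchor=self.anchor,
            step_cm=self.step_cm, window_cm=self.window_cm,
        )
        self.additive_ts_ = self.result_.additive_ts
        self.interaction_ts_ = self.result_.interaction_ts
        return self
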