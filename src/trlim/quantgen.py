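"""Genetic map utilities and QTL mapping for a biparental soybean population.

Genotypes are ABH-coded: AA = "Jackson"-parent homozygote, AB =
heterozygote, BB = "KS4895"-parent homozygote.  QTL genotype probabilities
at off-marker positions are exact conditionals on the nearest informative
flanking markers under F2-intercross transition probabilities with Haldane
map distances — the effective treatment of an early-selfing RIL set scanned
with an additive + dominance model.

Scans are Haley-Knott regressions of the phenotype on the expected additive
score P(AA) - P(BB) and dominance score P(AB), with

    LOD = (n/2) * log10(RSS0 / RSS1)

against the null of mean (plus any cofactors).  Composite interval mapping
adds forward-selected marker cofactors, excluding those within a window of
the test position.  Genome-wide significance comes from permutation of the
phenotype across lines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisWarning, InvalidInputError, RankDeficiencyError

__all__ = [
    "GeneticMap",
    "RILPopulation",
    "LODScan",
    "QTLResult",
    "haldane",
    "inverse_haldane",
    "f2_transition",
    "qtl_genotype_probs",
    "hk_scan",
    "cim_scan",
    "select_cofactors",
    "permutation_threshold",
    "support_interval",
    "fit_qtl_model",
]

GENO_CODES = {"AA": 0, "AB": 1, "BB": 2}
CODE_GENOS = {v: k for k, v in GENO_CODES.items()}
MISSING = -1
F2_PRIOR = np.array([0.25, 0.5, 0.25])


def haldane(r: float) -> float:
    """Haldane map distance (cM) from a recombination fraction.

    d = -50 * ln(1 - 2r), defined for 0 <= r < 0.5.
    """
    if not 0 <= r < 0.5:
        raise InvalidInputError(
            f"recombination fraction must be in [0, 0.5), got {r} "
            "(r >= 0.5 corresponds to infinite distance)"
        )
    return -50.0 * math.log(1.0 - 2.0 * r)


def inverse_haldane(d: float) -> float:
    """Recombination fraction from a Haldane distance in cM."""
    if d < 0:
        raise InvalidInputError(f"map distance must be >= 0, got {d}")
    return (1.0 - math.exp(-d / 50.0)) / 2.0


def f2_transition(r: float) -> np.ndarray:
    """F2-intercross genotype transition matrix between two loci.

    Entry [i, j] is P(genotype j at locus 2 | genotype i at locus 1) for
    recombination fraction r, treating the two gametes independently.
    """
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: name, chromosome, genetic position (cM).

    ``df`` has columns marker, chromosome, pos_cm (and optionally pos_bp
    for physical anchoring); positions must be nondecreasing within each
    chromosome and marker names unique.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chromosome", "pos_cm"}
        if not required.issubset(self.df.columns):
            raise InvalidInputError(f"map needs columns {sorted(required)}")
        if self.df["marker"].duplicated().any():
            dup = self.df.loc[self.df["marker"].duplicated(), "marker"].iloc[0]
            raise InvalidInputError(f"duplicate marker name {dup!r}")
        for chrom, sub in self.df.groupby("chromosome", sort=False, observed=True):
            if not sub["pos_cm"].is_monotonic_increasing:
                raise InvalidInputError(f"positions not nondecreasing on {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chromosome"]))

    def chrom_slice(self, chrom) -> pd.DataFrame:
        return self.df[self.df["chromosome"] == chrom]

    def marker_index(self) -> pd.Index:
        return pd.Index(self.df["marker"])

    @property
    def length_cm(self) -> float:
        return float(
            sum(
                sub["pos_cm"].iloc[-1] - sub["pos_cm"].iloc[0]
                for _, sub in self.df.groupby("chromosome", sort=False, observed=True)
            )
        )

    @classmethod
    def read_tsv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"marker": str, "chromosome": str}))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class RILPopulation:
    """ABH genotype matrix (lines x markers) plus its genetic map."""

    map: GeneticMap
    genotypes: np.ndarray  # int8, codes 0/1/2, -1 missing
    line_ids: list[str]
    generation: str = "F3"

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.shape != (len(self.line_ids), len(self.map.df)):
            raise InvalidInputError(
                f"genotype matrix {g.shape} inconsistent with "
                f"{len(self.line_ids)} lines x {len(self.map.df)} markers"
            )
        bad = set(np.unique(g)) - {-1, 0, 1, 2}
        if bad:
            raise InvalidInputError(f"invalid genotype codes {sorted(bad)}")
        object.__setattr__(self, "genotypes", g)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @classmethod
    def from_abh_csv(cls, genotype_csv, map_tsv, generation: str = "F3") -> "RILPopulation":
        """Read lines-x-markers ABH CSV (cells AA/AB/BB/NA) plus a map TSV."""
        gmap = GeneticMap.read_tsv(map_tsv)
        df = pd.read_csv(genotype_csv, index_col=0, dtype=str)
        df = df.reindex(columns=gmap.df["marker"])
        if df.isna().all(axis=None):
            raise InvalidInputError("no genotype columns match the map markers")
        codes = df.apply(lambda col: col.map(GENO_CODES).fillna(MISSING)).to_numpy()
        return cls(gmap, codes.astype(np.int8), [str(i) for i in df.index], generation)

    def to_abh_csv(self, path) -> None:
        sym = np.array(["AA", "AB", "BB"], dtype=object)
        cells = np.where(
            self.genotypes >= 0, sym[np.clip(self.genotypes, 0, 2)], "NA"
        )
        pd.DataFrame(
            cells, index=self.line_ids, columns=self.map.df["marker"]
        ).to_csv(path, index_label="line")


@dataclass
class LODScan:
    """A genome scan: ordered positions, LOD values, optional threshold."""

    positions: pd.DataFrame  # columns chromosome, pos_cm
    lod: np.ndarray
    threshold: float | None = None
    cofactors: list[str] = field(default_factory=list)
    step: float = 1.0

    def max_lod(self) -> float:
        return float(np.max(self.lod))

    def peak(self) -> tuple[str, float]:
        """(chromosome, pos_cm) of the global maximum; ties break to lower cM."""
        i = int(np.argmax(self.lod))
        row = self.positions.iloc[i]
        return str(row["chromosome"]), float(row["pos_cm"])

    def chrom_peaks(self, threshold: float | None = None) -> pd.DataFrame:
        """Per-chromosome maximum positions at or above a threshold."""
        thr = self.threshold if threshold is None else threshold
        d = self.positions.assign(lod=self.lod)
        peaks = d.loc[d.groupby("chromosome", sort=False, observed=True)["lod"].idxmax()]
        if thr is not None:
            peaks = peaks[peaks["lod"] >= thr]
        return peaks.reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.positions.assign(lod=self.lod).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class QTLResult:
    """One QTL from the joint additive model fit."""

    name: str
    chromosome: str
    pos_cm: float
    lod: float
    pct_var: float
    allelic_effect: float  # AA (Jackson hom.) mean minus BB (KS4895 hom.) mean
    type3_ss: float
    p_f: float
    df: int
    support_lo: float = math.nan
    support_hi: float = math.nan


# ---------------------------------------------------------------------------
# genotype probabilities
# ---------------------------------------------------------------------------


def _chrom_arrays(pop: RILPopulation, chrom) -> tuple[np.ndarray, np.ndarray]:
    sel = (pop.map.df["chromosome"] == chrom).to_numpy()
    mpos = pop.map.df.loc[sel, "pos_cm"].to_numpy(dtype=float)
    G = pop.genotypes[:, sel]
    return mpos, G


def _cond_probs_one(
    mpos: np.ndarray, g: np.ndarray, pos: float
) -> np.ndarray:
    """Conditional genotype probabilities for one line at one position."""
    obs = np.flatnonzero(g >= 0)
    if obs.size == 0:
        return F2_PRIOR.copy()
    opos = mpos[obs]
    # exact hit on an observed marker
    hit = np.flatnonzero(np.abs(opos - pos) < 1e-9)
    if hit.size:
        out = np.zeros(3)
        out[g[obs[hit[0]]]] = 1.0
        return out
    left = np.searchsorted(opos, pos) - 1
    right = left + 1
    if left < 0:
        rR = inverse_haldane(opos[right] - pos)
        T = f2_transition(rR)
        w = F2_PRIOR * T[:, g[obs[right]]]
        return w / w.sum()
    if right >= obs.size:
        rL = inverse_haldane(pos - opos[left])
        return f2_transition(rL)[g[obs[left]], :].copy()
    rL = inverse_haldane(pos - opos[left])
    rR = inverse_haldane(opos[right] - pos)
    w = f2_transition(rL)[g[obs[left]], :] * f2_transition(rR)[:, g[obs[right]]]
    return w / w.sum()


def qtl_genotype_probs(
    pop: RILPopulation, line: int, chromosome, pos_cm: float
) -> np.ndarray:
    """(P(AA), P(AB), P(BB)) for one line at a mapped position.

    Conditional on the nearest informative flanking markers; at an observed
    marker this is the indicator of the observed genotype.
    """
    mpos, G = _chrom_arrays(pop, chromosome)
    if mpos.size == 0:
        raise InvalidInputError(f"unknown chromosome {chromosome!r}")
    if not (mpos[0] - 1e-9 <= pos_cm <= mpos[-1] + 1e-9):
        raise InvalidInputError(
            f"position {pos_cm} cM off the mapped range "
            f"[{mpos[0]}, {mpos[-1]}] of {chromosome}"
        )
    return _cond_probs_one(mpos, G[line], float(pos_cm))


def _grid_positions(mpos: np.ndarray, step: float) -> np.ndarray:
    grid = np.arange(mpos[0], mpos[-1] + 1e-9, step)
    return np.unique(np.concatenate([grid, mpos]))


def _probs_on_chrom(
    mpos: np.ndarray, G: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Probabilities (n_positions, n_lines, 3); vectorized when no data missing."""
    n = G.shape[0]
    out = np.empty((grid.size, n, 3))
    complete = bool((G >= 0).all())
    for k, pos in enumerate(grid):
        j = int(np.searchsorted(mpos, pos))
        if j < mpos.size and abs(mpos[j] - pos) < 1e-9 and complete:
            P = np.zeros((n, 3))
            P[np.arange(n), G[:, j]] = 1.0
            out[k] = P
        elif complete:
            left = j - 1
            rL = inverse_haldane(pos - mpos[left])
            rR = inverse_haldane(mpos[j] - pos)
            TL = f2_transition(rL)
            TR = f2_transition(rR)
            W = TL[G[:, left], :] * TR[:, G[:, j]].T
            out[k] = W / W.sum(axis=1, keepdims=True)
        else:
            for i in range(n):
                out[k, i] = _cond_probs_one(mpos, G[i], float(pos))
    return out


def genotype_prob_grid(
    pop: RILPopulation, step: float = 1.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Scan grid (marker positions plus every ``step`` cM) with probabilities.

    Returns (positions DataFrame, array of shape (n_positions, n_lines, 3)).
    """
    if step <= 0:
        raise InvalidInputError("step must be > 0")
    frames, chunks = [], []
    for chrom in pop.map.chromosomes:
        mpos, G = _chrom_arrays(pop, chrom)
        grid = _grid_positions(mpos, step)
        frames.append(pd.DataFrame({"chromosome": chrom, "pos_cm": grid}))
        chunks.append(_probs_on_chrom(mpos, G, grid))
    return pd.concat(frames, ignore_index=True), np.concatenate(chunks, axis=0)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def _ortho_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-safe, via SVD)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    return U[:, s > tol]


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sums of squares of Y's columns after projection on X."""
    U = _ortho_basis(X)
    return np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", U.T @ Y, U.T @ Y)


def _marker_scores(pop: RILPopulation, markers: list[str]) -> np.ndarray:
    """Additive + dominance score columns for named markers (missing -> expected)."""
    cols = []
    midx = pop.map.marker_index()
    for m in markers:
        j = midx.get_loc(m)
        chrom = pop.map.df["chromosome"].iloc[j]
        pos = float(pop.map.df["pos_cm"].iloc[j])
        mpos, G = _chrom_arrays(pop, chrom)
        k = int(np.searchsorted(mpos, pos))
        g = G[:, k]
        if (g >= 0).all():
            a = np.where(g == 0, 1.0, np.where(g == 2, -1.0, 0.0))
            d = (g == 1).astype(float)
        else:
            P = np.array([_cond_probs_one(mpos, G[i], pos) for i in range(pop.n_lines)])
            a = P[:, 0] - P[:, 2]
            d = P[:, 1]
        cols.extend([a, d])
    return np.column_stack(cols) if cols else np.empty((pop.n_lines, 0))


def _clean_covariates(cov: np.ndarray | None, n: int) -> np.ndarray:
    if cov is None:
        return np.empty((n, 0))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if cov.shape[0] != n:
        cov = cov.T
    base = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(base)
    if rank < base.shape[1]:
        keep, cols = np.ones(n)[:, None], []
        for j in range(cov.shape[1]):
            trial = np.column_stack([keep, cov[:, j]])
            if np.linalg.matrix_rank(trial) > keep.shape[1]:
                keep = trial
                cols.append(j)
        warnings.warn(
            f"dropping {cov.shape[1] - len(cols)} collinear covariate column(s)",
            AnalysisWarning,
            stacklevel=3,
        )
        cov = cov[:, cols]
    return cov


def _scan_lod(
    probs: np.ndarray,
    positions: pd.DataFrame,
    Y: np.ndarray,
    covariates: np.ndarray | None = None,
    exclude: "callable | None" = None,
) -> np.ndarray:
    """LOD matrix (n_positions, n_phenotypes) for one or many phenotype columns.

    ``exclude(k)`` may return a boolean mask over covariate columns to drop
    at position index k (used by CIM's window rule).
    """
    Y = np.atleast_2d(Y.T).T  # (n, m)
    n = Y.shape[0]
    cov = _clean_covariates(covariates, n)
    ones = np.ones((n, 1))
    lod = np.empty((probs.shape[0], Y.shape[1]))
    if exclude is None:
        rss0 = _rss(np.column_stack([ones, cov]), Y)
    for k in range(probs.shape[0]):
        P = probs[k]
        a = (P[:, 0] - P[:, 2])[:, None]
        d = P[:, 1][:, None]
        ck = cov
        if exclude is not None:
            mask = exclude(k)
            ck = cov[:, mask] if mask is not None else cov
            rss0 = _rss(np.column_stack([ones, ck]), Y)
        rss1 = _rss(np.column_stack([ones, ck, a, d]), Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(rss1 > 0, rss0 / np.maximum(rss1, 1e-300), 1.0)
            lod[k] = (n / 2.0) * np.log10(np.maximum(ratio, 1.0))
    return lod


def hk_scan(
    pop: RILPopulation,
    phenotype,
    step: float = 1.0,
    covariates: np.ndarray | None = None,
    _grid: tuple[pd.DataFrame, np.ndarray] | None = None,
) -> LODScan:
    """Standard interval mapping by Haley-Knott regression.

    Phenotype is one value per line (lines with missing phenotype are
    dropped casewise).  At each grid position the phenotype is regressed on
    the expected additive and dominance scores plus any covariates;
    LOD = (n/2) log10(RSS0/RSS1) with the null of mean + covariates.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.size != pop.n_lines:
        raise InvalidInputError(
            f"phenotype length {y.size} != {pop.n_lines} lines"
        )
    positions, probs = _grid if _grid is not None else genotype_prob_grid(pop, step)
    keep = np.isfinite(y)
    y, probs_k = y[keep], probs[:, keep, :]
    cov = None if covariates is None else np.asarray(covariates)[keep]
    if np.std(y) == 0:
        warnings.warn(
            "zero phenotypic variance: all-zero LOD scan", AnalysisWarning, stacklevel=2
        )
        return LODScan(positions, np.zeros(probs.shape[0]), step=step)
    lod = _scan_lod(probs_k, positions, y[:, None], cov)[:, 0]
    return LODScan(positions, lod, step=step)


def select_cofactors(
    pop: RILPopulation,
    phenotype,
    n_cofactors: int = 3,
    enter_alpha: float = 0.05,
) -> list[str]:
    """Forward selection of marker cofactors by partial-F p-value.

    Single-marker additive+dominance regressions, adding the best marker
    each round while its partial F-test p-value is below ``enter_alpha``,
    up to ``n_cofactors`` markers.
    """
    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(y)
    y = y[keep]
    n = y.size
    markers = list(pop.map.df["marker"])
    scores = {m: _marker_scores(pop, [m])[keep] for m in markers}
    chosen: list[str] = []
    ones = np.ones((n, 1))
    while len(chosen) < n_cofactors:
        base_X = np.column_stack(
            [ones] + [scores[m] for m in chosen]
        ) if chosen else ones
        rss_base = float(_rss(base_X, y[:, None])[0])
        df_base = n - np.linalg.matrix_rank(base_X)
        best, best_p, best_rss = None, 1.0, None
        for m in markers:
            if m in chosen:
                continue
            X = np.column_stack([base_X, scores[m]])
            rss = float(_rss(X, y[:, None])[0])
            df_full = n - np.linalg.matrix_rank(X)
            q = df_base - df_full
            if df_full <= 0 or q <= 0 or rss <= 0:
                continue
            f = (rss_base - rss) / q / (rss / df_full)
            p = float(stats.f.sf(f, q, df_full))
            if p < best_p or (p == best_p and best_rss is not None and rss < best_rss):
                best, best_p, best_rss = m, p, rss
        if best is None or best_p >= enter_alpha:
            break
        chosen.append(best)
    return chosen


def cim_scan(
    pop: RILPopulation,
    phenotype,
    step: float = 1.0,
    n_cofactors: int = 3,
    window: float = 10.0,
    _grid: tuple[pd.DataFrame, np.ndarray] | None = None,
) -> LODScan:
    """Composite interval mapping.

    Marker cofactors are forward-selected (max ``n_cofactors``); at each
    test position, cofactors within ``window`` cM on the same chromosome
    are excluded from the model.  With zero cofactors this reduces exactly
    to :func:`hk_scan`.
    """
    if window <= 0:
        raise InvalidInputError("window must be > 0")
    y = np.asarray(phenotype, dtype=float)
    cof = select_cofactors(pop, y, n_cofactors) if n_cofactors > 0 else []
    positions, probs = _grid if _grid is not None else genotype_prob_grid(pop, step)
    if not cof:
        scan = hk_scan(pop, y, step, _grid=(positions, probs))
        scan.cofactors = []
        return scan
    keep = np.isfinite(y)
    yk = y[keep]
    if np.std(yk) == 0:
        warnings.warn("zero phenotypic variance", AnalysisWarning, stacklevel=2)
        return LODScan(positions, np.zeros(probs.shape[0]), cofactors=cof, step=step)
    cov = np.column_stack([_marker_scores(pop, [m])[keep] for m in cof])
    cof_info = pop.map.df.set_index("marker").loc[cof, ["chromosome", "pos_cm"]]
    cof_chrom = cof_info["chromosome"].to_numpy()
    cof_pos = cof_info["pos_cm"].to_numpy(dtype=float)
    pos_chrom = positions["chromosome"].to_numpy()
    pos_cm = positions["pos_cm"].to_numpy(dtype=float)

    def exclude(k: int) -> np.ndarray:
        near = (cof_chrom == pos_chrom[k]) & (np.abs(cof_pos - pos_cm[k]) < window)
        return np.repeat(~near, 2)  # two columns (a, d) per cofactor

    lod = _scan_lod(probs[:, keep, :], positions, yk[:, None], cov, exclude)[:, 0]
    return LODScan(positions, lod, cofactors=cof, step=step)


def active_cofactors(
    gmap: GeneticMap, cofactors: list[str], chromosome, pos_cm: float, window: float
) -> list[str]:
    """Cofactors retained at a test position under the CIM window rule."""
    info = gmap.df.set_index("marker").loc[cofactors]
    keep = ~(
        (info["chromosome"] == chromosome)
        & ((info["pos_cm"] - pos_cm).abs() < window)
    )
    return list(info.index[keep])


def permutation_threshold(
    pop: RILPopulation,
    phenotype,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    step: float = 1.0,
    _grid: tuple[pd.DataFrame, np.ndarray] | None = None,
    return_maxima: bool = False,
):
    """Genome-wide LOD threshold from phenotype permutations.

    The phenotype is permuted across lines ``n_perm`` times, a full SIM
    scan is run for each, and the empirical (1 - alpha) quantile of the
    per-permutation maximum LOD is returned.  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise InvalidInputError("n_perm must be >= 100")
    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(y)
    y = y[keep]
    positions, probs = _grid if _grid is not None else genotype_prob_grid(pop, step)
    probs = probs[:, keep, :]
    rng = np.random.default_rng(seed)
    n = y.size
    Y = np.empty((n, n_perm))
    for j in range(n_perm):
        Y[:, j] = y[rng.permutation(n)]
    lod = _scan_lod(probs, positions, Y)
    maxima = lod.max(axis=0)
    thr = float(np.quantile(maxima, 1.0 - alpha, method="higher"))
    if return_maxima:
        return thr, maxima
    return thr


def support_interval(
    scan: LODScan, peak: tuple[str, float], drop: float = 1.5
) -> tuple[float, float]:
    """LOD-drop support interval around a peak, clipped to chromosome ends.

    The widest contiguous region around the peak whose LOD stays within
    ``drop`` units of the peak LOD.
    """
    chrom, pos = peak
    on = scan.positions["chromosome"] == chrom
    pos_cm = scan.positions.loc[on, "pos_cm"].to_numpy(dtype=float)
    lod = scan.lod[on.to_numpy()]
    k = int(np.argmin(np.abs(pos_cm - pos)))
    cut = lod[k] - drop
    lo = k
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = k
    while hi < lod.size - 1 and lod[hi + 1] >= cut:
        hi += 1
    return float(pos_cm[lo]), float(pos_cm[hi])


def _refine_to_local_max(
    scan: LODScan, chromosome, pos_cm: float
) -> tuple[float, float]:
    on = scan.positions["chromosome"] == chromosome
    grid = scan.positions.loc[on, "pos_cm"].to_numpy(dtype=float)
    lod = scan.lod[on.to_numpy()]
    k = int(np.argmin(np.abs(grid - pos_cm)))
    while True:
        if k > 0 and lod[k - 1] > lod[k]:
            k -= 1
        elif k < lod.size - 1 and lod[k + 1] > lod[k]:
            k += 1
        else:
            break
    return float(grid[k]), float(lod[k])


def fit_qtl_model(
    pop: RILPopulation,
    phenotype,
    qtl_positions: list[tuple[str, float]],
    refine: bool = True,
    step: float = 1.0,
    drop: float = 1.5,
    name_prefix: str = "q",
) -> list[QTLResult]:
    """Joint additive (+dominance) model over the given QTL.

    Positions are first refined to local maxima of a SIM scan; QTL closer
    than 1 cM on the same chromosome are merged with a warning.  Per-QTL
    type III sums of squares come from drop-one refitting; pct_var is
    100 * SS_qtl / TSS of the phenotype; the allelic effect is the fitted
    AA-homozygote ("Jackson") minus BB-homozygote ("KS4895") difference,
    i.e. twice the additive coefficient.
    """
    if not qtl_positions:
        raise InvalidInputError("need at least one QTL position")
    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(y)
    yk = y[keep]
    n = yk.size
    grid = genotype_prob_grid(pop, step)
    scan = hk_scan(pop, y, step, _grid=grid)

    refined: list[tuple[str, float]] = []
    for chrom, pos in qtl_positions:
        p, _ = _refine_to_local_max(scan, chrom, pos) if refine else (pos, math.nan)
        merged = False
        for i, (c2, p2) in enumerate(refined):
            if c2 == chrom and abs(p2 - p) < 1.0:
                warnings.warn(
                    f"QTL at {chrom}:{p:.1f} within 1 cM of {chrom}:{p2:.1f}; merged",
                    AnalysisWarning,
                    stacklevel=2,
                )
                merged = True
        if not merged:
            refined.append((chrom, p))

    blocks = []
    for chrom, pos in refined:
        P = np.array(
            [qtl_genotype_probs(pop, i, chrom, pos) for i in range(pop.n_lines)]
        )[keep]
        a = P[:, 0] - P[:, 2]
        d = P[:, 1]
        blocks.append(np.column_stack([a, d]))

    ones = np.ones((n, 1))
    X_full = np.column_stack([ones] + blocks)
    rss_full = float(_rss(X_full, yk[:, None])[0])
    rank_full = np.linalg.matrix_rank(X_full)
    dfe = n - rank_full
    tss = float(((yk - yk.mean()) ** 2).sum())

    results = []
    for q, (chrom, pos) in enumerate(refined):
        X_red = np.column_stack([ones] + [b for i, b in enumerate(blocks) if i != q])
        rss_red = float(_rss(X_red, yk[:, None])[0])
        ss_q = max(rss_red - rss_full, 0.0)
        df_q = rank_full - np.linalg.matrix_rank(X_red)
        if dfe > 0 and rss_full > 0 and df_q > 0:
            f = (ss_q / df_q) / (rss_full / dfe)
            p_f = float(stats.f.sf(f, df_q, dfe))
        else:
            p_f = 0.0 if ss_q > 0 else 1.0
        lod_q = (n / 2.0) * math.log10(rss_red / rss_full) if rss_full > 0 else math.inf
        beta, *_ = np.linalg.lstsq(X_full, yk, rcond=None)
        a_coef = beta[1 + 2 * q]
        lo, hi = support_interval(scan, (chrom, pos), drop)
        results.append(
            QTLResult(
                name=f"{name_prefix}_{chrom}_{q + 1}",
                chromosome=str(chrom),
                pos_cm=float(pos),
                lod=float(lod_q),
                pct_var=100.0 * ss_q / tss if tss > 0 else math.nan,
                allelic_effect=float(2.0 * a_coef),
                type3_ss=ss_q,
                p_f=p_f,
                df=int(df_q),
                support_lo=lo,
                support_hi=hi,
            )
        )
    return results


def qtl_report(results: list[QTLResult]) -> pd.DataFrame:
    """Flat table of QTL model results (one row per QTL)."""
    return pd.DataFrame(
        [
            {
                "qtl": r.name,
                "chromosome": r.chromosome,
                "peak_cm": r.pos_cm,
                "interval_lo_cm": r.support_lo,
                "interval_hi_cm": r.support_hi,
                "df": r.df,
                "type3_ss": r.type3_ss,
                "lod": r.lod,
                "pct_var": r.pct_var,
                "p_f": r.p_f,
                "allelic_effect": r.allelic_effect,
            }
            for r in results
        ]
    )
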