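"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and seed, and emits a
:class:`SimulationTruth` sidecar describing the planted ground truth so
recovery tests can compare estimates against what was generated.

The default parameters mirror the study conditions the pipeline was built
for: 120 recombinant inbred lines from a biparental soybean cross grown in
6 experiment sets with 3 replicate plants, VPD response curves sampled over
0.5-4.0 kPa, and a genetic map scaled down to 5 chromosomes of 50 markers
at 2 cM spacing so the full pipeline stays desk-sized.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .candidate_genes import DEFAULT_KEYWORDS, GeneRecord
from .errors import ParameterError
from .quantgen import GeneticMap, RILPopulation, inverse_haldane, qtl_genotype_probs

__all__ = [
    "SimulationTruth",
    "QTLPlant",
    "default_map",
    "simulate_ril",
    "simulate_phenotypes",
    "simulate_weighing",
    "simulate_vpd_curve",
    "toy_annotation",
]


@dataclass(frozen=True)
class QTLPlant:
    """A planted QTL: map position plus effect size.

    Exactly one of ``additive`` (trait units per allele substitution) or
    ``pct_var`` (percent of per-line phenotypic variance, with ``sign``
    giving which parent raises the trait: +1 means the AA / "Jackson"
    homozygote is higher) must be given.
    """

    chromosome: str
    pos_cm: float
    additive: float | None = None
    pct_var: float | None = None
    sign: int = 1
    dominance: float = 0.0


@dataclass
class SimulationTruth:
    """Ground truth serialized beside every generated dataset."""

    seed: int
    kind: str
    qtl: list[dict] = field(default_factory=list)
    h2_target: float | None = None
    sigma_g2: float | None = None
    sigma_ge2: float | None = None
    sigma_e2: float | None = None
    bp_true: dict | None = None
    slope1_true: float | None = None
    slope2_true: float | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "SimulationTruth":
        text = str(text_or_path)
        if "\n" not in text and text.endswith(".json"):
            with open(text) as fh:
                text = fh.read()
        return cls(**json.loads(text))


def default_map(
    n_chromosomes: int = 5, n_markers: int = 50, spacing_cm: float = 2.0
) -> GeneticMap:
    """Evenly spaced toy map; chromosome names follow the Gm soybean style."""
    rows = [
        {
            "marker": f"M{c + 1:02d}_{i + 1:03d}",
            "chromosome": f"Gm{c + 1:02d}",
            "pos_cm": i * spacing_cm,
        }
        for c in range(n_chromosomes)
        for i in range(n_markers)
    ]
    return GeneticMap(pd.DataFrame(rows))


def _meiosis(h0: np.ndarray, h1: np.ndarray, r: np.ndarray, chrom_start: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per line from paired haplotypes (no interference).

    ``r`` holds the per-interval recombination fractions (Haldane), with
    ``chrom_start`` marking the first marker of each chromosome where the
    parental strand is redrawn at random.
    """
    n, m = h0.shape
    flips = rng.random((n, m)) < r  # r[chrom_start] == 0.5 -> fresh strand
    state = np.logical_xor.accumulate(flips, axis=1)
    return np.where(state, h1, h0)


def simulate_ril(
    n_lines: int,
    gmap: GeneticMap | None = None,
    selfing_generations: int = 2,
    seed: int | None = None,
) -> RILPopulation:
    """Simulate RIL genotypes by repeated selfing from a biparental F1.

    Crossovers follow the Haldane (no interference) model: at marker
    resolution, a gamete switches parental strand between adjacent markers
    with the Haldane recombination fraction of their map distance.
    ``selfing_generations = 2`` yields F3 lines (expected heterozygosity
    25%), ``4`` yields F5.  Genotypes are ABH-coded with AA the
    "Jackson"-parent homozygote.
    """
    if gmap is None:
        gmap = default_map()
    if n_lines < 2:
        raise ParameterError("n_lines must be >= 2")
    if selfing_generations < 1:
        raise ParameterError("selfing_generations must be >= 1")
    rng = np.random.default_rng(seed)
    m = len(gmap.df)
    pos = gmap.df["pos_cm"].to_numpy(dtype=float)
    chrom = gmap.df["chromosome"].to_numpy()
    new_chrom = np.ones(m, dtype=bool)
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    r = np.empty(m)
    r[0] = 0.5
    d = np.diff(pos)
    r[1:] = (1.0 - np.exp(-np.maximum(d, 0.0) / 50.0)) / 2.0
    r[new_chrom] = 0.5  # independent strand choice at each chromosome start

    # F1: one haplotype from each parent
    h0 = np.zeros((n_lines, m), dtype=np.int8)  # Jackson allele = 0
    h1 = np.ones((n_lines, m), dtype=np.int8)  # KS4895 allele = 1
    for _ in range(selfing_generations):
        g1 = _meiosis(h0, h1, r, new_chrom, rng)
        g2 = _meiosis(h0, h1, r, new_chrom, rng)
        h0, h1 = g1, g2
    codes = (h0 + h1).astype(np.int8)  # 0=AA, 1=AB, 2=BB
    gen = f"F{selfing_generations + 1}"
    ids = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    return RILPopulation(gmap, codes, ids, generation=gen)


def _qtl_scores(pop: RILPopulation, q: QTLPlant) -> tuple[np.ndarray, np.ndarray]:
    P = np.array(
        [qtl_genotype_probs(pop, i, q.chromosome, q.pos_cm) for i in range(pop.n_lines)]
    )
    return P[:, 0] - P[:, 2], P[:, 1]


def simulate_phenotypes(
    pop: RILPopulation,
    qtl: list[QTLPlant],
    h2_target: float | None = None,
    n_sets: int = 6,
    n_reps: int = 3,
    mean: float = 1.32,
    set_sd: float = 0.1,
    ge_share: float = 0.3,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Genotype x set x replicate trait table with planted QTL structure.

    Line genetic values are sums of additive (and optional dominance)
    effects at the planted QTL.  With ``pct_var`` QTL, effects are scaled
    from the realized genotype-score variances so the planted fractions
    refer to a per-line phenotypic variance of 1 (the implied line-mean
    heritability is then the summed fractions, unless ``h2_target``
    overrides it).  The non-genetic line-mean variance budget
    sigma_ge2/E + sigma_e2/(E*R) is split by ``ge_share`` between the
    genotype-x-set interaction and the residual; set main effects (SD
    ``set_sd``) do not enter the heritability denominator.
    """
    rng = np.random.default_rng(seed)
    n = pop.n_lines
    g = np.zeros(n)
    qtl_records = []
    for q in qtl:
        a_score, d_score = _qtl_scores(pop, q)
        var_a = float(np.var(a_score))
        if q.additive is not None:
            a = float(q.additive)
        elif q.pct_var is not None:
            if var_a <= 0:
                raise ParameterError(
                    f"QTL at {q.chromosome}:{q.pos_cm} has zero score variance"
                )
            a = (1 if q.sign >= 0 else -1) * float(
                np.sqrt(q.pct_var / 100.0 / var_a)
            )
        else:
            raise ParameterError("QTLPlant needs additive or pct_var")
        g += a * a_score + q.dominance * d_score
        qtl_records.append(
            {
                "chromosome": q.chromosome,
                "pos_cm": q.pos_cm,
                "additive": a,
                "dominance": q.dominance,
                "pct_var": q.pct_var,
                "sign": int(np.sign(a)) if a != 0 else 0,
            }
        )

    sigma_g2 = float(np.var(g))
    if h2_target is None and any(q.pct_var is not None for q in qtl):
        noise_line = max(1.0 - sigma_g2, 1e-12)
    elif h2_target is not None:
        if not 0 < h2_target < 1:
            raise ParameterError(f"h2_target must be in (0, 1), got {h2_target}")
        if sigma_g2 <= 0:
            raise ParameterError("zero genetic variance: cannot hit an h2 target")
        noise_line = sigma_g2 * (1.0 - h2_target) / h2_target
    else:
        noise_line = 0.0
    if not 0 <= ge_share < 1:
        raise ParameterError("ge_share must be in [0, 1)")
    sigma_ge2 = ge_share * noise_line * n_sets
    sigma_e2 = (1.0 - ge_share) * noise_line * n_sets * n_reps

    sets = [f"set{s + 1}" for s in range(n_sets)]
    set_eff = rng.normal(0.0, set_sd, n_sets)
    ge_eff = rng.normal(0.0, np.sqrt(sigma_ge2), (n, n_sets)) if sigma_ge2 > 0 else np.zeros((n, n_sets))
    rows = []
    for s in range(n_sets):
        for rep in range(n_reps):
            e = rng.normal(0.0, np.sqrt(sigma_e2), n) if sigma_e2 > 0 else np.zeros(n)
            vals = mean + g + set_eff[s] + ge_eff[:, s] + e
            rows.append(
                pd.DataFrame(
                    {
                        "genotype": pop.line_ids,
                        "set": sets[s],
                        "rep": rep + 1,
                        "value": vals,
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    realized_h2 = sigma_g2 / (
        sigma_g2 + sigma_ge2 / n_sets + sigma_e2 / (n_sets * n_reps)
    ) if sigma_g2 + noise_line > 0 else None
    truth = SimulationTruth(
        seed=-1 if seed is None else int(seed),
        kind="phenotypes",
        qtl=qtl_records,
        h2_target=h2_target if h2_target is not None else realized_h2,
        sigma_g2=sigma_g2,
        sigma_ge2=sigma_ge2,
        sigma_e2=sigma_e2,
        extra={"n_sets": n_sets, "n_reps": n_reps, "mean": mean, "ge_share": ge_share},
    )
    return table, truth


def line_means(table: pd.DataFrame, pop: RILPopulation) -> np.ndarray:
    """Per-line phenotype means ordered like ``pop.line_ids``."""
    m = table.groupby("genotype", observed=True)["value"].mean()
    return m.reindex(pop.line_ids).to_numpy(dtype=float)


def simulate_weighing(
    genotype_truth: pd.DataFrame,
    n_sets: int = 6,
    n_reps: int = 3,
    noise: float = 0.02,
    set_sd: float = 0.05,
    seed: int | None = None,
    water_interval: float = 60.0,
    agno3_interval: float = 180.0,
    initial_mass: float = 150.0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Flask-weighing records with planted inhibitor sensitivities.

    ``genotype_truth`` needs columns genotype, tr_h2o (mg/min) and
    sensitivity (fractional inhibitor-induced decrease, in [0, 1); the
    AgNO3-phase rate is tr_h2o * (1 - sensitivity)).  Optional column
    leaf_temp_c is passed through with small replicate noise.  Mass loss
    carries multiplicative Gaussian noise of relative SD ``noise``; set
    effects scale rates multiplicatively (SD ``set_sd``).  With zero noise
    the tier-1 analysis recovers DTR = 100 * sensitivity exactly.
    """
    req = {"genotype", "tr_h2o", "sensitivity"}
    if not req.issubset(genotype_truth.columns):
        raise ParameterError(f"genotype_truth needs columns {sorted(req)}")
    if (genotype_truth["tr_h2o"] <= 0).any():
        raise ParameterError("tr_h2o rates must be positive")
    sens = genotype_truth["sensitivity"]
    if ((sens < 0) | (sens >= 1)).any():
        raise ParameterError("sensitivity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    set_eff = rng.normal(0.0, set_sd, n_sets) if set_sd > 0 else np.zeros(n_sets)
    has_lt = "leaf_temp_c" in genotype_truth.columns
    rows = []
    for _, gt in genotype_truth.iterrows():
        for s in range(n_sets):
            for rep in range(n_reps):
                rate_w = gt["tr_h2o"] * (1.0 + set_eff[s])
                rate_a = rate_w * (1.0 - gt["sensitivity"])
                for phase, rate, interval in [
                    ("water", rate_w, water_interval),
                    ("agno3", rate_a, agno3_interval),
                ]:
                    eps = rng.normal(0.0, noise) if noise > 0 else 0.0
                    loss_g = rate * interval * (1.0 + eps) / 1000.0
                    row = {
                        "genotype": gt["genotype"],
                        "set": f"set{s + 1}",
                        "rep": rep + 1,
                        "phase": phase,
                        "mass_initial_g": initial_mass,
                        "mass_final_g": initial_mass - loss_g,
                        "interval_min": interval,
                    }
                    if has_lt:
                        row["leaf_temp_c"] = gt["leaf_temp_c"] + (
                            rng.normal(0.0, 0.2) if noise > 0 else 0.0
                        )
                    rows.append(row)
    truth = SimulationTruth(
        seed=-1 if seed is None else int(seed),
        kind="weighing",
        extra={
            "n_sets": n_sets,
            "n_reps": n_reps,
            "noise": noise,
            "genotypes": genotype_truth.to_dict(orient="list"),
        },
    )
    return pd.DataFrame(rows), truth


def simulate_vpd_curve(
    slope1: float,
    intercept1: float,
    bp: float | None = None,
    slope2: float | None = None,
    vpd_grid=None,
    noise: float = 0.05,
    seed: int | None = None,
    genotype: str = "G1",
    temperature_c: float = 32.0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Transpiration-vs-VPD points on a (possibly broken) line plus noise.

    With ``bp`` the mean is continuous piecewise-linear, switching from
    ``slope1`` to ``slope2`` at the breakpoint; with ``bp=None`` a single
    line.  Default grid: 24 points over 0.5-4.0 kPa.
    """
    v = np.linspace(0.5, 4.0, 24) if vpd_grid is None else np.asarray(vpd_grid, float)
    if bp is not None:
        if not (v.min() < bp < v.max()):
            raise ParameterError(f"bp {bp} outside the VPD grid span")
        if slope2 is None:
            raise ParameterError("slope2 required when bp is given")
        tr = intercept1 + slope1 * np.minimum(v, bp) + slope2 * np.maximum(v - bp, 0.0)
    else:
        tr = intercept1 + slope1 * v
    rng = np.random.default_rng(seed)
    if noise > 0:
        tr = tr + rng.normal(0.0, noise, v.size)
    df = pd.DataFrame(
        {
            "genotype": genotype,
            "temperature_c": temperature_c,
            "rep": 1,
            "vpd_kpa": v,
            "tr": tr,
        }
    )
    truth = SimulationTruth(
        seed=-1 if seed is None else int(seed),
        kind="vpd_curve",
        bp_true={genotype: bp},
        slope1_true=slope1,
        slope2_true=slope2,
        extra={"intercept1": intercept1, "noise": noise, "n": int(v.size)},
    )
    return df, truth


_NEUTRAL_GO = (
    ("GO:0006260", "DNA replication"),
    ("GO:0042254", "ribosome biogenesis"),
    ("GO:0006396", "RNA processing"),
    ("GO:0007049", "cell cycle"),
    ("GO:0006412", "translation"),
)


def toy_annotation(
    n_genes: int = 30,
    keyword_fraction: float = 0.3,
    seed: int | None = None,
    chromosome: str = "Gm10",
    region_start: int = 100_000,
) -> tuple[list[GeneRecord], SimulationTruth]:
    """Non-overlapping toy gene annotation with a planted candidate subset.

    A known fraction of genes receive a GO term name embedding one of the
    default drought keywords ("response to <keyword>"); the rest get
    neutral housekeeping terms.  The planted candidate gene ids are
    recorded in the truth sidecar.
    """
    if not 0 <= keyword_fraction <= 1:
        raise ParameterError("keyword_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_kw = int(round(keyword_fraction * n_genes))
    kw_idx = set(rng.choice(n_genes, size=n_kw, replace=False).tolist())
    genes, planted = [], []
    pos = region_start
    for i in range(n_genes):
        length = int(rng.integers(1_000, 5_000))
        gap = int(rng.integers(1_000, 10_000))
        gid = f"Toy.{chromosome}G{i + 1:04d}"
        if i in kw_idx:
            kw = DEFAULT_KEYWORDS[i % len(DEFAULT_KEYWORDS)]
            go = (("GO:1900000", f"response to {kw}"),)
            planted.append(gid)
        else:
            go = (_NEUTRAL_GO[i % len(_NEUTRAL_GO)],)
        genes.append(
            GeneRecord(
                gene_id=gid,
                chromosome=chromosome,
                start=pos,
                end=pos + length - 1,
                go_terms=go,
            )
        )
        pos += length + gap
    truth = SimulationTruth(
        seed=-1 if seed is None else int(seed),
        kind="annotation",
        extra={
            "planted_candidates": planted,
            "chromosome": chromosome,
            "region": [region_start, pos],
        },
    )
    return genes, truth
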