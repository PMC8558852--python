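"""Synthetic RNA-seq data with planted differential-expression and coexpression structure.

The generator emulates a three-group bulk RNA-seq study — two tumor cohorts
and a normal reference — at the gene level.  Counts are negative binomial
with a log-linear mean

    mu_gs = L_s * exp(b_g + delta_g * 1{s in DE cohort} + sum_m w_gm * z_ms)

where ``L_s`` is a per-sample depth factor, ``b_g`` a baseline log mean,
``delta_g`` a planted differential-expression effect (stored as log2 fold
change in the ground truth) and ``z_ms`` a standard-normal latent factor
shared by the members of coexpression module ``m`` and active only in the
cohorts where that module is switched on.  A single latent factor per module
yields a controllable within-module pairwise correlation of roughly
``w^2 / (w^2 + sigma^2)`` on the log scale.

The module also ships loaders for small packaged fixtures mirroring the
printed result tables of the motivating study (differential-expression
tables, coexpressed-pair table, and Venn overlap counts).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortDesign",
    "ModuleSpec",
    "GeneratorParams",
    "GroundTruth",
    "CountData",
    "generate_annotation",
    "generate_counts",
    "generate_survival",
    "generate_gene_sets",
    "load_fixture",
    "DEFAULT_GLEASON",
]

COHORTS = ("tumorA", "tumorB", "normal")

# Gleason-score census of the matched tumor cohorts (sum of the two pattern
# scores); identical in both cohorts by construction of the 1:1 matching.
DEFAULT_GLEASON = {6: 9, 7: 33, 8: 2, 9: 4, 10: 1}


@dataclass(frozen=True)
class CohortDesign:
    """Sample sizes and Gleason composition of the simulated study."""

    n_tumor_a: int = 49
    n_tumor_b: int = 49
    n_normal: int = 44
    gleason_distribution: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_GLEASON)
    )

    def __post_init__(self) -> None:
        if min(self.n_tumor_a, self.n_tumor_b, self.n_normal) < 0:
            raise ValueError("cohort sizes must be non-negative")
        total = sum(self.gleason_distribution.values())
        if self.n_tumor_a and total != self.n_tumor_a:
            raise ValueError(
                f"Gleason distribution sums to {total}, expected {self.n_tumor_a}"
            )


@dataclass(frozen=True)
class ModuleSpec:
    """One planted coexpression module.

    ``loading`` is the latent-factor weight w on the natural-log scale; with
    the default dispersion and well-expressed genes the implied within-module
    Pearson correlation of log expression is about w^2/(w^2 + 0.2).
    """

    size: int = 10
    loading: float = 0.9
    cohorts: tuple[str, ...] = ("tumorA",)


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable knobs of the count generator.

    base_log_mean_range: natural-log mean expression range (log-uniform draw).
    dispersion: NB dispersion phi, variance = mu + phi * mu^2.
    depth_range: per-sample depth factors, log-uniform multiples of nominal.
    de_fraction: fraction of genes planted as DE in each tumor cohort.
    de_log2fc: magnitude of planted log2 fold changes (sign randomised).
    modules: planted coexpression modules; members are drawn from the
        tumor-A DE genes so that they survive the DE gene-list step.
    hazard_log2hr: log2 hazard ratio planted on the first module gene's
        high-expression group (0 disables planted survival effects).
    """

    base_log_mean_range: tuple[float, float] = (np.log(5.0), np.log(500.0))
    dispersion: float = 0.2
    depth_range: tuple[float, float] = (0.5, 2.0)
    de_fraction: float = 0.15
    de_log2fc: float = 1.5
    modules: tuple[ModuleSpec, ...] = ()
    baseline_hazard: float = 1.0 / 1500.0
    censor_rate: float = 1.0 / 2000.0
    hazard_log2hr: float = 0.0


@dataclass
class GroundTruth:
    """What the generator planted, keyed for downstream recovery checks."""

    de_genes: dict[str, dict[str, float]]
    modules: list[dict]
    true_edges: dict[str, set[frozenset]]
    hazard_genes: dict[str, float]


@dataclass
class CountData:
    """Integer gene x sample counts with per-sample metadata."""

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.sample_meta.index):
            raise ValueError("counts columns and sample_meta index must agree")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.sample_meta["cohort"].isna().any():
            raise ValueError("every sample needs a cohort label")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def samples_in(self, *cohorts: str) -> list[str]:
        mask = self.sample_meta["cohort"].isin(cohorts)
        return list(self.sample_meta.index[mask])


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    n_mrna: int, n_lncrna: int, n_antisense_pairs: int, seed: int
) -> pd.DataFrame:
    """Build a synthetic gene annotation table.

    Exactly ``n_antisense_pairs`` lncRNAs are placed overlapping a distinct
    mRNA on the opposite strand; every other pair of gene intervals is
    disjoint.  Returns a DataFrame with columns gene_id, symbol, biotype,
    chrom, start, end, strand.
    """
    if min(n_mrna, n_lncrna, n_antisense_pairs) < 0:
        raise ValueError("counts must be non-negative")
    if n_antisense_pairs > min(n_mrna, n_lncrna):
        raise ValueError("more antisense pairs than available partners")
    rng = np.random.default_rng(seed)

    rows = []
    span = 5_000
    gap = 15_000
    pos = 1
    for i in range(n_mrna):
        rows.append(
            {
                "gene_id": f"ENSG1{i:010d}",
                "symbol": f"MRNA{i}",
                "biotype": "mRNA",
                "chrom": f"chr{(i % 22) + 1}",
                "start": pos,
                "end": pos + span - 1,
                "strand": "+",
            }
        )
        pos += span + gap
    # antisense lncRNAs overlap their partner mRNA by half its span
    partner_idx = rng.choice(n_mrna, size=n_antisense_pairs, replace=False) if n_antisense_pairs else []
    for j in range(n_lncrna):
        if j < n_antisense_pairs:
            partner = rows[int(partner_idx[j])]
            start = partner["start"] + span // 2
            chrom = partner["chrom"]
            end = start + span - 1
        else:
            chrom = f"chr{(j % 22) + 1}"
            start = pos
            end = pos + span - 1
            pos += span + gap
        rows.append(
            {
                "gene_id": f"ENSG2{j:010d}",
                "symbol": f"LNC{j}",
                "biotype": "lncRNA",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": "-",
            }
        )
    cols = ["gene_id", "symbol", "biotype", "chrom", "start", "end", "strand"]
    ann = pd.DataFrame(rows, columns=cols)
    return ann.set_index("gene_id", drop=False)


# ---------------------------------------------------------------------------
# counts


def _sample_table(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    gleason = []
    for score, count in sorted(design.gleason_distribution.items()):
        gleason.extend([score] * count)
    if design.n_tumor_a and len(gleason) != design.n_tumor_a:
        raise ValueError("Gleason distribution inconsistent with cohort size")
    rows = []
    for cohort, n in (
        ("tumorA", design.n_tumor_a),
        ("tumorB", design.n_tumor_b),
        ("normal", design.n_normal),
    ):
        for i in range(n):
            if cohort == "normal":
                gs = 0
            else:
                gs = gleason[i % len(gleason)] if gleason else 0
            rows.append({"sample_id": f"{cohort}_{i:03d}", "cohort": cohort, "gleason": gs})
    return pd.DataFrame(rows).set_index("sample_id")


def generate_counts(
    design: CohortDesign,
    annotation: pd.DataFrame,
    params: GeneratorParams | None = None,
    seed: int = 0,
) -> tuple[CountData, GroundTruth]:
    """Simulate NB counts with planted DE genes and coexpression modules.

    Tumor-A and tumor-B each receive an independent random draw of DE genes
    with log2 fold changes ±``de_log2fc`` versus normal, with a large shared
    fraction so the two cohorts resemble each other the way two tumor
    populations from the same tissue do.  Module members are taken from the
    tumor-A DE genes (boosted to solid expression so their correlations are
    estimable) and the within-module edge set per cohort is recorded in the
    returned :class:`GroundTruth`.
    """
    params = params or GeneratorParams()
    if params.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(annotation["gene_id"])
    n_genes = len(genes)
    meta = _sample_table(design, rng)
    n_samples = len(meta)

    lo, hi = params.base_log_mean_range
    b = rng.uniform(lo, hi, size=n_genes)
    depth = np.exp(rng.uniform(np.log(params.depth_range[0]), np.log(params.depth_range[1]), size=n_samples))

    # planted DE: shared core plus cohort-private remainder
    n_de = int(round(params.de_fraction * n_genes))
    de_pool = rng.choice(n_genes, size=min(2 * n_de, n_genes), replace=False) if n_de else np.array([], dtype=int)
    shared = de_pool[: int(0.7 * n_de)]
    private_a = de_pool[int(0.7 * n_de) : n_de]
    private_b = de_pool[n_de : 2 * n_de - len(shared)]
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    de_genes: dict[str, dict[str, float]] = {"tumorA": {}, "tumorB": {}}
    for idx in np.concatenate([shared, private_a]):
        de_genes["tumorA"][genes[idx]] = signs[idx] * params.de_log2fc
    for idx in np.concatenate([shared, private_b]):
        de_genes["tumorB"][genes[idx]] = signs[idx] * params.de_log2fc

    # planted modules drawn from tumor-A DE genes
    module_records: list[dict] = []
    true_edges: dict[str, set[frozenset]] = {c: set() for c in COHORTS}
    a_de_idx = [i for i in np.concatenate([shared, private_a])] if n_de else []
    cursor = 0
    loadings = np.zeros((n_genes, len(params.modules)))
    for m, spec in enumerate(params.modules):
        members_idx = a_de_idx[cursor : cursor + spec.size]
        cursor += spec.size
        if len(members_idx) < spec.size:
            raise ValueError("not enough DE genes to host all planted modules")
        member_ids = [genes[i] for i in members_idx]
        for i in members_idx:
            loadings[i, m] = spec.loading
            b[i] = max(b[i], np.log(100.0))  # keep module genes well expressed
        module_records.append(
            {"genes": member_ids, "loading": spec.loading, "cohorts": tuple(spec.cohorts)}
        )
        for c in spec.cohorts:
            for x in range(len(member_ids)):
                for y in range(x + 1, len(member_ids)):
                    true_edges[c].add(frozenset((member_ids[x], member_ids[y])))

    cohort = meta["cohort"].to_numpy()
    log_mu = np.tile(b[:, None], (1, n_samples))
    ln2 = np.log(2.0)
    for c in ("tumorA", "tumorB"):
        cols = cohort == c
        for g, lfc in de_genes[c].items():
            log_mu[genes.index(g), cols] += lfc * ln2

    z = rng.standard_normal((len(params.modules), n_samples))
    for m, spec in enumerate(params.modules):
        active = np.isin(cohort, spec.cohorts)
        log_mu += loadings[:, [m]] * (z[m] * active)[None, :]

    mu = np.exp(log_mu) * depth[None, :]
    phi = params.dispersion
    if phi > 0:
        # NB as gamma-Poisson: shape 1/phi, scale phi*mu
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    counts_df = pd.DataFrame(counts, index=genes, columns=meta.index)

    # survival: planted hazard driven by the first module gene when requested
    hazard_genes: dict[str, float] = {}
    hr = float(2.0 ** params.hazard_log2hr)
    if params.hazard_log2hr != 0.0 and module_records:
        gene = module_records[0]["genes"][0]
        hazard_genes[gene] = hr
        expr = counts_df.loc[gene]
        group = (expr > expr.median()).to_numpy().astype(int)
    else:
        group = np.zeros(n_samples, dtype=int)
        hr = 1.0
    surv_seed = int(rng.integers(0, 2**31 - 1))
    time, event = generate_survival(
        group, hr, params.baseline_hazard, params.censor_rate, seed=surv_seed
    )
    meta = meta.assign(time=time, event=event)

    data = CountData(counts=counts_df, sample_meta=meta)
    truth = GroundTruth(
        de_genes=de_genes,
        modules=module_records,
        true_edges=true_edges,
        hazard_genes=hazard_genes,
    )
    return data, truth


def generate_survival(
    expression_group,
    hr: float,
    baseline_hazard: float,
    censor_rate: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with hazard ``baseline * hr^[group == high]``.

    ``expression_group`` is a per-sample 0/1 (low/high) vector.  Censoring is
    independent exponential with rate ``censor_rate`` (0 disables censoring).
    Returns (time, event) arrays.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    group = np.asarray(expression_group, dtype=int)
    rng = np.random.default_rng(seed)
    hazard = baseline_hazard * np.where(group == 1, hr, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=group.shape)
    else:
        t_cens = np.full(group.shape, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def generate_gene_sets(
    annotation: pd.DataFrame,
    truth: GroundTruth,
    n_sets: int = 10,
    set_size: int = 25,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Small gene-set collection for exercising over-representation analysis.

    One set is deliberately loaded with planted tumor-A DE genes; the rest
    are random draws from the annotation.
    """
    rng = np.random.default_rng(seed)
    symbols = annotation.set_index("gene_id")["symbol"]
    all_ids = list(annotation["gene_id"])
    sets: dict[str, list[str]] = {}
    de_ids = list(truth.de_genes["tumorA"])
    if de_ids:
        picked = list(rng.choice(de_ids, size=min(set_size, len(de_ids)), replace=False))
        sets["PLANTED_DE_SET"] = sorted(symbols[g] for g in picked)
    for i in range(n_sets - len(sets)):
        picked = rng.choice(all_ids, size=min(set_size, len(all_ids)), replace=False)
        sets[f"RANDOM_SET_{i}"] = sorted(symbols[g] for g in picked)
    return sets


# ---------------------------------------------------------------------------
# fixtures


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table.

    Known names: ``table2`` (cohort-vs-cohort DE genes), ``table3``
    (coexpressed lncRNA-mRNA pairs), ``venn_counts`` (DE-set overlap
    counts), ``table3_coords`` (synthetic coordinates for the table3 genes
    encoding the two antisense overlaps).
    """
    files = {
        "table2": "table2.tsv",
        "table3": "table3.tsv",
        "venn_counts": "venn_counts.tsv",
        "table3_coords": "table3_coords_synthetic.tsv",
    }
    if name not in files:
        raise ValueError(f"unknown fixture {name!r}; expected one of {sorted(files)}")
    ref = importlib.resources.files("coexdiff") / "fixtures" / files[name]
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    return df
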