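"""End-to-end orchestration of the differential-coexpression analysis.

Stage order: (optional) simulate -> cohort matching -> filter/TMM/log-CPM ->
differential expression per contrast -> DE selection and overlap summary ->
per-cohort hard-threshold networks on the case-cohort DE gene list ->
difference network -> component census -> lncRNA-mRNA pair extraction with
antisense flags -> pathway over-representation -> median-split survival.
Every stage's outputs, row/edge counts, checksums and warnings land in a run
manifest so that identical configs and seeds give identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import compare, enrich_survival, io as cio, network, preprocess, synthetic

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_pipeline", "report"]

log = logging.getLogger("coexdiff")

CONTRASTS = (("tumorA", "normal"), ("tumorB", "normal"), ("tumorA", "tumorB"))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SyntheticBlock:
    """Synthetic-input settings (used when no count files are given)."""

    n_mrna: int = 900
    n_lncrna: int = 300
    n_antisense_pairs: int = 30
    n_tumor_a: int = 49
    n_tumor_b: int = 49
    n_normal: int = 44
    de_fraction: float = 0.15
    de_log2fc: float = 1.5
    dispersion: float = 0.2
    module_size: int = 10
    module_loading: float = 0.9
    n_shared_modules: int = 1
    n_case_modules: int = 1


@dataclass
class RunConfig:
    """Everything a run needs; round-trips through YAML."""

    out_dir: str = "coexdiff_run"
    seed: int = 0
    counts: str | None = None
    sample_meta: str | None = None
    annotation: str | None = None
    gmt: str | None = None
    synthetic: SyntheticBlock = field(default_factory=SyntheticBlock)
    fc_linear: float = 2.0
    fdr_max: float = 0.01
    min_cpm: float = 1.0
    min_fraction: float = 0.5
    tau_min: float = 0.50
    tau_max: float = 0.99
    tau_step: float = 0.01
    min_sf_r2: float = 0.8
    shared_tau: bool = False
    large_min_single: int = 9
    large_min_diff: int = 6
    survival_alpha: float = 0.05
    max_survival_genes: int = 25

    def __post_init__(self) -> None:
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticBlock(**self.synthetic)
        if not (0 < self.tau_min < self.tau_max < 1):
            raise ValueError("tau grid bounds must satisfy 0 < min < max < 1")
        if not (0 < self.fdr_max <= 1 and self.fc_linear >= 1):
            raise ValueError("invalid DE thresholds")

    def tau_grid(self) -> np.ndarray:
        n = int(round((self.tau_max - self.tau_min) / self.tau_step)) + 1
        return np.round(np.linspace(self.tau_min, self.tau_max, n), 6)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, outputs: dict[str, Path], counts: dict,
                  warnings_seen: list[str]) -> None:
        self.stages.append(
            {
                "stage": name,
                "outputs": {k: _checksum(p) for k, p in outputs.items()},
                "counts": counts,
                "warnings": warnings_seen,
            }
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path


def _checksum(path: Path) -> dict:
    h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return {"path": str(path), "sha256": h}


class _Stage:
    """Context manager recording a stage's outputs, counts and warnings."""

    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name
        self.outputs: dict[str, Path] = {}
        self.counts: dict = {}

    def __enter__(self):
        log.info("stage %s", self.name)
        self._wctx = warnings.catch_warnings(record=True)
        self._wlist = self._wctx.__enter__()
        warnings.simplefilter("always")
        return self

    def __exit__(self, exc_type, exc, tb):
        self._wctx.__exit__(None, None, None)
        msgs = [str(w.message) for w in self._wlist]
        if exc is None:
            self.manifest.add_stage(self.name, self.outputs, self.counts, msgs)
            return False
        self.manifest.stages.append(
            {"stage": self.name, "error": str(exc), "warnings": msgs}
        )
        raise PipelineError(self.name, exc) from exc


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis; returns the manifest (also written to disk).

    On a stage failure the partial manifest is persisted before a
    :class:`PipelineError` naming the stage propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(config), version=__version__, seed=config.seed
    )
    config.to_yaml(out / "config.yaml")
    try:
        _run_stages(config, out, manifest)
    finally:
        manifest.to_json(out / "manifest.json")
    return manifest


def _run_stages(config: RunConfig, out: Path, manifest: RunManifest) -> None:
    rng = np.random.default_rng(config.seed)

    # ------------------------------------------------------------------ input
    with _Stage(manifest, "input") as st:
        if config.counts:
            data = cio.load_count_data(config.counts, config.sample_meta)
            ann = cio.read_annotation(config.annotation)
            truth = None
        else:
            sb = config.synthetic
            ann = synthetic.generate_annotation(
                sb.n_mrna, sb.n_lncrna, sb.n_antisense_pairs,
                seed=int(rng.integers(2**31 - 1)),
            )
            modules = tuple(
                [synthetic.ModuleSpec(sb.module_size, sb.module_loading,
                                      ("tumorA", "tumorB"))] * sb.n_shared_modules
                + [synthetic.ModuleSpec(sb.module_size, sb.module_loading,
                                        ("tumorA",))] * sb.n_case_modules
            )
            params = synthetic.GeneratorParams(
                dispersion=sb.dispersion,
                de_fraction=sb.de_fraction,
                de_log2fc=sb.de_log2fc,
                modules=modules,
                hazard_log2hr=1.0,
            )
            design = synthetic.CohortDesign(sb.n_tumor_a, sb.n_tumor_b, sb.n_normal)
            data, truth = synthetic.generate_counts(
                design, ann, params, seed=int(rng.integers(2**31 - 1))
            )
            st.outputs["counts"] = cio.write_counts_tsv(data.counts, out / "counts.tsv")
            st.outputs["sample_meta"] = cio.write_sample_meta(
                data.sample_meta, out / "sample_meta.tsv"
            )
            st.outputs["annotation"] = cio.write_annotation(ann, out / "annotation.tsv")
        st.counts = {"genes": data.counts.shape[0], "samples": data.counts.shape[1]}

    # ------------------------------------------------------------------ match
    with _Stage(manifest, "match_cohorts") as st:
        meta = data.sample_meta
        a = meta[meta["cohort"] == "tumorA"]
        b = meta[meta["cohort"] == "tumorB"]
        matched_b = preprocess.match_cohorts(a, b, seed=int(rng.integers(2**31 - 1)))
        keep = list(a.index) + matched_b + list(meta.index[meta["cohort"] == "normal"])
        data = synthetic.CountData(
            counts=data.counts[keep], sample_meta=meta.loc[keep]
        )
        st.counts = {"tumorA": len(a), "tumorB_matched": len(matched_b)}

    # ------------------------------------------------------------ normalize
    with _Stage(manifest, "normalize") as st:
        data = preprocess.filter_low_expression(data, config.min_cpm, config.min_fraction)
        if data.counts.empty:
            raise ValueError("no genes survive the expression filter")
        factors = preprocess.tmm_factors(data)
        logcpm = preprocess.log_cpm(data, factors)
        st.outputs["tmm_factors"] = _write_tsv(factors.to_frame(), out / "tmm_factors.tsv")
        st.counts = {"genes_kept": data.counts.shape[0]}

    # ------------------------------------------------------------------- DE
    de_tables: dict[str, pd.DataFrame] = {}
    de_sets: dict[str, dict[str, list[str]]] = {}
    with _Stage(manifest, "differential_expression") as st:
        for case, ref in CONTRASTS:
            key = f"{case}_vs_{ref}"
            de = preprocess.fit_de(logcpm, data.sample_meta, case=case, reference=ref)
            sets = preprocess.select_de(de, ann, config.fc_linear, config.fdr_max)
            de_tables[key] = de
            de_sets[key] = sets
            tbl = de.assign(
                symbol=ann["symbol"].reindex(de.index),
                biotype=ann["biotype"].reindex(de.index),
            )
            st.outputs[key] = _write_tsv(tbl, out / f"de_{key}.tsv")
            st.counts[key] = {k: len(v) for k, v in sets.items()}

    with _Stage(manifest, "overlap_summary") as st:
        overlap = preprocess.overlap_summary(
            de_sets["tumorA_vs_normal"], de_sets["tumorB_vs_normal"]
        )
        st.outputs["overlap"] = _write_tsv(overlap, out / "overlap_summary.tsv")
        st.counts = {k: int(v) for k, v in overlap["shared"].items()}

    # ------------------------------------------------------------- networks
    nets: dict[str, "object"] = {}
    with _Stage(manifest, "coexpression_networks") as st:
        gene_list = sorted(set().union(*de_sets["tumorA_vs_normal"].values()))
        if len(gene_list) < 2:
            raise ValueError("fewer than 2 DE genes; cannot build networks")
        scans = {}
        for cohort in ("tumorA", "tumorB"):
            cols = data.samples_in(cohort)
            sim = network.pearson_similarity(logcpm.loc[gene_list, cols])
            scan = network.threshold_scan(sim, config.tau_grid())
            scans[cohort] = (sim, scan)
            st.outputs[f"scan_{cohort}"] = _write_tsv(
                scan, out / f"threshold_scan_{cohort}.tsv", index=False
            )
        if config.shared_tau:
            pooled = pd.concat([scans[c][1] for c in scans]).groupby("tau", as_index=False).mean()
            tau = network.select_threshold(pooled, config.min_sf_r2).tau
            taus = {c: tau for c in scans}
        else:
            taus = {
                c: network.select_threshold(scans[c][1], config.min_sf_r2).tau
                for c in scans
            }
        for cohort, (sim, _) in scans.items():
            net = network.build_network(sim, taus[cohort], ann)
            nets[cohort] = net
            st.outputs[f"net_{cohort}"] = compare.export_network(
                net, out / f"network_{cohort}.graphml"
            )
            compare.export_network(net, out / f"network_{cohort}.sif")
            st.counts[cohort] = {
                "tau": taus[cohort],
                "nodes": net.number_of_nodes(),
                "edges": net.number_of_edges(),
            }

    with _Stage(manifest, "network_difference") as st:
        diff = compare.network_difference(nets["tumorA"], nets["tumorB"])
        diff_ba = compare.network_difference(nets["tumorB"], nets["tumorA"])
        sym = compare.network_difference(nets["tumorA"], nets["tumorB"], mode="symmetric")
        for name, g in (("diff_a_minus_b", diff), ("diff_b_minus_a", diff_ba),
                        ("symmetric_difference", sym)):
            st.outputs[name] = compare.export_network(g, out / f"{name}.graphml")
            compare.export_network(g, out / f"{name}.sif")
        census = compare.component_census(diff, ann, config.large_min_diff)
        census_a = compare.component_census(nets["tumorA"], ann, config.large_min_single)
        census_b = compare.component_census(nets["tumorB"], ann, config.large_min_single)
        st.counts = {
            "difference": census.as_dict(),
            "tumorA": census_a.as_dict(),
            "tumorB": census_b.as_dict(),
        }

    with _Stage(manifest, "lncrna_mrna_pairs") as st:
        pairs = compare.lncrna_mrna_pairs(diff, ann, de_tables["tumorA_vs_normal"])
        pairs = compare.antisense_pairs(pairs, ann)
        n_mrna, n_up = compare.distinct_mrna_counts(pairs)
        st.outputs["pairs"] = _write_tsv(pairs, out / "lncrna_mrna_pairs.tsv", index=False)
        st.counts = {"pairs": len(pairs), "distinct_mrna": n_mrna, "upregulated_mrna": n_up}

    # ------------------------------------------------------------ enrichment
    with _Stage(manifest, "enrichment") as st:
        if config.gmt:
            sets = enrich_survival.read_gmt(config.gmt)
            symbols = ann["symbol"]
            universe = [symbols[g] for g in data.counts.index
                        if ann.loc[g, "biotype"] == "mRNA"]
            for direction in ("up", "down"):
                query = [symbols[g] for g in de_sets["tumorA_vs_normal"][f"mrna_{direction}"]]
                enr = enrich_survival.hypergeometric_enrichment(
                    query, universe, sets, alpha=config.survival_alpha
                )
                st.outputs[direction] = _write_tsv(
                    enr, out / f"enrichment_{direction}.tsv", index=False
                )
                st.counts[direction] = int(enr["enriched"].sum()) if not enr.empty else 0
        else:
            st.counts = {"skipped": "no GMT provided"}

    # -------------------------------------------------------------- survival
    with _Stage(manifest, "survival") as st:
        tumor = data.samples_in("tumorA", "tumorB")
        meta_t = data.sample_meta.loc[tumor]
        candidates = sorted({n for n in diff.nodes if ann.loc[n, "biotype"] == "mRNA"})
        candidates = candidates[: config.max_survival_genes]
        rows, km_rows = [], []
        for gene in candidates:
            expr = logcpm.loc[gene, tumor]
            try:
                group = enrich_survival.median_split(expr)
            except ValueError:
                continue
            chi2, p_lr = enrich_survival.logrank_test(
                meta_t["time"], meta_t["event"], group
            )
            cox = enrich_survival.cox_hr(meta_t["time"], meta_t["event"], group)
            rows.append(
                {
                    "gene_id": gene,
                    "symbol": ann.loc[gene, "symbol"],
                    "hr": cox.hr,
                    "p_logrank": p_lr,
                    "significant": p_lr < config.survival_alpha,
                    "n_high": cox.n_high,
                    "n_low": cox.n_low,
                }
            )
            for label, mask in (("high", group == 1), ("low", group == 0)):
                km = enrich_survival.km_estimate(
                    meta_t["time"][mask], meta_t["event"][mask]
                )
                km.insert(0, "group", label)
                km.insert(0, "gene_id", gene)
                km_rows.append(km)
        surv = pd.DataFrame(
            rows, columns=["gene_id", "symbol", "hr", "p_logrank", "significant",
                           "n_high", "n_low"],
        )
        st.outputs["survival"] = _write_tsv(surv, out / "survival.tsv", index=False)
        if km_rows:
            st.outputs["km_curves"] = _write_tsv(
                pd.concat(km_rows, ignore_index=True), out / "km_curves.tsv", index=False
            )
        st.counts = {"genes_tested": len(surv),
                     "significant": int(surv["significant"].sum()) if len(surv) else 0}

    if truth is not None:
        (out / "ground_truth.json").write_text(
            json.dumps(
                {
                    "de_genes": truth.de_genes,
                    "modules": truth.modules,
                    "hazard_genes": truth.hazard_genes,
                    "true_edges": {
                        c: sorted(sorted(e) for e in edges)
                        for c, edges in truth.true_edges.items()
                    },
                },
                indent=2,
            )
        )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, sep="\t", index=index)
    return path


# ---------------------------------------------------------------------------
# reporting


def report(run_dir: str | Path) -> str:
    """Human-readable run summary: DE counts, overlaps, census, pairs, survival."""
    run_dir = Path(run_dir)
    mpath = run_dir / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}")
    manifest = json.loads(mpath.read_text())
    stages = {s["stage"]: s for s in manifest["stages"] if "counts" in s}
    missing = [s for s in ("differential_expression", "network_difference",
                           "lncrna_mrna_pairs") if s not in stages]
    if missing:
        raise ValueError(f"missing stage outputs: {missing}")
    lines = [f"coexdiff {manifest['version']} run (seed {manifest['seed']})", ""]

    lines.append("Differential expression (selected genes):")
    lines.append(f"{'contrast':<22}{'biotype':<8}{'total':>6}{'up':>6}{'down':>6}")
    for contrast, cats in stages["differential_expression"]["counts"].items():
        for bt in ("mrna", "lncrna"):
            up, down = cats[f"{bt}_up"], cats[f"{bt}_down"]
            lines.append(f"{contrast:<22}{bt:<8}{up + down:>6}{up:>6}{down:>6}")
    lines.append("")

    if "overlap_summary" in stages:
        opath = run_dir / "overlap_summary.tsv"
        if opath.exists():
            overlap = pd.read_csv(opath, sep="\t", index_col=0)
            lines.append("DE-set overlap between cohorts:")
            for cat, row in overlap.iterrows():
                lines.append(
                    f"  {cat:<12} A={int(row['size_a'])} B={int(row['size_b'])} "
                    f"shared={int(row['shared'])} ({row['pct_a_shared']}% of A)"
                )
            lines.append("")

    census = stages["network_difference"]["counts"]["difference"]
    lines.append(
        "Difference network (case minus comparison): "
        f"{census['n_nodes']} nodes ({census['n_lncrna']} lncRNA / "
        f"{census['n_mrna']} mRNA); {census['pairs']} pairs, {census['trios']} trios, "
        f"{census['quartets']} quartets, {census['quintets']} quintets, "
        f"{len(census['large'])} components >= {census['large_min']} nodes"
    )
    pc = stages["lncrna_mrna_pairs"]["counts"]
    lines.append(
        f"lncRNA-mRNA pairs: {pc['pairs']} edges; {pc['distinct_mrna']} distinct mRNAs, "
        f"{pc['upregulated_mrna']} upregulated"
    )
    if "survival" in stages:
        sc = stages["survival"]["counts"]
        lines.append(
            f"Survival: {sc.get('genes_tested', 0)} genes tested, "
            f"{sc.get('significant', 0)} with log-rank p < alpha"
        )
    return "\n".join(lines) + "\n"
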