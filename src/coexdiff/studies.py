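"""Simulation studies validating the pipeline on data with known structure.

Each function runs a self-contained study at the package's reference
conditions (cohort sizes 49/49/44, NB dispersion 0.2, planted |log2FC| 1.5,
module loading implying within-module correlation around 0.8-0.85) and
returns summary statistics: type-I error calibration of the DE engine and
the log-rank test, power of the DE selection rule, hazard-ratio recovery of
the Cox fit, threshold-selection edge recovery, and end-to-end recovery of a
case-specific planted module through the difference network.
"""

from __future__ import annotations

import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, enrich_survival, network, preprocess, synthetic
from .pipeline import RunConfig, SyntheticBlock, run_pipeline

__all__ = [
    "de_null_calibration",
    "de_power",
    "threshold_recovery",
    "logrank_type1",
    "cox_recovery",
    "null_module_correlation",
    "module_correlation_contrast",
    "fold_change_recovery",
    "e2e_module_recovery",
]

_DESIGN = synthetic.CohortDesign(49, 49, 44)


def _seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def de_null_calibration(n_seeds: int = 50, n_genes: int = 2000, seed: int = 0,
                        alpha: float = 0.05) -> float:
    """Mean fraction of raw p < alpha on fully null data (no planted effects)."""
    ann = synthetic.generate_annotation(n_genes, 0, 0, seed=seed)
    params = synthetic.GeneratorParams(de_fraction=0.0, modules=())
    rates = []
    for s in _seeds(seed, n_seeds):
        data, _ = synthetic.generate_counts(_DESIGN, ann, params, seed=s)
        data = preprocess.filter_low_expression(data)
        logcpm = preprocess.log_cpm(data, preprocess.tmm_factors(data))
        de = preprocess.fit_de(logcpm, data.sample_meta, "tumorA", "normal")
        rates.append(float((de["p_raw"] < alpha).mean()))
    return float(np.mean(rates))


def de_power(n_seeds: int = 100, n_genes: int = 500, seed: int = 0,
             log2fc: float = 1.5) -> float:
    """Fraction of seeds in which a designated planted gene passes the selection rule."""
    ann = synthetic.generate_annotation(n_genes, 0, 0, seed=seed)
    params = synthetic.GeneratorParams(de_fraction=0.1, de_log2fc=log2fc, modules=())
    hits = 0
    for s in _seeds(seed, n_seeds):
        data, truth = synthetic.generate_counts(_DESIGN, ann, params, seed=s)
        target = sorted(truth.de_genes["tumorA"])[0]
        data = preprocess.filter_low_expression(data)
        if target not in data.counts.index:
            continue
        logcpm = preprocess.log_cpm(data, preprocess.tmm_factors(data))
        de = preprocess.fit_de(logcpm, data.sample_meta, "tumorA", "normal")
        sets = preprocess.select_de(de, ann)
        if any(target in genes for genes in sets.values()):
            hits += 1
    return hits / n_seeds


def null_module_correlation(n_seeds: int = 100, n_genes: int = 30, seed: int = 0) -> float:
    """Mean |r| among candidate module genes when nothing is planted."""
    ann = synthetic.generate_annotation(n_genes, 0, 0, seed=seed)
    params = synthetic.GeneratorParams(de_fraction=0.0, modules=())
    vals = []
    for s in _seeds(seed, n_seeds):
        data, _ = synthetic.generate_counts(_DESIGN, ann, params, seed=s)
        cols = data.samples_in("tumorA")
        logcpm = preprocess.log_cpm(data)
        r = network.pearson_similarity(logcpm[cols]).to_numpy()
        iu = np.triu_indices_from(r, k=1)
        vals.append(float(np.abs(r[iu]).mean()))
    return float(np.mean(vals))


def module_correlation_contrast(seed: int = 0, loading: float = 0.9) -> tuple[float, float]:
    """Mean within-module |r| in the module's cohort vs the inactive cohort."""
    ann = synthetic.generate_annotation(40, 10, 0, seed=seed)
    params = synthetic.GeneratorParams(
        de_fraction=0.4, modules=(synthetic.ModuleSpec(10, loading, ("tumorA",)),)
    )
    data, truth = synthetic.generate_counts(_DESIGN, ann, params, seed=seed)
    members = truth.modules[0]["genes"]
    logcpm = preprocess.log_cpm(data)
    out = []
    for cohort in ("tumorA", "tumorB"):
        r = network.pearson_similarity(
            logcpm.loc[members, data.samples_in(cohort)]
        ).to_numpy()
        iu = np.triu_indices_from(r, k=1)
        out.append(float(np.abs(r[iu]).mean()))
    return out[0], out[1]


def fold_change_recovery(seed: int = 0, log2fc: float = 1.0, n_genes: int = 200) -> float:
    """Empirical tumorA/normal depth-corrected mean-count ratio of a planted gene."""
    ann = synthetic.generate_annotation(n_genes, 0, 0, seed=seed)
    params = synthetic.GeneratorParams(de_fraction=0.2, de_log2fc=log2fc, modules=())
    data, truth = synthetic.generate_counts(_DESIGN, ann, params, seed=seed)
    up = [g for g, fc in truth.de_genes["tumorA"].items()
          if fc > 0 and g not in truth.de_genes["tumorB"]]
    c = preprocess.cpm(data.counts)
    ratios = [
        c.loc[g, data.samples_in("tumorA")].mean() / c.loc[g, data.samples_in("normal")].mean()
        for g in up
    ]
    return float(np.mean(ratios))


def threshold_recovery(n_seeds: int = 20, seed: int = 0,
                       loading: float = 1.1) -> list[tuple[float, float]]:
    """Edge precision/recall of the selected threshold on planted blocks.

    Two 10-gene modules over 40 background genes; the default loading puts
    the within-module correlation near 0.85.  Returns one (precision,
    recall) pair per seed, measured against the planted within-module edges.
    """
    out = []
    for s in _seeds(seed, n_seeds):
        ann = synthetic.generate_annotation(50, 10, 0, seed=s)
        params = synthetic.GeneratorParams(
            de_fraction=0.5,
            modules=(
                synthetic.ModuleSpec(10, loading, ("tumorA",)),
                synthetic.ModuleSpec(10, loading, ("tumorA",)),
            ),
        )
        data, truth = synthetic.generate_counts(_DESIGN, ann, params, seed=s)
        logcpm = preprocess.log_cpm(data, preprocess.tmm_factors(data))
        sim = network.pearson_similarity(logcpm[data.samples_in("tumorA")])
        scan = network.threshold_scan(sim)
        tau = network.select_threshold(scan).tau
        net = network.build_network(sim, tau, ann)
        found = {frozenset((u, v)) for u, v in net.edges}
        planted = truth.true_edges["tumorA"]
        tp = len(found & planted)
        precision = tp / len(found) if found else 0.0
        recall = tp / len(planted)
        out.append((precision, recall))
    return out


def logrank_type1(n_reps: int = 1000, n: int = 100, seed: int = 0,
                  alpha: float = 0.05) -> float:
    """Rejection rate of the log-rank test under equal hazards."""
    group = np.repeat([0, 1], n // 2)
    rej = 0
    for s in _seeds(seed, n_reps):
        time, event = synthetic.generate_survival(group, 1.0, 1 / 1500, 1 / 2000, seed=s)
        _, p = enrich_survival.logrank_test(time, event, group)
        rej += p < alpha
    return rej / n_reps


def cox_recovery(n_seeds: int = 200, n_per_arm: int = 500, hr: float = 2.0,
                 seed: int = 0) -> list[float]:
    """Cox hazard-ratio estimates across seeds at a planted hazard ratio."""
    group = np.repeat([0, 1], n_per_arm)
    out = []
    for s in _seeds(seed, n_seeds):
        time, event = synthetic.generate_survival(group, hr, 1 / 1500, 1 / 2000, seed=s)
        res = enrich_survival.cox_hr(time, event, group)
        out.append(res.hr)
    return out


def e2e_module_recovery(n_seeds: int = 10, seed: int = 0,
                        out_root: str | Path | None = None) -> list[float]:
    """Full-pipeline recovery of a case-specific planted module.

    Runs the default synthetic pipeline per seed and returns the fraction of
    the case-only module's within-module edges present in the A-minus-B
    difference network.
    """
    fractions = []
    root = Path(out_root) if out_root else Path(tempfile.mkdtemp(prefix="coexdiff_e2e_"))
    for i, s in enumerate(_seeds(seed, n_seeds)):
        cfg = RunConfig(
            out_dir=str(root / f"run_{i}"), seed=s,
            synthetic=SyntheticBlock(n_mrna=600, n_lncrna=200, n_antisense_pairs=20),
        )
        run_pipeline(cfg)
        import json

        truth = json.loads((root / f"run_{i}" / "ground_truth.json").read_text())
        case_mod = next(m for m in truth["modules"] if list(m["cohorts"]) == ["tumorA"])
        genes = case_mod["genes"]
        planted = {frozenset((a, b)) for i_, a in enumerate(genes) for b in genes[i_ + 1:]}
        diff = compare.read_network(root / f"run_{i}" / "diff_a_minus_b.graphml")
        found = {frozenset((u, v)) for u, v in diff.edges}
        fractions.append(len(found & planted) / len(planted))
    return fractions
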