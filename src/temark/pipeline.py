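"""Stage orchestration: a single config, a declared stage DAG, and a
one-shot synthetic demo that plants effects and checks their recovery.

Stages write under ``outdir/<stage>/`` and leave a ``.done`` marker; a
stage refuses to run until its prerequisites have completed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import accessibility as acc
from . import annotation as ann
from . import enrichment as enr
from . import expression as expr
from . import network as net
from . import signatures as sig
from . import synthetic as syn
from .coverage import read_chrom_sizes, read_coverage

__all__ = ["PipelineConfig", "DependencyError", "run_stage", "run_demo", "STAGES"]

log = logging.getLogger("temark")

#: stage -> prerequisite stages
STAGES: dict[str, list[str]] = {
    "synth": [],
    "annotate": ["synth"],
    "enrich": ["annotate"],
    "network": ["enrich"],
    "express": ["annotate"],
    "atac": ["annotate", "enrich"],
    "signature": ["express"],
}


class DependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline parameters, with the published defaults.

    ``paths`` points at inputs (bundle dir or individual files); every
    numeric default is the value used throughout the analysis: 500-bp
    bins, 300-bp/50-copy catalog filter, >2-fold enrichment calls
    (>1.5 relaxed), BH 0.05 + |fold| > 2 differential expression,
    1.2/0.8 accessibility rule, 10-kb proximity windows, top-200
    signature, 4.5e-9 substitutions/base/year.
    """

    outdir: str = "temark_out"
    paths: dict = field(default_factory=dict)
    bin_bp: int = 500
    min_len: int = 300
    min_copies: int = 50
    enrich_threshold: float = 2.0
    relaxed_threshold: float = 1.5
    pseudocount: float = 0.01
    de_alpha: float = 0.05
    de_fc: float = 2.0
    atac_up: float = 1.2
    atac_down: float = 0.8
    window: int = 10000
    sig_n: int = 200
    age_rate: float = 4.5e-9
    seed: int = 0
    strict_comparator: bool = True
    keep_isolates: bool = False

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_dir(config: PipelineConfig, name: str) -> str:
    return os.path.join(config.outdir, name)


def _done(config: PipelineConfig, name: str) -> str:
    return os.path.join(_stage_dir(config, name), ".done")


def _check_deps(config: PipelineConfig, name: str) -> None:
    if name not in STAGES:
        raise DependencyError(f"unknown stage {name!r}; stages: {sorted(STAGES)}")
    for dep in STAGES[name]:
        if not os.path.exists(_done(config, dep)):
            raise DependencyError(
                f"stage {name!r} requires {dep!r}; run `temark {dep}` (or run_stage) first"
            )


# -- demo fixture definition -------------------------------------------------
# The planted study conditions: a 5-Mb, 2-chromosome toy genome, six TE
# types spanning the four classes with realistic copy numbers (50-150)
# and divergence levels, chromatin marks planted at 2.5-6-fold (one
# bivalent mark pair on the IAP-like type, one 5'-biased promoter mark),
# knockdowns with planted TE upregulation, accessibility gains, and a
# planted top-200 2C signature.  Copy-length ranges are kept compact so
# each mark's elevated territory stays near 1% of the genome and every
# metagene bin averages many copies: the size-matched random background
# then sits close to 1.0 RPKM and planted folds are recovered cleanly.

DEMO_TE_TYPES = [
    syn.TETypeSpec("L1Md_toy", "LINE", 120, (600, 900), 50.0, te_family="L1"),
    syn.TETypeSpec("B1_toy", "SINE", 150, (300, 500), 150.0, te_family="Alu"),
    syn.TETypeSpec("IAP_toy", "LTR", 120, (300, 600), 40.0, te_family="ERVK"),
    syn.TETypeSpec("MERVL-int", "LTR", 100, (400, 700), 80.0, te_family="ERVL"),
    syn.TETypeSpec("MT2_Mm", "LTR", 100, (300, 500), 80.0, te_family="ERVL"),
    syn.TETypeSpec("Charlie_toy", "DNA", 70, (300, 1500), 250.0, te_family="hAT-Charlie"),
]

DEMO_MARK_EFFECTS = {
    "H3K9me3": [syn.PlantedEffect("IAP_toy", "mark_enrichment", 6.0)],
    "H3K27ac": [syn.PlantedEffect("IAP_toy", "mark_enrichment", 4.0)],  # bivalent with H3K9me3
    "H3K4me3": [syn.PlantedEffect("L1Md_toy", "mark_enrichment", 6.0, profile_bias="5prime")],
    "H3K56ac": [syn.PlantedEffect("MERVL-int", "mark_enrichment", 4.0)],
    "5mC": [syn.PlantedEffect("IAP_toy", "mark_enrichment", 2.5)],
    "input": [],
}

DEMO_CM_EFFECTS = {
    "RNF2": [
        syn.PlantedEffect("MERVL-int", "mark_enrichment", 4.0),
        syn.PlantedEffect("MT2_Mm", "mark_enrichment", 4.0),
    ],
    "SETDB1": [syn.PlantedEffect("IAP_toy", "mark_enrichment", 6.0)],
}

DEMO_EXPRESSION_EFFECTS = {
    "shRnf2": [
        syn.PlantedEffect("MERVL-int", "expression_fold", 8.0),
        syn.PlantedEffect("MT2_Mm", "expression_fold", 6.0),
        syn.PlantedEffect("toygene0000", "expression_fold", 6.0),
        syn.PlantedEffect("toygene0001", "expression_fold", 6.0),
    ],
    "shSetdb1": [
        syn.PlantedEffect("IAP_toy", "expression_fold", 8.0),
        syn.PlantedEffect("L1Md_toy", "expression_fold", 6.0),
    ],
}

DEMO_ATAC_EFFECTS = {
    "control": [],
    "shRnf2": [
        syn.PlantedEffect("MERVL-int", "accessibility_fold", 2.0),
        syn.PlantedEffect("MT2_Mm", "accessibility_fold", 2.0),
    ],
    "shSetdb1": [
        syn.PlantedEffect("IAP_toy", "accessibility_fold", 1.5),
        syn.PlantedEffect("B1_toy", "accessibility_fold", 0.6),
    ],
}


# knockdowns scored against the 2C signature: shRnf2 activates the planted
# 2C program 4-fold, shSetdb1 does not (fold 1)
DEMO_SIGNATURE_RESPONDERS = {"shRnf2": 4.0, "shSetdb1": 1.0}


def demo_spec(seed: int) -> syn.SyntheticGenomeSpec:
    return syn.SyntheticGenomeSpec(
        chrom_sizes={"chr1": 2_600_000, "chr2": 2_400_000},
        te_types=DEMO_TE_TYPES,
        seed=seed,
    )


# -- stages ------------------------------------------------------------------

def run_stage(name: str, config: PipelineConfig) -> dict:
    """Run one pipeline stage; outputs land under ``outdir/<name>/``.

    Raises :class:`DependencyError` when a prerequisite stage has not run.
    Returns a small dict of stage facts (also logged).
    """
    _check_deps(config, name)
    stage_dir = _stage_dir(config, name)
    os.makedirs(stage_dir, exist_ok=True)
    runner = _STAGE_RUNNERS[name]
    log.info("running stage %s (seed=%d)", name, config.seed)
    result = runner(config, stage_dir)
    config.to_yaml(os.path.join(stage_dir, "config.yaml"))
    with open(_done(config, name), "w") as fh:
        json.dump({"stage": name, "seed": config.seed}, fh)
    return result


def _bundle_dir(config: PipelineConfig) -> str:
    return config.paths.get("bundle", os.path.join(config.outdir, "synth", "bundle"))


def _stage_synth(config: PipelineConfig, stage_dir: str) -> dict:
    bundle = os.path.join(stage_dir, "bundle")
    manifest = syn.write_fixture_bundle(
        demo_spec(config.seed),
        DEMO_MARK_EFFECTS | DEMO_CM_EFFECTS,
        bundle,
        noise_sd=0.2,
        n_genes=2000,
        expression_effects=DEMO_EXPRESSION_EFFECTS,
        atac_effects=DEMO_ATAC_EFFECTS,
        signature_responders=DEMO_SIGNATURE_RESPONDERS,
    )
    return {"bundle": bundle, "n_files": len(manifest["files"])}


def _load_catalog(config: PipelineConfig) -> ann.TETypeCatalog:
    path = os.path.join(_stage_dir(config, "annotate"), "catalog_filtered.tsv")
    return ann.read_repeatmasker(path, dialect="ucsc_rmsk")


def _stage_annotate(config: PipelineConfig, stage_dir: str) -> dict:
    bundle = _bundle_dir(config)
    catalog = ann.read_repeatmasker(os.path.join(bundle, "te_rmsk.tsv"), dialect="ucsc_rmsk")
    filtered = ann.filter_te_catalog(catalog, min_len=config.min_len, min_copies=config.min_copies)
    filtered.to_rmsk_tsv(os.path.join(stage_dir, "catalog_filtered.tsv"))
    filtered.to_bed(os.path.join(stage_dir, "catalog_filtered.bed"))
    summary = filtered.summary(age_rate=config.age_rate)
    summary.to_csv(os.path.join(stage_dir, "type_summary.tsv"), sep="\t")
    return {
        "n_types_in": len(catalog.type_names),
        "n_types_kept": len(filtered.type_names),
        "n_copies_kept": len(filtered),
    }


def _read_tracks(config: PipelineConfig, prefix: str | None = None) -> dict:
    bundle = _bundle_dir(config)
    sizes = read_chrom_sizes(os.path.join(bundle, "chrom.sizes"))
    tracks = {}
    trackdir = os.path.join(bundle, "tracks")
    for fn in sorted(os.listdir(trackdir)):
        if not fn.endswith(".bedGraph"):
            continue
        name = fn[: -len(".bedGraph")]
        is_atac = name.startswith("ATAC_")
        if (prefix == "ATAC_") != is_atac:
            continue
        if prefix == "ATAC_":
            name = name[len("ATAC_"):]
        tracks[name] = read_coverage(os.path.join(trackdir, fn), sizes, label=name)
    return tracks


def _stage_enrich(config: PipelineConfig, stage_dir: str) -> dict:
    catalog = _load_catalog(config)
    tracks = _read_tracks(config)
    matrix = enr.compute_enrichment_matrix(
        tracks, catalog, bin_bp=config.bin_bp, pseudocount=config.pseudocount, seed=config.seed
    )
    matrix.to_tsv(os.path.join(stage_dir, "enrichment.tsv"))
    calls = enr.call_enriched_marks(
        matrix, threshold=config.enrich_threshold, relaxed=config.relaxed_threshold,
        strict=config.strict_comparator,
    )
    calls.calls.to_csv(os.path.join(stage_dir, "calls.tsv"), sep="\t")
    calls.per_te.to_csv(os.path.join(stage_dir, "per_te_tally.tsv"), sep="\t")
    calls.per_mark.to_csv(os.path.join(stage_dir, "per_mark_tally.tsv"), sep="\t")
    if len(matrix.marks) >= 2:
        order = enr.cluster_enrichment_matrix(matrix, axis="rows")
        pd.Series(order.leaf_order, name="mark").to_csv(
            os.path.join(stage_dir, "cluster_order.tsv"), sep="\t", index=False
        )
    ages = ann.estimate_te_age(catalog, rate=config.age_rate)["age_years"]
    enr.correlate_age_enrichment(matrix, ages).to_csv(
        os.path.join(stage_dir, "age_correlation.tsv"), sep="\t"
    )
    return {"n_marks": len(matrix.marks), "n_types": len(matrix.te_types),
            "n_calls": int(calls.calls.values.sum())}


def _load_enrichment(config: PipelineConfig) -> enr.EnrichmentMatrix:
    path = os.path.join(_stage_dir(config, "enrich"), "enrichment.tsv")
    long = pd.read_csv(path, sep="\t")
    obs = long.pivot(index="mark", columns="te_type", values="obs")
    exp = long.pivot(index="mark", columns="te_type", values="exp")
    return enr.EnrichmentMatrix(obs=obs, exp=exp, pseudocount=config.pseudocount)


def _stage_network(config: PipelineConfig, stage_dir: str) -> dict:
    matrix = _load_enrichment(config)
    cm_marks = [m for m in matrix.marks if m in DEMO_CM_EFFECTS]
    mark_rows = [m for m in matrix.marks if m not in cm_marks]
    mark_m = enr.EnrichmentMatrix(matrix.obs.loc[mark_rows], matrix.exp.loc[mark_rows],
                                  pseudocount=matrix.pseudocount)
    cm_m = None
    if cm_marks:
        cm_m = enr.EnrichmentMatrix(matrix.obs.loc[cm_marks], matrix.exp.loc[cm_marks],
                                    pseudocount=matrix.pseudocount)
    g = net.build_relational_network(
        mark_m, cm_m, threshold=config.enrich_threshold,
        strict=config.strict_comparator, keep_isolates=config.keep_isolates,
    )
    net.export_network(g, os.path.join(stage_dir, "network.tsv"), "tsv_edgelist")
    net.export_network(g, os.path.join(stage_dir, "network.graphml"), "graphml")
    summary = net.network_summary(g)
    summary["degrees"].to_csv(os.path.join(stage_dir, "degrees.tsv"), sep="\t", index=False)
    return {"n_edges": summary["n_edges"], "n_components": summary["n_components"]}


def _load_count_matrix(path: str) -> expr.CountMatrix:
    df = pd.read_csv(path, sep="\t").set_index("feature")
    kind = df.pop("kind")
    return expr.CountMatrix(counts=df, feature_kind=kind)


def _stage_express(config: PipelineConfig, stage_dir: str) -> dict:
    bundle = _bundle_dir(config)
    de_by_kd: dict[str, expr.DEResult] = {}
    for fn in sorted(os.listdir(bundle)):
        if not (fn.startswith("counts_") and fn.endswith(".tsv")):
            continue
        kd = fn[len("counts_"):-len(".tsv")]
        cm = _load_count_matrix(os.path.join(bundle, fn))
        control = [s for s in cm.samples if s.startswith("control_")]
        treat = [s for s in cm.samples if not s.startswith("control_")]
        de = expr.test_differential(cm, control, treat, alpha=config.de_alpha, fc_min=config.de_fc)
        de.table.to_csv(os.path.join(stage_dir, f"de_{kd}.tsv"), sep="\t")
        de_by_kd[kd] = de
        norm = expr.normalize_counts(cm)
        expr.compute_te_read_fraction(cm).rename("te_fraction").to_csv(
            os.path.join(stage_dir, f"te_fraction_{kd}.tsv"), sep="\t"
        )
        norm.counts.to_csv(os.path.join(stage_dir, f"norm_counts_{kd}.tsv"), sep="\t")
    summary = expr.summarize_deregulated_tes(de_by_kd)
    summary["per_knockdown"].to_csv(os.path.join(stage_dir, "te_deregulation.tsv"), sep="\t")
    summary["high_fold_upregulated"].to_csv(
        os.path.join(stage_dir, "te_high_fold.tsv"), sep="\t", index=False
    )
    return {
        "knockdowns": sorted(de_by_kd),
        "n_up_tes": int(summary["per_knockdown"]["n_up"].sum()),
        "n_down_tes": int(summary["per_knockdown"]["n_down"].sum()),
    }


def _stage_atac(config: PipelineConfig, stage_dir: str) -> dict:
    catalog = _load_catalog(config)
    tracks = _read_tracks(config, prefix="ATAC_")
    table = acc.quantify_te_accessibility(tracks, catalog)
    table.to_csv(os.path.join(stage_dir, "accessibility.tsv"), sep="\t")
    calls = acc.call_accessibility_changes(
        table, "control", up=config.atac_up, down=config.atac_down, pseudocount=config.pseudocount
    )
    calls.state.to_csv(os.path.join(stage_dir, "states.tsv"), sep="\t")
    opened = acc.summarize_opened_tes(calls.state)
    mark_calls = pd.read_csv(
        os.path.join(_stage_dir(config, "enrich"), "calls.tsv"), sep="\t", index_col=0
    ).astype(bool)
    fisher = acc.test_mark_enrichment_of_opened(calls.state, mark_calls, alpha=0.01)
    fisher.to_csv(os.path.join(stage_dir, "fisher_marks.tsv"), sep="\t", index=False)
    return {"n_opened_unique": opened["n_unique"], "n_opened_shared": opened["n_shared"]}


def _stage_signature(config: PipelineConfig, stage_dir: str) -> dict:
    bundle = _bundle_dir(config)
    expr_2c = pd.read_csv(os.path.join(bundle, "expr_2c.tsv"), sep="\t", index_col=0)
    signature = sig.build_signature(expr_2c, n=config.sig_n)
    signature.to_tsv(os.path.join(stage_dir, "signature_genes.tsv"))

    results = {}
    reverse_rows = []
    kd_expr_path = os.path.join(bundle, "expr_knockdowns.tsv")
    if os.path.exists(kd_expr_path):
        kd_expr = pd.read_csv(kd_expr_path, sep="\t", index_col=0)
        control = kd_expr["control"]
        for kd in [c for c in kd_expr.columns if c != "control"]:
            s = sig.score_signature(signature, kd_expr[kd], control)
            results[kd] = {"median_log2fc": s.median_log2fc, "mean_log2fc": s.mean_log2fc, "p": s.p}
            # reverse direction: the knockdown's top-upregulated genes measured in 2C
            fold = (kd_expr[kd] + 1.0) / (control + 1.0)
            up = fold.sort_values(ascending=False).index.tolist()
            rev = sig.reverse_signature(up, expr_2c, baseline="esc", n=config.sig_n)
            for stage_name, row in rev.iterrows():
                reverse_rows.append({"knockdown": kd, "stage": stage_name, **row.to_dict()})
    pd.DataFrame(results).T.to_csv(os.path.join(stage_dir, "signature_scores.tsv"), sep="\t")
    pd.DataFrame(reverse_rows).to_csv(os.path.join(stage_dir, "reverse_scores.tsv"), sep="\t", index=False)

    catalog = _load_catalog(config)
    genes = _read_genes_gtf(os.path.join(bundle, "genes.gtf"))
    orientation = sig.annotate_mervl_proximal_genes(genes, catalog, window=config.window)
    orientation.rename_axis("gene_id").to_csv(os.path.join(stage_dir, "mervl_orientation.tsv"), sep="\t")
    counts = orientation.value_counts().to_dict()
    return {"signature_size": len(signature), "orientation_counts": counts}


def _read_genes_gtf(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.strip().split(" ", 1) for kv in parts[8].strip().strip(";").split(";") if kv.strip()
            )
            gene_id = attrs.get("gene_id", '""').strip('"')
            rows.append((gene_id, parts[0], int(parts[3]) - 1, int(parts[4]), parts[6]))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


_STAGE_RUNNERS = {
    "synth": _stage_synth,
    "annotate": _stage_annotate,
    "enrich": _stage_enrich,
    "network": _stage_network,
    "express": _stage_express,
    "atac": _stage_atac,
    "signature": _stage_signature,
}


# -- demo --------------------------------------------------------------------

def run_demo(outdir: str, seed: int = 0) -> dict:
    """Generate the synthetic bundle, run every stage, and report planted vs
    recovered effects.  Returns the report dict (also written as
    ``report.json``)."""
    config = PipelineConfig(outdir=outdir, seed=seed)
    stage_facts = {name: run_stage(name, config) for name in
                   ["synth", "annotate", "enrich", "network", "express", "atac", "signature"]}

    report: dict = {"seed": seed, "stages": stage_facts, "planted_recovery": {}}

    # enrichment recovery: planted log2 folds vs measured, per (mark, type)
    matrix = _load_enrichment(config)
    lf = matrix.log2fold
    enrich_rows = []
    for mark, effects in (DEMO_MARK_EFFECTS | DEMO_CM_EFFECTS).items():
        for eff in effects:
            if eff.target not in lf.columns:
                continue
            measured = float(lf.loc[mark, eff.target])
            planted = float(np.log2(eff.magnitude))
            enrich_rows.append(
                {
                    "mark": mark, "te_type": eff.target,
                    "planted_log2fold": planted, "measured_log2fold": measured,
                    "recovered": bool(abs(measured - planted) <= 0.25),
                }
            )
    report["planted_recovery"]["enrichment"] = enrich_rows

    # expression recovery: planted TE folds called up
    express_dir = _stage_dir(config, "express")
    de_rows = []
    for kd, effects in DEMO_EXPRESSION_EFFECTS.items():
        table = pd.read_csv(os.path.join(express_dir, f"de_{kd}.tsv"), sep="\t", index_col=0)
        for eff in effects:
            if eff.target not in table.index:
                continue
            row = table.loc[eff.target]
            de_rows.append(
                {
                    "knockdown": kd, "feature": eff.target,
                    "planted_fold": eff.magnitude,
                    "measured_log2fc": float(row["log2fc"]),
                    "recovered": bool(row["call"] == "up"),
                }
            )
    report["planted_recovery"]["expression"] = de_rows

    # accessibility recovery
    states = pd.read_csv(os.path.join(_stage_dir(config, "atac"), "states.tsv"),
                         sep="\t", index_col=0)
    atac_rows = []
    for kd, effects in DEMO_ATAC_EFFECTS.items():
        if kd == "control":
            continue
        for eff in effects:
            if eff.target not in states.index:
                continue
            expected = "opened" if eff.magnitude >= 1.2 else ("closed" if eff.magnitude <= 0.8 else "unchanged")
            got = states.loc[eff.target, kd]
            atac_rows.append(
                {"knockdown": kd, "te_type": eff.target, "planted_fold": eff.magnitude,
                 "expected_state": expected, "state": got, "recovered": bool(got == expected)}
            )
    report["planted_recovery"]["accessibility"] = atac_rows

    # signature recovery: planted top set vs built signature
    bundle = _bundle_dir(config)
    with open(os.path.join(bundle, "ground_truth.json")) as fh:
        truth = json.load(fh)
    sig_genes = pd.read_csv(
        os.path.join(_stage_dir(config, "signature"), "signature_genes.tsv"), sep="\t"
    )["gene_id"].tolist()
    planted_sig = set(truth["signature_planted_genes"])
    report["planted_recovery"]["signature"] = {
        "n_planted": len(planted_sig),
        "n_recovered": len(planted_sig & set(sig_genes)),
        "exact": bool(planted_sig == set(sig_genes)),
    }

    # responder detection: planted responders score significant, others not
    scores = pd.read_csv(
        os.path.join(_stage_dir(config, "signature"), "signature_scores.tsv"),
        sep="\t", index_col=0,
    )
    responder_rows = []
    for kd, fold in DEMO_SIGNATURE_RESPONDERS.items():
        if kd not in scores.index:
            continue
        p = float(scores.loc[kd, "p"])
        is_responder = fold > 1.0
        responder_rows.append(
            {"knockdown": kd, "planted_fold": fold, "p": p,
             "recovered": bool((p < 0.05) == is_responder)}
        )
    report["planted_recovery"]["signature_responders"] = responder_rows

    for section in ("enrichment", "expression", "accessibility"):
        rows = report["planted_recovery"][section]
        report["planted_recovery"][f"{section}_recovered"] = (
            f"{sum(r['recovered'] for r in rows)}/{len(rows)}"
        )

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report
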