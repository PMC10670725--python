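"""End-to-end pipeline driver: DE -> overlap -> circuits -> hubs -> clinical.

``run_pipeline`` executes every stage on files in the package's TSV
dialect, writes each intermediate table under the output directory, and
returns a run manifest (library versions, seed, config hash, per-stage
row counts).  Reruns with an identical config and inputs produce
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, asdict, field

import lifelines
import networkx
import numpy
import pandas
import scipy
import yaml

from . import __version__
from . import clinstats, diffexpr, enrich, hubs, integrate, io as rio


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    Threshold defaults are the conventional ones for this analysis: genes
    need |log2FC| >= 1 and adjusted p <= 0.05, miRNAs any nonzero fold
    change at adjusted p <= 0.05, hub tables keep the top 5 (with
    regulator tie expansion), and an inverse correlation is significant
    at p <= 0.05 with r <= -0.3.
    """

    counts_mrna: str = ""
    counts_mirna: str = ""
    samples: str = ""
    proteins: str = ""
    interactions: str = ""
    clinical: str = ""  # optional
    collections: dict = field(default_factory=dict)  # category -> GMT path
    outdir: str = "regcircuit_out"
    gene_lfc: float = 1.0
    mirna_lfc: float = 0.0
    alpha: float = 0.05
    hub_k: int = 5
    corr_p: float = 0.05
    corr_r: float = -0.3
    seed: int = 0
    alias: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


@_stage("de")
def _run_de(config: PipelineConfig, kind: str, out: pathlib.Path):
    path = config.counts_mrna if kind == "mRNA" else config.counts_mirna
    cm = rio.read_counts(path, config.samples, kind)
    sf = diffexpr.estimate_size_factors(cm)
    result = diffexpr.nb_wald_test(cm, sf)
    lfc = config.gene_lfc if kind == "mRNA" else config.mirna_lfc
    sets = diffexpr.call_differential(result, kind, lfc_threshold=lfc, alpha=config.alpha)
    tag = "mrna" if kind == "mRNA" else "mirna"
    rio.write_de_result(result, out / f"de_{tag}.tsv")
    return cm, sf, result, sets


@_stage("integrate")
def _run_integrate(config: PipelineConfig, degs, dems, out: pathlib.Path):
    proteins = integrate.ProteinTable.from_frame(rio.read_proteins(config.proteins))
    raw = rio.read_interactions(config.interactions)
    validated = integrate.filter_validated(
        integrate.normalize_interactions(raw, alias=config.alias or None)
    )
    groups = integrate.build_overlap_groups(degs, proteins)
    circuits = integrate.assemble_circuits(dems, groups, validated)

    member_rows = []
    for name in ("g_down_down", "g_up_up", "g_up_down", "g_down_up"):
        for g in sorted(getattr(groups, name)):
            member_rows.append((name, g))
    rio.write_table(
        pandas.DataFrame(member_rows, columns=["group", "gene"]),
        out / "overlap_groups.tsv",
    )
    summaries = [integrate.circuit_summary(c) for c in circuits]
    rio.write_table(pandas.DataFrame(summaries), out / "circuit_summary.tsv")
    for c in circuits:
        rio.write_table(
            integrate.circuit_to_frame(c), out / f"circuit_{c.circuit_type.lower()}.tsv"
        )
        sif = out / f"circuit_{c.circuit_type.lower()}.sif"
        sif.write_text(integrate.circuit_to_sif(c), encoding="utf-8")
    return proteins, validated, groups, circuits


@_stage("hubs")
def _run_hubs(config: PipelineConfig, circuits, out: pathlib.Path):
    t_tables, r_tables = [], []
    for c in circuits:
        t, r = hubs.hub_tables(c, k=config.hub_k)
        t_tables.append(t)
        r_tables.append(r)
    targets = pandas.concat(t_tables, ignore_index=True)
    regulators = pandas.concat(r_tables, ignore_index=True)
    rio.write_table(targets, out / "hubs_targets.tsv")
    rio.write_table(regulators, out / "hubs_regulators.tsv")
    return targets, regulators


@_stage("enrich")
def _run_enrich(config: PipelineConfig, circuits, background_genes, out: pathlib.Path):
    results = []
    for category, gmt_path in sorted(config.collections.items()):
        coll = enrich.read_gmt(gmt_path, category, background_genes)
        for c in circuits:
            if not c.genes:
                continue
            df = enrich.ora_test(c.genes, coll, alpha=config.alpha)
            df.insert(0, "circuit", c.circuit_type)
            df.insert(0, "category", category)
            results.append(df)
    if results:
        rio.write_table(pandas.concat(results, ignore_index=True), out / "enrichment.tsv")
    return results


@_stage("clinical")
def _run_clinical(config, circuits, targets, regulators, expr_mrna, expr_mirna,
                  condition, out: pathlib.Path):
    clin = rio.read_clinical(config.clinical).set_index("sample")
    tumor_samples = [s for s in expr_mrna.columns if condition[s] == "tumor"]

    hub_rows = [("gene", h) for h in targets["hub"]] + [
        ("mirna", h) for h in regulators["hub"]
    ]
    assoc = []
    for kind, hub in hub_rows:
        expr = expr_mrna if kind == "gene" else expr_mirna
        if hub not in expr.index:
            continue
        vals = expr.loc[hub]
        roc = clinstats.roc_auc(vals.values, condition.loc[vals.index].values)
        tum = vals[tumor_samples]
        stage = clin["t_stage"].reindex(tum.index)
        try:
            ts = clinstats.t_stage_association(tum, stage)
            kw_p = ts["kw_p"]
        except ValueError:
            kw_p = float("nan")
        avail = clin.reindex(tum.index).dropna(subset=["os_time", "os_event"])
        logrank_p = float("nan")
        if len(avail) >= 8:
            low, high = clinstats.quartile_stratify(tum[avail.index])
            cmp_res = clinstats.logrank_test(
                (avail.loc[low, "os_time"], avail.loc[low, "os_event"]),
                (avail.loc[high, "os_time"], avail.loc[high, "os_event"]),
            )
            logrank_p = cmp_res.p_value
        assoc.append((hub, kind, roc.auc, roc.band, kw_p, logrank_p))
    assoc_df = pandas.DataFrame(
        assoc, columns=["hub", "kind", "auc", "auc_band", "kw_p", "logrank_p"]
    )
    rio.write_table(assoc_df, out / "hub_associations.tsv")

    # regulator-target correlations for hub pairs connected in a circuit
    hub_genes = set(targets["hub"])
    hub_mirnas = set(regulators["hub"])
    corr_rows = []
    for c in circuits:
        for m, g in sorted(c.edges):
            if m in hub_mirnas and g in hub_genes and m in expr_mirna.index and g in expr_mrna.index:
                res = clinstats.pearson_inverse(
                    expr_mirna.loc[m, tumor_samples].values,
                    expr_mrna.loc[g, tumor_samples].values,
                )
                inverse = bool(res.p_value <= config.corr_p and res.r <= config.corr_r)
                corr_rows.append((c.circuit_type, m, g, res.r, res.p_value, inverse))
    corr_df = pandas.DataFrame(
        corr_rows, columns=["circuit", "mirna", "gene", "r", "p_value", "inverse_significant"]
    )
    rio.write_table(corr_df, out / "hub_correlations.tsv")
    return assoc_df, corr_df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written as JSON)."""
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    cm_mrna, sf_mrna, res_mrna, degs = _run_de(config, "mRNA", out)
    cm_mirna, sf_mirna, res_mirna, dems = _run_de(config, "miRNA", out)
    proteins, validated, groups, circuits = _run_integrate(config, degs, dems, out)
    targets, regulators = _run_hubs(config, circuits, out)
    if config.collections:
        _run_enrich(config, circuits, set(cm_mrna.feature_ids), out)
    expr_mrna = diffexpr.vst_like_transform(cm_mrna, sf_mrna)
    expr_mirna = diffexpr.vst_like_transform(cm_mirna, sf_mirna)
    if config.clinical:
        _run_clinical(config, circuits, targets, regulators, expr_mrna,
                      expr_mirna, cm_mrna.condition, out)

    manifest = {
        "package": {"regcircuit": __version__},
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
            "lifelines": lifelines.__version__,
        },
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "row_counts": {
            "de_mrna_tested": int(res_mrna["p_value"].notna().sum()),
            "de_mirna_tested": int(res_mirna["p_value"].notna().sum()),
            "deg_up": len(degs.up),
            "deg_down": len(degs.down),
            "dem_up": len(dems.up),
            "dem_down": len(dems.down),
            "validated_interactions": int(len(validated)),
            **{
                f"{c.circuit_type.lower()}_edges": len(c.edges) for c in circuits
            },
            "target_hubs": int(len(targets)),
            "regulator_hubs": int(len(regulators)),
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
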