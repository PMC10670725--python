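"""Synthetic multi-omics study generator with a complete ground-truth audit.

Emulates the four inputs of a tumor/normal miRNA-mRNA-protein integration
study: NB-distributed mRNA and miRNA count matrices with planted log2 fold
changes and sample-specific sequencing depths, a validated-interaction
table with planted true edges plus decoys and "negative"-support rows, a
protein direction table with a controllable concordance fraction, and a
clinical table whose T-stage distribution and exponential survival times
are linked to a designated hazard gene's expression.

Every planted effect is recorded exactly once in a :class:`SyntheticTruth`
so downstream recovery (DE calls, circuit edges, survival associations)
can be tested against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix

_KIND_STREAM = {"mRNA": 1, "miRNA": 2}
_STREAM_PROTEIN = 3
_STREAM_EDGES = 4
_STREAM_CLINICAL = 5

# tumor-stage base probabilities (T1..T4) for an intestinal gastric cancer
# cohort: 11/50/69/44 annotated patients
T_STAGE_BASE = (11 / 174, 50 / 174, 69 / 174, 44 / 174)


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults follow the emulated cohort where it states them (180 tumor /
    18 normal samples; roughly a quarter of genes and miRNAs
    differentially expressed) and desk-scale but realistic choices
    elsewhere; see docs/methods.md.
    """

    n_genes: int = 4000
    n_mirnas: int = 800
    n_tumor: int = 180
    n_normal: int = 18
    frac_de_genes: float = 0.25
    frac_de_mirnas: float = 0.23
    lfc_magnitude: float = 2.0
    dispersion: float = 0.15
    base_mean_range: tuple = (10.0, 1000.0)
    n_true_edges: int = 400
    n_decoy_edges: int = 400
    frac_negative: float = 0.1
    frac_protein_concordant: float = 0.85
    survival_baseline_hazard: float = 0.01  # events per month at mean expression
    hub_hazard_lfc: float = 0.5  # log-hazard per SD of designated-gene expression
    t_stage_shift: float = 4.0  # cumulative-logit shift across expression quantiles
    censor_horizon: float = 120.0  # months, administrative censoring
    dropout_rate: float = 1.0 / 240.0  # independent exponential dropout
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_tumor", "n_normal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_true_edges", "n_decoy_edges"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("frac_de_genes", "frac_de_mirnas", "frac_negative",
                     "frac_protein_concordant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.base_mean_range
        if not (0 < lo <= hi):
            raise ValueError("base_mean_range must be a positive interval")
        if self.survival_baseline_hazard <= 0 or self.dropout_rate < 0:
            raise ValueError("hazard rates must be positive")


@dataclass
class SyntheticTruth:
    """Complete audit of planted effects."""

    true_de_genes: dict = field(default_factory=dict)  # gene -> signed log2FC
    true_de_mirnas: dict = field(default_factory=dict)  # mirna -> signed log2FC
    true_edges: set = field(default_factory=set)  # (mirna, gene)
    protein_directions: dict = field(default_factory=dict)  # gene -> up/down
    hazard_genes: dict = field(default_factory=dict)  # gene -> log-hazard coef

    def de_features(self, kind: str) -> dict:
        return self.true_de_genes if kind == "mRNA" else self.true_de_mirnas


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def _feature_ids(kind: str, n: int) -> list:
    if kind == "mRNA":
        return [f"GENE{i:05d}" for i in range(n)]
    return [f"hsa-mir-{i:04d}" for i in range(n)]


def _sample_ids(config: SimConfig) -> tuple[list, list]:
    tum = [f"T{i:03d}" for i in range(config.n_tumor)]
    nor = [f"N{i:03d}" for i in range(config.n_normal)]
    return tum, nor


def generate_counts(
    config: SimConfig, kind: str, truth: SyntheticTruth | None = None
) -> tuple[CountMatrix, SyntheticTruth]:
    """NB counts with planted tumor-vs-normal log2 fold changes.

    Base means are log-uniform over ``base_mean_range``; DE features get
    the tumor mean multiplied by ``2**(signed lfc_magnitude)`` (tumor is
    the fold-change numerator).  Sample-specific size factors are
    log-uniform in [0.5, 2].  The returned truth records every planted
    effect; pass an existing truth to accumulate across kinds.
    """
    if kind not in _KIND_STREAM:
        raise ValueError(f"kind must be 'mRNA' or 'miRNA', got {kind!r}")
    if config.n_tumor < 2 or config.n_normal < 2:
        raise ValueError("need >=2 tumor and >=2 normal samples for DE")
    truth = truth if truth is not None else SyntheticTruth()
    rng = _rng(config, _KIND_STREAM[kind])

    n = config.n_genes if kind == "mRNA" else config.n_mirnas
    frac_de = config.frac_de_genes if kind == "mRNA" else config.frac_de_mirnas
    ids = _feature_ids(kind, n)
    tum, nor = _sample_ids(config)

    lo, hi = config.base_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    n_de = int(round(frac_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(n)
    lfc[de_idx] = signs * config.lfc_magnitude

    size_factors = np.exp(
        rng.uniform(np.log(0.5), np.log(2.0), size=config.n_tumor + config.n_normal)
    )
    mean_t = base_mean * 2.0**lfc
    mu = np.concatenate(
        [
            np.repeat(mean_t[:, None], config.n_tumor, axis=1),
            np.repeat(base_mean[:, None], config.n_normal, axis=1),
        ],
        axis=1,
    ) * size_factors[None, :]

    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    samples = tum + nor
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=samples),
        condition=pd.Series(["tumor"] * len(tum) + ["normal"] * len(nor),
                            index=samples, name="condition"),
        kind=kind,
    )
    record = truth.de_features(kind)
    record.clear()
    for i in sorted(de_idx):
        record[ids[i]] = float(lfc[i])

    if kind == "mRNA" and config.hub_hazard_lfc != 0.0:
        up_genes = sorted(g for g, v in record.items() if v > 0)
        if up_genes:
            truth.hazard_genes = {up_genes[0]: config.hub_hazard_lfc}
    return cm, truth


def generate_protein_table(
    config: SimConfig, truth: SyntheticTruth
) -> pd.DataFrame:
    """Protein direction table over the planted DE genes.

    Exactly ``round(frac_protein_concordant * n_de)`` genes get a protein
    direction matching their planted mRNA direction; the remainder are
    flipped.  Directions are recorded in ``truth.protein_directions``.
    """
    if not truth.true_de_genes:
        truth.protein_directions = {}
        return pd.DataFrame(columns=["gene", "direction"])
    rng = _rng(config, _STREAM_PROTEIN)
    genes = sorted(truth.true_de_genes)
    n_conc = int(round(config.frac_protein_concordant * len(genes)))
    concordant = set(rng.choice(len(genes), size=n_conc, replace=False))
    truth.protein_directions = {}
    for i, g in enumerate(genes):
        mrna_dir = "up" if truth.true_de_genes[g] > 0 else "down"
        flipped = "down" if mrna_dir == "up" else "up"
        truth.protein_directions[g] = mrna_dir if i in concordant else flipped
    return pd.DataFrame(
        {
            "gene": genes,
            "direction": [truth.protein_directions[g] for g in genes],
        }
    )


def generate_interactions(config: SimConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Validated-interaction table: planted true edges, decoys, negatives.

    True edges connect planted DE miRNAs to planted DE genes (support
    "validated"); decoys connect non-DE miRNAs to non-DE genes so that no
    decoy can enter a circuit; ``round(frac_negative * (true + decoy))``
    extra rows are labelled "negative" support.  Databases cycle through
    three named sources for realism.
    """
    rng = _rng(config, _STREAM_EDGES)
    de_mirnas = sorted(truth.true_de_mirnas)
    de_genes = sorted(truth.true_de_genes)
    all_mirnas = _feature_ids("miRNA", config.n_mirnas)
    all_genes = _feature_ids("mRNA", config.n_genes)
    bg_mirnas = sorted(set(all_mirnas) - set(de_mirnas))
    bg_genes = sorted(set(all_genes) - set(de_genes))

    def _sample_pairs(mirnas, genes, n_pairs, taken):
        total = len(mirnas) * len(genes)
        if n_pairs > total - len(taken):
            raise ValueError("not enough feature pairs to draw edges without replacement")
        pairs = []
        while len(pairs) < n_pairs:
            m = mirnas[rng.integers(len(mirnas))]
            g = genes[rng.integers(len(genes))]
            if (m, g) not in taken:
                taken.add((m, g))
                pairs.append((m, g))
        return pairs

    taken: set = set()
    true_pairs = (
        _sample_pairs(de_mirnas, de_genes, config.n_true_edges, taken)
        if de_mirnas and de_genes
        else []
    )
    decoy_pairs = (
        _sample_pairs(bg_mirnas, bg_genes, config.n_decoy_edges, set())
        if bg_mirnas and bg_genes
        else []
    )
    truth.true_edges = set(true_pairs)

    n_neg = int(round(config.frac_negative * (len(true_pairs) + len(decoy_pairs))))
    neg_pairs = _sample_pairs(all_mirnas, all_genes, n_neg, set(taken) | set(decoy_pairs))

    dbs = ("miRecords", "miRTarBase", "TarBase")
    rows = []
    for i, (m, g) in enumerate(true_pairs + decoy_pairs):
        rows.append((m, g, "validated", dbs[i % 3]))
    for i, (m, g) in enumerate(neg_pairs):
        rows.append((m, g, "Negative", dbs[i % 3]))
    return pd.DataFrame(rows, columns=["mirna", "gene", "support_type", "database"])


def generate_clinical(
    config: SimConfig, counts: CountMatrix, truth: SyntheticTruth
) -> pd.DataFrame:
    """Clinical table for tumor samples: T stage, OS time, event flag.

    T stage (T1..T4) is drawn from cohort base probabilities shifted on
    the cumulative-logit scale by the designated hazard gene's expression
    quantile (higher expression pushes toward higher stage).  Survival is
    exponential with log-hazard = log(baseline) + sum of coefficient x
    standardized log2 expression over hazard genes; censoring combines an
    administrative horizon with independent exponential dropout.
    """
    tumor_samples = list(counts.samples_of("tumor"))
    if not tumor_samples:
        raise ValueError("no tumor samples in count matrix")
    if not truth.hazard_genes:
        if config.hub_hazard_lfc != 0.0:
            raise ValueError(
                "hub_hazard_lfc is nonzero but truth.hazard_genes is empty; "
                "generate mRNA counts with planted up-regulated genes first"
            )
    rng = _rng(config, _STREAM_CLINICAL)
    n = len(tumor_samples)
    expr = np.log2(counts.counts[tumor_samples].values + 1.0)
    ids = list(counts.feature_ids)

    # designated stage gene: the first hazard gene, else the first feature
    stage_gene = next(iter(sorted(truth.hazard_genes)), ids[0])
    gx = expr[ids.index(stage_gene)]
    # expression quantile in [0, 1]
    q = (pd.Series(gx).rank(method="average").values - 0.5) / n

    base_cum = np.cumsum(T_STAGE_BASE)[:3]
    logit = np.log(base_cum / (1 - base_cum))
    shift = config.t_stage_shift * (q - 0.5)
    cum = 1.0 / (1.0 + np.exp(-(logit[None, :] - shift[:, None])))
    u = rng.uniform(size=n)
    stage_idx = (u[:, None] > cum).sum(axis=1)
    t_stage = [f"T{i + 1}" for i in stage_idx]

    log_hazard = np.full(n, np.log(config.survival_baseline_hazard))
    for gene, coef in sorted(truth.hazard_genes.items()):
        gv = expr[ids.index(gene)]
        sd = gv.std()
        z = (gv - gv.mean()) / sd if sd > 0 else np.zeros(n)
        log_hazard += coef * z
    event_time = rng.exponential(1.0 / np.exp(log_hazard))
    dropout = (
        rng.exponential(1.0 / config.dropout_rate, size=n)
        if config.dropout_rate > 0
        else np.full(n, np.inf)
    )
    censor = np.minimum(config.censor_horizon, dropout)
    os_time = np.minimum(event_time, censor)
    os_event = (event_time <= censor).astype(int)

    return pd.DataFrame(
        {
            "sample": tumor_samples,
            "t_stage": t_stage,
            "os_time": np.round(os_time, 4),
            "os_event": os_event,
        }
    )


def simulate_study(config: SimConfig) -> dict:
    """Generate every pipeline input for one synthetic study.

    Returns a dict with keys ``mrna``, ``mirna`` (CountMatrix), ``proteins``,
    ``interactions``, ``clinical`` (DataFrames) and ``truth``.
    """
    truth = SyntheticTruth()
    mrna, truth = generate_counts(config, "mRNA", truth)
    mirna, truth = generate_counts(config, "miRNA", truth)
    proteins = generate_protein_table(config, truth)
    interactions = generate_interactions(config, truth)
    clinical = generate_clinical(config, mrna, truth)
    return {
        "config": config,
        "mrna": mrna,
        "mirna": mirna,
        "proteins": proteins,
        "interactions": interactions,
        "clinical": clinical,
        "truth": truth,
    }


def write_study(study: dict, outdir) -> dict:
    """Write all study tables (and truth sidecars) as TSVs; returns paths."""
    from . import io as rio  # deferred to avoid import cycles

    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    for key in ("mrna", "mirna"):
        cm = study[key]
        df = cm.counts.copy()
        df.insert(0, "feature", df.index)
        paths[f"counts_{key}"] = rio.write_table(df, out / f"counts_{key}.tsv")
    cm = study["mrna"]
    samples = pd.DataFrame({"sample": cm.sample_ids, "condition": cm.condition.values})
    paths["samples"] = rio.write_table(samples, out / "samples.tsv")
    paths["proteins"] = rio.write_table(study["proteins"], out / "proteins.tsv")
    paths["interactions"] = rio.write_table(study["interactions"], out / "interactions.tsv")
    paths["clinical"] = rio.write_table(study["clinical"], out / "clinical.tsv")

    truth = study["truth"]
    tg = pd.DataFrame(sorted(truth.true_de_genes.items()), columns=["feature", "log2fc"])
    tm = pd.DataFrame(sorted(truth.true_de_mirnas.items()), columns=["feature", "log2fc"])
    te = pd.DataFrame(sorted(truth.true_edges), columns=["mirna", "gene"])
    tp = pd.DataFrame(sorted(truth.protein_directions.items()), columns=["gene", "direction"])
    th = pd.DataFrame(sorted(truth.hazard_genes.items()), columns=["gene", "log_hazard"])
    for name, df in (("truth_de_genes", tg), ("truth_de_mirnas", tm),
                     ("truth_edges", te), ("truth_proteins", tp),
                     ("truth_hazard_genes", th)):
        paths[name] = rio.write_table(df, out / f"{name}.tsv")
    return paths


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["base_mean_range"] = list(d["base_mean_range"])
    return d
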