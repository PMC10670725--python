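"""Directional multi-omics overlap and regulatory-circuit assembly.

Genes differential at both the mRNA and protein level are split into four
directional overlap groups (down/down, up/up, up/down, down/up).  Validated
miRNA->gene interactions then connect differentially expressed miRNAs to
three mechanism-typed circuits:

* RRC1 (repressive, degradation): up-miRNAs targeting genes down at both
  mRNA and protein level;
* RRC2 (repressive, translational): up-miRNAs targeting genes up at the
  mRNA but down at the protein level;
* IRC (inductive): down-miRNAs failing to repress genes up at both levels.

Genes down at the mRNA but up at the protein level contradict the
canonical miRNA mechanism and yield no circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .diffexpr import DirectionalSets

CIRCUIT_TYPES = ("RRC1", "RRC2", "IRC")

INTERACTION_COLUMNS = ["mirna", "gene", "support_type", "database"]


@dataclass(frozen=True)
class ProteinTable:
    """Gene -> protein direction map (``up``/``down``), symbols uppercased."""

    directions: dict

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProteinTable":
        if not {"gene", "direction"} <= set(df.columns):
            raise ValueError("protein table needs 'gene' and 'direction' columns")
        genes = df["gene"].astype(str).str.upper()
        dirs = df["direction"].astype(str).str.lower()
        bad = set(dirs.unique()) - {"up", "down"}
        if bad:
            raise ValueError(f"protein direction must be up/down, got {sorted(bad)}")
        out: dict = {}
        for g, d in zip(genes, dirs):
            if g in out and out[g] != d:
                raise ValueError(f"gene {g} has conflicting protein directions")
            out[g] = d
        return cls(directions=out)

    def genes(self, direction: str) -> frozenset:
        return frozenset(g for g, d in self.directions.items() if d == direction)


@dataclass(frozen=True)
class OverlapGroups:
    """The four directional DEG/DEP intersection groups (pairwise disjoint)."""

    g_down_down: frozenset = field(default_factory=frozenset)
    g_up_up: frozenset = field(default_factory=frozenset)
    g_up_down: frozenset = field(default_factory=frozenset)
    g_down_up: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class RegulatoryCircuit:
    """A typed bipartite DEM -> DEG edge set with direction annotations."""

    circuit_type: str
    edges: frozenset  # of (mirna, gene)
    mirna_directions: dict
    gene_mrna_directions: dict
    gene_protein_directions: dict

    def __post_init__(self) -> None:
        if self.circuit_type not in CIRCUIT_TYPES:
            raise ValueError(f"unknown circuit type {self.circuit_type!r}")

    @property
    def mirnas(self) -> frozenset:
        return frozenset(m for m, _ in self.edges)

    @property
    def genes(self) -> frozenset:
        return frozenset(g for _, g in self.edges)


def normalize_interactions(
    df: pd.DataFrame, alias: dict | None = None
) -> pd.DataFrame:
    """Canonicalize an interaction table: miRNA IDs lowercased, gene symbols
    uppercased, optional miRNA alias map applied (e.g. precursor -> mature)."""
    missing = set(INTERACTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    out = df.copy()
    out["mirna"] = out["mirna"].astype(str).str.lower()
    out["gene"] = out["gene"].astype(str).str.upper()
    if (out["mirna"] == "").any() or (out["gene"] == "").any():
        raise ValueError("interaction table has empty IDs")
    if alias:
        alias_lc = {str(k).lower(): str(v).lower() for k, v in alias.items()}
        out["mirna"] = out["mirna"].map(lambda m: alias_lc.get(m, m))
    return out


def filter_validated(interactions: pd.DataFrame) -> pd.DataFrame:
    """Drop rows whose support type mentions "negative" (case-insensitive,
    substring) and deduplicate the surviving (miRNA, gene) pairs."""
    df = normalize_interactions(interactions)
    keep = ~df["support_type"].astype(str).str.lower().str.contains("negative")
    return df[keep].drop_duplicates(subset=["mirna", "gene"]).reset_index(drop=True)


def build_overlap_groups(
    degs: DirectionalSets, proteins: ProteinTable
) -> OverlapGroups:
    """Intersect directional DEG sets with directional protein sets."""
    deg_up = frozenset(str(g).upper() for g in degs.up)
    deg_down = frozenset(str(g).upper() for g in degs.down)
    prot_up = proteins.genes("up")
    prot_down = proteins.genes("down")
    return OverlapGroups(
        g_down_down=deg_down & prot_down,
        g_up_up=deg_up & prot_up,
        g_up_down=deg_up & prot_down,
        g_down_up=deg_down & prot_up,
    )


def _subcircuit(
    ctype: str,
    validated: pd.DataFrame,
    mirna_set: frozenset,
    gene_set: frozenset,
    mirna_dir: str,
    mrna_dir: str,
    protein_dir: str,
) -> RegulatoryCircuit:
    mask = validated["mirna"].isin(mirna_set) & validated["gene"].isin(gene_set)
    edges = frozenset(zip(validated.loc[mask, "mirna"], validated.loc[mask, "gene"]))
    mirnas = {m for m, _ in edges}
    genes = {g for _, g in edges}
    return RegulatoryCircuit(
        circuit_type=ctype,
        edges=edges,
        mirna_directions={m: mirna_dir for m in sorted(mirnas)},
        gene_mrna_directions={g: mrna_dir for g in sorted(genes)},
        gene_protein_directions={g: protein_dir for g in sorted(genes)},
    )


def assemble_circuits(
    dems: DirectionalSets, groups: OverlapGroups, validated: pd.DataFrame
) -> tuple[RegulatoryCircuit, RegulatoryCircuit, RegulatoryCircuit]:
    """Apply the three mechanism rules to the validated edge set.

    Genes in the down-mRNA/up-protein group intentionally produce no
    circuit.  Nodes without a surviving edge are dropped; empty circuits
    are valid outputs.
    """
    dem_up = frozenset(str(m).lower() for m in dems.up)
    dem_down = frozenset(str(m).lower() for m in dems.down)
    rrc1 = _subcircuit("RRC1", validated, dem_up, groups.g_down_down, "up", "down", "down")
    rrc2 = _subcircuit("RRC2", validated, dem_up, groups.g_up_down, "up", "up", "down")
    irc = _subcircuit("IRC", validated, dem_down, groups.g_up_up, "down", "up", "up")
    return rrc1, rrc2, irc


def circuit_summary(circuit: RegulatoryCircuit) -> dict:
    """(edges, regulators, targets) counted over nodes with >=1 edge."""
    return {
        "circuit": circuit.circuit_type,
        "n_edges": len(circuit.edges),
        "n_mirnas": len(circuit.mirnas),
        "n_genes": len(circuit.genes),
    }


def circuit_to_frame(circuit: RegulatoryCircuit) -> pd.DataFrame:
    """Edge list as a sorted DataFrame (mirna, gene, circuit)."""
    rows = sorted(circuit.edges)
    return pd.DataFrame(
        {
            "mirna": [m for m, _ in rows],
            "gene": [g for _, g in rows],
            "circuit": circuit.circuit_type,
        }
    )


def circuit_to_sif(circuit: RegulatoryCircuit) -> str:
    """SIF-dialect edge list (``mirna<TAB>represses<TAB>gene``)."""
    return "".join(f"{m}\trepresses\t{g}\n" for m, g in sorted(circuit.edges))
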