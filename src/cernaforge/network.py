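"""ceRNA network assembly: negative edge sets, MRE-sharing triads, export.

A "negative interaction" is an opposite differential-expression direction
within one contrast: a predicted MRE links a miRNA to a partner (mRNA or
lncRNA), and the pair becomes an edge only when both are significantly DE
with opposite signs. Triads (lncRNA, miRNA, mRNA) join a lncRNA-miRNA edge
and a miRNA-mRNA edge through the shared miRNA, which forces the lncRNA and
mRNA to move together and opposite to the miRNA — the ceRNA sponge pattern.
Networks are per contrast; graphs are exported as Cytoscape SIF plus a node
attribute table and a JSON graph.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .targets import TargetSite


@dataclass(frozen=True)
class CeRNAEdge:
    source_id: str
    target_id: str
    edge_type: str  # {"miRNA-mRNA", "lncRNA-miRNA"}
    mirna_direction: str  # {"up", "down"}
    partner_direction: str
    contrast: str
    evidence: tuple[TargetSite, ...]

    def __post_init__(self) -> None:
        if self.mirna_direction == self.partner_direction:
            raise ValueError(
                f"{self.source_id}->{self.target_id}: edge violates negativity "
                "(miRNA and partner share a DE direction)"
            )

    @property
    def mirna_id(self) -> str:
        return self.source_id if self.edge_type == "miRNA-mRNA" else self.target_id

    @property
    def partner_id(self) -> str:
        return self.target_id if self.edge_type == "miRNA-mRNA" else self.source_id


@dataclass(frozen=True)
class CeRNATriad:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    contrast: str
    shared_mirna_sites: tuple[TargetSite, ...]  # >= 1 on each partner

    def __post_init__(self) -> None:
        on_lnc = [s for s in self.shared_mirna_sites if s.transcript_id == self.lncrna_id]
        on_mrna = [s for s in self.shared_mirna_sites if s.transcript_id == self.mrna_id]
        if not on_lnc or not on_mrna:
            raise ValueError(
                f"triad {self.lncrna_id}/{self.mirna_id}/{self.mrna_id}: "
                "needs >= 1 shared-miRNA site on each partner"
            )

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.lncrna_id, self.mirna_id, self.mrna_id, self.contrast)


def _sites_by_pair(
    sites: Sequence[TargetSite],
) -> dict[tuple[str, str], list[TargetSite]]:
    index: dict[tuple[str, str], list[TargetSite]] = {}
    for s in sites:
        index.setdefault((s.mirna_id, s.transcript_id), []).append(s)
    return index


def _negative_edges(
    de_mirnas: Mapping[str, str],
    de_partners: Mapping[str, str],
    sites: Sequence[TargetSite],
    contrast: str,
    edge_type: str,
) -> list[CeRNAEdge]:
    edges = []
    for (mirna, partner), ev in sorted(_sites_by_pair(sites).items()):
        if mirna not in de_mirnas or partner not in de_partners:
            continue
        if de_mirnas[mirna] == de_partners[partner]:
            continue
        source, target = (
            (mirna, partner) if edge_type == "miRNA-mRNA" else (partner, mirna)
        )
        edges.append(
            CeRNAEdge(
                source,
                target,
                edge_type,
                de_mirnas[mirna],
                de_partners[partner],
                contrast,
                tuple(sorted(ev, key=lambda s: s.start)),
            )
        )
    return edges


def negative_mirna_mrna_edges(
    de_mirnas: Mapping[str, str],
    de_mrnas: Mapping[str, str],
    sites: Sequence[TargetSite],
    contrast: str,
) -> list[CeRNAEdge]:
    """miRNA->mRNA edges: predicted site present AND opposite DE directions.

    ``de_mirnas`` / ``de_mrnas`` map significant features of the contrast to
    their direction ('up'/'down' relative to the H group).
    """
    return _negative_edges(de_mirnas, de_mrnas, sites, contrast, "miRNA-mRNA")


def negative_lncrna_mirna_edges(
    de_lncrnas: Mapping[str, str],
    de_mirnas: Mapping[str, str],
    sites: Sequence[TargetSite],
    contrast: str,
) -> list[CeRNAEdge]:
    """lncRNA->miRNA edges: the lncRNA carries a site and moves opposite."""
    return _negative_edges(de_mirnas, de_lncrnas, sites, contrast, "lncRNA-miRNA")


def assemble_triads(
    mirna_mrna_edges: Sequence[CeRNAEdge],
    lncrna_mirna_edges: Sequence[CeRNAEdge],
) -> list[CeRNATriad]:
    """Join the two edge sets through shared miRNAs into deduplicated triads."""
    contrasts = {e.contrast for e in mirna_mrna_edges} | {
        e.contrast for e in lncrna_mirna_edges
    }
    if len(contrasts) > 1:
        raise ValueError(f"edges mix contrasts: {sorted(contrasts)}")
    by_mirna: dict[str, list[CeRNAEdge]] = {}
    for e in lncrna_mirna_edges:
        by_mirna.setdefault(e.mirna_id, []).append(e)
    triads: dict[tuple, CeRNATriad] = {}
    for mm in mirna_mrna_edges:
        for lm in by_mirna.get(mm.mirna_id, []):
            triad = CeRNATriad(
                lncrna_id=lm.partner_id,
                mirna_id=mm.mirna_id,
                mrna_id=mm.partner_id,
                contrast=mm.contrast,
                shared_mirna_sites=tuple(lm.evidence) + tuple(mm.evidence),
            )
            # sponge sign pattern follows from the two edge negativity checks
            assert lm.partner_direction == mm.partner_direction != mm.mirna_direction
            triads[triad.key] = triad
    return [triads[k] for k in sorted(triads)]


def triads_to_frame(triads: Sequence[CeRNATriad]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": t.lncrna_id,
                "mirna_id": t.mirna_id,
                "mrna_id": t.mrna_id,
                "contrast": t.contrast,
                "n_shared_sites": len(t.shared_mirna_sites),
            }
            for t in triads
        ],
        columns=["lncrna_id", "mirna_id", "mrna_id", "contrast", "n_shared_sites"],
    )


def _node_table(edges: Sequence[CeRNAEdge]) -> pd.DataFrame:
    nodes: dict[str, tuple[str, str]] = {}
    for e in edges:
        if e.edge_type == "miRNA-mRNA":
            nodes[e.source_id] = ("miRNA", e.mirna_direction)
            nodes[e.target_id] = ("mRNA", e.partner_direction)
        else:
            nodes[e.source_id] = ("lncRNA", e.partner_direction)
            nodes[e.target_id] = ("miRNA", e.mirna_direction)
    return pd.DataFrame(
        [
            {"node_id": n, "node_type": t, "direction": d}
            for n, (t, d) in sorted(nodes.items())
        ],
        columns=["node_id", "node_type", "direction"],
    )


def export_network(
    edges: Sequence[CeRNAEdge],
    triads: Sequence[CeRNATriad],
    out_dir: str | Path,
    prefix: str = "network",
) -> dict[str, Path]:
    """Write SIF, node attributes, triad table and a JSON graph; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sif": out / f"{prefix}.sif",
        "nodes": out / f"{prefix}.nodes.tsv",
        "triads": out / f"{prefix}.triads.tsv",
        "graph": out / f"{prefix}.graph.json",
    }
    if not edges:
        warnings.warn(f"{prefix}: empty graph; writing empty files", stacklevel=2)
    sif_lines = [f"{e.source_id}\t{e.edge_type}\t{e.target_id}" for e in edges]
    paths["sif"].write_text("\n".join(sif_lines) + ("\n" if sif_lines else ""))
    _node_table(list(edges)).to_csv(paths["nodes"], sep="\t", index=False)
    triads_to_frame(list(triads)).to_csv(paths["triads"], sep="\t", index=False)

    graph = nx.DiGraph()
    for _, row in _node_table(list(edges)).iterrows():
        graph.add_node(row.node_id, node_type=row.node_type, direction=row.direction)
    for e in edges:
        graph.add_edge(e.source_id, e.target_id, edge_type=e.edge_type)
    payload = nx.node_link_data(graph, edges="edges")
    payload["n_nodes"] = graph.number_of_nodes()
    payload["n_edges"] = graph.number_of_edges()
    paths["graph"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse a SIF edge list back into (source, interaction, target) rows."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        source, interaction, target = line.split("\t")
        rows.append((source, interaction, target))
    return rows


def evaluate_triads(
    recovered: Sequence[CeRNATriad], truth_triads: Sequence
) -> dict[str, float]:
    """Recall/precision of recovered triads against planted ground truth."""
    truth_keys = {
        (t.lncrna_id, t.mirna_id, t.mrna_id, t.contrast) for t in truth_triads
    }
    found = {t.key for t in recovered}
    tp = len(found & truth_keys)
    return {
        "n_truth": len(truth_keys),
        "n_recovered": len(found),
        "n_true_positive": tp,
        "recall": tp / len(truth_keys) if truth_keys else float("nan"),
        "precision": tp / len(found) if found else float("nan"),
    }
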