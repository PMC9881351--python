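"""Readers and writers for the pipeline's plain-text interchange formats.

Expression and atlas matrices are TSV (first column the gene ID, header row
of sample/tissue IDs); PPI edges are TSV ``node_a, node_b, combined_score``
(0-1 or STRING-style 0-1000 scores); predictions are TSV
``source, mirna, gene``; ncRNA interactions are TSV; survival is CSV
``sample, time, event``; genotypes are CSV ``subject, group, snp, genotype``;
gene sets are GMT. Networks export as SIF, GraphML and an edges CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .cerna import NcRnaInteraction, TargetPredictionSet
from .dge import ExpressionDataset
from .tissue import TissueAtlas

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_atlas_tsv", "write_atlas_tsv", "read_tissue_mapping",
    "read_edge_list", "write_edge_list",
    "read_predictions", "write_predictions",
    "read_interactions", "write_interactions",
    "read_survival", "write_survival",
    "read_genotype_calls", "write_genotype_calls",
    "read_gmt", "write_gmt",
    "write_sif", "write_graphml", "write_edges_csv",
    "write_json", "read_json",
]


def read_expression_tsv(
    matrix_path: str | Path, groups: dict[str, str] | str | Path, name: str = ""
) -> ExpressionDataset:
    """Read a genes x samples TSV plus sample -> group labels (mapping or a
    two-column CSV ``sample,group``)."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if isinstance(groups, (str, Path)):
        gdf = pd.read_csv(groups)
        groups = dict(zip(gdf["sample"], gdf["group"]))
    return ExpressionDataset(values, pd.Series(groups), name=name or Path(matrix_path).stem)


def write_expression_tsv(
    ds: ExpressionDataset, matrix_path: str | Path, groups_path: str | Path | None = None
) -> None:
    ds.values.to_csv(matrix_path, sep="\t", index_label="gene")
    if groups_path is not None:
        ds.groups.rename("group").to_frame().reset_index(names="sample").to_csv(
            groups_path, index=False
        )


def read_atlas_tsv(path: str | Path, mapping: dict[str, str]) -> TissueAtlas:
    return TissueAtlas(pd.read_csv(path, sep="\t", index_col=0), mapping)


def write_atlas_tsv(atlas: TissueAtlas, path: str | Path) -> None:
    atlas.values.to_csv(path, sep="\t", index_label="gene")


def read_tissue_mapping(path: str | Path) -> dict[str, str]:
    """Tissue -> organ-system map from a two-column CSV or a YAML mapping."""
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict):
            raise ValueError(f"{path}: YAML mapping expected")
        return {str(k): str(v) for k, v in mapping.items()}
    df = pd.read_csv(path)
    return dict(zip(df["tissue"].astype(str), df["system"].astype(str)))


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Edge-list TSV with a line-numbered error on malformed rows."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["node_a", "node_b", "combined_score"]:
            raise ValueError(
                f"{path}:1: expected header node_a/node_b/combined_score, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unparseable combined score {parts[2]!r}"
                ) from exc
            rows.append((parts[0], parts[1], score))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "combined_score"])


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> list[TargetPredictionSet]:
    df = pd.read_csv(path, sep="\t")
    return [
        TargetPredictionSet(source, set(zip(sub["mirna"], sub["gene"])))
        for source, sub in df.groupby("source")
    ]


def write_predictions(sets: list[TargetPredictionSet], path: str | Path) -> None:
    rows = [
        (ps.source, m, g) for ps in sets for m, g in sorted(ps.pairs)
    ]
    pd.DataFrame(rows, columns=["source", "mirna", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_interactions(path: str | Path) -> list[NcRnaInteraction]:
    df = pd.read_csv(path, sep="\t")
    return [
        NcRnaInteraction(
            ncrna=r["ncrna"], kind=r["kind"], mirna=r["mirna"],
            clip_support=int(r["clip_support"]), samples=int(r.get("samples", 0)),
            score=float(r.get("score", 0.0)), transcript=str(r.get("transcript", "")),
        )
        for _, r in df.iterrows()
    ]


def write_interactions(interactions: list[NcRnaInteraction], path: str | Path) -> None:
    pd.DataFrame([vars(i) for i in interactions]).to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival CSV missing columns {sorted(missing)}")
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_genotype_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject", "group", "snp", "genotype"} - set(df.columns)
    if missing:
        raise ValueError(f"genotype CSV missing columns {sorted(missing)}")
    return df


def write_genotype_calls(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")


def write_sif(g: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Simple interaction format readable by Cytoscape-like viewers."""
    with open(path, "w") as fh:
        for a, b, data in g.edges(data=True):
            fh.write(f"{a}\t{data.get('edge_type', relation)}\t{b}\n")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)


def write_edges_csv(g: nx.Graph, path: str | Path) -> None:
    rows = [
        {"node_a": a, "node_b": b, **data} for a, b, data in g.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
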