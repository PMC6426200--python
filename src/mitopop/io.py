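"""Readers and writers for the package's external formats.

FASTA for sequences (via Biopython), TSV with header for sample tables,
frequency tables and distance matrices, JSON for the reduced haplogroup tree
and for networks, GML for network export, and a JSON run manifest.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
import pandas as pd
import yaml
from Bio import SeqIO

from .model import (
    MT_LENGTH,
    ISLAND_CODES,
    Motif,
    PhyloTree,
    ReferenceSegment,
    SampleRecord,
    TreeNode,
    FrequencyTable,
    parse_variant_token,
)

PathLike = Union[str, Path]

_IUPAC = set("ACGTURYSWKMBDHVN-")


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence), normalizing to uppercase DNA.

    Ids are the first whitespace-delimited token of the header. U is mapped
    to T. Duplicate ids, non-IUPAC characters and empty files are rejected
    with the offending record named.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _IUPAC
        if bad:
            raise ValueError(
                f"record {rec.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_reference(path: PathLike, start: int = 1,
                   name: Optional[str] = None) -> ReferenceSegment:
    """Load a reference segment from a single-record FASTA.

    ``start`` is the 1-based reference coordinate of the first base; a
    header suffix like ``:16000-16400`` overrides it when present.
    """
    records = read_fasta(path)
    if len(records) != 1:
        raise ValueError(f"reference FASTA must hold one record, got {len(records)}")
    rec_id, seq = records[0]
    m = re.search(r":(\d+)-(\d+)$", rec_id)
    if m:
        start = int(m.group(1))
    return ReferenceSegment(name or rec_id, seq, start, start + len(seq) - 1)


_REQUIRED_COLUMNS = ("sample_id", "island", "period")


def read_sample_table(path: PathLike,
                      max_position: int = MT_LENGTH) -> list[SampleRecord]:
    """Read a TSV sample table into SampleRecords.

    Required columns: sample_id, island, period. Optional: site, haplogroup,
    motif (whitespace-separated variant tokens), multiplicity. Unknown island
    codes are mapped to "other" with a warning attribute left to the caller;
    unparseable motifs raise with the 1-based data row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing required columns: {missing}")
    out: list[SampleRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        motif: Optional[Motif] = None
        if "motif" in df.columns:
            raw_motif = getattr(row, "motif", "")
            try:
                motif = (
                    Motif.parse(raw_motif, max_position=max_position)
                    if raw_motif.strip()
                    else Motif()
                )
            except ValueError as exc:
                raise ValueError(f"row {i}: {exc}") from exc
        hg = getattr(row, "haplogroup", "") or None
        mult = int(getattr(row, "multiplicity", "") or 1)
        island = row.island if row.island in ISLAND_CODES else "other"
        out.append(
            SampleRecord(
                sample_id=row.sample_id,
                island=island,
                period=row.period,
                site=getattr(row, "site", ""),
                haplogroup=hg,
                motif=motif,
                multiplicity=mult,
            )
        )
    ids = [s.sample_id for s in out]
    dupes = {x for x in ids if ids.count(x) > 1}
    if dupes:
        raise ValueError(f"duplicate sample ids: {sorted(dupes)}")
    return out


def write_sample_table(samples: Sequence[SampleRecord], path: PathLike) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "island": s.island,
            "period": s.period,
            "site": s.site,
            "haplogroup": s.haplogroup or "",
            "motif": str(s.motif) if s.motif is not None else "",
            "multiplicity": s.multiplicity,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_frequency_table(path: PathLike) -> FrequencyTable:
    """Read a TSV with categories as rows and populations as columns.

    The first column holds category labels (header cell is ignored); the
    stored orientation is transposed so populations index the table.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FrequencyTable(df.T)


def write_frequency_table(table: FrequencyTable, path: PathLike) -> None:
    table.counts.T.to_csv(path, sep="\t", index_label="category")


def read_phylotree(path: PathLike) -> PhyloTree:
    """Load the reduced haplogroup tree from JSON.

    Schema: {"nodes": {label: {"parent": label|null, "variants": [tokens]}}}.
    """
    with open(path) as fh:
        doc = json.load(fh)
    nodes = {}
    for label, spec in doc["nodes"].items():
        variants = []
        for tok in spec.get("variants", []):
            variants.extend(parse_variant_token(tok))
        nodes[label] = TreeNode(parent=spec.get("parent"), variants=tuple(variants))
    return PhyloTree(nodes)


def write_phylotree(tree: PhyloTree, path: PathLike) -> None:
    doc = {
        "nodes": {
            label: {
                "parent": node.parent,
                "variants": [str(v) for v in node.variants],
            }
            for label, node in tree.nodes.items()
        }
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# -- haplotype network serialization ----------------------------------------

def _network_to_graph(net) -> nx.Graph:
    from .network import HaplotypeNetwork  # local import to avoid cycle

    if isinstance(net, HaplotypeNetwork):
        return net.graph
    return net


def write_network(net, path: PathLike, format: str = "json") -> None:
    """Serialize a haplotype network losslessly to JSON or GML.

    Nodes keep their motif text, sampled-vs-median flag and multiplicity;
    edges keep their length in mutation steps.
    """
    graph = _network_to_graph(net)
    epsilon = getattr(net, "epsilon", 0)
    if format == "json":
        doc = {
            "epsilon": epsilon,
            "nodes": [
                {
                    "motif": key,
                    "sampled": bool(attrs["sampled"]),
                    "multiplicity": int(attrs.get("multiplicity", 0)),
                }
                for key, attrs in graph.nodes(data=True)
            ],
            "edges": [
                {"u": u, "v": v, "length": int(attrs["length"])}
                for u, v, attrs in graph.edges(data=True)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    elif format == "gml":
        g = nx.Graph(epsilon=epsilon)
        for key, attrs in graph.nodes(data=True):
            g.add_node(key, sampled=int(attrs["sampled"]),
                       multiplicity=int(attrs.get("multiplicity", 0)))
        for u, v, attrs in graph.edges(data=True):
            g.add_edge(u, v, length=int(attrs["length"]))
        nx.write_gml(g, str(path))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: PathLike, format: str = "json"):
    from .network import HaplotypeNetwork

    graph = nx.Graph()
    if format == "json":
        with open(path) as fh:
            doc = json.load(fh)
        epsilon = doc.get("epsilon", 0)
        for node in doc["nodes"]:
            graph.add_node(
                node["motif"],
                motif=Motif.parse(node["motif"]) if node["motif"] else Motif(),
                sampled=bool(node["sampled"]),
                multiplicity=int(node["multiplicity"]),
            )
        for edge in doc["edges"]:
            graph.add_edge(edge["u"], edge["v"], length=int(edge["length"]))
    elif format == "gml":
        g = nx.read_gml(str(path))
        epsilon = g.graph.get("epsilon", 0)
        for key, attrs in g.nodes(data=True):
            graph.add_node(
                key,
                motif=Motif.parse(key) if key else Motif(),
                sampled=bool(attrs["sampled"]),
                multiplicity=int(attrs["multiplicity"]),
            )
        for u, v, attrs in g.edges(data=True):
            graph.add_edge(u, v, length=int(attrs["length"]))
    else:
        raise ValueError(f"unknown network format {format!r}")
    return HaplotypeNetwork(graph, epsilon=epsilon)


def read_distance_matrix(path: PathLike):
    from .distance import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))


def write_distance_matrix(dm, path: PathLike) -> None:
    pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels).to_csv(
        path, sep="\t", index_label="population"
    )


def read_config(path: PathLike) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a mapping")
    return doc


def write_manifest(manifest: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
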