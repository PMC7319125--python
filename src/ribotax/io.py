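"""Readers and writers: FASTA sequences, TSV tables, newick trees.

FASTA parsing goes through Biopython; trees are scikit-bio ``TreeNode``
objects read/written as newick with branch lengths and integer-percent
support values as internal node labels.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

from .records import SequenceRecord, Site, normalize_nucleotides


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into sequence records (provenance joined later).

    Sequences are normalized to upper case (ambiguity codes -> N). Order is
    preserved. An empty file or a duplicated header is an error.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA header: {entry.id!r}")
        seen.add(entry.id)
        records.append(
            SequenceRecord(
                sequence_id=entry.id,
                specimen_id="",
                site_id="",
                nucleotides=normalize_nucleotides(str(entry.seq), entry.id),
            )
        )
    if not records:
        raise ValueError(f"FASTA file {path} contains no sequences")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f">{r.sequence_id}\n")
            for i in range(0, len(r.nucleotides), width):
                fh.write(r.nucleotides[i : i + width] + "\n")


def read_metadata(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read the sequence metadata TSV: sequence_id, specimen_id, site_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sequence_id", "specimen_id", "site_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing column(s): {missing}")
    dup = df["sequence_id"][df["sequence_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicated sequence_id in metadata: {sorted(dup)}")
    out: dict[str, tuple[str, str]] = {}
    for idx, row in df.iterrows():
        for col in required:
            val = row[col]
            if not isinstance(val, str) or not val.strip():
                raise ValueError(f"metadata row {idx}: blank {col}")
        out[row["sequence_id"]] = (row["specimen_id"], row["site_id"])
    return out


def write_metadata(metadata: dict[str, tuple[str, str]], path: str | Path) -> None:
    rows = [
        {"sequence_id": s, "specimen_id": sp, "site_id": si}
        for s, (sp, si) in metadata.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> dict[str, Site]:
    """Read the site table TSV: site_id, name, latitude, longitude."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "name": str})
    required = ["site_id", "name", "latitude", "longitude"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing column(s): {missing}")
    if df["site_id"].duplicated().any():
        raise ValueError("duplicated site_id in site table")
    sites: dict[str, Site] = {}
    for _, row in df.iterrows():
        lat, lon = float(row["latitude"]), float(row["longitude"])
        if math.isnan(lat) or math.isnan(lon):
            raise ValueError(f"site {row['site_id']!r}: missing coordinates")
        sites[row["site_id"]] = Site(row["site_id"], row["name"], lat, lon)
    return sites


def write_sites(sites: dict[str, Site], path: str | Path) -> None:
    rows = [
        {"site_id": s.site_id, "name": s.name, "latitude": s.latitude, "longitude": s.longitude}
        for s in sites.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_newick(source: str | Path) -> TreeNode:
    """Read a newick tree (file path or literal newick string)."""
    text = str(source)
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    elif "(" not in text and ";" not in text:  # a path, not literal newick
        text = Path(source).read_text(encoding="utf-8")
    try:
        tree = TreeNode.read(_io.StringIO(text), convert_underscores=False)
    except Exception as exc:  # skbio raises its own parse errors
        raise ValueError(f"newick parse error: {exc}") from exc
    return tree


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize a tree to newick; branch lengths always written.

    Support values (``node.support``) are emitted as internal node labels,
    rounded to integer percent.
    """
    tree = tree.copy()
    for node in tree.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is not None:
            node.name = str(int(round(support)))
        if node.length is None:
            node.length = 0.0
    for tip in tree.tips():
        if tip.length is None:
            tip.length = 0.0
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue().strip()
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text
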