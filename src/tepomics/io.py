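"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: FASTA (mature miRNA reference; Biopython), a flank table TSV
(name, flank5, flank3), collapsed reads TSV (sequence, count), count-matrix
TSV (features in rows, samples in columns), sample sheet TSV, GMT gene-set
collections, edge-list TSV and GraphML for networks, and JSON for the
synthetic ground truth.  TSV outputs may carry ``#``-prefixed provenance
header lines (config hash, seed); all readers skip them.  Universal
newlines, so CRLF input is accepted everywhere.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrich import GeneSet
from .isomir import MatureMiRNA
from .normfilter import CountMatrix
from .xnet import Edge, OmicsNetwork


def _write_header(fh, provenance: dict | None) -> None:
    if provenance:
        for key in sorted(provenance):
            fh.write(f"# {key}={provenance[key]}\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    """TSV reader skipping leading ``#`` provenance lines only.

    pandas' ``comment='#'`` would also truncate data lines mid-field, and
    isomiR feature ids legitimately contain ``#`` (the nta#X classes).
    """
    with open(path) as fh:
        lines = fh.readlines()
    n_skip = 0
    for line in lines:
        if line.startswith("#"):
            n_skip += 1
        else:
            break
    return pd.read_csv(_io.StringIO("".join(lines[n_skip:])), sep="\t", **kwargs)


# -- reference ---------------------------------------------------------------

def write_reference(reference: list[MatureMiRNA], fasta_path, flank_path, provenance=None) -> None:
    records = [SeqRecord(Seq(r.mature_seq), id=r.name, description="") for r in reference]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    with open(flank_path, "w") as fh:
        _write_header(fh, provenance)
        fh.write("name\tflank5\tflank3\n")
        for r in reference:
            fh.write(f"{r.name}\t{r.flank5}\t{r.flank3}\n")


def read_reference(fasta_path, flank_path) -> list[MatureMiRNA]:
    seqs = {rec.id: str(rec.seq).upper().replace("T", "U") for rec in SeqIO.parse(fasta_path, "fasta")}
    flanks = read_tsv(flank_path, dtype=str).set_index("name")
    out = []
    for name, seq in seqs.items():
        if name not in flanks.index:
            raise ValueError(f"no flank entry for {name!r}")
        row = flanks.loc[name]
        out.append(MatureMiRNA(name, seq, str(row["flank5"]), str(row["flank3"])))
    return out


# -- reads -------------------------------------------------------------------

def write_collapsed_reads(reads: list[str], path, provenance=None) -> None:
    counts: dict[str, int] = {}
    for r in reads:
        counts[r] = counts.get(r, 0) + 1
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        fh.write("sequence\tcount\n")
        for seq in sorted(counts):
            fh.write(f"{seq}\t{counts[seq]}\n")


def read_collapsed_reads(path) -> list[str]:
    df = read_tsv(path, dtype={"sequence": str, "count": int})
    out: list[str] = []
    for _, row in df.iterrows():
        out.extend([row["sequence"]] * int(row["count"]))
    return out


# -- matrices and sample sheets ---------------------------------------------

def write_count_matrix(m: CountMatrix, path, provenance=None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        m.counts.to_csv(fh, sep="\t", index_label="feature")


def read_count_matrix(path, layer: str, groups: pd.Series) -> CountMatrix:
    df = read_tsv(path, index_col="feature")
    return CountMatrix(layer, df, groups)


def write_matrix(df: pd.DataFrame, path, provenance=None, index_label="feature") -> None:
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        df.to_csv(fh, sep="\t", index_label=index_label)


def write_sample_sheet(groups: pd.Series, path, layers: dict[str, list[str]] | None = None, provenance=None) -> None:
    """Sample sheet TSV: sample, group, comma-separated layers present."""
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        fh.write("sample\tgroup\tlayers\n")
        for s, g in groups.items():
            present = ",".join(
                sorted(l for l, ss in (layers or {}).items() if s in set(ss))
            ) if layers else ""
            fh.write(f"{s}\t{g}\t{present}\n")


def read_sample_sheet(path) -> pd.Series:
    df = read_tsv(path, dtype=str)
    return pd.Series(df["group"].to_numpy(), index=df["sample"].to_numpy())


# -- gene sets ---------------------------------------------------------------

def read_gmt(path, collection: str = "") -> list[GeneSet]:
    """Standard GMT: name <tab> description <tab> member...; one set per line."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno} (need >= 3 fields)")
            name, _desc, *members = parts
            members = [m for m in members if m]
            sets.append(GeneSet(name, frozenset(members), collection))
    return sets


def write_gmt(sets: dict[str, list[str]] | list[GeneSet], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        if isinstance(sets, dict):
            items = [(name, sorted(members)) for name, members in sets.items()]
        else:
            items = [(gs.name, sorted(gs.members)) for gs in sets]
        for name, members in items:
            fh.write("\t".join([name, description, *members]) + "\n")


# -- networks ----------------------------------------------------------------

def write_edges(net: OmicsNetwork, path, provenance=None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        net.to_frame().to_csv(fh, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    return read_tsv(path)


def write_graphml(net: OmicsNetwork, path) -> None:
    nx.write_graphml(net.to_networkx(), path)


# -- json helpers ------------------------------------------------------------

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
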