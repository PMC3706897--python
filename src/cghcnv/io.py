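"""File interchange: FASTA via Biopython, tables as TSV, design as BED/JSON.

Coordinates in all files are 0-based half-open. Missing values are left
absent (empty field), never written as sentinel numbers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(contigs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fragments_bed(fragments: pd.DataFrame, path) -> None:
    bed = fragments[["contig", "start", "end", "fragment_id"]]
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_fragments_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "start", "end", "fragment_id"]
    )
    return bed[["fragment_id", "contig", "start", "end"]]


def write_fragments_tsv(fragments: pd.DataFrame, path) -> None:
    out = fragments.copy()
    out["probe_ids"] = out["probe_ids"].map(",".join)
    out.to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t")
    out["probe_ids"] = out["probe_ids"].str.split(",")
    return out


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
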