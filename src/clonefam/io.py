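"""Tabular and sequence I/O.

Repertoires are exchanged as AIRR-rearrangement-style tables: one row per
sequence with columns ``sequence_id``, ``sequence``, ``v_call``, ``d_call``,
``j_call``, ``junction``, ``junction_start``, ``junction_end`` and
``clone_id``.  In-memory these are pandas DataFrames; on disk they are
tab-separated text.  Sequences alone travel as FASTA with the record id set
to the sequence_id.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import Repertoire

REARRANGEMENT_COLUMNS = [
    "sequence_id", "sequence", "v_call", "d_call", "j_call",
    "junction", "junction_start", "junction_end", "clone_id",
]


def repertoire_to_records(rep: Repertoire) -> pd.DataFrame:
    """Flatten a simulated repertoire into a ground-truth rearrangement table."""
    rows = []
    for fam in rep.families:
        ev = fam.event
        for tip_id, seq in fam.tip_sequences.items():
            rows.append({
                "sequence_id": tip_id,
                "sequence": seq,
                "v_call": ev.v_name,
                "d_call": ev.d_name,
                "j_call": ev.j_name,
                "junction": seq[ev.junction_start:ev.junction_end],
                "junction_start": ev.junction_start,
                "junction_end": ev.junction_end,
                "clone_id": fam.family_id,
            })
    return pd.DataFrame(rows, columns=REARRANGEMENT_COLUMNS)


def write_rearrangement_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_rearrangement_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "clone_id": str})


def write_fasta(df: pd.DataFrame, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row.sequence), id=str(row.sequence_id), description="")
        for row in df.itertuples()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> pd.DataFrame:
    rows = [
        {"sequence_id": rec.id, "sequence": str(rec.seq).upper()}
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return pd.DataFrame(rows, columns=["sequence_id", "sequence"])
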