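"""Plain-text table formats: envelope tables, uptake tables, maps, FASTA.

All tables are CSV with a one-line ``#`` header carrying the schema
version, seed and config hash so any output can be traced to its run.
Coordinates are 1-based inclusive; times in seconds with the sentinels
``undeut`` and ``FD``; masses in Da.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO

from .spectra import IsotopicEnvelope

__all__ = [
    "SCHEMA_VERSION",
    "envelopes_to_frame",
    "frame_to_envelopes",
    "write_table",
    "read_table",
    "read_fasta",
    "read_chain_map",
]

SCHEMA_VERSION = 1

ENVELOPE_COLUMNS = [
    "dataset_id", "state_id", "peptide_id", "chain", "start", "end",
    "sequence", "charge", "time_s", "mz", "intensity",
]


def envelopes_to_frame(envelopes: list[IsotopicEnvelope]) -> pd.DataFrame:
    """One row per stick peak."""
    rows = []
    for env in envelopes:
        for mz, inten in zip(env.mz, env.intensity):
            rows.append(
                (
                    env.dataset_id, env.state_id, env.peptide_id, env.chain,
                    env.start, env.end, env.sequence, env.charge,
                    str(env.time_s), mz, inten,
                )
            )
    return pd.DataFrame(rows, columns=ENVELOPE_COLUMNS)


def frame_to_envelopes(df: pd.DataFrame) -> list[IsotopicEnvelope]:
    missing = set(ENVELOPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"envelope table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("envelope table is empty")
    envelopes = []
    keys = ["dataset_id", "state_id", "peptide_id", "charge", "time_s"]
    for key, grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("mz")
        first = grp.iloc[0]
        t = first["time_s"]
        time_s: object = t if t in ("undeut", "FD") else float(t)
        envelopes.append(
            IsotopicEnvelope(
                peptide_id=str(first["peptide_id"]),
                chain=str(first["chain"]),
                start=int(first["start"]),
                end=int(first["end"]),
                sequence=str(first["sequence"]),
                charge=int(first["charge"]),
                time_s=time_s,
                mz=grp["mz"].to_numpy(dtype=float),
                intensity=grp["intensity"].to_numpy(dtype=float),
                state_id=str(first["state_id"]),
                dataset_id=str(first["dataset_id"]),
            )
        )
    return envelopes


def write_table(df: pd.DataFrame, path, seed: int | None = None, config_hash: str = "") -> None:
    header = f"# hdxpipe schema={SCHEMA_VERSION}"
    if seed is not None:
        header += f" seed={seed}"
    if config_hash:
        header += f" config={config_hash}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"{path}: empty table") from err


def read_fasta(path) -> dict[str, str]:
    chains = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not chains:
        raise ValueError(f"{path}: no FASTA records")
    return chains


def read_chain_map(path) -> list[dict]:
    """chain_map CSV: dataset_chain, pdb_chain, offset (added to dataset
    residue numbering to obtain PDB author numbering)."""
    df = read_table(path)
    required = {"dataset_chain", "pdb_chain", "offset"}
    if set(df.columns) < required:
        raise ValueError(f"chain_map needs columns {sorted(required)}")
    return df.to_dict("records")
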