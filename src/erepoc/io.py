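"""Tabular I/O contracts (TSV/JSON) shared by the command-line interface.

All floating-point columns are printed with a fixed format so that
re-running a command with identical inputs reproduces byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.6g"


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def pockets_to_frame(pockets) -> pd.DataFrame:
    rows = []
    for p in pockets:
        rows.append({
            "structure_id": p.structure_id,
            "het_code": p.ligand_id[0],
            "ligand_chain": p.ligand_id[1],
            "ligand_resnum": p.ligand_id[2],
            "residues": ",".join(f"{c}:{n}{i}:{name}" for (c, n, i), name in p.residues),
            "rule": p.rule,
            "n_residues": len(p),
        })
    return pd.DataFrame(rows)


def write_embeddings(ids, matrix: np.ndarray, path) -> None:
    matrix = np.asarray(matrix)
    df = pd.DataFrame(matrix, columns=[f"d{i}" for i in range(matrix.shape[1])])
    df.insert(0, "pocket_id", list(ids))
    write_tsv(df, path)


def read_embeddings(path) -> tuple[list[str], np.ndarray]:
    df = read_tsv(path)
    ids = df["pocket_id"].astype(str).tolist()
    return ids, df.drop(columns=["pocket_id"]).to_numpy(dtype=np.float64)


def write_fingerprints(ids, fingerprints, path) -> None:
    """Fingerprints as compact hex strings, one row per ligand."""
    from .chem import LigandFingerprint

    rows = []
    for lid, fp in zip(ids, fingerprints):
        if not isinstance(fp, LigandFingerprint):
            fp = LigandFingerprint(bits=np.asarray(fp, dtype=np.uint8), smiles="", ligand_id=str(lid))
        rows.append({"ligand_id": lid, "smiles": fp.smiles, "bits_hex": fp.to_hex()})
    write_tsv(pd.DataFrame(rows), path)


def read_fingerprints(path):
    from .chem import LigandFingerprint

    df = read_tsv(path)
    fps = [
        LigandFingerprint.from_hex(row.bits_hex,
                                   smiles="" if pd.isna(row.smiles) else str(row.smiles),
                                   ligand_id=str(row.ligand_id))
        for row in df.itertuples()
    ]
    return [str(x) for x in df["ligand_id"]], fps


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(parts)
            name = line[1:].split()[0]
            parts = []
        else:
            parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts)
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_path, command: str, parameters: dict, inputs=(),
                   seed=None) -> Path:
    """Write the run manifest next to an output file.

    Records the command, resolved parameters, seeds, input hashes, package
    version and a timestamp.
    """
    from . import __version__

    manifest = {
        "command": command,
        "parameters": {k: _jsonable(v) for k, v in parameters.items()},
        "seed": seed,
        "inputs": {str(p): file_sha256(p) for p in inputs if Path(p).exists()},
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, Path):
        return str(v)
    return v
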