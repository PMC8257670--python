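"""Readers and writers for the package's serialised interfaces.

Plain-text formats throughout: Ct tables and survival tables as CSV,
expression matrices as TSV (first column sample_id, header = feature ids),
gene signatures as GMT (two records per signed signature: NAME_UP, NAME_DN)
and as JSON with metadata, scores as CSV.  Floats are written with a fixed
format so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

from .scoring import GeneSignature, ScoreResult

FLOAT_FORMAT = "%.10g"


def write_ct_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, na_values=["Undetermined", "undetermined"])
    table["ct"] = pd.to_numeric(table["ct"], errors="coerce")
    return table


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_expression_matrix(path, platform: str | None = None) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="sample_id")
    if matrix.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    if matrix.columns.duplicated().any():
        raise ValueError(f"duplicate feature ids in {path}")
    if platform is not None:
        matrix.attrs["platform"] = platform
    return matrix


def write_survival_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_survival_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_gmt(signature: GeneSignature, path) -> None:
    """Signed signatures become two GMT records (NAME_UP / NAME_DN)."""
    with open(path, "w") as fh:
        if signature.signed:
            fh.write("\t".join([f"{signature.name}_UP", signature.provenance,
                                *signature.positive]) + "\n")
            fh.write("\t".join([f"{signature.name}_DN", signature.provenance,
                                *signature.negative]) + "\n")
        else:
            fh.write("\t".join([signature.name, signature.provenance,
                                *signature.positive]) + "\n")


def read_gmt(path) -> list[GeneSignature]:
    """Read a GMT file, pairing NAME_UP/NAME_DN records into signed signatures."""
    records: dict[str, tuple[str, list[str]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT record: {line!r}")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            records[name] = (desc, genes)
            order.append(name)
    signatures: list[GeneSignature] = []
    used: set[str] = set()
    for name in order:
        if name in used:
            continue
        if name.endswith("_UP") and name[:-3] + "_DN" in records:
            base = name[:-3]
            desc, pos = records[name]
            _, neg = records[base + "_DN"]
            signatures.append(GeneSignature(name=base, positive=tuple(pos),
                                            negative=tuple(neg), provenance=desc))
            used.update({name, base + "_DN"})
        elif name.endswith("_DN") and name[:-3] + "_UP" in records:
            continue  # handled with its _UP partner
        else:
            desc, genes = records[name]
            signatures.append(GeneSignature(name=name, positive=tuple(genes),
                                            provenance=desc))
            used.add(name)
    return signatures


def write_signature_json(signature: GeneSignature, path) -> None:
    with open(path, "w") as fh:
        json.dump(signature.to_dict(), fh, indent=1, sort_keys=True)


def read_signature_json(path) -> GeneSignature:
    with open(path) as fh:
        return GeneSignature.from_dict(json.load(fh))


def write_scores(result: ScoreResult, path) -> None:
    result.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(data: dict[str, Any], path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True, default=_json_default)


def _json_default(obj):
    import numpy as np
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
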