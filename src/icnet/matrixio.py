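"""Text serialization of residue correlation matrices.

Format: comment header lines (``# key: value``) carrying the residue count,
normalization mode and residue labels, followed by N whitespace-separated
rows of N values.  Also exports matrices as TSV edge lists for graph tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .correlation import ResidueCorrelationMatrix

_MAGIC = "icnet-matrix v1"


def write_matrix(M: ResidueCorrelationMatrix, path,
                 labels: list | None = None) -> None:
    n = M.n_residues
    if labels is None:
        labels = list(range(1, n + 1))
    if len(labels) != n:
        raise ValueError("label count must equal the residue count")
    with open(path, "w") as fh:
        fh.write(f"# {_MAGIC}\n")
        fh.write(f"# n_residues: {n}\n")
        fh.write(f"# mode: {M.mode}\n")
        fh.write("# labels: " + " ".join(str(l) for l in labels) + "\n")
        np.savetxt(fh, M.values, fmt="%.12g")


def read_matrix(path) -> ResidueCorrelationMatrix:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if line.strip():
                rows.append([float(x) for x in line.split()])
    if "n_residues" not in meta or "mode" not in meta:
        raise ValueError("malformed matrix file: missing header")
    n = int(meta["n_residues"])
    values = np.asarray(rows)
    if values.shape != (n, n):
        raise ValueError(f"matrix body has shape {values.shape}, "
                         f"expected {(n, n)}")
    return ResidueCorrelationMatrix(values, meta["mode"])


def write_edge_list(M: ResidueCorrelationMatrix, path,
                    threshold: float = 0.0) -> None:
    """TSV edge list (res_i, res_j, weight) of off-diagonal cells > threshold."""
    iu = np.triu_indices(M.n_residues, k=1)
    w = M.values[iu]
    keep = w > threshold
    pd.DataFrame({"res_i": iu[0][keep] + 1, "res_j": iu[1][keep] + 1,
                  "weight": w[keep]}).to_csv(path, sep="\t", index=False,
                                             float_format="%.10g")
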