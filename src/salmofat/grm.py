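"""VanRaden genomic relationship matrix and derived principal components.

G = Z Z' / (2 * sum_i p_i (1 - p_i)) with Z the dosage matrix centred at
twice the second-allele frequency; frequencies are taken from the analysed
sample, and missing dosages are mean-imputed to 2p (a zero contribution to
Z, the conventional treatment).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidConfigError, MonomorphicSNPError
from .genotypes import GenotypeMatrix


@dataclass
class GRMatrix:
    sample_ids: np.ndarray
    values: np.ndarray  # symmetric n x n
    n_snps: int

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise FormatError("GRM values must be n x n for n sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise FormatError("GRM must be symmetric")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, ids) -> "GRMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = np.array([index[s] for s in ids])
        return GRMatrix(np.asarray(list(ids), object), self.values[np.ix_(rows, rows)],
                        self.n_snps)


def compute_grm(genotypes: GenotypeMatrix) -> GRMatrix:
    """VanRaden G from a post-QC panel; errors on monomorphic SNPs."""
    p = genotypes.allele_freq()
    if np.isnan(p).any() or ((p <= 0) | (p >= 1)).any():
        raise MonomorphicSNPError(
            "panel contains monomorphic or uncalled SNPs; run apply_qc first"
        )
    d = genotypes.dosages
    d = np.where(np.isnan(d), 2 * p, d)
    z = d - 2 * p
    denom = 2.0 * np.sum(p * (1 - p))
    g = (z @ z.T) / denom
    g = (g + g.T) / 2.0
    return GRMatrix(genotypes.sample_ids.copy(), g, genotypes.n_snps)


def grm_pca(grm: GRMatrix, k: int) -> pd.DataFrame:
    """Top-k principal components: eigenvectors of G scaled by sqrt(eigenvalue).

    Sign convention: within each component the largest-magnitude loading is
    positive, so results are deterministic across linear-algebra backends.
    """
    if k <= 0:
        raise InvalidConfigError(f"k must be >= 1, got {k}")
    if k >= grm.n_samples:
        raise InvalidConfigError("k must be smaller than the number of samples")
    w, v = np.linalg.eigh(grm.values)
    order = np.argsort(w)[::-1][:k]
    w, v = np.clip(w[order], 0, None), v[:, order]
    for j in range(k):
        lead = np.argmax(np.abs(v[:, j]))
        if v[lead, j] < 0:
            v[:, j] = -v[:, j]
    coords = v * np.sqrt(w)[None, :]
    return pd.DataFrame(
        coords, index=grm.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )


# ---------------------------------------------------------------------------
# I/O: binary lower-triangle dialect and plain TSV


def write_grm(grm: GRMatrix, prefix: str, fmt: str = "binary") -> None:
    """``binary``: row-major lower triangle (incl. diagonal) of 4-byte
    little-endian floats in ``<prefix>.grm.bin`` plus an id sidecar
    ``<prefix>.grm.id``. ``tsv``: full square matrix with ids."""
    if fmt == "binary":
        n = grm.n_samples
        tri = grm.values[np.tril_indices(n)]
        with open(prefix + ".grm.bin", "wb") as fh:
            fh.write(np.asarray(tri, dtype="<f4").tobytes())
        with open(prefix + ".grm.id", "w") as fh:
            for s in grm.sample_ids:
                fh.write(f"{s}\t{grm.n_snps}\n")
    elif fmt == "tsv":
        df = pd.DataFrame(grm.values, index=grm.sample_ids, columns=grm.sample_ids)
        df.index.name = f"n_snps={grm.n_snps}"
        df.to_csv(prefix + ".grm.tsv", sep="\t")
    else:
        raise InvalidConfigError(f"unknown GRM format {fmt!r}")


def read_grm(prefix: str, fmt: str = "binary") -> GRMatrix:
    if fmt == "binary":
        id_path, bin_path = prefix + ".grm.id", prefix + ".grm.bin"
        if not (os.path.exists(id_path) and os.path.exists(bin_path)):
            raise FormatError(f"missing {prefix}.grm.id / .grm.bin")
        ids, n_snps = [], 0
        with open(id_path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                ids.append(fields[0])
                n_snps = int(fields[1]) if len(fields) > 1 else 0
        n = len(ids)
        expected = n * (n + 1) // 2
        raw = open(bin_path, "rb").read()
        if len(raw) != 4 * expected:
            raise FormatError(
                f"triangle size mismatch: {len(raw)} bytes for n={n} "
                f"(expected {4 * expected})"
            )
        tri = np.frombuffer(raw, dtype="<f4").astype(float)
        g = np.zeros((n, n))
        g[np.tril_indices(n)] = tri
        g = g + np.tril(g, -1).T
        return GRMatrix(np.asarray(ids, object), g, n_snps)
    if fmt == "tsv":
        df = pd.read_csv(prefix + ".grm.tsv", sep="\t", index_col=0)
        n_snps = 0
        if df.index.name and "n_snps=" in str(df.index.name):
            n_snps = int(str(df.index.name).split("=")[1])
        if list(df.index) != list(df.columns):
            raise FormatError("TSV GRM row/column ids disagree")
        vals = df.to_numpy(float)
        return GRMatrix(df.index.to_numpy(object), (vals + vals.T) / 2, n_snps)
    raise InvalidConfigError(f"unknown GRM format {fmt!r}")
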