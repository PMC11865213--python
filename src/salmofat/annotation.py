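"""Gene annotation index (1-based inclusive intervals) with GFF3 round-trip."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError


@dataclass
class AnnotationIndex:
    """Gene records sorted by (chrom, start) for interval queries.

    Coordinates are 1-based and inclusive on both ends, the convention of
    GFF3 and of the +/-200 kb candidate-gene windows downstream.
    """

    genes: pd.DataFrame  # gene_id, name, chrom, start, end

    def __post_init__(self) -> None:
        required = {"gene_id", "name", "chrom", "start", "end"}
        missing = required - set(self.genes.columns)
        if missing:
            raise FormatError(f"annotation lacks columns: {sorted(missing)}")
        if (self.genes["start"] > self.genes["end"]).any():
            raise FormatError("gene start must be <= end")
        if (self.genes["start"] < 1).any():
            raise FormatError("coordinates are 1-based; start must be >= 1")
        self.genes = (
            self.genes.sort_values(["chrom", "start"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.genes)

    def query(self, chrom, lo: int, hi: int) -> pd.DataFrame:
        """Genes whose [start, end] intersects the closed interval [lo, hi]."""
        sub = self.genes[self.genes["chrom"].astype(str) == str(chrom)]
        hit = (sub["start"] <= hi) & (sub["end"] >= lo)
        return sub.loc[hit].reset_index(drop=True)

    # -- GFF3 --------------------------------------------------------------

    def to_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, g in self.genes.iterrows():
                fh.write(
                    f"{g['chrom']}\tsalmofat\tgene\t{g['start']}\t{g['end']}\t.\t+\t.\t"
                    f"ID={g['gene_id']};Name={g['name']}\n"
                )

    @classmethod
    def from_gff3(cls, path: str) -> "AnnotationIndex":
        import pyranges

        df = pyranges.read_gff3(path).df
        df = df[df["Feature"] == "gene"]
        if df.empty:
            raise FormatError(f"no gene features in {path}")
        return cls(
            pd.DataFrame(
                {
                    "gene_id": df["ID"].to_numpy(),
                    "name": df.get("Name", df["ID"]).to_numpy(),
                    "chrom": df["Chromosome"].astype(str).to_numpy(),
                    # pyranges stores 0-based half-open starts
                    "start": df["Start"].to_numpy() + 1,
                    "end": df["End"].to_numpy(),
                }
            )
        )


def write_term_map(term_map: pd.DataFrame, path: str) -> None:
    term_map.to_csv(path, sep="\t", index=False)


def read_term_map(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise FormatError("term map needs gene_id and term_id columns")
    return df


def manhattan_offsets(chroms: pd.Series, pos: pd.Series) -> np.ndarray:
    """Cumulative genome coordinate for plotting, chromosome blocks abutted
    in natural sort order with any unmapped stratum last."""

    def key(c):
        c = str(c)
        return (0, int(c)) if c.isdigit() else (1, c)

    order = sorted(pd.unique(chroms.astype(str)), key=key)
    offsets, cum = {}, 0
    for c in order:
        offsets[c] = cum
        span = pos[chroms.astype(str) == c].max()
        cum += int(span) + 1
    return pos.to_numpy() + np.array([offsets[str(c)] for c in chroms])
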