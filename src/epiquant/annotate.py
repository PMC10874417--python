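"""SNP-to-gene mapping, gene-pair construction, disease grouping, PPI overlap.

A SNP maps to every gene whose interval, extended by a window (default
100 kb) on both sides, contains its position (1-based, inclusive ends) on
the same chromosome; multi-gene hits all count, and intergenic SNPs stay
unmapped.  Gene symbols are upper-cased before any matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import FormatError, GenotypeDataset, SNPInfo

DEFAULT_WINDOW_BP = 100_000


@dataclass(frozen=True)
class GeneInterval:
    """A gene's span on the reference assembly, 1-based inclusive."""

    name: str
    chrom: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene name must be non-empty")
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")


@dataclass
class GenePair:
    """An unordered gene pair lifted from one or more significant SNP pairs."""

    gene_a: str
    gene_b: str
    source_snp_pairs: list[tuple[int, int]] = field(default_factory=list)
    group: str = "unassigned"  # G1 / G2 / G3 once classified
    ppi_overlap: bool = False

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            raise ValueError("gene pair must be in canonical (lexicographic) order")
        if self.gene_a == self.gene_b:
            raise ValueError("same-gene pairs are excluded")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class PPIEdge:
    node_a: str
    node_b: str

    @property
    def key(self) -> tuple[str, str]:
        a, b = sorted((self.node_a.upper(), self.node_b.upper()))
        return (a, b)


# ---------------------------------------------------------------------------
# Interval I/O
# ---------------------------------------------------------------------------

def read_gene_intervals(path) -> list[GeneInterval]:
    """Read gene intervals from BED or header-declared TSV.

    A file whose first line names columns (``chrom  start  end  name``) is
    parsed as 1-based inclusive TSV; otherwise 4-column BED, 0-based
    half-open, converted to 1-based inclusive.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    header_tokens = [t.strip().lower() for t in first.rstrip("\n").split("\t")]
    has_header = {"chrom", "start", "end", "name"} <= set(header_tokens)
    out: list[GeneInterval] = []
    if has_header:
        frame = pd.read_csv(path, sep="\t")
        frame.columns = [c.strip().lower() for c in frame.columns]
        cols = frame[["chrom", "start", "end", "name"]]
        for chrom, start, end, name in cols.itertuples(index=False, name=None):
            out.append(GeneInterval(str(name), _chrom_to_int(chrom), int(start), int(end)))
    else:
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise FormatError(f"{path}: BED line with <4 columns")
                chrom, start, end, name = fields[:4]
                out.append(
                    GeneInterval(name, _chrom_to_int(chrom), int(start) + 1, int(end))
                )
    return out


def _chrom_to_int(token) -> int:
    token = str(token).strip()
    if token.lower().startswith("chr"):
        token = token[3:]
    aliases = {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}
    return aliases.get(token.upper(), None) or int(token)


def read_gene_list(path) -> set[str]:
    """One symbol per line, upper-cased."""
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}


def read_ppi_edges(path) -> list[PPIEdge]:
    """Two whitespace-separated symbols per line."""
    edges: list[PPIEdge] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}: PPI edge line with <2 columns")
            edges.append(PPIEdge(fields[0], fields[1]))
    return edges


# ---------------------------------------------------------------------------
# Mapping and grouping
# ---------------------------------------------------------------------------

def map_snp_to_genes(
    snp: SNPInfo,
    intervals: Sequence[GeneInterval],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[str]:
    """Genes whose window-extended interval contains the SNP position.

    Distance-0 (containing) genes and genes within exactly ``window_bp``
    are both included; cross-chromosome genes never match.  The empty list
    marks an intergenic SNP.
    """
    hits = [
        g.name.upper()
        for g in intervals
        if g.chrom == snp.chrom and g.start - window_bp <= snp.pos_bp <= g.end + window_bp
    ]
    # deterministic, duplicate-free order
    return sorted(set(hits))


def build_snp_gene_map(
    dataset: GenotypeDataset,
    intervals: Sequence[GeneInterval],
    snp_indices: Iterable[int],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> dict[int, list[str]]:
    return {
        int(i): map_snp_to_genes(dataset.snps[int(i)], intervals, window_bp)
        for i in snp_indices
    }


def build_gene_pairs(
    snp_pairs: Iterable[tuple[int, int]],
    snp_to_gene: Mapping[int, Sequence[str]],
) -> list[GenePair]:
    """Lift SNP pairs to deduplicated, canonically ordered gene pairs.

    Each SNP pair contributes the Cartesian product of its two gene lists;
    same-gene combinations are dropped, and an unmapped (intergenic) side
    contributes nothing.  Source SNP pairs accumulate on the merged pair.
    """
    merged: dict[tuple[str, str], GenePair] = {}
    for i, j in snp_pairs:
        genes_i = [g.upper() for g in snp_to_gene.get(int(i), [])]
        genes_j = [g.upper() for g in snp_to_gene.get(int(j), [])]
        for ga in genes_i:
            for gb in genes_j:
                if ga == gb:
                    continue
                key = tuple(sorted((ga, gb)))
                pair = merged.get(key)
                if pair is None:
                    pair = GenePair(key[0], key[1])
                    merged[pair.key] = pair
                if (i, j) not in pair.source_snp_pairs:
                    pair.source_snp_pairs.append((i, j))
    return [merged[k] for k in sorted(merged)]


def classify_ad_groups(pairs: list[GenePair], disease_genes: set[str]) -> list[GenePair]:
    """Partition pairs into G1 (both on the disease list), G2 (one), G3 (neither)."""
    disease = {g.upper() for g in disease_genes}
    for pair in pairs:
        n_hits = int(pair.gene_a in disease) + int(pair.gene_b in disease)
        pair.group = {2: "G1", 1: "G2", 0: "G3"}[n_hits]
    return pairs


def ppi_overlap(pairs: list[GenePair], edges: Iterable[PPIEdge]) -> tuple[list[GenePair], int]:
    """Flag pairs whose unordered symbols form a network edge; return the count."""
    edge_keys = {e.key for e in edges}
    count = 0
    for pair in pairs:
        pair.ppi_overlap = pair.key in edge_keys
        count += int(pair.ppi_overlap)
    return pairs, count


def write_gene_pairs(pairs: list[GenePair], path) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "n_source_snp_pairs": len(p.source_snp_pairs),
                "source_snp_pairs": ";".join(f"{i},{j}" for i, j in p.source_snp_pairs),
                "group": p.group,
                "ppi_overlap": int(p.ppi_overlap),
            }
            for p in pairs
        ],
        columns=["gene_a", "gene_b", "n_source_snp_pairs", "source_snp_pairs", "group", "ppi_overlap"],
    )
    frame.to_csv(path, sep="\t", index=False)
    return frame
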