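"""Multigene codon supermatrices and their compositional diagnostics.

Builds a concatenated alignment from per-gene codon alignments and computes
the descriptive statistics used to characterise compositional heterogeneity
in a mitochondrial (or any protein-coding) dataset: parsimony-informative
site counts by codon position, GC content at each codon position per taxon
and lineage, relative synonymous codon usage (RSCU) with a PCA of the RSCU
table, and the six gene/codon-position partition schemes commonly used for
partitioned phylogenetic analyses.

Columns are 0-based half-open internally; codon positions are reported
1-based (1, 2, 3).  Gaps and IUPAC ambiguity codes are excluded from GC and
informative-site state counts; codons containing any non-ACGT character are
skipped in RSCU counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

UNAMBIGUOUS = frozenset("ACGT")

# Synonymous-codon families of the standard genetic code with >= 2 members
# (stop codons and the single-codon families Met/Trp excluded): 59 codons.
_standard = CodonTable.unambiguous_dna_by_id[1]
_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in _standard.forward_table.items():
    _FAMILIES.setdefault(_aa, []).append(_codon)
_FAMILIES = {aa: sorted(cs) for aa, cs in _FAMILIES.items() if len(cs) >= 2}
SENSE_CODONS: list[str] = sorted(c for cs in _FAMILIES.values() for c in cs)
_FAMILY_OF: dict[str, str] = {c: aa for aa, cs in _FAMILIES.items() for c in cs}


@dataclass
class GeneAlignment:
    """One aligned gene: taxon names and equal-length sequences."""

    name: str
    taxa: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon in gene {self.name!r}: {dup}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths in gene {self.name!r}")
        if self.length % 3 != 0:
            raise ValueError(
                f"gene {self.name!r}: alignment length {self.length} "
                "not multiple of 3"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclass
class SuperMatrix:
    """Concatenated taxa x sites character table with gene annotation."""

    taxa: list[str]
    sequences: np.ndarray                      # (n_taxa, L) array of '<U1'
    gene_boundaries: list[tuple[str, int, int]]  # (gene, start, end) half-open
    lineage_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype="<U1")
        L = self.sequences.shape[1]
        cover = 0
        prev_end = 0
        for gene, start, end in self.gene_boundaries:
            if start != prev_end:
                raise ValueError("gene intervals not contiguous")
            if (end - start) % 3 != 0:
                raise ValueError(f"gene {gene!r} length not multiple of 3")
            cover += end - start
            prev_end = end
        if cover != L:
            raise ValueError("gene intervals do not cover all columns")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.sequences.shape[1]

    @property
    def codon_position(self) -> np.ndarray:
        """Per-column codon position (1, 2 or 3), cycling within each gene."""
        pos = np.empty(self.n_sites, dtype=int)
        for _, start, end in self.gene_boundaries:
            pos[start:end] = (np.arange(end - start) % 3) + 1
        return pos

    def gene_slice(self, gene: str) -> "GeneAlignment":
        for g, start, end in self.gene_boundaries:
            if g == gene:
                seqs = ["".join(row[start:end]) for row in self.sequences]
                return GeneAlignment(gene, list(self.taxa), seqs)
        raise KeyError(f"gene {gene!r} not in matrix")

    def sequence(self, taxon: str) -> str:
        return "".join(self.sequences[self.taxa.index(taxon)])

    # -- I/O ---------------------------------------------------------------
    def to_fasta(self, path) -> None:
        recs = [SeqRecord(Seq("".join(row)), id=t, description="")
                for t, row in zip(self.taxa, self.sequences)]
        SeqIO.write(recs, path, "fasta")

    def to_phylip(self, path) -> None:
        aln = MultipleSeqAlignment(
            SeqRecord(Seq("".join(row)), id=t, description="")
            for t, row in zip(self.taxa, self.sequences))
        AlignIO.write(aln, path, "phylip-relaxed")


def read_gene_alignments(paths) -> list[GeneAlignment]:
    """Read per-gene aligned FASTA files (one gene per file).

    Gene names are taken from the file stem.  Taxa missing from a gene are
    simply absent from that record; :func:`concatenate` gap-fills them.
    """
    import os

    genes = []
    for path in paths:
        name = os.path.splitext(os.path.basename(str(path)))[0]
        taxa, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            seqs.append(str(rec.seq).upper())
        if not taxa:
            raise ValueError(f"no sequences in {path}")
        genes.append(GeneAlignment(name, taxa, seqs))
    return genes


def filter_taxa_by_gene_count(genes: list[GeneAlignment],
                              min_genes: int = 15) -> list[GeneAlignment]:
    """Drop taxa present in fewer than ``min_genes`` genes (upstream filter)."""
    counts: dict[str, int] = {}
    for g in genes:
        for t in g.taxa:
            counts[t] = counts.get(t, 0) + 1
    keep = {t for t, c in counts.items() if c >= min_genes}
    out = []
    for g in genes:
        pairs = [(t, s) for t, s in zip(g.taxa, g.sequences) if t in keep]
        if pairs:
            out.append(GeneAlignment(g.name, [p[0] for p in pairs],
                                     [p[1] for p in pairs]))
    return out


def concatenate(genes: list[GeneAlignment],
                lineage_of: dict[str, str] | None = None) -> SuperMatrix:
    """Concatenate gene alignments into a supermatrix.

    Taxon set is the union over genes (exact string identity); taxa absent
    from a gene are filled with gaps in that gene's block.  Column order
    follows the input gene order.
    """
    if not genes:
        raise ValueError("no genes to concatenate")
    taxa: list[str] = []
    for g in genes:
        for t in g.taxa:
            if t not in taxa:
                taxa.append(t)
    L = sum(g.length for g in genes)
    mat = np.full((len(taxa), L), "-", dtype="<U1")
    boundaries = []
    offset = 0
    for g in genes:
        idx = {t: i for i, t in enumerate(g.taxa)}
        for ti, t in enumerate(taxa):
            if t in idx:
                mat[ti, offset:offset + g.length] = list(g.sequences[idx[t]])
        boundaries.append((g.name, offset, offset + g.length))
        offset += g.length
    return SuperMatrix(taxa, mat, boundaries, dict(lineage_of or {}))


def count_parsimony_informative(matrix: SuperMatrix,
                                positions=(1, 2, 3)) -> dict:
    """Count parsimony-informative columns per codon position.

    A column is informative iff at least two distinct unambiguous states
    (A/C/G/T) each occur in at least two taxa; gaps and ambiguity codes do
    not contribute to state counts.
    """
    positions = tuple(positions)
    if not positions:
        raise ValueError("empty position filter")
    codon_pos = matrix.codon_position
    seqs = matrix.sequences
    counts = {p: 0 for p in positions}
    for col in range(matrix.n_sites):
        p = int(codon_pos[col])
        if p not in counts:
            continue
        states, tallies = np.unique(seqs[:, col], return_counts=True)
        n_multi = sum(1 for s, c in zip(states, tallies)
                      if s in UNAMBIGUOUS and c >= 2)
        if n_multi >= 2:
            counts[p] += 1
    counts["total"] = sum(counts[p] for p in positions)
    return counts


def gc_content(matrix: SuperMatrix,
               grouping: dict[str, str] | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-taxon GC proportions at each codon position, plus lineage means.

    Returns ``(table, lineage_means)``.  ``table`` has one row per taxon with
    columns ``lineage, gc_all, gc_1, gc_2, gc_3`` and the countable-base
    totals ``n_1, n_2, n_3``; ``gc_all`` is the count-weighted combination of
    the per-position values.  Taxa with zero countable bases at a position
    get NaN there and are excluded from that position's lineage mean.
    """
    grouping = grouping if grouping is not None else matrix.lineage_of
    codon_pos = matrix.codon_position
    rows = []
    for ti, taxon in enumerate(matrix.taxa):
        seq = matrix.sequences[ti]
        row: dict = {"taxon": taxon, "lineage": grouping.get(taxon, "all")}
        total_gc = total_n = 0
        for p in (1, 2, 3):
            sub = seq[codon_pos == p]
            mask = np.isin(sub, ("A", "C", "G", "T"))
            n = int(mask.sum())
            gc = int(np.isin(sub, ("G", "C")).sum())
            row[f"gc_{p}"] = gc / n if n else np.nan
            row[f"n_{p}"] = n
            total_gc += gc
            total_n += n
        row["gc_all"] = total_gc / total_n if total_n else np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("taxon")
    means = table.groupby("lineage")[["gc_all", "gc_1", "gc_2", "gc_3"]].mean()
    return table, means


def codon_counts(matrix: SuperMatrix) -> pd.DataFrame:
    """Per-taxon counts of complete unambiguous codons (frame from genes)."""
    counts = pd.DataFrame(0, index=matrix.taxa, columns=SENSE_CODONS)
    for _, start, end in matrix.gene_boundaries:
        block = matrix.sequences[:, start:end]
        for c0 in range(0, end - start, 3):
            codons = block[:, c0] + block[:, c0 + 1] + block[:, c0 + 2]
            for ti, codon in enumerate(codons):
                if codon in _FAMILY_OF:
                    counts.iloc[ti, counts.columns.get_loc(codon)] += 1
    return counts


def rscu(matrix: SuperMatrix) -> pd.DataFrame:
    """Relative synonymous codon usage per taxon.

    For codon ``c`` in a synonymous family of size ``k`` with per-taxon
    counts ``x``: ``RSCU(c) = k * x(c) / sum(x over family)``.  Families with
    zero observations get RSCU 0 for all members.  Stop codons and the
    single-codon families (Met, Trp) are excluded; the returned table has
    the 59 remaining sense codons as columns.
    """
    x = codon_counts(matrix)
    if (x.sum(axis=1) == 0).any():
        bad = list(x.index[x.sum(axis=1) == 0])
        raise ValueError(f"taxa with no complete codons: {bad}")
    out = pd.DataFrame(0.0, index=x.index, columns=x.columns)
    for aa, codons in _FAMILIES.items():
        fam = x[codons]
        tot = fam.sum(axis=1)
        k = len(codons)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (k * fam).div(tot, axis=0)
        out[codons] = vals.fillna(0.0)
    return out


def rscu_pca(table: pd.DataFrame, n_components: int = 2
             ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of an RSCU table (column-centred SVD, unscaled).

    Returns per-taxon PC coordinates and the explained-variance fractions
    (summing to 1).  Component signs are fixed so that each component's
    largest-magnitude loading is positive.  A constant table yields all-zero
    coordinates.
    """
    if len(table) < 2:
        raise ValueError("PCA needs at least two taxa")
    X = table.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(np.abs(X) > 1e-12):
        coords = pd.DataFrame(
            0.0, index=table.index,
            columns=[f"PC{i+1}" for i in range(n_components)])
        return coords, np.zeros(n_components)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    var = S ** 2
    frac = var / var.sum()
    k = min(n_components, len(S))
    coords = pd.DataFrame(U[:, :k] * S[:k], index=table.index,
                          columns=[f"PC{i+1}" for i in range(k)])
    return coords, frac


@dataclass
class PartitionScheme:
    """A named partition of the supermatrix columns into disjoint blocks."""

    name: str
    blocks: list[tuple[str, np.ndarray]]   # (block_name, column indices)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def validate_covers(self, n_sites: int) -> bool:
        cols = np.concatenate([b for _, b in self.blocks]) if self.blocks \
            else np.array([], dtype=int)
        return len(cols) == n_sites and len(np.unique(cols)) == n_sites

    def to_raxml(self, path) -> None:
        """Write in RAxML format, e.g. ``DNA, gene1_pos3 = 7-27\\3``."""
        with open(path, "w") as fh:
            for bname, cols in self.blocks:
                fh.write(f"DNA, {bname} = {_ranges_1based(cols)}\n")


def _ranges_1based(cols: np.ndarray) -> str:
    """Compact 1-based range notation with \\3 stride where applicable."""
    cols = np.sort(np.asarray(cols))
    pieces = []
    i = 0
    while i < len(cols):
        # try stride-3 run first, then stride-1
        for stride in (3, 1):
            j = i
            while j + 1 < len(cols) and cols[j + 1] == cols[j] + stride:
                j += 1
            if j > i or stride == 1:
                start, end = cols[i] + 1, cols[j] + 1
                if stride == 3 and j > i:
                    pieces.append(f"{start}-{end}\\3")
                elif start == end:
                    pieces.append(f"{start}")
                else:
                    pieces.append(f"{start}-{end}")
                i = j + 1
                break
    return ", ".join(pieces)


def build_partition_schemes(matrix: SuperMatrix) -> list[PartitionScheme]:
    """The six gene/codon-position partition schemes.

    For G genes the schemes have 1, 2, 3, G, 2G and 3G blocks:
    (1) unpartitioned; (2) positions 1+2 vs 3; (3) one block per codon
    position; (4) one block per gene; (5) per gene, positions 1+2 vs 3;
    (6) per gene and codon position.
    """
    pos = matrix.codon_position
    all_cols = np.arange(matrix.n_sites)
    schemes = [
        PartitionScheme("unpartitioned", [("all", all_cols)]),
        PartitionScheme("pos12_vs_3", [
            ("pos12", all_cols[(pos == 1) | (pos == 2)]),
            ("pos3", all_cols[pos == 3]),
        ]),
        PartitionScheme("by_position", [
            (f"pos{p}", all_cols[pos == p]) for p in (1, 2, 3)
        ]),
    ]
    gene_blocks, gene12_blocks, genepos_blocks = [], [], []
    for gene, start, end in matrix.gene_boundaries:
        cols = np.arange(start, end)
        gpos = pos[start:end]
        gene_blocks.append((gene, cols))
        gene12_blocks.append((f"{gene}_pos12", cols[(gpos == 1) | (gpos == 2)]))
        gene12_blocks.append((f"{gene}_pos3", cols[gpos == 3]))
        for p in (1, 2, 3):
            genepos_blocks.append((f"{gene}_pos{p}", cols[gpos == p]))
    schemes.append(PartitionScheme("by_gene", gene_blocks))
    schemes.append(PartitionScheme("by_gene_pos12_vs_3", gene12_blocks))
    schemes.append(PartitionScheme("by_gene_and_position", genepos_blocks))
    return schemes


def read_lineage_map(path) -> dict[str, str]:
    """Two-column TSV (taxon, lineage) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["taxon", "lineage"],
                     dtype=str, comment="#")
    return dict(zip(df["taxon"], df["lineage"]))
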