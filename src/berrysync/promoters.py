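"""Promoter extraction, exact IUPAC motif scanning and positional-bias
Z-scores for cis-regulatory elements (CREs).

Promoters are the 1.5 kb upstream of the transcription start site (TSS).
Because gene models frequently lose the 5'UTR in one annotation, the TSS
is chosen per gene from two annotations by the longest-transcript rule:
the candidate lying further upstream on the gene's strand wins.  Motifs
(IUPAC consensus strings) are matched exactly on both strands, and each
gene x motif cell is summarised by a positional-bias Z-score: the summed
linear proximity weight of the observed sites, standardised under a null
of independent uniform placement over all valid offsets (exact
finite-population moments, so the score accounts for motif length, hit
frequency and position).  Genes with no hit carry an explicit *absent*
state, distinct from z = 0; absence is imputed to 0 only inside
clustering distances.

Coordinates: GFF3 input is 1-based inclusive; internal arithmetic is
0-based half-open.  Promoter sequences are stored 5'->3' on the gene's
sense strand (last base adjacent to the TSS); hit offsets measure the
distance of the TSS-proximal end of a match from the TSS.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "PromoterRecord",
    "MotifHit",
    "CREMatrix",
    "load_motif_library",
    "read_gene_annotation",
    "select_tss",
    "extract_promoter",
    "extract_promoters",
    "scan_motifs",
    "positional_zscore",
    "proximity_weight_moments",
    "build_cre_matrix",
    "cluster_cre",
    "cross_genotype_stability",
    "reverse_complement",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    contig: str
    strand: str
    tss: int  # 1-based genomic coordinate of the transcription start
    sequence: str  # 5'->3' sense orientation, last base adjacent to the TSS
    tss_source: str = ""
    clipped: bool = False


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    offset: int  # distance of the TSS-proximal match end from the TSS
    strand: str
    matched: str


def load_motif_library(source) -> pd.DataFrame:
    """Motif library TSV (motif_id, tf_family, consensus) or DataFrame.

    Raises at load time on any non-IUPAC character.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t", comment="#")
    required = {"motif_id", "consensus"}
    if missing := required - set(df.columns):
        raise ValueError(f"motif library missing columns: {sorted(missing)}")
    if "tf_family" not in df.columns:
        df = df.assign(tf_family="")
    for row in df.itertuples(index=False):
        bad = set(row.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {row.motif_id}: invalid IUPAC codes {sorted(bad)}")
    df = df.assign(consensus=df["consensus"].str.upper())
    return df[["motif_id", "tf_family", "consensus"]]


# ---------------------------------------------------------------------------
# TSS selection and promoter extraction


def read_gene_annotation(gff_path) -> pd.DataFrame:
    """Gene-level records (gene_id, contig, strand, start, end) from GFF3."""
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append({"gene_id": gene_id, "contig": feat.seqid, "strand": feat.strand,
                     "start": feat.start, "end": feat.end})
    return pd.DataFrame(rows)


def select_tss(annotation_a: pd.DataFrame, annotation_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene TSS by the longest-transcript rule across two annotations.

    Plus strand: the smaller start (more upstream) wins; minus strand: the
    larger end.  Genes present in a single annotation use it; strand
    conflicts are skipped with a warning.
    """
    a = annotation_a.set_index("gene_id")
    b = annotation_b.set_index("gene_id")
    rows = []
    for gene in sorted(set(a.index) | set(b.index)):
        in_a, in_b = gene in a.index, gene in b.index
        if in_a and in_b:
            ra, rb = a.loc[gene], b.loc[gene]
            if ra["strand"] != rb["strand"] or ra["contig"] != rb["contig"]:
                warnings.warn(f"select_tss: strand/contig conflict for {gene}, skipped")
                continue
            strand = ra["strand"]
            if strand == "+":
                tss, source = ((int(ra["start"]), "a") if ra["start"] <= rb["start"]
                               else (int(rb["start"]), "b"))
            else:
                tss, source = ((int(ra["end"]), "a") if ra["end"] >= rb["end"]
                               else (int(rb["end"]), "b"))
            contig = ra["contig"]
        else:
            r = a.loc[gene] if in_a else b.loc[gene]
            strand, contig = r["strand"], r["contig"]
            tss = int(r["start"]) if strand == "+" else int(r["end"])
            source = "a" if in_a else "b"
        rows.append({"gene_id": gene, "contig": contig, "strand": strand,
                     "tss": tss, "tss_source": source})
    return pd.DataFrame(rows)


def extract_promoter(genome, contig: str, tss: int, strand: str,
                     length: int = 1500, gene_id: str = "", tss_source: str = "") -> PromoterRecord:
    """Extract the ``length`` nt upstream of (and excluding) the TSS.

    ``genome`` is a mapping contig -> str or a ``pyfaidx.Fasta``.  Plus
    strand: 0-based [tss-1-length, tss-1); minus strand: [tss, tss+length)
    reverse-complemented.  Windows clipped at contig edges set ``clipped``.
    """
    seq_obj = genome[contig]
    contig_len = len(seq_obj)
    if not 1 <= tss <= contig_len:
        raise ValueError(f"TSS {tss} outside contig {contig} (length {contig_len})")

    def fetch(lo: int, hi: int) -> str:
        piece = seq_obj[lo:hi]
        return (piece if isinstance(piece, str) else str(piece)).upper()

    if strand == "+":
        lo, hi = tss - 1 - length, tss - 1
        clipped = lo < 0
        seq = fetch(max(lo, 0), hi)
    elif strand == "-":
        lo, hi = tss, tss + length
        clipped = hi > contig_len
        seq = reverse_complement(fetch(lo, min(hi, contig_len)))
    else:
        raise ValueError(f"invalid strand {strand!r}")
    return PromoterRecord(gene_id, contig, strand, tss, seq, tss_source, clipped)


def extract_promoters(genome, tss_table: pd.DataFrame, length: int = 1500) -> list[PromoterRecord]:
    return [
        extract_promoter(genome, row.contig, row.tss, row.strand, length,
                         gene_id=row.gene_id, tss_source=getattr(row, "tss_source", ""))
        for row in tss_table.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# exact motif scanning


def _iupac_regex(consensus: str) -> re.Pattern:
    return re.compile("(?=(" + "".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in consensus
    ) + "))")


def scan_motifs(promoter: PromoterRecord | str, motif_library: pd.DataFrame) -> list[MotifHit]:
    """All overlapping exact matches of each motif on both strands.

    Offsets measure the distance of the TSS-proximal match end from the
    TSS; output is sorted by (motif_id, offset, strand).
    """
    seq = promoter.sequence if isinstance(promoter, PromoterRecord) else promoter
    seq = seq.upper()
    p_len = len(seq)
    hits: list[MotifHit] = []
    for row in motif_library.itertuples(index=False):
        consensus = row.consensus
        L = len(consensus)
        if L > p_len:
            continue
        for strand, pattern in (("+", _iupac_regex(consensus)),
                                ("-", _iupac_regex(reverse_complement(consensus)))):
            for m in pattern.finditer(seq):
                start = m.start()
                hits.append(MotifHit(row.motif_id, p_len - (start + L), strand,
                                     seq[start:start + L]))
    hits.sort(key=lambda h: (h.motif_id, h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# positional-bias Z-score


def proximity_weight_moments(promoter_length: int, motif_length: int):
    """Exact finite-population mean/variance of the proximity weight
    w(d) = (P - d) / P over the P - L + 1 valid offsets."""
    if promoter_length <= motif_length:
        raise ValueError("promoter must be longer than the motif")
    d = np.arange(promoter_length - motif_length + 1, dtype=float)
    w = (promoter_length - d) / promoter_length
    return float(w.mean()), float(w.var())  # population variance

def positional_zscore(offsets, promoter_length: int, motif_length: int):
    """Standardised summed proximity weight of the observed sites.

    Null: k sites placed independently and uniformly over the valid
    offsets.  z = (S - k mu_w) / sqrt(k sigma_w^2) with S = sum w(d_i).
    Returns None (absent) for k = 0.
    """
    offsets = np.asarray(list(offsets), dtype=float)
    k = offsets.size
    if k == 0:
        return None
    if np.any(offsets < 0) or np.any(offsets > promoter_length - motif_length):
        raise ValueError("offset outside the valid range")
    mu, var = proximity_weight_moments(promoter_length, motif_length)
    s = np.sum((promoter_length - offsets) / promoter_length)
    return float((s - k * mu) / np.sqrt(k * var))


# ---------------------------------------------------------------------------
# gene x motif matrix and clustering


@dataclass
class CREMatrix:
    """Gene x motif positional Z-scores with an explicit absent state."""

    z: pd.DataFrame  # NaN where absent
    absent: pd.DataFrame  # boolean mask (True = no hit, distinct from z=0)
    motif_families: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def imputed(self) -> pd.DataFrame:
        """Absent cells imputed as 0 (for distance computations only)."""
        return self.z.fillna(0.0)


def build_cre_matrix(promoters, motif_library: pd.DataFrame,
                     promoter_length: int | None = None) -> CREMatrix:
    """Scan every promoter and assemble positional Z-scores per motif."""
    motif_ids = motif_library["motif_id"].tolist()
    lengths = dict(zip(motif_library["motif_id"], motif_library["consensus"].str.len()))
    z = pd.DataFrame(np.nan, index=[p.gene_id for p in promoters], columns=motif_ids)
    for prom in promoters:
        p_len = promoter_length or len(prom.sequence)
        hits = scan_motifs(prom, motif_library)
        by_motif: dict[str, list[int]] = {}
        for h in hits:
            by_motif.setdefault(h.motif_id, []).append(h.offset)
        for motif_id, offsets in by_motif.items():
            z.loc[prom.gene_id, motif_id] = positional_zscore(
                offsets, p_len, lengths[motif_id])
    families = motif_library.set_index("motif_id")["tf_family"]
    return CREMatrix(z=z, absent=z.isna(), motif_families=families)


@dataclass
class CREClustering:
    gene_linkage: np.ndarray
    motif_linkage: np.ndarray
    gene_order: list
    motif_order: list
    gene_clusters: pd.Series
    dropped_genes: list


def cluster_cre(matrix: CREMatrix, n_clusters: int = 2) -> CREClustering:
    """Ward clustering of genes and motifs on the imputed Z matrix.

    All-absent genes are dropped with a warning; absence is imputed to 0
    only here, inside the Euclidean distances.
    """
    z = matrix.imputed()
    all_absent = matrix.absent.all(axis=1)
    dropped = z.index[all_absent].tolist()
    if dropped:
        warnings.warn(f"cluster_cre: dropping all-absent genes: {dropped}")
        z = z.loc[~all_absent]
    if z.shape[0] < 2:
        raise ValueError("need >=2 genes with hits to cluster")
    gene_link = hierarchy.linkage(z.to_numpy(), method="ward", metric="euclidean")
    if z.shape[1] >= 2:
        motif_link = hierarchy.linkage(z.to_numpy().T, method="ward", metric="euclidean")
        motif_order = [z.columns[i] for i in hierarchy.leaves_list(motif_link)]
    else:
        motif_link = np.empty((0, 4))
        motif_order = list(z.columns)
    labels = hierarchy.fcluster(gene_link, t=min(n_clusters, z.shape[0]),
                                criterion="maxclust")
    return CREClustering(
        gene_linkage=gene_link,
        motif_linkage=motif_link,
        gene_order=[z.index[i] for i in hierarchy.leaves_list(gene_link)],
        motif_order=motif_order,
        gene_clusters=pd.Series(labels, index=z.index, name="cluster"),
        dropped_genes=dropped,
    )


def linkage_to_newick(linkage: np.ndarray, labels) -> str:
    """Serialise a scipy linkage as a Newick tree (branch lengths from
    merge heights)."""
    tree = hierarchy.to_tree(linkage)
    labels = list(labels)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def cross_genotype_stability(matrices: dict, n_clusters: int = 2) -> pd.DataFrame:
    """Pairwise dendrogram/cluster agreement across promoter sets.

    For each pair of genotype CRE matrices restricted to the shared gene
    set: the correlation of cophenetic distances of the two gene
    dendrograms, and the adjusted Rand index of the flat clusters at the
    same k.
    """
    from sklearn.metrics import adjusted_rand_score

    names = sorted(matrices)
    if len(names) < 2:
        raise ValueError("need >=2 promoter sets")
    shared = set(matrices[names[0]].z.index)
    for n in names[1:]:
        shared &= set(matrices[n].z.index)
    shared = sorted(shared)
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes")
    rows = []
    per_set = {}
    for n in names:
        sub = CREMatrix(matrices[n].z.loc[shared], matrices[n].absent.loc[shared],
                        matrices[n].motif_families)
        clus = cluster_cre(sub, n_clusters=n_clusters)
        kept = clus.gene_clusters.index
        per_set[n] = (clus, kept)
    for i, j in [(a, b) for ai, a in enumerate(names) for b in names[ai + 1:]]:
        ci, keep_i = per_set[i]
        cj, keep_j = per_set[j]
        common = [g for g in shared if g in keep_i and g in keep_j]
        coph_i = squareform(hierarchy.cophenet(ci.gene_linkage))
        coph_j = squareform(hierarchy.cophenet(cj.gene_linkage))
        idx_i = [list(keep_i).index(g) for g in common]
        idx_j = [list(keep_j).index(g) for g in common]
        di = squareform(coph_i[np.ix_(idx_i, idx_i)], checks=False)
        dj = squareform(coph_j[np.ix_(idx_j, idx_j)], checks=False)
        if di.size > 1 and np.std(di) > 0 and np.std(dj) > 0:
            coph_corr = float(np.corrcoef(di, dj)[0, 1])
        else:
            coph_corr = 1.0 if np.allclose(di, dj) else np.nan
        ari = adjusted_rand_score(ci.gene_clusters.loc[common],
                                  cj.gene_clusters.loc[common])
        rows.append({"set_a": i, "set_b": j, "cophenetic_correlation": coph_corr,
                     "adjusted_rand": float(ari), "n_shared_genes": len(common)})
    return pd.DataFrame(rows)
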