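"""Promoter extraction, exact IUPAC scanning, positional Z-scores and CRE
clustering."""

import numpy as np
import pandas as pd
import pytest

from berrysync import synthetic
from berrysync.promoters import (
    CREMatrix,
    build_cre_matrix,
    cluster_cre,
    cross_genotype_stability,
    extract_promoter,
    linkage_to_newick,
    load_motif_library,
    positional_zscore,
    proximity_weight_moments,
    reverse_complement,
    scan_motifs,
    select_tss,
)


def _lib(**motifs):
    return load_motif_library(pd.DataFrame(
        {"motif_id": list(motifs), "consensus": list(motifs.values())}))


def test_motif_library_rejects_invalid_iupac():
    with pytest.raises(ValueError):
        _lib(bad="ACGX")


def test_select_tss_longest_transcript_rule():
    a = pd.DataFrame([
        {"gene_id": "plus", "contig": "c1", "strand": "+", "start": 1000, "end": 2000},
        {"gene_id": "minus", "contig": "c2", "strand": "-", "start": 500, "end": 2000},
        {"gene_id": "only_a", "contig": "c3", "strand": "+", "start": 300, "end": 900},
    ])
    b = pd.DataFrame([
        {"gene_id": "plus", "contig": "c1", "strand": "+", "start": 900, "end": 2000},
        {"gene_id": "minus", "contig": "c2", "strand": "-", "start": 500, "end": 2100},
    ])
    tss = select_tss(a, b).set_index("gene_id")
    assert tss.loc["plus", "tss"] == 900      # smaller start wins on +
    assert tss.loc["plus", "tss_source"] == "b"
    assert tss.loc["minus", "tss"] == 2100    # larger end wins on -
    assert tss.loc["only_a", "tss"] == 300
    assert tss.loc["only_a", "tss_source"] == "a"


def test_select_tss_skips_strand_conflicts():
    a = pd.DataFrame([{"gene_id": "g", "contig": "c", "strand": "+", "start": 10, "end": 20}])
    b = pd.DataFrame([{"gene_id": "g", "contig": "c", "strand": "-", "start": 10, "end": 20}])
    with pytest.warns(UserWarning):
        assert select_tss(a, b).empty


def test_extract_promoter_exact_windows():
    genome = {"c": "A" * 1500 + "CCC"}
    rec = extract_promoter(genome, "c", tss=1501, strand="+", length=1500)
    assert rec.sequence == "A" * 1500
    assert not rec.clipped


def test_extract_promoter_minus_strand_hand_case():
    # contig ACGTACGT, gene on minus strand with TSS at base 4 (the T):
    # promoter = bases 5..8 (ACGT) reverse-complemented = ACGT
    genome = {"c": "ACGTACGT"}
    rec = extract_promoter(genome, "c", tss=4, strand="-", length=4)
    assert rec.sequence == reverse_complement("ACGT") == "ACGT"
    rec2 = extract_promoter(genome, "c", tss=4, strand="-", length=2)
    assert rec2.sequence == reverse_complement("AC") == "GT"


def test_extract_promoter_clipping_and_errors():
    genome = {"c": "ACGT" * 50}
    rec = extract_promoter(genome, "c", tss=101, strand="+", length=1500)
    assert rec.clipped and len(rec.sequence) == 100
    with pytest.raises(ValueError):
        extract_promoter(genome, "c", tss=0, strand="+")
    with pytest.raises(ValueError):
        extract_promoter(genome, "c", tss=10, strand="*")


@pytest.mark.parametrize(
    "seq, motif, expected",
    [
        ("AATGACGTTT", "TGACGT", [(2, "+")]),
        ("ACGT", "ACGT", [(0, "+"), (0, "-")]),  # palindrome hits both strands
        ("TGATGT", "TGW", [(0, "+"), (3, "+")]),
    ],
)
def test_scan_motifs_offsets(seq, motif, expected):
    hits = scan_motifs(seq, _lib(m=motif))
    got = sorted((h.offset, h.strand) for h in hits)
    for off, strand in expected:
        assert (off, strand) in got
    plus = [(h.offset, h.strand) for h in hits if h.strand == "+"]
    want_plus = [(o, s) for o, s in expected if s == "+"]
    assert sorted(plus) == sorted(want_plus)


def test_scan_motifs_overlapping_matches():
    hits = scan_motifs("AAAA", _lib(m="AA"))
    assert sorted(h.offset for h in hits if h.strand == "+") == [0, 1, 2]


def test_zscore_absent_for_no_hits():
    assert positional_zscore([], 1500, 6) is None


def test_zscore_single_hit_matches_enumeration_oracle():
    P, L = 1500, 6
    weights = [(P - d) / P for d in range(P - L + 1)]
    mu = sum(weights) / len(weights)
    var = sum((w - mu) ** 2 for w in weights) / len(weights)
    oracle = ((P - 0) / P - mu) / var**0.5
    assert abs(positional_zscore([0], P, L) - oracle) < 1e-10
    mu_i, var_i = proximity_weight_moments(P, L)
    assert mu_i == pytest.approx(mu, abs=1e-12)
    assert var_i == pytest.approx(var, abs=1e-15)


@pytest.mark.parametrize("k", [1, 3, 10])
def test_zscore_null_calibration(k):
    rng = np.random.default_rng(17)
    P, L = 1500, 6
    offs = rng.integers(0, P - L + 1, size=(10_000, k))
    z = np.array([positional_zscore(row, P, L) for row in offs])
    assert abs(z.mean()) <= 0.05
    assert 0.95 <= z.std() <= 1.05


def test_zscore_strand_symmetry():
    """Both strands are always scanned, so replacing a motif by its
    reverse complement yields the same hit offsets (strands swapped) and
    the same positional Z-score."""
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), 400))
    seq = seq[:50] + "TGACGT" + seq[56:]
    lib_f = _lib(m="TGACGT")
    lib_r = _lib(m=reverse_complement("TGACGT"))
    hits_f = scan_motifs(seq, lib_f)
    hits_r = scan_motifs(seq, lib_r)
    assert sorted(h.offset for h in hits_f) == sorted(h.offset for h in hits_r)
    assert sorted(h.strand for h in hits_f) == sorted(
        {"+": "-", "-": "+"}[h.strand] for h in hits_r)
    z_f = positional_zscore([h.offset for h in hits_f], 400, 6)
    z_r = positional_zscore([h.offset for h in hits_r], 400, 6)
    assert z_f == pytest.approx(z_r, abs=1e-12)


def _planted_matrices(seed, mutation_rate=0.0):
    from berrysync.promoters import extract_promoters

    lib = {"mA": "TGACGTCA", "mB": "TTGACCGA"}
    g1 = tuple(f"x{i}" for i in range(8))
    g2 = tuple(f"y{i}" for i in range(8))
    groups = [synthetic.PromoterGroupSpec("a", g1, ("mA",), center=60, jitter=30),
              synthetic.PromoterGroupSpec("b", g2, ("mB",), center=60, jitter=30)]
    sim = synthetic.simulate_promoters(groups, lib, seed=seed)
    genome = dict(sim.genome)
    if mutation_rate:
        rng = np.random.default_rng(seed + 1)
        for contig, seq in genome.items():
            arr = np.array(list(seq))
            mask = rng.random(len(arr)) < mutation_rate
            arr[mask] = rng.choice(list("ACGT"), mask.sum())
            genome[contig] = "".join(arr)
    tss = select_tss(sim.annotation_a, sim.annotation_b)
    proms = extract_promoters(genome, tss, 1500)
    mlib = load_motif_library(pd.DataFrame(
        {"motif_id": list(lib), "consensus": list(lib.values())}))
    return build_cre_matrix(proms, mlib, 1500), (g1, g2)


def test_cre_matrix_absent_distinct_from_zero():
    cre, _ = _planted_matrices(0)
    assert cre.absent.to_numpy().any()
    assert not cre.absent.to_numpy().all()
    imput = cre.imputed()
    assert (imput.to_numpy()[cre.absent.to_numpy()] == 0).all()
    assert cre.z.isna().equals(cre.absent)


def test_cluster_recovers_planted_groups():
    from sklearn.metrics import adjusted_rand_score

    cre, (g1, g2) = _planted_matrices(1)
    clus = cluster_cre(cre, n_clusters=2)
    labels = clus.gene_clusters
    truth = [0 if g in g1 else 1 for g in labels.index]
    assert adjusted_rand_score(truth, labels) == 1.0
    newick = linkage_to_newick(clus.gene_linkage, labels.index)
    assert newick.endswith(";") and labels.index[0] in newick


def test_cluster_identical_genes_merge_first():
    z = pd.DataFrame({"m1": [1.0, 1.0, 5.0], "m2": [2.0, 2.0, 0.0]},
                     index=["a", "b", "c"])
    cre = CREMatrix(z=z, absent=z.isna())
    clus = cluster_cre(cre)
    assert clus.gene_linkage[0, 2] == pytest.approx(0.0)


def test_cluster_single_motif_column_degenerate():
    z = pd.DataFrame({"m1": [0.2, 1.5, -1.0]}, index=["a", "b", "c"])
    cre = CREMatrix(z=z, absent=z.isna())
    clus = cluster_cre(cre)
    assert len(clus.gene_clusters) == 3


def test_cluster_drops_all_absent_gene():
    z = pd.DataFrame({"m1": [1.0, np.nan], "m2": [0.5, np.nan]}, index=["a", "b"])
    cre = CREMatrix(z=z, absent=z.isna())
    with pytest.raises(ValueError):
        with pytest.warns(UserWarning):
            cluster_cre(cre)


def test_stability_identical_matrices():
    cre, _ = _planted_matrices(2)
    out = cross_genotype_stability({"g1": cre, "g2": cre})
    assert out["cophenetic_correlation"].iloc[0] == pytest.approx(1.0)
    assert out["adjusted_rand"].iloc[0] == pytest.approx(1.0)


def test_stability_under_one_percent_mutation():
    base, _ = _planted_matrices(3)
    mut, _ = _planted_matrices(3, mutation_rate=0.01)
    out = cross_genotype_stability({"ref": base, "mut": mut})
    assert out["adjusted_rand"].iloc[0] >= 0.8


def test_stability_random_matrices_near_zero():
    rng = np.random.default_rng(9)
    aris = []
    for trial in range(5):
        z1 = pd.DataFrame(rng.normal(size=(20, 4)),
                          index=[f"g{i}" for i in range(20)])
        z2 = pd.DataFrame(rng.normal(size=(20, 4)), index=z1.index)
        m1 = CREMatrix(z=z1, absent=z1.isna())
        m2 = CREMatrix(z=z2, absent=z2.isna())
        out = cross_genotype_stability({"a": m1, "b": m2}, n_clusters=3)
        aris.append(out["adjusted_rand"].iloc[0])
    assert abs(float(np.mean(aris))) < 0.25


def test_stability_requires_shared_genes():
    z1 = pd.DataFrame({"m": [1.0, 2.0]}, index=["a", "b"])
    z2 = pd.DataFrame({"m": [1.0, 2.0]}, index=["c", "d"])
    with pytest.raises(ValueError):
        cross_genotype_stability({"a": CREMatrix(z1, z1.isna()),
                                  "b": CREMatrix(z2, z2.isna())})


def test_gff_roundtrip_through_gffutils(tmp_path):
    """Annotations written as GFF3 parse back identically via gffutils."""
    from berrysync.promoters import read_gene_annotation

    lib = {"m1": "TGACGT"}
    sim = synthetic.simulate_promoters(
        [synthetic.PromoterGroupSpec("g", ("a1", "a2", "a3"), ("m1",))], lib, seed=4)
    p = tmp_path / "a.gff3"
    p.write_text(sim.gff_text("a"))
    parsed = read_gene_annotation(p)
    pd.testing.assert_frame_equal(
        parsed.sort_values("gene_id").reset_index(drop=True),
        sim.annotation_a.sort_values("gene_id").reset_index(drop=True))
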