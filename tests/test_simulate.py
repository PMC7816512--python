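import numpy as np
import pandas as pd
import pytest

import retronaut as rn
from retronaut.simulate import SimConfig, generate_annotation, make_truth, simulate_reads


def _count_ir(cfg, truth=None):
    _, genes = generate_annotation(cfg)
    if truth is None:
        truth = make_truth(genes, cfg)
    reads, design = simulate_reads(cfg, genes, truth)
    ir, es = rn.derive_events(genes)
    idx = rn.JunctionIndex.build(genes, ir, es)
    return rn.count_junctions(reads, idx), design, truth, genes


def test_annotation_shape_and_determinism(tmp_path):
    cfg = SimConfig(n_genes=10, exons_per_gene=(3, 3), seed=5)
    genome, genes = generate_annotation(cfg)
    assert len(genes) == 10
    ir, es = rn.derive_events(genes)
    assert len(ir) == 20 and len(es) == 10
    genome2, genes2 = generate_annotation(cfg)
    assert genome == genome2
    p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
    rn.simulate.write_fasta(genome, p1)
    rn.simulate.write_fasta(genome2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_same_seed_gives_identical_reads():
    cfg = SimConfig(n_genes=5, seed=17)
    _, genes = generate_annotation(cfg)
    truth = make_truth(genes, cfg)
    r1, d1 = simulate_reads(cfg, genes, truth)
    r2, d2 = simulate_reads(cfg, genes, truth)
    pd.testing.assert_frame_equal(r1.blocks, r2.blocks)
    pd.testing.assert_frame_equal(r1.gaps, r2.gaps)
    pd.testing.assert_frame_equal(d1, d2)


def test_infeasible_lengths_and_bad_fractions_rejected():
    with pytest.raises(ValueError, match="exon length"):
        SimConfig(exon_length=(80, 400), read_length=100)
    with pytest.raises(ValueError, match="retention"):
        SimConfig(retention=(1.2, 0.1))
    with pytest.raises(ValueError, match="size factor"):
        SimConfig(n_replicates=2, library_size_factors=(1.0, 1.0, 1.0))


def test_zero_retention_yields_no_boundary_reads():
    cfg = SimConfig(n_genes=6, retention=(0.0, 0.0), inclusion=(1.0, 1.0), seed=2)
    counts, _, _, _ = _count_ir(cfg)
    assert counts.ir["EI5"].sum() == 0 and counts.ir["EI3"].sum() == 0
    assert counts.ir["EE"].sum() > 0


def test_full_retention_yields_no_splice_junction_reads():
    cfg = SimConfig(n_genes=6, retention=(1.0, 1.0), inclusion=(1.0, 1.0), seed=2)
    counts, _, _, _ = _count_ir(cfg)
    assert counts.ir["EE"].sum() == 0
    assert counts.ir["EI5"].sum() > 0 and counts.ir["EI3"].sum() > 0


def test_gene_counts_match_configured_mean():
    """Across many genes the mean fragment count is mu*sf within 3 SE."""
    mu = 60.0
    cfg = SimConfig(
        n_genes=150,
        mean_expression=mu,
        expression_sdlog=0.0,
        library_size_factors=(1.0,) * 6,
        seed=21,
    )
    counts, design, _, _ = _count_ir(cfg)
    draws = counts.gene.to_numpy().ravel().astype(float)
    se = np.sqrt((mu + cfg.dispersion * mu**2) / draws.size)
    assert abs(draws.mean() - mu) < 3 * se


@pytest.mark.parametrize("depth,tol_pp", [(100, 5.0), (1600, 1.5)])
def test_pir_estimate_converges_to_configured_retention(depth, tol_pp):
    """Empirical PIR approaches the true retention as depth grows."""
    cfg = SimConfig(n_genes=20, exons_per_gene=(3, 3), seed=13)
    _, genes = generate_annotation(cfg)
    ir, _ = rn.derive_events(genes)
    ret = pd.DataFrame(
        {"ret1": 0.3, "ret2": 0.3}, index=ir["event_id"]
    )
    truth = make_truth(genes, cfg, retention=ret, junction_depth=depth)
    reads, design = simulate_reads(cfg, genes, truth)
    es = rn.derive_events(genes)[1]
    idx = rn.JunctionIndex.build(genes, ir, es)
    counts = rn.count_junctions(reads, idx)
    res = rn.test_splicing(counts.ir, design, "IR")
    mae = (res["pir1"] - 30.0).abs().mean()
    assert mae < tol_pp


def test_truth_table_delta_signs_follow_fractions():
    cfg = SimConfig(n_genes=8, seed=1)
    _, genes = generate_annotation(cfg)
    ir, _ = rn.derive_events(genes)
    ret = pd.DataFrame({"ret1": 0.1, "ret2": 0.6}, index=ir["event_id"][:3])
    truth = make_truth(genes, cfg, retention=ret)
    changed = truth.introns.set_index("event_id").loc[ir["event_id"][:3]]
    assert (changed["delta_pir_true"] == 50.0).all()
    others = truth.introns[~truth.introns["event_id"].isin(ir["event_id"][:3])]
    assert (others["delta_pir_true"] == 0.0).all()
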