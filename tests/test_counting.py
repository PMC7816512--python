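import pytest

import retronaut as rn
from retronaut.counting import JunctionIndex, assign_read, count_junctions
from retronaut.reads import Read, ReadTable
from retronaut.simulate import SimConfig, generate_annotation, make_truth, simulate_reads

from conftest import make_gene
from helpers import counts_to_dicts, naive_junction_counts


@pytest.fixture
def index(three_exon_gene):
    ir, es = rn.derive_events([three_exon_gene])
    return JunctionIndex.build([three_exon_gene], ir, es)


def test_read_inside_exon_hits_nothing(index):
    read = Read("s", "chr1", ((10, 90),))
    assert assign_read(read, index) == set()


def test_spliced_read_matching_intron_hits_ee(index):
    # gap (100, 200) over intron 0, 20 aligned bases each side; the same
    # junction is inclusion evidence for the downstream internal exon
    read = Read("s", "chr1", ((80, 100), (200, 220)))
    assert assign_read(read, index, min_overhang=6) == {
        ("gA.I0", "EE"),
        ("gA.E1", "INC1"),
    }


def test_overhang_rule_blocks_short_anchors(index):
    # boundary at 100 covered with only 5 bases on the exon side
    read = Read("s", "chr1", ((95, 195),))
    assert assign_read(read, index, min_overhang=6) == set()
    # spliced read with 5-base anchor on the left
    read = Read("s", "chr1", ((95, 100), (200, 260)))
    assert assign_read(read, index, min_overhang=6) == set()


def test_boundary_read_hits_ei_cells(index):
    read = Read("s", "chr1", ((90, 190),))  # covers boundary 100 well
    assert assign_read(read, index) == {("gA.I0", "EI5")}
    read = Read("s", "chr1", ((150, 250),))  # covers boundary 200
    assert assign_read(read, index) == {("gA.I0", "EI3")}


def test_minus_strand_swaps_ei_labels():
    gene = make_gene(strand="-")
    ir, es = rn.derive_events([gene])
    idx = JunctionIndex.build([gene], ir, es)
    read = Read("s", "chr1", ((90, 190),))  # genomic start of intron 0
    assert assign_read(read, idx) == {("gA.I0", "EI3")}


def test_one_read_may_hit_both_boundaries_of_short_intron():
    gene = make_gene(exon_bounds=((0, 150), (190, 340)))  # 40 bp intron
    ir, es = rn.derive_events([gene])
    idx = JunctionIndex.build([gene], ir, es)
    read = Read("s", "chr1", ((120, 220),))  # spans the whole intron
    assert assign_read(read, idx) == {("gA.I0", "EI5"), ("gA.I0", "EI3")}


def test_splice_junction_feeds_inclusion_of_neighbour_exon(index):
    """An EE junction read is also inclusion evidence for the internal exon."""
    ir, es = rn.derive_events([make_gene()])
    read = Read("s", "chr1", ((80, 100), (200, 220)))
    hits = assign_read(read, index)
    # the same gap is INC1 of gA.E1
    rt = ReadTable.from_reads([read])
    counts = count_junctions(rt, index)
    assert counts.es.set_index("event_id").loc["gA.E1", "INC1"] == 1
    assert counts.ir.set_index("event_id").loc["gA.I0", "EE"] == 1


def test_skipping_read_counts_skp():
    read = Read("s", "chr1", ((80, 100), (400, 420)))  # gap (100, 400)
    gene = make_gene()
    ir, es = rn.derive_events([gene])
    idx = JunctionIndex.build([gene], ir, es)
    assert assign_read(read, idx) == {("gA.E1", "SKP")}


def test_empty_read_set_gives_all_zero_counts(index):
    rt = ReadTable.from_reads([Read("s", "chrZ", ((0, 50),))])
    counts = count_junctions(rt, index)
    assert counts.ir[["EE", "EI5", "EI3"]].to_numpy().sum() == 0
    assert counts.es[["INC1", "INC2", "SKP"]].to_numpy().sum() == 0
    assert counts.gene.to_numpy().sum() == 0


def test_counting_is_order_independent(rng):
    cfg = SimConfig(n_genes=4, mean_expression=40, seed=6)
    _, genes = generate_annotation(cfg)
    truth = make_truth(genes, cfg)
    reads, _ = simulate_reads(cfg, genes, truth)
    objs = list(reads.iter_reads())
    perm = list(rng.permutation(len(objs)))
    ir, es = rn.derive_events(genes)
    idx = JunctionIndex.build(genes, ir, es)
    c1 = count_junctions(ReadTable.from_reads(objs), idx)
    c2 = count_junctions(ReadTable.from_reads([objs[i] for i in perm]), idx)
    assert c1.ir.equals(c2.ir) and c1.es.equals(c2.es)
    assert c1.gene.equals(c2.gene)


def test_indexed_counter_matches_naive_oracle_small():
    cfg = SimConfig(n_genes=3, mean_expression=120, expression_sdlog=0.0,
                    retention=(0.3, 0.3), inclusion=(0.7, 0.7), seed=8)
    _, genes = generate_annotation(cfg)
    truth = make_truth(genes, cfg)
    reads, _ = simulate_reads(cfg, genes, truth)
    ir, es = rn.derive_events(genes)
    idx = JunctionIndex.build(genes, ir, es)
    counts = count_junctions(reads, idx)
    got = counts_to_dicts(counts)
    expect = naive_junction_counts(reads.iter_reads(), genes, ir, es)
    assert got == expect


def test_gene_count_is_reads_starting_in_span(index, three_exon_gene):
    rt = ReadTable.from_reads(
        [
            Read("s", "chr1", ((0, 100),)),      # at gene start -> counted
            Read("s", "chr1", ((499, 599),)),    # starts inside -> counted
            Read("s", "chr1", ((500, 600),)),    # starts at end -> not
        ]
    )
    counts = count_junctions(rt, index)
    assert counts.gene.loc["gA", "s"] == 2
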