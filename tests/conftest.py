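import os

import pytest

from episuite.fixtures import synth_alignments, synth_gene_models, synth_genome


@pytest.fixture(scope="session")
def small_genome(tmp_path_factory):
    """100 kb single-chromosome genome with ~1000 CpGs, seed 42."""
    d = tmp_path_factory.mktemp("genome")
    return synth_genome(str(d / "genome.fa"), length=100_000, gc=0.4,
                        cpg_density=0.01, seed=42)


@pytest.fixture(scope="session")
def small_gtf(tmp_path_factory):
    d = tmp_path_factory.mktemp("genes")
    return synth_gene_models({"chr1": 200_000}, str(d / "genes.gtf"),
                             n_genes=6, seed=2)


@pytest.fixture(scope="session")
def background_bam(tmp_path_factory):
    """Uniform-background alignments over a 200 kb chromosome."""
    d = tmp_path_factory.mktemp("aln")
    return synth_alignments({"chr1": 200_000}, str(d / "bg.bam"),
                            background_rate=0.02, seed=11)


@pytest.fixture(scope="session")
def small_methylomes(tmp_path_factory, small_genome):
    """2x2 grouped methylomes on the 100 kb genome, 3 planted DMRs, seed 7."""
    from episuite.fixtures import synth_methylomes

    d = tmp_path_factory.mktemp("meth")
    stores, truth = synth_methylomes(
        small_genome, str(d), groups=2, samples_per_group=2,
        dmr_spec=(3, 20, 0.4), seed=7,
    )
    return stores, truth


def write_table(path, rows):
    """Write a cytosine report TSV from (chrom,pos,strand,context,c,t) rows."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return str(path)
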