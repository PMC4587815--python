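"""Synthetic input generators with machine-readable ground truth.

Every data type the toolkit consumes can be simulated here: genomes
with a controlled CpG density, whole-genome bisulfite methylomes with
planted differentially methylated regions and partially methylated
domains, ChIP/RNA-style alignments with fold-enriched features, gene
models and GO annotation graphs.  All generators are deterministic
under a seed, and planted features are returned (and serializable as
BED + JSON) so recall/precision of the callers can be computed without
re-deriving any parameter.

The bisulfite emulation works at the per-cytosine count level: each
CpG's per-sample methylation level is Beta-distributed around its group
mean (concentration parameter controls overdispersion, so rank tests
face realistic between-sample noise), sequencing depth is Poisson, and
C-supporting reads are Binomial(depth, level).  It does not simulate
read sequences, alignment artefacts, or context-dependent conversion
failure.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pysam

from .intervals import Interval, IntervalSet
from .methstore import MethylomeStore, import_methylation_table

BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTruth:
    """Planted features and the parameters that produced them."""

    seed: int
    planted_dmrs: list[Interval] = field(default_factory=list)
    planted_pmds: list[Interval] = field(default_factory=list)
    planted_enhancers: list[Interval] = field(default_factory=list)
    planted_lncrnas: list[Interval] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def save(self, prefix: str) -> None:
        payload = {"seed": self.seed, "params": self.params}
        for name in ("planted_dmrs", "planted_pmds", "planted_enhancers", "planted_lncrnas"):
            ivs: list[Interval] = getattr(self, name)
            payload[name] = [[iv.chrom, iv.start, iv.end] for iv in ivs]
            if ivs:
                IntervalSet(ivs).to_bed(f"{prefix}.{name}.bed")
        with open(prefix + ".truth.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# genome

def synth_genome(
    out_path: str,
    n_chroms: int = 1,
    length: int = 1_000_000,
    gc: float = 0.4,
    cpg_density: float = 0.01,
    seed: int = 0,
) -> str:
    """Write a random FASTA with ~``cpg_density`` CpG dinucleotides per bp.

    Background bases are drawn i.i.d. at the requested GC content, then
    accidental CpGs are destroyed and the requested number planted back
    at random positions, so the realized density is controlled.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    with open(out_path, "w") as fh:
        for ci in range(n_chroms):
            chrom = f"chr{ci + 1}"
            seq = BASES[rng.choice(4, size=length, p=probs)]
            # remove chance CpGs, then plant the requested number
            cg = np.flatnonzero((seq[:-1] == "C") & (seq[1:] == "G"))
            seq[cg + 1] = "A"
            if gc > 0 and cpg_density > 0:
                n_cpg = int(round(length * cpg_density))
                starts = rng.choice(length - 1, size=min(3 * n_cpg, length // 2),
                                    replace=False)
                starts = np.sort(starts)
                picked: list[int] = []
                last = -2
                for s in starts:
                    if s - last >= 2:
                        picked.append(int(s))
                        last = s
                    if len(picked) == n_cpg:
                        break
                for s in picked:
                    seq[s] = "C"
                    seq[s + 1] = "G"
            fh.write(f">{chrom}\n")
            text = "".join(seq)
            for i in range(0, length, 60):
                fh.write(text[i : i + 60] + "\n")
    # refresh any stale index
    for ext in (".fai",):
        if os.path.exists(out_path + ext):
            os.remove(out_path + ext)
    return out_path


def cpg_positions(fasta_path: str) -> dict[str, np.ndarray]:
    """0-based positions of plus-strand CpG cytosines per chromosome."""
    import pyfaidx

    out: dict[str, np.ndarray] = {}
    fa = pyfaidx.Fasta(fasta_path)
    for chrom in fa.keys():
        seq = np.array(list(str(fa[chrom][:]).upper()))
        out[chrom] = np.flatnonzero((seq[:-1] == "C") & (seq[1:] == "G"))
    return out


# ---------------------------------------------------------------------------
# methylomes

def synth_methylomes(
    genome: str,
    out_dir: str,
    groups: int = 2,
    samples_per_group: int = 3,
    depth_mean: float = 30.0,
    base_level_beta: tuple[float, float] = (5.0, 1.5),
    concentration: float = 30.0,
    dmr_spec: tuple[int, int, float] = (10, 20, 0.4),
    pmd_spec: Optional[tuple[int, int, float]] = None,
    conversion_rate: float = 0.99,
    error_rate: float = 0.001,
    seed: int = 0,
) -> tuple[dict[str, list[MethylomeStore]], SyntheticTruth]:
    """Simulate grouped WGBS methylomes with planted DMRs and PMDs.

    Site grand means follow Beta(``base_level_beta``); inside a planted
    DMR the first group's mean is reset to Uniform(0.6, 0.9) and every
    other group's mean is lowered by ``delta`` (clipped), giving a known
    between-group difference.  ``dmr_spec`` = (count, CpGs per DMR,
    delta); ``pmd_spec`` = (count, width bp, level) plants domains of
    intermediate methylation in all groups.  Per-sample, per-site levels
    are Beta with the given concentration, depth Poisson, #C Binomial.
    Stores are written under ``out_dir`` and imported with the stated
    conversion/error rates.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    pos_by_chrom = cpg_positions(genome)
    n_dmr, width_cpg, delta = dmr_spec

    site_chrom: list[str] = []
    site_pos: list[np.ndarray] = []
    for chrom in sorted(pos_by_chrom):
        site_chrom.append(chrom)
        site_pos.append(pos_by_chrom[chrom])

    # group means per site, planted features
    truth = SyntheticTruth(seed=seed, params={
        "groups": groups, "samples_per_group": samples_per_group,
        "depth_mean": depth_mean, "dmr_spec": list(dmr_spec),
        "pmd_spec": list(pmd_spec) if pmd_spec else None,
        "concentration": concentration,
    })
    group_means: dict[str, np.ndarray] = {}
    for chrom, pos in zip(site_chrom, site_pos):
        m = rng.beta(*base_level_beta, size=pos.size)
        means = np.tile(m, (groups, 1))
        group_means[chrom] = means

    # DMRs: runs of consecutive CpGs, placed without overlap, spread evenly
    for chrom, pos in zip(site_chrom, site_pos):
        if n_dmr == 0 or pos.size < width_cpg:
            break
        usable = pos.size - width_cpg
        anchors = np.sort(rng.choice(usable // max(width_cpg * 3, 1),
                                     size=min(n_dmr, usable // max(width_cpg * 3, 1)),
                                     replace=False)) * max(width_cpg * 3, 1)
        for a in anchors[:n_dmr]:
            sl = slice(int(a), int(a) + width_cpg)
            high = rng.uniform(0.6, 0.9, size=width_cpg)
            group_means[chrom][0, sl] = high
            for g in range(1, groups):
                group_means[chrom][g, sl] = np.clip(high - delta, 0.02, 0.98)
            truth.planted_dmrs.append(
                Interval(chrom, int(pos[sl][0]), int(pos[sl][-1]) + 2)
            )
        break  # plant all DMRs on the first chromosome

    if pmd_spec:
        n_pmd, width_bp, pmd_level = pmd_spec
        chrom, pos = site_chrom[0], site_pos[0]
        chrom_len = int(pos[-1]) + 2
        for i in range(n_pmd):
            start = int(rng.integers(0, max(chrom_len - width_bp, 1)))
            sel = (pos >= start) & (pos < start + width_bp)
            lv = np.clip(rng.normal(pmd_level, 0.03, size=int(sel.sum())), 0.05, 0.95)
            group_means[chrom][:, sel] = lv
            truth.planted_pmds.append(Interval(chrom, start, start + width_bp))

    stores: dict[str, list[MethylomeStore]] = {}
    for g in range(groups):
        gname = f"group{g + 1}"
        stores[gname] = []
        for s in range(samples_per_group):
            sample = f"{gname}_s{s + 1}"
            tsv = os.path.join(out_dir, sample + ".cytosines.tsv")
            with open(tsv, "w") as fh:
                for chrom, pos in zip(site_chrom, site_pos):
                    m = np.clip(group_means[chrom][g], 0.01, 0.99)
                    lv = rng.beta(concentration * m, concentration * (1 - m))
                    depth = rng.poisson(depth_mean, size=pos.size)
                    c = rng.binomial(depth, lv)
                    for p, d, ci in zip(pos, depth, c):
                        if d == 0:
                            continue
                        fh.write(f"{chrom}\t{int(p) + 1}\t+\tCG\t{int(ci)}\t{int(d - ci)}\n")
            store = import_methylation_table(
                tsv, sample, conversion_rate, error_rate,
                os.path.join(out_dir, sample + ".bsstore.gz"),
            )
            stores[gname].append(store)
    truth.save(os.path.join(out_dir, "methylomes"))
    return stores, truth


# ---------------------------------------------------------------------------
# alignments

def synth_alignments(
    chrom_sizes: Mapping[str, int],
    out_bam: str,
    features: Sequence[tuple[Interval, float]] = (),
    background_rate: float = 0.01,
    read_len: int = 50,
    seed: int = 0,
) -> str:
    """Write a sorted, indexed BAM of uniform background reads plus
    ``fold``-enriched reads over feature intervals.

    ``background_rate`` is expected reads per bp; a feature with fold f
    receives (f - 1) x background extra reads so its total density is
    f x background.
    """
    for iv, fold in features:
        if fold < 1:
            raise ValueError("feature fold must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_sizes[c])} for c in chroms],
    }
    starts_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for c in chroms:
        span = max(chrom_sizes[c] - read_len, 1)
        n_bg = rng.poisson(background_rate * span)
        starts_by_chrom[c].extend(rng.integers(0, span, size=n_bg).tolist())
    for iv, fold in features:
        span = max(iv.length - read_len, 1)
        n_extra = rng.poisson((fold - 1.0) * background_rate * span)
        starts_by_chrom[iv.chrom].extend(
            (iv.start + rng.integers(0, span, size=n_extra)).tolist()
        )
    with pysam.AlignmentFile(out_bam, "wb", header=header) as bam:
        for tid, c in enumerate(chroms):
            for i, start in enumerate(sorted(starts_by_chrom[c])):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"read_{c}_{i}"
                a.reference_id = tid
                a.reference_start = int(start)
                a.mapping_quality = 60
                a.cigarstring = f"{read_len}M"
                a.query_sequence = "A" * read_len
                a.flag = 0
                bam.write(a)
    pysam.index(out_bam)
    return out_bam


# ---------------------------------------------------------------------------
# gene models

def synth_gene_models(
    chrom_sizes: Mapping[str, int],
    out_gtf: str,
    n_genes: int = 10,
    gene_length: tuple[int, int] = (3_000, 8_000),
    isoform_tss_spread: int = 200,
    seed: int = 0,
) -> str:
    """Write a GTF of non-overlapping genes with 1-2 isoforms each.

    Genes alternate strands pseudo-randomly; the second isoform's TSS is
    shifted inward by up to ``isoform_tss_spread`` bp.  Each transcript
    gets 2-4 exons covering both span ends.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    lines: list[str] = []
    gi = 0
    per_chrom = int(np.ceil(n_genes / len(chroms)))
    for chrom in chroms:
        L = chrom_sizes[chrom]
        cursor = int(rng.integers(2_000, 5_000))
        for _ in range(per_chrom):
            if gi >= n_genes:
                break
            glen = int(rng.integers(*gene_length))
            if cursor + glen + 2_000 > L:
                break
            start, end = cursor, cursor + glen  # 0-based half-open
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            gene_id = f"G{gi:04d}"
            n_iso = 1 + int(rng.random() < 0.5)
            for iso in range(n_iso):
                tx_id = f"{gene_id}.t{iso + 1}"
                shift = 0 if iso == 0 else int(rng.integers(1, isoform_tss_spread + 1))
                if strand == "+":
                    ts, te = start + shift, end
                else:
                    ts, te = start, end - shift
                attrs = (f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                         f'gene_name "sym{gene_id}";')
                lines.append(f"{chrom}\tsynth\ttranscript\t{ts + 1}\t{te}\t.\t{strand}\t.\t{attrs}")
                n_ex = int(rng.integers(2, 5))
                edges = np.sort(rng.choice(np.arange(ts + 100, te - 100, 50),
                                           size=2 * (n_ex - 1), replace=False))
                bounds = [ts] + edges.tolist() + [te]
                for e in range(n_ex):
                    es, ee = bounds[2 * e], bounds[2 * e + 1]
                    if e == n_ex - 1:
                        ee = te
                    lines.append(
                        f"{chrom}\tsynth\texon\t{es + 1}\t{ee}\t.\t{strand}\t.\t{attrs}"
                    )
            cursor = end + int(rng.integers(3_000, 10_000))
    with open(out_gtf, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return out_gtf


# ---------------------------------------------------------------------------
# gene ontology

def synth_go(
    out_dag: str,
    out_gene2term: str,
    n_terms: int = 30,
    max_parents: int = 2,
    n_genes: int = 100,
    terms_per_gene: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> tuple[str, str]:
    """Write an acyclic GO-like DAG and gene-to-term annotations.

    Term i may only point at earlier terms, which guarantees
    acyclicity; genes are annotated to random (leaf-biased) terms.
    """
    if n_terms < 1 or n_genes < 1:
        raise ValueError("need at least one term and one gene")
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    with open(out_dag, "w") as fh:
        fh.write(f"{terms[0]}\t.\tBP\troot\n")
        for i in range(1, n_terms):
            k = 1 + int(rng.integers(0, max_parents)) if i > 1 else 1
            parents = rng.choice(i, size=min(k, i), replace=False)
            for p in sorted(parents.tolist()):
                fh.write(f"{terms[i]}\t{terms[p]}\tBP\tterm{i + 1}\n")
    with open(out_gene2term, "w") as fh:
        for g in range(n_genes):
            gene = f"gene{g + 1:04d}"
            k = int(rng.integers(terms_per_gene[0], terms_per_gene[1] + 1))
            # leaf bias: sample from the deeper half of the term list
            lo = n_terms // 2 if n_terms > 3 else 0
            chosen = rng.choice(np.arange(lo, n_terms), size=min(k, n_terms - lo),
                                replace=False)
            for t in sorted(chosen.tolist()):
                fh.write(f"{gene}\t{terms[t]}\n")
    return out_dag, out_gene2term
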