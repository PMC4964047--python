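"""A coherent miniature dataset exercising the whole pipeline.

``write_fixtures`` lays out, on one synthetic chromosome, every input
the analyses consume — phased VCF genotypes, footprint/DHS/track BEDs,
depth/mappability/segdup artifact tracks, allele flank FASTA, JASPAR
PFMs, allelic read counts, an expression matrix with genotype dosages
and an enhancer-promoter map — with planted truths throughout:

* ten SNPs failing each artifact filter (depth flank, 50-mer
  mappability, segmental duplication, MAF < 1%, Hardy-Weinberg), plus a
  decoy segdup below the length/identity thresholds that must NOT flag;
* seventy clean footprint SNPs, each the center of a 5-kb coalescent
  cluster; seven clusters carry an old planted balanced polymorphism;
* one DHS track covering every balanced focal SNP but only a third of
  the controls (a ~3x overlap enrichment), among uninformative tracks;
* four "common" and four allele-specific PFMs at one balanced SNP
  (motif-divergence score exactly 1.0);
* allele-biased read counts (ref/alt ratio 2) at balanced SNPs against
  unbiased controls;
* one gene whose expression tracks the dosage of one balanced SNP (the
  planted eQTL) and one gene-set term collecting the balanced targets.

Everything is generated from the config seed; a manifest of the planted
truth is returned and written as JSON.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from . import io
from .simulate import (
    SimConfig,
    simulate_neutral_haplotypes,
    simulate_balanced_haplotypes,
    simulate_allelic_reads,
)

__all__ = ["write_fixtures"]

CHROM = "chr1"
N_CLUSTERS = 70
N_BALANCED = 7
CLUSTER_START = 5_000_000
CLUSTER_SPACING = 20_000
HIGH_DEPTH_REGION = (1_000_000, 1_010_000)
NONUNIQUE_REGION = (2_500_000, 2_501_000)
SEGDUP_REGION = (3_000_000, 3_005_000)
BASES = "ACGT"


def _focal_site(matrix, center: int) -> int:
    """Pick the site nearest the window center with MAF >= 0.1."""
    freqs = matrix.derived_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    ok = np.flatnonzero(maf >= 0.1)
    if not ok.size:
        ok = np.arange(matrix.n_sites)
    return int(ok[np.argmin(np.abs(matrix.positions[ok] - center))])


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _consensus_pfm(word: str, strong_pos: int | None = None) -> np.ndarray:
    """PFM whose consensus is ``word``: weak (40/20/20/20) columns, with
    one optional near-deterministic (100/0/0/0) column."""
    counts = np.full((4, len(word)), 20.0)
    for j, c in enumerate(word):
        counts[BASES.index(c), j] = 40.0
        if j == strong_pos:
            counts[:, j] = 0.0
            counts[BASES.index(c), j] = 100.0
    return counts


def write_fixtures(out_dir, config: SimConfig | None = None) -> dict:
    """Write the miniature dataset into ``out_dir``; return the manifest."""
    cfg = config or SimConfig(seed=0, n_haplotypes=120, theta=5.0, class_split_time=6.0)
    os.makedirs(out_dir, exist_ok=True)
    rng = cfg.rng()
    n_hap = cfg.n_haplotypes
    n_ind = n_hap // 2

    vcf_rows = []
    vcf_cols = []
    footprints = []
    manifest: dict = {
        "seed": cfg.seed,
        "n_individuals": n_ind,
        "planted_filter_failures": {},
        "balanced_clusters": [],
        "clean_focal_snps": [],
    }

    def add_snp(snp_id, pos, column, in_footprint=True):
        ref, alt = rng.choice(list(BASES), size=2, replace=False)
        vcf_rows.append(
            {"chrom": CHROM, "pos": int(pos), "snp_id": snp_id, "ref": ref, "alt": alt}
        )
        vcf_cols.append(np.asarray(column, dtype=np.int8))
        if in_footprint:
            footprints.append((CHROM, int(pos) - 7, int(pos) + 8, snp_id))

    # --- planted artifact-filter failures -------------------------------
    def random_column(freq):
        return (rng.random(n_hap) < freq).astype(np.int8)

    planted = {}
    pos_cursor = {"depth": 1_015_000, "mappability": NONUNIQUE_REGION[0] + 100,
                  "segdup": SEGDUP_REGION[0] + 200, "maf": 4_000_000, "hwe": 4_200_000}
    steps = {"depth": 3000, "mappability": 80, "segdup": 400, "maf": 5000, "hwe": 5000}
    for kind in ("depth", "mappability", "segdup", "maf", "hwe"):
        ids = []
        for i in range(10):
            snp_id = f"fail_{kind}_{i}"
            pos = pos_cursor[kind] + i * steps[kind]
            if kind == "maf":
                col = np.zeros(n_hap, dtype=np.int8)
                col[int(rng.integers(n_hap))] = 1
            elif kind == "hwe":
                col = np.tile([0, 1], n_ind).astype(np.int8)
            else:
                col = random_column(rng.uniform(0.2, 0.5))
            add_snp(snp_id, pos, col)
            ids.append(snp_id)
        planted[kind] = ids
    manifest["planted_filter_failures"] = planted

    # --- clean coalescent clusters --------------------------------------
    balanced_ids, control_candidate_ids = [], []
    flank_seqs = {}
    cluster_of = {}
    for c in range(N_CLUSTERS):
        center = CLUSTER_START + c * CLUSTER_SPACING
        is_balanced = c < N_BALANCED
        sub_cfg = SimConfig(
            seed=cfg.seed, n_haplotypes=n_hap, window_bp=cfg.window_bp,
            theta=cfg.theta, class_split_time=cfg.class_split_time,
        )
        if is_balanced:
            m = simulate_balanced_haplotypes(sub_cfg, rng=rng)
            focal = m.focal_index
        else:
            m = simulate_neutral_haplotypes(sub_cfg, rng=rng)
            focal = _focal_site(m, sub_cfg.window_bp // 2)
        # random mating: pair haplotypes into individuals in shuffled order
        m.alleles = m.alleles[rng.permutation(n_hap)]
        offset = center - sub_cfg.window_bp // 2
        for j in range(m.n_sites):
            snp_id = (
                f"clu{c:02d}_focal" if j == focal else f"clu{c:02d}_s{j}"
            )
            add_snp(snp_id, m.positions[j] + offset, m.alleles[:, j],
                    in_footprint=(j == focal))
        focal_id = f"clu{c:02d}_focal"
        cluster_of[focal_id] = c
        manifest["clean_focal_snps"].append(focal_id)
        if is_balanced:
            balanced_ids.append(focal_id)
            manifest["balanced_clusters"].append(focal_id)
        else:
            control_candidate_ids.append(focal_id)

    records = pd.DataFrame(vcf_rows)
    hap = np.array(vcf_cols, dtype=np.int8).T
    order = np.argsort(records["pos"].to_numpy(), kind="stable")
    records = records.iloc[order].reset_index(drop=True)
    hap = hap[:, order]
    io.write_vcf(os.path.join(out_dir, "genotypes.vcf"), records, hap)

    # --- BED tracks ------------------------------------------------------
    io.write_bed(
        os.path.join(out_dir, "footprints.bed"),
        pd.DataFrame(sorted(footprints), columns=["chrom", "start", "end", "name"]),
    )
    bg_starts = np.arange(8_000_000, 8_999_000, 1000)
    depth = pd.DataFrame(
        {
            "chrom": CHROM,
            "start": np.concatenate([[HIGH_DEPTH_REGION[0]], bg_starts]),
            "end": np.concatenate([[HIGH_DEPTH_REGION[1]], bg_starts + 1000]),
            "name": "depth",
            "score": np.concatenate(
                [[1000.0], np.round(rng.normal(30.0, 5.0, bg_starts.size), 3)]
            ),
        }
    ).sort_values(["chrom", "start"], ignore_index=True)
    io.write_bed(os.path.join(out_dir, "depth.bed"), depth)
    io.write_bed(
        os.path.join(out_dir, "mappability_nonunique.bed"),
        pd.DataFrame([(CHROM, *NONUNIQUE_REGION, "nonunique")],
                     columns=["chrom", "start", "end", "name"]),
    )
    segdups = pd.DataFrame(
        [
            (CHROM, *SEGDUP_REGION, "segdup_real", 0.95),
            # decoy below the identity threshold, overlapping a clean focal SNP
            (CHROM, CLUSTER_START + 9 * CLUSTER_SPACING - 1000,
             CLUSTER_START + 9 * CLUSTER_SPACING + 1000, "segdup_decoy", 0.85),
        ],
        columns=["chrom", "start", "end", "name", "identity"],
    )
    segdups["length"] = segdups["end"] - segdups["start"]
    segdups[["chrom", "start", "end", "name", "length", "identity"]].to_csv(
        os.path.join(out_dir, "segdups.tsv"), sep="\t", index=False
    )

    # DHS tracks: CT3 is the planted ~3x-enriched cell type
    focal_pos = {r.snp_id: r.pos for r in records.itertuples()
                 if r.snp_id.endswith("_focal")}
    tracks: dict[str, list] = {f"CT{i}": [] for i in range(1, 6)}
    for i, snp_id in enumerate(manifest["clean_focal_snps"]):
        pos = focal_pos[snp_id]
        iv = (CHROM, pos - 100, pos + 100, snp_id)
        if snp_id in balanced_ids or i % 3 == 0:
            tracks["CT3"].append(iv)
        for t in ("CT1", "CT2", "CT4", "CT5"):
            if rng.random() < 0.5:
                tracks[t].append(iv)
    for t, ivs in tracks.items():
        io.write_bed(
            os.path.join(out_dir, f"dhs_{t}.bed"),
            pd.DataFrame(sorted(ivs), columns=["chrom", "start", "end", "name"]),
        )
    manifest["planted_dhs_track"] = "CT3"

    # --- motif fixture at the first balanced SNP -------------------------
    motif_snp = balanced_ids[0]
    row = records[records["snp_id"] == motif_snp].iloc[0]
    flank = _random_seq(rng, 41)
    seq1 = flank[:20] + row["ref"] + flank[21:]
    seq2 = flank[:20] + row["alt"] + flank[21:]
    pfms = {}
    common_word = seq1[2:12]  # off-SNP: identical in both alleles
    for i in range(4):
        pfms[f"TF_common{i}"] = _consensus_pfm(common_word)
    specific_word = seq1[15:25]  # spans the SNP at motif position 5
    for i in range(4):
        pfms[f"TF_spec{i}"] = _consensus_pfm(specific_word, strong_pos=5)
    io.write_pfms(os.path.join(out_dir, "motifs.pfm"), pfms)
    flank_seqs[f"{motif_snp}_allele1"] = seq1
    flank_seqs[f"{motif_snp}_allele2"] = seq2
    for snp_id in balanced_ids[1:]:
        r = records[records["snp_id"] == snp_id].iloc[0]
        fl = _random_seq(rng, 41)
        flank_seqs[f"{snp_id}_allele1"] = fl[:20] + r["ref"] + fl[21:]
        flank_seqs[f"{snp_id}_allele2"] = fl[:20] + r["alt"] + fl[21:]
    io.write_fasta(os.path.join(out_dir, "flanks.fasta"), flank_seqs)
    manifest["motif_snp"] = motif_snp
    manifest["common_tfs"] = [f"TF_common{i}" for i in range(4)]
    manifest["specific_tfs"] = [f"TF_spec{i}" for i in range(4)]

    # --- allelic read counts ---------------------------------------------
    biased_cfg = SimConfig(seed=cfg.seed, allele_bias=2.0, depth_mean=100.0)
    neutral_cfg = SimConfig(seed=cfg.seed, allele_bias=1.0, depth_mean=100.0)
    reads = pd.concat(
        [
            simulate_allelic_reads(balanced_ids, biased_cfg, rng=rng),
            simulate_allelic_reads(control_candidate_ids, neutral_cfg, rng=rng),
        ],
        ignore_index=True,
    )
    io.write_tsv(os.path.join(out_dir, "allelic_counts.tsv"), reads)

    # --- enhancer-promoter map, expression, planted eQTL ------------------
    elements = pd.DataFrame(
        [(CHROM, focal_pos[s] - 7, focal_pos[s] + 8, s)
         for s in manifest["clean_focal_snps"]],
        columns=["chrom", "start", "end", "element_id"],
    )
    ep_map = pd.DataFrame(
        {
            "element_id": manifest["clean_focal_snps"],
            "gene": [f"gene{cluster_of[s]:02d}" for s in manifest["clean_focal_snps"]],
        }
    )
    io.write_tsv(os.path.join(out_dir, "elements.tsv"), elements)
    io.write_tsv(os.path.join(out_dir, "ep_map.tsv"), ep_map)

    snp_index = {r.snp_id: i for i, r in enumerate(records.itertuples())}
    dosages = {
        s: hap[0::2, snp_index[s]] + hap[1::2, snp_index[s]]
        for s in manifest["clean_focal_snps"]
    }
    eqtl_snp = balanced_ids[0]
    eqtl_gene = f"gene{cluster_of[eqtl_snp]:02d}"
    expr = pd.DataFrame(
        np.round(rng.normal(0.0, 1.0, size=(N_CLUSTERS, n_ind)), 6),
        index=[f"gene{c:02d}" for c in range(N_CLUSTERS)],
        columns=[f"ind{i:03d}" for i in range(n_ind)],
    )
    expr.loc[eqtl_gene] = np.round(
        1.5 * dosages[eqtl_snp] + rng.normal(0.0, 0.3, n_ind), 6
    )
    expr.rename_axis("gene").reset_index().to_csv(
        os.path.join(out_dir, "expression.tsv"), sep="\t", index=False
    )
    manifest["eqtl"] = {"snp_id": eqtl_snp, "gene": eqtl_gene}

    # gene-set term collecting the balanced-cluster target genes
    term_genes = [f"gene{cluster_of[s]:02d}" for s in balanced_ids] + [
        "gene20", "gene30", "gene40"
    ]
    terms = pd.DataFrame({"gene": term_genes, "term": "GO_planted"})
    decoys = pd.DataFrame(
        {"gene": [f"gene{c:02d}" for c in range(20, 50)], "term": "GO_decoy"}
    )
    io.write_tsv(os.path.join(out_dir, "terms.tsv"), pd.concat([terms, decoys], ignore_index=True))
    manifest["planted_term"] = "GO_planted"

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
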