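"""End-to-end orchestration of the balanced-SNP analysis on a dataset directory.

``run_pipeline`` consumes a directory in the layout produced by
:func:`balnoise.fixtures.write_fixtures` (VCF genotypes, footprint and
artifact BED tracks, DHS tracks, allele flanks, PFMs, read counts,
expression and enhancer-promoter map) and chains the whole analysis:
per-SNP Tajima's D over 5-kb windows, artifact filtering,
classification into balanced/control sets, cell-type overlap
enrichment, motif-divergence scanning, allelic-imbalance normalization,
genotype-expression regression and the target-gene set test.  All
steps are deterministic; writing the results twice gives byte-identical
files.
"""

from __future__ import annotations

import glob
import os

import numpy as np
import pandas as pd

from . import io
from .allelic import allelic_imbalance
from .association import genotype_expression_regression
from .enrichment import geneset_test, map_targets, overlap_enrichment
from .haplotypes import HaplotypeMatrix
from .motifs import scan_alleles
from .pipeline import FilterConfig, apply_artifact_filters, classify_by_selection
from .popgen import tajima_d_from_counts

__all__ = ["run_pipeline", "DEFAULT_SCAN_CONFIG"]

# quantiles suited to desk-scale SNP sets; genome-scale scans would use
# the 0.99 / (0.10, 0.90) defaults of FilterConfig
DEFAULT_SCAN_CONFIG = FilterConfig(
    balanced_quantile=0.90, control_quantiles=(0.10, 0.80)
)

WINDOW_BP = 5000


def _snp_table(records: pd.DataFrame, hap: np.ndarray, footprint_ids: set) -> pd.DataFrame:
    """Per-SNP annotations: MAF, genotype counts, windowed Tajima's D."""
    n_hap = hap.shape[0]
    pos = records["pos"].to_numpy()
    derived = hap.sum(axis=0)
    freq = derived / n_hap
    maf = np.minimum(freq, 1.0 - freq)
    g = hap[0::2] + hap[1::2]
    rows = []
    half = WINDOW_BP // 2
    for j, rec in enumerate(records.itertuples()):
        in_fp = rec.snp_id in footprint_ids
        d = np.nan
        if in_fp:
            lo, hi = np.searchsorted(pos, [rec.pos - half, rec.pos + half])
            res = tajima_d_from_counts(n_hap, derived[lo:hi])
            d = res.D
        rows.append(
            {
                "snp_id": rec.snp_id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "maf": maf[j],
                "in_footprint": in_fp,
                "n_aa": int((g[:, j] == 0).sum()),
                "n_ab": int((g[:, j] == 1).sum()),
                "n_bb": int((g[:, j] == 2).sum()),
                "tajima_d": d,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    data_dir: str,
    out_dir: str | None = None,
    config: FilterConfig = DEFAULT_SCAN_CONFIG,
) -> dict:
    """Run the full analysis on a dataset directory; return result tables."""
    records, hap = io.read_vcf_table(os.path.join(data_dir, "genotypes.vcf"))
    footprints = io.read_bed(os.path.join(data_dir, "footprints.bed"))
    footprint_ids = set(footprints["name"])

    snps = _snp_table(records, hap, footprint_ids)
    fp = snps[snps["in_footprint"]].reset_index(drop=True)

    depth = io.read_bed(os.path.join(data_dir, "depth.bed"))
    mapp = io.read_bed(os.path.join(data_dir, "mappability_nonunique.bed"))
    segdup = pd.read_csv(os.path.join(data_dir, "segdups.tsv"), sep="\t")
    flagged = apply_artifact_filters(fp, depth, mapp, segdup, config)
    classified = classify_by_selection(flagged, "tajima_d", config)

    balanced = classified[classified["class_label"] == "balanced"]
    control = classified[classified["class_label"] == "control"]

    tracks = {
        os.path.basename(p)[4:-4]: io.read_bed(p)
        for p in sorted(glob.glob(os.path.join(data_dir, "dhs_*.bed")))
    }
    enrich = overlap_enrichment(balanced, control, tracks)

    # motif divergence at SNPs with allele flanks
    flanks = io.read_fasta(os.path.join(data_dir, "flanks.fasta"))
    pwms = io.read_pfms(os.path.join(data_dir, "motifs.pfm"))
    motif_rows = []
    snp_flank_ids = sorted(
        {k.rsplit("_allele", 1)[0] for k in flanks if k.endswith("_allele1")}
    )
    for snp_id in snp_flank_ids:
        div = scan_alleles(
            snp_id, flanks[f"{snp_id}_allele1"], flanks[f"{snp_id}_allele2"], pwms
        )
        motif_rows.append(
            {
                "snp_id": snp_id,
                "n_allele1_only": len(div.tfs_allele1_only),
                "n_allele2_only": len(div.tfs_allele2_only),
                "n_common": len(div.tfs_common),
                "divergence_score": div.score,
            }
        )
    motif_div = pd.DataFrame(motif_rows)

    counts = pd.read_csv(os.path.join(data_dir, "allelic_counts.tsv"), sep="\t")
    imbalance = allelic_imbalance(counts, control_ids=set(control["snp_id"]))

    # genotype-expression association for every mapped SNP-gene pair
    expr = pd.read_csv(os.path.join(data_dir, "expression.tsv"), sep="\t").set_index("gene")
    ep_map = pd.read_csv(os.path.join(data_dir, "ep_map.tsv"), sep="\t")
    elements = pd.read_csv(os.path.join(data_dir, "elements.tsv"), sep="\t")
    snp_idx = {r.snp_id: j for j, r in enumerate(records.itertuples())}
    g = hap[0::2] + hap[1::2]
    pairs = ep_map[ep_map["element_id"].isin(snp_idx)]
    m = len(pairs)
    assoc_rows = []
    for row in pairs.itertuples():
        res = genotype_expression_regression(
            g[:, snp_idx[row.element_id]],
            expr.loc[row.gene].to_numpy(),
            m_tests=m,
            snp_id=row.element_id,
            gene_id=row.gene,
        )
        assoc_rows.append(res.__dict__)
    assoc = pd.DataFrame(assoc_rows)

    targets = map_targets(balanced, elements, ep_map)
    terms = pd.read_csv(os.path.join(data_dir, "terms.tsv"), sep="\t")
    geneset = geneset_test(targets, terms, background=set(ep_map["gene"]))

    results = {
        "snps": classified,
        "enrichment": enrich,
        "motif_divergence": motif_div,
        "allelic_imbalance": imbalance,
        "association": assoc,
        "geneset": geneset,
        "target_genes": pd.DataFrame({"gene": targets}),
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for name, df in results.items():
            io.write_tsv(os.path.join(out_dir, f"{name}.tsv"), df)
    return results
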