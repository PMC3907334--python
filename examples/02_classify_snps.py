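"""Annotate risk-correlated SNPs with chromatin biofeatures and classify
them into putative functional categories.

Generates random DNase/H3K27Ac-style interval tracks plus gene-anatomy
tracks, then reports the membership of each SNP and its single functional
class under the precedence rule coding_exon > mir_utr > promoter > enhancer.
"""

import pandas as pd

from riskenhancer import (GenomeSpec, TrackSet, annotate_biofeatures,
                          classify_functional, generate_biofeature_tracks,
                          snp_biofeature_matrix, cluster_matrix)
from riskenhancer.intervals import IntervalTrack
from riskenhancer.ld_annotation import CorrelatedSNP, Variant

spec = GenomeSpec(("chr1",), (5_000_000,))
frames = generate_biofeature_tracks(
    spec, ["DNaseI", "H3K27Ac", "H3K4me1", "AR"], density=40, seed=3)
tracks = TrackSet.from_frames(frames)

snps = [CorrelatedSNP("rs_index", Variant(f"snp{i}", "chr1", 25_000 * (i + 1),
                                          "A", "G"), {"EUR": 0.8})
        for i in range(40)]

gene_tracks = {
    "tss": IntervalTrack("tss", pd.DataFrame(
        {"chrom": ["chr1"], "start": [50_000], "end": [50_001],
         "name": ["geneA"], "score": [0], "strand": ["+"]})),
    "coding_exon": IntervalTrack("coding_exon", pd.DataFrame(
        {"chrom": ["chr1"], "start": [60_000], "end": [62_000]})),
    "utr3": IntervalTrack("utr3", pd.DataFrame(
        {"chrom": ["chr1"], "start": [70_000], "end": [71_000]})),
    "utr5": IntervalTrack("utr5", pd.DataFrame(
        {"chrom": ["chr1"], "start": [49_000], "end": [50_000]})),
    "mir_target": IntervalTrack("mir_target", pd.DataFrame(
        {"chrom": ["chr1"], "start": [70_200], "end": [70_300]})),
}

annotated = classify_functional(annotate_biofeatures(snps, tracks), gene_tracks)
counts = pd.Series([a.functional_class for a in annotated]).value_counts()
print("SNP counts by putative functional class:")
print(counts.to_string())

in_features = [a for a in annotated if a.memberships]
print(f"\n{len(in_features)} of {len(annotated)} SNPs fall in >= 1 biofeature")
mat = snp_biofeature_matrix(in_features)
if mat.shape[0] >= 2 and mat.shape[1] >= 2:
    clust = cluster_matrix(mat)
    print("clustered biofeature order:", clust["col_order"])
print("\nSNPs in enhancer-type chromatin with no exonic/UTR/promoter overlap "
      "are the 'risk enhancer' candidates taken forward to motif analysis.")
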