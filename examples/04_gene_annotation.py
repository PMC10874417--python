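"""Lift significant SNP pairs to gene pairs, classify them, count PPI hits.

Maps SNPs to genes within a 100 kb window, builds deduplicated gene pairs,
splits them into G1/G2/G3 by disease-list membership (both / one / neither
gene on the list) and flags pairs present in a protein-protein interaction
edge list.
"""

from epiquant import (
    GeneInterval,
    PPIEdge,
    SNPInfo,
    build_gene_pairs,
    classify_ad_groups,
    map_snp_to_genes,
    ppi_overlap,
)

intervals = [
    GeneInterval("APP", 21, 27_252_861, 27_543_446),
    GeneInterval("PSEN1", 14, 73_603_143, 73_690_399),
    GeneInterval("PLCG2", 16, 81_812_899, 81_991_899),
    GeneInterval("CD80", 3, 119_235_000, 119_270_000),
]
snps = {
    0: SNPInfo("rs_app", 21, 27_300_000, "A", "G"),       # inside APP
    1: SNPInfo("rs_psen1", 14, 73_590_000, "C", "T"),     # 13 kb upstream of PSEN1
    2: SNPInfo("rs_plcg2", 16, 81_900_000, "A", "C"),     # inside PLCG2
    3: SNPInfo("rs_cd80", 3, 119_236_500, "G", "T"),      # inside CD80
    4: SNPInfo("rs_desert", 8, 5_000_000, "A", "G"),      # intergenic
}
snp_to_gene = {i: map_snp_to_genes(s, intervals, window_bp=100_000) for i, s in snps.items()}
for i, genes in snp_to_gene.items():
    print(f"{snps[i].snp_id:10s} -> {genes or ['-']}")

significant_snp_pairs = [(0, 1), (2, 3), (0, 4)]
pairs = build_gene_pairs(significant_snp_pairs, snp_to_gene)
classify_ad_groups(pairs, disease_genes={"APP", "PSEN1", "PLCG2"})
ppi_overlap(pairs, [PPIEdge("CD80", "PLCG2")])

print("\ngene pairs:")
for p in pairs:
    print(f"  {p.gene_a}-{p.gene_b}: group {p.group}, "
          f"PPI overlap {'yes' if p.ppi_overlap else 'no'}, "
          f"{len(p.source_snp_pairs)} source SNP pair(s)")

# G1 = both genes on the disease list, G2 = one, G3 = neither; a SNP pair
# with an intergenic side contributes no gene pair, so (0, 4) vanishes.
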