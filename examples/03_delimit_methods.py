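"""Run the four delimitation families on one library.

Prunes identical haplotypes, computes K2P distances, builds the NJ tree
(for PTP/mPTP) and the UPGMA chronogram (for GMYC/mGMYC), and delimits
OTUs with single-linkage (RESL-like), barcode-gap partitioning (ABGD),
PTP and GMYC. Each method prints its OTU count next to the true species
count; model-based methods also report their fitted rates and, for GMYC,
the likelihood-ratio test against the one-species coalescent null.
"""

from barcodelim import (
    AbgdConfig,
    SimConfig,
    abgd_partition,
    collapse_haplotypes,
    gmyc_fit,
    make_benchmark,
    nj_tree,
    pairwise_matrix,
    ptp_fit,
    resl_like,
    select_abgd_partition,
    upgma_tree,
)

library, truth = make_benchmark(SimConfig(seed=42))
reps, members = collapse_haplotypes(library)
matrix = pairwise_matrix(library).submatrix(reps.ids)
print(f"{len(library)} records -> {len(reps)} unique haplotypes")
print(f"true species: {truth.true_partition.n_otus}\n")

part = resl_like(matrix)
print(f"RESL-like single linkage (2.2% threshold): {part.n_otus} OTUs")

part = select_abgd_partition(abgd_partition(matrix, AbgdConfig()))
print(f"ABGD (modal partition over priors):        {part.n_otus} OTUs")

tree = nj_tree(matrix)
tree.reroot_at_midpoint(update_bipartitions=False)
for mode, name in (("single", "PTP"), ("multi", "mPTP")):
    model, part = ptp_fit(tree, mode=mode, seed=42)
    print(f"{name:<42s} {part.n_otus} OTUs (logL {model.log_likelihood:.1f})")

chronogram = upgma_tree(matrix)
for mode, name in (("single", "GMYC"), ("multi", "mGMYC")):
    model, part = gmyc_fit(chronogram, mode=mode)
    print(
        f"{name:<42s} {part.n_otus} OTUs "
        f"(LR {model.lr_stat:.1f}, p {model.p_value:.2g})"
    )
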