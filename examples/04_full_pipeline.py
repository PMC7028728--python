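"""End-to-end pipeline with 50% majority consensus.

Runs QC, haplotype pruning, distances, trees, all six delimitation
methods and the consensus on one benchmark library, and prints the
per-method OTU counts, the consensus count against the truth, and the
barcoding-gap summaries at species and OTU level. The consensus count is
the headline number: the OTU inventory the library supports once
method-specific over- and under-splitting is voted away.
"""

import json

from barcodelim import PipelineConfig, SimConfig, make_benchmark, run_pipeline

library, truth = make_benchmark(SimConfig(seed=42, outgroup=True, orf_mode=True))
result = run_pipeline(
    PipelineConfig(
        library=library,
        outgroup_ids=["outgroup_s01"],
        seed=42,
        out_dir="scratch_pipeline",
    )
)
print(json.dumps(result.summary, indent=2, sort_keys=True))
print(
    f"\ntruth: {truth.true_partition.n_otus} species "
    f"(10 ingroup + 1 outgroup); consensus found "
    f"{result.summary['consensus_otus']} OTUs"
)
print(
    "a species listed under species_by_n_otus > 1 carries a deep "
    "within-species coalescence -- the molecular signature that reads as "
    "cryptic diversity in real libraries"
)
print("artifacts written to scratch_pipeline/ (matrix, trees, partitions, summary)")
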