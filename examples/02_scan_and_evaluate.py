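"""Scan a genome with a trained model and compare the two assessment schemes.

Slides a 40-nt window (step 20 here, for speed) over both strands, then
evaluates the probability track against the true promoter coordinates
with the strict overlap criterion (>=10% same-strand overlap) and the
relaxed cluster criterion (5 nearest predictions within 100 nt).
"""

import promforest as pf
from promforest.model import GRID_FAST

spec = pf.SyntheticSpec(genome_length=100_000, n_promoters=60, seed=3)
genome, tss, truth = pf.generate_genome(spec)
dataset = pf.build_dataset(genome, tss, neg_per_pos=10, seed=1)
model, _ = pf.train_rf(pf.encode_set(dataset, "HOT"), grid=GRID_FAST, folds=3, seed=0)

predictions = pf.scan_genome(model, genome, step=20)
print(f"scored {len(predictions)} windows on both strands")

overlap = pf.evaluate_genome_wide(predictions, truth, "OVERLAP")
cluster = pf.evaluate_genome_wide(predictions, truth, "CLUSTER")
print(f"overlap-mode AUPRC {overlap.auprc:.3f}, AUROC {overlap.auroc:.3f}")
print(f"cluster-mode AUPRC {cluster.auprc:.3f}, AUROC {cluster.auroc:.3f}")
print(
    "The cluster scheme credits predictions that land near (but not on) a\n"
    "true promoter, so its AUPRC is a multiple of the overlap-mode value —\n"
    "the model finds promoter neighbourhoods more reliably than exact loci.\n"
    f"For scale: a random classifier's AUPRC here would be ~{60/len(predictions):.4f}."
)
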