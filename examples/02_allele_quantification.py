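"""Allele-level expression quantification on simulated reads.

Builds a small augmented transcriptome (background transcripts plus two
~92%-identity HLA allele pairs, with the generic HLA decoys removed),
simulates 50k single-end 150-base reads from known TPM abundances, and
quantifies them back with the k-mer pseudoalignment + EM estimator.
"""

import numpy as np

from allovax import (
    AugmentationPlan,
    build_augmented_transcriptome,
    build_index,
    call_expressed,
    quantify_reads,
)
from allovax.simulate import SimulationConfig, make_transcriptome, simulate_reads

cfg = SimulationConfig(seed=1, n_reads=50_000)
reference, alleles, removal = make_transcriptome(10, 2, cfg)
plan = AugmentationPlan(removal_ids=removal, insertions=alleles)
transcriptome = build_augmented_transcriptome(reference, plan)

ids = [t.id for t in transcriptome]
allele_ids = [t.id for t in alleles]
true_tpm = {t: 0.0 for t in ids}
true_tpm[allele_ids[0]] = 0.5      # below the 1-TPM expression threshold
true_tpm[allele_ids[1]] = 2_000.0
true_tpm[allele_ids[2]] = 5_000.0
true_tpm[allele_ids[3]] = 20_000.0
rest = (1e6 - sum(true_tpm.values())) / (len(ids) - 4)
for t in ids:
    if t not in allele_ids:
        true_tpm[t] = rest

reads, truth = simulate_reads(transcriptome, true_tpm, cfg)
index = build_index(transcriptome, k=cfg.k, read_length=cfg.read_length)
table = quantify_reads(reads, index)
calls = {c.transcript_id: c.expressed for c in call_expressed(table, threshold=1.0)}

print(f"{'allele':<18}{'true TPM':>10}{'est TPM':>12}  expressed")
for a in allele_ids:
    print(
        f"{a:<18}{true_tpm[a]:>10.1f}{table.df.loc[a, 'tpm']:>12.1f}  "
        f"{calls[a]}"
    )
print(f"\nsum of TPM over all transcripts: {table.tpm.sum():,.0f} (= 1e6)")

# Estimated TPMs track the planted abundances despite the >90% sequence
# identity between allele pairs; the 0.5-TPM allele is called not
# expressed, mirroring how a silent allele is separated from its
# expressed homolog.
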